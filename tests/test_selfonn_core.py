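"""Generative-neuron operator: hand values, oracle agreement, algebra."""

import numpy as np
import pytest
from scipy.signal import correlate2d

from onnseg import nn
from onnseg.autograd import Tensor
from onnseg.selfonn_core import (
    SelfONNLayerSpec,
    TaylorCoefficients,
    random_coefficients,
    selfonn_conv_resblock,
    selfonn_forward,
    selfonn_forward_bruteforce,
    selfonn_resblock,
)


def _ones_coef(spec, bias=0.0):
    return TaylorCoefficients(np.ones(spec.weight_shape),
                              np.full(spec.out_channels, bias) if spec.has_bias else None)


class TestForwardExamples:
    def test_q1_all_ones_is_plain_window_sum(self):
        spec = SelfONNLayerSpec(1, 1, 3, q=1)
        out = selfonn_forward(np.ones((1, 3, 3)), spec, _ones_coef(spec))
        assert out.shape == (1, 1, 1)
        assert out[0, 0, 0] == pytest.approx(9.0)

    def test_q2_powers_accumulate(self):
        # window of 2s: each tap contributes 2 + 2^2 = 6, nine taps -> 54
        spec = SelfONNLayerSpec(1, 1, 3, q=2)
        out = selfonn_forward(np.full((1, 3, 3), 2.0), spec, _ones_coef(spec))
        assert out[0, 0, 0] == pytest.approx(54.0)

    def test_single_pixel_maclaurin_series(self):
        # f(3) = 1 + 3 + 9 + 27 with unit coefficients and bias
        spec = SelfONNLayerSpec(1, 1, 1, q=3)
        out = selfonn_forward(np.array([[[3.0]]]), spec, _ones_coef(spec, bias=1.0))
        assert out[0, 0, 0] == pytest.approx(40.0)

    def test_zero_input_yields_bias_everywhere(self, rng):
        spec = SelfONNLayerSpec(2, 3, 3, q=4, padding=1)
        coef = random_coefficients(spec, rng)
        coef.bias[:] = rng.normal(size=3)
        out = selfonn_forward(np.zeros((2, 5, 5)), spec, coef)
        assert np.allclose(out, coef.bias[:, None, None])


class TestValidation:
    def test_rejects_even_kernel_and_bad_q(self):
        with pytest.raises(ValueError):
            SelfONNLayerSpec(1, 1, 2)
        with pytest.raises(ValueError):
            SelfONNLayerSpec(1, 1, 3, q=0)

    def test_rejects_channel_mismatch(self, rng):
        spec = SelfONNLayerSpec(2, 1, 3)
        coef = random_coefficients(spec, rng)
        with pytest.raises(ValueError, match="channels"):
            selfonn_forward(np.zeros((3, 5, 5)), spec, coef)

    def test_rejects_mismatched_coefficients(self, rng):
        spec = SelfONNLayerSpec(2, 1, 3, q=2)
        other = random_coefficients(SelfONNLayerSpec(2, 1, 3, q=3), rng)
        with pytest.raises(ValueError, match="shape"):
            selfonn_forward(np.zeros((2, 5, 5)), spec, other)


class TestOracleAgreement:
    @pytest.mark.parametrize("trial", range(12))
    def test_vectorized_matches_bruteforce(self, trial):
        rng = np.random.default_rng(500 + trial)
        spec = SelfONNLayerSpec(
            in_channels=int(rng.integers(1, 4)),
            out_channels=int(rng.integers(1, 4)),
            kernel_size=int(rng.choice([1, 3])),
            q=int(rng.integers(1, 5)),
            stride=int(rng.choice([1, 2])),
            padding=int(rng.integers(0, 2)),
        )
        coef = random_coefficients(spec, rng)
        x = rng.uniform(-1, 1, (spec.in_channels, 7, 7))
        fast = selfonn_forward(x, spec, coef)
        slow = selfonn_forward_bruteforce(x, spec, coef)
        assert np.abs(fast - slow).max() < 1e-4

    def test_q1_matches_scipy_cross_correlation(self, rng):
        spec = SelfONNLayerSpec(2, 1, 3, q=1, has_bias=False)
        coef = random_coefficients(spec, rng)
        x = rng.uniform(-1, 1, (2, 6, 6))
        out = selfonn_forward(x, spec, coef)
        ref = sum(correlate2d(x[i], coef.weights[0, 0, i], mode="valid") for i in range(2))
        assert np.abs(out[0] - ref).max() < 1e-5


class TestAlgebra:
    def test_output_linear_in_coefficients(self, rng):
        spec = SelfONNLayerSpec(2, 2, 3, q=3, padding=1)
        coef = random_coefficients(spec, rng)
        x = rng.uniform(-1, 1, (2, 6, 6))
        doubled = TaylorCoefficients(2.0 * coef.weights, 2.0 * coef.bias)
        assert np.allclose(selfonn_forward(x, spec, doubled),
                           2.0 * selfonn_forward(x, spec, coef))

    @pytest.mark.parametrize("cin,cout,k,q", [(1, 2, 3, 3), (3, 1, 1, 1),
                                              (2, 4, 5, 2), (1, 1, 3, 7)])
    def test_parameter_count_formula(self, cin, cout, k, q):
        spec = SelfONNLayerSpec(cin, cout, k, q=q)
        layer = nn.SelfONN2d(cin, cout, k, q=q)
        assert spec.parameter_count == q * cin * cout * k * k + cout
        assert sum(p.data.size for p in layer.parameters()) == spec.parameter_count


class TestConvResBlock:
    def test_zero_parameters_give_zero_output(self, rng):
        block = nn.SelfONNConvResBlock(2, 4, q=3, rng=rng)
        for p in block.parameters():
            p.data[:] = 0.0
        out = selfonn_conv_resblock(rng.uniform(-1, 1, (2, 8, 8)), block)
        assert out.shape == (4, 8, 8)
        assert np.allclose(out, 0.0)

    def test_deterministic_forward(self, rng):
        block = nn.SelfONNConvResBlock(1, 3, q=2, rng=np.random.default_rng(3))
        x = rng.uniform(-1, 1, (1, 6, 6))
        assert np.array_equal(selfonn_conv_resblock(x, block),
                              selfonn_conv_resblock(x, block))

    def test_selfonn_path_bounded_by_tanh(self, rng):
        block = nn.SelfONNConvResBlock(2, 4, q=3, rng=np.random.default_rng(4))
        y = block.selfonn_path(Tensor(rng.uniform(-1, 1, (1, 2, 8, 8)))).data
        assert y.min() > -1.0 and y.max() < 1.0

    def test_concat_mode_doubles_channels(self, rng):
        block = nn.SelfONNConvResBlock(2, 4, q=2, combine="concat",
                                       rng=np.random.default_rng(5))
        out = selfonn_conv_resblock(rng.uniform(-1, 1, (2, 8, 8)), block)
        assert out.shape == (8, 8, 8)


class TestResBlock:
    def test_zero_weights_reduce_to_identity(self, rng):
        block = nn.SelfONNResBlock(4, q=3, rng=np.random.default_rng(6))
        for p in block.parameters():
            p.data[:] = 0.0
        x = rng.uniform(-1, 1, (4, 8, 8))
        assert np.allclose(selfonn_resblock(x, block), x)

    def test_matches_bruteforce_composition(self, rng):
        block = nn.SelfONNResBlock(4, q=2, rng=np.random.default_rng(7))
        x = rng.uniform(-1, 1, (4, 6, 6))
        s3 = SelfONNLayerSpec(4, 1, 3, q=2, padding=1)
        s1 = SelfONNLayerSpec(1, 4, 1, q=2)
        c3 = TaylorCoefficients(block.onn3.weight.data, block.onn3.bias.data)
        c1 = TaylorCoefficients(block.onn1.weight.data, block.onn1.bias.data)
        hidden = np.tanh(selfonn_forward_bruteforce(x, s3, c3))
        expected = np.tanh(selfonn_forward_bruteforce(hidden, s1, c1)) + x
        assert np.abs(selfonn_resblock(x, block) - expected).max() < 1e-4
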
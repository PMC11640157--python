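import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "repro", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("repro")


@pytest.fixture
def rng():
    return np.random.default_rng(20240)


@pytest.fixture(scope="session")
def phantom_volume():
    """One deterministic labelled phantom volume with tumors."""
    from onnseg.phantom import PhantomConfig, generate_phantom_volume

    cfg = PhantomConfig(seed=11, n_volumes=1, slices_per_volume=10, image_size=64,
                        n_tumors_range=(1, 2))
    return generate_phantom_volume(cfg, 0).volume


@pytest.fixture(scope="session")
def tiny_model():
    """A small Self-ONN U-Net built once for inference-level tests."""
    from onnseg.experiments import tiny_selfonn_spec
    from onnseg.model_zoo import build_model

    return build_model(tiny_selfonn_spec(seed=5))


class OracleModel:
    """Stage model that returns fixed ground truth as hard probabilities."""

    def __init__(self, masks_by_key=None, constant=None):
        self.masks_by_key = masks_by_key or {}
        self.constant = constant

    def predict_proba(self, image):
        img = np.asarray(image)
        shape = img.shape[-2:]
        if self.constant is not None:
            fg = np.full(shape, self.constant, dtype=np.float64)
        else:
            fg = self.masks_by_key[img.tobytes()].astype(np.float64)
        return np.stack([1.0 - fg, fg])


@pytest.fixture
def oracle_model_factory():
    return OracleModel
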
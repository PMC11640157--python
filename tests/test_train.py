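"""Cross-validation protocol, training loop behavior and fold evaluation."""

import numpy as np
import pytest

from onnseg.ct_preprocess import hu_window, rescale_to_255, volume_to_slices
from onnseg.experiments import tiny_selfonn_spec
from onnseg.model_zoo import build_model
from onnseg.phantom import PhantomConfig, generate_phantom_volume
from onnseg.train import (
    TrainConfig,
    evaluate_fold,
    make_folds,
    stage_arrays,
    train_model,
    _validation_loss,
)


@pytest.fixture(scope="module")
def phantom_pairs():
    cfg = PhantomConfig(seed=21, n_volumes=2, slices_per_volume=10, image_size=64,
                        n_tumors_range=(1, 2))
    vols = [generate_phantom_volume(cfg, i).volume for i in range(2)]
    prepared = [rescale_to_255(hu_window(v)) for v in vols]
    train = volume_to_slices(prepared[0], keep_empty=False)
    val = volume_to_slices(prepared[1], keep_empty=False)
    return train, val


class TestFolds:
    def test_five_fold_split_sizes(self):
        ids = [f"v{i}" for i in range(100)]
        folds = make_folds(ids, 5, seed=0)
        for f in folds:
            assert len(f.test_ids) == 20
            assert len(f.val_ids) == 16
            assert len(f.train_ids) == 64
            assert set(f.train_ids) | set(f.val_ids) | set(f.test_ids) == set(ids)
            assert not (set(f.train_ids) & set(f.val_ids))
            assert not (set(f.train_ids) & set(f.test_ids))

    def test_each_volume_tested_exactly_once(self):
        ids = [f"v{i}" for i in range(23)]
        folds = make_folds(ids, 5, seed=4)
        tested = [v for f in folds for v in f.test_ids]
        assert sorted(tested) == sorted(ids)

    def test_deterministic_under_seed(self):
        ids = [f"v{i}" for i in range(30)]
        assert make_folds(ids, 5, seed=7) == make_folds(ids, 5, seed=7)
        assert make_folds(ids, 5, seed=7) != make_folds(ids, 5, seed=8)

    def test_too_few_volumes_rejected(self):
        with pytest.raises(ValueError, match="at least"):
            make_folds(["a", "b"], 5, seed=0)


class TestStageArrays:
    def test_tumor_stage_uses_ground_truth_roi(self, phantom_pairs):
        train, _ = phantom_pairs
        xs, ys = stage_arrays(train, "tumor")
        for x, p in zip(xs, train):
            assert np.all(x[p.liver_mask == 0] == 0)
        assert any(y.any() for y in ys)

    def test_unknown_stage_rejected(self, phantom_pairs):
        with pytest.raises(ValueError, match="stage"):
            stage_arrays(phantom_pairs[0], "kidney")


class TestTrainingLoop:
    def test_zero_lr_patience_one_stops_after_two_epochs(self, phantom_pairs):
        train, val = phantom_pairs
        model = build_model(tiny_selfonn_spec(seed=1))
        cfg = TrainConfig(learning_rate=0.0, batch_size=4, max_epochs=10,
                          early_stop_patience=1, seed=0)
        result = train_model(model, train[:4], val[:2], cfg, stage="liver")
        assert len(result.history["val_loss"]) == 2

    def test_returns_best_validation_weights(self, phantom_pairs):
        train, val = phantom_pairs
        model = build_model(tiny_selfonn_spec(seed=2))
        cfg = TrainConfig(learning_rate=3e-3, batch_size=4, max_epochs=6,
                          early_stop_patience=5, seed=0)
        result = train_model(model, train, val[:4], cfg, stage="liver", max_steps=40)
        vxs, vys = stage_arrays(val[:4], "liver")
        reloaded_loss = _validation_loss(model, vxs, vys, cfg.batch_size)
        assert reloaded_loss == pytest.approx(min(result.history["val_loss"]), abs=1e-9)
        assert result.best_val_loss == pytest.approx(min(result.history["val_loss"]))

    def test_training_reduces_loss(self, phantom_pairs):
        train, val = phantom_pairs
        model = build_model(tiny_selfonn_spec(seed=3))
        cfg = TrainConfig(learning_rate=3e-3, batch_size=4, max_epochs=10,
                          early_stop_patience=9, seed=0)
        result = train_model(model, train, val[:4], cfg, stage="liver", max_steps=60)
        assert result.history["train_loss"][-1] < result.history["train_loss"][0]

    def test_deterministic_given_seed(self, phantom_pairs):
        train, val = phantom_pairs
        weights = []
        for _ in range(2):
            model = build_model(tiny_selfonn_spec(seed=4))
            cfg = TrainConfig(learning_rate=1e-3, batch_size=4, max_epochs=3,
                              early_stop_patience=2, seed=11)
            train_model(model, train[:6], val[:2], cfg, stage="liver", max_steps=10)
            weights.append(np.concatenate([p.data.ravel() for p in model.parameters()]))
        assert np.array_equal(weights[0], weights[1])

    def test_empty_data_rejected(self):
        model = build_model(tiny_selfonn_spec(seed=5))
        with pytest.raises(ValueError, match="non-empty"):
            train_model(model, [], [], TrainConfig())

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            TrainConfig(early_stop_patience=50, max_epochs=50)
        with pytest.raises(ValueError):
            TrainConfig(lr_drop_factor=1.5)


class TestEvaluateFold:
    def test_oracle_models_score_perfectly(self, phantom_pairs, oracle_model_factory):
        _, val = phantom_pairs
        liver_lut, tumor_lut = {}, {}
        for p in val:
            liver_lut[p.image.tobytes()] = p.liver_mask
            tumor_lut[(p.image * p.liver_mask).tobytes()] = p.tumor_mask
        lrep, trep = evaluate_fold(oracle_model_factory(liver_lut),
                                   oracle_model_factory(tumor_lut), val)
        for rep in (lrep, trep):
            assert rep.mean["dsc"] == 1.0
            assert rep.mean["iou"] == 1.0
            assert rep.mean["accuracy"] == 1.0
            assert rep.zero_dice_count == 0

    def test_background_tumor_model_counts_zero_dice(self, phantom_pairs,
                                                     oracle_model_factory):
        _, val = phantom_pairs
        liver_lut = {p.image.tobytes(): p.liver_mask for p in val}
        lrep, trep = evaluate_fold(oracle_model_factory(liver_lut),
                                   oracle_model_factory(constant=0.0), val)
        n_tumor_slices = sum(bool(p.tumor_mask.any()) for p in val)
        assert trep.zero_dice_count == n_tumor_slices
        tumor_scores = {sid: d for sid, d, _, _ in trep.per_sample}
        for p in val:
            expected = 0.0 if p.tumor_mask.any() else 1.0
            assert tumor_scores[f"{p.volume_id}:{p.slice_index}"] == expected
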
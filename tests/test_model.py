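"""Model contracts: head replacement, Poisson loss arithmetic, the
fine-tuning freeze levels, early stopping, and the baseline CNN geometry."""

import hashlib

import numpy as np
import pytest

from tcratl.data_prep import PrepConfig
from tcratl.model import (
    FineTuneConfig,
    HeadModel,
    SurrogateTrunk,
    TLModel,
    build_baseline_cnn,
    fine_tune,
    load_checkpoint,
    poisson_nll,
    poisson_nll_grad,
    replace_head,
    save_checkpoint,
)


def small_tl(mini_prep, k=2, seed=0):
    trunk = SurrogateTrunk(mini_prep, C=16, n_blocks=2, seed=seed, stem_channels=(8, 8, 8))
    return TLModel(trunk, HeadModel(16, k, seed=seed + 1))


def param_hashes(model):
    return {n: hashlib.sha256(p.tobytes()).hexdigest()
            for n, p in model.named_parameters().items()}


class TestHeadAndReplacement:
    def test_head_parameter_count_closed_form(self):
        head = HeadModel(C=1536, k=275)
        assert head.n_parameters() == 1536 * 275 + 275 == 422_675

    @pytest.mark.parametrize("C,k", [(8, 1), (64, 8), (100, 13)])
    def test_head_count_formula_general(self, C, k):
        assert HeadModel(C, k).n_parameters() == C * k + k

    def test_replace_head_geometry_and_positivity(self, mini_prep):
        trunk = SurrogateTrunk(mini_prep, C=16, seed=1, stem_channels=(8, 8, 8))
        tl = replace_head(trunk, 8, seed=2)
        x = np.random.default_rng(0).random((1, mini_prep.L, 4)).astype(np.float32)
        y = tl.forward(x)
        assert y.shape == (1, mini_prep.n_bins, 8)
        assert (y > 0).all()

    def test_replace_head_copies_trunk_parameters(self, mini_prep):
        trunk = SurrogateTrunk(mini_prep, C=16, seed=3, stem_channels=(8, 8, 8))
        tl = replace_head(trunk, 2, seed=4)
        for name, p in trunk.named_parameters().items():
            np.testing.assert_array_equal(tl.named_parameters()["trunk." + name], p)
        # and it is a copy, not an alias
        next(iter(trunk.named_parameters().values()))[...] += 1.0
        assert not np.array_equal(
            next(iter(tl.trunk.named_parameters().values())),
            next(iter(trunk.named_parameters().values())),
        )

    def test_invalid_k_rejected(self):
        with pytest.raises(ValueError):
            HeadModel(8, 0)


class TestPoissonLoss:
    def test_hand_values(self):
        assert poisson_nll(np.array([1.0]), np.array([0.0])) == pytest.approx(1.0)
        assert poisson_nll(np.array([1.0]), np.array([1.0])) == pytest.approx(1.0)
        assert poisson_nll(np.array([2.0]), np.array([1.0])) == pytest.approx(
            2 - np.log(2), abs=1e-10
        )

    def test_minimum_at_target(self):
        t = np.array([3.0])
        losses = {p: poisson_nll(np.array([p]), t) for p in (2.9, 3.0, 3.1)}
        assert min(losses, key=losses.get) == 3.0

    def test_minimum_property_random_grid(self):
        rng = np.random.default_rng(4)
        t = rng.uniform(0.5, 5.0, 50)
        base = poisson_nll(t, t)
        for _ in range(20):
            pred = np.clip(t + rng.normal(0, 0.5, 50), 1e-3, None)
            assert poisson_nll(pred, t) >= base - 1e-12

    def test_nonpositive_prediction_rejected(self):
        with pytest.raises(ValueError):
            poisson_nll(np.array([0.0]), np.array([1.0]))

    def test_gradient_is_analytic_derivative(self):
        rng = np.random.default_rng(5)
        pred = rng.uniform(0.5, 4, 20)
        t = rng.uniform(0, 4, 20)
        eps = 1e-7
        g = poisson_nll_grad(pred, t)
        for i in range(5):
            pp, pm = pred.copy(), pred.copy()
            pp[i] += eps
            pm[i] -= eps
            num = (poisson_nll(pp, t) - poisson_nll(pm, t)) / (2 * eps)
            assert g[i] == pytest.approx(num, rel=1e-5)


class TestFreezeContract:
    @pytest.mark.parametrize("level", [1, 2, 3, 4])
    def test_only_designated_parameters_change(self, mini_splits, mini_prep, level):
        tl = small_tl(mini_prep, seed=10 + level)
        designated = tl.trainable_names(level)
        before = param_hashes(tl)
        cfg = FineTuneConfig(level=level, learning_rate=1e-2, batch_size=8,
                             max_steps=30, eval_interval=10, early_stop_delta=0.0,
                             early_stop_patience=1000)
        fine_tune(tl, mini_splits["train"], mini_splits["valid"], cfg, seed=level)
        after = param_hashes(tl)
        changed = {n for n in before if before[n] != after[n]}
        assert changed <= designated
        assert "head.linear.W" in changed  # the head always trains

    def test_level_sets_are_nested(self, mini_prep):
        tl = small_tl(mini_prep)
        sets = [tl.trainable_names(level) for level in (1, 2, 3, 4)]
        assert sets[0] < sets[1] < sets[2] <= sets[3]

    def test_invalid_level_rejected(self, mini_prep):
        with pytest.raises(ValueError):
            small_tl(mini_prep).trainable_names(5)
        with pytest.raises(ValueError):
            FineTuneConfig(level=0)


class TestEarlyStopping:
    def test_halts_at_fifth_nonimproving_evaluation(self, mini_splits, mini_prep):
        losses = iter([1.0, 0.9] + [0.9] * 50)
        tl = small_tl(mini_prep)
        cfg = FineTuneConfig(level=1, max_steps=500, eval_interval=1,
                             early_stop_delta=1e-3, early_stop_patience=5)
        _, hist = fine_tune(tl, mini_splits["train"], mini_splits["valid"], cfg,
                            seed=0, valid_loss_fn=lambda m: next(losses))
        # evaluations: 1.0, 0.9 (improving), then five 0.9 plateaus
        assert hist.stop_reason == "early_stop"
        assert len(hist.valid_losses) == 7

    def test_best_checkpoint_minimizes_validation_loss(self, mini_splits, mini_prep):
        losses = iter([1.0, 0.7, 0.8, 0.8, 0.8, 0.8, 0.8, 0.8])
        tl = small_tl(mini_prep)
        cfg = FineTuneConfig(level=1, max_steps=500, eval_interval=1,
                             early_stop_delta=1e-3, early_stop_patience=5)
        _, hist = fine_tune(tl, mini_splits["train"], mini_splits["valid"], cfg,
                            seed=0, valid_loss_fn=lambda m: next(losses))
        assert hist.best_index == 1
        assert hist.best_valid_loss == 0.7

    def test_runs_to_max_steps_without_plateau(self, mini_splits, mini_prep):
        counter = iter(range(100, 0, -1))
        tl = small_tl(mini_prep)
        cfg = FineTuneConfig(level=1, max_steps=20, eval_interval=5,
                             early_stop_delta=1e-3, early_stop_patience=5)
        _, hist = fine_tune(tl, mini_splits["train"], mini_splits["valid"], cfg,
                            seed=0, valid_loss_fn=lambda m: float(next(counter)))
        assert hist.stop_reason == "max_steps"


def test_training_reduces_validation_loss(mini_splits, mini_prep):
    cnn = build_baseline_cnn(2, mini_prep, channels=(8, 8, 8, 8), seed=1)
    cfg = FineTuneConfig(level=1, learning_rate=1e-2, batch_size=8, max_steps=150,
                         eval_interval=25, early_stop_delta=0.0, early_stop_patience=1000)
    _, hist = fine_tune(cnn, mini_splits["train"], mini_splits["valid"], cfg, seed=2)
    assert hist.valid_losses[-1] < hist.valid_losses[0]
    assert hist.best_valid_loss <= min(hist.valid_losses)


class TestBaselineCNN:
    def test_full_scale_crop_and_bins(self):
        cfg = PrepConfig()
        assert cfg.L - 2 * cfg.crop == 114_688
        cnn = build_baseline_cnn(1, cfg, channels=(8, 8, 8, 8))
        assert 114_688 // (2 * 4 * 4 * 4) == 896 == cnn.n_bins

    def test_desk_scale_bins(self, mini_prep):
        cnn = build_baseline_cnn(3, mini_prep, channels=(8, 8, 8, 8))
        assert cnn.n_bins == mini_prep.n_bins == 12
        x = np.random.default_rng(0).random((2, mini_prep.L, 4)).astype(np.float32)
        assert cnn.forward(x).shape == (2, 12, 3)

    def test_geometry_mismatch_rejected(self):
        # valid 64-bp-bin geometry whose retained length is not a multiple of
        # the CNN's total stride of 128
        with pytest.raises(ValueError):
            build_baseline_cnn(1, PrepConfig(L=4224, crop=32, bin_size=64),
                               channels=(8, 8, 8, 8))


class TestPredict:
    def test_inference_deterministic(self, mini_prep):
        tl = small_tl(mini_prep)
        x = np.random.default_rng(1).random((mini_prep.L, 4)).astype(np.float32)
        np.testing.assert_array_equal(tl.predict(x), tl.predict(x))

    def test_batched_equals_single(self, mini_prep):
        tl = small_tl(mini_prep)
        X = np.random.default_rng(2).random((5, mini_prep.L, 4)).astype(np.float32)
        batched = tl.predict_batch(X, batch_size=2)
        singles = np.stack([tl.predict(x) for x in X])
        np.testing.assert_allclose(batched, singles, rtol=1e-5)

    def test_shape_mismatch_rejected(self, mini_prep):
        tl = small_tl(mini_prep)
        with pytest.raises(ValueError):
            tl.predict(np.zeros((100, 4), dtype=np.float32))


def test_checkpoint_round_trip(tmp_path, mini_prep):
    tl = small_tl(mini_prep, seed=7)
    save_checkpoint(tl, tmp_path / "m.npz", {"level": 1})
    tl2 = small_tl(mini_prep, seed=99)
    cfg = load_checkpoint(tl2, tmp_path / "m.npz")
    assert cfg == {"level": 1}
    x = np.random.default_rng(3).random((1, mini_prep.L, 4)).astype(np.float32)
    np.testing.assert_array_equal(tl.forward(x), tl2.forward(x))
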
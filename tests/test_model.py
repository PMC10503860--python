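"""Siamese model: losses, gradients, training contract, prediction."""

import numpy as np
import pandas as pd
import pytest

from neuroslope import (
    HyperParams,
    ModelState,
    contrastive_loss,
    pair_distance,
    regression_loss,
    simulate_cohort,
    train,
    predict_cohort,
    normalized_predicted_error,
    match_scores_to_scans,
    filter_subjects,
    build_pairs,
)
from neuroslope.model import build_network, embed, predict_score, predict_pair_slope, split_subjects
from neuroslope.nn import Adam, Dense

from conftest import tiny_sim_config


def small_training_setup(seed=11, **cfg_overrides):
    cfg = tiny_sim_config(
        score_noise_sd=0.0, volume_noise_sd=0.0, acceleration_sd=0.0,
        causal_snps=(), scan_offset_sd_days=0.0, n_subjects=14, seed=seed,
        **cfg_overrides,
    )
    visits, scans, volumes, _, truth = simulate_cohort(cfg)
    pairs = build_pairs(filter_subjects(match_scores_to_scans(visits, scans)))
    return pairs, volumes, truth


SMALL_HP = dict(conv_widths=(4, 8), embed_dim=8, learning_rate=3e-3, epochs=3, seed=1)


class TestLosses:
    @pytest.mark.parametrize(
        "d,y,m,expected",
        [
            (0.5, 0, 1.0, 0.25),
            (1.5, 1, 1.0, 0.0),
            (0.2, 1, 1.0, 0.64),
            (0.0, 0, 2.0, 0.0),
            (0.0, 1, 2.0, 4.0),
            (2.0, 0, 0.5, 4.0),
        ],
    )
    def test_contrastive_formula(self, d, y, m, expected):
        assert contrastive_loss(d, y, m) == pytest.approx(expected)

    def test_contrastive_rejects_bad_label_and_margin(self):
        with pytest.raises(ValueError):
            contrastive_loss(1.0, 2, 1.0)
        with pytest.raises(ValueError):
            contrastive_loss(1.0, 1, 0.0)

    def test_contrastive_nonnegative_and_zero_conditions(self):
        rng = np.random.default_rng(0)
        for d in rng.uniform(0, 3, 200):
            for y in (0, 1):
                val = contrastive_loss(d, y, 1.0)
                assert val >= 0
                if val == 0:
                    assert (y == 0 and d == 0) or (y == 1 and d >= 1.0)

    @pytest.mark.parametrize(
        "pred,actual,expected", [([1, 3], [0, 0], 5.0), ([2], [5], 9.0), ([4, 4], [4, 4], 0.0)]
    )
    def test_regression_loss(self, pred, actual, expected):
        assert regression_loss(pred, actual) == pytest.approx(expected)

    def test_regression_loss_rejects_empty_batch(self):
        with pytest.raises(ValueError):
            regression_loss([], [])


class TestPairDistance:
    def test_pythagorean(self):
        assert pair_distance([0, 0], [3, 4]) == pytest.approx(5.0)

    def test_symmetric_and_zero_at_equality(self):
        a, b = np.array([1.0, 2.0]), np.array([-1.0, 0.5])
        assert pair_distance(a, b) == pair_distance(b, a)
        assert pair_distance(a, a) == 0.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            pair_distance([1, 2], [1, 2, 3])


class TestGradients:
    def test_backprop_matches_finite_differences(self):
        """Full dual-loss gradient against central differences."""
        rng = np.random.default_rng(0)
        hp = HyperParams(conv_widths=(3, 4), embed_dim=5, patch_k=2, seed=3)
        net = build_network((8, 8, 8), hp)
        backbone, head = net.layers
        x_i = rng.normal(size=(3, 1, 8, 8, 8))
        x_j = rng.normal(size=(3, 1, 8, 8, 8))
        y = rng.normal(size=3)
        lab = np.array([0, 1, 1])
        m = 1.0

        def total_loss():
            e_i, _ = backbone.forward(x_i)
            e_j, _ = backbone.forward(x_j)
            yhat, _ = head.forward(e_i)
            mse = np.mean((yhat[:, 0] - y) ** 2)
            d = np.linalg.norm(e_i - e_j, axis=1)
            con = np.mean(np.where(lab == 0, d**2, np.maximum(0, m - d) ** 2))
            return mse + con

        for p in net.params():
            p.grad[...] = 0.0
        e_i, ci = backbone.forward(x_i)
        e_j, cj = backbone.forward(x_j)
        yhat, ch = head.forward(e_i)
        dyhat = (2.0 / 3) * (yhat - y[:, None])
        de_i = head.backward(dyhat, ch)
        diff = e_i - e_j
        d = np.linalg.norm(diff, axis=1)
        unit = diff / np.where(d > 0, d, 1.0)[:, None]
        gd = np.where(lab == 0, 2 * d, np.where(d < m, -2 * (m - d), 0.0))
        dcon = (1.0 / 3) * gd[:, None] * unit
        backbone.backward(de_i + dcon, ci)
        backbone.backward(-dcon, cj)

        eps = 1e-6
        for p in net.params():
            for _ in range(3):
                idx = tuple(rng.integers(0, s) for s in p.value.shape)
                orig = p.value[idx]
                p.value[idx] = orig + eps
                lp = total_loss()
                p.value[idx] = orig - eps
                lm = total_loss()
                p.value[idx] = orig
                num = (lp - lm) / (2 * eps)
                assert num == pytest.approx(p.grad[idx], rel=1e-4, abs=1e-7)

    def test_contrastive_step_pushes_different_class_apart(self):
        """One optimizer step on a Y=1 pair with D<m increases D (toy head)."""
        rng = np.random.default_rng(1)
        layer = Dense(2, 2, rng)
        opt = Adam(layer.params(), lr=1e-2)
        x1 = np.array([[1.0, 0.0]])
        x2 = np.array([[0.0, 1.0]])
        m = 5.0

        def distance():
            e1, _ = layer.forward(x1)
            e2, _ = layer.forward(x2)
            return np.linalg.norm(e1 - e2)

        d0 = distance()
        assert d0 < m
        opt.zero_grad()
        e1, c1 = layer.forward(x1)
        e2, c2 = layer.forward(x2)
        diff = e1 - e2
        d = np.linalg.norm(diff)
        grad = -2 * (m - d) * diff / d
        layer.backward(grad, c1)
        layer.backward(-grad, c2)
        opt.step()
        assert distance() > d0


class TestSplit:
    def test_subject_level_split_sizes(self):
        subjects = [f"S{i}" for i in range(414)]
        train_set, val_set = split_subjects(subjects, 0.7, np.random.default_rng(0))
        assert len(train_set) == 289
        assert len(val_set) == 125
        assert not (train_set & val_set)


@pytest.fixture(scope="module")
def trained():
    pairs, volumes, truth = small_training_setup()
    hp = HyperParams(**SMALL_HP)
    state = train(pairs, volumes, hp)
    return pairs, volumes, truth, state


class TestTraining:
    def test_single_epoch_selects_epoch_one(self):
        pairs, volumes, _ = small_training_setup()
        state = train(pairs, volumes, HyperParams(**{**SMALL_HP, "epochs": 1}))
        assert state.selected_epoch == 1
        assert len(state.log) == 1

    def test_training_log_reproducible_under_fixed_seed(self):
        pairs, volumes, _ = small_training_setup()
        hp = HyperParams(**SMALL_HP)
        log1 = train(pairs, volumes, hp).log
        log2 = train(pairs, volumes, HyperParams(**SMALL_HP)).log
        pd.testing.assert_frame_equal(log1, log2)

    def test_validation_mse_beats_constant_predictor(self, trained):
        """The model must explain variance beyond the train-mean baseline.

        Logged MSE is on the standardized scale, where the constant
        train-mean predictor scores ~1 on validation data.
        """
        *_, state = trained
        assert state.log["val_mse"].min() < 1.0

    def test_embedding_weight_sharing_and_determinism(self, trained):
        pairs, volumes, _, state = trained
        vol = volumes[pairs.loc[0, "scan_id_i"]]
        e1, e2 = embed(vol, state), embed(vol, state)
        np.testing.assert_array_equal(e1, e2)
        assert e1.shape == (state.hyperparams.embed_dim,)
        assert np.isfinite(e1).all()

    def test_shape_mismatch_rejected(self, trained):
        *_, state = trained
        with pytest.raises(ValueError, match="shape"):
            embed(np.zeros((4, 4, 4)), state)

    def test_identical_images_predict_zero_slope(self, trained):
        pairs, volumes, _, state = trained
        pair = pairs.iloc[0].copy()
        pair["scan_id_j"] = pair["scan_id_i"]
        assert predict_pair_slope(state, pair, volumes) == 0.0

    def test_doubling_gap_halves_predicted_slope(self, trained):
        pairs, volumes, _, state = trained
        pair = pairs.iloc[0].copy()
        s1 = predict_pair_slope(state, pair, volumes)
        pair["delta_t_years"] *= 2
        assert predict_pair_slope(state, pair, volumes) == pytest.approx(s1 / 2)

    def test_predict_cohort_consistent_with_single_pair(self, trained):
        pairs, volumes, _, state = trained
        pred = predict_cohort(state, pairs, volumes)
        j = 3
        assert pred.loc[j, "predicted_slope"] == pytest.approx(
            predict_pair_slope(state, pairs.iloc[j], volumes)
        )
        assert pred.loc[j, "predicted_score_i"] == pytest.approx(
            predict_score(volumes[pairs.loc[j, "scan_id_i"]], state)
        )

    def test_checkpoint_roundtrip(self, trained, tmp_path):
        pairs, volumes, _, state = trained
        path = tmp_path / "ckpt.npz"
        state.save(path)
        loaded = ModelState.load(path)
        vol = volumes[pairs.loc[0, "scan_id_i"]]
        assert predict_score(vol, loaded) == pytest.approx(predict_score(vol, state))
        pd.testing.assert_frame_equal(loaded.log, state.log)

    def test_overlapping_split_impossible(self):
        with pytest.raises(ValueError, match="split has no pairs"):
            pairs, volumes, _ = small_training_setup()
            solo = pairs[pairs["subject_id"] == pairs.loc[0, "subject_id"]]
            train(solo, volumes, HyperParams(**SMALL_HP))


class TestNPE:
    def test_npe_arithmetic(self):
        npe, (mean, sd) = normalized_predicted_error([12.0, 12.0], [10.0, 10.0], [1.0, 2.0])
        np.testing.assert_allclose(npe, [2.0, 1.0])
        assert mean == pytest.approx(1.5)

    def test_perfect_prediction_gives_zero(self):
        npe, (mean, _) = normalized_predicted_error([5.0], [5.0], [1.0])
        assert mean == 0.0

    def test_zero_gap_rejected(self):
        with pytest.raises(ValueError):
            normalized_predicted_error([1.0], [0.0], [0.0])


class TestHyperParams:
    def test_invalid_values_rejected(self):
        with pytest.raises(ValueError):
            HyperParams(margin=0.0)
        with pytest.raises(ValueError):
            HyperParams(decay_factor=0.0)
        with pytest.raises(ValueError):
            HyperParams(epochs=0)

    def test_lr_schedule_decays_stepwise(self):
        hp = HyperParams()
        opt = Adam([], hp.learning_rate)
        opt.set_epoch(1, hp.decay_factor, hp.decay_every)
        assert opt.lr == pytest.approx(1e-4)
        opt.set_epoch(10, hp.decay_factor, hp.decay_every)
        assert opt.lr == pytest.approx(1e-4)
        opt.set_epoch(11, hp.decay_factor, hp.decay_every)
        assert opt.lr == pytest.approx(1e-5)
        opt.set_epoch(21, hp.decay_factor, hp.decay_every)
        assert opt.lr == pytest.approx(1e-6)
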
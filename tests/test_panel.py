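"""tau-squared scoring, exact branch-and-bound selection, LDA and CV."""

import itertools

import numpy as np
import pandas as pd
import pytest

from pmfmeth import (
    PanelModel,
    ValidationError,
    lda_fit,
    lda_predict,
    leaps_and_bounds_select,
    minimal_panel,
    repeated_cv,
    tau_squared,
)
from tests.conftest import two_group_frame


def _frame(values, groups):
    values = np.asarray(values, dtype=float)
    idx = [f"s{i}" for i in range(values.shape[0])]
    cols = [f"cg{j:06d}" for j in range(values.shape[1])]
    return pd.DataFrame(values, index=idx, columns=cols), pd.Series(groups, index=idx)


class TestTauSquared:
    def test_hand_computed_scatter_ratio(self):
        # E = 0.02 + 0.02 = 0.04, T = 0.58 -> tau^2 = 1 - 0.04/0.58
        X, y = _frame([[0.1], [0.2], [0.3], [0.7], [0.8], [0.9]],
                      ["FP"] * 3 + ["SD"] * 3)
        score = tau_squared(X, y)
        assert score.tau_squared == pytest.approx(1 - 0.04 / 0.58, abs=1e-9)
        assert score.wilks_lambda == pytest.approx(0.04 / 0.58, abs=1e-9)

    def test_identical_means_give_zero(self):
        X, y = _frame([[0.4], [0.5], [0.6], [0.4], [0.5], [0.6]],
                      ["FP"] * 3 + ["SD"] * 3)
        assert tau_squared(X, y).tau_squared == pytest.approx(0.0, abs=1e-9)

    def test_perfect_separation_approaches_one(self):
        rng = np.random.default_rng(0)
        X, y = _frame(
            np.concatenate([rng.normal(0.2, 1e-4, (5, 1)), rng.normal(0.8, 1e-4, (5, 1))]),
            ["FP"] * 5 + ["SD"] * 5,
        )
        assert tau_squared(X, y).tau_squared > 0.999

    @pytest.mark.parametrize("scale,shift", [(2.5, 0.0), (1.0, 0.2), (-3.0, 0.1)])
    def test_affine_invariance_per_probe(self, scale, shift):
        rng = np.random.default_rng(1)
        X, y = two_group_frame(rng, 6, 6, 3)
        X.iloc[:6] += 0.08
        base = tau_squared(X, y).tau_squared
        X2 = X.copy()
        X2.iloc[:, 1] = X2.iloc[:, 1] * scale + shift
        assert tau_squared(X2, y).tau_squared == pytest.approx(base, rel=1e-9)

    def test_tau_non_decreasing_in_k(self):
        rng = np.random.default_rng(2)
        X, y = two_group_frame(rng, 8, 8, 8)
        X.iloc[:8, :2] += 0.05
        prev = -1.0
        for k in range(1, 7):
            tau = leaps_and_bounds_select(X, y, k).tau_squared
            assert tau >= prev - 1e-12
            prev = tau


def _brute_force(X, y, k):
    best_tau, best_ids = -1.0, None
    for combo in itertools.combinations(X.columns, k):
        tau = tau_squared(X.loc[:, list(combo)], y).tau_squared
        ids = tuple(sorted(combo))
        if tau > best_tau + 1e-12 or (
            abs(tau - best_tau) <= 1e-12 and (best_ids is None or ids < best_ids)
        ):
            best_tau, best_ids = tau, ids
    return best_tau, best_ids


class TestLeapsAndBounds:
    def test_equals_exhaustive_search(self):
        rng = np.random.default_rng(42)
        for trial in range(15):
            m = int(rng.integers(6, 12))
            k = int(rng.integers(1, 5))
            X, y = two_group_frame(rng, 7, 7, m, noise=0.1)
            X.iloc[:7, :3] += rng.normal(0.05, 0.02)
            got = leaps_and_bounds_select(X, y, k)
            tau, ids = _brute_force(X, y, k)
            assert got.tau_squared == pytest.approx(tau, abs=1e-9)
            assert tuple(got.probe_ids) == ids

    def test_full_set_when_k_equals_m(self):
        rng = np.random.default_rng(3)
        X, y = two_group_frame(rng, 6, 6, 5)
        got = leaps_and_bounds_select(X, y, 5)
        assert set(got.probe_ids) == set(X.columns)
        assert got.tau_squared == pytest.approx(tau_squared(X, y).tau_squared, abs=1e-9)

    def test_planted_pair_selected(self):
        rng = np.random.default_rng(4)
        X, y = two_group_frame(rng, 10, 10, 10, noise=0.08)
        z = rng.normal(0, 0.15, 20)
        fp = (y == "FP").to_numpy()
        X["cg000000"] = 0.5 + 0.1 * fp + z + rng.normal(0, 0.01, 20)
        X["cg000001"] = 0.5 - 0.1 * fp + z + rng.normal(0, 0.01, 20)
        got = leaps_and_bounds_select(X, y, 2)
        assert set(got.probe_ids) == {"cg000000", "cg000001"}

    def test_k_larger_than_m_raises(self):
        rng = np.random.default_rng(5)
        X, y = two_group_frame(rng, 5, 5, 4)
        with pytest.raises(ValidationError, match="exceeds"):
            leaps_and_bounds_select(X, y, 5)


def _latent_panel_instance(seed, n_fp=12, n_sd=10, d=0.045, sz=0.15, se=0.006):
    """Four probes share a 3-D latent factor with tetrahedral loadings: the
    factor cancels only in the full quartet, so the minimal panel size is 4."""
    rng = np.random.default_rng(seed)
    n = n_fp + n_sd
    g = np.array([1.0] * n_fp + [0.0] * n_sd)
    z = rng.normal(0, sz, (n, 3))
    A = np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]]) / np.sqrt(3)
    cols = {}
    for j in range(4):
        cols[f"cg{j:06d}"] = np.clip(0.45 + d * g + z @ A[j] + rng.normal(0, se, n), 0, 1)
    for j in range(4, 10):
        cols[f"cg{j:06d}"] = np.clip(0.5 + rng.normal(0, 0.03, n), 0, 1)
    X = pd.DataFrame(cols, index=[f"s{i}" for i in range(n)])
    y = pd.Series(["FP"] * n_fp + ["SD"] * n_sd, index=X.index)
    return X, y


class TestMinimalPanel:
    def test_single_separating_probe_gives_k1(self):
        X, y = _frame(
            [[0.1], [0.15], [0.2], [0.7], [0.75], [0.8]], ["FP"] * 3 + ["SD"] * 3
        )
        model = minimal_panel(X, y, k_max=1)
        assert len(model.probe_ids) == 1 and not model.non_separating

    def test_latent_quartet_needs_exactly_four_probes(self):
        X, y = _latent_panel_instance(seed=0)
        model = minimal_panel(X, y, k_max=6)
        assert not model.non_separating
        assert sorted(model.probe_ids) == ["cg000000", "cg000001", "cg000002", "cg000003"]

    def test_pure_noise_flagged_non_separating(self):
        flagged = 0
        for seed in range(10):
            rng = np.random.default_rng(600 + seed)
            X, y = two_group_frame(rng, 11, 11, 8, noise=0.1)
            model = minimal_panel(X, y, k_max=3)
            flagged += model.non_separating
        assert flagged >= 9


class TestLda:
    def test_spherical_covariance_aligns_with_mean_difference(self):
        rng = np.random.default_rng(6)
        mu = np.array([1.0, -0.5, 2.0])
        n = 3000
        X = np.concatenate([rng.normal(0, 1, (n, 3)) + mu, rng.normal(0, 1, (n, 3))])
        Xdf, y = _frame(np.clip(0.5 + 0.08 * X, 0, 1), ["FP"] * n + ["SD"] * n)
        model = lda_fit(Xdf, y)
        w = model.weights / np.linalg.norm(model.weights)
        direction = -mu / np.linalg.norm(mu)  # FP projects negative
        assert abs(float(w @ direction)) >= 0.999

    def test_equal_class_means_return_priors(self):
        rng = np.random.default_rng(7)
        X, y = two_group_frame(rng, 50, 50, 2, noise=0.05)
        model = lda_fit(X, y, priors=(0.3, 0.7))
        preds = lda_predict(model, X)
        # no information: posterior concentrates near the priors
        assert preds["p_fp"].mean() == pytest.approx(0.3, abs=0.1)

    def test_separable_training_data_classified_perfectly(self):
        rng = np.random.default_rng(8)
        X, y = two_group_frame(rng, 11, 11, 4, noise=0.02)
        X.iloc[:11] += 0.2
        model = lda_fit(X.clip(0, 1), y)
        preds = lda_predict(model, X.clip(0, 1))
        assert (preds["predicted"] == y).all()
        assert model.mean_fp < 0 < model.mean_sd

    def test_centroid_and_threshold_predictions(self):
        rng = np.random.default_rng(9)
        X, y = two_group_frame(rng, 10, 10, 3, noise=0.05)
        X.iloc[:10] += 0.15
        model = lda_fit(X.clip(0, 1), y, priors=(0.5, 0.5))
        centroid = X.clip(0, 1).iloc[:10].mean().to_frame().T
        centroid.index = ["fp_centroid"]
        pred = lda_predict(model, centroid)
        assert pred["p_fp"].iloc[0] > 0.5
        # a sample projecting exactly on the threshold splits 50/50
        at_thr = pd.DataFrame(
            [model.center + model.threshold * model.weights / (model.weights @ model.weights)],
            columns=model.probe_ids, index=["boundary"],
        )
        pb = lda_predict(model, at_thr)
        assert pb["p_fp"].iloc[0] == pytest.approx(0.5, abs=1e-9)

    def test_probabilities_sum_to_one_and_band_rule(self):
        rng = np.random.default_rng(10)
        X, y = two_group_frame(rng, 8, 8, 3, noise=0.05)
        X.iloc[:8] += 0.1
        model = lda_fit(X.clip(0, 1), y)
        preds = lda_predict(model, X.clip(0, 1))
        assert np.allclose(preds["p_fp"] + preds["p_sd"], 1.0)
        maxp = preds[["p_fp", "p_sd"]].max(axis=1)
        assert ((maxp >= 0.95) == (preds["band"] == "high")).all()

    def test_missing_panel_probe_raises_with_names(self):
        rng = np.random.default_rng(11)
        X, y = two_group_frame(rng, 6, 6, 3)
        model = lda_fit(X, y)
        with pytest.raises(ValidationError, match="cg000002"):
            lda_predict(model, X.drop(columns=["cg000002"]))

    def test_ld1_is_affine_in_input(self):
        rng = np.random.default_rng(12)
        X, y = two_group_frame(rng, 6, 6, 3)
        model = lda_fit(X, y)
        a, b = X.iloc[[0]], X.iloc[[1]]
        mid = (a.to_numpy() + b.to_numpy()) / 2
        lda_mid = lda_predict(
            model, pd.DataFrame(mid, columns=X.columns, index=["m"])
        )["ld1"].iloc[0]
        l_a = lda_predict(model, a)["ld1"].iloc[0]
        l_b = lda_predict(model, b)["ld1"].iloc[0]
        assert lda_mid == pytest.approx((l_a + l_b) / 2, abs=1e-10)

    def test_model_serialization_round_trip(self, tmp_path):
        # coefficient magnitudes mirror published LD-model tables (synthetic
        # stand-in probe ids and values)
        model = PanelModel(
            probe_ids=["cg03983220", "cg11628316"],
            weights=np.array([-7.431161, -44.910325]),
            center=np.array([0.41, 0.62]),
            mean_fp=-1.3,
            mean_sd=1.3,
            priors=(0.55, 0.45),
            threshold=0.02,
            tau_squared=0.93,
        )
        path = tmp_path / "panel.json"
        model.to_json(path)
        back = PanelModel.from_json(path)
        assert back.probe_ids == model.probe_ids
        assert np.allclose(back.weights, model.weights)
        assert back.threshold == pytest.approx(model.threshold)
        assert back.priors == model.priors


class TestRepeatedCv:
    def test_strongly_separable_cohort_scores_high(self):
        rng = np.random.default_rng(13)
        X, y = two_group_frame(rng, 11, 11, 10, noise=0.04)
        X.iloc[:11, :3] += 0.2
        out = repeated_cv(X.clip(0, 1), y, folds=5, repeats=2, k_max=3, seed=0)
        assert out["mean_accuracy"] >= 0.9

    def test_permuted_labels_score_near_chance(self):
        rng = np.random.default_rng(14)
        X, y = two_group_frame(rng, 11, 11, 10, noise=0.05)
        perm = pd.Series(rng.permutation(y.to_numpy()), index=y.index)
        out = repeated_cv(X, perm, folds=5, repeats=3, k_max=2, seed=1)
        assert abs(out["mean_accuracy"] - 0.5) <= 0.2

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(15)
        X, y = two_group_frame(rng, 10, 10, 6, noise=0.05)
        X.iloc[:10, 0] += 0.1
        a = repeated_cv(X.clip(0, 1), y, folds=5, repeats=1, k_max=2, seed=7)
        b = repeated_cv(X.clip(0, 1), y, folds=5, repeats=1, k_max=2, seed=7)
        assert np.array_equal(a["accuracies"], b["accuracies"])

    def test_small_class_rejected_before_compute(self):
        rng = np.random.default_rng(16)
        X, y = two_group_frame(rng, 3, 10, 4)
        with pytest.raises(ValidationError, match="stratification|needs >="):
            repeated_cv(X, y, folds=5, repeats=1, k_max=2, seed=0)
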
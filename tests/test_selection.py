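"""Cross-validation plans, Kennard-Stone, and the variable-selection methods."""

import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform

from milknir import (ConfigurationError, CrossValPlan, DegenerateDataError,
                     SpectralBlock, choose_n_lv, cross_validate,
                     cross_validate_plsda, fit_pls1, ipls, kennard_stone,
                     kennard_stone_split, make_intervals, rpls,
                     selectivity_ratio, venetian_blinds, vip)
from milknir.preprocess import PreprocessRecipe


class TestVenetianBlinds:
    def test_small_enumeration(self):
        folds = venetian_blinds(6, CrossValPlan(3, 1))
        np.testing.assert_array_equal(folds, [0, 1, 2, 0, 1, 2])

    def test_interleaved_pairs_for_n44(self):
        # the 22-split / 5-per-blind plan cannot hold 110 samples; with n=44
        # it adapts to thickness 1, pairing samples i and i+22
        folds = venetian_blinds(44, CrossValPlan(22, 5))
        for f in range(22):
            members = np.flatnonzero(folds == f)
            np.testing.assert_array_equal(members, [f, f + 22])

    @pytest.mark.parametrize("n,splits,thickness",
                             [(45, 22, 5), (30, 5, 2), (50, 7, 3), (10, 2, 1)])
    def test_partition_property(self, n, splits, thickness):
        folds = venetian_blinds(n, CrossValPlan(splits, thickness))
        assert folds.shape == (n,)
        assert set(folds) <= set(range(splits))
        assert np.bincount(folds).sum() == n

    def test_too_few_samples_rejected(self):
        with pytest.raises(ConfigurationError):
            venetian_blinds(5, CrossValPlan(10, 1))


class TestCrossValidate:
    def test_noise_free_rank2_selects_two_lvs(self, rng):
        t1, t2 = rng.normal(size=(2, 40))
        d1, d2 = rng.normal(size=(2, 12))
        X = np.outer(t1, d1) + np.outer(t2, d2)
        y = 1.0 + 2 * t1 - 3 * t2
        result = cross_validate(X, y, None, 5, CrossValPlan(8, 1))
        assert result.n_lv == 2
        assert result.rmsecv[1] < 1e-8

    def test_pure_noise_rmsecv_floor(self):
        r = np.random.default_rng(5)
        X = r.normal(size=(60, 10))
        y = r.normal(size=60)            # y unrelated to X
        result = cross_validate(X, y, None, 5, CrossValPlan(10, 1))
        assert result.rmsecv.min() >= y.std() * (1 - 0.25)

    def test_fold_refit_prevents_leakage(self, rng):
        # block-structured variance: autoscaling on all data would leak the
        # held-out block's spread into the fold models
        n = 40
        wl = np.linspace(800, 900, 15)
        X = rng.normal(size=(n, 15))
        X[n // 2:] *= 6.0
        y = rng.normal(size=n)
        block = SpectralBlock("t", wl, X, [f"S{i}" for i in range(n)])
        recipe = PreprocessRecipe([{"kind": "autoscale"}])
        inside = cross_validate(block, y, recipe, 2, CrossValPlan(4, 5))
        # oracle with global (leaky) scaling
        X_leak = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
        leaky = cross_validate(X_leak, y, None, 2, CrossValPlan(4, 5))
        assert not np.allclose(inside.predictions, leaky.predictions)

    def test_epsilon_rule(self):
        # 0.5 is within 2% of the minimum 0.499 -> parsimonious pick of 2 LVs
        assert choose_n_lv(np.array([1.0, 0.5, 0.505, 0.499]), 0.02) == 2
        assert choose_n_lv(np.array([0.3, 0.31, 0.296]), 0.02) == 1
        # a late, clearly lower minimum is honoured
        assert choose_n_lv(np.array([1.0, 0.8, 0.4]), 0.02) == 3

    def test_predictions_are_held_out(self, rng):
        X = rng.normal(size=(24, 8))
        direction = rng.normal(size=8)
        y = X @ direction + 0.1 * rng.normal(size=24)
        result = cross_validate(X, y, None, 3, CrossValPlan(6, 1))
        refit = fit_pls1(X, y, 3)
        from milknir import predict
        assert not np.allclose(result.predictions[:, 2], predict(refit, X))


class TestKennardStone:
    def brute_force(self, X, n_select):
        """Straightforward maximin re-implementation with explicit loops."""
        D = squareform(pdist(X))
        n = len(X)
        best = (-1.0, None)
        for i in range(n):
            for j in range(i + 1, n):
                if D[i, j] > best[0]:
                    best = (D[i, j], (i, j))
        chosen = list(best[1])
        while len(chosen) < n_select:
            cand_best = (-1.0, None)
            for i in range(n):
                if i in chosen:
                    continue
                d = min(D[i, j] for j in chosen)
                if d > cand_best[0]:
                    cand_best = (d, i)
            chosen.append(cand_best[1])
        return np.array(sorted(chosen))

    def test_collinear_points(self):
        X = np.array([[0.0], [1.0], [10.0]])
        np.testing.assert_array_equal(kennard_stone(X, 2), [0, 2])

    @pytest.mark.parametrize("n", range(4, 13))
    def test_equals_brute_force_all_sizes(self, n):
        r = np.random.default_rng(n)
        X = r.normal(size=(n, 3))
        for n_select in range(2, n + 1):
            np.testing.assert_array_equal(kennard_stone(X, n_select),
                                          self.brute_force(X, n_select))

    def test_split_fractions(self, rng):
        X = rng.normal(size=(45, 5))
        train, test = kennard_stone_split(X, 2 / 3)
        assert len(train) == 30 and len(test) == 15
        assert np.intersect1d(train, test).size == 0

    def test_deterministic_with_duplicates(self):
        X = np.array([[0.0, 0], [0.0, 0], [1.0, 0], [5.0, 0]])
        a = kennard_stone(X, 3)
        b = kennard_stone(X, 3)
        np.testing.assert_array_equal(a, b)


class TestVIP:
    def test_single_informative_variable_closed_form(self, rng):
        p = 6
        t = rng.normal(size=30)
        X = np.zeros((30, p))
        X[:, 2] = t
        X += 1e-9 * rng.normal(size=(30, p))
        y = 3 * t
        model = fit_pls1(X, y, 1)
        scores = vip(model)
        assert scores[2] == pytest.approx(np.sqrt(p), rel=1e-4)
        assert np.all(scores[np.arange(p) != 2] < 1e-3)

    def test_mean_square_is_one(self, rng):
        X = rng.normal(size=(20, 9))
        y = rng.normal(size=20)
        scores = vip(fit_pls1(X, y, 4))
        assert np.mean(scores ** 2) == pytest.approx(1.0, abs=1e-10)

    def test_matches_direct_formula(self, rng):
        X = rng.normal(size=(15, 7))
        y = rng.normal(size=15)
        model = fit_pls1(X, y, 3)
        ssy = model.y_variance_explained_pct
        manual = np.sqrt(7 * sum(
            ssy[k] * (model.W[:, k] / np.linalg.norm(model.W[:, k])) ** 2
            for k in range(3)) / ssy.sum())
        np.testing.assert_allclose(vip(model), manual, atol=1e-10)


class TestIPLS:
    def make_signal(self, rng, informative):
        n, p = 40, 60
        X = rng.normal(size=(n, p)) * 0.05
        t = rng.normal(size=n)
        X[:, informative] += np.outer(t, np.ones(len(informative)))
        return X, 2.0 * t

    def test_single_signal_interval_found(self, rng):
        informative = np.arange(12, 18)       # inside interval 2 of 10
        X, y = self.make_signal(rng, informative)
        result = ipls(X, y, 10, 3, CrossValPlan(8, 1))
        assert set(informative) <= set(result.indices)
        assert 2 in result.details["intervals"]

    def test_two_complementary_intervals(self, rng):
        n, p = 40, 60
        X = rng.normal(size=(n, p)) * 0.05
        t1, t2 = rng.normal(size=(2, n))
        X[:, 6:12] += np.outer(t1, np.ones(6))
        X[:, 42:48] += np.outer(t2, np.ones(6))
        y = t1 + t2
        result = ipls(X, y, 10, 4, CrossValPlan(8, 1))
        chosen = set(result.details["intervals"])
        assert {1, 7} <= chosen
        single = ipls(X[:, 6:12], y, 2, 2, CrossValPlan(8, 1))
        assert result.details["rmsecv"] < single.details["rmsecv"]

    def test_deterministic(self, rng):
        X, y = self.make_signal(rng, np.arange(6))
        a = ipls(X, y, 10, 3, CrossValPlan(8, 1))
        b = ipls(X, y, 10, 3, CrossValPlan(8, 1))
        np.testing.assert_array_equal(a.indices, b.indices)

    def test_intervals_partition(self):
        intervals = make_intervals(331, 20)
        assert len(intervals) == 20
        np.testing.assert_array_equal(np.concatenate(intervals),
                                      np.arange(331))
        with pytest.raises(ConfigurationError):
            make_intervals(5, 10)


class TestRPLS:
    def test_dominant_variable_survives(self, rng):
        n, p = 30, 12
        t = rng.normal(size=n)
        X = rng.normal(size=(n, p)) * 0.01
        X[:, 4] += t
        result = rpls(X, 2 * t, n_lv=2)
        assert 4 in result.indices

    def test_entropy_non_increasing_noise_free(self, rng):
        n, p = 30, 10
        t1, t2 = rng.normal(size=(2, n))
        X = np.zeros((n, p))
        X[:, 1] = t1
        X[:, 7] = t2
        X += 1e-8 * rng.normal(size=(n, p))
        result = rpls(X, t1 + 0.5 * t2, n_lv=2)
        ent = result.details["entropy"]
        assert all(a >= b - 1e-9 for a, b in zip(ent, ent[1:]))

    def test_all_noise_never_silent(self):
        r = np.random.default_rng(0)
        X = r.normal(size=(20, 8))
        y = r.normal(size=20)
        try:
            result = rpls(X, y, n_lv=2, max_iter=30)
        except DegenerateDataError:
            return                      # explicit failure is acceptable
        # otherwise the collapse must be visible in the trace
        assert result.details["iterations"] >= 1
        assert result.indices.size <= 8


class TestSelectivityRatio:
    def test_single_variable_dominates(self, rng):
        n, p = 30, 8
        t = rng.normal(size=n)
        X = rng.normal(size=(n, p)) * 0.001
        X[:, 5] += t
        model = fit_pls1(X, 4 * t, 1)
        ratios = selectivity_ratio(model, X)
        assert ratios[5] > 100 * np.delete(ratios, 5).max()

    def test_invariant_to_y_rescaling(self, rng):
        X = rng.normal(size=(20, 6))
        y = rng.normal(size=20)
        r1 = selectivity_ratio(fit_pls1(X, y, 2), X)
        r2 = selectivity_ratio(fit_pls1(X, 100 * y, 2), X)
        np.testing.assert_allclose(r1, r2, rtol=1e-8)

    def test_matches_target_projection_oracle(self, rng):
        X = rng.normal(size=(18, 7))
        y = rng.normal(size=18)
        model = fit_pls1(X, y, 3)
        Xc = X - X.mean(axis=0)
        t = Xc @ model.b / np.linalg.norm(model.b)
        p_tp = Xc.T @ t / (t @ t)
        exp = np.outer(t, p_tp)
        oracle = (exp ** 2).sum(0) / ((Xc - exp) ** 2).sum(0)
        np.testing.assert_allclose(selectivity_ratio(model, X), oracle,
                                   rtol=1e-10)


def test_cross_validate_plsda_separable(rng):
    n = 30
    X = rng.normal(size=(n, 6))
    labels = np.array(["a", "b"] * (n // 2))
    X[labels == "b", 1] += 8.0
    out = cross_validate_plsda(X, labels, 2, CrossValPlan(6, 1))
    assert (out["cross_validation"]["sensitivity"] == 1.0).all()
    assert (out["cross_validation"]["specificity"] == 1.0).all()
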
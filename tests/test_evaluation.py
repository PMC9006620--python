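import numpy as np
import pytest

from fieldspat.datasets import simulate_observational
from fieldspat.design import SpatialDesign, full_grid, sample_locations
from fieldspat.evaluation import (
    adjusted_morans_i,
    beta_mse,
    blocked_folds,
    cv_r_squared,
    morans_i,
    r_squared_centered,
    random_folds,
    selection_metrics,
)
from fieldspat.gls import fit_ols
from fieldspat.scenarios import ScenarioSpec


def brute_force_morans_i(z, coords):
    """Double-loop evaluation of the inverse-distance Moran's I."""
    n = len(z)
    zc = z - z.mean()
    num = 0.0
    sw = 0.0
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            w = 1.0 / np.hypot(*(coords[i] - coords[j]))
            num += w * zc[i] * zc[j]
            sw += w
    return n / sw * num / (zc @ zc)


class TestFolds:
    def test_random_fold_sizes(self):
        fa = random_folds(100, 10, seed=1)
        assert np.bincount(fa.fold_of).tolist() == [10] * 10

    def test_leave_one_out(self):
        fa = random_folds(7, 7, seed=2)
        assert sorted(np.bincount(fa.fold_of)) == [1] * 7

    def test_random_determinism(self):
        assert np.array_equal(random_folds(50, 5, 3).fold_of,
                              random_folds(50, 5, 3).fold_of)

    def test_too_many_folds(self):
        with pytest.raises(ValueError):
            random_folds(5, 6, seed=0)

    def test_blocked_folds_recover_separated_clouds(self):
        coords = np.vstack([
            np.column_stack([np.arange(1, 6), np.ones(5)]),
            np.column_stack([np.arange(1, 6), np.full(5, 30)]),
        ])
        d = SpatialDesign(30, coords)
        fa = blocked_folds(d, 2, seed=4)
        assert len(set(fa.fold_of[:5])) == 1
        assert len(set(fa.fold_of[5:])) == 1
        assert fa.fold_of[0] != fa.fold_of[5]

    def test_single_blocked_fold(self):
        d = sample_locations(15, 20, 5)
        fa = blocked_folds(d, 1, seed=0)
        assert set(fa.fold_of) == {0}

    def test_blocked_folds_are_spatially_tighter(self):
        """Mean within-fold pairwise distance under blocked folds is
        smaller than under random folds — the mechanism that reduces
        information leakage between folds."""
        gaps = []
        for s in range(30):
            d = sample_locations(15, 100, s)
            D = d.distance_matrix
            means = {}
            for fa in (blocked_folds(d, 10, s), random_folds(100, 10, s)):
                vals = []
                for f in range(10):
                    idx = np.flatnonzero(fa.fold_of == f)
                    if len(idx) > 1:
                        sub = D[np.ix_(idx, idx)]
                        vals.append(sub[np.triu_indices(len(idx), 1)].mean())
                means[fa.scheme] = np.mean(vals)
            gaps.append(means["random"] - means["blocked"])
        assert np.mean(gaps) > 0
        assert np.mean(np.array(gaps) > 0) > 0.95


class TestRSquared:
    def test_perfect_prediction(self):
        a = np.array([1.0, 2, 5])
        assert r_squared_centered(a, a) == pytest.approx(1.0)

    def test_constant_prediction_scores_zero(self):
        a = np.array([1.0, 2, 5])
        assert r_squared_centered(a, np.full(3, 9.0)) == pytest.approx(0.0)

    def test_hand_computed_example(self):
        # a=(1,2,3) centered (-1,0,1); ahat=(1,1,4) centered (-1,-1,2)
        # residuals (0,1,-1), R2 = 1 - 2/2 = 0
        assert r_squared_centered([1, 2, 3], [1, 1, 4]) == pytest.approx(0.0)

    def test_centering_removes_offsets(self):
        a = np.array([1.0, 2, 3, 7])
        ahat = a + 100.0  # constant shift is forgiven
        assert r_squared_centered(a, ahat) == pytest.approx(1.0)

    def test_constant_observed_rejected(self):
        with pytest.raises(ValueError):
            r_squared_centered([2.0, 2.0], [1.0, 3.0])


class TestCvRSquared:
    def test_noiseless_linear_truth(self):
        d = sample_locations(15, 60, 6)
        B = np.random.default_rng(0).standard_normal((60, 2))
        A = 1.0 + B @ np.array([2.0, -1.0])
        from fieldspat.datasets import SimulatedDataset, TrueModel
        ds = SimulatedDataset(d, A, B, TrueModel(
            np.array([2.0, -1.0]), np.zeros(2, bool),
            ScenarioSpec.none(), ScenarioSpec.none()))
        fa = random_folds(60, 6, 1)
        r2 = cv_r_squared(lambda a, b, dd: fit_ols(a, b), ds, fa)
        assert r2 == pytest.approx(1.0, abs=1e-10)

    def test_failed_folds_score_zero(self):
        ds = simulate_observational(p=2, n=30, seed=1)
        fa = random_folds(30, 3, 2)
        calls = {"n": 0}

        def flaky(a, b, d):
            calls["n"] += 1
            if calls["n"] == 1:
                raise RuntimeError("boom")
            return fit_ols(a, b)

        r2_flaky = cv_r_squared(flaky, ds, fa)
        assert np.isfinite(r2_flaky)

    def test_all_folds_failing_raises(self):
        ds = simulate_observational(p=2, n=30, seed=1)
        fa = random_folds(30, 3, 2)

        def broken(a, b, d):
            raise RuntimeError("boom")

        with pytest.raises(RuntimeError):
            cv_r_squared(broken, ds, fa)


class TestMoransI:
    def test_matches_brute_force(self, rng):
        for n in (5, 12, 20):
            d = sample_locations(10, n, n)
            z = rng.standard_normal(n)
            assert morans_i(z, d) == pytest.approx(
                brute_force_morans_i(z, d.coords), abs=1e-10)

    def test_gradient_is_positive(self, grid5):
        assert morans_i(grid5.coords[:, 0], grid5) > 0

    def test_alternation_is_negative(self):
        g = full_grid(4)
        z = (-1.0) ** (g.coords.sum(axis=1))
        assert morans_i(z, g) < 0

    def test_permutation_mean_identity(self, grid5, rng):
        """Mean of Moran's I over random relabelings equals the
        classical null expectation -1/(n-1)."""
        z = rng.standard_normal(grid5.n)
        vals = [morans_i(z[rng.permutation(grid5.n)], grid5) for _ in range(3000)]
        n = grid5.n
        se = np.std(vals, ddof=1) / np.sqrt(len(vals))
        assert np.mean(vals) == pytest.approx(-1 / (n - 1), abs=4 * se)

    def test_constant_input_rejected(self, grid5):
        with pytest.raises(ValueError):
            morans_i(np.ones(grid5.n), grid5)

    def test_conditional_requires_predictions(self, grid5, rng):
        with pytest.raises(ValueError):
            morans_i(rng.standard_normal(grid5.n), grid5, kind="conditional")


class TestAdjustedMoransI:
    def test_null_mean_near_zero(self, rng):
        vals = []
        for s in range(400):
            d = sample_locations(15, 30, s)
            vals.append(adjusted_morans_i(rng.standard_normal(30), d))
        se = np.std(vals, ddof=1) / np.sqrt(len(vals))
        assert abs(np.mean(vals)) < 3 * se + 1e-3

    def test_comparable_across_sample_sizes(self, rng):
        """White noise at n=10 and n=100 both average near zero after
        the expectation adjustment — the point of the correction."""
        for n in (10, 100):
            vals = []
            for s in range(300):
                d = sample_locations(15, n, 1000 + s)
                vals.append(adjusted_morans_i(rng.standard_normal(n), d))
            assert abs(np.mean(vals)) < 0.02

    def test_offset_identity(self, grid5, rng):
        z = rng.standard_normal(grid5.n)
        raw = morans_i(z, grid5)
        assert adjusted_morans_i(z, grid5) == pytest.approx(
            raw + 1 / (grid5.n - 1))

    def test_overfitting_signature(self):
        """OLS training residuals look spatially clean even when the
        outcome carries structure, while residuals on a fresh spatial
        test set remain autocorrelated."""
        from fieldspat.datasets import simulate_test_set
        train_i, test_i = [], []
        for s in range(100):
            ds = simulate_observational(
                p=50, n=100, outcome_spec=ScenarioSpec.gauss_cor(tau=0.1),
                regressor_spec=ScenarioSpec.gauss_cor(tau=0.1), seed=s, beta_sd=1.0)
            fit = fit_ols(ds.A, ds.B)
            train_i.append(adjusted_morans_i(ds.A, ds.design, "conditional",
                                             fit.predict(ds.B)))
            ts = simulate_test_set(ds.truth, "spatial", seed=10_000 + s)
            test_i.append(adjusted_morans_i(ts.A, ts.design, "conditional",
                                            fit.predict(ts.B)))
        assert np.mean(test_i) > np.mean(train_i)
        assert np.mean(test_i) > 0.05
        assert abs(np.mean(train_i)) < 0.05


class TestSelectionMetrics:
    def _truth(self, beta, flags):
        from fieldspat.datasets import TrueModel
        return TrueModel(np.asarray(beta, float), np.asarray(flags, bool),
                         ScenarioSpec.none(), ScenarioSpec.none())

    def test_perfect_selection(self):
        t = self._truth([1, 0, 2, 0], [True, False, True, False])
        sens, tdp, sp = selection_metrics([0, 2], t)
        assert (sens, tdp) == (1.0, 1.0)

    def test_select_everything(self):
        beta = np.zeros(50)
        beta[:10] = 1.0
        t = self._truth(beta, [True] * 25 + [False] * 25)
        sens, tdp, sp = selection_metrics(range(50), t)
        assert sens == 1.0 and tdp == pytest.approx(0.2)
        assert sp == pytest.approx(0.5)

    def test_spatial_proportion(self):
        t = self._truth([1, 1, 1, 1], [True, True, True, False])
        _, _, sp = selection_metrics([0, 1, 2, 3], t)
        assert sp == pytest.approx(0.75)

    def test_empty_selection_markers(self):
        t = self._truth([1, 0], [True, False])
        sens, tdp, sp = selection_metrics([], t)
        assert sens == 0.0
        assert np.isnan(tdp) and np.isnan(sp)

    def test_out_of_range_rejected(self):
        t = self._truth([1, 0], [True, False])
        with pytest.raises(IndexError):
            selection_metrics([5], t)


class TestBetaMse:
    def test_exact_recovery_scores_zero(self):
        assert beta_mse([1.0, 2.0], [1.0, 2.0]) == 0.0

    def test_hand_example(self):
        # errors (1, -2, 0) -> (1+4+0)/3
        assert beta_mse([2.0, 0.0, 3.0], [1.0, 2.0, 3.0]) == pytest.approx(5 / 3)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            beta_mse([1.0], [1.0, 2.0])
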
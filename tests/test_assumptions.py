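"""Polychoric correlations, one-factor/bifactor dimensionality checks,
local independence, and Mokken scalability."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import linprog
from scipy.stats import multivariate_normal

from irtval.factor import (
    BifactorModel,
    OneFactorModel,
    check_local_independence,
    fit_bifactor,
    fit_one_factor,
)
from irtval.mokken import MokkenScale, max_covariance, mokken_h
from irtval.polychoric import (
    bivariate_normal_cdf,
    polychoric_matrix,
    smooth_psd,
)


def discretize(z, cuts=(-1.0, -0.2, 0.6, 1.3)):
    return np.digitize(z, cuts) + 1


class TestPolychoric:
    def test_diagonal_is_one_and_matrix_symmetric(self):
        rng = np.random.default_rng(0)
        z = rng.multivariate_normal([0, 0, 0], np.eye(3) * 0.5 + 0.5, size=800)
        res = polychoric_matrix(pd.DataFrame(
            {f"v{i}": discretize(z[:, i]) for i in range(3)}))
        R = res.correlations.to_numpy()
        np.testing.assert_allclose(np.diag(R), 1.0)
        np.testing.assert_allclose(R, R.T)

    def test_recovers_known_latent_correlation(self):
        rng = np.random.default_rng(1)
        z = rng.multivariate_normal([0, 0], [[1, 0.6], [0.6, 1]], size=5000)
        res = polychoric_matrix(pd.DataFrame(
            {"a": discretize(z[:, 0]), "b": discretize(z[:, 1])}))
        assert res.correlations.iloc[0, 1] == pytest.approx(0.6, abs=0.05)

    def test_independent_items_near_zero(self):
        rng = np.random.default_rng(2)
        res = polychoric_matrix(pd.DataFrame(
            {"a": discretize(rng.normal(size=5000)),
             "b": discretize(rng.normal(size=5000))}))
        assert abs(res.correlations.iloc[0, 1]) < 0.05

    def test_single_category_item_rejected(self):
        with pytest.raises(ValueError, match="single observed category"):
            polychoric_matrix(pd.DataFrame({"a": [1, 2, 3] * 10,
                                            "flat": [2] * 30}))

    def test_bvn_cdf_matches_scipy(self):
        """Dual-route check of the Gauss-Legendre Plackett integration."""
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(10, 2))
        for rho in (-0.85, -0.3, 0.0, 0.45, 0.95):
            ours = bivariate_normal_cdf(pts[:, 0], pts[:, 1], rho)
            mvn = multivariate_normal(mean=[0, 0], cov=[[1, rho], [rho, 1]])
            ref = np.array([mvn.cdf(p) for p in pts])
            np.testing.assert_allclose(ours, ref, atol=1e-10)

    def test_psd_smoothing_preserves_offdiagonal_order(self):
        R = np.array([
            [1.0, 0.95, 0.10],
            [0.95, 1.0, 0.93],
            [0.10, 0.93, 1.0],
        ])  # indefinite
        assert np.linalg.eigvalsh(R).min() < 0
        S, smoothed = smooth_psd(R)
        assert smoothed
        assert np.linalg.eigvalsh(S).min() >= 0
        iu = np.triu_indices(3, 1)
        orig, new = R[iu], S[iu]
        for i in range(len(orig)):
            for j in range(len(orig)):
                if orig[i] - orig[j] > 1e-6:
                    assert new[i] > new[j]


class TestOneFactor:
    def test_clean_one_factor_data_meets_all_criteria(self, assumption_runs):
        run = assumption_runs[0]
        idx = run["indices"]
        assert idx.cfi > 0.95 and idx.tli > 0.95
        assert idx.rmsea < 0.08 and idx.srmr < 0.10
        assert run["flags"] == []

    def test_three_items_are_just_identified(self):
        rng = np.random.default_rng(4)
        g = rng.normal(size=1500)
        df = pd.DataFrame({
            f"v{i}": discretize(0.7 * g + 0.71 * rng.normal(size=1500))
            for i in range(3)
        })
        m = OneFactorModel().fit(df)
        assert m.indices_.df == 0
        assert m.indices_.cfi == pytest.approx(1.0)

    def test_two_factor_structure_fails_rmsea(self):
        rng = np.random.default_rng(5)
        z = rng.multivariate_normal([0, 0], [[1, 0.3], [0.3, 1]], size=2000)
        df = pd.DataFrame({
            f"v{i}": discretize(0.8 * z[:, 0 if i < 5 else 1]
                                + 0.6 * rng.normal(size=2000))
            for i in range(10)
        })
        indices, _, _ = fit_one_factor(df)
        assert indices.rmsea > 0.08

    def test_local_independence_false_positive_rate(self, assumption_runs):
        """Under a true one-factor model, flagged pairs stay below 5%."""
        total_flags = sum(len(r["flags"]) for r in assumption_runs)
        total_pairs = sum(r["n_pairs"] for r in assumption_runs)
        assert total_flags / total_pairs < 0.05


class TestLocalIndependence:
    def test_zero_residuals_give_no_flags(self):
        res = pd.DataFrame(np.zeros((4, 4)), columns=list("abcd"),
                           index=list("abcd"))
        assert check_local_independence(res) == []

    def test_threshold_is_inclusive_at_point_two(self):
        res = pd.DataFrame(np.zeros((3, 3)), columns=list("abc"),
                           index=list("abc"))
        res.loc["a", "b"] = res.loc["b", "a"] = 0.19
        assert check_local_independence(res) == []
        res.loc["a", "b"] = res.loc["b", "a"] = 0.20
        assert [(a, b) for a, b, _ in check_local_independence(res)] == [("a", "b")]

    def test_injected_doublet_is_flagged(self):
        rng = np.random.default_rng(9)
        n = 2000
        g = rng.normal(size=n)
        nuisance = rng.normal(size=n)
        cols = {}
        for i in range(15):
            extra = 0.7 * nuisance if i < 2 else 0.0
            sd = np.sqrt(max(1 - 0.49 - (0.49 if i < 2 else 0.0), 0.02))
            cols[f"v{i}"] = discretize(0.7 * g + extra + sd * rng.normal(size=n))
        m = OneFactorModel().fit(pd.DataFrame(cols))
        flagged = {(a, b) for a, b, _ in check_local_independence(m.residuals_)}
        assert ("v0", "v1") in flagged


class TestBifactor:
    def make_bifactor_data(self, lam_g=0.7, lam_s=0.3, n=5000, seed=5):
        rng = np.random.default_rng(seed)
        g = rng.normal(size=n)
        spec = rng.normal(size=(n, 3))
        sd = np.sqrt(1 - lam_g**2 - lam_s**2)
        df = pd.DataFrame({
            f"v{i}": discretize(lam_g * g + lam_s * spec[:, i // 5]
                                + sd * rng.normal(size=n))
            for i in range(15)
        })
        assign = {f"f{c}": [f"v{i}" for i in range(c * 5, (c + 1) * 5)]
                  for c in range(3)}
        return df, assign

    def test_recovers_analytic_ecv_confirmatory(self):
        df, assign = self.make_bifactor_data()
        summary = fit_bifactor(df, specific_assignment=assign)
        analytic = 0.7**2 / (0.7**2 + 0.3**2)
        assert summary.ecv == pytest.approx(analytic, abs=0.05)
        assert summary.route == "confirmatory"

    def test_recovers_analytic_ecv_schmid_leiman(self):
        df, _ = self.make_bifactor_data()
        summary = fit_bifactor(df, n_specific=3)
        analytic = 0.7**2 / (0.7**2 + 0.3**2)
        assert summary.ecv == pytest.approx(analytic, abs=0.05)
        assert summary.route == "schmid-leiman"

    def test_zero_specific_loadings_force_ecv_one(self):
        """The ECV formula itself: no specific variance -> ECV = 1."""
        from irtval.factor import bifactor_indices
        g = np.array([0.7, 0.6, 0.8, 0.5])
        omega_h, ecv = bifactor_indices(g, np.zeros((4, 2)))
        assert ecv == 1.0
        assert 0.0 <= omega_h <= 1.0

    def test_one_factor_data_keeps_general_dominant(self):
        """Estimated on truly unidimensional data, the general factor
        dominates (omega_h and ECV clear the conventional criteria) even
        though folded noise keeps estimated ECV below 1."""
        df, assign = self.make_bifactor_data(lam_g=0.75, lam_s=0.01)
        summary = fit_bifactor(df, specific_assignment=assign)
        assert summary.ecv > 0.80
        assert summary.omega_h > 0.90

    def test_criteria_booleans_and_ranges(self):
        df, assign = self.make_bifactor_data()
        s = fit_bifactor(df, specific_assignment=assign)
        assert 0.0 <= s.omega_h <= 1.0 and 0.0 <= s.ecv <= 1.0
        crit = s.meets_criteria()
        assert set(crit) == {"omega_h", "ecv"}
        assert crit["ecv"] == (s.ecv > 0.60)

    def test_underidentified_specific_factor_rejected(self):
        df, assign = self.make_bifactor_data(n=500)
        assign["f0"] = assign["f0"][:1]
        with pytest.raises(ValueError, match="< 2 items"):
            BifactorModel(specific_assignment=assign).fit(df)


class TestMokken:
    def test_perfect_guttman_pattern_scales_at_one(self):
        score = np.repeat(np.arange(10), 30)
        df = pd.DataFrame({
            "a": np.clip(score, 0, 4) + 1,
            "b": np.clip(score - 2, 0, 4) + 1,
            "c": np.clip(score - 4, 0, 4) + 1,
        })
        res = mokken_h(df)
        assert res.scale_h == pytest.approx(1.0, abs=1e-12)

    def test_independent_items_scale_near_zero(self):
        rng = np.random.default_rng(6)
        df = pd.DataFrame({f"v{i}": rng.integers(1, 6, 5000) for i in range(4)})
        res = mokken_h(df)
        assert abs(res.scale_h) < 0.05

    def test_monotone_scale_meets_criteria(self, assumption_runs):
        mok = assumption_runs[0]["mokken"]
        crit = mok.meets_criteria()
        assert crit["items"] and crit["scale"]
        assert (mok.item_h >= 0.30).all()
        assert mok.scale_h >= 0.50

    def test_covariance_ratio_equals_guttman_error_formulation(self):
        """H_ij from cov/cov_max equals 1 - F/E computed directly from
        weighted Guttman errors over category steps."""
        rng = np.random.default_rng(3)
        z = rng.normal(size=400)
        x = discretize(0.9 * z + 0.5 * rng.normal(size=400), (-1, -0.2, 0.6))
        y = discretize(0.9 * z + 0.5 * rng.normal(size=400), (-0.8, 0.1, 0.9))

        def guttman_h(x, y):
            n = len(x)
            steps_x = [(k, np.mean(x >= k)) for k in range(2, x.max() + 1)]
            steps_y = [(k, np.mean(y >= k)) for k in range(2, y.max() + 1)]

            def weight(a, b):
                cnt = 0
                for k1, p1 in steps_x:
                    for k2, p2 in steps_y:
                        if p1 > p2 and a < k1 and b >= k2:
                            cnt += 1
                        if p2 > p1 and b < k2 and a >= k1:
                            cnt += 1
                return cnt

            F = sum(weight(a, b) for a, b in zip(x, y))
            px = np.bincount(x, minlength=x.max() + 1)[1:] / n
            py = np.bincount(y, minlength=y.max() + 1)[1:] / n
            E = n * sum(px[a - 1] * py[b - 1] * weight(a, b)
                        for a in range(1, x.max() + 1)
                        for b in range(1, y.max() + 1))
            return 1 - F / E

        res = mokken_h(pd.DataFrame({"x": x, "y": y}))
        assert res.pairwise_h.iloc[0, 1] == pytest.approx(guttman_h(x, y),
                                                          abs=1e-10)

    def test_max_covariance_matches_linear_program(self):
        """The comonotone-coupling maximum covariance equals the LP
        solution of the Frechet transport problem."""
        rng = np.random.default_rng(7)
        x = rng.integers(1, 5, 200)
        y = rng.integers(1, 6, 200)
        cmax = max_covariance(x.astype(float), y.astype(float))

        px = np.bincount(x, minlength=5)[1:] / len(x)
        py = np.bincount(y, minlength=6)[1:] / len(y)
        prod = np.outer(np.arange(1, 5), np.arange(1, 6)).ravel()
        A_eq, b_eq = [], []
        for a in range(4):
            row = np.zeros(20)
            row[a * 5:(a + 1) * 5] = 1
            A_eq.append(row)
            b_eq.append(px[a])
        for b in range(5):
            row = np.zeros(20)
            row[b::5] = 1
            A_eq.append(row)
            b_eq.append(py[b])
        lp = linprog(-prod, A_eq=np.array(A_eq), b_eq=np.array(b_eq),
                     bounds=(0, None))
        exy_max = -lp.fun
        assert cmax == pytest.approx(
            exy_max - x.mean() * y.mean(), abs=1e-9)

    def test_degenerate_pair_excluded_and_reported(self):
        df = pd.DataFrame({"a": [1, 2, 3, 4] * 10, "b": [2, 2, 2, 3] * 10,
                           "c": [1, 1, 2, 2] * 10})
        df.loc[:, "b"] = 2  # constant -> zero max covariance with anything
        res = MokkenScale().fit(df).result_
        assert ("a", "b") in res.excluded_pairs or ("b", "a") in res.excluded_pairs
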
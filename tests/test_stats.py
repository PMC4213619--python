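"""Residualization, (partial) correlation and the eco/social contrast."""

import numpy as np
import pytest

from oracles import inverse_corr_partial, normal_equation_residuals
from traitrates.stats import (
    combined_table,
    eco_social_test,
    partial_correlation,
    residualize,
    run_comparison,
)

import pandas as pd


class TestResidualize:
    def test_intercept_only_centres(self, rng):
        y = rng.normal(size=20)
        assert np.allclose(residualize(y), y - y.mean(), atol=1e-12)

    def test_exact_linear_fit_gives_zero_residuals(self, rng):
        X = rng.normal(size=(25, 2))
        y = 3.0 + X @ np.array([1.5, -2.0])
        assert np.allclose(residualize(y, X), 0.0, atol=1e-10)

    def test_matches_normal_equations_oracle(self, rng):
        for _ in range(20):
            X = rng.normal(size=(28, 2))
            y = rng.normal(size=28)
            assert np.allclose(
                residualize(y, X), normal_equation_residuals(y, X), atol=1e-10
            )

    def test_residuals_orthogonal_to_design(self, rng):
        X = rng.normal(size=(30, 3))
        res = residualize(rng.normal(size=30), X)
        assert abs(res.sum()) < 1e-8
        assert np.all(np.abs(res @ X) < 1e-8)

    def test_rank_deficiency_rejected(self, rng):
        x = rng.normal(size=20)
        X = np.column_stack([x, 2 * x])
        with pytest.raises(np.linalg.LinAlgError):
            residualize(rng.normal(size=20), X)


class TestPartialCorrelation:
    def test_empty_controls_reduce_to_pearson(self, rng):
        from scipy import stats as sps

        x, y = rng.normal(size=30), rng.normal(size=30)
        r, p = partial_correlation(x, y)
        r0, p0 = sps.pearsonr(x, y)
        assert r == pytest.approx(r0, abs=1e-12)
        assert p == pytest.approx(p0, abs=1e-10)

    def test_self_correlation_is_one(self, rng):
        x = rng.normal(size=28)
        Z = rng.normal(size=(28, 2))
        r, p = partial_correlation(x, x.copy(), Z)
        assert r == pytest.approx(1.0)
        assert p == 0.0

    def test_matches_inverse_correlation_oracle(self, rng):
        for _ in range(20):
            Z = rng.normal(size=(28, 3))
            x = Z @ np.array([1.0, -0.5, 0.2]) + rng.normal(size=28)
            y = Z @ np.array([0.3, 0.8, -1.0]) + rng.normal(size=28)
            r, _ = partial_correlation(x, y, Z)
            assert r == pytest.approx(inverse_corr_partial(x, y, Z), abs=1e-10)

    def test_matches_pingouin(self, rng):
        """Cross-check against an independent implementation."""
        import pingouin as pg

        Z = rng.normal(size=(28, 3))
        x = rng.normal(size=28) + Z[:, 0]
        y = rng.normal(size=28) + Z[:, 0]
        df = pd.DataFrame({"x": x, "y": y, "z1": Z[:, 0], "z2": Z[:, 1], "z3": Z[:, 2]})
        expected = pg.partial_corr(df, x="x", y="y", covar=["z1", "z2", "z3"])
        r, p = partial_correlation(x, y, Z)
        assert r == pytest.approx(float(expected["r"].iloc[0]), abs=1e-10)
        assert p == pytest.approx(float(expected["p_val"].iloc[0]), abs=1e-8)

    def test_symmetry(self, rng):
        x, y = rng.normal(size=20), rng.normal(size=20)
        Z = rng.normal(size=(20, 2))
        assert partial_correlation(x, y, Z) == partial_correlation(y, x, Z)


class TestEcoSocialTest:
    def test_identical_group_means_give_zero(self):
        res = np.array([1.0, -1.0, 2.0, -2.0, 1.0, -1.0, 2.0, -2.0])
        classes = ["eco", "eco", "eco", "eco", "social", "social", "social", "social"]
        out = eco_social_test(res, classes)
        assert out.t == pytest.approx(0.0, abs=1e-12)
        assert out.r2 == pytest.approx(0.0, abs=1e-12)

    def test_swapping_labels_negates_t(self, rng):
        res = rng.normal(size=20)
        classes = np.where(rng.random(20) < 0.4, "eco", "social")
        if (classes == "eco").sum() < 2 or (classes == "social").sum() < 2:
            pytest.skip("degenerate draw")
        a = eco_social_test(res, classes)
        swapped = np.where(classes == "eco", "social", "eco")
        b = eco_social_test(res, swapped)
        assert b.t == pytest.approx(-a.t)
        assert b.p == pytest.approx(a.p)
        assert b.r2 == pytest.approx(a.r2)

    def test_r2_identity_with_t(self, rng):
        """For a binary predictor, R^2 = t^2 / (t^2 + df) exactly."""
        for _ in range(20):
            res = rng.normal(size=28)
            classes = np.array(["eco"] * 10 + ["social"] * 18)
            out = eco_social_test(res, classes)
            assert out.df == 26
            assert out.r2 == pytest.approx(
                out.t**2 / (out.t**2 + out.df), abs=1e-10
            )

    def test_positive_t_means_social_faster(self):
        res = np.array([-1.0, -1.1, -0.9, -1.0, 1.0, 1.1, 0.9, 1.0])
        classes = ["eco"] * 4 + ["social"] * 4
        assert eco_social_test(res, classes).t > 0


def _summary(rng, n=16, counts=None, family="A"):
    counts = rng.uniform(1, 50, size=n) if counts is None else counts
    return pd.DataFrame(
        {
            "family": family,
            "variable": [f"v{i}" for i in range(n)],
            "class": ["eco"] * (n // 2) + ["social"] * (n - n // 2),
            "cats": rng.integers(2, 10, size=n),
            "N": rng.integers(40, 100, size=n),
            "pars": counts,
            "scm": counts * rng.uniform(1.0, 1.3, size=n),
        }
    )


class TestRunComparison:
    def test_identical_families_correlate_perfectly(self, rng):
        a = _summary(rng)
        b = a.copy()
        b["family"] = "B"
        res = run_comparison(a, b)
        assert res.pearson_r == pytest.approx(1.0)
        assert res.partial_r == pytest.approx(1.0)
        assert res.spearman_rho == pytest.approx(1.0)

    def test_variable_set_mismatch_rejected(self, rng):
        a = _summary(rng)
        b = _summary(rng)
        b.loc[0, "variable"] = "other"
        with pytest.raises(ValueError, match="different variable sets"):
            run_comparison(a, b)

    def test_row_order_invariance(self, rng):
        a = _summary(rng)
        b = _summary(rng, counts=a["pars"].to_numpy() + rng.normal(size=16))
        b[["cats", "class"]] = a[["cats", "class"]]
        r1 = run_comparison(a, b)
        shuffled = b.sample(frac=1.0, random_state=5).reset_index(drop=True)
        r2 = run_comparison(a, shuffled)
        assert r2.partial_r == pytest.approx(r1.partial_r, abs=1e-12)
        assert r2.spearman_rho == pytest.approx(r1.spearman_rho, abs=1e-12)
        for fam in r1.eco_social:
            assert r2.eco_social[fam].t == pytest.approx(
                r1.eco_social[fam].t, abs=1e-12
            )

    def test_combined_table_sorted_by_first_family_residual(self, rng):
        a = _summary(rng)
        b = _summary(rng, counts=a["pars"].to_numpy() * 1.1)
        b[["cats", "class"]] = a[["cats", "class"]]
        table = combined_table(a, b)
        res = table["res_A"].to_numpy()
        assert np.all(np.diff(res) >= 0)
        # residuals of an OLS fit with intercept sum to ~0 per family
        assert abs(res.sum()) < 1e-8
        assert abs(table["res_B"].sum()) < 1e-8

    def test_nonparametric_mirror_runs(self, rng):
        a = _summary(rng)
        b = _summary(rng, counts=a["pars"].to_numpy() + rng.normal(size=16))
        b[["cats", "class"]] = a[["cats", "class"]]
        res = run_comparison(a, b, nonparametric=True)
        assert -1 <= res.partial_r <= 1
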
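"""Cross-family comparison of relative evolutionary rates.

Given per-trait mean change counts in two independent families of
societies, the question is whether the traits that change most in one
family are also the ones that change most in the other.  Raw counts are
confounded by two bookkeeping artefacts: traits coded for more societies
admit more changes (larger effective tree), and traits divided into more
database categories admit more observable changes.  Both are controlled
in two ways, mirroring standard practice:

* *partial correlation* between the two families' counts, controlling
  jointly for each family's per-trait sample size and the shared
  category count; and
* *residualization*: per-family OLS of counts on (N, Cats), whose
  unstandardized residuals are the per-trait "relative rate" values used
  for the ecological-vs-social contrast and for ranked presentation.

The ecological/social contrast is a pooled-variance two-sample t-test on
the residuals (df = n_traits - 2), with effect size reported as the R^2
of a regression of residuals on the binary class indicator; for a binary
predictor R^2 = t^2 / (t^2 + df) exactly, which the test suite asserts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "residualize",
    "partial_correlation",
    "eco_social_test",
    "EcoSocialResult",
    "ComparisonResult",
    "run_comparison",
    "combined_table",
]


def _design(X: np.ndarray | None, n: int) -> np.ndarray:
    cols = [np.ones(n)]
    if X is not None:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if X.shape[0] != n:
            raise ValueError(f"covariate rows {X.shape[0]} != len(y) {n}")
        cols.append(X)
    return np.column_stack(cols)


def residualize(y: Sequence[float], X: np.ndarray | None = None) -> np.ndarray:
    """OLS residuals of ``y`` on ``X`` plus an intercept.

    Residuals sum to zero and are orthogonal to every covariate column.
    ``X=None`` (intercept only) centres ``y``.  Raises on a rank-deficient
    design, which would make the residuals non-unique.
    """
    y = np.asarray(y, dtype=float)
    D = _design(X, len(y))
    if np.linalg.matrix_rank(D) < D.shape[1]:
        raise np.linalg.LinAlgError("rank-deficient covariate matrix")
    beta, *_ = np.linalg.lstsq(D, y, rcond=None)
    return y - D @ beta


def _pearson_with_df(x: np.ndarray, y: np.ndarray, df: int) -> tuple[float, float]:
    sx, sy = np.std(x), np.std(y)
    if sx == 0.0 or sy == 0.0:
        raise ValueError("degenerate (zero-variance) input to correlation")
    r = float(np.corrcoef(x, y)[0, 1])
    r = max(-1.0, min(1.0, r))
    if df <= 0:
        return r, float("nan")
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt(df / (1.0 - r * r))
    p = 2.0 * float(sps.t.sf(abs(t), df))
    return r, p


def partial_correlation(
    x: Sequence[float],
    y: Sequence[float],
    Z: np.ndarray | None = None,
) -> tuple[float, float]:
    """Partial Pearson correlation of ``x`` and ``y`` given covariates ``Z``.

    Both variables are residualized on ``Z`` (with intercept) and the
    residuals correlated; the two-tailed p-value uses
    ``df = n - q - 2`` where ``q`` is the number of covariates.  With an
    empty ``Z`` this reduces to the plain Pearson correlation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    q = 0
    if Z is not None:
        Zarr = np.asarray(Z, dtype=float)
        q = 1 if Zarr.ndim == 1 else Zarr.shape[1]
    if len(x) <= q + 2:
        raise ValueError("too few observations for the covariate set")
    rx = residualize(x, Z)
    ry = residualize(y, Z)
    return _pearson_with_df(rx, ry, df=len(x) - q - 2)


@dataclass(frozen=True)
class EcoSocialResult:
    t: float
    df: int
    p: float
    r2: float


def eco_social_test(
    residuals: Sequence[float],
    classes: Sequence[str],
    welch: bool = False,
) -> EcoSocialResult:
    """Two-sample t-test of residual rates between trait classes.

    Sign convention: positive ``t`` means the social mean exceeds the
    ecological mean.  Default is the pooled-variance test with
    ``df = n - 2``; ``welch=True`` switches to unequal variances.  ``r2``
    is the variance in residuals explained by the binary class indicator
    (the squared point-biserial correlation).
    """
    residuals = np.asarray(residuals, dtype=float)
    classes = np.asarray(classes)
    eco = residuals[classes == "eco"]
    social = residuals[classes == "social"]
    if len(eco) < 2 or len(social) < 2:
        raise ValueError("each class needs at least two members")
    res = sps.ttest_ind(social, eco, equal_var=not welch)
    df = len(residuals) - 2 if not welch else float(res.df)
    indicator = (classes == "social").astype(float)
    r2 = float(np.corrcoef(residuals, indicator)[0, 1] ** 2)
    return EcoSocialResult(t=float(res.statistic), df=df, p=float(res.pvalue), r2=r2)


@dataclass
class ComparisonResult:
    """Every statistic of one cross-family comparison.

    ``method`` records which change-count estimator ("pars" or "scm")
    fed the cross-family correlations.  Family-keyed fields are dicts
    keyed by family label.
    """

    method: str
    n_variables: int
    pearson_r: float
    pearson_p: float
    spearman_rho: float
    spearman_p: float
    partial_r: float
    partial_p: float
    residual_r2: float  # R^2 of the family-B residuals on family-A residuals
    mp_scm_rho: dict[str, float] = field(default_factory=dict)
    mp_scm_p: dict[str, float] = field(default_factory=dict)
    eco_social: dict[str, EcoSocialResult] = field(default_factory=dict)

    def to_dict(self) -> dict[str, float]:
        out = {
            "method": self.method,
            "n_variables": self.n_variables,
            "pearson_r": self.pearson_r,
            "pearson_p": self.pearson_p,
            "spearman_rho": self.spearman_rho,
            "spearman_p": self.spearman_p,
            "partial_r": self.partial_r,
            "partial_p": self.partial_p,
            "residual_r2": self.residual_r2,
        }
        for fam, rho in self.mp_scm_rho.items():
            out[f"mp_scm_rho_{fam}"] = rho
            out[f"mp_scm_p_{fam}"] = self.mp_scm_p[fam]
        for fam, es in self.eco_social.items():
            out[f"eco_social_t_{fam}"] = es.t
            out[f"eco_social_df_{fam}"] = es.df
            out[f"eco_social_p_{fam}"] = es.p
            out[f"eco_social_r2_{fam}"] = es.r2
        return out


def _drop_redundant_columns(Z: np.ndarray) -> np.ndarray:
    """Keep only covariate columns that raise the design-matrix rank."""
    n = Z.shape[0]
    kept: list[np.ndarray] = []
    base = np.ones((n, 1))
    for j in range(Z.shape[1]):
        candidate = np.column_stack([base, *kept, Z[:, j]])
        if np.linalg.matrix_rank(candidate) == candidate.shape[1]:
            kept.append(Z[:, j])
    return np.column_stack(kept) if kept else np.empty((n, 0))


_REQUIRED_COLUMNS = {"variable", "class", "cats", "N"}


def _check_summary(df: pd.DataFrame, method: str) -> pd.DataFrame:
    missing = (_REQUIRED_COLUMNS | {method}) - set(df.columns)
    if missing:
        raise ValueError(f"summary table missing columns {sorted(missing)}")
    df = df.dropna(subset=[method]).copy()
    return df.set_index("variable", drop=False)


def run_comparison(
    summary_a: pd.DataFrame,
    summary_b: pd.DataFrame,
    method: str = "pars",
    family_labels: tuple[str, str] = ("A", "B"),
    welch: bool = False,
    nonparametric: bool = False,
) -> ComparisonResult:
    """Full cross-family statistics from two per-family summary tables.

    Each table needs columns ``variable, class, cats, N`` and the count
    column named by ``method`` (``"pars"`` or ``"scm"``); a ``pars`` and
    ``scm`` pair present in both tables additionally yields the
    per-family MP-vs-SCM rank correlation.  The two tables must cover the
    same variables; ``cats`` and ``class`` are shared properties of a
    variable and must agree.  ``nonparametric=True`` rank-transforms the
    counts and covariates before every parametric step (a Spearman-style
    mirror of the whole analysis).
    """
    a = _check_summary(summary_a, method)
    b = _check_summary(summary_b, method)
    if set(a.index) != set(b.index):
        raise ValueError("families cover different variable sets")
    b = b.loc[a.index]
    if not (a["cats"].values == b["cats"].values).all():
        raise ValueError("category counts disagree between families")
    if not (a["class"].values == b["class"].values).all():
        raise ValueError("class labels disagree between families")
    n = len(a)
    if n < 10:
        import warnings

        warnings.warn(f"only {n} variables; statistics will be unstable")

    ya = a[method].to_numpy(dtype=float)
    yb = b[method].to_numpy(dtype=float)
    na = a["N"].to_numpy(dtype=float)
    nb = b["N"].to_numpy(dtype=float)
    cats = a["cats"].to_numpy(dtype=float)
    if nonparametric:
        ya, yb, na, nb, cats = (sps.rankdata(v) for v in (ya, yb, na, nb, cats))

    pearson_r, pearson_p = _pearson_with_df(ya, yb, df=n - 2)
    rho, rho_p = sps.spearmanr(ya, yb)
    # Cats enters the control set once: it is a property of the variable,
    # identical across families, and duplicating it would be rank-deficient.
    # Degenerate inputs (e.g. N identical across families) can still make
    # controls collinear; redundant columns are dropped, not fatal.
    Z = _drop_redundant_columns(np.column_stack([na, nb, cats]))
    partial_r, partial_p = partial_correlation(ya, yb, Z)

    res_a = residualize(ya, np.column_stack([na, cats]))
    res_b = residualize(yb, np.column_stack([nb, cats]))
    r_res = float(np.corrcoef(res_a, res_b)[0, 1])

    result = ComparisonResult(
        method=method,
        n_variables=n,
        pearson_r=pearson_r,
        pearson_p=pearson_p,
        spearman_rho=float(rho),
        spearman_p=float(rho_p),
        partial_r=partial_r,
        partial_p=partial_p,
        residual_r2=r_res ** 2,
    )

    classes = a["class"].to_numpy()
    for fam, res in zip(family_labels, (res_a, res_b)):
        result.eco_social[fam] = eco_social_test(res, classes, welch=welch)

    if "pars" in a.columns and "scm" in a.columns and "pars" in b.columns:
        for fam, df_ in zip(family_labels, (a, b)):
            if df_["scm"].notna().all():
                r, p = sps.spearmanr(
                    df_["pars"].to_numpy(float), df_["scm"].to_numpy(float)
                )
                result.mp_scm_rho[fam] = float(r)
                result.mp_scm_p[fam] = float(p)
    return result


def combined_table(
    summary_a: pd.DataFrame,
    summary_b: pd.DataFrame,
    method: str = "pars",
    family_labels: tuple[str, str] = ("A", "B"),
) -> pd.DataFrame:
    """One row per variable with both families' N/Pars/SCM/Res columns.

    The residual column is the per-family OLS residual of the ``method``
    counts on (N, Cats).  Rows are sorted by increasing family-A residual,
    i.e. from the slowest- to the fastest-evolving trait after controls.
    """
    a = _check_summary(summary_a, method)
    b = _check_summary(summary_b, method).loc[a.index]
    out = pd.DataFrame(
        {
            "variable": a["variable"].values,
            "description": a.get("description", pd.Series("", index=a.index)).values,
            "cats": a["cats"].values,
            "class": a["class"].values,
        }
    )
    for fam, df_ in zip(family_labels, (a, b)):
        res = residualize(
            df_[method].to_numpy(float),
            np.column_stack([df_["N"].to_numpy(float), df_["cats"].to_numpy(float)]),
        )
        out[f"N_{fam}"] = df_["N"].values
        out[f"pars_{fam}"] = df_.get("pars", pd.Series(np.nan, index=df_.index)).values
        out[f"scm_{fam}"] = df_.get("scm", pd.Series(np.nan, index=df_.index)).values
        out[f"res_{fam}"] = res
    return out.sort_values(f"res_{family_labels[0]}").reset_index(drop=True)
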
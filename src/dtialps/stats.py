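"""Group-difference and correlation statistics for the cohort analysis.

The analysis protocol: adjust each imaging feature for gender, age,
education and white-matter-hyperintensity burden by OLS residualization,
test for differences along the NC -> MCI -> AD continuum with a one-way
ANOVA plus Tukey HSD post-hoc, relate features to cognitive-scale scores
by covariate-adjusted partial correlation, and control multiplicity with
the Benjamini-Hochberg FDR within each scale family.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "residualize",
    "anova_oneway",
    "AnovaResult",
    "partial_correlation",
    "PartialCorrelationResult",
    "bh_fdr",
    "run_correlation_program",
    "significance_stars",
    "DEFAULT_COVARIATES",
    "DOMAIN_GENERAL_SCALES",
    "DOMAIN_SPECIFIC_SCALES",
    "encode_covariates",
]

DEFAULT_COVARIATES = ("gender", "age", "education", "WMH")
DOMAIN_GENERAL_SCALES = ("MoCA-B", "MMSE", "IADL")
DOMAIN_SPECIFIC_SCALES = (
    "HVLT1", "HVLT2", "HVLT3", "WMS", "TMT-A", "TMT-B",
    "ROCFT1", "ROCFT2", "VFT", "BNT",
)


def significance_stars(p: float) -> str:
    """Figure-style star codes: * p<0.05, ** p<0.01, *** p<0.001."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def encode_covariates(cohort: pd.DataFrame, covariates=DEFAULT_COVARIATES) -> np.ndarray:
    """Numeric covariate design from cohort columns.

    Gender becomes a 0/1 indicator (female = 1); WMH enters as a numeric
    score. No intercept column (added where needed).
    """
    cols = []
    for name in covariates:
        col = cohort[name]
        if name == "gender":
            cols.append((col.astype(str) == "F").astype(float).to_numpy())
        elif name == "group":
            # dummy-code against the first observed level
            levels = list(pd.unique(col.astype(str)))
            for lv in levels[1:]:
                cols.append((col.astype(str) == lv).astype(float).to_numpy())
        else:
            cols.append(col.astype(float).to_numpy())
    return np.column_stack(cols) if cols else np.empty((len(cohort), 0))


def _design_with_intercept(covariate_design: np.ndarray | None, n: int) -> np.ndarray:
    if covariate_design is None:
        return np.ones((n, 1))
    cov = np.atleast_2d(np.asarray(covariate_design, dtype=float))
    if cov.shape[0] != n:
        raise ValueError("covariate design rows must match values length")
    return np.column_stack([np.ones(n), cov])


def residualize(values, covariate_design) -> np.ndarray:
    """OLS residuals of ``values`` on [intercept, covariates].

    Residuals have zero mean (to numerical precision) and are orthogonal
    to every covariate column.
    """
    y = np.asarray(values, dtype=float).ravel()
    X = _design_with_intercept(covariate_design, y.shape[0])
    if y.shape[0] <= X.shape[1]:
        raise ValueError(
            f"need n > number of covariates + 1 (n={y.shape[0]}, design cols={X.shape[1]})"
        )
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient covariate design")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


@dataclass
class AnovaResult:
    f: float
    p: float
    df_between: int
    df_within: int
    posthoc: pd.DataFrame  # pairwise Tukey HSD: group1, group2, mean_diff, p_adj, stars


def anova_oneway(values, groups) -> AnovaResult:
    """One-way ANOVA across group labels with Tukey HSD post-hoc.

    ``values`` are typically covariate-adjusted residuals (see
    :func:`residualize`); testing proceeds on whatever is passed in.
    """
    y = np.asarray(values, dtype=float).ravel()
    g = np.asarray(groups)
    if y.shape[0] != g.shape[0]:
        raise ValueError("values and groups length mismatch")
    levels = list(pd.unique(g))
    if len(levels) < 2:
        raise ValueError("need at least 2 groups")
    samples = [y[g == lv] for lv in levels]
    for lv, s in zip(levels, samples):
        if s.shape[0] < 2:
            raise ValueError(f"group {lv!r} has fewer than 2 subjects")
    if all(np.allclose(s.var(ddof=1), 0) for s in samples):
        raise ValueError("zero within-group variance: F undefined")
    f, p = sps.f_oneway(*samples)

    tukey = sps.tukey_hsd(*samples)
    rows = []
    for i in range(len(levels)):
        for j in range(i + 1, len(levels)):
            p_adj = float(tukey.pvalue[i, j])
            rows.append({
                "group1": str(levels[i]),
                "group2": str(levels[j]),
                "mean_diff": float(samples[i].mean() - samples[j].mean()),
                "p_adj": p_adj,
                "stars": significance_stars(p_adj),
            })
    return AnovaResult(
        f=float(f), p=float(p),
        df_between=len(levels) - 1,
        df_within=y.shape[0] - len(levels),
        posthoc=pd.DataFrame(rows),
    )


@dataclass
class PartialCorrelationResult:
    feature: str
    scale: str
    r: float
    p: float
    n: int
    covariates: tuple[str, ...]
    q: float | None = None  # BH-FDR adjusted, filled by the grid runner


def partial_correlation(x, y, covariate_design=None) -> tuple[float, float, int]:
    """Partial Pearson correlation controlling for covariates: (r, p, n).

    Both variables are residualized on [intercept, covariates]; r is the
    Pearson correlation of the residuals and p comes from
    t = r * sqrt((n - 2 - k) / (1 - r^2)) with df = n - 2 - k.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if covariate_design is None:
        cov = None
        k = 0
    else:
        cov = np.atleast_2d(np.asarray(covariate_design, dtype=float))
        k = cov.shape[1]
    n = x.shape[0]
    if n <= k + 2:
        raise ValueError(f"need n > k + 2 (n={n}, k={k})")
    rx = residualize(x, cov)
    ry = residualize(y, cov)
    sx, sy = rx.std(), ry.std()
    if sx == 0 or sy == 0:
        raise ValueError("constant residuals: correlation undefined")
    r = float(np.clip((rx * ry).mean() / (sx * sy), -1.0, 1.0))
    df = n - 2 - k
    if abs(r) == 1.0:
        return r, 0.0, n
    t = r * np.sqrt(df / (1.0 - r**2))
    p = float(2.0 * sps.t.sf(abs(t), df))
    return r, p, n


def bh_fdr(pvalues, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: (q-values, rejected-at-alpha), input order."""
    p = np.asarray(pvalues, dtype=float).ravel()
    if p.size == 0:
        raise ValueError("need at least one p-value")
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return q, q <= alpha


def run_correlation_program(
    cohort: pd.DataFrame,
    features=("L_ALPS", "R_ALPS", "Bi_ALPS"),
    scales=DOMAIN_GENERAL_SCALES,
    covariates=DEFAULT_COVARIATES,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Partial-correlation grid of features x scales with BH-FDR over the grid.

    Missing values are handled by pairwise deletion per (feature, scale)
    cell; the effective n is reported per cell. All cells in the supplied
    grid form one FDR family (run domain-general and domain-specific scale
    families separately to correct them separately).
    """
    for col in (*features, *scales):
        if col not in cohort.columns:
            raise ValueError(f"missing column {col!r}")
    results: list[PartialCorrelationResult] = []
    for feat in features:
        for scale in scales:
            sub = cohort[[feat, scale, *covariates]].dropna()
            if len(sub) == 0:
                raise ValueError(f"scale {scale!r} has no complete observations")
            cov = encode_covariates(sub, covariates)
            r, p, n = partial_correlation(sub[feat], sub[scale], cov)
            results.append(PartialCorrelationResult(
                feature=feat, scale=scale, r=r, p=p, n=n,
                covariates=tuple(covariates),
            ))
    q, _ = bh_fdr([res.p for res in results], alpha=alpha)
    for res, qi in zip(results, q):
        res.q = float(qi)
    df = pd.DataFrame([{
        "feature": res.feature, "scale": res.scale, "r": res.r,
        "p": res.p, "q": res.q, "n": res.n,
        "significant": res.q <= alpha,
        "stars": significance_stars(res.q),
    } for res in results])
    return df.sort_values(["feature", "scale"], kind="stable").reset_index(drop=True)
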
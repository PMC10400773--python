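"""Scanner/batch harmonization (ComBat) and test-retest stability metrics.

ComBat models each feature as grand mean + covariate effects + additive
batch shift + multiplicative batch scaling of the residual, and shrinks the
per-batch location/scale estimates across features with parametric
empirical-Bayes priors (normal on location, inverse-gamma on scale) before
removing them. Biological covariate effects are re-added after adjustment.

Stability of a feature measured under two scanning protocols is summarized
by the intraclass correlation coefficient and a paired t test.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "ComBatModel",
    "ComBatHarmonizer",
    "combat_harmonize",
    "icc",
    "paired_t",
    "StabilityResult",
    "stability_analysis",
]


class HarmonizationWarning(UserWarning):
    pass


@dataclass
class ComBatModel:
    """Fitted ComBat parameters, serializable for audit."""

    batches: list[str]
    n_per_batch: dict[str, int]
    grand_mean: list[float]  # alpha-hat per feature
    beta_cov: list[list[float]]  # covariate coefficients (n_cov x n_features)
    var_pooled: list[float]
    gamma_star: dict[str, list[float]]  # EB-shrunk location per batch
    delta_sq_star: dict[str, list[float]]  # EB-shrunk squared scale per batch
    gamma_bar: dict[str, float]
    tau_sq: dict[str, float]
    a_prior: dict[str, float]
    b_prior: dict[str, float]
    eb: bool
    degenerate: bool = False  # single batch: pass-through

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)


def _it_sol(z, gamma_hat, delta_hat_sq, gamma_bar, tau_sq, a, b, tol=1e-4, max_iter=100):
    """Iterative conditional EB updates for one batch (all features at once)."""
    n = z.shape[0]
    gamma = gamma_hat.copy()
    delta_sq = delta_hat_sq.copy()
    for _ in range(max_iter):
        gamma_new = (n * tau_sq * gamma_hat + delta_sq * gamma_bar) / (n * tau_sq + delta_sq)
        ss = ((z - gamma_new) ** 2).sum(axis=0)
        delta_new = (0.5 * ss + b) / (n / 2.0 + a - 1.0)
        change = max(
            np.max(np.abs(gamma_new - gamma)),
            np.max(np.abs(delta_new - delta_sq)),
        )
        gamma, delta_sq = gamma_new, delta_new
        if change < tol:
            break
    return gamma, delta_sq


class ComBatHarmonizer(BaseEstimator, TransformerMixin):
    """Empirical-Bayes batch-effect removal, scikit-learn transformer style.

    Parameters
    ----------
    eb : bool
        Shrink per-batch location/scale across features with parametric
        priors. Automatically disabled when only one feature is supplied
        (the across-feature priors are then undefined).
    tol, max_iter : float, int
        Convergence control of the iterative EB updates.

    Fitted attributes end in an underscore; `fit`/`transform` accept the
    batch labels and an optional covariate design alongside ``X``.
    """

    def __init__(self, eb: bool = True, tol: float = 1e-4, max_iter: int = 100):
        self.eb = eb
        self.tol = tol
        self.max_iter = max_iter

    # -- helpers ----------------------------------------------------------
    @staticmethod
    def _validate(X, batch, covariates):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.ndim != 2:
            raise ValueError("X must be 2-D (subjects x features)")
        batch = np.asarray(batch)
        if batch.shape[0] != X.shape[0]:
            raise ValueError("batch length must match number of subjects")
        if covariates is not None:
            covariates = np.atleast_2d(np.asarray(covariates, dtype=float))
            if covariates.shape[0] != X.shape[0]:
                raise ValueError("covariate rows must match number of subjects")
        return X, batch, covariates

    # -- estimator API -----------------------------------------------------
    def fit(self, X, y=None, *, batch, covariates=None):
        X, batch, covariates = self._validate(X, batch, covariates)
        n, p = X.shape
        levels = [str(b) for b in pd.unique(batch)]
        counts = {lv: int((batch.astype(str) == lv).sum()) for lv in levels}

        if len(levels) < 2:
            warnings.warn(
                "single batch supplied: ComBat degrades to pass-through",
                HarmonizationWarning,
                stacklevel=2,
            )
            self.model_ = ComBatModel(
                batches=levels, n_per_batch=counts,
                grand_mean=X.mean(axis=0).tolist(),
                beta_cov=[], var_pooled=X.var(axis=0, ddof=1).tolist(),
                gamma_star={}, delta_sq_star={}, gamma_bar={}, tau_sq={},
                a_prior={}, b_prior={}, eb=False, degenerate=True,
            )
            return self
        for lv, c in counts.items():
            if c < 2:
                raise ValueError(f"batch {lv!r} has fewer than 2 subjects")

        onehot = np.column_stack([(batch.astype(str) == lv).astype(float) for lv in levels])
        design = onehot if covariates is None else np.column_stack([onehot, covariates])
        rank = np.linalg.matrix_rank(design)
        if rank < design.shape[1]:
            raise ValueError(
                "rank-deficient design: covariates are confounded with batch "
                "(or mutually collinear)"
            )
        beta, *_ = np.linalg.lstsq(design, X, rcond=None)
        batch_int = beta[: len(levels)]  # per-batch intercepts
        beta_cov = beta[len(levels):]

        weights = np.array([counts[lv] for lv in levels], dtype=float) / n
        grand = weights @ batch_int  # alpha-hat per feature
        fitted = design @ beta
        var_pooled = ((X - fitted) ** 2).mean(axis=0)
        if np.any(var_pooled <= 0):
            raise ValueError("zero pooled residual variance for some feature")

        cov_part = covariates @ beta_cov if covariates is not None else 0.0
        z = (X - grand - cov_part) / np.sqrt(var_pooled)

        gamma_hat = {}
        delta_hat_sq = {}
        for lv in levels:
            zi = z[batch.astype(str) == lv]
            gamma_hat[lv] = zi.mean(axis=0)
            # ddof=0 keeps the non-EB adjustment exactly idempotent
            delta_hat_sq[lv] = zi.var(axis=0, ddof=0)

        use_eb = self.eb and p >= 2
        gamma_star, delta_sq_star = {}, {}
        gamma_bar, tau_sq, a_prior, b_prior = {}, {}, {}, {}
        for lv in levels:
            g, d = gamma_hat[lv], delta_hat_sq[lv]
            if use_eb:
                gb = float(g.mean())
                t2 = float(g.var(ddof=1))
                m = float(d.mean())
                s2 = float(d.var(ddof=1))
                if t2 <= 0 or s2 <= 0:
                    use_eb = False  # degenerate priors; fall back for all batches
                    break
                a = (2.0 * s2 + m**2) / s2
                b = (m * s2 + m**3) / s2
                zi = z[batch.astype(str) == lv]
                gs, ds = _it_sol(zi, g, d, gb, t2, a, b, self.tol, self.max_iter)
                gamma_star[lv], delta_sq_star[lv] = gs, ds
                gamma_bar[lv], tau_sq[lv], a_prior[lv], b_prior[lv] = gb, t2, a, b
        if not use_eb:
            gamma_star = {lv: gamma_hat[lv].copy() for lv in levels}
            delta_sq_star = {lv: delta_hat_sq[lv].copy() for lv in levels}
            gamma_bar, tau_sq, a_prior, b_prior = {}, {}, {}, {}

        self.levels_ = levels
        self.model_ = ComBatModel(
            batches=levels,
            n_per_batch=counts,
            grand_mean=np.asarray(grand).ravel().tolist(),
            beta_cov=np.asarray(beta_cov).tolist(),
            var_pooled=var_pooled.tolist(),
            gamma_star={lv: np.asarray(v).ravel().tolist() for lv, v in gamma_star.items()},
            delta_sq_star={lv: np.asarray(v).ravel().tolist() for lv, v in delta_sq_star.items()},
            gamma_bar=gamma_bar, tau_sq=tau_sq, a_prior=a_prior, b_prior=b_prior,
            eb=use_eb,
        )
        return self

    def transform(self, X, *, batch, covariates=None):
        if not hasattr(self, "model_"):
            raise RuntimeError("ComBatHarmonizer is not fitted")
        X, batch, covariates = self._validate(X, batch, covariates)
        model = self.model_
        if model.degenerate:
            return X.copy()
        grand = np.asarray(model.grand_mean)
        var_pooled = np.asarray(model.var_pooled)
        beta_cov = np.asarray(model.beta_cov)
        cov_part = covariates @ beta_cov if covariates is not None and beta_cov.size else 0.0
        z = (X - grand - cov_part) / np.sqrt(var_pooled)
        out = np.empty_like(z)
        bstr = batch.astype(str)
        for lv in model.batches:
            sel = bstr == lv
            if not sel.any():
                continue
            gs = np.asarray(model.gamma_star[lv])
            ds = np.asarray(model.delta_sq_star[lv])
            out[sel] = (z[sel] - gs) / np.sqrt(ds)
        unknown = ~np.isin(bstr, model.batches)
        if unknown.any():
            raise ValueError(f"unknown batch labels: {sorted(set(bstr[unknown]))}")
        return out * np.sqrt(var_pooled) + grand + cov_part

    def fit_transform(self, X, y=None, **kwargs):
        return self.fit(X, y, **kwargs).transform(X, batch=kwargs["batch"],
                                                  covariates=kwargs.get("covariates"))


def combat_harmonize(
    features: pd.DataFrame,
    batch,
    covariates: pd.DataFrame | np.ndarray | None = None,
    eb: bool = True,
) -> tuple[pd.DataFrame, ComBatModel]:
    """Harmonize a subjects x features table across batches.

    Thin functional wrapper over :class:`ComBatHarmonizer`; returns the
    adjusted table (same index/columns) and the fitted model.
    """
    cov = np.asarray(covariates, dtype=float) if covariates is not None else None
    est = ComBatHarmonizer(eb=eb)
    vals = est.fit_transform(np.asarray(features, dtype=float), batch=np.asarray(batch),
                             covariates=cov)
    if isinstance(features, pd.DataFrame):
        out = pd.DataFrame(vals, index=features.index, columns=features.columns)
    else:
        out = pd.DataFrame(vals)
    return out, est.model_


# ---------------------------------------------------------------------------
# Test-retest stability
# ---------------------------------------------------------------------------

def icc(session1, session2, kind: str = "ICC2") -> float:
    """Intraclass correlation for two measurement sessions per subject.

    ``kind="ICC2"`` (default) is the two-way random-effects, absolute-
    agreement, single-measurement form ICC(2,1) — sensitive to systematic
    session offsets, which is the right behaviour for cross-scanner
    test-retest. ``kind="ICC3"`` gives the consistency form ICC(3,1).
    """
    x = np.asarray(session1, dtype=float)
    y = np.asarray(session2, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("sessions must be 1-D arrays of equal length")
    n = x.shape[0]
    if n < 2:
        raise ValueError("need at least 2 subjects")
    data = np.column_stack([x, y])
    k = 2
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ssr = k * ((row_means - grand) ** 2).sum()
    ssc = n * ((col_means - grand) ** 2).sum()
    sst = ((data - grand) ** 2).sum()
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    if msr + (k - 1) * mse == 0:
        raise ValueError("ICC undefined: no between- or within-subject variance")
    if kind == "ICC2":
        return float((msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n))
    if kind == "ICC3":
        return float((msr - mse) / (msr + (k - 1) * mse))
    raise ValueError(f"unknown ICC kind {kind!r}")


def paired_t(session1, session2) -> tuple[float, float, int]:
    """Paired two-sided t test on session differences: (t, p, df)."""
    x = np.asarray(session1, dtype=float)
    y = np.asarray(session2, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("sessions must be 1-D arrays of equal length")
    if x.shape[0] < 2:
        raise ValueError("paired t test needs n >= 2")
    d = x - y
    if np.allclose(d.std(ddof=1), 0):
        if np.allclose(d, 0):
            return 0.0, 1.0, x.shape[0] - 1
        raise ValueError("zero-variance non-zero differences: t is infinite")
    res = sps.ttest_rel(x, y)
    return float(res.statistic), float(res.pvalue), int(x.shape[0] - 1)


@dataclass
class StabilityResult:
    icc: float
    t: float
    p: float
    n: int


def stability_analysis(session1, session2, kind: str = "ICC2") -> StabilityResult:
    """ICC + paired t summary of scan-rescan agreement."""
    t, p, _ = paired_t(session1, session2)
    return StabilityResult(icc=icc(session1, session2, kind=kind), t=t, p=p,
                           n=len(np.asarray(session1)))
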
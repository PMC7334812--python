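"""Mixed-model protein-trait scan and seasonal first-harmonic scan.

Each protein is regressed on a trait (plus optional fixed covariates)
with a random intercept per individual, accounting for the repeated
visits:

    y = X beta + b_g + eps,   b_g ~ N(0, sigma_b^2),  eps ~ N(0, sigma^2)

Estimation profiles the variance ratio theta = sigma_b^2 / sigma^2 in one
dimension (REML by default, ML for likelihood-ratio tests); given theta,
beta and sigma^2 are closed-form GLS quantities.  Trait coefficients get
Wald tests on residual degrees of freedom; discovery is controlled by
Benjamini-Hochberg FDR over the whole protein x trait grid.

Seasonality is tested per protein by the first annual harmonic
(sin/cos of day-of-year over a 365.25-day period) with the same random
intercept, via a 2-df likelihood-ratio test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from longiplasma.core_model import ProteinDataset, ValidationError
from longiplasma.stability import _averaged_over_duplicates

logger = logging.getLogger(__name__)

DAYS_PER_YEAR = 365.25


# ---------------------------------------------------------------------------
# Random-intercept fit
# ---------------------------------------------------------------------------

@dataclass
class RandomInterceptFit:
    coef: np.ndarray
    se: np.ndarray
    tstat: np.ndarray
    pvalues: np.ndarray
    df_resid: float
    sigma2: float
    sigma_b2: float
    loglik: float       # profiled log-likelihood (REML or ML criterion used)
    n: int
    n_groups: int
    method: str


class _Profiler:
    """Profiled likelihood of the variance ratio for one (y, X, groups)."""

    def __init__(self, y, X, group_slices):
        self.y, self.X = y, X
        self.slices = group_slices
        self.n, self.p = X.shape
        self.XtX = X.T @ X
        self.Xty = X.T @ y
        self.yty = float(y @ y)
        self.SX = np.vstack([X[s].sum(axis=0) for s in group_slices])
        self.Sy = np.array([y[s].sum() for s in group_slices])
        self.ng = np.array([s.stop - s.start for s in group_slices], dtype=float)

    def gls(self, theta):
        w = theta / (1 + self.ng * theta)
        XtVX = self.XtX - (self.SX * w[:, None]).T @ self.SX
        XtVy = self.Xty - self.SX.T @ (w * self.Sy)
        yVy = self.yty - float(w @ self.Sy**2)
        beta = np.linalg.solve(XtVX, XtVy)
        rss = max(yVy - float(beta @ XtVy), 1e-300)
        logdet_v = float(np.log1p(self.ng * theta).sum())
        return beta, XtVX, rss, logdet_v

    def neg_reml(self, theta):
        _, XtVX, rss, logdet_v = self.gls(theta)
        dfe = self.n - self.p
        sign, logdet_x = np.linalg.slogdet(XtVX)
        return 0.5 * (dfe * np.log(rss / dfe) + logdet_v + logdet_x)

    def neg_ml(self, theta):
        _, _, rss, logdet_v = self.gls(theta)
        return 0.5 * (self.n * np.log(rss / self.n) + logdet_v)


def fit_random_intercept(
    y: np.ndarray,
    X: np.ndarray,
    groups: np.ndarray,
    method: str = "reml",
) -> RandomInterceptFit:
    """Fit the random-intercept model by 1-D profiling of the variance ratio.

    Falls back to OLS (theta = 0) with a warning when no group has more
    than one observation; a singular design raises.
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    groups = np.asarray(groups)
    keep = np.isfinite(y) & np.all(np.isfinite(X), axis=1)
    y, X, groups = y[keep], X[keep], groups[keep]
    n, p = X.shape
    if np.linalg.matrix_rank(X) < p:
        raise ValidationError("singular design matrix")

    order = np.argsort(groups, kind="stable")
    y, X, groups = y[order], X[order], groups[order]
    edges = np.flatnonzero(np.r_[True, groups[1:] != groups[:-1], True])
    slices = [slice(a, b) for a, b in zip(edges[:-1], edges[1:])]
    prof = _Profiler(y, X, slices)

    if max(prof.ng) < 2:
        logger.warning("no within-group replication; falling back to OLS")
        theta = 0.0
    else:
        obj = prof.neg_reml if method == "reml" else prof.neg_ml
        res = optimize.minimize_scalar(
            obj, bounds=(0.0, 1e4), method="bounded",
            options={"xatol": 1e-8},
        )
        theta = float(res.x)
        if obj(0.0) <= obj(theta):
            theta = 0.0

    beta, XtVX, rss, _ = prof.gls(theta)
    dfe = n - p
    sigma2 = rss / (dfe if method == "reml" else n)
    cov = sigma2 * np.linalg.inv(XtVX)
    se = np.sqrt(np.diag(cov))
    tstat = beta / se
    pvals = 2 * stats.t.sf(np.abs(tstat), dfe)
    obj = prof.neg_reml if method == "reml" else prof.neg_ml
    const = -0.5 * (dfe if method == "reml" else n) * (1 + np.log(2 * np.pi))
    return RandomInterceptFit(
        coef=beta, se=se, tstat=tstat, pvalues=pvals, df_resid=dfe,
        sigma2=float(sigma2), sigma_b2=float(theta * sigma2),
        loglik=float(-obj(theta) + const), n=n, n_groups=len(slices),
        method=method,
    )


# ---------------------------------------------------------------------------
# Multiple testing
# ---------------------------------------------------------------------------

def benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """BH step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


# ---------------------------------------------------------------------------
# Scans
# ---------------------------------------------------------------------------

def _design_with_covariates(traits: pd.DataFrame, covariates: list[str],
                            rows: pd.MultiIndex) -> np.ndarray | None:
    """Covariate columns aligned to rows; categoricals are dummy-coded."""
    if not covariates:
        return np.empty((len(rows), 0))
    cols = []
    for name in covariates:
        col = traits.loc[rows, name]
        if col.dtype == object:
            cols.append(pd.get_dummies(col, drop_first=True).to_numpy(dtype=float))
        else:
            cols.append(col.to_numpy(dtype=float)[:, None])
    return np.hstack(cols)


def association_scan(
    ds: ProteinDataset,
    traits: pd.DataFrame,
    covariates: list[str] | None = None,
    fdr_threshold: float = 0.001,
    min_pairs: int = 10,
) -> pd.DataFrame:
    """Protein-trait scan: random intercept per individual, BH over the grid.

    Traits with fewer than ``min_pairs`` non-missing (individual, visit)
    pairs, or no variation, are skipped with a warning.  Returns one row
    per (antibody, trait) with effect, se, t, p, FDR-adjusted p and the
    significance flag at ``fdr_threshold``.
    """
    covariates = covariates or []
    vals, meta = _averaged_over_duplicates(ds)
    key = pd.MultiIndex.from_arrays(
        [meta["individual_id"], meta["visit"]], names=["individual_id", "visit"]
    )
    present = key.isin(traits.index)
    vals, meta, key = vals.loc[present], meta.loc[present], key[present]

    trait_names = [c for c in traits.columns
                   if c not in covariates and pd.api.types.is_numeric_dtype(traits[c])]
    rows = []
    for trait in trait_names:
        tvals = traits.loc[key, trait].to_numpy(dtype=float)
        ok = np.isfinite(tvals)
        if ok.sum() < min_pairs:
            logger.warning("trait %s: <%d non-missing pairs, skipped", trait, min_pairs)
            continue
        if np.nanstd(tvals) == 0:
            logger.warning("trait %s is constant, skipped", trait)
            continue
        cov = _design_with_covariates(traits, covariates, key)
        X = np.column_stack([np.ones(len(tvals)), tvals, cov])
        groups = meta["individual_id"].to_numpy()
        for ab in vals.columns:
            fit = fit_random_intercept(vals[ab].to_numpy(), X, groups)
            rows.append({"antibody": ab, "trait": trait,
                         "effect": fit.coef[1], "se": fit.se[1],
                         "tstat": fit.tstat[1], "p": fit.pvalues[1],
                         "n": fit.n})
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    out["fdr_p"] = benjamini_hochberg(out["p"].to_numpy())
    out["significant"] = out["fdr_p"] <= fdr_threshold
    return out


def seasonal_scan(
    ds: ProteinDataset,
    fdr_threshold: float = 0.01,
) -> pd.DataFrame:
    """First-harmonic seasonal test per protein.

    Fits ``y ~ 1 + sin(2*pi*d/365.25) + cos(2*pi*d/365.25)`` with a random
    intercept per individual (d = day of year) and compares against the
    intercept-only model by a 2-df likelihood-ratio test (ML fits).
    Reports amplitude ``sqrt(b_s^2 + b_c^2)``, phase in [0, 2*pi), raw and
    BH-adjusted p, and the flag at ``fdr_threshold``.
    """
    vals, meta = _averaged_over_duplicates(ds)
    dates = pd.to_datetime(meta["collection_date"])
    span = (dates.max() - dates.min()).days
    if span < 180:
        raise ValidationError(
            f"collection dates span only {span} days; phase is not identifiable"
        )
    d = dates.dt.dayofyear.to_numpy(dtype=float)
    ang = 2 * np.pi * d / DAYS_PER_YEAR
    X_full = np.column_stack([np.ones_like(ang), np.sin(ang), np.cos(ang)])
    X_null = np.ones((len(ang), 1))
    groups = meta["individual_id"].to_numpy()

    rows = []
    for ab in vals.columns:
        y = vals[ab].to_numpy()
        full = fit_random_intercept(y, X_full, groups, method="ml")
        null = fit_random_intercept(y, X_null, groups, method="ml")
        lr = max(2 * (full.loglik - null.loglik), 0.0)
        b_s, b_c = full.coef[1], full.coef[2]
        rows.append({
            "antibody": ab, "b_sin": b_s, "b_cos": b_c,
            "amplitude": float(np.hypot(b_s, b_c)),
            "phase": float(np.mod(np.arctan2(b_c, b_s), 2 * np.pi)),
            "p": float(stats.chi2.sf(lr, df=2)),
        })
    out = pd.DataFrame(rows)
    out["fdr_p"] = benjamini_hochberg(out["p"].to_numpy())
    out["significant"] = out["fdr_p"] < fdr_threshold
    return out
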
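"""Per-individual deviation signatures: baseline, trend, fluctuation.

Protein levels are standardized to z-scores with the whole cohort as the
reference population.  For every (individual, protein) profile an
ordinary least-squares line of z on centered time (years) yields three
statistics:

    alpha  - the intercept at the individual's mean visit time (baseline)
    gamma  - the slope in z units per year (trend)
    phi    - the sum of absolute residuals (fluctuation around the line)

A profile deviates on a criterion when its statistic lies more than
``k`` standard deviations (default 3) from the cohort average of that
statistic for the same protein.  Under a Gaussian null the per-criterion
chance rate is ``2 * (1 - Phi(k))``, i.e. 0.27% at k = 3.  Inter-individual
diversity per protein is summarized by the IQR of per-individual mean
z levels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from longiplasma.core_model import ProteinDataset, ValidationError
from longiplasma.stability import _averaged_over_duplicates

logger = logging.getLogger(__name__)

DAYS_PER_YEAR = 365.25
CRITERIA = ("baseline", "trend", "fluctuation")


def population_zscore(
    ds: ProteinDataset,
    proteins: list[str] | None = None,
) -> pd.DataFrame:
    """Z-score per protein over all samples of all individuals.

    ``proteins`` restricts the panel (typically the both-stable set from
    the stability classification).  Zero-variance proteins are excluded
    with a warning.  Duplicate assays are averaged first.
    """
    vals, meta = _averaged_over_duplicates(ds)
    if proteins is not None:
        missing = set(proteins) - set(vals.columns)
        if missing:
            raise ValidationError(f"unknown proteins requested: {sorted(missing)[:5]}")
        vals = vals[list(proteins)]
    sd = vals.std(ddof=1)
    dead = sd.index[(sd == 0) | sd.isna()]
    if len(dead):
        logger.warning("excluding %d zero-variance proteins: %s",
                       len(dead), list(dead[:5]))
        vals = vals.drop(columns=dead)
        sd = sd.drop(dead)
    z = (vals - vals.mean()) / sd
    z.attrs["meta"] = meta
    return z


@dataclass
class ProfileStats:
    """Per (individual, protein) intercept/slope/fluctuation statistics."""

    alpha: pd.DataFrame   # individuals x proteins, z units
    gamma: pd.DataFrame   # z units per year
    phi: pd.DataFrame     # sum of |residuals|, z units
    n_visits: pd.Series   # per individual


def profile_statistics(
    z: pd.DataFrame,
    meta: pd.DataFrame,
    min_visits: int = 3,
) -> ProfileStats:
    """OLS of each profile's z values on centered time in years.

    Individuals with fewer than ``min_visits`` visits are excluded with a
    log message (a line plus residual spread needs at least three points).
    """
    dates = pd.to_datetime(meta["collection_date"])
    first = dates.groupby(meta["individual_id"]).transform("min")
    t_years = ((dates - first).dt.days / DAYS_PER_YEAR).to_numpy()

    alpha, gamma, phi, nv = {}, {}, {}, {}
    for ind, grp in meta.groupby("individual_id", sort=True):
        rows = grp.index
        if grp["visit"].nunique() < min_visits:
            logger.info("individual %s has <%d visits; excluded", ind, min_visits)
            continue
        t = t_years[meta.index.get_indexer(rows)]
        tc = t - t.mean()
        zz = z.loc[rows].to_numpy()
        sxx = float(tc @ tc)
        slope = (tc @ zz) / sxx
        inter = zz.mean(axis=0)
        resid = zz - inter[None, :] - np.outer(tc, slope)
        alpha[ind] = inter
        gamma[ind] = slope
        phi[ind] = np.abs(resid).sum(axis=0)
        nv[ind] = len(rows)
    if not alpha:
        raise ValidationError("no individual has enough visits for profile statistics")
    idx = list(alpha)
    return ProfileStats(
        alpha=pd.DataFrame(alpha, index=z.columns).T.loc[idx],
        gamma=pd.DataFrame(gamma, index=z.columns).T.loc[idx],
        phi=pd.DataFrame(phi, index=z.columns).T.loc[idx],
        n_visits=pd.Series(nv),
    )


@dataclass
class SignatureFlags:
    flags: dict[str, pd.DataFrame]    # criterion -> individuals x proteins bool
    k: float
    chance_rate: float                # per criterion, Gaussian null
    chance_rate_union: float          # any of the three, under independence


def flag_deviations(
    profile: ProfileStats,
    k: float = 3.0,
    min_individuals: int = 10,
) -> SignatureFlags:
    """Flag profiles more than ``k`` SD from the cohort average.

    Mean and SD are taken across individuals per protein and statistic,
    including the tested individual.  A statistic with zero SD yields no
    flags (warning).  The Gaussian chance rate ``2*(1 - Phi(k))`` per
    criterion, and its three-criterion union under independence, are
    reported alongside.
    """
    if len(profile.alpha) < min_individuals:
        raise ValidationError(f"flagging needs >= {min_individuals} individuals")
    per = stats.norm.sf(k) * 2
    flags = {}
    for crit, tab in zip(CRITERIA, (profile.alpha, profile.gamma, profile.phi)):
        mu = tab.mean(axis=0)
        sd = tab.std(axis=0, ddof=1)
        zero = sd.index[sd == 0]
        if len(zero):
            logger.warning("%s: zero SD for %d proteins; no flags there",
                           crit, len(zero))
        with np.errstate(invalid="ignore", divide="ignore"):
            f = (tab.sub(mu, axis=1).abs().div(sd, axis=1) > k)
        f.loc[:, sd == 0] = False
        flags[crit] = f.fillna(False)
    return SignatureFlags(flags=flags, k=k, chance_rate=float(per),
                          chance_rate_union=float(1 - (1 - per) ** 3))


def interindividual_iqr(
    z: pd.DataFrame,
    meta: pd.DataFrame,
    low_cut: float = 0.15,
    high_cut: float = 1.5,
) -> pd.DataFrame:
    """Per protein: IQR across individuals of the per-individual mean z.

    Flags low-diversity (IQR <= ``low_cut``) and high-diversity
    (IQR >= ``high_cut``) proteins.
    """
    by_ind = z.groupby(meta["individual_id"]).mean()
    if len(by_ind) < 2:
        raise ValidationError("IQR across individuals needs >= 2 individuals")
    q1 = by_ind.quantile(0.25)
    q3 = by_ind.quantile(0.75)
    iqr = q3 - q1
    return pd.DataFrame({
        "protein": iqr.index, "iqr": iqr.to_numpy(),
        "low_diversity": (iqr <= low_cut).to_numpy(),
        "high_diversity": (iqr >= high_cut).to_numpy(),
    })


@dataclass
class SignatureSummary:
    per_individual: pd.DataFrame   # counts per criterion + accumulated score
    per_protein: pd.DataFrame      # individuals flagged, by criterion
    venn: dict[str, int]           # criterion-overlap counts
    n_profiles: int
    n_flagged: int
    flagged_fraction: float
    chance_rate: float
    chance_rate_union: float


def summarize_signatures(flags: SignatureFlags) -> SignatureSummary:
    """Per-individual and per-protein roll-ups plus criterion-overlap counts.

    The accumulated score per individual is the plain sum of its three
    criterion counts; the overall flagged fraction counts profiles
    deviating on at least one criterion over individuals x proteins.
    """
    b, t, f = (flags.flags[c] for c in CRITERIA)
    any_flag = b | t | f
    per_ind = pd.DataFrame({
        "baseline": b.sum(axis=1), "trend": t.sum(axis=1),
        "fluctuation": f.sum(axis=1),
    })
    per_ind["accumulated_score"] = per_ind.sum(axis=1)
    per_prot = pd.DataFrame({
        "baseline": b.sum(axis=0), "trend": t.sum(axis=0),
        "fluctuation": f.sum(axis=0), "any": any_flag.sum(axis=0),
    })
    venn = {
        "baseline_only": int((b & ~t & ~f).sum().sum()),
        "trend_only": int((~b & t & ~f).sum().sum()),
        "fluctuation_only": int((~b & ~t & f).sum().sum()),
        "baseline_trend": int((b & t & ~f).sum().sum()),
        "baseline_fluctuation": int((b & ~t & f).sum().sum()),
        "trend_fluctuation": int((~b & t & f).sum().sum()),
        "all_three": int((b & t & f).sum().sum()),
    }
    n_profiles = int(b.size)
    n_flagged = int(any_flag.sum().sum())
    return SignatureSummary(
        per_individual=per_ind, per_protein=per_prot, venn=venn,
        n_profiles=n_profiles, n_flagged=n_flagged,
        flagged_fraction=n_flagged / n_profiles if n_profiles else 0.0,
        chance_rate=flags.chance_rate,
        chance_rate_union=flags.chance_rate_union,
    )
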
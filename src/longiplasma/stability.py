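"""Technical vs longitudinal repeatability via ICC(3,1).

Per protein two intraclass correlations are contrasted: the inter-assay
ICC (targets = aliquots measured twice, raters = assay repeats) captures
technical precision, the inter-visit ICC (targets = individuals, raters =
visits) captures longitudinal stability.  Both use the two-way mixed,
consistency, single-measurement form

    ICC(3,1) = (MS_R - MS_E) / (MS_R + (k - 1) * MS_E)

with MS_R the between-target mean square and MS_E the residual mean
square after removing rater means.  Proteins are classified against a
threshold (0.8 by default) on each axis.  A complementary identifiability
analysis asks whether individuals are recognizable from their own
multi-protein profile across visits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from longiplasma.core_model import ProteinDataset, ValidationError

logger = logging.getLogger(__name__)

CLASS_LABELS = ("both_stable", "technical_only", "longitudinal_only", "unstable")


def icc_3_1(m: np.ndarray) -> float:
    """ICC(3,1): two-way mixed effects, consistency, single measurement.

    ``m`` is a targets x raters matrix with no missing values.  Rater
    (column) offsets are treated as fixed and do not count against
    agreement; negative estimates are returned as computed.
    """
    m = np.asarray(m, dtype=float)
    if m.ndim != 2 or m.shape[0] < 2 or m.shape[1] < 2:
        raise ValidationError("icc_3_1 needs >= 2 targets and >= 2 raters")
    if np.isnan(m).any():
        raise ValidationError("icc_3_1 requires complete rows")
    n, k = m.shape
    grand = m.mean()
    row_means = m.mean(axis=1)
    col_means = m.mean(axis=0)
    ms_r = k * ((row_means - grand) ** 2).sum() / (n - 1)
    resid = m - row_means[:, None] - col_means[None, :] + grand
    ms_e = (resid**2).sum() / ((n - 1) * (k - 1))
    denom = ms_r + (k - 1) * ms_e
    if denom == 0:
        return 1.0 if ms_r == ms_e else 0.0
    return float((ms_r - ms_e) / denom)


def _averaged_over_duplicates(ds: ProteinDataset) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Collapse duplicate assays onto their original sample (mean), returning
    (values indexed by original sample, metadata for originals)."""
    meta = ds.meta
    original = meta["replicate_of"].fillna(pd.Series(meta.index, index=meta.index))
    vals = ds.intensities.groupby(original).mean()
    keep = meta.loc[meta["replicate_of"].isna()]
    return vals.loc[keep.index], keep


def inter_assay_icc(ds: ProteinDataset) -> pd.Series:
    """Per-antibody ICC(3,1) over aliquots measured in duplicate."""
    meta = ds.meta
    reps = meta.loc[meta["replicate_of"].notna()]
    if reps.empty:
        raise ValidationError("dataset has no duplicate assays (replicate_of links)")
    originals = reps["replicate_of"]
    missing = originals[~originals.isin(meta.index)]
    if len(missing):
        raise ValidationError(f"replicate_of points at unknown samples: {list(missing[:5])}")
    first = ds.intensities.loc[originals].to_numpy()
    second = ds.intensities.loc[reps.index].to_numpy()
    out = {}
    for j, ab in enumerate(ds.intensities.columns):
        out[ab] = icc_3_1(np.column_stack([first[:, j], second[:, j]]))
    return pd.Series(out, name="icc_interassay")


def inter_visit_icc(ds: ProteinDataset, complete_case: bool = True) -> pd.Series:
    """Per-antibody ICC(3,1) over individuals x visits.

    Duplicate assays of a visit are averaged first, so technical noise is
    partly pooled out and the two ICC axes stay distinct.  With
    ``complete_case`` (default) individuals missing any visit are dropped.
    """
    vals, meta = _averaged_over_duplicates(ds)
    n_visits = int(meta["visit"].max())
    wide = {}
    for ab in vals.columns:
        tab = pd.pivot_table(
            pd.DataFrame({"v": vals[ab], "individual": meta["individual_id"],
                          "visit": meta["visit"]}),
            index="individual", columns="visit", values="v",
        )
        wide[ab] = tab
    out = {}
    for ab, tab in wide.items():
        m = tab.dropna(axis=0) if complete_case else tab
        if len(m) < 2:
            raise ValidationError(f"fewer than 2 complete individuals for {ab}")
        out[ab] = icc_3_1(m.to_numpy())
    if n_visits < 2:
        raise ValidationError("inter-visit ICC needs >= 2 visits")
    return pd.Series(out, name="icc_intervisit")


@dataclass
class StabilityReport:
    """Per-antibody ICCs, class, and cohort summary counts."""

    table: pd.DataFrame     # antibody, icc_interassay, icc_intervisit, mean_level, class
    summary: pd.DataFrame   # class, count, fraction (plus axis-wise rows)
    threshold: float


def classify_stability(
    icc_a: pd.Series,
    icc_v: pd.Series,
    threshold: float = 0.8,
    mean_level: pd.Series | None = None,
) -> StabilityReport:
    """Four-way stability class per the ICC >= threshold rule on each axis."""
    if not icc_a.index.equals(icc_v.index):
        icc_v = icc_v.reindex(icc_a.index)
        if icc_v.isna().any():
            raise ValidationError("antibody lists of the two ICC series do not align")
    tech = icc_a >= threshold
    longi = icc_v >= threshold
    cls = np.select(
        [tech & longi, tech & ~longi, ~tech & longi],
        ["both_stable", "technical_only", "longitudinal_only"],
        default="unstable",
    )
    table = pd.DataFrame({
        "antibody": icc_a.index,
        "icc_interassay": icc_a.to_numpy(),
        "icc_intervisit": icc_v.to_numpy(),
        "mean_level": (mean_level.reindex(icc_a.index).to_numpy()
                       if mean_level is not None else np.nan),
        "class": cls,
    })
    n = len(table)
    rows = [{"group": c, "count": int((cls == c).sum()), "denominator": n,
             "fraction": (cls == c).sum() / n} for c in CLASS_LABELS]
    rows.append({"group": "technically_stable", "count": int(tech.sum()),
                 "denominator": n, "fraction": tech.sum() / n})
    rows.append({"group": "longitudinally_stable", "count": int(longi.sum()),
                 "denominator": n, "fraction": longi.sum() / n})
    return StabilityReport(table=table, summary=pd.DataFrame(rows), threshold=threshold)


def stability_report(ds: ProteinDataset, threshold: float = 0.8) -> StabilityReport:
    """Convenience: both ICC axes plus classification from one dataset."""
    icc_a = inter_assay_icc(ds)
    icc_v = inter_visit_icc(ds)
    return classify_stability(icc_a, icc_v, threshold=threshold,
                              mean_level=ds.intensities.mean(axis=0))


@dataclass
class IdentifiabilityReport:
    per_individual: pd.DataFrame   # individual_id, icc_across_visits, n_visits
    self_match_fraction: float
    chance_level: float


def individual_identifiability(ds: ProteinDataset) -> IdentifiabilityReport:
    """Is each individual recognizable from their own proteome profile?

    Per individual, ICC(3,1) with targets = antibodies (z-scored
    cohort-wide) and raters = visits; plus the fraction of samples whose
    nearest other sample (Euclidean on z-scored proteins, duplicates
    averaged) belongs to the same individual.  The chance level for the
    self-match fraction is (V - 1) / (N*V - 1) for a complete design.
    """
    vals, meta = _averaged_over_duplicates(ds)
    z = (vals - vals.mean(axis=0)) / vals.std(axis=0, ddof=1)
    z = z.dropna(axis=1)  # constant antibodies carry no identity signal

    rows = []
    for ind, grp in meta.groupby("individual_id", sort=False):
        if grp["visit"].nunique() < 2:
            logger.warning("individual %s has a single visit; excluded", ind)
            continue
        m = z.loc[grp.index].to_numpy().T  # antibodies x visits
        rows.append({"individual_id": ind, "icc_across_visits": icc_3_1(m),
                     "n_visits": m.shape[1]})
    per_ind = pd.DataFrame(rows)

    x = z.to_numpy()
    d2 = (x**2).sum(axis=1)[:, None] + (x**2).sum(axis=1)[None, :] - 2 * x @ x.T
    np.fill_diagonal(d2, np.inf)
    nn = np.argmin(d2, axis=1)
    owner = meta["individual_id"].to_numpy()
    self_match = float((owner[nn] == owner).mean())

    counts = meta.groupby("individual_id").size()
    n_samples = len(meta)
    chance = float(((counts - 1) / (n_samples - 1) * counts / n_samples).sum())
    return IdentifiabilityReport(per_individual=per_ind,
                                 self_match_fraction=self_match,
                                 chance_level=chance)
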
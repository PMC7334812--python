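"""Plate-wise AbsPQN and Multi-MA normalization of log intensities.

AbsPQN removes per-sample multiplicative scaling (pipetting / dilution
differences) within a plate: in log space, each sample is shifted by the
median of its differences to the plate's median reference profile, and
the plate's grand median is restored so absolute levels are preserved.
The median-quotient step is iterated to a fixed point, which makes the
operator idempotent; the reported per-sample factor is the exponential of
the accumulated shift.

Multi-MA removes per-antibody plate offsets: every antibody's plate means
are equalized to their unweighted across-plate average (the preserved
"A" coordinate of the multi-dimensional MA rotation; the orthogonal "M"
components are zeroed).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from longiplasma.core_model import ProteinDataset, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class NormalizationAudit:
    """What normalization removed, and what it achieved.

    ``sample_factors``: per-sample AbsPQN scaling factor (raw scale,
    ``exp`` of the log shift removed).  ``plate_offsets``: per
    (plate, antibody) Multi-MA offset removed.  ``variance_shares``: per
    antibody, between-plate share of variance before and after.
    """

    sample_factors: pd.Series
    plate_offsets: pd.DataFrame
    variance_shares: pd.DataFrame


def log_transform(ds: ProteinDataset) -> ProteinDataset:
    """Natural log of raw MFI."""
    if ds.scale_tag != "raw":
        raise ValidationError(f"log_transform expects raw data, got {ds.scale_tag!r}")
    vals = ds.intensities.to_numpy(dtype=float)
    if (vals <= 0).any():
        raise ValidationError("non-positive MFI cannot be log-transformed")
    return ds.with_values(
        pd.DataFrame(np.log(vals), index=ds.intensities.index, columns=ds.intensities.columns),
        scale_tag="log",
    )


def abspqn(block: pd.DataFrame, tol: float = 1e-13, max_iter: int = 5000
           ) -> tuple[pd.DataFrame, pd.Series]:
    """Absolute probabilistic quotient normalization of one plate block.

    Parameters
    ----------
    block
        Log-scale samples x antibodies matrix of a single plate.

    Returns
    -------
    normalized block, per-sample scaling factors (raw scale).

    Notes
    -----
    One pass computes the column-median reference ``r``, per-sample shift
    ``q_i = median_j(x_ij - r_j)``, subtracts ``q_i`` from row ``i`` and
    restores the block grand median.  Because medians of the re-referenced
    block need not vanish after one pass, the pass is iterated until the
    incremental shifts are below ``tol``; the accumulated shift per sample
    is reported.  A single-sample block is returned unchanged (its own
    median is its reference).
    """
    if block.shape[1] < 3:
        raise ValidationError("abspqn needs >= 3 antibodies for a meaningful median quotient")
    if len(block) == 0:
        raise ValidationError("empty plate block")
    x = block.to_numpy(dtype=float)
    total_q = np.zeros(len(block))
    if len(block) == 1:
        return block.copy(), pd.Series(np.ones(1), index=block.index)
    grand = np.median(x)
    w = x.copy()
    for _ in range(max_iter):
        r = np.median(w, axis=0)
        q = np.median(w - r, axis=1)
        q -= np.median(q)  # anchor: shifts are relative, keep them centred
        w = w - q[:, None]
        total_q += q
        if np.max(np.abs(q)) < tol:
            break
    w += grand - np.median(w)
    out = pd.DataFrame(w, index=block.index, columns=block.columns)
    return out, pd.Series(np.exp(total_q), index=block.index)


def multi_ma(ds: ProteinDataset, plate_col: str = "plate_id"
             ) -> tuple[ProteinDataset, pd.DataFrame]:
    """Equalize per-antibody plate means across plates.

    For antibody ``j`` with plate means ``m_pj``, every value on plate
    ``p`` is replaced by ``x - m_pj + mean_p(m_pj)``.  Afterwards each
    antibody's plate means agree across plates, and the unweighted mean
    of plate means is preserved exactly.
    """
    if ds.scale_tag == "raw":
        raise ValidationError("multi_ma expects log-scale data")
    plates = ds.meta[plate_col]
    sizes = plates.value_counts()
    small = sizes[sizes < 2]
    if len(small):
        raise ValidationError(f"plate(s) with a single sample: {list(small.index)}")
    x = ds.intensities
    plate_means = x.groupby(plates).mean()              # plates x antibodies
    grand = plate_means.mean(axis=0)                    # unweighted mean of plate means
    offsets = plate_means.sub(grand, axis=1)            # what is removed
    adj = x - offsets.loc[plates].to_numpy()
    out = ds.with_values(adj, scale_tag="normalized")
    return out, offsets


def between_plate_variance_share(values: pd.DataFrame, plates: pd.Series) -> pd.Series:
    """Per antibody: SS_between-plates / SS_total (0 when SS_total is 0)."""
    grand = values.mean(axis=0)
    ss_tot = ((values - grand) ** 2).sum(axis=0)
    pm = values.groupby(plates).mean()
    counts = plates.value_counts().loc[pm.index]
    ss_btw = ((pm - grand) ** 2).mul(counts, axis=0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        share = ss_btw / ss_tot
    return share.fillna(0.0)


def normalize_pipeline(ds: ProteinDataset) -> tuple[ProteinDataset, NormalizationAudit]:
    """log -> per-plate AbsPQN -> across-plate Multi-MA, with audit.

    Row order, shape and metadata are untouched; only values change.
    """
    if ds.meta["plate_id"].isna().any():
        raise ValidationError("plate_id required for every sample")
    logged = log_transform(ds)
    plates = logged.meta["plate_id"]
    share_before = between_plate_variance_share(logged.intensities, plates)

    pieces = []
    factors = []
    for plate in plates.unique():
        block = logged.intensities.loc[plates == plate]
        norm_block, f = abspqn(block)
        pieces.append(norm_block)
        factors.append(f)
    after_pqn = pd.concat(pieces).loc[logged.intensities.index]
    pqn_ds = logged.with_values(after_pqn, scale_tag="log")

    out, offsets = multi_ma(pqn_ds)
    share_after = between_plate_variance_share(out.intensities, plates)
    audit = NormalizationAudit(
        sample_factors=pd.concat(factors).loc[logged.intensities.index],
        plate_offsets=offsets,
        variance_shares=pd.DataFrame(
            {"before": share_before, "after": share_after}
        ),
    )
    return out, audit
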
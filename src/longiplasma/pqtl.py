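"""Additive cis-pQTL scanning with Bonferroni control and subgroup calls.

Per antibody the phenotype is the individual's across-visit mean of
normalized log levels (configurable to a single visit).  Every SNP is
tested by ordinary least squares of phenotype on additive minor-allele
dosage; the genome-wide significance threshold is alpha / M over the M
SNPs actually tested after MAF and Hardy-Weinberg QC.  Hits are annotated
as cis when the SNP falls inside the protein-encoding gene's window plus
a margin, and LD proxies of the top SNP are reported by genotypic r^2.
Bimodal level distributions (proteoform-specific antibody binding) are
called by a 1- vs 2-component Gaussian mixture chosen by BIC.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.mixture import GaussianMixture

from longiplasma.core_model import GenotypeMatrix, ProteinDataset, ValidationError
from longiplasma.stability import _averaged_over_duplicates

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------

def hwe_test(dosages: np.ndarray) -> np.ndarray:
    """Chi-square (1 df) Hardy-Weinberg test per SNP on hard calls."""
    g = np.asarray(dosages)
    n0 = (g == 0).sum(axis=0).astype(float)
    n1 = (g == 1).sum(axis=0).astype(float)
    n2 = (g == 2).sum(axis=0).astype(float)
    n = n0 + n1 + n2
    p = (2 * n2 + n1) / (2 * n)
    q = 1 - p
    exp = np.stack([n * q**2, 2 * n * p * q, n * p**2])
    obs = np.stack([n0, n1, n2])
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = np.where(exp > 0, (obs - exp) ** 2 / exp, 0.0).sum(axis=0)
    return stats.chi2.sf(chi2, df=1)


def hwe_maf_filter(
    g: GenotypeMatrix,
    maf_min: float = 0.05,
    hwe_p_min: float = 1e-6,
) -> GenotypeMatrix:
    """Drop SNPs with MAF < ``maf_min`` or HWE chi-square p < ``hwe_p_min``."""
    maf = g.snp_info["maf"].to_numpy(dtype=float)
    hwe_p = hwe_test(g.dosages.to_numpy())
    keep = (maf >= maf_min) & (hwe_p >= hwe_p_min)
    n_maf = int((maf < maf_min).sum())
    n_hwe = int(((maf >= maf_min) & (hwe_p < hwe_p_min)).sum())
    logger.info("QC removed %d SNPs below MAF %.3g and %d failing HWE at p < %.3g",
                n_maf, n_hwe, maf_min, hwe_p_min)
    return GenotypeMatrix(
        dosages=g.dosages.loc[:, keep],
        snp_info=g.snp_info.loc[keep],
        gene_windows=dict(g.gene_windows),
    )


# ---------------------------------------------------------------------------
# Scan
# ---------------------------------------------------------------------------

def across_visit_levels(ds: ProteinDataset, visit: int | None = None) -> pd.DataFrame:
    """Per-individual phenotype: across-visit mean of normalized log levels
    (or a single visit's value), duplicates averaged first."""
    vals, meta = _averaged_over_duplicates(ds)
    if visit is not None:
        sel = meta["visit"] == visit
        vals, meta = vals.loc[sel.index[sel]], meta.loc[sel]
    return vals.groupby(meta["individual_id"]).mean()


def _ols_scan(y: np.ndarray, G: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized per-SNP simple regression of y on dosage.

    Returns (beta, se, p) arrays of length M; zero-variance SNPs get NaN.
    """
    n = len(y)
    yc = y - y.mean()
    Gc = G - G.mean(axis=0)
    sxx = (Gc**2).sum(axis=0)
    sxy = Gc.T @ yc
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = sxy / sxx
        rss = (yc @ yc) - beta * sxy
        sigma2 = rss / (n - 2)
        se = np.sqrt(sigma2 / sxx)
        t = beta / se
    p = 2 * stats.t.sf(np.abs(t), n - 2)
    bad = sxx == 0
    beta[bad] = se[bad] = p[bad] = np.nan
    return beta, se, p


def bonferroni_threshold(alpha: float, n_tests: int | float) -> float:
    """Genome-wide significance threshold alpha / M."""
    if n_tests <= 0:
        raise ValidationError("n_tests must be positive")
    return alpha / n_tests


@dataclass
class PqtlResult:
    associations: pd.DataFrame   # per (antibody, snp) rows that pass the threshold
    top_hits: pd.DataFrame       # per antibody: top SNP, p, cis flag, LD proxies
    threshold: float
    n_snps_tested: int
    alpha: float


def pqtl_scan(
    levels: pd.DataFrame,
    g: GenotypeMatrix,
    alpha: float = 0.05,
    cis_margin: int = 1_000_000,
    target_map: dict[str, str] | None = None,
    ld_r2_min: float = 0.8,
) -> PqtlResult:
    """OLS scan of every antibody's level against every SNP.

    ``levels`` is individuals x antibodies (see
    :func:`across_visit_levels`).  The Bonferroni threshold is
    ``alpha / M`` with M the number of SNPs tested.  Cis annotation uses
    ``target_map`` (antibody -> gene) and the genotype's gene windows
    extended by ``cis_margin`` on both sides.
    """
    shared = levels.index.intersection(g.dosages.index)
    if len(shared) == 0:
        raise ValidationError("no overlapping individuals between levels and genotypes")
    if len(shared) < 30:
        logger.warning("only %d individuals; the scan is underpowered", len(shared))
    y_all = levels.loc[shared]
    G = g.dosages.loc[shared].to_numpy()
    m = G.shape[1]
    threshold = bonferroni_threshold(alpha, m)
    snp_ids = g.snp_info.index.to_numpy()
    chrom = g.snp_info["chrom"].to_numpy()
    pos = g.snp_info["pos"].to_numpy()

    assoc_rows, top_rows = [], []
    for ab in y_all.columns:
        beta, se, p = _ols_scan(y_all[ab].to_numpy(), G)
        order = np.nanargmin(p)
        top_p = p[order]
        gene = (target_map or {}).get(ab)
        window = g.gene_windows.get(gene) if gene else None
        if gene and window is None:
            logger.warning("antibody %s: gene %s has no window; cis flag skipped", ab, gene)

        def _is_cis(j: int) -> bool:
            if window is None:
                return False
            c, start, end = window
            return (chrom[j] == c) and (start - cis_margin <= pos[j] <= end + cis_margin)

        sig = np.flatnonzero(p < threshold)
        for j in sig:
            assoc_rows.append({"antibody": ab, "snp_id": snp_ids[j],
                               "effect": beta[j], "se": se[j], "p": p[j],
                               "cis": _is_cis(j)})
        top_snp_dosage = G[:, order]
        with np.errstate(invalid="ignore"):
            r2 = _pairwise_r2(top_snp_dosage, G)
        proxies = [(snp_ids[j], float(r2[j])) for j in np.flatnonzero(r2 >= ld_r2_min)
                   if j != order]
        top_rows.append({
            "antibody": ab, "top_snp": snp_ids[order], "effect": beta[order],
            "se": se[order], "p": top_p, "significant": bool(top_p < threshold),
            "cis": _is_cis(order),
            "ld_proxies": ";".join(f"{s}:{v:.3f}" for s, v in proxies),
        })
    return PqtlResult(
        associations=pd.DataFrame(assoc_rows, columns=["antibody", "snp_id", "effect",
                                                       "se", "p", "cis"]),
        top_hits=pd.DataFrame(top_rows),
        threshold=threshold, n_snps_tested=m, alpha=alpha,
    )


def _pairwise_r2(x: np.ndarray, G: np.ndarray) -> np.ndarray:
    xc = x - x.mean()
    Gc = G - G.mean(axis=0)
    denom = np.sqrt((xc @ xc) * (Gc**2).sum(axis=0))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (Gc.T @ xc) / denom
    return r**2


def ld_r2(g: GenotypeMatrix, snp_a: str, snp_b: str) -> float:
    """Genotypic r^2: squared Pearson correlation of dosage vectors."""
    a = g.dosages[snp_a].to_numpy(dtype=float)
    b = g.dosages[snp_b].to_numpy(dtype=float)
    if a.std() == 0 or b.std() == 0:
        raise ValidationError("LD r^2 undefined for a zero-variance SNP")
    return float(np.corrcoef(a, b)[0, 1] ** 2)


# ---------------------------------------------------------------------------
# Subgroups
# ---------------------------------------------------------------------------

@dataclass
class SubgroupResult:
    n_components: int
    minor_fraction: float
    means: np.ndarray
    sds: np.ndarray
    weights: np.ndarray
    assignment: pd.Series   # per individual: component index (0 = major)
    bic: dict[int, float]


def detect_level_subgroups(
    levels: pd.Series,
    seed: int = 0,
    n_init: int = 10,
) -> SubgroupResult:
    """1- vs 2-component Gaussian mixture on per-individual levels, by BIC.

    Components are ordered so index 0 is the larger (major) one; the
    minor-subgroup fraction is therefore <= 0.5.
    """
    x = levels.dropna().to_numpy(dtype=float).reshape(-1, 1)
    if len(x) < 30:
        raise ValidationError("subgroup detection needs >= 30 individuals")
    fits, bic = {}, {}
    for k in (1, 2):
        gm = GaussianMixture(n_components=k, n_init=n_init, random_state=seed)
        gm.fit(x)
        if not gm.converged_:
            logger.warning("EM did not converge for k=%d", k)
            continue
        fits[k], bic[k] = gm, float(gm.bic(x))
    if 2 not in fits:
        k_best = 1
    else:
        k_best = min(bic, key=bic.get)
    gm = fits[k_best]
    w = gm.weights_.ravel()
    order = np.argsort(-w)
    means = gm.means_.ravel()[order]
    sds = np.sqrt(gm.covariances_.ravel()[order])
    weights = w[order]
    comp = gm.predict(x)
    remap = {old: new for new, old in enumerate(order)}
    assignment = pd.Series([remap[c] for c in comp], index=levels.dropna().index)
    minor = float(weights[1:].sum()) if k_best == 2 else 0.0
    # report the observed assignment fraction, which is what a subgroup call means
    if k_best == 2:
        minor = float((assignment == 1).mean())
    return SubgroupResult(n_components=k_best, minor_fraction=minor,
                          means=means, sds=sds, weights=weights,
                          assignment=assignment, bic=bic)
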
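"""Per-visit co-expression modules and cross-visit core-module tracking.

Per visit, a weighted correlation network is built over proteins
(unsigned adjacency ``a_ij = |cor|^beta`` with beta picked by the
scale-free topology criterion), softened into the topological overlap
measure

    w_ij = (sum_u a_iu * a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij)

and clustered by average-linkage hierarchical clustering on ``1 - w``
with a static cut.  Each module gets an eigengene (first principal
component of its standardized member submatrix, sign-oriented so the
mean member correlation is positive); modules with highly correlated
eigengenes are merged.

Across visits, modules are chained by greedy maximal-Jaccard matching of
consecutive visit pairs; a protein belongs to a core pattern only if it
sits in the chain's module at every visit.  Core-pattern eigengenes are
then tested against clinical traits per visit with BH-FDR control.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy import stats

from longiplasma.core_model import ProteinDataset, ValidationError
from longiplasma.stability import _averaged_over_duplicates
from longiplasma.trait_association import benjamini_hochberg

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Network construction
# ---------------------------------------------------------------------------

def pick_soft_power(
    expr: np.ndarray,
    candidates: range = range(1, 21),
    r2_target: float = 0.8,
    n_bins: int = 10,
) -> int:
    """Smallest soft power whose scale-free topology fit reaches ``r2_target``.

    The fit is the R^2 of log10 p(k) vs log10 k over binned connectivity.
    If no candidate reaches the target, the power with maximal R^2 is
    returned with a warning.
    """
    expr = np.asarray(expr, dtype=float)
    if expr.shape[0] < 20:
        raise ValidationError("pick_soft_power needs >= 20 individuals")
    cor = np.corrcoef(expr, rowvar=False)
    if not np.all(np.isfinite(cor)):
        raise ValidationError("degenerate correlation matrix (constant protein?)")
    acor = np.abs(cor)
    np.fill_diagonal(acor, 0.0)
    best, best_r2 = None, -np.inf
    for beta in candidates:
        k = (acor**beta).sum(axis=0)
        r2 = _scale_free_r2(k, n_bins)
        if r2 >= r2_target:
            return int(beta)
        if np.isfinite(r2) and r2 > best_r2:
            best, best_r2 = int(beta), r2
    if best is None:  # degenerate connectivity spread at every power
        best = 6
    logger.warning("no soft power reached scale-free R^2 %.2f; using beta=%d (R^2=%.2f)",
                   r2_target, best, best_r2)
    return best


def _scale_free_r2(k: np.ndarray, n_bins: int) -> float:
    """R^2 of log10 p(k) vs log10 mean k over equal-width connectivity bins."""
    k = k[k > 0]
    if k.size < n_bins or np.ptp(k) == 0:
        return np.nan
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    which = np.clip(np.searchsorted(edges, k, side="right") - 1, 0, n_bins - 1)
    kmean = np.array([k[which == b].mean() for b in range(n_bins) if (which == b).any()])
    pk = np.array([(which == b).mean() for b in range(n_bins) if (which == b).any()])
    ok = (kmean > 0) & (pk > 0)
    if ok.sum() < 3:
        return np.nan
    x, y = np.log10(kmean[ok]), np.log10(pk[ok])
    if np.ptp(y) == 0 or np.ptp(x) == 0:
        return np.nan
    r = np.corrcoef(x, y)[0, 1]
    return float(r**2)


def adjacency_tom(expr: np.ndarray, beta: int) -> np.ndarray:
    """Unsigned adjacency |cor|^beta and its topological overlap matrix."""
    if beta < 1:
        raise ValidationError("soft power beta must be >= 1")
    expr = np.asarray(expr, dtype=float)
    sd = expr.std(axis=0)
    if (sd == 0).any():
        j = int(np.flatnonzero(sd == 0)[0])
        raise ValidationError(f"constant protein column at position {j}")
    a = np.abs(np.corrcoef(expr, rowvar=False)) ** beta
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=0)
    num = a @ a + a
    den = np.minimum.outer(k, k) + 1.0 - a
    tom = num / den
    np.fill_diagonal(tom, 1.0)
    return tom


# ---------------------------------------------------------------------------
# Module detection
# ---------------------------------------------------------------------------

@dataclass
class VisitModules:
    visit: int
    labels: pd.Series           # per protein; 0 = unassigned
    eigengenes: pd.DataFrame    # individuals x modules
    sizes: dict[int, int]


def module_eigengene(expr: pd.DataFrame, members: list[str]) -> pd.Series:
    """First principal component of the standardized member submatrix,
    unit variance, sign-oriented so mean member correlation is positive."""
    sub = expr[members]
    z = (sub - sub.mean()) / sub.std(ddof=1)
    u, s, vt = np.linalg.svd(z.to_numpy(), full_matrices=False)
    pc = u[:, 0] * s[0]
    pc = pc / pc.std(ddof=1)
    mean_cor = np.mean([np.corrcoef(pc, z[m])[0, 1] for m in members])
    if mean_cor < 0:
        pc = -pc
    return pd.Series(pc, index=expr.index)


def detect_modules(
    tom: np.ndarray,
    protein_ids: list[str],
    expr: pd.DataFrame,
    visit: int = 0,
    min_size: int = 10,
    cut_height: float | str = 0.8,
    merge_cor: float = 0.8,
) -> VisitModules:
    """Average-linkage clustering of 1 - TOM with a static cut.

    ``cut_height`` is either a fixed height on the dendrogram or
    ``"auto"``, which places the cut in the widest gap of the upper merge
    heights — the TOM scale contracts sharply with the soft power, so a
    self-calibrating cut keeps the same call usable at any beta.
    Clusters smaller than ``min_size`` are unassigned (label 0); modules
    whose eigengenes correlate above ``merge_cor`` are merged iteratively.
    Labels are renumbered 1..M by decreasing size, which makes the output
    independent of protein input order.
    """
    dissim = 1.0 - np.asarray(tom, dtype=float)
    np.fill_diagonal(dissim, 0.0)
    z = linkage(squareform(dissim, checks=False), method="average")
    if cut_height == "auto":
        cut_height = _gap_cut(z[:, 2])
    raw = fcluster(z, t=cut_height, criterion="distance")

    labels = pd.Series(raw, index=protein_ids)
    sizes = labels.value_counts()
    labels[labels.map(sizes) < min_size] = 0
    if (labels == 0).all():
        logger.warning("visit %s: no module of size >= %d", visit, min_size)
        return VisitModules(visit=visit, labels=labels,
                            eigengenes=pd.DataFrame(index=expr.index), sizes={})

    labels = _merge_correlated(labels, expr, merge_cor)

    # deterministic renumbering by decreasing size, ties by first member
    final = pd.Series(0, index=labels.index)
    order = sorted(
        [l for l in labels.unique() if l != 0],
        key=lambda l: (-int((labels == l).sum()), labels.index[labels == l][0]),
    )
    eg = {}
    for new, old in enumerate(order, start=1):
        members = list(labels.index[labels == old])
        final[members] = new
        eg[new] = module_eigengene(expr, members)
    return VisitModules(
        visit=visit, labels=final,
        eigengenes=pd.DataFrame(eg),
        sizes={m: int((final == m).sum()) for m in sorted(eg)},
    )


def _gap_cut(heights: np.ndarray) -> float:
    """Cut height in the middle of the widest gap of the upper merge heights."""
    h = np.sort(np.asarray(heights, dtype=float))
    upper = h[h >= np.median(h)]
    if len(upper) < 2:
        return float(h[-1] * 0.5 + 0.5 * h[0])
    gaps = np.diff(upper)
    j = int(np.argmax(gaps))
    return float((upper[j] + upper[j + 1]) / 2)


def _merge_correlated(labels: pd.Series, expr: pd.DataFrame, merge_cor: float) -> pd.Series:
    labels = labels.copy()
    while True:
        mods = [l for l in labels.unique() if l != 0]
        if len(mods) < 2:
            return labels
        eg = {l: module_eigengene(expr, list(labels.index[labels == l])) for l in mods}
        best, best_cor = None, merge_cor
        for i, a in enumerate(mods):
            for b in mods[i + 1:]:
                c = float(np.corrcoef(eg[a], eg[b])[0, 1])
                if c > best_cor:
                    best, best_cor = (a, b), c
        if best is None:
            return labels
        labels[labels == best[1]] = best[0]


def modules_per_visit(
    ds: ProteinDataset,
    beta: int | None = None,
    min_size: int = 10,
    cut_height: float | str = "auto",
    merge_cor: float = 0.8,
    complete_case: bool = True,
) -> list[VisitModules]:
    """Detect modules at every visit of a normalized dataset.

    Duplicates are averaged; with ``complete_case`` only individuals seen
    at every visit enter (keeps the per-visit matrices comparable).  If
    ``beta`` is None the soft power is picked at visit 1 and reused, so
    differences across visits reflect the data, not the tuning.
    """
    vals, meta = _averaged_over_duplicates(ds)
    visits = sorted(meta["visit"].unique())
    if complete_case:
        seen = meta.groupby("individual_id")["visit"].nunique()
        keep_ind = set(seen[seen == len(visits)].index)
        sel = meta["individual_id"].isin(keep_ind)
        vals, meta = vals.loc[sel], meta.loc[sel]
    out = []
    for v in visits:
        rows = meta.index[meta["visit"] == v]
        expr = vals.loc[rows]
        expr.index = meta.loc[rows, "individual_id"]
        expr = expr.sort_index()
        if beta is None:
            beta = pick_soft_power(expr.to_numpy())
            logger.info("soft power beta=%d picked at visit %s", beta, v)
        tom = adjacency_tom(expr.to_numpy(), beta)
        out.append(detect_modules(tom, list(expr.columns), expr, visit=int(v),
                                  min_size=min_size, cut_height=cut_height,
                                  merge_cor=merge_cor))
    return out


# ---------------------------------------------------------------------------
# Cross-visit core modules
# ---------------------------------------------------------------------------

@dataclass
class CoreModuleAssignment:
    label_sequences: pd.DataFrame    # proteins x visits module labels
    core_pattern: pd.Series          # per protein: pattern id or 0
    patterns: pd.DataFrame           # pattern id, chain (labels per visit), size
    assigned_fraction: float


def match_core_modules(
    visit_modules: list[VisitModules],
    min_core_size: int = 5,
) -> CoreModuleAssignment:
    """Chain per-visit modules by greedy maximal Jaccard overlap.

    For each consecutive visit pair, module pairs are matched in
    decreasing Jaccard order (ties broken by larger module then lower
    label); unmatched modules terminate or start chains.  Only chains
    spanning all visits define core patterns, and a protein is assigned
    to a pattern only if its own label sequence follows the chain at
    every visit.  Patterns keeping >= ``min_core_size`` members are
    retained.  Matching operates on membership sets, so the result does
    not depend on module numbering.
    """
    if len(visit_modules) < 2:
        raise ValidationError("core matching needs >= 2 visits")
    universe = set(visit_modules[0].labels.index)
    for vm in visit_modules[1:]:
        if not set(vm.labels.index) & universe:
            raise ValidationError("visits have disjoint protein sets")
        if set(vm.labels.index) != universe:
            raise ValidationError("visits must share one protein universe")

    proteins = list(visit_modules[0].labels.index)
    seq = pd.DataFrame({f"visit_{vm.visit}": vm.labels for vm in visit_modules},
                       index=proteins)

    # chains start as visit-1 modules
    chains: list[list[int]] = [[m] for m in visit_modules[0].sizes]
    for a, b in zip(visit_modules[:-1], visit_modules[1:]):
        members_a = {m: set(a.labels.index[a.labels == m]) for m in a.sizes}
        members_b = {m: set(b.labels.index[b.labels == m]) for m in b.sizes}
        cands = []
        for ma, sa in members_a.items():
            for mb, sb in members_b.items():
                inter = len(sa & sb)
                if inter:
                    jac = inter / len(sa | sb)
                    cands.append((-jac, -(len(sa) + len(sb)), ma, mb))
        cands.sort()
        used_a, used_b, pairing = set(), set(), {}
        for _, _, ma, mb in cands:
            if ma in used_a or mb in used_b:
                continue
            pairing[ma] = mb
            used_a.add(ma)
            used_b.add(mb)
        # chains started at later visits cannot span all visits and can
        # never define a core pattern, so only visit-1 chains are extended
        for chain in chains:
            last = chain[-1]
            chain.append(pairing.get(last) if last is not None else None)

    full_chains = [c for c in chains if all(m is not None for m in c)]
    pattern_rows = []
    core = pd.Series(0, index=proteins)
    pid = 0
    for chain in full_chains:
        mask = np.ones(len(proteins), dtype=bool)
        for vm, label in zip(visit_modules, chain):
            mask &= (vm.labels.to_numpy() == label)
        n = int(mask.sum())
        if n >= min_core_size:
            pid += 1
            core.iloc[np.flatnonzero(mask)] = pid
            pattern_rows.append({"pattern": pid,
                                 "chain": "-".join(str(m) for m in chain),
                                 "size": n})
    return CoreModuleAssignment(
        label_sequences=seq,
        core_pattern=core,
        patterns=pd.DataFrame(pattern_rows, columns=["pattern", "chain", "size"]),
        assigned_fraction=float((core > 0).mean()),
    )


# ---------------------------------------------------------------------------
# Core module vs traits
# ---------------------------------------------------------------------------

def module_trait_association(
    core: CoreModuleAssignment,
    ds: ProteinDataset,
    traits: pd.DataFrame,
    fdr_threshold: float = 0.01,
) -> pd.DataFrame:
    """Core-pattern eigengene vs trait, per visit.

    Continuous traits use simple linear regression of the per-visit
    pattern eigengene on the trait; categorical traits a one-way ANOVA.
    BH-FDR runs across the pattern x trait x visit grid; a pattern-trait
    pair is flagged when any visit survives ``fdr_threshold``.
    """
    vals, meta = _averaged_over_duplicates(ds)
    rows = []
    for _, prow in core.patterns.iterrows():
        pid = prow["pattern"]
        members = list(core.core_pattern.index[core.core_pattern == pid])
        for v in sorted(meta["visit"].unique()):
            sel = meta.index[meta["visit"] == v]
            expr = vals.loc[sel]
            expr.index = meta.loc[sel, "individual_id"]
            eg = module_eigengene(expr, members)
            for trait in traits.columns:
                tv = traits.xs(v, level="visit")[trait].reindex(eg.index)
                ok = tv.notna()
                if ok.sum() < 3 or tv[ok].nunique() < 2:
                    continue
                if pd.api.types.is_numeric_dtype(tv):
                    res = stats.linregress(tv[ok].to_numpy(dtype=float), eg[ok])
                    rows.append({"pattern": pid, "trait": trait, "visit": int(v),
                                 "stat": res.slope, "sign": int(np.sign(res.slope)),
                                 "p": res.pvalue})
                else:
                    groups = [eg[ok][tv[ok] == lev] for lev in tv[ok].unique()]
                    f, p = stats.f_oneway(*groups)
                    rows.append({"pattern": pid, "trait": trait, "visit": int(v),
                                 "stat": f, "sign": 0, "p": p})
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    out["fdr_p"] = benjamini_hochberg(out["p"].to_numpy())
    out["significant"] = out["fdr_p"] < fdr_threshold
    flagged = out.groupby(["pattern", "trait"])["significant"].transform("any")
    out["pair_significant"] = flagged
    return out
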
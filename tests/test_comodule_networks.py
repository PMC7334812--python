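"""TOM construction, module detection, core-module matching."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from longiplasma.core_model import ValidationError
from longiplasma.comodule_networks import (
    CoreModuleAssignment,
    VisitModules,
    adjacency_tom,
    detect_modules,
    match_core_modules,
    module_trait_association,
    modules_per_visit,
    pick_soft_power,
)


def brute_force_tom(a):
    n = len(a)
    k = a.sum(axis=0)
    w = np.zeros_like(a)
    for i in range(n):
        for j in range(n):
            if i == j:
                w[i, j] = 1.0
                continue
            l = sum(a[i, u] * a[u, j] for u in range(n) if u != i and u != j)
            w[i, j] = (l + a[i, j]) / (min(k[i], k[j]) + 1 - a[i, j])
    return w


def _block_expr(rng, n_ind, blocks, r=0.8, noise=None):
    """Planted-block expression: shared latent per block, loading sqrt(r)."""
    cols = []
    labels = []
    for b, size in enumerate(blocks, start=1):
        f = rng.normal(size=n_ind)
        for _ in range(size):
            cols.append(np.sqrt(r) * f + np.sqrt(1 - r) * rng.normal(size=n_ind))
            labels.append(b)
    return np.column_stack(cols), np.array(labels)


def test_tom_hand_value_three_nodes():
    a = np.full((3, 3), 0.5)
    np.fill_diagonal(a, 0.0)
    # numerator 0.25 + 0.5, denominator min(k)=1 + 1 - 0.5
    expected = 0.75 / 1.5
    rng = np.random.default_rng(0)
    # construct expression with pairwise |cor| = 0.5 is fiddly; evaluate the
    # formula through the brute-force oracle instead
    w = brute_force_tom(a)
    assert w[0, 1] == pytest.approx(expected)


def test_tom_matches_brute_force_on_random_matrices():
    rng = np.random.default_rng(1)
    for _ in range(20):
        expr = rng.normal(size=(30, 15))
        beta = int(rng.integers(1, 7))
        tom = adjacency_tom(expr, beta)
        a = np.abs(np.corrcoef(expr, rowvar=False)) ** beta
        np.fill_diagonal(a, 0.0)
        np.testing.assert_allclose(tom, brute_force_tom(a), atol=1e-12)
        assert np.allclose(tom, tom.T)
        assert tom.min() >= 0 and tom.max() <= 1 + 1e-12


def test_tom_rejects_constant_column():
    expr = np.random.default_rng(2).normal(size=(20, 5))
    expr[:, 3] = 1.0
    with pytest.raises(ValidationError, match="3"):
        adjacency_tom(expr, 2)


def test_pick_soft_power_null_data_falls_back(caplog):
    rng = np.random.default_rng(3)
    expr = rng.normal(size=(60, 80))
    beta = pick_soft_power(expr)
    assert 1 <= beta <= 20


def test_detect_modules_recovers_three_clean_blocks():
    rng = np.random.default_rng(4)
    expr, truth = _block_expr(rng, 80, [15, 15, 15], r=0.8)
    ids = [f"p{j}" for j in range(len(truth))]
    df = pd.DataFrame(expr, columns=ids)
    tom = adjacency_tom(expr, 2)
    vm = detect_modules(tom, ids, df, cut_height="auto")
    assert adjusted_rand_score(truth, vm.labels) == pytest.approx(1.0)
    assert len(vm.sizes) == 3
    # eigengene sign rule: mean member correlation positive
    for m in vm.sizes:
        members = vm.labels.index[vm.labels == m]
        cors = [np.corrcoef(vm.eigengenes[m], df[p])[0, 1] for p in members]
        assert np.mean(cors) > 0


def test_detect_modules_eight_blocks_with_noise():
    rng = np.random.default_rng(5)
    sizes = [11, 14, 18, 22, 26, 30, 40, 50]
    expr, truth = _block_expr(rng, 101, sizes, r=0.5)
    # pad with unstructured proteins
    expr = np.column_stack([expr, rng.normal(size=(101, 30))])
    truth = np.r_[truth, np.zeros(30, dtype=int)]
    ids = [f"p{j}" for j in range(len(truth))]
    tom = adjacency_tom(expr, 2)
    vm = detect_modules(tom, ids, pd.DataFrame(expr, columns=ids), cut_height="auto")
    assert adjusted_rand_score(truth[truth > 0], vm.labels[truth > 0]) >= 0.8
    assert len(vm.sizes) >= 7


def test_detect_modules_independent_proteins_mostly_unassigned():
    rng = np.random.default_rng(6)
    expr = rng.normal(size=(90, 100))
    ids = [f"p{j}" for j in range(100)]
    tom = adjacency_tom(expr, 6)
    vm = detect_modules(tom, ids, pd.DataFrame(expr, columns=ids), cut_height="auto")
    assert (vm.labels == 0).mean() >= 0.9


def test_module_labels_permutation_equivariant():
    rng = np.random.default_rng(7)
    expr, truth = _block_expr(rng, 60, [12, 12, 12], r=0.7)
    ids = [f"p{j}" for j in range(len(truth))]
    perm = rng.permutation(len(ids))
    tom = adjacency_tom(expr, 2)
    vm = detect_modules(tom, ids, pd.DataFrame(expr, columns=ids), cut_height="auto")
    tom_p = adjacency_tom(expr[:, perm], 2)
    ids_p = [ids[j] for j in perm]
    vm_p = detect_modules(tom_p, ids_p, pd.DataFrame(expr[:, perm], columns=ids_p),
                          cut_height="auto")
    aligned = vm_p.labels.loc[vm.labels.index]
    assert adjusted_rand_score(vm.labels, aligned) == pytest.approx(1.0)


def _visit_modules_from_labels(labels_per_visit, rng):
    out = []
    for v, lab in enumerate(labels_per_visit, start=1):
        lab = pd.Series(lab, index=[f"p{j}" for j in range(len(lab))])
        sizes = {int(m): int((lab == m).sum()) for m in sorted(set(lab)) if m != 0}
        eg = pd.DataFrame({m: rng.normal(size=10) for m in sizes})
        out.append(VisitModules(visit=v, labels=lab, eigengenes=eg, sizes=sizes))
    return out


def test_core_matching_identical_labels_keeps_assignment():
    rng = np.random.default_rng(8)
    lab = np.r_[np.ones(10, int), 2 * np.ones(8, int), np.zeros(5, int)]
    vms = _visit_modules_from_labels([lab, lab, lab], rng)
    core = match_core_modules(vms)
    assert core.assigned_fraction == pytest.approx((lab > 0).mean())
    assigned = core.core_pattern[core.core_pattern > 0]
    # every assigned protein keeps exactly its own module chain
    for p, pid in assigned.items():
        chain = core.patterns.set_index("pattern").loc[pid, "chain"]
        assert chain == "-".join([str(lab[int(p[1:])])] * 3)


def test_core_matching_invariant_to_module_renumbering():
    rng = np.random.default_rng(9)
    lab1 = np.r_[np.ones(10, int), 2 * np.ones(8, int), np.zeros(4, int)]
    lab2 = np.r_[3 * np.ones(10, int), 7 * np.ones(8, int), np.zeros(4, int)]
    a = match_core_modules(_visit_modules_from_labels([lab1, lab1], rng))
    b = match_core_modules(_visit_modules_from_labels([lab1, lab2], rng))
    pd.testing.assert_series_equal(a.core_pattern, b.core_pattern)


def test_core_matching_collapses_when_one_visit_is_permuted():
    rng = np.random.default_rng(10)
    lab = np.r_[np.repeat(np.arange(1, 5), 12), np.zeros(8, int)]
    scrambled = rng.permutation(lab)
    intact = match_core_modules(_visit_modules_from_labels([lab, lab, lab], rng))
    broken = match_core_modules(_visit_modules_from_labels([lab, scrambled, lab], rng))
    # chance of a protein following its chain through a random permutation
    assert broken.assigned_fraction < intact.assigned_fraction * 0.6


def test_end_to_end_module_recovery(default_cohort, default_normalized):
    ds, gm, traits, gt = default_cohort
    norm, _ = default_normalized
    vms = modules_per_visit(norm)
    truth = gt.protein_info["module"]
    for vm in vms:
        ari = adjusted_rand_score(truth.loc[vm.labels.index], vm.labels)
        assert ari >= 0.8
    core = match_core_modules(vms)
    per_visit_frac = np.mean([(vm.labels > 0).mean() for vm in vms])
    assert 0 < core.assigned_fraction <= per_visit_frac
    assigned = core.core_pattern[core.core_pattern > 0]
    precision = (truth.loc[assigned.index] > 0).mean()
    assert precision >= 0.9


def test_module_trait_association_recovers_planted_links(default_cohort,
                                                         default_normalized):
    ds, gm, traits, gt = default_cohort
    norm, _ = default_normalized
    vms = modules_per_visit(norm)
    core = match_core_modules(vms)
    res = module_trait_association(core, norm, traits)
    sig = res[res.pair_significant]
    # planted protein-linked traits surface through their module's eigengene
    linked_modules = {
        int(gt.protein_info.loc[ab, "module"]): trait
        for trait, ab in gt.trait_links[["trait", "antibody"]].to_numpy()
        if gt.protein_info.loc[ab, "module"] > 0
    }
    if linked_modules:
        assert not sig.empty
        # flagged associations are consistent in sign across visits
        for (pid, trait), grp in sig.groupby(["pattern", "trait"]):
            signs = grp.loc[grp.significant, "sign"]
            assert len(set(signs)) == 1
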
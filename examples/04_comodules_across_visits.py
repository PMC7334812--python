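"""Detect co-expression modules per visit and track them across the year.

Per visit: unsigned weighted correlation network -> topological overlap ->
average-linkage clustering -> module eigengenes.  Across visits: modules
are chained by maximal Jaccard overlap; a protein joins a core pattern
only if it follows the same chain at every visit.
"""

from sklearn.metrics import adjusted_rand_score

from longiplasma.comodule_networks import (
    match_core_modules,
    module_trait_association,
    modules_per_visit,
)
from longiplasma.normalization import normalize_pipeline
from longiplasma.synthetic_data import SimConfig, simulate_cohort

ds, _, traits, truth = simulate_cohort(SimConfig(seed=1))
norm, _ = normalize_pipeline(ds)

vms = modules_per_visit(norm)
for vm in vms:
    ari = adjusted_rand_score(truth.protein_info["module"].loc[vm.labels.index],
                              vm.labels)
    print(f"visit {vm.visit}: {len(vm.sizes)} modules, "
          f"sizes {sorted(vm.sizes.values(), reverse=True)}, ARI {ari:.2f}")

core = match_core_modules(vms)
print(f"\ncore patterns: {len(core.patterns)}; "
      f"{core.assigned_fraction:.1%} of proteins follow one pattern all year")
print(core.patterns.to_string(index=False))

mta = module_trait_association(core, norm, traits)
sig = mta[mta.pair_significant]
print("\nmodule-trait links (consistent sign across visits):")
print(sig.groupby(["pattern", "trait"])["sign"].agg(["first", "count"]))
# Patterns whose eigengene tracks a clinical trait at every visit mirror
# the planted protein-trait links routed through module co-expression.
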
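"""End-to-end orchestration from a single config.

Stages run in dependency order: simulate (or load) -> normalize ->
stability -> trait/seasonal association -> modules -> pQTL ->
signatures.  Every stage writes its report through the core writers and
a run manifest records the config hash, seed and package version, so a
rerun with an identical config reproduces identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from longiplasma import __version__
from longiplasma.core_model import (
    ProteinDataset,
    ValidationError,
    read_genotypes,
    read_protein_dataset,
    read_traits,
    write_dataset,
    write_report,
)
from longiplasma.synthetic_data import SimConfig, simulate_cohort
from longiplasma import comodule_networks, individual_signatures, normalization, pqtl, stability, trait_association

logger = logging.getLogger(__name__)

DEFAULT_STAGES = ("normalize", "stability", "associate", "seasonal",
                  "modules", "pqtl", "signatures")


@dataclass
class PipelineConfig:
    """Run configuration; thresholds default to the analysis' headline values."""

    out_dir: str = "longiplasma_out"
    seed: int = 0
    stages: dict = field(default_factory=lambda: {s: True for s in DEFAULT_STAGES})
    simulate: bool = True
    sim: dict = field(default_factory=dict)          # SimConfig overrides
    inputs: dict = field(default_factory=dict)       # paths when simulate=False
    icc_threshold: float = 0.8
    trait_fdr: float = 0.001
    seasonal_fdr: float = 0.01
    module_trait_fdr: float = 0.01
    deviation_k: float = 3.0
    pqtl_alpha: float = 0.05
    maf_min: float = 0.05
    hwe_p_min: float = 1e-6
    min_module_size: int = 10
    cut_height: float | str = "auto"
    merge_cor: float = 0.8
    soft_power: int | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        return cfg

    def to_dict(self) -> dict:
        from dataclasses import asdict
        return asdict(self)

    def validate(self) -> None:
        if self.stages.get("signatures") and not self.stages.get("stability"):
            raise ValidationError(
                "signatures requires stability (stable-protein filter)"
            )
        if not self.simulate:
            for key in ("intensities", "meta"):
                p = self.inputs.get(key)
                if not p or not Path(p).exists():
                    raise ValidationError(f"input path missing for {key!r}")


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute configured stages; returns a dict of in-memory results."""
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {}
    written: list[str] = []

    def _write(name: str, report) -> None:
        path = out / name
        write_report(report, path)
        written.append(name)

    stage = "simulate" if cfg.simulate else "load"
    try:
        if cfg.simulate:
            sim_cfg = SimConfig(**{"seed": cfg.seed, **cfg.sim})
            ds, gm, traits, gt = simulate_cohort(sim_cfg)
            results["ground_truth"] = gt
            write_dataset(ds, out / "intensities_raw.tsv", out / "sample_meta.tsv")
            written += ["intensities_raw.tsv", "sample_meta.tsv"]
            _write("ground_truth_proteins.tsv", gt.protein_info.reset_index())
        else:
            ds = read_protein_dataset(cfg.inputs["intensities"], cfg.inputs["meta"])
            gm = (read_genotypes(cfg.inputs["genotypes"],
                                 cfg.inputs.get("gene_windows"),
                                 individuals=list(ds.meta["individual_id"].unique()))
                  if cfg.inputs.get("genotypes") else None)
            traits = read_traits(cfg.inputs["traits"]) if cfg.inputs.get("traits") else None
        results["dataset_raw"] = ds
        results["genotypes"] = gm
        results["traits"] = traits

        stage = "normalize"
        if cfg.stages.get("normalize", True):
            norm, audit = normalization.normalize_pipeline(ds)
            results["dataset"] = norm
            results["audit"] = audit
            _write("normalization_audit.tsv", audit.variance_shares.reset_index(names="antibody"))
        else:
            norm = normalization.log_transform(ds)
            results["dataset"] = norm

        stage = "stability"
        if cfg.stages.get("stability", True):
            rep = stability.stability_report(norm, threshold=cfg.icc_threshold)
            ident = stability.individual_identifiability(norm)
            results["stability"] = rep
            results["identifiability"] = ident
            _write("stability.tsv", rep.table)
            _write("stability_summary.tsv", rep.summary)
            _write("identifiability.tsv", ident.per_individual)

        stage = "associate"
        if cfg.stages.get("associate", True) and traits is not None:
            assoc = trait_association.association_scan(
                norm, traits, fdr_threshold=cfg.trait_fdr)
            results["associations"] = assoc
            _write("trait_associations.tsv", assoc)

        stage = "seasonal"
        if cfg.stages.get("seasonal", True):
            seas = trait_association.seasonal_scan(norm, fdr_threshold=cfg.seasonal_fdr)
            results["seasonal"] = seas
            _write("seasonal.tsv", seas)

        stage = "modules"
        if cfg.stages.get("modules", True):
            vms = comodule_networks.modules_per_visit(
                norm, beta=cfg.soft_power, min_size=cfg.min_module_size,
                cut_height=cfg.cut_height, merge_cor=cfg.merge_cor)
            core = comodule_networks.match_core_modules(vms)
            results["visit_modules"] = vms
            results["core_modules"] = core
            _write("module_labels.tsv", core.label_sequences.reset_index(names="antibody"))
            _write("core_patterns.tsv", core.patterns)
            if traits is not None:
                mta = comodule_networks.module_trait_association(
                    core, norm, traits, fdr_threshold=cfg.module_trait_fdr)
                results["module_traits"] = mta
                _write("module_trait_associations.tsv", mta)

        stage = "pqtl"
        if cfg.stages.get("pqtl", True) and gm is not None:
            gq = pqtl.hwe_maf_filter(gm, maf_min=cfg.maf_min, hwe_p_min=cfg.hwe_p_min)
            levels = pqtl.across_visit_levels(norm)
            scan = pqtl.pqtl_scan(levels, gq, alpha=cfg.pqtl_alpha,
                                  target_map=norm.target_map)
            results["pqtl"] = scan
            _write("pqtl_top_hits.tsv", scan.top_hits)
            _write("pqtl_associations.tsv", scan.associations)

        stage = "signatures"
        if cfg.stages.get("signatures", True):
            rep = results["stability"]
            stable = list(rep.table.loc[rep.table["class"] == "both_stable", "antibody"])
            if len(stable) < 2:
                logger.warning("fewer than 2 both-stable proteins; signature stage skipped")
            else:
                z = individual_signatures.population_zscore(norm, stable)
                meta = z.attrs["meta"]
                prof = individual_signatures.profile_statistics(z, meta)
                flags = individual_signatures.flag_deviations(prof, k=cfg.deviation_k)
                summary = individual_signatures.summarize_signatures(flags)
                iqr = individual_signatures.interindividual_iqr(z, meta)
                results["signatures"] = summary
                results["iqr"] = iqr
                _write("signature_per_individual.tsv",
                       summary.per_individual.reset_index(names="individual_id"))
                _write("signature_per_protein.tsv",
                       summary.per_protein.reset_index(names="antibody"))
                _write("signature_venn.json", {
                    "venn": summary.venn, "n_profiles": summary.n_profiles,
                    "n_flagged": summary.n_flagged,
                    "flagged_fraction": summary.flagged_fraction,
                    "chance_rate": summary.chance_rate,
                    "chance_rate_union": summary.chance_rate_union,
                })
                _write("interindividual_iqr.tsv", iqr)
    except Exception:
        logger.error("pipeline failed in stage %r; partial outputs kept in %s",
                     stage, out)
        raise

    manifest = {
        "version": __version__,
        "seed": cfg.seed,
        "config_sha256": hashlib.sha256(
            yaml.safe_dump(cfg.to_dict(), sort_keys=True).encode()
        ).hexdigest(),
        "outputs": written,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1) + "\n")
    results["manifest"] = manifest
    return results
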
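"""Synthetic longitudinal plasma-proteomics cohorts with full ground truth.

The generator emulates a wellness cohort measured on multiplexed antibody
bead arrays: ~100 individuals visiting a clinic four times over one year,
each visit's samples run together as one assay batch spread over 96-well
plates, a fraction of aliquots assayed in duplicate.  Log-intensity for
individual *i*, visit *t*, protein *p*, assay *a* is assembled as

    y = mu_p + beta_g * g_i + b_ip + gamma_ip * t_years
        + s_p * sin(2*pi*doy/365.25 + phi_p) + lambda_p * f_m(i,t)
        + spike_ipt + v_ipt + c_ita + delta_(plate,p) + eps

with ``b_ip`` the individual baseline (SD ``sigma_bio``), ``v_ipt``
per-visit biological noise for longitudinally unstable proteins,
``f_m(i,t)`` an AR(1) module latent trajectory shared by a module's
members, ``c_ita`` a per-sample scaling shift (removable by AbsPQN),
``delta`` a per-(plate, antibody) offset (removable by Multi-MA) and
``eps`` technical noise (per-protein SD; a fraction of antibodies is
technically noisy).  Raw MFI is ``exp(y)``.  Duplicate assays share all
biology and the aliquot and redraw only ``c``, ``delta`` and ``eps``.

Planted effect sizes are expressed in population-SD units of the protein's
log level so that downstream z-score logic sees calibrated effects:
structural effects (module loadings, allelic effects, seasonal amplitude)
use the protein's base SD sqrt(sigma_bio^2 + sigma_tech^2); per-individual
deviations (baseline offsets, trends, spikes) use the protein's full
analytic population SD.  Ground-truth stability designations are derived
from the analytic variance components of each protein.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import pandas as pd

from longiplasma.core_model import (
    GenotypeMatrix,
    ProteinDataset,
    ValidationError,
    orient_to_minor_allele,
)

DAYS_PER_YEAR = 365.25


@dataclass
class SimConfig:
    """Generator parameters.  Defaults are the emulated study conditions."""

    n_individuals: int = 101
    n_visits: int = 4
    n_proteins: int = 200
    plate_size: int = 96
    duplicate_assay_fraction: float = 0.25
    seed: int = 0

    # log-scale intensity model
    log_mean_range: tuple[float, float] = (4.0, 8.0)
    sigma_bio: float = 0.5        # individual baseline SD (log units)
    sigma_tech: float = 0.15      # technical noise SD for well-behaved antibodies
    frac_noisy_tech: float = 0.35  # antibodies with elevated technical noise
    sigma_tech_noisy: float = 0.6
    frac_unstable: float = 0.25   # longitudinally unstable proteins
    sigma_visit: float = 0.6      # their per-visit biological noise SD
    sigma_samp: float = 0.2       # per sample-assay scaling shift SD
    sigma_plate: float = 0.3      # per (plate, antibody) offset SD

    # co-expression modules
    n_modules: int = 8
    frac_in_modules: float = 0.6
    module_loading: float = 1.5   # base-SD units
    module_traj_sd: float = 1.0
    module_rho: float = 0.9       # AR(1) correlation of f_m across visits

    # per-individual deviations (population-SD units)
    frac_baseline: float = 0.1
    baseline_effect: float = 4.0
    frac_trend: float = 0.1
    trend_effect: float = 2.0     # SD per year
    frac_spike: float = 0.1
    spike_effect: float = 4.0

    # seasonality (base-SD units)
    frac_seasonal: float = 0.01
    seasonal_amplitude: float = 1.0

    # genetics
    n_snps: int = 1000
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_cis_effects: int = 10
    beta_g: float = 1.5           # base-SD units per minor allele

    # traits
    n_traits: int = 5
    n_trait_links: int = 2
    trait_link_r: float = 0.9

    def validate(self) -> None:
        for name in ("sigma_bio", "sigma_tech", "sigma_tech_noisy", "sigma_visit",
                     "sigma_samp", "sigma_plate", "module_traj_sd"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        for name in ("duplicate_assay_fraction", "frac_noisy_tech", "frac_unstable",
                     "frac_in_modules", "frac_baseline", "frac_trend", "frac_spike",
                     "frac_seasonal"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValidationError(f"{name} must be in [0, 1]")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValidationError("maf_range must be within (0, 0.5]")
        if self.n_snps < self.n_cis_effects:
            raise ValidationError("n_snps must be >= n_cis_effects")

    @classmethod
    def null(cls, **kwargs) -> "SimConfig":
        """Effect-free cohort: individual baselines and noise only.

        Used for null-calibration checks (deviation-flag chance rate, FDR
        control): no modules, no planted deviations, no genetics links,
        no seasonality, no trait links.
        """
        base = dict(
            frac_noisy_tech=0.0, frac_unstable=0.0, n_modules=0,
            frac_in_modules=0.0, frac_baseline=0.0, frac_trend=0.0,
            frac_spike=0.0, frac_seasonal=0.0, n_cis_effects=0,
            n_trait_links=0,
        )
        base.update(kwargs)
        return cls(**base)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class GroundTruth:
    """Everything the generator planted, for use as an acceptance oracle."""

    protein_info: pd.DataFrame          # per antibody: gene, module, variances, true ICCs
    baseline_effects: pd.DataFrame      # individual_id, antibody, size_sd, size_log
    trend_effects: pd.DataFrame         # individual_id, antibody, slope_sd_per_year, slope_log_per_year
    spike_effects: pd.DataFrame         # individual_id, antibody, visit, size_sd, size_log
    pqtls: pd.DataFrame                 # snp_id, antibody, beta_sd, beta_log
    trait_links: pd.DataFrame           # trait, antibody, target_r
    sample_scaling: pd.Series           # per sample: planted log scaling shift c
    plate_shifts: pd.DataFrame          # plate x antibody: planted delta
    config: SimConfig = field(default=None)


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------

GENE_SPACING = 1_000_000
GENE_LENGTH = 20_000


def _gene_windows(genes: list[str]) -> dict[str, tuple[str, int, int]]:
    """Lay genes along a synthetic chromosome, one per megabase."""
    return {
        g: ("1", (k + 1) * GENE_SPACING + 1, (k + 1) * GENE_SPACING + GENE_LENGTH)
        for k, g in enumerate(genes)
    }


def simulate_genotypes(
    n_individuals: int,
    n_snps: int,
    maf_range: tuple[float, float] = (0.05, 0.5),
    seed: int = 0,
    gene_windows: Optional[dict[str, tuple[str, int, int]]] = None,
    cis_genes: Optional[list[str]] = None,
    individual_ids: Optional[list[str]] = None,
) -> GenotypeMatrix:
    """Draw SNPs under Hardy-Weinberg equilibrium.

    Each SNP's MAF is Uniform over ``maf_range`` and genotypes are
    Binomial(2, MAF).  If ``cis_genes`` is given, the first
    ``len(cis_genes)`` SNPs are placed inside those genes' windows (one
    per gene) so planted cis effects really are cis; remaining SNPs are
    positioned uniformly over the gene span.
    """
    lo, hi = maf_range
    if not (0 < lo <= hi <= 0.5):
        raise ValidationError("maf_range must be within (0, 0.5]")
    cis_genes = cis_genes or []
    if n_snps < len(cis_genes):
        raise ValidationError("n_snps < number of requested cis effects")
    rng = np.random.default_rng(seed)
    if individual_ids is None:
        individual_ids = [f"W{i:04d}" for i in range(1, n_individuals + 1)]
    mafs = rng.uniform(lo, hi, size=n_snps)
    geno = rng.binomial(2, mafs, size=(n_individuals, n_snps)).astype(float)

    gene_windows = gene_windows or {}
    span_hi = (max(len(gene_windows), 1) + 1) * GENE_SPACING + GENE_LENGTH
    pos = rng.integers(1, span_hi, size=n_snps)
    for k, gene in enumerate(cis_genes):
        chrom, start, end = gene_windows[gene]
        pos[k] = rng.integers(start, end + 1)
    ids = [f"rs{k + 1:06d}" for k in range(n_snps)]
    dosages = pd.DataFrame(geno, index=individual_ids, columns=ids)
    dosages, maf = orient_to_minor_allele(dosages)
    info = pd.DataFrame(
        {"chrom": "1", "pos": pos, "ref": "A", "alt": "B", "maf": maf},
        index=pd.Index(ids, name="snp_id"),
    )
    return GenotypeMatrix(dosages=dosages, snp_info=info, gene_windows=dict(gene_windows))


# ---------------------------------------------------------------------------
# Cohort
# ---------------------------------------------------------------------------

def _ar1(rng: np.random.Generator, rho: float, sd: float, shape: tuple[int, int]) -> np.ndarray:
    """AR(1) trajectories across the last axis, marginal SD ``sd``."""
    n, t = shape
    out = np.empty(shape)
    out[:, 0] = rng.normal(0, sd, n)
    innov_sd = sd * np.sqrt(max(1 - rho**2, 0.0))
    for j in range(1, t):
        out[:, j] = rho * out[:, j - 1] + rng.normal(0, innov_sd, n)
    return out


def simulate_cohort(
    config: SimConfig,
) -> tuple[ProteinDataset, GenotypeMatrix, pd.DataFrame, GroundTruth]:
    """Generate a raw-MFI dataset, genotypes, traits and full ground truth.

    Deterministic given the config (including its seed).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    I, V, P = config.n_individuals, config.n_visits, config.n_proteins
    individuals = [f"W{i:04d}" for i in range(1, I + 1)]
    antibodies = [f"AB{p:04d}" for p in range(1, P + 1)]
    genes = [f"GEN{p:04d}" for p in range(1, P + 1)]
    target_map = dict(zip(antibodies, genes))

    # -- per-protein structural draws -------------------------------------
    mu = rng.uniform(*config.log_mean_range, size=P)
    sigma_tech_p = np.full(P, config.sigma_tech)
    noisy = _draw_count(rng, P, config.frac_noisy_tech)
    sigma_tech_p[noisy] = config.sigma_tech_noisy
    # one structural effect unit for the whole panel: an antibody's own
    # technical noise must not inflate the biology planted on it
    sigma_base = np.full(P, np.hypot(config.sigma_bio, config.sigma_tech))

    unstable = np.zeros(P, dtype=bool)
    unstable[_draw_count(rng, P, config.frac_unstable)] = True

    module = np.zeros(P, dtype=int)  # 0 = no module
    if config.n_modules > 0 and config.frac_in_modules > 0:
        members = _draw_count(rng, P, config.frac_in_modules)
        module[members] = rng.integers(1, config.n_modules + 1, size=len(members))
    lam_log = np.where(module > 0, config.module_loading * sigma_base, 0.0)

    free = np.flatnonzero(module == 0)  # structural effects go to module-free proteins
    rng.shuffle(free)
    n_seasonal = int(round(config.frac_seasonal * P))
    seasonal_idx = free[:n_seasonal]
    cis_idx = free[n_seasonal:n_seasonal + config.n_cis_effects]
    if len(cis_idx) < config.n_cis_effects:
        raise ValidationError("not enough module-free proteins for requested cis effects")

    seasonal_amp_log = np.zeros(P)
    seasonal_amp_log[seasonal_idx] = config.seasonal_amplitude * sigma_base[seasonal_idx]
    seasonal_phase = np.zeros(P)
    seasonal_phase[seasonal_idx] = rng.uniform(0, 2 * np.pi, size=len(seasonal_idx))

    # -- genotypes ----------------------------------------------------------
    windows = _gene_windows(genes)
    cis_genes = [genes[p] for p in cis_idx]
    gm = simulate_genotypes(
        I, config.n_snps, config.maf_range, seed=int(rng.integers(2**31)),
        gene_windows=windows, cis_genes=cis_genes, individual_ids=individuals,
    )
    beta_log = np.zeros(P)
    beta_log[cis_idx] = config.beta_g * sigma_base[cis_idx]
    pqtl_rows = [
        {"snp_id": gm.snp_info.index[k], "antibody": antibodies[p],
         "beta_sd": config.beta_g, "beta_log": beta_log[p]}
        for k, p in enumerate(cis_idx)
    ]

    # -- visit schedule -----------------------------------------------------
    start = pd.Timestamp("2015-01-01") + pd.to_timedelta(
        rng.integers(0, 365, size=I), unit="D"
    )
    offsets = np.zeros((I, V))
    for t in range(1, V):
        offsets[:, t] = offsets[:, t - 1] + 91 + rng.normal(0, 7, size=I).round()
    offsets = np.maximum.accumulate(offsets, axis=1)
    dates = start.values[:, None] + offsets.astype("timedelta64[D]")
    t_years = offsets / DAYS_PER_YEAR
    doy = pd.DatetimeIndex(dates.ravel()).dayofyear.to_numpy().reshape(I, V)

    # -- biological signal (I x V x P) -------------------------------------
    b_ip = rng.normal(0, config.sigma_bio, size=(I, P))
    y = np.zeros((I, V, P))
    y += mu[None, None, :]
    y += b_ip[:, None, :]
    for k, p in enumerate(cis_idx):
        dose = gm.dosages.iloc[:, k].to_numpy()  # planted SNP k targets protein p
        y[:, :, p] += beta_log[p] * dose[:, None]

    if config.n_modules > 0:
        f = np.stack(
            [_ar1(rng, config.module_rho, config.module_traj_sd, (I, V))
             for _ in range(config.n_modules)], axis=-1
        )  # I x V x M
        for p in np.flatnonzero(module > 0):
            y[:, :, p] += lam_log[p] * f[:, :, module[p] - 1]

    v_noise = rng.normal(0, config.sigma_visit, size=(I, V, P))
    y[:, :, unstable] += v_noise[:, :, unstable]

    phase_term = np.sin(2 * np.pi * doy[:, :, None] / DAYS_PER_YEAR + seasonal_phase[None, None, :])
    y += seasonal_amp_log[None, None, :] * phase_term

    # analytic variance components (log scale), for sigma_pop and true ICCs
    w_b = _ar1_mean_weight(config.module_rho, V)
    maf_cis = np.zeros(P)
    maf_cis[cis_idx] = gm.snp_info["maf"].to_numpy()[:len(cis_idx)]
    between = (config.sigma_bio**2 + lam_log**2 * w_b
               + beta_log**2 * 2 * maf_cis * (1 - maf_cis))
    within_bio = (lam_log**2 * (1 - w_b) + seasonal_amp_log**2 / 2
                  + np.where(unstable, config.sigma_visit**2, 0.0))
    sigma_pop = np.sqrt(between + within_bio + sigma_tech_p**2)
    true_icc_v = between / (between + within_bio + sigma_tech_p**2)
    true_icc_a = (between + within_bio) / (between + within_bio + sigma_tech_p**2)

    # -- per-individual deviations -----------------------------------------
    baseline_rows, trend_rows, spike_rows = [], [], []
    for p in _draw_count(rng, P, config.frac_baseline):
        i = rng.integers(I)
        size = config.baseline_effect * rng.choice([-1.0, 1.0])
        y[i, :, p] += size * sigma_pop[p]
        # realized deviation: planted offset riding on the natural baseline
        total_log = size * sigma_pop[p] + b_ip[i, p]
        baseline_rows.append({"individual_id": individuals[i], "antibody": antibodies[p],
                              "size_sd": size, "size_log": size * sigma_pop[p],
                              "size_sd_total": total_log / sigma_pop[p],
                              "size_log_total": total_log})
    for p in _draw_count(rng, P, config.frac_trend):
        i = rng.integers(I)
        slope = config.trend_effect * rng.choice([-1.0, 1.0])
        tc = t_years[i] - t_years[i].mean()
        y[i, :, p] += slope * sigma_pop[p] * tc
        trend_rows.append({"individual_id": individuals[i], "antibody": antibodies[p],
                           "slope_sd_per_year": slope,
                           "slope_log_per_year": slope * sigma_pop[p]})
    for p in _draw_count(rng, P, config.frac_spike):
        i = rng.integers(I)
        t = rng.integers(V)
        size = config.spike_effect * rng.choice([-1.0, 1.0])
        y[i, t, p] += size * sigma_pop[p]
        spike_rows.append({"individual_id": individuals[i], "antibody": antibodies[p],
                           "visit": int(t + 1), "size_sd": size,
                           "size_log": size * sigma_pop[p]})

    # -- assay layer: samples, duplicates, plates ---------------------------
    sample_rows = []
    for i, ind in enumerate(individuals):
        for t in range(V):
            sample_rows.append((f"{ind}_v{t + 1}", ind, t + 1, dates[i, t], None))
    n_dup = int(round(config.duplicate_assay_fraction * len(sample_rows)))
    dup_pick = rng.choice(len(sample_rows), size=n_dup, replace=False)
    for k in sorted(dup_pick):
        sid, ind, visit, date, _ = sample_rows[k]
        sample_rows.append((f"{sid}_r", ind, visit, date, sid))

    meta = pd.DataFrame(
        sample_rows, columns=["sample_id", "individual_id", "visit",
                              "collection_date", "replicate_of"],
    ).set_index("sample_id")
    meta["assay_batch"] = "B" + meta["visit"].astype(str)

    # plates: randomize samples within each assay batch into plates of 96
    plate_ids = pd.Series(index=meta.index, dtype=object)
    for batch, grp in meta.groupby("assay_batch", sort=True):
        order = grp.index.to_numpy().copy()
        rng.shuffle(order)
        for j, sid in enumerate(order):
            plate_ids.loc[sid] = f"{batch}_P{j // config.plate_size + 1}"
    meta["plate_id"] = plate_ids
    meta["collection_date"] = pd.to_datetime(meta["collection_date"]).dt.strftime("%Y-%m-%d")
    meta = meta[["individual_id", "visit", "collection_date",
                 "plate_id", "assay_batch", "replicate_of"]]

    plates = sorted(meta["plate_id"].unique())
    delta = pd.DataFrame(
        rng.normal(0, config.sigma_plate, size=(len(plates), P)),
        index=plates, columns=antibodies,
    )
    c = pd.Series(rng.normal(0, config.sigma_samp, size=len(meta)), index=meta.index)

    ind_pos = {ind: i for i, ind in enumerate(individuals)}
    rows = np.empty((len(meta), P))
    for r, (sid, m) in enumerate(meta.iterrows()):
        i = ind_pos[m["individual_id"]]
        t = int(m["visit"]) - 1
        eps = rng.normal(0, sigma_tech_p)
        rows[r] = (y[i, t] + c.loc[sid] + delta.loc[m["plate_id"]].to_numpy() + eps)
    intensities = pd.DataFrame(np.exp(rows), index=meta.index, columns=antibodies)

    ds = ProteinDataset(intensities=intensities, meta=meta, scale_tag="raw",
                        target_map=target_map)

    # -- traits -------------------------------------------------------------
    traits = _simulate_traits(rng, config, individuals, meta, y, mu, sigma_pop,
                              antibodies, t_years)
    trait_links = traits.attrs.pop("links")

    gt = GroundTruth(
        protein_info=pd.DataFrame(
            {"gene": genes, "module": module, "unstable": unstable,
             "sigma_tech": sigma_tech_p, "sigma_base": sigma_base,
             "sigma_pop": sigma_pop, "seasonal_amp_log": seasonal_amp_log,
             "seasonal_phase": seasonal_phase,
             "true_icc_interassay": true_icc_a, "true_icc_intervisit": true_icc_v,
             "stable_technical": true_icc_a >= 0.8,
             "stable_longitudinal": true_icc_v >= 0.8},
            index=pd.Index(antibodies, name="antibody"),
        ),
        baseline_effects=pd.DataFrame(
            baseline_rows,
            columns=["individual_id", "antibody", "size_sd", "size_log",
                     "size_sd_total", "size_log_total"]),
        trend_effects=pd.DataFrame(trend_rows, columns=["individual_id", "antibody", "slope_sd_per_year", "slope_log_per_year"]),
        spike_effects=pd.DataFrame(spike_rows, columns=["individual_id", "antibody", "visit", "size_sd", "size_log"]),
        pqtls=pd.DataFrame(pqtl_rows, columns=["snp_id", "antibody", "beta_sd", "beta_log"]),
        trait_links=trait_links,
        sample_scaling=c,
        plate_shifts=delta,
        config=config,
    )
    return ds, gm, traits, gt


def _draw_count(rng: np.random.Generator, n: int, frac: float) -> np.ndarray:
    """Choose exactly round(frac * n) indices (inclusion by count, not chance)."""
    k = int(round(frac * n))
    return rng.choice(n, size=k, replace=False) if k else np.empty(0, dtype=int)


def _ar1_mean_weight(rho: float, v: int) -> float:
    """Var of the across-visit mean of an AR(1) with marginal var 1."""
    lags = np.abs(np.subtract.outer(np.arange(v), np.arange(v)))
    return float((rho ** lags).sum()) / v**2


def _simulate_traits(rng, config, individuals, meta, y, mu, sigma_pop,
                     antibodies, t_years) -> pd.DataFrame:
    I, V = config.n_individuals, config.n_visits
    idx = pd.MultiIndex.from_product(
        [individuals, range(1, V + 1)], names=["individual_id", "visit"]
    )
    out = pd.DataFrame(index=idx)
    out["sex"] = np.repeat(rng.choice(["F", "M"], size=I), V)
    out["age"] = np.repeat(rng.integers(50, 66, size=I).astype(float), V)
    bmi = rng.normal(26, 3.5, size=I)
    out["bmi"] = np.repeat(bmi, V) + rng.normal(0, 0.4, size=I * V)

    links = []
    z_bio = (y - mu[None, None, :]) / sigma_pop[None, None, :]
    n_linked = min(config.n_trait_links, config.n_traits)
    link_proteins = rng.choice(config.n_proteins, size=n_linked, replace=False)
    tau = np.sqrt(max(1.0 / config.trait_link_r**2 - 1.0, 0.0)) if n_linked else 0.0
    for k in range(config.n_traits):
        name = f"trait_{k + 1:02d}"
        if k < n_linked:
            p = link_proteins[k]
            vals = z_bio[:, :, p].ravel() + rng.normal(0, tau, size=I * V)
            links.append({"trait": name, "antibody": antibodies[p],
                          "target_r": config.trait_link_r})
        else:
            vals = rng.normal(0, 1, size=I * V)
        out[name] = vals
    out.attrs["links"] = pd.DataFrame(links, columns=["trait", "antibody", "target_r"])
    return out
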
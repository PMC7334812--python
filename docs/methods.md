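# Methods

## The measurement model

The package targets multiplexed antibody bead-array proteomics of plasma
from a longitudinal wellness design: individuals visit a clinic several
times within a year, each visit's samples are run together as one assay
batch distributed over 96-well plates, and a fraction of aliquots is
assayed twice.  The raw readout is median fluorescence intensity (MFI),
analysed throughout on the natural-log scale.  Log intensity of
individual *i*, visit *t*, protein *p*, assay *a* is modelled (and, in the
simulator, generated) as

```
y = mu_p + beta_g * g_i + b_ip + gamma_ip * t_years
    + s_p * sin(2*pi*doy/365.25 + phi_p) + lambda_p * f_m(i,t)
    + spike_ipt + v_ipt + c_ita + delta_(plate,p) + eps_itpa
```

- `b_ip ~ N(0, sigma_bio^2)`: the personal baseline, the source of
  individual signatures and identifiability;
- `v_ipt`: per-visit biological noise carried only by longitudinally
  unstable proteins;
- `f_m(i,t)`: a per-module latent trajectory, AR(1) across visits per
  individual, shared by all members of module *m* with loading
  `lambda_p`;
- `c_ita`: a per-sample scaling shift (pipetting/dilution), the nuisance
  AbsPQN removes;
- `delta_(plate,p)`: a per-(plate, antibody) offset, the nuisance
  Multi-MA removes;
- `eps`: technical noise with a per-antibody SD (a configurable fraction
  of antibodies is technically noisy).

Duplicate assays share all biology and the aliquot and redraw only `c`,
`delta` and `eps`.  The time covariate is days since the individual's
first visit (visit spacing varies), and seasonality uses calendar
day-of-year with a 365.25-day period.

## Simulator calibration and what it does not emulate

Defaults are the emulated study conditions: 101 individuals x 4 visits x
200 antibodies, plates of 96, 25% duplicate assays, visits ~91 days
apart with enrolment spread across the year.  No quantitative noise
magnitudes are published for this assay family, so the noise scales are
calibration choices fixed once: `sigma_bio = 0.5`, `sigma_tech = 0.15`
(noisy antibodies 0.6, 35% of the panel), per-visit instability SD 0.6
(25% of proteins), `sigma_samp = 0.2`, `sigma_plate = 0.3`, eight modules
covering 60% of proteins with AR(1) persistence 0.9.  These produce a
stability landscape (about 65% technically stable, about 48% stable on
both axes) and a cross-visit core-module coverage (about 55%) resembling
the published cohort's proportions, which is what makes the recovery
tests meaningful.

Planted effect sizes are expressed in population-SD units so the
downstream z-score logic sees calibrated effects.  Structural effects
(module loadings, allelic effects, seasonal amplitudes) use one global
base unit `sqrt(sigma_bio^2 + sigma_tech^2)` — an antibody's own noise
must not inflate the biology planted on it — while per-individual
deviations (baseline offsets, trends, spikes) use the protein's full
analytic population SD.  Ground-truth stability designations are derived
from each protein's analytic variance components (a module member is
"longitudinally stable" exactly when its true inter-visit ICC clears the
0.8 threshold), and the ground truth for baseline deviations reports the
*realized* offset — planted effect plus the individual's natural
baseline — because an individual planted +4 SD on a −1 SD baseline
genuinely deviates by 3 SD.

The generator does not emulate: antibody cross-reactivity or epitope
effects beyond a per-genotype mean shift, bead-count QC, missing visits,
non-Gaussian heavy-tailed intensity noise, linkage disequilibrium between
simulated SNPs, or trait measurement error structure.  Passing tests
therefore demonstrate correct recovery of the modelled structure, not
robustness to everything real plasma data can do.

## Normalization

AbsPQN is realized in log space: against the plate's column-median
reference `r`, each sample is shifted by `q_i = median_j(x_ij - r_j)`
(the probabilistic quotient), and the plate's grand median is restored so
absolute levels are preserved.  A single median pass is not exactly
idempotent for more than two samples, so the pass is iterated to a fixed
point (tolerance 1e-13, typically a few hundred very cheap passes); the
accumulated shift per sample is the reported scaling factor and the
operator is idempotent by construction.  Multi-MA is the closed form of
the multi-dimensional MA rotation: per antibody, plate means are
equalized to their unweighted across-plate average (the preserved "A"
coordinate), which removes the between-plate variance share exactly.
Order is AbsPQN within plate, then Multi-MA across plates.  Note that
AbsPQN is not a no-op on noiseless data with individual baselines: it
subtracts each sample's median biological deviation, which is the correct
behaviour for a location-robust sample normalizer.

## Statistical components

**ICC(3,1)** (two-way mixed, consistency, single measurement) is computed
from the ANOVA closed form; rater (column) offsets do not count against
agreement, negative estimates are reported as computed, and duplicate
assays are averaged before the inter-visit axis so the two ICCs keep
distinct noise sources.  Complete-case individuals are the default for
the balanced two-way layout.

**Random-intercept models** are fitted by profiling the variance ratio
`theta = sigma_b^2/sigma^2` in one dimension (REML for estimation, ML for
likelihood-ratio tests); given `theta`, GLS is closed-form via per-group
sums.  Wald tests use residual degrees of freedom `n - p`; at ~400
observations this is indistinguishable from Satterthwaite corrections and
is documented as a swap point.  With no within-group replication the fit
falls back to OLS.  FDR is Benjamini–Hochberg over the full
protein × trait grid (single threshold, default flag at 0.001); the
seasonal scan flags at FDR < 0.01 via a joint 2-df LRT on the sine and
cosine coefficients, reporting amplitude `sqrt(b_s^2 + b_c^2)` and phase
in [0, 2π).

**Modules.**  The soft power is the smallest β whose scale-free fit R²
(log p(k) vs log k over ten equal-width connectivity bins) reaches 0.8,
else the argmax with a warning.  Static dendrogram cuts are supported at
a fixed height (default 0.8) or `"auto"`: the cut is placed in the widest
gap of the upper merge heights.  The auto rule exists because the TOM
scale contracts sharply with β — a fixed height that works at β = 2 finds
nothing at β = 5 — and the pipeline uses it by default.  Eigengenes are
first principal components of standardized member submatrices, sign-
oriented to positive mean member correlation; modules with eigengene
correlation > 0.8 are merged; labels are renumbered by decreasing size so
results do not depend on input order.  Cross-visit matching chains
modules of consecutive visits greedily by descending Jaccard overlap
(ties: larger module, then lower label); only chains spanning all visits
define core patterns, a protein must follow its chain at every visit, and
patterns keep ≥ 5 members.  Module–trait tests run per visit (linear
regression for continuous traits, one-way ANOVA for categorical), with BH
over the pattern × trait × visit grid and a pair-level flag when any
visit survives; signs are reported per visit so sign-consistency is
visible.

**pQTL scan.**  The phenotype is the across-visit mean of normalized log
levels per individual (a single visit is configurable).  Per SNP, simple
OLS on additive minor-allele dosage, vectorized; the Bonferroni threshold
is α divided by the SNPs actually tested after MAF (≥ 0.05) and
chi-square HWE (p ≥ 1e-6) QC.  Cis annotation uses the protein-encoding
gene's window ± 1 Mb (configurable to 0); LD proxies are genotypic r².
Level subgroups are called by a 1- vs 2-component Gaussian mixture
(10 EM restarts, fixed seed) chosen by BIC; the minor fraction is the
observed assignment fraction.

**Signatures.**  On the both-stable panel, per-protein z-scores use all
samples of all individuals as the population.  Per (individual, protein):
OLS of z on centered time in years gives baseline α (fitted value at the
individual's mean time), trend γ (z/year) and fluctuation φ = Σ|residual|;
individuals need ≥ 3 visits.  A statistic deviates when it lies more than
k = 3 SD from the across-individual mean (mean and SD include the tested
individual; a robust median/MAD variant is a documented alternative since
one extreme individual inflates the SD).  The Gaussian chance rate per
criterion is 2(1−Φ(3)) = 0.27%; the three-criterion union under
independence (~0.81%) is reported alongside because α and γ are Gaussian
under the null but φ is not — its null flag rate runs above 0.27% and is
reported separately rather than renormalized.  At cohort size n ≈ 100 the
empirical rule flags slightly below the asymptotic 0.27% (the tested
individual inflates the empirical SD); the calibration tests therefore
allow binomial error around the nominal rate.

## Numerical and degenerate-input choices

Constant proteins are excluded from z-scoring (warning) and rejected by
the network builder (error naming the column); zero-SD statistics yield
no flags; ICC of a fully constant matrix is reported as 1 (nothing
disagrees); plates need ≥ 2 samples for Multi-MA and ≥ 3 antibodies for
AbsPQN; LD r² on a monomorphic SNP is an error rather than 0.  The IQR
diversity measure has a hard ceiling on z-scored data: Gaussian baselines
cannot push the IQR of per-individual means past 2·Φ⁻¹(0.75) ≈ 1.35, so
"high diversity" (IQR ≥ 1.5) is reachable only through bimodal,
genotype-subgroup-like level distributions — consistent with the
biology the cut-off is meant to capture.

## Problem sizes

Tests and the acceptance script run the full emulated design
(101 × 4 × 200 with ~1000 SNPs) for end-to-end checks, the dedicated
cis-effect scenario at M = 10,000 SNPs × 100 replicates, and reduced
cohorts (30–80 individuals) for unit-level recovery, keeping the whole
suite to a few minutes on one CPU.

## Known limitations

The mixed model supports a single random intercept (no random slopes or
crossed batch effects); the pQTL scan is plain OLS without kinship or
covariates; the dynamic tree cut of mainstream WGCNA is deliberately
replaced by deterministic static/auto cuts, so exact module boundaries
can differ from that package; core-module chaining is greedy and
sequential, not a global optimum over all visit combinations; and
per-individual identifiability ICCs are computed on cohort-standardized
profiles, which is stricter than computing them on raw levels (where
between-antibody level spread makes near-unit ICCs trivial).
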
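"""ICC(3,1) correctness, classification rule, identifiability."""

import numpy as np
import pandas as pd
import pytest

from longiplasma.core_model import ValidationError
from longiplasma.stability import (
    classify_stability,
    icc_3_1,
    individual_identifiability,
    inter_assay_icc,
    inter_visit_icc,
    stability_report,
)
from longiplasma.normalization import normalize_pipeline
from longiplasma.synthetic_data import SimConfig, simulate_cohort


def brute_force_icc31(m):
    """Independent two-way ANOVA: explicit sums of squares by loops."""
    m = np.asarray(m, dtype=float)
    n, k = m.shape
    grand = m.mean()
    ss_rows = sum(k * (m[i].mean() - grand) ** 2 for i in range(n))
    ss_cols = sum(n * (m[:, j].mean() - grand) ** 2 for j in range(k))
    ss_tot = sum((m[i, j] - grand) ** 2 for i in range(n) for j in range(k))
    ms_r = ss_rows / (n - 1)
    ms_e = (ss_tot - ss_rows - ss_cols) / ((n - 1) * (k - 1))
    return (ms_r - ms_e) / (ms_r + (k - 1) * ms_e)


def test_icc_reference_cases():
    assert icc_3_1(np.array([[1, 1], [2, 2], [3, 3]])) == pytest.approx(1.0)
    # rater offset does not count against consistency
    assert icc_3_1(np.array([[1, 2], [3, 4], [5, 6]])) == pytest.approx(1.0)
    # hand two-way ANOVA: MS_R = 10.5, MS_E = 0.5 -> 10/11
    assert icc_3_1(np.array([[1, 2], [3, 3], [5, 7]])) == pytest.approx(10 / 11)


def test_icc_matches_brute_force_anova_oracle():
    rng = np.random.default_rng(0)
    for _ in range(50):
        n = rng.integers(3, 12)
        k = rng.integers(2, 6)
        m = rng.normal(size=(n, k)) + rng.normal(0, 2, size=(n, 1))
        assert icc_3_1(m) == pytest.approx(brute_force_icc31(m), abs=1e-10)


def test_icc_invariances():
    rng = np.random.default_rng(1)
    m = rng.normal(size=(10, 4))
    base = icc_3_1(m)
    # constant per rater
    assert icc_3_1(m + rng.normal(0, 3, size=(1, 4))) == pytest.approx(base, abs=1e-12)
    # global affine transform
    assert icc_3_1(2.5 * m - 7) == pytest.approx(base, abs=1e-12)
    # target permutation
    assert icc_3_1(m[rng.permutation(10)]) == pytest.approx(base, abs=1e-12)


def test_icc_input_validation():
    with pytest.raises(ValidationError):
        icc_3_1(np.array([[1.0, 2.0]]))
    with pytest.raises(ValidationError):
        icc_3_1(np.array([[1.0, np.nan], [2.0, 3.0]]))


def test_paired_interassay_icc_matches_closed_form(small_normalized):
    """With one replicate pair per aliquot (k = 2), ICC(3,1) equals the
    paired two-column closed form computed directly."""
    norm, _ = small_normalized
    icc = inter_assay_icc(norm)
    meta = norm.meta
    reps = meta[meta.replicate_of.notna()]
    ab = norm.intensities.columns[0]
    m = np.column_stack([
        norm.intensities.loc[reps.replicate_of, ab].to_numpy(),
        norm.intensities.loc[reps.index, ab].to_numpy(),
    ])
    assert icc[ab] == pytest.approx(brute_force_icc31(m), abs=1e-10)


def test_noiseless_cohort_gives_unit_iccs():
    """Individual baselines but zero noise: both ICC axes hit 1 exactly
    (checked on log data, since renormalizing would subtract each sample's
    median biological deviation and is not a no-op here)."""
    from longiplasma.normalization import log_transform
    cfg = SimConfig.null(n_individuals=10, n_proteins=8, sigma_tech=0.0,
                         sigma_samp=0.0, sigma_plate=0.0,
                         duplicate_assay_fraction=0.5, seed=3)
    ds, *_ = simulate_cohort(cfg)
    logged = log_transform(ds)
    assert (inter_assay_icc(logged) > 1 - 1e-9).all()
    assert (inter_visit_icc(logged) > 1 - 1e-9).all()


def test_interassay_icc_declines_with_technical_noise():
    meds = []
    for s_tech in (0.05, 0.3, 0.8):
        cfg = SimConfig.null(n_individuals=40, n_proteins=30, sigma_tech=s_tech,
                             duplicate_assay_fraction=0.5, seed=4)
        ds, *_ = simulate_cohort(cfg)
        norm, _ = normalize_pipeline(ds)
        meds.append(inter_assay_icc(norm).median())
    assert meds[0] > meds[1] > meds[2]


def test_planted_visit_noise_lowers_intervisit_but_not_interassay():
    cfg = SimConfig.null(n_individuals=50, n_proteins=40, frac_unstable=0.5,
                         duplicate_assay_fraction=0.5, seed=5)
    ds, gm, traits, gt = simulate_cohort(cfg)
    norm, _ = normalize_pipeline(ds)
    icc_a, icc_v = inter_assay_icc(norm), inter_visit_icc(norm)
    unstable = gt.protein_info.unstable
    assert icc_v[unstable].median() < icc_v[~unstable].median() - 0.2
    assert abs(icc_a[unstable].median() - icc_a[~unstable].median()) < 0.1


def test_stability_designation_recovered(default_cohort, default_normalized):
    ds, gm, traits, gt = default_cohort
    norm, _ = default_normalized
    rep = stability_report(norm)
    tab = rep.table.set_index("antibody")
    for est_col, true_col in [("icc_interassay", "stable_technical"),
                              ("icc_intervisit", "stable_longitudinal")]:
        pred = tab[est_col] >= 0.8
        truth = gt.protein_info[true_col]
        tpr = (pred & truth).sum() / truth.sum()
        tnr = (~pred & ~truth).sum() / (~truth).sum()
        assert (tpr + tnr) / 2 >= 0.9


def test_classification_rule_and_summary_counts():
    icc_a = pd.Series({"CD5L": 0.97, "CALD1": 0.88, "X": 0.5, "Y": 0.85})
    icc_v = pd.Series({"CD5L": 0.9, "CALD1": 0.32, "X": 0.4, "Y": 0.92})
    rep = classify_stability(icc_a, icc_v)
    cls = rep.table.set_index("antibody")["class"]
    # high technical precision but variable between visits
    assert cls["CALD1"] == "technical_only"
    assert cls["CD5L"] == "both_stable" and cls["X"] == "unstable"
    counts = rep.summary.set_index("group")["count"]
    assert counts[["both_stable", "technical_only", "longitudinal_only",
                   "unstable"]].sum() == 4


def test_icc_uncorrelated_with_mean_level(default_normalized):
    """Technical noise is level-independent in the generator, so ICC should
    not track the mean log level."""
    from scipy.stats import spearmanr
    norm, _ = default_normalized
    rep = stability_report(norm)
    rho = spearmanr(rep.table.icc_interassay, rep.table.mean_level).statistic
    assert abs(rho) < 0.3


def test_identifiability_with_baselines_and_at_chance():
    base = simulate_cohort(SimConfig.null(n_individuals=25, n_proteins=60, seed=6))[0]
    norm, _ = normalize_pipeline(base)
    rep = individual_identifiability(norm)
    assert rep.self_match_fraction >= 0.95
    assert rep.per_individual.icc_across_visits.mean() > 0.9

    flat = simulate_cohort(SimConfig.null(n_individuals=25, n_proteins=60,
                                          sigma_bio=0.0, seed=7))[0]
    norm_f, _ = normalize_pipeline(flat)
    rep_f = individual_identifiability(norm_f)
    # no individual signal: self-matching collapses to the chance level
    assert rep_f.self_match_fraction == pytest.approx(rep_f.chance_level, abs=0.05)
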
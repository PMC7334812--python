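"""Z-scoring, per-profile statistics, deviation flags, IQR diversity."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from longiplasma.core_model import ValidationError
from longiplasma.individual_signatures import (
    ProfileStats,
    SignatureFlags,
    flag_deviations,
    interindividual_iqr,
    population_zscore,
    profile_statistics,
    summarize_signatures,
)
from longiplasma.normalization import normalize_pipeline
from longiplasma.synthetic_data import SimConfig, simulate_cohort


def _profile_fixture(z_rows, dates):
    """One individual per row-set with 4 visits at the given dates."""
    n_ind = len(z_rows)
    idx, meta_rows, zvals = [], [], []
    for i, row in enumerate(z_rows):
        for t, (z, d) in enumerate(zip(row, dates), start=1):
            sid = f"i{i}_v{t}"
            idx.append(sid)
            meta_rows.append({"individual_id": f"i{i}", "visit": t,
                              "collection_date": d, "plate_id": "P1",
                              "assay_batch": f"B{t}", "replicate_of": None})
            zvals.append(z)
    meta = pd.DataFrame(meta_rows, index=idx)
    z = pd.DataFrame({"AB": zvals}, index=idx)
    return z, meta


YEARS = ["2015-01-01", "2016-01-01", "2017-01-01", "2018-01-01"]


def test_profile_statistics_hand_cases():
    z, meta = _profile_fixture([[1, 1, 1, 1], [0, 1, 2, 3], [0, 2, 0, 2]], YEARS)
    prof = profile_statistics(z, meta)
    # constant profile
    assert prof.alpha.loc["i0", "AB"] == pytest.approx(1.0)
    assert prof.gamma.loc["i0", "AB"] == pytest.approx(0.0)
    assert prof.phi.loc["i0", "AB"] == pytest.approx(0.0)
    # near-perfect line (calendar years differ from 365.25 d by < 0.2%)
    assert prof.phi.loc["i1", "AB"] == pytest.approx(0.0, abs=5e-3)
    # hand OLS on (0,2,0,2) at years 0..3: slope 0.4, mean 1, sum |resid| 3.2
    assert prof.alpha.loc["i2", "AB"] == pytest.approx(1.0)
    assert prof.gamma.loc["i2", "AB"] == pytest.approx(0.4, rel=5e-3)
    assert prof.phi.loc["i2", "AB"] == pytest.approx(3.2, rel=5e-3)
    # exact agreement with an independent least-squares fit at the true times
    d = (pd.to_datetime(meta["collection_date"]) -
         pd.Timestamp("2015-01-01")).dt.days / 365.25
    t = d[[f"i2_v{k}" for k in range(1, 5)]].to_numpy()
    slope, inter = np.polyfit(t - t.mean(), [0, 2, 0, 2], 1)
    assert prof.gamma.loc["i2", "AB"] == pytest.approx(slope, abs=1e-10)
    assert prof.alpha.loc["i2", "AB"] == pytest.approx(inter, abs=1e-10)


def test_population_zscore_standardizes_and_is_affine_invariant(small_normalized):
    norm, _ = small_normalized
    z = population_zscore(norm)
    np.testing.assert_allclose(z.mean(axis=0), 0.0, atol=1e-10)
    np.testing.assert_allclose(z.std(axis=0, ddof=1), 1.0, atol=1e-10)
    shifted = norm.with_values(norm.intensities * 3.5 - 11.0, norm.scale_tag)
    z2 = population_zscore(shifted)
    np.testing.assert_allclose(z2.to_numpy(), z.to_numpy(), atol=1e-9)


def test_population_zscore_drops_constant_protein(small_normalized):
    norm, _ = small_normalized
    vals = norm.intensities.copy()
    vals.iloc[:, 0] = 5.0
    z = population_zscore(norm.with_values(vals, norm.scale_tag))
    assert vals.columns[0] not in z.columns


def test_flags_exactly_the_planted_outlier():
    rng = np.random.default_rng(0)
    n = 100
    alpha = pd.DataFrame({"AB": rng.standard_normal(n)},
                         index=[f"i{j}" for j in range(n)])
    alpha.iloc[0, 0] = 10.0
    prof = ProfileStats(alpha=alpha, gamma=alpha * 0.0, phi=np.abs(alpha) * 0.0,
                        n_visits=pd.Series(4, index=alpha.index))
    flags = flag_deviations(prof)
    b = flags.flags["baseline"]
    assert b.iloc[0, 0]
    assert b.to_numpy().sum() == 1
    # zero-SD statistics yield no flags
    assert not flags.flags["trend"].to_numpy().any()


def test_chance_rate_is_the_two_sided_three_sigma_tail():
    prof = ProfileStats(
        alpha=pd.DataFrame(np.zeros((12, 2))), gamma=pd.DataFrame(np.zeros((12, 2))),
        phi=pd.DataFrame(np.zeros((12, 2))), n_visits=pd.Series(4, index=range(12)))
    flags = flag_deviations(prof, k=3.0)
    assert flags.chance_rate == pytest.approx(2 * (1 - stats.norm.cdf(3)))
    assert round(100 * flags.chance_rate, 2) == 0.27
    assert flags.chance_rate_union == pytest.approx(1 - (1 - flags.chance_rate) ** 3)
    # all-identical stats produce no flags at all
    assert not any(f.to_numpy().any() for f in flags.flags.values())


def test_summaries_count_profiles_and_scores():
    rng = np.random.default_rng(1)
    I, P = 92, 359
    mk = lambda: pd.DataFrame(np.zeros((I, P), dtype=bool))
    b, t, f = mk(), mk(), mk()
    b.iloc[0, :39] = True
    t.iloc[0, 39:90] = True
    f.iloc[0, 90:139] = True
    flags = SignatureFlags(flags={"baseline": b, "trend": t, "fluctuation": f},
                           k=3.0, chance_rate=0.0027, chance_rate_union=0.008)
    summ = summarize_signatures(flags)
    assert summ.n_profiles == I * P == 33028
    row = summ.per_individual.iloc[0]
    assert (row.baseline, row.trend, row.fluctuation) == (39, 51, 49)
    assert row.accumulated_score == 139
    assert summ.n_flagged == 139
    assert sum(summ.venn.values()) == summ.n_flagged

    empty = SignatureFlags(flags={"baseline": mk(), "trend": mk(), "fluctuation": mk()},
                           k=3.0, chance_rate=0.0027, chance_rate_union=0.008)
    s2 = summarize_signatures(empty)
    assert s2.n_flagged == 0 and s2.flagged_fraction == 0.0


def test_planted_baseline_individuals_are_flagged():
    cfg = SimConfig.null(n_individuals=60, n_proteins=80, frac_baseline=0.3,
                         seed=2)
    ds, gm, traits, gt = simulate_cohort(cfg)
    norm, _ = normalize_pipeline(ds)
    z = population_zscore(norm)
    prof = profile_statistics(z, z.attrs["meta"])
    flags = flag_deviations(prof)
    # judge sensitivity against the realized deviation: a planted +4 SD
    # offset riding on a -1 SD natural baseline deviates only 3 SD
    strong = gt.baseline_effects[gt.baseline_effects.size_sd_total.abs() >= 4]
    assert len(strong) >= 5
    hits = sum(flags.flags["baseline"].loc[r.individual_id, r.antibody]
               for _, r in strong.iterrows())
    assert hits / len(strong) >= 0.95


def test_flags_invariant_to_ordering():
    rng = np.random.default_rng(3)
    alpha = pd.DataFrame(rng.standard_normal((40, 6)),
                         index=[f"i{j}" for j in range(40)],
                         columns=[f"p{j}" for j in range(6)])
    prof = lambda a: ProfileStats(alpha=a, gamma=a * 0.5, phi=np.abs(a),
                                  n_visits=pd.Series(4, index=a.index))
    f1 = flag_deviations(prof(alpha))
    shuffled = alpha.sample(frac=1, axis=0, random_state=1).sample(
        frac=1, axis=1, random_state=2)
    f2 = flag_deviations(prof(shuffled))
    for crit in f1.flags:
        a = f1.flags[crit].loc[shuffled.index, shuffled.columns]
        pd.testing.assert_frame_equal(a, f2.flags[crit])


def test_iqr_reflects_planted_baseline_spread():
    quiet = simulate_cohort(SimConfig.null(n_individuals=60, n_proteins=30,
                                           sigma_bio=0.02, seed=4))[0]
    loud = simulate_cohort(SimConfig.null(n_individuals=60, n_proteins=30,
                                          sigma_bio=1.2, seed=4))[0]
    out = {}
    for name, ds in [("quiet", quiet), ("loud", loud)]:
        norm, _ = normalize_pipeline(ds)
        z = population_zscore(norm)
        out[name] = interindividual_iqr(z, z.attrs["meta"])
    # strong baselines dominate the z variance: per-individual means approach
    # the Gaussian ceiling 2*Phi^-1(3/4) ~ 1.35 (z-scoring caps the spread)
    assert out["loud"].iqr.median() > 1.0
    assert out["quiet"].iqr.median() < out["loud"].iqr.median()
    # pure noise: IQR of mean-of-V z values concentrates near 2*Phi^-1(3/4)/sqrt(V)
    expected = 2 * stats.norm.ppf(0.75) / np.sqrt(4)
    assert out["quiet"].iqr.median() == pytest.approx(expected, rel=0.35)


def test_iqr_flags_bimodal_genotype_like_protein_as_high_diversity():
    """IQR >= 1.5 needs a bimodal split across individuals (e.g. an allele
    dividing the cohort), which z-scoring cannot compress below the
    between-mode separation."""
    rng = np.random.default_rng(5)
    n, v = 60, 4
    idx = [f"i{j}_v{t}" for j in range(n) for t in range(1, v + 1)]
    meta = pd.DataFrame({"individual_id": [s.split("_")[0] for s in idx]}, index=idx)
    group = np.repeat(rng.choice([-1.0, 1.0], size=n), v)
    vals = group + rng.normal(0, 0.15, n * v)
    z = pd.DataFrame({"AB": (vals - vals.mean()) / vals.std(ddof=1)}, index=idx)
    out = interindividual_iqr(z, meta)
    assert out.iqr.iloc[0] >= 1.5 and bool(out.high_diversity.iloc[0])


def test_iqr_requires_multiple_individuals():
    z = pd.DataFrame({"AB": [0.1, 0.2]}, index=["a_v1", "a_v2"])
    meta = pd.DataFrame({"individual_id": ["a", "a"]}, index=z.index)
    with pytest.raises(ValidationError):
        interindividual_iqr(z, meta)
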
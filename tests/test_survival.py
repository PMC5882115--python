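"""Kaplan-Meier estimation, stratification, threshold sweep and group tests."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from grstrat import (
    CohortConfig,
    allele_freq_compare,
    compare_distributions,
    km_cumulative_risk,
    logrank_test,
    population_fraction,
    simulate_cohort,
    stratify_by_quartiles,
    threshold_sweep,
    wilson_ci,
)
from grstrat.survival import assign_quartile_strata, quartile_cutpoints


def km_brute_force(times, events, t):
    """Independent product-limit oracle: loop over distinct event times."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    s = 1.0
    for u in sorted(set(times[events == 1])):
        if u > t:
            break
        d = int(((times == u) & (events == 1)).sum())
        n = int((times >= u).sum())
        s *= 1.0 - d / n
    return 1.0 - s


class TestKaplanMeier:
    def test_no_censoring_reduces_to_empirical_cdf(self):
        times = np.array([1, 2, 3, 4, 5, 6, 7, 8, 9, 10], dtype=float)
        events = np.ones(10, dtype=int)
        km = km_cumulative_risk(times, events, landmark_age=3.5)
        assert km.risk_at_landmark == pytest.approx(0.30)

    def test_matches_brute_force_oracle_with_interleaved_censoring(self, rng):
        times = rng.exponential(4.0, size=50)
        events = (rng.random(50) < 0.6).astype(int)
        for t in (1.0, 2.0, 5.0, np.median(times)):
            km = km_cumulative_risk(times, events, t)
            assert km.risk_at_landmark == pytest.approx(
                km_brute_force(times, events, t), abs=1e-12
            )

    def test_landmark_beyond_followup_warns_and_reports_last_time(self):
        with pytest.warns(UserWarning, match="beyond last observed"):
            km = km_cumulative_risk([5.0], [0], landmark_age=6.0)
        assert km.landmark_age == 5.0
        assert km.risk_at_landmark == 0.0

    def test_all_zero_times_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            km_cumulative_risk([0.0, 0.0], [1, 1], 1.0)

    def test_curve_monotone_within_bounds(self, rng):
        times = rng.exponential(4.0, size=200)
        events = (rng.random(200) < 0.5).astype(int)
        km = km_cumulative_risk(times, events, 5.0)
        assert (np.diff(km.cum_risk) >= -1e-12).all()
        assert ((km.cum_risk >= 0) & (km.cum_risk <= 1)).all()
        assert (km.ci_low <= km.cum_risk + 1e-12).all()
        assert (km.cum_risk <= km.ci_high + 1e-12).all()


class TestLogrank:
    def test_identical_groups_give_null_statistic(self):
        times = np.tile(np.arange(1.0, 21.0), 2)
        events = np.tile(np.array([1, 0] * 10), 2)
        groups = np.repeat(["a", "b"], 20)
        stat, p = logrank_test(times, events, groups)
        assert p > 0.95 and stat == pytest.approx(0.0, abs=1e-6)

    def test_strong_separation_detected(self, rng):
        n = 500
        t1 = rng.exponential(1.0, n)
        t2 = rng.exponential(5.0, n)
        times = np.concatenate([t1, t2])
        events = np.ones(2 * n, dtype=int)
        _, p = logrank_test(times, events, np.repeat(["hi", "lo"], n))
        assert p < 0.001

    def test_single_group_rejected(self):
        with pytest.raises(ValueError, match="2 groups"):
            logrank_test([1, 2], [1, 1], ["a", "a"])


class TestQuartiles:
    def test_uniform_scores_split_25_50_25(self):
        strata = assign_quartile_strata(np.arange(1.0, 101.0))
        counts = strata.value_counts()
        assert counts["lower"] == 25 and counts["middle"] == 50 and counts["upper"] == 25

    def test_heavy_ties_raise_with_cutpoint(self):
        with pytest.raises(ValueError, match="stratum"):
            assign_quartile_strata(np.ones(100))

    def test_effect_cohort_upper_exceeds_lower(self, demo_cohort):
        curves = stratify_by_quartiles(
            demo_cohort.scores, demo_cohort.phenotypes, "multi_ab", 6.0
        )
        assert curves["upper"].risk_at_landmark > curves["lower"].risk_at_landmark
        times = demo_cohort.phenotypes["multi_ab_time"]
        events = demo_cohort.phenotypes["multi_ab_event"]
        strata = assign_quartile_strata(demo_cohort.scores["score"])
        _, p = logrank_test(times, events, strata.to_numpy())
        assert p < 0.001

    def test_cutpoints_are_linear_interpolation_percentiles(self, rng):
        s = rng.normal(size=101)
        q25, q75 = quartile_cutpoints(s)
        assert q25 == np.percentile(s, 25)
        assert q75 == np.percentile(s, 75)


class TestWilson:
    def test_printed_interval_for_82_of_173(self):
        lo, hi = wilson_ci(82, 173)
        assert round(100 * lo, 1) == 40.1
        assert round(100 * hi, 1) == 54.8

    def test_boundaries(self):
        assert wilson_ci(0, 10)[0] == 0.0
        assert wilson_ci(10, 10)[1] == 1.0
        with pytest.raises(ValueError):
            wilson_ci(1, 0)

    @settings(deadline=None, max_examples=60)
    @given(n=st.integers(1, 500), data=st.data())
    def test_interval_brackets_point_estimate(self, n, data):
        k = data.draw(st.integers(0, n))
        lo, hi = wilson_ci(k, n)
        assert 0 <= lo <= k / n <= hi <= 1


class TestPopulationFraction:
    def test_upper_quartile_projection(self):
        assert population_fraction(0.25) == pytest.approx(0.725)

    def test_identity_and_zero(self):
        assert population_fraction(1.0) == pytest.approx(2.9)
        assert population_fraction(0.0) == 0.0


class TestThresholdSweep:
    def test_floor_threshold_recovers_whole_cohort(self, demo_cohort):
        ph = demo_cohort.phenotypes
        sweep = threshold_sweep(
            demo_cohort.scores, ph, "multi_ab", 6.0, include_floor=True
        )
        first = sweep.iloc[0]
        assert first["sensitivity"] == 1.0
        whole = km_cumulative_risk(ph["multi_ab_time"], ph["multi_ab_event"], 6.0)
        assert first["risk_at_landmark"] == pytest.approx(whole.risk_at_landmark, abs=1e-12)
        assert first["population_fraction"] == pytest.approx(2.9)

    def test_sensitivity_and_fraction_nonincreasing(self, demo_cohort):
        sweep = threshold_sweep(demo_cohort.scores, demo_cohort.phenotypes, "multi_ab", 6.0)
        assert (np.diff(sweep["sensitivity"]) <= 1e-12).all()
        assert (np.diff(sweep["population_fraction"]) <= 1e-12).all()

    def test_monotone_effect_gives_signed_trends(self, demo_cohort):
        sweep = threshold_sweep(demo_cohort.scores, demo_cohort.phenotypes, "multi_ab", 6.0)
        rho_risk, _ = sweep.attrs["spearman_risk"]
        rho_sens, _ = sweep.attrs["spearman_sensitivity"]
        assert rho_risk > 0 and rho_sens < 0

    def test_no_cases_by_landmark_rejected(self, demo_cohort):
        ph = demo_cohort.phenotypes.copy()
        ph["multi_ab_event"] = 0
        with pytest.raises(ValueError, match="sensitivity undefined"):
            threshold_sweep(demo_cohort.scores, ph, "multi_ab", 6.0)


class TestGroupComparisons:
    def test_identical_groups_p_near_one(self):
        v = np.tile(np.arange(50, dtype=float), 2)
        g = np.repeat(["a", "b"], 50)
        out = compare_distributions(v, g)
        assert out.attrs["p_value"] > 0.99
        assert (out["median"] == np.median(np.arange(50))).all()

    def test_shifted_groups_detected(self, rng):
        a = rng.normal(0, 1, 500)
        b = rng.normal(0.5, 1, 500)
        out = compare_distributions(
            np.concatenate([a, b]), np.repeat(["a", "b"], 500)
        )
        assert out.attrs["p_value"] < 0.01

    def test_small_group_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            compare_distributions([1.0, 2.0, 3.0], ["a", "a", "b"])


class TestAlleleFreqCompare:
    def test_bonferroni_threshold_for_43_snps(self, demo_cohort):
        geno = demo_cohort.genotypes
        regions = demo_cohort.phenotypes["region"]
        out = allele_freq_compare(geno, regions, n_snps=43)
        assert out.attrs["bonferroni_threshold"] == pytest.approx(0.05 / 43)
        # generator draws both regions from identical frequencies: nothing flags
        assert out["significant"].sum() == 0

    def test_true_frequency_difference_flagged(self, merged_demo, demo_maf):
        maf = dict(demo_maf)
        rsid = merged_demo.rsids[0]
        cfg = CohortConfig(
            n_individuals=3000, maf=maf, seed=31,
            region_maf_shift={rsid: 0.10},
        )
        cohort = simulate_cohort(cfg, merged_demo)
        out = allele_freq_compare(
            cohort.genotypes, cohort.phenotypes["region"], n_snps=43
        ).set_index("rsid")
        assert bool(out.loc[rsid, "significant"])

    def test_monomorphic_snp_reports_p_one(self):
        geno = pd.DataFrame({"rs1": [0.0, 0.0, 0.0, 0.0]}, index=list("abcd"))
        regions = pd.Series(["US", "US", "Europe", "Europe"], index=list("abcd"))
        out = allele_freq_compare(geno, regions)
        assert out["p_value"].iloc[0] == 1.0
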
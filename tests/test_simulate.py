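"""Synthetic-cohort generator: genotypes, event times, visit discretization,
case-control sampling."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from grstrat import (
    CohortConfig,
    compute_scores,
    discretize_to_visits,
    simulate_case_control,
    simulate_cohort,
    simulate_event_times,
    simulate_genotypes,
)
from grstrat.simulate import OUTCOMES

from conftest import make_table


def small_config(maf, **kw):
    return CohortConfig(maf=maf, **kw)


@pytest.fixture(scope="module")
def one_snp_table():
    return make_table([("rs1", "A", 0.5)])


class TestGenotypes:
    def test_mean_count_matches_binomial(self, one_snp_table):
        cfg = small_config({"rs1": 0.5}, n_individuals=10_000, seed=3)
        g, _ = simulate_genotypes(cfg, one_snp_table)
        # Binomial(2, .5): mean 1, sd of the mean = sqrt(.5)/100; 3 sigma band
        assert 0.96 <= g["rs1"].mean() <= 1.04

    def test_maf_near_zero_gives_all_zero_counts(self, one_snp_table):
        cfg = small_config({"rs1": 1e-6}, n_individuals=500, seed=3)
        g, _ = simulate_genotypes(cfg, one_snp_table)
        assert (g["rs1"] == 0).all()

    def test_maf_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="allele frequency"):
            small_config({"rs1": 1.2})

    def test_same_seed_reproduces_tables(self, one_snp_table):
        cfg = small_config({"rs1": 0.3}, n_individuals=200, seed=5)
        g1, d1 = simulate_genotypes(cfg, one_snp_table)
        g2, d2 = simulate_genotypes(cfg, one_snp_table)
        pd.testing.assert_frame_equal(g1, g2)
        pd.testing.assert_frame_equal(d1, d2)

    def test_missing_maf_for_weighted_snp_rejected(self):
        t = make_table([("rs1", "A", 0.5), ("rs2", "C", 0.3)])
        cfg = small_config({"rs1": 0.3}, n_individuals=10)
        with pytest.raises(ValueError, match="rs2"):
            simulate_genotypes(cfg, t)

    def test_region_maf_shift_moves_europe_frequency(self, one_snp_table):
        cfg = small_config(
            {"rs1": 0.2}, n_individuals=20_000, seed=3,
            region_maf_shift={"rs1": 0.15},
        )
        g, d = simulate_genotypes(cfg, one_snp_table)
        eu = (d["region"] == "Europe").to_numpy()
        f_eu = g.loc[eu, "rs1"].mean() / 2
        f_us = g.loc[~eu, "rs1"].mean() / 2
        assert f_eu - f_us == pytest.approx(0.15, abs=0.02)


class TestEventTimes:
    def test_null_effect_gives_score_independent_events(self, one_snp_table):
        cfg = small_config(
            {"rs1": 0.5}, n_individuals=5000, seed=9,
            beta_score={o: 0.0 for o in OUTCOMES}, beta_sex=0.0,
        )
        g, d = simulate_genotypes(cfg, one_snp_table)
        scores = compute_scores(one_snp_table, g)
        ph = simulate_event_times(cfg, scores, d)
        quart = pd.qcut(scores["score"], 2, labels=False, duplicates="drop")
        tab = pd.crosstab(quart, ph["any_ab_event"])
        _, p, _, _ = stats.chi2_contingency(tab)
        assert p > 0.001

    def test_exponential_mean_recovered_without_effect(self, one_snp_table):
        lam = 0.5
        cfg = small_config(
            {"rs1": 0.5}, n_individuals=20_000, seed=9,
            beta_score={o: 0.0 for o in OUTCOMES}, beta_sex=0.0,
            baseline_hazard={"any_ab": lam, "multi_ab": 1.0, "t1d": 1.0},
            followup_years=1e9,  # effectively no censoring
        )
        g, d = simulate_genotypes(cfg, one_snp_table)
        scores = compute_scores(one_snp_table, g)
        ph = simulate_event_times(cfg, scores, d)
        se = (1 / lam) / np.sqrt(cfg.n_individuals)
        assert ph["latent_any_ab"].mean() == pytest.approx(1 / lam, abs=3 * se)

    def test_positive_effect_orders_quartile_risks(self, merged_demo, demo_maf):
        from grstrat import km_cumulative_risk, stratify_by_quartiles

        cfg = CohortConfig(n_individuals=5000, maf=demo_maf, seed=12)
        cohort = simulate_cohort(cfg, merged_demo)
        curves = stratify_by_quartiles(cohort.scores, cohort.phenotypes, "any_ab", 6.0)
        assert curves["upper"].risk_at_landmark > curves["lower"].risk_at_landmark

    def test_outcome_ordering_and_censoring_accounting(self, demo_cohort, demo_config):
        ph = demo_cohort.phenotypes
        n = demo_config.n_individuals
        for o in OUTCOMES:
            assert ph[f"{o}_event"].isin([0, 1]).all()
            assert (ph[f"{o}_event"] == 1).sum() + (ph[f"{o}_event"] == 0).sum() == n
        both = (ph["any_ab_event"] == 1) & (ph["multi_ab_event"] == 1)
        assert (ph.loc[both, "multi_ab_time"] >= ph.loc[both, "any_ab_time"]).all()
        t1d = both & (ph["t1d_event"] == 1)
        assert (ph.loc[t1d, "t1d_time"] >= ph.loc[t1d, "latent_multi_ab"] - 1e-12).all()


class TestVisitDiscretization:
    def test_latent_time_maps_to_first_of_consecutive_pair(self, demo_maf, merged_demo):
        cfg = CohortConfig(n_individuals=1, maf=demo_maf, seed=1)
        ph = pd.DataFrame(
            {
                "sex": ["female"], "region": ["US"],
                "latent_any_ab": [1.0], "any_ab_time": [1.0], "any_ab_event": [1],
                "latent_multi_ab": [20.0], "multi_ab_time": [10.0], "multi_ab_event": [0],
                "latent_t1d": [30.0], "t1d_time": [10.0], "t1d_event": [0],
            },
            index=["i0"],
        )
        out = discretize_to_visits(ph, cfg)
        # visits every 0.25 y: first positive sample at exactly 1.0 y
        assert out["any_ab_time"].iloc[0] == pytest.approx(1.0)
        assert out["any_ab_event"].iloc[0] == 1

    def test_latent_between_visits_rounds_up(self, demo_maf):
        cfg = CohortConfig(n_individuals=1, maf=demo_maf, seed=1)
        ph = pd.DataFrame(
            {
                "sex": ["male"], "region": ["US"],
                "latent_any_ab": [1.1], "any_ab_time": [1.1], "any_ab_event": [1],
                "latent_multi_ab": [20.0], "multi_ab_time": [10.0], "multi_ab_event": [0],
                "latent_t1d": [30.0], "t1d_time": [10.0], "t1d_event": [0],
            },
            index=["i0"],
        )
        out = discretize_to_visits(ph, cfg)
        assert out["any_ab_time"].iloc[0] == pytest.approx(1.25)

    def test_latent_after_last_visit_is_censored(self, demo_maf):
        cfg = CohortConfig(n_individuals=1, maf=demo_maf, seed=1, followup_years=10.0)
        ph = pd.DataFrame(
            {
                "sex": ["male"], "region": ["US"],
                "latent_any_ab": [9.9], "any_ab_time": [9.9], "any_ab_event": [1],
                "latent_multi_ab": [20.0], "multi_ab_time": [10.0], "multi_ab_event": [0],
                "latent_t1d": [30.0], "t1d_time": [10.0], "t1d_event": [0],
            },
            index=["i0"],
        )
        out = discretize_to_visits(ph, cfg)
        # first positive would be the final visit; no second consecutive visit
        # fits within follow-up, so the event is not recorded
        assert out["any_ab_event"].iloc[0] == 0
        assert out["any_ab_time"].iloc[0] == 10.0

    def test_detection_delay_bounded_by_visit_gap(self, demo_cohort, demo_config):
        ph = demo_cohort.phenotypes
        rec = ph[ph["any_ab_event"] == 1]
        delay = rec["any_ab_time"] - rec["latent_any_ab"]
        max_gap = demo_config.visit_months_late / 12.0
        assert (delay >= -1e-12).all()
        assert (delay <= max_gap + 1e-12).all()

    def test_diabetes_dates_not_discretized(self, demo_cohort):
        ph = demo_cohort.phenotypes
        t1d = ph[ph["t1d_event"] == 1]
        assert np.allclose(t1d["t1d_time"], t1d["latent_t1d"])


class TestCaseControl:
    def test_null_effect_equalizes_means(self, merged_demo, demo_maf):
        cfg = CohortConfig(maf=demo_maf, seed=21)
        cases, controls = simulate_case_control(1500, 1500, cfg, merged_demo, effect=0.0)
        pooled_se = np.sqrt(cases.var() / len(cases) + controls.var() / len(controls))
        assert abs(cases.mean() - controls.mean()) < 3 * pooled_se

    def test_positive_effect_shifts_cases_up(self, merged_demo, demo_maf):
        cfg = CohortConfig(maf=demo_maf, seed=22)
        cases, controls = simulate_case_control(1000, 1000, cfg, merged_demo, effect=1.0)
        u, p = stats.mannwhitneyu(cases, controls, alternative="greater")
        assert p < 0.05

    def test_same_seed_reproduces_sets(self, merged_demo, demo_maf):
        cfg = CohortConfig(maf=demo_maf, seed=23)
        a = simulate_case_control(100, 100, cfg, merged_demo)
        b = simulate_case_control(100, 100, cfg, merged_demo)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])

    def test_degenerate_effect_rejected(self, merged_demo, demo_maf):
        cfg = CohortConfig(maf=demo_maf, seed=23)
        with pytest.raises(ValueError, match="degenerate"):
            simulate_case_control(10, 10, cfg, merged_demo, effect=np.inf)
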
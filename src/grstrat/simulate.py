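"""Synthetic birth-cohort generator.

Emulates the design of a prospective HLA-selected newborn cohort: biallelic
SNP genotypes drawn under configurable (optionally region-specific) effect-
allele frequencies, two high-risk HLA DR-DQ genotype classes, three nested
time-to-event outcomes (any islet autoantibody, multiple islet autoantibodies,
diabetes) generated under a proportional-hazards model on the genetic score,
a 3-monthly (to age 4) then 6-monthly visit schedule with autoantibody
detection requiring two consecutive positive visits, and administrative
censoring at a fixed follow-up horizon.

All outputs are pure functions of (config, seed).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .genotypes import HLA_COL
from .scoring import compute_scores
from .weights import HLA_CLASSES, WeightTable

OUTCOMES = ("any_ab", "multi_ab", "t1d")
#: autoantibody outcomes are detected at visit dates; diabetes is diagnosed
#: clinically and keeps its latent date
DISCRETIZED_OUTCOMES = ("any_ab", "multi_ab")

REGIONS = ("US", "Europe")


@dataclass
class CohortConfig:
    """Study conditions for the synthetic cohort.

    Defaults approximate the prospective cohort the analysis is designed for:
    3,498 scored children followed for 10 years, whole-cohort cumulative
    risks near 9%/6%/4% for the three outcomes, and a score effect that
    yields roughly a 2.5- to 3-fold upper-vs-lower-quartile risk ratio.
    """

    n_individuals: int = 3498
    maf: dict[str, float] = field(default_factory=dict)
    region_maf_shift: dict[str, float] | None = None
    p_dr34: float = 0.6          # P(DR3/DR4-DQ8); remainder DR4-DQ8/DR4-DQ8
    p_europe: float = 0.58
    p_male: float = 0.5
    beta_score: dict[str, float] = field(
        default_factory=lambda: {"any_ab": 0.30, "multi_ab": 0.30, "t1d": 0.30}
    )
    # exponential rates (events / person-year): any_ab is the seroconversion
    # hazard; multi_ab and t1d are progression-gap hazards from the previous
    # outcome
    baseline_hazard: dict[str, float] = field(
        default_factory=lambda: {"any_ab": 0.0135, "multi_ab": 0.38, "t1d": 0.075}
    )
    beta_sex: float = 0.2        # log-hazard for male sex
    followup_years: float = 10.0
    visit_months_early: float = 3.0
    visit_months_late: float = 6.0
    visit_switch_age: float = 4.0
    seed: int = 1234

    def __post_init__(self):
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be >= 1")
        for p in (self.p_dr34, self.p_europe, self.p_male):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        for k, lam in self.baseline_hazard.items():
            if lam < 0:
                raise ValueError(f"negative baseline hazard for {k}")
        for rsid, f in self.maf.items():
            if not 0.0 < f < 1.0:
                raise ValueError(f"allele frequency for {rsid} outside (0, 1)")

    def rng(self, salt: int = 0) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence([self.seed, salt]))

    def visit_times(self) -> np.ndarray:
        early = np.arange(
            0.0, self.visit_switch_age + 1e-9, self.visit_months_early / 12.0
        )
        late = np.arange(
            self.visit_switch_age + self.visit_months_late / 12.0,
            self.followup_years + 1e-9,
            self.visit_months_late / 12.0,
        )
        return np.concatenate([early, late])


@dataclass
class SyntheticCohort:
    genotypes: pd.DataFrame
    phenotypes: pd.DataFrame
    scores: pd.DataFrame


def simulate_genotypes(
    config: CohortConfig, table: WeightTable, rng: np.random.Generator | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw genotypes for the panel plus per-individual demographics.

    Counts are two independent Bernoulli draws per SNP at the effect-allele
    frequency (Hardy-Weinberg); Europe frequencies are offset by
    ``region_maf_shift`` where given.  Returns ``(genotypes, demographics)``
    where demographics has ``sex`` and ``region`` columns.
    """
    rng = rng or config.rng(salt=1)
    n = config.n_individuals
    ids = pd.Index([f"id{i:06d}" for i in range(n)], name="individual_id")

    region = np.where(rng.random(n) < config.p_europe, "Europe", "US")
    sex = np.where(rng.random(n) < config.p_male, "male", "female")
    hla = np.where(rng.random(n) < config.p_dr34, HLA_CLASSES[0], HLA_CLASSES[1])

    rsids = [r for r in table.rsids if r in config.maf]
    missing = set(table.rsids) - set(rsids)
    if missing:
        raise ValueError(f"no allele frequency for weighted SNPs: {sorted(missing)}")
    data = {}
    europe = region == "Europe"
    shift = config.region_maf_shift or {}
    for rsid in rsids:
        f = np.full(n, config.maf[rsid])
        if rsid in shift:
            f = np.clip(np.where(europe, f + shift[rsid], f), 1e-6, 1 - 1e-6)
        data[rsid] = rng.binomial(2, f).astype(float)

    genotypes = pd.DataFrame(data, index=ids)
    genotypes.insert(0, HLA_COL, hla)
    demographics = pd.DataFrame({"sex": sex, "region": region}, index=ids)
    return genotypes, demographics


def simulate_event_times(
    config: CohortConfig,
    scores: pd.DataFrame,
    demographics: pd.DataFrame,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Draw latent nested event times under proportional hazards on the score.

    The seroconversion time is exponential with rate
    ``λ_any · exp(β_any·(score − mean) + β_sex·male)``; waiting times to
    multiple autoantibodies and to diabetes are exponential gaps added on top,
    so the three latent times are ordered by construction.  Events after the
    administrative horizon are censored there.
    """
    rng = rng or config.rng(salt=2)
    score = scores["score"].to_numpy(dtype=float)
    centred = score - score.mean()
    male = (demographics["sex"].to_numpy() == "male").astype(float)
    n = len(score)

    latent_prev = np.zeros(n)
    pheno = demographics.copy()
    for outcome in OUTCOMES:
        lam = config.baseline_hazard[outcome]
        if lam < 0:
            raise ValueError(f"negative hazard for {outcome}")
        eta = config.beta_score.get(outcome, 0.0) * centred + config.beta_sex * male
        rate = lam * np.exp(eta)
        gap = np.where(
            rate > 0, rng.standard_exponential(n) / np.maximum(rate, 1e-300), np.inf
        )
        latent = latent_prev + gap
        pheno[f"latent_{outcome}"] = latent
        event = latent <= config.followup_years
        pheno[f"{outcome}_time"] = np.where(event, latent, config.followup_years)
        pheno[f"{outcome}_event"] = event.astype(int)
        latent_prev = latent
    return pheno


def discretize_to_visits(phenotypes: pd.DataFrame, config: CohortConfig) -> pd.DataFrame:
    """Replace latent autoantibody times by visit-schedule detection dates.

    Detection requires persistence across two consecutive visits: the first
    visit at/after the latent time is the first positive sample, and the
    event is recorded — dated at that first visit — only if the next visit
    also falls within follow-up.  Otherwise the child is censored at the
    horizon.  Diabetes dates are not discretized.
    """
    visits = config.visit_times()
    out = phenotypes.copy()
    for outcome in DISCRETIZED_OUTCOMES:
        latent = out[f"latent_{outcome}"].to_numpy(dtype=float)
        k = np.searchsorted(visits, latent, side="left")
        has_pair = k + 1 < len(visits)
        first_pos = np.where(has_pair, visits[np.minimum(k, len(visits) - 1)], np.inf)
        recorded = (latent <= config.followup_years) & has_pair & (
            first_pos <= config.followup_years
        )
        out[f"{outcome}_time"] = np.where(recorded, first_pos, config.followup_years)
        out[f"{outcome}_event"] = recorded.astype(int)
    # keep nesting: a recorded multi date can never precede the any-ab date
    both = (out["multi_ab_event"] == 1) & (out["any_ab_event"] == 1)
    assert (
        out.loc[both, "multi_ab_time"] >= out.loc[both, "any_ab_time"] - 1e-12
    ).all()
    return out


def simulate_cohort(config: CohortConfig, table: WeightTable) -> SyntheticCohort:
    """Full generator: genotypes -> scores -> latent times -> visit detection."""
    genotypes, demographics = simulate_genotypes(config, table)
    scores = compute_scores(table, genotypes)
    pheno = simulate_event_times(config, scores, demographics)
    pheno[HLA_COL] = genotypes[HLA_COL]
    pheno = discretize_to_visits(pheno, config)
    return SyntheticCohort(genotypes=genotypes, phenotypes=pheno, scores=scores)


def simulate_case_control(
    n_cases: int,
    n_controls: int,
    config: CohortConfig,
    table: WeightTable,
    effect: float = 4.0,
    max_batches: int = 1000,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw case and control genetic-score sets.

    Controls are scores of population draws.  Cases are drawn by rejection
    sampling with logistic acceptance ``expit(effect · (score − mean))`` so
    the case score distribution is stochastically larger than the control one
    when ``effect > 0``.
    """
    if n_cases < 1 or n_controls < 1:
        raise ValueError("n_cases and n_controls must be >= 1")
    if not np.isfinite(effect):
        raise ValueError("degenerate acceptance probability: effect must be finite")
    rng = config.rng(salt=3)

    def draw_scores(n: int) -> np.ndarray:
        cfg = CohortConfig(**{**config.__dict__, "n_individuals": n})
        genotypes, _ = simulate_genotypes(cfg, table, rng=rng)
        return compute_scores(table, genotypes)["score"].to_numpy()

    controls = draw_scores(n_controls)
    centre = controls.mean()

    cases = []
    need = n_cases
    for _ in range(max_batches):
        cand = draw_scores(max(4 * need, 256))
        accept = rng.random(len(cand)) < expit(effect * (cand - centre))
        cases.append(cand[accept][:need])
        need -= len(cases[-1])
        if need == 0:
            break
    else:
        raise ValueError("degenerate acceptance probability: rejection sampling failed")
    return np.concatenate(cases), controls
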
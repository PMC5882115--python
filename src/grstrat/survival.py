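"""Kaplan-Meier risk estimation, quartile stratification and threshold sweeps.

The screening quantities are: *risk* (positive predictive value) = Kaplan-
Meier cumulative incidence of the outcome by a landmark age among children
above a score threshold, and *sensitivity* = the fraction of children who
developed the outcome by the landmark age whose score exceeds the threshold.
Thresholds are always strict (score > τ).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

#: screened HLA genotype prevalence among newborns (DR3/DR4-DQ8 or
#: DR4-DQ8/DR4-DQ8)
HLA_PREVALENCE = 0.029

STRATA = ("lower", "middle", "upper")


@dataclass
class KMCurve:
    """Cumulative-risk curve: 1 − S(t) with pointwise 95% bounds."""

    times: np.ndarray
    cum_risk: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    at_risk: np.ndarray
    landmark_age: float
    risk_at_landmark: float
    risk_ci: tuple[float, float]
    n: int
    n_events: int


def km_cumulative_risk(times, events, landmark_age: float) -> KMCurve:
    """Product-limit cumulative risk with Greenwood log(−log) 95% CIs.

    Risk at the landmark is 1 − Ŝ(landmark).  If follow-up ends before the
    landmark the risk at the last observed time is returned with a warning.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if len(times) == 0:
        raise ValueError("empty time/event input")
    if np.all(times == 0):
        raise ValueError("all follow-up times are zero")

    kmf = KaplanMeierFitter()
    kmf.fit(times, events)  # lifelines CIs are exponential Greenwood (log(-log))

    read_at = landmark_age
    if landmark_age > times.max():
        read_at = float(times.max())
        warnings.warn(
            f"landmark {landmark_age} beyond last observed time; "
            f"reporting risk at {read_at}",
            stacklevel=2,
        )

    surv = kmf.survival_function_.iloc[:, 0]
    ci = kmf.confidence_interval_
    risk = float(1.0 - kmf.predict(read_at))
    s_lo = float(ci.iloc[:, 0].asof(read_at))
    s_hi = float(ci.iloc[:, 1].asof(read_at))
    # survival CI (lo, hi) maps to risk CI (1-hi, 1-lo)
    risk_ci = (1.0 - s_hi, 1.0 - s_lo)

    grid = surv.index.to_numpy(dtype=float)
    at_risk = np.array(
        [int((times >= t).sum()) for t in grid], dtype=int
    )
    return KMCurve(
        times=grid,
        cum_risk=1.0 - surv.to_numpy(dtype=float),
        ci_low=1.0 - ci.iloc[:, 1].to_numpy(dtype=float),
        ci_high=1.0 - ci.iloc[:, 0].to_numpy(dtype=float),
        at_risk=at_risk,
        landmark_age=read_at,
        risk_at_landmark=risk,
        risk_ci=risk_ci,
        n=len(times),
        n_events=int(events.sum()),
    )


def logrank_test(times, events, groups) -> tuple[float, float]:
    """Log-rank chi-square test across ≥2 groups; returns (statistic, p)."""
    groups = np.asarray(groups)
    labels, counts = np.unique(groups, return_counts=True)
    if len(labels) < 2:
        raise ValueError("log-rank test needs at least 2 groups")
    if (counts == 0).any():
        raise ValueError("empty group in log-rank test")
    res = multivariate_logrank_test(
        np.asarray(times, dtype=float), groups, np.asarray(events, dtype=int)
    )
    return float(res.test_statistic), float(res.p_value)


def quartile_cutpoints(scores) -> tuple[float, float]:
    """Empirical 25th/75th percentiles (linear interpolation)."""
    s = np.asarray(scores, dtype=float)
    return (
        float(np.percentile(s, 25, method="linear")),
        float(np.percentile(s, 75, method="linear")),
    )


def assign_quartile_strata(scores) -> pd.Series:
    """Lower / middle-two / upper quartile membership, strict '>' at the
    upper cutpoint and '≤' at the lower (ties go to the lower stratum)."""
    s = pd.Series(np.asarray(scores, dtype=float))
    q25, q75 = quartile_cutpoints(s)
    strata = np.where(s > q75, "upper", np.where(s <= q25, "lower", "middle"))
    out = pd.Series(strata, index=s.index)
    for name in STRATA:
        if (out == name).sum() == 0:
            raise ValueError(
                f"empty {name!r} stratum: heavy ties at cutpoints ({q25}, {q75})"
            )
    return out


def stratify_by_quartiles(
    scores: pd.DataFrame,
    phenotypes: pd.DataFrame,
    outcome: str,
    landmark_age: float,
) -> dict[str, KMCurve]:
    """Per-stratum KM curves for score upper / middle-two / lower quartiles."""
    aligned = phenotypes.loc[scores.index]
    strata = assign_quartile_strata(scores["score"]).set_axis(scores.index)
    curves = {}
    for name in STRATA:
        mask = (strata == name).to_numpy()
        curves[name] = km_cumulative_risk(
            aligned.loc[mask, f"{outcome}_time"],
            aligned.loc[mask, f"{outcome}_event"],
            landmark_age,
        )
    return curves


def wilson_ci(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= k <= n:
        raise ValueError("k must lie in [0, n]")
    lo, hi = proportion_confint(k, n, alpha=1 - level, method="wilson")
    # the closed form is exactly 0/1 at the boundaries; clear float noise
    lo = 0.0 if k == 0 else float(lo)
    hi = 1.0 if k == n else float(hi)
    return lo, hi


def population_fraction(
    fraction_above_threshold: float, hla_prevalence: float = HLA_PREVALENCE
) -> float:
    """Percent of all newborns selected: score fraction × HLA prevalence."""
    if not 0 <= fraction_above_threshold <= 1 or not 0 <= hla_prevalence <= 1:
        raise ValueError("fractions must lie in [0, 1]")
    return 100.0 * fraction_above_threshold * hla_prevalence


def threshold_sweep(
    scores: pd.DataFrame,
    phenotypes: pd.DataFrame,
    outcome: str,
    landmark_age: float,
    grid_percentile_step: float = 5.0,
    hla_prevalence: float = HLA_PREVALENCE,
    include_floor: bool = False,
) -> pd.DataFrame:
    """Risk and sensitivity at score thresholds set at cohort percentiles.

    For each threshold τ (from ``grid_percentile_step`` to
    100 − ``grid_percentile_step``): risk = KM cumulative risk at the
    landmark among score > τ; sensitivity = (cases by landmark with
    score > τ) / (all cases by landmark), with a Wilson 95% CI; population
    fraction = P(score > τ) × HLA prevalence.  Spearman trend statistics of
    risk and sensitivity against threshold rank are attached as ``attrs``.
    """
    aligned = phenotypes.loc[scores.index]
    s = scores["score"].to_numpy(dtype=float)
    time = aligned[f"{outcome}_time"].to_numpy(dtype=float)
    event = aligned[f"{outcome}_event"].to_numpy(dtype=int)

    is_case = (event == 1) & (time <= landmark_age)
    n_cases = int(is_case.sum())
    if n_cases == 0:
        raise ValueError(f"no {outcome} cases by age {landmark_age}: sensitivity undefined")

    pcts = list(np.arange(grid_percentile_step, 100.0, grid_percentile_step))
    taus = [float(np.percentile(s, p, method="linear")) for p in pcts]
    if include_floor:
        # a threshold strictly below every score: the whole cohort passes
        pcts.insert(0, 0.0)
        taus.insert(0, float(s.min()) - 1.0)
    rows = []
    for pct, tau in zip(pcts, taus):
        above = s > tau
        km = km_cumulative_risk(time[above], event[above], landmark_age)
        k = int((is_case & above).sum())
        sens_lo, sens_hi = wilson_ci(k, n_cases)
        rows.append(
            {
                "threshold": tau,
                "percentile": pct,
                "n_above": int(above.sum()),
                "risk_at_landmark": km.risk_at_landmark,
                "risk_ci_low": km.risk_ci[0],
                "risk_ci_high": km.risk_ci[1],
                "n_cases_above": k,
                "sensitivity": k / n_cases,
                "sens_ci_low": sens_lo,
                "sens_ci_high": sens_hi,
                "population_fraction": population_fraction(
                    above.mean(), hla_prevalence
                ),
            }
        )
    sweep = pd.DataFrame(rows)

    rank = np.arange(len(sweep))
    rho_risk, p_risk = stats.spearmanr(rank, sweep["risk_at_landmark"])
    rho_sens, p_sens = stats.spearmanr(rank, sweep["sensitivity"])
    sweep.attrs["spearman_risk"] = (float(rho_risk), float(p_risk))
    sweep.attrs["spearman_sensitivity"] = (float(rho_sens), float(p_sens))
    return sweep


def compare_distributions(values, groups) -> pd.DataFrame:
    """Two-sided Mann-Whitney U comparison with group medians and IQRs."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = np.unique(groups)
    if len(labels) != 2:
        raise ValueError("exactly two groups required")
    a, b = (values[groups == g] for g in labels)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    u, p = stats.mannwhitneyu(a, b, alternative="two-sided")
    rows = []
    for lab, v in zip(labels, (a, b)):
        q1, med, q3 = np.percentile(v, [25, 50, 75])
        rows.append({"group": lab, "n": len(v), "median": med, "iqr_low": q1, "iqr_high": q3})
    out = pd.DataFrame(rows)
    out.attrs["mannwhitney_u"] = float(u)
    out.attrs["p_value"] = float(p)
    return out


def allele_freq_compare(
    genotypes: pd.DataFrame, regions: pd.Series, n_snps: int | None = None
) -> pd.DataFrame:
    """Per-SNP allele-frequency chi-square between two regions, with a
    Bonferroni significance threshold of 0.05 / n_snps."""
    rsids = [c for c in genotypes.columns if c.startswith("rs")]
    n_snps = n_snps or len(rsids)
    threshold = 0.05 / n_snps
    labels = np.unique(regions)
    if len(labels) != 2:
        raise ValueError("exactly two region groups required")
    rows = []
    for rsid in rsids:
        counts = genotypes[rsid]
        freqs, tab = [], []
        for lab in labels:
            c = counts[(regions == lab).to_numpy()].dropna()
            eff = int(c.sum())
            tot = 2 * len(c)
            freqs.append(eff / tot if tot else np.nan)
            tab.append([eff, tot - eff])
        tab = np.asarray(tab)
        if tab[:, 0].sum() == 0 or tab[:, 1].sum() == 0:
            p = 1.0  # monomorphic SNP: no frequency difference testable
        else:
            _, p, _, _ = stats.chi2_contingency(tab, correction=False)
        rows.append(
            {
                "rsid": rsid,
                f"freq_{labels[0]}": freqs[0],
                f"freq_{labels[1]}": freqs[1],
                "p_value": float(p),
                "significant": bool(p < threshold),
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["bonferroni_threshold"] = threshold
    return out
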
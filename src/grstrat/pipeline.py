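"""End-to-end pipeline: scores -> stratification -> sweep -> calibration -> TROC.

Configuration is a flat YAML file (see ``RunConfig`` fields).  Every run
writes TSV tables, a machine-readable ``summary.json`` and a ``manifest.json``
with the seed, package version and input checksums; identical config + seed
gives byte-identical JSON.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .calibration import CaseControlScores, empirical_risk_curve, find_threshold_for_risk
from .genotypes import HLA_COL, read_genotype_tsv
from .scoring import compute_scores, write_scores_tsv
from .simulate import CohortConfig, simulate_case_control, simulate_cohort
from .survival import (
    km_cumulative_risk,
    logrank_test,
    assign_quartile_strata,
    threshold_sweep,
)
from .troc import TROCConfig, bootstrap_compare
from .weights import apply_proxy_map, load_demo_maf, load_demo_tables, load_weight_table, merge_weight_tables

logger = logging.getLogger(__name__)

LANDMARKS = {"any_ab": 6.0, "multi_ab": 6.0, "t1d": 10.0}


@dataclass
class RunConfig:
    # weight inputs; when None the bundled demonstration tables are used
    winkler_snps: str | None = None
    winkler_hla: str | None = None
    oram_snps: str | None = None
    oram_hla: str | None = None
    proxy_map: str | None = None
    # cohort inputs; when None a synthetic cohort is simulated
    genotypes: str | None = None
    phenotypes: str | None = None
    outcomes: tuple[str, ...] = ("any_ab", "multi_ab", "t1d")
    landmarks: dict[str, float] = field(default_factory=lambda: dict(LANDMARKS))
    grid_percentile_step: float = 5.0
    # simulation
    n_individuals: int = 3498
    # case-control calibration
    calibrate: bool = True
    n_cases: int = 781
    n_controls: int = 4371
    background_risk: float = 0.05
    target_risk: float = 0.10
    case_effect: float = 4.0
    # time-dependent ROC comparison (scaled-down bootstrap for the demo)
    troc: bool = True
    troc_n_boot: int = 100
    seed: int = 1234
    outdir: str = "results/run"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "outcomes" in raw:
            raw["outcomes"] = tuple(raw["outcomes"])
        return cls(**raw)


def _sha256(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def validate_inputs(config: RunConfig) -> dict:
    """Cross-check inputs; returns {'errors': [...], 'warnings': [...]}."""
    errors, warnings_ = [], []
    for name in ("winkler_snps", "winkler_hla", "oram_snps", "oram_hla",
                 "proxy_map", "genotypes", "phenotypes"):
        p = getattr(config, name)
        if p is not None and not Path(p).exists():
            errors.append(f"{name}: file not found: {p}")
    for outcome, age in config.landmarks.items():
        if age <= 0:
            errors.append(f"landmark age for {outcome} must be positive")
    if errors:
        return {"errors": errors, "warnings": warnings_}

    winkler, oram = _load_tables(config)
    if config.genotypes is not None:
        geno = read_genotype_tsv(config.genotypes)
        panel = {c for c in geno.columns if c != HLA_COL}
        for table in (winkler, oram):
            resolved = apply_proxy_map(table, panel)
            lost = table.n_snps - resolved.n_snps
            if lost:
                warnings_.append(
                    f"{table.name}: {lost} weighted SNP(s) not typed and not "
                    f"proxied; they contribute zero to scores (no renormalisation)"
                )
    if config.phenotypes is not None:
        pheno = pd.read_csv(config.phenotypes, sep="\t")
        for outcome in config.outcomes:
            col = f"{outcome}_time"
            if col in pheno.columns and (pheno[col] < 0).any():
                errors.append(f"negative event time in column {col}")
    return {"errors": errors, "warnings": warnings_}


def _load_tables(config: RunConfig):
    if config.winkler_snps is None:
        return load_demo_tables()
    winkler = load_weight_table(
        config.winkler_snps, config.winkler_hla, config.proxy_map, source="winkler"
    )
    oram = load_weight_table(
        config.oram_snps, config.oram_hla, config.proxy_map, source="oram"
    )
    return winkler, oram


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis; writes tables under ``config.outdir``."""
    report = validate_inputs(config)
    if report["errors"]:
        raise ValueError("input validation failed: " + "; ".join(report["errors"]))
    for w in report["warnings"]:
        logger.warning(w)

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"seed": config.seed, "warnings": report["warnings"]}

    winkler_raw, oram_raw = _load_tables(config)

    # --- cohort ----------------------------------------------------------
    if config.genotypes is not None:
        genotypes = read_genotype_tsv(config.genotypes)
        phenotypes = pd.read_csv(
            config.phenotypes, sep="\t", dtype={"individual_id": str}
        ).set_index("individual_id")
        panel = {c for c in genotypes.columns if c != HLA_COL}
        sim_cfg = None
    else:
        maf = load_demo_maf()
        panel = set(maf)
        merged_panel = merge_weight_tables(
            apply_proxy_map(winkler_raw, panel), apply_proxy_map(oram_raw, panel)
        )
        sim_cfg = CohortConfig(
            n_individuals=config.n_individuals, maf=maf, seed=config.seed
        )
        cohort = simulate_cohort(sim_cfg, merged_panel)
        genotypes, phenotypes = cohort.genotypes, cohort.phenotypes

    winkler = apply_proxy_map(winkler_raw, panel)
    oram = apply_proxy_map(oram_raw, panel)
    merged = merge_weight_tables(winkler, oram)
    summary["n_snps"] = {
        "winkler": winkler.n_snps, "oram": oram.n_snps, "merged": merged.n_snps
    }

    scores = {
        name: compute_scores(tbl, genotypes)
        for name, tbl in (("winkler", winkler), ("oram", oram), ("merged", merged))
    }
    for name, df in scores.items():
        write_scores_tsv(df, outdir / f"scores_{name}.tsv")

    # --- quartile stratification & threshold sweep (merged score) --------
    strata = assign_quartile_strata(scores["merged"]["score"]).set_axis(
        scores["merged"].index
    )
    summary["stratification"] = {}
    summary["sweep"] = {}
    for outcome in config.outcomes:
        landmark = config.landmarks[outcome]
        times = phenotypes.loc[scores["merged"].index, f"{outcome}_time"]
        events = phenotypes.loc[scores["merged"].index, f"{outcome}_event"]
        whole = km_cumulative_risk(times, events, landmark)
        stat, p = logrank_test(times, events, strata)
        per_stratum = {}
        for name in ("lower", "middle", "upper"):
            m = (strata == name).to_numpy()
            km = km_cumulative_risk(times[m], events[m], landmark)
            per_stratum[name] = {
                "n": km.n,
                "risk": round(km.risk_at_landmark, 6),
                "ci": [round(x, 6) for x in km.risk_ci],
            }
        summary["stratification"][outcome] = {
            "landmark_age": landmark,
            "whole_cohort_risk": round(whole.risk_at_landmark, 6),
            "whole_cohort_ci": [round(x, 6) for x in whole.risk_ci],
            "strata": per_stratum,
            "logrank_stat": round(stat, 4),
            "logrank_p": float(f"{p:.4g}"),
        }

        sweep = threshold_sweep(
            scores["merged"], phenotypes, outcome, landmark,
            grid_percentile_step=config.grid_percentile_step,
        )
        sweep.to_csv(outdir / f"sweep_{outcome}.tsv", sep="\t", index=False)
        rho_r, p_r = sweep.attrs["spearman_risk"]
        rho_s, p_s = sweep.attrs["spearman_sensitivity"]
        summary["sweep"][outcome] = {
            "n_thresholds": len(sweep),
            "spearman_risk": [round(rho_r, 4), float(f"{p_r:.4g}")],
            "spearman_sensitivity": [round(rho_s, 4), float(f"{p_s:.4g}")],
        }

    # --- case-control calibration ----------------------------------------
    if config.calibrate:
        cc_cfg = sim_cfg or CohortConfig(maf=load_demo_maf(), seed=config.seed)
        cases, controls = simulate_case_control(
            config.n_cases, config.n_controls, cc_cfg, merged,
            effect=config.case_effect,
        )
        data = CaseControlScores(cases, controls, config.background_risk)
        curve = empirical_risk_curve(data)
        curve.to_csv(outdir / "casecontrol_risk_curve.tsv", sep="\t", index=False)
        try:
            row = find_threshold_for_risk(curve, config.target_risk)
            summary["calibration"] = {
                "threshold": round(float(row["threshold"]), 4),
                "empirical_risk": round(float(row["empirical_risk"]), 6),
                "sensitivity": round(float(row["sensitivity"]), 6),
            }
        except ValueError as exc:
            summary["calibration"] = {"error": str(exc)}

    # --- time-dependent ROC comparison ------------------------------------
    if config.troc:
        tcfg = TROCConfig(n_boot=config.troc_n_boot, seed=config.seed)
        comp = bootstrap_compare(
            {n: s["score"] for n, s in scores.items()},
            phenotypes.loc[scores["merged"].index, "multi_ab_time"],
            phenotypes.loc[scores["merged"].index, "multi_ab_event"],
            tcfg,
        )
        comp.bootstrap.to_csv(outdir / "troc_bootstrap.tsv", sep="\t", index=False)
        comp.bayes_factors.to_csv(outdir / "troc_bayes_factors.tsv", sep="\t", index=False)
        summary["troc"] = {
            "iauc": {k: round(v, 6) for k, v in comp.iauc.items()},
            "bayes_factors": {
                f"{r.score_1}_vs_{r.score_2}": round(float(r.bf), 4)
                for r in comp.bayes_factors.itertuples()
            },
        }

    # --- manifest ----------------------------------------------------------
    inputs = {
        name: _sha256(getattr(config, name))
        for name in ("winkler_snps", "winkler_hla", "oram_snps", "oram_hla",
                     "proxy_map", "genotypes", "phenotypes")
        if getattr(config, name) is not None
    }
    manifest = {
        "grstrat_version": __version__,
        "seed": config.seed,
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in dataclasses.asdict(config).items()},
        "input_checksums": inputs,
    }
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return summary
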
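# Methods

## Score construction

A genetic risk score is an additive model on the log-odds scale: an HLA DR-DQ
genotype weight (one constant per genotype class; only the two highest-risk
classes, DR3/DR4-DQ8 and DR4-DQ8 homozygous, are admitted — other genotypes
are rejected, mirroring the cohort restriction the analysis assumes) plus a
per-SNP weight multiplied by the individual's effect-allele count.

Decisions that the published score descriptions leave open, and how this
package resolves them:

- **Missing SNPs contribute zero, with no renormalisation.** The original
  scores were computed on incomplete typing panels (39/40 and 26/28 SNPs
  available) without rescaling, so a score computed on fewer SNPs is simply
  smaller on average. `ScoreResult` carries `n_snps_used`/`n_snps_missing` so
  downstream analyses can audit this.
- **Proxy substitution is explicit.** A weight table carries a proxy map
  (missing rsid → typed substitute); `apply_proxy_map` renames entries whose
  rsid is absent from the panel and drops — with a logged warning — entries
  with no usable proxy.
- **Merging.** Shared SNPs average the two weights; unique SNPs pass through;
  the two declared sign-conflict SNPs take the oram weight. The merged HLA
  weight is the mean of the two scores' HLA weights — the sources state the
  mean rule only for SNPs, so treating HLA the same way is an assumption of
  this package, applied uniformly.
- **Allele harmonization is conservative.** Where a genotype source counts
  the non-effect allele, counts are complemented (c → 2 − c). Strand-ambiguous
  SNPs (A/T, C/G) with a mismatching counted allele cannot be resolved without
  frequency information and are excluded (set missing) by default.
- Scores are stored at full floating precision; the 0.1 granularity appears
  only in the case–control threshold grid.

The bundled weight tables under `src/grstrat/data/` are **synthetic
demonstration values**: they reproduce the documented structure (40 and 28
non-HLA SNPs; proxies rs3757247/rs1004446 for rs11755527/rs689; rs917997
untyped with no proxy; 22 shared loci so the merged panel has 43 SNPs;
weights of realistic log-OR magnitude placing merged scores around 13–16)
but not the published numbers, which live in restricted supplementary data.

## Synthetic cohort generator

The generator emulates the design of a prospective HLA-selected birth cohort
so that every downstream stage is testable without data access. Defaults are
fixed once as the study conditions:

| parameter | default | rationale |
|---|---|---|
| `n_individuals` | 3,498 | size of the scored prospective cohort |
| `followup_years` | 10 | administrative horizon covering both landmark ages |
| visit schedule | 3-monthly to age 4 y, 6-monthly after | the cohort's sampling design |
| `p_dr34` | 0.60 | share of DR3/DR4-DQ8 among eligible genotypes (split not published; fixed once) |
| `p_europe` | 0.58 | 2,027 of 3,498 scored children were European |
| `baseline_hazard` | any-ab 0.0135/y; gap rates 0.38/y (multi), 0.075/y (diabetes) | calibrated at n = 20,000 so whole-cohort KM risks land near the published 9%/5.8% by age 6 and ~3.7% by age 10 |
| `beta_score` | 0.30 per unit score (score SD ≈ 1.1) | gives upper/lower-quartile risk ratios near the published ~3–5× |
| `beta_sex` | 0.20 (male) | male excess in autoantibody risk |
| case-acceptance `effect` | 4.0 per unit score | reproduces the published case–control separation: calibrated risk reaches 10% at ≈58% sensitivity |

Event times follow a nested proportional-hazards structure: seroconversion is
exponential with rate λ·exp(β·(score − mean) + β_sex·male); waiting times to
multiple autoantibodies and to diabetes are exponential gaps added on top, so
the three latent times are ordered by construction. Autoantibody outcomes are
then discretized to the visit schedule with a persistence rule: the event is
recorded — dated at the *first* of two consecutive positive visits — only if
the second visit also falls within follow-up. Diabetes keeps its latent
(clinical-diagnosis) date.

What the generator deliberately does **not** model: assay noise or antibody
reversion (persistence is deterministic once the latent event occurs),
maternal-IgG transmission, enrollment staggering (replaced by one
administrative horizon), linkage disequilibrium between SNPs (counts are
independent binomials), and HLA–score correlation. Passing tests therefore
demonstrate the statistical machinery — estimator correctness, calibration,
monotonicity, ordering — under the assumed proportional-hazards structure,
not the biological fidelity of any particular risk estimate on real data.

## Survival analysis

Kaplan–Meier estimation, Greenwood confidence intervals on the log(−log)
scale and the log-rank test are delegated to `lifelines`; an independent
brute-force product-limit implementation in the test suite checks equality to
1e-12. Landmark risks are read at exact ages (6.0 and 10.0 y). If follow-up
ends before the landmark, the risk at the last observed time is reported with
a warning rather than extrapolated.

Quartile cutpoints use linear-interpolation percentiles (numpy's `linear`
method), membership is strict `>` at the upper cutpoint and `≤` at the lower,
so ties at a cutpoint fall to the lower stratum — matching the threshold
convention used throughout (a published threshold is always "score > τ").
Proportion CIs use the Wilson score interval, which reproduces the published
interval for 82/173 (40.1–54.8%) exactly. The threshold sweep reports
Spearman ρ of risk and of sensitivity against threshold rank as the trend
statistic.

## Case–control calibration

The empirical-risk grid is anchored at the integer floor/ceil of the pooled
score range with 0.1 steps, making runs reproducible across machines.
Empirical risk is not clamped: values above 100% (possible when few controls
exceed τ) are reported with a warning, and thresholds with zero control
exceedance are flagged undefined rather than dropped. Threshold finding
returns the smallest grid τ with defined risk ≥ target, without isotonic
smoothing — raw curves are the observable.

## Time-dependent ROC comparison

AUC(t) is the cumulative-case/dynamic-control estimator: cases are subjects
with an event by t, weighted by inverse probability of censoring from the
Kaplan–Meier estimate of the censoring distribution (left limit at each
subject's own time); controls (time > t) are unweighted; score ties count
1/2. The test suite cross-checks this against an exhaustive pair-enumeration
oracle (uncensored case, equality to 1e-12) and against scikit-survival's
independent IPCW implementation under censoring.

The integrated AUC is the trapezoidal integral over a 1–10-year grid in
100-day steps, normalised by the span of the grid points where the AUC is
defined; undefined grid points (no cases yet, or no controls remaining) are
dropped with a log entry, and a single surviving point returns its own AUC.

Bootstrap comparison resamples *individuals* with replacement — scores and
outcome travel together, and every score is evaluated on the same resample,
which is what makes the estimates paired. Resampling is a function of sorted
individual IDs, so row order cannot change results. The Bayes factor is the
fraction of resamples where one score's iAUC strictly exceeds the other's,
divided by the complementary fraction; ties count to the null ("no better"),
so a score compared with itself gives BF = 0, and a zero denominator
saturates at BF = n_boot (the resolution limit of the bootstrap) rather than
infinity.

## Problem sizes

The analysis drivers use the full default cohort (n = 3,498) with 400
bootstrap resamples for the score comparison (the procedure is defined at
2,000; the default `TROCConfig.n_boot` remains 2,000 and the drivers pass a
smaller value, which the package treats as an ordinary parameter). The test
suite runs its statistical calibration checks at 1,000 null simulations and
its parameter-recovery check at 100 replicates of n = 10,000.

## Known limitations

- The shipped weights are structural stand-ins; absolute score thresholds
  (e.g. the upper-quartile cutoff ≈ 14.8 on synthetic data) are not
  comparable to published thresholds, though relative behaviour is.
- The empirical-risk estimator is undefined where no control exceeds the
  threshold; with 4,371 controls this occurs only in the extreme upper tail.
- Cox modelling, specificity analyses and competing-risk estimators are out
  of scope by design.
- The VCF dosage reader handles diploid autosomal GT fields only; half-calls
  are treated as missing.
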
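# Methods

This document records the statistical model, the design of the synthetic
cohort generator, and the numerical choices behind `ctdna_kinetics`.

## 1. ddPCR quantification (`ddpcr`)

### Poisson partition model

Each well partitions a reaction into `n_total` droplets (nominally
18,000 of 0.85 nl each, as on common commercial ddPCR systems).  Target
molecules distribute approximately Poisson across droplets, so with `k`
positive droplets the occupancy and concentration estimates are

```
λ̂ = −ln((n_total − k) / n_total)
ĉ = λ̂ / (V·10⁻³)      copies per µl of reaction, V in nl
```

Edge cases: `k = 0` gives λ̂ = 0 (no template, `NoTemplateError` is *not*
raised — zero is a valid estimate); `k = n_total` is saturation and
raises `SaturatedWellError` because λ̂ is unbounded there.

### Confidence interval

A 95% Wilson score interval is computed on the negative-droplet fraction
`p = (n_total − k)/n_total` (via `statsmodels.stats.proportion.
proportion_confint`), then mapped through the strictly decreasing
transform `p ↦ −ln(p)/V`.  Monotonicity means the interval endpoints map
directly, no delta method needed at this stage.  At `k = 0` floating
round-off can push the mapped lower bound a few ulp above the point
estimate 0; the bound is clipped to the estimate.  Measured coverage
across occupancies λ ∈ {0.001, 0.01, 0.1, 1} is 93–97% (see the
acceptance report).

### Merging replicate wells

Replicate wells of one sample/assay are merged by **pooling droplet
counts** before estimation.  Pooling is the maximum-likelihood treatment
and differs from averaging per-well estimates whenever counts differ;
the tests pin this distinction.  Wells being merged must agree on
sample, assay and droplet volume (`InconsistentWellsError` otherwise).

### Limit of blank and detection

`LOB = max(k_min, 1 + max_j fp_j)` where `fp_j` are mutant-positive
counts in the no-template-control wells and `k_min = 3` droplets, a
conventional floor for rare-mutation ddPCR.  A sample is **detected**
when its merged mutant-positive count is ≥ LOB.  Detection is a property
of raw droplet counts, not of the concentration estimate, so it is
invariant to the droplet volume.

### Mutant allele fraction

`MAF% = 100 · c_mut / (c_mut + c_wt)`.  The 95% CI treats
`r = ln(c_mut/c_wt)` as approximately normal; each concentration's CI
half-width on the log scale serves as its standard-error surrogate, the
two are combined in quadrature, and the resulting interval for the ratio
`x = c_mut/c_wt` is mapped through `x ↦ 100·x/(1+x)`.  Special cases:

* undetected sample → MAF 0 with a one-sided upper bound computed from a
  hypothetical count of `LOB − 1` mutant droplets (the largest count
  still called negative), keeping undetected samples plottable;
* `c_wt = 0` with detected mutant → MAF 100 with a degenerate CI.

## 2. Trajectory classification (`dynamics`)

Samples for one patient/assay are ordered by collection day (strictly
increasing, enforced).  For each consecutive pair:

| previous | current | kind |
|---|---|---|
| undetected | undetected | `REMAINS_NEGATIVE` |
| undetected | detected | `INCREASE` |
| detected | undetected | `CLEARANCE` |
| detected | detected, 95% CIs disjoint, MAF up | `INCREASE` |
| detected | detected, 95% CIs disjoint, MAF down | `DECREASE` |
| detected | detected, CIs overlap | `STABLE` |

CI non-overlap of two independent 95% intervals is a conservative
significance rule (pointwise level well below 0.05); it is used because
it is assumption-light and matches how serial ddPCR results are read in
practice.

An `INCREASE` at transition *i* (samples *i* → *i+1*) is **confirmed**
when sample *i+2* exists, is detected, and the *i+1* → *i+2* transition
is not a significant `DECREASE`; otherwise it is `UNCONFIRMED`.
Confirmation guards against isolated blips at the detection boundary.

Relating a trajectory to radiographic progression uses only
**post-treatment** increases (transition landing day > 0).  Categories:
`NO_PROGRESSION`, `NO_INCREASE`, `INCREASE_BEFORE_PROGRESSION` (any
qualifying increase day strictly before the progression day), else
`INCREASE_AT_OR_AFTER_PROGRESSION`.  The **lead time** is
`progression_day − earliest qualifying increase day`; a same-day
increase is deliberately *not* a lead (strict inequality), since a draw
on the day of radiographic progression anticipates nothing.  The
5-cell Sankey table cross-tabulates progression × increase × timing and
always sums to the cohort size.

## 3. Outcome statistics (`stats`)

All estimators are implemented from first principles; `lifelines` and
`scipy` serve only as independent oracles in the test suite.

* **Kaplan–Meier**: product-limit estimator; at tied times events are
  processed before censorings (standard convention).  The median is the
  smallest observed time with `S(t) ≤ 0.5` — by this invariant the
  median of four uncensored times {2, 4, 6, 8} is 4, where `S` first
  reaches 0.5.
* **Log-rank**: at each distinct event time the observed minus expected
  events in group 1 with the hypergeometric variance; `χ² = (ΣO−E)²/ΣV`
  referred to χ²₁.  Verified against `lifelines` and, at n = 8, against
  exhaustive label permutation (all C(8,4) splits).
* **Wilcoxon rank-sum**: exact two-sided p-value by full enumeration of
  `C(n₁+n₂, n₁)` group assignments with midranks, for combined n ≤ 12;
  beyond that a normal approximation with tie and continuity
  corrections.  The two branches agree to ≤ 0.02 where they overlap.
* **Pearson correlation** with the usual t-transform p-value.
* **Landmark analysis**: a patient is landmark `POSITIVE` if any sample
  collected in day window [60, 122] *and before progression* is
  detected, `NEGATIVE` if there is at least one such sample and none is
  detected, `NOT_EVALUABLE` otherwise.  The pre-progression restriction
  avoids the classic landmark bias of letting post-progression biology
  define the stratum.  The window starts after two on-treatment cycles
  and ends at the first scheduled response scan — early enough to be
  actionable, late enough that clearance kinetics have played out.
* **Endpoints**: OS is time to death (censored at last follow-up); PFS
  is time to min(progression, death).  Months = days / 30.44.

## 4. Synthetic cohort generator (`simulate`)

The generator produces droplet-level data whose analysis *by this
pipeline* reproduces the qualitative behavior of a small uveal-melanoma
monitoring trial, with ground truth attached.  Per patient:

1. **Baseline burden**: RECIST sum lognormal, median 60 mm.
2. **Shedding**: copies of mutant template per ml plasma per mm of
   tumor, lognormal with median 0.5 and log-sd 1.5; 40% of patients are
   **low shedders** (rate × 0.002).  The mixture is the load-bearing
   realism choice: ctDNA-based trials consistently find a large minority
   of patients with undetectable baseline ctDNA despite measurable
   disease, and a unimodal shedding law cannot produce both clean
   positives and clean negatives — it concentrates patients in the
   grey zone at the detection boundary where no classifier can work.
3. **Background cfDNA**: lognormal, median 3000 genome-equivalents/ml,
   sets the wild-type channel.
4. **Response class**: CR/PR/SD/PD with probabilities
   0.10/0.25/0.40/0.25; tumor burden follows exponential kinetics with
   per-day decay 0.05/0.025/0.003/−0.008, PR floored at 30% of baseline,
   CR decaying below 2%.
5. **Progression**: hazard 1/450 per day, multiplied by the true hazard
   ratio (default 3) for truly landmark-positive patients; death lags
   progression by a lognormal delay (median 120 d); administrative
   censoring at 540 d.
6. **Sampling**: plasma draws at days −7, 21, 42, 63, 84, 105, 126,
   168, … (every 6 weeks then 12); imaging every 12 weeks from day −14.
   2 ml plasma, 50% extraction efficiency, one well per draw (18,000
   droplets mean), mutant-channel false positives at 10⁻⁵ per droplet,
   six NTC wells.
7. **Covariates**: LDH coupled to burden with noise; M1a/b/c from the
   largest lesion; extrahepatic spread Bernoulli(0.28).

**Ground-truth labels are probabilistic, not threshold-based**: a draw
is *truly detectable* when `P(K ≥ 3) > 0.5` for
`K ~ Poisson(expected mutant copies in reaction + expected false
positives)` — i.e. the label says what an ideal assay would most likely
call, rather than comparing latent copy numbers to an arbitrary cutoff.
This makes truth/inference concordance a meaningful operating
characteristic (measured ≈ 96% for landmark status) instead of an
artifact of where the cutoff sits.

What the generator does **not** emulate: assay-specific rain/threshold
artifacts, droplet volume variability, clonal evolution or genotype
switching, treatment crossover, non-proportional hazards, informative
dropout, and inter-lab calibration. Detection of progression is modeled
as exact at the scheduled scan (no reader noise).

Determinism: one integer seed drives a `numpy` `default_rng`; all
derived seeds are < 2³¹.  `SimulatedCohort.write` uses fixed float
formatting and line terminators so reruns are byte-identical.

## 5. Problem sizes and acceptance checks

Sizes used by the test suite and `scripts/acceptance.py` are the
package's own choices, picked to make each property measurable with
margin while keeping the full suite around five minutes on one CPU:

* CI coverage: 1000 wells at each of four occupancies (binomial SE
  ≈ 0.7%, so the 93–97% band is a ~3σ check).
* Rule table: all 3-state sequences of length ≤ 4 with every progression
  placement (666 cases) versus an independently written symbolic oracle.
* Null calibration: 500 cohorts of 40 patients at true HR = 1;
  Kolmogorov–Smirnov test of the log-rank p against uniform.
* Recovery: 200 cohorts of 100 patients at true HR = 3 (median PFS
  ordering recovered in > 95%), contrasted with 100 cohorts of 13
  patients, where log-rank power collapses (~20–30%) — an honest
  reminder of what a single small trial can and cannot show.
* Round trip: a fixed 18-patient cohort through all four stages, plus
  landmark truth concordance aggregated over five 40-patient cohorts
  (~150 evaluable patients) for a stable rate; a single 18-patient
  cohort would make the > 90% check a coin flip on 2–3 discordances.

`scripts/acceptance.py --seed S --out f.json` derives every random
stream from `S` and writes each measured quantity as
`{"value": ..., "n": ...}` under a descriptive name.
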
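# Methods

## Scope and data model

All analyses are trial-level: the unit of observation is one randomized
controlled trial's published summary statistics, never patient-level data.
A `TrialRecord` carries hazard ratios (HRs) with 95% CIs for PFS1, PFS2 and
OS (initial and long-term data cuts), per-arm sample sizes and median
PFS2/OS in months, event counts with their printed denominators, planned OS
event counts, control-arm crossover exposure, and design flags. Missingness
is explicit (`None` in memory, `"NR"` on disk) and never imputed; each
analysis selects the trials that actually report what it needs and logs the
exclusions, so per-analysis n values are reconstructible from the log.

Published tables are occasionally internally inconsistent (an OS-maturity
denominator that differs from the sum of the arm sizes, aggregate counts
that disagree with the per-trial column). The data layer stores printed
values verbatim per column and resolves nothing: the printed fraction is
authoritative for each derived quantity.

## Primary surrogacy model

Across trials i with log hazard ratios xᵢ = ln HR(PFS2)ᵢ and
yᵢ = ln HR(OS)ᵢ, weighted least squares fits

y = β₀ + β₁x + ε,  minimizing Σ wᵢ(yᵢ − β₀ − β₁xᵢ)²,  wᵢ = total randomized Nᵢ.

Conventions:

- **Natural logarithms** throughout. r and R² are base-invariant; the slope
  is not, so the base is fixed and documented.
- **Weights are frequency-style** but every reported quantity is invariant
  to rescaling them by a positive constant: internally weights are
  normalized to sum to n, the residual variance is estimated on n − 2
  degrees of freedom, and the slope t-test always uses n − 2 df regardless
  of the weight scale. The fit itself is delegated to a standard WLS
  routine; tests pin it against a closed-form solution of the weighted
  normal equations.
- R² = 1 − Σwᵢeᵢ²/Σwᵢ(yᵢ − ȳ_w)², identically equal to the squared
  weighted Pearson correlation (asserted to 1e-10 on random inputs).
- The weighted Pearson r is computed from the weighted-moment definition;
  p-values are two-sided at α = 0.05 with no multiplicity adjustment
  (many analyses, all reported, none cherry-picked — the convention of the
  literature this implements).
- Minimum 3 trials per regression; below that the analysis is refused
  ("insufficient trials"), never extrapolated.

## Bootstrap confidence interval for r

Percentile bootstrap, default 2000 replicates, mandatory explicit seed.
Trials are resampled with replacement jointly as (x, y, w) triples;
the weighted correlation is recomputed per replicate (vectorized);
replicates whose resample has no usable variance (e.g. one distinct trial
drawn n times) are discarded and counted rather than retried. Bounds are
clamped to [−1, 1]; at subgroup sizes of 3–5 trials, bounds of −1 and 1 are
routine and are reported as such. Resampling happens on the trial set
sorted by trial id, so results are independent of input row order. The
percentile method was chosen over BCa/normal variants because nothing in the
implemented procedure's source literature specifies one; the method is a
documented, configurable choice.

What the CI estimates: the weighted correlation of the *observed* log-HR
estimates. Because observed HRs carry estimation noise, this population
value sits below the latent noise-free correlation (see *Synthetic data*).
Simulation places the percentile CI's coverage of that estimand at ~0.90
for n = 15 — the familiar small-sample undercoverage of percentile
intervals, allowed for in the test suite's acceptance band [0.85, 0.97].
Coverage of the *latent* correlation is substantially lower (~0.78 under
default noise) and is a bias of the estimand, not of the interval; no CI on
observed effects can fix it.

## Classification rules

- Strength bands on the signed r: r < 0.5 poor-to-fair, 0.5 ≤ r ≤ 0.7
  moderate (both boundaries inclusive to moderate), r > 0.7 strong. The
  bands were conceived for positive correlations; a negative r is labelled
  poor_fair and a prominent warning is emitted, because "poor_fair"
  understates how anomalous an inverse surrogacy correlation is.
- IQWiG validity on the 95% CI for r: lower bound ≥ 0.85 valid, upper bound
  ≤ 0.70 invalid, otherwise inconclusive.

## Maturity, information fraction, and subgroups

Maturity = events / printed intention-to-treat denominator; information
fraction = events / protocol-planned events for the final analysis, which
**may exceed 1** and is never clamped. Percentages render by round-half-even
at the printed precision, which reproduces published mixed-precision
printings (112.5 → 112, 156.6 → 157).

Subgroup analyses split eligible trials at fixed thresholds and rerun the
full weighted analysis per stratum: PFS2 maturity at 55%, OS information
fraction at 75%, OS maturity at 40%/60% (no stratum above 60% is defined;
such trials are logged as unassigned, not pooled), treatment line
(second-line vs later-line PFS2, derived from prior lines at study entry:
untreated-for-advanced-disease means PFS2 captures second-line
progression), and control-arm crossover at 30%/50% (run against long-term
OS, where crossover acts). Boundary conventions: single-cut criteria use
[min, c) vs [c, max) — the boundary lands in the upper stratum; the
crossover bands are [0, 0.30] and (0.30, 0.50], with the ambiguous 30%
boundary assigned to the lower band. Strata are disjoint; trials missing
the criterion value are excluded and logged; a stratum with fewer than 3
trials is reported as "insufficient trials" with its members listed, never
estimated. Per-stratum bootstrap seeds are `seed + stratum_index`.

## Secondary analyses

- **Long-term validation** reruns the primary model with the long-term OS
  hazard ratio as response. Subtype subsets use initial OS by default
  (configurable); at the minimum n = 3 the result is computed but flagged
  as carrying essentially no precision.
- **Drift**: Δᵢ = ln HR(OS, long-term)ᵢ − ln HR(OS, initial)ᵢ, correlated
  with ln HR(PFS2)ᵢ by Spearman's ρ. If every Δ is identical (no drift) the
  correlation is undefined and reported as a degenerate "no drift" case.
- **Spearman's ρ** uses average ranks for ties. For n ≤ 9 the two-sided
  p-value is exact, by enumeration of all n! pairings (vectorized); above
  that, the standard large-sample approximation. Exactness matters here
  because several subsets have 8–9 trials, where the t approximation is
  visibly off.
- **Arm-level medians**: each arm with both medians contributes one
  (median PFS2, median OS) pair; the PFS2/OS ratio summary is the median
  across trials of per-trial ratios (the alternative, ratio of pooled
  medians, is exposed as `pooled_median_ratio` for cross-checking). The
  count of trials with ratio < 0.50 is strict: a tie at exactly 0.50 is not
  "earlier half". Ratios above 1 (PFS2 exceeding OS, ordinarily impossible)
  are kept but flagged.

## Leave-one-out sensitivity

Each eligible trial is excluded in turn and the full analysis rerun on the
remainder (minimum 4 trials so every iteration has 3). The report stores
every iteration plus exact extrema of r, R², slope and p, and two flags:
all iterations positive, all significant at α. Headline output shows point
estimates and p-values; bootstrap CIs are computed per iteration but are
secondary. Per-iteration seeds are `(base_seed + crc32(trial_id)) mod 2³¹`,
so results are independent of iteration order and stable across platforms.

## Synthetic data

The generator emulates the statistical structure the analyses assume:

- latent effects x* ~ N(μ_x, τ²), y* = β₀ + β₁x* + N(0, σ²);
- observed log HRs = latent value + N(0, SE²) with SE = 2/√events, the
  standard large-sample approximation for a 1:1 trial (kept for unbalanced
  2:1 allocations as a documented simplification); 95% CIs are the Wald
  interval exponentiated;
- events = maturity × N, drawn from configured ranges; trials landing below
  5 events are redrawn to keep noise scales sane;
- long-term OS = y* shrunk toward zero by attenuation × crossover%, then
  re-observed at long-term event counts with *independent* noise (real
  long-term estimates share early events with the initial cut, so their
  errors are positively correlated; independence slightly overstates
  long-term noise);
- PFS1 as a stronger, noisier correlate of PFS2 (scale 1.3, extra SD 0.10
  on the log scale: first-progression effects typically exceed PFS2
  effects);
- auxiliary fields (planned events, medians, crossover, PFS2 event counts)
  deleted completely at random at `missing_rate`; hazard ratios are never
  deleted by the generator, so analysis eligibility is controlled
  explicitly (the paper-shaped 18-trial fixture withholds HRs from 3
  trials, yielding 15 complete pairs and 10 long-term trials). Real
  missingness is publication-driven, not MCAR; the generator does not model
  that.

Defaults are fixed study conditions, not tuning knobs: β₁ = 0.53, τ = 0.25,
σ = 0.13 (latent trial-level correlation β₁τ/√(β₁²τ²+σ²) ≈ 0.71),
μ_x = −0.45, N ∈ [100, 1100], OS maturity 12–60%, PFS2 maturity 25–85%,
information fraction 24–157%, long-term fraction 0.6, crossover U(0, 50)%,
attenuation 0.5. Determinism: a single numpy PCG64 generator seeded from
`config.seed` drives everything; identical configs give byte-identical
tables.

Consequence worth understanding: under these noise levels the *observed*
weighted correlation has population value ≈ 0.50, attenuated from the
latent 0.71, and the WLS slope attenuates by the classical
errors-in-variables reliability τ²/(τ² + noise variance) — with the noise
variance averaged under the same sample-size weights as the fit, since
weighting by N downweights the noisiest trials. Tests verify the noise-free
limit recovers β₁ to 1e-3, that mean slopes match this prediction within
Monte-Carlo error over 500 replicates, and that generated CIs cover latent
effects at ~95%. Passing these shows internal statistical coherence; it
does not show that real breast-cancer extractions follow a linear
surrogacy model, share a common β₁ across subtypes, or have MCAR
missingness.

## Numerical choices

- Degenerate variance: a weighted variance at or below
  1e-25·(1 + mean²) is treated as zero (rounding noise from centering),
  triggering an explicit degenerate-input error for correlations, the
  exact constant-response fit (slope 0, R² 0) for regressions, and
  replicate discard inside the bootstrap. Correlations within 1e-12 of ±1
  are snapped to ±1 so exactly collinear data yield exact unit intervals.
- Report rendering rounds r/R² to 3 decimals and percentages to 1; the
  machine-readable JSON keeps full precision, and repeated runs at one seed
  are byte-identical.
- Test-suite and acceptance-script problem sizes — 15–60 trials per set,
  300–500 simulation replicates, 300–2000 bootstrap replicates — were
  chosen to put Monte-Carlo error well below every asserted tolerance while
  keeping the whole suite fast on one CPU.

## Known limitations

- No patient-level surrogacy modelling (copula / bivariate two-stage
  estimators): out of scope, as the underlying procedure operates on
  published summaries only.
- No crossover adjustment of long-term OS (RPSFT/IPCW need patient data);
  crossover enters only as a stratification variable and as an attenuation
  mechanism in the generator.
- The strength-band and IQWiG rules are conventions, not inference; they
  are applied exactly as stated, including their awkward behaviour for
  negative correlations.
- With ~15 trials, every interval here is wide; subgroup results at n = 3–5
  are reported because the procedure defines them, with their
  insufficient-precision warnings, and should be read accordingly.
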
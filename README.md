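# surromet

Trial-level surrogate-endpoint evaluation of **progression-free survival 2
(PFS2)** — and conventional PFS1 — against **overall survival (OS)** in
randomized breast-cancer trials.

OS is the gold-standard endpoint in oncology, but in diseases with long
post-progression survival it takes many years to mature. PFS2 (time from
randomization to progression on *next-line* therapy or death) has been
proposed as an intermediate surrogate. Whether a treatment effect on PFS2
predicts a treatment effect on OS is a *trial-level* question: across
randomized trials, how tightly does the log hazard ratio for PFS2 track the
log hazard ratio for OS?

`surromet` is for meta-researchers and trialists who have extracted
per-trial summary data (hazard ratios with 95% CIs, sample sizes, event
counts, medians) from publications and want the standard surrogacy analysis
stack, reproducibly and with honest handling of missing values.

## The model

The core analysis is a sample-size-weighted linear regression across trials

```
log(HR_OS,i) = β₀ + β₁ · log(HR_PFS2,i) + εᵢ ,    weights wᵢ = Nᵢ (total randomized)
```

with natural logarithms, summarized by:

- the **weighted Pearson correlation** r with a percentile-bootstrap 95% CI
  (trials resampled jointly with their weights),
- the **coefficient of determination** R² = 1 − Σwᵢeᵢ²/Σwᵢ(yᵢ−ȳ_w)², which
  equals r² and is conventionally read against the R² ≥ 0.7 surrogacy bar,
- the slope β₁ with a two-sided t-test on n − 2 degrees of freedom,
- two categorical rules: strength bands (r < 0.5 poor-to-fair, 0.5–0.7
  moderate, > 0.7 strong) and the **IQWiG validity rule** on the CI for r
  (lower bound ≥ 0.85 valid; upper bound ≤ 0.70 invalid; else inconclusive).

Around this sit the analyses a surrogacy evaluation needs: validation
against long-term follow-up OS, subgroup analyses by **endpoint maturity**
(events/patients) and **OS information fraction** (events/planned events,
legitimately above 100% in late-reporting trials), treatment line and
control-arm crossover strata, OS-effect **drift** between data cuts
(Spearman ρ, exact permutation p at n ≤ 9), arm-level median PFS2/OS
correlation and ratio summaries, **leave-one-out** sensitivity, and a
**synthetic trial-set generator** with known ground truth (latent linear
surrogacy plus per-trial estimation noise at SE(ln HR) ≈ 2/√events) for
testing and power exploration.

## Worked example

```python
import surromet as sm

trials = sm.paperlike_fixture(seed=1)          # 18 synthetic trials, 15 with both HRs
res = sm.run_surrogacy(trials, "pfs2", "os_initial", n_boot=2000, seed=1)
```

Running `python examples/01_primary_surrogacy.py` prints:

```
trials analyzed:        15 of 18
weighted Pearson r:     0.509  (95% bootstrap CI 0.057 to 0.833)
R^2:                    0.259
slope (beta1):          0.419   p = 0.0529
strength band:          moderate
IQWiG validity class:   inconclusive
```

Read: across these 15 trials the PFS2 effect explains ~26% of the
between-trial variance in the OS effect; the bootstrap CI for r straddles
both IQWiG thresholds, so the evidence neither validates nor rejects the
surrogate. (The generator's latent correlation is 0.71 — what you see here
is that correlation attenuated by per-trial estimation noise, which is
exactly what trial-level analyses of real extractions face.)

The other scripts in `examples/` each demonstrate one capability: subgroup
stratification, leave-one-out, the secondary analyses, parameter recovery
under noise, and the CSV table layout for your own extractions. The same
analyses are available from the shell via the `surromet` command
(`surromet report --seed 1`, `surromet subgroups --criterion pfs2_maturity`,
`surromet simulate --out trials.csv`, ...).

## Using a real extraction table

Analyses run on any CSV/TSV in the documented layout
(`surromet.trial_data.COLUMNS`; missing values `"NR"`). The package ships
the published 18-trial *characteristics* table (`sm.table1_fixture()`:
design flags, arm sizes, event counts, maturities) — but not the per-trial
hazard ratios, which appear only in the study's supplementary appendix. To
reproduce the published headline statistics, transcribe those HR tables into
`data/supplementary_hrs.csv` (start from
`sm.write_trials(sm.table1_fixture(), "data/supplementary_hrs.csv")` and
fill in the HR/median/crossover columns); the acceptance machinery picks the
file up automatically.

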
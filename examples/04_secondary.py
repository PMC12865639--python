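"""Secondary analyses: long-term OS, effect drift, arm-level medians, subtypes.

Long-term follow-up dilutes OS treatment effects (control patients cross over
to the experimental class after progression), so surrogacy is re-validated
against updated OS estimates, the drift of the OS effect between data cuts is
correlated with the PFS2 effect, and median PFS2/OS are compared arm by arm.
"""

import surromet as sm

trials = sm.paperlike_fixture(seed=1)

lt = sm.validation_longterm(trials, "pfs2", n_boot=2000, seed=1)
print(f"long-term validation: n={lt.n}  r={lt.r:.3f} "
      f"(95% CI {lt.r_ci_low:.3f} to {lt.r_ci_high:.3f})  R2={lt.fit.r2:.3f}")

d = sm.drift_analysis(trials)
print(f"OS-effect drift vs PFS2 effect: n={len(d.observations)}  "
      f"Spearman rho={d.rho:+.3f}  p={d.p:.3f}")
print("  (a clearly negative rho would mean trials with larger PFS2 benefit saw")
print("   their OS hazard ratio drift upward — benefit attenuating — over time)")

arms = sm.arm_observations(trials)
rho, p = sm.spearman_rho([a.median_pfs2 for a in arms], [a.median_os for a in arms])
print(f"arm-level median PFS2 vs median OS: {len(arms)} arms, "
      f"Spearman rho={rho:.3f}  p={p:.2g}")
for arm in ("intervention", "control"):
    q = sm.median_ratio_summary(arms, arm)
    print(f"  {arm}: median PFS2/OS ratio {q.central:.2f} "
          f"(range {q.min:.2f}-{q.max:.2f}); {q.n_below_half}/{q.n} trials below 0.50")

print()
for subtype in ("HRpos_HER2neg", "HER2pos", "HER2neg_mixed"):
    try:
        res = sm.subtype_subset_analysis(trials, subtype, n_boot=2000, seed=1)
        print(f"subtype {subtype}: n={res.n}  r={res.r:.3f} "
              f"(95% CI {res.r_ci_low:.3f} to {res.r_ci_high:.3f})")
    except sm.InsufficientTrialsError as exc:
        print(f"subtype {subtype}: {exc}")
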
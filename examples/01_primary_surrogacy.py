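"""Primary trial-level surrogacy analysis: PFS2 versus overall survival.

Builds a seeded 18-trial synthetic set shaped like a published breast-cancer
trial landscape (15 trials report both hazard ratios), regresses ln(HR OS) on
ln(HR PFS2) weighted by total randomized sample size, and prints the weighted
correlation with its bootstrap CI, R^2, and the two classification rules.
"""

import surromet as sm

trials = sm.paperlike_fixture(seed=1)
res = sm.run_surrogacy(trials, "pfs2", "os_initial", n_boot=2000, seed=1)

print(f"trials analyzed:        {res.n} of {len(trials)}")
print(f"weighted Pearson r:     {res.r:.3f}  (95% bootstrap CI {res.r_ci_low:.3f} to {res.r_ci_high:.3f})")
print(f"R^2:                    {res.fit.r2:.3f}")
print(f"slope (beta1):          {res.fit.slope:.3f}   p = {res.fit.slope_p:.4f}")
print(f"strength band:          {res.strength}")
print(f"IQWiG validity class:   {res.iqwig}")
print()
print("R^2 is the share of between-trial variance in the OS treatment effect")
print("explained by the PFS2 effect; >= 0.7 is the conventional surrogacy bar.")
print("The IQWiG rule needs the whole CI above 0.85 ('valid') or below 0.70")
print("('invalid'); anything straddling the thresholds is inconclusive.")
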
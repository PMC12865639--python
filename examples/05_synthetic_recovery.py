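"""Parameter recovery on synthetic trials: what estimation noise does to slopes.

Generates trial sets from a known surrogacy model (slope beta1 = 0.53) under
three noise regimes and shows that (i) with precise hazard-ratio estimates
the weighted fit recovers beta1, and (ii) with event-scaled noise the slope
attenuates toward zero by the classical errors-in-variables factor
tau^2 / (tau^2 + noise variance).
"""

import numpy as np

import surromet as sm
from surromet.surrogacy_core import wls_fit

REPS = 200
regimes = {
    "precise (N~25k, mature)": dict(
        n_range=(20000, 30000), pfs2_maturity_range=(0.95, 1.0), os_maturity_range=(0.95, 1.0)
    ),
    "default (N 100-1100)": {},
    "noisy (N 60-150, immature)": dict(n_range=(60, 150), pfs2_maturity_range=(0.15, 0.30)),
}

print(f"true slope beta1 = 0.53; {REPS} replicates of 15 trials per regime\n")
for label, kw in regimes.items():
    slopes, noise_vars = [], []
    for k in range(REPS):
        trials, truth = sm.generate_trials(sm.SyntheticConfig(seed=1 + 1000 * k, **kw))
        x = np.array([r.hr_pfs2.log_hr for r in trials])
        y = np.array([r.hr_os_initial.log_hr for r in trials])
        w = np.array([float(r.total_n) for r in trials])
        slopes.append(wls_fit(x, y, w).slope)
        noise_vars.append(np.average([t.se_pfs2**2 for t in truth.trials], weights=w))
    lam = 0.25**2 / (0.25**2 + np.mean(noise_vars))
    print(f"{label:28s} mean slope {np.mean(slopes):.3f} "
          f"(MC se {np.std(slopes, ddof=1)/np.sqrt(REPS):.3f}); "
          f"errors-in-variables prediction {0.53 * lam:.3f}")

print("\nThe prediction uses the reliability tau^2/(tau^2 + avg noise var) with")
print("the noise variance averaged under the same sample-size weights as the")
print("fit — weighting by N partially protects the slope from attenuation.")
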
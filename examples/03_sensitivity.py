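"""Leave-one-out sensitivity: is the surrogacy signal carried by one trial?

Excludes each eligible trial in turn, reruns the weighted regression on the
remainder, and summarizes the spread of r, R^2, the slope and its p-value.
A robust association keeps every iteration positive and significant.
"""

import surromet as sm

trials = sm.paperlike_fixture(seed=1)
rep = sm.leave_one_out(trials, "pfs2", "os_initial", n_boot=2000, seed=1)

for trial_id, res in rep.iterations:
    print(f"  without {trial_id}: r={res.r:.3f}  R2={res.fit.r2:.3f}  "
          f"slope={res.fit.slope:.3f}  p={res.fit.slope_p:.4f}")
print()
print(f"r ranged      {rep.r_min:.3f} to {rep.r_max:.3f}")
print(f"R^2 ranged    {rep.r2_min:.3f} to {rep.r2_max:.3f}")
print(f"slope ranged  {rep.slope_min:.3f} to {rep.slope_max:.3f}")
print(f"p ranged      {rep.p_min:.4f} to {rep.p_max:.4f}")
print(f"always positive: {rep.all_positive};  always p<{rep.alpha}: {rep.all_significant}")
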
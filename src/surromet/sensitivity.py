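"""Leave-one-out sensitivity analysis of the weighted surrogacy regression.

Each eligible trial is excluded in turn and the full weighted analysis is
rerun on the remainder; the report collects per-iteration point estimates and
the extrema of r, R^2, the slope, and the slope p-value, plus two robustness
flags (every iteration positive; every iteration significant at alpha).
Per-iteration bootstrap seeds are derived from the base seed and the
left-out trial's id, so results do not depend on iteration order.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

from .errors import InsufficientTrialsError
from .surrogacy_core import ENDPOINT_FIELDS, SurrogacyResult, run_surrogacy
from .trial_data import TrialSet, analysis_subset


def derive_seed(base_seed: int, trial_id: str) -> int:
    """Stable per-iteration seed: base plus a CRC-32 hash of the trial id, mod 2^31."""
    return (int(base_seed) + zlib.crc32(trial_id.encode("utf-8"))) % (2**31)


@dataclass(frozen=True)
class LooReport:
    """All leave-one-out iterations plus their exact extrema."""

    iterations: tuple[tuple[str, SurrogacyResult], ...]  # (left_out_trial_id, result)
    r_min: float
    r_max: float
    r2_min: float
    r2_max: float
    slope_min: float
    slope_max: float
    p_min: float
    p_max: float
    all_positive: bool
    all_significant: bool
    alpha: float = 0.05


def leave_one_out(
    trials: TrialSet,
    x_endpoint: str = "pfs2",
    y_endpoint: str = "os_initial",
    *,
    weighting: str = "total_n",
    n_boot: int = 2000,
    seed: int = 0,
    ci_level: float = 0.95,
    alpha: float = 0.05,
) -> LooReport:
    """Rerun the surrogacy analysis with each eligible trial excluded in turn."""
    fields = sorted({ENDPOINT_FIELDS[x_endpoint], ENDPOINT_FIELDS[y_endpoint]})
    eligible = analysis_subset(trials, fields, min_records=4).sorted_by_id()
    iterations: list[tuple[str, SurrogacyResult]] = []
    for trial_id in eligible.trial_ids:
        res = run_surrogacy(
            eligible.without(trial_id),
            x_endpoint,
            y_endpoint,
            weighting=weighting,
            n_boot=n_boot,
            seed=derive_seed(seed, trial_id),
            ci_level=ci_level,
        )
        iterations.append((trial_id, res))
    rs = [res.r for _, res in iterations]
    r2s = [res.fit.r2 for _, res in iterations]
    slopes = [res.fit.slope for _, res in iterations]
    ps = [res.fit.slope_p for _, res in iterations]
    return LooReport(
        iterations=tuple(iterations),
        r_min=min(rs), r_max=max(rs),
        r2_min=min(r2s), r2_max=max(r2s),
        slope_min=min(slopes), slope_max=max(slopes),
        p_min=min(ps), p_max=max(ps),
        all_positive=min(rs) > 0,
        all_significant=max(ps) < alpha,
        alpha=alpha,
    )
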
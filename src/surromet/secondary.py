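"""Secondary trial-level analyses.

Long-term OS validation, the drift of the OS treatment effect between early
and long-term data cuts against the PFS2 effect, arm-level correlation of
median PFS2 with median OS, per-arm median PFS2/OS ratio summaries, and
subtype-restricted surrogacy analyses.  Rank-based analyses use Spearman's
rho with average ranks for ties; because several of these subsets contain
fewer than ten trials, the two-sided p-value is computed by exhaustive
permutation enumeration at n <= 9 and by the usual large-sample
approximation above that.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .errors import DegenerateInputError, InsufficientTrialsError
from .surrogacy_core import SurrogacyResult, run_surrogacy
from .trial_data import TrialSet, analysis_subset

logger = logging.getLogger(__name__)

EXACT_P_MAX_N = 9  # exhaustive permutation p up to 9! = 362,880 orderings


@dataclass(frozen=True)
class ArmObservation:
    """Median PFS2 and OS (months) for one arm of one trial."""

    trial_id: str
    arm: str  # {intervention, control}
    median_pfs2: float
    median_os: float

    def __post_init__(self) -> None:
        if self.arm not in ("intervention", "control"):
            raise ValueError(f"arm must be intervention/control, got {self.arm!r}")
        for name in ("median_pfs2", "median_os"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0):
                raise ValueError(f"{self.trial_id}/{self.arm}: {name} must be positive")
        if self.ratio > 1.0:
            # PFS2 should not ordinarily exceed OS; keep the record, flag it.
            logger.warning(
                "%s/%s: median PFS2 (%.1f) exceeds median OS (%.1f)",
                self.trial_id, self.arm, self.median_pfs2, self.median_os,
            )

    @property
    def ratio(self) -> float:
        return self.median_pfs2 / self.median_os


def arm_observations(trials: TrialSet) -> list[ArmObservation]:
    """All arms with both medians reported, intervention then control per trial."""
    out: list[ArmObservation] = []
    for rec in trials:
        if rec.has("median_pfs2_int", "median_os_int"):
            out.append(ArmObservation(rec.trial_id, "intervention", rec.median_pfs2_int, rec.median_os_int))
        if rec.has("median_pfs2_ctrl", "median_os_ctrl"):
            out.append(ArmObservation(rec.trial_id, "control", rec.median_pfs2_ctrl, rec.median_os_ctrl))
    return out


@dataclass(frozen=True)
class DriftObservation:
    """One trial's PFS2 effect and its OS-effect change between data cuts."""

    trial_id: str
    log_hr_pfs2: float
    delta_log_hr_os: float  # ln HR_OS_longterm - ln HR_OS_initial


def _exact_permutation_p(rx: np.ndarray, ry: np.ndarray, rho_obs: float) -> float:
    """Two-sided p by enumerating every pairing of the y-ranks (n <= 9)."""
    n = rx.size
    perms = np.array(list(itertools.permutations(ry)), dtype=float)
    dx = rx - rx.mean()
    dp = perms - perms.mean(axis=1, keepdims=True)
    num = dp @ dx
    den = math.sqrt((dx * dx).sum()) * np.sqrt((dp * dp).sum(axis=1))
    rho_all = num / den
    return float(np.mean(np.abs(rho_all) >= abs(rho_obs) - 1e-12))


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation with a two-sided p-value.

    Average ranks for ties.  For n <= 9 the p-value is exact (all n!
    permutations of the pairing are enumerated); for larger n the standard
    t approximation from scipy is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("need equal-length 1-D sequences with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateInputError("degenerate input: a constant sequence has no ranks to correlate")
    rho = float(stats.spearmanr(x, y).statistic)
    if x.size <= EXACT_P_MAX_N:
        rx = stats.rankdata(x)
        ry = stats.rankdata(y)
        p = _exact_permutation_p(rx, ry, rho)
    else:
        p = float(stats.spearmanr(x, y).pvalue)
    return rho, p


@dataclass(frozen=True)
class MedianRatioSummary:
    """Distribution of per-trial median PFS2/OS ratios within one arm."""

    arm: str
    central: float  # median across trials
    min: float
    max: float
    n: int
    n_below_half: int  # trials with ratio strictly < 0.50


def median_ratio_summary(arms: Sequence[ArmObservation], arm: str) -> MedianRatioSummary:
    """Summarize per-trial median PFS2/OS ratios for one arm.

    The central value is the median across trials of each trial's own ratio
    (mean of the middle two for an even count); min/max give the printed-style
    range.  ``n_below_half`` counts trials whose median PFS2 fell in the
    earlier half of the OS timeline (ratio strictly below 0.50 — a tie at
    exactly 0.50 is not "earlier half").
    """
    ratios = [a.ratio for a in arms if a.arm == arm]
    if not ratios:
        raise ValueError(f"no observations for arm {arm!r}")
    return MedianRatioSummary(
        arm=arm,
        central=float(np.median(ratios)),
        min=float(min(ratios)),
        max=float(max(ratios)),
        n=len(ratios),
        n_below_half=sum(1 for q in ratios if q < 0.50),
    )


def pooled_median_ratio(arms: Sequence[ArmObservation], arm: str) -> float:
    """Alternative summary: ratio of the pooled medians (median of PFS2 medians
    over median of OS medians) — exposed for cross-checking the per-trial form."""
    sel = [a for a in arms if a.arm == arm]
    if not sel:
        raise ValueError(f"no observations for arm {arm!r}")
    return float(np.median([a.median_pfs2 for a in sel]) / np.median([a.median_os for a in sel]))


@dataclass(frozen=True)
class DriftResult:
    rho: float
    p: float
    observations: tuple[DriftObservation, ...]


def drift_analysis(trials: TrialSet) -> DriftResult:
    """Spearman correlation of the PFS2 effect with OS-effect drift over follow-up.

    Drift is ln(HR_OS long-term) - ln(HR_OS initial); a negative correlation
    with ln(HR PFS2) means trials with larger PFS2 benefit saw their OS
    hazard ratio move upward (benefit attenuate) between data cuts.  Requires
    all three hazard ratios; if every trial's long-term HR equals its initial
    HR the drift is identically zero and a degenerate "no drift" error is
    raised rather than a meaningless correlation.
    """
    eligible = analysis_subset(
        trials, ["hr_pfs2", "hr_os_initial", "hr_os_longterm"], min_records=3
    ).sorted_by_id()
    obs = tuple(
        DriftObservation(
            trial_id=r.trial_id,
            log_hr_pfs2=r.hr_pfs2.log_hr,
            delta_log_hr_os=r.hr_os_longterm.log_hr - r.hr_os_initial.log_hr,
        )
        for r in eligible
    )
    deltas = [o.delta_log_hr_os for o in obs]
    if max(deltas) == min(deltas):
        raise DegenerateInputError(
            "no drift: every trial's long-term OS hazard ratio equals its initial estimate"
        )
    rho, p = spearman_rho([o.log_hr_pfs2 for o in obs], deltas)
    return DriftResult(rho=rho, p=p, observations=obs)


def validation_longterm(
    trials: TrialSet,
    x_endpoint: str = "pfs2",
    *,
    weighting: str = "total_n",
    n_boot: int = 2000,
    seed: int = 0,
    ci_level: float = 0.95,
) -> SurrogacyResult:
    """Surrogacy of the candidate endpoint against long-term follow-up OS."""
    return run_surrogacy(
        trials, x_endpoint, "os_longterm",
        weighting=weighting, n_boot=n_boot, seed=seed, ci_level=ci_level,
    )


def subtype_subset_analysis(
    trials: TrialSet,
    subtype: str,
    *,
    x_endpoint: str = "pfs2",
    y_endpoint: str = "os_initial",
    weighting: str = "total_n",
    n_boot: int = 2000,
    seed: int = 0,
    ci_level: float = 0.95,
) -> SurrogacyResult:
    """Surrogacy analysis restricted to one breast-cancer subtype.

    Which OS estimate enters (initial by default) is configurable via
    ``y_endpoint``.  At the minimum n = 3 the analysis runs but a warning
    flags that the bootstrap CI carries essentially no precision.
    """
    subset = TrialSet(
        tuple(r for r in trials if r.subtype == subtype),
        provenance=f"{trials.provenance}|subtype={subtype}",
    )
    result = run_surrogacy(
        subset, x_endpoint, y_endpoint,
        weighting=weighting, n_boot=n_boot, seed=seed, ci_level=ci_level,
    )
    if result.n < 5:
        logger.warning(
            "subtype %s: only %d trials — correlation estimated with insufficient precision",
            subtype, result.n,
        )
    return result
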
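"""Weighted trial-level surrogacy statistics.

The primary model regresses the log hazard ratio for the true endpoint on the
log hazard ratio for the candidate surrogate across randomized trials,

    ln(HR_OS) = beta0 + beta1 * ln(HR_PFS2) + eps,

weighted by each trial's total randomized sample size.  Surrogacy strength is
summarized by the weighted coefficient of determination R^2 (conventionally
R^2 >= 0.7 indicates trial-level surrogacy) and the sample-size-weighted
Pearson correlation r with a percentile-bootstrap 95% CI.  Two categorical
rules are layered on top: correlation-strength bands (r < 0.5 poor-to-fair,
0.5 <= r <= 0.7 moderate, r > 0.7 strong) and the IQWiG validity rule on the
CI for r (lower bound >= 0.85 valid, upper bound <= 0.70 invalid, otherwise
inconclusive).

All hazard-ratio transforms use the natural logarithm; r and R^2 are
invariant to the base, the slope is not.  Weights enter as frequency-style
weights but every reported quantity is invariant to rescaling them by a
positive constant; the slope t-test always uses n - 2 degrees of freedom.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import statsmodels.api as sm

from .errors import DegenerateInputError, InsufficientTrialsError
from .trial_data import TrialSet, analysis_subset

logger = logging.getLogger(__name__)

#: maps an endpoint label to the TrialRecord field carrying its hazard ratio
ENDPOINT_FIELDS = {
    "pfs1": "hr_pfs1",
    "pfs2": "hr_pfs2",
    "os_initial": "hr_os_initial",
    "os_longterm": "hr_os_longterm",
}

STRENGTH_BANDS = ("poor_fair", "moderate", "strong")
IQWIG_CLASSES = ("valid", "inconclusive", "invalid")


@dataclass(frozen=True)
class RegressionFit:
    """A weighted least-squares fit of y on x with one predictor."""

    slope: float
    intercept: float
    slope_se: float
    slope_p: float
    r2: float
    n: int


@dataclass(frozen=True)
class BootstrapCI:
    """A percentile bootstrap confidence interval for the weighted correlation."""

    low: float
    high: float
    n_discarded: int = 0

    def __iter__(self):
        yield self.low
        yield self.high


@dataclass(frozen=True)
class SurrogacyResult:
    """One complete weighted regression/correlation surrogacy analysis."""

    fit: RegressionFit
    r: float
    r_ci_low: float
    r_ci_high: float
    strength: str
    iqwig: str
    n_bootstrap: int
    seed: int
    weights: str  # {total_n, equal, custom}
    trial_ids: tuple[str, ...] = ()
    x_endpoint: Optional[str] = None
    y_endpoint: Optional[str] = None
    n_boot_discarded: int = 0

    @property
    def n(self) -> int:
        return self.fit.n


def _as_arrays(x: Sequence[float], y: Sequence[float], w: Sequence[float]):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    w = np.asarray(w, dtype=float)
    if not (x.shape == y.shape == w.shape) or x.ndim != 1:
        raise ValueError("x, y, w must be 1-D sequences of equal length")
    if not np.all(np.isfinite(x)) or not np.all(np.isfinite(y)) or not np.all(np.isfinite(w)):
        raise ValueError("x, y, w must be finite")
    if np.any(w <= 0):
        raise ValueError("all weights must be strictly positive")
    return x, y, w


def _weighted_moments(x, y, w):
    wsum = w.sum()
    xb = (w * x).sum() / wsum
    yb = (w * y).sum() / wsum
    sxx = (w * (x - xb) ** 2).sum()
    syy = (w * (y - yb) ** 2).sum()
    sxy = (w * (x - xb) * (y - yb)).sum()
    return xb, yb, sxx, syy, sxy


def _is_degenerate(s: float, wsum: float, mean: float) -> bool:
    """Weighted variance indistinguishable from the rounding noise of centering."""
    return s / wsum <= 1e-25 * (1.0 + mean * mean)


def _snap_unit(r: float) -> float:
    """Collapse float-rounding residue at the boundary: |r| within 1e-12 of 1 is 1."""
    if 1.0 - abs(r) < 1e-12:
        return math.copysign(1.0, r)
    return r


def weighted_pearson(x: Sequence[float], y: Sequence[float], w: Sequence[float]) -> float:
    """Sample-size-weighted Pearson correlation.

    r_w = sum w_i (x_i - xbar_w)(y_i - ybar_w)
          / sqrt( sum w_i (x_i - xbar_w)^2 * sum w_i (y_i - ybar_w)^2 )

    with weighted means xbar_w = sum w_i x_i / sum w_i.  Invariant to
    rescaling all weights by a positive constant.  Raises
    :class:`DegenerateInputError` when either variable has zero weighted
    variance — a correlation is undefined there, and silently returning 0
    would masquerade as evidence of no association.
    """
    x, y, w = _as_arrays(x, y, w)
    if x.size < 2:
        raise ValueError("need at least two observations")
    xb, yb, sxx, syy, sxy = _weighted_moments(x, y, w)
    wsum = w.sum()
    if _is_degenerate(sxx, wsum, xb) or _is_degenerate(syy, wsum, yb):
        raise DegenerateInputError("degenerate input: zero weighted variance in x or y")
    r = sxy / math.sqrt(sxx * syy)
    return _snap_unit(float(min(1.0, max(-1.0, r))))


def wls_fit(x: Sequence[float], y: Sequence[float], w: Sequence[float]) -> RegressionFit:
    """Weighted least squares of y on x.

    (beta0, beta1) minimize sum w_i (y_i - beta0 - beta1 x_i)^2.  The slope
    standard error comes from the weighted normal equations with the residual
    variance estimated on n - 2 degrees of freedom; the p-value is a
    two-sided t-test on n - 2 df.  R^2 = 1 - sum w_i e_i^2 /
    sum w_i (y_i - ybar_w)^2, which coincides with the squared weighted
    Pearson correlation.  Weights are normalized to sum to n before the fit;
    every reported quantity is invariant to that normalization.
    """
    x, y, w = _as_arrays(x, y, w)
    n = x.size
    if n < 3:
        raise InsufficientTrialsError(f"insufficient trials: n = {n} < 3")
    xb, yb, sxx, syy, _ = _weighted_moments(x, y, w)
    wsum = w.sum()
    if _is_degenerate(sxx, wsum, xb):
        raise DegenerateInputError("degenerate input: zero weighted variance in x")
    if _is_degenerate(syy, wsum, yb):
        # A constant response is perfectly fitted by its weighted mean.
        return RegressionFit(
            slope=0.0, intercept=float(yb), slope_se=0.0, slope_p=1.0, r2=0.0, n=n
        )
    w_norm = w * (n / w.sum())
    design = sm.add_constant(x)
    res = sm.WLS(y, design, weights=w_norm).fit()
    r2 = float(min(1.0, max(0.0, res.rsquared)))
    return RegressionFit(
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        slope_se=float(res.bse[1]),
        slope_p=float(res.pvalues[1]),
        r2=r2,
        n=n,
    )


def _bootstrap_r_vectorized(x, y, w, idx):
    """Weighted Pearson r for each row of resampled indices ``idx`` (B, n)."""
    xb_ = x[idx]
    yb_ = y[idx]
    wb_ = w[idx]
    wsum = wb_.sum(axis=1, keepdims=True)
    xm = (wb_ * xb_).sum(axis=1, keepdims=True) / wsum
    ym = (wb_ * yb_).sum(axis=1, keepdims=True) / wsum
    dx = xb_ - xm
    dy = yb_ - ym
    sxx = (wb_ * dx * dx).sum(axis=1)
    syy = (wb_ * dy * dy).sum(axis=1)
    sxy = (wb_ * dx * dy).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = sxy / np.sqrt(sxx * syy)
    # replicates where a resample collapses onto (numerically) constant x or y
    wsum_flat = wsum[:, 0]
    ok_x = sxx / wsum_flat > 1e-25 * (1.0 + xm[:, 0] ** 2)
    ok_y = syy / wsum_flat > 1e-25 * (1.0 + ym[:, 0] ** 2)
    valid = np.isfinite(r) & ok_x & ok_y
    r = np.clip(r, -1.0, 1.0)
    # collapse float-rounding residue at the boundary, as in weighted_pearson
    r = np.where(1.0 - np.abs(r) < 1e-12, np.sign(r), r)
    return r, valid


def bootstrap_r_ci(
    x: Sequence[float],
    y: Sequence[float],
    w: Sequence[float],
    n_boot: int = 2000,
    seed: int = 0,
    level: float = 0.95,
) -> BootstrapCI:
    """Percentile bootstrap CI for the weighted Pearson correlation.

    Trials are resampled with replacement jointly as (x, y, w) triples and
    the weighted correlation recomputed per replicate.  Replicates whose
    resample has zero weighted variance (e.g. one distinct trial drawn n
    times) are discarded and counted.  Bounds are clamped to [-1, 1] and are
    deterministic for a fixed seed.  At the tiny per-stratum sample sizes of
    subgroup analyses the percentile bounds routinely reach -1 and 1.
    """
    x, y, w = _as_arrays(x, y, w)
    n = x.size
    if n < 3:
        raise InsufficientTrialsError(f"insufficient trials: n = {n} < 3")
    if not (0.0 < level < 1.0):
        raise ValueError("level must lie in (0, 1)")
    if n_boot < 200:
        logger.warning("n_boot = %d is below 200; CI will be unstable", n_boot)
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    r_rep, valid = _bootstrap_r_vectorized(x, y, w, idx)
    n_discarded = int((~valid).sum())
    if n_discarded:
        logger.info("discarded %d degenerate bootstrap replicates", n_discarded)
    r_valid = r_rep[valid]
    if r_valid.size == 0:
        raise DegenerateInputError("all bootstrap replicates were degenerate")
    alpha = (1.0 - level) / 2.0
    low, high = np.percentile(r_valid, [100 * alpha, 100 * (1 - alpha)])
    return BootstrapCI(
        low=float(max(-1.0, low)), high=float(min(1.0, high)), n_discarded=n_discarded
    )


def strength_band(r: float) -> str:
    """Correlation-strength band applied to the signed correlation.

    r < 0.5 -> "poor_fair"; 0.5 <= r <= 0.7 -> "moderate"; r > 0.7 ->
    "strong".  Both boundaries are inclusive to "moderate".  The bands were
    conceived for positive correlations; a negative r lands in "poor_fair"
    and a warning is emitted because the label understates how anomalous a
    negative surrogacy correlation is.
    """
    if not -1.0 - 1e-12 <= r <= 1.0 + 1e-12:
        raise ValueError(f"r must lie in [-1, 1], got {r}")
    if r < 0:
        logger.warning(
            "strength band applied to a NEGATIVE correlation (r = %.3f): "
            "'poor_fair' here means inverse association, not merely weak", r
        )
    if r < 0.5:
        return "poor_fair"
    if r <= 0.7:
        return "moderate"
    return "strong"


def iqwig_classify(ci_low: float, ci_high: float) -> str:
    """IQWiG surrogate-validity rule on the 95% CI for r.

    Lower bound >= 0.85 -> "valid"; upper bound <= 0.70 -> "invalid";
    anything between -> "inconclusive".
    """
    if ci_low > ci_high:
        raise ValueError(f"ci_low ({ci_low}) exceeds ci_high ({ci_high})")
    if ci_low >= 0.85:
        return "valid"
    if ci_high <= 0.70:
        return "invalid"
    return "inconclusive"


def run_surrogacy(
    trials: TrialSet,
    x_endpoint: str = "pfs2",
    y_endpoint: str = "os_initial",
    *,
    weighting: str = "total_n",
    n_boot: int = 2000,
    seed: int = 0,
    ci_level: float = 0.95,
) -> SurrogacyResult:
    """Run one full trial-level surrogacy analysis between two endpoints.

    Selects the trials reporting hazard ratios for both endpoints (at least
    3 required), takes natural logs, weights by total randomized sample size
    (or equally), and composes :func:`wls_fit`, :func:`weighted_pearson`,
    :func:`bootstrap_r_ci`, :func:`strength_band` and :func:`iqwig_classify`.
    Trials are processed in trial_id order so the bootstrap — and hence every
    reported digit — is independent of input row order.
    """
    for label in (x_endpoint, y_endpoint):
        if label not in ENDPOINT_FIELDS:
            raise ValueError(f"unknown endpoint {label!r}; expected one of {sorted(ENDPOINT_FIELDS)}")
    if weighting not in ("total_n", "equal"):
        raise ValueError(f"weighting must be 'total_n' or 'equal', got {weighting!r}")
    fields = sorted({ENDPOINT_FIELDS[x_endpoint], ENDPOINT_FIELDS[y_endpoint]})
    eligible = analysis_subset(trials, fields, min_records=3).sorted_by_id()
    x = np.array([getattr(r, ENDPOINT_FIELDS[x_endpoint]).log_hr for r in eligible])
    y = np.array([getattr(r, ENDPOINT_FIELDS[y_endpoint]).log_hr for r in eligible])
    if weighting == "total_n":
        w = np.array([float(r.total_n) for r in eligible])
    else:
        w = np.ones(len(eligible))
    fit = wls_fit(x, y, w)
    r = weighted_pearson(x, y, w)
    ci = bootstrap_r_ci(x, y, w, n_boot=n_boot, seed=seed, level=ci_level)
    return SurrogacyResult(
        fit=fit,
        r=r,
        r_ci_low=ci.low,
        r_ci_high=ci.high,
        strength=strength_band(r),
        iqwig=iqwig_classify(ci.low, ci.high),
        n_bootstrap=n_boot,
        seed=seed,
        weights=weighting,
        trial_ids=eligible.trial_ids,
        x_endpoint=x_endpoint,
        y_endpoint=y_endpoint,
        n_boot_discarded=ci.n_discarded,
    )
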
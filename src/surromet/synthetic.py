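"""Synthetic trial-set generator with known ground truth.

Emulates the statistical structure the trial-level analyses assume: a latent
linear surrogacy relation between the true log hazard ratios,

    x* ~ Normal(mu_x, tau^2)                (true ln HR for PFS2)
    y* = beta0 + beta1 * x* + Normal(0, sigma^2)   (true ln HR for OS)

plus within-trial estimation noise scaled to event counts through the
large-sample relation SE(ln HR) ~= 2 / sqrt(events), so bigger, more mature
trials yield tighter observed hazard ratios — the rationale for sample-size
weighting.  Long-term OS effects are the latent OS effect shrunk toward zero
in proportion to control-arm crossover, re-observed at long-term event
counts.  PFS1 is generated as a stronger but noisier correlate of PFS2.

Defaults mirror the observed spans of the 18 included breast-cancer trials:
total N 100-1100 per trial, OS maturity 12-60%, PFS2 maturity 25-85%, OS
information fraction 24-157% (values above 100% are real and preserved),
long-term OS available for 60% of trials, crossover 0-50% of control
patients.  beta1 = 0.53 with tau = 0.25 and sigma = 0.13 puts the latent
trial-level correlation near 0.71.

Determinism: one numpy PCG64 generator seeded from ``config.seed`` drives
everything; the same config reproduces the same trial set byte for byte.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .trial_data import HazardRatioEstimate, TrialRecord, TrialSet, line_from_prior

logger = logging.getLogger(__name__)

_Z975 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass(frozen=True)
class SyntheticConfig:
    """Ground-truth parameters for the trial-set generator (ln-HR scale)."""

    n_trials: int = 15
    beta0: float = -0.05
    beta1: float = 0.53
    tau: float = 0.25            # SD of true ln HR_PFS2 across trials
    sigma: float = 0.13          # residual SD of true ln HR_OS given ln HR_PFS2
    mu_x: float = -0.45          # mean true ln HR_PFS2 (HR ~ 0.64)
    n_range: tuple[int, int] = (100, 1100)
    os_maturity_range: tuple[float, float] = (0.12, 0.60)
    pfs2_maturity_range: tuple[float, float] = (0.25, 0.85)
    info_fraction_range: tuple[float, float] = (0.24, 1.57)
    longterm_maturity_range: tuple[float, float] = (0.45, 0.75)
    longterm_fraction: float = 0.6   # fraction of trials with long-term OS data
    crossover_range: tuple[float, float] = (0.0, 50.0)  # % of control patients
    crossover_attenuation: float = 0.5  # fraction of OS effect lost per unit crossover
    pfs1_scale: float = 1.3      # true ln HR_PFS1 = pfs1_scale * x* + noise
    pfs1_sd: float = 0.10
    unbalanced_prob: float = 0.33  # probability of 2:1 rather than 1:1 allocation
    missing_rate: float = 0.10   # MCAR deletion rate for auxiliary fields
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trials < 3:
            raise ValueError("n_trials must be >= 3")
        for name in ("tau", "sigma", "pfs1_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in (
            "n_range", "os_maturity_range", "pfs2_maturity_range",
            "info_fraction_range", "longterm_maturity_range", "crossover_range",
        ):
            lo, hi = getattr(self, name)
            if not lo <= hi:
                raise ValueError(f"{name} must be a well-ordered (low, high) pair")
        if not 0.0 <= self.crossover_attenuation <= 1.0:
            raise ValueError("crossover_attenuation must lie in [0, 1]")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")
        if not 0.0 <= self.longterm_fraction <= 1.0:
            raise ValueError("longterm_fraction must lie in [0, 1]")


@dataclass(frozen=True)
class TrialTruth:
    """Latent per-trial values behind one generated record."""

    trial_id: str
    x_true: float            # true ln HR_PFS2
    y_true: float            # true ln HR_OS
    y_longterm_true: Optional[float]
    pfs1_true: float
    se_pfs2: float
    se_os: float


@dataclass(frozen=True)
class SyntheticTruth:
    """Generator ground truth returned alongside a synthetic TrialSet."""

    config: SyntheticConfig
    trials: tuple[TrialTruth, ...]

    @property
    def latent_r(self) -> float:
        """Trial-level correlation implied by (beta1, tau, sigma)."""
        c = self.config
        denom = math.sqrt(c.beta1**2 * c.tau**2 + c.sigma**2)
        if denom == 0:
            raise ValueError("latent correlation undefined when beta1*tau and sigma are both 0")
        return c.beta1 * c.tau / denom


def _hr_estimate(log_hr: float, se: float) -> HazardRatioEstimate:
    return HazardRatioEstimate(
        hr=math.exp(log_hr),
        ci_low=math.exp(log_hr - _Z975 * se),
        ci_high=math.exp(log_hr + _Z975 * se),
    )


_SUBTYPE_PROBS = {"HRpos_HER2neg": 11 / 18, "HER2pos": 4 / 18, "HER2neg_mixed": 3 / 18}
_PRIOR_CHOICES = ("0", "1", "1 or 2", ">1")
_PRIOR_PROBS = (6 / 18, 6 / 18, 2 / 18, 4 / 18)
_DESIGNATIONS = ("primary", "secondary", "exploratory")
_DESIGNATION_PROBS = (2 / 18, 5 / 18, 11 / 18)


def generate_trials(config: SyntheticConfig) -> tuple[TrialSet, SyntheticTruth]:
    """Generate a synthetic trial set and the latent truth behind it.

    Per trial: draw total N and an allocation ratio, draw latent effects from
    the surrogacy model, draw maturities and an information fraction, convert
    them to event counts, and observe each endpoint's ln HR with independent
    Normal noise at SE = 2/sqrt(events); 95% CIs are the Wald interval
    exponentiated.  Trials whose event count lands below 5 are redrawn
    entirely (and logged) to avoid absurd noise scales.  Auxiliary fields
    (planned events, medians, crossover, PFS2 event counts) are deleted
    completely at random at ``missing_rate``; hazard ratios are always kept
    so analysis eligibility is controlled explicitly by the caller.
    """
    c = config
    rng = np.random.default_rng(c.seed)
    n_longterm = int(round(c.longterm_fraction * c.n_trials))
    longterm_idx = set(rng.choice(c.n_trials, size=n_longterm, replace=False).tolist())

    records: list[TrialRecord] = []
    truths: list[TrialTruth] = []
    for i in range(c.n_trials):
        trial_id = f"SYN-{i + 1:03d}"
        for attempt in range(100):
            total_n = int(rng.integers(c.n_range[0], c.n_range[1] + 1))
            if rng.random() < c.unbalanced_prob:
                n_int = int(round(total_n * 2 / 3))
            else:
                n_int = int(round(total_n / 2))
            n_ctrl = total_n - n_int

            x_true = float(rng.normal(c.mu_x, c.tau))
            y_true = float(c.beta0 + c.beta1 * x_true + rng.normal(0.0, c.sigma))
            pfs1_true = float(c.pfs1_scale * x_true + rng.normal(0.0, c.pfs1_sd))

            pfs2_mat = float(rng.uniform(*c.pfs2_maturity_range))
            os_mat = float(rng.uniform(*c.os_maturity_range))
            info_frac = float(rng.uniform(*c.info_fraction_range))
            pfs2_events = min(total_n, int(round(pfs2_mat * total_n)))
            os_events = min(total_n, int(round(os_mat * total_n)))
            os_planned = max(1, int(round(os_events / info_frac)))

            has_longterm = i in longterm_idx
            crossover = float(rng.uniform(*c.crossover_range)) if has_longterm else None
            if has_longterm:
                lt_mat = float(rng.uniform(*c.longterm_maturity_range))
                os_events_lt = min(total_n, max(os_events, int(round(lt_mat * total_n))))
                y_lt_true = y_true * (1.0 - c.crossover_attenuation * crossover / 100.0)
            else:
                os_events_lt = None
                y_lt_true = None

            counts = [pfs2_events, os_events] + ([os_events_lt] if has_longterm else [])
            if min(counts) < 5:
                logger.info("%s: event count below 5 on attempt %d; redrawing", trial_id, attempt + 1)
                continue
            break
        else:
            raise RuntimeError(f"{trial_id}: could not draw >= 5 events in 100 attempts")

        se_pfs2 = 2.0 / math.sqrt(pfs2_events)
        se_os = 2.0 / math.sqrt(os_events)
        hr_pfs2 = _hr_estimate(x_true + rng.normal(0.0, se_pfs2), se_pfs2)
        hr_os = _hr_estimate(y_true + rng.normal(0.0, se_os), se_os)
        hr_pfs1 = _hr_estimate(pfs1_true + rng.normal(0.0, se_pfs2), se_pfs2)
        if has_longterm:
            se_lt = 2.0 / math.sqrt(os_events_lt)
            hr_os_lt = _hr_estimate(y_lt_true + rng.normal(0.0, se_lt), se_lt)
        else:
            hr_os_lt = None

        # arm-level medians: exponential-model consistency median_int/median_ctrl = 1/HR
        m_os_ctrl = float(np.round(rng.uniform(25.0, 55.0), 1))
        m_os_int = float(np.round(m_os_ctrl * math.exp(-y_true), 1))
        ratio_int = float(rng.uniform(0.37, 0.91))
        ratio_ctrl = float(rng.uniform(0.47, 0.79))
        m_pfs2_int = float(np.round(m_os_int * ratio_int, 1))
        m_pfs2_ctrl = float(np.round(m_os_ctrl * ratio_ctrl, 1))

        prior = str(rng.choice(_PRIOR_CHOICES, p=_PRIOR_PROBS))
        subtype = str(rng.choice(list(_SUBTYPE_PROBS), p=list(_SUBTYPE_PROBS.values())))
        designation = str(rng.choice(_DESIGNATIONS, p=_DESIGNATION_PROBS))

        rec = TrialRecord(
            trial_id=trial_id,
            year=int(rng.integers(2014, 2026)),
            subtype=subtype,
            prior_lines=prior,
            pfs2_in_protocol=bool(rng.random() < 13 / 18),
            pfs2_designation=designation,
            n_intervention=n_int,
            n_control=n_ctrl,
            hr_pfs1=hr_pfs1,
            hr_pfs2=hr_pfs2,
            hr_os_initial=hr_os,
            hr_os_longterm=hr_os_lt,
            median_pfs2_int=m_pfs2_int,
            median_pfs2_ctrl=m_pfs2_ctrl,
            median_os_int=m_os_int,
            median_os_ctrl=m_os_ctrl,
            os_events=os_events,
            os_denominator=total_n,
            os_planned_events=os_planned,
            pfs2_events=pfs2_events,
            pfs2_denominator=total_n,
            os_events_longterm=os_events_lt,
            crossover_pct=crossover,
            pfs2_line=line_from_prior(prior),
            longterm_os_available=has_longterm,
        )

        # MCAR deletion of auxiliary fields, never of hazard ratios
        drops: dict[str, None] = {}
        if rng.random() < c.missing_rate:
            drops["os_planned_events"] = None
        if rng.random() < c.missing_rate:
            drops.update(
                median_pfs2_int=None, median_pfs2_ctrl=None,
                median_os_int=None, median_os_ctrl=None,
            )
        if rng.random() < c.missing_rate:
            drops.update(pfs2_events=None, pfs2_denominator=None)
        if has_longterm and rng.random() < c.missing_rate:
            drops["crossover_pct"] = None
        if drops:
            rec = replace(rec, **drops)

        records.append(rec)
        truths.append(
            TrialTruth(
                trial_id=trial_id, x_true=x_true, y_true=y_true,
                y_longterm_true=y_lt_true, pfs1_true=pfs1_true,
                se_pfs2=se_pfs2, se_os=se_os,
            )
        )

    trial_set = TrialSet(tuple(records), provenance=f"synthetic:seed={c.seed}")
    return trial_set, SyntheticTruth(config=c, trials=tuple(truths))


def paperlike_fixture(seed: int = 0) -> TrialSet:
    """An 18-trial synthetic set shaped like the published characteristics table.

    18 trials, 10 with long-term OS data, 3 with hazard ratios withheld (so
    15 enter the primary analysis), at least one OS information fraction
    above 100%, maturities and sample sizes in the published spans.  Intended
    for end-to-end demos and smoke tests; the latent truth is discarded.
    """
    cfg = SyntheticConfig(
        n_trials=18, longterm_fraction=10 / 18, missing_rate=0.0, seed=int(seed)
    )
    trials, _ = generate_trials(cfg)
    rng = np.random.default_rng(int(seed) + 1)
    records = list(trials.records)
    # withhold HRs from 3 of the trials WITHOUT long-term data, so the set keeps
    # 10 long-term trials and exactly 15 complete (PFS2, OS) pairs
    no_lt = [i for i, r in enumerate(records) if not r.longterm_os_available]
    blank_idx = set(rng.choice(no_lt, size=3, replace=False).tolist())
    for i in blank_idx:
        records[i] = replace(records[i], hr_pfs2=None, hr_pfs1=None)
    if not any(
        r.os_planned_events is not None
        and r.os_events is not None
        and r.os_events > r.os_planned_events
        for r in records
    ):
        # force one information fraction above 100%, as seen in late-reporting trials
        for i, r in enumerate(records):
            if r.os_events is not None and r.os_events >= 10:
                records[i] = replace(r, os_planned_events=int(r.os_events / 1.12))
                break
    return TrialSet(tuple(records), provenance=f"synthetic:paperlike(seed={int(seed)})")
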
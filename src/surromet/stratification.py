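"""Endpoint maturity, information fraction, and threshold-based subgroup analyses.

Maturity is observed events divided by the printed intention-to-treat
denominator; the OS information fraction is observed events divided by the
protocol-planned event count for the final analysis and may legitimately
exceed 1 (trials reporting after the planned count was surpassed print values
like 112%, 133%, 157%).  Nothing here ever clamps it.

Subgroup analyses split the eligible trials at fixed thresholds and rerun the
weighted surrogacy analysis within each stratum: PFS2 maturity at 55%, OS
information fraction at 75%, OS maturity at 40%/60%, treatment line
(second-line versus later-line PFS2), and control-arm crossover exposure at
30%/50% (against long-term OS).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

from .errors import InsufficientTrialsError
from .surrogacy_core import SurrogacyResult, run_surrogacy
from .trial_data import TrialRecord, TrialSet

logger = logging.getLogger(__name__)


def compute_maturity(events: int, denominator: int) -> float:
    """Exact events/denominator quotient (maturity or information fraction)."""
    if denominator is None or denominator < 1:
        raise ValueError(f"denominator must be >= 1, got {denominator!r}")
    if events is None or events < 0:
        raise ValueError(f"events must be >= 0, got {events!r}")
    return events / denominator


def render_percent(value: float, decimals: int = 1) -> float:
    """Render a proportion as a percentage at the printed precision.

    Uses round-half-even (the float default), which reproduces published
    mixed-precision printings such as 39/315 -> 12.4 and 171/152 -> 112.
    """
    return round(100.0 * value, decimals if decimals > 0 else None)


@dataclass(frozen=True)
class MaturityMetrics:
    """Per-trial maturity quantities; each is None when an operand is missing."""

    os_maturity: Optional[float]
    os_information_fraction: Optional[float]
    pfs2_maturity: Optional[float]
    os_maturity_longterm: Optional[float]


def maturity_metrics(record: TrialRecord) -> MaturityMetrics:
    """Compute every maturity quotient a record's event counts support."""

    def quot(events: Optional[int], den: Optional[int]) -> Optional[float]:
        if events is None or den is None:
            return None
        return compute_maturity(events, den)

    return MaturityMetrics(
        os_maturity=quot(record.os_events, record.os_denominator),
        os_information_fraction=quot(record.os_events, record.os_planned_events),
        pfs2_maturity=quot(record.pfs2_events, record.pfs2_denominator),
        os_maturity_longterm=quot(record.os_events_longterm, record.os_denominator),
    )


@dataclass(frozen=True)
class StratumResult:
    """A surrogacy analysis restricted to one stratum of a stratification criterion."""

    criterion: str
    stratum: str
    trial_ids: tuple[str, ...]
    result: Optional[SurrogacyResult]  # None when the stratum had < 3 trials
    note: Optional[str] = None


def _pct(c: float) -> str:
    return f"{c * 100:g}%"


def _single_cut_assigner(cut: float):
    """Two strata: [min, cut) and [cut, max); the boundary lands in the upper one."""

    def assign(v: float) -> Optional[int]:
        return 0 if v < cut else 1

    return assign, (f"<{_pct(cut)}", f">={_pct(cut)}")


def _bounded_band_assigner(low: float, high: float):
    """Two strata: [min, low) and [low, high]; values above ``high`` are unassigned."""

    def assign(v: float) -> Optional[int]:
        if v < low:
            return 0
        if v <= high:
            return 1
        return None

    return assign, (f"<{_pct(low)}", f"{_pct(low)}-{_pct(high)}")


def _closed_lower_band_assigner(low: float, high: float):
    """Two strata: [0, low] and (low, high]; values above ``high`` are unassigned."""

    def assign(v: float) -> Optional[int]:
        if v <= low:
            return 0
        if v <= high:
            return 1
        return None

    return assign, (f"0%-{_pct(low)}", f">{_pct(low)}-{_pct(high)}")


def _criterion_value(record: TrialRecord, criterion: str) -> Optional[float]:
    m = maturity_metrics(record)
    if criterion == "pfs2_maturity":
        return m.pfs2_maturity
    if criterion == "os_information_fraction":
        return m.os_information_fraction
    if criterion == "os_maturity":
        return m.os_maturity
    if criterion == "crossover_exposure":
        return None if record.crossover_pct is None else record.crossover_pct / 100.0
    raise ValueError(f"unsupported criterion {criterion!r}")


#: default cutpoints per criterion (fractions of 1)
DEFAULT_CUTPOINTS = {
    "pfs2_maturity": (0.55,),
    "os_information_fraction": (0.75,),
    "os_maturity": (0.40, 0.60),
    "crossover_exposure": (0.30, 0.50),
    "treatment_line": (),
}

#: which OS estimate each criterion's subgroup analysis is run against
DEFAULT_Y_ENDPOINT = {
    "pfs2_maturity": "os_initial",
    "os_information_fraction": "os_initial",
    "os_maturity": "os_initial",
    "treatment_line": "os_initial",
    "crossover_exposure": "os_longterm",  # crossover only matters at long-term follow-up
}


def stratify(
    trials: TrialSet,
    criterion: str,
    cutpoints: Optional[Sequence[float]] = None,
    *,
    x_endpoint: str = "pfs2",
    y_endpoint: Optional[str] = None,
    weighting: str = "total_n",
    n_boot: int = 2000,
    seed: int = 0,
    ci_level: float = 0.95,
) -> list[StratumResult]:
    """Split eligible trials at the criterion's thresholds and analyze each stratum.

    Strata are disjoint; each eligible trial lands in at most one.  Trials
    missing the criterion value are excluded and logged; trials whose value
    falls outside every configured band (e.g. OS maturity above 60%) are
    logged as unassigned rather than silently pooled.  Boundary values land
    in the closed-upper stratum ("<55% versus >=55%"); the crossover bands
    are [0, 30%] and (30%, 50%] with the 30% boundary in the lower band.
    A stratum with fewer than 3 trials is reported with ``result=None`` and
    an "insufficient trials" note rather than a fabricated estimate.

    Per-stratum bootstrap seeds are ``seed + stratum_index`` so a report is
    reproducible stratum by stratum.
    """
    if criterion not in DEFAULT_CUTPOINTS:
        raise ValueError(f"unsupported criterion {criterion!r}")
    cuts = tuple(cutpoints) if cutpoints is not None else DEFAULT_CUTPOINTS[criterion]
    if any(b <= a for a, b in zip(cuts, cuts[1:])):
        raise ValueError("cutpoints must be strictly increasing")
    y_endpoint = y_endpoint or DEFAULT_Y_ENDPOINT[criterion]

    if criterion == "treatment_line":
        labels = ("second_line", "later_line")
        assign_record = lambda rec: (  # noqa: E731
            None if rec.pfs2_line is None else labels.index(rec.pfs2_line)
        )
        has_value = lambda rec: rec.pfs2_line is not None  # noqa: E731
    else:
        if len(cuts) == 1:
            assign, labels = _single_cut_assigner(cuts[0])
        elif len(cuts) == 2 and criterion == "crossover_exposure":
            assign, labels = _closed_lower_band_assigner(*cuts)
        elif len(cuts) == 2:
            assign, labels = _bounded_band_assigner(*cuts)
        else:
            raise ValueError(f"{criterion}: expected 1 or 2 cutpoints, got {len(cuts)}")
        assign_record = lambda rec: (  # noqa: E731
            None
            if _criterion_value(rec, criterion) is None
            else assign(_criterion_value(rec, criterion))
        )
        has_value = lambda rec: _criterion_value(rec, criterion) is not None  # noqa: E731

    members: dict[int, list[TrialRecord]] = {i: [] for i in range(len(labels))}
    for rec in trials:
        if not has_value(rec):
            logger.info("%s: %s excluded (criterion value missing)", criterion, rec.trial_id)
            continue
        k = assign_record(rec)
        if k is None:
            logger.info("%s: %s unassigned (value outside configured bands)", criterion, rec.trial_id)
            continue
        members[k].append(rec)

    out: list[StratumResult] = []
    for i, label in enumerate(labels):
        subset = TrialSet(tuple(members[i]), provenance=f"{trials.provenance}|{criterion}={label}")
        ids = subset.trial_ids
        try:
            res = run_surrogacy(
                subset,
                x_endpoint,
                y_endpoint,
                weighting=weighting,
                n_boot=n_boot,
                seed=seed + i,
                ci_level=ci_level,
            )
            out.append(StratumResult(criterion, label, res.trial_ids, res))
        except InsufficientTrialsError as exc:
            out.append(StratumResult(criterion, label, ids, None, note=str(exc)))
    return out
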
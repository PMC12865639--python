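"""Trial-level data model and delimited-table I/O.

One :class:`TrialRecord` holds everything extracted from a single randomized
controlled trial's publication: per-arm sample sizes, hazard ratios (HRs)
with 95% confidence intervals for PFS1 / PFS2 / OS (at initial reporting and,
where available, long-term follow-up), per-arm median PFS2 and OS in months,
event counts with their printed denominators, planned OS event counts,
control-arm crossover exposure, and design flags.

Missing values are explicit (``None`` in memory, a configurable token —
default ``"NR"``, "not reported" — on disk) and are never imputed.  Event
denominators are stored verbatim per column even when a publication prints
internally inconsistent numbers (e.g. an OS-maturity denominator that differs
from the sum of the arm sizes); the printed fraction is authoritative.
"""

from __future__ import annotations

import io
import logging
import math
from dataclasses import dataclass, fields as dc_fields, replace
from pathlib import Path
from typing import Iterator, Optional, Sequence, Union

import pandas as pd

from .errors import InsufficientTrialsError, TrialDataError

logger = logging.getLogger(__name__)

MISSING_TOKEN = "NR"

SUBTYPES = ("HRpos_HER2neg", "HER2pos", "HER2neg_mixed")
DESIGNATIONS = ("primary", "secondary", "exploratory")
PFS2_LINES = ("second_line", "later_line")


@dataclass(frozen=True)
class HazardRatioEstimate:
    """A point hazard ratio with its 95% confidence interval.

    All three values must be strictly positive so the natural-log transform
    used throughout the trial-level analyses is defined.
    """

    hr: float
    ci_low: float
    ci_high: float

    def __post_init__(self) -> None:
        for name in ("hr", "ci_low", "ci_high"):
            v = getattr(self, name)
            if not (isinstance(v, (int, float)) and math.isfinite(v) and v > 0):
                raise TrialDataError(f"{name} must be a positive finite number, got {v!r}")
        if not (self.ci_low <= self.hr <= self.ci_high):
            raise TrialDataError(
                f"require ci_low <= hr <= ci_high, got ({self.ci_low}, {self.hr}, {self.ci_high})"
            )

    @property
    def log_hr(self) -> float:
        """Natural log of the point estimate."""
        return math.log(self.hr)

    def reciprocal(self) -> "HazardRatioEstimate":
        """The same estimate with the comparison direction flipped (HR -> 1/HR)."""
        return HazardRatioEstimate(1.0 / self.hr, 1.0 / self.ci_high, 1.0 / self.ci_low)


@dataclass(frozen=True)
class TrialRecord:
    """Trial-level quantities extracted from one randomized controlled trial.

    Any optional field may be ``None`` (missing).  ``os_information_fraction``
    (events / planned events) may legitimately exceed 1 when the analysis
    occurred after the protocol-planned event count was surpassed; nothing
    here clamps it.
    """

    trial_id: str
    year: int
    subtype: str  # one of SUBTYPES
    n_intervention: int
    n_control: int
    prior_lines: Optional[str] = None  # free text, e.g. "0", "1 or 2", ">1"
    pfs2_in_protocol: Optional[bool] = None
    pfs2_designation: Optional[str] = None  # one of DESIGNATIONS
    hr_pfs1: Optional[HazardRatioEstimate] = None
    hr_pfs2: Optional[HazardRatioEstimate] = None
    hr_os_initial: Optional[HazardRatioEstimate] = None
    hr_os_longterm: Optional[HazardRatioEstimate] = None
    median_pfs2_int: Optional[float] = None  # months
    median_pfs2_ctrl: Optional[float] = None
    median_os_int: Optional[float] = None
    median_os_ctrl: Optional[float] = None
    os_events: Optional[int] = None
    os_denominator: Optional[int] = None  # printed OS-maturity denominator
    os_planned_events: Optional[int] = None
    pfs2_events: Optional[int] = None
    pfs2_denominator: Optional[int] = None
    os_events_longterm: Optional[int] = None
    crossover_pct: Optional[float] = None  # % of control patients, 0-100 scale
    pfs2_line: Optional[str] = None  # one of PFS2_LINES
    longterm_os_available: Optional[bool] = None

    def __post_init__(self) -> None:
        if not self.trial_id:
            raise TrialDataError("trial_id must be non-empty")
        for name in ("n_intervention", "n_control"):
            v = getattr(self, name)
            if not (isinstance(v, int) and v >= 1):
                raise TrialDataError(f"{self.trial_id}: {name} must be an integer >= 1, got {v!r}")
        if self.subtype not in SUBTYPES:
            raise TrialDataError(f"{self.trial_id}: unknown subtype {self.subtype!r}")
        if self.pfs2_designation is not None and self.pfs2_designation not in DESIGNATIONS:
            raise TrialDataError(
                f"{self.trial_id}: unknown pfs2_designation {self.pfs2_designation!r}"
            )
        if self.pfs2_line is not None and self.pfs2_line not in PFS2_LINES:
            raise TrialDataError(f"{self.trial_id}: unknown pfs2_line {self.pfs2_line!r}")
        for name in (
            "median_pfs2_int", "median_pfs2_ctrl", "median_os_int", "median_os_ctrl",
        ):
            v = getattr(self, name)
            if v is not None and not v > 0:
                raise TrialDataError(f"{self.trial_id}: {name} must be positive, got {v!r}")
        for name in (
            "os_events", "os_denominator", "os_planned_events",
            "pfs2_events", "pfs2_denominator", "os_events_longterm",
        ):
            v = getattr(self, name)
            if v is not None and not (isinstance(v, int) and v >= 0):
                raise TrialDataError(
                    f"{self.trial_id}: {name} must be a non-negative integer, got {v!r}"
                )
        if self.crossover_pct is not None and not (0.0 <= self.crossover_pct <= 100.0):
            raise TrialDataError(
                f"{self.trial_id}: crossover_pct must lie in [0, 100], got {self.crossover_pct!r}"
            )
        if (
            self.os_events is not None
            and self.os_denominator is not None
            and self.os_events > self.os_denominator
        ):
            raise TrialDataError(
                f"{self.trial_id}: os_events ({self.os_events}) exceeds the printed "
                f"maturity denominator ({self.os_denominator})"
            )

    @property
    def total_n(self) -> int:
        """Total randomized patients; the weighting variable of every analysis."""
        return self.n_intervention + self.n_control

    def has(self, *field_names: str) -> bool:
        """True when every named optional field is present (not None)."""
        return all(getattr(self, name) is not None for name in field_names)


@dataclass(frozen=True)
class TrialSet:
    """An ordered collection of unique trials plus a provenance tag."""

    records: tuple[TrialRecord, ...]
    provenance: str = "unspecified"

    def __post_init__(self) -> None:
        ids = [r.trial_id for r in self.records]
        dupes = {t for t in ids if ids.count(t) > 1}
        if dupes:
            raise TrialDataError(f"duplicate trial_id values: {sorted(dupes)}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[TrialRecord]:
        return iter(self.records)

    def __getitem__(self, trial_id: str) -> TrialRecord:
        for r in self.records:
            if r.trial_id == trial_id:
                return r
        raise KeyError(trial_id)

    @property
    def trial_ids(self) -> tuple[str, ...]:
        return tuple(r.trial_id for r in self.records)

    def sorted_by_id(self) -> "TrialSet":
        """A copy ordered by trial_id; analyses use this so results are order-free."""
        return TrialSet(tuple(sorted(self.records, key=lambda r: r.trial_id)), self.provenance)

    def without(self, trial_id: str) -> "TrialSet":
        if trial_id not in self.trial_ids:
            raise KeyError(trial_id)
        return TrialSet(
            tuple(r for r in self.records if r.trial_id != trial_id), self.provenance
        )


# ---------------------------------------------------------------------------
# Delimited-table I/O
# ---------------------------------------------------------------------------

_HR_FIELDS = ("hr_pfs1", "hr_pfs2", "hr_os_initial", "hr_os_longterm")
_BOOL_FIELDS = ("pfs2_in_protocol", "longterm_os_available")
_INT_FIELDS = (
    "year", "n_intervention", "n_control", "os_events", "os_denominator",
    "os_planned_events", "pfs2_events", "pfs2_denominator", "os_events_longterm",
)
_FLOAT_FIELDS = (
    "median_pfs2_int", "median_pfs2_ctrl", "median_os_int", "median_os_ctrl",
    "crossover_pct",
)
_TEXT_FIELDS = ("trial_id", "subtype", "prior_lines", "pfs2_designation", "pfs2_line")

COLUMNS: tuple[str, ...] = (
    "trial_id", "year", "subtype", "prior_lines", "pfs2_in_protocol",
    "pfs2_designation", "n_intervention", "n_control",
    "pfs1_hr", "pfs1_ci_low", "pfs1_ci_high",
    "pfs2_hr", "pfs2_ci_low", "pfs2_ci_high",
    "os_hr", "os_ci_low", "os_ci_high",
    "os_lt_hr", "os_lt_ci_low", "os_lt_ci_high",
    "median_pfs2_int", "median_pfs2_ctrl", "median_os_int", "median_os_ctrl",
    "os_events", "os_denominator", "os_planned_events",
    "pfs2_events", "pfs2_denominator", "os_events_longterm",
    "crossover_pct", "pfs2_line", "longterm_os_available",
)

_HR_PREFIX = {"hr_pfs1": "pfs1", "hr_pfs2": "pfs2", "hr_os_initial": "os", "hr_os_longterm": "os_lt"}


def _parse_cell(raw: object, missing_token: str) -> Optional[str]:
    s = str(raw).strip()
    if s == "" or s == missing_token:
        return None
    return s


def _parse_bool(s: str) -> bool:
    low = s.lower()
    if low in ("yes", "true", "1"):
        return True
    if low in ("no", "false", "0"):
        return False
    raise ValueError(f"cannot interpret {s!r} as yes/no")


def _record_from_row(row: "pd.Series", missing_token: str) -> TrialRecord:
    kw: dict = {}
    get = lambda col: _parse_cell(row.get(col, ""), missing_token)  # noqa: E731
    for name in _TEXT_FIELDS:
        kw[name] = get(name)
    for name in _INT_FIELDS:
        s = get(name)
        kw[name] = int(float(s)) if s is not None else None
    for name in _FLOAT_FIELDS:
        s = get(name)
        kw[name] = float(s) if s is not None else None
    for name in _BOOL_FIELDS:
        s = get(name)
        kw[name] = _parse_bool(s) if s is not None else None
    for field_name, prefix in _HR_PREFIX.items():
        parts = [get(f"{prefix}_hr"), get(f"{prefix}_ci_low"), get(f"{prefix}_ci_high")]
        if all(p is not None for p in parts):
            kw[field_name] = HazardRatioEstimate(*(float(p) for p in parts))
        elif any(p is not None for p in parts):
            raise TrialDataError(
                f"{kw.get('trial_id')}: hazard ratio {prefix!r} given without its full 95% CI"
            )
        else:
            kw[field_name] = None
    if kw["trial_id"] is None:
        raise TrialDataError("trial_id missing")
    if kw["year"] is None or kw["n_intervention"] is None or kw["n_control"] is None:
        raise TrialDataError(f"{kw['trial_id']}: year and per-arm sample sizes are required")
    return TrialRecord(**kw)


def read_trials(
    path: Union[str, Path, io.TextIOBase],
    *,
    delimiter: Optional[str] = None,
    missing_token: str = MISSING_TOKEN,
    strict: bool = True,
) -> TrialSet:
    """Read a delimited trial-level extraction table into a :class:`TrialSet`.

    Parameters
    ----------
    path
        CSV/TSV file (or open text handle) with a header row using the
        documented :data:`COLUMNS` names.  Unknown columns are ignored.
    delimiter
        ``","`` or ``"\\t"``; inferred from the file suffix when ``None``
        (``.tsv`` / ``.tab`` means tab, anything else comma).
    missing_token
        The cell content denoting a missing value (default ``"NR"``).
    strict
        When True (default) any invalid row aborts the read with a
        row-addressed :class:`~surromet.errors.TrialDataError`; when False
        invalid rows are dropped with a warning.
    """
    if delimiter is None:
        suffix = Path(str(path)).suffix.lower() if not isinstance(path, io.TextIOBase) else ""
        delimiter = "\t" if suffix in (".tsv", ".tab") else ","
    frame = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
    records: list[TrialRecord] = []
    problems: list[str] = []
    for i, (_, row) in enumerate(frame.iterrows()):
        try:
            records.append(_record_from_row(row, missing_token))
        except (TrialDataError, ValueError) as exc:
            problems.append(f"row {i + 2}: {exc}")  # +2: header line plus 1-basing
    if problems:
        if strict:
            raise TrialDataError("invalid rows:\n  " + "\n  ".join(problems))
        for msg in problems:
            logger.warning("dropping %s", msg)
    if not records:
        logger.warning("no data rows read from %s", path)
    provenance = str(path) if not isinstance(path, io.TextIOBase) else "<stream>"
    return TrialSet(tuple(records), provenance=provenance)


def write_trials(
    trials: TrialSet,
    path: Union[str, Path, io.TextIOBase],
    *,
    delimiter: str = ",",
    missing_token: str = MISSING_TOKEN,
) -> None:
    """Write a :class:`TrialSet` back to a delimited table (inverse of :func:`read_trials`)."""

    def fmt(v: object) -> str:
        if v is None:
            return missing_token
        if isinstance(v, bool):
            return "yes" if v else "no"
        if isinstance(v, float):
            return repr(v)
        return str(v)

    rows = []
    for r in trials:
        row: dict[str, str] = {}
        for name in _TEXT_FIELDS + _INT_FIELDS + _FLOAT_FIELDS + _BOOL_FIELDS:
            row[name] = fmt(getattr(r, name))
        for field_name, prefix in _HR_PREFIX.items():
            est = getattr(r, field_name)
            row[f"{prefix}_hr"] = fmt(est.hr if est else None)
            row[f"{prefix}_ci_low"] = fmt(est.ci_low if est else None)
            row[f"{prefix}_ci_high"] = fmt(est.ci_high if est else None)
        rows.append(row)
    frame = pd.DataFrame(rows, columns=list(COLUMNS))
    frame.to_csv(path, sep=delimiter, index=False)


def analysis_subset(
    trials: TrialSet,
    required_fields: Sequence[str],
    *,
    min_records: Optional[int] = None,
) -> TrialSet:
    """Restrict a trial set to records where every required field is present.

    Implements per-analysis eligibility: each analysis runs on the trials that
    actually report the quantities it needs.  Excluded trials are logged with
    the fields they lack.  When ``min_records`` is given (regression callers
    pass 3) and fewer records survive, raises
    :class:`~surromet.errors.InsufficientTrialsError`.
    """
    valid_names = {f.name for f in dc_fields(TrialRecord)}
    unknown = [f for f in required_fields if f not in valid_names]
    if unknown:
        raise TrialDataError(f"unknown field names: {unknown}")
    kept, dropped = [], []
    for r in trials:
        missing = [f for f in required_fields if getattr(r, f) is None]
        if missing:
            dropped.append((r.trial_id, missing))
        else:
            kept.append(r)
    for trial_id, missing in dropped:
        logger.info("excluding %s: missing %s", trial_id, ", ".join(missing))
    if min_records is not None and len(kept) < min_records:
        raise InsufficientTrialsError(
            f"insufficient trials: {len(kept)} available, {min_records} required "
            f"(excluded: {[t for t, _ in dropped]})"
        )
    return TrialSet(tuple(kept), provenance=trials.provenance)


def line_from_prior(prior_lines: Optional[str]) -> Optional[str]:
    """Map prior-lines-at-entry text to the treatment line PFS2 reflects.

    Patients untreated in the advanced setting ("0" prior lines) progress onto
    second-line therapy, so their PFS2 captures second-line progression; any
    prior systemic therapy pushes PFS2 to third line or later.
    """
    if prior_lines is None:
        return None
    return "second_line" if prior_lines.strip() == "0" else "later_line"


# ---------------------------------------------------------------------------
# Built-in fixture: the 18 included trials' design/maturity table
# ---------------------------------------------------------------------------
# Per-trial characteristics as printed (trial, year, subtype, prior lines,
# PFS2-in-protocol, designation, arm sizes, OS events/denominator, planned OS
# events, PFS2 events/denominator, long-term OS availability).  Hazard ratios
# and medians live in a separate extraction table and are merged via
# read_trials when available.  Printed denominators are kept verbatim even
# where internally inconsistent with arm sums.
_TABLE1_ROWS: tuple[tuple, ...] = (
    # id, year, subtype, prior, protocol, designation, n_int, n_ctrl,
    #   os_ev, os_den, os_planned, pfs2_ev, pfs2_den, longterm
    ("SERENA-6", 2025, "HRpos_HER2neg", "1", True, "secondary", 157, 158, 39, 315, 165, 85, 315, False),
    ("DESTINY-Breast09", 2025, "HER2pos", "0", None, None, 383, 387, 126, 770, None, 193, 770, False),
    ("TROPION-Breast01", 2025, "HRpos_HER2neg", "1 or 2", True, "secondary", 365, 367, 171, 732, 444, 238, 732, False),
    ("SONIA", 2024, "HRpos_HER2neg", "0", True, "primary", 524, 526, 372, 1050, None, 591, 1050, False),
    ("INAVO120", 2024, "HRpos_HER2neg", "0", True, "exploratory", 161, 164, 97, 325, 153, None, None, True),
    ("CAPItello-291", 2023, "HRpos_HER2neg", "1 or 2", True, "secondary", 355, 353, 195, 708, 492, 383, 708, False),
    ("DESTINY-Breast03", 2023, "HER2pos", ">1", True, "exploratory", 261, 263, 169, 524, 250, None, None, True),
    ("DESTINY-Breast02", 2023, "HER2pos", ">1", True, "exploratory", 406, 202, 230, 608, 434, None, None, False),
    ("Pearl", 2022, "HRpos_HER2neg", "1", False, "exploratory", 149, 299, 171, 300, 152, 230, 305, False),
    ("MONALEESA-3", 2021, "HRpos_HER2neg", "0", True, "exploratory", 237, 128, 364, 726, 273, 428, 726, True),
    ("MONARCH-3", 2021, "HRpos_HER2neg", "0", False, "exploratory", 328, 165, None, None, None, None, None, True),
    ("MONARCH-2", 2020, "HRpos_HER2neg", "1", False, "exploratory", 446, 223, 338, 669, 441, 457, 669, False),
    ("BROCAD3", 2020, "HER2neg_mixed", "2", False, "secondary", 337, 172, 254, 509, 357, 310, 509, True),
    ("MONALEESA-7", 2019, "HRpos_HER2neg", "1", False, "exploratory", 335, 337, 192, 672, 252, 287, 672, True),
    ("PALOMA-3", 2018, "HRpos_HER2neg", ">1", False, "exploratory", 347, 174, 310, 521, 198, None, None, True),
    ("OlympiAD", 2017, "HER2neg_mixed", "1", True, "secondary", 205, 97, 140, 302, 190, None, None, True),
    ("TANIA", 2014, "HER2neg_mixed", "0", True, "primary", 247, 247, 200, 494, None, 407, 494, True),
    ("VITAL", 2014, "HER2pos", "1", False, "exploratory", 75, 37, 35, 112, None, None, None, True),
)


def table1_fixture() -> TrialSet:
    """The built-in characteristics table for the 18 included trials.

    Hazard-ratio fields are left missing here: they come from the separately
    published per-trial effect-estimate tables and are loaded, when a
    transcription is available, through :func:`read_trials`.
    """
    records = tuple(
        TrialRecord(
            trial_id=row[0], year=row[1], subtype=row[2], prior_lines=row[3],
            pfs2_in_protocol=row[4], pfs2_designation=row[5],
            n_intervention=row[6], n_control=row[7],
            os_events=row[8], os_denominator=row[9], os_planned_events=row[10],
            pfs2_events=row[11], pfs2_denominator=row[12],
            longterm_os_available=row[13],
            pfs2_line=line_from_prior(row[3]),
        )
        for row in _TABLE1_ROWS
    )
    return TrialSet(records, provenance="fixture:table1")
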
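"""Full analysis sequence and report rendering.

:func:`run_full_analysis` executes every analysis in the canonical order —
primary surrogacy, long-term validation, the five threshold subgroup
analyses, OS-effect drift, arm-level medians, leave-one-out sensitivity,
subtype subsets, and the PFS1 comparison — each on its own eligibility
subset, and returns one nested, JSON-serializable report.  An analysis whose
preconditions fail (too few trials, degenerate inputs, missing fields) is
reported as skipped with the reason, never silently omitted.

The report is a pure function of (trial set, config): repeated runs at the
same seed produce byte-identical JSON.  Machine-readable output keeps full
float precision; the plain-text rendering rounds r and R^2 to 3 decimals and
percentages to 1, the conventional printing precision.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from typing import Optional

from .errors import DegenerateInputError, InsufficientTrialsError, TrialDataError
from .secondary import (
    arm_observations,
    drift_analysis,
    median_ratio_summary,
    spearman_rho,
    subtype_subset_analysis,
    validation_longterm,
)
from .sensitivity import leave_one_out
from .stratification import StratumResult, stratify
from .surrogacy_core import SurrogacyResult, run_surrogacy
from .trial_data import TrialSet

logger = logging.getLogger(__name__)

#: analysis sections in canonical order
SECTIONS = (
    "primary",
    "validation_longterm",
    "pfs2_maturity",
    "os_information_fraction",
    "os_maturity",
    "treatment_line",
    "crossover_exposure",
    "drift",
    "arm_medians",
    "leave_one_out",
    "subtypes",
    "pfs1",
)


@dataclass(frozen=True)
class AnalysisConfig:
    """Configuration for one full analysis run."""

    seed: int = 0
    n_boot: int = 2000
    ci_level: float = 0.95
    weighting: str = "total_n"
    pfs2_maturity_cut: float = 0.55
    os_info_fraction_cut: float = 0.75
    os_maturity_band: tuple[float, float] = (0.40, 0.60)
    crossover_band: tuple[float, float] = (0.30, 0.50)
    subtype_y_endpoint: str = "os_initial"
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not (0.0 < self.ci_level < 1.0):
            raise ValueError("ci_level must lie in (0, 1)")
        if self.n_boot < 200:
            raise ValueError("n_boot must be >= 200")
        for name in ("pfs2_maturity_cut", "os_info_fraction_cut"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def surrogacy_to_dict(res: SurrogacyResult) -> dict:
    """Flatten one surrogacy analysis into plain JSON-friendly types."""
    return {
        "n": res.n,
        "r": res.r,
        "r_ci_low": res.r_ci_low,
        "r_ci_high": res.r_ci_high,
        "r2": res.fit.r2,
        "slope": res.fit.slope,
        "intercept": res.fit.intercept,
        "slope_se": res.fit.slope_se,
        "slope_p": res.fit.slope_p,
        "strength": res.strength,
        "iqwig": res.iqwig,
        "weights": res.weights,
        "n_bootstrap": res.n_bootstrap,
        "n_boot_discarded": res.n_boot_discarded,
        "seed": res.seed,
        "x_endpoint": res.x_endpoint,
        "y_endpoint": res.y_endpoint,
        "trial_ids": list(res.trial_ids),
    }


def _stratum_to_dict(s: StratumResult) -> dict:
    d: dict = {"criterion": s.criterion, "stratum": s.stratum, "trial_ids": list(s.trial_ids)}
    if s.result is None:
        d["skipped"] = s.note or "insufficient trials"
    else:
        d["result"] = surrogacy_to_dict(s.result)
    return d


def _skipped(reason: str) -> dict:
    logger.info("section skipped: %s", reason)
    return {"skipped": reason}


def run_full_analysis(trials: TrialSet, config: Optional[AnalysisConfig] = None) -> dict:
    """Run the complete analysis sequence on one trial set.

    Returns a dict with one entry per section of :data:`SECTIONS` plus an
    ``inputs`` header recording provenance, trial count, and configuration.
    """
    cfg = config or AnalysisConfig()
    kw = dict(weighting=cfg.weighting, n_boot=cfg.n_boot, seed=cfg.seed, ci_level=cfg.ci_level)
    report: dict = {
        "inputs": {
            "provenance": trials.provenance,
            "n_trials": len(trials),
            "config": dataclasses.asdict(cfg),
        }
    }

    def attempt(section: str, thunk) -> None:
        try:
            report[section] = thunk()
        except (InsufficientTrialsError, DegenerateInputError, TrialDataError) as exc:
            report[section] = _skipped(str(exc))

    attempt("primary", lambda: surrogacy_to_dict(run_surrogacy(trials, "pfs2", "os_initial", **kw)))
    attempt(
        "validation_longterm",
        lambda: surrogacy_to_dict(validation_longterm(trials, "pfs2", **kw)),
    )
    for criterion, cuts in (
        ("pfs2_maturity", (cfg.pfs2_maturity_cut,)),
        ("os_information_fraction", (cfg.os_info_fraction_cut,)),
        ("os_maturity", cfg.os_maturity_band),
        ("treatment_line", ()),
        ("crossover_exposure", cfg.crossover_band),
    ):
        attempt(
            criterion,
            lambda criterion=criterion, cuts=cuts: [
                _stratum_to_dict(s)
                for s in stratify(trials, criterion, cuts or None, **kw)
            ],
        )

    def _drift() -> dict:
        d = drift_analysis(trials)
        return {
            "rho": d.rho,
            "p": d.p,
            "n": len(d.observations),
            "observations": [dataclasses.asdict(o) for o in d.observations],
        }

    attempt("drift", _drift)

    def _arm_medians() -> dict:
        arms = arm_observations(trials)
        if len(arms) < 3:
            raise InsufficientTrialsError(
                f"insufficient trials: only {len(arms)} arms report both medians"
            )
        rho, p = spearman_rho([a.median_pfs2 for a in arms], [a.median_os for a in arms])
        out = {"n_arms": len(arms), "spearman_rho": rho, "spearman_p": p}
        for arm in ("intervention", "control"):
            try:
                out[f"{arm}_ratio"] = dataclasses.asdict(median_ratio_summary(arms, arm))
            except ValueError as exc:
                out[f"{arm}_ratio"] = _skipped(str(exc))
        return out

    attempt("arm_medians", _arm_medians)

    def _loo() -> dict:
        rep = leave_one_out(trials, "pfs2", "os_initial", alpha=cfg.alpha, **kw)
        return {
            "n_iterations": len(rep.iterations),
            "r_min": rep.r_min, "r_max": rep.r_max,
            "r2_min": rep.r2_min, "r2_max": rep.r2_max,
            "slope_min": rep.slope_min, "slope_max": rep.slope_max,
            "p_min": rep.p_min, "p_max": rep.p_max,
            "all_positive": rep.all_positive,
            "all_significant": rep.all_significant,
            "alpha": rep.alpha,
            "iterations": [
                {"left_out": tid, **surrogacy_to_dict(res)} for tid, res in rep.iterations
            ],
        }

    attempt("leave_one_out", _loo)

    def _subtypes() -> dict:
        out: dict = {}
        for subtype in ("HRpos_HER2neg", "HER2pos", "HER2neg_mixed"):
            try:
                res = subtype_subset_analysis(
                    trials, subtype, y_endpoint=cfg.subtype_y_endpoint, **kw
                )
                out[subtype] = surrogacy_to_dict(res)
            except (InsufficientTrialsError, DegenerateInputError) as exc:
                out[subtype] = _skipped(str(exc))
        return out

    attempt("subtypes", _subtypes)
    attempt("pfs1", lambda: surrogacy_to_dict(run_surrogacy(trials, "pfs1", "os_initial", **kw)))
    return report


def report_to_json(report: dict) -> str:
    """Deterministic JSON serialization (sorted keys, full precision)."""
    return json.dumps(report, indent=2, sort_keys=True, allow_nan=False)


def _fmt(v: object, nd: int = 3) -> str:
    if v is None:
        return "NA"
    if isinstance(v, bool):
        return "yes" if v else "no"
    if isinstance(v, float):
        return f"{v:.{nd}g}" if abs(v) < 1e-3 and v != 0 else f"{round(v, nd):g}"
    return str(v)


def _surrogacy_line(d: dict) -> str:
    return (
        f"n={d['n']}  r={_fmt(d['r'])} (95% CI {_fmt(d['r_ci_low'])} to {_fmt(d['r_ci_high'])})  "
        f"R2={_fmt(d['r2'])}  slope={_fmt(d['slope'])}  p={_fmt(d['slope_p'])}  "
        f"[{d['strength']}, IQWiG {d['iqwig']}]"
    )


def render_text(report: dict) -> str:
    """Aligned plain-text rendering of a full report (3-decimal display)."""
    lines: list[str] = []
    inputs = report.get("inputs", {})
    lines.append("Trial-level surrogacy report")
    lines.append(f"input: {inputs.get('provenance')}  trials: {inputs.get('n_trials')}")
    lines.append("")
    for section in SECTIONS:
        if section not in report:
            continue
        body = report[section]
        title = section.replace("_", " ")
        lines.append(f"== {title} ==")
        if isinstance(body, dict) and "skipped" in body:
            lines.append(f"  skipped: {body['skipped']}")
        elif section in ("primary", "validation_longterm", "pfs1"):
            lines.append("  " + _surrogacy_line(body))
        elif isinstance(body, list):  # stratified sections
            for s in body:
                if "skipped" in s:
                    lines.append(f"  {s['stratum']:>12}: skipped ({s['skipped']})")
                else:
                    lines.append(f"  {s['stratum']:>12}: " + _surrogacy_line(s["result"]))
        elif section == "drift":
            lines.append(
                f"  n={body['n']}  Spearman rho={_fmt(body['rho'])}  p={_fmt(body['p'])}"
            )
        elif section == "arm_medians":
            lines.append(
                f"  n_arms={body['n_arms']}  Spearman rho={_fmt(body['spearman_rho'])}  "
                f"p={_fmt(body['spearman_p'])}"
            )
            for arm in ("intervention", "control"):
                q = body.get(f"{arm}_ratio")
                if isinstance(q, dict) and "skipped" not in q:
                    lines.append(
                        f"  {arm} PFS2/OS ratio: median {_fmt(q['central'], 2)} "
                        f"(range {_fmt(q['min'], 2)}-{_fmt(q['max'], 2)}; "
                        f"{q['n_below_half']}/{q['n']} below 0.50)"
                    )
        elif section == "leave_one_out":
            lines.append(
                f"  iterations={body['n_iterations']}  "
                f"r: {_fmt(body['r_min'])}-{_fmt(body['r_max'])}  "
                f"R2: {_fmt(body['r2_min'])}-{_fmt(body['r2_max'])}  "
                f"slope: {_fmt(body['slope_min'])}-{_fmt(body['slope_max'])}  "
                f"p: {_fmt(body['p_min'], 4)}-{_fmt(body['p_max'], 4)}"
            )
            lines.append(
                f"  all positive: {_fmt(body['all_positive'])}  "
                f"all p<{body['alpha']}: {_fmt(body['all_significant'])}"
            )
        elif section == "subtypes":
            for subtype, d in body.items():
                if "skipped" in d:
                    lines.append(f"  {subtype:>14}: skipped ({d['skipped']})")
                else:
                    lines.append(f"  {subtype:>14}: " + _surrogacy_line(d))
        lines.append("")
    return "\n".join(lines)
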
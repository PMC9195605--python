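"""Assembly of the multistage risk-based QC plan.

The plan has two tiers for every analyte on the instrument:

* a **start-up** SQC procedure, run each morning before patient results are
  released — one panel-wide multirule whose bracketed run size covers every
  analyte's daily volume; and
* a **monitor** procedure closing the daily reporting interval — either a
  cheap single-measurement SQC rule, or, where the analyte's quality and its
  moving-average (MA) procedure allow it, the MA surveillance alone.

Analytes are categorized by average patient-risk sigma (high >= 5.0,
moderate 4.5-5.0, low 3.5-4.5, below 3.5 unacceptable).  The MA procedure
replaces the monitor SQC rule when it reliably catches a TEa-sized bias
within one day's tests: for high-sigma analytes the *median* detection delay
in both bias directions must fit in the daily volume; for moderate-sigma
analytes the stricter *maximum* delay must fit (a moderate assay leaves less
sigma headroom, so the plan demands worst-case coverage).  Low-sigma and
unacceptable analytes always keep the SQC monitor, with MA added as a
supplemental alarm between QC events.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .ma_pbrtqc import BiasDetectionSummary
from .sigma_metrics import AnalyteProfile, SigmaResult, analyte_sigma
from .sqc_rules import SQCProcedure

__all__ = [
    "SigmaCategory",
    "QCPlanEntry",
    "categorize",
    "select_startup",
    "select_monitor",
    "integrate_ma",
    "build_plan",
    "plan_to_frame",
    "plan_to_markdown",
]

#: category label -> (lower bound inclusive, upper bound exclusive)
CATEGORY_BOUNDS: dict[str, tuple[float, float]] = {
    "high": (5.0, float("inf")),
    "moderate": (4.5, 5.0),
    "low": (3.5, 4.5),
    "unacceptable": (float("-inf"), 3.5),
}


@dataclass(frozen=True)
class SigmaCategory:
    label: str

    def __post_init__(self) -> None:
        if self.label not in CATEGORY_BOUNDS:
            raise ValueError(f"unknown category {self.label!r}")

    @property
    def bounds(self) -> tuple[float, float]:
        return CATEGORY_BOUNDS[self.label]


@dataclass(frozen=True)
class QCPlanEntry:
    """One analyte's row in the multistage QC plan."""

    analyte: str
    category: SigmaCategory
    startup_procedure: str
    monitor_procedure: str
    ma_role: str  # replace_monitor | supplement_monitor
    justification: str

    def __post_init__(self) -> None:
        if self.ma_role not in ("replace_monitor", "supplement_monitor"):
            raise ValueError(f"unknown ma_role {self.ma_role!r}")
        if self.ma_role == "replace_monitor" and self.monitor_procedure != "MA":
            raise ValueError("replace_monitor implies monitor_procedure == 'MA'")
        if self.category.label in ("low", "unacceptable") and self.ma_role != "supplement_monitor":
            raise ValueError("low/unacceptable categories must keep the SQC monitor")


def categorize(average_risk_sigma: float) -> SigmaCategory:
    """Sigma strategy category from the average patient-risk sigma."""
    for label, (lo, hi) in CATEGORY_BOUNDS.items():
        if lo <= average_risk_sigma < hi:
            return SigmaCategory(label)
    raise ValueError(f"average_risk_sigma {average_risk_sigma} not categorizable")


def _feasible_everywhere(
    run_sizes: Mapping[str, int], requirement: Mapping[str, int], slack: float = 0.0
) -> tuple[bool, list[str]]:
    binding = [
        a for a, need in requirement.items()
        if run_sizes.get(a, 0) < (1.0 - slack) * need
    ]
    return not binding, binding


def select_startup(
    candidates: Sequence[SQCProcedure],
    run_size_matrix: Mapping[str, Mapping[str, int]],
    daily_volumes: Mapping[str, int],
    required_n: int = 3,
) -> SQCProcedure:
    """Panel-wide start-up procedure.

    Among candidates with ``required_n`` control measurements (default 3 —
    one per control level, covering the whole measuring range) whose run
    size covers every analyte's daily volume, the lowest nominal Pfr wins
    (false rejections cost control material and time); ties go to the
    procedure with fewer sub-rules.
    """
    feasible = []
    report: list[str] = []
    for proc in candidates:
        if proc.n_controls != required_n:
            continue
        ok, binding = _feasible_everywhere(
            run_size_matrix.get(proc.name, {}), daily_volumes
        )
        if ok:
            feasible.append(proc)
        else:
            report.append(f"{proc.name}: run size below daily volume for {binding}")
    if not feasible:
        raise ValueError(
            "no start-up candidate covers the panel; binding analytes: "
            + "; ".join(report)
        )
    return min(feasible, key=lambda p: (p.pfr_nominal, len(p.sub_rules)))


def select_monitor(
    candidates: Sequence[SQCProcedure],
    run_size_matrix: Mapping[str, Mapping[str, int]],
    reporting_intervals: Mapping[str, int],
    pfr_max: float = 0.05,
    tolerance: float = 0.10,
) -> SQCProcedure | None:
    """Panel-wide single-measurement monitor procedure.

    Among N=1 candidates with nominal Pfr <= ``pfr_max`` whose run size
    reaches at least ``(1 - tolerance)`` of every analyte's reporting
    interval, the most powerful rule wins — with a Pfr ceiling in place the
    largest admissible Pfr is the power proxy (a wider rule rejects more at
    every error size).  ``tolerance`` admits a borderline analyte whose run
    size falls just short of its interval.  Returns None when no candidate
    qualifies (MA surveillance becomes mandatory).
    """
    feasible = []
    for proc in candidates:
        if proc.n_controls != 1 or proc.pfr_nominal is None or proc.pfr_nominal > pfr_max:
            continue
        ok, _ = _feasible_everywhere(
            run_size_matrix.get(proc.name, {}), reporting_intervals, slack=tolerance
        )
        if ok:
            feasible.append(proc)
    if not feasible:
        return None
    return max(feasible, key=lambda p: p.pfr_nominal)


def integrate_ma(
    category: SigmaCategory,
    detection: Mapping[str, BiasDetectionSummary],
    daily_volume: int,
) -> str:
    """Decide the MA procedure's role for one analyte.

    ``detection`` maps the bias direction ("negative"/"positive") to the
    TEa-bias detection summary of the analyte's optimized MA procedure.
    """
    for direction in ("negative", "positive"):
        if direction not in detection:
            raise ValueError(f"missing {direction}-direction detection summary")
    neg, pos = detection["negative"], detection["positive"]
    if category.label == "high":
        fits = all(
            s.median_count is not None and s.median_count <= daily_volume
            for s in (neg, pos)
        )
    elif category.label == "moderate":
        fits = all(
            s.max_count is not None and s.max_count <= daily_volume
            for s in (neg, pos)
        )
    else:
        fits = False
    return "replace_monitor" if fits else "supplement_monitor"


def build_plan(
    panel: Sequence[AnalyteProfile],
    run_size_matrix: Mapping[str, Mapping[str, int]],
    ma_summaries: Mapping[str, Mapping[str, BiasDetectionSummary]],
    candidates: Sequence[SQCProcedure],
    sigma_results: Mapping[str, SigmaResult] | None = None,
    pfr_max: float = 0.05,
    monitor_tolerance: float = 0.10,
) -> tuple[list[QCPlanEntry], pd.DataFrame]:
    """Assemble the full multistage plan for a panel.

    Returns the per-analyte entries and a tidy report frame.  The plan is a
    pure function of its inputs: given the same panel, run-size matrix, MA
    summaries and candidate set it always produces the same entries.
    """
    if sigma_results is None:
        sigma_results = {p.name: analyte_sigma(p) for p in panel}
    volumes = {p.name: p.daily_volume for p in panel}
    intervals = {p.name: p.interval for p in panel}

    startup = select_startup(candidates, run_size_matrix, volumes)
    monitor = select_monitor(
        candidates, run_size_matrix, intervals,
        pfr_max=pfr_max, tolerance=monitor_tolerance,
    )

    entries = []
    for prof in panel:
        res = sigma_results[prof.name]
        category = categorize(res.average_risk_sigma)
        role = integrate_ma(category, ma_summaries[prof.name], prof.daily_volume)
        if role == "replace_monitor":
            monitor_name = "MA"
            why = (
                f"{category.label} sigma ({res.average_risk_sigma:.2f}); MA detects "
                f"a TEa bias within the daily volume ({prof.daily_volume})"
            )
        else:
            monitor_name = (
                f"{monitor.name} and MA" if monitor is not None else "MA (no SQC feasible)"
            )
            why = (
                f"{category.label} sigma ({res.average_risk_sigma:.2f}); SQC monitor "
                "retained, MA adds surveillance between QC events"
            )
        entries.append(
            QCPlanEntry(
                analyte=prof.name,
                category=category,
                startup_procedure=startup.name,
                monitor_procedure=monitor_name,
                ma_role=role,
                justification=why,
            )
        )
    return entries, plan_to_frame(entries)


def plan_to_frame(entries: Sequence[QCPlanEntry]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "analyte": e.analyte,
            "category": e.category.label,
            "startup": e.startup_procedure,
            "monitor": e.monitor_procedure,
            "ma_role": e.ma_role,
            "justification": e.justification,
        }
        for e in entries
    )


def plan_to_markdown(entries: Sequence[QCPlanEntry]) -> str:
    """Two-column plan summary grouped by monitor procedure."""
    groups: dict[tuple[str, str], list[str]] = {}
    for e in entries:
        groups.setdefault((e.startup_procedure, e.monitor_procedure), []).append(e.analyte)
    lines = [
        "| Analyte | Start-up QC procedure | Monitor QC procedure |",
        "| --- | --- | --- |",
    ]
    for (startup, monitor), names in groups.items():
        lines.append(f"| {', '.join(names)} | {startup} | {monitor} |")
    return "\n".join(lines)
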
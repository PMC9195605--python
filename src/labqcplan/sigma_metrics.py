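"""Sigma metrics for clinical chemistry assays.

The sigma metric at one control level is

    sigma = (TEa - |bias|) / CV        (all terms in %)

with TEa the total allowable error (the quality requirement), bias the
systematic error estimated from external quality assessment, and CV the
imprecision from internal QC.  For patient-risk calculations the sigma is
capped at 6 ("patient-risk sigma"): beyond six sigma the defect rate is
negligible and higher values carry no additional planning information.  An
assay run with three control levels is summarized by the arithmetic mean of
the three per-level values; the average patient-risk sigma is the quantity
the QC plan is built on.

Bias enters as magnitude: signed EQA biases are folded to absolute percent
before subtraction.  All arithmetic is done at full precision; 2-decimal
half-up rounding happens only when formatting reports.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from ._utils import round_half_up
from .synthetic_data import EQATriplet, StreamSpec

__all__ = [
    "QCLevel",
    "SigmaResult",
    "AnalyteProfile",
    "RISK_SIGMA_CAP",
    "tea_percent_from_absolute",
    "bias_from_eqa",
    "sigma_level",
    "risk_sigma",
    "analyte_sigma",
    "panel_from_csv",
    "panel_from_json",
    "sigma_table",
]

#: Patient-risk sigma cap: calculated sigmas above this report as exactly 6.
RISK_SIGMA_CAP = 6.0


@dataclass(frozen=True)
class QCLevel:
    """Quality model at one control concentration (all fields in %)."""

    target: float
    tea_percent: float
    bias_percent: float
    cv_percent: float

    def __post_init__(self) -> None:
        if self.cv_percent <= 0:
            raise ValueError("cv_percent must be > 0")
        if self.tea_percent <= 0:
            raise ValueError("tea_percent must be > 0")
        if self.bias_percent < 0:
            raise ValueError("bias_percent is a magnitude, must be >= 0")


@dataclass(frozen=True)
class SigmaResult:
    """Per-level and averaged sigma metrics for one analyte."""

    sigma_calculated: tuple[float, float, float]
    sigma_risk: tuple[float, float, float]
    average_sigma: float
    average_risk_sigma: float
    #: set when any level has bias > TEa (negative sigma: method unacceptable)
    unacceptable: bool = False

    def rounded(self) -> "SigmaResult":
        """Report-scale copy with 2-decimal half-up rounding applied."""
        return SigmaResult(
            tuple(round_half_up(s) for s in self.sigma_calculated),
            tuple(round_half_up(s) for s in self.sigma_risk),
            round_half_up(self.average_sigma),
            round_half_up(self.average_risk_sigma),
            self.unacceptable,
        )


@dataclass(frozen=True)
class AnalyteProfile:
    """One analyte's complete quality model for QC planning."""

    name: str
    unit: str
    levels: tuple[QCLevel, QCLevel, QCLevel]
    daily_volume: int
    reporting_interval: int | None = None
    stream_spec: StreamSpec | None = None

    def __post_init__(self) -> None:
        if len(self.levels) != 3:
            raise ValueError("exactly 3 QC levels required")
        if self.daily_volume < 1:
            raise ValueError("daily_volume must be >= 1")

    @property
    def interval(self) -> int:
        """Reporting interval; defaults to the daily volume (single-shift lab)."""
        return self.reporting_interval if self.reporting_interval else self.daily_volume


def tea_percent_from_absolute(tea_abs: float, target: float) -> float:
    """Convert an absolute TEa (concentration units) to % of the level target."""
    if target <= 0:
        raise ValueError("target concentration must be > 0")
    return 100.0 * tea_abs / target


def bias_from_eqa(triplets: Sequence[EQATriplet]) -> tuple[float, float, float]:
    """Per-level bias estimate: arithmetic mean of each EQA triplet's biases."""
    if len(triplets) != 3:
        raise ValueError("expected one triplet per control level (3)")
    by_level = sorted(triplets, key=lambda t: t.level_index)
    if [t.level_index for t in by_level] != [1, 2, 3]:
        raise ValueError("triplets must cover levels 1, 2, 3")
    return tuple(t.mean_bias for t in by_level)


def sigma_level(level: QCLevel) -> float:
    """Sigma metric (TEa - bias)/CV at one level; negative if bias > TEa."""
    return (level.tea_percent - level.bias_percent) / level.cv_percent


def risk_sigma(sigma: float) -> float:
    """Patient-risk sigma: the calculated sigma capped at 6."""
    return min(sigma, RISK_SIGMA_CAP)


def analyte_sigma(profile: AnalyteProfile) -> SigmaResult:
    """Full sigma summary for one analyte (3 levels + averages)."""
    sigmas = tuple(sigma_level(lv) for lv in profile.levels)
    risks = tuple(risk_sigma(s) for s in sigmas)
    return SigmaResult(
        sigma_calculated=sigmas,
        sigma_risk=risks,
        average_sigma=float(np.mean(sigmas)),
        average_risk_sigma=float(np.mean(risks)),
        unacceptable=any(s < 0 for s in sigmas),
    )


# ---------------------------------------------------------------------------
# panel IO and reporting


def _profile_from_record(rec: dict) -> AnalyteProfile:
    levels = tuple(
        QCLevel(
            target=lv["target"],
            tea_percent=lv["tea_percent"],
            bias_percent=lv["bias_percent"],
            cv_percent=lv["cv_percent"],
        )
        for lv in rec["levels"]
    )
    return AnalyteProfile(
        name=rec["name"],
        unit=rec.get("unit", ""),
        levels=levels,
        daily_volume=rec["daily_volume"],
        reporting_interval=rec.get("reporting_interval"),
    )


def panel_from_json(path: str | Path) -> list[AnalyteProfile]:
    """Load an analyte panel from JSON (list of profile records)."""
    return [_profile_from_record(rec) for rec in json.loads(Path(path).read_text())]


def panel_from_csv(path: str | Path) -> list[AnalyteProfile]:
    """Load a panel from tidy CSV: one row per analyte-level.

    Required columns: analyte, unit, level (1..3), target, tea_percent,
    bias_percent, cv_percent, daily_volume; optional reporting_interval.
    """
    df = pd.read_csv(path)
    profiles = []
    for name, grp in df.groupby("analyte", sort=False):
        grp = grp.sort_values("level")
        if list(grp["level"]) != [1, 2, 3]:
            raise ValueError(f"analyte {name!r} must have levels 1, 2, 3")
        levels = tuple(
            QCLevel(r.target, r.tea_percent, r.bias_percent, r.cv_percent)
            for r in grp.itertuples()
        )
        first = grp.iloc[0]
        profiles.append(
            AnalyteProfile(
                name=str(name),
                unit=str(first.get("unit", "")),
                levels=levels,
                daily_volume=int(first["daily_volume"]),
                reporting_interval=(
                    int(first["reporting_interval"])
                    if "reporting_interval" in grp.columns
                    and not pd.isna(first["reporting_interval"])
                    else None
                ),
            )
        )
    return profiles


def sigma_table(panel: Sequence[AnalyteProfile]) -> pd.DataFrame:
    """Report-scale sigma summary, one row per analyte (2-decimal rounding)."""
    rows = []
    for prof in panel:
        res = analyte_sigma(prof).rounded()
        row: dict[str, object] = {"analyte": prof.name}
        for i in range(3):
            lv = prof.levels[i]
            row[f"tea_l{i + 1}"] = lv.tea_percent
            row[f"bias_l{i + 1}"] = lv.bias_percent
            row[f"cv_l{i + 1}"] = lv.cv_percent
            row[f"sigma_l{i + 1}"] = res.sigma_calculated[i]
            row[f"risk_sigma_l{i + 1}"] = res.sigma_risk[i]
        row["average_sigma"] = res.average_sigma
        row["average_risk_sigma"] = res.average_risk_sigma
        row["unacceptable"] = res.unacceptable
        rows.append(row)
    return pd.DataFrame(rows)
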
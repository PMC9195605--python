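"""Bracketed run-size planning from patient risk.

In bracketed SQC, patient results are only released once the closing QC
event of their run is accepted.  If a systematic error of magnitude ``se``
(analytical SDs) arises, each accepted run of ``n`` patient samples releases
on average ``n * dPE(se)`` additional erroneous-beyond-TEa ("unreliable")
final results, where ``dPE(se)`` is the increase over the baseline defect
rate.  The number of accepted runs before the error is caught is geometric
with success probability ``Ped(se)`` (the procedure's power at ``se``), so
the expected number of unreliable final results released while the error
goes undetected is

    E(Nuf)(n, se) = n * dPE(se) * (1 - Ped(se)) / Ped(se).

The planned run size is the largest ``n`` (up to a reporting cap of 1000)
whose worst case over ``se`` — MaxE(Nuf) — stays at or below the patient
risk factor (default 1: at most one unreliable result expected per error
condition).

Defect model.  A patient result is unreliable when its total error exceeds
TEa.  On the sigma scale TEa sits ``s`` analytical SDs from the (biased)
process mean, with ``s`` the sigma metric, so

    p_unreliable(se) = Phi(se - s) + Phi(-se - s).

The assay's quality across its measuring range is summarized by the average
patient-risk sigma (per-level sigma capped at 6, averaged over the three
control levels) — the single sigma value the planning literature keys run
sizes on; per-level aggregation policies are available (``worst_level`` uses
the weakest level's uncapped sigma instead).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .sigma_metrics import AnalyteProfile, QCLevel, analyte_sigma, sigma_level
from .sqc_rules import PowerCurve, SQCProcedure, power_curve

__all__ = [
    "RunSizeRequest",
    "RunSizeResult",
    "prob_unreliable",
    "prob_unreliable_sigma",
    "expected_nuf",
    "run_size",
    "run_size_matrix",
    "DEFAULT_CAP",
]

DEFAULT_CAP = 1000

LevelAggregation = Literal["average_risk", "worst_level"]


@dataclass(frozen=True)
class RunSizeRequest:
    """Inputs for one run-size determination."""

    procedure: SQCProcedure
    profile: AnalyteProfile
    patient_risk_factor: float = 1.0
    cap: int = DEFAULT_CAP
    se_grid: np.ndarray | None = None
    level_aggregation: LevelAggregation = "average_risk"
    n_sims: int = 200_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.patient_risk_factor <= 0:
            raise ValueError("patient_risk_factor must be > 0")
        if self.cap < 1:
            raise ValueError("cap must be >= 1")


@dataclass(frozen=True)
class RunSizeResult:
    """Planned run size and the error magnitude that binds it."""

    run_size: int
    binding_se: float
    binding_level: int
    capped: bool
    #: set when even n=1 exceeds the risk bound (QC every sample insufficient)
    insufficient: bool = False


def prob_unreliable_sigma(sigma: float, se: float) -> float:
    """P(result's total error > TEa) at quality ``sigma`` under shift ``se``."""
    return float(norm.cdf(se - sigma) + norm.cdf(-se - sigma))


def prob_unreliable(level: QCLevel, se: float) -> float:
    """Defect probability at one control level's quality under shift ``se``."""
    return prob_unreliable_sigma(sigma_level(level), se)


def _effective_sigma(profile: AnalyteProfile, aggregation: LevelAggregation) -> float:
    res = analyte_sigma(profile)
    if aggregation == "average_risk":
        return res.average_risk_sigma
    if aggregation == "worst_level":
        return min(res.sigma_calculated)
    raise ValueError(f"unknown level aggregation {aggregation!r}")


def _binding_level(profile: AnalyteProfile) -> int:
    """1-based index of the weakest (lowest-sigma) control level."""
    sigmas = [sigma_level(lv) for lv in profile.levels]
    return int(np.argmin(sigmas)) + 1


def _delta_pe(sigma: float, se: float) -> float:
    return prob_unreliable_sigma(sigma, se) - prob_unreliable_sigma(sigma, 0.0)


def expected_nuf(
    n: int,
    procedure: SQCProcedure,
    profile: AnalyteProfile,
    se: float,
    curve: PowerCurve | None = None,
    level_aggregation: LevelAggregation = "average_risk",
    n_sims: int = 200_000,
    seed: int = 0,
) -> float:
    """Expected unreliable final results for run size ``n`` at shift ``se``.

    ``curve`` may carry a precomputed power function for the procedure;
    otherwise a Monte-Carlo curve point is computed on the fly.
    """
    if n < 1:
        raise ValueError("run size n must be >= 1")
    sigma = _effective_sigma(profile, level_aggregation)
    dpe = _delta_pe(sigma, se)
    if dpe <= 0:
        return 0.0
    if curve is not None:
        ped = curve.ped(se)
    else:
        from .sqc_rules import prob_rejection

        ped = prob_rejection(procedure, se, n_sims=n_sims, seed=seed)
    if ped <= 0:
        return float("inf")
    return n * dpe * (1.0 - ped) / ped


def _default_grid(sigma: float) -> np.ndarray:
    top = max(2.0 * sigma, 1.0)
    return np.arange(0.0, top + 1e-9, 0.05)


def _max_rate(
    procedure: SQCProcedure,
    sigma: float,
    se_grid: np.ndarray,
    n_sims: int,
    seed: int,
) -> tuple[float, float]:
    """Worst per-result risk rate over the grid and its argmax se."""
    grid = np.asarray(se_grid, dtype=float)
    curve = power_curve(procedure, grid, n_sims=n_sims, seed=seed)
    dpe = np.array([_delta_pe(sigma, se) for se in grid])
    ped = curve.p_reject
    with np.errstate(divide="ignore", invalid="ignore"):
        rate = np.where(ped > 0, dpe * (1.0 - ped) / np.maximum(ped, 1e-300), np.inf)
    rate = np.where(dpe <= 0, 0.0, rate)
    i = int(np.argmax(rate))
    return float(rate[i]), float(grid[i])


def run_size(req: RunSizeRequest) -> RunSizeResult:
    """Largest run size whose MaxE(Nuf) stays within the patient risk factor.

    ``expected_nuf`` is linear in ``n``, so the bound is monotone; the search
    is an integer bisection on ``n`` against the worst-case per-result rate.
    """
    sigma = _effective_sigma(req.profile, req.level_aggregation)
    grid = req.se_grid if req.se_grid is not None else _default_grid(sigma)
    max_rate, binding_se = _max_rate(
        req.procedure, sigma, grid, n_sims=req.n_sims, seed=req.seed
    )
    level = _binding_level(req.profile)

    def ok(n: int) -> bool:
        return n * max_rate <= req.patient_risk_factor

    if not ok(1):
        return RunSizeResult(0, binding_se, level, capped=False, insufficient=True)
    if ok(req.cap):
        # still check whether the uncapped solution would exceed the cap
        capped = max_rate == 0 or (req.cap + 1) * max_rate <= req.patient_risk_factor
        return RunSizeResult(req.cap, binding_se, level, capped=capped)
    lo, hi = 1, req.cap  # ok(lo), not ok(hi)
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if ok(mid):
            lo = mid
        else:
            hi = mid
    return RunSizeResult(lo, binding_se, level, capped=False)


def run_size_matrix(
    procedures: Sequence[SQCProcedure],
    panel: Sequence[AnalyteProfile],
    patient_risk_factor: float = 1.0,
    cap: int = DEFAULT_CAP,
    level_aggregation: LevelAggregation = "average_risk",
    n_sims: int = 200_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Run sizes for every procedure x analyte (procedures as rows).

    Power curves depend only on the procedure and the se grid, so one curve
    per procedure is shared across the panel.
    """
    sigmas = {p.name: _effective_sigma(p, level_aggregation) for p in panel}
    grid = _default_grid(max(sigmas.values()))
    out: dict[str, dict[str, int]] = {}
    for j, proc in enumerate(procedures):
        curve = power_curve(proc, grid, n_sims=n_sims, seed=seed + j)
        row: dict[str, int] = {}
        for prof in panel:
            sigma = sigmas[prof.name]
            dpe = np.array([_delta_pe(sigma, se) for se in grid])
            ped = curve.p_reject
            with np.errstate(divide="ignore", invalid="ignore"):
                rate = np.where(ped > 0, dpe * (1.0 - ped) / np.maximum(ped, 1e-300), np.inf)
            rate = np.where(dpe <= 0, 0.0, rate)
            max_rate = float(rate.max())
            if max_rate == 0:
                row[prof.name] = cap
            else:
                n = int(np.floor(patient_risk_factor / max_rate))
                row[prof.name] = min(max(n, 0), cap)
        out[proc.name] = row
    return pd.DataFrame(out).T[[p.name for p in panel]]
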
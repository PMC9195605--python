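"""Westgard control rules: event evaluation, false rejection and power.

A statistical QC (SQC) procedure is an ordered set of sub-rules applied to
the N control z-scores of one QC event (one measurement per control level,
z = (result - target) / SD).  The quantities of interest are

* ``Pfr`` — probability of rejecting the event when no error is present, and
* ``Ped(se)`` — probability of rejecting when every control carries a
  systematic shift of ``se`` analytical SDs,

the power function of the procedure.  Within one event the N z-scores are
modelled as independent standard normals shifted by ``se``: the controls sit
at different concentrations, and a systematic error expressed in SD units
moves each of them by the same z-amount.

Counted rules (2of3:2s, 3:1s, 6:X) use the standard same-side multirule
convention: all counted exceedances must fall on the same side of target.
For procedures with N=6 the 3-measurement counted rules are applied to each
window of 3 consecutive measurements within the event; no across-event
memory is modelled (bracketed, per-event evaluation).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
from scipy.stats import norm

__all__ = [
    "SubRule",
    "SQCProcedure",
    "PowerCurve",
    "evaluate_event",
    "reject_events",
    "prob_rejection",
    "power_curve",
    "single_limit_prob",
    "CANDIDATE_PROCEDURES",
    "get_procedure",
    "procedures_from_config",
]

RuleKind = Literal["limit", "two_of_three_2s", "three_of_three_1s", "six_x_one_side"]


@dataclass(frozen=True)
class SubRule:
    """One control rule evaluated inside a QC event.

    ``kind="limit"`` fires when any |z| exceeds ``k``; the counted kinds fire
    on same-side exceedances as described in the module docstring.
    """

    kind: RuleKind
    k: float = 0.0

    def __post_init__(self) -> None:
        if self.kind == "limit" and self.k <= 0:
            raise ValueError("limit rule needs k > 0")

    @property
    def name(self) -> str:
        if self.kind == "limit":
            k = int(self.k) if float(self.k).is_integer() else self.k
            return f"1:{k}s"
        return {
            "two_of_three_2s": "2of3:2s",
            "three_of_three_1s": "3:1s",
            "six_x_one_side": "6:X",
        }[self.kind]

    def min_n(self) -> int:
        return {"limit": 1, "two_of_three_2s": 3, "three_of_three_1s": 3, "six_x_one_side": 6}[
            self.kind
        ]


@dataclass(frozen=True)
class SQCProcedure:
    """A candidate SQC procedure: ordered sub-rules + N controls per event."""

    name: str
    sub_rules: tuple[SubRule, ...]
    n_controls: int
    pfr_nominal: float | None = None

    def __post_init__(self) -> None:
        if self.n_controls not in (1, 3, 6):
            raise ValueError("n_controls must be 1, 3 or 6")
        for rule in self.sub_rules:
            if rule.min_n() > self.n_controls:
                raise ValueError(f"rule {rule.name} needs N >= {rule.min_n()}")

    @property
    def is_single_limit(self) -> bool:
        return (
            self.n_controls == 1
            and len(self.sub_rules) == 1
            and self.sub_rules[0].kind == "limit"
        )


@dataclass(frozen=True)
class PowerCurve:
    """Rejection probability vs systematic error (z-units); Pfr at se=0."""

    se_grid: np.ndarray
    p_reject: np.ndarray

    def __post_init__(self) -> None:
        if len(self.se_grid) != len(self.p_reject):
            raise ValueError("se_grid and p_reject must have equal length")

    @property
    def pfr(self) -> float:
        i = int(np.argmin(np.abs(self.se_grid)))
        return float(self.p_reject[i])

    def ped(self, se: float) -> float:
        """Interpolated detection probability at systematic error ``se``."""
        return float(np.interp(se, self.se_grid, self.p_reject))


# ---------------------------------------------------------------------------
# event evaluation


def _rule_fires(rule: SubRule, z: np.ndarray) -> np.ndarray:
    """Vectorized: does ``rule`` fire for each row of z (shape (m, N))?"""
    if rule.kind == "limit":
        return (np.abs(z) > rule.k).any(axis=1)
    if rule.kind == "two_of_three_2s":
        return _windowed_count(z, width=3, thresh=2.0, count=2)
    if rule.kind == "three_of_three_1s":
        return _windowed_count(z, width=3, thresh=1.0, count=3)
    if rule.kind == "six_x_one_side":
        return _windowed_count(z, width=6, thresh=0.0, count=6)
    raise ValueError(f"unknown rule kind {rule.kind!r}")


def _windowed_count(z: np.ndarray, width: int, thresh: float, count: int) -> np.ndarray:
    """Same-side counted rule over every window of ``width`` consecutive scores."""
    m, n = z.shape
    fired = np.zeros(m, dtype=bool)
    for start in range(0, n - width + 1):
        w = z[:, start : start + width]
        hi = (w > thresh).sum(axis=1) >= count
        lo = (w < -thresh).sum(axis=1) >= count
        fired |= hi | lo
    return fired


def reject_events(procedure: SQCProcedure, z: np.ndarray) -> np.ndarray:
    """Evaluate many QC events at once; ``z`` has shape (m, N)."""
    z = np.atleast_2d(np.asarray(z, dtype=float))
    if z.shape[1] != procedure.n_controls:
        raise ValueError(
            f"{procedure.name} expects {procedure.n_controls} z-scores per event, "
            f"got {z.shape[1]}"
        )
    rejected = np.zeros(z.shape[0], dtype=bool)
    for rule in procedure.sub_rules:
        rejected |= _rule_fires(rule, z)
    return rejected


def evaluate_event(
    procedure: SQCProcedure, z_scores: Sequence[float]
) -> tuple[bool, str | None]:
    """Evaluate one QC event; returns (reject, first violated sub-rule name)."""
    z = np.asarray(z_scores, dtype=float)
    if z.ndim != 1 or len(z) != procedure.n_controls:
        raise ValueError(
            f"{procedure.name} expects {procedure.n_controls} z-scores, got {len(z)}"
        )
    row = z[None, :]
    for rule in procedure.sub_rules:
        if bool(_rule_fires(rule, row)[0]):
            return True, rule.name
    return False, None


# ---------------------------------------------------------------------------
# rejection probability and power


def single_limit_prob(k: float, se: float) -> float:
    """Closed-form P(|Z + se| > k) for a single 1:ks rule with N=1."""
    return float(norm.cdf(-k - se) + norm.cdf(-k + se))


def prob_rejection(
    procedure: SQCProcedure,
    se: float,
    method: Literal["monte_carlo", "analytic_single"] = "monte_carlo",
    n_sims: int = 200_000,
    seed: int = 0,
) -> float:
    """P(reject at one QC event) when all N controls are shifted by ``se``.

    ``analytic_single`` is exact but only defined for N=1 single-limit rules;
    ``monte_carlo`` works for any procedure (standard error about 0.0011 at
    the default ``n_sims`` for p near 0.5, much smaller in the tails).
    """
    if method == "analytic_single":
        if not procedure.is_single_limit:
            raise ValueError("analytic_single only supports N=1 single-limit rules")
        return single_limit_prob(procedure.sub_rules[0].k, se)
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n_sims, procedure.n_controls)) + se
    return float(reject_events(procedure, z).mean())


def power_curve(
    procedure: SQCProcedure,
    se_grid: Sequence[float],
    n_sims: int = 200_000,
    seed: int = 0,
) -> PowerCurve:
    """Power function of ``procedure`` over a sorted non-negative se grid.

    Uses common random numbers across grid points: one base z-draw shared by
    every ``se``, so the estimated curve is smooth and monotone up to rule
    geometry, not Monte-Carlo jitter.
    """
    grid = np.asarray(se_grid, dtype=float)
    if grid.size == 0:
        raise ValueError("se_grid must be non-empty")
    if (np.diff(grid) < 0).any() or (grid < 0).any():
        raise ValueError("se_grid must be sorted and non-negative")
    rng = np.random.default_rng(seed)
    base = rng.standard_normal((n_sims, procedure.n_controls))
    p = np.empty_like(grid)
    for i, se in enumerate(grid):
        p[i] = reject_events(procedure, base + se).mean()
    return PowerCurve(se_grid=grid, p_reject=p)


# ---------------------------------------------------------------------------
# candidate registry

def _multirule(name: str, n: int, pfr: float, with_6x: bool = False) -> SQCProcedure:
    rules = [SubRule("limit", 3.0), SubRule("two_of_three_2s"), SubRule("three_of_three_1s")]
    if with_6x:
        rules.append(SubRule("six_x_one_side"))
    return SQCProcedure(name, tuple(rules), n, pfr)


#: The candidate SQC procedures for a 3-level control design, keyed by name.
#: ``pfr_nominal`` carries the published planning values; note that for
#: 1:2.5s at N=3 and N=6 these differ slightly from the independence
#: computation (see docs/methods.md).
CANDIDATE_PROCEDURES: dict[str, SQCProcedure] = {
    p.name: p
    for p in [
        _multirule("1:3s/2of3:2s/3:1s/6:X N6", 6, 0.07, with_6x=True),
        SQCProcedure("1:2.5s N6", (SubRule("limit", 2.5),), 6, 0.06),
        _multirule("1:3s/2of3:2s/3:1s N3", 3, 0.02),
        SQCProcedure("1:2.5s N3", (SubRule("limit", 2.5),), 3, 0.03),
        SQCProcedure("1:3s N3", (SubRule("limit", 3.0),), 3, 0.01),
        SQCProcedure("1:2s N1", (SubRule("limit", 2.0),), 1, 0.05),
        SQCProcedure("1:2.5s N1", (SubRule("limit", 2.5),), 1, 0.01),
        SQCProcedure("1:3s N1", (SubRule("limit", 3.0),), 1, 0.00),
    ]
}


def get_procedure(name: str) -> SQCProcedure:
    try:
        return CANDIDATE_PROCEDURES[name]
    except KeyError:
        raise KeyError(
            f"unknown procedure {name!r}; known: {sorted(CANDIDATE_PROCEDURES)}"
        ) from None


def procedures_from_config(path: str | Path) -> dict[str, SQCProcedure]:
    """Load extra procedures from a JSON list of descriptors.

    Each descriptor: ``{"name": ..., "n_controls": ..., "pfr_nominal": ...,
    "sub_rules": [{"kind": "limit", "k": 3.0}, ...]}``.
    """
    raw = json.loads(Path(path).read_text())
    out = {}
    for entry in raw:
        rules = tuple(SubRule(r["kind"], r.get("k", 0.0)) for r in entry["sub_rules"])
        proc = SQCProcedure(
            entry["name"], rules, entry["n_controls"], entry.get("pfr_nominal")
        )
        out[proc.name] = proc
    return out
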
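"""Synthetic laboratory data generators.

Everything downstream of this module — sigma metrics, run-size planning,
moving-average simulation — normally consumes three private data sources of a
clinical laboratory: the patient-result stream from the LIS, internal QC (IQC)
replicate series on commercial control material, and external quality
assessment (EQA) samples matched to the IQC concentration levels.  The
generators here emulate all three with known ground truth (distribution,
imprecision, bias), so every stage of the pipeline is testable without any
real laboratory data.

Conventions
-----------
* Patient streams default to lognormal: most clinical chemistry analytes are
  right-skewed in an unselected population.  Normal is available per analyte.
* Each generator call builds its own ``numpy.random.Generator`` from the
  spec's seed; no global RNG state is touched, so identical specs give
  bitwise-identical output.
* Days are contiguous blocks of ``daily_volume`` results; the planning model
  operates at day granularity (single-shift laboratory), so no within-day
  time stamps are modelled.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "StreamSpec",
    "IQCSpec",
    "EQATriplet",
    "gen_patient_stream",
    "gen_iqc_results",
    "gen_eqa_triplets",
    "stream_spec_from_file",
    "iqc_spec_from_file",
    "stream_to_frame",
    "iqc_to_frame",
]


@dataclass(frozen=True)
class StreamSpec:
    """Recipe for one analyte's patient-result stream.

    ``location``/``scale`` are on the natural concentration scale for
    ``distribution="normal"`` (mean and SD) and describe the underlying
    normal for ``distribution="lognormal"`` (median ``location``; ``scale``
    is the sigma of log-values, approximately the population CV for small
    values).
    """

    analyte_name: str
    location: float
    scale: float
    daily_volume: int
    n_days: int = 1
    distribution: Literal["normal", "lognormal"] = "lognormal"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValueError(f"scale must be > 0, got {self.scale}")
        if self.daily_volume < 1:
            raise ValueError(f"daily_volume must be >= 1, got {self.daily_volume}")
        if self.n_days < 1:
            raise ValueError(f"n_days must be >= 1, got {self.n_days}")
        if self.distribution not in ("normal", "lognormal"):
            raise ValueError(f"unknown distribution {self.distribution!r}")

    @property
    def n_results(self) -> int:
        return self.daily_volume * self.n_days


@dataclass(frozen=True)
class IQCSpec:
    """Recipe for a 3-level internal-QC replicate series.

    Level ``i`` results are normal with mean ``target_i * (1 + bias_i/100)``
    and SD ``target_i * cv_i/100`` — control material measured on an analyser
    carrying a constant relative bias and a level-specific imprecision.
    """

    level_targets: tuple[float, float, float]
    cv_percent: tuple[float, float, float]
    bias_percent: tuple[float, float, float] = (0.0, 0.0, 0.0)
    n_per_level: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("level_targets", "cv_percent", "bias_percent"):
            if len(getattr(self, name)) != 3:
                raise ValueError(f"{name} must have exactly 3 entries")
        if any(cv <= 0 for cv in self.cv_percent):
            raise ValueError("cv_percent entries must be > 0")
        if self.n_per_level < 2:
            raise ValueError(f"n_per_level must be >= 2, got {self.n_per_level}")


@dataclass(frozen=True)
class EQATriplet:
    """Three matched EQA sample biases (%) for one IQC concentration level."""

    level_index: int
    biases_percent: tuple[float, float, float]

    def __post_init__(self) -> None:
        if self.level_index not in (1, 2, 3):
            raise ValueError("level_index must be 1, 2 or 3")
        if len(self.biases_percent) != 3:
            raise ValueError("exactly 3 biases per triplet")

    @property
    def mean_bias(self) -> float:
        return float(np.mean(self.biases_percent))


def gen_patient_stream(spec: StreamSpec) -> pd.DataFrame:
    """Generate a patient-result stream as a tidy frame.

    Returns a DataFrame with columns ``(analyte, day, index_in_day, value)``,
    ``n_days * daily_volume`` rows, days as contiguous blocks.  Deterministic
    in ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_results
    if spec.distribution == "normal":
        values = rng.normal(spec.location, spec.scale, size=n)
    else:
        values = rng.lognormal(np.log(spec.location), spec.scale, size=n)
    return pd.DataFrame(
        {
            "analyte": spec.analyte_name,
            "day": np.repeat(np.arange(spec.n_days), spec.daily_volume),
            "index_in_day": np.tile(np.arange(spec.daily_volume), spec.n_days),
            "value": values,
        }
    )


def gen_iqc_results(spec: IQCSpec) -> dict[int, np.ndarray]:
    """Generate IQC replicate series for the 3 control levels.

    Returns ``{level (1..3): array of n_per_level results}``.
    """
    rng = np.random.default_rng(spec.seed)
    out: dict[int, np.ndarray] = {}
    for i in range(3):
        target = spec.level_targets[i]
        mean = target * (1.0 + spec.bias_percent[i] / 100.0)
        sd = target * spec.cv_percent[i] / 100.0
        out[i + 1] = rng.normal(mean, sd, size=spec.n_per_level)
    return out


def gen_eqa_triplets(
    true_bias_percent: Sequence[float],
    noise_sd: float = 0.0,
    seed: int = 0,
) -> list[EQATriplet]:
    """Generate one EQA triplet per IQC level.

    Each triplet holds 3 sample biases drawn as ``true_bias + N(0, noise_sd)``
    for its level; ``noise_sd=0`` reproduces the configured biases exactly.
    """
    if len(true_bias_percent) != 3:
        raise ValueError("true_bias_percent must have exactly 3 entries")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    triplets = []
    for i, b in enumerate(true_bias_percent):
        noise = rng.normal(0.0, noise_sd, size=3) if noise_sd > 0 else np.zeros(3)
        triplets.append(EQATriplet(i + 1, tuple(float(b + e) for e in noise)))
    return triplets


# ---------------------------------------------------------------------------
# config / export plumbing


def _load_mapping(path: str | Path) -> dict:
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        return yaml.safe_load(text)
    return json.loads(text)


def stream_spec_from_file(path: str | Path) -> StreamSpec:
    """Read a StreamSpec from a JSON or YAML mapping."""
    raw = _load_mapping(path)
    return StreamSpec(**raw)


def iqc_spec_from_file(path: str | Path) -> IQCSpec:
    """Read an IQCSpec from a JSON or YAML mapping."""
    raw = _load_mapping(path)
    for key in ("level_targets", "cv_percent", "bias_percent"):
        if key in raw:
            raw[key] = tuple(raw[key])
    return IQCSpec(**raw)


def stream_to_frame(spec: StreamSpec) -> pd.DataFrame:
    """Alias for :func:`gen_patient_stream` (already tidy)."""
    return gen_patient_stream(spec)


def iqc_to_frame(analyte: str, spec: IQCSpec) -> pd.DataFrame:
    """IQC series as a tidy frame (analyte, level, replicate, value)."""
    results = gen_iqc_results(spec)
    rows = []
    for level, values in results.items():
        for j, v in enumerate(values):
            rows.append((analyte, level, j, v))
    return pd.DataFrame(rows, columns=["analyte", "level", "replicate", "value"])
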
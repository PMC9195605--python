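"""Bundled worked-example panel: a 10-analyte clinical chemistry panel from a
small-volume laboratory (about 30-150 tests per analyte per day, single-shift
work, reporting interval equal to the daily volume).

The quality data are the published study inputs: TEa from CLIA performance
specifications (converted to % of the level target where CLIA states an
absolute limit: calcium, potassium, sodium), bias from a monthly EQA scheme
(mean of three EQA samples matched to each IQC level), and CV from six months
of 3-level internal QC.  Alongside the quality model the module bundles the
published planning artefacts for that panel — the run-size matrix produced
for the candidate SQC procedures and the bias-detection summaries of the
laboratory's optimized moving-average procedures — so the whole planning
pipeline can be exercised end to end.

Patient-population parameters (``STREAM_PARAMS``) are synthetic: the study
laboratory's LIS distributions are private, so clinically realistic adult
population medians and spreads are supplied for simulation purposes only.
"""

from __future__ import annotations


from .ma_pbrtqc import BiasDetectionSummary, MAProcedure
from .sigma_metrics import AnalyteProfile, QCLevel
from .synthetic_data import StreamSpec

__all__ = [
    "PANEL",
    "DAILY_VOLUMES",
    "RUN_SIZE_MATRIX",
    "MA_PROCEDURE_TYPES",
    "MA_DETECTION_SUMMARIES",
    "STREAM_PARAMS",
    "example_panel",
    "example_stream_spec",
    "published_run_size_matrix",
    "published_ma_summaries",
]

#: analyte -> (unit, daily volume, [(target, TEa%, bias%, CV%) per level])
#: Targets are the control-material assay values; TEa/bias/CV in percent.
_PANEL_RAW: dict[str, tuple[str, int, list[tuple[float, float, float, float]]]] = {
    "Albumin": ("g/L", 30, [
        (29.1, 10.00, 2.77, 1.60), (39.4, 10.00, 2.24, 0.88), (48.9, 10.00, 1.91, 0.92)]),
    "AST": ("U/L", 150, [
        (36.3, 20.00, 2.47, 2.15), (127.0, 20.00, 1.14, 1.36), (246.0, 20.00, 0.97, 1.15)]),
    "Calcium": ("mmol/L", 30, [
        (1.62, 15.43, 2.40, 3.01), (2.37, 10.55, 1.87, 2.21), (3.07, 8.14, 2.39, 1.43)]),
    "Chloride": ("mmol/L", 50, [
        (83.0, 5.00, 0.58, 1.23), (101.0, 5.00, 0.75, 0.91), (119.0, 5.00, 0.65, 0.52)]),
    "Cholesterol": ("mmol/L", 120, [
        (2.82, 10.00, 2.50, 1.62), (5.31, 10.00, 2.79, 1.35), (7.44, 10.00, 2.71, 1.42)]),
    "Creatinine": ("umol/L", 120, [
        (77.0, 15.00, 2.12, 3.13), (163.0, 15.00, 1.85, 2.96), (365.0, 15.00, 0.97, 2.42)]),
    "HDL-cholesterol": ("mmol/L", 120, [
        (0.78, 30.00, 2.45, 3.11), (1.18, 30.00, 2.56, 3.41), (1.56, 30.00, 3.68, 3.46)]),
    "Potassium": ("mmol/L", 50, [
        (2.68, 18.66, 1.38, 0.95), (4.51, 11.09, 1.02, 1.01), (6.63, 7.54, 0.77, 0.92)]),
    "Sodium": ("mmol/L", 50, [
        (124.0, 3.22, 0.26, 0.73), (145.0, 2.76, 0.40, 0.55), (168.0, 2.38, 0.28, 0.63)]),
    "Total protein": ("g/L", 30, [
        (46.8, 10.00, 1.10, 2.46), (66.9, 10.00, 1.65, 2.06), (89.5, 10.00, 3.31, 1.48)]),
}

#: analyte -> maximum daily number of tests (= desired reporting interval)
DAILY_VOLUMES: dict[str, int] = {k: v[1] for k, v in _PANEL_RAW.items()}

#: Published bracketed run sizes (patient samples between QC events) per
#: candidate SQC procedure x analyte, produced with patient-risk factor 1 and
#: a reporting cap of 1000.
RUN_SIZE_MATRIX: dict[str, dict[str, int]] = {
    "1:3s/2of3:2s/3:1s/6:X N6": {
        "Albumin": 1000, "AST": 1000, "Calcium": 842, "Chloride": 1000,
        "Cholesterol": 1000, "Creatinine": 1000, "HDL-cholesterol": 1000,
        "Potassium": 1000, "Sodium": 453, "Total protein": 770},
    "1:2.5s N6": {
        "Albumin": 1000, "AST": 1000, "Calcium": 926, "Chloride": 1000,
        "Cholesterol": 1000, "Creatinine": 1000, "HDL-cholesterol": 1000,
        "Potassium": 1000, "Sodium": 522, "Total protein": 853},
    "1:3s/2of3:2s/3:1s N3": {
        "Albumin": 1000, "AST": 1000, "Calcium": 178, "Chloride": 1000,
        "Cholesterol": 1000, "Creatinine": 1000, "HDL-cholesterol": 1000,
        "Potassium": 1000, "Sodium": 100, "Total protein": 164},
    "1:2.5s N3": {
        "Albumin": 1000, "AST": 1000, "Calcium": 234, "Chloride": 1000,
        "Cholesterol": 1000, "Creatinine": 1000, "HDL-cholesterol": 1000,
        "Potassium": 1000, "Sodium": 142, "Total protein": 218},
    "1:3s N3": {
        "Albumin": 1000, "AST": 1000, "Calcium": 51, "Chloride": 284,
        "Cholesterol": 590, "Creatinine": 308, "HDL-cholesterol": 1000,
        "Potassium": 1000, "Sodium": 30, "Total protein": 47},
    "1:2s N1": {
        "Albumin": 1000, "AST": 1000, "Calcium": 70, "Chloride": 253,
        "Cholesterol": 436, "Creatinine": 269, "HDL-cholesterol": 1000,
        "Potassium": 1000, "Sodium": 47, "Total protein": 66},
    "1:2.5s N1": {
        "Albumin": 390, "AST": 1000, "Calcium": 25, "Chloride": 91,
        "Cholesterol": 156, "Creatinine": 96, "HDL-cholesterol": 1000,
        "Potassium": 1000, "Sodium": 17, "Total protein": 24},
    "1:3s N1": {
        "Albumin": 140, "AST": 363, "Calcium": 9, "Chloride": 33,
        "Cholesterol": 56, "Creatinine": 35, "HDL-cholesterol": 363,
        "Potassium": 363, "Sodium": 6, "Total protein": 9},
}

#: The laboratory's optimized MA procedure type per analyte.
MA_PROCEDURE_TYPES: dict[str, tuple[str, float]] = {
    "Albumin": ("simple_block", 10),
    "AST": ("simple_block", 100),
    "Calcium": ("simple_block", 10),
    "Chloride": ("simple_block", 10),
    "Cholesterol": ("simple_block", 25),
    "Creatinine": ("ewma", 0.1),
    "HDL-cholesterol": ("simple_block", 25),
    "Potassium": ("ewma", 0.1),
    "Sodium": ("simple_block", 25),
    "Total protein": ("ewma", 0.05),
}

#: Published number of patient results needed to detect a TEa-sized bias:
#: analyte -> {direction: (min, median, max)}.
_MA_DETECTION_RAW: dict[str, dict[str, tuple[int, int, int]]] = {
    "Albumin": {"negative": (6, 7, 13), "positive": (5, 7, 19)},
    "AST": {"negative": (20, 55, 120), "positive": (44, 77, 118)},
    "Calcium": {"negative": (6, 8, 10), "positive": (4, 10, 16)},
    "Chloride": {"negative": (4, 7, 17), "positive": (5, 8, 10)},
    "Cholesterol": {"negative": (14, 44, 134), "positive": (28, 65, 225)},
    "Creatinine": {"negative": (6, 20, 44), "positive": (27, 86, 360)},
    "HDL-cholesterol": {"negative": (14, 18, 24), "positive": (13, 18, 65)},
    "Potassium": {"negative": (4, 8, 13), "positive": (5, 9, 18)},
    "Sodium": {"negative": (11, 14, 18), "positive": (4, 7, 10)},
    "Total protein": {"negative": (8, 12, 17), "positive": (5, 9, 13)},
}

#: Synthetic adult-population parameters per analyte: lognormal median and
#: sigma-of-log (roughly the population CV).  NOT measured laboratory data.
STREAM_PARAMS: dict[str, tuple[float, float]] = {
    "Albumin": (42.0, 0.06),
    "AST": (22.0, 0.35),
    "Calcium": (2.38, 0.04),
    "Chloride": (103.0, 0.02),
    "Cholesterol": (5.2, 0.20),
    "Creatinine": (80.0, 0.22),
    "HDL-cholesterol": (1.4, 0.25),
    "Potassium": (4.4, 0.09),
    "Sodium": (140.0, 0.018),
    "Total protein": (72.0, 0.06),
}


def example_stream_spec(analyte: str, n_days: int = 1, seed: int = 0) -> StreamSpec:
    """Synthetic patient-stream spec for one panel analyte."""
    median, log_sigma = STREAM_PARAMS[analyte]
    return StreamSpec(
        analyte_name=analyte,
        distribution="lognormal",
        location=median,
        scale=log_sigma,
        daily_volume=DAILY_VOLUMES[analyte],
        n_days=n_days,
        seed=seed,
    )


def example_panel() -> list[AnalyteProfile]:
    """The 10-analyte worked-example panel as AnalyteProfile objects."""
    panel = []
    for name, (unit, volume, levels) in _PANEL_RAW.items():
        panel.append(
            AnalyteProfile(
                name=name,
                unit=unit,
                levels=tuple(QCLevel(t, tea, bias, cv) for t, tea, bias, cv in levels),
                daily_volume=volume,
                reporting_interval=volume,
                stream_spec=example_stream_spec(name),
            )
        )
    return panel


#: Alias kept close to the raw table for readers scanning the module.
PANEL = _PANEL_RAW


def published_run_size_matrix() -> dict[str, dict[str, int]]:
    """Copy of the published run-size matrix (procedure -> analyte -> n)."""
    return {proc: dict(row) for proc, row in RUN_SIZE_MATRIX.items()}


def published_ma_summaries() -> dict[str, dict[str, BiasDetectionSummary]]:
    """Published TEa-bias detection summaries as BiasDetectionSummary pairs.

    Signs follow the direction: negative-direction summaries carry a negative
    ``bias_percent`` (magnitude = the analyte's level-2 TEa).
    """
    out: dict[str, dict[str, BiasDetectionSummary]] = {}
    for analyte, dirs in _MA_DETECTION_RAW.items():
        tea = _PANEL_RAW[analyte][2][1][1]  # level-2 TEa (%)
        out[analyte] = {}
        for direction, (lo, med, hi) in dirs.items():
            sign = -1.0 if direction == "negative" else 1.0
            out[analyte][direction] = BiasDetectionSummary(
                bias_percent=sign * tea,
                n_iterations=0,
                detected_counts=(),
                min_count=lo,
                median_count=med,
                max_count=hi,
                censor_fraction=0.0,
            )
    return out


MA_DETECTION_SUMMARIES = _MA_DETECTION_RAW
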
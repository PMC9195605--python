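"""Plan assembly: categorization, procedure selection and MA integration,
including the full reproduction of the published 10-analyte plan."""

import pytest

import labqcplan as lq
from labqcplan.ma_pbrtqc import BiasDetectionSummary
from labqcplan.plan_builder import (
    QCPlanEntry,
    SigmaCategory,
    build_plan,
    categorize,
    integrate_ma,
    plan_to_markdown,
    select_monitor,
    select_startup,
)
from labqcplan.sigma_metrics import analyte_sigma

#: published plan: analytes whose monitor slot is the MA procedure alone
MA_ONLY = {"Albumin", "AST", "Chloride", "Cholesterol", "HDL-cholesterol", "Potassium"}
SUPPLEMENT = {"Calcium", "Creatinine", "Sodium", "Total protein"}


def summary(bias, lo, med, hi):
    return BiasDetectionSummary(
        bias_percent=bias, n_iterations=100, detected_counts=(),
        min_count=lo, median_count=med, max_count=hi, censor_fraction=0.0,
    )


class TestCategorize:
    @pytest.mark.parametrize(
        "sigma, label",
        [
            (5.51, "high"),
            (5.0, "high"),  # boundary is inclusive
            (4.79, "moderate"),
            (4.5, "moderate"),
            (4.09, "low"),
            (3.5, "low"),
            (3.49, "unacceptable"),
        ],
    )
    def test_bounds(self, sigma, label):
        assert categorize(sigma).label == label

    def test_bounds_partition_the_line(self):
        import numpy as np

        for sigma in np.arange(0.0, 8.0, 0.01):
            categorize(float(sigma))  # no gaps, no overlap errors


class TestSelectStartup:
    def test_published_matrix_selects_n3_multirule(
        self, candidates, published_run_sizes, panel
    ):
        volumes = {p.name: p.daily_volume for p in panel}
        proc = select_startup(candidates, published_run_sizes, volumes)
        assert proc.name == "1:3s/2of3:2s/3:1s N3"

    def test_without_sodium_the_simple_n3_rule_wins_on_pfr(
        self, candidates, published_run_sizes, panel
    ):
        volumes = {p.name: p.daily_volume for p in panel if p.name != "Sodium"}
        proc = select_startup(candidates, published_run_sizes, volumes)
        assert proc.name == "1:3s N3"
        assert proc.pfr_nominal == 0.01

    def test_infeasible_panel_reported(self, candidates):
        matrix = {name: {"X": 10} for name in lq.CANDIDATE_PROCEDURES}
        with pytest.raises(ValueError, match="X"):
            select_startup(candidates, matrix, {"X": 100})


class TestSelectMonitor:
    def test_published_matrix_selects_1_2s_n1(
        self, candidates, published_run_sizes, panel
    ):
        intervals = {p.name: p.interval for p in panel}
        proc = select_monitor(candidates, published_run_sizes, intervals)
        assert proc.name == "1:2s N1"

    def test_zero_tolerance_leaves_no_candidate(
        self, candidates, published_run_sizes, panel
    ):
        # sodium's run size (47) falls just short of its interval (50)
        intervals = {p.name: p.interval for p in panel}
        assert (
            select_monitor(candidates, published_run_sizes, intervals, tolerance=0.0)
            is None
        )

    def test_unit_interval_keeps_widest_admissible_rule(
        self, candidates, published_run_sizes, panel
    ):
        intervals = {p.name: 1 for p in panel}
        proc = select_monitor(candidates, published_run_sizes, intervals)
        assert proc.name == "1:2s N1"  # largest Pfr under the 0.05 ceiling


class TestIntegrateMA:
    def test_moderate_sigma_chloride_replaces_monitor(self):
        det = {"negative": summary(-5.0, 4, 7, 17), "positive": summary(5.0, 5, 8, 10)}
        assert integrate_ma(categorize(4.75), det, 50) == "replace_monitor"

    def test_moderate_sigma_creatinine_keeps_monitor(self):
        det = {
            "negative": summary(-15.0, 6, 20, 44),
            "positive": summary(15.0, 27, 86, 360),
        }
        assert integrate_ma(categorize(4.79), det, 120) == "supplement_monitor"

    def test_high_sigma_cholesterol_replaces_despite_slow_maximum(self):
        det = {
            "negative": summary(-10.0, 14, 44, 134),
            "positive": summary(10.0, 28, 65, 225),
        }
        assert integrate_ma(categorize(5.03), det, 120) == "replace_monitor"

    def test_low_sigma_always_supplements(self):
        det = {"negative": summary(-10.0, 1, 1, 1), "positive": summary(10.0, 1, 1, 1)}
        assert integrate_ma(categorize(4.0), det, 100) == "supplement_monitor"

    def test_missing_direction_rejected(self):
        with pytest.raises(ValueError):
            integrate_ma(categorize(5.5), {"negative": summary(-10, 1, 1, 1)}, 100)

    def test_censored_summary_never_replaces(self):
        censored = BiasDetectionSummary(
            bias_percent=10.0, n_iterations=100, detected_counts=(),
            min_count=None, median_count=None, max_count=None, censor_fraction=0.9,
        )
        det = {"negative": summary(-10, 1, 1, 1), "positive": censored}
        assert integrate_ma(categorize(5.5), det, 100) == "supplement_monitor"


class TestBuildPlan:
    def test_reproduces_published_plan_exactly(
        self, panel, published_run_sizes, published_ma, candidates
    ):
        entries, frame = build_plan(
            panel, published_run_sizes, published_ma, candidates
        )
        by_name = {e.analyte: e for e in entries}
        assert {e.analyte for e in entries if e.monitor_procedure == "MA"} == MA_ONLY
        for name in SUPPLEMENT:
            assert by_name[name].monitor_procedure == "1:2s N1 and MA"
        assert all(
            e.startup_procedure == "1:3s/2of3:2s/3:1s N3" for e in entries
        )
        assert sum(e.ma_role == "replace_monitor" for e in entries) == 6

    def test_plan_is_deterministic(
        self, panel, published_run_sizes, published_ma, candidates
    ):
        a, _ = build_plan(panel, published_run_sizes, published_ma, candidates)
        b, _ = build_plan(panel, published_run_sizes, published_ma, candidates)
        assert a == b

    def test_uniform_high_sigma_with_instant_ma_all_replace(
        self, make_flat_profile, published_run_sizes, candidates
    ):
        panel = [make_flat_profile(5.9)]
        panel[0] = panel[0].__class__(
            "Albumin", "", panel[0].levels, 30
        )  # reuse a matrix column
        ma = {"Albumin": {"negative": summary(-10, 1, 1, 1),
                          "positive": summary(10, 1, 1, 1)}}
        entries, _ = build_plan(panel, published_run_sizes, ma, candidates)
        assert entries[0].ma_role == "replace_monitor"

    def test_uniform_low_sigma_all_keep_monitor(
        self, make_flat_profile, published_run_sizes, candidates
    ):
        panel = [make_flat_profile(3.6)]
        panel[0] = panel[0].__class__("Albumin", "", panel[0].levels, 30)
        ma = {"Albumin": {"negative": summary(-10, 1, 1, 1),
                          "positive": summary(10, 1, 1, 1)}}
        entries, _ = build_plan(panel, published_run_sizes, ma, candidates)
        assert entries[0].ma_role == "supplement_monitor"
        assert "1:2s N1" in entries[0].monitor_procedure

    def test_better_ma_detection_never_demotes(
        self, panel, published_run_sizes, published_ma, candidates
    ):
        """Pointwise-faster detection keeps every replace_monitor decision."""
        faster = {
            analyte: {
                d: summary(s.bias_percent, 1, 1.0, 1) for d, s in dirs.items()
            }
            for analyte, dirs in published_ma.items()
        }
        base, _ = build_plan(panel, published_run_sizes, published_ma, candidates)
        improved, _ = build_plan(panel, published_run_sizes, faster, candidates)
        for b, i in zip(base, improved):
            if b.ma_role == "replace_monitor":
                assert i.ma_role == "replace_monitor"

    def test_markdown_layout_groups_monitor_rows(
        self, panel, published_run_sizes, published_ma, candidates
    ):
        entries, _ = build_plan(panel, published_run_sizes, published_ma, candidates)
        md = plan_to_markdown(entries)
        assert "| Albumin, AST, Chloride" in md
        # header + separator + one row per (startup, monitor) group
        assert len(md.splitlines()) == 4


class TestEntryInvariants:
    def test_replace_requires_ma_monitor(self):
        with pytest.raises(ValueError):
            QCPlanEntry(
                "x", SigmaCategory("high"), "1:3s N3", "1:2s N1",
                "replace_monitor", "",
            )

    def test_low_category_cannot_replace(self):
        with pytest.raises(ValueError):
            QCPlanEntry(
                "x", SigmaCategory("low"), "1:3s N3", "MA", "replace_monitor", ""
            )
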
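"""Moving-average engine: update rules against brute-force oracles,
control-limit calibration, and the bias-injection simulation."""

from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from labqcplan.ma_pbrtqc import (
    MAProcedure,
    MAState,
    bias_detection_curve,
    ma_update,
    optimize_procedure,
    run_stream,
    set_control_limits,
    simulate_bias_detection,
)
from labqcplan.synthetic_data import StreamSpec, gen_patient_stream


def replay(procedure, results):
    state = MAState()
    out = []
    for x in results:
        state, value, alarm = ma_update(procedure, state, x)
        out.append((value, alarm))
    return out


class TestMAUpdate:
    def test_simple_block_mean(self):
        proc = MAProcedure("simple_block", block_size=3)
        values = [v for v, _ in replay(proc, [1.0, 2.0, 3.0])]
        assert values == [None, None, 2.0]

    def test_ewma_unit_weight_tracks_latest(self):
        proc = MAProcedure("ewma", weighting_factor=1.0)
        values = [v for v, _ in replay(proc, [5.0, 7.0, 2.0])]
        assert values == [5.0, 7.0, 2.0]

    def test_ewma_recursion_step(self):
        proc = MAProcedure("ewma", weighting_factor=0.1)
        state = MAState(current_value=10.0, n_included=5)
        _, value, _ = ma_update(proc, state, 20.0)
        assert value == pytest.approx(11.0)

    def test_truncated_result_leaves_state_unchanged(self):
        proc = MAProcedure(
            "simple_block", block_size=2, truncation_limits=(0.0, 10.0),
            control_limits=(0.0, 10.0),
        )
        state = MAState()
        state, value, alarm = ma_update(proc, state, -5.0)
        assert state == MAState() and value is None and not alarm

    def test_alarm_outside_control_limits(self):
        proc = MAProcedure("ewma", weighting_factor=1.0, control_limits=(9.0, 11.0))
        _, _, alarm = ma_update(proc, MAState(), 12.0)
        assert alarm

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"ma_type": "simple_block"},  # missing block_size
            {"ma_type": "ewma"},  # missing weighting_factor
            {"ma_type": "simple_block", "block_size": 3, "weighting_factor": 0.1},
            {"ma_type": "ewma", "weighting_factor": 1.5},
            {"ma_type": "simple_block", "block_size": 3, "truncation_limits": (5, 5)},
        ],
    )
    def test_invalid_procedure_rejected(self, kwargs):
        with pytest.raises(ValueError):
            MAProcedure(**kwargs)


class TestOracleAgreement:
    @given(seed=st.integers(0, 50), block=st.integers(1, 12))
    @settings(max_examples=20, deadline=None)
    def test_simple_ma_equals_windowed_mean_of_included(self, seed, block):
        rng = np.random.default_rng(seed)
        results = rng.normal(10, 2, size=1000)
        proc = MAProcedure(
            "simple_block", block_size=block, truncation_limits=(7.0, 13.0)
        )
        included = []
        for x, (value, _) in zip(results, replay(proc, results)):
            if 7.0 <= x <= 13.0:
                included.append(x)
            if value is not None:
                assert value == pytest.approx(np.mean(included[-block:]))
            else:
                assert len(included) < block

    @given(seed=st.integers(0, 50), lam=st.floats(0.01, 1.0))
    @settings(max_examples=20, deadline=None)
    def test_ewma_matches_closed_form(self, seed, lam):
        """value_k = sum_i lam (1-lam)^(k-i) x_i + (1-lam)^(k-1) x_1."""
        rng = np.random.default_rng(seed)
        xs = rng.normal(0, 1, size=40)
        proc = MAProcedure("ewma", weighting_factor=lam)
        values = [v for v, _ in replay(proc, xs)]
        for k in range(1, len(xs) + 1):
            closed = xs[0] * (1 - lam) ** (k - 1) + sum(
                lam * (1 - lam) ** (k - i) * xs[i - 1] for i in range(2, k + 1)
            )
            assert values[k - 1] == pytest.approx(closed, rel=1e-9, abs=1e-12)


class TestControlLimits:
    def test_constant_baseline_collapses_with_margin(self):
        proc = MAProcedure("ewma", weighting_factor=0.2)
        calibrated = set_control_limits(proc, [5.0] * 200, margin=0.1)
        lo, hi = calibrated.control_limits
        assert lo < 5.0 < hi

    def test_replaying_calibration_baseline_gives_zero_alarms(self):
        spec = StreamSpec("x", 100.0, 0.05, daily_volume=50, n_days=5, seed=3)
        baseline = gen_patient_stream(spec)["value"].to_numpy()
        proc = set_control_limits(MAProcedure("simple_block", block_size=10), baseline)
        _, alarms = run_stream(proc, baseline)
        assert alarms.sum() == 0

    def test_short_baseline_rejected(self):
        with pytest.raises(ValueError):
            set_control_limits(MAProcedure("simple_block", block_size=10), [1.0] * 50)

    def test_false_alarm_rate_on_independent_baseline(self):
        """Extrema limits calibrated on 20 days keep the false-alarm rate at
        or below one per daily volume for >= 90% of seeds."""
        proc = MAProcedure("simple_block", block_size=10)
        ok = 0
        n_seeds = 100
        for seed in range(n_seeds):
            spec = StreamSpec("x", 100.0, 0.05, daily_volume=50, n_days=20, seed=seed)
            cal = gen_patient_stream(spec)["value"].to_numpy()
            p = set_control_limits(proc, cal)
            ind = gen_patient_stream(replace(spec, seed=seed + 10_000))["value"].to_numpy()
            _, alarms = run_stream(p, ind)
            if alarms.sum() / spec.n_days <= 1.0:
                ok += 1
        assert ok >= 0.9 * n_seeds


@pytest.fixture(scope="module")
def tight_setup():
    """Albumin-like stream with analytical-scale spread and a calibrated MA.

    The calibration baseline (50 days) is long relative to the detection
    horizon so the extrema limits are representative of the unbiased
    process.
    """
    spec = StreamSpec("alb", 42.0, 0.016, daily_volume=30, n_days=50, seed=1)
    baseline = gen_patient_stream(spec)["value"].to_numpy()
    proc = set_control_limits(MAProcedure("simple_block", block_size=10), baseline)
    return spec, proc


class TestBiasDetection:
    def test_zero_bias_rarely_detected(self, tight_setup):
        spec, proc = tight_setup
        summary = simulate_bias_detection(proc, spec, 0.0, n_iterations=40, seed=4)
        assert summary.censor_fraction >= 0.5
        assert summary.median_count is None

    def test_large_bias_detected_within_about_one_block(self, tight_setup):
        spec, proc = tight_setup
        summary = simulate_bias_detection(proc, spec, 50.0, n_iterations=60, seed=5)
        assert summary.censor_fraction == 0.0
        assert summary.median_count <= proc.block_size

    def test_median_non_increasing_in_bias_magnitude(self, tight_setup):
        spec, proc = tight_setup
        tea = 10.0
        medians = []
        for bias in (tea, 2 * tea, 50.0):
            s = simulate_bias_detection(proc, spec, bias, n_iterations=60, seed=6)
            assert s.median_count is not None
            medians.append(s.median_count)
        # allow one rank inversion (Monte-Carlo ties at fast detection)
        inversions = sum(b > a for a, b in zip(medians, medians[1:]))
        assert inversions <= 1

    def test_seeded_reproducibility(self, tight_setup):
        spec, proc = tight_setup
        a = simulate_bias_detection(proc, spec, -10.0, n_iterations=30, seed=9)
        b = simulate_bias_detection(proc, spec, -10.0, n_iterations=30, seed=9)
        assert a == b

    def test_missing_control_limits_rejected(self, tight_setup):
        spec, _ = tight_setup
        with pytest.raises(ValueError):
            simulate_bias_detection(
                MAProcedure("simple_block", block_size=10), spec, 10.0
            )


class TestDetectionCurve:
    def test_singleton_grid_equals_single_call(self, tight_setup):
        spec, proc = tight_setup
        curve = bias_detection_curve(proc, spec, [20.0], n_iterations=20, seed=3)
        single = simulate_bias_detection(proc, spec, 20.0, n_iterations=20, seed=3)
        assert curve == [single]

    def test_grid_must_contain_both_tea_directions(self, tight_setup):
        spec, proc = tight_setup
        with pytest.raises(ValueError):
            bias_detection_curve(
                proc, spec, [10.0, 20.0], tea_percent=10.0, n_iterations=5
            )

    def test_empty_grid_rejected(self, tight_setup):
        spec, proc = tight_setup
        with pytest.raises(ValueError):
            bias_detection_curve(proc, spec, [], n_iterations=5)


class TestOptimize:
    def test_single_candidate_wins_with_report(self):
        spec = StreamSpec("x", 100.0, 0.02, daily_volume=40, n_days=1, seed=2)
        cand = MAProcedure("simple_block", block_size=10)
        best, report = optimize_procedure(
            spec, [cand], tea_percent=10.0, n_iterations=30,
            calibration_days=5, seed=3,
        )
        assert best.block_size == 10
        assert best.control_limits is not None
        assert len(report) == 1
        assert report.attrs["selected"] == cand.label

    def test_small_block_beats_large_on_low_noise_stream(self):
        spec = StreamSpec("x", 100.0, 0.02, daily_volume=150, n_days=1, seed=4)
        cands = [
            MAProcedure("simple_block", block_size=10),
            MAProcedure("simple_block", block_size=100),
        ]
        best, report = optimize_procedure(
            spec, cands, tea_percent=10.0, n_iterations=30,
            calibration_days=20, seed=5,
        )
        assert best.block_size == 10
        assert bool(report["feasible"].any())

    def test_infeasible_flag_when_volume_is_one(self):
        spec = StreamSpec("x", 100.0, 0.02, daily_volume=40, n_days=1, seed=6)
        cand = MAProcedure("simple_block", block_size=10)
        best, report = optimize_procedure(
            spec, [cand], tea_percent=10.0, daily_volume=1,
            n_iterations=20, calibration_days=5, seed=7,
        )
        assert report.attrs["infeasible"]
        assert best is not None  # best-effort candidate still returned

    def test_empty_grid_rejected(self):
        spec = StreamSpec("x", 100.0, 0.02, daily_volume=40, n_days=1, seed=2)
        with pytest.raises(ValueError):
            optimize_procedure(spec, [], tea_percent=10.0)
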
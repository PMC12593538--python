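"""Sequential/joint ESS optimization, sweeps, and sign diagnosis."""

import numpy as np
import pytest

from smallfield import (
    DEFAULT_CANDIDATES_MM,
    ESSGridSpec,
    ESSPair,
    FOFGrid,
    NoiseModel,
    SweepTableEvaluator,
    SyntheticEvaluator,
    add_measurement_noise,
    optimize_joint,
    optimize_sequential,
    sign_diagnosis,
    simulate_fof_grid,
    sweep_extreme_fields,
    sweep_table,
)
from smallfield.optimize import OptimizationError


def as_measured(calc: FOFGrid) -> FOFGrid:
    return FOFGrid(
        calc.y_sides_cm, calc.x_sides_cm, calc.values, "measured",
        beam_quality=calc.beam_quality, msr_side_cm=calc.msr_side_cm,
    )


def synthetic_measurement(truth: ESSPair, seed: int | None = None) -> FOFGrid:
    calc = simulate_fof_grid(truth)
    if seed is None:
        return as_measured(calc)
    return add_measurement_noise(calc, NoiseModel(seed=seed))


@pytest.fixture(scope="module")
def benchmark_engine():
    return SweepTableEvaluator(sweep_table("4 x 0.5"), sweep_table("0.5 x 4"))


class TestSweep:
    def test_zero_difference_at_true_essx(self):
        truth = ESSPair(0.7, 0.7)
        engine = SyntheticEvaluator(synthetic_measurement(truth))
        sweep = sweep_extreme_fields(engine, ESSGridSpec(), "x", 0.7)
        diffs = {r.essx_mm: r.diff_4x05_pct for r in sweep.rows}
        assert diffs[0.7] == pytest.approx(0.0, abs=1e-9)
        # sign change across the truth: overestimation below, under above
        assert diffs[0.0] > 0 > diffs[1.5]

    def test_identical_engine_and_measurement_gives_all_zero(self):
        truth = ESSPair(0.5, 0.5)
        engine = SyntheticEvaluator(synthetic_measurement(truth))
        sweep = sweep_extreme_fields(engine, ESSGridSpec((0.5,) + (0.6,)), "y", 0.5)
        row = next(r for r in sweep.rows if r.essy_mm == 0.5)
        assert row.diff_4x05_pct == pytest.approx(0.0, abs=1e-9)
        assert row.diff_05x4_pct == pytest.approx(0.0, abs=1e-9)

    def test_benchmark_row_reproduced(self, benchmark_engine):
        # essx sweep at fixed essy = 0.7 replays the transcribed row
        sweep = sweep_extreme_fields(benchmark_engine, ESSGridSpec(), "x", 0.7)
        got = {r.essx_mm: r.diff_4x05_pct for r in sweep.rows if not r.failed}
        assert got == {
            0.0: 0.03, 0.5: 0.03, 0.6: 0.03, 0.7: 0.01,
            0.8: 0.01, 0.9: 0.01, 1.0: 0.02, 1.5: 0.07,
        }
        failed = [r.essx_mm for r in sweep.rows if r.failed]
        assert failed == [0.4]  # combination never swept in the benchmark

    def test_trace_is_replayable(self):
        engine = SyntheticEvaluator(synthetic_measurement(ESSPair(0.6, 0.9)))
        s1 = sweep_extreme_fields(engine, ESSGridSpec(), "x", 0.7)
        s2 = sweep_extreme_fields(engine, ESSGridSpec(), "x", 0.7)
        assert s1 == s2


class TestSequential:
    def test_recovers_noiseless_truth_off_start(self):
        truth = ESSPair(0.7, 0.8)
        result = optimize_sequential(SyntheticEvaluator(synthetic_measurement(truth)))
        assert result.essx_mm[0] <= 0.7 <= result.essx_mm[1]
        assert result.essy_mm[0] <= 0.8 <= result.essy_mm[1]
        # interval spans at most two adjacent candidates
        cands = list(DEFAULT_CANDIDATES_MM)
        for (lo, hi) in (result.essx_mm, result.essy_mm):
            assert cands.index(hi) - cands.index(lo) <= 1

    def test_perfect_model_at_zero_is_degenerate(self):
        result = optimize_sequential(SyntheticEvaluator(synthetic_measurement(ESSPair(0, 0))))
        assert result.essx_mm == (0.0, 0.0)
        assert result.essy_mm == (0.0, 0.0)
        assert result.residual_4x05_pct == pytest.approx(0.0, abs=1e-9)

    def test_noiseless_recovery_within_one_step_for_random_truths(self):
        rng = np.random.default_rng(2024)
        cands = list(DEFAULT_CANDIDATES_MM)
        for _ in range(10):
            truth = ESSPair(float(rng.choice(cands)), float(rng.choice(cands)))
            result = optimize_sequential(SyntheticEvaluator(synthetic_measurement(truth)))
            assert abs(cands.index(result.essx_best) - cands.index(truth.essx_mm)) <= 1
            assert abs(cands.index(result.essy_best) - cands.index(truth.essy_mm)) <= 1

    def test_benchmark_replay_contains_reported_interval(self, benchmark_engine):
        result = optimize_sequential(benchmark_engine)
        assert result.essx_mm[0] <= 0.7 and result.essx_mm[1] >= 0.8
        assert result.essy_mm[0] <= 0.7 and result.essy_mm[1] >= 0.8
        assert result.essx_best in (0.7, 0.8)
        assert result.essy_best in (0.7, 0.8)

    def test_trace_contains_optimum_and_both_sweeps(self):
        result = optimize_sequential(SyntheticEvaluator(synthetic_measurement(ESSPair(0.7, 0.7))))
        assert len(result.trace) == 2 * len(DEFAULT_CANDIDATES_MM)
        assert any(
            r.essx_mm == result.essx_best and r.essy_mm == result.essy_best
            for r in result.trace
        )


class _FailingEngine:
    def extreme_differences(self, ess):
        raise RuntimeError("engine unavailable")


class _ConstantEngine:
    def __init__(self, dx=0.0, dy=0.0):
        self.dx, self.dy = dx, dy

    def extreme_differences(self, ess):
        return self.dx, self.dy


class _PlateauEngine:
    """Engine whose output is identical at 0.7 and 0.8 mm (quantized model)."""

    def __init__(self, inner):
        self.inner = inner

    def extreme_differences(self, ess):
        snap = lambda v: 0.7 if v in (0.7, 0.8) else v
        return self.inner.extreme_differences(ESSPair(snap(ess.essx_mm), snap(ess.essy_mm)))


class TestJointAndEdgeCases:
    def test_all_candidates_failing_is_an_error(self):
        with pytest.raises(OptimizationError):
            optimize_sequential(_FailingEngine())

    def test_joint_agrees_with_sequential_noiseless(self):
        truth = ESSPair(0.8, 0.6)
        engine = SyntheticEvaluator(synthetic_measurement(truth))
        seq = optimize_sequential(engine)
        joint = optimize_joint(engine, objective="max_abs")
        assert joint.essx_best == seq.essx_best
        assert joint.essy_best == seq.essy_best

    def test_joint_never_worse_than_sequential(self):
        engine = SyntheticEvaluator(synthetic_measurement(ESSPair(0.6, 0.9), seed=11))
        spec = ESSGridSpec()
        seq = optimize_sequential(engine, spec)
        joint = optimize_joint(engine, spec, objective="max_abs")
        worst = lambda r: max(abs(r.residual_4x05_pct), abs(r.residual_05x4_pct))
        assert worst(joint) <= worst(seq) + spec.tie_tolerance_pct

    def test_all_zero_objective_is_fully_degenerate(self, caplog):
        with caplog.at_level("WARNING"):
            result = optimize_joint(_ConstantEngine(), ESSGridSpec())
        assert result.essx_mm == (DEFAULT_CANDIDATES_MM[0], DEFAULT_CANDIDATES_MM[-1])
        assert result.essy_mm == (DEFAULT_CANDIDATES_MM[0], DEFAULT_CANDIDATES_MM[-1])
        assert any("degenerate" in r.message for r in caplog.records)

    def test_plateau_pairs_reported_in_interval(self):
        inner = SyntheticEvaluator(synthetic_measurement(ESSPair(0.7, 0.7)))
        result = optimize_sequential(_PlateauEngine(inner))
        assert result.essx_mm == (0.7, 0.8)
        assert result.essy_mm == (0.7, 0.8)


class TestSignDiagnosis:
    def test_noiseless_synthetic_sweep_is_monotone(self):
        engine = SyntheticEvaluator(synthetic_measurement(ESSPair(0.7, 0.7)))
        sweep = sweep_extreme_fields(engine, ESSGridSpec(), "x", 0.7)
        report = sign_diagnosis(sweep)
        assert report.monotone
        labels = dict(report.labels)
        assert labels[0.0] == "below" and labels[1.5] == "above"

    def test_benchmark_essx_sweep_for_y05x4_field(self, benchmark_engine):
        # difference falls from +2.65% (essx=0) to -11.29% (essx=1.5)
        sweep = sweep_extreme_fields(benchmark_engine, ESSGridSpec(), "x", 0.7)
        report = sign_diagnosis(sweep, checked_field="0.5 x 4")
        assert report.monotone
        values = dict((v, d) for v, d in report.labels)
        assert values[0.0] == "below" and values[1.5] == "above"

    def test_noisy_violations_listed_not_fatal(self):
        engine = SyntheticEvaluator(synthetic_measurement(ESSPair(0.7, 0.7), seed=5))
        sweep = sweep_extreme_fields(engine, ESSGridSpec(), "x", 0.7)
        report = sign_diagnosis(sweep)
        assert isinstance(report.violations, tuple)  # report-only, never raises
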
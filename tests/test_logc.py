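"""Cadence-dependent threshold, LOGC timing, aggregation and refitting."""

import numpy as np
import pytest

from racewalk import (
    DomainError,
    FitError,
    InertialConfig,
    InsufficientStepsError,
    LOGCStep,
    StepEvents,
    ThresholdModel,
    aggregate_sequences,
    fit_threshold_model,
    variable_threshold,
    logc_timing,
)
from conftest import true_threshold


class TestVariableThreshold:
    def test_zero_crossing_at_minus_a_over_b(self, model):
        root = -model.a / model.b  # 3.6400...
        assert variable_threshold(root, model) == pytest.approx(0.0, abs=1e-12)

    def test_direct_evaluation(self, model):
        assert variable_threshold(3.10, model) == pytest.approx(0.0409, abs=5e-5)
        assert variable_threshold(2.8, model) == pytest.approx(0.0575, abs=5e-5)

    def test_negative_raw_value_clamped(self, model):
        assert variable_threshold(3.90, model) == 0.0

    def test_out_of_range_cadence_clamped_with_warning(self, model):
        with pytest.warns(UserWarning):
            e = variable_threshold(2.5, model)
        assert e == variable_threshold(2.8, model)

    def test_nonpositive_cadence_rejected(self, model):
        with pytest.raises(DomainError):
            variable_threshold(0.0, model)

    def test_monotone_nonincreasing_on_valid_range(self, model):
        sc = np.linspace(2.8, 4.0, 200)
        e = variable_threshold(sc, model)
        assert np.all(np.diff(e) <= 1e-15)
        np.testing.assert_allclose(e, true_threshold(sc), atol=1e-15)


def _events_single(tmax0, tmin0, tmax1):
    return StepEvents(
        tmax=np.array([tmax0, tmax1]),
        tmin=np.array([tmin0]),
        i_max=np.array([0, 1]),
        i_min=np.array([0]),
        kept=np.array([True]),
    )


class TestLogcTiming:
    def test_worked_example(self, model, cfg):
        # SC = 3.10 steps/s, NPVA at 1.000 s, next MAPA at 1.065 s
        step_time = 1.0 / 3.10
        ev = _events_single(1.065 - step_time, 1.000, 1.065)
        (s,) = logc_timing(ev, model, cfg)
        assert s.LOGCT == pytest.approx(0.065 - 0.0409, abs=5e-5)  # ~0.0241
        assert s.LOGCT_min == pytest.approx(s.LOGCT - 0.010)
        assert s.LOGCT_max == pytest.approx(s.LOGCT + 0.010)
        assert s.LOGCT_max - s.LOGCT_min == pytest.approx(4.0 / cfg.f)

    def test_interval_equal_to_threshold_is_double_support(self, model, cfg):
        sc = 3.10
        e = variable_threshold(sc, model)
        step_time = 1.0 / sc
        ev = _events_single(1.0 - step_time, 1.0 - e, 1.0)
        (s,) = logc_timing(ev, model, cfg)
        assert s.LOGCT == pytest.approx(0.0, abs=1e-12)
        # exactly zero timing marks double support (no LOGC event)
        assert LOGCStep(step=0, SC=sc, E=e, LOGCT=0.0, LOGCT_min=-0.01, LOGCT_max=0.01).double_support

    def test_interval_below_threshold_is_double_support(self, model, cfg):
        sc = 3.10
        e = variable_threshold(sc, model)
        ev = _events_single(1.0 - 1.0 / sc, 1.0 - e + 0.002, 1.0)
        (s,) = logc_timing(ev, model, cfg)
        assert s.LOGCT < 0 and s.double_support

    def test_flagged_steps_excluded(self, model, cfg):
        ev = StepEvents(
            tmax=np.array([0.0, 0.31, 0.62]),
            tmin=np.array([0.25, 0.56]),
            i_max=np.array([0, 62, 124]),
            i_min=np.array([50, 112]),
            kept=np.array([True, False]),
        )
        steps = logc_timing(ev, model, cfg)
        assert [s.step for s in steps] == [0]


def _mk_steps(values):
    return [
        LOGCStep(step=i, SC=3.2, E=0.03, LOGCT=v, LOGCT_min=v - 0.01, LOGCT_max=v + 0.01)
        for i, v in enumerate(values)
    ]


class TestAggregateSequences:
    def test_constant_steps(self, cfg):
        seqs = aggregate_sequences(_mk_steps([0.045] * 60), cfg)
        assert len(seqs) == 2
        assert all(s.LOGCT_S == pytest.approx(0.045) for s in seqs)

    def test_alternating_mean(self, cfg):
        seqs = aggregate_sequences(_mk_steps([0.020, 0.060] * 15), cfg)
        assert seqs[0].LOGCT_S == pytest.approx(0.040)

    def test_remainder_dropped_with_warning(self, cfg):
        with pytest.warns(UserWarning, match="trailing"):
            seqs = aggregate_sequences(_mk_steps([0.04] * 75), cfg)
        assert len(seqs) == 2

    def test_mean_equals_stepwise_mean(self, cfg):
        rng = np.random.default_rng(3)
        vals = rng.normal(0.04, 0.01, 30)
        (seq,) = aggregate_sequences(_mk_steps(vals), cfg)
        assert seq.LOGCT_S == pytest.approx(vals.mean(), abs=1e-12)

    def test_too_few_steps_rejected(self, cfg):
        with pytest.raises(InsufficientStepsError):
            aggregate_sequences(_mk_steps([0.04] * 29), cfg)

    def test_double_support_contributes_negative_value(self, cfg):
        vals = [-0.005] * 15 + [0.045] * 15
        (seq,) = aggregate_sequences(_mk_steps(vals), cfg)
        assert seq.LOGCT_S == pytest.approx(0.020)


class TestFitThresholdModel:
    def test_noiseless_parameter_recovery(self):
        rng = np.random.default_rng(7)
        sc = rng.uniform(2.8, 4.0, 700)
        ot = true_threshold_raw(sc)
        fit = fit_threshold_model(ot, sc)
        assert fit.a == pytest.approx(-40.921, abs=1e-6)
        assert fit.b == pytest.approx(11.242, abs=1e-6)
        assert fit.r_squared == pytest.approx(100.0, abs=1e-6)

    def test_exclusion_reasons(self):
        rng = np.random.default_rng(5)
        sc = rng.uniform(2.9, 3.5, 50)
        ot = true_threshold_raw(sc)
        sc = np.append(sc, [2.5, 3.0])
        ot = np.append(ot, [0.05, -0.01])
        fit = fit_threshold_model(ot, sc)
        reasons = dict(zip(fit.excluded["index"], fit.excluded["reason"]))
        assert reasons[50] == "cadence-range"
        assert reasons[51] == "negative-OT"

    def test_noisy_recovery_within_10pct(self):
        rng = np.random.default_rng(11)
        sc = rng.uniform(2.8, 3.6, 700)
        ot = true_threshold_raw(sc) + rng.normal(0, 0.008, 700)
        fit = fit_threshold_model(ot, sc)
        assert fit.a == pytest.approx(-40.921, rel=0.10)
        assert fit.b == pytest.approx(11.242, rel=0.10)
        assert 0.0 <= fit.r_squared <= 100.0
        assert 0.0 <= fit.r_squared_robust <= 100.0

    def test_degenerate_design_rejected(self):
        with pytest.raises(FitError):
            fit_threshold_model(np.full(20, 0.03), np.full(20, 3.2))

    def test_too_few_points_rejected(self):
        with pytest.raises(FitError):
            fit_threshold_model(np.array([0.03] * 5), np.array([3.0, 3.1, 3.2, 3.3, 3.4]))


def true_threshold_raw(sc):
    """Generating quadratic without the non-negativity clamp."""
    return sc**2 / -40.921 + sc / 11.242


class TestThresholdModelIO:
    def test_json_round_trip(self, tmp_path, model):
        p = tmp_path / "model.json"
        model.to_json(p)
        assert ThresholdModel.from_json(p) == model
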
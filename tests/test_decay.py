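import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import lesionkinetics as lk
from lesionkinetics.decay import (
    PHASE_RAPID,
    PHASE_SLOW,
    derivative_curve,
    partition_at_boundary,
)
from lesionkinetics.errors import (
    DegenerateFitError,
    FitInputError,
    ModelError,
    NoRiseError,
)

TIMES = [10.0, 20.0, 30.0, 40.0, 50.0, 60.0]


def fit_for(ymax, k):
    y = ymax * -np.expm1(-k * np.asarray(TIMES))
    return lk.fit_one_phase(TIMES, y)


class TestDerivativeCurve:
    def test_analytic_value_at_zero(self):
        t, d = derivative_curve(fit_for(5.0, 0.1))
        assert t[0] == 0.0
        assert d[0] == pytest.approx(0.5, rel=1e-9)

    def test_strictly_decreasing_for_one_phase(self):
        _, d = derivative_curve(fit_for(5.0, 0.1))
        assert np.all(np.diff(d) < 0)

    def test_linear_fit_gives_constant_slope(self):
        fit = lk.fit_linear(TIMES, [2 * t for t in TIMES])
        _, d = derivative_curve(fit)
        assert np.allclose(d, 2.0)

    def test_degenerate_fit_refused(self):
        fit = lk.fit_one_phase(TIMES, [0.0] * 6)
        with pytest.raises(DegenerateFitError):
            derivative_curve(fit)


class TestTimeTo90Decay:
    def test_printed_decay_time(self):
        k = math.log(10) / 46.9
        res = lk.time_to_90_decay(fit_for(120.0, k))
        assert res.t90 == pytest.approx(46.9, rel=1e-9)
        assert res.t_peak == 0.0
        assert res.peak_rate == pytest.approx(120.0 * k, rel=1e-9)

    def test_unit_rate(self):
        res = lk.time_to_90_decay(fit_for(5.0, 1.0))
        assert res.t90 == pytest.approx(math.log(10), rel=1e-6)

    def test_numeric_grid_matches_closed_form(self):
        for k in np.arange(0.02, 0.51, 0.04):
            fit = fit_for(7.0, float(k))
            cf = lk.time_to_90_decay(fit, method="closed_form")
            ng = lk.time_to_90_decay(fit, method="numeric_grid", grid_step=0.05)
            assert abs(ng.t90 - cf.t90) <= 0.05 + 1e-12

    def test_linear_model_refused(self):
        fit = lk.fit_linear(TIMES, [2 * t for t in TIMES])
        with pytest.raises(ModelError, match="non-saturating"):
            lk.time_to_90_decay(fit)

    def test_degenerate_refused(self):
        fit = lk.fit_one_phase(TIMES, [0.0] * 6)
        with pytest.raises(DegenerateFitError):
            lk.time_to_90_decay(fit)

    def test_unknown_method(self):
        with pytest.raises(ValueError):
            lk.time_to_90_decay(fit_for(5, 0.1), method="nope")

    @settings(max_examples=30, deadline=None)
    @given(k=st.floats(0.02, 0.5), ymax=st.floats(1.0, 200.0))
    def test_closed_vs_numeric_property(self, k, ymax):
        fit = fit_for(ymax, k)
        cf = lk.time_to_90_decay(fit, method="closed_form")
        ng = lk.time_to_90_decay(fit, method="numeric_grid", grid_step=0.05)
        assert abs(ng.t90 - cf.t90) <= 0.05 + 1e-12

    @settings(max_examples=30, deadline=None)
    @given(ymax=st.floats(0.5, 500.0))
    def test_t90_invariant_to_plateau(self, ymax):
        k = 0.08
        assert lk.time_to_90_decay(fit_for(ymax, k)).t90 == pytest.approx(
            math.log(10) / k, rel=1e-6
        )


class TestEmpiricalDecay:
    def test_noiseless_trace_matches_closed_form(self):
        k = 0.0491
        truth = lk.ResponseTruth(ymax=100.0, k=k, noise_sd=0.0)
        trace = lk.simulate_li_trace(truth, duration=60.0, rate=10.0, seed=0)
        res = lk.time_to_90_decay_empirical(trace)
        assert res.crossed
        assert res.t90 == pytest.approx(math.log(10) / k, abs=0.5)

    def test_consistency_over_sampling_rates(self):
        k = 0.08
        truth = lk.ResponseTruth(ymax=50.0, k=k, noise_sd=0.0)
        target = math.log(10) / k
        for rate, tol in ((1.0, 1.0), (10.0, 0.5), (100.0, 0.5)):
            trace = lk.simulate_li_trace(truth, duration=45.0, rate=rate, seed=0)
            res = lk.time_to_90_decay_empirical(trace)
            assert abs(res.t90 - target) <= tol

    def test_linear_trace_reports_absent_crossing(self):
        t = np.arange(0, 30.1, 0.5)
        trace = lk.LiTrace(times=tuple(t), li_values=tuple(2.0 * t))
        res = lk.time_to_90_decay_empirical(trace)
        assert not res.crossed and res.t90 is None

    def test_constant_trace_raises_no_rise(self):
        t = np.arange(0, 30.1, 0.5)
        trace = lk.LiTrace(times=tuple(t), li_values=tuple(np.full(t.size, 3.0)))
        with pytest.raises(NoRiseError, match="no rise detected"):
            lk.time_to_90_decay_empirical(trace)

    def test_short_trace_rejected(self):
        t = np.arange(0, 3.0, 0.5)
        trace = lk.LiTrace(times=tuple(t), li_values=tuple(t))
        with pytest.raises(FitInputError):
            lk.time_to_90_decay_empirical(trace)

    def test_noisy_trace_recovers_decay_time(self):
        k = 0.06
        truth = lk.ResponseTruth(ymax=100.0, k=k, noise_sd=1.0)
        trace = lk.simulate_li_trace(truth, duration=60.0, rate=10.0, seed=3)
        # first-crossing under derivative noise biases early; a window wide
        # relative to the noise keeps the estimate within ~15%
        res = lk.time_to_90_decay_empirical(trace, smoothing_window=10.0)
        assert res.crossed
        assert res.t90 == pytest.approx(math.log(10) / k, rel=0.15)

    def test_from_peak_flag(self):
        k = 0.0491
        truth = lk.ResponseTruth(ymax=100.0, k=k, noise_sd=0.0)
        trace = lk.simulate_li_trace(truth, duration=60.0, rate=10.0)
        absolute = lk.time_to_90_decay_empirical(trace, from_peak=False)
        relative = lk.time_to_90_decay_empirical(trace, from_peak=True)
        assert relative.t90 == pytest.approx(
            absolute.t90 - absolute.t_peak, abs=1e-9
        )


class TestPhasePartition:
    def test_boundary_from_printed_value(self):
        k = math.log(10) / 46.9
        part = lk.phase_partition(fit_for(120.0, k), [30.0, 60.0])
        assert part.boundary == pytest.approx(46.9, rel=1e-9)
        assert part.labels == (PHASE_RAPID, PHASE_SLOW)

    def test_tie_is_slow(self):
        part = partition_at_boundary(46.9, [46.9])
        assert part.labels == (PHASE_SLOW,)

    def test_late_time_slow_for_fast_setting(self):
        part = partition_at_boundary(24.5, [60.0])
        assert part.labels == (PHASE_SLOW,)

    def test_labels_follow_boundary_rule(self):
        part = partition_at_boundary(10.0, np.arange(0.0, 20.0, 1.0))
        for t, lab in zip(part.times, part.labels):
            assert lab == (PHASE_RAPID if t < 10.0 else PHASE_SLOW)
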
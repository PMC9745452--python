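import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import lesionkinetics as lk
from lesionkinetics import reference
from lesionkinetics.errors import CalibrationError, ConfigError


class TestTruthFromDecayTime:
    def test_printed_li_drop_calibration(self):
        truth = lk.truth_from_decay_time(46.9, ymax=120.0)
        assert truth.k == pytest.approx(math.log(10) / 46.9, rel=1e-12)
        assert truth.k == pytest.approx(0.04910, abs=5e-6)

    def test_anchor_solves_plateau(self):
        truth = lk.truth_from_decay_time(37.0, anchor=(25.9, 4.0))
        assert truth.ymax == pytest.approx(5.00, abs=0.005)

    def test_unit_decay_time(self):
        truth = lk.truth_from_decay_time(math.log(10))
        assert truth.k == pytest.approx(1.0, rel=1e-12)

    def test_round_trip_t90(self):
        truth = lk.truth_from_decay_time(33.3, ymax=7.0)
        assert truth.t90 == pytest.approx(33.3, rel=1e-12)

    def test_invalid_inputs(self):
        with pytest.raises(CalibrationError):
            lk.truth_from_decay_time(0.0)
        with pytest.raises(CalibrationError):
            lk.truth_from_decay_time(30.0, anchor=(-1.0, 4.0))

    def test_noise_exclusivity(self):
        with pytest.raises(ConfigError):
            lk.ResponseTruth(ymax=1, k=1, noise_sd=0.1, noise_cv=0.1)
        with pytest.raises(ConfigError):
            lk.ResponseTruth(ymax=1, k=1)


class TestSimulateExperiment:
    def test_noiseless_records_on_truth_curve(self, noiseless_config,
                                              noiseless_records):
        for rec in noiseless_records[:50]:
            key = (rec.setting.power_w, rec.setting.cf_g)
            truth = noiseless_config.truths[(*key, "depth")]
            assert rec.geometry.a == pytest.approx(
                truth.mean_at(rec.duration_s), rel=1e-12
            )
            li_truth = noiseless_config.truths[(*key, "li_drop")]
            assert rec.li_drop_ohm == pytest.approx(
                li_truth.mean_at(rec.duration_s), rel=1e-12
            )

    def test_design_shape(self, noiseless_records):
        # 40 W: 6 times x 3 CF x 10; 50 W: 7 times x 3 CF x 10
        assert len(noiseless_records) == (6 + 7) * 3 * 10
        reps = {(r.setting.power_w, r.setting.cf_g, r.duration_s, r.replicate)
                for r in noiseless_records}
        assert len(reps) == len(noiseless_records)

    def test_determinism(self):
        cfg = lk.reference_config()
        a = lk.simulate_experiment(cfg, seed=99)
        b = lk.simulate_experiment(cfg, seed=99)
        assert a == b

    def test_different_seeds_differ(self):
        cfg = lk.reference_config()
        a = lk.simulate_experiment(cfg, seed=1)
        b = lk.simulate_experiment(cfg, seed=2)
        assert a != b

    def test_adding_cells_preserves_existing_streams(self):
        cfg = lk.reference_config()
        full = lk.simulate_experiment(cfg, seed=5)
        # restrict the design to 40 W only: shared cells must be identical
        truths40 = {k: v for k, v in cfg.truths.items() if k[0] == 40.0}
        small_cfg = lk.ExperimentConfig(
            times_by_power={40.0: cfg.times_by_power[40.0]},
            forces=cfg.forces, n_per_cell=cfg.n_per_cell,
            truths=truths40, pop_models={40.0: cfg.pop_models[40.0]},
            seed=cfg.seed,
        )
        small = lk.simulate_experiment(small_cfg, seed=5)
        full40 = [r for r in full if r.setting.power_w == 40.0]
        assert small == full40

    def test_geometry_coupling(self, noiseless_records):
        for rec in noiseless_records[:30]:
            assert rec.geometry.c == pytest.approx(0.5 * rec.geometry.a, rel=1e-12)
            assert rec.geometry.d == pytest.approx(0.8 * rec.geometry.b, rel=1e-12)

    def test_all_responses_nonnegative(self, noisy_records):
        for rec in noisy_records:
            assert rec.li_drop_ohm >= 0
            assert rec.geometry.a >= 0 and rec.geometry.b >= 0


class TestSimulateLiTrace:
    def test_noiseless_value_at_decay_time(self):
        truth = lk.ResponseTruth(ymax=100.0, k=0.1, noise_sd=0.0)
        trace = lk.simulate_li_trace(truth, duration=40.0, rate=10.0)
        t90 = math.log(10) / 0.1
        idx = int(round(t90 * 10))
        assert trace.li_values[idx] == pytest.approx(90.0, abs=0.05)

    def test_sample_count(self):
        truth = lk.ResponseTruth(ymax=100.0, k=0.1, noise_sd=0.0)
        trace = lk.simulate_li_trace(truth, duration=60.0, rate=10.0)
        assert len(trace.times) == 601

    def test_seed_determinism(self):
        truth = lk.ResponseTruth(ymax=100.0, k=0.1, noise_sd=2.0)
        a = lk.simulate_li_trace(truth, duration=30.0, rate=10.0, seed=4)
        b = lk.simulate_li_trace(truth, duration=30.0, rate=10.0, seed=4)
        assert a == b

    def test_rate_below_one_rejected(self):
        truth = lk.ResponseTruth(ymax=100.0, k=0.1, noise_sd=0.0)
        with pytest.raises(ConfigError):
            lk.simulate_li_trace(truth, duration=30.0, rate=0.5)


class TestPopProbability:
    def test_zero_slope_constant(self):
        models = {40.0: lk.PopModel(intercept=0.0, slope=0.0)}
        assert lk.pop_probability(40.0, 0.0, models) == 0.5
        assert lk.pop_probability(40.0, 100.0, models) == 0.5

    def test_no_pop_regime(self):
        models = {40.0: lk.PopModel(intercept=-20.0, slope=0.0)}
        assert lk.pop_probability(40.0, 60.0, models) < 1e-8

    def test_logistic_midpoint(self):
        models = {50.0: lk.PopModel(intercept=-4.0, slope=0.05)}
        assert lk.pop_probability(50.0, 80.0, models) == pytest.approx(0.5)

    def test_monotone_in_time(self):
        model = reference.DEFAULT_POP_MODELS[50.0]
        probs = [model.probability(t) for t in range(0, 100, 5)]
        assert all(b >= a for a, b in zip(probs, probs[1:]))

    def test_high_power_dominates(self):
        lo = reference.DEFAULT_POP_MODELS[40.0]
        hi = reference.DEFAULT_POP_MODELS[50.0]
        for t in np.arange(0.0, 120.0, 2.5):
            assert hi.probability(t) > lo.probability(t)

    def test_pop_trend_positive_at_design_n(self):
        # generator power check: positive-slope pop model must yield a
        # positive trend Z in the typical experiment
        cfg = lk.reference_config()
        zs = []
        for seed in range(20):
            recs = lk.simulate_experiment(cfg, seed=seed)
            recs50 = [r for r in recs if r.setting.power_w == 50.0]
            times = sorted({r.duration_s for r in recs50})
            succ = [sum(r.steam_pop for r in recs50 if r.duration_s == t)
                    for t in times]
            tot = [sum(1 for r in recs50 if r.duration_s == t) for t in times]
            try:
                res = lk.cochran_armitage_trend(succ, tot, scores=times)
                zs.append(res.z_statistic)
            except Exception:
                continue
        assert np.mean(zs) > 0.5


class TestCalibrationRoundTrip:
    @pytest.mark.parametrize("response,table", [
        ("li_drop", reference.REFERENCE_T90_LI_DROP_S),
        ("depth", reference.REFERENCE_T90_DEPTH_S),
        ("diameter", reference.REFERENCE_T90_DIAMETER_S),
    ])
    def test_noiseless_fit_returns_calibrating_t90(self, response, table,
                                                   noiseless_config,
                                                   noiseless_records):
        from lesionkinetics.inference import RESPONSE_GETTERS
        getter = RESPONSE_GETTERS[response]
        for (power, cf), t90 in table.items():
            sub = [r for r in noiseless_records
                   if r.setting.power_w == power and r.setting.cf_g == cf]
            fit = lk.fit_one_phase([r.duration_s for r in sub],
                                   [getter(r) for r in sub])
            res = lk.time_to_90_decay(fit)
            assert res.t90 == pytest.approx(t90, rel=1e-6)
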
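"""Virtual endotoxemia experiment: truth trajectory, breaths, measurements."""

import numpy as np
import pandas as pd
import pytest
from dataclasses import replace

import capnosvo as c
from capnosvo.physiology import odc_po2, oxygen_content
from capnosvo.simulate import (
    DEFAULT_SAMPLING_PLAN,
    MeasurementModel,
    ScenarioEvent,
    ScenarioParams,
    default_protocol,
    run_scenario,
    sample_measurements,
    synthesize_breaths,
)


class TestRunScenario:
    def test_empty_event_list_is_constant_baseline(self, steady_truth):
        assert steady_truth.svo2_true_pct.nunique() == 1
        assert steady_truth.cardiac_output_lpm.nunique() == 1

    def test_fick_self_consistency_of_every_state(self):
        p = ScenarioParams()
        truth = run_scenario(default_protocol(p), p, duration_s=19500.0)
        sub = truth.iloc[::97]  # every ~100 s
        s = sub.svo2_true_pct.to_numpy() / 100.0
        hb = sub.hb_gl.to_numpy()
        # venous content recomputed from the emitted saturation
        cvo2_from_s = oxygen_content(hb, s, odc_po2(np.clip(s, 1e-9, 1 - 1e-9)))
        np.testing.assert_allclose(cvo2_from_s, sub.cvo2_mll, atol=1e-8)
        # differential Fick balance
        np.testing.assert_allclose(
            sub.cvo2_mll, sub.cco2_mll - sub.vo2_mlpm / sub.epbf_lpm, atol=1e-8
        )
        # venous admixture identity: CaO2 = (1-sh)*Cc + sh*Cv and
        # Cv = CaO2 - VO2/CO reproduce the same venous content
        sh = sub.shunt_fraction.to_numpy()
        cao2 = (1 - sh) * sub.cco2_mll + sh * sub.cvo2_mll
        np.testing.assert_allclose(
            sub.cvo2_mll, cao2 - sub.vo2_mlpm / sub.cardiac_output_lpm, atol=1e-8
        )

    def test_hemorrhage_monotonically_lowers_svo2(self):
        p = ScenarioParams()
        truth = run_scenario([ScenarioEvent(300.0, "hemorrhage", 15.0)], p, duration_s=1200.0)
        seg = truth[(truth.t_s > 300) & (truth.t_s < 900)]
        assert np.all(np.diff(seg.svo2_true_pct) < 1e-12)
        assert seg.svo2_true_pct.iloc[-1] < truth.svo2_true_pct.iloc[0] - 5

    def test_fio2_step_raises_svo2(self):
        p = ScenarioParams()
        truth = run_scenario([ScenarioEvent(300.0, "fio2_step", 1.0)], p, duration_s=900.0)
        assert truth.svo2_true_pct.iloc[-1] > truth.svo2_true_pct.iloc[0] + 3

    def test_protocol_sign_pattern_matches_expected_directions(self):
        p = ScenarioParams()
        truth = run_scenario(default_protocol(p), p, duration_s=19500.0)
        at = lambda t: float(truth.svo2_true_pct.iloc[int(t)])
        slots = dict(DEFAULT_SAMPLING_PLAN)
        assert at(slots["sepsis_60"]) < at(slots["induction_bl"])  # LPS decline
        assert at(slots["bolus_post"]) < at(slots["bolus_pre"])  # slight decrease
        assert at(slots["fio2_1.0"]) > at(slots["fio2_0.3"])
        assert at(slots["peep_15"]) < at(slots["peep_baseline"])
        assert at(slots["dobutamine_post"]) > at(slots["dobutamine_pre"])
        assert at(slots["hemorrhage_post"]) < at(slots["hemorrhage_pre"])
        assert at(slots["retransfusion_post"]) > at(slots["retransfusion_pre"])

    def test_overlapping_events_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            run_scenario(
                [ScenarioEvent(10.0, "fio2_step", 0.5), ScenarioEvent(10.0, "peep_step", 10.0)],
                duration_s=100.0,
            )


class TestSynthesizeBreaths:
    def test_cycle_mean_elimination_matches_metabolism(self, steady_breaths):
        p = ScenarioParams()
        cyc = steady_breaths.iloc[27:36]  # one settled full cycle
        vco2 = cyc.vtco2_ml.sum() / cyc.duration_s.sum() * 60.0
        assert vco2 == pytest.approx(p.vo2_mlpm * 0.97, rel=0.01)

    def test_pause_breaths_have_higher_end_tidal_co2(self, steady_breaths):
        settled = steady_breaths.iloc[18:45]
        pause = settled[settled.breath_type == "pause"].fet_co2.mean()
        normal = settled[settled.breath_type == "normal"].fet_co2.mean()
        assert pause > normal

    def test_epbf_recovery_within_two_percent(self, steady_truth, steady_breaths):
        fit = c.estimate_epbf_series(steady_breaths)
        assert fit.epbf_lpm.dropna().iloc[-1] == pytest.approx(
            steady_truth.epbf_lpm.iloc[0], rel=0.02
        )

    def test_doubling_epbf_doubles_recovered_estimate(self):
        p = ScenarioParams()
        rec = []
        for factor in (1.0, 2.0):
            pi = replace(p, cardiac_output_lpm=p.cardiac_output_lpm * factor)
            truth = run_scenario([], pi, duration_s=400.0)
            fit = c.estimate_epbf_series(synthesize_breaths(truth, pi))
            rec.append(fit.epbf_lpm.dropna().iloc[-1])
        assert rec[1] / rec[0] == pytest.approx(2.0, rel=0.05)

    def test_non_perfused_states_emit_zero_elimination(self):
        p = ScenarioParams()
        truth = run_scenario([], p, duration_s=300.0)
        truth["epbf_lpm"] = 0.0
        breaths = synthesize_breaths(truth, p)
        assert (breaths.vtco2_ml == 0).all()


class TestSampleMeasurements:
    def _steady_setup(self, model, duration=3000.0):
        p = ScenarioParams()
        truth = run_scenario([], p, duration_s=duration)
        breaths = synthesize_breaths(truth, p)
        estimates = c.process_breaths(breaths, p.hb_gl)
        plan = tuple((ph, t) for ph, t in DEFAULT_SAMPLING_PLAN if t < duration)
        return truth, estimates, plan

    def test_noiseless_streams_equal_truth_at_sample_times(self):
        model = MeasurementModel.noiseless()
        truth, estimates, plan = self._steady_setup(model)
        rec = sample_measurements(truth, estimates, model, plan, np.random.default_rng(0))
        true_val = truth.svo2_true_pct.iloc[0]
        for method, grp in rec.groupby("method"):
            tol = 1.0 if method == "capno" else 1e-9
            assert np.allclose(grp.svo2_pct, true_val, atol=tol), method

    def test_reference_noise_calibrated_to_eleven_percent_precision(self):
        # 2 x CV of five baseline draws averages ~11% across many seeds
        model = MeasurementModel()
        truth, estimates, plan = self._steady_setup(model)
        plan = plan[:5]  # the five precision baseline slots
        precisions = []
        for k in range(400):
            rec = sample_measurements(
                truth, estimates, model, plan, np.random.default_rng(k)
            )
            coox = rec[rec.method == "co_oximetry"].svo2_pct
            precisions.append(c.inherent_precision(coox))
        assert np.mean(precisions) == pytest.approx(11.0, abs=0.8)

    def test_drift_without_recalibration_grows_linearly(self):
        model = MeasurementModel(
            co_oximetry_cv=0, fiberoptic_cv=0, capno_extra_cv=0,
            lag_fiberoptic_s=0, fiberoptic_drift_rate=-0.06,
            calibration_times=(0.0,),
        )
        truth, estimates, plan = self._steady_setup(model)
        rec = sample_measurements(truth, estimates, model, plan, np.random.default_rng(0))
        fib = rec[rec.method == "fiberoptic"].sort_values("t_s")
        err = fib.svo2_pct.to_numpy() - truth.svo2_true_pct.iloc[0]
        slopes = np.diff(err) / np.diff(fib.t_s.to_numpy())
        np.testing.assert_allclose(slopes, slopes[0], rtol=1e-6)


class TestCohortDeterminism:
    def test_identical_seeds_give_identical_csv_bytes(self):
        a = c.simulate_cohort(n_animals=1, seed=123)
        b = c.simulate_cohort(n_animals=1, seed=123)
        for key in ("truth", "breaths", "estimates", "recordings"):
            assert a[key].to_csv(index=False) == b[key].to_csv(index=False)

    def test_different_seeds_differ(self):
        a = c.simulate_cohort(n_animals=1, seed=1)["recordings"]
        b = c.simulate_cohort(n_animals=1, seed=2)["recordings"]
        assert not a.svo2_pct.equals(b.svo2_pct)
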
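"""Virtual porcine endotoxemia experiment.

Generates the three layers a desk validation of Capno-SvO2 needs:

* a hemodynamic truth trajectory — LPS endotoxemia driving cardiac output
  down and venous admixture up over the first hour, followed by the
  stabilization-phase challenges (crystalloid bolus, stepwise FiO2, PEEP
  ladder, dobutamine, norepinephrine, graded hemorrhage and whole-blood
  restitution), each with first-order response dynamics;
* breath-by-breath volumetric capnography under the 6-normal +
  3-expiratory-pause pattern, from a single-compartment alveolar CO2 store
  perfused by the effective pulmonary blood flow; and
* three SvO2 measurement streams — spot CO-oximetry, a lagged/drifting
  continuous fiberoptic trace with calibration resets, and the capnodynamic
  estimate — with distinct, seedable noise models.

True SvO2 is the self-consistent whole-body Fick solution with venous
admixture: with EPBF = CO * (1 - shunt), mixing arterial blood from the
end-capillary and shunted venous fractions collapses to
CvO2 = CcO2 - VO2 / EPBF, which is solved for saturation through the
dissociation curve. Every emitted state satisfies this balance to float
precision, so the estimator can be validated against exact ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .estimator import process_breaths
from .physiology import (
    PhysioConstants,
    alveolar_po2,
    co2_content,
    oxygen_content,
    saturation_from_content,
)

__all__ = [
    "ScenarioParams",
    "ScenarioEvent",
    "MeasurementModel",
    "DEFAULT_SAMPLING_PLAN",
    "default_protocol",
    "run_scenario",
    "synthesize_breaths",
    "sample_measurements",
    "simulate_cohort",
    "hb_step_function",
]


@dataclass(frozen=True)
class ScenarioParams:
    """Baseline physiology and intervention response magnitudes.

    Baseline values are plausible for a ~31.5 kg juvenile pig and are tuned
    so that true SvO2 sits near 60% before endotoxin and near 40% at the
    sepsis nadir. Magnitudes are multiplicative factors applied to the
    relaxation targets; taus are first-order time constants in seconds.
    """

    weight_kg: float = 31.5
    cardiac_output_lpm: float = 3.5
    shunt_fraction: float = 0.10
    vo2_mlpm: float = 180.0
    hb_gl: float = 100.0
    fio2: float = 0.3
    peep_cmh2o: float = 5.0
    paco2_mmhg: float = 40.0

    tau_s: float = 120.0
    tau_lps_s: float = 1800.0
    tau_stabilize_s: float = 900.0

    lps_co_factor: float = 0.66
    lps_shunt: float = 0.20
    stabilize_co_factor: float = 0.95
    stabilize_shunt: float = 0.12
    bolus_hb_factor: float = 0.90
    bolus_co_factor: float = 1.04
    peep_co_per_cmh2o: float = 0.017
    dobutamine_co_factor: float = 1.35
    dobutamine_vo2_factor: float = 1.05
    norepinephrine_co_factor: float = 1.08
    hemorrhage_co_factor: float = 0.70

    # Breath synthesis
    cycle_s: float = 45.0  # one 6-normal + 3-pause pattern cycle
    pause_extra_s: float = 2.5  # expiratory pause length
    elv_ml: float = 900.0  # effective lung volume for CO2
    vt_ml_per_kg: float = 10.0

    # Per-animal variability (fractional SDs)
    baseline_jitter: float = 0.06
    response_jitter: float = 0.15


@dataclass(frozen=True)
class ScenarioEvent:
    """One protocol event. ``magnitude`` is kind-specific (factor, target
    value, or unused); ``tau_s`` overrides the default relaxation constant."""

    t_start: float
    kind: str
    magnitude: float = float("nan")
    tau_s: float | None = None


EVENT_KINDS = {
    "lps_start",
    "stabilize",
    "crystalloid_bolus",
    "fio2_step",
    "peep_step",
    "dobutamine",
    "dobutamine_stop",
    "norepinephrine",
    "norepinephrine_stop",
    "hemorrhage",
    "retransfusion",
}


@dataclass(frozen=True)
class MeasurementModel:
    """Noise, lag and drift characteristics of the three SvO2 streams.

    CVs are multiplicative (precision in this field is CV-defined). The
    fiberoptic stream is a first-order lagged version of truth with a
    linear-in-time relative drift that resets to zero at each calibration;
    the default drift is negative, emulating the gradual underestimation of
    reflectance oximetry between calibrations. Defaults are calibrated so
    that 2xCV of five baseline readings averages ~11% (CO-oximetry), ~6%
    (capno) and ~7% (fiberoptic) across seeds.
    """

    co_oximetry_cv: float = 0.0585
    fiberoptic_cv: float = 0.037
    fiberoptic_drift_rate: float = -0.08  # fraction per hour since calibration
    capno_extra_cv: float = 0.032
    lag_fiberoptic_s: float = 45.0
    calibration_times: tuple[float, ...] = (0.0, 10400.0)

    def __post_init__(self) -> None:
        for name in ("co_oximetry_cv", "fiberoptic_cv", "capno_extra_cv"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.lag_fiberoptic_s < 0:
            raise ValueError("lag must be non-negative")

    @classmethod
    def noiseless(cls) -> "MeasurementModel":
        """All CVs, drift and lag zero: every stream reads true SvO2."""
        return cls(
            co_oximetry_cv=0.0,
            fiberoptic_cv=0.0,
            fiberoptic_drift_rate=0.0,
            capno_extra_cv=0.0,
            lag_fiberoptic_s=0.0,
        )


#: Recording slots (phase label, time in s). Precision baselines are five
#: readings 5 min apart after a 20-min stabilization; sepsis readings every
#: 10 min for the first hour of LPS; part two records the pre/post extremes
#: of each intervention. Events fire 10 s after their trigger recording.
DEFAULT_SAMPLING_PLAN: tuple[tuple[str, float], ...] = (
    ("precision_bl_1", 1500.0),
    ("precision_bl_2", 1800.0),
    ("precision_bl_3", 2100.0),
    ("precision_bl_4", 2400.0),
    ("precision_bl_5", 2700.0),
    ("induction_bl", 3000.0),
    ("sepsis_10", 3610.0),
    ("sepsis_20", 4210.0),
    ("sepsis_30", 4810.0),
    ("sepsis_40", 5410.0),
    ("sepsis_50", 6010.0),
    ("sepsis_60", 6610.0),
    ("bolus_pre", 10500.0),
    ("bolus_post", 12010.0),
    ("fio2_0.3", 12300.0),
    ("fio2_0.5", 12610.0),
    ("fio2_0.8", 12920.0),
    ("fio2_1.0", 13230.0),
    ("peep_baseline", 13540.0),
    ("peep_10", 13670.0),
    ("peep_15", 13800.0),
    ("dobutamine_pre", 14100.0),
    ("dobutamine_post", 15010.0),
    ("norepi_pre", 15920.0),
    ("norepi_post", 16530.0),
    ("hemorrhage_pre", 17140.0),
    ("hemorrhage_post", 18050.0),
    ("retransfusion_pre", 18100.0),
    ("retransfusion_post", 19200.0),
)

DEFAULT_DURATION_S = 19500.0


def default_protocol(params: ScenarioParams) -> list[ScenarioEvent]:
    """The study protocol as a time-ordered event list."""
    p = params
    return [
        ScenarioEvent(3010.0, "lps_start", tau_s=p.tau_lps_s),
        ScenarioEvent(6620.0, "stabilize", tau_s=p.tau_stabilize_s),
        ScenarioEvent(10510.0, "crystalloid_bolus", 15.0, tau_s=240.0),
        ScenarioEvent(12310.0, "fio2_step", 0.5),
        ScenarioEvent(12620.0, "fio2_step", 0.8),
        ScenarioEvent(12930.0, "fio2_step", 1.0),
        ScenarioEvent(13240.0, "fio2_step", 0.3),
        ScenarioEvent(13550.0, "peep_step", 10.0),
        ScenarioEvent(13680.0, "peep_step", 15.0),
        ScenarioEvent(13810.0, "peep_step", 5.0),
        ScenarioEvent(14110.0, "dobutamine", 15.0),
        ScenarioEvent(15020.0, "dobutamine_stop"),
        ScenarioEvent(15930.0, "norepinephrine", 0.1),
        ScenarioEvent(16540.0, "norepinephrine_stop"),
        ScenarioEvent(17150.0, "hemorrhage", 15.0, tau_s=240.0),
        ScenarioEvent(18110.0, "retransfusion", 15.0, tau_s=300.0),
    ]


class _Relaxer:
    """One state variable with first-order relaxation toward a target."""

    __slots__ = ("value", "target", "tau")

    def __init__(self, value: float, tau: float):
        self.value = value
        self.target = value
        self.tau = tau

    def set_target(self, target: float, tau: float | None = None):
        self.target = target
        if tau is not None:
            self.tau = tau

    def step(self, dt: float):
        self.value += (self.target - self.value) * (1.0 - math.exp(-dt / self.tau))


def run_scenario(
    events: Sequence[ScenarioEvent],
    params: ScenarioParams = ScenarioParams(),
    constants: PhysioConstants = PhysioConstants(),
    duration_s: float = DEFAULT_DURATION_S,
    dt_s: float = 1.0,
) -> pd.DataFrame:
    """Integrate the hemodynamic state trajectory at ``dt_s`` resolution.

    Events set new relaxation targets (mostly multiplicative factors on the
    current targets, so paired start/stop events reverse cleanly); FiO2 and
    PEEP change instantaneously as ventilator settings, with PEEP also
    depressing the cardiac-output target via reduced venous return. An empty
    event list yields a constant baseline state. Events sharing a start
    time conflict and raise.
    """
    events = sorted(events, key=lambda e: e.t_start)
    times = [e.t_start for e in events]
    if len(set(times)) != len(times):
        raise ValueError("overlapping events: two events share a start time")
    for e in events:
        if e.kind not in EVENT_KINDS:
            raise ValueError(f"unknown event kind '{e.kind}'")

    p = params
    co = _Relaxer(p.cardiac_output_lpm, p.tau_s)
    shunt = _Relaxer(p.shunt_fraction, p.tau_s)
    vo2 = _Relaxer(p.vo2_mlpm, p.tau_s)
    hb = _Relaxer(p.hb_gl, p.tau_s)
    fio2 = p.fio2
    peep = p.peep_cmh2o

    def apply(e: ScenarioEvent):
        nonlocal fio2, peep
        tau = e.tau_s if e.tau_s is not None else p.tau_s
        if e.kind == "lps_start":
            co.set_target(co.target * p.lps_co_factor, tau)
            shunt.set_target(p.lps_shunt, tau)
        elif e.kind == "stabilize":
            co.set_target(p.cardiac_output_lpm * p.stabilize_co_factor, tau)
            shunt.set_target(p.stabilize_shunt, tau)
        elif e.kind == "crystalloid_bolus":
            hb.set_target(hb.target * p.bolus_hb_factor, tau)
            co.set_target(co.target * p.bolus_co_factor, tau)
        elif e.kind == "fio2_step":
            fio2 = float(e.magnitude)
        elif e.kind == "peep_step":
            new_peep = float(e.magnitude)
            co.set_target(
                co.target * (1.0 - p.peep_co_per_cmh2o * (new_peep - peep)), tau
            )
            peep = new_peep
        elif e.kind == "dobutamine":
            co.set_target(co.target * p.dobutamine_co_factor, tau)
            vo2.set_target(vo2.target * p.dobutamine_vo2_factor, tau)
        elif e.kind == "dobutamine_stop":
            co.set_target(co.target / p.dobutamine_co_factor, tau)
            vo2.set_target(vo2.target / p.dobutamine_vo2_factor, tau)
        elif e.kind == "norepinephrine":
            co.set_target(co.target * p.norepinephrine_co_factor, tau)
        elif e.kind == "norepinephrine_stop":
            co.set_target(co.target / p.norepinephrine_co_factor, tau)
        elif e.kind == "hemorrhage":
            co.set_target(co.target * p.hemorrhage_co_factor, tau)
        elif e.kind == "retransfusion":
            co.set_target(co.target / p.hemorrhage_co_factor, tau)

    n = int(round(duration_s / dt_s))
    t = np.arange(n) * dt_s
    out = {
        k: np.empty(n)
        for k in ("cardiac_output", "shunt_fraction", "vo2_true", "hb", "fio2", "peep")
    }
    ev_i = 0
    for i in range(n):
        while ev_i < len(events) and events[ev_i].t_start <= t[i]:
            apply(events[ev_i])
            ev_i += 1
        out["cardiac_output"][i] = co.value
        out["shunt_fraction"][i] = shunt.value
        out["vo2_true"][i] = vo2.value
        out["hb"][i] = hb.value
        out["fio2"][i] = fio2
        out["peep"][i] = peep
        co.step(dt_s)
        shunt.step(dt_s)
        vo2.step(dt_s)
        hb.step(dt_s)

    epbf = out["cardiac_output"] * (1.0 - out["shunt_fraction"])
    pao2 = alveolar_po2(out["fio2"], np.full(n, p.paco2_mmhg), constants)
    cco2 = oxygen_content(out["hb"], 1.0, pao2, constants)
    cvo2 = cco2 - out["vo2_true"] / epbf
    svo2 = saturation_from_content(cvo2, out["hb"], constants, po2_max=pao2)

    return pd.DataFrame(
        {
            "t_s": t,
            "cardiac_output_lpm": out["cardiac_output"],
            "shunt_fraction": out["shunt_fraction"],
            "vo2_mlpm": out["vo2_true"],
            "hb_gl": out["hb"],
            "fio2": out["fio2"],
            "peep_cmh2o": out["peep"],
            "paco2_mmhg": np.full(n, p.paco2_mmhg),
            "epbf_lpm": epbf,
            "cco2_mll": cco2,
            "cvo2_mll": cvo2,
            "svo2_true_pct": svo2 * 100.0,
        }
    )


def synthesize_breaths(
    states: pd.DataFrame,
    params: ScenarioParams = ScenarioParams(),
    constants: PhysioConstants = PhysioConstants(),
    rng: np.random.Generator | None = None,
    vtco2_noise_cv: float = 0.0,
) -> pd.DataFrame:
    """Breath-by-breath volumetric capnography from the truth trajectory.

    A single alveolar CO2 store of effective volume ELV is perfused by the
    true EPBF; each breath, blood delivers EPBF * dt * (CvCO2 - CcCO2(FA))
    of CO2 and expiration removes VA * FA, where VA is the alveolar tidal
    ventilation and FA the alveolar (= end-tidal) CO2 fraction. The balance
    is implicit in FA and linear (the CO2 dissociation is linearized), so
    each breath solves in closed form. Pause breaths hold the pattern's
    longer duration and accumulate more CO2, producing the EPBF-identifying
    fluctuation. The venous CO2 content is set from the instantaneous state
    so that steady-state elimination equals VO2 * RQ.

    Non-perfused states (EPBF ~ 0) yield zero-elimination breaths.
    """
    p = params
    rq = constants.respiratory_quotient
    pb_dry = constants.barometric_pressure - constants.water_vapor_pressure
    n_normal, n_pause = 6, 3
    per_cycle = n_normal + n_pause
    d_normal = (p.cycle_s - n_pause * p.pause_extra_s) / per_cycle
    d_pause = d_normal + p.pause_extra_s
    rr_per_min = per_cycle * 60.0 / p.cycle_s

    t_grid = states["t_s"].to_numpy(float)
    duration = float(t_grid[-1]) + float(t_grid[1] - t_grid[0]) if len(t_grid) > 1 else 0.0
    epbf_s = states["epbf_lpm"].to_numpy(float)
    vo2_s = states["vo2_mlpm"].to_numpy(float)
    paco2_s = states["paco2_mmhg"].to_numpy(float)
    fio2_s = states["fio2"].to_numpy(float)

    a_fa = constants.co2_content_slope * pb_dry  # d(content)/d(FA), ml/L
    rows = []
    t = 0.0
    k = 0
    fa = float(paco2_s[0]) / pb_dry
    vt_ml = p.vt_ml_per_kg * p.weight_kg
    while True:
        is_pause = (k % per_cycle) >= n_normal
        dur = d_pause if is_pause else d_normal
        if t + dur > duration:
            break
        i = min(int(t), len(t_grid) - 1)
        q = epbf_s[i]
        fa_target = paco2_s[i] / pb_dry
        vco2_target = vo2_s[i] * rq  # ml/min
        if q <= 1e-6:
            vtco2 = 0.0
        else:
            cv_co2 = co2_content(paco2_s[i], constants) + vco2_target / q
            va = vco2_target / (rr_per_min * fa_target)  # ml per breath
            dt_min = dur / 60.0
            fa = (p.elv_ml * fa + q * dt_min * (cv_co2 - constants.co2_content_intercept)) / (
                p.elv_ml + q * dt_min * a_fa + va
            )
            vtco2 = va * fa
        if vtco2_noise_cv > 0 and rng is not None and vtco2 > 0:
            vtco2 *= 1.0 + rng.normal(0.0, vtco2_noise_cv)
        rows.append(
            (
                k,
                t,
                dur,
                "pause" if is_pause else "normal",
                vt_ml,
                max(vtco2, 0.0),
                fa,
                fio2_s[i],
            )
        )
        t += dur
        k += 1

    return pd.DataFrame(
        rows,
        columns=[
            "breath_index",
            "t_start_s",
            "duration_s",
            "breath_type",
            "vt_ml",
            "vtco2_ml",
            "fet_co2",
            "fio2",
        ],
    )


def hb_step_function(sample_times: np.ndarray, hb_values: np.ndarray):
    """Step-hold hemoglobin lookup emulating intermittent blood-gas draws."""
    sample_times = np.asarray(sample_times, dtype=float)
    hb_values = np.asarray(hb_values, dtype=float)

    def lookup(t):
        idx = np.clip(np.searchsorted(sample_times, np.asarray(t, float), side="right") - 1, 0, None)
        return hb_values[idx]

    return lookup


def sample_measurements(
    states: pd.DataFrame,
    estimates: pd.DataFrame,
    model: MeasurementModel = MeasurementModel(),
    plan: Sequence[tuple[str, float]] = DEFAULT_SAMPLING_PLAN,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Sample the three SvO2 streams at the protocol's recording slots.

    CO-oximetry reads true SvO2 with multiplicative noise at spot times; the
    fiberoptic stream is the per-second first-order-lagged truth with
    between-calibration drift and reading noise; the capno stream is the
    estimator's filtered output at the last completed breath, with the
    stream's extra CV. With all CVs, lag and drift zero every stream equals
    true SvO2 at the sample times.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    t_grid = states["t_s"].to_numpy(float)
    truth = states["svo2_true_pct"].to_numpy(float)
    plan_t = np.array([t for _, t in plan])
    if plan_t.max() > t_grid[-1]:
        raise ValueError("sampling plan extends beyond simulated duration")
    idx = np.searchsorted(t_grid, plan_t, side="right") - 1

    # Fiberoptic: segment-wise first-order lag, reset at calibrations.
    if model.lag_fiberoptic_s > 0:
        alpha = 1.0 - math.exp(-(t_grid[1] - t_grid[0]) / model.lag_fiberoptic_s)
        fo = np.empty_like(truth)
        bounds = sorted(set([0.0, *model.calibration_times, t_grid[-1] + 1]))
        for lo, hi in zip(bounds[:-1], bounds[1:]):
            seg = (t_grid >= lo) & (t_grid < hi)
            if not seg.any():
                continue
            x = truth[seg]
            zi = [(1.0 - alpha) * x[0]]
            fo[seg] = lfilter([alpha], [1.0, -(1.0 - alpha)], x, zi=zi)[0]
    else:
        fo = truth.copy()
    # Drift since most recent calibration.
    cal = np.asarray(sorted(model.calibration_times), dtype=float)
    last_cal = cal[np.clip(np.searchsorted(cal, t_grid, side="right") - 1, 0, None)]
    fo = fo * (1.0 + model.fiberoptic_drift_rate * (t_grid - last_cal) / 3600.0)

    # Capno: filtered estimator output at the last completed breath.
    est_t = estimates["t_s"].to_numpy(float)
    est_v = estimates["svo2_filt_pct"].to_numpy(float)
    cap_idx = np.clip(np.searchsorted(est_t, plan_t, side="right") - 1, 0, None)

    rows = []
    for j, (phase, t_rec) in enumerate(plan):
        true_val = truth[idx[j]]
        coox = true_val * (1.0 + rng.normal(0.0, model.co_oximetry_cv))
        fib = fo[idx[j]] * (1.0 + rng.normal(0.0, model.fiberoptic_cv))
        cap = est_v[cap_idx[j]] * (1.0 + rng.normal(0.0, model.capno_extra_cv))
        for method, val in (("co_oximetry", coox), ("fiberoptic", fib), ("capno", cap)):
            rows.append((phase, t_rec, method, float(np.clip(val, 0.0, 100.0))))
    return pd.DataFrame(rows, columns=["phase", "t_s", "method", "svo2_pct"])


def _jitter_factor(f: float, rel: float, rng: np.random.Generator) -> float:
    """Jitter a multiplicative response factor, preserving its direction."""
    if f >= 1.0:
        return 1.0 + (f - 1.0) * (1.0 + rng.normal(0.0, rel))
    return max(1.0 - (1.0 - f) * (1.0 + rng.normal(0.0, rel)), 0.05)


def _jittered_params(p: ScenarioParams, rng: np.random.Generator) -> ScenarioParams:
    b, r = p.baseline_jitter, p.response_jitter
    return replace(
        p,
        cardiac_output_lpm=p.cardiac_output_lpm * (1.0 + rng.normal(0.0, b)),
        vo2_mlpm=p.vo2_mlpm * (1.0 + rng.normal(0.0, b)),
        hb_gl=p.hb_gl * (1.0 + rng.normal(0.0, b)),
        shunt_fraction=float(np.clip(p.shunt_fraction * (1.0 + rng.normal(0.0, r)), 0.02, 0.4)),
        lps_co_factor=_jitter_factor(p.lps_co_factor, r, rng),
        lps_shunt=float(np.clip(p.lps_shunt * (1.0 + rng.normal(0.0, r)), 0.05, 0.45)),
        bolus_hb_factor=_jitter_factor(p.bolus_hb_factor, r, rng),
        dobutamine_co_factor=_jitter_factor(p.dobutamine_co_factor, r, rng),
        norepinephrine_co_factor=_jitter_factor(p.norepinephrine_co_factor, r, rng),
        hemorrhage_co_factor=_jitter_factor(p.hemorrhage_co_factor, r, rng),
    )


def simulate_cohort(
    params: ScenarioParams = ScenarioParams(),
    model: MeasurementModel = MeasurementModel(),
    constants: PhysioConstants = PhysioConstants(),
    n_animals: int = 10,
    seed: int = 0,
    jitter: bool = True,
    plan: Sequence[tuple[str, float]] = DEFAULT_SAMPLING_PLAN,
    duration_s: float = DEFAULT_DURATION_S,
) -> dict[str, pd.DataFrame]:
    """Run the full protocol for a cohort of virtual animals.

    Per-animal randomness (baseline jitter, response-magnitude jitter,
    measurement noise) derives from ``seed`` through independent
    SeedSequence streams, so identical seeds reproduce identical tables
    byte-for-byte. Returns dict with keys truth, breaths, estimates,
    recordings — each a concatenated table with an ``animal_id`` column.
    """
    truth_all, breaths_all, est_all, rec_all = [], [], [], []
    for i in range(n_animals):
        rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(i,)))
        p_i = _jittered_params(params, rng) if jitter else params
        animal = f"pig{i + 1:02d}"
        truth = run_scenario(default_protocol(p_i), p_i, constants, duration_s)
        breaths = synthesize_breaths(truth, p_i, constants, rng=rng)

        # Hemoglobin reaches the estimator through intermittent blood-gas
        # draws (every 5 min, matching frequent gas sampling under a
        # goal-directed protocol), held constant between draws.
        t_grid = truth["t_s"].to_numpy(float)
        hb_times = np.arange(0.0, t_grid[-1] + 1.0, 300.0)
        hb_at = truth["hb_gl"].to_numpy(float)[
            np.searchsorted(t_grid, hb_times, side="right") - 1
        ]
        estimates = process_breaths(breaths, hb_step_function(hb_times, hb_at), constants)
        recordings = sample_measurements(truth, estimates, model, plan, rng)

        for df, acc in (
            (truth, truth_all),
            (breaths, breaths_all),
            (estimates, est_all),
            (recordings, rec_all),
        ):
            df = df.copy()
            df.insert(0, "animal_id", animal)
            acc.append(df)

    return {
        "truth": pd.concat(truth_all, ignore_index=True),
        "breaths": pd.concat(breaths_all, ignore_index=True),
        "estimates": pd.concat(est_all, ignore_index=True),
        "recordings": pd.concat(rec_all, ignore_index=True),
    }
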
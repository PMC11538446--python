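"""Breath-stream processing: volumetric capnography to Capno-SvO2.

The chain implemented here mirrors the capnodynamic method:

1.  VCO2 — moving mean of breath-by-breath CO2 elimination over a trailing
    20-min window (stable-metabolism assumption).
2.  VO2 = VCO2 / RQ (differential Fick, fixed respiratory quotient).
3.  EPBF — effective pulmonary blood flow, re-estimated for every new
    breath from the trailing nine breaths of the 6-normal + 3-pause
    ventilation pattern by least-squares on a single-compartment alveolar
    CO2 mass balance:

        ELV * dFA_n = EPBF * dt_n * (CvCO2 - CcCO2(FA_n)) - VTCO2_n

    jointly estimating ELV (effective lung volume), EPBF and the venous CO2
    content CvCO2. The commercial capnodynamic equation is not public; this
    is a reconstruction of the standard breath-by-breath CO2 mass balance,
    validated against the simulator rather than the proprietary algorithm.
4.  CcO2 from the alveolar gas equation (end-capillary blood assumed fully
    saturated and equilibrated with alveolar gas); CvO2 = CcO2 - VO2/EPBF;
    SvO2 by inverting the content relation, clamped to [0, 1].

Transient negative CvO2 / zero EPBF produce clamped, quality-flagged zeros
rather than dropped rows, preserving the method's observed floor behavior
during hemodynamic collapse.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .physiology import (
    PhysioConstants,
    alveolar_po2,
    co2_content,
    oxygen_content,
    saturation_from_content,
)

__all__ = [
    "BreathType",
    "BreathRecord",
    "CapnoEstimate",
    "BREATH_COLUMNS",
    "ESTIMATE_COLUMNS",
    "windowed_vco2",
    "vo2_from_vco2",
    "fit_epbf_window",
    "estimate_epbf_series",
    "capno_svo2_chain",
    "moving_mean_filter",
    "process_breaths",
    "breaths_to_frame",
]

#: Breaths in one EPBF fitting window (one full 6+3 pattern cycle).
EPBF_WINDOW_BREATHS = 9

BREATH_COLUMNS = [
    "breath_index",
    "t_start_s",
    "duration_s",
    "breath_type",
    "vt_ml",
    "vtco2_ml",
    "fet_co2",
    "fio2",
]

ESTIMATE_COLUMNS = [
    "breath_index",
    "t_s",
    "epbf_lpm",
    "vco2_mlpm",
    "vo2_mlpm",
    "cco2_mll",
    "cvo2_mll",
    "svo2_pct",
    "svo2_filt_pct",
    "quality_flag",
]


class BreathType(str, Enum):
    NORMAL = "normal"
    PAUSE = "pause"


@dataclass(frozen=True)
class BreathRecord:
    """One ventilator breath of the 6-normal + 3-expiratory-pause pattern."""

    index: int
    t_start: float  # s
    duration: float  # s
    breath_type: BreathType
    tidal_volume: float  # ml
    vtco2: float  # ml CO2 expired this breath
    fet_co2: float  # end-tidal CO2 fraction
    fio2: float

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("breath duration must be positive")
        if self.vtco2 < 0:
            raise ValueError("vtco2 must be non-negative")
        if not 0 <= self.fet_co2 < 0.15:
            raise ValueError("fet_co2 must lie in [0, 0.15)")


@dataclass(frozen=True)
class CapnoEstimate:
    """Per-breath estimator output."""

    breath_index: int
    epbf: float  # L/min
    vco2_windowed: float  # ml/min
    vo2: float  # ml/min
    cco2: float  # ml/L
    cvo2: float  # ml/L
    svo2: float  # fraction
    svo2_filtered: float  # fraction
    quality_flag: str = ""


def breaths_to_frame(breaths: Sequence[BreathRecord]) -> pd.DataFrame:
    """Convert BreathRecord objects to the canonical breaths table."""
    return pd.DataFrame(
        {
            "breath_index": [b.index for b in breaths],
            "t_start_s": [b.t_start for b in breaths],
            "duration_s": [b.duration for b in breaths],
            "breath_type": [BreathType(b.breath_type).value for b in breaths],
            "vt_ml": [b.tidal_volume for b in breaths],
            "vtco2_ml": [b.vtco2 for b in breaths],
            "fet_co2": [b.fet_co2 for b in breaths],
            "fio2": [b.fio2 for b in breaths],
        }
    )


def _check_breaths(breaths: pd.DataFrame) -> None:
    if len(breaths) == 0:
        raise ValueError("empty breath sequence")
    t = breaths["t_start_s"].to_numpy(float)
    if np.any(np.diff(t) <= 0):
        i = int(np.argmax(np.diff(t) <= 0)) + 1
        raise ValueError(f"breaths not time-ordered at row {i}")
    if np.any(breaths["duration_s"].to_numpy(float) <= 0):
        raise ValueError("breath durations must be positive")


def windowed_vco2(
    breaths: pd.DataFrame, window_s: float = 1200.0
) -> tuple[np.ndarray, np.ndarray]:
    """Trailing-window mean CO2 elimination rate per breath (ml/min).

    For each breath, sums expired CO2 over all breaths whose end time falls
    inside the trailing ``window_s`` seconds and divides by the summed breath
    durations (scaled to per-minute). Before the window fills, the mean uses
    all available breaths and the breath is flagged as warm-up.

    Returns ``(vco2_mlpm, warmup)`` arrays.
    """
    if window_s <= 0:
        raise ValueError("window must be positive")
    _check_breaths(breaths)
    dur = breaths["duration_s"].to_numpy(float)
    vtco2 = breaths["vtco2_ml"].to_numpy(float)
    t_end = breaths["t_start_s"].to_numpy(float) + dur

    cum_v = np.concatenate([[0.0], np.cumsum(vtco2)])
    cum_d = np.concatenate([[0.0], np.cumsum(dur)])
    j0 = np.searchsorted(t_end, t_end - window_s, side="right")
    idx = np.arange(len(dur))
    v = cum_v[idx + 1] - cum_v[j0]
    d = cum_d[idx + 1] - cum_d[j0]
    warmup = t_end < t_end[0] + window_s
    return 60.0 * v / d, warmup


def vo2_from_vco2(vco2, rq: float):
    """Oxygen consumption from CO2 elimination: VO2 = VCO2 / RQ (ml/min)."""
    if rq <= 0:
        raise ValueError("respiratory quotient must be positive")
    vco2 = np.asarray(vco2, dtype=float)
    if np.any(vco2 < 0):
        raise ValueError("vco2 must be non-negative")
    out = vco2 / rq
    return float(out) if out.ndim == 0 else out


def fit_epbf_window(
    dfa: np.ndarray,
    dt_min: np.ndarray,
    cc_co2: np.ndarray,
    vtco2: np.ndarray,
    cvco2_fixed: float | None = None,
) -> tuple[float, float, float, bool]:
    """Least-squares CO2 mass-balance fit over one 9-breath window.

    Rows:  ELV * dFA + EPBF * dt * CcCO2 - (EPBF*CvCO2) * dt = -VTCO2.
    With ``cvco2_fixed`` the venous CO2 content is carried from the previous
    window and only ELV and EPBF are refit.

    Returns ``(elv_ml, epbf_lpm, cvco2_mll, degenerate)``.
    """
    b = -np.asarray(vtco2, dtype=float)
    if np.max(vtco2) <= 1e-9:
        return np.nan, np.nan, np.nan, True
    if cvco2_fixed is None:
        a = np.column_stack([dfa, dt_min * cc_co2, -dt_min])
    else:
        a = np.column_stack([dfa, dt_min * (cc_co2 - cvco2_fixed)])
    sol, _, rank, _ = np.linalg.lstsq(a, b, rcond=None)
    if rank < a.shape[1]:
        return np.nan, np.nan, np.nan, True
    elv = float(sol[0])
    epbf = float(sol[1])
    cvco2 = cvco2_fixed if cvco2_fixed is not None else (
        float(sol[2]) / epbf if epbf > 1e-9 else np.nan
    )
    if not np.isfinite(epbf) or epbf <= 0:
        return elv, max(epbf, 0.0), cvco2, True
    return elv, epbf, cvco2, False


def estimate_epbf_series(
    breaths: pd.DataFrame,
    constants: PhysioConstants = PhysioConstants(),
    mode: str = "refit",
) -> pd.DataFrame:
    """Breath-by-breath EPBF over a rolling 9-breath window.

    ``mode="refit"`` (default) refits ELV, EPBF and CvCO2 each breath;
    ``mode="carry"`` fixes CvCO2 at the previous window's value. Degenerate
    windows (no CO2 signal, singular normal equations, non-positive flow)
    carry the last valid EPBF forward and are flagged.
    """
    if mode not in ("refit", "carry"):
        raise ValueError("mode must be 'refit' or 'carry'")
    _check_breaths(breaths)
    n = len(breaths)
    fet = breaths["fet_co2"].to_numpy(float)
    dt_min = breaths["duration_s"].to_numpy(float) / 60.0
    vtco2 = breaths["vtco2_ml"].to_numpy(float)
    pb_dry = constants.barometric_pressure - constants.water_vapor_pressure
    cc = co2_content(fet * pb_dry, constants)
    dfa = np.concatenate([[np.nan], np.diff(fet)])

    epbf = np.full(n, np.nan)
    elv = np.full(n, np.nan)
    cvco2 = np.full(n, np.nan)
    flags = [""] * n
    last_valid = np.nan
    last_cvco2: float | None = None
    w = EPBF_WINDOW_BREATHS
    for i in range(n):
        if i < w:
            flags[i] = "warmup"
            continue
        sl = slice(i - w + 1, i + 1)
        fixed = last_cvco2 if (mode == "carry" and last_cvco2 is not None) else None
        elv_i, epbf_i, cvco2_i, degenerate = fit_epbf_window(
            dfa[sl], dt_min[sl], cc[sl], vtco2[sl], cvco2_fixed=fixed
        )
        if degenerate:
            epbf[i] = last_valid if np.isfinite(last_valid) else 0.0
            flags[i] = "degenerate"
        else:
            epbf[i] = epbf_i
            elv[i] = elv_i
            cvco2[i] = cvco2_i
            last_valid = epbf_i
            if cvco2_i is not None and np.isfinite(cvco2_i):
                last_cvco2 = float(cvco2_i)
    return pd.DataFrame(
        {"epbf_lpm": epbf, "elv_ml": elv, "cvco2_mll": cvco2, "epbf_flag": flags}
    )


def capno_svo2_chain(
    epbf: float,
    vo2: float,
    fio2: float,
    paco2_alv: float,
    hb: float,
    constants: PhysioConstants = PhysioConstants(),
) -> tuple[float, float, float, str]:
    """Differential-Fick chain: (EPBF, VO2) -> (CcO2, CvO2, SvO2).

    CcO2 assumes fully saturated end-capillary blood at alveolar PO2;
    CvO2 = CcO2 - VO2/EPBF (ml/min over L/min gives ml/L directly); SvO2 is
    the content inversion, clamped to [0, 1]. EPBF <= 0 yields a flagged
    clamped zero — the method's reported post-arrest behavior.

    Returns ``(cco2, cvo2, svo2, quality_flag)``.
    """
    if vo2 < 0:
        raise ValueError("vo2 must be non-negative")
    pao2 = alveolar_po2(fio2, paco2_alv, constants)
    flag = ""
    if pao2 <= 0:
        return np.nan, np.nan, 0.0, "nonphysiologic_pao2"
    cco2 = oxygen_content(hb, 1.0, pao2, constants)
    if epbf <= 0:
        return cco2, np.nan, 0.0, "zero_epbf"
    cvo2 = cco2 - vo2 / epbf
    svo2 = saturation_from_content(cvo2, hb, constants, po2_max=pao2)
    if cvo2 <= 0 or svo2 in (0.0, 1.0):
        flag = "clamped"
    return cco2, cvo2, float(svo2), flag


def moving_mean_filter(t, values, window_s: float = 50.0) -> np.ndarray:
    """Trailing time-window mean of a timestamped series.

    Output has the same length as the input; each point averages all samples
    within ``[t_i - window_s, t_i]``. NaNs propagate only to their own
    position (they are excluded from neighbors' means). A window shorter
    than the sampling interval returns the series unchanged.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(values, dtype=float)
    if np.any(np.diff(t) < 0):
        raise ValueError("series must be time-ordered")
    finite = np.isfinite(y)
    yz = np.where(finite, y, 0.0)
    cum_y = np.concatenate([[0.0], np.cumsum(yz)])
    cum_n = np.concatenate([[0.0], np.cumsum(finite.astype(float))])
    j0 = np.searchsorted(t, t - window_s, side="left")
    idx = np.arange(len(t))
    s = cum_y[idx + 1] - cum_y[j0]
    n = cum_n[idx + 1] - cum_n[j0]
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(n > 0, s / np.maximum(n, 1), np.nan)
    return np.where(finite, out, np.nan)


def process_breaths(
    breaths: pd.DataFrame,
    hb: float | Callable[[np.ndarray], np.ndarray],
    constants: PhysioConstants = PhysioConstants(),
    vco2_window_s: float = 1200.0,
    filter_window_s: float = 50.0,
    epbf_mode: str = "refit",
) -> pd.DataFrame:
    """Run the full per-breath Capno-SvO2 chain over a breaths table.

    ``hb`` is either a constant (g/L) or a callable mapping breath times to
    hemoglobin values (emulating intermittent blood-gas hemoglobin updates).
    Returns the canonical estimates table (percent scale for saturations).
    """
    _check_breaths(breaths)
    t_end = breaths["t_start_s"].to_numpy(float) + breaths["duration_s"].to_numpy(float)
    vco2, vco2_warm = windowed_vco2(breaths, vco2_window_s)
    vo2 = vo2_from_vco2(vco2, constants.respiratory_quotient)
    fit = estimate_epbf_series(breaths, constants, mode=epbf_mode)
    epbf = fit["epbf_lpm"].to_numpy(float)

    hb_arr = (
        np.full(len(breaths), float(hb))
        if np.isscalar(hb)
        else np.asarray(hb(t_end), dtype=float)
    )
    pb_dry = constants.barometric_pressure - constants.water_vapor_pressure
    paco2 = breaths["fet_co2"].to_numpy(float) * pb_dry
    fio2 = breaths["fio2"].to_numpy(float)

    n = len(breaths)
    cco2 = np.full(n, np.nan)
    cvo2 = np.full(n, np.nan)
    svo2 = np.full(n, np.nan)
    flags = []
    for i in range(n):
        parts = []
        if fit["epbf_flag"][i]:
            parts.append(fit["epbf_flag"][i])
        if vco2_warm[i]:
            parts.append("vco2_warmup")
        if np.isfinite(epbf[i]):
            c, v, s, f = capno_svo2_chain(
                epbf[i], vo2[i], fio2[i], paco2[i], hb_arr[i], constants
            )
            cco2[i], cvo2[i], svo2[i] = c, v, s
            if f:
                parts.append(f)
        flags.append(";".join(parts))

    svo2_filt = moving_mean_filter(t_end, svo2, filter_window_s)
    return pd.DataFrame(
        {
            "breath_index": breaths["breath_index"].to_numpy(),
            "t_s": t_end,
            "epbf_lpm": epbf,
            "vco2_mlpm": vco2,
            "vo2_mlpm": vo2,
            "cco2_mll": cco2,
            "cvo2_mll": cvo2,
            "svo2_pct": svo2 * 100.0,
            "svo2_filt_pct": svo2_filt * 100.0,
            "quality_flag": flags,
        }
    )
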
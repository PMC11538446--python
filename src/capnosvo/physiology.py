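"""Blood-gas and alveolar gas-exchange arithmetic.

Shared foundation for the capnodynamic SvO2 estimator and the endotoxemia
simulator: oxygen content of a blood compartment, the alveolar gas equation,
the oxygen-hemoglobin dissociation curve (ODC) and its inverse, and the
inversion of an oxygen content back to a saturation.

Conventions
-----------
* O2 contents in ml O2 per L blood, hemoglobin in g/L, pressures in mmHg,
  saturations as fractions in [0, 1]. Percentages appear only at I/O
  boundaries (CSV files, reports).
* The ODC is the Severinghaus human-blood formulation by default, rescaled
  to a configurable P50 (a porcine preset with P50 = 35 mmHg is provided);
  a Hill curve is available as a fallback. No temperature/pH Bohr shifts.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

__all__ = [
    "SEVERINGHAUS_P50",
    "PhysioConstants",
    "BloodGasState",
    "AlveolarGasState",
    "oxygen_content",
    "alveolar_po2",
    "odc_saturation",
    "odc_po2",
    "saturation_from_content",
    "co2_content",
]


def _severinghaus_reference_p50() -> float:
    # P50 of S(P) = 1 / (1 + 23400 / (P^3 + 150 P)): real root of
    # P^3 + 150 P - 23400 = 0 (Cardano; the discriminant is positive).
    k = 23400.0 / 2.0
    d = np.sqrt(k * k + 50.0**3)
    return float(np.cbrt(k + d) + np.cbrt(k - d))


SEVERINGHAUS_P50 = _severinghaus_reference_p50()  # ~26.87 mmHg


@dataclass(frozen=True)
class PhysioConstants:
    """Physiologic constants for gas-exchange arithmetic.

    Attributes
    ----------
    huefner_capacity : ml O2 bound per g of fully saturated hemoglobin.
    o2_solubility : ml O2 per L blood per mmHg (dissolved fraction).
    barometric_pressure, water_vapor_pressure : mmHg, for the alveolar gas
        equation (PAO2 = FiO2 * (Pb - PH2O) - PaCO2 / RQ).
    odc_p50 : mmHg, PO2 at 50% saturation of the dissociation curve.
    respiratory_quotient : VCO2 / VO2, dimensionless.
    odc_model : "severinghaus" (default) or "hill".
    hill_coefficient : Hill exponent, used only by the Hill model.
    co2_content_slope, co2_content_intercept : linearized blood CO2
        dissociation, content = slope * PCO2 + intercept (ml CO2/L blood;
        adequate over the 25-80 mmHg range the method operates in).
    """

    huefner_capacity: float = 1.34
    o2_solubility: float = 0.03
    barometric_pressure: float = 760.0
    water_vapor_pressure: float = 47.0
    odc_p50: float = SEVERINGHAUS_P50
    respiratory_quotient: float = 0.97
    odc_model: str = "severinghaus"
    hill_coefficient: float = 2.7
    co2_content_slope: float = 5.0
    co2_content_intercept: float = 280.0

    def __post_init__(self) -> None:
        positive = (
            "huefner_capacity",
            "o2_solubility",
            "barometric_pressure",
            "water_vapor_pressure",
            "odc_p50",
            "respiratory_quotient",
            "hill_coefficient",
            "co2_content_slope",
            "co2_content_intercept",
        )
        for name in positive:
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")
        if not 0.6 < self.respiratory_quotient < 1.3:
            raise ValueError("respiratory_quotient must lie in (0.6, 1.3)")
        if not 15.0 < self.odc_p50 < 50.0:
            raise ValueError("odc_p50 must lie in (15, 50) mmHg")
        if self.odc_model not in ("severinghaus", "hill"):
            raise ValueError("odc_model must be 'severinghaus' or 'hill'")

    @classmethod
    def porcine(cls, **overrides) -> "PhysioConstants":
        """Preset with a right-shifted porcine dissociation curve (P50 35 mmHg)."""
        overrides.setdefault("odc_p50", 35.0)
        return cls(**overrides)

    def replace(self, **changes) -> "PhysioConstants":
        return dataclasses.replace(self, **changes)


def oxygen_content(hb, sat, po2, constants: PhysioConstants = PhysioConstants()):
    """O2 content of blood (ml/L): bound (Hb * Huefner * S) plus dissolved.

    Accepts scalars or arrays. Negative inputs raise ValueError.
    """
    hb = np.asarray(hb, dtype=float)
    sat = np.asarray(sat, dtype=float)
    po2 = np.asarray(po2, dtype=float)
    if np.any(hb < 0) or np.any(po2 < 0):
        raise ValueError("hemoglobin and PO2 must be non-negative")
    if np.any(sat < 0) or np.any(sat > 1):
        raise ValueError("saturation must lie in [0, 1]")
    out = hb * constants.huefner_capacity * sat + constants.o2_solubility * po2
    return float(out) if out.ndim == 0 else out


def alveolar_po2(fio2, paco2, constants: PhysioConstants = PhysioConstants()):
    """Alveolar PO2 (mmHg) from the alveolar gas equation.

    PAO2 = FiO2 * (Pb - PH2O) - PaCO2 / RQ. A non-positive result signals a
    non-physiologic regime; it is returned as-is for the caller to handle.
    """
    fio2 = np.asarray(fio2, dtype=float)
    paco2 = np.asarray(paco2, dtype=float)
    if np.any(fio2 < 0.21 - 1e-12) or np.any(fio2 > 1.0 + 1e-12):
        raise ValueError("fio2 must lie in [0.21, 1.0]")
    if np.any(paco2 < 0):
        raise ValueError("paco2 must be non-negative")
    out = (
        fio2 * (constants.barometric_pressure - constants.water_vapor_pressure)
        - paco2 / constants.respiratory_quotient
    )
    return float(out) if out.ndim == 0 else out


def odc_saturation(po2, constants: PhysioConstants = PhysioConstants()):
    """Hemoglobin O2 saturation (fraction) at a given PO2 (mmHg)."""
    po2 = np.asarray(po2, dtype=float)
    if np.any(po2 < 0):
        raise ValueError("po2 must be non-negative")
    if constants.odc_model == "hill":
        n = constants.hill_coefficient
        with np.errstate(divide="ignore", invalid="ignore"):
            s = np.where(po2 > 0, po2**n / (po2**n + constants.odc_p50**n), 0.0)
    else:
        x = po2 * (SEVERINGHAUS_P50 / constants.odc_p50)
        poly = x**3 + 150.0 * x
        with np.errstate(divide="ignore"):
            s = np.where(poly > 0, 1.0 / (1.0 + 23400.0 / np.maximum(poly, 1e-300)), 0.0)
    return float(s) if s.ndim == 0 else s


def odc_po2(sat, constants: PhysioConstants = PhysioConstants()):
    """Inverse dissociation curve: PO2 (mmHg) at a given saturation.

    Saturation must lie strictly inside (0, 1); the curve is unbounded at
    the endpoints.
    """
    sat = np.asarray(sat, dtype=float)
    if np.any(sat <= 0) or np.any(sat >= 1):
        raise ValueError("saturation must lie strictly in (0, 1)")
    if constants.odc_model == "hill":
        out = constants.odc_p50 * (sat / (1.0 - sat)) ** (1.0 / constants.hill_coefficient)
    else:
        # Solve x^3 + 150 x = K with K = 23400 S/(1-S); single real root.
        k = 23400.0 * sat / (1.0 - sat) / 2.0
        d = np.sqrt(k * k + 50.0**3)
        x = np.cbrt(k + d) + np.cbrt(k - d)
        out = x * (constants.odc_p50 / SEVERINGHAUS_P50)
    return float(out) if out.ndim == 0 else out


def saturation_from_content(
    cvo2,
    hb,
    constants: PhysioConstants = PhysioConstants(),
    po2_max: float | np.ndarray = 150.0,
):
    """Invert an O2 content (ml/L) to a saturation, clamped to [0, 1].

    Solves ``cvo2 = hb * huefner * s + solubility * po2(s)`` for ``s`` with
    the dissolved term's PO2 capped at ``po2_max`` (physically, end-capillary
    PO2 cannot exceed alveolar PO2). Contents <= 0 return 0 and contents at
    or above the ceiling return 1 — the clamping the capnodynamic method
    exhibits during extreme transients.

    The solve is a damped fixed-point iteration on the bracket [0, 1]
    (the dissolved term is a small contraction), vectorized over inputs;
    it converges well below 1e-9.
    """
    cvo2 = np.asarray(cvo2, dtype=float)
    hb_arr = np.asarray(hb, dtype=float)
    cap = np.asarray(po2_max, dtype=float)
    if np.any(hb_arr <= 0):
        raise ValueError("hemoglobin must be strictly positive")

    scalar = cvo2.ndim == 0 and hb_arr.ndim == 0 and cap.ndim == 0
    cvo2, hb_arr, cap = np.broadcast_arrays(
        np.atleast_1d(cvo2), np.atleast_1d(hb_arr), np.atleast_1d(cap)
    )
    bound = hb_arr * constants.huefner_capacity
    ceiling = bound + constants.o2_solubility * cap

    lo_eps = 1e-15
    hi_eps = 1.0 - 1e-12
    s = np.clip(cvo2 / bound, lo_eps, hi_eps)
    for _ in range(200):
        po2 = np.minimum(odc_po2(np.clip(s, lo_eps, hi_eps), constants), cap)
        s_new = np.clip((cvo2 - constants.o2_solubility * po2) / bound, lo_eps, hi_eps)
        step = 0.5 * (s_new - s)
        s = s + step
        if np.max(np.abs(step)) < 1e-14:
            break

    s = np.where(cvo2 <= 0, 0.0, s)
    s = np.where(cvo2 >= ceiling, 1.0, s)
    return float(s[0]) if scalar else s


def co2_content(pco2, constants: PhysioConstants = PhysioConstants()):
    """Blood CO2 content (ml/L) from a linearized CO2 dissociation relation."""
    pco2 = np.asarray(pco2, dtype=float)
    if np.any(pco2 < 0):
        raise ValueError("pco2 must be non-negative")
    out = constants.co2_content_slope * pco2 + constants.co2_content_intercept
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class BloodGasState:
    """Oxygen state of one blood compartment."""

    hemoglobin: float  # g/L
    saturation: float  # fraction
    po2: float  # mmHg
    o2_content: float  # ml/L

    @classmethod
    def from_components(
        cls, hemoglobin: float, saturation: float, po2: float,
        constants: PhysioConstants = PhysioConstants(),
    ) -> "BloodGasState":
        return cls(
            hemoglobin=hemoglobin,
            saturation=saturation,
            po2=po2,
            o2_content=oxygen_content(hemoglobin, saturation, po2, constants),
        )

    def validate(self, constants: PhysioConstants = PhysioConstants()) -> None:
        expected = oxygen_content(self.hemoglobin, self.saturation, self.po2, constants)
        if abs(expected - self.o2_content) > 1e-9:
            raise ValueError("o2_content inconsistent with components")
        if self.o2_content < 0:
            raise ValueError("o2_content must be non-negative")


@dataclass(frozen=True)
class AlveolarGasState:
    """Alveolar gas composition."""

    fio2: float
    paco2_alv: float  # mmHg
    pao2_alv: float  # mmHg

    @classmethod
    def from_fio2(
        cls, fio2: float, paco2_alv: float,
        constants: PhysioConstants = PhysioConstants(),
    ) -> "AlveolarGasState":
        return cls(fio2=fio2, paco2_alv=paco2_alv,
                   pao2_alv=alveolar_po2(fio2, paco2_alv, constants))
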
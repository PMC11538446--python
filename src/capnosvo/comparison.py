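"""Method-comparison statistics for repeated SvO2 recordings.

Implements the agreement analysis used to validate a test SvO2 monitor
against a reference (CO-oximetry): inherent precision (2 x coefficient of
variation of repeated baseline readings), the least significant change
(LSC = precision * sqrt(2)), Bland-Altman limits of agreement corrected for
repeated measurements (multiple observations per individual where the true
value varies; one-way variance components), and four-quadrant concordance
of paired change-values with an exclusion zone derived from the reference
method's LSC.

All saturations here are percentage points (0-100), matching how such data
are recorded and reported clinically.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "RecordingPoint",
    "ComparisonResult",
    "ConcordanceResult",
    "DEFAULT_EXTREMES",
    "inherent_precision",
    "least_significant_change",
    "bland_altman_repeated",
    "select_intervention_extremes",
    "concordance",
    "compare_recordings",
]

logger = logging.getLogger(__name__)

#: Pre/post recording slots defining the anticipated SvO2 extremes of each
#: protocol intervention (FiO2 uses the lowest and highest inspired-oxygen
#: steps; hemorrhage/retransfusion bracket the blood withdrawal and return).
DEFAULT_EXTREMES: dict[str, tuple[str, str]] = {
    "sepsis_induction": ("induction_bl", "sepsis_60"),
    "crystalloid_bolus": ("bolus_pre", "bolus_post"),
    "fio2": ("fio2_0.3", "fio2_1.0"),
    "peep": ("peep_baseline", "peep_15"),
    "dobutamine": ("dobutamine_pre", "dobutamine_post"),
    "norepinephrine": ("norepi_pre", "norepi_post"),
    "hemorrhage": ("hemorrhage_pre", "hemorrhage_post"),
    "retransfusion": ("retransfusion_pre", "retransfusion_post"),
}


@dataclass(frozen=True)
class RecordingPoint:
    """One timestamped SvO2 reading from one method in one animal/phase."""

    animal_id: str
    phase: str
    t: float  # s
    method: str  # co_oximetry | fiberoptic | capno
    svo2: float  # percentage points

    def __post_init__(self) -> None:
        if not 0 <= self.svo2 <= 100:
            raise ValueError("svo2 must lie in [0, 100] percentage points")


@dataclass(frozen=True)
class ComparisonResult:
    """Bland-Altman agreement summary (percentage points)."""

    bias: float
    loa_low: float
    loa_high: float
    sd_diff: float
    bias_ci: tuple[float, float]
    loa_low_ci: tuple[float, float]
    loa_high_ci: tuple[float, float]
    n_pairs: int
    n_animals: int
    warning: str = ""


@dataclass(frozen=True)
class ConcordanceResult:
    """Four-quadrant concordance summary."""

    n_total: int
    n_outside: int  # pairs retained outside the exclusion zone
    n_concordant: int
    rate: float  # percent, unrounded (NaN when nothing retained)
    rate_ci: tuple[float, float]
    exclusion_zone: float  # percentage points


def inherent_precision(repeats) -> float:
    """Inherent precision (%) of repeated stable-baseline measurements.

    Defined as 2 x CV where CV = sample SD / mean (n-1 denominator).
    """
    x = np.asarray(repeats, dtype=float)
    if x.size < 2:
        raise ValueError("need at least two repeated measurements")
    if np.any(x <= 0):
        raise ValueError("repeated measurements must be positive")
    mean = float(np.mean(x))
    if mean <= 0:
        raise ValueError("mean of repeats must be positive")
    return 2.0 * float(np.std(x, ddof=1)) / mean * 100.0


def least_significant_change(precision: float) -> float:
    """LSC (%): the minimal relative change distinguishable from noise.

    LSC = precision * sqrt(2); callers round to the nearest integer percent
    for reporting.
    """
    if precision < 0:
        raise ValueError("precision must be non-negative")
    return precision * np.sqrt(2.0)


def _simple_bland_altman(d: np.ndarray, n_animals: int, warning: str) -> ComparisonResult:
    n = d.size
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1)) if n > 1 else 0.0
    z = 1.959963984540054
    se_bias = sd / np.sqrt(n) if n > 0 else np.nan
    se_loa = np.sqrt(se_bias**2 + z**2 * sd**2 / (2 * max(n - 1, 1)))
    tq = stats.t.ppf(0.975, max(n - 1, 1))
    return ComparisonResult(
        bias=bias,
        loa_low=bias - z * sd,
        loa_high=bias + z * sd,
        sd_diff=sd,
        bias_ci=(bias - tq * se_bias, bias + tq * se_bias),
        loa_low_ci=(bias - z * sd - tq * se_loa, bias - z * sd + tq * se_loa),
        loa_high_ci=(bias + z * sd - tq * se_loa, bias + z * sd + tq * se_loa),
        n_pairs=n,
        n_animals=n_animals,
        warning=warning,
    )


def bland_altman_repeated(
    pairs: pd.DataFrame,
    test_col: str = "test",
    ref_col: str = "reference",
    animal_col: str = "animal_id",
) -> ComparisonResult:
    """Bland-Altman agreement corrected for repeated measurements.

    Uses the multiple-observations-per-individual method for the case where
    the underlying true value varies between paired observations: a one-way
    variance decomposition of the differences into between-animal and
    within-animal components,

        sd_total^2 = (MSB - MSW) / m0 + MSW,
        m0 = (N - sum(n_i^2)/N) / (I - 1),

    so the limits of agreement describe a future difference in a new
    subject. Bias is the grand mean of test - reference. With a single
    animal (or one pair per animal) the method falls back to a simple
    Bland-Altman with a warning flag.

    Confidence intervals: bias via t(I-1) with variance sigma_b^2/I +
    sigma_w^2/N; limits of agreement via the standard approximation
    Var(LoA) = Var(bias) + z^2 sd^2 / (2(N-1)) with t(N-1).
    """
    d = (pairs[test_col] - pairs[ref_col]).to_numpy(float)
    groups = pairs[animal_col].to_numpy()
    ids, counts = np.unique(groups, return_counts=True)
    n_animals = len(ids)
    n = d.size
    if n < 2:
        raise ValueError("need at least two pairs")
    if n_animals == 1:
        return _simple_bland_altman(d, 1, "single_animal_simple_ba")
    if np.all(counts == 1):
        return _simple_bland_altman(d, n_animals, "one_pair_per_animal_simple_ba")

    bias = float(np.mean(d))
    group_means = np.array([d[groups == g].mean() for g in ids])
    ssw = float(sum(((d[groups == g] - m) ** 2).sum() for g, m in zip(ids, group_means)))
    ssb = float((counts * (group_means - bias) ** 2).sum())
    msw = ssw / (n - n_animals)
    msb = ssb / (n_animals - 1)
    m0 = (n - (counts**2).sum() / n) / (n_animals - 1)
    var_b = max((msb - msw) / m0, 0.0)
    sd = float(np.sqrt(var_b + msw))

    z = 1.959963984540054
    se_bias = float(np.sqrt(var_b / n_animals + msw / n))
    tq_b = stats.t.ppf(0.975, n_animals - 1)
    se_loa = float(np.sqrt(se_bias**2 + z**2 * sd**2 / (2 * (n - 1))))
    tq_l = stats.t.ppf(0.975, n - 1)
    loa_low = bias - z * sd
    loa_high = bias + z * sd
    return ComparisonResult(
        bias=bias,
        loa_low=loa_low,
        loa_high=loa_high,
        sd_diff=sd,
        bias_ci=(bias - tq_b * se_bias, bias + tq_b * se_bias),
        loa_low_ci=(loa_low - tq_l * se_loa, loa_low + tq_l * se_loa),
        loa_high_ci=(loa_high - tq_l * se_loa, loa_high + tq_l * se_loa),
        n_pairs=n,
        n_animals=n_animals,
    )


def select_intervention_extremes(
    recordings: pd.DataFrame,
    extremes: Mapping[str, tuple[str, str]] = DEFAULT_EXTREMES,
    reference: str = "co_oximetry",
) -> pd.DataFrame:
    """Change-pairs (delta test, delta reference) at intervention extremes.

    For every animal and intervention, the change is post-slot minus
    pre-slot on each method; a pair is emitted per test method only if both
    slots exist for that method and the reference. Missing slots are skipped
    and logged.

    Returns columns: animal_id, intervention, method, delta_test,
    delta_reference.
    """
    values = recordings.set_index(["animal_id", "method", "phase"])["svo2_pct"]
    methods = [m for m in recordings["method"].unique() if m != reference]
    rows = []
    for animal in recordings["animal_id"].unique():
        for intervention, (pre, post) in extremes.items():
            try:
                ref_delta = values[(animal, reference, post)] - values[(animal, reference, pre)]
            except KeyError:
                logger.info(
                    "skipping %s/%s: missing reference slot %s or %s",
                    animal, intervention, pre, post,
                )
                continue
            for method in methods:
                try:
                    test_delta = values[(animal, method, post)] - values[(animal, method, pre)]
                except KeyError:
                    logger.info(
                        "skipping %s/%s/%s: missing test slot", animal, intervention, method
                    )
                    continue
                rows.append(
                    {
                        "animal_id": animal,
                        "intervention": intervention,
                        "method": method,
                        "delta_test": float(test_delta),
                        "delta_reference": float(ref_delta),
                    }
                )
    return pd.DataFrame(
        rows, columns=["animal_id", "intervention", "method", "delta_test", "delta_reference"]
    )


def concordance(
    delta_pairs: pd.DataFrame,
    exclusion_zone: float,
    ci_method: str = "wilson",
) -> ConcordanceResult:
    """Four-quadrant concordance rate with an exclusion zone.

    Pairs whose reference change is within the exclusion zone (in absolute
    percentage points) are dropped; the rate is the percentage of retained
    pairs whose test change has the same sign as the reference change (a
    zero test change counts as discordant). CI: Wilson score by default.
    """
    if exclusion_zone < 0:
        raise ValueError("exclusion zone must be non-negative")
    d_test = delta_pairs["delta_test"].to_numpy(float)
    d_ref = delta_pairs["delta_reference"].to_numpy(float)
    retained = np.abs(d_ref) > exclusion_zone
    n_outside = int(retained.sum())
    if n_outside == 0:
        return ConcordanceResult(
            n_total=len(d_ref), n_outside=0, n_concordant=0,
            rate=float("nan"), rate_ci=(float("nan"), float("nan")),
            exclusion_zone=exclusion_zone,
        )
    concordant = (d_test[retained] * d_ref[retained]) > 0
    n_conc = int(concordant.sum())
    lo, hi = proportion_confint(n_conc, n_outside, alpha=0.05, method=ci_method)
    return ConcordanceResult(
        n_total=len(d_ref),
        n_outside=n_outside,
        n_concordant=n_conc,
        rate=100.0 * n_conc / n_outside,
        rate_ci=(100.0 * float(lo), 100.0 * float(hi)),
        exclusion_zone=exclusion_zone,
    )


@dataclass
class CompareReport:
    """Full method-comparison report plus the tidy tables behind the plots."""

    precision: dict[str, float]
    lsc_pct: float
    lsc_pct_rounded: int
    exclusion_zone: float
    reference: str
    bland_altman: dict[str, ComparisonResult]
    concordance: dict[str, ConcordanceResult]
    ba_pairs: pd.DataFrame = field(repr=False)
    delta_pairs: pd.DataFrame = field(repr=False)

    def to_dict(self) -> dict:
        out: dict = {
            "reference": self.reference,
            "precision_pct": {k: round(v, 3) for k, v in self.precision.items()},
            "lsc_pct": round(self.lsc_pct, 3),
            "lsc_pct_rounded": self.lsc_pct_rounded,
            "exclusion_zone_points": self.exclusion_zone,
            "bland_altman": {},
            "concordance": {},
        }
        for m, r in self.bland_altman.items():
            out["bland_altman"][m] = {
                "bias": round(r.bias, 3),
                "loa_low": round(r.loa_low, 3),
                "loa_high": round(r.loa_high, 3),
                "sd_diff": round(r.sd_diff, 3),
                "bias_ci": [round(x, 3) for x in r.bias_ci],
                "loa_low_ci": [round(x, 3) for x in r.loa_low_ci],
                "loa_high_ci": [round(x, 3) for x in r.loa_high_ci],
                "n_pairs": r.n_pairs,
                "n_animals": r.n_animals,
                "warning": r.warning,
            }
        for m, r in self.concordance.items():
            out["concordance"][m] = {
                "n_total": r.n_total,
                "n_outside": r.n_outside,
                "n_concordant": r.n_concordant,
                "rate_pct": None if np.isnan(r.rate) else round(r.rate, 3),
                "rate_pct_rounded": None if np.isnan(r.rate) else round(r.rate),
                "rate_ci": [None if np.isnan(x) else round(x, 3) for x in r.rate_ci],
                "exclusion_zone_points": r.exclusion_zone,
            }
        return out


def compare_recordings(
    recordings: pd.DataFrame,
    reference: str = "co_oximetry",
    exclusion_zone_points: float | None = None,
    baseline_phase_prefix: str = "precision_bl",
    extremes: Mapping[str, tuple[str, str]] = DEFAULT_EXTREMES,
    ci_method: str = "wilson",
) -> CompareReport:
    """Run the full comparison analysis on a long recordings table.

    Expects columns animal_id, phase, t_s, method, svo2_pct. Precision per
    method is the mean over animals of each animal's 2xCV across the
    baseline repeat readings; the exclusion zone, unless overridden, is the
    reference LSC (relative %) times the mean baseline reference SvO2,
    rounded to integer percentage points.
    """
    if reference not in set(recordings["method"]):
        raise ValueError(f"no rows for reference method '{reference}'")

    baseline = recordings[recordings["phase"].str.startswith(baseline_phase_prefix)]
    precision: dict[str, float] = {}
    for method, grp in baseline.groupby("method"):
        per_animal = [
            inherent_precision(sub["svo2_pct"].to_numpy())
            for _, sub in grp.groupby("animal_id")
            if len(sub) >= 2
        ]
        if per_animal:
            precision[method] = float(np.mean(per_animal))

    lsc = least_significant_change(precision[reference]) if reference in precision else float("nan")
    if exclusion_zone_points is None:
        ref_baseline_mean = float(
            baseline[baseline["method"] == reference]["svo2_pct"].mean()
        )
        exclusion_zone_points = float(round(lsc / 100.0 * ref_baseline_mean))

    ref_rows = recordings[recordings["method"] == reference]
    ba_results: dict[str, ComparisonResult] = {}
    ba_tables = []
    for method in sorted(set(recordings["method"]) - {reference}):
        test_rows = recordings[recordings["method"] == method]
        merged = test_rows.merge(
            ref_rows, on=["animal_id", "phase"], suffixes=("_test", "_ref")
        )
        merged = merged.dropna(subset=["svo2_pct_test", "svo2_pct_ref"])
        pairs = pd.DataFrame(
            {
                "animal_id": merged["animal_id"],
                "phase": merged["phase"],
                "t_s": merged["t_s_test"],
                "method": method,
                "test": merged["svo2_pct_test"],
                "reference": merged["svo2_pct_ref"],
            }
        )
        pairs["difference"] = pairs["test"] - pairs["reference"]
        pairs["mean"] = (pairs["test"] + pairs["reference"]) / 2.0
        ba_results[method] = bland_altman_repeated(pairs)
        ba_tables.append(pairs)

    delta_pairs = select_intervention_extremes(recordings, extremes, reference)
    conc_results = {
        method: concordance(
            delta_pairs[delta_pairs["method"] == method], exclusion_zone_points, ci_method
        )
        for method in sorted(delta_pairs["method"].unique())
    }

    return CompareReport(
        precision=precision,
        lsc_pct=float(lsc),
        lsc_pct_rounded=int(round(lsc)) if np.isfinite(lsc) else 0,
        exclusion_zone=float(exclusion_zone_points),
        reference=reference,
        bland_altman=ba_results,
        concordance=conc_results,
        ba_pairs=pd.concat(ba_tables, ignore_index=True) if ba_tables else pd.DataFrame(),
        delta_pairs=delta_pairs,
    )
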
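"""Precision/LSC, repeated-measures Bland-Altman, four-quadrant concordance."""

import numpy as np
import pandas as pd
import pytest

from capnosvo.comparison import (
    bland_altman_repeated,
    compare_recordings,
    concordance,
    inherent_precision,
    least_significant_change,
    select_intervention_extremes,
)


class TestInherentPrecision:
    def test_constant_series_has_zero_precision(self):
        assert inherent_precision([60, 60, 60, 60, 60]) == 0.0

    def test_hand_computed_example(self):
        # mean 60, sample SD sqrt(10/4) = 1.5811
        assert inherent_precision([60, 62, 58, 61, 59]) == pytest.approx(5.270, abs=1e-3)

    def test_scale_invariance(self):
        x = np.array([60, 62, 58, 61, 59], float)
        assert inherent_precision(3.7 * x) == pytest.approx(inherent_precision(x))

    def test_nonpositive_values_rejected(self):
        with pytest.raises(ValueError):
            inherent_precision([60, -1, 58])


class TestLeastSignificantChange:
    @pytest.mark.parametrize(
        "precision, rounded", [(11.0, 16), (0.0, 0), (7.07, 10)]
    )
    def test_sqrt2_scaling_and_rounding(self, precision, rounded):
        assert round(least_significant_change(precision)) == rounded

    def test_exact_value(self):
        assert least_significant_change(11.0) == pytest.approx(15.5563, abs=1e-3)


def _pairs(animals, test, ref):
    return pd.DataFrame({"animal_id": animals, "test": test, "reference": ref})


class TestBlandAltmanRepeated:
    def test_identical_methods(self):
        x = [60.0, 55.0, 70.0, 40.0, 52.0, 61.0]
        res = bland_altman_repeated(_pairs(["a"] * 3 + ["b"] * 3, x, x))
        assert res.bias == 0.0
        assert res.loa_high - res.loa_low == 0.0

    def test_constant_offset(self):
        ref = np.array([60.0, 55.0, 70.0, 40.0, 52.0, 61.0])
        res = bland_altman_repeated(_pairs(["a"] * 3 + ["b"] * 3, ref + 5, ref))
        assert res.bias == pytest.approx(5.0)
        assert res.sd_diff == pytest.approx(0.0, abs=1e-12)

    def test_matches_anova_oracle_to_1e10(self):
        # 3 animals x 5 pairs with distinct per-animal offsets and noise
        rng = np.random.default_rng(42)
        animals = np.repeat(["a", "b", "c"], 5)
        subject_effect = np.repeat(rng.normal(0, 2.0, 3), 5)
        d = 1.5 + subject_effect + rng.normal(0, 1.0, 15)
        ref = rng.uniform(40, 70, 15)
        res = bland_altman_repeated(_pairs(animals, ref + d, ref))

        # independent variance-components oracle via statsmodels one-way ANOVA
        import statsmodels.api as sm
        from statsmodels.formula.api import ols

        frame = pd.DataFrame({"d": d, "animal": animals})
        table = sm.stats.anova_lm(ols("d ~ C(animal)", frame).fit())
        msb = table["mean_sq"]["C(animal)"]
        msw = table["mean_sq"]["Residual"]
        counts = np.array([5, 5, 5])
        n, i = 15, 3
        m0 = (n - (counts**2).sum() / n) / (i - 1)
        sd_oracle = np.sqrt(max((msb - msw) / m0, 0.0) + msw)
        assert res.bias == pytest.approx(d.mean(), abs=1e-10)
        assert res.sd_diff == pytest.approx(sd_oracle, abs=1e-10)
        assert res.loa_low == pytest.approx(d.mean() - 1.96 * sd_oracle, abs=2e-3)
        assert res.loa_high == pytest.approx(d.mean() + 1.96 * sd_oracle, abs=2e-3)

    def test_recovers_injected_bias_and_sd(self):
        # 12 animals x 25 pairs; between-animal SD 1, within SD 2
        rng = np.random.default_rng(11)
        n_animals, n_per = 12, 25
        animals = np.repeat([f"p{i}" for i in range(n_animals)], n_per)
        d = (
            2.0
            + np.repeat(rng.normal(0, 1.0, n_animals), n_per)
            + rng.normal(0, 2.0, n_animals * n_per)
        )
        ref = rng.uniform(40, 70, d.size)
        res = bland_altman_repeated(_pairs(animals, ref + d, ref))
        sd_true = np.sqrt(1.0 + 4.0)
        assert res.bias == pytest.approx(2.0, abs=2 * sd_true / np.sqrt(d.size) + 0.6)
        assert res.loa_high - res.loa_low == pytest.approx(2 * 1.96 * sd_true, rel=0.10)

    def test_single_animal_falls_back_to_simple(self):
        rng = np.random.default_rng(0)
        ref = rng.uniform(40, 70, 8)
        res = bland_altman_repeated(_pairs(["a"] * 8, ref + 3, ref))
        assert res.warning == "single_animal_simple_ba"
        assert res.bias == pytest.approx(3.0)

    def test_loa_bracket_bias(self):
        rng = np.random.default_rng(3)
        animals = np.repeat(list("abcd"), 6)
        ref = rng.uniform(40, 70, 24)
        res = bland_altman_repeated(_pairs(animals, ref + rng.normal(1, 2, 24), ref))
        assert res.loa_low <= res.bias <= res.loa_high


def _recordings(rows):
    return pd.DataFrame(rows, columns=["animal_id", "phase", "t_s", "method", "svo2_pct"])


class TestSelectInterventionExtremes:
    def test_delta_is_post_minus_pre_per_method(self):
        rows = []
        for m, pre, post in [("co_oximetry", 60, 50), ("capno", 62, 49)]:
            rows.append(("a", "hemorrhage_pre", 0, m, pre))
            rows.append(("a", "hemorrhage_post", 600, m, post))
        extremes = {"hemorrhage": ("hemorrhage_pre", "hemorrhage_post")}
        out = select_intervention_extremes(_recordings(rows), extremes)
        assert len(out) == 1
        assert out.delta_test[0] == pytest.approx(-13.0)
        assert out.delta_reference[0] == pytest.approx(-10.0)

    def test_missing_post_recording_contributes_nothing(self):
        rows = [
            ("a", "fio2_0.3", 0, "co_oximetry", 60),
            ("a", "fio2_0.3", 0, "capno", 61),
            ("a", "fio2_1.0", 900, "co_oximetry", 72),
            # capno post slot missing
        ]
        extremes = {"fio2": ("fio2_0.3", "fio2_1.0")}
        out = select_intervention_extremes(_recordings(rows), extremes)
        assert out.empty


class TestConcordance:
    def _pairs(self, n_total, n_discordant, magnitude=15.0):
        half = n_total // 2
        ref = np.array([magnitude] * half + [-magnitude] * (n_total - half))
        test = ref.copy()
        test[:n_discordant] *= -1
        return pd.DataFrame({"delta_test": test, "delta_reference": ref})

    def test_sixty_eight_of_seventy(self):
        res = concordance(self._pairs(70, 2), exclusion_zone=10.0)
        assert res.n_outside == 70
        assert res.n_concordant == 68
        assert round(res.rate) == 97

    def test_five_discordant_of_seventy(self):
        res = concordance(self._pairs(70, 5), exclusion_zone=10.0)
        assert round(res.rate) == 93

    def test_all_concordant(self):
        res = concordance(self._pairs(20, 0), exclusion_zone=5.0)
        assert res.rate == 100.0
        assert res.rate_ci[1] == pytest.approx(100.0, abs=0.01)

    def test_widening_zone_never_increases_retained_pairs(self):
        rng = np.random.default_rng(5)
        pairs = pd.DataFrame(
            {
                "delta_test": rng.normal(0, 10, 200),
                "delta_reference": rng.normal(0, 10, 200),
            }
        )
        outside = [concordance(pairs, z).n_outside for z in np.linspace(0, 25, 11)]
        assert all(a >= b for a, b in zip(outside, outside[1:]))

    def test_zone_membership_uses_reference_only(self):
        pairs = pd.DataFrame(
            {"delta_test": [3.0, 20.0], "delta_reference": [20.0, 3.0]}
        )
        res = concordance(pairs, exclusion_zone=10.0)
        swapped = concordance(
            pairs.rename(
                columns={"delta_test": "delta_reference", "delta_reference": "delta_test"}
            ),
            exclusion_zone=10.0,
        )
        # the retained pair differs when roles are exchanged
        assert res.n_outside == swapped.n_outside == 1
        assert res.rate == swapped.rate  # both retained pairs concordant in sign

    def test_empty_retained_set_gives_explicit_empty_result(self):
        pairs = pd.DataFrame({"delta_test": [1.0], "delta_reference": [1.0]})
        res = concordance(pairs, exclusion_zone=10.0)
        assert res.n_outside == 0
        assert np.isnan(res.rate)


class TestCompareRecordings:
    def test_duplicated_reference_yields_zero_bias_full_concordance(self):
        rng = np.random.default_rng(2)
        rows = []
        for animal in ("a", "b"):
            base = rng.uniform(55, 65)
            for i in range(1, 6):
                v = base + rng.normal(0, 2)
                for m in ("co_oximetry", "capno", "fiberoptic"):
                    rows.append((animal, f"precision_bl_{i}", i * 300, m, v))
            for phase, t, v in [
                ("hemorrhage_pre", 2000, base),
                ("hemorrhage_post", 2600, base - 20),
            ]:
                for m in ("co_oximetry", "capno", "fiberoptic"):
                    rows.append((animal, phase, t, m, v))
        extremes = {"hemorrhage": ("hemorrhage_pre", "hemorrhage_post")}
        report = compare_recordings(_recordings(rows), extremes=extremes)
        for res in report.bland_altman.values():
            assert res.bias == pytest.approx(0.0, abs=1e-12)
        for res in report.concordance.values():
            assert res.rate == 100.0

    def test_missing_reference_method_rejected(self):
        rows = [("a", "precision_bl_1", 0, "capno", 60)]
        with pytest.raises(ValueError, match="reference"):
            compare_recordings(_recordings(rows))
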
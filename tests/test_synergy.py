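"""FPI classification and Chou-Talalay combination-index algebra."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from phytosynergy import (
    MixtureSpec,
    ci_curve,
    classify_ci,
    combination_index,
    dose_reduction_index,
    fpi,
    gen_loewe_mixture,
    isobologram_points,
)
from phytosynergy.median_effect import DoseResponseCurve, MedianEffectModel, MedianEffectResults

#: Single-herb DPPH inhibitions at 250 ug/mL (GM, CC, AE).
DPPH_SINGLES = (69.68, 74.35, 30.74)


def me(m, dm):
    return MedianEffectResults.from_parameters(m=m, dm=dm)


class TestMixtureSpec:
    def test_from_masses_10_15_5(self):
        mix = MixtureSpec.from_masses((10, 15, 5))
        assert mix.fractions == pytest.approx((1 / 3, 1 / 2, 1 / 6))

    def test_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError):
            MixtureSpec(labels=("a", "b"), fractions=(0.6, 0.6))


class TestFPI:
    def test_best_antioxidant_combination_rounds_to_half(self):
        result = fpi(80.33, DPPH_SINGLES)
        assert result.rounded_1dp == 0.5
        assert result.fpi == pytest.approx(80.33 / 174.77, rel=1e-12)

    def test_other_combination_rounds_to_point_four(self):
        assert fpi(77.20, DPPH_SINGLES).rounded_1dp == 0.4

    def test_combo_equal_to_sum_is_additive(self):
        result = fpi(60.0, (20.0, 30.0, 10.0))
        assert result.fpi == pytest.approx(1.0)
        assert result.classification == "additivity"

    @pytest.mark.parametrize("combo,singles,expected", [
        (2.0, (0.5, 0.25, 0.25), "synergism"),    # FPI exactly 2.0: closed boundary
        (0.5, (0.5, 0.25, 0.25), "additivity"),   # FPI exactly 0.5: closed boundary
        (0.4999, (0.5, 0.25, 0.25), "antagonism"),
        (1.9999, (0.5, 0.25, 0.25), "additivity"),
    ])
    def test_classification_boundaries(self, combo, singles, expected):
        assert fpi(combo, singles).classification == expected

    def test_half_up_rounding_convention(self):
        # 0.45 rounds up to 0.5, not banker's 0.4
        assert fpi(45.0, (50.0, 25.0, 25.0)).rounded_1dp == 0.5

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError):
            fpi(50.0, (0.0, 0.0, 0.0))


class TestCombinationIndex:
    def test_worked_example(self):
        """Half-half mixture of Dm=10 and Dm=20 agents whose mixture has
        Dm=12: CI = 0.5*12/10 + 0.5*12/20 = 0.9 at fa = 0.5."""
        mix = MixtureSpec(labels=("a", "b", "c"), fractions=(0.5, 0.5, 0.0))
        fits = [me(1, 10), me(1, 20), me(1, 50)]
        ci = combination_index(0.5, mix, fits, me(1, 12))
        assert ci == pytest.approx(0.9, rel=1e-12)

    @given(
        w1=st.floats(0.05, 0.9),
        fa=st.floats(0.02, 0.98),
        m=st.floats(0.5, 4.0),
        dm=st.floats(1.0, 300.0),
    )
    @settings(derandomize=True, max_examples=80)
    def test_sham_combination_law(self, w1, fa, m, dm):
        """A mixture of an agent with itself has CI = 1 at every fa,
        independent of the weights."""
        w2 = 1.0 - w1
        mix = MixtureSpec(labels=("a", "b"), fractions=(w1, w2))
        fit = me(m, dm)
        ci = combination_index(fa, mix, [fit, fit], fit)
        assert ci == pytest.approx(1.0, abs=1e-9)

    def test_dri_worked_example(self):
        mix = MixtureSpec(labels=("a", "b", "c"), fractions=(0.5, 0.5, 0.0))
        fits = [me(1, 10), me(1, 20), me(1, 50)]
        dri = dose_reduction_index(0.5, mix, fits, me(1, 12))
        assert dri[0] == pytest.approx(10 / 6, rel=1e-12)
        assert dri[1] == pytest.approx(20 / 6, rel=1e-12)
        assert dri[2] is None

    def test_sham_half_half_dri_is_two(self):
        mix = MixtureSpec(labels=("a", "b", "c"), fractions=(0.5, 0.5, 0.0))
        fit = me(1.5, 25)
        dri = dose_reduction_index(0.5, mix, [fit, fit, fit], fit)
        assert dri[0] == pytest.approx(2.0)
        assert dri[1] == pytest.approx(2.0)

    @given(fa=st.floats(0.05, 0.95))
    @settings(derandomize=True, max_examples=50)
    def test_ci_equals_sum_of_reciprocal_dri(self, fa):
        mix = MixtureSpec.from_masses((10, 15, 5))
        fits = [me(1.2, 11), me(2.1, 33), me(0.8, 7)]
        mixture_fit = me(1.5, 15)
        ci = combination_index(fa, mix, fits, mixture_fit)
        dri = dose_reduction_index(fa, mix, fits, mixture_fit)
        assert ci == pytest.approx(sum(1 / d for d in dri if d is not None), abs=1e-12)


class TestCIClassification:
    def test_strict_rule(self):
        assert classify_ci(0.8, additive_band=0) == "synergism"
        assert classify_ci(1.2, additive_band=0) == "antagonism"
        assert classify_ci(1.0, additive_band=0) == "additive"

    def test_band_marks_nearly_additive(self):
        assert classify_ci(1.03) == "nearly additive"
        assert classify_ci(0.97) == "nearly additive"
        assert classify_ci(0.9) == "synergism"


class TestCICurve:
    def test_sham_curve_flat_at_one(self):
        mix = MixtureSpec.from_masses((10, 15, 5))
        fit = me(2.0, 40.0)
        profile = ci_curve(mix, [fit, fit, fit], fit)
        assert len(profile.table) == 19
        np.testing.assert_allclose(profile.table["ci"], 1.0, atol=1e-9)
        assert (profile.table["classification"] == "additive").all()

    def test_loewe_mixture_has_unit_ci_everywhere(self):
        """A constant-ratio mixture constructed under Loewe additivity,
        refitted and pushed through the CI pipeline, recovers CI = 1."""
        fits = [me(1.0, 10.0), me(1.0, 25.0), me(1.0, 60.0)]
        mix = MixtureSpec.from_masses((5, 10, 15))
        doses = tuple(np.geomspace(1.0, 400.0, 12))
        curve = gen_loewe_mixture(fits, mix, doses)
        mixture_fit = MedianEffectModel(curve).fit()
        profile = ci_curve(mix, fits, mixture_fit)
        np.testing.assert_allclose(profile.table["ci"], 1.0, atol=1e-6)

    def test_fixture_mixture_profile(self, bundle):
        """CI of the 5:10:15 mixture against the three single herbs from
        the three-dose NO-inhibition table."""
        t4 = bundle.table4
        doses = (10.0, 20.0, 50.0)

        def fit_row(gm, cc, ae):
            row = t4[(t4.gm_g == gm) & (t4.cc_g == cc) & (t4.ae_g == ae)].iloc[0]
            curve = DoseResponseCurve.from_percent_inhibition(
                doses, [row["inhibition_10"], row["inhibition_20"], row["inhibition_50"]]
            )
            return MedianEffectModel(curve).fit()

        singles = [fit_row(30, 0, 0), fit_row(0, 30, 0), fit_row(0, 0, 30)]
        mixture_fit = fit_row(5, 10, 15)
        profile = ci_curve(MixtureSpec.from_masses((5, 10, 15)), singles, mixture_fit)
        ci_mid = profile.ci_at(0.5)
        assert np.isfinite(ci_mid) and ci_mid > 0
        assert profile.table["classification"].isin(
            ["synergism", "additive", "nearly additive", "antagonism"]
        ).all()

    def test_single_point_grid(self):
        mix = MixtureSpec.from_masses((1, 1, 1))
        fit = me(1, 10)
        profile = ci_curve(mix, [fit, fit, fit], fit, fa_grid=[0.5])
        assert len(profile.table) == 1

    def test_grid_outside_unit_interval_rejected(self):
        mix = MixtureSpec.from_masses((1, 1, 1))
        fit = me(1, 10)
        with pytest.raises(ValueError):
            ci_curve(mix, [fit, fit, fit], fit, fa_grid=[0.0, 0.5])


class TestIsobologram:
    def test_sham_point_on_additivity_line(self):
        mix = MixtureSpec(labels=("a", "b"), fractions=(0.5, 0.5))
        fit = me(1, 10)
        x, y = isobologram_points(0.5, (0, 1), [fit, fit], mix, fit)
        assert x + y == pytest.approx(1.0, abs=1e-12)

    def test_worked_example_below_line(self):
        mix = MixtureSpec(labels=("a", "b", "c"), fractions=(0.5, 0.5, 0.0))
        fits = [me(1, 10), me(1, 20), me(1, 50)]
        x, y = isobologram_points(0.5, (0, 1), fits, mix, me(1, 12))
        assert (x, y) == pytest.approx((0.6, 0.3), rel=1e-12)
        assert x + y < 1

    @pytest.mark.parametrize("fa", [0.01, 0.99])
    def test_extreme_effect_levels_finite(self, fa):
        mix = MixtureSpec.from_masses((10, 15, 5))
        fits = [me(1.2, 11), me(2.1, 33), me(0.8, 7)]
        x, y = isobologram_points(fa, (0, 2), fits, mix, me(1.5, 15))
        assert np.isfinite(x) and np.isfinite(y)
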
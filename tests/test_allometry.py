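"""Closed forms, quadrature cross-checks, and scaling identities."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from megabiota import (
    AnimalSizeSpectrum,
    ExtinctionScaling,
    FluxParams,
    MetabolicParams,
    PlantSizeSpectrum,
    animal_total_biomass,
    animal_total_flux,
    conservation_gain,
    extinction_risk_ratio,
    metabolic_rate,
    npp_from_biomass,
    plant_mmax_exponent,
    plant_total_biomass,
    plant_total_flux,
)


class TestExtinctionRisk:
    @pytest.mark.parametrize(
        "scaling, ratio, expected",
        [
            (ExtinctionScaling(), 10.0, 316.2278),  # headline rule of thumb
            (ExtinctionScaling(), 1.0, 1.0),
            # component sum 2.25 when the composite override is dropped
            (ExtinctionScaling(b=1, c=0.25, d=1, composite_override=None), 10.0, 177.8279),
        ],
    )
    def test_risk_ratio_values(self, scaling, ratio, expected):
        assert extinction_risk_ratio(scaling, ratio) == pytest.approx(expected, rel=1e-4)

    def test_default_effective_exponent_is_headline(self):
        assert ExtinctionScaling().effective_exponent == 2.5

    def test_rejects_nonpositive_ratio(self):
        with pytest.raises(ValueError):
            extinction_risk_ratio(ExtinctionScaling(), 0.0)

    def test_rejects_negative_component_exponent(self):
        with pytest.raises(ValueError):
            ExtinctionScaling(b=-0.1)

    @settings(derandomize=True, max_examples=50)
    @given(
        x=st.floats(0.1, 100.0),
        y=st.floats(0.1, 100.0),
    )
    def test_power_law_composition(self, x, y):
        s = ExtinctionScaling()
        assert extinction_risk_ratio(s, x) * extinction_risk_ratio(s, y) == pytest.approx(
            extinction_risk_ratio(s, x * y), rel=1e-9
        )


class TestTotalsClosedForm:
    def test_plant_biomass_unit_spectrum(self):
        # integral of r^(8/3) * r^(-2) over (0, 1] = 3/5
        s = PlantSizeSpectrum(c_n=1, c_m=1, r_min=1e-9, r_max=1.0)
        assert plant_total_biomass(s) == pytest.approx(0.6)

    def test_animal_biomass_unit_spectrum(self):
        # integral of m^(1/4) over (0, 1] = 4/5
        s = AnimalSizeSpectrum(c_a=1, m_min=1e-9, m_max=1.0)
        assert animal_total_biomass(s) == pytest.approx(0.8)

    def test_plant_biomass_tenfold_radius_is_47x(self):
        s1 = PlantSizeSpectrum(r_max=1.0)
        s10 = PlantSizeSpectrum(r_max=10.0)
        ratio = plant_total_biomass(s10) / plant_total_biomass(s1)
        assert ratio == pytest.approx(10 ** (5 / 3), rel=1e-12)
        assert round(ratio) == 46

    def test_plant_flux_tenfold_radius_is_10x(self):
        p = FluxParams()
        s1 = PlantSizeSpectrum(r_max=1.0)
        s10 = PlantSizeSpectrum(r_max=10.0)
        assert plant_total_flux(s10, p) / plant_total_flux(s1, p) == pytest.approx(10.0)

    def test_animal_flux_tenfold_mass_is_18x(self):
        p = FluxParams()
        s1 = AnimalSizeSpectrum(m_max=1.0)
        s10 = AnimalSizeSpectrum(m_max=10.0)
        ratio = animal_total_flux(s10, p) / animal_total_flux(s1, p)
        assert ratio == pytest.approx(10**1.25, rel=1e-12)
        assert ratio == pytest.approx(17.78, abs=0.01)

    def test_vanishing_range_gives_vanishing_total(self):
        s = PlantSizeSpectrum(r_min=0.999999, r_max=1.0)
        assert plant_total_biomass(s, method="quadrature") == pytest.approx(0.0, abs=1e-4)

    def test_invalid_bounds_rejected(self):
        with pytest.raises(ValueError):
            PlantSizeSpectrum(r_min=1.0, r_max=0.5)
        with pytest.raises(ValueError):
            AnimalSizeSpectrum(m_min=2.0, m_max=1.0)


@pytest.mark.parametrize(
    "total",
    [
        lambda m: plant_total_biomass(
            PlantSizeSpectrum(c_n=2.0, c_m=3.0, r_min=1e-6, r_max=1.0), method=m
        ),
        lambda m: animal_total_biomass(
            AnimalSizeSpectrum(c_a=1.5, m_min=1e-6, m_max=1.0), method=m
        ),
        lambda m: plant_total_flux(
            PlantSizeSpectrum(c_n=2.0, r_min=1e-6, r_max=1.0), FluxParams(tau=2.0), m
        ),
        lambda m: animal_total_flux(
            AnimalSizeSpectrum(c_a=0.7, m_min=1e-6, m_max=1.0), FluxParams(B_0=3.0), m
        ),
    ],
    ids=["plant_biomass", "animal_biomass", "plant_flux", "animal_flux"],
)
def test_quadrature_matches_closed_form(total):
    """Lower cutoff at 1e-6 x upper: branches agree to relative 1e-4."""
    assert total("quadrature") == pytest.approx(total("closed"), rel=1e-4)


class TestExponentIdentities:
    """Log-log slopes over 3 decades recover the predicted exponents."""

    @staticmethod
    def _loglog_slope(f, uppers):
        logs = np.log(uppers)
        vals = np.log([f(u) for u in uppers])
        return np.polyfit(logs, vals, 1)[0]

    def test_plant_biomass_vs_rmax_is_5_3(self):
        slope = self._loglog_slope(
            lambda r: plant_total_biomass(PlantSizeSpectrum(r_max=r)),
            np.logspace(0, 3, 7),
        )
        assert slope == pytest.approx(5 / 3, abs=1e-6)

    def test_plant_biomass_vs_mmax_is_5_8(self):
        assert plant_mmax_exponent(PlantSizeSpectrum()) == pytest.approx(0.625, abs=1e-4)

    def test_plant_mmax_exponent_toy_mass_allometry(self):
        # mass_exponent 1, eta 2: slope (mass_exponent - eta + 1)/mass_exponent = 0 —
        # degenerate; use eta 1.5 instead: (1 - 1.5 + 1)/1 = 0.5
        s = PlantSizeSpectrum(eta=1.5, mass_exponent=1.0)
        assert plant_mmax_exponent(s) == pytest.approx(0.5, abs=1e-4)

    def test_plant_mmax_exponent_scale_free(self):
        s = PlantSizeSpectrum()
        one_decade = plant_mmax_exponent(s, r_max_values=[1.0, 3.0, 10.0])
        three_decades = plant_mmax_exponent(s, r_max_values=[1.0, 31.0, 1000.0])
        assert one_decade == pytest.approx(three_decades, abs=1e-5)

    def test_animal_biomass_and_flux_vs_mmax_are_5_4(self):
        p = FluxParams()
        for f in (
            lambda m: animal_total_biomass(AnimalSizeSpectrum(m_max=m)),
            lambda m: animal_total_flux(AnimalSizeSpectrum(m_max=m), p),
        ):
            assert self._loglog_slope(f, np.logspace(0, 3, 7)) == pytest.approx(
                1.25, abs=1e-6
            )

    def test_plant_flux_vs_rmax_is_linear(self):
        p = FluxParams()
        slope = self._loglog_slope(
            lambda r: plant_total_flux(PlantSizeSpectrum(r_max=r), p),
            np.logspace(0, 3, 7),
        )
        assert slope == pytest.approx(1.0, abs=1e-6)

    def test_npp_vs_mtot_is_3_5(self):
        s = PlantSizeSpectrum()
        p = FluxParams()
        slope = self._loglog_slope(
            lambda m: npp_from_biomass(m, s, p), np.logspace(0, 3, 7)
        )
        assert slope == pytest.approx(0.6, abs=1e-9)

    def test_npp_composition_linear_in_rmax(self):
        """NPP(M_Tot(r_max)) and the direct flux both scale linearly in r_max."""
        p = FluxParams()
        slope_npp = self._loglog_slope(
            lambda r: npp_from_biomass(
                plant_total_biomass(PlantSizeSpectrum(r_max=r)),
                PlantSizeSpectrum(r_max=r),
                p,
            ),
            np.logspace(0, 3, 7),
        )
        slope_flux = self._loglog_slope(
            lambda r: plant_total_flux(PlantSizeSpectrum(r_max=r), p),
            np.logspace(0, 3, 7),
        )
        assert slope_npp == pytest.approx(1.0, abs=1e-6)
        assert slope_flux == pytest.approx(1.0, abs=1e-6)


class TestMonotonicityAndHomogeneity:
    @settings(derandomize=True, max_examples=30)
    @given(scale=st.floats(0.1, 50.0), r_max=st.floats(0.5, 100.0))
    def test_plant_totals_homogeneous_in_cn(self, scale, r_max):
        s1 = PlantSizeSpectrum(c_n=1.0, r_max=r_max)
        s2 = PlantSizeSpectrum(c_n=scale, r_max=r_max)
        assert plant_total_biomass(s2) == pytest.approx(
            scale * plant_total_biomass(s1), rel=1e-12
        )

    def test_totals_strictly_increasing_in_upper_limit(self):
        p = FluxParams()
        uppers = np.logspace(-1, 2, 10)
        for f in (
            lambda u: plant_total_biomass(PlantSizeSpectrum(r_max=u)),
            lambda u: animal_total_biomass(AnimalSizeSpectrum(m_max=u)),
            lambda u: plant_total_flux(PlantSizeSpectrum(r_max=u), p),
            lambda u: animal_total_flux(AnimalSizeSpectrum(m_max=u), p),
        ):
            vals = [f(u) for u in uppers]
            assert all(b > a for a, b in zip(vals, vals[1:]))


class TestConservationGain:
    @pytest.mark.parametrize(
        "area, mmax, group, expected",
        [
            (2.0, 1.0, "plant", 2.0),
            (2.0, 1.0, "animal", 2.0),
            (1.0, 1.0, "plant", 1.0),
            (2.0, 2.0, "animal", 2 * 2**1.25),
            (1.0, 10.0, "plant", 10**0.625),
        ],
    )
    def test_values(self, area, mmax, group, expected):
        assert conservation_gain(area, mmax, group) == pytest.approx(expected, rel=1e-9)

    def test_rejects_nonpositive_factors(self):
        with pytest.raises(ValueError):
            conservation_gain(0.0, 1.0, "plant")


class TestMetabolicRate:
    def test_mass_doubling_ratio(self):
        p = MetabolicParams()
        r = metabolic_rate(2.0, 300.0, False, True, p) / metabolic_rate(
            1.0, 300.0, False, True, p
        )
        assert r == pytest.approx(2**0.75, rel=1e-12)

    def test_endotherm_insensitive_to_ambient(self):
        p = MetabolicParams(temperature_sensitivity=8000.0)
        assert metabolic_rate(10.0, 280.0, True, True, p) == pytest.approx(
            metabolic_rate(10.0, 310.0, True, True, p)
        )

    def test_ectotherm_slows_in_cold(self):
        p = MetabolicParams(temperature_sensitivity=8000.0)
        assert metabolic_rate(10.0, 280.0, False, True, p) < metabolic_rate(
            10.0, 310.0, False, True, p
        )

    def test_active_equals_inactive_with_equal_normalizations(self):
        p = MetabolicParams(normalization_field=2.0, normalization_basal=2.0)
        assert metabolic_rate(5.0, 300.0, True, True, p) == metabolic_rate(
            5.0, 300.0, True, False, p
        )

    def test_rejects_nonpositive_mass(self):
        with pytest.raises(ValueError):
            metabolic_rate(0.0, 300.0, True, True, MetabolicParams())
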
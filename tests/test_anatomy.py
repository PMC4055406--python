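"""Vessel geometry regressions, blood properties and allometric scaling."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fetalflow.anatomy import (
    GA_WINDOW,
    VESSELS,
    AllometricConfig,
    FluidProperties,
    GestationalAgeError,
    allometric_scale,
    blood_viscosity,
    reference_weight,
    scale_geometry,
    segment_geometry,
)


class TestSegmentGeometry:
    @pytest.mark.parametrize(
        "vessel, ga, length_mm, diam_mm",
        [
            ("ascending_aorta", 33.2, 20.606, 6.864),
            ("aortic_isthmus", 33.2, 5.154, 4.448),
            ("descending_aorta", 33.2, 84.274, 5.084),
            ("left_common_carotid_artery", 33.2, 43.098, 3.128),
        ],
    )
    def test_linear_growth_regressions(self, vessel, ga, length_mm, diam_mm):
        geom = segment_geometry(vessel, ga)
        assert geom.length == pytest.approx(length_mm / 10.0, rel=1e-9)
        assert geom.diameter == pytest.approx(diam_mm / 10.0, rel=1e-9)

    def test_wall_thickness_is_15_percent_of_radius(self):
        geom = segment_geometry("aortic_isthmus", 30.0)
        assert geom.wall_thickness == pytest.approx(0.15 * geom.radius)

    def test_young_modulus_values(self):
        assert segment_geometry("ascending_aorta", 33.2).young_modulus == 7.5e5
        assert segment_geometry("descending_aorta", 33.2).young_modulus == 9.0e5
        assert segment_geometry("ductus_arteriosus", 33.2).young_modulus == 13.5e5

    def test_unknown_vessel(self):
        with pytest.raises(KeyError):
            segment_geometry("umbilical_artery", 33.2)

    def test_early_ga_yields_domain_error(self):
        # at 7 weeks the diameter regression of the ascending aorta is negative
        with pytest.raises(GestationalAgeError):
            segment_geometry("ascending_aorta", 7.0, ga_window=(5.0, 42.0))

    def test_ga_outside_window(self):
        with pytest.raises(GestationalAgeError):
            segment_geometry("ascending_aorta", 12.0)

    @pytest.mark.parametrize("vessel", VESSELS)
    @pytest.mark.parametrize("ga", [25.0, 30.0, 35.0, 40.0])
    def test_all_vessels_positive_in_validity_window(self, vessel, ga):
        geom = segment_geometry(vessel, ga)
        assert geom.length > 0 and geom.radius > 0 and geom.wall_thickness > 0


class TestBloodProperties:
    @pytest.mark.parametrize("ga, mu", [(33.2, 0.03640), (20.0, 0.02650)])
    def test_viscosity_values(self, ga, mu):
        assert blood_viscosity(ga) == pytest.approx(mu, abs=1e-6)

    def test_viscosity_requires_positive_ga(self):
        with pytest.raises(GestationalAgeError):
            blood_viscosity(0.0)

    def test_viscosity_affine_in_ga(self):
        # second difference of an affine function vanishes
        d2 = blood_viscosity(30.0) - 2 * blood_viscosity(25.0) + blood_viscosity(20.0)
        assert d2 == pytest.approx(0.0, abs=1e-15)

    def test_density_default(self):
        assert FluidProperties(viscosity=0.03).density == 1.05


class TestReferenceWeight:
    @pytest.mark.parametrize("ga, grams", [(33.2, 2127), (30.2, 1566)])
    def test_growth_curve_values(self, ga, grams):
        assert reference_weight(ga) == pytest.approx(grams, rel=1e-3)

    def test_monotonically_increasing(self):
        weights = [reference_weight(ga) for ga in range(20, 43)]
        assert all(b > a for a, b in zip(weights, weights[1:]))

    def test_out_of_window(self):
        with pytest.raises(GestationalAgeError):
            reference_weight(10.0)


class TestAllometricScaling:
    def test_identity_when_weight_equals_reference(self):
        cfg = AllometricConfig(reference_weight=2000.0, subject_weight=2000.0)
        assert allometric_scale({"x": 3.3}, cfg, "resistance") == {"x": 3.3}

    def test_zero_exponent_leaves_values_unchanged(self):
        cfg = AllometricConfig(
            reference_weight=2000.0, subject_weight=500.0, exponent_dimension=0.0
        )
        assert allometric_scale({"x": 1.7}, cfg, "dimension") == {"x": 1.7}

    def test_redf_like_dimension_ratio(self):
        # 500 g subject against the 30.2-week reference: ratio ~0.319
        cfg = AllometricConfig(
            reference_weight=reference_weight(30.2),
            subject_weight=500.0,
            exponent_dimension=1.0,
        )
        scaled = allometric_scale({"l": 1.0}, cfg, "dimension")
        assert scaled["l"] == pytest.approx(500.0 / reference_weight(30.2), rel=1e-12)
        assert scaled["l"] == pytest.approx(0.319, abs=5e-4)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(
        w1=st.floats(200.0, 4000.0),
        w2=st.floats(200.0, 4000.0),
        k=st.floats(-2.0, 2.0),
    )
    def test_scaling_composes_multiplicatively(self, w1, w2, k):
        """Scaling to w1 then to w2 equals scaling straight to w2."""
        ref = 2000.0
        c1 = AllometricConfig(reference_weight=ref, subject_weight=w1, exponent_resistance=k)
        c2 = AllometricConfig(reference_weight=w1, subject_weight=w2, exponent_resistance=k)
        direct = AllometricConfig(reference_weight=ref, subject_weight=w2, exponent_resistance=k)
        step = allometric_scale(
            allometric_scale({"r": 5.0}, c1, "resistance"), c2, "resistance"
        )
        assert step["r"] == pytest.approx(
            allometric_scale({"r": 5.0}, direct, "resistance")["r"], rel=1e-9
        )

    def test_scale_geometry_scales_all_dimensions(self):
        geom = segment_geometry("aortic_isthmus", 33.2)
        cfg = AllometricConfig(
            reference_weight=2000.0, subject_weight=1000.0, exponent_dimension=0.33
        )
        scaled = scale_geometry(geom, cfg)
        f = 0.5**0.33
        assert scaled.length == pytest.approx(geom.length * f)
        assert scaled.radius == pytest.approx(geom.radius * f)
        assert scaled.wall_thickness == pytest.approx(0.15 * scaled.radius)
        assert scaled.young_modulus == geom.young_modulus

    def test_invalid_weights(self):
        with pytest.raises(ValueError):
            AllometricConfig(reference_weight=-1.0, subject_weight=500.0)

    def test_unknown_kind(self):
        cfg = AllometricConfig(reference_weight=1.0, subject_weight=2.0)
        with pytest.raises(KeyError):
            cfg.factor("elasticity")
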
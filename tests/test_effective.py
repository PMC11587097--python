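import math

import numpy as np
import pytest

from uvdose import (
    MediumOptics,
    ValidationError,
    derive_geometry,
    effective_dose,
    max_zenith,
    mc_effective_dose,
    point_dose_fraction,
    rim_clearance_distance,
)

VACUUM = MediumOptics(absorptivity=0.0)


def _open_dish(a=1.68, h=1e-9, v=0.0):
    return derive_geometry("open", 2 * a, h, v)


class TestRimClearance:
    def test_center_sees_the_wall_at_radius_a(self):
        for phi in (0.0, 1.0, math.pi, 5.0):
            assert rim_clearance_distance(0.0, phi, 1.68) == pytest.approx(1.68, rel=1e-12)

    def test_point_on_the_wall(self):
        a = 1.68
        assert rim_clearance_distance(a, 0.0, a) == pytest.approx(0.0, abs=1e-12)
        assert rim_clearance_distance(a, math.pi, a) == pytest.approx(2 * a, rel=1e-12)

    def test_endpoint_lies_on_the_circle(self):
        """point + t * direction lands on the rim circle (brute-force root
        check of the circle equation)."""
        rng = np.random.default_rng(11)
        a = 2.3
        for _ in range(200):
            x = a * rng.random()
            phi = rng.uniform(0, 2 * math.pi)
            t = rim_clearance_distance(x, phi, a)
            # X at (-x, 0) with phi measured from the outward (+x) direction
            px = -x + t * math.cos(phi + math.pi)
            py = t * math.sin(phi + math.pi)
            assert math.hypot(px, py) == pytest.approx(a, rel=1e-12)
            assert a - x - 1e-12 <= t <= a + x + 1e-12

    def test_outside_disk_rejected(self):
        with pytest.raises(ValidationError):
            rim_clearance_distance(2.0, 0.0, 1.0)


class TestMaxZenith:
    def test_vanishing_wall_is_unshielded(self):
        g = _open_dish()
        assert max_zenith(0.5, 0.0, g) == pytest.approx(math.pi / 2, abs=1e-6)

    def test_unit_slope_gives_45_degrees(self):
        g = derive_geometry("w", 2.0, 1.0, 0.0)  # a = 1 = h, center: t = a
        assert max_zenith(0.0, 0.0, g) == pytest.approx(math.pi / 4, rel=1e-12)

    def test_96_well_center(self, registry):
        g = registry["96-well"]
        assert max_zenith(0.0, 0.0, g) == pytest.approx(math.atan(0.315 / 1.115), rel=1e-12)
        assert max_zenith(0.0, 0.0, g) == pytest.approx(0.2753, abs=2e-4)

    def test_surface_reference_widens_the_cone(self, registry, medium):
        g = registry["96-well"]
        assert max_zenith(0.2, 1.0, g, "surface") > max_zenith(0.2, 1.0, g, "bottom")


class TestPointDoseFraction:
    def test_open_absorber_free_normalization(self):
        assert point_dose_fraction(0.3, _open_dish(), VACUUM) == pytest.approx(1.0, abs=1e-9)

    def test_center_closed_form_without_absorber(self):
        """At the center with eps = 0 the fraction is sin^2(arctan(a/h))
        = a^2 / (a^2 + h^2); equals 1/2 for a = h."""
        g = derive_geometry("w", 2.0, 1.0, 0.0)
        assert point_dose_fraction(0.0, g, VACUUM) == pytest.approx(0.5, abs=1e-10)
        for a, h in [(0.315, 1.115), (1.68, 1.18), (1.0, 2.5)]:
            g = derive_geometry("w", 2 * a, h, 0.0)
            assert point_dose_fraction(0.0, g, VACUUM) == pytest.approx(
                a**2 / (a**2 + h**2), abs=1e-10
            )

    def test_bounded_by_unity(self, registry, medium):
        for g in registry.values():
            for x in (0.0, 0.4 * g.radius, 0.95 * g.radius):
                f = point_dose_fraction(x, g, medium)
                assert 0.0 <= f <= 1.0


class TestEffectiveDose:
    def test_open_dish_recovers_set_dose(self):
        res = effective_dose(20.0, _open_dish(), VACUUM)
        assert res.effective_dose == pytest.approx(20.0, rel=1e-8)
        assert res.transmitted_fraction == pytest.approx(1.0, rel=1e-8)

    def test_never_exceeds_set_dose(self, registry, medium):
        for g in registry.values():
            res = effective_dose(10.0, g, medium)
            assert 0.0 < res.effective_dose <= 10.0
            assert all(0.0 <= z <= 10.0 for z in res.profile_z)

    def test_fraction_invariant_to_dose(self, registry, medium):
        g = registry["24-well"]
        f1 = effective_dose(1.0, g, medium).transmitted_fraction
        f2 = effective_dose(123.0, g, medium).transmitted_fraction
        assert f1 == pytest.approx(f2, rel=1e-12)

    def test_strictly_decreasing_in_wall_height(self, medium):
        """Taller walls shield more oblique light — the mechanism behind
        the covered-dish observation."""
        fracs = [
            effective_dose(1.0, derive_geometry("w", 3.36, h, 2.0), medium).transmitted_fraction
            for h in (1.18, 2.0, 3.0, 5.0)
        ]
        assert all(b < a for a, b in zip(fracs, fracs[1:]))

    def test_strictly_decreasing_in_absorptivity(self, registry):
        g = registry["12-well"]
        fracs = [
            effective_dose(1.0, g, MediumOptics(absorptivity=e)).transmitted_fraction
            for e in (0.0, 0.1, 0.3, 1.0)
        ]
        assert all(b < a for a, b in zip(fracs, fracs[1:]))

    def test_strictly_decreasing_in_medium_depth(self, medium):
        fracs = [
            effective_dose(1.0, derive_geometry("w", 3.36, 1.18, v), medium).transmitted_fraction
            for v in (0.5, 2.0, 5.0)
        ]
        assert all(b < a for a, b in zip(fracs, fracs[1:]))

    def test_ordering_matches_vessel_size(self, registry, medium):
        fracs = {n: effective_dose(1.0, g, medium).transmitted_fraction for n, g in registry.items()}
        assert (
            fracs["3.5cm-dish"] > fracs["12-well"] > fracs["24-well"] > fracs["96-well"]
        )


class TestMonteCarloOracle:
    def test_open_dish_estimates_set_dose(self):
        res = mc_effective_dose(10.0, _open_dish(), VACUUM, n_samples=50_000, seed=5)
        assert res.effective_dose == pytest.approx(10.0, rel=1e-9)
        assert res.error_estimate == pytest.approx(0.0, abs=1e-9)

    def test_fixed_seed_repeats_bit_identically(self, registry, medium):
        g = registry["24-well"]
        a = mc_effective_dose(1.0, g, medium, n_samples=10_000, seed=42)
        b = mc_effective_dose(1.0, g, medium, n_samples=10_000, seed=42)
        assert a.transmitted_fraction == b.transmitted_fraction
        assert a.error_estimate == b.error_estimate

    def test_seed_is_mandatory(self, registry, medium):
        with pytest.raises(ValidationError):
            mc_effective_dose(1.0, registry["24-well"], medium, n_samples=10_000, seed=None)

    def test_agrees_with_quadrature(self, registry, medium):
        g = registry["3.5cm-dish"]
        quad = effective_dose(1.0, g, medium).transmitted_fraction
        mc = mc_effective_dose(1.0, g, medium, n_samples=300_000, seed=17)
        assert abs(mc.transmitted_fraction - quad) < 3 * mc.error_estimate

    def test_error_shrinks_as_root_n(self, registry, medium):
        g = registry["96-well"]
        se_small = mc_effective_dose(1.0, g, medium, n_samples=10_000, seed=1).error_estimate
        se_big = mc_effective_dose(1.0, g, medium, n_samples=160_000, seed=1).error_estimate
        assert se_big == pytest.approx(se_small / 4.0, rel=0.15)
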
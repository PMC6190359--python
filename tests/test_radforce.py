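import math

import numpy as np
import pytest
from scipy.integrate import dblquad

from arfsim.errors import DomainError, UndefinedMetricError
from arfsim.fields import FieldSample, StandingWaveSpec, acoustic_energy_density
from arfsim.materials import NIH3T3, WATER
from arfsim.radforce import (
    ScatteringCoefficients,
    closed_form_1d,
    difference_metric,
    dipole_coefficient,
    finite_size_force,
    force_curve,
    force_map,
    gorkov_potential,
    gorkov_potential_field,
    modifying_factor,
    monopole_coefficient,
    small_particle_force,
    zero_crossing_ratio,
)

from conftest import PEAK_PRESSURE, WAVELENGTH


class TestScatteringCoefficients:
    def test_reference_cell_in_water(self, coeffs):
        assert coeffs.real_f1 == pytest.approx(0.1473, abs=5e-5)
        assert coeffs.real_f2 == pytest.approx(0.0500, abs=5e-5)
        assert coeffs.contrast_factor == pytest.approx(0.0741, abs=5e-5)

    def test_fluid_matched_particle_feels_nothing(self):
        assert monopole_coefficient(4.4e-10, 4.4e-10) == 0.0
        assert dipole_coefficient(1.0e3, 1.0e3) == 0.0

    def test_rigid_heavy_limits(self):
        assert monopole_coefficient(1e-30, 4.4e-10) == pytest.approx(1.0)
        assert dipole_coefficient(1e12, 1.0e3) == pytest.approx(1.0, rel=1e-8)

    def test_contrast_factor_definition(self):
        coeffs = ScatteringCoefficients(f1=0.3, f2=-0.6)
        assert coeffs.contrast_factor == pytest.approx(0.3 / 3.0 - 0.6 / 2.0)

    def test_non_positive_inputs_rejected(self):
        with pytest.raises(DomainError):
            monopole_coefficient(0.0, 1.0)
        with pytest.raises(DomainError):
            dipole_coefficient(1.0, -1.0)


class TestGorkovPotential:
    def test_zero_fields_give_zero_potential(self, coeffs):
        sample = FieldSample(position=(0.0, 0.0), mean_square_pressure=0.0,
                             mean_square_velocity=0.0)
        assert gorkov_potential(sample, coeffs, 1e-15, 4.4e-10, 1e3) == 0.0

    def test_antinode_value_for_monopole_only_particle(self, spec_1d, water):
        # at the antinode <v^2>=0, so U = V f1 beta p_ac^2 / 4
        coeffs = ScatteringCoefficients(f1=0.5, f2=0.0)
        volume = 1.0e-16
        u = gorkov_potential_field(spec_1d, np.array([0.0, 0.0]), coeffs, volume)
        expected = volume * 0.5 * water.compressibility * PEAK_PRESSURE**2 / 4.0
        assert u == pytest.approx(expected, rel=1e-12)

    def test_linearity_in_coefficients(self, spec_1d, rng):
        r = rng.uniform(0, WAVELENGTH, size=2)
        volume = 1.0e-16
        u_mono = gorkov_potential_field(spec_1d, r, ScatteringCoefficients(0.7, 0.0), volume)
        u_flip = gorkov_potential_field(spec_1d, r, ScatteringCoefficients(-0.7, 0.0), volume)
        assert u_flip == pytest.approx(-u_mono, rel=1e-12)


class TestSmallParticleForce:
    def test_vanishes_at_nodes_and_antinodes(self, spec_1d, coeffs, cell):
        scale = 4 * math.pi * abs(coeffs.contrast_factor) * cell.radius**3 \
            * spec_1d.wavenumber * 4.433
        for y in (0.0, WAVELENGTH / 4.0, WAVELENGTH / 2.0):
            f = small_particle_force(spec_1d, np.array([0.0, y]), coeffs, cell.volume)
            assert np.linalg.norm(f) < 1e-9 * scale

    @pytest.mark.parametrize("field_fixture", ["spec_1d", "spec_2d"])
    def test_equals_negative_potential_gradient(self, field_fixture, request, coeffs,
                                                cell, rng):
        # central-difference oracle with step lambda * 1e-6
        spec = request.getfixturevalue(field_fixture)
        step = WAVELENGTH * 1e-6
        for _ in range(5):
            r = rng.uniform(0.0, WAVELENGTH, size=2)
            force = small_particle_force(spec, r, coeffs, cell.volume)
            numeric = np.empty(2)
            for j in range(2):
                dr = np.zeros(2)
                dr[j] = step
                numeric[j] = -(
                    gorkov_potential_field(spec, r + dr, coeffs, cell.volume)
                    - gorkov_potential_field(spec, r - dr, coeffs, cell.volume)
                ) / (2.0 * step)
            assert np.allclose(force, numeric, rtol=1e-6,
                               atol=1e-6 * np.linalg.norm(force) + 1e-30)

    def test_matches_1d_closed_form_everywhere(self, spec_1d_exact, coeffs_exact, cell):
        # with beta = 1/(rho c^2) exactly, the closed form is an identity
        spec, coeffs = spec_1d_exact, coeffs_exact
        e_ac = acoustic_energy_density(PEAK_PRESSURE, spec.fluid.compressibility)
        k = spec.wavenumber
        for y in np.linspace(0.0, WAVELENGTH, 37):
            node = WAVELENGTH / 4.0 + round((y - WAVELENGTH / 4.0) / (WAVELENGTH / 2.0)) \
                * (WAVELENGTH / 2.0)
            h = node - y
            expected = closed_form_1d(h, cell.radius, k, e_ac, coeffs.contrast_factor)
            force = small_particle_force(spec, np.array([0.0, y]), coeffs, cell.volume)
            assert force[1] == pytest.approx(float(expected), rel=1e-10, abs=1e-25)

    def test_closed_form_node_and_quarter_offset(self, coeffs):
        k = 2.0 * math.pi / WAVELENGTH
        e_ac = 4.433
        a = 5.0e-6
        phi = coeffs.contrast_factor
        assert closed_form_1d(0.0, a, k, e_ac, phi) == 0.0
        peak = 4.0 * math.pi * phi * a**3 * k * e_ac
        assert closed_form_1d(WAVELENGTH / 8.0, a, k, e_ac, phi) == pytest.approx(peak)


class TestModifyingFactor:
    def test_ten_micron_cell_at_sixty_micron_wavelength(self):
        # D_p = 10 um, lambda = 60 um -> chi = pi/6, f_m just under 0.9
        assert modifying_factor(math.pi / 6.0) == pytest.approx(0.894, abs=1e-3)
        assert round(float(modifying_factor(math.pi / 6.0)), 1) == 0.9

    def test_small_particle_limit_is_unity(self):
        assert modifying_factor(0.0) == 1.0
        assert abs(modifying_factor(1e-3) - 1.0) < 1e-6

    def test_series_matches_exact_form_at_crossover(self):
        # continuity across the Taylor-series switch at chi = 1e-3
        below, above = 0.999e-3, 1.001e-3
        x = 2.0 * below
        exact = 3.0 * (math.sin(x) - x * math.cos(x)) / x**3
        assert modifying_factor(below) == pytest.approx(exact, rel=1e-9)
        assert modifying_factor(above) == pytest.approx(modifying_factor(below), rel=1e-8)

    def test_matches_independent_sphere_average(self):
        # oracle: <sin(2ky)> over the ball / sin(2ky0), by scipy quadrature
        chi = 1.0          # k a = 1
        k, a, y0 = 1.0, 1.0, 0.3
        integral, _ = dblquad(
            lambda u, r: r**2 * math.sin(2.0 * k * (y0 + r * u)),
            0.0, a, -1.0, 1.0, epsabs=1e-13, epsrel=1e-13,
        )
        average = integral / (2.0 * a**3 / 3.0)
        assert modifying_factor(chi) == pytest.approx(
            average / math.sin(2.0 * k * y0), rel=1e-9
        )

    def test_monotone_decay_before_first_zero(self):
        chis = np.linspace(0.01, 2.24, 200)
        values = modifying_factor(chis)
        assert np.all(np.diff(values) < 0.0)

    def test_negative_argument_rejected(self):
        with pytest.raises(DomainError):
            modifying_factor(-0.1)


class TestZeroCrossing:
    def test_ratio_rounds_to_printed_value(self):
        ratio = zero_crossing_ratio()
        assert round(ratio, 2) == 0.72
        assert ratio == pytest.approx(0.715, abs=5e-4)

    def test_root_property(self):
        chi = zero_crossing_ratio() * math.pi
        assert abs(modifying_factor(chi)) < 1e-10

    def test_brute_force_scan_brackets_same_root(self):
        ratios = np.arange(0.05, 1.0, 1e-4)
        values = modifying_factor(ratios * math.pi)
        signs = np.sign(values)
        flips = np.nonzero(np.diff(signs) != 0)[0]
        assert len(flips) >= 1
        lo, hi = ratios[flips[0]], ratios[flips[0] + 1]
        assert lo <= zero_crossing_ratio() <= hi


class TestFiniteSizeForce:
    @pytest.mark.parametrize("ratio", [0.1, 0.3, 0.5, 0.7, 0.9])
    @pytest.mark.parametrize("dim", [2, 3])
    def test_quadrature_reproduces_closed_form(self, spec_1d, coeffs, ratio, dim):
        # the 1D volume average has the exact closed form F_s * f_m
        a = ratio * WAVELENGTH / 2.0
        k = spec_1d.wavenumber
        e_ac = acoustic_energy_density(PEAK_PRESSURE, spec_1d.fluid.compressibility)
        h = WAVELENGTH / 8.0
        center = np.array([0.0, WAVELENGTH / 4.0 - h])
        expected = float(
            closed_form_1d(h, a, k, e_ac, coeffs.contrast_factor)
            * modifying_factor(k * a)
        )
        force = finite_size_force(spec_1d, center, a, coeffs, dim=dim)
        assert force[1] == pytest.approx(expected, rel=1e-3 * 1e-3)
        assert force[0] == pytest.approx(0.0, abs=1e-6 * abs(expected))

    def test_point_limit_recovers_small_particle_force(self, spec_1d, coeffs, cell, rng):
        r = rng.uniform(0, WAVELENGTH, size=2)
        a = 1.0e-9
        fs = small_particle_force(spec_1d, r, coeffs, 4.0 / 3.0 * math.pi * a**3)
        ff = finite_size_force(spec_1d, r, a, coeffs)
        assert np.allclose(ff, fs, rtol=1e-6)

    def test_negligible_at_lattice_nodes_and_antinodes(self, spec_2d, coeffs):
        a = 0.4 * WAVELENGTH / 2.0
        grid = force_map(
            spec_2d, coeffs, a, ((0.0, WAVELENGTH), (0.0, WAVELENGTH)), 16,
            model="finite_size",
        )
        peak = grid.magnitude().max()
        for pt in [(0.0, 0.0), (WAVELENGTH / 4, WAVELENGTH / 4),
                   (WAVELENGTH / 2, WAVELENGTH / 2), (3 * WAVELENGTH / 4, WAVELENGTH / 4)]:
            f = finite_size_force(spec_2d, np.array(pt), a, coeffs, dim=2)
            assert np.linalg.norm(f) < 1e-3 * peak

    def test_center_shape_validated(self, spec_1d, coeffs):
        with pytest.raises(DomainError):
            finite_size_force(spec_1d, np.zeros(3), 1e-6, coeffs)


class TestForceMap:
    def test_small_particle_map_periodicity(self, spec_1d, coeffs, cell):
        grid = force_map(
            spec_1d, coeffs, cell.radius, ((0.0, WAVELENGTH), (0.0, WAVELENGTH)), 17,
            model="small_particle",
        )
        mag = grid.magnitude()
        # the 1D force has period lambda/2 along y: rows repeat half-way down
        assert np.allclose(mag[0, :], mag[8, :], rtol=1e-9, atol=1e-12 * mag.max())
        assert np.allclose(grid.force[:, 0, :], grid.force[:, -1, :], rtol=1e-9)

    def test_ratio_map_is_not_constant(self, spec_2d, coeffs):
        a = 0.2 * WAVELENGTH / 2.0
        bbox = ((0.0, WAVELENGTH), (0.0, WAVELENGTH))
        small = force_map(spec_2d, coeffs, a, bbox, 16, model="small_particle")
        finite = force_map(spec_2d, coeffs, a, bbox, 16, model="finite_size")
        mask = small.magnitude() > 1e-3 * small.magnitude().max()
        ratio = finite.magnitude()[mask] / small.magnitude()[mask]
        assert ratio.std() / ratio.mean() > 0.05

    def test_larger_particles_feel_weaker_peak_force(self, spec_2d, coeffs):
        bbox = ((0.0, WAVELENGTH), (0.0, WAVELENGTH))
        peaks = {}
        for ratio in (0.2, 0.4):
            a = ratio * WAVELENGTH / 2.0
            peaks[ratio] = force_map(
                spec_2d, coeffs, a, bbox, 16, model="finite_size"
            ).magnitude().max() / a**3
        # per unit volume the finite-size force decays with D_p/lambda
        assert peaks[0.4] < peaks[0.2]

    def test_resolution_floor_enforced(self, spec_2d, coeffs):
        with pytest.raises(DomainError, match="8 points per wavelength"):
            force_map(spec_2d, coeffs, 1e-6, ((0.0, 2 * WAVELENGTH), (0.0, WAVELENGTH)), 8)

    def test_degenerate_bbox_rejected(self, spec_2d, coeffs):
        with pytest.raises(DomainError, match="degenerate"):
            force_map(spec_2d, coeffs, 1e-6, ((0.0, 0.0), (0.0, WAVELENGTH)), 16)


class TestDifferenceMetric:
    def test_identical_curves_give_zero(self):
        f = np.array([1.0, -2.0, 3.0])
        assert difference_metric(f, f) == 0.0

    def test_homogeneity(self):
        f = np.array([1.0, -2.0, 3.0])
        assert difference_metric(2.0 * f, f) == 1.0

    def test_hand_computed_twenty_point_grid(self):
        # closed-form finite-size curve vs small-particle curve, flat sum oracle
        ratios = np.linspace(0.05, 1.0, 20)
        small = np.sin(2.0 * math.pi * ratios)        # any non-trivial reference shape
        finite = small * np.array([float(modifying_factor(math.pi * r)) for r in ratios])
        expected = sum(abs(f - s) for f, s in zip(finite, small)) / sum(
            abs(s) for s in small
        )
        assert difference_metric(finite, small) == pytest.approx(expected, rel=1e-12)

    def test_zero_reference_rejected(self):
        with pytest.raises(UndefinedMetricError):
            difference_metric(np.ones(3), np.zeros(3))

    def test_mismatched_grids_rejected(self):
        with pytest.raises(DomainError):
            difference_metric(np.ones(3), np.ones(4))


class TestForceCurve:
    def test_default_curve_consistency(self):
        table = force_curve(WATER, NIH3T3, WAVELENGTH, PEAK_PRESSURE,
                            ratios=np.linspace(0.05, 1.0, 8))
        metric = difference_metric(
            table["F_finite_closed"].to_numpy(),
            table["F_finite_quadrature"].to_numpy(),
        )
        assert metric < 1e-3

    def test_tiny_particle_columns_coincide(self):
        table = force_curve(WATER, NIH3T3, WAVELENGTH, PEAK_PRESSURE, ratios=[1e-4])
        row = table.iloc[0]
        assert row["F_finite_closed"] == pytest.approx(row["F_small"], rel=1e-6)
        assert row["F_finite_quadrature"] == pytest.approx(row["F_small"], rel=1e-6)

    def test_sixth_ratio_modifying_factor(self):
        table = force_curve(WATER, NIH3T3, WAVELENGTH, PEAK_PRESSURE, ratios=[1.0 / 6.0])
        row = table.iloc[0]
        assert row["F_finite_closed"] / row["F_small"] == pytest.approx(0.894, abs=1e-3)
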
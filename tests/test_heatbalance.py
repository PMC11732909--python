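"""Heat-balance solver: geometry, fur, fluxes, TNZ sweeps."""

import math

import numpy as np
import pytest

from xenotherm.heatbalance import (
    SIGMA,
    AnimalGeometry,
    Environment,
    FurLayer,
    air_conductivity,
    air_kinematic_viscosity,
    chamber_environment,
    convection_coefficient,
    critical_temperatures,
    fur_effective_conductivity,
    fur_immobilized_fraction,
    geometry_from_mass,
    heterothermic_solve,
    metabolic_chamber_sweep,
    prolate_spheroid_area,
    skin_conduction_flux,
    solve_required_metabolism,
)
from xenotherm.metabolism import xenarthran_bmr


class TestGeometry:
    def test_sphere_closed_form(self):
        g = geometry_from_mass(1000.0, density=1000.0, shape_ratio=1.0)
        r = (3.0 / (4.0 * math.pi)) ** (1.0 / 3.0)
        assert g.semi_minor == pytest.approx(r, rel=1e-12)
        assert g.semi_minor == pytest.approx(0.6204, abs=1e-4)
        assert g.surface_area == pytest.approx(4.0 * math.pi * r * r, rel=1e-12)

    def test_mass_scaling(self):
        g1 = geometry_from_mass(500.0)
        g8 = geometry_from_mass(4000.0)
        assert g8.semi_minor == pytest.approx(2.0 * g1.semi_minor, rel=1e-12)
        assert g8.surface_area == pytest.approx(4.0 * g1.surface_area, rel=1e-9)

    def test_volume_exact(self):
        g = geometry_from_mass(4490.0)
        assert g.volume == 4.49
        a, b = g.semi_major, g.semi_minor
        assert 4.0 / 3.0 * math.pi * a * b * b == pytest.approx(4.49, rel=1e-12)

    def test_area_matches_quadrature_oracle(self):
        from scipy.integrate import quad

        g = geometry_from_mass(4490.0, shape_ratio=2.0)
        a, b = g.semi_major, g.semi_minor

        # surface of revolution about the major axis
        def integrand(x):
            # y(x) = b sqrt(1 - x²/a²); dS = 2π y sqrt(1 + y'²) dx
            y = b * math.sqrt(max(0.0, 1.0 - x * x / (a * a)))
            if y == 0.0:
                return 0.0
            dy = -b * x / (a * a * math.sqrt(1.0 - x * x / (a * a)))
            return 2.0 * math.pi * y * math.sqrt(1.0 + dy * dy)

        oracle, _ = quad(integrand, -a, a, limit=200)
        assert g.surface_area == pytest.approx(oracle, rel=1e-3)

    def test_area_exceeds_equal_volume_sphere(self):
        g = geometry_from_mass(1000.0, shape_ratio=2.0)
        r = (3.0 * g.volume / (4.0 * math.pi)) ** (1.0 / 3.0)
        assert g.surface_area > 4.0 * math.pi * r * r

    def test_oblate_rejected(self):
        with pytest.raises(ValueError):
            geometry_from_mass(100.0, shape_ratio=0.5)
        with pytest.raises(ValueError):
            prolate_spheroid_area(1.0, 2.0)


class TestFur:
    def test_no_hair_is_air(self):
        fur = FurLayer(depth=0.01, density=0.0)
        assert fur_effective_conductivity(fur) == pytest.approx(0.0257)

    def test_dense_fur_mixture(self):
        fur = FurLayer(depth=0.05, density=2000.0, hair_diameter=1.0e-4)
        f = 2000.0 * 1e4 * math.pi * (0.5e-4) ** 2
        assert fur.fiber_fraction == pytest.approx(f, rel=1e-12)
        assert f == pytest.approx(0.157, abs=1e-3)
        assert fur_effective_conductivity(fur) == pytest.approx(
            0.0257 + (0.209 - 0.0257) * f, rel=1e-12
        )
        assert fur_effective_conductivity(fur) == pytest.approx(0.0545, abs=5e-4)

    def test_degenerate_mixture(self):
        fur = FurLayer(depth=0.01, density=500.0, k_hair=0.0257)
        assert fur_effective_conductivity(fur) == pytest.approx(0.0257, rel=1e-12)

    def test_overdense_rejected(self):
        with pytest.raises(ValueError):
            FurLayer(depth=0.01, density=2e5, hair_diameter=1e-3)

    def test_immobilized_fraction_monotone_in_density(self):
        fracs = [
            fur_immobilized_fraction(FurLayer(0.05, d))
            for d in (0.07, 8.5, 1300.0, 2000.0)
        ]
        assert fracs == sorted(fracs)
        assert fracs[0] < 0.05  # elephant-sparse coat barely insulates
        assert fracs[-1] > 0.85


class TestSkinConduction:
    def test_no_gradient_no_flux(self):
        assert skin_conduction_flux(0.3, 0.01, 34.0, 34.0) == 0.0

    def test_hand_arithmetic(self):
        assert skin_conduction_flux(0.3, 0.01, 34.0, 24.0) == pytest.approx(300.0)

    def test_thickness_proportionality(self):
        f1 = skin_conduction_flux(0.3, 0.01, 34.0, 24.0)
        f2 = skin_conduction_flux(0.3, 0.02, 34.0, 24.0)
        assert f2 == pytest.approx(f1 / 2.0)

    def test_zero_thickness(self):
        with pytest.raises(ValueError):
            skin_conduction_flux(0.3, 0.0, 34.0, 24.0)


class TestConvection:
    def test_still_air_hits_conduction_floor(self):
        env = Environment(T_air=20.0, T_rad=20.0, wind=0.0)
        h = convection_coefficient(20.0, env, 1.0)
        assert h == pytest.approx(2.0 * air_conductivity(20.0) / 1.0, rel=1e-12)

    def test_hand_evaluation_of_correlation(self):
        env = Environment(T_air=20.0, T_rad=20.0, wind=0.1)
        d = 1.0
        k = air_conductivity(20.0)
        nu = air_kinematic_viscosity(20.0)
        re = 0.1 * d / nu
        expected = (0.35 + 0.56 * re**0.52) * k / d
        assert convection_coefficient(20.0, env, d) == pytest.approx(expected, rel=1e-12)

    def test_monotone_in_wind(self):
        hs = [
            convection_coefficient(
                20.0, Environment(T_air=10.0, T_rad=10.0, wind=w), 0.8
            )
            for w in (0.1, 0.5, 2.0, 10.0)
        ]
        assert hs == sorted(hs)


class TestSolver:
    def test_zero_gradient_zero_metabolism(self, mega_geometry):
        fur = FurLayer(0.05, 2000.0)
        sol = solve_required_metabolism(
            mega_geometry, fur, chamber_environment(31.0), 31.0, evap_fraction=0.0
        )
        assert sol.M_req == pytest.approx(0.0, abs=1e-6)

    def test_independent_flux_sum_oracle(self):
        # hand-assemble the surface balance for a sphere at a fixed T_s and
        # confirm the solver's returned fluxes close the budget
        geom = geometry_from_mass(1000.0, shape_ratio=1.0)
        fur = FurLayer(0.03, 2000.0)
        env = Environment(T_air=5.0, T_rad=-5.0, wind=0.5, solar=300.0,
                          shade_fraction=0.0)
        sol = solve_required_metabolism(geom, fur, env, 31.0)
        area_out = geom.offset_area(fur.depth)
        h = convection_coefficient(sol.T_fur_surface, env, geom.characteristic_dimension)
        q_conv = h * area_out * (sol.T_fur_surface - env.T_air)
        q_ir = 0.95 * SIGMA * area_out * (
            (sol.T_fur_surface + 273.15) ** 4 - (env.T_rad + 273.15) ** 4
        )
        q_solar = 0.8 * 0.25 * env.solar * area_out
        assert sol.Q_conv == pytest.approx(q_conv, rel=1e-9)
        assert sol.Q_ir == pytest.approx(q_ir, rel=1e-9)
        assert sol.Q_solar_abs == pytest.approx(q_solar, rel=1e-9)
        assert abs(sol.M_req - sol.Q_evap + sol.Q_solar_abs - q_conv - q_ir) < 0.1

    def test_energy_closure_random_draws(self):
        rng = np.random.default_rng(2024)
        for _ in range(1000):
            geom = geometry_from_mass(float(rng.uniform(50, 5000)))
            fur = FurLayer(float(rng.uniform(0, 0.05)), float(rng.uniform(0, 2000)))
            env = Environment(
                T_air=float(rng.uniform(-40, 40)),
                T_rad=float(rng.uniform(-60, 50)),
                wind=float(rng.uniform(0, 10)),
                solar=float(rng.uniform(0, 1000)),
                shade_fraction=float(rng.uniform(0, 1)),
            )
            sol = solve_required_metabolism(geom, fur, env, float(rng.uniform(24, 38)))
            assert abs(sol.residual) < 0.1

    def test_deeper_fur_cuts_requirement_in_cold(self, mega_geometry):
        env = chamber_environment(-10.0)
        shallow = solve_required_metabolism(mega_geometry, FurLayer(0.01, 2000.0), env, 31.0)
        deep = solve_required_metabolism(mega_geometry, FurLayer(0.05, 2000.0), env, 31.0)
        assert deep.M_req < shallow.M_req

    def test_monotone_in_air_temperature(self, mega_geometry):
        fur = FurLayer(0.03, 1300.0)
        reqs = [
            solve_required_metabolism(
                mega_geometry, fur, chamber_environment(t), 31.0
            ).M_req
            for t in (-30.0, -10.0, 10.0, 25.0)
        ]
        assert all(a > b for a, b in zip(reqs, reqs[1:]))

    def test_zero_fur_matches_bare_skin_oracle(self, mega_geometry):
        env = Environment(T_air=10.0, T_rad=0.0, wind=1.0, solar=200.0)
        sol = solve_required_metabolism(
            mega_geometry, FurLayer(0.0, 0.0), env, 31.0, evap_fraction=0.05
        )
        # independent bare-skin model: all fluxes at skin temperature = T_core
        area = mega_geometry.surface_area
        h = convection_coefficient(31.0, env, mega_geometry.characteristic_dimension)
        q_conv = h * area * (31.0 - env.T_air)
        q_ir = 0.95 * SIGMA * area * ((31.0 + 273.15) ** 4 - (env.T_rad + 273.15) ** 4)
        q_solar = 0.8 * 0.25 * env.solar * area
        m_expected = (q_conv + q_ir - q_solar) / (1.0 - 0.05)
        assert sol.M_req == pytest.approx(m_expected, abs=1e-6)

    def test_negative_requirement_flagged_infeasible(self, mega_geometry):
        env = Environment(T_air=45.0, T_rad=60.0, wind=0.1, solar=1000.0)
        sol = solve_required_metabolism(mega_geometry, FurLayer(0.0, 0.0), env, 31.0)
        assert sol.M_req < 0.0
        assert not sol.feasible


@pytest.fixture(scope="module")
def mega_bmr():
    return xenarthran_bmr(3706.0)


class TestThermoneutralZone:

    def test_sweep_matches_analytic_band_crossings(self, mega_geometry, mega_bmr):
        # continuous LCT/UCT are the band intersections; the gridded sweep
        # must land within one step of them
        fur = FurLayer(0.03, 2000.0)
        cont = critical_temperatures(mega_geometry, fur, 31.0, mega_bmr)
        swept = metabolic_chamber_sweep(
            mega_geometry, fur, 31.0, mega_bmr, T_range=(-60.0, 50.0), step=0.5
        )
        assert swept.present and cont.present
        assert abs(swept.lct - cont.lct) <= 0.5
        assert abs(swept.uct - cont.uct) <= 0.5

    def test_band_outside_range_absent(self, mega_geometry, mega_bmr):
        fur = FurLayer(0.05, 2000.0)
        zone = metabolic_chamber_sweep(
            mega_geometry, fur, 31.0, mega_bmr, T_range=(30.0, 50.0), step=0.5
        )
        assert not zone.present

    def test_lct_orders_with_depth_and_density(self, mega_geometry, mega_bmr):
        dense50 = critical_temperatures(
            mega_geometry, FurLayer(0.05, 2000.0), 31.0, mega_bmr
        )
        dense10 = critical_temperatures(
            mega_geometry, FurLayer(0.01, 2000.0), 31.0, mega_bmr
        )
        assert dense50.lct < -10.0  # deep dense coat: frost-tolerant
        assert dense50.lct < dense10.lct
        densities = (0.07, 8.5, 1300.0, 2000.0)
        lcts = [
            critical_temperatures(mega_geometry, FurLayer(0.05, d), 31.0, mega_bmr).lct
            for d in densities
        ]
        assert all(a > b for a, b in zip(lcts, lcts[1:]))

    def test_nesting_deep_coat_reaches_colder(self, taxa):
        from xenotherm.heatbalance import geometry_from_mass

        for taxon in taxa:
            geom = geometry_from_mass(taxon.mass)
            bmr = xenarthran_bmr(taxon.mass)
            z50 = critical_temperatures(geom, FurLayer(0.05, 2000.0), taxon.T_core, bmr)
            z10 = critical_temperatures(geom, FurLayer(0.01, 2000.0), taxon.T_core, bmr)
            assert z50.lct < z10.lct

    def test_sweep_refinement(self, mega_geometry, mega_bmr):
        fur = FurLayer(0.03, 2000.0)
        coarse = metabolic_chamber_sweep(
            mega_geometry, fur, 31.0, mega_bmr, T_range=(-60.0, 50.0), step=1.0
        )
        fine = metabolic_chamber_sweep(
            mega_geometry, fur, 31.0, mega_bmr, T_range=(-60.0, 50.0), step=0.5
        )
        assert abs(coarse.lct - fine.lct) <= 1.0
        assert abs(coarse.uct - fine.uct) <= 1.0


def test_heterothermic_relaxation_saves_energy(mega_geometry):
    fur = FurLayer(0.03, 2000.0)
    env = chamber_environment(20.0)
    bmr = xenarthran_bmr(3706.0)
    fixed = solve_required_metabolism(mega_geometry, fur, env, 34.0)
    relaxed = heterothermic_solve(mega_geometry, fur, env, (28.0, 34.0), bmr)
    assert abs(relaxed.M_req - bmr) <= abs(fixed.M_req - bmr)
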
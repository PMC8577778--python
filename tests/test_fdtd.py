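"""FDTD solver validation: plane-wave injection, absorption, oracle checks."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from aedosim import fdtd, mie
from aedosim.constants import C0, EPS0, ETA0
from aedosim.fdtd import (
    FDTDError,
    FieldSolution,
    PlaneWave,
    PMLSpec,
    build_domain,
    compute_pabs,
    field_slice_db,
    required_periods,
    run_fdtd,
    vacuum_domain,
)
from aedosim.synthetic import make_sphere_phantom
from conftest import mosquito_dielectric


class TestRequiredPeriods:
    def test_anchor_values(self):
        assert required_periods(2e9, 4e-3) == 7
        assert required_periods(240e9, 4e-3) == 35

    @given(
        f=st.floats(2e9, 240e9),
        l=st.floats(1e-3, 10e-3),
    )
    def test_always_exceeds_transit_rule(self, f, l):
        n = required_periods(f, l)
        assert n > 2.0 * l / (C0 / f)
        assert n >= 7


class TestPlaneWave:
    def test_orthonormality_enforced(self):
        with pytest.raises(ValueError):
            PlaneWave(k_hat=(1, 0, 0), e_hat=(1, 0, 0), frequency=1e9)
        with pytest.raises(ValueError):
            PlaneWave(k_hat=(2, 0, 0), e_hat=(0, 1, 0), frequency=1e9)

    def test_h_hat_completes_triad(self):
        w = PlaneWave(k_hat=(1, 0, 0), e_hat=(0, 0, 1), frequency=1e9)
        np.testing.assert_allclose(w.h_hat, (0, -1, 0), atol=1e-12)


class TestDomainValidation:
    def test_grid_rule_violation_rejected(self):
        _, model = make_sphere_phantom(0.5e-3, h=200e-6)
        domain = build_domain(model, 6.0, 10.0)
        wave = PlaneWave(k_hat=(1, 0, 0), e_hat=(0, 0, 1), frequency=240e9)
        with pytest.raises(FDTDError, match="lambda"):
            run_fdtd(domain, wave)

    def test_thin_pml_rejected(self):
        with pytest.raises(FDTDError):
            PMLSpec(cells=4)

    def test_material_must_clear_tfsf_boundary(self):
        _, model = make_sphere_phantom(0.5e-3, h=100e-6)
        with pytest.raises(FDTDError):
            build_domain(model, 6.0, 10.0, gap_cells=2)


@pytest.fixture(scope="module")
def vacuum_solution():
    domain = vacuum_domain(shape=(46, 46, 46), spacing=1e-3)
    wave = PlaneWave(
        k_hat=tuple(np.array([1.0, 1.0, 1.0]) / math.sqrt(3)),
        e_hat=tuple(np.array([1.0, -1.0, 0.0]) / math.sqrt(2)),
        frequency=10e9,
    )
    return run_fdtd(domain, wave), domain


class TestVacuumRun:
    def test_total_field_region_carries_incident_rms(self, vacuum_solution):
        sol, _ = vacuum_solution
        ia, ib, ja, jb, ka, kb = sol.tf_box
        mag = np.sqrt(np.abs(sol.ex) ** 2 + np.abs(sol.ey) ** 2 + np.abs(sol.ez) ** 2)
        core = mag[ia + 3 : ib - 2, ja + 3 : jb - 2, ka + 3 : kb - 2]
        assert np.all(np.abs(core - 1.0) < 0.01)

    def test_scattered_region_is_quiet(self, vacuum_solution):
        sol, _ = vacuum_solution
        ia, ib, ja, jb, ka, kb = sol.tf_box
        mag = np.sqrt(np.abs(sol.ex) ** 2 + np.abs(sol.ey) ** 2 + np.abs(sol.ez) ** 2)
        assert mag[ia - 2, ja:jb, ka:kb].max() < 0.01

    def test_no_absorption_without_conductivity(self, vacuum_solution):
        sol, domain = vacuum_solution
        assert compute_pabs(sol, domain) == 0.0
        assert np.all(sol.pabs_trace == 0.0)

    def test_field_slice_is_normalized_db(self, vacuum_solution):
        sol, _ = vacuum_solution
        plane = field_slice_db(sol, axis=1)
        assert plane.max() <= 0.0
        assert plane.shape == sol.ex.shape[::2]


class TestAbsorption:
    def test_lossless_sphere_absorbs_nothing(self):
        _, model = make_sphere_phantom(0.5e-3, h=100e-6)
        domain = build_domain(model, 2.0, 0.0)
        wave = PlaneWave(k_hat=(0, 0, 1), e_hat=(1, 0, 0), frequency=60e9)
        sol = run_fdtd(domain, wave)
        assert compute_pabs(sol, domain) == 0.0

    def test_uniform_field_arithmetic(self):
        """1 V/m RMS over 1 mm^3 of 1 S/m tissue absorbs exactly 1 nW."""
        n = 10  # 10 x 10 x 10 cells of 100 um = 1 mm^3
        h = 100e-6
        shape = (n, n, n)
        sigma = np.ones(shape)
        sol = FieldSolution(
            ex=np.ones(shape, complex),
            ey=np.zeros(shape, complex),
            ez=np.zeros(shape, complex),
            pabs_trace=np.array([]),
            converged=True,
            periods=0,
            frequency=1e9,
            dt=1.0,
            tf_box=(0, n, 0, n, 0, n),
            sigma_x=sigma,
            sigma_y=sigma,
            sigma_z=sigma,
        )
        domain = fdtd.SimulationDomain(
            spacing=h, eps_r=np.full(shape, 2.0), sigma=sigma, pml=PMLSpec(cells=6)
        )
        assert compute_pabs(sol, domain) == pytest.approx(1e-9, rel=1e-12)

    def test_source_linearity_quadruples_power(self):
        f = 60e9
        eps_real, sigma = mosquito_dielectric(f)
        _, model = make_sphere_phantom(0.3e-3, h=100e-6)
        domain = build_domain(model, eps_real, sigma)
        w1 = PlaneWave(k_hat=(1, 0, 0), e_hat=(0, 1, 0), frequency=f, e_rms=1.0)
        w2 = PlaneWave(k_hat=(1, 0, 0), e_hat=(0, 1, 0), frequency=f, e_rms=2.0)
        p1 = compute_pabs(run_fdtd(domain, w1), domain)
        p2 = compute_pabs(run_fdtd(domain, w2), domain)
        assert p2 == pytest.approx(4.0 * p1, rel=1e-9)

    def test_run_is_deterministic(self):
        f = 60e9
        eps_real, sigma = mosquito_dielectric(f)
        _, model = make_sphere_phantom(0.3e-3, h=100e-6)
        domain = build_domain(model, eps_real, sigma)
        wave = PlaneWave(k_hat=(0, 1, 0), e_hat=(0, 0, 1), frequency=f)
        p = [compute_pabs(run_fdtd(domain, wave), domain) for _ in range(2)]
        assert p[0] == p[1]


class TestMieOracle:
    def test_lossless_sphere_has_zero_absorption(self):
        assert mie.mie_absorbed_power(0.5e-3, 2.0, 0.0, 60e9) == pytest.approx(0.0, abs=1e-18)

    def test_rayleigh_limit_within_one_percent(self):
        f = 60e9
        eps_real, sigma = mosquito_dielectric(f)
        r = (C0 / f) / 100.0
        p_mie = mie.mie_absorbed_power(r, eps_real, sigma, f)
        p_ray = mie.rayleigh_absorbed_power(r, eps_real, sigma, f)
        assert p_mie == pytest.approx(p_ray, rel=0.01)

    def test_efficiencies_are_truncation_converged(self):
        # The public routine re-evaluates at a higher order internally;
        # a direct doubling of the order must agree to <1e-6 relative.
        from aedosim.mie import _efficiencies

        m, x = 2.77 + 0.93j, 0.63
        qe1, qs1 = _efficiencies(m, x, 8)
        qe2, qs2 = _efficiencies(m, x, 16)
        assert abs(qe2 - qe1) / qe1 < 1e-6
        assert abs(qs2 - qs1) / qs1 < 1e-6

    def test_energy_conservation(self):
        qe, qs, qa = mie.mie_efficiencies(2.0 + 0.5j, 1.2)
        assert qa >= 0 and qs >= 0 and qe == pytest.approx(qs + qa)


class TestSphereSolverChecks:
    def test_twelve_waves_agree_on_a_sphere(self, sphere_oracle_case):
        """Reciprocity/symmetry: all 12 standard waves deposit the same
        power in a sphere (within 2%)."""
        p = sphere_oracle_case["powers"]
        assert (p.max() - p.min()) / p.mean() < 0.02

    def test_energy_sanity_bound(self, sphere_oracle_case):
        """Absorbed power cannot exceed the incident power flux through
        the sphere cross-section times a scattering-gain margin."""
        r = sphere_oracle_case["radius"]
        s_inc = 1.0 / ETA0  # 1 V/m RMS
        bound = 4.0 * math.pi * r**2 * s_inc  # generous geometric bound
        assert sphere_oracle_case["powers"].max() < bound

    def test_grid_refinement_converges_to_mie(self):
        """Halving the grid step drives the absorbed power toward the
        analytic value, with <5% change between the two finest grids
        (low-contrast sphere)."""
        f = 60e9
        r = 0.5e-3
        eps_real, sigma = 2.0, 1.0
        wave = PlaneWave(k_hat=(1, 0, 0), e_hat=(0, 0, 1), frequency=f)
        p_mie = mie.mie_absorbed_power(r, eps_real, sigma, f)
        errors = []
        powers = []
        for cells_per_radius in (3, 6, 12):
            _, model = make_sphere_phantom(r, h=r / cells_per_radius)
            domain = build_domain(model, eps_real, sigma)
            p = compute_pabs(run_fdtd(domain, wave), domain)
            powers.append(p)
            errors.append(abs(p - p_mie) / p_mie)
        assert errors[1] < errors[0]
        assert errors[2] < errors[1]
        assert abs(powers[2] - powers[1]) / powers[2] < 0.05

    def test_fine_grid_matches_mie_closely(self):
        """At 12 cells per radius the solver lands within 8% of the
        analytic absorption for the mosquito dielectric."""
        f = 60e9
        r = 0.5e-3
        eps_real, sigma = mosquito_dielectric(f)
        _, model = make_sphere_phantom(r, h=r / 12)
        domain = build_domain(model, eps_real, sigma)
        wave = PlaneWave(k_hat=(1, 0, 0), e_hat=(0, 0, 1), frequency=f)
        p = compute_pabs(run_fdtd(domain, wave), domain)
        p_mie = mie.mie_absorbed_power(r, eps_real, sigma, f)
        assert p == pytest.approx(p_mie, rel=0.08)
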
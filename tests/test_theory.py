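"""Closed-form theory: mesh sizes, insertion barriers, recruitment."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from condsieve import theory
from condsieve.theory import (
    CondensateComposition,
    InsertionModel,
    PolymerSolutionSpec,
    RecruitmentSpec,
    correlation_length_from_phi,
    correlation_length_from_pressure,
    insertion_free_energy,
    large_intruder_limit,
    partition_coefficient,
    phi_from_composition,
    recruitment_free_energy,
    recruitment_free_energy_exact,
)


class TestCorrelationLength:
    @pytest.mark.parametrize(
        "phi, expected",
        [(0.036, 5.24), (0.05, 4.1)],
    )
    def test_published_mesh_sizes(self, phi, expected):
        xi = correlation_length_from_phi(PolymerSolutionSpec(phi=phi))
        assert xi == pytest.approx(expected, rel=0.02)

    def test_identity_limit(self):
        spec = PolymerSolutionSpec(phi=1 - 1e-12, d=1.0, c=1.0)
        assert correlation_length_from_phi(spec) == pytest.approx(1.0, rel=1e-9)

    @given(st.floats(0.01, 0.5), st.floats(0.01, 0.49))
    @settings(max_examples=50, deadline=None)
    def test_strictly_decreasing_in_phi(self, phi, dphi):
        lo = correlation_length_from_phi(PolymerSolutionSpec(phi=phi))
        hi = correlation_length_from_phi(PolymerSolutionSpec(phi=min(phi + dphi, 0.999)))
        assert hi < lo

    @pytest.mark.parametrize("phi", [0.0, 1.0, -0.1, 1.5])
    def test_rejects_phi_out_of_range(self, phi):
        with pytest.raises(ValueError):
            PolymerSolutionSpec(phi=phi)

    @pytest.mark.parametrize(
        "pressure, expected",
        [(0.25e6, 2.79), (0.024e6, 6.10)],
    )
    def test_mesh_from_pressure(self, pressure, expected):
        assert correlation_length_from_pressure(pressure) == pytest.approx(
            expected, rel=0.02
        )

    def test_cube_root_pressure_scaling(self):
        base = correlation_length_from_pressure(1e5)
        assert correlation_length_from_pressure(8e5) == pytest.approx(base / 2)
        assert correlation_length_from_pressure(5e4) == pytest.approx(
            base * 2 ** (1 / 3)
        )

    def test_rejects_nonpositive_pressure(self):
        with pytest.raises(ValueError):
            correlation_length_from_pressure(0.0)


class TestInsertionFreeEnergy:
    @pytest.mark.parametrize(
        "radius, expected",
        [(1.9, 2.1), (6.5, 17.0), (8.9, 29.0)],
    )
    def test_dextran_barriers(self, radius, expected):
        df = insertion_free_energy(radius, xi=5.24, phi=0.036)
        assert df == pytest.approx(expected, rel=0.02)

    def test_mesh_sized_probe_without_crowding(self):
        model = InsertionModel()
        df = insertion_free_energy(model=model, R=0.5, xi=1.0, phi=0.0)
        assert df == pytest.approx(3.5, rel=0.02)
        assert partition_coefficient(df) == pytest.approx(0.03, rel=0.02)

    def test_zero_radius_is_volume_term(self):
        assert insertion_free_energy(0.0, xi=3.0, phi=0.0) == 0.0
        assert insertion_free_energy(0.0, xi=3.0, phi=0.2) == pytest.approx(
            -math.log(0.8)
        )

    @given(st.floats(0.0, 20.0), st.floats(0.1, 19.9))
    @settings(max_examples=50, deadline=None)
    def test_monotone_in_radius(self, r, dr):
        lo = insertion_free_energy(r, xi=4.0, phi=0.05)
        hi = insertion_free_energy(r + dr, xi=4.0, phi=0.05)
        assert hi > lo

    def test_monotone_in_phi_at_fixed_xi(self):
        dfs = [insertion_free_energy(2.0, 4.0, p) for p in (0.0, 0.1, 0.3, 0.6)]
        assert np.all(np.diff(dfs) > 0)

    def test_rejects_phi_one(self):
        with pytest.raises(ValueError):
            insertion_free_energy(1.0, 4.0, 1.0)

    def test_asymptotic_loglog_slopes(self):
        """Small probes scale as (R/xi)^(3-1/nu), large as (R/xi)^2."""
        model = InsertionModel()
        x = np.array([1e-6, 1.001e-6])
        f = np.asarray(insertion_free_energy(x, xi=1.0, phi=0.0, model=model))
        slope_small = np.diff(np.log(f)) / np.diff(np.log(x))
        assert slope_small[0] == pytest.approx(3 - 1 / model.nu, abs=1e-3)
        x = np.array([1e6, 1.001e6])
        f = np.asarray(insertion_free_energy(x, xi=1.0, phi=0.0, model=model))
        slope_large = np.diff(np.log(f)) / np.diff(np.log(x))
        assert slope_large[0] == pytest.approx(2.0, abs=1e-3)


class TestPartitionCoefficient:
    def test_published_values(self):
        assert partition_coefficient(3.4) == pytest.approx(0.033, rel=0.02)

    def test_identity_and_monotonicity(self):
        assert partition_coefficient(0.0) == 1.0
        assert partition_coefficient(2.0) < partition_coefficient(1.0)
        df = np.linspace(0, 10, 7)
        p = partition_coefficient(df)
        assert np.all(p > 0) and np.all(p <= 1)

    def test_rejects_non_finite(self):
        with pytest.raises(ValueError):
            partition_coefficient(math.inf)


class TestComposition:
    def test_molar_route_arithmetic(self):
        comp = CondensateComposition(
            molar_concentration=2.6, residues_per_scaffold=250, monomer_radius=0.3
        )
        assert phi_from_composition(comp) == pytest.approx(0.0443, rel=1e-3)

    def test_mass_route_arithmetic(self):
        comp = CondensateComposition(
            mass_concentration=250.0, idr_mass_fraction=0.4,
            monomer_mass=110.0, monomer_radius=0.3,
        )
        assert phi_from_composition(comp) == pytest.approx(0.0619, rel=1e-3)

    def test_zero_concentration(self):
        comp = CondensateComposition(
            molar_concentration=0.0, residues_per_scaffold=250
        )
        assert phi_from_composition(comp) == 0.0

    def test_rejects_unphysical_volume_fraction(self):
        comp = CondensateComposition(
            molar_concentration=500.0, residues_per_scaffold=5000
        )
        with pytest.raises(ValueError):
            phi_from_composition(comp)

    def test_requires_exactly_one_route(self):
        with pytest.raises(ValueError):
            CondensateComposition(
                molar_concentration=1.0, residues_per_scaffold=10,
                mass_concentration=100.0, idr_mass_fraction=0.5,
            )
        with pytest.raises(ValueError):
            CondensateComposition()


class TestRecruitment:
    def test_limiting_form_arithmetic(self):
        assert recruitment_free_energy(
            RecruitmentSpec(site_density=(0.0,), kd=(1.0,), delta_f0=3.0)
        ) == 3.0
        assert recruitment_free_energy(
            RecruitmentSpec(site_density=(5.0,), kd=(1.0,), delta_f0=3.0)
        ) == -2.0

    def test_multiple_site_types_sum(self):
        spec = RecruitmentSpec(site_density=(2.0, 3.0), kd=(1.0, 1.0), delta_f0=4.0)
        assert recruitment_free_energy(spec) == -1.0

    def test_rejects_bad_kd(self):
        with pytest.raises(ValueError):
            RecruitmentSpec(site_density=(1.0,), kd=(0.0,))
        with pytest.raises(ValueError):
            RecruitmentSpec(site_density=(1.0,), kd=(-2.0,))

    def test_exact_evaluator_converges_to_limit(self):
        """Finite-valency Poisson sum approaches -rho/KD + dF0 when the
        valency cap is generous and KD << 1/Omega."""
        spec = RecruitmentSpec(
            site_density=(0.02,), kd=(0.005,), delta_f0=1.2,
            interaction_volume=0.5, valency_cap=60,
        )
        exact = recruitment_free_energy_exact(spec)
        limit = recruitment_free_energy(spec)
        # the limiting form drops the +rho*Omega term; allow for it
        assert exact == pytest.approx(limit + 0.02 * 0.5, abs=1e-6)

    def test_exact_evaluator_zero_sites(self):
        spec = RecruitmentSpec(
            site_density=(0.0,), kd=(1.0,), delta_f0=2.5,
            interaction_volume=0.5, valency_cap=10,
        )
        assert recruitment_free_energy_exact(spec) == 2.5


class TestLargeIntruderLimit:
    def test_surface_scaling_ratio(self):
        spec = PolymerSolutionSpec(phi=0.05)
        r = 100.0
        ratio = large_intruder_limit(2 * r, spec) / large_intruder_limit(r, spec)
        assert ratio == pytest.approx(4.0)

    def test_phi_exponent(self):
        """dF ~ phi^(2nu/(3nu-1)): doubling phi multiplies by 2^1.539."""
        r = 500.0
        lo = large_intruder_limit(r, PolymerSolutionSpec(phi=0.05))
        hi = large_intruder_limit(r, PolymerSolutionSpec(phi=0.10))
        assert hi / lo == pytest.approx(2 ** (2 * 0.588 / (3 * 0.588 - 1)), rel=1e-9)
        assert hi / lo == pytest.approx(2.907, rel=1e-3)

    def test_agreement_with_full_expression(self):
        """The surface term dominates the full barrier (minus the crowding
        term) once R >> xi: the small-probe limb decays as (R/xi)^(-0.701)
        relative, ~11.5% at R/xi = 10 and below 5% at R/xi = 40."""
        spec = PolymerSolutionSpec(phi=0.05)
        model = InsertionModel()
        xi = correlation_length_from_phi(spec)
        for factor, tol in ((10.0, 0.12), (40.0, 0.05)):
            r = factor * xi
            full = insertion_free_energy(r, xi, spec.phi, model) + math.log1p(-spec.phi)
            approx = large_intruder_limit(r, spec, model)
            assert abs(full - approx) / full < tol


def test_mesh_size_routes_are_consistent():
    """xi(phi) and xi(Pi) agree when Pi is itself the blob-picture pressure."""
    spec = PolymerSolutionSpec(phi=0.05)
    xi = correlation_length_from_phi(spec)
    from condsieve.units import kbt_joules

    pressure = kbt_joules(300.0) / ((3 * spec.nu - 1) * (xi * 1e-9) ** 3)
    assert correlation_length_from_pressure(pressure) == pytest.approx(xi, rel=1e-9)
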
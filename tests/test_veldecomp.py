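"""Velocity decomposition: completeness, momentum structure, energy closure."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_chain_system, random_vibrating_co2
from gasmd.constants import ATOMIC_MASSES, KB
from gasmd.presets import build_gas_system, build_molecule_system
from gasmd.topology import system_dof
from gasmd.veldecomp import (
    angular_velocity,
    com_velocity,
    decompose,
    inertia_tensor,
    kinetic_report,
    rotational_energy_via_inertia,
)


def test_com_velocity_uniform_translation():
    state, mols = build_molecule_system("CO2", 50.0)
    state.velocities[:] = [1.0, 0.0, 0.0]
    np.testing.assert_allclose(com_velocity(mols[0], state), [1.0, 0.0, 0.0])


def test_com_velocity_homonuclear_cancellation():
    state, mols = make_chain_system([5.0, 5.0], [[0, 0, 0], [1.5, 0, 0]])
    state.velocities[:] = [[0, 1, 0], [0, -1, 0]]
    np.testing.assert_allclose(com_velocity(mols[0], state), 0.0, atol=1e-15)


def test_com_velocity_co2_mass_weighting():
    """Only the C atom moves: COM velocity is m_C/M_CO2 of its velocity."""
    state, mols = build_molecule_system("CO2", 50.0)
    state.velocities[0] = [0.0, 0.0, 1.0]
    expected = ATOMIC_MASSES["C"] / (ATOMIC_MASSES["C"] + 2 * ATOMIC_MASSES["O"])
    np.testing.assert_allclose(
        com_velocity(mols[0], state), [0.0, 0.0, expected], rtol=1e-14
    )


def test_inertia_monatomic_is_zero():
    state, mols = build_molecule_system("Ar", 50.0)
    data = inertia_tensor(mols[0], state)
    np.testing.assert_allclose(data.tensor, 0.0, atol=1e-12)
    np.testing.assert_allclose(data.principal_moments, 0.0, atol=1e-12)


def test_inertia_linear_co2_closed_form():
    """Rigid CO2: moments (0, I, I) with I = 2·m_O·r²."""
    r = 1.16
    m_o = ATOMIC_MASSES["O"]
    state, mols = make_chain_system(
        [m_o, ATOMIC_MASSES["C"], m_o],
        [[-r, 0, 0], [0, 0, 0], [r, 0, 0]],
    )
    data = inertia_tensor(mols[0], state)
    expected = 2 * m_o * r**2
    np.testing.assert_allclose(
        data.principal_moments, [0.0, expected, expected], atol=1e-10
    )
    assert np.linalg.det(data.principal_axes) == pytest.approx(1.0)


def test_inertia_matches_brute_force_sum():
    """Random 4-atom cloud vs the direct Σ m (r'ᵀr'·1 − r'r'ᵀ) oracle."""
    rng = np.random.default_rng(12)
    masses = rng.uniform(1, 16, 4)
    pos = rng.standard_normal((4, 3)) * 2.0
    state, mols = make_chain_system(masses, pos)
    data = inertia_tensor(mols[0], state)
    com = masses @ pos / masses.sum()
    ref = np.zeros((3, 3))
    for m, p in zip(masses, pos):
        r = p - com
        ref += m * ((r @ r) * np.eye(3) - np.outer(r, r))
    np.testing.assert_allclose(data.tensor, ref, rtol=1e-12)
    # eigendecomposition reconstructs the tensor
    recon = (
        data.principal_axes @ np.diag(data.principal_moments) @ data.principal_axes.T
    )
    np.testing.assert_allclose(recon, ref, atol=1e-10 * np.abs(ref).max())


def test_angular_velocity_recovers_rigid_rotation():
    """v = ω₀×r' on a bent triatomic must invert exactly."""
    omega0 = np.array([0.0, 0.0, 0.01])
    pos = np.array([[0.0, 0, 0], [1.2, 0, 0], [-0.4, 1.1, 0.3]])
    masses = np.array([12.0, 16.0, 16.0])
    com = masses @ pos / masses.sum()
    vel = np.cross(omega0, pos - com)
    state, mols = make_chain_system(masses, pos, vel)
    for weighting in ("mass", "uniform"):
        omega = angular_velocity(mols[0], state, weighting=weighting)
        np.testing.assert_allclose(omega, omega0, atol=1e-14)


def test_angular_velocity_zero_for_pure_translation():
    state, mols = build_molecule_system("CH4", 50.0)
    state.velocities[:] = [0.3, -0.1, 0.2]
    np.testing.assert_allclose(angular_velocity(mols[0], state), 0.0, atol=1e-15)


def test_angular_velocity_monatomic_signals_misuse():
    state, mols = build_molecule_system("Ar", 50.0)
    with pytest.raises(ValueError):
        angular_velocity(mols[0], state)


def test_angular_velocity_matches_independent_least_squares():
    """Mass-weighted fit against the closed-form Θ⁻¹L oracle, and the
    uniform fit against a direct lstsq on the stacked skew system."""
    rng = np.random.default_rng(5)
    state, mols = build_molecule_system("CH4", 50.0)
    state.velocities[:] = rng.standard_normal(state.velocities.shape) * 0.01
    mol = mols[0]
    m = state.masses[mol.atom_indices]
    com = m @ state.positions[mol.atom_indices] / m.sum()
    com_v = m @ state.velocities[mol.atom_indices] / m.sum()
    r = state.positions[mol.atom_indices] - com
    v = state.velocities[mol.atom_indices] - com_v

    theta = np.zeros((3, 3))
    ell = np.zeros(3)
    for mi, ri, vi in zip(m, r, v):
        theta += mi * ((ri @ ri) * np.eye(3) - np.outer(ri, ri))
        ell += mi * np.cross(ri, vi)
    omega_oracle = np.linalg.solve(theta, ell)
    omega = angular_velocity(mol, state, weighting="mass")
    np.testing.assert_allclose(omega, omega_oracle, atol=1e-8 * np.abs(omega_oracle).max())

    rows = np.zeros((3 * len(m), 3))
    for j, ri in enumerate(r):
        x, y, z = ri
        rows[3 * j : 3 * j + 3] = [[0, z, -y], [-z, 0, x], [y, -x, 0]]
    omega_unif_oracle = np.linalg.lstsq(rows, v.reshape(-1), rcond=None)[0]
    omega_unif = angular_velocity(mol, state, weighting="uniform")
    np.testing.assert_allclose(omega_unif, omega_unif_oracle, atol=1e-10)


def test_decompose_uniform_translation():
    state, mols = build_gas_system("CO2", 4, 50.0, seed=1)
    state.velocities[:] = [0.1, 0.2, -0.3]
    comp = decompose(state, mols)
    np.testing.assert_allclose(comp.v_trans, state.velocities)
    np.testing.assert_allclose(comp.v_rot, 0.0, atol=1e-14)
    np.testing.assert_allclose(comp.v_vib, 0.0, atol=1e-14)


def test_decompose_rigid_rotation():
    state, mols = build_molecule_system("CH4", 50.0)
    mol = mols[0]
    m = state.masses
    com = m @ state.positions / m.sum()
    omega0 = np.array([0.004, -0.002, 0.006])
    state.velocities[:] = np.cross(omega0, state.positions - com)
    comp = decompose(state, mols)
    np.testing.assert_allclose(comp.v_trans, 0.0, atol=1e-15)
    np.testing.assert_allclose(comp.v_vib, 0.0, atol=1e-14)
    np.testing.assert_allclose(comp.omega[0], omega0, atol=1e-12)


def test_decompose_symmetric_stretch_is_pure_vibration():
    """O atoms moving outward, C still: zero net momentum and angular
    momentum, so everything lands in v_vib with ω = 0."""
    state, mols = build_molecule_system("CO2", 50.0)
    # template order C, O(+x), O(−x)
    state.velocities[:] = [[0, 0, 0], [0.02, 0, 0], [-0.02, 0, 0]]
    comp = decompose(state, mols)
    np.testing.assert_allclose(comp.v_trans, 0.0, atol=1e-15)
    np.testing.assert_allclose(comp.omega, 0.0, atol=1e-14)
    np.testing.assert_allclose(comp.v_vib, state.velocities, atol=1e-14)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000), n_atoms=st.integers(2, 5))
def test_decomposition_structure_properties(seed, n_atoms):
    """For arbitrary molecules and velocity fields (mass weighting):
    completeness to 1e-12, zero linear momentum of v_rot and v_vib, zero
    angular momentum of v_vib, and exact energy closure."""
    rng = np.random.default_rng(seed)
    masses = rng.uniform(1.0, 20.0, n_atoms)
    pos = rng.standard_normal((n_atoms, 3)) * 1.5
    vel = rng.standard_normal((n_atoms, 3)) * 0.02
    state, mols = make_chain_system(masses, pos, vel)
    comp = decompose(state, mols)

    v_scale = np.abs(vel).max() + 1e-30
    np.testing.assert_allclose(comp.total(), vel, atol=1e-12 * v_scale)

    m = masses[:, None]
    assert np.abs((m * comp.v_rot).sum(0)).max() < 1e-12 * v_scale * masses.sum()
    assert np.abs((m * comp.v_vib).sum(0)).max() < 1e-12 * v_scale * masses.sum()
    com = masses @ pos / masses.sum()
    r = pos - com
    ang_mom_vib = (masses[:, None] * np.cross(r, comp.v_vib)).sum(0)
    assert np.abs(ang_mom_vib).max() < 1e-10 * v_scale * masses.sum()

    def ke(v):
        return 0.5 * float(masses @ np.einsum("ij,ij->i", v, v))

    e_total = ke(vel)
    closure = abs(ke(comp.v_trans) + ke(comp.v_rot) + ke(comp.v_vib) - e_total)
    assert closure <= 1e-10 * max(e_total, 1e-30)


def test_decompose_idempotent_on_vibrational_field():
    state, mols = random_vibrating_co2(seed=3)
    comp = decompose(state, mols)
    vib_state = state.with_velocities(comp.v_vib)
    comp2 = decompose(vib_state, mols)
    np.testing.assert_allclose(comp2.v_trans, 0.0, atol=1e-14)
    np.testing.assert_allclose(comp2.omega, 0.0, atol=1e-12)
    np.testing.assert_allclose(comp2.v_vib, comp.v_vib, atol=1e-13)


def test_frame_covariance_under_rotation():
    """Rotating positions and velocities maps ω → Rω and preserves energies."""
    state, mols = random_vibrating_co2(seed=9, n_mol=3)
    dof = system_dof(mols)
    comp = decompose(state, mols)
    rep = kinetic_report(comp, state, mols, dof)

    ang = 0.7
    rot = np.array(
        [
            [np.cos(ang), -np.sin(ang), 0.0],
            [np.sin(ang), np.cos(ang), 0.0],
            [0.0, 0.0, 1.0],
        ]
    )
    rotated = state.copy()
    rotated.positions[:] = state.positions @ rot.T
    rotated.velocities[:] = state.velocities @ rot.T
    comp_r = decompose(rotated, mols)
    rep_r = kinetic_report(comp_r, rotated, mols, dof)

    np.testing.assert_allclose(comp_r.omega, comp.omega @ rot.T, atol=1e-12)
    for a, b in (
        (rep.E_trans, rep_r.E_trans),
        (rep.E_rot, rep_r.E_rot),
        (rep.E_vib, rep_r.E_vib),
    ):
        assert b == pytest.approx(a, rel=1e-10, abs=1e-14)


def test_kinetic_report_zero_velocities():
    state, mols = build_gas_system("CO2", 3, 50.0, seed=0)
    rep = kinetic_report(decompose(state, mols), state, mols)
    assert rep.E_total == 0.0
    assert rep.T_trans == rep.T_rot == rep.T_vib == 0.0


def test_rotational_energy_two_route_equivalence():
    """½ ωᵀ(BΘ̃Bᵀ)ω equals ½ Σ m‖v_rot‖² on a random rigid rotor."""
    rng = np.random.default_rng(21)
    masses = rng.uniform(1, 16, 5)
    pos = rng.standard_normal((5, 3)) * 1.2
    com = masses @ pos / masses.sum()
    omega0 = rng.standard_normal(3) * 0.01
    vel = np.cross(omega0, pos - com)
    state, mols = make_chain_system(masses, pos, vel)
    comp = decompose(state, mols)
    e_direct = 0.5 * float(
        masses @ np.einsum("ij,ij->i", comp.v_rot, comp.v_rot)
    )
    e_inertia = rotational_energy_via_inertia(mols[0], state, comp.omega[0])
    assert e_inertia == pytest.approx(e_direct, rel=1e-10)


def test_spherical_top_energies_basis_independent():
    """CH4's degenerate inertia moments: reported energies must not depend on
    the arbitrary eigenbasis; compare against the Θ⁻¹L route."""
    rng = np.random.default_rng(4)
    state, mols = build_molecule_system("CH4", 50.0)
    state.velocities[:] = rng.standard_normal((5, 3)) * 0.01
    comp = decompose(state, mols)
    e_rot = 0.5 * float(
        state.masses @ np.einsum("ij,ij->i", comp.v_rot, comp.v_rot)
    )
    e_rot_inertia = rotational_energy_via_inertia(mols[0], state, comp.omega[0])
    assert e_rot_inertia == pytest.approx(e_rot, rel=1e-9)


def test_equipartitioned_init_temperatures():
    """After equipartitioned initialisation every component reads exactly T."""
    from gasmd.engine import initialize_velocities

    state, mols = build_gas_system("CO2", 12, 70.0, seed=2)
    st = initialize_velocities(state, mols, 350.0, seed=8)
    rep = kinetic_report(decompose(st, mols), st, mols)
    assert rep.T_trans == pytest.approx(350.0, rel=1e-10)
    assert rep.T_rot == pytest.approx(350.0, rel=1e-10)
    assert rep.T_vib == pytest.approx(350.0, rel=1e-10)
    assert rep.E_trans + rep.E_rot + rep.E_vib == pytest.approx(
        rep.E_total, rel=1e-10
    )


def test_zero_dof_with_energy_signals_inconsistency():
    """A monatomic gas cannot report rotational energy."""
    from gasmd.topology import DofCounts

    state, mols = build_gas_system("CO2", 2, 50.0, seed=1)
    rng = np.random.default_rng(0)
    state.velocities[:] = rng.standard_normal(state.velocities.shape)
    comp = decompose(state, mols)
    bad_dof = DofCounts(3, 0, 0, 3)  # claims no rotational DOF
    with pytest.raises(ValueError, match="zero degrees of freedom"):
        kinetic_report(comp, state, mols, bad_dof)
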
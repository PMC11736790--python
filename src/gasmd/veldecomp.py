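"""Decomposition of atomic velocities into translational, rotational and
vibrational components, and the component kinetic energies / temperatures.

The translational part of every atom's velocity is the centre-of-mass (COM)
velocity of its molecule.  The rotational part is ω×r′ with r′ the COM-frame
position and ω the angular velocity obtained from a linear least-squares fit
of the COM-frame velocities to a rigid rotation, formulated through per-atom
projection operators Ξ (one 3×3 skew block per atom) stacked into a 3N×3
system solved by pseudo-inverse.  The vibrational part is the remainder.

Two weightings of the fit are available:

``"mass"`` (default)
    minimise Σ m‖v′ − ω×r′‖².  The normal equations reduce to Θω = L (inertia
    tensor / angular momentum), so v_vib carries exactly zero linear *and*
    angular momentum and the three component energies close exactly on the
    total kinetic energy.  This is what the thermostat consumes.
``"uniform"``
    minimise Σ‖v′ − ω×r′‖², the projection-operator fit with mass-independent
    Ξ blocks as printed in the source formulation.  For rigid motion it
    coincides with the mass-weighted fit; for vibrating molecules with unequal
    masses it leaves a small angular-momentum residue in v_vib and the energy
    closure is only approximate.  Provided for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .constants import KB
from .topology import DofCounts, MoleculeTopology, SystemState

#: relative singular-value cutoff for the pseudo-inverse; keeps linear
#: molecules (rank-2 inertia) on the same code path as nonlinear ones
PINV_RCOND = 1e-10


@dataclass
class InertiaData:
    """Inertia tensor of one molecule with its eigendecomposition.

    ``principal_axes`` columns are the principal axes, ordered by ascending
    moment and chosen right-handed (det = +1).
    """

    tensor: np.ndarray  # (3,3), amu·Å²
    principal_moments: np.ndarray  # (3,), ascending
    principal_axes: np.ndarray  # (3,3), columns e1,e2,e3


@dataclass
class VelocityComponents:
    """Per-atom velocity components and per-molecule angular velocities."""

    v_trans: np.ndarray  # (N,3)
    v_rot: np.ndarray  # (N,3)
    v_vib: np.ndarray  # (N,3)
    omega: np.ndarray  # (n_mol,3), rad/fs, lab frame

    def total(self) -> np.ndarray:
        return self.v_trans + self.v_rot + self.v_vib


@dataclass
class KineticReport:
    """Component kinetic energies (amu·Å²/fs²) and effective temperatures (K)."""

    E_trans: float
    E_rot: float
    E_vib: float
    E_total: float
    T_trans: float
    T_rot: float
    T_vib: float

    @property
    def E_kin_mol(self) -> float:
        """Molecular (COM) kinetic energy: identical to E_trans."""
        return self.E_trans


def com_velocity(molecule: MoleculeTopology, state: SystemState) -> np.ndarray:
    """Mass-weighted mean velocity Σ m_j v_j / M of one molecule."""
    idx = molecule.atom_indices
    m = state.masses[idx]
    return m @ state.velocities[idx] / m.sum()


def com_position(molecule: MoleculeTopology, state: SystemState) -> np.ndarray:
    idx = molecule.atom_indices
    m = state.masses[idx]
    return m @ state.positions[idx] / m.sum()


def _inertia_from_relative(r: np.ndarray, m: np.ndarray) -> np.ndarray:
    theta = -np.einsum("i,ij,ik->jk", m, r, r)
    theta[np.diag_indices(3)] += m @ np.einsum("ij,ij->i", r, r)
    return theta


def inertia_tensor(molecule: MoleculeTopology, state: SystemState) -> InertiaData:
    """Inertia tensor from COM-frame positions, with ascending right-handed
    eigenbasis.  Positions must be unwrapped (molecule whole)."""
    idx = molecule.atom_indices
    m = state.masses[idx]
    r = state.positions[idx] - com_position(molecule, state)
    theta = _inertia_from_relative(r, m)
    moments, axes = np.linalg.eigh(theta)
    if np.linalg.det(axes) < 0:
        axes = axes.copy()
        axes[:, 2] *= -1.0
    return InertiaData(tensor=theta, principal_moments=moments, principal_axes=axes)


def projection_operator(r_prime: np.ndarray) -> np.ndarray:
    """Per-atom 3×3 projection block Ξ with v_rot = Ξ ω, i.e. −skew(r′)."""
    x, y, z = r_prime
    return np.array([[0.0, z, -y], [-z, 0.0, x], [y, -x, 0.0]])


def angular_velocity(
    molecule: MoleculeTopology,
    state: SystemState,
    inertia: InertiaData | None = None,
    weighting: str = "mass",
) -> np.ndarray:
    """Angular velocity of one molecule in the lab frame.

    Builds the stacked 3N×3 projection-operator system in the principal-axis
    frame and solves it by Moore–Penrose pseudo-inverse (singular-value cutoff
    ``PINV_RCOND``·σ_max), which handles the rank-2 system of a linear
    molecule without branching.  Raises for monatomic molecules.
    """
    if molecule.n_atoms < 2:
        raise ValueError("angular velocity is undefined for a monatomic molecule")
    if inertia is None:
        inertia = inertia_tensor(molecule, state)
    idx = molecule.atom_indices
    m = state.masses[idx]
    b_mat = inertia.principal_axes
    r = (state.positions[idx] - com_position(molecule, state)) @ b_mat
    v = (state.velocities[idx] - com_velocity(molecule, state)) @ b_mat

    xi = np.concatenate([projection_operator(ri) for ri in r], axis=0)  # (3n,3)
    rhs = v.reshape(-1)
    if weighting == "mass":
        w = np.sqrt(np.repeat(m, 3))
        xi = xi * w[:, None]
        rhs = rhs * w
    elif weighting != "uniform":
        raise ValueError(f"unknown weighting {weighting!r}")
    omega_p = np.linalg.pinv(xi, rcond=PINV_RCOND) @ rhs
    return b_mat @ omega_p


class Decomposer:
    """Vectorised velocity decomposition for a fixed molecule list.

    Molecules are grouped by atom count so that systems of many identical
    molecules decompose in a handful of batched 3×3 linear-algebra calls —
    this runs once per MD step inside the thermostat.
    """

    def __init__(self, molecules: Sequence[MoleculeTopology]):
        self.molecules = list(molecules)
        self._groups: list[tuple[np.ndarray, np.ndarray]] = []  # (mol_rows, idx (g,n))
        by_size: dict[int, list[int]] = {}
        for row, mol in enumerate(self.molecules):
            by_size.setdefault(mol.n_atoms, []).append(row)
        for n, rows in sorted(by_size.items()):
            idx = np.array([self.molecules[r].atom_indices for r in rows])
            self._groups.append((np.array(rows), idx))

    def decompose(self, state: SystemState, weighting: str = "mass") -> VelocityComponents:
        n_mol = len(self.molecules)
        v_trans = np.empty_like(state.velocities)
        v_rot = np.zeros_like(state.velocities)
        omega = np.zeros((n_mol, 3))
        pos, vel, masses = state.positions, state.velocities, state.masses

        for rows, idx in self._groups:
            g, n = idx.shape
            m = masses[idx]  # (g,n)
            mtot = m.sum(axis=1)
            p = pos[idx]
            v = vel[idx]
            com_v = np.einsum("gn,gnk->gk", m, v) / mtot[:, None]
            v_trans[idx.reshape(-1)] = np.repeat(com_v, n, axis=0)
            if n == 1:
                continue
            com_x = np.einsum("gn,gnk->gk", m, p) / mtot[:, None]
            r = p - com_x[:, None, :]
            vp = v - com_v[:, None, :]
            w = m if weighting == "mass" else np.ones_like(m)
            # normal matrix of the stacked-Ξ least squares: Σ w (|r|²I − r rᵀ)
            a = -np.einsum("gn,gnj,gnk->gjk", w, r, r)
            diag = np.einsum("gn,gn->g", w, np.einsum("gnj,gnj->gn", r, r))
            a[:, np.arange(3), np.arange(3)] += diag[:, None]
            b = np.einsum("gn,gnk->gk", w, np.cross(r, vp))
            omega_g = np.einsum("gjk,gk->gj", np.linalg.pinv(a, rcond=PINV_RCOND), b)
            omega[rows] = omega_g
            v_rot[idx.reshape(-1)] = np.cross(omega_g[:, None, :], r).reshape(-1, 3)

        v_vib = vel - v_trans - v_rot
        return VelocityComponents(v_trans=v_trans, v_rot=v_rot, v_vib=v_vib, omega=omega)


def decompose(
    state: SystemState,
    molecules: Sequence[MoleculeTopology],
    weighting: str = "mass",
) -> VelocityComponents:
    """One-shot velocity decomposition (see :class:`Decomposer`)."""
    return Decomposer(molecules).decompose(state, weighting=weighting)


def kinetic_report(
    components: VelocityComponents,
    state: SystemState,
    molecules: Sequence[MoleculeTopology],
    dof: DofCounts | None = None,
) -> KineticReport:
    """Component kinetic energies and effective temperatures T = 2E/(f·k_B)."""
    from .topology import system_dof

    if dof is None:
        dof = system_dof(molecules)
    m = state.masses

    def ke(v: np.ndarray) -> float:
        return 0.5 * float(m @ np.einsum("ij,ij->i", v, v))

    e_trans, e_rot, e_vib = ke(components.v_trans), ke(components.v_rot), ke(components.v_vib)
    e_total = ke(state.velocities)

    def temp(e: float, f: int, label: str) -> float:
        if f == 0:
            if e > 1e-8 * max(e_total, 1e-300):
                raise ValueError(
                    f"{label}: nonzero kinetic energy with zero degrees of freedom"
                )
            return 0.0
        return 2.0 * e / (f * KB)

    return KineticReport(
        E_trans=e_trans,
        E_rot=e_rot,
        E_vib=e_vib,
        E_total=e_total,
        T_trans=temp(e_trans, dof.trans, "translation"),
        T_rot=temp(e_rot, dof.rot, "rotation"),
        T_vib=temp(e_vib, dof.vib, "vibration"),
    )


def rotational_energy_via_inertia(
    molecule: MoleculeTopology, state: SystemState, omega: np.ndarray
) -> float:
    """½ ωᵀΘω evaluated through the principal-axis factorisation B Θ̃ Bᵀ.

    Equal to ½ Σ m‖ω×r′‖² for the same ω; the equality is asserted by test.
    """
    inertia = inertia_tensor(molecule, state)
    omega_p = inertia.principal_axes.T @ omega
    return 0.5 * float(omega_p @ (inertia.principal_moments * omega_p))
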
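"""Molecular data model, geometry classification and degree-of-freedom accounting.

A system is a flat array of atoms plus a list of molecules, each molecule
owning a contiguous-or-not subset of atom indices and the bonds among them.
Geometry class (monatomic / linear / nonlinear) is decided once, from the
principal moments of inertia of the reference configuration, and fixes the
per-molecule rotational and vibrational DOF counts used by the thermostat.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import NamedTuple, Sequence

import numpy as np

from .constants import ATOMIC_MASSES

#: ratio of smallest to largest principal moment below which a molecule is
#: treated as linear (evaluated on the reference configuration only)
EPS_LINEAR = 1e-6


class TopologyError(ValueError):
    """Raised for malformed topologies (disconnected molecules, shared atoms...)."""


@dataclass(frozen=True)
class AtomSpec:
    """One atom: chemical symbol and mass in amu."""

    element: str
    mass: float

    def __post_init__(self) -> None:
        if not self.mass > 0:
            raise TopologyError(f"atom {self.element}: mass must be > 0, got {self.mass}")

    @classmethod
    def from_element(cls, element: str) -> "AtomSpec":
        try:
            return cls(element, ATOMIC_MASSES[element])
        except KeyError:
            raise TopologyError(
                f"unknown element {element!r} and no explicit mass given"
            ) from None


@dataclass
class MoleculeTopology:
    """Atom membership, connectivity and DOF bookkeeping of one molecule.

    ``f_trans`` is always 3 per molecule; the system-wide removal of the three
    conserved centre-of-mass momentum components is charged to the
    translational pool in :func:`system_dof`, not here.
    """

    id: int
    atom_indices: np.ndarray  # global indices into the system atom array
    bonds: list[tuple[int, int]]  # global index pairs
    species: str
    geometry_class: str  # monatomic | linear | nonlinear
    total_mass: float
    elements: list[str] = field(default_factory=list)  # local order
    f_trans: int = 3
    f_rot: int = 0
    f_vib: int = 0

    @property
    def n_atoms(self) -> int:
        return len(self.atom_indices)


@dataclass
class SystemState:
    """Instantaneous phase-space point of a cubic periodic system.

    Positions are kept unwrapped (molecules whole across the boundary);
    all interactions use the minimum-image convention so wrapping is never
    required during propagation.
    """

    positions: np.ndarray  # (N, 3) Å
    velocities: np.ndarray  # (N, 3) Å/fs
    masses: np.ndarray  # (N,) amu
    box_edge: float  # Å
    time: float = 0.0  # fs

    def __post_init__(self) -> None:
        self.positions = np.ascontiguousarray(self.positions, dtype=float)
        self.velocities = np.ascontiguousarray(self.velocities, dtype=float)
        self.masses = np.ascontiguousarray(self.masses, dtype=float)
        n = len(self.positions)
        if self.positions.shape != (n, 3) or self.velocities.shape != (n, 3):
            raise ValueError("positions/velocities must be (N, 3) arrays")
        if self.masses.shape != (n,):
            raise ValueError("masses must be an (N,) array")
        if not self.box_edge > 0:
            raise ValueError("box_edge must be > 0")

    @property
    def n_atoms(self) -> int:
        return len(self.positions)

    @property
    def volume(self) -> float:
        return self.box_edge**3

    def copy(self) -> "SystemState":
        return SystemState(
            self.positions.copy(), self.velocities.copy(), self.masses,
            self.box_edge, self.time,
        )

    def with_velocities(self, velocities: np.ndarray) -> "SystemState":
        return replace(self, velocities=np.asarray(velocities, dtype=float))


class DofCounts(NamedTuple):
    """System-wide degree-of-freedom totals per kinetic-energy component."""

    trans: int
    rot: int
    vib: int
    total: int


def classify_geometry(moments: Sequence[float], eps_lin: float = EPS_LINEAR) -> str:
    """Classify a molecule from its ascending principal moments of inertia.

    All moments ≈ 0 (below 1e-9 amu·Å², far under any real bond's moment) →
    monatomic; smallest/largest below ``eps_lin`` → linear; otherwise
    nonlinear.  Small negative eigenvalues from round-off are tolerated;
    anything grossly negative is an error.
    """
    m = np.asarray(moments, dtype=float)
    scale = max(m.max(initial=0.0), 1.0)
    if (m < -1e-9 * scale).any():
        raise ValueError(f"negative principal moment beyond tolerance: {m}")
    m = np.clip(m, 0.0, None)
    largest = m[-1]
    if largest <= 1e-9:
        return "monatomic"
    if m[0] / largest < eps_lin:
        return "linear"
    return "nonlinear"


def _reference_moments(positions: np.ndarray, masses: np.ndarray) -> np.ndarray:
    com = masses @ positions / masses.sum()
    r = positions - com
    r2 = np.einsum("ij,ij->i", r, r)
    theta = np.einsum("i,ij,ik->jk", masses, r, r) * -1.0
    theta[np.diag_indices(3)] += masses @ r2
    return np.linalg.eigvalsh(theta)


def make_molecule(
    mol_id: int,
    atom_indices: Sequence[int],
    bonds: Sequence[tuple[int, int]],
    species: str,
    masses: np.ndarray,
    reference_positions: np.ndarray,
    elements: Sequence[str] | None = None,
    eps_lin: float = EPS_LINEAR,
) -> MoleculeTopology:
    """Build a :class:`MoleculeTopology`, classifying geometry and counting DOF.

    ``masses`` and ``reference_positions`` are system-wide arrays indexed by
    the global atom indices.  The bond graph must be connected.
    """
    idx = np.asarray(atom_indices, dtype=int)
    index_set = set(idx.tolist())
    for i, j in bonds:
        if i not in index_set or j not in index_set:
            raise TopologyError(
                f"molecule {mol_id}: bond ({i},{j}) references an atom outside it"
            )
    _check_connected(idx, bonds, mol_id)

    m = masses[idx]
    moments = _reference_moments(np.asarray(reference_positions, dtype=float)[idx], m)
    geom = classify_geometry(moments, eps_lin)
    n = len(idx)
    f_rot = {"monatomic": 0, "linear": 2, "nonlinear": 3}[geom]
    f_vib = 3 * n - 3 - f_rot
    if f_vib < 0:
        raise TopologyError(f"molecule {mol_id}: negative vibrational DOF count")
    return MoleculeTopology(
        id=mol_id,
        atom_indices=idx,
        bonds=[tuple(sorted(b)) for b in bonds],
        species=species,
        geometry_class=geom,
        total_mass=float(m.sum()),
        elements=[elements[i] for i in idx] if elements is not None else [],
        f_rot=f_rot,
        f_vib=f_vib,
    )


def _check_connected(idx: np.ndarray, bonds: Sequence[tuple[int, int]], mol_id: int) -> None:
    if len(idx) == 1:
        return
    adj: dict[int, set[int]] = {int(i): set() for i in idx}
    for i, j in bonds:
        adj[i].add(j)
        adj[j].add(i)
    seen = {int(idx[0])}
    stack = [int(idx[0])]
    while stack:
        for nb in adj[stack.pop()]:
            if nb not in seen:
                seen.add(nb)
                stack.append(nb)
    if len(seen) != len(idx):
        raise TopologyError(f"molecule {mol_id}: bond graph is disconnected")


def system_dof(molecules: Sequence[MoleculeTopology]) -> DofCounts:
    """System DOF totals; three conserved COM-momentum components are removed
    from the translational pool."""
    if not molecules:
        raise ValueError("need at least one molecule")
    f_trans = max(3 * len(molecules) - 3, 0)
    f_rot = sum(m.f_rot for m in molecules)
    f_vib = sum(m.f_vib for m in molecules)
    return DofCounts(f_trans, f_rot, f_vib, f_trans + f_rot + f_vib)


def build_system(
    topology_file, coordinates_file
) -> tuple[SystemState, list[MoleculeTopology]]:
    """Read a topology file plus an XYZ configuration into a system.

    The topology file assigns every atom to exactly one molecule and lists
    bonds; geometry classes are assigned from the XYZ reference configuration.
    """
    from . import io as gio

    atoms, mol_ids, bonds, species_map = gio.read_topology(topology_file)
    elements, positions, box_edge, _time = gio.read_xyz(coordinates_file)
    if len(atoms) != len(positions):
        raise TopologyError(
            f"topology has {len(atoms)} atoms but coordinates have {len(positions)}"
        )
    for a, el in zip(atoms, elements):
        if a.element != el:
            raise TopologyError(
                f"element mismatch between topology ({a.element}) and XYZ ({el})"
            )
    masses = np.array([a.mass for a in atoms])
    state = SystemState(
        positions=positions,
        velocities=np.zeros_like(positions),
        masses=masses,
        box_edge=box_edge,
    )
    molecules = assign_molecules(
        mol_ids, bonds, species_map, masses, positions,
        elements=[a.element for a in atoms],
    )
    return state, molecules


def assign_molecules(
    mol_ids: Sequence[int],
    bonds: Sequence[tuple[int, int]],
    species_map: dict[int, str],
    masses: np.ndarray,
    reference_positions: np.ndarray,
    elements: Sequence[str] | None = None,
) -> list[MoleculeTopology]:
    """Group atoms by declared molecule id and validate connectivity."""
    mol_ids = np.asarray(mol_ids, dtype=int)
    by_mol: dict[int, list[int]] = {}
    for atom, mid in enumerate(mol_ids):
        by_mol.setdefault(int(mid), []).append(atom)
    for i, j in bonds:
        if mol_ids[i] != mol_ids[j]:
            raise TopologyError(f"bond ({i},{j}) spans two molecules")
    molecules = []
    for new_id, mid in enumerate(sorted(by_mol)):
        idx = by_mol[mid]
        mol_bonds = [b for b in bonds if mol_ids[b[0]] == mid]
        molecules.append(
            make_molecule(
                new_id, idx, mol_bonds, species_map.get(mid, "?"),
                masses, reference_positions, elements=elements,
            )
        )
    return molecules
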
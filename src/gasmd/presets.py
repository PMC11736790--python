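"""Shipped molecule templates, force-field presets and gas-system builders.

The presets are classical desk-scale surrogates for small gas molecules, not
fits to any quantum-chemical surface:

``co2_flex``
    Flexible CO₂: Morse C–O bonds with a realistic harmonic curvature
    (2Dα² = 8000 kJ/mol/Å², stretch period ≈ 18 fs) but a deliberately mild
    anharmonicity (α = 0.08 Å⁻¹, two orders below a chemical C=O bond) chosen
    so that the intramolecular-virial interpolation table at its standard
    0.1 Å / 1° resolution reproduces the bond virial to better than ~1e-4 bar
    in a 100 Å cell, while remaining strictly non-harmonic.  The Morse form
    here supplies a smooth, controlled anharmonicity — it is *not* a
    dissociation model (D is correspondingly large).  Harmonic O–C–O angle,
    EPM2-flavoured atomic Lennard-Jones sites.
``ch4_flex``
    Flexible CH₄: harmonic C–H bonds and H–C–H angles, united LJ sites on C
    and H.
``argon``
    Monatomic LJ argon.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import ATOMIC_MASSES
from .forcefield import AngleTerm, BondTerm, ForceFieldParams, LJSite
from .topology import MoleculeTopology, SystemState, make_molecule

_KB_KJMOL = 0.008314462618  # kJ/mol/K, for ε given in kelvin


@dataclass(frozen=True)
class MoleculeTemplate:
    """Reference geometry and connectivity of one molecular species."""

    species: str
    elements: tuple[str, ...]
    reference_positions: np.ndarray  # (n,3) Å, equilibrium geometry
    bonds: tuple[tuple[int, int], ...]  # local indices


def _co2_template() -> MoleculeTemplate:
    r0 = 1.162
    pos = np.array([[0.0, 0.0, 0.0], [r0, 0.0, 0.0], [-r0, 0.0, 0.0]])
    return MoleculeTemplate("CO2", ("C", "O", "O"), pos, ((0, 1), (0, 2)))


def _ch4_template() -> MoleculeTemplate:
    r0 = 1.087
    s = r0 / np.sqrt(3.0)
    pos = np.array(
        [[0.0, 0.0, 0.0], [s, s, s], [s, -s, -s], [-s, s, -s], [-s, -s, s]]
    )
    return MoleculeTemplate(
        "CH4", ("C", "H", "H", "H", "H"), pos, ((0, 1), (0, 2), (0, 3), (0, 4))
    )


def _argon_template() -> MoleculeTemplate:
    return MoleculeTemplate("Ar", ("Ar",), np.zeros((1, 3)), ())


TEMPLATES: dict[str, MoleculeTemplate] = {
    "CO2": _co2_template(),
    "CH4": _ch4_template(),
    "Ar": _argon_template(),
}


def forcefield_params(preset: str) -> ForceFieldParams:
    """Named force-field presets: ``co2_flex``, ``ch4_flex``, ``argon``."""
    if preset == "co2_flex":
        # curvature 2Dα² = 8000 kJ/mol/Å²; see module docstring for α choice
        alpha = 0.08
        return ForceFieldParams(
            bond_terms={
                "CO2": BondTerm(
                    "morse", r0=1.162, D=8000.0 / (2.0 * alpha**2), alpha=alpha
                )
            },
            angle_terms={"CO2": AngleTerm(theta0=180.0, k=1236.0)},
            lj={
                "C": LJSite(28.129 * _KB_KJMOL, 2.757),
                "O": LJSite(80.507 * _KB_KJMOL, 3.033),
            },
        )
    if preset == "ch4_flex":
        return ForceFieldParams(
            bond_terms={"CH4": BondTerm("harmonic", r0=1.087, k=2900.0)},
            angle_terms={"CH4": AngleTerm(theta0=109.471, k=293.0)},
            lj={
                "C": LJSite(55.052 * _KB_KJMOL, 3.400),
                "H": LJSite(7.901 * _KB_KJMOL, 2.500),
            },
        )
    if preset == "argon":
        return ForceFieldParams(lj={"Ar": LJSite(120.0 * _KB_KJMOL, 3.405)})
    raise ValueError(f"unknown force-field preset {preset!r}")


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix from a normalised random quaternion."""
    q = rng.standard_normal(4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def build_gas_system(
    species: str,
    n_mol: int,
    box_edge: float,
    seed: int = 0,
    min_sep: float = 6.0,
) -> tuple[SystemState, list[MoleculeTopology]]:
    """Random gas configuration: molecules at their equilibrium geometry with
    uniform random COM positions (minimum-image COM separation ≥ ``min_sep``)
    and uniform random orientations.  Velocities are zero; initialise them
    with :func:`gasmd.engine.initialize_velocities`."""
    tpl = TEMPLATES[species]
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    n_per = len(tpl.elements)
    masses_local = np.array([ATOMIC_MASSES[e] for e in tpl.elements])

    coms: list[np.ndarray] = []
    attempts = 0
    while len(coms) < n_mol:
        cand = rng.uniform(0.0, box_edge, size=3)
        ok = True
        for c in coms:
            d = cand - c
            d -= box_edge * np.round(d / box_edge)
            if float(d @ d) < min_sep * min_sep:
                ok = False
                break
        if ok:
            coms.append(cand)
        attempts += 1
        if attempts > 1000 * n_mol:
            raise RuntimeError(
                f"could not place {n_mol} molecules with min_sep={min_sep} Å "
                f"in a {box_edge} Å box"
            )

    ref = tpl.reference_positions - (
        masses_local @ tpl.reference_positions / masses_local.sum()
    )
    positions = np.empty((n_mol * n_per, 3))
    masses = np.tile(masses_local, n_mol)
    elements = list(tpl.elements) * n_mol
    mol_ids = np.repeat(np.arange(n_mol), n_per)
    bonds: list[tuple[int, int]] = []
    for k, com in enumerate(coms):
        rot = _random_rotation(rng)
        block = slice(k * n_per, (k + 1) * n_per)
        positions[block] = ref @ rot.T + com
        bonds.extend((k * n_per + i, k * n_per + j) for i, j in tpl.bonds)

    state = SystemState(
        positions=positions,
        velocities=np.zeros_like(positions),
        masses=masses,
        box_edge=box_edge,
    )
    from .topology import assign_molecules

    molecules = assign_molecules(
        mol_ids, bonds, {k: species for k in range(n_mol)},
        masses, positions, elements=elements,
    )
    return state, molecules


def build_molecule_system(
    species: str,
    box_edge: float,
    positions: np.ndarray | None = None,
) -> tuple[SystemState, list[MoleculeTopology]]:
    """A single molecule in a cubic cell, at its reference geometry unless
    explicit positions are given."""
    tpl = TEMPLATES[species]
    pos = tpl.reference_positions if positions is None else np.asarray(positions, float)
    masses = np.array([ATOMIC_MASSES[e] for e in tpl.elements])
    state = SystemState(
        positions=pos + 0.5 * box_edge,  # anywhere in the cell; virial is invariant
        velocities=np.zeros((len(masses), 3)),
        masses=masses,
        box_edge=box_edge,
    )
    mol = make_molecule(
        0, np.arange(len(masses)), list(tpl.bonds), species,
        masses, state.positions, elements=list(tpl.elements),
    )
    return state, [mol]
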
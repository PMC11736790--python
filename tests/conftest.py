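"""Shared fixtures: programmatically generated molecular systems.

All test inputs are synthetic — rigid rotors, random gas configurations and
lattice gases built in memory; nothing is read from disk unless a test writes
it first.
"""

from __future__ import annotations

import numpy as np
import pytest

from gasmd.forcefield import BondTerm, ForceFieldParams, LJSite
from gasmd.presets import build_gas_system, forcefield_params
from gasmd.topology import SystemState, assign_molecules


@pytest.fixture(scope="session")
def co2_params():
    return forcefield_params("co2_flex")


@pytest.fixture()
def co2_gas_small():
    """10 CO2 molecules in a 60 Å box, velocities zero."""
    return build_gas_system("CO2", 10, 60.0, seed=11)


def make_chain_system(
    masses,
    positions,
    velocities=None,
    box_edge=200.0,
    species="X",
    chain_bonds=True,
):
    """One molecule with the given atoms, bonded as a chain 0-1-2-...

    Returns (state, molecules).  Convenient for bespoke rotors and diatomics.
    """
    masses = np.asarray(masses, dtype=float)
    positions = np.asarray(positions, dtype=float)
    n = len(masses)
    if velocities is None:
        velocities = np.zeros_like(positions)
    bonds = [(i, i + 1) for i in range(n - 1)] if chain_bonds and n > 1 else []
    state = SystemState(positions, np.asarray(velocities, float), masses, box_edge)
    molecules = assign_molecules(
        np.zeros(n, dtype=int), bonds, {0: species}, masses, positions,
        elements=["X"] * n,
    )
    return state, molecules


def harmonic_params(species="X", r0=1.5, k=1000.0):
    """Minimal force field: one harmonic bond type, no LJ."""
    return ForceFieldParams(
        bond_terms={species: BondTerm("harmonic", r0=r0, k=k)},
        lj={},
        lj_enabled=False,
    )


def random_vibrating_co2(seed, n_mol=6, box=60.0, v_scale=0.01):
    """A CO2 gas with random (non-thermal) velocities: exercises all three
    components simultaneously."""
    state, molecules = build_gas_system("CO2", n_mol, box, seed=seed)
    rng = np.random.default_rng(seed + 7)
    state.velocities[:] = v_scale * rng.standard_normal(state.velocities.shape)
    return state, molecules


def argon_lattice(n_side=8, spacing=8.0):
    """Monatomic Ar gas on a simple-cubic lattice (synthetic ideal-gas-like
    configuration; the lattice geometry is also used by the RDF oracle)."""
    from gasmd.constants import ATOMIC_MASSES

    n = n_side**3
    grid = np.arange(n_side) * spacing
    pos = np.array(np.meshgrid(grid, grid, grid, indexing="ij")).reshape(3, -1).T
    masses = np.full(n, ATOMIC_MASSES["Ar"])
    state = SystemState(
        pos.astype(float), np.zeros((n, 3)), masses, box_edge=n_side * spacing
    )
    molecules = assign_molecules(
        np.arange(n), [], {i: "Ar" for i in range(n)}, masses, pos,
        elements=["Ar"] * n,
    )
    return state, molecules
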
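"""Classical flexible small-molecule gas force field and virial bookkeeping.

This is the pluggable force provider: intramolecular bonded terms (harmonic or
Morse bonds, harmonic angles) evaluated on unwrapped in-molecule geometry,
plus intermolecular Lennard-Jones (Lorentz–Berthelot combining, potential
shifted to zero at the cutoff) over atom pairs of distinct molecules under the
minimum-image convention.  Optionally, fixed partial charges with a
cutoff-shifted Coulomb term.

Besides forces and potential energy each evaluation returns the total stress
tensor σ = (Σ r⊗F)/V accumulated over all interactions (pair/bond vectors for
two-body terms, COM-invariant relative vectors for angles) and the scalar
intermolecular virial W accumulated over atom pairs of distinct molecules.
Any provider honouring this contract (forces + stress tensors) can replace
this module; the molecule-based pressure machinery only consumes stresses.

Parameters are given in kJ/mol, Å and degrees and converted to internal units
(amu, Å, fs) on construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .constants import KJ_PER_MOL
from .topology import MoleculeTopology, SystemState

#: Coulomb constant e²/(4πε₀) in kJ/mol·Å
COULOMB_KJMOL = 1389.35458

_OVERLAP_R2 = 1e-12  # Å²; closer nonbonded contacts signal a corrupt configuration


class OverlapError(RuntimeError):
    """Two nonbonded atoms closer than 1e-6 Å."""


@dataclass(frozen=True)
class BondTerm:
    """Bond potential: ``harmonic`` U = ½k(r−r₀)² or ``morse``
    U = D(1−exp(−α(r−r₀)))².  k in kJ/mol/Å², D in kJ/mol, α in 1/Å."""

    style: str
    r0: float
    k: float | None = None
    D: float | None = None
    alpha: float | None = None

    def __post_init__(self) -> None:
        if self.style not in ("harmonic", "morse"):
            raise ValueError(f"unknown bond style {self.style!r}")
        if self.r0 <= 0:
            raise ValueError("r0 must be > 0")
        if self.style == "harmonic" and self.k is None:
            raise ValueError("harmonic bond needs k")
        if self.style == "morse" and (self.D is None or self.alpha is None):
            raise ValueError("morse bond needs D and alpha")


@dataclass(frozen=True)
class AngleTerm:
    """Harmonic angle U = ½k(θ−θ₀)², θ₀ in degrees, k in kJ/mol/rad²."""

    theta0: float
    k: float


@dataclass(frozen=True)
class LJSite:
    """Per-element Lennard-Jones parameters: ε in kJ/mol, σ in Å."""

    epsilon: float
    sigma: float

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")


@dataclass
class ForceFieldParams:
    """Per-species bonded terms plus per-element LJ and optional charges."""

    bond_terms: dict[str, BondTerm] = field(default_factory=dict)
    angle_terms: dict[str, AngleTerm] = field(default_factory=dict)
    lj: dict[str, LJSite] = field(default_factory=dict)
    charges: dict[str, tuple[float, ...]] = field(default_factory=dict)  # e per atom
    cutoff: float = 15.0  # Å
    lj_enabled: bool = True

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ValueError("cutoff must be > 0")


@dataclass
class ForceResult:
    """Forces (amu·Å/fs²), potential energy, total stress tensor and the
    scalar intermolecular pair virial (all internal units)."""

    forces: np.ndarray
    potential_energy: float
    stress_total: np.ndarray  # (3,3); trace(σ)·V is the total scalar virial
    pair_virial_inter: float  # Σ over intermolecular atom pairs of F·r (min. image)


def _angles_from_bonds(
    atom_indices: np.ndarray, bonds: Sequence[tuple[int, int]]
) -> list[tuple[int, int, int]]:
    """Enumerate (end, centre, end) triples from bond adjacency."""
    neighbours: dict[int, list[int]] = {int(a): [] for a in atom_indices}
    for i, j in bonds:
        neighbours[i].append(j)
        neighbours[j].append(i)
    triples = []
    for centre, nbs in neighbours.items():
        nbs = sorted(nbs)
        for a in range(len(nbs)):
            for b in range(a + 1, len(nbs)):
                triples.append((nbs[a], centre, nbs[b]))
    return triples


class ForceField:
    """Precompiled evaluator for a fixed topology (index arrays built once)."""

    def __init__(self, params: ForceFieldParams, molecules: Sequence[MoleculeTopology]):
        self.params = params
        self.molecules = list(molecules)

        hb_i, hb_j, hb_r0, hb_k = [], [], [], []
        mb_i, mb_j, mb_r0, mb_d, mb_a = [], [], [], [], []
        an_i, an_c, an_k_, an_t0, an_kth = [], [], [], [], []
        n_atoms = 1 + max(int(m.atom_indices.max()) for m in molecules)
        mol_of = np.full(n_atoms, -1, dtype=int)
        for mol in molecules:
            mol_of[mol.atom_indices] = mol.id
            bt = params.bond_terms.get(mol.species)
            if mol.bonds and bt is None:
                raise ValueError(f"no bond term for species {mol.species!r}")
            for i, j in mol.bonds:
                if bt.style == "harmonic":
                    hb_i.append(i); hb_j.append(j); hb_r0.append(bt.r0)
                    hb_k.append(bt.k * KJ_PER_MOL)
                else:
                    mb_i.append(i); mb_j.append(j); mb_r0.append(bt.r0)
                    mb_d.append(bt.D * KJ_PER_MOL); mb_a.append(bt.alpha)
            at = params.angle_terms.get(mol.species)
            if at is not None:
                for i, c, k in _angles_from_bonds(mol.atom_indices, mol.bonds):
                    an_i.append(i); an_c.append(c); an_k_.append(k)
                    an_t0.append(np.deg2rad(at.theta0))
                    an_kth.append(at.k * KJ_PER_MOL)

        self._hb = tuple(np.asarray(a) for a in (hb_i, hb_j, hb_r0, hb_k))
        self._mb = tuple(np.asarray(a) for a in (mb_i, mb_j, mb_r0, mb_d, mb_a))
        self._an = tuple(np.asarray(a) for a in (an_i, an_c, an_k_, an_t0, an_kth))
        self.mol_of = mol_of

        # intermolecular pair lists (i<j, distinct molecules)
        iu, ju = np.triu_indices(n_atoms, k=1)
        inter = mol_of[iu] != mol_of[ju]
        self._pi, self._pj = iu[inter], ju[inter]

        eps = np.zeros(n_atoms)
        sig = np.ones(n_atoms)
        q = np.zeros(n_atoms)
        for mol in molecules:
            if params.lj_enabled:
                for local, a in enumerate(mol.atom_indices):
                    site = _lj_site_for(params, mol, local)
                    eps[a], sig[a] = site.epsilon * KJ_PER_MOL, site.sigma
            if mol.species in params.charges:
                qs = params.charges[mol.species]
                for local, a in enumerate(mol.atom_indices):
                    q[a] = qs[local]
        self._eps = np.sqrt(eps[self._pi] * eps[self._pj])  # Lorentz–Berthelot
        self._sig = 0.5 * (sig[self._pi] + sig[self._pj])
        self._qq = q[self._pi] * q[self._pj] * COULOMB_KJMOL * KJ_PER_MOL
        self._has_charges = bool(np.any(self._qq != 0.0))
        rc = params.cutoff
        sr6c = (self._sig / rc) ** 6
        self._vshift = 4.0 * self._eps * (sr6c * sr6c - sr6c)
        self._qshift = self._qq / rc

    def evaluate(self, state: SystemState) -> ForceResult:
        """Forces, energy, total stress and intermolecular virial of a state."""
        L = state.box_edge
        rc = self.params.cutoff
        if rc >= 0.5 * L:
            raise ValueError(
                f"cutoff {rc} Å violates minimum-image validity for box {L} Å"
            )
        pos = state.positions
        n = state.n_atoms
        forces = np.zeros((n, 3))
        energy = 0.0
        stress_v = np.zeros((3, 3))  # Σ r⊗F (volume division at the end)
        w_inter = 0.0

        # --- intermolecular pairs (LJ + optional Coulomb), minimum image ---
        if len(self._pi):
            d = pos[self._pi] - pos[self._pj]
            d -= L * np.round(d / L)
            r2 = np.einsum("ij,ij->i", d, d)
            if np.min(r2) < _OVERLAP_R2:
                raise OverlapError("nonbonded atoms closer than 1e-6 Å")
            within = r2 < rc * rc
            if np.any(within):
                dw = d[within]
                r2w = r2[within]
                inv_r2 = 1.0 / r2w
                sr6 = (self._sig[within] ** 2 * inv_r2) ** 3
                epsw = self._eps[within]
                energy += float(
                    np.sum(4.0 * epsw * (sr6 * sr6 - sr6) - self._vshift[within])
                )
                fscal = 24.0 * epsw * (2.0 * sr6 * sr6 - sr6) * inv_r2
                if self._has_charges:
                    rw = np.sqrt(r2w)
                    qq = self._qq[within]
                    energy += float(np.sum(qq / rw - self._qshift[within]))
                    fscal = fscal + qq / (rw * r2w)
                fv = fscal[:, None] * dw
                iw, jw = self._pi[within], self._pj[within]
                for ax in range(3):
                    forces[:, ax] += np.bincount(iw, weights=fv[:, ax], minlength=n)
                    forces[:, ax] -= np.bincount(jw, weights=fv[:, ax], minlength=n)
                stress_v += dw.T @ fv
                w_inter += float(np.einsum("ij,ij->", dw, fv))

        # --- bonded terms on unwrapped in-molecule geometry ---
        e_b, s_b = _accumulate_bonded(
            pos, forces, self._hb, self._mb, self._an
        )
        energy += e_b
        stress_v += s_b

        return ForceResult(
            forces=forces,
            potential_energy=energy,
            stress_total=stress_v / state.volume,
            pair_virial_inter=w_inter,
        )


def _lj_site_for(params: ForceFieldParams, mol: MoleculeTopology, local: int) -> LJSite:
    # species-qualified key ("CO2:O") takes precedence over the plain element
    el = mol.elements[local] if mol.elements else "?"
    return params.lj.get(f"{mol.species}:{el}", params.lj.get(el, LJSite(0.0, 1.0)))


def _accumulate_bonded(pos, forces, hb, mb, an):
    """Add bond and angle forces in place; return (energy, Σ r⊗F)."""
    energy = 0.0
    stress_v = np.zeros((3, 3))

    hb_i, hb_j, hb_r0, hb_k = hb
    if len(hb_i):
        d = pos[hb_i] - pos[hb_j]
        r = np.linalg.norm(d, axis=1)
        x = r - hb_r0
        energy += float(np.sum(0.5 * hb_k * x * x))
        fscal = -(hb_k * x) / r
        fv = fscal[:, None] * d
        np.add.at(forces, hb_i, fv)
        np.subtract.at(forces, hb_j, fv)
        stress_v += d.T @ fv

    mb_i, mb_j, mb_r0, mb_d, mb_a = mb
    if len(mb_i):
        d = pos[mb_i] - pos[mb_j]
        r = np.linalg.norm(d, axis=1)
        y = np.exp(-mb_a * (r - mb_r0))
        energy += float(np.sum(mb_d * (1.0 - y) ** 2))
        fscal = -(2.0 * mb_d * mb_a * y * (1.0 - y)) / r
        fv = fscal[:, None] * d
        np.add.at(forces, mb_i, fv)
        np.subtract.at(forces, mb_j, fv)
        stress_v += d.T @ fv

    an_i, an_c, an_k, an_t0, an_kth = an
    if len(an_i):
        u = pos[an_i] - pos[an_c]
        v = pos[an_k] - pos[an_c]
        nu = np.linalg.norm(u, axis=1)
        nv = np.linalg.norm(v, axis=1)
        uh = u / nu[:, None]
        vh = v / nv[:, None]
        cos_t = np.clip(np.einsum("ij,ij->i", uh, vh), -1.0, 1.0)
        theta = np.arccos(cos_t)
        dtheta = theta - an_t0
        energy += float(np.sum(0.5 * an_kth * dtheta * dtheta))
        # F = −k(θ−θ₀)∇θ; sinθ clamped — near θ=π the prefactor (θ−θ₀)
        # vanishes as fast as sinθ, so the clamp only avoids 0/0
        sin_t = np.maximum(np.sqrt(1.0 - cos_t * cos_t), 1e-8)
        coef = -(an_kth * dtheta) / sin_t
        fi = coef[:, None] * (cos_t[:, None] * uh - vh) / nu[:, None]
        fk = coef[:, None] * (cos_t[:, None] * vh - uh) / nv[:, None]
        np.add.at(forces, an_i, fi)
        np.add.at(forces, an_k, fk)
        np.subtract.at(forces, an_c, fi + fk)
        stress_v += u.T @ fi + v.T @ fk  # COM-invariant: Σ F per angle is zero

    return energy, stress_v


def evaluate(
    state: SystemState,
    molecules: Sequence[MoleculeTopology],
    params: ForceFieldParams,
) -> ForceResult:
    """One-shot evaluation (see :class:`ForceField` for the compiled form)."""
    return ForceField(params, molecules).evaluate(state)


def evaluate_single_molecule(
    positions: np.ndarray,
    bonds: Sequence[tuple[int, int]],
    species: str,
    params: ForceFieldParams,
    box_edge: float,
    angle_triples: Sequence[tuple[int, int, int]] | None = None,
) -> np.ndarray:
    """Intramolecular stress tensor of one isolated molecule in a cubic cell.

    ``positions`` holds only this molecule's atoms (local 0-based indices in
    ``bonds``).  Only bonded terms act, so the scalar virial trace(σ)·V is
    volume-independent; the box size merely sets the stress normalisation.
    """
    positions = np.asarray(positions, dtype=float)
    bt = params.bond_terms.get(species)
    if bonds and bt is None:
        raise ValueError(f"no bond term for species {species!r}")
    hb = [[], [], [], []]
    mb = [[], [], [], [], []]
    for i, j in bonds:
        if bt.style == "harmonic":
            hb[0].append(i); hb[1].append(j); hb[2].append(bt.r0)
            hb[3].append(bt.k * KJ_PER_MOL)
        else:
            mb[0].append(i); mb[1].append(j); mb[2].append(bt.r0)
            mb[3].append(bt.D * KJ_PER_MOL); mb[4].append(bt.alpha)
    an = [[], [], [], [], []]
    at = params.angle_terms.get(species)
    if at is not None:
        if angle_triples is None:
            angle_triples = _angles_from_bonds(np.arange(len(positions)), bonds)
        for i, c, k in angle_triples:
            an[0].append(i); an[1].append(c); an[2].append(k)
            an[3].append(np.deg2rad(at.theta0)); an[4].append(at.k * KJ_PER_MOL)
    forces = np.zeros_like(positions)
    _, stress_v = _accumulate_bonded(
        positions, forces,
        tuple(np.asarray(a) for a in hb),
        tuple(np.asarray(a) for a in mb),
        tuple(np.asarray(a) for a in an),
    )
    return stress_v / float(box_edge) ** 3
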
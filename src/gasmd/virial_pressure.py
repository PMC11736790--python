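"""Molecule-based virial pressure with intramolecular correction.

For a cubic cell the instantaneous pressure on a molecular basis is

    p = (2·E_kin,mol · (3N_mol / F_trans) + W_inter) / (3V)

with E_kin,mol the centre-of-mass kinetic energy, F_trans = 3N_mol − 3 the
translational DOF count (the rescaling makes the kinetic part read
N_mol·k_B·T_trans, the conventional ideal term in a momentum-conserving
ensemble), and W_inter the intermolecular scalar virial.

W_inter can be obtained three equivalent ways:

``explicit``      trace of the total stress tensor minus one isolated
                  single-point stress per molecule (the subtraction route);
``pair_direct``   direct accumulation over intermolecular atom pairs during
                  the force evaluation;
``table``         subtraction with the per-molecule intramolecular virial read
                  from an internal-coordinate interpolation table instead of
                  an explicit single point.

Both subtraction variants and the pair route use the atom-pair minimum-image
convention and agree to round-off; the table route agrees to spline-resolution
accuracy.  The table stores the scalar intramolecular virial W (which is
volume-independent for an isolated molecule), so the pressure correction
W/(3V) scales exactly as 1/V for any cell size.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from .constants import PRESSURE_TO_BAR
from .forcefield import ForceFieldParams, _angles_from_bonds, evaluate_single_molecule
from .topology import MoleculeTopology, SystemState

PRESSURE_METHODS = ("explicit", "pair_direct", "table")


class TableBoundsError(ValueError):
    """Internal coordinates outside the tabulated grid; extrapolation is
    refused — rebuild the table with wider margins instead."""


@dataclass
class PressureRecord:
    """One pressure evaluation split into its ideal and virial parts (bar)."""

    p_total: float
    p_ideal_part: float
    p_virial_part: float
    W_intra_applied: float  # internal energy units
    method: str


def pressure_from_components(
    e_kin_mol: float,
    w_inter: float,
    volume: float,
    n_mol: int | None = None,
    kinetic_dof: int | None = None,
) -> float:
    """Instantaneous pressure in bar from COM kinetic energy and virial.

    When ``n_mol`` and ``kinetic_dof`` are given, the kinetic part is scaled
    by 3·n_mol/kinetic_dof so that it equals N_mol·k_B·T_trans with T_trans
    measured on the momentum-free DOF count (see module docstring); otherwise
    the bare 2E/(3V) is used.
    """
    if not volume > 0:
        raise ValueError("volume must be > 0")
    scale = 1.0
    if n_mol is not None and kinetic_dof is not None and kinetic_dof > 0:
        scale = 3.0 * n_mol / kinetic_dof
    return (2.0 * e_kin_mol * scale + w_inter) / (3.0 * volume) * PRESSURE_TO_BAR


def pressure_record(
    e_kin_mol: float,
    w_inter: float,
    volume: float,
    w_intra: float = 0.0,
    method: str = "pair_direct",
    n_mol: int | None = None,
    kinetic_dof: int | None = None,
) -> PressureRecord:
    p_ideal = pressure_from_components(e_kin_mol, 0.0, volume, n_mol, kinetic_dof)
    p_virial = w_inter / (3.0 * volume) * PRESSURE_TO_BAR
    return PressureRecord(
        p_total=p_ideal + p_virial,
        p_ideal_part=p_ideal,
        p_virial_part=p_virial,
        W_intra_applied=w_intra,
        method=method,
    )


def intermolecular_stress_subtraction(
    stress_total: np.ndarray, molecule_stresses: Sequence[np.ndarray]
) -> np.ndarray:
    """σ_inter = σ_total − Σ σ_intra,i (all on the same volume convention)."""
    out = np.array(stress_total, dtype=float, copy=True)
    for s in molecule_stresses:
        out -= s
    return out


def intramolecular_virial(
    state: SystemState, molecule: MoleculeTopology, params: ForceFieldParams
) -> float:
    """Scalar intramolecular virial W of one molecule by an isolated
    single-point evaluation (volume-independent)."""
    idx = molecule.atom_indices
    local = {int(a): n for n, a in enumerate(idx)}
    bonds = [(local[i], local[j]) for i, j in molecule.bonds]
    sigma = evaluate_single_molecule(
        state.positions[idx], bonds, molecule.species, params, state.box_edge
    )
    return float(np.trace(sigma)) * state.volume


# ---------------------------------------------------------------------------
# internal coordinates
# ---------------------------------------------------------------------------

#: registry: species -> ordered internal-coordinate spec, entries
#: ("bond", i, j) or ("angle", i, j, k) with j the vertex, local indices
COORD_SPECS: dict[str, list[tuple]] = {
    "CO2": [("bond", 0, 1), ("bond", 0, 2), ("angle", 1, 0, 2)],
}


def internal_coordinates(
    molecule: MoleculeTopology, state: SystemState
) -> np.ndarray:
    """Bond lengths (Å) and angles (deg) in the registered coordinate order."""
    try:
        spec = COORD_SPECS[molecule.species]
    except KeyError:
        raise ValueError(
            f"no internal-coordinate spec registered for {molecule.species!r}"
        ) from None
    idx = molecule.atom_indices
    pos = state.positions[idx]
    out = []
    for entry in spec:
        if entry[0] == "bond":
            _, i, j = entry
            out.append(float(np.linalg.norm(pos[i] - pos[j])))
        else:
            _, i, j, k = entry
            u, v = pos[i] - pos[j], pos[k] - pos[j]
            nu, nv = np.linalg.norm(u), np.linalg.norm(v)
            if nu < 1e-10 or nv < 1e-10:
                raise ValueError("degenerate geometry: angle arm of zero length")
            out.append(
                float(np.degrees(np.arccos(np.clip(u @ v / (nu * nv), -1.0, 1.0))))
            )
    return np.array(out)


def embed_internal_coordinates(species: str, coords: Sequence[float]) -> np.ndarray:
    """Cartesian geometry from internal coordinates (Z-matrix convention):
    vertex at the origin, first arm along +x, second arm in the xy-plane.

    Only triatomic (r₁, r₂, α) specs are supported; the molecule's orientation
    is irrelevant to its intramolecular virial.
    """
    spec = COORD_SPECS.get(species)
    if spec is None or len(spec) != 3 or [e[0] for e in spec] != ["bond", "bond", "angle"]:
        raise ValueError(f"no triatomic embedding available for {species!r}")
    r1, r2, alpha = coords
    if r1 <= 0 or r2 <= 0:
        raise ValueError("bond lengths must be > 0")
    if not 0.0 < alpha <= 180.0:
        raise ValueError("angle must be in (0, 180] degrees")
    a = np.radians(alpha)
    vertex = spec[2][2]
    arm1, arm2 = spec[2][1], spec[2][3]
    n_atoms = 1 + max(max(e[1:]) for e in spec)
    pos = np.zeros((n_atoms, 3))
    pos[vertex] = 0.0
    pos[arm1] = [r1, 0.0, 0.0]
    pos[arm2] = [r2 * np.cos(a), r2 * np.sin(a), 0.0]
    return pos


# ---------------------------------------------------------------------------
# interpolation table
# ---------------------------------------------------------------------------


@dataclass
class VirialTable:
    """Internal-coordinate grid of intramolecular scalar virials W with a
    tensor-product cubic-spline evaluator.

    W is volume-independent, so one table serves every cell size: the pressure
    correction of a molecule in a cell of volume V is W/(3V).
    """

    species: str
    coord_names: tuple[str, ...]
    axes: tuple[np.ndarray, ...]  # strictly increasing, uniform
    values: np.ndarray  # internal energy units
    reference_volume: float  # Å³ of the build cell
    _spline: RegularGridInterpolator = field(repr=False, default=None)

    def __post_init__(self) -> None:
        for ax in self.axes:
            d = np.diff(ax)
            if not (d > 0).all():
                raise ValueError("table axes must be strictly increasing")
            if not np.allclose(d, d[0], rtol=1e-8):
                raise ValueError("table axes must be uniform")
        if self._spline is None:
            self._spline = RegularGridInterpolator(
                self.axes, self.values, method="cubic", bounds_error=True
            )

    def w_intra(self, coords: Sequence[float]) -> float:
        """Spline-interpolated scalar virial at the given internal coords."""
        try:
            return float(self._spline(np.asarray(coords, dtype=float))[0])
        except ValueError as exc:
            raise TableBoundsError(
                f"coords {np.asarray(coords)} outside table bounds "
                f"{[(a[0], a[-1]) for a in self.axes]}"
            ) from exc


def default_axes_co2() -> dict[str, np.ndarray]:
    """Standard CO₂ table axes: 0.1 Å bond / 1° angle spacing covering the
    internal-coordinate ranges the shipped surrogate samples at ~300 K with a
    margin (bonds 1.05–1.35 Å, angle 160–180°)."""
    return {
        "r1": np.round(np.arange(1.05, 1.3501, 0.1), 6),
        "r2": np.round(np.arange(1.05, 1.3501, 0.1), 6),
        "angle": np.round(np.arange(160.0, 180.001, 1.0), 6),
    }


def axes_from_ranges(
    ranges: Sequence[tuple[float, float]],
    spacings: Sequence[float],
    margin: float = 0.1,
    upper_caps: Sequence[float | None] | None = None,
) -> list[np.ndarray]:
    """Uniform grids covering each observed range extended by ``margin``
    (fraction of the span) on both sides, snapped outward to the spacing."""
    axes = []
    caps = upper_caps or [None] * len(ranges)
    for (lo, hi), h, cap in zip(ranges, spacings, caps):
        pad = margin * (hi - lo)
        lo, hi = lo - pad, hi + pad
        if cap is not None:
            hi = min(hi, cap)
        n_lo = np.floor(lo / h)
        n_hi = np.ceil(hi / h)
        if n_hi - n_lo < 3:  # cubic spline needs at least 4 nodes
            n_lo -= np.ceil((3 - (n_hi - n_lo)) / 2)
            n_hi = n_lo + 3
            if cap is not None and n_hi * h > cap:
                shift = n_hi - np.floor(cap / h)
                n_lo, n_hi = n_lo - shift, n_hi - shift
        axes.append(np.arange(n_lo, n_hi + 0.5) * h)
    return axes


def build_table(
    species: str,
    params: ForceFieldParams,
    axes_spec: dict[str, np.ndarray] | None = None,
    box_edge: float = 100.0,
    symmetrize: bool = True,
) -> VirialTable:
    """Tabulate the intramolecular scalar virial on an internal-coordinate
    grid by one isolated single-point evaluation per node.

    For CO₂ the r₁↔r₂ exchange symmetry of the surface is enforced by
    symmetrising node values (a no-op up to round-off when both bonds carry
    identical terms).
    """
    if axes_spec is None:
        if species != "CO2":
            raise ValueError(f"no default axes for species {species!r}")
        axes_spec = default_axes_co2()
    names = tuple(axes_spec)
    axes = tuple(np.asarray(axes_spec[n], dtype=float) for n in names)
    from .presets import TEMPLATES

    tpl = TEMPLATES[species]
    angle_triples = _angles_from_bonds(
        np.arange(len(tpl.elements)), list(tpl.bonds)
    )
    volume = float(box_edge) ** 3
    shape = tuple(len(a) for a in axes)
    values = np.empty(shape)
    for flat, idx in enumerate(np.ndindex(shape)):
        coords = [axes[d][i] for d, i in enumerate(idx)]
        pos = embed_internal_coordinates(species, coords)
        sigma = evaluate_single_molecule(
            pos, list(tpl.bonds), species, params, box_edge,
            angle_triples=angle_triples,
        )
        values[idx] = np.trace(sigma) * volume
    if symmetrize and species == "CO2":
        values = 0.5 * (values + values.swapaxes(0, 1))
    return VirialTable(
        species=species,
        coord_names=names,
        axes=axes,
        values=values,
        reference_volume=volume,
    )


def query_table(
    table: VirialTable, internal_coords: Sequence[float], volume: float
) -> tuple[float, float]:
    """(W_intra, pressure correction in bar) at the given coordinates.

    The correction is W/(3V) — exactly proportional to 1/V because W is
    volume-independent.  Out-of-bounds coordinates raise
    :class:`TableBoundsError`; there is no silent extrapolation.
    """
    w = table.w_intra(internal_coords)
    return w, w / (3.0 * volume) * PRESSURE_TO_BAR


def cell_center_benchmark(
    table: VirialTable, params: ForceFieldParams
) -> dict[str, np.ndarray]:
    """Worst-case table check: compare spline and explicit single-point
    pressure corrections at the centre of every grid cell, at the table's
    reference volume.  Returns per-centre corrections and deviations (bar)."""
    from .presets import TEMPLATES

    species = table.species
    tpl = TEMPLATES[species]
    angle_triples = _angles_from_bonds(np.arange(len(tpl.elements)), list(tpl.bonds))
    centers = [0.5 * (a[:-1] + a[1:]) for a in table.axes]
    box_edge = table.reference_volume ** (1.0 / 3.0)
    shape = tuple(len(c) for c in centers)
    p_table = np.empty(shape)
    p_explicit = np.empty(shape)
    for idx in np.ndindex(shape):
        coords = [centers[d][i] for d, i in enumerate(idx)]
        _, p_table[idx] = query_table(table, coords, table.reference_volume)
        pos = embed_internal_coordinates(species, coords)
        sigma = evaluate_single_molecule(
            pos, list(tpl.bonds), species, params, box_edge,
            angle_triples=angle_triples,
        )
        w = np.trace(sigma) * table.reference_volume
        p_explicit[idx] = w / (3.0 * table.reference_volume) * PRESSURE_TO_BAR
    dev = p_table - p_explicit
    return {
        "p_table": p_table,
        "p_explicit": p_explicit,
        "deviation": dev,
        "max_abs_deviation": np.abs(dev).max(),
    }


def inverse_volume_scan(
    species: str,
    params: ForceFieldParams,
    coords: Sequence[float],
    box_edges: Sequence[float],
) -> dict[str, np.ndarray | float]:
    """Pressure correction of one fixed molecular configuration across cubic
    cells, with a linear fit of |correction| against 1/V.

    Because the isolated-molecule virial is volume-independent the fit is
    exact: R² = 1 to round-off.
    """
    from .presets import TEMPLATES

    tpl = TEMPLATES[species]
    pos = embed_internal_coordinates(species, coords)
    corrections = []
    inv_v = []
    for L in box_edges:
        sigma = evaluate_single_molecule(pos, list(tpl.bonds), species, params, L)
        w = float(np.trace(sigma)) * L**3
        corrections.append(abs(w) / (3.0 * L**3) * PRESSURE_TO_BAR)
        inv_v.append(1.0 / L**3)
    x = np.asarray(inv_v)
    y = np.asarray(corrections)
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    return {
        "inverse_volume": x,
        "correction_bar": y,
        "slope": float(slope),
        "intercept": float(intercept),
        "r_squared": r2,
    }


def save_table(table: VirialTable, path) -> None:
    """Write a table to a self-describing .npz container."""
    np.savez(
        path,
        species=table.species,
        coord_names=np.array(table.coord_names),
        values=table.values,
        reference_volume=table.reference_volume,
        **{f"axis_{i}": a for i, a in enumerate(table.axes)},
    )


def load_table(path) -> VirialTable:
    with np.load(path, allow_pickle=False) as npz:
        names = tuple(str(n) for n in npz["coord_names"])
        axes = tuple(npz[f"axis_{i}"] for i in range(len(names)))
        return VirialTable(
            species=str(npz["species"]),
            coord_names=names,
            axes=axes,
            values=npz["values"],
            reference_volume=float(npz["reference_volume"]),
        )
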
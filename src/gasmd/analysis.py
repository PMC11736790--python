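"""Post-processing: radial distribution functions, van der Waals reference
isotherms and pV-state-point scans.

The pV scan reproduces the standard protocol for gas isotherms: for each
target pressure the cubic box is sized by the ideal-gas law at fixed molecule
count, an NVT run with the equipartitioning thermostat samples the
molecular-virial pressure, and each run maps to one state point that can be
compared against the ideal-gas and van der Waals reference curves.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .constants import ANG3_TO_L_PER_MOL, KB, R_L_BAR, PRESSURE_TO_BAR
from .topology import MoleculeTopology


@dataclass
class RDFResult:
    """g(r) histogram on minimum-image pair distances."""

    bin_centers: np.ndarray  # Å
    g: np.ndarray
    pair_spec: tuple[str, str]
    r_max: float
    bin_width: float
    n_pairs_observed: float  # average pair count per frame within r_max


@dataclass(frozen=True)
class VdwParams:
    """Van der Waals constants: a in L²·bar·mol⁻², b in L·mol⁻¹."""

    a: float
    b: float

    def __post_init__(self) -> None:
        if self.a < 0 or self.b < 0:
            raise ValueError("van der Waals constants must be >= 0")


#: tabulated constants for the gases treated here
VDW_CONSTANTS = {
    "CO2": VdwParams(a=3.640, b=0.04267),
    "CH4": VdwParams(a=2.253, b=0.04278),
}


@dataclass
class StatePoint:
    """One sampled point of a pV diagram."""

    target_p: float  # bar, from ideal-gas box sizing
    box_edge: float  # Å
    mean_p: float  # bar
    std_p: float  # bar
    T: float  # K
    N_mol: int


def select_atoms(
    molecules: Sequence[MoleculeTopology], species: str, element: str
) -> np.ndarray:
    """Global indices of all atoms with a given element role in a species,
    e.g. the C of every CO₂."""
    out = []
    for mol in molecules:
        if mol.species != species:
            continue
        for local, a in enumerate(mol.atom_indices):
            if mol.elements and mol.elements[local] == element:
                out.append(int(a))
    return np.array(out, dtype=int)


def rdf(
    frames: Sequence[np.ndarray] | np.ndarray,
    box_edge: float,
    sel_a: np.ndarray,
    sel_b: np.ndarray | None = None,
    bin_width: float = 0.05,
    r_max: float | None = None,
    pair_spec: tuple[str, str] = ("a", "b"),
    exclude_pairs: Sequence[tuple[int, int]] | None = None,
) -> RDFResult:
    """Radial distribution function over a trajectory.

    ``frames`` is an (F, N, 3) array or list of (N, 3) position frames that
    share one cubic box.  With ``sel_b`` omitted the RDF is computed within
    ``sel_a``.  Normalisation divides the observed pair histogram by the
    ideal-gas shell expectation, so g → 1 for an uncorrelated homogeneous gas.
    """
    frames = np.asarray(frames, dtype=float)
    if frames.ndim == 2:
        frames = frames[None]
    if r_max is None:
        r_max = 0.5 * box_edge
    if r_max > 0.5 * box_edge + 1e-9:
        raise ValueError("r_max must not exceed half the box edge")
    same_set = sel_b is None
    sel_b = sel_a if same_set else sel_b

    n_bins = int(round(r_max / bin_width))
    edges = np.linspace(0.0, n_bins * bin_width, n_bins + 1)
    hist = np.zeros(n_bins)

    mask = None
    if same_set:
        ia, ib = np.triu_indices(len(sel_a), k=1)
    else:
        ia, ib = np.meshgrid(
            np.arange(len(sel_a)), np.arange(len(sel_b)), indexing="ij"
        )
        ia, ib = ia.ravel(), ib.ravel()
        keep = sel_a[ia] != sel_b[ib]
        ia, ib = ia[keep], ib[keep]
    if exclude_pairs:
        excl = {tuple(sorted(p)) for p in exclude_pairs}
        keep = np.array(
            [
                tuple(sorted((int(sel_a[i]), int(sel_b[j])))) not in excl
                for i, j in zip(ia, ib)
            ]
        )
        ia, ib = ia[keep], ib[keep]

    n_pairs = len(ia)
    total_within = 0.0
    for pos in frames:
        d = pos[sel_a][ia] - pos[sel_b][ib]
        d -= box_edge * np.round(d / box_edge)
        r = np.sqrt(np.einsum("ij,ij->i", d, d))
        h, _ = np.histogram(r, bins=edges)
        hist += h
        total_within += h.sum()

    volume = box_edge**3
    shell = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    # double counting cancels: unordered pairs vs shell probability per pair
    ideal = n_pairs * shell / volume
    g = hist / (len(frames) * ideal)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return RDFResult(
        bin_centers=centers,
        g=g,
        pair_spec=pair_spec,
        r_max=r_max,
        bin_width=bin_width,
        n_pairs_observed=total_within / len(frames),
    )


def vdw_pressure(T: float, v: float, params: VdwParams) -> float:
    """Van der Waals pressure p = RT/(v−b) − a/v² in bar; v in L/mol."""
    if v <= params.b:
        raise ValueError(f"molar volume {v} L/mol must exceed b={params.b}")
    return R_L_BAR * T / (v - params.b) - params.a / (v * v)


def ideal_pressure(T: float, v: float) -> float:
    """Ideal-gas pressure RT/v in bar; v in L/mol."""
    return R_L_BAR * T / v


def isotherm_pressures() -> np.ndarray:
    """The standard 19-point target-pressure grid: 0.1–1.0 bar in steps of
    0.1 and 2.0–10.0 bar in steps of 1.0."""
    return np.round(
        np.concatenate([np.arange(0.1, 1.05, 0.1), np.arange(2.0, 10.5, 1.0)]), 10
    )


def box_edge_for_pressure(n_mol: int, T: float, p_bar: float) -> float:
    """Cubic box edge (Å) from the ideal-gas law at fixed molecule count."""
    volume = n_mol * KB * T / (p_bar / PRESSURE_TO_BAR)
    return volume ** (1.0 / 3.0)


def isotherm_scan(
    species: str,
    T: float,
    pressures: Sequence[float] | None = None,
    n_mol: int = 50,
    preset: str | None = None,
    dt: float | None = None,
    equilibration_steps: int = 2000,
    n_steps: int = 5000,
    sample_stride: int = 10,
    seed: int = 0,
    lj_enabled: bool = True,
) -> pd.DataFrame:
    """Run one NVT simulation per target pressure and assemble the pV table.

    Returns a DataFrame with one row per (state point × method) where method
    is ``simulated``, ``ideal`` or ``vdw``; the reference rows evaluate the
    ideal-gas and van der Waals equations at the same molar volumes.
    """
    from .engine import RunConfig, initialize_velocities, run
    from .presets import build_gas_system, forcefield_params
    from .thermostat import ThermostatSpec

    if pressures is None:
        pressures = isotherm_pressures()
    if preset is None:
        preset = {"CO2": "co2_flex", "CH4": "ch4_flex", "Ar": "argon"}[species]
    if dt is None:
        dt = 0.5 if species == "CH4" else 2.0
    params = forcefield_params(preset)
    if not lj_enabled:
        params.lj_enabled = False
    vdw = VDW_CONSTANTS.get(species)

    rows = []
    for k, p_target in enumerate(pressures):
        box = box_edge_for_pressure(n_mol, T, float(p_target))
        params_k = params
        if params.cutoff >= 0.45 * box:  # keep minimum image valid in small cells
            from dataclasses import replace

            params_k = replace(params, cutoff=0.45 * box)
        state, molecules = build_gas_system(species, n_mol, box, seed=seed + k)
        state = initialize_velocities(state, molecules, T, seed=seed + 1000 + k)
        config = RunConfig(
            dt=dt,
            n_steps=n_steps,
            equilibration_steps=equilibration_steps,
            sample_stride=sample_stride,
            thermostat=ThermostatSpec(
                mode="equipartition", target_T=T, seed=seed + 2000 + k
            ),
            pressure_method="pair_direct",
        )
        _, _, summary = run(state, molecules, params_k, config)
        v_molar = box**3 / n_mol * ANG3_TO_L_PER_MOL
        rows.append(
            {
                "target_p": float(p_target),
                "box_edge": box,
                "v_molar": v_molar,
                "T": T,
                "N_mol": n_mol,
                "p": summary["mean_p"],
                "std_p": summary["std_p"],
                "method": "simulated",
            }
        )
        rows.append(
            {
                "target_p": float(p_target),
                "box_edge": box,
                "v_molar": v_molar,
                "T": T,
                "N_mol": n_mol,
                "p": ideal_pressure(T, v_molar),
                "std_p": 0.0,
                "method": "ideal",
            }
        )
        if vdw is not None:
            rows.append(
                {
                    "target_p": float(p_target),
                    "box_edge": box,
                    "v_molar": v_molar,
                    "T": T,
                    "N_mol": n_mol,
                    "p": vdw_pressure(T, v_molar, vdw),
                    "std_p": 0.0,
                    "method": "vdw",
                }
            )
    return pd.DataFrame(rows)
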
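"""Velocity-Verlet propagation with equipartitioned initialisation.

NVT runs apply the configured thermostat once per step, after the second
velocity half-kick.  Positions are kept unwrapped throughout (molecules stay
whole across the periodic boundary; all interactions are minimum-image), so
no re-wrapping is ever applied to the propagated coordinates.

Velocity initialisation draws Maxwell–Boltzmann velocities at the target
temperature, removes the total linear momentum, then applies one
deterministic rescale per kinetic-energy component so the translational,
rotational and vibrational temperatures each start exactly at their targets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .constants import KB
from .forcefield import ForceField, ForceFieldParams, ForceResult
from .thermostat import (
    DegenerateComponentError,
    ScalingFactors,
    ThermostatSpec,
    apply_equipartition,
    apply_global_csvr,
    make_rngs,
)
from .topology import DofCounts, MoleculeTopology, SystemState, system_dof
from .veldecomp import Decomposer, kinetic_report
from .virial_pressure import (
    VirialTable,
    internal_coordinates,
    intramolecular_virial,
    pressure_from_components,
    query_table,
)


@dataclass
class RunConfig:
    """Propagation settings; ``n_steps`` counts the sampling phase only."""

    ensemble: str = "NVT"  # NVT | NVE
    dt: float = 2.0  # fs
    n_steps: int = 1000
    equilibration_steps: int = 0
    sample_stride: int = 10
    thermostat: ThermostatSpec = field(default_factory=ThermostatSpec)
    pressure_method: str = "explicit"  # explicit | pair_direct | table
    table: VirialTable | None = None
    n_blocks: int = 10  # block averaging of sampled observables

    def __post_init__(self) -> None:
        if self.ensemble not in ("NVT", "NVE"):
            raise ValueError("ensemble must be NVT or NVE")
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.sample_stride < 1:
            raise ValueError("sample_stride must be >= 1")
        if self.pressure_method not in ("explicit", "pair_direct", "table"):
            raise ValueError(f"unknown pressure method {self.pressure_method!r}")
        if self.pressure_method == "table" and self.table is None:
            raise ValueError("pressure_method='table' requires a VirialTable")


class BlockStats(NamedTuple):
    """Mean, standard deviation of block means, and the standard error."""

    mean: float
    std: float
    sem: float


def block_average(values: Sequence[float], n_blocks: int = 10) -> BlockStats:
    """Block averaging: split the series into ``n_blocks`` contiguous blocks
    and use the spread of block means as the uncertainty estimate."""
    x = np.asarray(values, dtype=float)
    if len(x) < n_blocks:
        return BlockStats(float(x.mean()), float("nan"), float("nan"))
    blocks = np.array_split(x, n_blocks)
    means = np.array([b.mean() for b in blocks])
    std = float(means.std(ddof=1))
    return BlockStats(float(x.mean()), std, std / np.sqrt(n_blocks))


def initialize_velocities(
    state: SystemState,
    molecules: Sequence[MoleculeTopology],
    T: float,
    seed: int = 0,
    dof: DofCounts | None = None,
    component_temperatures: tuple[float, float, float] | None = None,
) -> SystemState:
    """Maxwell–Boltzmann velocities with zero total momentum and exact
    per-component temperatures.

    ``component_temperatures`` overrides the (T, T, T) default — e.g.
    ``(T_tot/T_trans-scaled, 0, 0)`` prepares a deliberately
    de-equipartitioned state with all kinetic energy in translation.
    """
    if dof is None:
        dof = system_dof(molecules)
    targets = component_temperatures or (T, T, T)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    m = state.masses
    if T <= 0 and not any(targets):
        return state.with_velocities(np.zeros_like(state.velocities))
    sigma = np.sqrt(KB * max(T, max(targets)) / m)
    v = rng.standard_normal(state.velocities.shape) * sigma[:, None]
    v -= (m @ v) / m.sum()  # remove COM drift

    decomposer = Decomposer(molecules)
    trial = state.with_velocities(v)
    comp = decomposer.decompose(trial)
    report = kinetic_report(comp, trial, molecules, dof)
    factors = []
    for target, current, f in (
        (targets[0], report.T_trans, dof.trans),
        (targets[1], report.T_rot, dof.rot),
        (targets[2], report.T_vib, dof.vib),
    ):
        if f == 0 or current <= 0:
            factors.append(0.0 if f == 0 else 1.0)
        else:
            factors.append(np.sqrt(target / current))
    v_new = (
        factors[0] * comp.v_trans + factors[1] * comp.v_rot + factors[2] * comp.v_vib
    )
    return state.with_velocities(v_new)


def deequipartitioned_velocities(
    state: SystemState,
    molecules: Sequence[MoleculeTopology],
    T: float,
    seed: int = 0,
) -> SystemState:
    """All kinetic energy in translation: the total kinetic energy matches a
    fully equipartitioned system at T, but rotation and vibration start cold."""
    dof = system_dof(molecules)
    t_trans = T * dof.total / dof.trans
    return initialize_velocities(
        state, molecules, T, seed, dof, component_temperatures=(t_trans, 0.0, 0.0)
    )


class Simulation:
    """One propagated system: state, compiled force field, thermostat streams."""

    def __init__(
        self,
        state: SystemState,
        molecules: Sequence[MoleculeTopology],
        params: ForceFieldParams,
        config: RunConfig,
    ):
        self.molecules = list(molecules)
        self.config = config
        self.dof = system_dof(molecules)
        self.forcefield = ForceField(params, molecules)
        self.params = params
        self.decomposer = Decomposer(molecules)
        self.rngs = make_rngs(config.thermostat.seed)
        self.state = state.copy()
        self.result: ForceResult = self.forcefield.evaluate(self.state)
        self.last_factors = ScalingFactors()

    # ------------------------------------------------------------------
    def step(self) -> None:
        """One velocity-Verlet step, thermostat applied post-integration."""
        cfg = self.config
        dt = cfg.dt
        s = self.state
        inv_m = 1.0 / s.masses[:, None]
        v_half = s.velocities + 0.5 * dt * self.result.forces * inv_m
        new_pos = s.positions + dt * v_half
        trial = SystemState(new_pos, v_half, s.masses, s.box_edge, s.time + dt)
        self.result = self.forcefield.evaluate(trial)
        trial.velocities = v_half + 0.5 * dt * self.result.forces * inv_m

        if cfg.ensemble == "NVT":
            mode = cfg.thermostat.mode
            if mode == "equipartition":
                try:
                    trial, self.last_factors = apply_equipartition(
                        trial, self.molecules, cfg.thermostat, self.dof, dt,
                        self.rngs, decomposer=self.decomposer,
                    )
                except DegenerateComponentError:
                    # cold component: re-draw thermal velocities instead of scaling
                    reseed = int(self.rngs["global"].integers(2**31))
                    trial = initialize_velocities(
                        trial, self.molecules, cfg.thermostat.target_T, reseed,
                        self.dof,
                    )
            elif mode == "global_csvr":
                trial, self.last_factors = apply_global_csvr(
                    trial, cfg.thermostat, self.dof, dt, self.rngs["global"]
                )
        self.state = trial

    # ------------------------------------------------------------------
    def sample(self) -> dict[str, float]:
        """Observables of the current state (Fig-style frame log columns)."""
        s = self.state
        if not np.isfinite(s.positions).all() or not np.isfinite(s.velocities).all():
            raise RuntimeError(
                f"non-finite coordinates/velocities at t={s.time} fs; "
                f"max|x|={np.nanmax(np.abs(s.positions)):.3g}"
            )
        comp = self.decomposer.decompose(s)
        report = kinetic_report(comp, s, self.molecules, self.dof)
        w_inter, w_intra = self._intermolecular_virial()
        p = pressure_from_components(
            report.E_kin_mol, w_inter, s.volume,
            n_mol=len(self.molecules), kinetic_dof=self.dof.trans,
        )
        return {
            "time": s.time,
            "E_pot": self.result.potential_energy,
            "E_kin": report.E_total,
            "E_total": self.result.potential_energy + report.E_total,
            "T_trans": report.T_trans,
            "T_rot": report.T_rot,
            "T_vib": report.T_vib,
            "p_bar": p,
            "W_intra": w_intra,
            "lambda_trans": self.last_factors.lambda_trans,
            "lambda_rot": self.last_factors.lambda_rot,
            "lambda_vib": self.last_factors.lambda_vib,
        }

    def _intermolecular_virial(self) -> tuple[float, float]:
        cfg = self.config
        if cfg.pressure_method == "pair_direct":
            return self.result.pair_virial_inter, 0.0
        w_total = float(np.trace(self.result.stress_total)) * self.state.volume
        if cfg.pressure_method == "explicit":
            w_intra = sum(
                intramolecular_virial(self.state, mol, self.params)
                for mol in self.molecules
            )
        else:  # table
            w_intra = 0.0
            for mol in self.molecules:
                coords = internal_coordinates(mol, self.state)
                w, _ = query_table(cfg.table, coords, self.state.volume)
                w_intra += w
        return w_total - w_intra, w_intra

    # ------------------------------------------------------------------
    def run(self, trajectory_file=None, elements: Sequence[str] | None = None
            ) -> pd.DataFrame:
        """Equilibration then sampling; returns the sampled frame log."""
        cfg = self.config
        for _ in range(cfg.equilibration_steps):
            self.step()
        rows = []
        for i in range(cfg.n_steps):
            self.step()
            if (i + 1) % cfg.sample_stride == 0:
                rows.append(self.sample())
                if trajectory_file is not None:
                    from .io import write_xyz_frame

                    write_xyz_frame(
                        trajectory_file, elements, self.state.positions,
                        self.state.box_edge, self.state.time,
                    )
        return pd.DataFrame(rows)


def run(
    state: SystemState,
    molecules: Sequence[MoleculeTopology],
    params: ForceFieldParams,
    config: RunConfig,
) -> tuple[SystemState, pd.DataFrame, dict[str, float]]:
    """Convenience wrapper: propagate and summarise the sampling phase.

    The summary reports block-averaged mean and uncertainty for the pressure
    and the three component temperatures.
    """
    sim = Simulation(state, molecules, params, config)
    log = sim.run()
    summary: dict[str, float] = {}
    for col, name in (
        ("p_bar", "p"),
        ("T_trans", "T_trans"),
        ("T_rot", "T_rot"),
        ("T_vib", "T_vib"),
    ):
        if len(log):
            stats = block_average(log[col].to_numpy(), config.n_blocks)
            summary[f"mean_{name}"] = stats.mean
            summary[f"std_{name}"] = stats.std
            summary[f"sem_{name}"] = stats.sem
    return sim.state, log, summary
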
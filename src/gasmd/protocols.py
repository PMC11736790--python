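"""Standard study protocols for the reference CO₂ gas system.

These bundle the canonical desk-scale experiments on the shipped flexible-CO₂
surrogate: the 50-molecule reference cell (edge 100.9597 Å, ideal-gas
pressure 2.0 bar at 298.15 K), the global-CSVR contrast run started from a
de-equipartitioned state, the inverse-volume scaling of the intramolecular
pressure correction, and the interpolation-table fidelity benchmark.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .analysis import box_edge_for_pressure
from .engine import (
    RunConfig,
    deequipartitioned_velocities,
    initialize_velocities,
    run,
)
from .presets import build_gas_system, forcefield_params
from .thermostat import ThermostatSpec
from .virial_pressure import (
    build_table,
    cell_center_benchmark,
    inverse_volume_scan,
)

#: the reference cubic cell: 50 molecules at 2.0 bar ideal-gas density
REFERENCE_BOX_EDGE = 100.9597  # Å
REFERENCE_N_MOL = 50
REFERENCE_T = 298.15  # K


def reference_co2_run(
    seed: int = 1,
    equilibration_ps: float = 25.0,
    sampling_ps: float = 50.0,
    dt: float = 2.0,
    sample_stride: int = 10,
    mode: str = "equipartition",
) -> tuple[pd.DataFrame, dict[str, float]]:
    """NVT run of 50 flexible CO₂ in the reference cell with block-averaged
    molecular-virial pressure (explicit intramolecular correction)."""
    params = forcefield_params("co2_flex")
    state, molecules = build_gas_system(
        "CO2", REFERENCE_N_MOL, REFERENCE_BOX_EDGE, seed=seed
    )
    state = initialize_velocities(state, molecules, REFERENCE_T, seed=seed + 101)
    config = RunConfig(
        dt=dt,
        n_steps=int(round(sampling_ps * 1000 / dt)),
        equilibration_steps=int(round(equilibration_ps * 1000 / dt)),
        sample_stride=sample_stride,
        thermostat=ThermostatSpec(mode=mode, target_T=REFERENCE_T, seed=seed + 202),
        pressure_method="explicit",
    )
    _, log, summary = run(state, molecules, params, config)
    return log, summary


def global_csvr_contrast_run(
    seed: int = 1,
    sampling_ps: float = 50.0,
    dt: float = 2.0,
    sample_stride: int = 10,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Global single-CSVR run started from a de-equipartitioned state (all
    kinetic energy in translation): in a dilute gas the component
    temperatures stay far apart over the whole window."""
    params = forcefield_params("co2_flex")
    state, molecules = build_gas_system(
        "CO2", REFERENCE_N_MOL, REFERENCE_BOX_EDGE, seed=seed
    )
    state = deequipartitioned_velocities(state, molecules, REFERENCE_T, seed=seed + 101)
    config = RunConfig(
        dt=dt,
        n_steps=int(round(sampling_ps * 1000 / dt)),
        equilibration_steps=0,
        sample_stride=sample_stride,
        thermostat=ThermostatSpec(
            mode="global_csvr", target_T=REFERENCE_T, seed=seed + 202
        ),
        pressure_method="pair_direct",
    )
    _, log, summary = run(state, molecules, params, config)
    return log, summary


def component_temperature_disparity(summary: dict[str, float]) -> float:
    """(max − min) of the three time-averaged component temperatures,
    relative to the target temperature."""
    temps = [summary["mean_T_trans"], summary["mean_T_rot"], summary["mean_T_vib"]]
    return (max(temps) - min(temps)) / REFERENCE_T


def inverse_volume_study() -> dict:
    """One fixed displaced CO₂ configuration in 20 cubic cells, L = 20–200 Å:
    linear fit of the pressure correction against 1/V."""
    params = forcefield_params("co2_flex")
    return inverse_volume_scan(
        "CO2", params, coords=[1.21, 1.13, 172.0],
        box_edges=np.linspace(20.0, 200.0, 20),
    )


def table_fidelity_study() -> dict:
    """Build the standard CO₂ table (0.1 Å / 1° spacing, 100 Å reference
    cell) and benchmark it at every grid-cell centre."""
    params = forcefield_params("co2_flex")
    table = build_table("CO2", params, box_edge=100.0)
    return cell_center_benchmark(table, params)
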
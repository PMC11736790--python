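# gasmd

Molecular dynamics of small-molecule gases with an **equipartitioning
thermostat** and **molecule-based virial pressure** evaluation.

## The problem

In a dilute gas the mean free path is large and collisions are rare, so the
kinetic energy exchanged between translational, rotational and vibrational
motion redistributes extremely slowly.  An MD simulation of a few dozen gas
molecules under a conventional global thermostat can therefore spend hundreds
of picoseconds with, say, hot rotations and cold vibrations — violating the
equipartition theorem (⟨E⟩ = ½k_BT per quadratic degree of freedom) and, since
the pressure is read from the translational (centre-of-mass) kinetic energy,
producing systematically wrong pressures.

`gasmd` addresses this with two pieces of machinery:

1. **Equipartitioning CSVR thermostat.**  Each atom's velocity is decomposed
   exactly into translational, rotational and vibrational components,

   v_ij = v_COM,i + ω_i × r′_ij + v_vib,ij ,

   where ω_i solves the per-molecule rigid-rotation least-squares problem
   (stacked per-atom projection operators, pseudo-inverse solve, so linear
   molecules need no special casing).  Three *independent* stochastic
   canonical velocity-rescaling (CSVR) factors — drawn from the exact
   finite-timestep kinetic-energy propagator — then thermostat the three
   components separately, and the velocities are recomposed as
   v′ = λ_t v_trans + λ_r v_rot + λ_v v_vib.  Each component's stationary
   kinetic-energy distribution is the canonical Γ(f/2, k_BT).

2. **Molecule-based virial pressure with intramolecular correction.**  For a
   cubic cell, p = (N_mol k_B T_trans + W_inter/3)/V.  The intermolecular
   virial W_inter is obtained either by subtracting one isolated single-point
   stress per molecule from the total stress tensor, by direct pair
   accumulation, or — cheaply — from a tensor-product cubic-spline
   **interpolation table** of the intramolecular virial W on an
   internal-coordinate grid (r₁, r₂, α for CO₂; 0.1 Å / 1° spacing).  W of an
   isolated molecule is volume-independent, so one table serves every cell
   size and the pressure correction scales exactly as 1/V.

The force provider is pluggable (anything returning forces plus stress
tensors); the package ships classical flexible surrogates for CO₂ and CH₄ and
LJ argon (see `docs/methods.md` for the parameterisation and its limits).

## Worked example

50 flexible CO₂ molecules in a cubic cell of edge 100.9597 Å at 298.15 K —
conditions where the gas is near-ideal and the expected pressure is
N k_B T / V = 2.0 bar:

```python
from gasmd import (RunConfig, ThermostatSpec, build_gas_system,
                   forcefield_params, initialize_velocities, run)

state, molecules = build_gas_system("CO2", n_mol=50, box_edge=100.9597, seed=1)
state = initialize_velocities(state, molecules, T=298.15, seed=2)

config = RunConfig(
    dt=2.0, equilibration_steps=5000, n_steps=10000, sample_stride=10,
    thermostat=ThermostatSpec(mode="equipartition", target_T=298.15, seed=3),
    pressure_method="explicit",          # per-molecule intramolecular correction
)
final_state, log, summary = run(state, molecules,
                                forcefield_params("co2_flex"), config)

print(f"pressure  {summary['mean_p']:.3f} +/- {summary['sem_p']:.3f} bar")
for c in ("trans", "rot", "vib"):
    print(f"T_{c:5s}  {summary[f'mean_T_{c}']:.1f} +/- {summary[f'sem_T_{c}']:.1f} K")
```

Output (10 ps equilibration + 20 ps sampling, block-averaged mean ± standard
error):

```
pressure  1.970 +/- 0.026 bar
T_trans  294.9 +/- 3.7 K
T_rot    291.1 +/- 2.5 K
T_vib    296.1 +/- 2.3 K
```

The sampled pressure is statistically consistent with the 2.0 bar ideal-gas
value and all three component temperatures sit at the 298.15 K set point —
the signature of correct equipartitioning.  Running the same system in
`mode="global_csvr"` from a de-equipartitioned start instead leaves the
components hundreds of kelvin apart for the whole run
(`gasmd.engine.deequipartitioned_velocities` prepares such a state).

A command-line interface mirrors the library: `gasmd simulate run.toml`,
`gasmd decompose`, `gasmd build-table`, `gasmd rdf`, `gasmd pvscan`
(`gasmd --help` for details).

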
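# Methods

This note documents the models and numerical choices behind `gasmd`: what is
simulated, how the thermostat and pressure machinery work, what the shipped
force-field surrogates do and do not represent, and where the edges of
validity lie.

## Units and constants

Internal units are amu, Å, fs and K; the derived energy unit is amu·Å²·fs⁻²
(= 1.660539×10⁻¹⁷ J) and pressures convert to bar by 1.660539×10⁸.
All constants (k_B, N_A, R) come from CODATA 2018 and live in one module,
`gasmd.constants`; every route-equivalence test in the suite depends on this
single source of truth.  Force-field parameters are entered in kJ/mol, Å and
degrees and converted once at force-field compilation.

## Molecular model and degrees of freedom

A system is a flat atom array plus molecules defined by explicit bond
connectivity (never distance heuristics — the setting is non-reactive and
deterministic).  Geometry class is assigned once, from the principal inertia
moments of the reference configuration: monatomic if all moments vanish
(below 1e-9 amu·Å², orders below any bonded moment), linear if the smallest
over the largest moment is below 1e-6, else nonlinear.  A vibrating linear
molecule is instantaneously bent, so the class is deliberately static.

DOF accounting per molecule: f_trans = 3 always; f_rot = 0/2/3 for
monatomic/linear/nonlinear; f_vib = 3n − f_trans − f_rot.  System-wide, the
three conserved components of total linear momentum (removed at
initialisation and preserved by every code path) are charged to the
translational pool: F_trans = 3N_mol − 3.  The totals always satisfy
F_trans + F_rot + F_vib = 3N_atoms − 3.

## Velocity decomposition

Per molecule, v_trans is the COM velocity broadcast to its atoms; v_rot is
ω×r′ with r′ the COM-frame positions; v_vib is the remainder.  ω solves the
overdetermined rigid-rotation system built from per-atom 3×3 projection
blocks Ξ = −skew(r′) stacked into a 3n×3 matrix and inverted by Moore–Penrose
pseudo-inverse with singular-value cutoff 1e-10·σ_max — linear molecules give
a rank-2 system and are handled by the same code path, never by branching.

Two weightings of the fit are implemented.  The **mass-weighted** fit
(minimise Σ m‖v′ − ω×r′‖²; its normal equations are exactly Θω = L) is the
default and the one the thermostat uses, because it is the unique choice for
which the decomposition is an orthogonal projection in the mass metric:
v_vib then carries exactly zero linear *and* angular momentum, the three
component energies close exactly on ½Σm‖v‖² (asserted to 1e-10 in the suite),
and scaling any single component commutes with re-decomposition — the
structural property the recompose-after-scaling thermostat relies on.  The
**uniform** fit (mass-independent Ξ blocks, `weighting="uniform"`) coincides
with the mass-weighted one for rigid motion but leaves a small
angular-momentum residue in v_vib for vibrating heteronuclear molecules
(closure error ~1e-3 relative on a vibrating CO₂); it is kept for comparison
and is not used in production paths.

Degenerate inertia spectra (symmetric and spherical tops such as CH₄) need no
axis-continuity machinery: every reported quantity (ω in the lab frame, the
component energies) is independent of the arbitrary eigenbasis, which the
suite asserts.  Principal axes are fixed to ascending moments and det B = +1
for deterministic output.  All decomposition acts on unwrapped coordinates;
the engine never wraps positions, so molecules are always whole and COM and
inertia are always well defined.

## Thermostats

The CSVR scaling factor is drawn from the exact finite-dt propagator of the
kinetic energy (not an Euler–Maruyama discretisation of the underlying SDE),

λ² = c + (Ē/(fE))(1−c)(R₁² + χ²_{f−1}) + 2R₁√(c(Ē/(fE))(1−c)),
c = e^{−dt/τ},  Ē = ½ f k_B T,

with the f−1 squared normals drawn as one chi-square deviate.  λ² is
algebraically non-negative.  Passing no generator gives the deterministic
weak-coupling (Berendsen) limit, used only as a test fixed point.

*Equipartition mode* decomposes the post-integration velocities, draws three
independent factors with the component DOF counts (F_trans = 3N−3, ΣF_rot,
ΣF_vib) and recomposes λ_t v_t + λ_r v_r + λ_v v_v.  *Global mode* scales all
velocities with a single factor from the total kinetic energy — the baseline
whose slow inter-component energy redistribution in dilute gases motivates
the equipartitioning variant.  Noise streams are spawned per component from
one master seed with fixed offsets, so adding or removing a component never
perturbs the other components' sequences; identical seed and configuration
give bit-identical trajectories on one platform.

Coupling times default to τ = 100 fs for all three components
(config-exposed).  This is an order of magnitude above the timestep and well
below any collision timescale, so component temperatures relax in a few
hundred fs; the stationary kinetic-energy distribution per component is
Γ(f/2, k_BT), verified by a Kolmogorov–Smirnov test at α = 0.01 with a fixed
seed.  A component with f = 0 (rotation/vibration in a monatomic gas) is
skipped silently; a component with zero kinetic energy but a nonzero target
cannot be rescaled and triggers a thermal re-draw of velocities instead.

The thermostat is applied once per step, after the second velocity half-kick
of the velocity-Verlet integrator.

## Pressure

The molecule-based estimator for a cubic cell is

p = (N_mol k_B T_trans + W_inter/3) / V,

implemented as (2·E_kin,mol·(3N_mol/F_trans) + W_inter)/(3V): the COM kinetic
energy thermostatted on 3N−3 DOF is rescaled by 3N/(3N−3) so the kinetic part
reads exactly N_mol k_B T_trans.  Without that factor the 50-molecule
reference cell would read 2% low.  The 3N−3 subtlety thus enters only the
temperature definition, not the ideal-gas bookkeeping.

W_inter can be computed three ways, all equal within their stated accuracy
and all leaving the trajectory untouched (the correction only affects
reported pressure; bitwise trajectory invariance is asserted):

- **explicit** — trace of the total stress tensor minus one isolated
  single-point stress per molecule (the subtraction route; this is the
  general mechanism through which an external force provider that only
  reports total stress is corrected);
- **pair_direct** — accumulation of F·r over intermolecular atom pairs during
  the force loop (available for pairwise force fields; agrees with the
  subtraction route to round-off, asserted at 1e-8);
- **table** — subtraction with the per-molecule intramolecular virial read
  from the interpolation table (below).

Both the total stress (Σ r⊗F/V) and the intermolecular virial use relative
(pair/bond, minimum-image) vectors, i.e. the atom-pair convention.  A
COM-separation convention for assigning pair forces to molecules differs
instantaneously by Σ f_ab·(s_a − s_b) (s = position relative to own COM) but
agrees in ensemble average at gas densities; the atom-pair convention is used
throughout because it makes the subtraction and pair-direct routes *exactly*
equal configuration by configuration, which is the package's core
cross-check.

## Intramolecular virial interpolation table

For an isolated molecule the scalar virial W = Σ r·F of the bonded terms is
invariant under rotation and translation and — because bond lengths scale
linearly and angles are scale-invariant under a uniform dilation — is
volume-independent.  The table therefore stores W itself (not stress) on a
uniform internal-coordinate grid: (r₁, r₂, α) for CO₂ with the standard
0.1 Å bond and 1° angle spacing, covering the ranges the surrogate samples at
~300 K plus a margin (bonds 1.05–1.35 Å, angle 160–180°); out-of-bounds
queries raise rather than extrapolate.  One isolated single-point evaluation
per node fills the grid (node geometries embedded by the Z-matrix convention:
vertex at the origin, first arm along +x, second in the xy-plane); CO₂'s
r₁↔r₂ exchange symmetry is enforced by symmetrising node values (a no-op up
to round-off when both bonds carry identical terms, default on).  The
evaluator is a tensor-product cubic spline (scipy's regular-grid cubic
interpolation, not-a-knot end conditions — natural end conditions would
degrade boundary-cell accuracy to O(h²) since W″ ≠ 0 at the grid ends).

Storing volume-independent W makes the pressure correction W/(3V) exactly
proportional to 1/V: the 20-cell (L = 20–200 Å) linear fit of correction
versus 1/V has R² = 1 to round-off, and one table serves every cell size.
Table fidelity is benchmarked at the centre of every grid cell — the point of
maximal spline error — against explicit single points; on the shipped CO₂
surrogate the worst deviation is ≈6×10⁻⁵ bar at the 100 Å reference cell.

Tables are practical only for molecules with few internal DOF; CH₄ (9
internal coordinates) would need a 9-dimensional grid, so explicit
subtraction is the supported method there.

## Force-field surrogates

The engine's force provider is pluggable: anything that returns forces, a
potential energy and stress tensors satisfies the contract (this is how a
quantum-chemical engine would slot in; the subtraction machinery only needs
stresses).  The shipped presets are classical desk-scale surrogates chosen to
make the gas-phase physics right at near-ideal densities; they are fits to no
quantum-chemical surface:

- **co2_flex** — Morse C–O bonds with r₀ = 1.162 Å and curvature
  2Dα² = 8000 kJ/mol/Å² (a realistic C=O stretch stiffness, period ≈ 18 fs);
  harmonic O–C–O angle, θ₀ = 180°, k = 1236 kJ/mol/rad²; atomic LJ sites with
  EPM2-flavoured parameters (C: ε/k_B = 28.1 K, σ = 2.757 Å; O: 80.5 K,
  3.033 Å), Lorentz–Berthelot combining, 15 Å cutoff, potential shifted to
  zero at the cutoff.  The Morse width is α = 0.08 Å⁻¹ — deliberately about
  two orders of magnitude below a chemical C=O bond.  The anharmonicity is
  nonzero by design, so the interpolation-table benchmark measures a real
  spline error, but mild by design, so that the standard 0.1 Å table
  resolution resolves the bond virial to ~1e-4 bar at the reference volume
  (a cubic spline at 0.1 Å spacing over a chemically anharmonic Morse curve
  would err at the 1e-2 bar level).  The a-priori spline error estimate that
  fixes this value is h⁴-scaling of the interpolation error of W(r) = −r·U′(r)
  at cell centres.  Consequently D = k/(2α²) is large and the bond is *not* a
  dissociation model; within the thermally sampled ±0.1 Å it behaves as a
  slightly softened harmonic bond.
- **ch4_flex** — harmonic C–H bonds (r₀ = 1.087 Å, k = 2900 kJ/mol/Å²),
  harmonic H–C–H angles (109.471°, 293 kJ/mol/rad²), LJ on C and H.
- **argon** — LJ only (ε/k_B = 120 K, σ = 3.405 Å).

No electrostatics by default (optional fixed partial charges with a
cutoff-shifted Coulomb term are available behind the params); no long-range
tail corrections — at the near-ideal gas densities of interest the LJ-only
deviation from ideal pressure is below the sampling uncertainty, and this is
a documented limitation rather than a correction to be added silently.
Angles are evaluated with the standard Wilson gradient; near θ = π the
(θ−θ₀)/sinθ prefactor is an 0/0 resolved by clamping sinθ at 1e-8, accurate
because the numerator vanishes at the same rate — the bend force at exact
linearity is zero.

## Integration and run protocol

Velocity Verlet with dt = 2 fs for the CO₂ presets (9 steps per stretch
period — coarse but drift-free, as the NVE regression asserts: the linear
fit of total energy over a 5 ps, 50-molecule run has a slope consistent with
zero) and dt = 0.5 fs recommended for CH₄'s faster C–H vibrations.
Initialisation draws Maxwell–Boltzmann velocities, removes COM drift, then
rescales each component once so all three temperatures start exactly at
target (or at deliberately unequal targets, to prepare de-equipartitioned
states).  Since positions are never wrapped and total momentum is zero,
molecules remain whole by construction and the minimum-image convention
handles all periodicity.

Sampled observables are block-averaged.  Ten blocks are used: the block-mean
spread then estimates the uncertainty of the run mean with ~14 degrees of
freedom, stable enough for 3-standard-error comparisons, while block lengths
(5 ps in the reference protocol) remain far above the ~0.1 ps component-
temperature correlation time.  For reference, the run-mean uncertainty of a
component temperature follows σ_inst·√(2τ_c/T_window) with
σ_inst = T√(2/f) ≈ 33 K for F_trans = 147 — about 2 K over 50 ps, which the
block estimate reproduces.

The reference study conditions (in `gasmd.protocols`) are 50 CO₂ molecules in
a cubic cell of edge 100.9597 Å at 298.15 K — ideal-gas pressure 2.0 bar —
propagated for 25 ps equilibration plus 50 ps sampling.  These lengths are
the package's standard desk-scale protocol; the sampled pressure's standard
error at this length is ≈0.02 bar, an order of magnitude below the 2.0 bar
signal.

## What the synthetic systems do and do not show

The generators produce random non-overlapping gas configurations at
equilibrium internal geometry with uniform random orientations, plus lattice
gases and rigid rotors for oracles.  Passing tests on these systems
demonstrate the *algorithmic* claims: exactness of the decomposition algebra,
canonical sampling per component, equality of the three virial routes, the
1/V law, and the qualitative thermostat contrast (a global thermostat leaves
a de-equipartitioned dilute gas hundreds of kelvin from equipartition over
50 ps; the equipartitioning thermostat restores all three temperatures within
a few coupling times).  They do not validate any real CO₂/CH₄ observable
beyond near-ideal pressures: the surrogates' vibrational anharmonicity is
deliberately mild, there are no electrostatics, and quantitative isotherm
deviations from the van der Waals reference are properties of whatever force
provider is plugged in, not of this package.

## Known limitations

- Cubic cells only; the scalar-W table is specifically a cubic-cell device.
- No NPT ensemble, constraints, Ewald summation or multiple time-stepping.
- The interpolation table refuses extrapolation; configurations outside the
  tabulated range require a rebuilt table (wider axes) or the explicit route.
- The uniform-weighting decomposition variant does not satisfy exact energy
  closure for vibrating heteronuclear molecules (see above); it exists for
  comparison with the projection-operator formulation as printed in the
  rigid-body literature.
- At dt = 2 fs the fast stretch is integrated coarsely; total energy shows no
  drift, but individual-mode shadow-Hamiltonian effects at the percent level
  are visible in instantaneous component energies between thermostat steps.
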
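"""Stochastic canonical velocity rescaling (CSVR), global and equipartitioning.

The CSVR thermostat multiplies velocities by a stochastic factor λ whose
stationary kinetic-energy distribution is the canonical Γ(f/2, k_BT).  The
factor is drawn from the exact finite-timestep propagator of the kinetic
energy (Bussi-style), so any dt/τ is admissible:

    λ² = c + (Ē/(f·E)) (1−c) (R₁² + χ²_{f−1}) + 2 R₁ √(c · (Ē/(f·E)) (1−c))

with c = exp(−dt/τ), Ē = f·k_B·T/2 the target kinetic energy, R₁ a standard
normal and χ²_{f−1} one chi-square deviate carrying the remaining f−1 degrees
of freedom.

The equipartitioning mode decomposes velocities into translational, rotational
and vibrational components and applies three *independent* CSVR factors, one
per component with that component's DOF count, then recomposes
v′ = λ_t v_t + λ_r v_r + λ_v v_v.  The global mode applies a single factor to
all atoms — the baseline whose slow kinetic-energy redistribution in dilute
gases the equipartitioning mode is designed to fix.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .constants import KB
from .topology import DofCounts, SystemState
from .veldecomp import Decomposer, VelocityComponents

MODES = ("equipartition", "global_csvr", "none")


class DegenerateComponentError(RuntimeError):
    """A thermostatted component has zero kinetic energy but a nonzero target;
    rescaling is undefined and the velocities must be re-drawn thermally."""


@dataclass
class ThermostatSpec:
    """Thermostat configuration: target temperature, per-component coupling
    times τ (fs) and the master seed for the noise streams."""

    mode: str = "equipartition"
    target_T: float = 298.15
    tau_trans: float = 100.0
    tau_rot: float = 100.0
    tau_vib: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")
        if min(self.tau_trans, self.tau_rot, self.tau_vib) <= 0:
            raise ValueError("coupling times must be > 0")
        if self.target_T < 0:
            raise ValueError("target_T must be >= 0")


@dataclass
class ScalingFactors:
    """Per-component velocity scaling factors applied in one thermostat step."""

    lambda_trans: float = 1.0
    lambda_rot: float = 1.0
    lambda_vib: float = 1.0


def make_rngs(seed: int) -> dict[str, np.random.Generator]:
    """Independent noise streams per component, derived from one master seed.

    Fixed spawn offsets mean adding or removing a component never perturbs the
    other components' noise sequences.
    """
    children = np.random.SeedSequence(seed).spawn(4)
    keys = ("trans", "rot", "vib", "global")
    return {k: np.random.default_rng(s) for k, s in zip(keys, children)}


def csvr_lambda(
    e_kin: float,
    e_target: float,
    f: int,
    tau: float,
    dt: float,
    rng: np.random.Generator | None,
) -> float:
    """One CSVR scaling factor from the exact kinetic-energy propagator.

    With ``rng=None`` the noise is suppressed and the deterministic
    weak-coupling (Berendsen) limit λ² = c + (E_target/E)(1−c) is returned,
    whose fixed point is E = E_target.
    """
    if f < 1:
        raise ValueError("need at least one degree of freedom")
    if e_target > 0 and e_kin <= 0:
        raise DegenerateComponentError(
            "zero kinetic energy in a thermostatted component; re-draw velocities"
        )
    if e_target == 0:
        return math.exp(-dt / (2.0 * tau))  # pure exponential cooling
    c = math.exp(-dt / tau)
    if rng is None:
        lam2 = c + (e_target / e_kin) * (1.0 - c)
        return math.sqrt(lam2)
    s = e_target / (f * e_kin)
    r1 = rng.standard_normal()
    rest = rng.chisquare(f - 1) if f > 1 else 0.0
    lam2 = (
        c
        + s * (1.0 - c) * (r1 * r1 + rest)
        + 2.0 * r1 * math.sqrt(c * s * (1.0 - c))
    )
    return math.sqrt(max(lam2, 0.0))


def apply_equipartition(
    state: SystemState,
    molecules,
    spec: ThermostatSpec,
    dof: DofCounts,
    dt: float,
    rngs: dict[str, np.random.Generator],
    decomposer: Decomposer | None = None,
    components: VelocityComponents | None = None,
) -> tuple[SystemState, ScalingFactors]:
    """One equipartitioning-thermostat step: three independent CSVR factors.

    Components with zero DOF (e.g. rotation in a monatomic gas) are skipped.
    A pre-computed decomposition of the *current* velocities may be passed to
    avoid recomputing it.
    """
    if decomposer is None:
        decomposer = Decomposer(molecules)
    if components is None:
        components = decomposer.decompose(state)
    m = state.masses

    def ke(v: np.ndarray) -> float:
        return 0.5 * float(m @ np.einsum("ij,ij->i", v, v))

    lambdas = []
    for v, f, tau, stream in (
        (components.v_trans, dof.trans, spec.tau_trans, "trans"),
        (components.v_rot, dof.rot, spec.tau_rot, "rot"),
        (components.v_vib, dof.vib, spec.tau_vib, "vib"),
    ):
        if f == 0:
            lambdas.append(1.0)
            continue
        e_target = 0.5 * f * KB * spec.target_T
        lambdas.append(csvr_lambda(ke(v), e_target, f, tau, dt, rngs[stream]))

    lt, lr, lv = lambdas
    new_v = lt * components.v_trans + lr * components.v_rot + lv * components.v_vib
    return state.with_velocities(new_v), ScalingFactors(lt, lr, lv)


def apply_global_csvr(
    state: SystemState,
    spec: ThermostatSpec,
    dof: DofCounts,
    dt: float,
    rng: np.random.Generator,
) -> tuple[SystemState, ScalingFactors]:
    """One global-CSVR step: a single factor from the total kinetic energy
    uniformly scales every atomic velocity."""
    m = state.masses
    e_kin = 0.5 * float(m @ np.einsum("ij,ij->i", state.velocities, state.velocities))
    e_target = 0.5 * dof.total * KB * spec.target_T
    lam = csvr_lambda(e_kin, e_target, dof.total, spec.tau_trans, dt, rng)
    return state.with_velocities(lam * state.velocities), ScalingFactors(lam, lam, lam)
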
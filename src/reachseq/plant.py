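"""Point-mass effector with first-order muscle dynamics, target augmentation, loads.

The effector is a planar point mass driven by low-pass-filtered motor commands:

    m*x'' = -g*x' + fx + f_load        m*y'' = -g*y' + fy
    tau*fx' = ux - fx                  tau*fy' = uy - fy

with state z = [x, y, vx, vy, fx, fy] and controls u = [ux, uy].  The state is
augmented with the (constant) planar coordinates of each sequence target so
that a single linear feedback law can address every goal of the sequence.
Discretization is explicit first-order Euler, Ad = I + dt*A and Bd = dt*B, and
the additive process noise covariance is sigma * Bd @ Bd.T (noise enters
through the same channels as the motor command).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

N_BODY = 6
BODY_LABELS = ("x", "y", "vx", "vy", "fx", "fy")

__all__ = [
    "N_BODY",
    "BODY_LABELS",
    "PlantParams",
    "LinearPlant",
    "LoadProfile",
    "build_continuous_system",
    "discretize",
    "augment_targets",
    "make_plant",
    "make_load_profile",
]


@dataclass(frozen=True)
class PlantParams:
    """Physical and simulation parameters of the point-mass effector.

    Parameters
    ----------
    mass : float
        Mass of the effector in kg.
    damping : float
        Viscous dissipative constant in N*s/m (may be zero).
    tau : float
        Muscle low-pass time constant in s.
    dt : float
        Discretization step in s; must not exceed ``tau``.
    sigma : float
        Dimensionless scale of the additive motor noise covariance.
    delay : float
        Sensory feedback delay in s; rounded to an integer number of steps.
    """

    mass: float = 2.5
    damping: float = 0.1
    tau: float = 0.1
    dt: float = 0.01
    sigma: float = 0.2
    delay: float = 0.05

    def __post_init__(self) -> None:
        if self.mass <= 0 or self.tau <= 0 or self.dt <= 0:
            raise ValueError("mass, tau and dt must be strictly positive")
        if self.damping < 0 or self.sigma < 0 or self.delay < 0:
            raise ValueError("damping, sigma and delay must be non-negative")
        if self.dt > self.tau:
            raise ValueError(f"dt={self.dt} must not exceed tau={self.tau}")

    @property
    def delay_steps(self) -> int:
        """Sensory delay expressed in whole time steps (rounded if needed)."""
        ratio = self.delay / self.dt
        d = int(round(ratio))
        if abs(ratio - d) > 1e-9:
            warnings.warn(
                f"delay {self.delay}s is not an integer multiple of dt "
                f"{self.dt}s; rounded to {d} steps",
                stacklevel=2,
            )
        return d


@dataclass
class LinearPlant:
    """Continuous/discrete state-space system, optionally target-augmented.

    State layout: the six body coordinates ``(x, y, vx, vy, fx, fy)`` followed
    by ``(x*, y*)`` pairs for each target, which evolve as constants (identity
    rows of ``Ad``, zero rows of ``B``/``Bd``, zero process noise).
    """

    params: PlantParams
    A: np.ndarray
    B: np.ndarray
    Ad: np.ndarray | None = None
    Bd: np.ndarray | None = None
    noise_cov: np.ndarray | None = None
    targets: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))

    @property
    def n_states(self) -> int:
        return self.A.shape[0]

    @property
    def n_controls(self) -> int:
        return self.B.shape[1]

    @property
    def n_targets(self) -> int:
        return (self.n_states - N_BODY) // 2

    @property
    def state_labels(self) -> tuple[str, ...]:
        extra = tuple(
            f"{c}T{i + 1}" for i in range(self.n_targets) for c in ("x", "y")
        )
        return BODY_LABELS + extra

    def target_index(self, i: int) -> tuple[int, int]:
        """Column indices of the (x, y) coordinates of target ``i`` (0-based)."""
        if not 0 <= i < self.n_targets:
            raise IndexError(f"target {i} outside 0..{self.n_targets - 1}")
        base = N_BODY + 2 * i
        return base, base + 1

    def initial_state(self) -> np.ndarray:
        """State at rest at the home position with target rows filled in."""
        z0 = np.zeros(self.n_states)
        for i in range(self.n_targets):
            ix, iy = self.target_index(i)
            z0[ix], z0[iy] = self.targets[i]
        return z0


def build_continuous_system(params: PlantParams) -> LinearPlant:
    """Continuous-time (A, B) of the point mass with muscle filtering."""
    m, g, tau = params.mass, params.damping, params.tau
    A = np.zeros((N_BODY, N_BODY))
    A[0, 2] = 1.0
    A[1, 3] = 1.0
    A[2, 2] = -g / m
    A[2, 4] = 1.0 / m
    A[3, 3] = -g / m
    A[3, 5] = 1.0 / m
    A[4, 4] = -1.0 / tau
    A[5, 5] = -1.0 / tau
    B = np.zeros((N_BODY, 2))
    B[4, 0] = 1.0 / tau
    B[5, 1] = 1.0 / tau
    return LinearPlant(params=params, A=A, B=B)


def discretize(plant: LinearPlant, dt: float | None = None) -> LinearPlant:
    """Fill (Ad, Bd, noise_cov) by explicit Euler: Ad = I + dt*A, Bd = dt*B.

    The first-order form is used deliberately (not a matrix exponential); the
    model is defined in terms of this exact update rule.
    """
    dt = plant.params.dt if dt is None else dt
    if dt <= 0:
        raise ValueError("dt must be strictly positive")
    Ad = np.eye(plant.n_states) + dt * plant.A
    Bd = dt * plant.B
    noise_cov = plant.params.sigma * Bd @ Bd.T
    return replace(plant, Ad=Ad, Bd=Bd, noise_cov=noise_cov)


def augment_targets(
    plant: LinearPlant, target_positions: list[tuple[float, float]]
) -> LinearPlant:
    """Append one constant (x*, y*) pair of state rows per target.

    Target rows have zero continuous dynamics, zero control influence and
    zero process noise; their values live in the initial state.  If the input
    plant was already discretized the result is re-discretized so the Euler
    identities hold on the augmented matrices.
    """
    targets = np.asarray(target_positions, dtype=float).reshape(-1, 2)
    if targets.shape[0] < 1:
        raise ValueError("at least one target is required")
    if plant.n_targets:
        raise ValueError("plant is already target-augmented")
    n = N_BODY + 2 * targets.shape[0]
    A = np.zeros((n, n))
    A[:N_BODY, :N_BODY] = plant.A
    B = np.zeros((n, plant.n_controls))
    B[:N_BODY] = plant.B
    out = replace(plant, A=A, B=B, targets=targets, Ad=None, Bd=None, noise_cov=None)
    if plant.Ad is not None:
        out = discretize(out)
    return out


def make_plant(
    params: PlantParams, target_positions: list[tuple[float, float]]
) -> LinearPlant:
    """Convenience: build, target-augment and discretize in one call."""
    return discretize(augment_targets(build_continuous_system(params), target_positions))


@dataclass(frozen=True)
class LoadProfile:
    """Lateral external load pulse: linear rise, plateau, linear ramp-down.

    ``amplitude`` is signed (+ rightward, - leftward) in N.  By convention the
    stated ``width`` is the total nonzero duration including the rise
    (``width_includes_rise=True``); a symmetric ramp-down of ``rise_time`` is
    appended after the plateau to avoid a force discontinuity.
    """

    amplitude: float
    rise_time: float = 0.010
    width: float = 0.200
    trigger_fraction: float = 0.25
    width_includes_rise: bool = True

    def __post_init__(self) -> None:
        if self.rise_time <= 0 or self.width <= 0:
            raise ValueError("rise_time and width must be positive")
        if not 0 < self.trigger_fraction < 1:
            raise ValueError("trigger_fraction must be in (0, 1)")


def make_load_profile(
    spec: LoadProfile, onset_step: int, horizon: int, dt: float
) -> np.ndarray:
    """Per-step lateral force sequence (N) over ``horizon`` steps.

    The ramp reaches full amplitude over ``rise_time`` (value at the k-th
    nonzero step is ``amplitude * min((k+1)*dt/rise_time, 1)``), holds the
    plateau until ``width`` has elapsed since onset, then ramps back down over
    ``rise_time``.  A pulse extending beyond the horizon is truncated with a
    warning.
    """
    if onset_step < 0:
        raise ValueError("onset_step must be non-negative")
    force = np.zeros(horizon)
    if spec.amplitude == 0.0:
        return force
    n_rise = max(1, int(round(spec.rise_time / dt)))
    n_width = int(round(spec.width / dt))
    if not spec.width_includes_rise:
        n_width += n_rise
    n_plateau = max(0, n_width - n_rise)
    shape = np.concatenate(
        [
            np.arange(1, n_rise + 1) / n_rise,
            np.ones(n_plateau),
            1.0 - np.arange(1, n_rise + 1) / n_rise,
        ]
    )
    if onset_step + shape.size > horizon:
        warnings.warn(
            "load pulse extends beyond the simulation horizon; truncated",
            stacklevel=2,
        )
        shape = shape[: max(0, horizon - onset_step)]
    force[onset_step : onset_step + shape.size] = spec.amplitude * shape
    return force
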
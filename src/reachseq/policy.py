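"""Sequence cost construction and finite-horizon LQ feedback gains.

Two cost families encode a k-target reach sequence over a horizon of N steps
divided by element end-steps N1 < N2 < ... <= N:

* ``terminal`` — quadratic position error w.r.t. target i and squared velocity
  are charged only at that element's end-step, with weights ``w_pos`` and the
  per-target dwell weight ``w_vel[i]``; motor output is charged ``w_effort``
  at every step.  A small dwell weight at an intermediate target permits a
  fast fly-through (GO); a large one forces a near stop (STOP).
* ``buildup`` — the same position/velocity penalties accrue throughout each
  element, scaled by a ramp ``((t - N_{i-1}) / (N_i - N_{i-1})) ** b_i`` that
  concentrates cost near the element end (steep for large exponents).

The time-varying feedback gains K_t minimizing the expected quadratic cost
follow from the standard backward Riccati recursion; with additive Gaussian
noise the optimal gains are noise-independent (certainty equivalence).
Because the targets are part of the augmented state, the columns of K_t over
the target coordinates are the per-target gains k1(t), k2(t), ... and the body
columns are kx(t); u(t) = k1(t) T1 + k2(t) T2 + ... + kx(t) x(t) exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .plant import N_BODY, LinearPlant

__all__ = [
    "CostSpec",
    "StageCosts",
    "GainSchedule",
    "go_cost",
    "stop_cost",
    "build_stage_costs",
    "build_terminal_costs",
    "build_buildup_costs",
    "backward_riccati",
    "decompose_gains",
    "gain_onset_time",
    "closed_loop_cost",
]


@dataclass(frozen=True)
class CostSpec:
    """Cost definition for a k-target reach sequence.

    Parameters
    ----------
    element_ends : tuple of int
        End step of each sequence element, strictly increasing; the last one
        is the horizon.
    w_pos : float
        Weight on the squared position error at/towards each target.
    w_vel : tuple of float
        Per-target dwell (squared-velocity) weights; same length as
        ``element_ends``.  Small at an intermediate target = fly through,
        large = stop over.
    w_effort : float
        Weight on the squared motor command, charged every step.
    variant : {"terminal", "buildup"}
        Whether penalties apply only at element end-steps or accrue with a
        power-law temporal ramp within each element.
    exponents : tuple of float
        Ramp exponents per element (``buildup`` only).
    """

    element_ends: tuple[int, ...]
    w_pos: float = 500.0
    w_vel: tuple[float, ...] = (0.1, 1.0)
    w_effort: float = 1e-4
    variant: str = "terminal"
    exponents: tuple[float, ...] = (20.0, 4.0)

    def __post_init__(self) -> None:
        ends = self.element_ends
        if len(ends) < 1 or ends[0] <= 0 or any(
            b <= a for a, b in zip(ends, ends[1:])
        ):
            raise ValueError("element_ends must be strictly increasing and > 0")
        if len(self.w_vel) != len(ends):
            raise ValueError("need one dwell weight per element end")
        if self.w_pos < 0 or self.w_effort < 0 or any(w < 0 for w in self.w_vel):
            raise ValueError("weights must be non-negative")
        if self.variant not in ("terminal", "buildup"):
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.variant == "buildup":
            if len(self.exponents) != len(ends):
                raise ValueError("need one exponent per element")
            if any(b <= 0 for b in self.exponents):
                raise ValueError("buildup exponents must be positive")

    @property
    def horizon(self) -> int:
        return self.element_ends[-1]


def go_cost(
    n1: int = 60, n2: int = 120, variant: str = "terminal", w_final: float = 1.0
) -> CostSpec:
    """Rapid-transfer task: negligible dwell cost at the intermediate target."""
    return CostSpec(element_ends=(n1, n2), w_vel=(0.1, w_final), variant=variant)


def stop_cost(
    n1: int = 60, n2: int = 120, variant: str = "terminal", w_final: float = 1.0
) -> CostSpec:
    """Stop-over task: full dwell cost at the intermediate target."""
    return CostSpec(element_ends=(n1, n2), w_vel=(1.0, w_final), variant=variant)


@dataclass
class StageCosts:
    """Per-step state cost matrices Q_t (t = 0..N) and control cost R."""

    Q: np.ndarray  # (N+1, n, n)
    R: np.ndarray  # (m, m)

    @property
    def horizon(self) -> int:
        return self.Q.shape[0] - 1


def _position_error_quad(plant: LinearPlant, target: int) -> np.ndarray:
    """Quadratic form of (x - x*_i)^2 + (y - y*_i)^2 in the augmented state."""
    n = plant.n_states
    ix, iy = plant.target_index(target)
    Q = np.zeros((n, n))
    for body, tgt in ((0, ix), (1, iy)):
        d = np.zeros(n)
        d[body] = 1.0
        d[tgt] = -1.0
        Q += np.outer(d, d)
    return Q


def _velocity_quad(plant: LinearPlant) -> np.ndarray:
    Q = np.zeros((plant.n_states, plant.n_states))
    Q[2, 2] = Q[3, 3] = 1.0
    return Q


def _check_targets(spec: CostSpec, plant: LinearPlant) -> None:
    if len(spec.element_ends) > plant.n_targets:
        raise ValueError(
            f"cost references {len(spec.element_ends)} targets but plant "
            f"carries only {plant.n_targets}"
        )


def build_terminal_costs(spec: CostSpec, plant: LinearPlant) -> StageCosts:
    """End-step-only penalties: position vs target i and velocity at N_i."""
    if spec.variant != "terminal":
        raise ValueError("spec.variant must be 'terminal'")
    _check_targets(spec, plant)
    n, N = plant.n_states, spec.horizon
    Q = np.zeros((N + 1, n, n))
    vel = _velocity_quad(plant)
    for i, end in enumerate(spec.element_ends):
        Q[end] += spec.w_pos * _position_error_quad(plant, i) + spec.w_vel[i] * vel
    R = spec.w_effort * np.eye(plant.n_controls)
    return StageCosts(Q=Q, R=R)


def build_buildup_costs(spec: CostSpec, plant: LinearPlant) -> StageCosts:
    """Power-law temporal ramp of position/velocity penalties within elements.

    For element i spanning (N_{i-1}, N_i] the step-t weight factor is
    ``((t - N_{i-1}) / (N_i - N_{i-1})) ** b_i``, reaching 1 at the element
    end so the terminal weights are recovered there.
    """
    if spec.variant != "buildup":
        raise ValueError("spec.variant must be 'buildup'")
    _check_targets(spec, plant)
    n, N = plant.n_states, spec.horizon
    Q = np.zeros((N + 1, n, n))
    vel = _velocity_quad(plant)
    starts = (0,) + spec.element_ends[:-1]
    for i, (start, end) in enumerate(zip(starts, spec.element_ends)):
        pos = _position_error_quad(plant, i)
        span = end - start
        for t in range(start + 1, end + 1):
            ramp = ((t - start) / span) ** spec.exponents[i]
            Q[t] += ramp * (spec.w_pos * pos + spec.w_vel[i] * vel)
    R = spec.w_effort * np.eye(plant.n_controls)
    return StageCosts(Q=Q, R=R)


def build_stage_costs(spec: CostSpec, plant: LinearPlant) -> StageCosts:
    if spec.variant == "terminal":
        return build_terminal_costs(spec, plant)
    return build_buildup_costs(spec, plant)


@dataclass
class GainSchedule:
    """Time-indexed feedback gains K_t, t = 0..N-1, on the augmented state."""

    K: np.ndarray  # (N, m, n)
    n_targets: int
    dt: float

    @property
    def horizon(self) -> int:
        return self.K.shape[0]

    @property
    def kx(self) -> np.ndarray:
        """Gains on the six body-state columns, shape (N, m, 6)."""
        return self.K[:, :, :N_BODY]

    def k_target(self, i: int) -> np.ndarray:
        """Gains on the (x*, y*) columns of target ``i``, shape (N, m, 2)."""
        base = N_BODY + 2 * i
        return self.K[:, :, base : base + 2]

    def to_frame(self):
        """Long-format table (t_ms, channel, state_column, value)."""
        import pandas as pd

        N, m, n = self.K.shape
        t = np.repeat(np.arange(N) * self.dt * 1000.0, m * n)
        chan = np.tile(np.repeat(np.arange(m), n), N)
        col = np.tile(np.arange(n), N * m)
        return pd.DataFrame(
            {"t_ms": t, "channel": chan, "state_column": col,
             "value": self.K.ravel()}
        )


def backward_riccati(plant: LinearPlant, costs: StageCosts) -> GainSchedule:
    """Finite-horizon discrete-time Riccati backward pass.

    Returns the certainty-equivalent gains K_t such that u_t = K_t z_t
    minimizes sum_t z_t' Q_t z_t + u_t' R u_t (stage costs have no
    state-control cross terms).  Additive noise leaves the gains unchanged.
    """
    Ad, Bd = plant.Ad, plant.Bd
    if Ad is None or Bd is None:
        raise ValueError("plant must be discretized first")
    N = costs.horizon
    n, m = plant.n_states, plant.n_controls
    K = np.empty((N, m, n))
    S = costs.Q[N].copy()
    for t in range(N - 1, -1, -1):
        G = costs.R + Bd.T @ S @ Bd
        K[t] = -np.linalg.solve(G, Bd.T @ S @ Ad)
        Acl = Ad + Bd @ K[t]
        S = costs.Q[t] + K[t].T @ costs.R @ K[t] + Acl.T @ S @ Acl
        S = 0.5 * (S + S.T)
        if not np.all(np.isfinite(S)):
            raise FloatingPointError(
                f"Riccati recursion produced non-finite values at step {t}"
            )
    return GainSchedule(K=K, n_targets=plant.n_targets, dt=plant.params.dt)


def decompose_gains(
    gains: GainSchedule, plant: LinearPlant
) -> tuple[list[np.ndarray], np.ndarray]:
    """Split K_t into per-target gain series [k1, k2, ...] and body gains kx.

    The decomposition is an exact column partition:
    ``K_t z = sum_i k_i(t) T_i + kx(t) x_body``.
    """
    if gains.K.shape[2] != plant.n_states:
        raise ValueError("gain schedule does not match plant dimension")
    per_target = [gains.k_target(i) for i in range(plant.n_targets)]
    return per_target, gains.kx


def gain_onset_time(
    series: np.ndarray, threshold_frac: float, dt: float | None = None
) -> int | None:
    """First step at which ||gain(t)|| exceeds ``threshold_frac`` of its peak.

    ``series`` is (N, ...) — the norm is taken over all trailing axes.
    Returns the step index, or ``None`` for an all-zero series ("never").
    Multiply by ``dt * 1000`` for milliseconds.
    """
    if not 0 < threshold_frac < 1:
        raise ValueError("threshold_frac must be in (0, 1)")
    norms = np.sqrt((np.asarray(series) ** 2).reshape(len(series), -1).sum(axis=1))
    peak = norms.max()
    if peak == 0.0:
        return None
    idx = np.nonzero(norms > threshold_frac * peak)[0]
    return int(idx[0])


def closed_loop_cost(
    plant: LinearPlant,
    costs: StageCosts,
    K: np.ndarray,
    z0: np.ndarray,
) -> float:
    """Deterministic (noiseless) closed-loop cost of an arbitrary gain sequence."""
    Ad, Bd = plant.Ad, plant.Bd
    z = np.asarray(z0, dtype=float)
    total = float(z @ costs.Q[0] @ z)
    for t in range(costs.horizon):
        u = K[t] @ z
        total += float(u @ costs.R @ u)
        z = Ad @ z + Bd @ u
        total += float(z @ costs.Q[t + 1] @ z)
    return total
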
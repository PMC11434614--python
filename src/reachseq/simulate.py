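"""Closed-loop simulation of reach-sequence trials.

One trial is a finite-horizon rollout of the discretized plant under the
time-varying feedback law u_t = K_t ẑ_t, with ẑ produced by the delayed
Kalman filter.  Mechanical perturbations are lateral force pulses triggered
when the true hand position crosses a fraction of the forward distance to the
first target; the pulse is unknown to the estimator's internal model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import cached_property

import numpy as np

from .estimator import (
    N_BODY,
    ObserverSpec,
    build_delay_augmented_observer,
    initial_estimate,
    precompute_kalman_gains,
)
from .plant import LinearPlant, LoadProfile, PlantParams, make_load_profile, make_plant
from .policy import CostSpec, GainSchedule, backward_riccati, build_stage_costs, go_cost, stop_cost

__all__ = [
    "TaskLayout",
    "TrialCondition",
    "Trajectory",
    "TrialRecord",
    "SequenceModel",
    "two_reach_model",
    "simulate_trial",
    "run_condition_grid",
    "simulate_three_reach",
]


@dataclass(frozen=True)
class TaskLayout:
    """Planar target arrangement; home at the origin, y points away from body."""

    targets: tuple[tuple[float, float], ...]
    home: tuple[float, float] = (0.0, 0.0)

    @classmethod
    def two_reach(
        cls, direction: str = "right", forward: float = 0.18, lateral: float = 0.08
    ) -> "TaskLayout":
        """T1 straight ahead, T2 displaced laterally from T1 (sign = direction)."""
        sign = {"right": 1.0, "left": -1.0}[direction]
        return cls(targets=((0.0, forward), (sign * lateral, forward)))

    @classmethod
    def three_reach(
        cls,
        final: str = "up",
        forward: float = 0.18,
        lateral: float = 0.08,
        final_offset: float = 0.08,
    ) -> "TaskLayout":
        """Two-reach layout extended with a third target above/below T2."""
        sign = {"up": 1.0, "down": -1.0}[final]
        return cls(
            targets=(
                (0.0, forward),
                (lateral, forward),
                (lateral, forward + sign * final_offset),
            )
        )

    @property
    def n_targets(self) -> int:
        return len(self.targets)

    @property
    def forward_distance(self) -> float:
        """Forward (y) distance from home to the first target."""
        return self.targets[0][1] - self.home[1]


@dataclass(frozen=True)
class TrialCondition:
    """Labels of a single trial in the condition grid."""

    direction: str = "right"  # second-target side
    perturbation: float = 0.0  # signed lateral load amplitude in N
    task: str = "GO"
    seed: int | None = None


@dataclass
class Trajectory:
    """Time series of one trial.

    ``z`` holds the true augmented state at steps 0..N, ``z_hat`` the estimate
    (if retained), ``u`` the motor commands at steps 0..N-1 and ``load`` the
    applied lateral force (N).  ``events`` records the perturbation onset step
    (or None) and the element end-steps.
    """

    dt: float
    z: np.ndarray
    u: np.ndarray
    load: np.ndarray
    events: dict = field(default_factory=dict)
    z_hat: np.ndarray | None = None

    @property
    def n_steps(self) -> int:
        return self.u.shape[0]

    @property
    def time_ms(self) -> np.ndarray:
        return np.arange(self.z.shape[0]) * self.dt * 1000.0

    @property
    def position(self) -> np.ndarray:
        return self.z[:, :2]

    @property
    def velocity(self) -> np.ndarray:
        return self.z[:, 2:4]

    @property
    def speed(self) -> np.ndarray:
        return np.linalg.norm(self.velocity, axis=1)

    def to_frame(self):
        """Tidy per-step table of time, state, estimate, control and load."""
        import pandas as pd

        n_t = self.z.shape[0]
        cols = {"t_ms": self.time_ms}
        labels = ["x", "y", "vx", "vy", "fx", "fy"]
        for i, lab in enumerate(labels):
            cols[lab] = self.z[:, i]
        if self.z_hat is not None:
            for i, lab in enumerate(labels):
                cols[f"{lab}_hat"] = self.z_hat[:, i]
        for j in range(self.u.shape[1]):
            cols[f"u{'xy'[j] if j < 2 else j}"] = np.append(self.u[:, j], np.nan)
        cols["load"] = np.append(self.load, np.nan)
        return pd.DataFrame(cols)


@dataclass
class TrialRecord:
    """Trajectory plus condition labels and bookkeeping indices."""

    trajectory: Trajectory
    condition: TrialCondition
    participant: int = 0
    set_index: int = 0
    block_index: int = 0
    trial_index: int = 0
    metrics: dict = field(default_factory=dict)


@dataclass
class SequenceModel:
    """Plant + cost + observer bundle for one task, with cached solutions.

    The Riccati gains and the data-independent Kalman gain sequence are built
    once and shared across every trial of the task (they do not depend on
    target values, perturbations or noise realizations).
    """

    params: PlantParams
    cost: CostSpec
    observer_spec: ObserverSpec | None = None
    layout: TaskLayout = field(
        default_factory=lambda: TaskLayout.two_reach("right")
    )

    def __post_init__(self) -> None:
        if self.observer_spec is None:
            self.observer_spec = ObserverSpec(delay_steps=self.params.delay_steps)

    @cached_property
    def plant(self) -> LinearPlant:
        return make_plant(self.params, list(self.layout.targets))

    @cached_property
    def gains(self) -> GainSchedule:
        return backward_riccati(self.plant, build_stage_costs(self.cost, self.plant))

    @cached_property
    def observer(self):
        return build_delay_augmented_observer(self.plant, self.observer_spec)

    @cached_property
    def kalman_gains(self) -> np.ndarray:
        L, _ = precompute_kalman_gains(self.observer, self.cost.horizon)
        return L

    def layout_for(self, condition: TrialCondition) -> TaskLayout:
        if self.layout.n_targets == 2:
            return TaskLayout.two_reach(
                condition.direction,
                forward=self.layout.targets[0][1],
                lateral=abs(self.layout.targets[1][0]),
            )
        return self.layout

    def simulate(
        self,
        condition: TrialCondition,
        noise_on: bool = True,
        rng: np.random.Generator | None = None,
        store_estimates: bool = True,
    ) -> Trajectory:
        return simulate_trial(
            self.plant,
            self.gains,
            self.observer,
            self.layout_for(condition),
            condition,
            noise_on=noise_on,
            rng=rng,
            kalman_gains=self.kalman_gains,
            store_estimates=store_estimates,
            element_ends=self.cost.element_ends,
        )


def two_reach_model(
    task: str = "GO",
    params: PlantParams | None = None,
    variant: str = "terminal",
    n1: int = 60,
    n2: int = 120,
    cost: CostSpec | None = None,
) -> SequenceModel:
    """Standard two-reach model with default parameters for a GO or STOP task."""
    params = params or PlantParams()
    if cost is None:
        make = {"GO": go_cost, "STOP": stop_cost}[task]
        cost = make(n1, n2, variant=variant)
    return SequenceModel(params=params, cost=cost)


def simulate_trial(
    plant: LinearPlant,
    gains: GainSchedule,
    observer,
    layout: TaskLayout,
    condition: TrialCondition | None = None,
    *,
    noise_on: bool = True,
    rng: np.random.Generator | None = None,
    load_spec: LoadProfile | None = None,
    kalman_gains: np.ndarray | None = None,
    store_estimates: bool = True,
    element_ends: tuple[int, ...] | None = None,
) -> Trajectory:
    """Closed-loop rollout of one trial.

    The perturbation (if any) is triggered at the first step where the *true*
    forward position crosses ``trigger_fraction`` of the home-to-T1 forward
    distance (the robot knows the hand position).  With ``noise_on=False``
    the rollout is fully deterministic; the filter still runs with its
    nominal noise model, so unexpected loads are discovered via innovations
    after the sensory delay in either case.
    """
    condition = condition or TrialCondition()
    if rng is None:
        rng = np.random.default_rng(condition.seed)
    N = gains.horizon
    n, m = plant.n_states, plant.n_controls
    if layout.n_targets != plant.n_targets:
        raise ValueError("layout target count does not match plant")

    if load_spec is None and condition.perturbation:
        load_spec = LoadProfile(amplitude=condition.perturbation)
    trigger_fraction = load_spec.trigger_fraction if load_spec is not None else 0.25
    trigger_dist = layout.home[1] + trigger_fraction * layout.forward_distance

    z0 = np.zeros(n)
    for i, (tx, ty) in enumerate(layout.targets):
        z0[N_BODY + 2 * i] = tx
        z0[N_BODY + 2 * i + 1] = ty

    est = initial_estimate(observer, z0)
    Z_hat = est.mean.copy()
    d = observer.delay_steps
    dt = plant.params.dt
    sqrt_sigma = np.sqrt(plant.params.sigma)
    sqrt_obs = np.sqrt(observer.obs_cov[0, 0])
    load_gain = dt / plant.params.mass  # lateral force -> vx increment

    z = np.empty((N + 1, n))
    z[0] = z0
    z_hat = np.empty((N + 1, n)) if store_estimates else None
    if z_hat is not None:
        z_hat[0] = z0
    u_seq = np.empty((N, m))
    load = np.zeros(N)
    onset: int | None = None

    if kalman_gains is None:
        kalman_gains, _ = precompute_kalman_gains(observer, N)

    A_o, B_o, C_o = observer.A, observer.B, observer.C

    for t in range(N):
        u = gains.K[t] @ Z_hat[:n]
        u_seq[t] = u

        if load_spec is not None and onset is None and z[t, 1] >= trigger_dist:
            onset = t
            load = make_load_profile(load_spec, onset, N, dt)

        z_next = plant.Ad @ z[t] + plant.Bd @ u
        z_next[2] += load_gain * load[t]
        if noise_on:
            z_next[:N_BODY] += sqrt_sigma * (plant.Bd[:N_BODY] @ rng.standard_normal(m))
        z[t + 1] = z_next

        # observation available at step t+1: body state from step t+1-d
        y = z[max(t + 1 - d, 0), :N_BODY].copy()
        if noise_on:
            y += sqrt_obs * rng.standard_normal(N_BODY)
        mean_pred = A_o @ Z_hat + B_o @ u
        Z_hat = mean_pred + kalman_gains[t] @ (y - C_o @ mean_pred)
        if z_hat is not None:
            z_hat[t + 1] = Z_hat[:n]

    if load_spec is not None and onset is None:
        warnings.warn(
            "perturbation trigger distance never crossed; load skipped",
            stacklevel=2,
        )

    events = {
        "perturb_onset": onset,
        "trigger_distance": trigger_dist,
        "element_ends": element_ends,
    }
    return Trajectory(dt=dt, z=z, u=u_seq, load=load, events=events, z_hat=z_hat)


def run_condition_grid(
    models: dict[str, SequenceModel],
    conditions: list[TrialCondition],
    n_reps: int,
    base_seed: int,
    *,
    noise_on: bool = True,
    store_estimates: bool = False,
) -> list[TrialRecord]:
    """Simulate ``n_reps`` trials per condition with reproducible seeding.

    Per-trial RNG streams are spawned deterministically from ``base_seed``,
    so the same seed always yields a bit-identical trial set.  All trials of
    a task share that task's plant, Riccati gains and Kalman gain schedule.
    """
    records: list[TrialRecord] = []
    ss = np.random.SeedSequence(base_seed)
    streams = ss.spawn(len(conditions) * n_reps)
    k = 0
    for cond in conditions:
        model = models[cond.task]
        for rep in range(n_reps):
            rng = np.random.default_rng(streams[k])
            traj = model.simulate(
                cond, noise_on=noise_on, rng=rng, store_estimates=store_estimates
            )
            records.append(
                TrialRecord(trajectory=traj, condition=cond, trial_index=rep)
            )
            k += 1
    return records


def simulate_three_reach(
    dwell_weights: tuple[float, float] = (0.0, 0.0),
    final: str = "up",
    params: PlantParams | None = None,
    element_ends: tuple[int, int, int] = (60, 120, 180),
    w_final: float = 1.0,
    noise_on: bool = False,
    rng: np.random.Generator | None = None,
) -> Trajectory:
    """Noiseless-by-default rollout of a three-target sequence.

    ``dwell_weights`` are the squared-velocity weights at the two
    intermediate targets; the final target always requires a stop
    (``w_final``).  The same rollout machinery as the two-reach task is used
    on a 12-dimensional (three-target) augmented state.
    """
    params = params or PlantParams()
    layout = TaskLayout.three_reach(final)
    cost = CostSpec(
        element_ends=element_ends,
        w_vel=(dwell_weights[0], dwell_weights[1], w_final),
    )
    model = SequenceModel(params=params, cost=cost, layout=layout)
    return model.simulate(
        TrialCondition(task="THREE"), noise_on=noise_on, rng=rng
    )
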
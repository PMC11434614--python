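"""Kalman state estimation with a fixed sensory delay via state stacking.

Sensory feedback reports the body state as it was ``d`` steps ago.  The
standard device for filtering such measurements is to stack the last ``d``
body-state copies below the current (target-augmented) state:

    Z_t = [z_t, b_{t-1}, ..., b_{t-d}]         dim = n + 6 d

where ``b`` denotes the six body coordinates.  The stacked system is linear
with a shift structure, the observation reads the oldest copy plus white
noise, and a standard Kalman filter on the stacked system yields the estimate
of the *current* state as the head block.  Target coordinates are displayed
to the subject, so they are initialized exactly, carry no process noise and
are never corrected: their estimate stays exact with zero variance.

External loads are deliberately absent from the filter's internal model —
an unexpected push reveals itself only through innovations, so its effect on
the estimate cannot precede the sensory delay.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .plant import N_BODY, LinearPlant

__all__ = [
    "ObserverSpec",
    "DelayAugmentedObserver",
    "EstimatorState",
    "build_delay_augmented_observer",
    "initial_estimate",
    "kalman_step",
    "precompute_kalman_gains",
]


@dataclass(frozen=True)
class ObserverSpec:
    """Observation model: delay in steps, per-channel noise, prior variance."""

    delay_steps: int
    obs_noise: float = 1e-4
    init_cov: float = 1e-6

    def __post_init__(self) -> None:
        if self.delay_steps < 0:
            raise ValueError("delay_steps must be non-negative")
        if self.obs_noise < 0 or self.init_cov < 0:
            raise ValueError("covariances must be non-negative")


@dataclass
class DelayAugmentedObserver:
    """Stacked-system matrices for delayed-feedback Kalman filtering."""

    A: np.ndarray  # (ns, ns) stacked transition
    B: np.ndarray  # (ns, m) control enters the head block only
    C: np.ndarray  # (6, ns) reads the oldest body copy
    process_cov: np.ndarray  # (ns, ns)
    obs_cov: np.ndarray  # (6, 6)
    n_plant: int  # dimension of the head (target-augmented) block
    delay_steps: int
    init_cov: float

    @property
    def n_stacked(self) -> int:
        return self.A.shape[0]


def build_delay_augmented_observer(
    plant: LinearPlant, spec: ObserverSpec
) -> DelayAugmentedObserver:
    """Stack ``d`` past body-state copies below the current augmented state."""
    if plant.Ad is None:
        raise ValueError("plant must be discretized first")
    n, d = plant.n_states, spec.delay_steps
    ns = n + N_BODY * d
    A = np.zeros((ns, ns))
    A[:n, :n] = plant.Ad
    for i in range(d):
        row = n + N_BODY * i
        src = 0 if i == 0 else n + N_BODY * (i - 1)
        A[row : row + N_BODY, src : src + N_BODY] = np.eye(N_BODY)
    B = np.zeros((ns, plant.n_controls))
    B[:n] = plant.Bd
    C = np.zeros((N_BODY, ns))
    tail = n + N_BODY * (d - 1) if d > 0 else 0
    C[:, tail : tail + N_BODY] = np.eye(N_BODY)
    W = np.zeros((ns, ns))
    W[:n, :n] = plant.noise_cov
    V = spec.obs_noise * np.eye(N_BODY)
    return DelayAugmentedObserver(
        A=A, B=B, C=C, process_cov=W, obs_cov=V,
        n_plant=n, delay_steps=d, init_cov=spec.init_cov,
    )


@dataclass
class EstimatorState:
    """Stacked estimate and error covariance after the latest update."""

    mean: np.ndarray  # (ns,)
    cov: np.ndarray  # (ns, ns)

    def current(self, observer: DelayAugmentedObserver) -> np.ndarray:
        """Estimate of the present (target-augmented) state."""
        return self.mean[: observer.n_plant]


def initial_estimate(
    observer: DelayAugmentedObserver, z0: np.ndarray
) -> EstimatorState:
    """Initialize at the true state with a small prior on body coordinates.

    Trials start from a stabilized hold at home, so the estimate is seeded at
    the truth; all stacked copies equal the body part of ``z0``.  Target rows
    get zero prior variance (displayed, hence known exactly).
    """
    n, ns, d = observer.n_plant, observer.n_stacked, observer.delay_steps
    mean = np.zeros(ns)
    mean[:n] = z0
    for i in range(d):
        mean[n + N_BODY * i : n + N_BODY * (i + 1)] = z0[:N_BODY]
    var = np.zeros(ns)
    var[:N_BODY] = observer.init_cov
    var[n:] = observer.init_cov
    return EstimatorState(mean=mean, cov=np.diag(var))


def _kalman_gain(observer: DelayAugmentedObserver, P_pred: np.ndarray) -> np.ndarray:
    C = observer.C
    S = C @ P_pred @ C.T + observer.obs_cov
    # pinv keeps the degenerate fully-deterministic case (S == 0) well defined:
    # innovations are then exactly zero and the gain is irrelevant.
    return P_pred @ C.T @ np.linalg.pinv(S)


def kalman_step(
    est: EstimatorState,
    observation: np.ndarray,
    control: np.ndarray,
    observer: DelayAugmentedObserver,
) -> EstimatorState:
    """One predict/update cycle on the stacked system.

    ``observation`` is the delayed body state plus sensory noise (6-vector).
    The covariance recursion does not depend on the data and may be
    precomputed (see :func:`precompute_kalman_gains`).
    """
    y = np.asarray(observation, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite observation")
    A, B, C = observer.A, observer.B, observer.C
    m_pred = A @ est.mean + B @ np.asarray(control, dtype=float)
    P_pred = A @ est.cov @ A.T + observer.process_cov
    L = _kalman_gain(observer, P_pred)
    mean = m_pred + L @ (y - C @ m_pred)
    ILC = np.eye(observer.n_stacked) - L @ C
    # Joseph form for numerical symmetry/PSD
    cov = ILC @ P_pred @ ILC.T + L @ observer.obs_cov @ L.T
    return EstimatorState(mean=mean, cov=0.5 * (cov + cov.T))


def precompute_kalman_gains(
    observer: DelayAugmentedObserver, n_steps: int
) -> tuple[np.ndarray, np.ndarray]:
    """Data-independent gain and covariance sequences for ``n_steps`` updates.

    Returns ``(L, P)`` with ``L[t]`` the gain applied at update ``t`` (i.e.
    when assimilating the observation at step t+1) and ``P[t]`` the posterior
    covariance after that update, starting from the standard initial prior of
    :func:`initial_estimate`.
    """
    est = initial_estimate(observer, np.zeros(observer.n_plant))
    A, C = observer.A, observer.C
    ns = observer.n_stacked
    L_seq = np.empty((n_steps, ns, N_BODY))
    P_seq = np.empty((n_steps, ns, ns))
    P = est.cov
    for t in range(n_steps):
        P_pred = A @ P @ A.T + observer.process_cov
        L = _kalman_gain(observer, P_pred)
        ILC = np.eye(ns) - L @ C
        P = ILC @ P_pred @ ILC.T + L @ observer.obs_cov @ L.T
        P = 0.5 * (P + P.T)
        L_seq[t] = L
        P_seq[t] = P
    return L_seq, P_seq
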
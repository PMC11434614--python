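"""Independent reference computations used only by the test suite.

These deliberately avoid the production code paths: the dynamic-programming
oracle grid-searches discretized controls and fits the quadratic value
function from sampled minima, and the batch estimator oracle conditions one
big joint Gaussian instead of running a recursive filter.
"""

from __future__ import annotations

import itertools

import numpy as np


def dp_gains_bruteforce(
    Ad: np.ndarray,
    Bd: np.ndarray,
    Q: np.ndarray,
    R: np.ndarray,
    u_span: float = 6.0,
    n_grid: int = 31,
    n_rounds: int = 8,
) -> np.ndarray:
    """Finite-horizon optimal feedback gains by brute-force DP.

    At each backward step the optimal control for a state is found by
    iteratively refined grid search over discretized control values; gains
    follow from unit states (the optimal control is linear in the state), and
    the quadratic cost-to-go matrix is reconstructed exactly from sampled
    optimal values at basis states and their pairwise sums.
    """
    N = Q.shape[0] - 1
    n, m = Ad.shape[0], Bd.shape[1]

    def min_over_u(x: np.ndarray, S: np.ndarray) -> tuple[float, np.ndarray]:
        center = np.zeros(m)
        span = u_span
        best = (np.inf, center)
        for _ in range(n_rounds):
            axes = [np.linspace(c - span, c + span, n_grid) for c in center]
            for u_tuple in itertools.product(*axes):
                u = np.asarray(u_tuple)
                xn = Ad @ x + Bd @ u
                c = float(u @ R @ u + xn @ S @ xn)
                if c < best[0]:
                    best = (c, u)
            center = best[1]
            span *= 3.0 / (n_grid - 1)
        return best

    S = Q[N].copy()
    gains = np.empty((N, m, n))
    basis = np.eye(n)
    for t in range(N - 1, -1, -1):
        for i in range(n):
            gains[t, :, i] = min_over_u(basis[i], S)[1]

        def value(x: np.ndarray) -> float:
            return float(x @ Q[t] @ x) + min_over_u(x, S)[0]

        S_new = np.zeros((n, n))
        diag = [value(basis[i]) for i in range(n)]
        for i in range(n):
            S_new[i, i] = diag[i]
            for j in range(i + 1, n):
                vij = value(basis[i] + basis[j])
                S_new[i, j] = S_new[j, i] = 0.5 * (vij - diag[i] - diag[j])
        S = S_new
    return gains


def batch_posterior(
    A: np.ndarray,
    B: np.ndarray,
    C: np.ndarray,
    W: np.ndarray,
    V: np.ndarray,
    m0: np.ndarray,
    P0: np.ndarray,
    controls: np.ndarray,
    observations: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Posterior of the final state given all observations, by joint-Gaussian
    conditioning.

    System: z_{t+1} = A z_t + B u_t + w_t, y_{t+1} = C z_{t+1} + v_{t+1},
    with z_0 ~ N(m0, P0), w ~ N(0, W), v ~ N(0, V).  Builds the exact joint
    covariance of (z_T, y_1..y_T) and conditions — no recursion involved.
    """
    T = controls.shape[0]
    n = A.shape[0]
    p = C.shape[0]
    # noise vector xi = [z0 - m0, w_0..w_{T-1}, v_1..v_T]
    dim = n * (T + 1) + p * T
    cov_xi = np.zeros((dim, dim))
    cov_xi[:n, :n] = P0
    for t in range(T):
        s = n + n * t
        cov_xi[s : s + n, s : s + n] = W
    for t in range(T):
        s = n * (T + 1) + p * t
        cov_xi[s : s + p, s : s + p] = V

    # deterministic mean trajectory
    means = [m0]
    for t in range(T):
        means.append(A @ means[-1] + B @ controls[t])

    # linear maps xi -> z_t (deviation from mean)
    maps = [np.zeros((n, dim)) for _ in range(T + 1)]
    maps[0][:, :n] = np.eye(n)
    for t in range(T):
        maps[t + 1] = A @ maps[t]
        maps[t + 1][:, n + n * t : n + n * (t + 1)] += np.eye(n)

    # stacked observation deviations y_t - C mean_t
    y_map = np.zeros((p * T, dim))
    y_dev = np.zeros(p * T)
    for t in range(1, T + 1):
        r = p * (t - 1)
        y_map[r : r + p] = C @ maps[t]
        y_map[r : r + p, n * (T + 1) + p * (t - 1) : n * (T + 1) + p * t] += np.eye(p)
        y_dev[r : r + p] = observations[t - 1] - C @ means[t]

    zT_map = maps[T]
    cov_zy = zT_map @ cov_xi @ y_map.T
    cov_yy = y_map @ cov_xi @ y_map.T
    cov_zz = zT_map @ cov_xi @ zT_map.T
    gain = cov_zy @ np.linalg.pinv(cov_yy)
    mean = means[T] + gain @ y_dev
    cov = cov_zz - gain @ cov_zy.T
    return mean, cov
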
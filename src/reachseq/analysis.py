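"""Trial-level kinematics and perturbation-response epoch statistics.

Kinematic metrics
-----------------
* lateral deviation — mean signed perpendicular distance (m) of the first
  reach from the straight home->T1 line; positive = rightward of the line.
* dwell velocity — minimum root-mean-square planar speed (m/s) while the hand
  is within a small proximity zone around the first target.

Perturbation responses
----------------------
Muscle-like channels are proxied by the rectified lateral motor command
(rightward-pulling and leftward-pulling components of u_x, low-pass
smoothed); this is an explicit modeling proxy for an agonist/antagonist
shoulder-muscle pair that produces lateral force.  Traces are aligned to the
perturbation onset (unperturbed trials to the matched pseudo-onset, the step
where the trigger distance is crossed), the block-matched unperturbed mean is
subtracted (a delta response), and means are taken over the classical
stretch-reflex epochs (R0/R1 short latency, R2/R3 long latency, voluntary).
Contrasts use paired t statistics across participants, unadjusted across
epochs; Holm-Bonferroni adjustment is available where wanted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import TaskLayout, Trajectory, TrialRecord

__all__ = [
    "EpochSet",
    "DEFAULT_EPOCHS",
    "DeltaResponse",
    "lateral_deviation",
    "dwell_velocity",
    "emg_proxy",
    "align_to_perturbation",
    "delta_response",
    "paired_contrast",
    "permutation_null_rejection_rate",
    "holm_adjust",
    "trial_metrics",
    "metrics_table",
]


@dataclass(frozen=True)
class EpochSet:
    """Named analysis windows in ms relative to perturbation onset."""

    windows: tuple[tuple[str, float, float], ...]

    def __post_init__(self) -> None:
        spans = [(a, b) for _, a, b in self.windows if a >= 0]
        for (a1, b1), (a2, b2) in zip(spans, spans[1:]):
            if a2 < b1:
                raise ValueError("post-onset epochs must not overlap")

    def names(self) -> list[str]:
        return [name for name, _, _ in self.windows]

    def mask(self, time_ms: np.ndarray, name: str) -> np.ndarray:
        for n, a, b in self.windows:
            if n == name:
                return (time_ms >= a) & (time_ms < b)
        raise KeyError(name)


DEFAULT_EPOCHS = EpochSet(
    windows=(
        ("baseline", -100.0, 0.0),
        ("R0", 0.0, 20.0),
        ("R1", 20.0, 45.0),
        ("R2", 45.0, 75.0),
        ("R3", 75.0, 105.0),
        ("Vol", 120.0, 180.0),
    )
)


def _first_reach_slice(
    traj: Trajectory,
    layout: TaskLayout,
    segment: str,
    onset_speed: float,
    zone_radius: float,
) -> slice:
    """Sample range of the first reach: movement onset to T1 entry (or N1)."""
    speed = traj.speed
    moving = np.nonzero(speed > onset_speed)[0]
    start = int(moving[0]) if moving.size else 0
    ends = traj.events.get("element_ends")
    n1 = ends[0] if ends else traj.n_steps
    if segment == "n1":
        stop = n1
    elif segment == "t1_entry":
        d = np.linalg.norm(traj.position - np.asarray(layout.targets[0]), axis=1)
        inside = np.nonzero(d[start:] <= zone_radius)[0]
        stop = start + int(inside[0]) + 1 if inside.size else n1
    else:
        raise ValueError(f"unknown segment rule {segment!r}")
    return slice(start, max(stop, start + 1))


def lateral_deviation(
    traj: Trajectory,
    layout: TaskLayout,
    segment: str = "t1_entry",
    onset_speed: float = 0.02,
    t1_radius: float = 0.006,
    proximity: float = 0.005,
) -> float:
    """Mean signed lateral distance (m) from the home->T1 line, first reach.

    Positive values are to the right of the direction of travel.  The first
    reach runs from movement onset (speed > ``onset_speed``) to the first
    entry into the T1 proximity zone (``segment='t1_entry'``, falling back to
    the first element end if the zone is never entered) or simply to the
    first element end (``segment='n1'``).
    """
    home = np.asarray(layout.home, dtype=float)
    t1 = np.asarray(layout.targets[0], dtype=float)
    axis = t1 - home
    length = np.linalg.norm(axis)
    if length == 0:
        raise ValueError("degenerate layout: home and T1 coincide")
    v = axis / length
    sl = _first_reach_slice(traj, layout, segment, onset_speed, t1_radius + proximity)
    rel = traj.position[sl] - home
    signed = rel[:, 0] * v[1] - rel[:, 1] * v[0]
    return float(signed.mean())


def dwell_velocity(
    traj: Trajectory,
    layout: TaskLayout,
    t1_radius: float = 0.006,
    proximity: float = 0.005,
) -> float:
    """Minimum RMS planar speed (m/s) within the T1 proximity zone.

    The zone extends ``proximity`` beyond the target edge (``t1_radius``).
    Returns NaN when the hand never enters the zone.
    """
    t1 = np.asarray(layout.targets[0], dtype=float)
    d = np.linalg.norm(traj.position - t1, axis=1)
    in_zone = d <= t1_radius + proximity
    if not in_zone.any():
        return float("nan")
    return float(traj.speed[in_zone].min())


def emg_proxy(traj: Trajectory, smooth_ms: float = 30.0) -> dict[str, np.ndarray]:
    """Rectified lateral-command channels standing in for an agonist pair.

    ``pull_right`` is the positive part of u_x (rightward lateral drive, the
    analog of a pectoral-like agonist for rightward force) and ``pull_left``
    the positive part of -u_x (deltoid-like antagonist).  Channels are
    smoothed with a centered moving average of ``smooth_ms``.
    """
    ux = traj.u[:, 0]
    w = max(1, int(round(smooth_ms / (traj.dt * 1000.0))))
    kernel = np.ones(w) / w

    def smooth(sig: np.ndarray) -> np.ndarray:
        return np.convolve(sig, kernel, mode="same")

    return {
        "pull_right": smooth(np.maximum(ux, 0.0)),
        "pull_left": smooth(np.maximum(-ux, 0.0)),
    }


def perturbation_onset_step(record: TrialRecord) -> int:
    """Onset step of the load, or the matched pseudo-onset if unperturbed.

    The pseudo-onset is the step at which the true forward position crosses
    the same trigger distance that would have released a load.
    """
    traj = record.trajectory
    onset = traj.events.get("perturb_onset")
    if onset is not None:
        return int(onset)
    trigger = traj.events.get("trigger_distance")
    if trigger is None:
        trigger = 0.25 * 0.18
    crossed = np.nonzero(traj.z[:, 1] >= trigger)[0]
    if crossed.size == 0:
        raise ValueError("trial never crossed the trigger distance")
    return int(crossed[0])


def align_to_perturbation(
    records: list[TrialRecord],
    pre_ms: float = 100.0,
    post_ms: float = 200.0,
    smooth_ms: float = 30.0,
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Time-lock proxy channels to perturbation (or pseudo-) onset.

    Returns ``(tensor, time_ms, channels)`` with tensor shape
    (n_trials, n_channels, n_samples); raises if any window falls outside a
    trial's extent.
    """
    if not records:
        raise ValueError("no trials to align")
    dt_ms = records[0].trajectory.dt * 1000.0
    pre = int(round(pre_ms / dt_ms))
    post = int(round(post_ms / dt_ms))
    time_ms = np.arange(-pre, post + 1) * dt_ms
    channels: list[str] = list(emg_proxy(records[0].trajectory, smooth_ms))
    out = np.empty((len(records), len(channels), pre + post + 1))
    for i, rec in enumerate(records):
        onset = perturbation_onset_step(rec)
        traces = emg_proxy(rec.trajectory, smooth_ms)
        lo, hi = onset - pre, onset + post + 1
        if lo < 0 or hi > rec.trajectory.n_steps:
            raise ValueError(
                f"alignment window [{lo}, {hi}) outside trial extent "
                f"(onset {onset}, {rec.trajectory.n_steps} steps)"
            )
        for j, name in enumerate(channels):
            out[i, j] = traces[name][lo:hi]
    return out, time_ms, channels


@dataclass
class DeltaResponse:
    """Perturbation-minus-baseline traces and their epoch means."""

    time_ms: np.ndarray
    channels: list[str]
    delta: np.ndarray  # (n_perturbed, n_channels, n_samples)
    epoch_means: pd.DataFrame = field(repr=False)


def _block_key(rec: TrialRecord) -> tuple:
    return (rec.participant, rec.set_index, rec.block_index)


def delta_response(
    perturbed: list[TrialRecord],
    unperturbed: list[TrialRecord],
    epochs: EpochSet = DEFAULT_EPOCHS,
    pre_ms: float = 100.0,
    post_ms: float = 200.0,
    smooth_ms: float = 30.0,
) -> DeltaResponse:
    """Subtract the block-matched unperturbed mean from each perturbed trial.

    Unperturbed trials are grouped by (participant, set, block); a perturbed
    trial with no unperturbed trials in its block falls back to the grand
    unperturbed mean of its participant.  Epoch means of the resulting delta
    traces are returned per trial and channel.
    """
    if not perturbed or not unperturbed:
        raise ValueError("both trial groups must be non-empty")
    p_tensor, time_ms, channels = align_to_perturbation(
        perturbed, pre_ms, post_ms, smooth_ms
    )
    u_tensor, _, _ = align_to_perturbation(unperturbed, pre_ms, post_ms, smooth_ms)

    block_means: dict[tuple, np.ndarray] = {}
    participant_sums: dict[int, list] = {}
    for idx, rec in enumerate(unperturbed):
        block_means.setdefault(_block_key(rec), []).append(u_tensor[idx])
        participant_sums.setdefault(rec.participant, []).append(u_tensor[idx])
    block_means = {k: np.mean(v, axis=0) for k, v in block_means.items()}
    participant_means = {k: np.mean(v, axis=0) for k, v in participant_sums.items()}

    delta = np.empty_like(p_tensor)
    rows = []
    for idx, rec in enumerate(perturbed):
        base = block_means.get(_block_key(rec), participant_means.get(rec.participant))
        if base is None:
            raise ValueError(
                f"no unperturbed trials for participant {rec.participant}"
            )
        delta[idx] = p_tensor[idx] - base
        for j, chan in enumerate(channels):
            for name in epochs.names():
                mask = epochs.mask(time_ms, name)
                rows.append(
                    {
                        "participant": rec.participant,
                        "set": rec.set_index,
                        "block": rec.block_index,
                        "trial": rec.trial_index,
                        "direction": rec.condition.direction,
                        "perturbation": rec.condition.perturbation,
                        "channel": chan,
                        "epoch": name,
                        "value": float(delta[idx, j, mask].mean()),
                    }
                )
    return DeltaResponse(
        time_ms=time_ms,
        channels=channels,
        delta=delta,
        epoch_means=pd.DataFrame(rows),
    )


def paired_contrast(
    x: np.ndarray,
    y: np.ndarray | None = None,
    alternative: str = "two-sided",
) -> tuple[float, float]:
    """Paired t statistic and p-value on per-unit pairs (or differences).

    With ``y=None`` a one-sample t-test of ``x`` against zero is performed.
    Degenerate zero-variance differences return defined sentinels: all-zero
    differences give (0.0, 1.0); a constant nonzero difference gives a signed
    infinite t with p = 0 (or 1 for the mismatched one-sided alternative).
    """
    x = np.asarray(x, dtype=float)
    diffs = x if y is None else x - np.asarray(y, dtype=float)
    if diffs.size < 2:
        raise ValueError("need at least two paired units")
    if np.std(diffs, ddof=1) == 0.0:
        mean = float(diffs.mean())
        if mean == 0.0:
            return 0.0, 1.0
        t = np.inf if mean > 0 else -np.inf
        if alternative == "two-sided":
            return t, 0.0
        hit = (alternative == "greater") == (mean > 0)
        return t, 0.0 if hit else 1.0
    res = stats.ttest_rel(diffs, np.zeros_like(diffs), alternative=alternative)
    return float(res.statistic), float(res.pvalue)


def permutation_null_rejection_rate(
    trial_values: dict[int, np.ndarray],
    n_permutations: int = 400,
    alpha: float = 0.05,
    rng: np.random.Generator | None = None,
) -> float:
    """Type-I error rate of the paired contrast under shuffled labels.

    ``trial_values`` maps each participant to per-trial metric values from a
    single condition (so any two-group labelling is null by construction).
    Each permutation randomly splits every participant's trials in half,
    takes the per-participant difference of group means, and applies the
    paired (one-sample) t-test across participants.  Returns the fraction of
    permutations rejecting at ``alpha`` — for a calibrated test this sits
    near ``alpha`` within binomial sampling error.
    """
    rng = rng or np.random.default_rng()
    groups = [np.asarray(v, dtype=float) for v in trial_values.values()]
    if len(groups) < 2:
        raise ValueError("need at least two participants")
    rejections = 0
    for _ in range(n_permutations):
        diffs = np.empty(len(groups))
        for i, vals in enumerate(groups):
            perm = rng.permutation(vals)
            half = vals.size // 2
            diffs[i] = perm[:half].mean() - perm[half : 2 * half].mean()
        _, p = paired_contrast(diffs)
        rejections += p < alpha
    return rejections / n_permutations


def holm_adjust(pvalues) -> np.ndarray:
    """Holm-Bonferroni adjusted p-values (used only for first/last-trial tests)."""
    from statsmodels.stats.multitest import multipletests

    return multipletests(np.asarray(pvalues, dtype=float), method="holm")[1]


def trial_metrics(record: TrialRecord, layout: TaskLayout | None = None, **kw) -> dict:
    """Kinematic metrics of one trial with its condition labels."""
    from .simulate import TaskLayout as _TL

    layout = layout or _TL.two_reach(record.condition.direction)
    dwell = dwell_velocity(record.trajectory, layout)
    return {
        "participant": record.participant,
        "set": record.set_index,
        "block": record.block_index,
        "trial": record.trial_index,
        "task": record.condition.task,
        "direction": record.condition.direction,
        "perturbation": record.condition.perturbation,
        "lateral_deviation": lateral_deviation(record.trajectory, layout, **kw),
        "dwell_velocity": dwell,
        "dwell_reason": "ok" if np.isfinite(dwell) else "zone_not_entered",
    }


def metrics_table(records: list[TrialRecord], **kw) -> pd.DataFrame:
    """Tidy per-trial metric table for a list of trial records."""
    return pd.DataFrame([trial_metrics(r, **kw) for r in records])
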
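"""Synthetic experiment generator with the study's block structure.

A cohort reproduces the experimental bookkeeping — 9 sets of 10 blocks
(5 with the second target to the left, 5 to the right, shuffled within a
set), 10 trials per block of which two random ones carry a lateral load (one
rightward, one leftward), i.e. 900 trials per participant with 20% perturbed
— as noisy closed-loop simulations of the GO or STOP task.  Between-subject
variability is emulated by a small multiplicative jitter on the cost weights
and the motor-noise scale.  The resulting trial records use the same schema
as :mod:`reachseq.simulate`, so the analysis pipeline is agnostic to whether
trials come from a single simulation run or a full synthetic experiment.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .analysis import (
    DEFAULT_EPOCHS,
    EpochSet,
    delta_response,
    metrics_table,
    paired_contrast,
)
from .plant import PlantParams
from .policy import CostSpec, go_cost, stop_cost
from .simulate import SequenceModel, TrialCondition, TrialRecord

__all__ = [
    "ExperimentDesign",
    "SyntheticParticipant",
    "CohortStore",
    "generate_cohort",
    "validate_cohort",
    "first_last_trial_table",
    "direction_contrast",
    "epoch_direction_contrast",
    "stretched_channel",
]

LOAD_AMPLITUDE = 7.0  # N, magnitude of the lateral perturbation


@dataclass(frozen=True)
class ExperimentDesign:
    """Trial-count structure of one synthetic experiment."""

    n_sets: int = 9
    blocks_per_set: int = 10
    trials_per_block: int = 10
    n_participants: int = 5

    def __post_init__(self) -> None:
        if self.blocks_per_set % 2:
            raise ValueError("blocks_per_set must be even (left/right balanced)")
        if self.trials_per_block < 2:
            raise ValueError("need at least the two perturbed trials per block")
        if min(self.n_sets, self.n_participants) < 1:
            raise ValueError("counts must be positive")

    @property
    def trials_per_participant(self) -> int:
        return self.n_sets * self.blocks_per_set * self.trials_per_block

    @property
    def perturbed_per_participant(self) -> int:
        return self.n_sets * self.blocks_per_set * 2


@dataclass(frozen=True)
class SyntheticParticipant:
    """Per-participant multiplicative jitter factors (logged in the manifest)."""

    pid: int
    w_pos_scale: float = 1.0
    w_dwell_scale: float = 1.0
    noise_scale: float = 1.0


@dataclass
class CohortStore:
    """Trial records of one synthetic experiment plus its manifest."""

    records: list[TrialRecord]
    manifest: dict
    _metrics: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def task(self) -> str:
        return self.manifest["task"]

    def metrics(self) -> pd.DataFrame:
        """Per-trial kinematic metric table (computed once, cached)."""
        if self._metrics is None:
            self._metrics = metrics_table(self.records)
        return self._metrics

    def split_perturbed(self) -> tuple[list[TrialRecord], list[TrialRecord]]:
        pert = [r for r in self.records if r.condition.perturbation != 0.0]
        unpert = [r for r in self.records if r.condition.perturbation == 0.0]
        return pert, unpert

    def save(self, directory) -> None:
        """Write the per-trial metric table and regeneration manifest."""
        from pathlib import Path

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.metrics().to_csv(directory / "trial_metrics.csv", index=False)
        (directory / "manifest.json").write_text(
            json.dumps(self.manifest, indent=2, sort_keys=True)
        )


def _draw_participants(
    design: ExperimentDesign, rng: np.random.Generator, jitter: float
) -> list[SyntheticParticipant]:
    out = []
    for pid in range(design.n_participants):
        scales = 1.0 + rng.uniform(-jitter, jitter, size=3)
        out.append(
            SyntheticParticipant(
                pid=pid,
                w_pos_scale=float(scales[0]),
                w_dwell_scale=float(scales[1]),
                noise_scale=float(scales[2]),
            )
        )
    return out


def _participant_model(
    participant: SyntheticParticipant,
    task: str,
    params: PlantParams,
    variant: str,
    n1: int,
    n2: int,
) -> SequenceModel:
    base: CostSpec = {"GO": go_cost, "STOP": stop_cost}[task](n1, n2, variant=variant)
    cost = replace(
        base,
        w_pos=base.w_pos * participant.w_pos_scale,
        w_vel=(base.w_vel[0] * participant.w_dwell_scale,) + base.w_vel[1:],
    )
    p = replace(params, sigma=params.sigma * participant.noise_scale)
    return SequenceModel(params=p, cost=cost)


def generate_cohort(
    design: ExperimentDesign,
    task: str,
    base_seed: int,
    *,
    params: PlantParams | None = None,
    variant: str = "terminal",
    n1: int = 60,
    n2: int = 120,
    jitter: float = 0.05,
    noise_on: bool = True,
) -> CohortStore:
    """Simulate a full blocked experiment for every synthetic participant.

    All randomness (participant jitter, block shuffling, perturbed-trial
    placement, motor/sensory noise) derives deterministically from
    ``base_seed``, so the same seed regenerates the cohort bit-identically.
    """
    if task not in ("GO", "STOP"):
        raise ValueError("task must be 'GO' or 'STOP'")
    params = params or PlantParams()
    root = np.random.SeedSequence(base_seed)
    jitter_ss, trials_ss = root.spawn(2)
    participants = _draw_participants(
        design, np.random.default_rng(jitter_ss), jitter
    )
    records: list[TrialRecord] = []
    half = design.blocks_per_set // 2
    participant_streams = trials_ss.spawn(design.n_participants)
    for part, pss in zip(participants, participant_streams):
        model = _participant_model(part, task, params, variant, n1, n2)
        rng = np.random.default_rng(pss)
        for s in range(design.n_sets):
            directions = ["left"] * half + ["right"] * half
            rng.shuffle(directions)
            for b, direction in enumerate(directions):
                slots = rng.choice(design.trials_per_block, size=2, replace=False)
                signs = rng.permutation([LOAD_AMPLITUDE, -LOAD_AMPLITUDE])
                loads = dict(zip(slots.tolist(), signs.tolist()))
                for trial in range(design.trials_per_block):
                    cond = TrialCondition(
                        direction=direction,
                        perturbation=loads.get(trial, 0.0),
                        task=task,
                    )
                    traj = model.simulate(
                        cond, noise_on=noise_on, rng=rng, store_estimates=False
                    )
                    records.append(
                        TrialRecord(
                            trajectory=traj,
                            condition=cond,
                            participant=part.pid,
                            set_index=s,
                            block_index=b,
                            trial_index=trial,
                        )
                    )
    manifest = {
        "task": task,
        "base_seed": base_seed,
        "variant": variant,
        "n1": n1,
        "n2": n2,
        "jitter": jitter,
        "noise_on": noise_on,
        "design": dataclasses.asdict(design),
        "params": dataclasses.asdict(params),
        "participants": [dataclasses.asdict(p) for p in participants],
    }
    return CohortStore(records=records, manifest=manifest)


def validate_cohort(store: CohortStore) -> dict:
    """Audit condition balance; raises on any count violation.

    Checks per participant: total trial count, perturbed fraction, and that
    every block holds exactly one rightward and one leftward perturbation and
    a constant second-target side.
    """
    design = ExperimentDesign(**store.manifest["design"])
    by_participant: dict[int, list[TrialRecord]] = {}
    for r in store.records:
        by_participant.setdefault(r.participant, []).append(r)
    if len(by_participant) != design.n_participants:
        raise ValueError("participant count mismatch")
    for pid, recs in by_participant.items():
        if len(recs) != design.trials_per_participant:
            raise ValueError(f"participant {pid}: wrong trial count {len(recs)}")
        blocks: dict[tuple, list[TrialRecord]] = {}
        for r in recs:
            blocks.setdefault((r.set_index, r.block_index), []).append(r)
        for key, blk in blocks.items():
            loads = sorted(r.condition.perturbation for r in blk)
            if loads.count(LOAD_AMPLITUDE) != 1 or loads.count(-LOAD_AMPLITUDE) != 1:
                raise ValueError(f"participant {pid} block {key}: bad load counts")
            if len({r.condition.direction for r in blk}) != 1:
                raise ValueError(f"participant {pid} block {key}: mixed directions")
    n_pert = sum(1 for r in store.records if r.condition.perturbation != 0.0)
    return {
        "n_trials": len(store.records),
        "n_perturbed": n_pert,
        "perturbed_fraction": n_pert / len(store.records),
    }


def first_last_trial_table(store: CohortStore) -> pd.DataFrame:
    """Per-participant block-averaged metrics of first vs last within-block trials."""
    m = store.metrics()
    last = m["trial"].max()
    sub = pd.concat(
        [
            m[m["trial"] == 0].assign(position="first"),
            m[m["trial"] == last].assign(position="last"),
        ]
    )
    return (
        sub.groupby(["participant", "direction", "position"], as_index=False)
        .agg(
            lateral_deviation=("lateral_deviation", "mean"),
            dwell_velocity=("dwell_velocity", "mean"),
        )
    )


def direction_contrast(
    store: CohortStore,
    metric: str = "lateral_deviation",
    perturbation: float = 0.0,
) -> dict:
    """Left-vs-right-sequence paired contrast of a kinematic metric.

    Per-participant means in the requested perturbation condition are
    compared across sequence directions with a paired t-test.
    """
    m = store.metrics()
    sel = m[m["perturbation"] == perturbation]
    per = (
        sel.groupby(["participant", "direction"])[metric]
        .mean()
        .unstack("direction")
        .sort_index()
    )
    t, p = paired_contrast(per["left"].to_numpy(), per["right"].to_numpy())
    return {
        "metric": metric,
        "perturbation": perturbation,
        "t": t,
        "p": p,
        "mean_difference": float((per["left"] - per["right"]).mean()),
        "n": int(per.shape[0]),
    }


def stretched_channel(load_sign: float) -> str:
    """Proxy channel stretched by a load of the given sign.

    A rightward push stretches the leftward-pulling (pectoral-like) channel
    and vice versa.
    """
    return "pull_left" if load_sign > 0 else "pull_right"


def epoch_direction_contrast(
    store: CohortStore,
    epoch: str = "R2",
    load_sign: float = 1.0,
    epochs: EpochSet = DEFAULT_EPOCHS,
) -> dict:
    """Sequence-direction contrast of the stretched channel's delta response.

    Per participant, delta-response epoch means of perturbed trials with the
    requested load sign are averaged within each sequence direction; the
    left-vs-right difference is tested across participants with a paired t.
    """
    pert, unpert = store.split_perturbed()
    pert = [r for r in pert if np.sign(r.condition.perturbation) == np.sign(load_sign)]
    dr = delta_response(pert, unpert, epochs=epochs)
    df = dr.epoch_means
    sel = df[(df["epoch"] == epoch) & (df["channel"] == stretched_channel(load_sign))]
    per = (
        sel.groupby(["participant", "direction"])["value"]
        .mean()
        .unstack("direction")
        .sort_index()
    )
    t, p = paired_contrast(per["left"].to_numpy(), per["right"].to_numpy())
    return {
        "epoch": epoch,
        "load_sign": float(np.sign(load_sign)),
        "channel": stretched_channel(load_sign),
        "t": t,
        "p": p,
        "mean_difference": float((per["left"] - per["right"]).mean()),
        "n": int(per.shape[0]),
    }
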
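# reachseq

Optimal feedback control of two-reach movement sequences: when do consecutive
reaches **coarticulate** — the upcoming goal shaping the movement in flight —
and when are they executed as separate elements?

`reachseq` implements the computational account in which both modes emerge
from a *single* task-dependent controller. A point-mass effector with
muscle-like command filtering is driven by a finite-horizon
linear-quadratic-Gaussian (LQG) feedback law whose state is augmented with
the coordinates of every target in the sequence:

    u(t) = k1(t)·T1 + k2(t)·T2 + kx(t)·x̂(t)

The time-varying gains K_t = [k1, k2, kx] are the solution of a backward
Riccati recursion for a sequence-level quadratic cost: position error at each
target at its deadline (weight w1), squared velocity at each target (dwell
weights w2, w3), and motor effort (w4). A small dwell weight at the
intermediate target (w2 = 0.1, the "GO" task) lets k2 overlap with the first
reach — the sequence coarticulates; a large one (w2 = 1, "STOP") defers the
second target's influence — the elements separate. State estimates come from
Kalman filtering with a 50 ms sensory delay handled by state stacking, so
responses to unexpected mechanical loads respect sensorimotor latency.

The package is aimed at computational motor-control researchers who want a
tested, reproducible implementation of the model, its perturbation paradigm
(±7 N lateral load pulses during the first reach), the trial-level kinematic
and stretch-epoch (R0–R3, voluntary) analyses, and a synthetic blocked
experiment generator (9 sets × 10 blocks × 10 trials per participant, 20%
perturbed) for exercising every analysis stage without any experimental data.

## Worked example

```python
import numpy as np
from reachseq import (
    two_reach_model, TrialCondition, TaskLayout,
    lateral_deviation, dwell_velocity, gain_onset_time,
)

layout = TaskLayout.two_reach("right")   # T1 18 cm ahead, T2 8 cm right of T1
for task in ("GO", "STOP"):
    model = two_reach_model(task)        # plant + costs + Riccati gains + filter
    traj = model.simulate(TrialCondition(direction="right"), noise_on=False)
    print(f"{task}: speed at T1 = {traj.speed[60]:.3f} m/s, "
          f"dwell velocity = {dwell_velocity(traj, layout):.3f} m/s")

go = two_reach_model("GO", variant="buildup")
stop = two_reach_model("STOP", variant="buildup")
print("k2 onset (10% of peak): GO step",
      gain_onset_time(go.gains.k_target(1), 0.1),
      "| STOP step", gain_onset_time(stop.gains.k_target(1), 0.1))
```

prints

```
GO: speed at T1 = 0.282 m/s, dwell velocity = 0.236 m/s
STOP: speed at T1 = 0.192 m/s, dwell velocity = 0.133 m/s
k2 onset (10% of peak): GO step 52 | STOP step 53
```

Under the rapid-transfer (GO) objective the hand flies through the first
target above 0.2 m/s and the second-target gain k2 becomes substantial
earlier; requiring a stop (STOP) cuts the transfer speed and delays k2 —
the same controller structure, different dwell cost, producing coarticulated
versus separated sequences.

A command-line interface mirrors the library:

```
reachseq simulate --task GO --direction right --noiseless --out trial.csv
reachseq gains --task STOP --out gains.csv
reachseq cohort --task GO --n-participants 5 --seed 1 --out cohort/
reachseq analyze --store cohort/trial_metrics.csv --out summary.csv
```

## Layout

| module | contents |
| --- | --- |
| `reachseq.plant` | point-mass + muscle-filter plant, Euler discretization, target augmentation, load pulses |
| `reachseq.policy` | terminal / buildup sequence costs, backward Riccati gains, per-target gain decomposition |
| `reachseq.estimator` | delay-stacked Kalman filter |
| `reachseq.simulate` | closed-loop trials, condition grids, three-reach extension |
| `reachseq.analysis` | lateral deviation, dwell velocity, delta responses, epoch statistics, paired contrasts |
| `reachseq.cohort` | synthetic blocked experiments with per-participant jitter |
| `reachseq.cli` | `reachseq` console entry point |
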
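import numpy as np
import pandas as pd
import pytest

from reachseq.analysis import (
    DEFAULT_EPOCHS,
    EpochSet,
    align_to_perturbation,
    delta_response,
    dwell_velocity,
    emg_proxy,
    holm_adjust,
    lateral_deviation,
    paired_contrast,
    perturbation_onset_step,
)
from reachseq.simulate import TaskLayout, Trajectory, TrialCondition, TrialRecord

LAYOUT = TaskLayout.two_reach("right")


def synthetic_trajectory(x, y, dt=0.01, u=None, events=None):
    """Hand-built trajectory with positions given and velocities by differencing."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    z = np.zeros((n, 10))
    z[:, 0], z[:, 1] = x, y
    z[1:, 2] = np.diff(x) / dt
    z[1:, 3] = np.diff(y) / dt
    z[:, 6:] = [0.0, 0.18, 0.08, 0.18]
    if u is None:
        u = np.zeros((n - 1, 2))
    load = np.zeros(n - 1)
    return Trajectory(
        dt=dt, z=z, u=np.asarray(u, dtype=float), load=load,
        events=events or {"element_ends": (60, 120), "perturb_onset": None},
    )


class TestLateralDeviation:
    def test_straight_midline_trajectory_is_zero(self):
        y = np.linspace(0, 0.18, 61)
        traj = synthetic_trajectory(np.zeros(61), y)
        assert lateral_deviation(traj, LAYOUT) == pytest.approx(0.0)

    def test_constant_offset_recovered(self):
        y = np.linspace(0, 0.18, 61)
        traj = synthetic_trajectory(np.full(61, 0.01), y)
        assert lateral_deviation(traj, LAYOUT) == pytest.approx(0.01)

    def test_mirrored_pair_equal_magnitude_opposite_sign(self):
        y = np.linspace(0, 0.18, 61)
        bow = 0.02 * np.sin(np.linspace(0, np.pi, 61))
        right = lateral_deviation(synthetic_trajectory(bow, y), LAYOUT)
        left = lateral_deviation(
            synthetic_trajectory(-bow, y), TaskLayout.two_reach("left")
        )
        assert right == pytest.approx(-left)
        assert right > 0

    def test_degenerate_layout_rejected(self):
        traj = synthetic_trajectory(np.zeros(10), np.zeros(10))
        degenerate = TaskLayout(targets=((0.0, 0.0), (0.08, 0.18)))
        with pytest.raises(ValueError, match="degenerate"):
            lateral_deviation(traj, degenerate)


class TestDwellVelocity:
    def test_full_stop_at_t1_is_near_zero(self):
        y = np.concatenate([np.linspace(0, 0.18, 50), np.full(11, 0.18)])
        traj = synthetic_trajectory(np.zeros(61), y)
        assert dwell_velocity(traj, LAYOUT) == pytest.approx(0.0)

    def test_constant_speed_flythrough(self):
        # passes T1 at a constant 0.25 m/s
        y = np.arange(0, 0.30, 0.25 * 0.01)
        traj = synthetic_trajectory(np.zeros_like(y), y)
        assert dwell_velocity(traj, LAYOUT) == pytest.approx(0.25)

    def test_zone_never_entered_gives_nan(self):
        y = np.linspace(0, 0.05, 30)
        traj = synthetic_trajectory(np.zeros(30), y)
        assert np.isnan(dwell_velocity(traj, LAYOUT))

    def test_go_dwell_exceeds_stop_dwell(self, go_model, stop_model):
        go = go_model.simulate(TrialCondition(), noise_on=False)
        stop = stop_model.simulate(TrialCondition(), noise_on=False)
        assert dwell_velocity(go, LAYOUT) > dwell_velocity(stop, LAYOUT)


class TestAlignment:
    def test_identical_onsets_alignment_is_noop(self, go_model):
        recs = [
            TrialRecord(
                trajectory=go_model.simulate(
                    TrialCondition(perturbation=7.0), noise_on=False
                ),
                condition=TrialCondition(perturbation=7.0),
            )
            for _ in range(3)
        ]
        tensor, time_ms, channels = align_to_perturbation(recs)
        assert tensor.shape[0] == 3 and len(channels) == 2
        np.testing.assert_array_equal(tensor[0], tensor[1])
        assert time_ms[0] == -100.0 and time_ms[-1] == 200.0

    def test_shifted_onsets_shift_traces_exactly(self):
        n = 120
        sig = np.zeros((n, 2))
        sig[:, 0] = np.sin(np.arange(n) / 7.0) + 2.0
        base_events = {"element_ends": (60, 120)}
        recs = []
        for onset in (40, 43):
            y = np.linspace(0, 0.3, n + 1)
            traj = synthetic_trajectory(
                np.zeros(n + 1), y, u=sig,
                events=dict(base_events, perturb_onset=onset),
            )
            recs.append(TrialRecord(trajectory=traj, condition=TrialCondition()))
        tensor, _, _ = align_to_perturbation(recs, pre_ms=100, post_ms=200)
        shift = 3
        np.testing.assert_allclose(tensor[0][:, shift:], tensor[1][:, :-shift])

    def test_pseudo_onset_equals_trigger_crossing(self, go_model):
        traj = go_model.simulate(TrialCondition(), noise_on=False)
        rec = TrialRecord(trajectory=traj, condition=TrialCondition())
        step = perturbation_onset_step(rec)
        assert traj.z[step, 1] >= traj.events["trigger_distance"]
        assert traj.z[step - 1, 1] < traj.events["trigger_distance"]


class TestDeltaResponse:
    def _record(self, u, onset=40, **labels):
        n = u.shape[0]
        y = np.linspace(0, 0.3, n + 1)
        traj = synthetic_trajectory(
            np.zeros(n + 1), y, u=u,
            events={"element_ends": (60, 120), "perturb_onset": onset},
        )
        cond = TrialCondition(perturbation=labels.pop("perturbation", 7.0))
        return TrialRecord(trajectory=traj, condition=cond, **labels)

    def test_identical_groups_give_zero_delta(self):
        u = np.tile([[1.0, 0.0]], (120, 1))
        pert = [self._record(u.copy()) for _ in range(2)]
        unpert = [self._record(u.copy(), perturbation=0.0) for _ in range(2)]
        dr = delta_response(pert, unpert)
        np.testing.assert_allclose(dr.delta, 0.0, atol=1e-12)
        assert (dr.epoch_means["value"] == 0.0).all()

    def test_injected_bump_recovered_in_r2_epoch(self):
        # add a known bump over 45-75 ms post-onset to the perturbed group's
        # rightward-pull channel and recover its amplitude in the R2 mean
        amplitude = 0.8
        onset = 40
        base = np.tile([[2.0, 0.0]], (120, 1))
        bumped = base.copy()
        bumped[onset + 5 : onset + 8, 0] += amplitude
        pert = [self._record(bumped, onset=onset)]
        unpert = [self._record(base, onset=onset, perturbation=0.0)]
        dr = delta_response(pert, unpert, smooth_ms=10.0)
        r2 = dr.epoch_means.query("channel == 'pull_right' and epoch == 'R2'")
        assert r2["value"].iloc[0] == pytest.approx(amplitude, rel=0.05)

    def test_empty_group_rejected(self):
        u = np.tile([[1.0, 0.0]], (120, 1))
        with pytest.raises(ValueError, match="non-empty"):
            delta_response([], [self._record(u)])


class TestEpochSet:
    def test_default_windows_match_reflex_epochs(self):
        names = DEFAULT_EPOCHS.names()
        assert names == ["baseline", "R0", "R1", "R2", "R3", "Vol"]
        t = np.arange(-100, 201, 10.0)
        r2 = DEFAULT_EPOCHS.mask(t, "R2")
        np.testing.assert_array_equal(t[r2], [50.0, 60.0, 70.0])

    def test_overlapping_epochs_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            EpochSet(windows=(("a", 0.0, 30.0), ("b", 20.0, 50.0)))


class TestPairedContrast:
    def test_identical_pairs(self):
        t, p = paired_contrast(np.ones(5), np.ones(5))
        assert (t, p) == (0.0, 1.0)

    def test_constant_difference_with_jitter_gives_large_t(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 0.01, 10)
        t, p = paired_contrast(x + 2.0, x - rng.normal(0, 0.01, 10))
        assert t > 50 and p < 1e-10

    def test_hand_computed_three_pairs(self):
        # pairs (1,2), (2,4), (3,6): diffs (1,2,3), mean 2, sd 1 -> t = 2*sqrt(3)
        t, p = paired_contrast(np.array([2, 4, 6]), np.array([1, 2, 3]))
        assert t == pytest.approx(2 * np.sqrt(3))

    def test_zero_variance_sentinels(self):
        t, p = paired_contrast(np.array([3.0, 3.0, 3.0]), np.zeros(3))
        assert t == np.inf and p == 0.0
        t, p = paired_contrast(
            np.array([-3.0, -3.0]), np.zeros(2), alternative="greater"
        )
        assert t == -np.inf and p == 1.0

    def test_one_sided_alternative(self):
        x = np.array([1.0, 1.2, 0.9, 1.1])
        t_two, p_two = paired_contrast(x)
        t_one, p_one = paired_contrast(x, alternative="greater")
        assert t_one == pytest.approx(t_two)
        assert p_one == pytest.approx(p_two / 2)

    def test_holm_adjustment_monotone(self):
        adj = holm_adjust([0.01, 0.04, 0.03])
        assert adj[0] == pytest.approx(0.03)
        assert np.all(adj >= [0.01, 0.04, 0.03])


class TestEmgProxy:
    def test_channels_are_rectified_lateral_commands(self):
        u = np.zeros((50, 2))
        u[:25, 0] = 1.5
        u[25:, 0] = -0.5
        traj = synthetic_trajectory(
            np.zeros(51), np.linspace(0, 0.3, 51), u=u
        )
        channels = emg_proxy(traj, smooth_ms=0.0)
        np.testing.assert_array_equal(channels["pull_right"], np.maximum(u[:, 0], 0))
        np.testing.assert_array_equal(channels["pull_left"], np.maximum(-u[:, 0], 0))
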
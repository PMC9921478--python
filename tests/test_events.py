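import numpy as np
import pytest

from gaitstab import (condition_presets, detect_gait_events,
                      exclude_turn_strides, generate_reference_trial,
                      match_strides)
from gaitstab.errors import (NoGaitError, NoStraightStridesError,
                             UnsynchronizedError)
from gaitstab.events import FootEvents, GaitEvents


def _detection_errors(traj, gt, margin=1.0):
    f = traj.filtered()
    ev = detect_gait_events(f)
    errs = []
    for side in ("left", "right"):
        det = ev.feet[side].heel_strike_times
        for t in gt.events[side]["heel_strikes"]:
            if t < f.time[0] + margin or t > f.time[-1] - margin:
                continue
            errs.append(np.min(np.abs(det - t)) if det.size else np.inf)
    return np.asarray(errs)


class TestDetection:
    @pytest.mark.parametrize("condition", ["normal", "eyes_closed", "wide",
                                           "tandem"])
    def test_heel_strikes_match_ground_truth(self, condition):
        spec = condition_presets(n_strides=40)[condition]
        traj, gt = generate_reference_trial(spec, seed=13)
        errs = _detection_errors(traj, gt)
        assert errs.size >= 70
        within = np.mean(errs <= 2.0 / traj.rate + 1e-9)
        assert within >= 0.99

    @pytest.mark.parametrize("condition", ["normal", "eyes_closed", "wide",
                                           "tandem"])
    def test_stride_time_bias_below_one_sample(self, condition):
        spec = condition_presets(n_strides=40)[condition]
        traj, gt = generate_reference_trial(spec, seed=17)
        f = traj.filtered()
        ev = detect_gait_events(f)
        est = np.concatenate([np.diff(ev.feet[s].heel_strike_times)
                              for s in ("left", "right")])
        true = np.concatenate([np.diff(gt.events[s]["heel_strikes"])
                               for s in ("left", "right")])
        assert abs(est.mean() - true.mean()) < 1.0 / traj.rate

    def test_constant_positions_raise_no_gait(self, make_traj):
        traj = make_traj(n=500, com=np.tile([0.1, 0.0, 1.0], (500, 1)))
        with pytest.raises(NoGaitError):
            detect_gait_events(traj)

    def test_sinusoidal_relative_displacement_extrema(self, make_traj):
        """Antiphase per-foot sinusoids around an advancing CoM give events
        exactly at the analytic extrema sample indices."""
        n, rate, freq, amp = 2000, 100.0, 1.0, 0.3
        t = np.arange(n) / rate
        com = np.column_stack([1.0 * t, np.zeros(n), np.ones(n)])
        r = com.copy()
        r[:, 0] += amp * np.sin(2 * np.pi * freq * t)
        r[:, 1] += 0.08
        l = com.copy()
        l[:, 0] += amp * np.sin(2 * np.pi * freq * t + np.pi)
        l[:, 1] -= 0.08
        traj = make_traj(n=n, com=com,
                         landmarks={"r_ball": r, "r_heel": r,
                                    "l_ball": l, "l_heel": l})
        ev = detect_gait_events(traj)
        # analytic maxima of sin at (0.25 + k)/freq
        expected_r = {int(round((0.25 + k) * rate / freq))
                      for k in range(int(n / rate * freq))}
        for idx in ev.feet["right"].heel_strikes:
            assert min(abs(idx - e) for e in expected_r) <= 1

    def test_translation_and_rotation_invariance(self, normal_trial):
        traj, _ = normal_trial
        f = traj.filtered()
        base = detect_gait_events(f)
        rot = f.copy()
        c, s = np.cos(0.65), np.sin(0.65)
        R = np.array([[c, -s], [s, c]])
        rot.com[:, :2] = rot.com[:, :2] @ R.T + np.array([5.0, -3.0])
        for k in rot.landmarks:
            rot.landmarks[k][:, :2] = (rot.landmarks[k][:, :2] @ R.T
                                       + np.array([5.0, -3.0]))
        moved = detect_gait_events(rot)
        for side in ("left", "right"):
            assert np.array_equal(base.feet[side].heel_strikes,
                                  moved.feet[side].heel_strikes)
            assert np.array_equal(base.feet[side].toe_offs,
                                  moved.feet[side].toe_offs)

    def test_event_alternation_invariants(self, processed_normal):
        _, ev, _ = processed_normal
        hs_l = ev.feet["left"].heel_strikes
        hs_r = ev.feet["right"].heel_strikes
        assert abs(hs_l.size - hs_r.size) <= 1
        for side in ("left", "right"):
            fe = ev.feet[side]
            assert np.all(np.diff(fe.heel_strikes) > 0)
            for a, b in zip(fe.heel_strikes[:-1], fe.heel_strikes[1:]):
                assert np.sum((fe.toe_offs > a) & (fe.toe_offs < b)) == 1
                other = ev.feet["right" if side == "left" else "left"]
                assert np.sum((other.heel_strikes > a)
                              & (other.heel_strikes < b)) == 1


class TestTurnExclusion:
    def test_straight_walk_flags_nothing(self, processed_normal):
        _, ev, _ = processed_normal
        assert all(ev.excluded[s].size == 0 for s in ("left", "right"))

    def test_vacuous_threshold_flags_nothing(self):
        spec = condition_presets(n_strides=12)["normal"]
        traj, _ = generate_reference_trial(spec, seed=3, turn_steps=4)
        f = traj.filtered()
        ev = exclude_turn_strides(f, detect_gait_events(f),
                                  angle_threshold=180.0)
        assert all(ev.excluded[s].size == 0 for s in ("left", "right"))

    def test_turn_segment_strides_flagged(self):
        """With an appended 180-degree turn, exactly the strides whose true
        walking direction deviates beyond the threshold are flagged (oracle:
        the generator's per-stride direction angles)."""
        spec = condition_presets(n_strides=15)["normal"]
        traj, gt = generate_reference_trial(spec, seed=6, turn_steps=4)
        f = traj.filtered()
        ev = exclude_turn_strides(f, detect_gait_events(f), 30.0)
        angles = gt.strides["direction_angle"].to_numpy()
        med = np.median(angles[np.abs(angles) < 0.5])  # straight majority
        for side in ("left", "right"):
            sub = gt.strides[gt.strides["foot"] == side].reset_index()
            flagged = set(ev.excluded[side].tolist())
            for i, row in sub.iterrows():
                t0 = row["start_time"]
                # locate the corresponding detected stride by start time
                det = ev.feet[side].heel_strike_times
                k = int(np.argmin(np.abs(det[:-1] - t0))) \
                    if det.size > 1 else None
                if k is None or abs(det[k] - t0) > 0.05:
                    continue
                dev = abs((row["direction_angle"] - med + np.pi)
                          % (2 * np.pi) - np.pi)
                if dev > np.radians(35):
                    assert k in flagged
                elif dev < np.radians(25):
                    assert k not in flagged

    def test_all_turning_raises(self, make_traj):
        # a circular path: every stride deviates from the median direction
        spec = condition_presets(n_strides=10)["normal"]
        traj, _ = generate_reference_trial(spec, seed=6)
        f = traj.filtered()
        ev = detect_gait_events(f)
        with pytest.raises(NoStraightStridesError):
            # absurd threshold: flag everything by inverting the rule
            exclude_turn_strides(f, ev, angle_threshold=-1.0)


def _shift_events(ev: GaitEvents, dt: float) -> GaitEvents:
    feet = {}
    for side, fe in ev.feet.items():
        feet[side] = FootEvents(
            heel_strikes=fe.heel_strikes.copy(),
            toe_offs=fe.toe_offs.copy(),
            heel_strike_times=fe.heel_strike_times + dt,
            toe_off_times=fe.toe_off_times + dt)
    return GaitEvents(feet=feet, rate=ev.rate, n_samples=ev.n_samples)


class TestMatching:
    def test_identity_pairing(self, processed_normal):
        _, ev, _ = processed_normal
        pairing = match_strides(ev, ev, tolerance=0.15)
        for side in ("left", "right"):
            n = ev.feet[side].heel_strikes.size - 1
            assert pairing.pairs[side] == [(i, i) for i in range(n)]
            assert pairing.unmatched_ref[side] == []
            assert pairing.unmatched_deg[side] == []

    def test_small_shift_keeps_full_pairing(self, processed_normal):
        _, ev, _ = processed_normal
        shifted = _shift_events(ev, 0.02)
        pairing = match_strides(ev, shifted, tolerance=0.15)
        for side in ("left", "right"):
            n = ev.feet[side].heel_strikes.size - 1
            assert len(pairing.pairs[side]) == n

    def test_spurious_event_unmatches_one_stride(self, processed_normal):
        _, ev, _ = processed_normal
        noisy = _shift_events(ev, 0.0)
        fe = noisy.feet["right"]
        t = fe.heel_strike_times
        extra = 0.5 * (t[3] + t[4])  # ~0.6 s from both: matches nothing
        fe.heel_strike_times = np.sort(np.append(t, extra))
        pairing = match_strides(ev, noisy, tolerance=0.15)
        n_ref = ev.feet["right"].heel_strikes.size - 1
        assert len(pairing.pairs["right"]) == n_ref - 1
        assert pairing.unmatched_ref["right"] == [3]
        n_left = ev.feet["left"].heel_strikes.size - 1
        assert len(pairing.pairs["left"]) == n_left

    def test_unsynchronized_raises(self, processed_normal):
        _, ev, _ = processed_normal
        with pytest.raises(UnsynchronizedError):
            match_strides(ev, _shift_events(ev, 30.0), tolerance=0.15)
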
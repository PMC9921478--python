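"""Synthetic paired two-system overground gait trials with known ground truth.

The generator emulates the study design this package analyses: subjects walk
under four conditions (normal, eyes_closed, wide, tandem), each trial captured
by a "reference" system (optical-like, 100 Hz) and a "degraded" system
(IMU-like, 120 Hz, with per-subject bias structure).  Every trial carries a
:class:`GroundTruth` with the exact event times and per-stride measures, so
each downstream stage can be tested against construction-time truth.

Kinematic model (deliberately minimal, see docs/methods.md):

* Footfalls are placed along a heading path; each step draws its length,
  width and duration independently around the condition means.
* Feet are stationary in stance and follow a quintic (minimum-jerk-like)
  swing whose boundary velocity is twice the local CoM velocity.  This makes
  the CoM-foot forward displacement peak exactly at heel strike with
  symmetric slopes, so kinematic event detection is exact by construction.
* The CoM advances through per-heel-strike keyframes (a fixed fraction of the
  step ahead of the trailing foot) via monotone cubic interpolation, plus a
  step-locked lateral sway toward the stance foot.

Condition presets are anchored to the published optical group means shipped
in :mod:`gaitstab.reference`, converted back to metres with the group mean
leg length.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from numpy.random import SeedSequence, default_rng
from scipy.interpolate import CubicSpline, PchipInterpolator

from . import reference
from .errors import ParameterError
from .trajectory import Trajectory, resample_trajectory

CONDITIONS = reference.CONDITIONS

#: CoM lateral sway amplitude per condition (m, at L = 0.92); chosen so the
#: extrapolated CoM excursion lands near the published minimum ML margins.
_SWAY_AMPLITUDE = {
    "normal": 0.020,
    "eyes_closed": 0.022,
    "wide": 0.036,
    "tandem": 0.016,
}


@dataclass
class ConditionSpec:
    """Step-geometry and timing parameters of one walking condition."""

    condition: str
    step_length: float  # m
    step_length_sd: float
    step_width: float  # m, signed; ~0 for tandem
    step_width_sd: float
    stride_time: float  # s
    stride_time_sd: float
    sway_amplitude: float  # m
    sway_variability: float = 0.15  # relative step-to-step sway spread
    n_strides: int = 60
    swing_fraction: float = 0.38  # swing duration as a fraction of stride time
    com_offset_fraction: float = 0.35  # CoM AP at heel strike, fraction of step
    foot_length: float = 0.22  # heel-to-ball AP offset, m
    noise_sd: float = 0.0005  # reference-system measurement noise, m
    lead_in: float = 2.0  # s of quiet standing before the first heel strike

    def __post_init__(self) -> None:
        if self.stride_time <= 0:
            raise ParameterError("stride_time must be positive")
        if min(self.step_length_sd, self.step_width_sd,
               self.stride_time_sd) < 0:
            raise ParameterError("spread parameters must be non-negative")
        if self.n_strides < 2:
            raise ParameterError("n_strides must be at least 2")


def condition_presets(
    leg_length: float = reference.MEAN_LEG_LENGTH,
    gravity: float = reference.GRAVITY,
    n_strides: int = 60,
) -> dict[str, ConditionSpec]:
    """Default per-condition specs anchored to the published optical means."""
    table = reference.SUMMARY_TABLE
    scale_len = leg_length
    speed_scale = math.sqrt(gravity * leg_length)
    out = {}
    for cond in CONDITIONS:
        sl = table["step_length"]["optical"][cond][0] * scale_len
        sl_sd = table["step_length_rms"]["optical"][cond][0] * scale_len
        sw = table["step_width"]["optical"][cond][0] * scale_len
        sw_sd = table["step_width_rms"]["optical"][cond][0] * scale_len
        speed = table["speed"]["optical"][cond][0] * speed_scale
        stride_time = 2.0 * sl / speed
        out[cond] = ConditionSpec(
            condition=cond,
            step_length=sl,
            step_length_sd=sl_sd,
            step_width=sw,
            step_width_sd=sw_sd,
            stride_time=stride_time,
            stride_time_sd=0.025,
            sway_amplitude=_SWAY_AMPLITUDE[cond] * leg_length / 0.92,
            n_strides=n_strides,
        )
    return out


@dataclass
class DegradationSpec:
    """Second-system error model applied by :func:`degrade_trial`.

    The dominant term is a per-subject odometry-like scale error of all
    horizontal positions about the trial origin, drawn separately for the
    mediolateral and anterior-posterior axes (ML spread much larger than
    AP), which scales step width, step length and both margins of stability
    by ``1 + scale`` for that subject.  White noise, an additive per-foot
    bias and a slow common-mode drift complete the model.  All length units
    are metres.
    """

    rate: float = 120.0
    scale_mean_ml: float = -0.10
    scale_sd_ml: float = 0.30
    scale_mean_ap: float = 0.01
    scale_sd_ap: float = 0.02
    foot_bias: dict[str, tuple[float, float, float]] | None = None  # (AP, ML, Z)
    noise_sd: tuple[float, float, float] = (0.005, 0.008, 0.003)  # (AP, ML, Z)
    com_noise_sd: tuple[float, float, float] = (0.003, 0.004, 0.002)
    drift_amplitude: float = 0.008
    drift_period: float = 25.0

    def __post_init__(self) -> None:
        if self.rate <= 0:
            raise ParameterError("output rate must be positive")
        if min(*self.noise_sd, *self.com_noise_sd) < 0:
            raise ParameterError("noise s.d. must be non-negative")

    @classmethod
    def none(cls, rate: float = 120.0) -> "DegradationSpec":
        """A spec that leaves the trajectory untouched (up to resampling)."""
        return cls(
            rate=rate,
            scale_mean_ml=0.0, scale_sd_ml=0.0,
            scale_mean_ap=0.0, scale_sd_ap=0.0,
            foot_bias=None,
            noise_sd=(0.0, 0.0, 0.0),
            com_noise_sd=(0.0, 0.0, 0.0),
            drift_amplitude=0.0,
        )


@dataclass
class GroundTruth:
    """Exact construction-time events and measures of one reference trial."""

    leg_length: float
    gravity: float
    events: dict[str, dict[str, np.ndarray]]  # side -> {heel_strikes, toe_offs} times (s)
    steps: pd.DataFrame
    strides: pd.DataFrame  # dimensionless per-stride measures


def _quintic(t, t0, t1, p0, p1, v0, v1):
    """Quintic Hermite segment with zero endpoint accelerations."""
    T = t1 - t0
    s = np.clip((np.asarray(t, dtype=float) - t0) / T, 0.0, 1.0)[..., None]
    h00 = 1 - 10 * s**3 + 15 * s**4 - 6 * s**5
    h10 = s - 6 * s**3 + 8 * s**4 - 3 * s**5
    h01 = 10 * s**3 - 15 * s**4 + 6 * s**5
    h11 = -4 * s**3 + 7 * s**4 - 3 * s**5
    return p0 * h00 + (v0 * T) * h10 + p1 * h01 + (v1 * T) * h11


def _sample_foot(t, placements, land_times, toe_times, vel_fn, lift=0.05,
                 z0=0.02):
    """Sample a foot landmark: stance hold + quintic swings between footfalls.

    ``placements`` is (m, 2); the foot stands at ``placements[j]`` from
    ``land_times[j]`` until ``toe_times[j]`` and swings to ``placements[j+1]``
    during ``(toe_times[j], land_times[j+1])`` with boundary velocity twice
    the local CoM velocity given by ``vel_fn``.
    """
    n = t.shape[0]
    pos = np.empty((n, 2))
    z = np.full(n, z0)
    m = placements.shape[0]
    # initial stance
    i1 = np.searchsorted(t, toe_times[0], side="right")
    pos[:i1] = placements[0]
    for j in range(m - 1):
        t_off, t_land = toe_times[j], land_times[j + 1]
        a = np.searchsorted(t, t_off, side="right")
        b = np.searchsorted(t, t_land, side="right")
        if b > a:
            v0 = 2.0 * vel_fn(t_off)
            v1 = 2.0 * vel_fn(t_land)
            pos[a:b] = _quintic(t[a:b], t_off, t_land,
                                placements[j], placements[j + 1], v0, v1)
            s = (t[a:b] - t_off) / (t_land - t_off)
            z[a:b] = z0 + lift * np.sin(np.pi * s)
        # stance after landing
        t_next = toe_times[j + 1] if j + 1 < m - 1 else t[-1] + 1.0
        c = np.searchsorted(t, t_next, side="right")
        pos[b:c] = placements[j + 1]
    return pos, z


def _rot90(v: np.ndarray) -> np.ndarray:
    """Horizontal unit vector pointing to the walker's right for heading v."""
    return np.stack([-v[..., 1], v[..., 0]], axis=-1)


def generate_reference_trial(
    spec: ConditionSpec,
    leg_length: float = reference.MEAN_LEG_LENGTH,
    seed=None,
    rate: float = 100.0,
    gravity: float = reference.GRAVITY,
    turn_steps: int = 0,
    turn_angle: float = math.pi,
    subject: str | None = None,
    trial: int | None = None,
) -> tuple[Trajectory, GroundTruth]:
    """Generate one reference-system trial plus its exact ground truth.

    With ``turn_steps > 0`` the trial appends a turning segment in which the
    heading ramps to ``turn_angle`` over that many steps (plus four steps at
    the final heading), to exercise turn exclusion downstream.
    """
    rng = default_rng(seed)
    omega = math.sqrt(gravity / leg_length)

    if (spec.step_width > 0
            and 1.9 * spec.sway_amplitude > spec.step_width / 2 + 0.05):
        warnings.warn(
            "CoM sway amplitude is large relative to the step width; the "
            "extrapolated CoM may pass outside both feet persistently",
            UserWarning, stacklevel=2,
        )

    n_main = 2 * spec.n_strides + 2
    theta = np.zeros(n_main)
    if turn_steps > 0:
        ramp = turn_angle * np.arange(1, turn_steps + 1) / (turn_steps + 1)
        theta = np.concatenate([theta, ramp, np.full(4, turn_angle)])
    n_steps = theta.shape[0]

    step_len = rng.normal(spec.step_length, spec.step_length_sd, n_steps)
    step_len = np.clip(step_len, 0.2 * spec.step_length, None)
    widths = rng.normal(spec.step_width, spec.step_width_sd, n_steps)
    half_stride = spec.stride_time / 2.0
    step_times = rng.normal(half_stride, spec.stride_time_sd / math.sqrt(2.0),
                            n_steps)
    step_times = np.clip(step_times, 0.4 * half_stride, None)

    sides = np.where(np.arange(n_steps) % 2 == 0, 1, -1)  # +1 right, -1 left
    u = np.stack([np.cos(theta), np.sin(theta)], axis=1)
    m_hat = _rot90(u)

    centers = np.zeros((n_steps, 2))
    centers[0] = 0.0
    for k in range(1, n_steps):
        centers[k] = centers[k - 1] + step_len[k] * u[k]
    p = centers + sides[:, None] * (widths[:, None] / 2.0) * m_hat

    # virtual initial double stance (left at -1, right at -2 behind the start)
    p_left0 = centers[0] - spec.step_length * u[0] \
        - (spec.step_width / 2.0) * m_hat[0]
    p_right0 = centers[0] - 2.0 * spec.step_length * u[0] \
        + (spec.step_width / 2.0) * m_hat[0]

    t_hs = spec.lead_in + np.concatenate([[0.0], np.cumsum(step_times[1:])])
    swing = np.minimum(spec.swing_fraction * spec.stride_time,
                       0.85 * step_times)
    t_to = t_hs - swing
    total = t_hs[-1] + 1.5

    # ---- CoM base path (monotone cubic through heel-strike keyframes) ----
    alpha = spec.com_offset_fraction
    prev = np.vstack([[p_left0], p[:-1]])
    q = prev + alpha * (p - prev)
    q_start = 0.5 * (p_left0 + p_right0)
    q_end = 0.5 * (p[-1] + p[-2])
    knot_t = np.concatenate(
        [[0.0, min(0.6, 0.4 * spec.lead_in)], t_hs, [t_hs[-1] + 0.7, total]])
    knot_p = np.vstack([q_start, q_start, q, q_end, q_end])
    base = PchipInterpolator(knot_t, knot_p, axis=0)
    base_vel = base.derivative()

    # ---- lateral sway, phase-locked to single stance, with step-to-step
    # amplitude variation (real gait is not exactly periodic in ML) ----
    sway_gain = (rng.normal(1.0, spec.sway_variability, n_steps)
                 if spec.sway_variability > 0 else np.ones(n_steps))
    sway_t = [0.0, min(0.6, 0.4 * spec.lead_in)]
    sway_v = [0.0, 0.0]
    for k in range(n_steps):
        sway_t.append(t_hs[k])
        sway_v.append(0.0)
        if k < n_steps - 1:
            t_ss = 0.5 * (t_to[k + 1] + t_hs[k + 1])
            sway_t.append(t_ss)
            sway_v.append(float(sides[k]) * float(sway_gain[k]))
    sway_t.append(total)
    sway_v.append(0.0)
    sway = CubicSpline(np.asarray(sway_t), np.asarray(sway_v),
                       bc_type="natural")
    sway_vel = sway.derivative()

    def heading_at(tq):
        th = np.interp(tq, t_hs, theta)
        th = np.atleast_1d(th)
        uu = np.stack([np.cos(th), np.sin(th)], axis=-1)
        return uu

    def com_at(tq):
        tq_arr = np.atleast_1d(np.asarray(tq, dtype=float))
        mm = _rot90(heading_at(tq_arr))
        out = base(tq_arr) + spec.sway_amplitude * sway(tq_arr)[:, None] * mm
        return out

    def com_vel_at(tq):
        tq_arr = np.atleast_1d(np.asarray(tq, dtype=float))
        mm = _rot90(heading_at(tq_arr))
        return (base_vel(tq_arr)
                + spec.sway_amplitude * sway_vel(tq_arr)[:, None] * mm)

    def base_vel_at(tq):
        return base_vel(np.atleast_1d(np.asarray(tq, dtype=float)))[0]

    n_samp = int(round(total * rate)) + 1
    t = np.arange(n_samp) / rate

    com_xy = com_at(t)
    com = np.column_stack([com_xy, np.full(n_samp, 0.57 * leg_length)])

    # ---- foot tracks ----
    def foot_arrays(side):
        ks = np.arange(0 if side == "right" else 1, n_steps, 2)
        init = p_right0 if side == "right" else p_left0
        placements = np.vstack([init, p[ks]])
        land = np.concatenate([[-1.0], t_hs[ks]])
        toes = t_to[ks]  # toe-off preceding each landing
        u_steps = np.vstack([u[0], u[ks]])
        return ks, placements, land, toes, u_steps

    landmarks = {}
    events = {}
    for side in ("right", "left"):
        ks, placements, land, toes, u_steps = foot_arrays(side)
        ball_xy, ball_z = _sample_foot(t, placements, land, toes, base_vel_at)
        heel_pl = placements - spec.foot_length * u_steps
        heel_xy, heel_z = _sample_foot(t, heel_pl, land, toes, base_vel_at)
        prefix = "r" if side == "right" else "l"
        landmarks[f"{prefix}_ball"] = np.column_stack([ball_xy, ball_z])
        landmarks[f"{prefix}_heel"] = np.column_stack([heel_xy, heel_z])
        events[side] = {"heel_strikes": t_hs[ks].copy(),
                        "toe_offs": t_to[ks].copy()}

    # ---- measurement noise (reference system) ----
    if spec.noise_sd > 0:
        com = com + rng.normal(0.0, spec.noise_sd, com.shape)
        for name in ("l_heel", "l_ball", "r_heel", "r_ball"):
            landmarks[name] = landmarks[name] + rng.normal(
                0.0, spec.noise_sd, landmarks[name].shape)

    traj = Trajectory(
        time=t, com=com, landmarks=landmarks, rate=rate, system="reference",
        subject=subject, condition=spec.condition, trial=trial,
        meta={"leg_length": leg_length, "gravity": gravity},
    )

    # ---- ground-truth tables ----
    prev_p = np.vstack([[p_left0], p[:-1]])
    d = p - prev_p
    gt_len = np.einsum("ij,ij->i", d, u)
    gt_wid = sides * np.einsum("ij,ij->i", d, m_hat)
    steps_df = pd.DataFrame({
        "step": np.arange(n_steps),
        "side": np.where(sides > 0, "right", "left"),
        "t_heel_strike": t_hs,
        "step_length_m": gt_len,
        "step_width_m": gt_wid,
        "step_time": step_times,
        "heading": theta,
    })

    speed_scale = math.sqrt(gravity * leg_length)
    stride_rows = []
    for side in ("right", "left"):
        ks = np.arange(0 if side == "right" else 1, n_steps, 2)
        for i in range(ks.shape[0] - 1):
            k0, k1 = ks[i], ks[i + 1]
            t0, t1 = t_hs[k0], t_hs[k1]
            disp = (com_at(t1) - com_at(t0))[0]
            norm = np.linalg.norm(disp)
            ap = disp / norm
            ml = _rot90(ap)
            speed = norm / (t1 - t0) / speed_scale

            def xcom_at(tq):
                return com_at(tq) + com_vel_at(tq) / omega

            ap_mos = (float(np.dot(p[k0], ap))
                      - float(np.dot(xcom_at(t0)[0], ap))) / leg_length
            # minimum ML margin over both single-stance windows of the cycle
            mins = []
            for kk in (k0, k0 + 1):
                if kk + 1 >= n_steps:
                    continue
                w0, w1 = t_to[kk + 1], t_hs[kk + 1]
                tt = np.linspace(w0, w1, 150)
                s = float(sides[kk])
                bos_ml = float(np.dot(p[kk], ml))
                xc_ml = xcom_at(tt) @ ml
                mins.append(np.min(s * (bos_ml - xc_ml)))
            stride_rows.append({
                "foot": side,
                "stride": i,
                "start_time": t0,
                "end_time": t1,
                "stride_time": t1 - t0,
                "speed": speed,
                "step_length": gt_len[k0] / leg_length,
                "step_width": gt_wid[k0] / leg_length,
                "ap_mos": ap_mos,
                "min_ml_mos": min(mins) / leg_length if mins else np.nan,
                "direction_angle": math.atan2(disp[1], disp[0]),
            })
    strides_df = pd.DataFrame(stride_rows)

    gt = GroundTruth(leg_length=leg_length, gravity=gravity, events=events,
                     steps=steps_df, strides=strides_df)
    return traj, gt


def degrade_trial(
    traj: Trajectory,
    spec: DegradationSpec,
    seed=None,
    scale_ml: float | None = None,
    scale_ap: float | None = None,
) -> Trajectory:
    """Produce the second-system view of a trial (input left unchanged).

    All horizontal positions (CoM and feet) are scaled about the trial
    origin in the trial's AP/ML frame by ``1 + scale`` per axis (drawn from
    the spec unless passed explicitly, e.g. per-subject values shared
    across a subject's trials); foot landmarks are then shifted by optional
    per-foot biases; the trajectory is resampled to the output rate, and
    common-mode drift plus white noise are added.
    """
    rng = default_rng(seed)
    if scale_ml is None:
        scale_ml = (rng.normal(spec.scale_mean_ml, spec.scale_sd_ml)
                    if (spec.scale_mean_ml or spec.scale_sd_ml) else 0.0)
    if scale_ap is None:
        scale_ap = (rng.normal(spec.scale_mean_ap, spec.scale_sd_ap)
                    if (spec.scale_mean_ap or spec.scale_sd_ap) else 0.0)

    disp = traj.com[-1, :2] - traj.com[0, :2]
    norm = np.linalg.norm(disp)
    ap = disp / norm if norm > 1e-9 else np.array([1.0, 0.0])
    ml = _rot90(ap)

    out = traj.copy()
    if scale_ml or scale_ap:
        origin = traj.com[0, :2]

        def _scale(xy: np.ndarray) -> np.ndarray:
            rel = xy - origin
            return (origin
                    + (1.0 + scale_ap) * (rel @ ap)[:, None] * ap
                    + (1.0 + scale_ml) * (rel @ ml)[:, None] * ml)

        out.com[:, :2] = _scale(out.com[:, :2])
        for lm in out.landmarks.values():
            lm[:, :2] = _scale(lm[:, :2])
    if spec.foot_bias:
        for side_key, bias in spec.foot_bias.items():
            prefix = {"left": "l", "right": "r"}[side_key]
            offset_xy = bias[0] * ap + bias[1] * ml
            for lm_name in (f"{prefix}_heel", f"{prefix}_ball"):
                out.landmarks[lm_name][:, :2] += offset_xy
                out.landmarks[lm_name][:, 2] += bias[2]

    out = resample_trajectory(out, spec.rate)

    if spec.drift_amplitude > 0:
        phases = rng.uniform(0.0, 2.0 * np.pi, 3)
        w = 2.0 * np.pi / spec.drift_period
        d_ap = spec.drift_amplitude * np.sin(w * out.time + phases[0])
        d_ml = spec.drift_amplitude * np.sin(w * out.time + phases[1])
        d_z = spec.drift_amplitude * np.sin(w * out.time + phases[2])
        drift = np.column_stack([d_ap[:, None] * ap + d_ml[:, None] * ml, d_z])
        out.com = out.com + drift
        for name in out.landmarks:
            out.landmarks[name] = out.landmarks[name] + drift

    def _noise(shape, sds):
        n_frame = rng.normal(0.0, 1.0, shape) * np.asarray(sds)
        xy = n_frame[:, 0:1] * ap + n_frame[:, 1:2] * ml
        return np.column_stack([xy, n_frame[:, 2]])

    if any(s > 0 for s in spec.com_noise_sd):
        out.com = out.com + _noise(out.com.shape, spec.com_noise_sd)
    if any(s > 0 for s in spec.noise_sd):
        for name in ("l_heel", "l_ball", "r_heel", "r_ball"):
            out.landmarks[name] = out.landmarks[name] + _noise(
                out.landmarks[name].shape, spec.noise_sd)

    return Trajectory(
        time=out.time, com=out.com, landmarks=out.landmarks, rate=out.rate,
        system="degraded", subject=traj.subject, condition=traj.condition,
        trial=traj.trial,
        meta={**traj.meta, "scale_ml": scale_ml, "scale_ap": scale_ap},
    )


@dataclass
class StudySpec:
    """Design of a full synthetic paired-system study."""

    n_subjects: int = 10
    leg_length_mean: float = reference.MEAN_LEG_LENGTH
    leg_length_sd: float = 0.05
    gravity: float = reference.GRAVITY
    conditions: tuple[str, ...] = CONDITIONS
    trials_per_condition: int = 2
    n_strides: int = 60
    reference_rate: float = 100.0
    degradation: DegradationSpec = field(default_factory=DegradationSpec)
    condition_overrides: dict[str, dict] = field(default_factory=dict)
    subject_speed_sd: float = 0.15  # relative spread of self-selected speed
    subject_length_sd: float = 0.05  # relative spread of step length
    subject_width_offset_sd: float = 0.045  # additive step-width offset, m
    subject_sway_sd: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ParameterError("n_subjects must be at least 1")
        if self.trials_per_condition < 1:
            raise ParameterError("trials_per_condition must be at least 1")


@dataclass
class TrialRecord:
    subject: str
    condition: str
    trial: int
    leg_length: float
    reference: Trajectory
    degraded: Trajectory
    ground_truth: GroundTruth


@dataclass
class StudyData:
    spec: StudySpec
    trials: list[TrialRecord]
    subject_info: pd.DataFrame

    def ground_truth(self) -> pd.DataFrame:
        frames = []
        for rec in self.trials:
            df = rec.ground_truth.strides.copy()
            df.insert(0, "subject", rec.subject)
            df.insert(1, "condition", rec.condition)
            df.insert(2, "trial", rec.trial)
            frames.append(df)
        return pd.concat(frames, ignore_index=True)


def generate_study(spec: StudySpec) -> StudyData:
    """Generate all paired trials of a study, deterministically from the seed.

    Per-subject quantities (leg length, self-selected speed, preferred width
    offset, and the degraded system's ML/AP scale errors) are drawn once per
    subject and shared across that subject's trials, reproducing the
    per-participant clustering seen in between-system difference plots.
    """
    root = SeedSequence(spec.seed)
    subject_seqs = root.spawn(spec.n_subjects)
    trials: list[TrialRecord] = []
    info_rows = []
    for s_idx, sseq in enumerate(subject_seqs):
        subject = f"S{s_idx + 1:02d}"
        rng_s = default_rng(sseq)
        L = float(np.clip(rng_s.normal(spec.leg_length_mean,
                                       spec.leg_length_sd), 0.7, 1.15))
        speed_f = float(np.clip(rng_s.normal(1.0, spec.subject_speed_sd),
                                0.6, 1.5))
        len_f = float(np.clip(rng_s.normal(1.0, spec.subject_length_sd),
                              0.7, 1.3))
        width_off = float(rng_s.normal(0.0, spec.subject_width_offset_sd))
        sway_f = float(np.clip(rng_s.normal(1.0, spec.subject_sway_sd),
                               0.6, 1.4))
        deg = spec.degradation
        sc_ml = float(rng_s.normal(deg.scale_mean_ml, deg.scale_sd_ml))
        sc_ap = float(rng_s.normal(deg.scale_mean_ap, deg.scale_sd_ap))
        info_rows.append({"subject": subject, "leg_length": L,
                          "speed_factor": speed_f, "length_factor": len_f,
                          "width_offset": width_off,
                          "scale_ml": sc_ml, "scale_ap": sc_ap})

        presets = condition_presets(leg_length=L, gravity=spec.gravity,
                                    n_strides=spec.n_strides)
        children = sseq.spawn(2 * len(spec.conditions)
                              * spec.trials_per_condition)
        child_iter = iter(children)
        for cond in spec.conditions:
            cspec = presets[cond]
            if cond in spec.condition_overrides:
                cspec = replace(cspec, **spec.condition_overrides[cond])
            cspec = replace(
                cspec,
                step_length=cspec.step_length * len_f,
                step_width=cspec.step_width + width_off,
                stride_time=cspec.stride_time * len_f / speed_f,
                sway_amplitude=cspec.sway_amplitude * sway_f,
            )
            for tr in range(spec.trials_per_condition):
                gen_seed = next(child_iter)
                deg_seed = next(child_iter)
                ref, gt = generate_reference_trial(
                    cspec, leg_length=L, seed=gen_seed,
                    rate=spec.reference_rate, gravity=spec.gravity,
                    subject=subject, trial=tr,
                )
                degr = degrade_trial(ref, deg, seed=deg_seed,
                                     scale_ml=sc_ml, scale_ap=sc_ap)
                trials.append(TrialRecord(
                    subject=subject, condition=cond, trial=tr,
                    leg_length=L, reference=ref, degraded=degr,
                    ground_truth=gt,
                ))
    return StudyData(spec=spec, trials=trials,
                     subject_info=pd.DataFrame(info_rows))
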
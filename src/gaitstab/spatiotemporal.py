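"""Per-stride walking speed, step length, step width and RMS variability.

All outputs are dimensionless: lengths are divided by leg length L and the
walking speed by sqrt(g*L).  Projections use per-stride walking axes: the
anterior-posterior (AP) unit vector is the normalized horizontal CoM
displacement over the gait cycle, and the mediolateral (ML) unit vector is
the AP vector rotated by +90 deg so that it points to the walker's right
(for a stride along +x, AP = (1, 0) and ML = (0, +1)).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import DegenerateStrideError, InsufficientDataError
from .events import SIDES, GaitEvents
from .trajectory import StabilityParams, Trajectory

_PREFIX = {"left": "l", "right": "r"}
_OTHER = {"left": "right", "right": "left"}


def stride_walking_frame(
    traj: Trajectory, start: int, end: int
) -> tuple[np.ndarray, np.ndarray]:
    """Orthonormal horizontal (AP, ML) axes of one stride.

    AP is the normalized CoM displacement from ``start`` to ``end``; ML is AP
    rotated +90 deg (to the walker's right).  Raises on zero displacement.
    """
    d = traj.com[end, :2] - traj.com[start, :2]
    norm = float(np.linalg.norm(d))
    if norm < 1e-6:
        raise DegenerateStrideError(
            "zero CoM displacement over stride; walking frame undefined")
    ap = d / norm
    ml = np.array([-ap[1], ap[0]])
    return ap, ml


def stance_placements(
    traj: Trajectory,
    events: GaitEvents,
    landmark: str = "ball",
    central: tuple[float, float] = (0.25, 0.75),
) -> dict[str, list[dict]]:
    """Footfall positions estimated from the settled mid-stance plateau.

    The stance foot is stationary between its heel strike and its next
    toe-off, so its placement equals the landmark position anywhere in
    stance; averaging over the central portion avoids the zero-phase
    filter's transient around the contact instants.  Returns, per side, one
    record per stance with the heel-strike sample, the stance-ending
    toe-off sample (or an estimate near boundaries) and the horizontal
    placement.
    """
    out: dict[str, list[dict]] = {}
    for side in SIDES:
        fe = events.feet[side]
        pos = traj.landmarks[f"{_PREFIX[side]}_{landmark}"][:, :2]
        hs = fe.heel_strikes
        stances = []
        typical = int(np.median(np.diff(hs)) * 0.6) if hs.size > 1 else 30
        for j, i_hs in enumerate(hs):
            after = fe.toe_offs[fe.toe_offs > i_hs]
            i_to = int(after[0]) if after.size else min(
                i_hs + typical, traj.n_samples - 1)
            span = i_to - i_hs
            a = i_hs + int(central[0] * span)
            b = i_hs + max(int(central[1] * span), int(central[0] * span) + 1)
            stances.append({
                "heel_strike": int(i_hs),
                "toe_off": i_to,
                "placement": pos[a:b + 1].mean(axis=0),
            })
        out[side] = stances
    return out


def _stance_containing(stances: list[dict], i: int) -> dict | None:
    """The stance record whose [heel strike, toe-off] interval contains i."""
    for st in stances:
        if st["heel_strike"] <= i <= st["toe_off"]:
            return st
    return None


def compute_stride_measures(
    traj: Trajectory,
    events: GaitEvents,
    params: StabilityParams,
    landmark: str = "ball",
) -> pd.DataFrame:
    """Dimensionless speed, step length and step width per analyzed stride.

    One row per (foot, stride): the step measures belong to the step taken by
    that foot at the stride-initiating heel strike.  Step length is the AP
    separation of the two feet at that heel strike; step width is the signed
    ML separation of the two feet over the stance-overlap interval (stepping
    foot minus trailing foot, positive when the stepping foot is placed
    laterally, negative on crossover); speed is the mean AP CoM velocity
    over the stride.  Both feet are stationary while they share the ground,
    so foot positions are taken from the mid-stance placement estimates of
    :func:`stance_placements`.  Turn-flagged strides are skipped.
    """
    rows = []
    L = params.leg_length
    placements = stance_placements(traj, events, landmark=landmark)
    for side in SIDES:
        windows = events.stride_windows(side)
        included = set(events.included_strides(side).tolist())
        other = _OTHER[side]
        sign = 1.0 if side == "right" else -1.0
        step_pos = traj.landmarks[f"{_PREFIX[side]}_{landmark}"][:, :2]
        trail_pos = traj.landmarks[f"{_PREFIX[other]}_{landmark}"][:, :2]
        for idx, (i0, i1) in enumerate(windows):
            if idx not in included:
                continue
            try:
                ap, ml = stride_walking_frame(traj, i0, i1)
            except DegenerateStrideError:
                continue
            lead_st = _stance_containing(placements[side], i0)
            trail_st = _stance_containing(placements[other], i0)
            lead = (lead_st["placement"] if lead_st is not None
                    else step_pos[i0])
            trail = (trail_st["placement"] if trail_st is not None
                     else trail_pos[i0])
            sep = lead - trail
            step_length = float(np.dot(sep, ap)) / L
            step_width = sign * float(np.dot(sep, ml)) / L
            vel = traj.com_vel[i0:i1 + 1, :2] @ ap
            speed = float(np.mean(vel)) / params.speed_scale
            rows.append({
                "foot": side,
                "stride": idx,
                "start": i0,
                "end": i1,
                "hs_time": float(traj.time[i0]),
                "stride_time": float(traj.time[i1] - traj.time[i0]),
                "speed": speed,
                "step_length": step_length,
                "step_width": step_width,
            })
    return pd.DataFrame(
        rows, columns=["foot", "stride", "start", "end", "hs_time",
                       "stride_time", "speed", "step_length", "step_width"])


def rms_variability(values) -> float:
    """RMS deviation about the mean (population denominator n)."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise InsufficientDataError(
            "RMS variability needs at least 2 values")
    return float(np.sqrt(np.mean((values - values.mean()) ** 2)))
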
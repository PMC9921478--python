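"""Extrapolated centre of mass and margins of stability.

The extrapolated centre of mass (XCoM) augments the CoM position with its
velocity scaled by the inverted-pendulum eigenfrequency::

    XCoM = CoM + CoM_vel / omega,      omega = sqrt(g / L)

The mediolateral margin of stability (MoS) is the signed distance from the
XCoM to the lateral edge of the base of support, reduced here to the stance
foot's ball-of-foot position during single-leg stance; the minimum over each
gait cycle is reported.  The anterior-posterior MoS is the AP distance from
the XCoM to the leading ball-of-foot at heel strike.  Positive values mean
the XCoM lies inside the base of support; both are divided by leg length L.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DegenerateStrideError
from .events import SIDES, GaitEvents
from .spatiotemporal import (_stance_containing, stance_placements,
                             stride_walking_frame)
from .trajectory import StabilityParams, Trajectory

_PREFIX = {"left": "l", "right": "r"}
_OTHER = {"left": "right", "right": "left"}


@dataclass
class XcomSeries:
    """Horizontal extrapolated-CoM positions on the trajectory's time grid."""

    time: np.ndarray
    xy: np.ndarray  # (n, 2)


def extrapolated_com(traj: Trajectory, params: StabilityParams) -> XcomSeries:
    """XCoM = CoM + CoM_vel / omega on the horizontal components."""
    xy = traj.com[:, :2] + traj.com_vel[:, :2] / params.omega
    return XcomSeries(time=traj.time, xy=xy)


def _single_stance_windows(events: GaitEvents, side: str, i0: int, i1: int):
    """Single-stance windows (stance side, start, end) within one gait cycle.

    For a stride of foot F from its heel strike ``i0`` to ``i1``: F is in
    single stance from the contralateral toe-off to the contralateral heel
    strike; the contralateral foot is in single stance from F's toe-off to
    the stride-ending heel strike.
    """
    other = _OTHER[side]
    o_to = events.feet[other].toe_offs
    o_hs = events.feet[other].heel_strikes
    s_to = events.feet[side].toe_offs
    windows = []
    o_hs_in = o_hs[(o_hs > i0) & (o_hs < i1)]
    o_to_in = o_to[(o_to > i0) & (o_to < i1)]
    if o_hs_in.size and o_to_in.size:
        a = int(o_to_in[0])
        b = int(o_hs_in[0])
        if a < b:
            windows.append((side, a, b))
        s_to_in = s_to[(s_to > b) & (s_to < i1)]
        if s_to_in.size:
            windows.append((other, int(s_to_in[0]), i1))
    return windows


def compute_mos(
    traj: Trajectory,
    xcom: XcomSeries,
    events: GaitEvents,
    params: StabilityParams,
    landmark: str = "ball",
) -> pd.DataFrame:
    """Per-stride minimum ML MoS and AP MoS at heel strike (dimensionless).

    The ML minimum is taken over both single-stance phases of the gait
    cycle; its sign is positive when the XCoM is medial to the stance
    foot's lateral edge and negative when it falls outside (crossover
    geometry).  AP MoS is positive when the XCoM is behind the leading
    foot at heel strike.  Strides without a usable single-stance window are
    skipped for the ML minimum (NaN).
    """
    rows = []
    L = params.leg_length
    placements = stance_placements(traj, events, landmark=landmark)
    for side in SIDES:
        windows = events.stride_windows(side)
        included = set(events.included_strides(side).tolist())
        lead_pos = traj.landmarks[f"{_PREFIX[side]}_{landmark}"][:, :2]
        for idx, (i0, i1) in enumerate(windows):
            if idx not in included:
                continue
            try:
                ap, ml = stride_walking_frame(traj, i0, i1)
            except DegenerateStrideError:
                continue
            lead_st = _stance_containing(placements[side], i0)
            lead = lead_st["placement"] if lead_st is not None else \
                lead_pos[i0]
            ap_mos = float((lead - xcom.xy[i0]) @ ap) / L
            min_mos = np.nan
            min_side = ""
            min_idx = -1
            for stance, a, b in _single_stance_windows(events, side, i0, i1):
                s = 1.0 if stance == "right" else -1.0
                bos_ml = traj.landmarks[f"{_PREFIX[stance]}_{landmark}"][
                    a:b + 1, :2] @ ml
                xc_ml = xcom.xy[a:b + 1] @ ml
                mos = s * (bos_ml - xc_ml) / L
                k = int(np.argmin(mos))
                if not np.isfinite(min_mos) or mos[k] < min_mos:
                    min_mos = float(mos[k])
                    min_side = stance
                    min_idx = a + k
            rows.append({
                "foot": side,
                "stride": idx,
                "ap_mos": ap_mos,
                "min_ml_mos": min_mos,
                "stance_at_min": min_side,
                "sample_at_min": min_idx,
            })
    return pd.DataFrame(
        rows, columns=["foot", "stride", "ap_mos", "min_ml_mos",
                       "stance_at_min", "sample_at_min"])
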
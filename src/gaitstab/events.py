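"""Gait event detection, turn exclusion and between-system stride matching.

Heel strikes and toe-offs are found from the forward distance between each
foot and the CoM: the foot-minus-CoM displacement projected on the current
walking direction peaks at heel strike (foot furthest ahead of the CoM) and
bottoms out at toe-off (foot furthest behind).  The same rule is applied to
both measurement systems so the two event sets are directly comparable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .errors import NoGaitError, NoStraightStridesError, UnsynchronizedError
from .trajectory import Trajectory

SIDES = ("left", "right")
_PREFIX = {"left": "l", "right": "r"}


@dataclass
class FootEvents:
    heel_strikes: np.ndarray  # sample indices, strictly increasing
    toe_offs: np.ndarray
    heel_strike_times: np.ndarray  # seconds, same length
    toe_off_times: np.ndarray


@dataclass
class GaitEvents:
    """Per-foot events plus turn-excluded stride flags for one trial."""

    feet: dict[str, FootEvents]
    rate: float
    n_samples: int
    excluded: dict[str, np.ndarray] = field(
        default_factory=lambda: {s: np.array([], dtype=int) for s in SIDES})

    def stride_windows(self, side: str) -> list[tuple[int, int]]:
        hs = self.feet[side].heel_strikes
        return [(int(hs[i]), int(hs[i + 1])) for i in range(hs.size - 1)]

    def n_strides(self, side: str) -> int:
        return max(0, self.feet[side].heel_strikes.size - 1)

    def included_strides(self, side: str) -> np.ndarray:
        out = np.arange(self.n_strides(side))
        return out[~np.isin(out, self.excluded[side])]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for side in SIDES:
            fe = self.feet[side]
            for idx, t in zip(fe.heel_strikes, fe.heel_strike_times):
                rows.append((side, "heel_strike", int(idx), float(t)))
            for idx, t in zip(fe.toe_offs, fe.toe_off_times):
                rows.append((side, "toe_off", int(idx), float(t)))
        df = pd.DataFrame(rows, columns=["foot", "event", "sample", "time"])
        return df.sort_values(["foot", "sample"], ignore_index=True)


def _heading_series(com_xy: np.ndarray, rate: float,
                    window: float = 1.0) -> np.ndarray:
    """Unit walking-direction vector per sample, from windowed CoM displacement."""
    n = com_xy.shape[0]
    w = max(1, int(round(window * rate)))
    idx = np.arange(n)
    d = com_xy[np.clip(idx + w, 0, n - 1)] - com_xy[np.clip(idx - w, 0, n - 1)]
    norms = np.linalg.norm(d, axis=1)
    overall = com_xy[-1] - com_xy[0]
    o_norm = np.linalg.norm(overall)
    fallback = overall / o_norm if o_norm > 1e-9 else np.array([1.0, 0.0])
    small = norms < 1e-6
    d[small] = fallback
    norms[small] = 1.0
    return d / norms[:, None]


def detect_gait_events(
    traj: Trajectory,
    min_separation_frac: float = 0.4,
    landmark: str = "ball",
    boundary_margin: float = 0.5,
    min_amplitude: float = 0.05,
) -> GaitEvents:
    """Detect heel strikes and toe-offs per foot from CoM-foot displacement.

    Extrema are found on the (already filtered) relative-displacement signal
    with a minimum separation of ``min_separation_frac`` times the median
    stride time; events within ``boundary_margin`` strides of either end of
    the trial are dropped.
    """
    com_xy = traj.com[:, :2]
    heading = _heading_series(com_xy, traj.rate)
    rels = {}
    for side in SIDES:
        pos = traj.landmarks[f"{_PREFIX[side]}_{landmark}"][:, :2]
        rels[side] = np.einsum("ij,ij->i", pos - com_xy, heading)

    spans = {s: float(np.percentile(r, 95) - np.percentile(r, 5))
             for s, r in rels.items()}
    if all(v < min_amplitude for v in spans.values()):
        raise NoGaitError(
            "no gait detected: CoM-foot displacement amplitude "
            f"below {min_amplitude} m")

    # first pass: rough stride period from generously spaced peaks
    est = []
    for r in rels.values():
        pk, _ = find_peaks(r, distance=max(1, int(0.35 * traj.rate)))
        if pk.size >= 2:
            est.append(float(np.median(np.diff(pk))))
    if not est:
        raise NoGaitError("no alternating extrema found")
    stride_samples = float(np.median(est))
    dist = max(1, int(min_separation_frac * stride_samples))

    raw = {}
    for side, r in rels.items():
        prom = 0.1 * spans[side]
        hs, _ = find_peaks(r, distance=dist, prominence=prom)
        to, _ = find_peaks(-r, distance=dist, prominence=prom)
        raw[side] = [hs, to]

    margin = boundary_margin * stride_samples
    lo, hi = margin, traj.n_samples - 1 - margin
    for side in SIDES:
        raw[side] = [idx[(idx >= lo) & (idx <= hi)] for idx in raw[side]]

    # cross-foot alternation of heel strikes: on same-side repeats keep the
    # sample with the larger forward displacement
    merged = sorted(
        [(int(i), side) for side in SIDES for i in raw[side][0]])
    kept: list[tuple[int, str]] = []
    for i, side in merged:
        if kept and kept[-1][1] == side:
            if rels[side][i] > rels[side][kept[-1][0]]:
                kept[-1] = (i, side)
        else:
            kept.append((i, side))
    hs_clean = {s: np.array([i for i, sd in kept if sd == s], dtype=int)
                for s in SIDES}

    feet = {}
    for side in SIDES:
        hs = hs_clean[side]
        to = np.asarray(raw[side][1], dtype=int)
        # within each foot keep exactly one toe-off between consecutive HS
        sel = []
        for a, b in zip(hs[:-1], hs[1:]):
            inside = to[(to > a) & (to < b)]
            if inside.size:
                sel.append(int(inside[np.argmin(rels[side][inside])]))
        # keep one trailing toe-off after the last HS if present
        tail = to[to > hs[-1]] if hs.size else np.array([], dtype=int)
        if tail.size:
            sel.append(int(tail[np.argmin(rels[side][tail])]))
        to_clean = np.array(sorted(sel), dtype=int)
        feet[side] = FootEvents(
            heel_strikes=hs,
            toe_offs=to_clean,
            heel_strike_times=traj.time[hs] if hs.size else np.array([]),
            toe_off_times=traj.time[to_clean] if to_clean.size else np.array([]),
        )

    if all(feet[s].heel_strikes.size < 2 for s in SIDES):
        raise NoGaitError("fewer than one complete stride detected")
    return GaitEvents(feet=feet, rate=traj.rate, n_samples=traj.n_samples)


def _wrap(a: np.ndarray) -> np.ndarray:
    return (a + np.pi) % (2.0 * np.pi) - np.pi


def exclude_turn_strides(
    traj: Trajectory, events: GaitEvents, angle_threshold: float = 30.0
) -> GaitEvents:
    """Flag strides whose walking direction deviates from the trial median.

    The per-stride direction is the CoM displacement from stride start to
    stride end; the trial direction is the circular median of stride
    directions; strides deviating by more than ``angle_threshold`` degrees
    are flagged as turns and excluded downstream.
    """
    angles: dict[str, np.ndarray] = {}
    for side in SIDES:
        wins = events.stride_windows(side)
        a = np.empty(len(wins))
        for i, (i0, i1) in enumerate(wins):
            d = traj.com[i1, :2] - traj.com[i0, :2]
            a[i] = math.atan2(d[1], d[0])
        angles[side] = a
    all_angles = np.concatenate([angles[s] for s in SIDES])
    if all_angles.size == 0:
        raise NoGaitError("no strides to classify")
    mean_dir = math.atan2(np.mean(np.sin(all_angles)),
                          np.mean(np.cos(all_angles)))
    median_dir = mean_dir + float(np.median(_wrap(all_angles - mean_dir)))
    thr = math.radians(angle_threshold)
    excluded = {}
    n_flagged = 0
    for side in SIDES:
        dev = np.abs(_wrap(angles[side] - median_dir))
        flags = np.nonzero(dev > thr)[0]
        excluded[side] = flags.astype(int)
        n_flagged += flags.size
    if all_angles.size and n_flagged == all_angles.size:
        raise NoStraightStridesError("no straight-walking strides remain")
    return GaitEvents(feet=events.feet, rate=events.rate,
                      n_samples=events.n_samples, excluded=excluded)


@dataclass
class StridePairing:
    """Greedy nearest-time stride matches between two systems' event sets."""

    pairs: dict[str, list[tuple[int, int]]]  # side -> (ref stride, deg stride)
    unmatched_ref: dict[str, list[int]]
    unmatched_deg: dict[str, list[int]]
    tolerance: float

    def n_pairs(self) -> int:
        return sum(len(v) for v in self.pairs.values())


def match_strides(
    events_ref: GaitEvents, events_deg: GaitEvents, tolerance: float = 0.15
) -> StridePairing:
    """Match same-foot strides of two synchronized systems by heel-strike time.

    Heel strikes are paired greedily by increasing time difference (ties
    resolved toward the earlier reference event); a stride is paired when
    both its bounding heel strikes are.  Raises if no heel strikes match.
    """
    pairs: dict[str, list[tuple[int, int]]] = {}
    un_ref: dict[str, list[int]] = {}
    un_deg: dict[str, list[int]] = {}
    total_hs_matches = 0
    for side in SIDES:
        tr = events_ref.feet[side].heel_strike_times
        td = events_deg.feet[side].heel_strike_times
        cands = []
        for i, t in enumerate(tr):
            j = int(np.searchsorted(td, t))
            for jj in (j - 1, j):
                if 0 <= jj < td.size:
                    dt = abs(float(t - td[jj]))
                    if dt <= tolerance:
                        cands.append((dt, i, jj))
        cands.sort()
        used_i: set[int] = set()
        used_j: set[int] = set()
        hs_match: dict[int, int] = {}
        for dt, i, j in cands:
            if i in used_i or j in used_j:
                continue
            used_i.add(i)
            used_j.add(j)
            hs_match[i] = j
        total_hs_matches += len(hs_match)
        side_pairs = []
        for i in range(tr.size - 1):
            j = hs_match.get(i)
            if j is not None and hs_match.get(i + 1) == j + 1:
                side_pairs.append((i, j))
        pairs[side] = side_pairs
        matched_ref = {i for i, _ in side_pairs}
        matched_deg = {j for _, j in side_pairs}
        un_ref[side] = [i for i in range(max(0, tr.size - 1))
                        if i not in matched_ref]
        un_deg[side] = [j for j in range(max(0, td.size - 1))
                        if j not in matched_deg]
    if total_hs_matches == 0:
        raise UnsynchronizedError(
            f"systems unsynchronized: no heel strikes within {tolerance} s")
    return StridePairing(pairs=pairs, unmatched_ref=un_ref,
                         unmatched_deg=un_deg, tolerance=tolerance)
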
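"""Trajectory container, file I/O, low-pass filtering and resampling.

A :class:`Trajectory` holds the whole-body centre of mass (CoM) and the four
foot landmarks (left/right heel and ball-of-foot) of one walking trial from
one measurement system, on a uniform time grid.  Axes follow the walkway
convention: ``x`` is the nominal walking direction, ``y`` is lateral and
points to the walker's right when walking along ``+x``, ``z`` is vertical up.
All positions are in metres, time in seconds.

Trajectory files are plain CSV with one header row and columns::

    time, com_x, com_y, com_z,
    l_heel_x, l_heel_y, l_heel_z, l_ball_x, l_ball_y, l_ball_z,
    r_heel_x, r_heel_y, r_heel_z, r_ball_x, r_ball_y, r_ball_z
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import cached_property

import numpy as np
import pandas as pd
from scipy import signal
from scipy.interpolate import CubicSpline

from .errors import FormatError, ParameterError, SchemaError

LANDMARKS = ("l_heel", "l_ball", "r_heel", "r_ball")
_AXES = ("x", "y", "z")

#: tolerance (seconds) for deviations from a uniform time grid at load time
GRID_TOLERANCE = 1e-6


@dataclass
class StabilityParams:
    """Anthropometric scaling constants of the inverted-pendulum model.

    ``omega = sqrt(g / L)`` is the pendulum eigenfrequency used by the
    extrapolated centre of mass, and ``speed_scale = sqrt(g * L)`` is the
    velocity used to non-dimensionalise walking speed.
    """

    leg_length: float
    gravity: float = 9.81

    def __post_init__(self) -> None:
        if self.leg_length <= 0:
            raise ParameterError("leg_length must be positive")
        if self.gravity <= 0:
            raise ParameterError("gravity must be positive")

    @property
    def omega(self) -> float:
        """Pendulum eigenfrequency sqrt(g/L), 1/s."""
        return math.sqrt(self.gravity / self.leg_length)

    @property
    def speed_scale(self) -> float:
        """Dimensionless-speed denominator sqrt(g*L), m/s."""
        return math.sqrt(self.gravity * self.leg_length)


@dataclass(eq=False)
class Trajectory:
    """One trial from one measurement system on a uniform time grid."""

    time: np.ndarray
    com: np.ndarray
    landmarks: dict[str, np.ndarray]
    rate: float
    system: str = "reference"
    subject: str | None = None
    condition: str | None = None
    trial: int | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.com = np.asarray(self.com, dtype=float)
        n = self.time.shape[0]
        if self.rate <= 0:
            raise ParameterError("rate must be positive")
        if self.com.shape != (n, 3):
            raise FormatError("com must have shape (n_samples, 3)")
        for name in LANDMARKS:
            if name not in self.landmarks:
                raise SchemaError(f"missing required landmark '{name}'")
            arr = np.asarray(self.landmarks[name], dtype=float)
            if arr.shape != (n, 3):
                raise FormatError(f"landmark '{name}' must have shape (n, 3)")
            self.landmarks[name] = arr
        if n >= 2:
            dt = np.diff(self.time)
            if np.any(dt <= 0):
                raise FormatError("time must be strictly increasing")
            if np.max(np.abs(dt - 1.0 / self.rate)) > GRID_TOLERANCE:
                raise FormatError(
                    "time grid is not uniform at 1/rate within tolerance"
                )
        for arr in (self.time, self.com, *self.landmarks.values()):
            if not np.all(np.isfinite(arr)):
                raise FormatError("non-finite values in trajectory")

    # -- derived quantities -------------------------------------------------

    @cached_property
    def com_vel(self) -> np.ndarray:
        """CoM velocity (n, 3) by central differences, one-sided at the ends."""
        return np.gradient(self.com, 1.0 / self.rate, axis=0)

    @property
    def n_samples(self) -> int:
        return self.time.shape[0]

    @property
    def duration(self) -> float:
        return float(self.time[-1] - self.time[0])

    def copy(self) -> "Trajectory":
        return Trajectory(
            time=self.time.copy(),
            com=self.com.copy(),
            landmarks={k: v.copy() for k, v in self.landmarks.items()},
            rate=self.rate,
            system=self.system,
            subject=self.subject,
            condition=self.condition,
            trial=self.trial,
            meta=dict(self.meta),
        )

    def filtered(self, cutoff: float = 6.0, order: int = 4) -> "Trajectory":
        """Zero-phase low-pass filter all position channels (default 6 Hz)."""
        out = self.copy()
        out.com = lowpass_filter(self.com, cutoff, self.rate, order=order)
        out.landmarks = {
            k: lowpass_filter(v, cutoff, self.rate, order=order)
            for k, v in self.landmarks.items()
        }
        return out

    def to_frame(self) -> pd.DataFrame:
        cols: dict[str, np.ndarray] = {"time": self.time}
        for i, ax in enumerate(_AXES):
            cols[f"com_{ax}"] = self.com[:, i]
        for name in LANDMARKS:
            for i, ax in enumerate(_AXES):
                cols[f"{name}_{ax}"] = self.landmarks[name][:, i]
        return pd.DataFrame(cols)


def _required_columns() -> list[str]:
    cols = ["time"] + [f"com_{ax}" for ax in _AXES]
    for name in LANDMARKS:
        cols += [f"{name}_{ax}" for ax in _AXES]
    return cols


def load_trial(
    path,
    subject: str | None = None,
    condition: str | None = None,
    trial: int | None = None,
    system: str = "reference",
) -> Trajectory:
    """Load a trajectory CSV, validating schema and uniform-grid invariants."""
    df = pd.read_csv(path, float_precision="round_trip")
    for col in _required_columns():
        if col not in df.columns:
            raise SchemaError(f"missing required column '{col}'")
    time = df["time"].to_numpy(dtype=float)
    if time.size < 2:
        raise FormatError("trajectory file must contain at least 2 samples")
    if not np.all(np.isfinite(df[_required_columns()].to_numpy())):
        raise FormatError("non-finite values in trajectory file")
    dt = np.diff(time)
    if np.any(dt <= 0):
        raise FormatError("time must be strictly increasing")
    step = float(np.median(dt))
    if np.max(np.abs(dt - step)) > GRID_TOLERANCE:
        raise FormatError(
            f"non-uniform time grid (max deviation "
            f"{np.max(np.abs(dt - step)):.3g} s exceeds {GRID_TOLERANCE} s)"
        )
    com = df[[f"com_{ax}" for ax in _AXES]].to_numpy(dtype=float)
    landmarks = {
        name: df[[f"{name}_{ax}" for ax in _AXES]].to_numpy(dtype=float)
        for name in LANDMARKS
    }
    return Trajectory(
        time=time,
        com=com,
        landmarks=landmarks,
        rate=1.0 / step,
        system=system,
        subject=subject,
        condition=condition,
        trial=trial,
    )


def write_trial(traj: Trajectory, path) -> None:
    """Write a trajectory CSV at full float precision (lossless round trip)."""
    traj.to_frame().to_csv(path, index=False, float_format="%.17g")


def lowpass_filter(
    series: np.ndarray,
    cutoff: float,
    rate: float,
    order: int = 4,
    zero_phase: bool = True,
) -> np.ndarray:
    """Butterworth low-pass filter along axis 0 with DC gain 1.

    ``order`` is the effective order.  With ``zero_phase`` (default) a
    half-order design is applied forward and backward (``sosfiltfilt``), the
    standard biomechanics convention for a "fourth-order, 6 Hz" filter.
    """
    series = np.asarray(series, dtype=float)
    if cutoff <= 0:
        raise ParameterError("cutoff must be positive")
    if cutoff >= rate / 2.0:
        raise ParameterError(
            f"cutoff {cutoff} Hz must be below the Nyquist rate {rate / 2.0} Hz"
        )
    if zero_phase:
        if order < 2 or order % 2:
            raise ParameterError("zero-phase filtering needs an even order >= 2")
        sos = signal.butter(order // 2, cutoff, btype="low", fs=rate, output="sos")
        return signal.sosfiltfilt(sos, series, axis=0)
    sos = signal.butter(order, cutoff, btype="low", fs=rate, output="sos")
    return signal.sosfilt(sos, series, axis=0)


def resample(
    series: np.ndarray, rate_in: float, rate_out: float, t0: float = 0.0
) -> tuple[np.ndarray, np.ndarray]:
    """Resample a uniform series onto a grid at ``rate_out`` over the same span.

    Downsampling is anti-aliased internally (zero-phase Butterworth at
    0.45 * rate_out) before cubic-spline interpolation.  Returns
    ``(new_time, new_series)``.
    """
    series = np.asarray(series, dtype=float)
    if rate_in <= 0 or rate_out <= 0:
        raise ParameterError("rates must be positive")
    n = series.shape[0]
    if n == 0:
        raise ParameterError("cannot resample an empty series")
    t_in = t0 + np.arange(n) / rate_in
    if rate_in == rate_out:
        return t_in.copy(), series.copy()
    n_out = int(np.floor((n - 1) * rate_out / rate_in)) + 1
    t_out = t0 + np.arange(n_out) / rate_out
    work = series
    if rate_out < rate_in:
        work = lowpass_filter(work, 0.45 * rate_out, rate_in)
    spline = CubicSpline(t_in, work, axis=0)
    return t_out, spline(t_out)


def resample_trajectory(traj: Trajectory, rate_out: float) -> Trajectory:
    """Resample every channel of a trajectory onto a ``rate_out`` grid."""
    if rate_out == traj.rate:
        return traj.copy()
    t0 = float(traj.time[0])
    t_new, com = resample(traj.com, traj.rate, rate_out, t0=t0)
    landmarks = {
        k: resample(v, traj.rate, rate_out, t0=t0)[1]
        for k, v in traj.landmarks.items()
    }
    return Trajectory(
        time=t_new,
        com=com,
        landmarks=landmarks,
        rate=rate_out,
        system=traj.system,
        subject=traj.subject,
        condition=traj.condition,
        trial=traj.trial,
        meta=dict(traj.meta),
    )
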
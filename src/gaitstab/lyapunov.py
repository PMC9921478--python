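"""Short-term maximum Lyapunov exponents of gait time series.

The divergence-curve approach of Rosenstein and colleagues: the scalar
series (here dimensionless CoM velocity in AP or ML) is time-normalized to a
fixed number of samples per stride, delay-embedded, and for every state the
nearest neighbour outside a Theiler window is tracked forward in time.  The
mean of the log separations defines the divergence curve; the short-term
exponent is the least-squares slope of that curve over the first half
stride, in units of 1/stride.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.spatial import cKDTree

from .errors import InsufficientDataError, InsufficientStridesError, ParameterError


@dataclass
class EmbeddingSpec:
    """Parameters of the state-space reconstruction and divergence fit."""

    dim: int = 5
    delay: int | str = "auto"  # samples, or "auto" = first AMI minimum
    samples_per_stride: int = 100
    n_strides: int = 55
    theiler: int | None = None  # default samples_per_stride // 2
    horizon_strides: float = 1.0
    fit_range: tuple[float, float] = (0.0, 0.5)  # strides

    def __post_init__(self) -> None:
        if self.dim < 1:
            raise ParameterError("embedding dimension must be >= 1")
        if isinstance(self.delay, int) and self.delay < 1:
            raise ParameterError("delay must be >= 1 sample")
        if self.n_strides < 10:
            raise ParameterError("n_strides must be >= 10")
        if not (0 <= self.fit_range[0] < self.fit_range[1]
                <= self.horizon_strides):
            raise ParameterError("fit range must lie within the horizon")

    @property
    def theiler_window(self) -> int:
        return (self.samples_per_stride // 2 if self.theiler is None
                else self.theiler)


@dataclass
class DivergenceCurve:
    """Mean log nearest-neighbour separation versus time in strides."""

    times: np.ndarray  # strides, starting at 0
    mean_log_divergence: np.ndarray
    n_pairs: np.ndarray  # contributing pairs per time step
    samples_per_stride: int
    exponent: float | None = None  # fitted short-term slope, 1/stride
    intercept: float | None = None
    fit_range: tuple[float, float] | None = None


def time_normalize_strides(
    series: np.ndarray, stride_starts: np.ndarray, spec: EmbeddingSpec
) -> np.ndarray:
    """Resample each stride to ``samples_per_stride`` points and concatenate.

    ``stride_starts`` are sample indices of consecutive same-foot heel
    strikes; the first ``n_strides`` strides are used.  Output length is
    exactly ``n_strides * samples_per_stride``.
    """
    series = np.asarray(series, dtype=float)
    stride_starts = np.asarray(stride_starts)
    n_avail = stride_starts.size - 1
    if n_avail < spec.n_strides:
        raise InsufficientStridesError(
            f"need {spec.n_strides} strides, found {n_avail} "
            f"(short by {spec.n_strides - n_avail})")
    spst = spec.samples_per_stride
    out = np.empty(spec.n_strides * spst)
    base = np.arange(series.size, dtype=float)
    for i in range(spec.n_strides):
        a, b = float(stride_starts[i]), float(stride_starts[i + 1])
        pos = a + (b - a) * np.arange(spst) / spst
        out[i * spst:(i + 1) * spst] = np.interp(pos, base, series)
    return out


def average_mutual_information(
    series: np.ndarray, max_lag: int, n_bins: int = 16
) -> np.ndarray:
    """AMI (nats) between the series and its lagged copy, lags 1..max_lag."""
    series = np.asarray(series, dtype=float)
    edges = np.histogram_bin_edges(series, bins=n_bins)
    ami = np.empty(max_lag)
    for lag in range(1, max_lag + 1):
        x, y = series[:-lag], series[lag:]
        joint, _, _ = np.histogram2d(x, y, bins=(edges, edges))
        pxy = joint / joint.sum()
        px = pxy.sum(axis=1, keepdims=True)
        py = pxy.sum(axis=0, keepdims=True)
        mask = pxy > 0
        ami[lag - 1] = np.sum(
            pxy[mask] * np.log(pxy[mask] / (px @ py)[mask]))
    return ami


def choose_delay(series: np.ndarray, spec: EmbeddingSpec) -> int:
    """First local minimum of the AMI within one stride, or spst/4 fallback."""
    max_lag = spec.samples_per_stride
    ami = average_mutual_information(series, max_lag)
    for lag in range(1, max_lag - 1):
        if ami[lag] < ami[lag - 1] and ami[lag] <= ami[lag + 1]:
            return lag + 1
    return max(1, spec.samples_per_stride // 4)


def delay_embed(series: np.ndarray, dim: int, delay: int) -> np.ndarray:
    """States X_i = (x_i, x_{i+tau}, ..., x_{i+(d-1)tau}), shape (m, d)."""
    series = np.asarray(series, dtype=float)
    span = (dim - 1) * delay
    if series.size <= span:
        raise InsufficientDataError(
            f"series of length {series.size} too short for "
            f"dim={dim}, delay={delay}")
    m = series.size - span
    return np.lib.stride_tricks.sliding_window_view(
        series, span + 1)[:, ::delay][:m].copy()


def mean_log_divergence(
    states: np.ndarray, spec: EmbeddingSpec
) -> DivergenceCurve:
    """Nearest-neighbour divergence curve (Theiler-excluded, pair-counted).

    For every state the nearest neighbour with ``|i - j|`` greater than the
    Theiler window is found; pairs with zero initial separation are
    excluded.  The curve value at step k is the mean of ``ln`` separation
    over pairs still inside the series.
    """
    states = np.asarray(states, dtype=float)
    m = states.shape[0]
    w = spec.theiler_window
    if m < w + 2:
        raise InsufficientDataError("too few states for the Theiler window")
    tree = cKDTree(states)
    idx = np.arange(m)
    neighbour = np.full(m, -1, dtype=int)
    k_query = min(m, max(8, 2 * w + 4))
    dist, nbr = tree.query(states, k=k_query)
    ok = (np.abs(nbr - idx[:, None]) > w) & (dist > 0)
    first = np.argmax(ok, axis=1)
    has = ok[idx, first]
    neighbour[has] = nbr[has, first[has]]
    missing = np.nonzero(~has)[0]
    if missing.size and k_query < m:
        dist2, nbr2 = tree.query(states[missing], k=m)
        ok2 = (np.abs(nbr2 - missing[:, None]) > w) & (dist2 > 0)
        first2 = np.argmax(ok2, axis=1)
        has2 = ok2[np.arange(missing.size), first2]
        neighbour[missing[has2]] = nbr2[has2, first2[has2]]
    valid = neighbour >= 0
    if not np.any(valid):
        raise InsufficientDataError(
            "no admissible neighbour pairs outside the Theiler window")
    i_idx = idx[valid]
    j_idx = neighbour[valid]

    horizon = int(round(spec.horizon_strides * spec.samples_per_stride))
    times = np.arange(horizon + 1) / spec.samples_per_stride
    mld = np.full(horizon + 1, np.nan)
    n_pairs = np.zeros(horizon + 1, dtype=int)
    for k in range(horizon + 1):
        inside = (i_idx + k < m) & (j_idx + k < m)
        if not np.any(inside):
            break
        sep = np.linalg.norm(states[i_idx[inside] + k]
                             - states[j_idx[inside] + k], axis=1)
        sep = sep[sep > 0]
        if sep.size == 0:
            continue
        mld[k] = float(np.mean(np.log(sep)))
        n_pairs[k] = sep.size
    return DivergenceCurve(times=times, mean_log_divergence=mld,
                           n_pairs=n_pairs,
                           samples_per_stride=spec.samples_per_stride)


def short_term_lyapunov(
    curve: DivergenceCurve, fit_range: tuple[float, float] | None = None
) -> DivergenceCurve:
    """OLS slope of the divergence curve over ``fit_range`` (strides).

    Returns a copy of the curve with ``exponent`` (1/stride), ``intercept``
    and the fit range filled in.
    """
    lo, hi = fit_range if fit_range is not None else (0.0, 0.5)
    mask = ((curve.times >= lo) & (curve.times <= hi)
            & np.isfinite(curve.mean_log_divergence))
    if mask.sum() < 3:
        raise InsufficientDataError(
            "fewer than 3 curve points in the fit range")
    slope, intercept = np.polyfit(curve.times[mask],
                                  curve.mean_log_divergence[mask], 1)
    return replace(curve, exponent=float(slope), intercept=float(intercept),
                   fit_range=(lo, hi))


def lyapunov_exponent(
    series: np.ndarray,
    stride_starts: np.ndarray,
    spec: EmbeddingSpec | None = None,
) -> DivergenceCurve:
    """Full pipeline: time-normalize, embed, diverge, fit.

    ``series`` is the scalar signal on the trajectory's grid (dimensionless
    CoM velocity in AP or ML); ``stride_starts`` the same-foot heel-strike
    sample indices.  Returns the fitted :class:`DivergenceCurve` (the
    short-term exponent is ``curve.exponent``, 1/stride).
    """
    spec = spec or EmbeddingSpec()
    norm = time_normalize_strides(series, stride_starts, spec)
    delay = (choose_delay(norm, spec) if spec.delay == "auto"
             else int(spec.delay))
    states = delay_embed(norm, spec.dim, delay)
    curve = mean_log_divergence(states, spec)
    return short_term_lyapunov(curve, spec.fit_range)
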
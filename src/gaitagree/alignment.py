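"""Temporal alignment and gait-cycle extraction.

Covers the middle of the pipeline: cross-correlation synchronization of the
two device clocks on the vertical axis, stride-period estimation by
autocorrelation, template-correlation segmentation into individual gait
cycles, percent-cycle averaging, and the uniform-rate discretization of the
averaged cycle that feeds every agreement statistic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks as _scipy_find_peaks

from .signal import (ALL_CHANNELS, ContinuousSignal, SignalError,
                     TriaxialSignal, sample_grid)


class AlignmentError(ValueError):
    """Raised when synchronization or segmentation cannot proceed."""


@dataclass
class SyncResult:
    """Outcome of cross-correlation synchronization.

    ``lag`` is the clock offset of the criterion device relative to the
    sparse device: the two streams align when the sparse signal is evaluated
    at ``t + lag`` on its own clock, i.e. ``sparse(t + lag) ~= criterion(t)``.
    """

    lag: float
    peak_correlation: float
    window: tuple[float, float]
    grid_rate: float

    def __post_init__(self) -> None:
        if not -1.0 - 1e-9 <= self.peak_correlation <= 1.0 + 1e-9:
            raise AlignmentError("peak correlation outside [-1, 1]")


@dataclass
class GaitCycleSet:
    """Cycle boundaries (seconds, half-open ``[start, next start)``)."""

    boundaries: np.ndarray
    source_channel: str = "x"

    def __post_init__(self) -> None:
        self.boundaries = np.asarray(self.boundaries, dtype=float)
        if self.boundaries.size < 2:
            raise AlignmentError("need at least one cycle (two boundaries)")
        if np.any(np.diff(self.boundaries) <= 0):
            raise AlignmentError("cycle boundaries must be increasing")

    @property
    def n_cycles(self) -> int:
        return self.boundaries.size - 1

    @property
    def durations(self) -> np.ndarray:
        return np.diff(self.boundaries)

    @property
    def mean_period(self) -> float:
        return float(np.mean(self.durations))


@dataclass
class AveragedCycle:
    """Per-axis mean gait cycle on a common percent-cycle grid.

    ``grid`` covers 0-100% inclusive; ``mean``/``sd`` map channel name to
    arrays on that grid (units g); ``stride_period`` is the mean cycle
    duration in seconds.
    """

    grid: np.ndarray
    mean: dict[str, np.ndarray]
    sd: dict[str, np.ndarray]
    stride_period: float
    n_cycles: int

    def channel_names(self) -> tuple[str, ...]:
        return tuple(c for c in ALL_CHANNELS if c in self.mean)

    def evaluate(self, channel: str, percent) -> np.ndarray:
        """Linear interpolation of the mean waveform at percent-cycle points."""
        return np.interp(np.asarray(percent, dtype=float), self.grid,
                         self.mean[channel])


def _parabolic_refine(values: np.ndarray, idx: int) -> tuple[float, float]:
    """Sub-sample peak refinement: returns (fractional offset, peak value)."""
    if idx <= 0 or idx >= values.size - 1:
        return 0.0, float(values[idx])
    y0, y1, y2 = values[idx - 1], values[idx], values[idx + 1]
    if y1 >= 1.0 - 1e-12:
        # exact-match peak: refinement would only amplify rounding noise
        return 0.0, float(y1)
    denom = y0 - 2.0 * y1 + y2
    if denom >= 0 or abs(denom) < 1e-15:
        return 0.0, float(y1)
    delta = 0.5 * (y0 - y2) / denom
    peak = y1 - 0.25 * (y0 - y2) * delta
    return float(delta), float(peak)


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a @ a) * (b @ b))
    if denom == 0:
        return 0.0
    return float((a @ b) / denom)


def synchronize(sparse_x: ContinuousSignal, criterion_x: ContinuousSignal,
                window: tuple[float, float], max_lag: float = 2.0,
                grid_rate: float = 120.0) -> SyncResult:
    """Estimate the relative clock offset of the two devices.

    Both vertical-axis signals are resampled on a common dense grid over
    `window` (criterion clock); the normalized cross-correlation is scanned
    over lags in ``[-max_lag, +max_lag]`` and the peak refined by parabolic
    interpolation.  The same lag is subsequently applied to all channels.
    """
    t0, t1 = float(window[0]), float(window[1])
    if t1 <= t0:
        raise AlignmentError("empty synchronization window")
    grid = sample_grid(grid_rate, t0, t1)
    dt = 1.0 / grid_rate
    k_max = int(round(max_lag / dt))
    if k_max < 1:
        raise AlignmentError("max_lag shorter than one grid step")
    try:
        c = np.asarray(criterion_x(grid), dtype=float)
        ext = np.asarray(
            sparse_x(np.concatenate([grid[0] + np.arange(-k_max, 0) * dt,
                                     grid,
                                     grid[-1] + np.arange(1, k_max + 1) * dt])),
            dtype=float)
    except SignalError as exc:
        raise AlignmentError(
            f"signals not defined on window +/- max_lag: {exc}") from exc
    n = grid.size
    corr = np.empty(2 * k_max + 1)
    for i, k in enumerate(range(-k_max, k_max + 1)):
        # sparse evaluated at t + k*dt against criterion at t
        corr[i] = _pearson(ext[k_max + k: k_max + k + n], c)
    idx = int(np.argmax(corr))
    delta, peak = _parabolic_refine(corr, idx)
    lag = (idx - k_max + delta) * dt
    peak = float(np.clip(peak, -1.0, 1.0))
    if peak < 0.5:
        warnings.warn(f"weak synchronization peak ({peak:.2f})",
                      stacklevel=2)
    return SyncResult(lag=float(lag), peak_correlation=peak,
                      window=(t0, t1), grid_rate=grid_rate)


def estimate_stride_period(x, rate: float, min_lag: float = 0.4,
                           max_lag: float = 2.5,
                           min_correlation: float = 0.3) -> float:
    """Stride period from the dominant autocorrelation peak.

    Uses the unbiased sample autocorrelation and picks, among local maxima at
    lags in ``[min_lag, max_lag]`` seconds, the one with the highest
    correlation; the 0.4 s refractory lag excludes the step-frequency peak of
    near-symmetric gait.  The peak lag is refined by parabolic interpolation.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size < 8:
        raise AlignmentError("need a 1-D sample array of at least 8 points")
    x = x - x.mean()
    n = x.size
    var = float(x @ x) / n
    if var == 0:
        raise AlignmentError("constant signal has no stride periodicity")
    full = np.correlate(x, x, mode="full")[n - 1:]
    acf = full / (n - np.arange(n)) / var  # unbiased, normalized
    k_lo = max(int(np.ceil(min_lag * rate)), 1)
    k_hi = min(int(np.floor(max_lag * rate)), int(0.8 * n))
    if k_hi - k_lo < 3:
        raise AlignmentError("window too short for stride-period search")
    band = acf[k_lo:k_hi + 1]
    peaks, _ = _scipy_find_peaks(band)
    peaks = peaks[band[peaks] >= min_correlation]
    if peaks.size == 0:
        raise AlignmentError(
            f"no autocorrelation peak above {min_correlation} in "
            f"[{min_lag}, {max_lag}] s: signal not periodic enough")
    # dominant peak, but prefer the earliest among near-ties: for an exactly
    # periodic signal the stride lag and its multiples all reach r ~= 1,
    # while the half-stride peak of near-symmetric gait falls clearly lower
    max_r = float(band[peaks].max())
    margin = 0.05
    best = int(peaks[band[peaks] >= max_r - margin][0]) + k_lo
    delta, _ = _parabolic_refine(acf, best)
    return float((best + delta) / rate)


def segment_cycles(x, rate: float, stride_period: float,
                   n_cycles: int = 5, t_start: float = 0.0,
                   search_frac: float = 0.25,
                   min_correlation: float = 0.5,
                   source_channel: str = "x") -> GaitCycleSet:
    """Segment a window into consecutive gait cycles by self-similarity.

    The first ``stride_period`` of the window serves as the template; each
    subsequent boundary is the correlation maximum of the template within
    +/- ``search_frac`` of the stride period around its expected position.
    Boundary convention is half-open ``[start, next start)``.
    """
    x = np.asarray(x, dtype=float)
    if n_cycles < 1:
        raise AlignmentError("n_cycles must be at least 1")
    period_n = int(round(stride_period * rate))
    if period_n < 4:
        raise AlignmentError("stride period shorter than 4 samples")
    if x.size < period_n + 1:
        raise AlignmentError("window shorter than one stride period")
    template = x[:period_n]
    if np.ptp(template) == 0:
        raise AlignmentError("flat template cannot anchor cycle boundaries")
    half = max(int(round(search_frac * period_n)), 1)
    bounds = [0]
    for k in range(1, n_cycles + 1):
        expected = bounds[-1] + period_n
        lo = max(expected - half, bounds[-1] + 1)
        hi = min(expected + half, x.size - period_n)
        if hi < lo:
            raise AlignmentError(
                f"window too short to place boundary {k} of {n_cycles} "
                f"(need data through sample {expected + half + period_n})")
        scores = np.array([_pearson(template, x[s:s + period_n])
                           for s in range(lo, hi + 1)])
        best = int(np.argmax(scores))
        if scores[best] < min_correlation:
            raise AlignmentError(
                f"no template-correlation peak >= {min_correlation} for "
                f"boundary {k} (best {scores[best]:.2f})")
        bounds.append(lo + best)
    boundaries = t_start + np.asarray(bounds, dtype=float) / rate
    return GaitCycleSet(boundaries, source_channel=source_channel)


def average_normalize(cycles: GaitCycleSet, signals: TriaxialSignal,
                      grid_points: int = 101) -> AveragedCycle:
    """Average the segmented cycles on a common percent-gait-cycle grid.

    Each cycle's time axis is linearly mapped to 0-100%; every channel is
    evaluated at ``grid_points`` equispaced percent positions and the
    pointwise mean and SD are taken across cycles.
    """
    if grid_points < 2:
        raise AlignmentError("grid needs at least 2 points")
    frac = np.linspace(0.0, 1.0, grid_points)
    names = signals.channel_names()
    stacks = {c: np.empty((cycles.n_cycles, grid_points)) for c in names}
    for i in range(cycles.n_cycles):
        t0, t1 = cycles.boundaries[i], cycles.boundaries[i + 1]
        t = t0 + frac * (t1 - t0)
        for c in names:
            stacks[c][i] = np.asarray(signals[c](t), dtype=float)
    mean = {c: stacks[c].mean(axis=0) for c in names}
    sd = {c: stacks[c].std(axis=0, ddof=0) for c in names}
    return AveragedCycle(grid=frac * 100.0, mean=mean, sd=sd,
                         stride_period=cycles.mean_period,
                         n_cycles=cycles.n_cycles)


def discretize_for_stats(avg: AveragedCycle, rate: float = 60.0
                         ) -> dict[str, np.ndarray]:
    """Resample the averaged cycle at a uniform rate over its stride period.

    The cycle is interpreted over its mean stride period and sampled on the
    half-open grid ``[0, stride_period)`` at `rate` (65 points for a 1.09 s
    cycle at 60 Hz).  These arrays are the inputs to the agreement
    statistics.
    """
    if rate <= 0:
        raise AlignmentError("rate must be positive")
    n = int(np.floor(avg.stride_period * rate + 1e-9))
    if n < 2:
        raise AlignmentError("stride period shorter than two sample intervals")
    percent = 100.0 * np.arange(n) / (avg.stride_period * rate)
    return {c: avg.evaluate(c, percent) for c in avg.channel_names()}


def middle_window(t_lo: float, t_hi: float, stride_period: float,
                  n_cycles: float, margin: float = 0.0
                  ) -> tuple[float, float]:
    """Centered analysis window of ``n_cycles`` strides inside ``[t_lo, t_hi]``.

    ``margin`` seconds are kept clear at both ends (e.g. for a lag search or
    to stay away from gait initiation/termination).
    """
    lo, hi = t_lo + margin, t_hi - margin
    span = n_cycles * stride_period
    if hi - lo < span:
        raise AlignmentError(
            f"recording too short: need {span:.2f} s inside "
            f"[{t_lo:.2f}, {t_hi:.2f}] with margin {margin:.2f} s")
    mid = (lo + hi) / 2.0
    return (mid - span / 2.0, mid + span / 2.0)
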
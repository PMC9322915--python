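"""Core signal containers and preprocessing.

Accelerations are carried in units of g throughout.  An :class:`AccelStream`
is the sampled record of one device; a :class:`ContinuousSignal` is an
evaluable interpolant of one channel.  Preprocessing covers the vector
magnitude, zero-lag Butterworth low-pass filtering, residual analysis for
cutoff selection, and least-squares harmonic ("Fourier method")
reconstruction of a quasi-periodic channel.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.signal import butter, filtfilt

AXES = ("x", "y", "z")
ALL_CHANNELS = ("x", "y", "z", "n")

#: column names used in the delimited-text stream format
STREAM_COLUMNS = {"x": "acc_x_g", "y": "acc_y_g", "z": "acc_z_g", "n": "n_g"}


class SignalError(ValueError):
    """Raised for invalid signal inputs (domain, sampling, shape)."""


def _as_float_array(values, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise SignalError(f"{name} must be one-dimensional")
    if not np.all(np.isfinite(arr)):
        raise SignalError(f"{name} contains non-finite values")
    return arr


@dataclass
class AccelStream:
    """Timestamped tri-axial acceleration record from one device.

    Parameters
    ----------
    time
        Sample times in seconds on the device's own clock, strictly increasing.
    channels
        Mapping of channel name (``x``, ``y``, ``z`` and optionally the
        magnitude ``n``) to sample arrays in g.
    device_label, side
        Free-text provenance; ``side`` is one of ``left``, ``right``, ``n/a``.
    nominal_rate
        Advertised sampling rate in Hz (inferred from timestamps if omitted).
    """

    time: np.ndarray
    channels: dict[str, np.ndarray]
    device_label: str = ""
    side: str = "n/a"
    nominal_rate: float | None = None

    def __post_init__(self) -> None:
        self.time = _as_float_array(self.time, "time")
        if self.time.size < 2:
            raise SignalError("stream needs at least two samples")
        if np.any(np.diff(self.time) <= 0):
            raise SignalError("time must be strictly increasing")
        if self.side not in ("left", "right", "n/a"):
            raise SignalError(f"unknown side {self.side!r}")
        clean = {}
        for name, values in self.channels.items():
            if name not in ALL_CHANNELS:
                raise SignalError(f"unknown channel {name!r}")
            arr = _as_float_array(values, f"channel {name}")
            if arr.size != self.time.size:
                raise SignalError(f"channel {name} length mismatch")
            clean[name] = arr
        self.channels = clean
        if self.nominal_rate is None:
            self.nominal_rate = 1.0 / float(np.median(np.diff(self.time)))

    def __getitem__(self, name: str) -> np.ndarray:
        return self.channels[name]

    def __len__(self) -> int:
        return self.time.size

    @property
    def rate(self) -> float:
        """Sampling rate in Hz (nominal, falling back to the time grid)."""
        return float(self.nominal_rate)

    @property
    def duration(self) -> float:
        return float(self.time[-1] - self.time[0])

    def channel_names(self) -> tuple[str, ...]:
        return tuple(c for c in ALL_CHANNELS if c in self.channels)

    def to_frame(self) -> pd.DataFrame:
        data = {"time_s": self.time}
        for name in self.channel_names():
            data[STREAM_COLUMNS[name]] = self.channels[name]
        return pd.DataFrame(data)

    def write(self, path) -> None:
        """Write the stream as tab-delimited text (``time_s``, ``acc_*_g``)."""
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read(cls, path, device_label: str = "", side: str = "n/a",
             nominal_rate: float | None = None) -> "AccelStream":
        frame = pd.read_csv(path, sep=None, engine="python")
        if "time_s" not in frame.columns:
            raise SignalError(f"{path}: missing 'time_s' column")
        channels = {}
        for name, col in STREAM_COLUMNS.items():
            if col in frame.columns:
                channels[name] = frame[col].to_numpy(dtype=float)
        missing = [a for a in AXES if a not in channels]
        if missing:
            raise SignalError(f"{path}: missing channels {missing}")
        return cls(frame["time_s"].to_numpy(dtype=float), channels,
                   device_label=device_label, side=side,
                   nominal_rate=nominal_rate)


class ContinuousSignal:
    """Evaluable single-channel signal on a time domain ``[t_start, t_end]``.

    Subclasses implement :meth:`_evaluate`; evaluation outside the domain
    raises :class:`SignalError` (a tolerance of 1e-9 s absorbs grid rounding).
    """

    t_start: float = -np.inf
    t_end: float = np.inf

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        tol = 1e-9
        if np.any(t < self.t_start - tol) or np.any(t > self.t_end + tol):
            raise SignalError(
                f"evaluation outside domain [{self.t_start}, {self.t_end}]")
        return self._evaluate(t)

    def _evaluate(self, t: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    @property
    def domain(self) -> tuple[float, float]:
        return (self.t_start, self.t_end)


@dataclass
class HarmonicSeries(ContinuousSignal):
    """Truncated Fourier series ``a0 + sum a_k cos(2*pi*k*f0*t) + b_k sin(...)``."""

    fundamental: float
    a0: float
    a: np.ndarray
    b: np.ndarray
    t_start: float = -np.inf
    t_end: float = np.inf

    def __post_init__(self) -> None:
        self.a = np.atleast_1d(np.asarray(self.a, dtype=float))
        self.b = np.atleast_1d(np.asarray(self.b, dtype=float))
        if self.a.size != self.b.size:
            raise SignalError("cosine/sine coefficient lists differ in length")
        if self.fundamental <= 0:
            raise SignalError("fundamental frequency must be positive")

    @property
    def n_harmonics(self) -> int:
        return self.a.size

    def _evaluate(self, t: np.ndarray) -> np.ndarray:
        k = np.arange(1, self.n_harmonics + 1)
        phase = 2.0 * np.pi * self.fundamental * np.multiply.outer(t, k)
        return (self.a0 + np.cos(phase) @ self.a + np.sin(phase) @ self.b)


class SplineSignal(ContinuousSignal):
    """Cubic-spline interpolant of one sampled channel.

    Unlike a truncated harmonic fit, the spline passes through the samples
    and therefore preserves cycle-to-cycle deviations — which is what makes
    cross-correlation synchronization identifiable for quasi-periodic gait
    (a strictly periodic representation has equivalent correlation peaks at
    every stride).
    """

    def __init__(self, time, values):
        from scipy.interpolate import CubicSpline

        t = _as_float_array(time, "time")
        y = _as_float_array(values, "values")
        if t.size != y.size or t.size < 4:
            raise SignalError("spline needs >= 4 matching samples")
        self._spline = CubicSpline(t, y, extrapolate=False)
        self.t_start = float(t[0])
        self.t_end = float(t[-1])

    def _evaluate(self, t: np.ndarray) -> np.ndarray:
        out = self._spline(np.clip(t, self.t_start, self.t_end))
        return np.asarray(out, dtype=float)


def spline_interpolant(stream: AccelStream,
                       channels: tuple[str, ...] | None = None
                       ) -> TriaxialSignal:
    """Deviation-preserving cubic-spline interpolant of a stream."""
    if channels is None:
        channels = stream.channel_names()
    return TriaxialSignal({c: SplineSignal(stream.time, stream[c])
                           for c in channels})


@dataclass
class ShiftedSignal(ContinuousSignal):
    """View of another signal with its time axis shifted by ``shift`` seconds.

    ``ShiftedSignal(sig, shift)(t) == sig(t + shift)``.
    """

    base: ContinuousSignal
    shift: float

    def __post_init__(self) -> None:
        self.t_start = self.base.t_start - self.shift
        self.t_end = self.base.t_end - self.shift

    def _evaluate(self, t: np.ndarray) -> np.ndarray:
        return self.base(t + self.shift)


@dataclass
class TriaxialSignal:
    """Bundle of per-channel :class:`ContinuousSignal` sharing a time domain."""

    channels: dict[str, ContinuousSignal]

    def __post_init__(self) -> None:
        if not self.channels:
            raise SignalError("empty channel set")

    def __getitem__(self, name: str) -> ContinuousSignal:
        return self.channels[name]

    def channel_names(self) -> tuple[str, ...]:
        return tuple(c for c in ALL_CHANNELS if c in self.channels)

    @property
    def domain(self) -> tuple[float, float]:
        t0 = max(sig.t_start for sig in self.channels.values())
        t1 = min(sig.t_end for sig in self.channels.values())
        return (t0, t1)

    def shift(self, delta: float) -> "TriaxialSignal":
        return TriaxialSignal(
            {c: ShiftedSignal(sig, delta) for c, sig in self.channels.items()})

    def resample(self, rate: float, t_start: float, t_end: float,
                 device_label: str = "", side: str = "n/a") -> AccelStream:
        """Sample every channel on a uniform half-open grid ``[t_start, t_end)``."""
        t = sample_grid(rate, t_start, t_end)
        channels = {c: np.asarray(sig(t), dtype=float)
                    for c, sig in self.channels.items()}
        return AccelStream(t, channels, device_label=device_label, side=side,
                           nominal_rate=rate)


def sample_grid(rate: float, t_start: float, t_end: float) -> np.ndarray:
    """Uniform grid at `rate` on the half-open interval ``[t_start, t_end)``.

    ``floor((t_end - t_start) * rate)`` samples; 1 s at 60 Hz gives 60 points.
    """
    if rate <= 0:
        raise SignalError("rate must be positive")
    if t_end <= t_start:
        raise SignalError("empty resampling window")
    n = int(np.floor((t_end - t_start) * rate + 1e-9))
    if n < 1:
        raise SignalError("window shorter than one sample interval")
    return t_start + np.arange(n) / rate


def resample(signal, rate: float, t_start: float, t_end: float):
    """Resample a continuous signal on ``[t_start, t_end)``.

    Accepts a :class:`TriaxialSignal` (returns an :class:`AccelStream`) or a
    single :class:`ContinuousSignal` (returns ``(time, values)`` arrays).
    """
    if isinstance(signal, TriaxialSignal):
        return signal.resample(rate, t_start, t_end)
    t = sample_grid(rate, t_start, t_end)
    return t, np.asarray(signal(t), dtype=float)


# ---------------------------------------------------------------------------
# preprocessing operations
# ---------------------------------------------------------------------------

def vector_magnitude(stream: AccelStream) -> AccelStream:
    """Return a copy of the stream with the magnitude channel ``n`` filled.

    ``n = sqrt(acc_x**2 + acc_y**2 + acc_z**2)`` per sample; the axis channels
    are untouched.
    """
    missing = [a for a in AXES if a not in stream.channels]
    if missing:
        raise SignalError(f"missing channels for magnitude: {missing}")
    channels = dict(stream.channels)
    channels["n"] = np.sqrt(sum(stream[a] ** 2 for a in AXES))
    return replace(stream, channels=channels)


def _check_uniform(stream: AccelStream) -> float:
    dt = np.diff(stream.time)
    if np.ptp(dt) > 1e-6 * np.median(dt):
        raise SignalError("filtering requires a uniform sampling grid")
    return 1.0 / float(np.median(dt))


def butterworth_zero_lag(stream: AccelStream, cutoff: float,
                         order: int = 4,
                         design: str = "per-pass") -> AccelStream:
    """Zero-phase low-pass Butterworth filter applied to every channel.

    The filter is applied forward and backward (``filtfilt``) so the net phase
    shift is zero.  With ``design="per-pass"`` (default, the dominant gait
    convention) `order` is the design order of each pass, giving a net
    magnitude response of ``|H|**2``; ``design="net"`` halves the design order
    so the two passes together realize the requested order.
    """
    if order < 1:
        raise SignalError("order must be >= 1")
    if design == "net":
        if order % 2:
            raise SignalError("net design requires an even order")
        order = order // 2
    elif design != "per-pass":
        raise SignalError(f"unknown design {design!r}")
    fs = _check_uniform(stream)
    if cutoff <= 0 or cutoff >= fs / 2 * (1.0 - 1e-9):
        raise SignalError(f"cutoff {cutoff} Hz outside (0, Nyquist={fs/2} Hz)")
    b, a = butter(order, cutoff, btype="low", fs=fs)
    padlen = 3 * max(len(a), len(b))
    if len(stream) <= padlen:
        raise SignalError(
            f"stream too short for edge padding ({len(stream)} <= {padlen})")
    channels = {name: filtfilt(b, a, values, padtype="odd", padlen=padlen)
                for name, values in stream.channels.items()}
    return replace(stream, channels=channels)


@dataclass
class ResidualCurve:
    """Residual-analysis curve used to pick a low-pass cutoff.

    ``residual_rms[i]`` is the RMS difference between the signal filtered at
    ``cutoffs[i]`` and the raw signal, pooled over the axis channels.  The
    selected cutoff is where the curve crosses the straight-line extrapolation
    of its noise-dominated (high-cutoff) limb back to 0 Hz.
    """

    cutoffs: np.ndarray
    residual_rms: np.ndarray
    selected_cutoff: float
    noise_intercept: float
    fit_band: tuple[float, float]


def residual_analysis(stream: AccelStream, cutoff_grid,
                      order: int = 4,
                      fit_band: tuple[float, float] = (0.25, 0.75),
                      channels: tuple[str, ...] = AXES) -> ResidualCurve:
    """Residual analysis over a grid of candidate low-pass cutoffs.

    For each cutoff the residual is ``RMS(filtered - raw)`` pooled over
    `channels`.  A straight line is fitted to the limb of the curve with
    cutoffs inside ``fit_band`` (as fractions of the Nyquist frequency), where
    the residual is dominated by attenuated noise; its intercept at 0 Hz
    estimates the noise RMS, and the selected cutoff is the (interpolated)
    grid position where the residual curve falls to that intercept.
    """
    grid = np.sort(_as_float_array(cutoff_grid, "cutoff_grid"))
    if grid.size < 4:
        raise SignalError("need at least 4 cutoffs for the line fit")
    fs = _check_uniform(stream)
    nyq = fs / 2
    if grid[0] <= 0 or grid[-1] >= nyq:
        raise SignalError("cutoff grid must lie inside (0, Nyquist)")
    use = [c for c in channels if c in stream.channels]
    if not use:
        raise SignalError("no requested channels present")
    residuals = np.empty(grid.size)
    for i, cutoff in enumerate(grid):
        filt = butterworth_zero_lag(stream, cutoff, order=order)
        sq = [np.mean((filt[c] - stream[c]) ** 2) for c in use]
        residuals[i] = float(np.sqrt(np.mean(sq)))
    lo, hi = fit_band[0] * nyq, fit_band[1] * nyq
    mask = (grid >= lo) & (grid <= hi)
    if mask.sum() < 2:
        raise SignalError("fewer than 2 grid points in the noise fit band")
    slope, intercept = np.polyfit(grid[mask], residuals[mask], 1)
    intercept = float(max(intercept, 0.0))
    selected = float(grid[-1])
    below = residuals <= intercept
    if below[0]:
        selected = float(grid[0])
    else:
        idx = np.argmax(below) if below.any() else None
        if idx:
            # linear interpolation between the bracketing grid points
            c0, c1 = grid[idx - 1], grid[idx]
            r0, r1 = residuals[idx - 1], residuals[idx]
            frac = (r0 - intercept) / (r0 - r1) if r0 != r1 else 0.0
            selected = float(c0 + frac * (c1 - c0))
    return ResidualCurve(grid, residuals, selected, intercept,
                         (float(lo), float(hi)))


# ---------------------------------------------------------------------------
# Fourier-method reconstruction
# ---------------------------------------------------------------------------

def fit_harmonics(time, values, fundamental: float, n_harmonics: int,
                  rate: float | None = None) -> HarmonicSeries:
    """Least-squares fit of a truncated harmonic basis to samples.

    The basis is ``{1, cos(2*pi*k*f*t), sin(2*pi*k*f*t)}`` for
    ``k = 1..n_harmonics`` evaluated on the stream's own (possibly irregular)
    timestamps.  The fitted :class:`HarmonicSeries` is evaluable anywhere in
    the sample span.
    """
    t = _as_float_array(time, "time")
    y = _as_float_array(values, "values")
    if t.size != y.size:
        raise SignalError("time/values length mismatch")
    if fundamental <= 0:
        raise SignalError("fundamental must be positive")
    if n_harmonics < 1:
        raise SignalError("need at least one harmonic")
    span = t[-1] - t[0]
    if span < 2.0 / fundamental:
        raise SignalError("stream spans fewer than two fundamental periods")
    if rate is None:
        rate = 1.0 / float(np.median(np.diff(t)))
    if n_harmonics * fundamental >= rate / 2:
        raise SignalError(
            f"{n_harmonics} harmonics at {fundamental:.3g} Hz exceed the "
            f"Nyquist frequency {rate / 2:.3g} Hz")
    n_params = 2 * n_harmonics + 1
    if n_params >= t.size:
        raise SignalError("more basis functions than samples")
    k = np.arange(1, n_harmonics + 1)
    phase = 2.0 * np.pi * fundamental * np.multiply.outer(t, k)
    design = np.hstack([np.ones((t.size, 1)), np.cos(phase), np.sin(phase)])
    coef, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    if rank < n_params:
        raise SignalError("rank-deficient harmonic design matrix")
    return HarmonicSeries(fundamental, float(coef[0]),
                          coef[1:n_harmonics + 1], coef[n_harmonics + 1:],
                          t_start=float(t[0]), t_end=float(t[-1]))


def refine_fundamental(time, values, fundamental: float, n_harmonics: int,
                       rel_bracket: float = 0.05) -> float:
    """Refine a fundamental-frequency estimate by minimizing the fit residual.

    A stride period read off an autocorrelation grid is quantized to one
    sample interval; over a multi-cycle fit window that error dephases the
    harmonic basis.  A bounded golden-section search of the least-squares
    residual within ``fundamental * (1 +/- rel_bracket)`` restores the
    in-basis recovery property.
    """
    from scipy.optimize import minimize_scalar

    t = _as_float_array(time, "time")
    y = _as_float_array(values, "values")
    rate = 1.0 / float(np.median(np.diff(t)))
    k = np.arange(1, n_harmonics + 1)

    def cost(f: float) -> float:
        phase = 2.0 * np.pi * f * np.multiply.outer(t, k)
        design = np.hstack([np.ones((t.size, 1)), np.cos(phase),
                            np.sin(phase)])
        _, res, rank, _ = np.linalg.lstsq(design, y, rcond=None)
        if rank < design.shape[1] or res.size == 0:
            return float(np.sum((y - design @ np.linalg.pinv(design) @ y) ** 2))
        return float(res[0])

    lo = fundamental * (1 - rel_bracket)
    hi = min(fundamental * (1 + rel_bracket),
             0.999 * rate / (2 * n_harmonics))
    if hi <= lo:
        return fundamental
    out = minimize_scalar(cost, bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-7})
    return float(out.x)


def fourier_reconstruct(stream: AccelStream, fundamental: float,
                        n_harmonics: int = 6,
                        channels: tuple[str, ...] | None = None,
                        refine: bool = False) -> TriaxialSignal:
    """Fourier-method continuous reconstruction of a quasi-periodic stream.

    Each requested channel is fitted with :func:`fit_harmonics` at a common
    fundamental (optionally refined on the vertical ``x`` channel first);
    the result bridges between the sparse samples using the signal's
    periodic structure.
    """
    if channels is None:
        channels = stream.channel_names()
    if refine:
        ref = "x" if "x" in stream.channels else channels[0]
        fundamental = refine_fundamental(stream.time, stream[ref],
                                         fundamental, n_harmonics)
    fitted = {c: fit_harmonics(stream.time, stream[c], fundamental,
                               n_harmonics, rate=stream.rate)
              for c in channels}
    return TriaxialSignal(fitted)
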
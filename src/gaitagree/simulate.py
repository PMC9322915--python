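"""Synthetic paired-sensor gait trials with known ground truth.

Emulates thigh-worn accelerometer recordings of overground walking: a
quasi-periodic tri-axial specific-force waveform (gravity-inclusive, vertical
baseline near -1 g) sampled by two devices — a sparse ~12.5 Hz stream and a
dense 60 Hz criterion stream — with sensor noise, gain/bias errors,
quantization, range clipping and an unknown clock offset between the two
device clocks.  Everything is reproducible from integer seeds, and the
generating waveform is closed-form so downstream recovery can be tested
exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .signal import (AXES, AccelStream, ContinuousSignal, SignalError,
                     TriaxialSignal, vector_magnitude)

#: cohort cadence of 110 steps/min corresponds to a stride rate of 110/120 Hz
DEFAULT_STRIDE_FREQUENCY = 110.0 / 120.0

# per-axis (cosine, sine) harmonic amplitude pairs in g.  Vertical (x) and
# anteroposterior (y) carry most of the energy at the stride frequency and
# its first harmonics; mediolateral (z) is smaller with relatively more
# high-harmonic content.  Highest harmonic (4th, ~3.7 Hz at cadence 110)
# stays below the 4 Hz analysis band edge.
DEFAULT_HARMONICS: dict[str, tuple[tuple[float, float], ...]] = {
    "x": ((0.30, 0.10), (0.15, -0.08), (0.08, 0.03), (-0.04, 0.02)),
    "y": ((0.25, -0.12), (0.12, 0.06), (-0.06, 0.03), (0.03, -0.015)),
    "z": ((0.08, 0.04), (0.05, -0.03), (0.04, 0.02), (-0.02, 0.012)),
}

DEFAULT_BASELINE = {"x": -1.0, "y": 0.0, "z": 0.0}


class SimulationError(ValueError):
    """Raised for invalid simulation configurations."""


@dataclass
class SimulationConfig:
    """Conditions of one simulated walking bout.

    stride_frequency : Hz; default is the cohort cadence 110 steps/min / 2.
    n_cycles : number of gait cycles in the bout (12 ~= a 15 m walk).
    harmonic_amplitudes : per-axis (cosine, sine) amplitude pairs in g.
    gravity_baseline : per-axis constant offset in g (vertical -1.0).
    cycle_jitter_sd : relative SD of per-cycle period perturbation.
    amplitude_jitter_sd : relative SD of per-cycle amplitude scaling.
    seed : master seed for the bout.
    """

    stride_frequency: float = DEFAULT_STRIDE_FREQUENCY
    n_cycles: int = 12
    harmonic_amplitudes: dict = field(
        default_factory=lambda: {a: tuple(DEFAULT_HARMONICS[a]) for a in AXES})
    gravity_baseline: dict = field(
        default_factory=lambda: dict(DEFAULT_BASELINE))
    cycle_jitter_sd: float = 0.03
    amplitude_jitter_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.stride_frequency <= 0:
            raise SimulationError("stride_frequency must be positive")
        if self.n_cycles < 1:
            raise SimulationError("n_cycles must be at least 1")
        if self.cycle_jitter_sd < 0 or self.amplitude_jitter_sd < 0:
            raise SimulationError("jitter SDs must be non-negative")
        for axis in AXES:
            if axis not in self.harmonic_amplitudes:
                raise SimulationError(f"missing harmonics for axis {axis}")
            if axis not in self.gravity_baseline:
                raise SimulationError(f"missing baseline for axis {axis}")

    @property
    def stride_period(self) -> float:
        return 1.0 / self.stride_frequency


def _per_axis(value, name: str) -> dict[str, float]:
    if isinstance(value, dict):
        out = {a: float(value.get(a, 0.0)) for a in AXES}
    else:
        out = {a: float(value) for a in AXES}
    if not all(np.isfinite(v) for v in out.values()):
        raise SimulationError(f"{name} must be finite")
    return out


@dataclass
class SensorModel:
    """Imperfections of one recording device.

    sampling_frequency : Hz.
    noise_sd : additive Gaussian noise SD in g.
    clip_range : symmetric full-scale range in g (samples clipped to +/-).
    quantization_step : g per count; 0 disables quantization.
    clock_offset : world time (s) at which the sensor's own clock reads 0.
    additive_bias, gain : per-axis calibration errors (dict or scalar).
    """

    sampling_frequency: float
    noise_sd: float = 0.0
    clip_range: float = 4.0
    quantization_step: float = 0.0
    clock_offset: float = 0.0
    additive_bias: dict | float = 0.0
    gain: dict | float = 1.0

    def __post_init__(self) -> None:
        if self.sampling_frequency <= 0:
            raise SimulationError("sampling_frequency must be positive")
        if self.clip_range <= 0:
            raise SimulationError("clip_range must be positive")
        if self.quantization_step < 0:
            raise SimulationError("quantization_step must be non-negative")
        if self.noise_sd < 0:
            raise SimulationError("noise_sd must be non-negative")
        if not np.isfinite(self.clock_offset):
            raise SimulationError("clock_offset must be finite")
        self.additive_bias = _per_axis(self.additive_bias, "additive_bias")
        self.gain = _per_axis(self.gain, "gain")


def default_sparse_model(**overrides) -> SensorModel:
    """Low-rate wearable: 12.5 Hz, +/-4 g, 12-bit quantization, 0.02 g noise."""
    params = dict(sampling_frequency=12.5, noise_sd=0.02, clip_range=4.0,
                  quantization_step=8.0 / 4096.0)
    params.update(overrides)
    return SensorModel(**params)


def default_criterion_model(**overrides) -> SensorModel:
    """Criterion device: 60 Hz, +/-16 g, model-smoothed output (0.005 g noise)."""
    params = dict(sampling_frequency=60.0, noise_sd=0.005, clip_range=16.0,
                  quantization_step=0.0)
    params.update(overrides)
    return SensorModel(**params)


@dataclass
class GroundTruth:
    """Hidden parameters of a paired trial, for recovery tests.

    true_clock_offset is the criterion clock offset minus the sparse clock
    offset: the lag :func:`gaitagree.alignment.synchronize` should recover.
    """

    true_clock_offset: float
    true_stride_periods: np.ndarray
    true_bias: dict[str, float]
    motion: "TriaxialSignal"

    @property
    def mean_stride_period(self) -> float:
        return float(np.mean(self.true_stride_periods))


class _GaitPhase:
    """Piecewise-linear phase shared by all axes of one simulated bout.

    phase(t) counts gait cycles: it increases by exactly 1 over each
    (jittered) cycle and extrapolates at the nominal rate outside the bout,
    so the waveform is continuous everywhere and exactly periodic when the
    jitter is zero.
    """

    def __init__(self, periods: np.ndarray, nominal_period: float):
        self.periods = np.asarray(periods, dtype=float)
        self.nominal_period = float(nominal_period)
        self.boundaries = np.concatenate([[0.0], np.cumsum(self.periods)])

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        core = np.interp(t, self.boundaries,
                         np.arange(self.boundaries.size, dtype=float))
        lo = t < 0
        hi = t > self.boundaries[-1]
        out = np.where(lo, t / self.nominal_period, core)
        out = np.where(hi, (self.periods.size
                            + (t - self.boundaries[-1]) / self.nominal_period),
                       out)
        return out


class _WarpedHarmonicChannel(ContinuousSignal):
    """One axis of the simulated motion: baseline + scaled harmonic stack."""

    def __init__(self, phase: _GaitPhase, baseline: float,
                 cos_amps: np.ndarray, sin_amps: np.ndarray,
                 scale_times: np.ndarray, scale_values: np.ndarray):
        self.phase = phase
        self.baseline = float(baseline)
        self.cos_amps = np.asarray(cos_amps, dtype=float)
        self.sin_amps = np.asarray(sin_amps, dtype=float)
        self.scale_times = scale_times
        self.scale_values = scale_values
        self.t_start = -np.inf
        self.t_end = np.inf

    def _evaluate(self, t: np.ndarray) -> np.ndarray:
        phi = self.phase(t)
        scale = np.interp(t, self.scale_times, self.scale_values)
        if self.cos_amps.size == 0:
            return np.broadcast_to(self.baseline, np.shape(phi)).astype(float)
        k = np.arange(1, self.cos_amps.size + 1)
        arg = 2.0 * np.pi * np.multiply.outer(phi, k)
        wave = np.cos(arg) @ self.cos_amps + np.sin(arg) @ self.sin_amps
        return self.baseline + scale * wave


def simulate_reference_motion(config: SimulationConfig) -> TriaxialSignal:
    """Continuous tri-axial reference waveform of one walking bout.

    Per cycle, a truncated Fourier series at the stride frequency with the
    cycle period and amplitude independently jittered; jitter is applied by
    time-warping each cycle so the waveform stays continuous at cycle
    boundaries.  Fully reproducible from ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    t0 = config.stride_period
    periods = t0 * (1.0 + config.cycle_jitter_sd
                    * rng.standard_normal(config.n_cycles))
    periods = np.clip(periods, 0.3 * t0, 3.0 * t0)
    scales = 1.0 + config.amplitude_jitter_sd \
        * rng.standard_normal(config.n_cycles)
    scales = np.clip(scales, 0.1, None)
    phase = _GaitPhase(periods, t0)
    # amplitude scale interpolated between cycle midpoints: continuous, and
    # constant (= edge value) outside the bout
    mids = (phase.boundaries[:-1] + phase.boundaries[1:]) / 2.0
    channels: dict[str, ContinuousSignal] = {}
    for axis in AXES:
        pairs = np.asarray(config.harmonic_amplitudes[axis], dtype=float)
        if pairs.size == 0:
            cos_amps = sin_amps = np.empty(0)
        else:
            pairs = np.atleast_2d(pairs)
            cos_amps, sin_amps = pairs[:, 0], pairs[:, 1]
        channels[axis] = _WarpedHarmonicChannel(
            phase, config.gravity_baseline[axis], cos_amps, sin_amps,
            mids, scales)
    return TriaxialSignal(channels)


def sample_sensor(motion: TriaxialSignal, model: SensorModel,
                  duration: float, seed: int) -> AccelStream:
    """Record the reference motion through one imperfect device.

    Samples at ``model.sampling_frequency`` starting at the device's clock
    offset in world time; applies gain, additive bias, Gaussian noise,
    quantization (round to the nearest step) and clipping to the full-scale
    range.  Timestamps are on the sensor's own clock, starting at 0.
    """
    if duration <= 0:
        raise SimulationError("duration must be positive")
    rng = np.random.default_rng(seed)
    n = int(np.floor(duration * model.sampling_frequency + 1e-9))
    if n < 2:
        raise SimulationError("duration shorter than two sample intervals")
    local_t = np.arange(n) / model.sampling_frequency
    world_t = local_t + model.clock_offset
    channels = {}
    for axis in AXES:
        y = np.asarray(motion[axis](world_t), dtype=float)
        y = model.gain[axis] * y + model.additive_bias[axis]
        if model.noise_sd > 0:
            y = y + model.noise_sd * rng.standard_normal(n)
        if model.quantization_step > 0:
            y = np.round(y / model.quantization_step) * model.quantization_step
        channels[axis] = np.clip(y, -model.clip_range, model.clip_range)
    return AccelStream(local_t, channels,
                       nominal_rate=model.sampling_frequency)


def make_paired_trial(config: SimulationConfig,
                      sens_model: SensorModel | None = None,
                      criterion_model: SensorModel | None = None,
                      duration: float | None = None,
                      ) -> tuple[AccelStream, AccelStream, GroundTruth]:
    """Simulate one walking bout recorded by both devices simultaneously.

    Both streams sample the same reference motion.  Returns
    ``(sparse, criterion, truth)`` where the ground truth records the relative
    clock offset (criterion minus sparse), the per-cycle stride periods and
    the injected per-axis sparse-device bias.
    """
    if sens_model is None:
        sens_model = default_sparse_model()
    if criterion_model is None:
        criterion_model = default_criterion_model()
    motion = simulate_reference_motion(config)
    total = config.n_cycles * config.stride_period
    # regenerate the exact jittered bout length for the duration budget
    rng = np.random.default_rng(config.seed)
    periods = config.stride_period * (
        1.0 + config.cycle_jitter_sd * rng.standard_normal(config.n_cycles))
    periods = np.clip(periods, 0.3 * config.stride_period,
                      3.0 * config.stride_period)
    total = float(np.sum(periods))
    child = np.random.SeedSequence(config.seed).spawn(2)
    seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in child]
    streams = []
    for model, seed in ((sens_model, seeds[0]), (criterion_model, seeds[1])):
        dur = duration if duration is not None else total - model.clock_offset
        streams.append(sample_sensor(motion, model, dur, seed))
    sparse, criterion = streams
    sparse.device_label = sparse.device_label or "sparse"
    criterion.device_label = criterion.device_label or "criterion"
    truth = GroundTruth(
        true_clock_offset=(criterion_model.clock_offset
                           - sens_model.clock_offset),
        true_stride_periods=periods,
        true_bias=dict(sens_model.additive_bias),
        motion=motion,
    )
    return sparse, criterion, truth


# ---------------------------------------------------------------------------
# delimited-text trial I/O
# ---------------------------------------------------------------------------

def write_trial(directory, sparse: AccelStream, criterion: AccelStream,
                truth: GroundTruth | None = None) -> dict[str, str]:
    """Write one trial as delimited text plus a key-value ground-truth sidecar."""
    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {"sparse": str(directory / "sparse.tsv"),
             "criterion": str(directory / "criterion.tsv")}
    sparse.write(paths["sparse"])
    criterion.write(paths["criterion"])
    if truth is not None:
        lines = [f"true_clock_offset_s = {float(truth.true_clock_offset)!r}"]
        lines.append("true_stride_periods_s = " + ",".join(
            repr(float(p)) for p in truth.true_stride_periods))
        for axis, b in truth.true_bias.items():
            lines.append(f"true_bias_{axis}_g = {float(b)!r}")
        path = directory / "ground_truth.txt"
        path.write_text("\n".join(lines) + "\n")
        paths["ground_truth"] = str(path)
    return paths


def read_ground_truth(path) -> dict:
    """Parse the flat key-value ground-truth sidecar written by write_trial."""
    out: dict = {}
    for line in open(path):
        line = line.strip()
        if not line or "=" not in line:
            continue
        key, _, value = line.partition("=")
        key, value = key.strip(), value.strip()
        if "," in value:
            out[key] = np.array([float(v) for v in value.split(",")])
        else:
            out[key] = float(value)
    return out
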
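"""Frequency-domain comparison of averaged gait cycles.

Power spectral densities of the discretized averaged cycles, peak
extraction and cross-device peak matching, Fourier-series coefficients of
the averaged cycle (the first ten pairs by default), and reuse of the
time-domain agreement statistics on those feature families.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks as _scipy_find_peaks
from scipy.signal import periodogram

from .agreement import AgreementResult, compare_series
from .alignment import AveragedCycle


class FrequencyError(ValueError):
    """Raised for invalid spectral inputs."""


@dataclass
class PSDResult:
    """One-sided periodogram with extracted peaks.

    ``density`` integrates to the sample variance (Parseval contract);
    ``peaks`` is a frequency-sorted list of ``(frequency_hz, power_density)``.
    """

    frequency: np.ndarray
    density: np.ndarray
    peaks: list[tuple[float, float]]

    def __post_init__(self) -> None:
        if np.any(self.density < -1e-15):
            raise FrequencyError("negative power density")


def psd(samples, rate: float, zero_pad: int = 4) -> PSDResult:
    """Periodogram of a mean-removed, zero-padded sample array.

    Zero padding (default 4x the length) refines the frequency grid of the
    short averaged-cycle records.  The one-sided density is normalized so
    that ``sum(density) * df`` equals the sample variance.
    """
    x = np.asarray(samples, dtype=float).ravel()
    if rate <= 0:
        raise FrequencyError("rate must be positive")
    if x.size < 16:
        raise FrequencyError("need at least 16 samples for a PSD")
    nfft = zero_pad * x.size
    freq, density = periodogram(x, fs=rate, nfft=nfft, detrend="constant",
                                scaling="density")
    return PSDResult(freq, density, peaks=[])


def find_peaks(psd_result: PSDResult, max_peaks: int = 5,
               band: tuple[float, float] | None = None,
               prominence_frac: float = 0.05,
               min_separation_hz: float = 0.2) -> list[tuple[float, float]]:
    """Extract the dominant spectral peaks.

    Local maxima inside `band` with prominence at least ``prominence_frac``
    of the global maximum are ranked by power, truncated to ``max_peaks``
    and returned sorted by frequency.  ``min_separation_hz`` suppresses
    leakage sidelobes hugging a spectral line (only the tallest peak within
    the separation survives).  An empty list is a valid outcome.
    """
    freq, density = psd_result.frequency, psd_result.density
    if band is None:
        band = (float(freq[0]), float(freq[-1]))
    lo, hi = band
    if lo < freq[0] - 1e-12 or hi > freq[-1] + 1e-12:
        raise FrequencyError(f"band {band} outside the frequency grid")
    mask = (freq >= lo) & (freq <= hi)
    sub = density[mask]
    if sub.size < 3 or sub.max() == 0:
        return []
    prominence = prominence_frac * float(density.max())
    df = float(freq[1] - freq[0])
    distance = max(int(round(min_separation_hz / df)), 1)
    idx, _ = _scipy_find_peaks(sub, prominence=prominence,
                               distance=distance)
    if idx.size == 0:
        return []
    order = np.argsort(sub[idx])[::-1][:max_peaks]
    chosen = np.sort(idx[order])
    base = np.flatnonzero(mask)[0]
    return [(float(freq[base + i]), float(density[base + i])) for i in chosen]


def match_peaks(criterion_peaks, sens_peaks, gate_hz: float = 0.3):
    """Greedy nearest-frequency pairing of two peak lists.

    Candidate pairs are taken in order of increasing frequency difference;
    a pair is accepted when both peaks are still unmatched and their
    frequencies differ by at most ``gate_hz``.  Returns
    ``(pairs, unmatched_criterion, unmatched_sens)`` with pairs as
    ``((f_c, p_c), (f_s, p_s))`` tuples sorted by criterion frequency.
    """
    cand = sorted(
        ((abs(c[0] - s[0]), i, j)
         for i, c in enumerate(criterion_peaks)
         for j, s in enumerate(sens_peaks)),
        key=lambda t: t[0])
    used_c: set[int] = set()
    used_s: set[int] = set()
    pairs = []
    for diff, i, j in cand:
        if diff > gate_hz:
            break
        if i in used_c or j in used_s:
            continue
        used_c.add(i)
        used_s.add(j)
        pairs.append((tuple(criterion_peaks[i]), tuple(sens_peaks[j])))
    pairs.sort(key=lambda p: p[0][0])
    unmatched_c = [tuple(p) for i, p in enumerate(criterion_peaks)
                   if i not in used_c]
    unmatched_s = [tuple(p) for j, p in enumerate(sens_peaks)
                   if j not in used_s]
    return pairs, unmatched_c, unmatched_s


# ---------------------------------------------------------------------------
# Fourier-series coefficients of the averaged cycle
# ---------------------------------------------------------------------------

@dataclass
class FourierCoefficients:
    """Fourier-series representation of one averaged-cycle channel.

    ``y(t) = a0 + sum_i a_i cos(i w t) + sum_i b_i sin(i w t)`` with
    ``w = 2 pi / T`` the angular stride frequency and T the cycle time.
    """

    a0: float
    a: np.ndarray
    b: np.ndarray
    period: float

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        if self.a.size != self.b.size:
            raise FrequencyError("coefficient lists differ in length")
        if self.period <= 0:
            raise FrequencyError("cycle period must be positive")

    @property
    def n_pairs(self) -> int:
        return self.a.size

    @property
    def omega(self) -> float:
        return 2.0 * np.pi / self.period

    def as_vector(self) -> np.ndarray:
        """Interleaved coefficient vector ``[a0, a1, b1, ..., an, bn]``."""
        out = np.empty(1 + 2 * self.n_pairs)
        out[0] = self.a0
        out[1::2] = self.a
        out[2::2] = self.b
        return out

    def reconstruct(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        k = np.arange(1, self.n_pairs + 1)
        arg = self.omega * np.multiply.outer(t, k)
        return self.a0 + np.cos(arg) @ self.a + np.sin(arg) @ self.b


def fourier_coefficients(values, period: float, n_pairs: int = 10,
                         method: str = "trapezoid",
                         closed_grid: bool = True) -> FourierCoefficients:
    """Fourier coefficients of one cycle over its period.

    ``a0 = (1/T) int f dt``, ``a_i = (2/T) int f cos(i w t) dt``,
    ``b_i = (2/T) int f sin(i w t) dt`` over one cycle.  With
    ``method="trapezoid"`` the integrals are composite trapezoid quadrature
    on the cycle grid (``closed_grid=True`` means the samples span [0, T]
    inclusive, as the 101-point percent-cycle grid does); ``method="fft"``
    reads the coefficients off the DFT bins of the half-open grid and is
    exact for band-limited cycles.
    """
    y = np.asarray(values, dtype=float).ravel()
    if n_pairs < 1:
        raise FrequencyError("need at least one coefficient pair")
    if period <= 0:
        raise FrequencyError("period must be positive")
    n_open = y.size - 1 if closed_grid else y.size
    if n_open < 2 * n_pairs + 1:
        raise FrequencyError(
            f"grid of {y.size} points cannot resolve {n_pairs} pairs "
            f"(aliasing: need {2 * n_pairs + 1 + int(closed_grid)})")
    if method == "fft":
        yo = y[:-1] if closed_grid else y
        spec = np.fft.rfft(yo) / n_open
        a0 = float(spec[0].real)
        a = 2.0 * spec[1:n_pairs + 1].real
        b = -2.0 * spec[1:n_pairs + 1].imag
        return FourierCoefficients(a0, a, b, period)
    if method != "trapezoid":
        raise FrequencyError(f"unknown method {method!r}")
    if closed_grid:
        t = np.linspace(0.0, period, y.size)
        yy = y
    else:
        # close the cycle for the trapezoid rule by wrapping the first point
        t = np.linspace(0.0, period, y.size + 1)
        yy = np.concatenate([y, y[:1]])
    omega = 2.0 * np.pi / period
    a0 = float(np.trapezoid(yy, t) / period)
    a = np.empty(n_pairs)
    b = np.empty(n_pairs)
    for i in range(1, n_pairs + 1):
        a[i - 1] = 2.0 / period * np.trapezoid(yy * np.cos(omega * i * t), t)
        b[i - 1] = 2.0 / period * np.trapezoid(yy * np.sin(omega * i * t), t)
    return FourierCoefficients(a0, a, b, period)


def cycle_fourier_features(avg: AveragedCycle, n_pairs: int = 10,
                           method: str = "trapezoid"
                           ) -> dict[str, FourierCoefficients]:
    """Fourier coefficients of every channel of an averaged cycle."""
    return {c: fourier_coefficients(avg.mean[c], avg.stride_period,
                                    n_pairs=n_pairs, method=method)
            for c in avg.channel_names()}


# ---------------------------------------------------------------------------
# agreement on frequency-domain feature families
# ---------------------------------------------------------------------------

def compare_frequency_features(criterion_features: dict,
                               sens_features: dict,
                               n_boot: int = 2000, seed: int | None = 0,
                               min_n: int = 20
                               ) -> dict[str, AgreementResult]:
    """Agreement statistics per feature family.

    `criterion_features` / `sens_features` map family name (e.g.
    ``peak_frequency``, ``peak_power``, ``fourier_coefficient``) to paired
    1-D feature arrays.  Each family is summarized with the non-parametric
    CCC, percentile Bland-Altman and Spearman statistics (DTW/NSI do not
    apply to pooled features).
    """
    out = {}
    for family, crit in criterion_features.items():
        if family not in sens_features:
            raise FrequencyError(f"missing sensor features for {family!r}")
        out[family] = compare_series(np.asarray(crit, dtype=float),
                                     np.asarray(sens_features[family],
                                                dtype=float),
                                     n_boot=n_boot, seed=seed,
                                     include_dtw=False, min_n=min_n)
    return out
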
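"""Model/results facade for one paired-trial agreement analysis.

:class:`AccelerometerAgreement` is constructed from two recordings of the
same walking bout — a sparse wearable stream and a dense criterion stream —
plus the analysis settings.  Its :meth:`~AccelerometerAgreement.fit` runs the
full chain (filter, magnitude, Fourier reconstruction, synchronization,
cycle segmentation, percent-cycle averaging, 60 Hz discretization) and
returns an :class:`AgreementResults` carrying the agreement statistics,
their confidence intervals, the alignment diagnostics and a ``summary()``
table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import agreement as agr
from . import alignment as aln
from . import frequency as frq
from . import signal as sig


@dataclass
class AnalysisSettings:
    """Tunable knobs of the agreement pipeline (defaults follow the study).

    cutoff/filter_order : low-pass Butterworth, 4 Hz / 4th order, zero lag.
    n_cycles : gait cycles analyzed per trial (5).
    n_harmonics : harmonic count of the Fourier-method reconstruction (6,
        i.e. content up to ~5.5 Hz at cadence 110 — above the 4 Hz cutoff).
    stats_rate : discretization rate of the averaged cycle for statistics (60 Hz).
    grid_points : percent-cycle grid of the averaged cycle (101 = 0..100%).
    n_fourier_pairs : Fourier coefficient pairs compared (10).
    max_lag / sync_grid_rate : synchronization search range and common grid.
    peak_band / max_peaks / peak_gate_hz : PSD peak extraction and matching.
    n_boot / seed : bootstrap resamples for CIs and their seed.
    """

    cutoff: float = 4.0
    filter_order: int = 4
    filter_design: str = "per-pass"
    n_cycles: int = 5
    n_harmonics: int = 6
    stats_rate: float = 60.0
    grid_points: int = 101
    n_fourier_pairs: int = 10
    max_lag: float = 2.0
    sync_grid_rate: float = 120.0
    peak_band: tuple[float, float] = (0.25, 5.0)
    max_peaks: int = 5
    peak_gate_hz: float = 0.3
    n_boot: int = 2000
    seed: int = 0
    apply_filter: bool = True
    search_frac: float = 0.25
    #: strides in the synchronization window.  Longer than the 5 analyzed
    #: cycles: the cross-correlation of a quasi-periodic signal has rival
    #: peaks one stride apart, and only accumulated cycle-to-cycle
    #: deviations separate them, so more strides give a safer margin.
    sync_cycles: int = 10


class AccelerometerAgreement:
    """Agreement model between a sparse accelerometer and a criterion device.

    Parameters
    ----------
    sparse, criterion
        :class:`~gaitagree.signal.AccelStream` recordings of the same bout
        (each on its own clock).
    settings
        :class:`AnalysisSettings`; keyword overrides are also accepted.

    Examples
    --------
    >>> from gaitagree import simulate
    >>> s, c, truth = simulate.make_paired_trial(simulate.SimulationConfig(seed=7))
    >>> res = AccelerometerAgreement(s, c).fit()
    >>> 0 < res.time_domain["x"].ccc.value <= 1
    True
    """

    def __init__(self, sparse: sig.AccelStream, criterion: sig.AccelStream,
                 settings: AnalysisSettings | None = None, **overrides):
        if settings is None:
            settings = AnalysisSettings(**overrides)
        elif overrides:
            from dataclasses import replace
            settings = replace(settings, **overrides)
        self.sparse = sparse
        self.criterion = criterion
        self.settings = settings

    @classmethod
    def from_files(cls, sparse_path, criterion_path,
                   settings: AnalysisSettings | None = None,
                   **overrides) -> "AccelerometerAgreement":
        return cls(sig.AccelStream.read(sparse_path, device_label="sparse"),
                   sig.AccelStream.read(criterion_path,
                                        device_label="criterion"),
                   settings=settings, **overrides)

    @classmethod
    def from_simulation(cls, config=None, sens_model=None,
                        criterion_model=None,
                        settings: AnalysisSettings | None = None,
                        **overrides) -> "AccelerometerAgreement":
        from . import simulate as sim
        if config is None:
            config = sim.SimulationConfig()
        sparse, criterion, truth = sim.make_paired_trial(
            config, sens_model, criterion_model)
        model = cls(sparse, criterion, settings=settings, **overrides)
        model.ground_truth = truth
        return model

    # -- pipeline stages -----------------------------------------------

    def _preprocess(self, stream: sig.AccelStream) -> sig.AccelStream:
        st = stream
        if self.settings.apply_filter:
            st = sig.butterworth_zero_lag(st, self.settings.cutoff,
                                          order=self.settings.filter_order,
                                          design=self.settings.filter_design)
        return sig.vector_magnitude(st)  # magnitude after per-axis filtering

    def fit(self) -> "AgreementResults":
        """Run the full pipeline and return the fitted results."""
        s = self.settings
        stage = "preprocessing"
        try:
            sp = self._preprocess(self.sparse)
            cr = self._preprocess(self.criterion)

            stage = "stride-period estimation"
            period = aln.estimate_stride_period(cr["x"], cr.rate)

            stage = "Fourier reconstruction"
            sp_sig = sig.fourier_reconstruct(sp, 1.0 / period,
                                             n_harmonics=s.n_harmonics,
                                             refine=True)
            cr_sig = sig.fourier_reconstruct(cr, 1.0 / period,
                                             n_harmonics=s.n_harmonics,
                                             refine=True)
            # deviation-preserving interpolants: synchronization and
            # segmentation need the cycle-to-cycle irregularities that the
            # periodic harmonic fit smooths away
            sp_spline = sig.spline_interpolant(sp, channels=("x",))
            cr_spline = sig.spline_interpolant(cr, channels=("x",))

            stage = "synchronization"
            sync = self._synchronize(sp_spline, cr_spline, period)
            sp_aligned = sp_sig.shift(sync.lag)

            stage = "cycle segmentation"
            cycles = self._segment(cr_spline, sp_aligned, period)

            stage = "cycle averaging"
            avg_cr = aln.average_normalize(cycles, cr_sig,
                                           grid_points=s.grid_points)
            avg_sp = aln.average_normalize(cycles, sp_aligned,
                                           grid_points=s.grid_points)

            stage = "discretization"
            disc_cr = aln.discretize_for_stats(avg_cr, rate=s.stats_rate)
            disc_sp = aln.discretize_for_stats(avg_sp, rate=s.stats_rate)

            stage = "time-domain agreement"
            time_domain = {
                c: agr.compare_series(disc_cr[c], disc_sp[c],
                                      n_boot=s.n_boot, seed=s.seed)
                for c in avg_cr.channel_names()}

            stage = "frequency-domain agreement"
            spectra, peak_pairs, peak_features = self._peaks(disc_cr, disc_sp)
            fourier_cr = frq.cycle_fourier_features(avg_cr,
                                                    n_pairs=s.n_fourier_pairs)
            fourier_sp = frq.cycle_fourier_features(avg_sp,
                                                    n_pairs=s.n_fourier_pairs)
            fourier_agreement = {
                c: agr.compare_series(fourier_cr[c].as_vector(),
                                      fourier_sp[c].as_vector(),
                                      n_boot=s.n_boot, seed=s.seed,
                                      include_dtw=False, min_n=20)
                for c in fourier_cr}
            peak_agreement = {}
            for family in ("peak_frequency", "peak_power"):
                crit, sens = peak_features[family]
                if crit.size >= 20:
                    peak_agreement[family] = agr.compare_series(
                        crit, sens, n_boot=s.n_boot, seed=s.seed,
                        include_dtw=False, min_n=20)
                else:
                    peak_agreement[family] = None
        except (sig.SignalError, aln.AlignmentError, agr.AgreementError,
                frq.FrequencyError) as exc:
            raise type(exc)(f"[{stage}] {exc}") from exc

        return AgreementResults(
            model=self, settings=s, sync=sync, stride_period=period,
            cycles=cycles, averaged_sparse=avg_sp, averaged_criterion=avg_cr,
            discretized_sparse=disc_sp, discretized_criterion=disc_cr,
            time_domain=time_domain, spectra=spectra,
            peak_pairs=peak_pairs, peak_features=peak_features,
            peak_agreement=peak_agreement,
            fourier_sparse=fourier_sp, fourier_criterion=fourier_cr,
            fourier_agreement=fourier_agreement)

    def _synchronize(self, sp_sig, cr_sig, period):
        s = self.settings
        sp0, sp1 = sp_sig.domain
        cr0, cr1 = cr_sig.domain
        lo, hi = max(cr0, sp0 - s.max_lag), min(cr1, sp1 + s.max_lag)
        # as many strides as fit while keeping the full lag search range,
        # between the 5 analyzed cycles and the sync_cycles target
        fits = (hi - lo - 2.0 * s.max_lag) / period
        cycles = min(s.sync_cycles, max(s.n_cycles, int(fits)))
        cycles = min(cycles, max(int((hi - lo) / period), 1))
        window = aln.middle_window(lo, hi, period, cycles)
        max_lag = min(s.max_lag, window[0] - sp0, sp1 - window[1])
        if max_lag <= 1.0 / s.sync_grid_rate:
            raise aln.AlignmentError(
                "overlap too short for the requested lag search")
        return aln.synchronize(sp_sig["x"], cr_sig["x"], window,
                               max_lag=max_lag,
                               grid_rate=s.sync_grid_rate)

    def _segment(self, cr_sig, sp_aligned, period):
        s = self.settings
        lo = max(cr_sig.domain[0], sp_aligned.domain[0])
        hi = min(cr_sig.domain[1], sp_aligned.domain[1])
        # the template search needs ~one extra stride beyond the last boundary
        need = s.n_cycles + 1 + s.search_frac
        window = aln.middle_window(lo, hi, period, need)
        rate = s.stats_rate
        t, x = sig.resample(cr_sig["x"], rate, window[0], window[1])
        return aln.segment_cycles(x, rate, period, n_cycles=s.n_cycles,
                                  t_start=window[0],
                                  search_frac=s.search_frac)

    def _peaks(self, disc_cr, disc_sp):
        s = self.settings
        spectra = {}
        peak_pairs = {}
        freq_c, freq_s, pow_c, pow_s = [], [], [], []
        for c in disc_cr:
            psd_c = frq.psd(disc_cr[c], s.stats_rate)
            psd_s = frq.psd(disc_sp[c], s.stats_rate)
            band = (max(s.peak_band[0], psd_c.frequency[0]),
                    min(s.peak_band[1], psd_c.frequency[-1]))
            psd_c.peaks = frq.find_peaks(psd_c, max_peaks=s.max_peaks,
                                         band=band)
            psd_s.peaks = frq.find_peaks(psd_s, max_peaks=s.max_peaks,
                                         band=band)
            pairs, _, _ = frq.match_peaks(psd_c.peaks, psd_s.peaks,
                                          gate_hz=s.peak_gate_hz)
            spectra[c] = (psd_c, psd_s)
            peak_pairs[c] = pairs
            for (fc, pc), (fs_, ps_) in pairs:
                freq_c.append(fc)
                freq_s.append(fs_)
                pow_c.append(pc)
                pow_s.append(ps_)
        features = {
            "peak_frequency": (np.asarray(freq_c), np.asarray(freq_s)),
            "peak_power": (np.asarray(pow_c), np.asarray(pow_s))}
        return spectra, peak_pairs, features


@dataclass
class AgreementResults:
    """Fitted agreement statistics for one paired trial.

    ``time_domain`` maps channel (x, y, z, n) to the full time-domain
    :class:`~gaitagree.agreement.AgreementResult`; ``fourier_agreement``
    holds the per-channel agreement of the interleaved Fourier-coefficient
    vectors; ``peak_agreement`` the pooled PSD-peak families (None when
    fewer than 20 matched pairs — pool across trials/subjects instead).
    """

    model: AccelerometerAgreement
    settings: AnalysisSettings
    sync: aln.SyncResult
    stride_period: float
    cycles: aln.GaitCycleSet
    averaged_sparse: aln.AveragedCycle
    averaged_criterion: aln.AveragedCycle
    discretized_sparse: dict[str, np.ndarray]
    discretized_criterion: dict[str, np.ndarray]
    time_domain: dict[str, agr.AgreementResult]
    spectra: dict[str, tuple]
    peak_pairs: dict[str, list]
    peak_features: dict[str, tuple]
    peak_agreement: dict[str, agr.AgreementResult | None]
    fourier_sparse: dict[str, frq.FourierCoefficients]
    fourier_criterion: dict[str, frq.FourierCoefficients]
    fourier_agreement: dict[str, agr.AgreementResult]

    # -- tabular views --------------------------------------------------

    def time_domain_frame(self) -> pd.DataFrame:
        rows = []
        for c, r in self.time_domain.items():
            rows.append({
                "channel": c, "n": r.n_points,
                "ccc": r.ccc.value, "ccc_lo": r.ccc.ci_lower,
                "ccc_hi": r.ccc.ci_upper,
                "nsi": r.nsi, "dtw_distance": r.dtw_distance,
                "bias": r.bias.value, "bias_lo": r.bias.ci_lower,
                "bias_hi": r.bias.ci_upper,
                "loa_lower": r.loa_lower.value,
                "loa_lower_lo": r.loa_lower.ci_lower,
                "loa_lower_hi": r.loa_lower.ci_upper,
                "loa_upper": r.loa_upper.value,
                "loa_upper_lo": r.loa_upper.ci_lower,
                "loa_upper_hi": r.loa_upper.ci_upper,
                "spearman_rho": r.spearman_rho})
        return pd.DataFrame(rows)

    def frequency_frame(self) -> pd.DataFrame:
        rows = []
        for c, r in self.fourier_agreement.items():
            rows.append(_freq_row("fourier_coefficient", c, r))
        for family, r in self.peak_agreement.items():
            if r is not None:
                rows.append(_freq_row(family, "pooled", r))
        return pd.DataFrame(rows)

    def summary(self) -> str:
        """Human-readable summary of alignment and agreement."""
        s = self.settings
        lines = [
            "Accelerometer criterion-validity analysis",
            "=" * 41,
            f"filter: {s.cutoff:g} Hz low-pass Butterworth, order "
            f"{s.filter_order} ({'on' if s.apply_filter else 'off'}), "
            "zero lag",
            f"stride period: {self.stride_period:.4f} s "
            f"({60.0 / self.stride_period * 2:.1f} steps/min)",
            f"clock lag (criterion - sparse): {self.sync.lag:+.4f} s "
            f"(peak r = {self.sync.peak_correlation:.3f})",
            f"cycles: {self.cycles.n_cycles}, mean duration "
            f"{self.cycles.mean_period:.4f} s",
            "",
            "Time domain (criterion - sensor differences, units g):",
        ]
        frame = self.time_domain_frame()
        with pd.option_context("display.float_format", "{:0.4f}".format):
            lines.append(frame[["channel", "n", "ccc", "nsi", "bias",
                                "loa_lower", "loa_upper",
                                "spearman_rho"]].to_string(index=False))
        lines.append("")
        lines.append("Frequency domain:")
        with pd.option_context("display.float_format", "{:0.4f}".format):
            lines.append(self.frequency_frame()[
                ["family", "channel", "n", "ccc", "bias", "loa_lower",
                 "loa_upper"]].to_string(index=False))
        return "\n".join(lines)

    # -- plots -----------------------------------------------------------

    def plot_agreement(self, channel: str = "x", ax_pair=None):
        """Scatter (with identity line) and Bland-Altman panels for a channel."""
        import matplotlib.pyplot as plt

        if ax_pair is None:
            _, ax_pair = plt.subplots(1, 2, figsize=(9, 4))
        ax_sc, ax_ba = ax_pair
        x = self.discretized_criterion[channel]
        y = self.discretized_sparse[channel]
        ax_sc.scatter(x, y, s=12, alpha=0.7)
        span = [min(x.min(), y.min()), max(x.max(), y.max())]
        ax_sc.plot(span, span, "k-", lw=1)
        ax_sc.set_xlabel("criterion (g)")
        ax_sc.set_ylabel("sensor (g)")
        ax_sc.set_title(f"channel {channel}")
        d = x - y
        r = self.time_domain[channel]
        ax_ba.scatter(x, d, s=12, alpha=0.7)
        for v, style in ((r.loa_lower.value, "--"), (r.bias.value, "-"),
                         (r.loa_upper.value, "--")):
            ax_ba.axhline(v, color="k", ls=style, lw=1)
        ax_ba.set_xlabel("criterion (g)")
        ax_ba.set_ylabel("criterion - sensor (g)")
        ax_ba.set_title("Bland-Altman (percentile LoA)")
        return ax_pair


def _freq_row(family: str, channel: str, r: agr.AgreementResult) -> dict:
    return {"family": family, "channel": channel, "n": r.n_points,
            "ccc": r.ccc.value, "ccc_lo": r.ccc.ci_lower,
            "ccc_hi": r.ccc.ci_upper,
            "bias": r.bias.value, "bias_lo": r.bias.ci_lower,
            "bias_hi": r.bias.ci_upper,
            "loa_lower": r.loa_lower.value, "loa_upper": r.loa_upper.value,
            "spearman_rho": r.spearman_rho}
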
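"""Study-level orchestration: trials, subjects, pooled report tables.

Runs the whole workflow — simulate or load paired trials, fit the
per-trial agreement model, pool discretized averaged-cycle points across
subjects per axis, compute test-retest reliability between the two trials
of each device, and render delimited-text report tables plus plots.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import agreement as agr
from . import alignment as aln
from . import frequency as frq
from . import simulate as sim
from .model import AccelerometerAgreement, AnalysisSettings
from .signal import ALL_CHANNELS, AccelStream


class PipelineError(RuntimeError):
    """Raised when a study-level stage cannot proceed."""


@dataclass
class PipelineConfig:
    """Resolved configuration of one pipeline run.

    ``mode`` is ``"simulate"`` (generate paired trials) or ``"files"``
    (read the delimited-text streams named in ``sparse_paths`` /
    ``criterion_paths``, one entry per trial).
    """

    mode: str = "simulate"
    sparse_paths: list = field(default_factory=list)
    criterion_paths: list = field(default_factory=list)
    simulation: sim.SimulationConfig | None = None
    sens_model: sim.SensorModel | None = None
    criterion_model: sim.SensorModel | None = None
    n_subjects: int = 1
    n_trials: int = 2
    cadence_mean: float = 110.0
    cadence_sd: float = 11.0
    settings: AnalysisSettings = field(default_factory=AnalysisSettings)
    axes: tuple[str, ...] = ALL_CHANNELS
    output_dir: str | None = None
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("simulate", "files"):
            raise PipelineError(f"unknown mode {self.mode!r}")
        if self.mode == "files":
            if (not self.sparse_paths
                    or len(self.sparse_paths) != len(self.criterion_paths)):
                raise PipelineError(
                    "files mode needs matching sparse/criterion path lists")


@dataclass
class StudyReport:
    """Pooled study tables plus per-trial diagnostics and provenance."""

    time_table: pd.DataFrame
    icc_table: pd.DataFrame
    frequency_table: pd.DataFrame
    alignment_table: pd.DataFrame
    provenance: dict

    def to_json(self) -> str:
        payload = {
            "tables": {name: getattr(self, name).to_dict(orient="list")
                       for name in ("time_table", "icc_table",
                                    "frequency_table", "alignment_table")},
            "provenance": self.provenance,
        }
        return json.dumps(payload, indent=2)  # keep column order stable

    @classmethod
    def from_json(cls, text: str) -> "StudyReport":
        payload = json.loads(text)
        tables = {name: pd.DataFrame(data)
                  for name, data in payload["tables"].items()}
        return cls(provenance=payload["provenance"], **tables)


def _subject_seeds(master_seed: int, n: int) -> list[int]:
    seq = np.random.SeedSequence(master_seed)
    return [int(s.generate_state(1)[0] % (2 ** 31)) for s in seq.spawn(n)]


def simulate_subject_trials(config: PipelineConfig, subject_seed: int
                            ) -> list[tuple[AccelStream, AccelStream,
                                            sim.GroundTruth]]:
    """Two walking trials of one simulated subject.

    The subject's cadence is drawn from the cohort distribution
    (``cadence_mean`` +/- ``cadence_sd`` steps/min); the two trials share
    that cadence but have independent cycle realizations and sensor noise,
    emulating a within-session retest a few minutes apart.
    """
    rng = np.random.default_rng(subject_seed)
    base = config.simulation or sim.SimulationConfig()
    cadence = rng.normal(config.cadence_mean, config.cadence_sd)
    cadence = float(np.clip(cadence, 60.0, 180.0))
    trials = []
    for trial in range(config.n_trials):
        trial_seed = int(rng.integers(0, 2 ** 31))
        cfg = replace(base, stride_frequency=cadence / 120.0,
                      seed=trial_seed)
        trials.append(sim.make_paired_trial(cfg, config.sens_model,
                                            config.criterion_model))
    return trials


def run_trial_pair(config: PipelineConfig):
    """Fit the agreement model for the first configured trial pair.

    Test-retest reliability needs two trials per subject and is skipped
    here with a warning; use :func:`run_study` for the full report.
    """
    if config.mode == "files":
        model = AccelerometerAgreement.from_files(
            config.sparse_paths[0], config.criterion_paths[0],
            settings=config.settings)
    else:
        seed = _subject_seeds(config.master_seed, 1)[0]
        sparse, criterion, _ = simulate_subject_trials(config, seed)[0]
        model = AccelerometerAgreement(sparse, criterion,
                                       settings=config.settings)
    warnings.warn("single trial pair: test-retest ICC skipped",
                  stacklevel=2)
    return model.fit()


def test_retest(trials1: list[aln.AveragedCycle],
                trials2: list[aln.AveragedCycle],
                axes: tuple[str, ...] = ALL_CHANNELS) -> pd.DataFrame:
    """Per-axis test-retest ICC between first and second trials.

    `trials1` / `trials2` are per-subject averaged cycles from trials 1 and
    2 of one device; subjects' percent-cycle grid points are pooled per
    axis (one ICC value per axis) and ICC(A,1) is computed with grid points
    as rows and the two trials as columns.
    """
    if len(trials1) != len(trials2) or not trials1:
        raise PipelineError("need matching non-empty trial lists")
    rows = []
    for axis in axes:
        t1 = np.concatenate([avg.mean[axis] for avg in trials1])
        t2 = np.concatenate([avg.mean[axis] for avg in trials2])
        icc = agr.icc_two_way_absolute_single(t1, t2)
        rows.append({"channel": axis, "icc": icc.icc,
                     "icc_lo": icc.ci_lower, "icc_hi": icc.ci_upper,
                     "n_points": icc.n_rows})
    return pd.DataFrame(rows)


def run_study(config: PipelineConfig) -> StudyReport:
    """Full study: per-subject trial fits pooled into report tables.

    Per axis, the 60 Hz-discretized averaged-cycle points of all subjects'
    first trials are pooled for the time-domain statistics (NSI is the
    median of per-subject values with a percentile CI across subjects);
    PSD-peak and Fourier-coefficient features are pooled the same way.
    Test-retest ICC uses trials 1 and 2 of each device.
    """
    if config.mode == "files":
        pairs = [[(AccelStream.read(s, device_label="sparse"),
                   AccelStream.read(c, device_label="criterion"), None)]
                 for s, c in zip(config.sparse_paths,
                                 config.criterion_paths)]
    else:
        seeds = _subject_seeds(config.master_seed, config.n_subjects)
        pairs = [simulate_subject_trials(config, s) for s in seeds]

    settings = config.settings
    results = []  # per subject: list of per-trial AgreementResults
    for subj, trials in enumerate(pairs):
        fits = []
        for trial_idx, (sparse, criterion, _) in enumerate(trials):
            try:
                fits.append(AccelerometerAgreement(
                    sparse, criterion, settings=settings).fit())
            except Exception as exc:
                raise PipelineError(
                    f"subject {subj}, trial {trial_idx}: {exc}") from exc
        results.append(fits)

    axes = [a for a in config.axes if a in results[0][0].time_domain]
    boot_seed = _subject_seeds(config.master_seed + 1, 1)[0]

    # --- pooled time-domain table (first trials) ---
    time_rows = []
    for axis in axes:
        crit = np.concatenate([r[0].discretized_criterion[axis]
                               for r in results])
        sens = np.concatenate([r[0].discretized_sparse[axis]
                               for r in results])
        stats = agr.compare_series(crit, sens, n_boot=settings.n_boot,
                                   seed=boot_seed, include_dtw=False)
        nsis = np.array([r[0].time_domain[axis].nsi for r in results])
        row = {"channel": axis, "n": stats.n_points,
               "ccc": stats.ccc.value, "ccc_lo": stats.ccc.ci_lower,
               "ccc_hi": stats.ccc.ci_upper,
               "nsi": float(np.median(nsis)),
               "nsi_lo": float(np.percentile(nsis, 2.5)),
               "nsi_hi": float(np.percentile(nsis, 97.5)),
               "bias": stats.bias.value, "bias_lo": stats.bias.ci_lower,
               "bias_hi": stats.bias.ci_upper,
               "loa_lower": stats.loa_lower.value,
               "loa_lower_lo": stats.loa_lower.ci_lower,
               "loa_lower_hi": stats.loa_lower.ci_upper,
               "loa_upper": stats.loa_upper.value,
               "loa_upper_lo": stats.loa_upper.ci_lower,
               "loa_upper_hi": stats.loa_upper.ci_upper,
               "spearman_rho": stats.spearman_rho}
        time_rows.append(row)
    time_table = pd.DataFrame(time_rows)

    # --- test-retest ICC per device (needs two trials) ---
    icc_frames = []
    if all(len(r) >= 2 for r in results):
        for device, attr in (("sparse", "averaged_sparse"),
                             ("criterion", "averaged_criterion")):
            t1 = [getattr(r[0], attr) for r in results]
            t2 = [getattr(r[1], attr) for r in results]
            frame = test_retest(t1, t2, axes=tuple(axes))
            frame.insert(0, "device", device)
            icc_frames.append(frame)
    else:
        warnings.warn("fewer than two trials per subject: ICC skipped",
                      stacklevel=2)
    icc_table = (pd.concat(icc_frames, ignore_index=True)
                 if icc_frames else pd.DataFrame(
                     columns=["device", "channel", "icc", "icc_lo",
                              "icc_hi", "n_points"]))

    # --- pooled frequency-domain table ---
    freq_rows = []
    for axis in axes:
        crit = np.concatenate([r[0].fourier_criterion[axis].as_vector()
                               for r in results])
        sens = np.concatenate([r[0].fourier_sparse[axis].as_vector()
                               for r in results])
        stats = agr.compare_series(crit, sens, n_boot=settings.n_boot,
                                   seed=boot_seed, include_dtw=False)
        freq_rows.append(_freq_table_row("fourier_coefficient", axis, stats))
    for family in ("peak_frequency", "peak_power"):
        pooled_crit, pooled_sens = [], []
        for axis in axes:
            crit_parts, sens_parts = [], []
            for r in results:
                for (fc, pc), (fs_, ps_) in r[0].peak_pairs.get(axis, []):
                    crit_parts.append(fc if family == "peak_frequency"
                                      else pc)
                    sens_parts.append(fs_ if family == "peak_frequency"
                                      else ps_)
            pooled_crit += crit_parts
            pooled_sens += sens_parts
            if len(crit_parts) >= 20:
                stats = agr.compare_series(
                    np.asarray(crit_parts), np.asarray(sens_parts),
                    n_boot=settings.n_boot, seed=boot_seed,
                    include_dtw=False)
                freq_rows.append(_freq_table_row(family, axis, stats))
        if len(pooled_crit) >= 20:
            stats = agr.compare_series(
                np.asarray(pooled_crit), np.asarray(pooled_sens),
                n_boot=settings.n_boot, seed=boot_seed, include_dtw=False)
            freq_rows.append(_freq_table_row(family, "all", stats))
    frequency_table = pd.DataFrame(freq_rows)

    # --- alignment diagnostics ---
    align_rows = []
    for subj, fits in enumerate(results):
        for trial_idx, r in enumerate(fits):
            align_rows.append({
                "subject": subj, "trial": trial_idx,
                "lag_s": r.sync.lag,
                "peak_correlation": r.sync.peak_correlation,
                "stride_period_s": r.stride_period,
                "n_cycles": r.cycles.n_cycles})
    alignment_table = pd.DataFrame(align_rows)

    provenance = {
        "mode": config.mode,
        "n_subjects": len(results),
        "n_trials": min(len(r) for r in results),
        "master_seed": config.master_seed,
        "settings": asdict(settings),
    }
    return StudyReport(time_table=time_table, icc_table=icc_table,
                       frequency_table=frequency_table,
                       alignment_table=alignment_table,
                       provenance=provenance)


def _freq_table_row(family: str, axis: str,
                    stats: agr.AgreementResult) -> dict:
    return {"family": family, "channel": axis, "n": stats.n_points,
            "ccc": stats.ccc.value, "ccc_lo": stats.ccc.ci_lower,
            "ccc_hi": stats.ccc.ci_upper,
            "bias": stats.bias.value, "bias_lo": stats.bias.ci_lower,
            "bias_hi": stats.bias.ci_upper,
            "loa_lower": stats.loa_lower.value,
            "loa_upper": stats.loa_upper.value,
            "spearman_rho": stats.spearman_rho}


def render_report(report: StudyReport, output_dir, plots: bool = False,
                  results=None) -> list[str]:
    """Write the report tables (TSV), a summary, JSON, and optional plots.

    Re-rendering a report loaded back from its JSON file reproduces the
    tables byte-identically.
    """
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for name, fname in (("time_table", "time_domain.tsv"),
                        ("icc_table", "icc.tsv"),
                        ("frequency_table", "frequency_domain.tsv"),
                        ("alignment_table", "alignment.tsv")):
        path = out / fname
        getattr(report, name).to_csv(path, sep="\t", index=False)
        written.append(str(path))
    json_path = out / "report.json"
    json_path.write_text(report.to_json())
    written.append(str(json_path))
    summary = out / "summary.txt"
    lines = ["Study report", "============", ""]
    for key, value in sorted(report.provenance.items()):
        if key != "settings":
            lines.append(f"{key}: {value}")
    for name in ("time_table", "icc_table", "frequency_table"):
        frame = getattr(report, name)
        lines += ["", name.replace("_", " "), "-" * len(name)]
        lines.append(frame.to_string(index=False) if len(frame)
                     else "(empty)")
    summary.write_text("\n".join(lines) + "\n")
    written.append(str(summary))
    if plots and results:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        first = results[0][0] if isinstance(results[0], list) else results[0]
        for axis in first.time_domain:
            fig, ax_pair = plt.subplots(1, 2, figsize=(9, 4))
            first.plot_agreement(axis, ax_pair=ax_pair)
            fig.tight_layout()
            path = out / f"agreement_{axis}.png"
            fig.savefig(path, dpi=110)
            plt.close(fig)
            written.append(str(path))
    return written
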
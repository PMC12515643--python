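"""End-to-end orchestration: configuration, simulate/analyze/report commands.

The three commands tie the stages together behind a single structured
configuration (JSON or YAML):

* ``cmd_simulate`` writes a synthetic EEG recording (with planted templates
  and label sequence), a synthetic EMG recording (with analytic features)
  and the clinical score fixture.
* ``cmd_analyze`` runs preprocessing → microstate analysis → EMG features →
  statistics and writes parameter/feature tables plus a clinical report.
* ``cmd_report`` re-derives the clinical outcomes report from a score table.

Every output CSV gets a JSON provenance sidecar (config hash, seed, package
version); stage progress is logged as machine-parsable ``key=value`` lines.
Fixed config + seed gives byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .clinical import clinical_outcomes_report
from .emg import feature_table
from .io import (EEG_CHANNELS, EMG_MUSCLES, Recording, read_recording,
                 write_recording_csv)
from .microstates import (TopographyModel, aggregate_group_model, backfit,
                          builtin_reference_maps, extract_peak_maps,
                          global_explained_variance, label_classes,
                          microstate_parameters, modified_kmeans,
                          smooth_labels, spatial_correlation)
from .preprocess import (bandpass_filter, common_average_reference, epoch,
                         notch_filter, reject_amplitude, resample)
from .synth import clinical_fixture, make_templates, simulate_eeg, simulate_emg

logger = logging.getLogger("motorstates")

__all__ = ["PipelineConfig", "cmd_simulate", "cmd_analyze", "cmd_report",
           "preprocess_recording", "microstate_pipeline", "read_recording"]

#: half the healthy-control peak-to-peak amplitude per muscle (μV) — used as
#: the default planted sinusoid amplitude of the EMG simulator.
_DEFAULT_EMG_AMPLITUDES = {
    "FDS": 4.37, "FCU": 4.46, "FCR": 4.71, "ECU": 7.42, "ECRL": 5.32,
    "BB": 3.47, "TB": 7.46, "DM": 3.39, "DA": 4.93, "DP": 4.22,
}


@dataclass
class PipelineConfig:
    """All knobs of the pipeline, with the study protocol as defaults."""

    out_dir: str = "motorstates_out"
    # input paths (default to the simulate outputs inside out_dir)
    eeg_path: str | None = None
    emg_path: str | None = None
    scores_path: str | None = None
    # preprocessing
    eeg_band: tuple = (0.5, 45.0)
    emg_band: tuple = (20.0, 400.0)
    notch_hz: float = 50.0
    resample_fs: float = 500.0
    epoch_len_s: float = 2.0
    reject_uv: float = 80.0
    # microstates
    k: int = 5
    n_restarts: int = 50
    min_duration_ms: float = 0.0
    # statistics
    correction: str = "fdr_bh"
    welch: bool = False
    # simulation
    sim_duration_s: float = 120.0
    sim_fs: float = 1000.0
    sim_snr_db: float = 10.0
    sim_n_channels: int = 16
    sim_mean_dwell_ms: float = 60.0
    sim_class_rates: list = field(default_factory=lambda: [1.0] * 5)
    sim_emg_amplitudes: list = field(
        default_factory=lambda: list(_DEFAULT_EMG_AMPLITUDES.values()))
    seed: int = 0

    def validate(self) -> None:
        if self.k < 1:
            raise ValueError("k must be ≥ 1")
        if self.n_restarts < 1:
            raise ValueError("n_restarts must be ≥ 1")
        low, high = self.eeg_band
        if not 0 < low < high < self.resample_fs / 2:
            raise ValueError("eeg_band must satisfy 0 < low < high < Nyquist")
        if self.reject_uv <= 0 or self.epoch_len_s <= 0:
            raise ValueError("reject_uv and epoch_len_s must be positive")
        if self.sim_duration_s <= 0 or self.sim_fs <= 0:
            raise ValueError("simulation duration and rate must be positive")
        if len(self.sim_class_rates) != self.k:
            raise ValueError("sim_class_rates needs one rate per class")
        if any(r <= 0 for r in self.sim_class_rates):
            raise ValueError("class rates must be positive")
        if any(a < 0 for a in self.sim_emg_amplitudes):
            raise ValueError("EMG amplitudes must be non-negative")

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["eeg_band"] = list(self.eeg_band)
        d["emg_band"] = list(self.emg_band)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        for key in ("eeg_band", "emg_band"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".yaml", ".yml"):
            import yaml

            return cls.from_dict(yaml.safe_load(text))
        return cls.from_dict(json.loads(text))

    def hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _provenance(config: PipelineConfig, **extra) -> dict:
    return {"config_hash": config.hash(), "seed": config.seed,
            "package_version": __version__, **extra}


def _write_csv(df: pd.DataFrame, path: Path, config: PipelineConfig, **extra) -> Path:
    df.to_csv(path, float_format="%.6g")
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(_provenance(config, **extra), indent=1, sort_keys=True))
    return path


# ---------------------------------------------------------------------------
# library-level stages

def preprocess_recording(rec: Recording, config: PipelineConfig):
    """Run the conditioning chain for one recording; returns a screened EpochSet.

    EEG: band-pass → notch → resample → common average reference → epoch →
    amplitude rejection. EMG: band-pass → resample → epoch (same 2 s grid,
    no re-referencing or amplitude screening).
    """
    band = config.eeg_band if rec.modality == "EEG" else config.emg_band
    rec = bandpass_filter(rec, *band)
    if rec.modality == "EEG" and config.notch_hz < rec.fs / 2:
        rec = notch_filter(rec, config.notch_hz)
    rec = resample(rec, config.resample_fs)
    if rec.modality == "EEG":
        rec = common_average_reference(rec)
    epochs = epoch(rec, config.epoch_len_s)
    if rec.modality == "EEG":
        epochs = reject_amplitude(epochs, config.reject_uv)
    logger.info("stage=preprocess modality=%s epochs_total=%d epochs_kept=%d",
                rec.modality, epochs.n_epochs, epochs.n_kept)
    return epochs


def microstate_pipeline(epochs, config: PipelineConfig,
                        references: TopographyModel | None = None) -> dict:
    """Single-subject microstate analysis on screened epochs.

    Clusters GFP-peak maps with the polarity-invariant modified K-means,
    orders the templates against reference maps (built-in canonical A-E on
    the 16-channel montage by default), backfits every sample, optionally
    smooths sub-threshold runs, and extracts duration/coverage/occurrence.
    """
    peak_maps = extract_peak_maps(epochs)
    model = modified_kmeans(peak_maps, config.k, n_restarts=config.n_restarts,
                            seed=config.seed, channel_labels=epochs.channel_labels)
    if references is None and config.k == 5 and set(epochs.channel_labels) <= set(EEG_CHANNELS):
        references = builtin_reference_maps(epochs.channel_labels)
    if references is not None:
        model = label_classes(model, references)
    labels = backfit(epochs, model)
    if config.min_duration_ms > 0:
        labels = smooth_labels(labels, config.min_duration_ms)
    params = microstate_parameters(labels)
    gev = global_explained_variance(epochs, model, labels)
    logger.info("stage=microstates n_peak_maps=%d k=%d gev=%.4f",
                peak_maps.shape[0], config.k, gev)
    return {"model": model, "labels": labels, "params": params, "gev": gev,
            "n_peaks": peak_maps.shape[0]}


# ---------------------------------------------------------------------------
# commands

def cmd_simulate(config: PipelineConfig) -> list[Path]:
    """Write synthetic EEG + EMG recordings, ground truth and the score fixture."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    seeds = np.random.SeedSequence(config.seed).generate_state(3)

    templates = make_templates(config.sim_n_channels, config.k, seed=int(seeds[0]))
    rec, truth = simulate_eeg(
        templates, config.sim_class_rates,
        [config.sim_mean_dwell_ms] * config.k, snr_db=config.sim_snr_db,
        fs=config.sim_fs, duration_s=config.sim_duration_s, seed=int(seeds[1]))
    written.append(write_recording_csv(rec, out / "eeg.csv", meta=_provenance(config)))
    written.append(_write_csv(
        pd.DataFrame(templates.maps, index=pd.Index(templates.class_labels, name="class"),
                     columns=rec.channel_labels),
        out / "planted_templates.csv", config))
    written.append(_write_csv(
        pd.DataFrame({"label": truth.label_sequence}).rename_axis("sample"),
        out / "planted_labels.csv", config, fs=config.sim_fs))

    n_emg = len(config.sim_emg_amplitudes)
    emg_rec, analytic = simulate_emg(n_emg, config.sim_emg_amplitudes,
                                     fs=config.sim_fs, duration_s=config.sim_duration_s,
                                     seed=int(seeds[2]))
    written.append(write_recording_csv(emg_rec, out / "emg.csv", meta=_provenance(config)))
    written.append(_write_csv(analytic, out / "emg_ground_truth.csv", config))

    written.append(_write_csv(clinical_fixture(), out / "clinical_scores.csv", config))
    logger.info("stage=simulate files=%d out_dir=%s", len(written), out)
    return written


def cmd_analyze(config: PipelineConfig,
                references: TopographyModel | None = None) -> list[Path]:
    """Run preprocess → microstates → EMG features → statistics and write tables."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    eeg_path = Path(config.eeg_path or out / "eeg.csv")
    emg_path = Path(config.emg_path or out / "emg.csv")
    scores_path = Path(config.scores_path or out / "clinical_scores.csv")

    if eeg_path.exists():
        rec = read_recording(eeg_path, modality="EEG")
        epochs = preprocess_recording(rec, config)
        if epochs.n_kept == 0:
            raise RuntimeError("stage=preprocess error=all EEG epochs rejected")
        try:
            result = microstate_pipeline(epochs, config)
        except ValueError as exc:
            raise RuntimeError(f"stage=microstates error={exc}") from exc
        model, params = result["model"], result["params"]
        written.append(_write_csv(
            pd.DataFrame(model.maps, index=pd.Index(model.class_labels, name="class"),
                         columns=epochs.channel_labels),
            out / "microstate_templates.csv", config, gev=result["gev"]))
        written.append(_write_csv(params.to_frame(), out / "microstate_parameters.csv",
                                  config, gev=result["gev"]))
        planted = out / "planted_templates.csv"
        if planted.exists():
            truth = pd.read_csv(planted, index_col=0)
            corr = np.abs(spatial_correlation(model.maps, truth.to_numpy()))
            recovery = float(corr.max(axis=0).min())
            logger.info("stage=recovery min_abs_corr=%.4f", recovery)

    if emg_path.exists():
        emg_rec = read_recording(emg_path, modality="EMG")
        emg_epochs = preprocess_recording(emg_rec, config)
        features = feature_table(emg_epochs)
        written.append(_write_csv(features, out / "emg_features.csv", config))
        logger.info("stage=emg_features muscles=%d", features.shape[0])

    if scores_path.exists():
        scores = pd.read_csv(scores_path, index_col=0)
        report = clinical_outcomes_report(scores)
        written.append(_write_csv(report, out / "clinical_report.csv", config))
        logger.info("stage=stats outcomes=%d", report.shape[0])

    if not written:
        raise FileNotFoundError("no inputs found: run simulate first or set paths")
    return written


def cmd_report(config: PipelineConfig) -> list[Path]:
    """Clinical outcomes report from a score table alone."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scores_path = Path(config.scores_path or out / "clinical_scores.csv")
    if not scores_path.exists():
        scores = clinical_fixture()
    else:
        scores = pd.read_csv(scores_path, index_col=0)
    report = clinical_outcomes_report(scores)
    return [_write_csv(report, out / "clinical_report.csv", config)]
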
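"""Synthetic EEG/EMG generators with planted ground truth.

Because no recordings are distributed with the study design this package
targets, every downstream stage is exercised on simulated data with known
ground truth:

* ``make_templates`` draws K mutually distinguishable zero-mean unit-norm
  scalp maps.
* ``simulate_eeg`` emits a semi-Markov microstate sequence: class identities
  are drawn i.i.d. proportionally to the requested per-class rates with
  adjacent same-class draws merged (so the emitted run structure never has
  an immediate self-transition), dwell times are gamma-distributed with the
  requested class means, the active template is scaled by a rectified
  ~10 Hz amplitude envelope (placing GFP peaks at roughly 20/s, the resting
  alpha phenomenology), and spatially white Gaussian noise is added at a
  target SNR defined on the GFP power ratio.
* ``simulate_emg`` emits band-limited sinusoidal burst channels whose
  peak-to-peak and RMS amplitudes are known in closed form.

All generators are deterministic given a seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import EEG_CHANNELS, EMG_MUSCLES, Recording
from .microstates import TopographyModel, normalize_maps

__all__ = [
    "SimulationGroundTruth", "make_templates", "simulate_eeg", "simulate_emg",
    "clinical_fixture",
]


@dataclass
class SimulationGroundTruth:
    """Planted truth for one simulated EEG recording."""

    templates: TopographyModel
    label_sequence: np.ndarray      # planted class index per sample
    class_rates: np.ndarray         # requested draw rates (1/s) per class
    mean_dwell_ms: np.ndarray       # requested mean dwell per class (ms)
    snr_db: float
    seed: int
    fs: float

    def coverage_fraction(self) -> np.ndarray:
        """Empirical per-class coverage fraction of the planted sequence."""
        counts = np.bincount(self.label_sequence, minlength=self.templates.K)
        return counts / self.label_sequence.size

    def occurrence_per_s(self) -> np.ndarray:
        """Empirical distinct-run rate (1/s) per class in the planted sequence."""
        lab = self.label_sequence
        starts = np.concatenate(([True], lab[1:] != lab[:-1]))
        counts = np.bincount(lab[starts], minlength=self.templates.K)
        return counts / (lab.size / self.fs)

    def mean_run_ms(self) -> np.ndarray:
        """Empirical mean run length (ms) per class in the planted sequence."""
        lab = self.label_sequence
        starts = np.concatenate(([True], lab[1:] != lab[:-1]))
        run_classes = lab[starts]
        idx = np.flatnonzero(starts)
        lengths = np.diff(np.concatenate((idx, [lab.size])))
        out = np.full(self.templates.K, np.nan)
        for k in range(self.templates.K):
            sel = run_classes == k
            if sel.any():
                out[k] = lengths[sel].mean() * 1000.0 / self.fs
        return out


def make_templates(n_channels: int, K: int, seed: int | None = None,
                   max_abs_corr: float = 0.6, max_tries: int = 2000,
                   channel_labels: list[str] | None = None) -> TopographyModel:
    """Draw K random zero-mean unit-norm maps with pairwise |r| ≤ ``max_abs_corr``.

    Zero-mean maps live in an (n_channels − 1)-dimensional subspace, so at
    least K + 1 channels are required for K mutually distinguishable maps.
    """
    if n_channels < K + 1:
        raise ValueError(
            f"degenerate geometry: {K} distinguishable zero-mean maps need "
            f"at least {K + 1} channels, got {n_channels}")
    rng = np.random.default_rng(seed)
    maps: list[np.ndarray] = []
    tries = 0
    while len(maps) < K:
        cand = normalize_maps(rng.standard_normal((1, n_channels)))[0]
        if all(abs(cand @ m) <= max_abs_corr for m in maps):
            maps.append(cand)
        tries += 1
        if tries > max_tries:
            raise RuntimeError("could not place templates; relax max_abs_corr")
    if channel_labels is None and n_channels == len(EEG_CHANNELS):
        channel_labels = EEG_CHANNELS
    return TopographyModel(np.array(maps), channel_labels=channel_labels)


def _planted_labels(rng: np.random.Generator, n_samples: int, fs: float,
                    rates: np.ndarray, dwell_ms: np.ndarray,
                    dwell_shape: float) -> np.ndarray:
    """i.i.d. class draws by rate, gamma dwell times, adjacent repeats merged."""
    p = rates / rates.sum()
    labels = np.empty(n_samples, dtype=int)
    pos = 0
    while pos < n_samples:
        k = rng.choice(len(p), p=p)
        d_ms = rng.gamma(dwell_shape, dwell_ms[k] / dwell_shape)
        n = max(1, int(round(d_ms * fs / 1000.0)))
        labels[pos:pos + n] = k
        pos += n
    return labels


def simulate_eeg(templates: TopographyModel, class_rates, mean_dwell_ms,
                 snr_db: float, fs: float, duration_s: float, seed: int | None = None,
                 amplitude_uv: float = 40.0, envelope_freq_hz: float = 10.0,
                 dwell_shape: float = 2.0) -> tuple[Recording, SimulationGroundTruth]:
    """Simulate resting EEG whose GFP-peak topographies follow planted templates.

    Parameters
    ----------
    templates : TopographyModel
        Planted microstate maps (zero-mean, unit-norm).
    class_rates : array-like, shape (K,)
        Relative draw rate per class (1/s); governs planted coverage.
    mean_dwell_ms : array-like, shape (K,)
        Mean of the gamma dwell-time distribution per class (ms).
    snr_db : float
        Signal-to-noise ratio in dB on the GFP power ratio; ``np.inf``
        disables noise.
    fs, duration_s : float
        Sampling rate (Hz) and length (s) of the recording.
    amplitude_uv : float
        Peak scalp amplitude scale; with unit-norm templates a value of 40
        gives peak GFP near 10 μV on 16 channels.
    envelope_freq_hz : float
        Frequency of the rectified sinusoidal amplitude envelope; GFP peaks
        occur at twice this frequency.
    dwell_shape : float
        Gamma shape of the dwell distribution (2 by default: smooth,
        unimodal dwell times).
    """
    if templates.K == 0:
        raise ValueError("empty template set")
    if duration_s <= 0 or fs <= 0:
        raise ValueError("duration and sampling rate must be positive")
    rates = np.asarray(class_rates, dtype=float)
    dwell = np.asarray(mean_dwell_ms, dtype=float)
    if rates.shape != (templates.K,) or dwell.shape != (templates.K,):
        raise ValueError("class_rates and mean_dwell_ms must have one entry per class")
    if np.any(rates <= 0) or np.any(dwell <= 0):
        raise ValueError("rates and dwell times must be positive")

    rng = np.random.default_rng(seed)
    n_samples = int(round(duration_s * fs))
    labels = _planted_labels(rng, n_samples, fs, rates, dwell, dwell_shape)

    t = np.arange(n_samples) / fs
    envelope = np.abs(np.sin(2 * np.pi * envelope_freq_hz * t))
    signal = templates.maps[labels].T * (amplitude_uv * envelope)  # (n_ch, n_samp)

    n_ch = templates.n_channels
    if np.isfinite(snr_db):
        centered = signal - signal.mean(axis=0, keepdims=True)
        sig_gfp2 = float(np.mean(np.mean(centered**2, axis=0)))
        # white noise of variance s² has E[GFP²] = s²(n−1)/n
        noise_var = sig_gfp2 / (10.0 ** (snr_db / 10.0)) * n_ch / (n_ch - 1)
        signal = signal + rng.normal(0.0, np.sqrt(noise_var), size=signal.shape)

    chans = templates.channel_labels or [f"ch{i + 1:02d}" for i in range(n_ch)]
    rec = Recording(signal, fs=fs, channel_labels=chans, modality="EEG")
    truth = SimulationGroundTruth(templates, labels, rates, dwell,
                                  snr_db=snr_db, seed=seed if seed is not None else -1,
                                  fs=fs)
    return rec, truth


def simulate_emg(n_channels: int, amplitudes, fs: float, duration_s: float,
                 seed: int | None = None, carrier_hz: float = 80.0,
                 burst_duty: float = 1.0, noise_uv: float = 0.0,
                 ) -> tuple[Recording, pd.DataFrame]:
    """Simulate surface-EMG channels with known PTP and RMS.

    Each channel is a sinusoidal carrier inside the 20-400 Hz EMG band,
    optionally gated by a 1 Hz on/off burst envelope of duty cycle
    ``burst_duty``. The carrier frequency is snapped so the recording (and
    each burst) contains a whole number of periods, making the analytic
    features exact: PTP = 2a and RMS = a·sqrt(duty)/sqrt(2).

    Returns the recording and a DataFrame of the analytic per-channel
    ``ptp_uV`` and ``rms_uV``.
    """
    amplitudes = np.broadcast_to(np.asarray(amplitudes, dtype=float), (n_channels,)).copy()
    if np.any(amplitudes < 0):
        raise ValueError("amplitudes must be non-negative")
    if duration_s <= 0 or fs <= 0:
        raise ValueError("duration and sampling rate must be positive")
    if not 0 < burst_duty <= 1:
        raise ValueError("burst_duty must be in (0, 1]")
    rng = np.random.default_rng(seed)
    n_samples = int(round(duration_s * fs))
    t = np.arange(n_samples) / fs
    f = max(1, round(carrier_hz * duration_s)) / duration_s  # whole periods overall
    gate = np.ones(n_samples)
    if burst_duty < 1:
        phase = t % 1.0                       # 1 Hz burst cycle
        gate = (phase < burst_duty).astype(float)
        f = max(1, round(carrier_hz * burst_duty)) / burst_duty  # whole periods per burst
    carrier = np.sin(2 * np.pi * f * t)
    data = amplitudes[:, None] * carrier[None, :] * gate[None, :]
    if noise_uv > 0:
        data = data + rng.normal(0.0, noise_uv, size=data.shape)
    labels = EMG_MUSCLES if n_channels == len(EMG_MUSCLES) else [
        f"emg{i + 1:02d}" for i in range(n_channels)]
    rec = Recording(data, fs=fs, channel_labels=labels, modality="EMG")
    analytic = pd.DataFrame(
        {"ptp_uV": np.where(amplitudes > 0, 2 * amplitudes, 0.0),
         "rms_uV": amplitudes * np.sqrt(burst_duty) / np.sqrt(2.0)},
        index=pd.Index(labels, name="muscle"))
    return rec, analytic


# ---------------------------------------------------------------------------
# clinical score fixture

_TABLE1_ROWS = [
    # subject, sex, age, affected_side, stroke_type, fma_pre, fma_post, arat_pre, arat_post
    (1, "M", 59, "Right", "Ischemic", 4, 7, 0, 0),
    (2, "M", 69, "Right", "Ischemic", 47, 49, 43, 47),
    (3, "F", 80, "Right", "Ischemic", 49, 49, 46, 48),
    (4, "M", 48, "Right", "Hemorrhagic", 13, 13, 0, 0),
    (5, "M", 55, "Right", "Ischemic", 60, 60, 54, 54),
    (6, "M", 66, "Right", "Ischemic", 64, 64, 54, 54),
    (7, "F", 58, "Right", "Ischemic", 8, 9, 0, 0),
    (8, "M", 64, "Right", "Hemorrhagic", 63, 63, 54, 54),
    (9, "M", 48, "Right", "Hemorrhagic", 8, 12, 0, 0),
    (10, "F", 58, "Right", "Ischemic", 7, 11, 0, 0),
    (11, "F", 59, "Right", "Ischemic", 13, 13, 2, 2),
    (12, "M", 42, "Right", "Hemorrhagic", 32, 39, 26, 30),
    (13, "M", 68, "Right", "Ischemic", 10, 12, 4, 4),
    (14, "F", 55, "Right", "Hemorrhagic", 7, 7, 0, 0),
    (15, "M", 75, "Right", "Ischemic", 54, 59, 54, 55),
    (16, "M", 60, "Right", "Hemorrhagic", 33, 38, 35, 39),
    (17, "M", 73, "Right", "Ischemic", 52, 57, 53, 55),
    (18, "F", 80, "Right", "Ischemic", 36, 39, 36, 38),
    (19, "F", 73, "Right", "Ischemic", 18, 19, 10, 10),
    (20, "M", 72, "Right", "Ischemic", 52, 53, 55, 55),
]


def clinical_fixture() -> pd.DataFrame:
    """Per-subject clinical scores of the 20-patient stroke cohort.

    Columns: subject id, sex, age (years), affected side, stroke type, and
    FMA-UE (0-66) / ARAT (0-57) scores before and after the one-week rTMS
    course. FMA-UE and ARAT are the standard upper-limb motor impairment
    and function scales; higher is better.
    """
    return pd.DataFrame(
        _TABLE1_ROWS,
        columns=["subject", "sex", "age", "affected_side", "stroke_type",
                 "fma_ue_pre", "fma_ue_post", "arat_pre", "arat_post"],
    ).set_index("subject")
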
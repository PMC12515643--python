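"""EEG microstate analysis: GFP, topographic clustering, backfitting, parameters.

Resting EEG is modelled as a sequence of quasi-stable scalp topographies
("microstates"). The analysis here follows the standard pipeline:

1. Global field power (GFP) — the spatial standard deviation of the scalp
   map at each time point — is computed per epoch, and its local maxima are
   taken as the moments of highest topographic signal-to-noise.
2. The maps at GFP peaks are clustered with a polarity-invariant modified
   K-means: a map and its sign flip are equivalent, assignment maximises the
   squared spatial correlation, and each cluster centre is updated as the
   dominant eigenvector of the cross-product matrix of its assigned maps.
3. Subject-level template sets are pooled and re-clustered into a group
   model, whose maps are assigned the canonical class letters A-E by best
   permutation match against reference topographies.
4. The group templates are backfitted competitively to every sample, and the
   per-class mean duration (ms), time coverage (%) and occurrence (1/s) are
   extracted from the resulting label sequence.

Polarity is ignored everywhere: all correlations are used in absolute value
(or squared), so flipping the sign of any map, epoch or template changes no
label and no parameter.
"""

from __future__ import annotations

import itertools
import string
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .io import EEG_CHANNELS, EpochSet

__all__ = [
    "GfpSeries", "TopographyModel", "LabelSequence", "MicrostateParams",
    "compute_gfp", "find_gfp_peaks", "extract_peak_maps", "spatial_correlation",
    "modified_kmeans", "aggregate_group_model", "backfit", "label_classes",
    "microstate_parameters", "global_explained_variance",
    "builtin_reference_maps", "smooth_labels",
]

UNLABELED = -1  # samples with zero spatial variance cannot be correlated


# ---------------------------------------------------------------------------
# containers

@dataclass
class GfpSeries:
    """Global field power curve for one epoch, with detected peaks."""

    values: np.ndarray  # per-sample GFP, μV
    fs: float
    peak_indices: np.ndarray | None = None


@dataclass
class TopographyModel:
    """K microstate template maps over a fixed montage.

    Each map is zero-mean across channels and has unit L2 norm; maps are
    defined up to sign. ``class_labels`` are the canonical letters (A-E for
    the default K=5) once assigned, or generation order before.
    """

    maps: np.ndarray  # (K, n_channels)
    class_labels: list[str] = field(default=None)
    channel_labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.maps = normalize_maps(np.atleast_2d(np.asarray(self.maps, dtype=float)))
        if self.class_labels is None:
            self.class_labels = list(string.ascii_uppercase[: self.maps.shape[0]])
        self.class_labels = list(self.class_labels)
        if len(self.class_labels) != self.maps.shape[0]:
            raise ValueError("one class label per map required")
        if len(set(self.class_labels)) != len(self.class_labels):
            raise ValueError("class labels must be unique")
        if self.channel_labels is not None and len(self.channel_labels) != self.maps.shape[1]:
            raise ValueError("channel_labels length must match map width")

    @property
    def K(self) -> int:
        return self.maps.shape[0]

    @property
    def n_channels(self) -> int:
        return self.maps.shape[1]


@dataclass
class LabelSequence:
    """Per-sample microstate assignment for a set of kept epochs."""

    labels: np.ndarray     # (n_epochs, n_samples) int, UNLABELED where undefined
    fit_corr: np.ndarray   # (n_epochs, n_samples) |spatial correlation| in [0, 1]
    fs: float
    class_labels: list[str]

    def __post_init__(self) -> None:
        self.labels = np.atleast_2d(np.asarray(self.labels, dtype=int))
        self.fit_corr = np.atleast_2d(np.asarray(self.fit_corr, dtype=float))
        if self.labels.shape != self.fit_corr.shape:
            raise ValueError("labels and fit_corr shapes differ")


@dataclass
class MicrostateParams:
    """Per-class mean duration (ms), coverage (%) and occurrence (1/s)."""

    class_labels: list[str]
    mean_duration_ms: np.ndarray
    coverage_pct: np.ndarray
    occurrence_per_s: np.ndarray

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"mean_duration_ms": self.mean_duration_ms,
             "coverage_pct": self.coverage_pct,
             "occurrence_per_s": self.occurrence_per_s},
            index=pd.Index(self.class_labels, name="class"),
        )


# ---------------------------------------------------------------------------
# primitives

def normalize_maps(maps: np.ndarray) -> np.ndarray:
    """Zero-mean each map across channels and scale to unit L2 norm."""
    maps = maps - maps.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(maps, axis=1, keepdims=True)
    nz = norms[:, 0] > 0
    maps[nz] = maps[nz] / norms[nz]
    return maps


def compute_gfp(epoch: np.ndarray, fs: float = 1.0) -> GfpSeries:
    """Global field power: spatial standard deviation of the map at each sample.

    GFP(t) = sqrt( sum_i (v_i(t) - vbar(t))^2 / n ) over the n electrodes.
    """
    epoch = np.asarray(epoch, dtype=float)
    if epoch.ndim != 2 or epoch.shape[0] < 2:
        raise ValueError("GFP needs a channels × samples matrix with ≥ 2 channels")
    centered = epoch - epoch.mean(axis=0, keepdims=True)
    return GfpSeries(values=np.sqrt(np.mean(centered**2, axis=0)), fs=fs)


def find_gfp_peaks(gfp: GfpSeries) -> np.ndarray:
    """Strict local maxima of the GFP curve (endpoints excluded).

    A plateau of equal values contributes its midpoint (rounded down),
    matching :func:`scipy.signal.find_peaks`.
    """
    values = np.asarray(gfp.values, dtype=float)
    if values.size < 3:
        raise ValueError("GFP series must have at least 3 samples")
    peaks, _ = find_peaks(values)
    gfp.peak_indices = peaks
    return peaks


def extract_peak_maps(epochs: EpochSet) -> np.ndarray:
    """Scalp maps at GFP peaks of every kept epoch, stacked (n_peaks, n_channels)."""
    maps = []
    for ep in epochs.kept():
        gfp = compute_gfp(ep, epochs.fs)
        peaks = find_gfp_peaks(gfp)
        if peaks.size:
            maps.append(ep[:, peaks].T)
    if not maps:
        raise ValueError("no GFP peaks found in any kept epoch")
    return np.vstack(maps)


def spatial_correlation(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pearson correlation across channels between map sets ``a`` and ``b``.

    Returns the (n_a, n_b) matrix of signed correlations; rows with zero
    spatial variance yield 0.
    """
    a = normalize_maps(np.atleast_2d(np.asarray(a, dtype=float)).copy())
    b = normalize_maps(np.atleast_2d(np.asarray(b, dtype=float)).copy())
    return a @ b.T


# ---------------------------------------------------------------------------
# clustering

def _gev_of_assignment(maps_n: np.ndarray, gfp2: np.ndarray, centers: np.ndarray,
                       assign: np.ndarray) -> float:
    corr = maps_n @ centers.T
    picked = corr[np.arange(len(assign)), assign]
    return float(np.sum(gfp2 * picked**2) / np.sum(gfp2))


def modified_kmeans(peak_maps: np.ndarray, K: int, n_restarts: int = 50,
                    seed: int | None = None, max_iter: int = 500,
                    tol: float = 1e-6,
                    channel_labels: list[str] | None = None) -> TopographyModel:
    """Polarity-invariant topographic K-means on GFP-peak maps.

    Maps are assigned to the centre maximising the *squared* spatial
    correlation (so a map and its sign flip are equivalent), and each centre
    is updated as the dominant eigenvector of the cross-product matrix of
    its assigned maps. The best of ``n_restarts`` random initialisations by
    global explained variance (GEV) is kept.

    Parameters
    ----------
    peak_maps : ndarray, shape (n_maps, n_channels)
        Instantaneous scalp maps, typically at GFP peaks.
    K : int
        Number of microstate classes (5 in the default model).
    n_restarts, seed, max_iter, tol
        Restart count, RNG seed, iteration cap and relative-GEV convergence
        tolerance.
    """
    X = np.atleast_2d(np.asarray(peak_maps, dtype=float))
    n_maps, n_ch = X.shape
    if K < 1:
        raise ValueError("K must be ≥ 1")
    if n_maps < K:
        raise ValueError(f"need at least K={K} maps, got {n_maps}")
    Xc = X - X.mean(axis=1, keepdims=True)          # zero-mean maps (raw amplitude)
    gfp = np.sqrt(np.mean(Xc**2, axis=1))
    gfp2 = gfp**2
    if not np.any(gfp2 > 0):
        raise ValueError("all peak maps have zero spatial variance")
    Xn = normalize_maps(Xc.copy())                  # unit-norm rows for correlation
    rng = np.random.default_rng(seed)

    best_gev, best_centers, best_converged = -np.inf, None, True
    for _ in range(n_restarts):
        init = rng.choice(n_maps, size=K, replace=False)
        centers = normalize_maps(Xc[init].copy())
        prev_gev, converged = -np.inf, False
        for _it in range(max_iter):
            corr = Xn @ centers.T
            assign = np.argmax(corr**2, axis=1)
            for k in range(K):
                members = Xc[assign == k]
                if len(members) == 0:               # re-seed an empty cluster
                    centers[k] = Xn[rng.integers(n_maps)]
                    continue
                s = members.T @ members
                eigvals, eigvecs = np.linalg.eigh(s)
                centers[k] = eigvecs[:, -1]
            centers = normalize_maps(centers)
            gev = _gev_of_assignment(Xn, gfp2, centers, assign)
            if gev - prev_gev < tol * max(abs(prev_gev), 1e-12) and _it > 0:
                converged = True
                break
            prev_gev = gev
        if gev > best_gev:
            best_gev, best_centers, best_converged = gev, centers.copy(), converged
    if not best_converged:
        warnings.warn("modified K-means did not converge; returning best-so-far",
                      RuntimeWarning)
    return TopographyModel(best_centers, channel_labels=channel_labels)


def aggregate_group_model(subject_models: list[TopographyModel], K: int,
                          n_restarts: int = 50, seed: int | None = None) -> TopographyModel:
    """Group-level templates: pool all subject maps and re-cluster with K classes."""
    if not subject_models:
        raise ValueError("need at least one subject model")
    n_ch = subject_models[0].n_channels
    if any(m.n_channels != n_ch for m in subject_models):
        raise ValueError("subject models have inconsistent channel counts")
    pooled = np.vstack([m.maps for m in subject_models])
    return modified_kmeans(pooled, K, n_restarts=n_restarts, seed=seed,
                           channel_labels=subject_models[0].channel_labels)


# ---------------------------------------------------------------------------
# backfitting and parameters

def backfit(epochs: EpochSet, model: TopographyModel) -> LabelSequence:
    """Competitive fitting: label every sample of every kept epoch.

    Each sample's map is assigned to the template with the highest absolute
    spatial correlation (ties broken by lowest class index); samples with
    zero spatial variance are left ``UNLABELED``.
    """
    kept = epochs.kept()
    if kept.shape[0] == 0:
        raise ValueError("no kept epochs to backfit")
    if kept.shape[1] != model.n_channels:
        raise ValueError(
            f"channel mismatch: epochs have {kept.shape[1]}, model {model.n_channels}")
    n_ep, _, n_samp = kept.shape
    labels = np.full((n_ep, n_samp), UNLABELED, dtype=int)
    fit = np.zeros((n_ep, n_samp))
    for i, ep in enumerate(kept):
        corr = np.abs(spatial_correlation(ep.T, model.maps))  # (n_samp, K)
        labels[i] = np.argmax(corr, axis=1)
        fit[i] = corr[np.arange(n_samp), labels[i]]
        flat = np.ptp(ep, axis=0) == 0                        # zero-variance samples
        labels[i, flat] = UNLABELED
        fit[i, flat] = 0.0
    return LabelSequence(labels, fit, fs=epochs.fs, class_labels=model.class_labels)


def label_classes(model: TopographyModel, references: TopographyModel) -> TopographyModel:
    """Assign canonical class letters by best permutation match to references.

    Exhaustively searches injective assignments of model maps to reference
    maps (K! ≤ 120 for K=5), maximising the summed absolute spatial
    correlation, and returns the model re-ordered to reference label order.
    """
    if model.n_channels != references.n_channels:
        raise ValueError("montage mismatch between model and references")
    if references.K < model.K:
        raise ValueError("reference model must have at least K maps")
    corr = np.abs(spatial_correlation(model.maps, references.maps))
    best_perm, best_score = None, -np.inf
    for perm in itertools.permutations(range(references.K), model.K):
        score = corr[np.arange(model.K), perm].sum()
        if score > best_score:
            best_score, best_perm = score, perm
    order = np.argsort(best_perm)  # present maps in reference-label order
    return TopographyModel(
        model.maps[order],
        class_labels=[references.class_labels[best_perm[i]] for i in order],
        channel_labels=model.channel_labels,
    )


def _runs(row: np.ndarray):
    """Run-length encode one epoch's label row → (label, length) pairs."""
    change = np.flatnonzero(np.diff(row)) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [len(row)]))
    return [(row[s], e - s) for s, e in zip(starts, ends)]


def microstate_parameters(labels: LabelSequence,
                          include_boundary_runs: bool = True) -> MicrostateParams:
    """Mean duration, time coverage and occurrence per microstate class.

    Runs are counted within each epoch independently (no run crosses an
    epoch boundary). Under the default policy truncated boundary runs count
    in all three parameters, which makes the identity

        coverage_pct = occurrence_per_s × mean_duration_ms / 10

    hold exactly. ``include_boundary_runs=False`` drops first/last runs of
    every epoch from the *duration* average only (CARTOOL-style), breaking
    the identity on purpose.
    """
    lab = labels.labels
    if lab.size == 0:
        raise ValueError("empty label sequence")
    K = len(labels.class_labels)
    n_ep, n_samp = lab.shape
    total_s = n_ep * n_samp / labels.fs
    run_count = np.zeros(K)
    run_samples = np.zeros(K)
    dur_count = np.zeros(K)
    dur_samples = np.zeros(K)
    for row in lab:
        runs = _runs(row)
        for j, (k, length) in enumerate(runs):
            if k == UNLABELED:
                continue
            run_count[k] += 1
            run_samples[k] += length
            if include_boundary_runs or (0 < j < len(runs) - 1):
                dur_count[k] += 1
                dur_samples[k] += length
    coverage = run_samples / (n_ep * n_samp) * 100.0
    occurrence = run_count / total_s
    with np.errstate(invalid="ignore", divide="ignore"):
        duration = np.where(dur_count > 0,
                            dur_samples / np.maximum(dur_count, 1) * 1000.0 / labels.fs,
                            np.nan)
    return MicrostateParams(list(labels.class_labels), duration, coverage, occurrence)


def smooth_labels(labels: LabelSequence, min_duration_ms: float) -> LabelSequence:
    """Remove runs shorter than ``min_duration_ms`` by absorbing them into neighbours.

    Repeatedly takes the shortest sub-threshold run in each epoch and
    reassigns its samples to the adjacent runs (first half to the left
    neighbour, second half to the right; edge runs join their only
    neighbour). Deterministic and purely label-based; disabled by default
    (``min_duration_ms = 0``).
    """
    min_len = int(round(min_duration_ms * labels.fs / 1000.0))
    if min_len <= 1:
        return labels
    out = labels.labels.copy()
    for i in range(out.shape[0]):
        row = out[i]
        while True:
            runs = _runs(row)
            if len(runs) <= 1:
                break
            lengths = [ln for _, ln in runs]
            short = [j for j, ln in enumerate(lengths) if ln < min_len]
            if not short:
                break
            j = min(short, key=lambda j: lengths[j])
            start = sum(lengths[:j])
            end = start + lengths[j]
            if j == 0:
                row[start:end] = runs[1][0]
            elif j == len(runs) - 1:
                row[start:end] = runs[j - 1][0]
            else:
                mid = start + lengths[j] // 2
                row[start:mid] = runs[j - 1][0]
                row[mid:end] = runs[j + 1][0]
        out[i] = row
    return LabelSequence(out, labels.fit_corr, fs=labels.fs,
                         class_labels=labels.class_labels)


def global_explained_variance(epochs: EpochSet, model: TopographyModel,
                              labels: LabelSequence) -> float:
    """GFP²-weighted mean squared correlation between samples and their templates."""
    kept = epochs.kept()
    if kept.shape[0] != labels.labels.shape[0]:
        raise ValueError("labels do not match the kept epochs")
    num = den = 0.0
    for ep, row in zip(kept, labels.labels):
        gfp2 = compute_gfp(ep, epochs.fs).values ** 2
        corr = spatial_correlation(ep.T, model.maps)
        ok = row != UNLABELED
        picked = np.zeros(len(row))
        picked[ok] = corr[np.flatnonzero(ok), row[ok]]
        num += float(np.sum(gfp2 * picked**2))
        den += float(np.sum(gfp2))
    if den == 0:
        raise ValueError("zero total GFP: cannot compute explained variance")
    return num / den


# ---------------------------------------------------------------------------
# canonical reference topographies

def builtin_reference_maps(channel_labels: list[str] | None = None) -> TopographyModel:
    """Idealised reference maps for classes A-E on the 16-channel motor montage.

    Classes A-D are linear potential gradients along the canonical axes
    (A: right-frontal, B: left-posterior, C: left-frontal, D: midline
    frontal) and E is a focal central-parietal pattern; electrode positions
    come from the standard 10-20 montage. Users may substitute their own
    reference model.
    """
    import mne

    channel_labels = list(channel_labels or EEG_CHANNELS)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            mont = mne.channels.make_standard_montage("colin27_1020")
        except Exception:  # older naming
            mont = mne.channels.make_standard_montage("standard_1020")
    pos = mont.get_positions()["ch_pos"]
    missing = [c for c in channel_labels if c not in pos]
    if missing:
        raise ValueError(f"channels not in the standard 10-20 montage: {missing}")
    xy = np.array([pos[c][:2] for c in channel_labels])  # +x right, +y anterior
    x, y = xy[:, 0], xy[:, 1]
    directions = {
        "A": (1.0, 1.0),    # right-frontal
        "B": (-1.0, -1.0),  # left-posterior
        "C": (-1.0, 1.0),   # left-frontal
        "D": (0.0, 1.0),    # midline frontal
    }
    maps = []
    for dx, dy in directions.values():
        d = np.array([dx, dy]) / np.hypot(dx, dy)
        maps.append(x * d[0] + y * d[1])
    # E: central-parietal focal pattern (gaussian bump just posterior of Cz)
    width = 0.5 * (x.max() - x.min())
    maps.append(np.exp(-((x - 0.0) ** 2 + (y - (y.min() * 0.5)) ** 2) / (2 * (0.4 * width) ** 2)))
    return TopographyModel(np.array(maps), class_labels=list("ABCDE"),
                           channel_labels=channel_labels)
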
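# motorstates

EEG microstate and surface-EMG analysis of upper-limb motor recovery.

`motorstates` is a Python library for neurophysiologists studying motor
rehabilitation (e.g. rTMS intervention in hemiplegic stroke) who need to
quantify cortical dynamics and muscle output from synchronized resting-state
EEG and surface EMG, and to relate pre/post changes in the two. It covers
the full analysis chain:

* **Preprocessing** — zero-phase FIR band-pass (0.5–45 Hz EEG, 20–400 Hz
  EMG) and 50 Hz notch filtering, downsampling to 500 Hz, common average
  reference, segmentation into 2 s epochs, ±80 μV amplitude rejection.
* **Microstate analysis** — global field power (GFP), GFP-peak extraction,
  polarity-invariant modified K-means clustering of peak topographies,
  group-template aggregation, competitive backfitting, and the per-class
  temporal parameters (mean duration, coverage, occurrence).
* **EMG features** — per-epoch peak-to-peak (PTP) and RMS amplitude per
  muscle, averaged across epochs, and pre/post change scores.
* **Statistics** — paired/independent t tests with a normality-gated
  Wilcoxon alternative, mixed two-way ANOVA (group × microstate class) with
  partial η² and simple effects, Pearson correlation of microstate change
  scores against EMG change scores, Bonferroni/Benjamini–Hochberg
  correction.
* **Synthetic data** — seeded generators that plant known microstate
  templates, dwell dynamics and EMG amplitudes, so every stage is testable
  without recorded data, plus an embedded 20-patient clinical score table
  (FMA-UE and ARAT, pre/post).

## The model

The multichannel EEG signal is treated as a sequence of instantaneous scalp
maps. The global field power at time *t* over *n* electrodes,

```
GFP(t) = sqrt( Σ_i (v_i(t) − v̄(t))² / n ),
```

is the spatial standard deviation of the map; its local maxima are the
moments of highest topographic signal-to-noise. Maps at GFP peaks are
clustered with a **polarity-invariant modified K-means**: each map is
assigned to the template *a_k* maximizing the squared spatial correlation
(so *v* and *−v* are equivalent), and each template is updated as the
dominant eigenvector of Σ v vᵀ over its assigned maps. The resulting K = 5
templates are ordered into the canonical classes A–E by best permutation
match against reference topographies, then **backfitted**: every sample is
labeled with the template of highest |spatial correlation|. From the label
sequence the package computes, per class, the mean duration (ms), time
coverage (%) and occurrence rate (1/s); under the default run-counting
policy these satisfy `coverage = occurrence × duration / 10` exactly. Fit
quality is summarized by the GFP²-weighted global explained variance (GEV).

EMG contraction output is summarized per muscle by `PTP = max(x) − min(x)`
and `RMS = sqrt(Σ x_i²/N)`.

## Worked example

```python
import numpy as np
import motorstates as ms

templates = ms.make_templates(n_channels=16, K=5, seed=1)
rec, truth = ms.simulate_eeg(templates, class_rates=[1.0]*5,
                             mean_dwell_ms=[60.0]*5, snr_db=10.0,
                             fs=500, duration_s=60, seed=2)
epochs = ms.epoch(rec, 2.0)
model = ms.modified_kmeans(ms.extract_peak_maps(epochs), K=5,
                           n_restarts=50, seed=3)
print(np.abs(ms.spatial_correlation(model.maps, templates.maps)).max(axis=0))
# [1. 1. 1. 1. 1.]   ← each planted topography recovered with |r| = 1.0

aligned = ms.label_classes(model, templates)
labels = ms.smooth_labels(ms.backfit(epochs, aligned), min_duration_ms=20)
print(ms.microstate_parameters(labels).to_frame().round(2))
#        mean_duration_ms  coverage_pct  occurrence_per_s
# class
# A                 77.19         18.01              2.33
# B                 77.56         18.61              2.40
# C                 88.73         21.00              2.37
# D                 84.81         19.08              2.25
# E                 94.43         23.29              2.47
```

The recovered coverage sits within a fraction of a percentage point of the
planted values (18.04, 18.59, 21.09, 19.07, 23.21). The clinical layer
works the same way from the embedded table:

```python
report = ms.clinical_outcomes_report(ms.clinical_fixture())
# FMA-UE: 31.50 ± 21.97 → 33.65 ± 21.92, paired t(19) = 4.357, p < 0.001
# ARAT:   26.30 ± 24.00 → 27.25 ± 24.57, paired t(19) = 2.826, p = 0.011
```

The scripts in `examples/` walk through each capability (simulation and
recovery, clinical outcomes, EMG features, group statistics) and print the
numbers above. A thin CLI mirrors the pipeline:
`motorstates simulate|analyze|report --config cfg.json --seed N`.

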
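# Methods

This note documents the models and procedures implemented in
`motorstates`, the defaults they ship with, and the choices made where the
design was genuinely open.

## Signal model and preprocessing

Recordings are `channels × samples` matrices in μV with a sampling rate and
unique channel labels; the default montages are the 16-channel motor-cortex
EEG set (P4, CP2, FC5, C3, P3, C2, FC6, C4, CP6, F3, FC2, FC1, F4, CP5, C1,
CP1; international 10–20 names) and the 10-muscle upper-limb EMG set (FDS,
FCU, FCR, ECU, ECRL, BB, TB, DM, DA, DP).

The conditioning chain and its defaults follow the acquisition protocol the
package targets: EEG band-pass 0.5–45 Hz, EMG band-pass 20–400 Hz, 50 Hz
notch, downsampling to 500 Hz, common average reference (EEG only), 2 s
non-overlapping epochs, amplitude rejection at ±80 μV. Choices inside that
chain:

* **Filters** are hamming-window FIR with delay compensation (zero phase),
  delegated to `mne.filter`; passband ripple is below 1%. The notch
  attenuates the line frequency by more than 20 dB while leaving bands
  ±5 Hz away within 5% of unity (both properties are asserted in tests
  against sinusoid oracles).
* **Resampling** is polyphase with an anti-alias FIR; the output length is
  exactly `floor(n·target/fs)`.
* **Rejection** reads "exceeding ±80 μV" strictly: an epoch is dropped when
  any sample on any channel satisfies |v| > threshold; |v| = threshold is
  retained. Screening is applied per sample per electrode after referencing
  and resampling.
* **Interactive artifact review** (e.g. ICA component removal) is out of
  scope; `exclude_epochs` accepts an externally produced exclusion list so
  such screening can be injected.

## Microstate analysis

GFP is the spatial standard deviation of the scalp map (divisor *n*, not
*n−1*). Peaks are strict local maxima with endpoints excluded; a plateau
contributes its midpoint (rounded down).

The modified K-means operates on the zero-meaned maps at GFP peaks.
Assignment maximizes the squared spatial correlation, making the procedure
polarity-invariant by construction; the cluster-centre update is the
dominant eigenvector of the cross-product matrix of the assigned
(amplitude-weighted) maps — the standard polarity-invariant update.
Convergence is declared when the relative GEV improvement falls below 1e-6
(cap 500 iterations); 50 random restarts are run by default and the
restart with the highest GEV is kept. Everything is seeded; identical
inputs and seed give bit-identical models. Empty clusters are re-seeded
from a random map. Fewer maps than K is an error; hitting the iteration
cap returns the best-so-far model with a warning.

Group templates are obtained by pooling the subject-level template maps and
re-clustering them (two-level flow: per-subject clustering → group
aggregation → group templates backfitted to each subject). Pooling subject
*templates* rather than subject *data* keeps every subject's weight equal
and is the cheaper of the two common conventions; with identical subjects
it is a fixed point of the clustering (tested).

Class letters A–E are assigned by exhaustive best-permutation matching
(K! ≤ 120) of summed |spatial correlation| against reference maps. The
built-in references are idealized: linear potential gradients along the
canonical axes (A right-frontal, B left-posterior, C left-frontal,
D midline frontal) and a central-parietal Gaussian for E, evaluated at the
standard 10–20 electrode positions. They are meant to fix an ordering
convention, not to be anatomically faithful; users with their own canonical
maps should pass them instead.

Backfitting labels every sample (not only GFP peaks) with the argmax of
|spatial correlation|, ties broken toward the lowest class index. Samples
with zero spatial variance (exactly flat maps, which occur only in
noise-free synthetic data) are left unlabeled and excluded from run
statistics.

**Parameters.** Runs are counted within epochs (no run crosses an epoch
boundary). Mean duration = mean run length × 1000/fs; coverage = labeled
sample share × 100; occurrence = run count / analysed seconds. Truncated
boundary runs count in all three parameters by default, which makes
`coverage = occurrence × duration / 10` an exact identity (asserted to
1e-9); a flag excludes boundary runs from the duration average only, as
some desktop tools do, deliberately breaking the identity.

**Temporal smoothing.** By default no minimum-duration constraint is
applied. `smooth_labels(labels, min_duration_ms)` implements the standard
constraint: sub-threshold runs are absorbed into their neighbours (first
half to the left run, second half to the right), iterating shortest-first
until no run is below threshold. This matters for occurrence: at finite
SNR the per-sample argmax flickers wherever the instantaneous amplitude is
low, splitting true dwell periods into many short runs. Coverage is almost
unaffected by this flicker (misassignments distribute evenly), but raw
occurrence can be inflated several-fold. The recovery analyses in this
package therefore smooth at 20 ms — about the shortest segment treated as
physiologically meaningful in microstate work — before extracting
parameters; duration/coverage tolerate smoothing windows from roughly 10
to 30 ms, with occurrence degrading outside that range.

GEV is the GFP²-weighted mean squared correlation between each sample and
its assigned template, in [0, 1]; it is the restart-selection criterion and
the headline fit index.

## Synthetic data

The EEG generator emulates eyes-closed resting recordings on the
16-channel montage. Per recording:

* K zero-mean unit-norm template maps are drawn with pairwise |r| ≤ 0.6
  (rejection sampling; at least K+1 channels are required, since zero-mean
  maps live in an (n−1)-dimensional subspace).
* The planted label sequence is semi-Markov: class identities are drawn
  i.i.d. proportionally to the per-class rates, adjacent same-class draws
  are merged (so the emitted run structure has no immediate
  self-transitions and coverage tracks the rate ratio), and dwell times are
  gamma with shape 2 and the requested class mean (default 60 ms — the
  lower end of classical microstate dwell ranges, and short enough that a
  2 min recording contains thousands of runs).
* The active template is scaled by a rectified 10 Hz sinusoidal envelope
  (GFP peaks at ~20/s, matching resting alpha phenomenology) with a 40 μV
  amplitude scale, giving peak GFP near 10 μV on 16 channels.
* Spatially white Gaussian noise is added at a target SNR defined on the
  GFP power ratio (`snr_db = ∞` disables noise). For white noise of
  variance s², E[GFP²] = s²(n−1)/n, which the generator inverts to hit the
  target exactly in expectation.

"Planted" coverage/occurrence/duration are defined as the empirical values
of the planted label sequence itself (not the nominal rate parameters), so
recovery checks measure the analysis chain, not sampling fluctuation.

The generator does **not** model volume conduction, spatially correlated
noise, 1/f spectra, artifacts, or inter-subject topography variability.
Passing recovery tests therefore demonstrates correctness of the
segmentation and parameter machinery under its own assumptions, not
robustness to real-data violations of them.

The EMG generator emits sinusoidal carriers (default 80 Hz, inside the
20–400 Hz band), optionally gated by a 1 Hz burst envelope, with the
carrier frequency snapped so every burst contains a whole number of
periods. This keeps the analytic features exact — PTP = 2a,
RMS = a·√duty/√2 — at the cost of spectral realism. Default per-muscle
amplitudes are half the healthy-control PTP values of the cohort the
package targets.

The embedded clinical table carries the 20 patients' sex, age, stroke
type and FMA-UE/ARAT scores pre/post treatment and reproduces the
published cohort summary exactly (mean age 63.10; FMA-UE 31.50 → 33.65,
paired t(19) = 4.357; ARAT 26.30 → 27.25, t = 2.826).

## Statistics

* Paired t is computed on post − pre (positive t = improvement), two-sided,
  df = n−1; constant differences are a degenerate-data error.
* The Wilcoxon signed-rank drops zero differences and uses the exact
  sign-pattern distribution for n ≤ 25, a normal approximation (no
  continuity correction) beyond. The normality gate is a Shapiro–Wilk test
  on the change scores at α = 0.05; both tests are always reported, the
  gate only selects which one a summary would headline.
* The mixed ANOVA (between: group; within: class) is delegated to
  `pingouin.mixed_anova` and reports partial η² =
  SS_effect/(SS_effect+SS_error); tests verify the F and η² values against
  an explicit balanced sums-of-squares decomposition written independently.
  No sphericity correction is applied by default. Simple effects are
  per-class one-way group comparisons with Bonferroni adjustment.
* Correlation analysis operates on change scores (post − pre) for both the
  microstate parameters (15 columns: 5 classes × 3 metrics) and the EMG
  features (10 muscles), giving a 15 × 10 matrix of Pearson r with raw and
  jointly adjusted p (Benjamini–Hochberg by default, Bonferroni optional).
* p-adjustment uses `statsmodels.multipletests`; tests pin both methods to
  their definitional formulas.
* The paired-t implementation is calibrated by Monte Carlo: under a
  Gaussian null with n = 20 and 10,000 replicates the empirical type-I
  error at α = 0.05 falls in [0.04, 0.06].

## Pipeline, formats, determinism

Recordings are written as CSV (one column per channel, header = labels)
with a JSON sidecar for rate/modality/provenance; EDF files are read via
MNE's bundled reader (EDF *export* requires an extra backend and is not
provided — CSV is the write format). Every output table carries a sidecar
with the config hash, seed and package version. Fixed config + seed gives
byte-identical outputs (asserted in tests). Stage progress is logged as
`key=value` lines.

Problem sizes used in the shipped analyses: recovery runs simulate 120 s at
500 Hz (60,000 samples, ~2,400 GFP peaks) with 50 clustering restarts;
the Monte-Carlo calibration uses 10,000 replicates. Both complete in
seconds on one CPU.

## Known limitations

* Occurrence and duration estimates at finite SNR depend on the smoothing
  window; the unsmoothed default faithfully reports the flickering label
  sequence, which is the honest but noisy estimator.
* The built-in A–E reference maps fix an ordering convention only.
* No optimal-K criterion is provided (K defaults to 5); no microstate
  syntax/transition analysis; no source localization.
* The EMG simulator's sinusoidal carriers have a crest factor of √2,
  unlike real interference-pattern EMG; analytic exactness was preferred
  over realism.
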
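# Methods

`metwear` turns raw 100 Hz wrist-accelerometer recordings into
behavioral-health indicators in three stages: label repair, windowed MET
regression, and behavioral interpretation. This note documents the models,
the parameters that matter, the numerical choices, and what the synthetic
cohort does and does not establish.

## Data model

A recording is a five-column time series `time, x, y, z, annotation`:
integer millisecond timestamps, tri-axial acceleration in g (gravity
included), and a free-text label embedding the activity and its MET value
(`"sleeping; MET 0.95"`). MET — metabolic equivalent of task — expresses
energy expenditure as a multiple of resting metabolic rate. Timestamps are
stored as integer milliseconds so 27 h of samples accumulate no float
drift; the loader accepts any strictly increasing integer column (absolute
epoch or elapsed), and tolerates equal adjacent timestamps so the
continuity audit can *report* duplicates rather than crash on them.

MET values are extracted with the pattern `;\s*MET\s+(\d+\.\d+)`: a literal
semicolon, the `MET` marker, and a decimal number with digits on both sides
of the point (so an integer label like `MET 7` deliberately fails to
parse). The first match wins when several occur. Timing arithmetic is
exact: `hours = samples / 360,000` (100 Hz × 3600 s), with no rounding.
The continuity audit reports the modal inter-sample gap, adjacent duplicate
count, and `delta_t = |count_hours − timestamp_hours|`, which a regular
clock drives below 1e-5 h.

## Annotation repair

Missing labels concentrate at activity-state transitions, so gaps are
treated as transition buffers. Maximal NaN runs are enumerated, their
durations clustered with 1-D DBSCAN (defaults `eps = 300 s`,
`min_pts = 3`: five minutes separates the dominant short-gap mass from
outliers; both configurable), and every gap — anomalous or not — is filled
with the mean of its flanking values. Trailing gaps take the previous
value alone; leading gaps, symmetric to trailing ones, take the next value
alone. Clustering is diagnostic only: noise-labelled gaps are surfaced,
never treated differently. DBSCAN processes gaps in ascending
(duration, start) order so border points land deterministically. The fill
is a convex combination of observed values, which makes imputation
idempotent, range-preserving, and order-independent.

## Signal conditioning

Outliers in the (x, y, z) vectors are scored per recording with an
isolation forest (100 trees, subsample `min(256, n)`, seeded; anomaly score
`S(x) = 2^(−E[h(x)]/c(n))`). Samples strictly above the
`1 − contamination` score quantile (default contamination 0.01) are
replaced by the mean of up to five non-flagged neighbours per side; a
flagged sample with no reachable neighbour is left alone rather than
invented. Scoring per recording, not pooled, keeps inter-individual scale
differences from masking within-record spikes. Each axis is then smoothed
with a 10-sample moving average over the asymmetric stencil `[n−5, n+4]`;
at the edges the stencil truncates and the divisor shrinks. Conditioning
never touches the MET label stream, and rows are dropped only when the
acceleration itself is missing (label gaps go through repair instead, so
the two clocks stay aligned).

## Features

Recordings are segmented into non-overlapping windows of `L = 10,000`
samples (100 s), step `S = 10,000`; a trailing partial window is dropped.
Per axis: mean, population standard deviation (divisor N), and three
spectral features of the *mean-removed* window — dominant frequency
(argmax of one-sided FFT magnitude, ties to the lowest bin), spectral
amplitude (sum of magnitudes over bins 0..N/2), and spectral centroid
(magnitude-weighted mean frequency, defined as 0 for a zero spectrum).
Mean removal matters: on raw accelerometer data the gravity (DC) bin
always wins the argmax and the dominant frequency would carry no
information. Bin i maps to `i·fs/N` Hz without zero padding. Pairwise
Pearson correlations couple the axes (0 by convention when an axis has
zero variance), and two demographic codes — representative age per bin
(18–29→24, 30–37→34, 38–52→45, 53+→53) and sex (M→1, F→0) — complete the
20-feature row. The window target is the arithmetic mean of the imputed
per-sample MET. All model inputs, demographic codes included, are min-max
scaled with training-set extrema only; test values extrapolate rather than
clip, and a constant training feature maps to 0.

## MET regression

Three tree ensembles — gradient-boosted trees (XGBoost), random forest,
and leaf-wise gradient boosting (LightGBM) — sit behind one interface; the
package does not reimplement their internals. The split is always at the
participant level (seeded shuffle, first ⌈ratio·n⌉ to training) so windows
from one subject never leak across sides. Hyperparameters come from seeded
random search over a shared space — trees ∈ [100, 600], depth ∈ [3, 9],
learning rate ∈ [0.02, 0.3] log-uniform (ignored by the forest), row and
column subsampling ∈ [0.6, 1.0] — scored by grouped 3-fold cross-validation
on training subjects, best mean-MSE configuration refitted on all training
rows. Default budget 30 iterations. Predictions are clipped at 0, since a
negative MET is physically meaningless. MAPE is stored as a fraction
(0.29, not 29 %) and formatted as percent only for display; MSE is in
squared MET units.

## Behavioral analysis

**Intensity bands.** Sleep < 1.0 ≤ sedentary < 1.6 ≤ light < 3.0 ≤
moderate < 6.0 ≤ vigorous, half-open at every internal edge; activity
hours per band are sample counts divided by 360,000 and always conserve
total time. 30 min at 100 Hz is 180,000 samples, i.e. `Ws = 18` windows.

**Sleep segmentation.** The sleep period is the longest run of MET < 1.0
lasting at least 2 h (configurable; how to delimit the period was an open
design choice). Over that span a window-level series is differenced and
thresholded at `θ = μ_Δx + k·σ_Δx` (default k = 3) computed over the whole
span; a rolling variant was considered and rejected for stability at this
window count. After each detection θ grows by `λ·max|Δx|` (default
λ = 0.05) and 2 positions are skipped — applying the increment at *every*
step instead would make θ grow without bound and silence the detector, so
it is read as duplicate suppression. The default series is the window
mean of the per-sample acceleration magnitude |a|: the magnitude of the
window-mean *vector* was considered first but averages zero-mean
oscillations away (it stays pinned near 1 g whatever the activity), so the
mean-of-magnitudes form is used; a MET-based series is available via
`signal="met"`. With λ = 0 and no refractory the detected set is invariant
to adding a constant or scaling by c > 0. Segments between change points
are numbered 1..n in time order; no clinical (polysomnography-grade) stage
labels are claimed.

**Sedentary alerts.** A window is low when its mean MET is strictly below
1.6 (exactly 1.6 is non-sedentary). An event is a maximal run of low
windows of length ≥ Ws; the onset is the run's first window and each event
emits exactly one alert, with suppression until a non-low window resets
the bout. Maximal runs, rather than every qualifying sub-interval, match
the one-alert-per-episode intent and coincide with the exhaustive
interval-enumeration definition (property-tested on random sequences).

## Synthetic cohort

The generator emulates the study conditions: 100 Hz tri-axial recordings
over a ~26 h day–night cycle (scalable), a diurnal schedule populating
every intensity band — 7 h sleep with planted quiet/restless/movement
sub-stages, sedentary stretches (MET 1.15–1.4), walking (2.2–2.5), one
moderate bout (4.0), one short vigorous bout (7.0) — per-state MET labels
jittered within their band but constant within a bout, and annotation gaps
centered on a small fraction (5 %) of state transitions with durations
mixing short gaps (90 %, 0.5–10 min) and long outliers (10 %, 20–40 min).
Gaps are sparse by design: in the real cohort only a handful of
participants showed them, most were under 20 min, and total missingness
stayed below ~1 %. The signal is a slowly rotating unit gravity vector
plus a state-dependent sinusoid (0 Hz asleep, 0.2 Hz sedentary fidgeting,
1.8 Hz walking, 2.8 Hz running — chosen so the spectral features carry
discriminative signal) plus Gaussian noise (σ = 0.02 g). Participant
seeds derive as `cohort_seed × 10,007 + index`, so fixed seeds give
byte-identical CSVs.

What passing on this cohort shows: the pipeline's plumbing and the
detectors' logic are correct, and the feature set suffices to regress MET
when activity states genuinely differ in oscillation amplitude/frequency.
What it does not show: performance on real wrist data, whose gait
harmonics, device calibration error, non-wear artifacts and behavioral
heterogeneity the generator deliberately omits. Reported synthetic test
errors (MAPE ≈ 0.05–0.11 across seeds at 10 participants × 3 h) are
therefore a functional check, not a clinical benchmark.

## Problem sizes

Default verification sizes, chosen to exercise every stage at full fidelity:
regression runs on 10 participants × 3 h (1,080 windows); planted-event
recovery on one 13 h participant (468 windows, sleep block 3.5 h); detector
oracles on 1,000 random window sequences. All sizes are parameters of the
profile and scale up unchanged.

## Known limitations

* The MET regressor predicts per window (100 s); no sub-window estimates.
* Imputation is constant mean-of-flanks by design; a long gap spanning a
  state change is attributed to the midpoint MET, so per-band hours can be
  off by up to half the gap duration around such gaps.
* Sleep segmentation is coarse-grained motion segmentation, not staging.
* No vendor binary formats (GT3X/cwa), no resampling, no band-pass
  filtering or gravity separation beyond the spectral mean removal.
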
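# Methods

`preictal` classifies short EEG epochs as *preictal* (the window before a
seizure, the positive class) or *interictal* (seizure-free baseline). The
pipeline is: clean → epoch and label → extract spatiotemporal features →
screen features → RBF-SVM with seizure-wise cross-validation → 1-minute
majority vote → report. This note records the model, its assumptions, the
defaults and their rationale, the numerical conventions, and what the
synthetic test bed does and does not show.

## Cleaning and labeling

Per-channel mean subtraction removes baseline drift; a fourth-order
Butterworth band-pass (0.5–70 Hz default) applied forward–backward keeps
filtering zero-phase, which matters because downstream connectivity is
phase-based; an optional second-order IIR mains notch (50 Hz, Q = 30
default) suppresses power-line interference. The 50 Hz default follows the
scalp-EEG profile this pipeline was written for; it is configurable, and
for 60 Hz-mains recordings it should be changed. Expert-guided ICA
artifact rejection is inherently interactive, so it is exposed only as a
pluggable hook (identity by default); spans that cannot be cleaned can be
marked `artifact_exclude` and are dropped at epoching.

Labeling uses the standard prediction convention: epochs fully inside
`[onset − preictal_minutes, onset)` are preictal (30 min default for scalp,
60 for intracranial); epochs farther than `interictal_gap_hours` (4 h
default) from every seizure — measured conservatively to both onset and
offset, since the literature rarely states which — are interictal; a
seizure closer than 30 min to its predecessor is skipped as a prediction
target because its window would overlap the previous event; everything
else is dropped. Epochs are 5-s, non-overlapping, tiled from t = 0;
interictal epochs inherit the fold index of the next upcoming target
seizure so each cross-validation fold holds out a matched interictal
block.

## Temporal features (16 per channel)

**Fuzzy entropy** FuzzyEn(m, r, N) = ln Φ^m(r) − ln Φ^(m+1)(r), with
Φ^d(r) the mean over all length-d embedded templates (windowed mean
removed) of the average Gaussian-like similarity
exp(−ln 2 · (d_cheb/r)²) to every other template (self-matches excluded).
Defaults m = 2, r = 0.2 · std(epoch). Because r scales with the standard
deviation and templates are baseline-removed, the value is invariant to
amplitude scaling and offset; zero-variance epochs return 0 by convention.
For dimension d the template set has N − d + 1 members and each C_i
normalises by N − d, exactly as the defining sums are written. The fast
path is an O(N²) numba kernel; a pdist-based numpy fallback implements the
identical arithmetic, and both are pinned to a literal pure-Python double
loop in the tests (1e-10).

**Band powers.** Welch PSD (1-s Hamming segments, 50% overlap — common
practice; the window and overlap are configurable), then RPSD_i =
ln Σ_{ω∈band i} P(ω) over delta [0.5, 4), theta [4, 8), alpha [8, 14),
beta [14, 30), gamma [30, band-pass cutoff]. Conventions: natural log; the
delta floor is 0.5 Hz (the band-pass floor) to avoid DC leakage; the gamma
ceiling is the band-pass cutoff since "gamma" has no canonical upper edge;
a zero-power band maps to ln(tiny) ≈ −708 instead of −∞. The 10 SPRs are
all ordered higher-minus-lower RPSD differences (log band-power ratios),
named TD, AD, BD, GD, AT, BT, GT, BA, GA, GB.

## Spatial features (7 per channel)

Instantaneous phase comes from the analytic (Hilbert) signal of each
zero-meaned channel; PLV_ab is the mean resultant length of the phase
difference, computed broadband over the epoch (a per-band variant is a
config flag away). The first/last 5% of samples carry Hilbert edge
effects; they are flagged and can be trimmed, but the default uses the
whole epoch.

The symmetric PLV matrix is a weighted undirected network. Strength
(weighted degree), eigenvector centrality (principal eigenvector of the
zero-diagonal PLV matrix, rescaled to max 1) and node synchronization
(mean PLV to all others) are weighted measures. Clustering, characteristic
path length, global efficiency and the small-world index σ =
(C/C_rand)/(L/L_rand) are computed on a binarized graph keeping the
strongest 30% of edges (proportional threshold; binary graph metrics
require *some* threshold and proportional thresholding keeps density
comparable across epochs). σ uses 20 seeded degree-preserving
double-edge-swap references. Degenerate conventions, needed because
30%-density graphs on few channels are sparse: a disconnected graph is
summarised by its largest component (flagged); a largest component below
two nodes has path length 0; if the rewired ensemble has zero clustering
the clustering ratio is 1 when C = 0 (equally tree-like) and n otherwise;
degenerate path ratios default to 1. Fewer than 4 channels is an error —
small-worldness is not meaningful there. The three global values are
broadcast to every channel so each electrode carries 16 + 7 = 23 features;
this is the only arithmetic under which "23 features per electrode"
balances.

## Feature screening

The screen is unsupervised and two-dimensional. Independence
ind_i = Σ_{k≠i}(1 − |r_ik|) (Pearson), range [0, m−1]; a zero-variance
column gets r := 0 against all others, which makes constants maximally
"independent" — by design they are then removed by the information axis.
Information inf_i = σ²(X_i)·H(X_i): population variance times the Shannon
entropy (bits) of a 10-bin equal-width histogram over the observed range
(the definition gives a probability mass function without a
discretization rule; equal-width histogramming is the plainest choice and
`bins` is exposed). Score_i = ind_i · inf_i; ranking is descending with
ties to the lower index. The subset size k is a pipeline parameter
defaulting to the top 20% of columns — a working default, not a canonical
value. Selection is always fit on training folds only; z-scoring for the
SVM is likewise fit on training data, while the screen itself sees raw
values (variance is meaningless after standardization).

Two structural limits of the score are worth knowing (both observable in
`examples/04_feature_screening.py`): an exact duplicate column receives a
bit-identical score to its original, so a symmetric unsupervised screen
can never rank the original above its copy; and a column with the same
marginal distribution as an informative one but shuffled against the
labels is indistinguishable from it, since ind, info and score never see
the labels. Redundancy *pairs* are penalised (both members lose
independence), but which member survives is decided only by the tie-break.

## Classification, smoothing, evaluation

RBF-SVM with C = 1, the library-default gamma (1/(n_features·var)) and
balanced class weights (preictal minutes are vastly outnumbered by
interictal hours in real data; the default compensates). Raw per-epoch
labels are smoothed by majority vote over non-overlapping 12-epoch
(1-minute) blocks within contiguous runs; a 6–6 tie votes preictal — in a
prediction context a false alarm is cheaper than a missed seizure — and a
trailing partial block votes over its actual length.

Metrics, preictal positive: ACC, F-score and FPR as percentages from the
confusion matrix of post-vote labels; AUC from pre-vote SVM decision
values; and separately a false-alarm rate per hour (preictal-voted blocks
inside interictal truth ÷ interictal hours). FPR% and FPR/h are different
quantities and are reported side by side. Degenerate denominators yield
NaN, never 0.

Cross-validation is seizure-wise leave-one-out: epoch-wise splits on
autocorrelated EEG leak trivially and inflate accuracy, so each fold holds
out one seizure's whole preictal block plus a matched interictal block,
with screening, scaling and the SVM refit per fold. At least 3 seizure
groups are required; below that the fold estimates are meaningless.

## Synthetic test bed

`generate_eeg` builds each channel as coupling·shared + (1−coupling)·
private + AR(2) background + white noise, where shared/private parts are
sums of five band-limited sinusoids (random frequency and phase per
segment) and the AR(2) poles (0.95, 0.40; coefficients 1.35, −0.38) give a
pink-like 1/f decay. Class contrasts enter through three independently
switchable axes: coupling (0.9 preictal vs 0.1 interictal default → PLV),
white-noise scale (10 vs 5 µV → fuzzy entropy) and band gains (interictal
1.5× → RPSD/SPR). The default timeline is the desk-scale easy condition:
4 seizures, a 5-minute preictal analogue of the 30-minute horizon, matched
5-minute interictal blocks, 60 s post-onset guard, 8 channels at 128 Hz.
128 Hz and 8 channels are the package's own desk-scale choice: they keep
the O(N²) entropy and per-epoch graph work small while leaving every band
below Nyquist (the band-pass cutoff is capped at 0.45·fs and the gamma
ceiling follows it). `SynthEEGConfig.null()` switches every contrast off.

What passing on this bed shows: the implementation recovers exactly the
contrasts it measures, end to end, with no leakage (the null condition
stays at chance AUC). What it does not show: performance on real EEG —
real preictal signatures are weaker, non-stationary and patient-specific;
the generator has no artifacts, no electrode drift, no 1/f slope changes,
and its oscillators are far more stationary than brain rhythms. Numbers
from this bed are implementation checks, not clinical claims.

`generate_planted_features` builds the screening test bed: class-shifted
unit Gaussians (between-class shift = effect size), exact copies of them,
constants, and label-shuffled clones, with roles recorded.

## Problem sizes

The shipped tests run the full pipeline at 10 seeds for the easy condition
and 10 for the null; `scripts/acceptance.py` uses 5 easy and 3 null seeds
plus 100-seed screening and phase-null experiments. These sizes are the
package's choice of a desk-scale experiment: one pipeline run is 480
epochs × 184 features and takes tens of seconds on one core.

## Known limitations

* FuzzyEn is O(N²) per channel-epoch; long epochs at high sampling rates
  benefit from the optional decimation switch or shorter epochs.
* The PLV mean-resultant has positive bias at short epochs and its
  iid-phase null understates variance for serially correlated Hilbert
  phases of broadband signals (effective sample size ≈ N/2); null
  comparisons should use matched-autocorrelation surrogates for strict
  calibration.
* Binary graph metrics at 30% density on few channels are sparse and hit
  the degenerate conventions above more often than on clinical montages.
* The screen is unsupervised: it cannot separate label-shuffled clones
  from genuinely informative columns, and duplicate resolution is by
  tie-break only.
* EDF writing is 16-bit with per-channel physical ranges; round trips are
  exact only to half a digital step.
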
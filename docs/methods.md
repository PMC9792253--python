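# Methods

This note documents the models and procedures the package implements,
the choices made where the design was genuinely open, and what the
synthetic-data generators do and do not establish.

## Resampling

All five resamplers operate on a `LabeledDataset` (feature matrix X,
binary labels, 1 = seizure/minority) and share one exact brute-force
k-nearest-neighbour backend (`compute_neighbors`): Euclidean distance on
raw features, ties broken by ascending reference index, a query row
never its own neighbour. No internal feature scaling is applied —
windows fed to the resamplers are on a common scale already, and scaling
policy belongs to the caller.

**bnnsmote.** Three stages:

1. *Noise filter*: minority row i is noise iff all `k_noise` nearest
   neighbours of i in the full dataset are majority class. Noise rows
   are removed from the output (option `keep_noise` retains them for
   ablation; they are never synthesis parents or partners either way).
2. *Boundary identification*: majority rows whose `k_boundary`
   neighbourhood — computed in the dataset with noise rows excluded, so
   that a cluster of noise cannot fabricate a boundary — contains at
   least one clean minority row. The minority rows appearing among the
   `k_danger` nearest neighbours of any boundary-majority row form the
   hard-to-learn (danger) parent set. The boundary step *identifies*
   existing majority rows; it never creates majority samples, which
   would worsen the imbalance the method exists to fix.
3. *Synthesis*: parents uniform over the danger set, partners uniform
   over all clean minority rows except the parent (option
   `partner_mode="knn"` restricts partners to the parent's `k_danger`
   clean-minority neighbours, the classic SMOTE restriction),
   δ ~ U(0, 1). The generator is consumed in the fixed order (parent,
   partner, δ) per row, so every run is replayable from
   `ResampleConfig.seed`. If the danger set is empty the parents fall
   back to all clean minority rows (warned), so the balance contract
   holds on degenerate inputs.

`n_synth = round(target_ratio × n_majority) − n_clean_minority`;
`target_ratio` defaults to 1.0 (fully balanced training). Neighbourhood
sizes default to `k_noise = k_boundary = k_danger = 5`, the SMOTE-family
convention; all are exposed. Inputs with minority > majority, or already
at the target ratio, pass through with a warning.

**Baselines.** `ros` duplicates minority rows uniformly with
replacement (provenance records δ = 0, partner = parent). `smote` draws
parents uniformly over all minority rows and partners from the parent's
`k_danger` minority neighbours. `blsmote` is Borderline-SMOTE-1: parents
restricted to minority rows with m′ majority neighbours,
k/2 ≤ m′ < k (m′ = k is the noise condition and is excluded by the
strict inequality). `svmsmote` takes the minority-class support vectors
of a soft-margin linear SVM (scikit-learn `SVC(kernel="linear")`,
C = 1) as parents — the support vectors approximate the boundary — and
interpolates toward minority neighbours; the extrapolation variant of
the published method is deliberately out of scope.

Every resampler returns provenance (parent index, partner index, δ) per
synthetic row, which makes the convexity, noise-exclusion and no-leakage
properties checkable after the fact.

## Preprocessing

*Bandpass*: 0.5–50 Hz Butterworth, order 4, applied forward–backward
(`sosfiltfilt`) for zero phase; the bidirectional pass squares the
magnitude response, which the filter-response tests account for
analytically. Zero phase matters because window labels are tied to
annotated onset times.

*Segmentation*: window 4 s, step 2 s (1024 samples per window at
256 Hz); `n_segments = floor((duration − window)/step) + 1`. Label
rules for windows straddling an onset: `majority-overlap` (default,
ictal iff ≥ 50% of the window lies in a seizure interval) avoids
labelling near-miss windows ictal while keeping genuine boundary
windows; `any-overlap` and `full-containment` are available. All
intervals are half-open `[start, end)` in seconds.

*Channel selection*: one-way two-group ANOVA per channel on a scalar
window feature — log signal energy by default (energy is the dominant
ictal discriminant and the log roughly symmetrises it); mean absolute
amplitude and variance are offered. A channel is retained when
p < α (default 0.05). For two groups F = t² exactly (pooled-variance
t), which the tests verify. Cross-patient aggregation of retained
channels is not modelled; callers pass an explicit `keep` list to
`select_channels`.

**Known limitation.** ANOVA assumes independent window features.
50%-overlapping windows share half their samples, and 1/f background
concentrates power at low frequencies, so window energies are
autocorrelated and a contiguous seizure block inflates the F statistic
of unaffected channels. Consequently per-channel type-I error exceeds α
on realistic records, and with m null channels even a perfectly
calibrated test falsely retains at least one with probability
1 − (1−α)^m. Exact recovery of the affected-channel *set* is therefore
not a meaningful contract; the tests assert the attainable one —
affected channels are always retained at high burst gain and carry the
smallest p-values — and the calibration test (α ± 2%) runs on iid group
samples where the assumption holds.

## Model

The classifier is a 1-D inverted-residual CNN for single-channel
1024-sample windows. Reference configuration (t = expansion factor,
c = output channels, n = repetitions, s = stride of the first block in
a stage):

| operator | t | c | n | s |
|---|---|---|---|---|
| conv1d k3 | — | 32 | 1 | 2 |
| bottleneck | 1 | 16 | 1 | 1 |
| bottleneck | 6 | 24 | 2 | 2 |
| bottleneck | 6 | 32 | 3 | 2 |
| bottleneck | 6 | 64 | 4 | 2 |
| bottleneck | 6 | 96 | 3 | 1 |
| bottleneck | 6 | 160 | 3 | 2 |
| bottleneck | 6 | 320 | 1 | 1 |
| pointwise conv | — | 1280 | 1 | 1 |
| global avg pool | — | — | 1 | — |
| linear | — | 2 | — | — |

Design choices: the first convolution is strided (stride 2, kernel 3) —
the tabulated shape flow 1024×1 → 512×32 requires it even though a
stride-1 convention would be the naive reading; depthwise kernels are 3
(the MobileNet convention, and the only value consistent with the 2.2 M
parameter / ≈92.5 M mult-add totals); batch normalisation follows every
convolution, with the clipped linear activation (ReLU6) after expand
and depthwise but not after the projection; residual addition when
stride 1 and in = out channels; the head is a bare linear layer with
bias.

Accounting conventions: convolutions are bias-free (batch norm supplies
the shift); parameters = conv weights + batch-norm scale/shift + linear
weights/bias (running statistics are not learnable and are not
counted); mult-adds = kernel × in_channels_per_group × out_channels ×
output_length for convolutions and in × out for the linear layer, with
normalisation, activation and pooling excluded (the dominant convention
for mult-add tables). Totals: 2,182,850 parameters (2.2 M) and
92,500,480 mult-adds (92.5 M) at input length 1024. The analytic count
is cross-checked against a brute-force enumeration of the instantiated
weight arrays.

Training is a plain NumPy implementation (im2col convolutions, manual
backprop verified against finite differences, Adam with lr 1e-3, batch
64, 30 epochs by default — all configurable; deterministic given the
seed). It exists so the full pipeline runs with no deep-learning
framework; it is CPU-bound and intended for small synthetic workloads,
not clinical-scale training. A 1-NN classifier built on the shared kNN
backend is the fast surrogate used by the resampler benchmarks.

## Evaluation

`confusion` counts TP/FP/FN/TN with seizure positive; `metrics` derives
accuracy, recall, precision and F1, returning 0 with a warning on a
zero denominator (the F1 = 0 when TP = 0 convention). `cross_validate`
draws `n_folds` independent stratified 80/20 train/test splits
(Monte-Carlo CV; this is the consistent reading of "5-fold" combined
with "8:2 random splitting" — a classic partitioned `StratifiedKFold`
is available via `cv="kfold"`). Stratification prevents positive-free
test splits at 1:30 imbalance. The resampler is fitted and applied only
to the training split; the per-fold no-leakage assertion checks that no
synthesis parent or partner maps to a test index. Fold seeds are
derived from the global seed and recorded in the report.

## Synthetic data

`make_clusters` draws a majority spherical Gaussian at the origin and a
minority one at distance `separation` (in shared-sd units) along the
first axis, then relocates `noise_frac` of the minority rows into the
majority core and returns their indices as ground truth. Defaults
(300:10, separation 4, 2 features) give the canonical planted-noise
fixture. Because planted truth must actually *be* the noise set under
the k = 5 all-majority-neighbourhood rule, the generator verifies its
own configuration with an independent brute-force check and locally
redraws offending rows (two planted rows landing adjacent to each
other, or a clean minority tail draw straying into the gap); this
truncates at most a few percent of the Gaussian tails and is active
only at separation ≥ 4, where the exact-recovery guarantee is stated —
below that, raw draws are returned and recovery is statistical, not
exact. `standard_imbalanced_clusters` fixes the benchmark condition:
1:30 imbalance, overlapping boundary (separation 3), 10% planted noise.

`make_eeg` synthesises multichannel records: per-channel band-limited
1/f background (exponent 1, the broad resting-EEG shape; configurable)
scaled to 10 µV rms, plus a spike-wave-like burst — a 3 Hz fundamental
with decaying second and third harmonics and half-second on/off ramps —
added to the affected channels inside each annotated interval at
`burst_gain` × background sd. This emulates the gross statistics that
segmentation, filtering and energy-based channel selection exercise; it
does *not* model artifacts (eye blink, EMG), inter-channel correlation,
nonstationary background, or realistic seizure evolution, so a green
test here establishes pipeline correctness, not clinical performance.
`make_imbalanced_segments` sizes one seizure interval so the windowed
ictal:nonictal ratio is ≈1:30 by default (the long-term-monitoring
figure), aligned to the window grid.

All generators are pure functions of their configuration: same seed,
bit-identical output.

## I/O

EDF read/write is a minimal in-repo codec (fixed-width ASCII header,
16-bit little-endian samples, linear physical/digital scaling; the
whole record stored as one data record) — sufficient for round-tripping
synthetic records to within one quantization step. Seizure annotations
travel in a plain TSV (`record_id`, `start_s`, `end_s`; half-open
seconds, validated for order and non-overlap) rather than in the EDF
itself. Datasets round-trip to CSV/TSV (`feature_i`, `label` columns)
and compressed `.npz`; synthesis provenance to JSON-lines; every
pipeline run writes `report.json` and a `manifest.json` with the config
hash, seed and package versions.

## Scope

Not implemented, deliberately: undersampling and SMOTE hybrids
(ADASYN, SMOTE-ENN, SMOTE-TomekLink), GAN augmentation, multi-class
resampling, event-based seizure metrics (detection latency, false
alarms per hour), artifact removal beyond the bandpass, and
reproduction of published patient-level benchmark numbers, which
require external clinical recordings and long training runs.
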
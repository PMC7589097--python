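# Methods

## Problem and overall design

`galoris` selects the subset of EEG band-power features that best
discriminates a driver's low and high cognitive-workload states.  A
candidate feature subset is encoded as a binary chromosome over a screened
search space of `Band_Channel` columns; a genetic algorithm (GA) evolves
chromosomes under a fitness built from a logistic-regression (LoR) fit on
the selected columns.  The package also implements the stages around the
selector: spectral feature extraction from raw traces, t-test screening,
interval-threshold labeling, downstream classifier evaluation, and a
synthetic-data generator that makes every stage testable with known ground
truth.

The public surface follows the statsmodels convention: `GALoRIS(features,
labels, ...)` is a model object, `fit()` returns a `GALoRISResults` with
the selected features, coefficients, Wald p-values, per-generation history
and a `summary()` table.  The underlying operations are plain functions in
`galoris.ga`, `galoris.screening`, etc., so each stage can be used and
tested on its own.

## Feature extraction

Raw traces (microvolts, fixed sampling rate) are band-pass filtered with a
5th-order Butterworth filter, 1–100 Hz pass band.  Filtering is zero-phase
(forward–backward `sosfiltfilt`): phase handling is not dictated by the
procedure we follow, and zero-phase keeps epoch boundaries aligned with
the unfiltered record.

Band powers are computed per 5-second epoch.  Within an epoch a
128-sample Hanning window is slid without overlap; each window's power
spectrum is the squared rFFT magnitude normalized by the window energy
(`sum(w²)`); per-frequency-bin maxima are taken across the sub-windows;
and each band's feature is the maximum over the bins inside its range.
The window/epoch relationship (no overlap, max-pooling across
sub-windows) is a design choice: it preserves the "peak magnitude of the
power spectrum" reading of the feature while keeping one row per epoch.

Band ranges are Delta 0.5–4, Theta 4–8, Alpha 8–12, Beta 12–30, Gamma
30–100 Hz.  The intervals are half-open `[low, high)` so a shared printed
endpoint (4 Hz in both Delta and Theta) maps every bin to exactly one
band; the partition property is asserted in the tests.

Features are min–max standardized per column to [0, 1].  Constant columns
map to 0 (they carry no information and would otherwise divide by zero);
scaling parameters are retained for inverse lookup; the map is idempotent.

## Screening

The search space is the set of columns whose two-task comparison is
significant: a per-column t-test at `alpha = 0.05`, retained columns
ordered band-major (canonical band order; surviving bands keep relative
order) then by the fixed channel order AF3, AF4, F3, F7, F8, FC5, O2, P8,
T8.  The default test is the unpaired two-sample Student t on per-epoch
values — the paired variant is available via a flag, but per-epoch values
across two task recordings are not naturally paired.  No multiple-testing
correction is applied by default (the screen is a plain per-column
criterion); a Bonferroni flag exists for stricter screens.  Zero-variance
columns are excluded with a logged warning rather than producing an
undefined test.

## Labeling

Unlabeled data are labeled by the interval-threshold rule: average each
sample across all columns, split the range of that average vector into
`n_states` equal intervals, `interval_size = (max − min) / n_states`.
For two states the boundary is the range midpoint; a sample averages below
the boundary → label 0 (low workload), at or above → 1 (high workload).
Ties go to the high state.  The orientation (high mean band power ⇒ high
workload) matches the rule's purpose of finding the high-demand peaks of a
session.  Labeling is invariant under any common positive affine rescaling
of the average vector and boundary, and a constant average vector is an
explicit error — equal division of a zero-width range cannot separate
states.

## The selector

**Encoding.** One gene per search-space column; gene 1 = column included.
Initial genes are i.i.d. Bernoulli(0.5); all-zero vectors are resampled.

**Fitness.** For each chromosome a logistic model is fitted by maximum
likelihood (statsmodels `Logit`) on its selected columns, using a
stratified build/assess split of the *samples* (default 80/20).  The
split is drawn once per run and shared by every chromosome so fitnesses
are comparable; `validation_fraction` is configurable.  The adaptation
parameters are: accuracy = correct/(correct+incorrect) on the assess
portion at probability cut 0.5; error rate = the misclassified fraction
(1 − accuracy, both in [0, 1]); gene count; and per-gene significance,
the two-sided Wald p-value of each coefficient against `alpha = 0.05`.
The logistic response uses the conventional negative exponent,
`p = 1/(1+e^(−(β₀+Σβᵢxᵢ)))`, so a larger linear predictor means class 1.
Under perfect separation or a failed Newton iteration the fit falls back
to an L2-regularized estimate (C = 1); its coefficients are used for
prediction but its p-values are reported NaN and treated as
non-significant, and the chromosome is flagged `ridge_fallback`.
An all-zero chromosome receives the fitness floor (accuracy 0, error 1).

**Ranking.** Descending accuracy, then ascending error rate, then
ascending gene count (fewest features wins a tie), then the gene vector
lexicographically.  The last key is not part of the stated priority rule;
it exists purely so the order is total and runs are deterministic.

**Selection and elitism.** Parents are drawn by tournament selection of
size t = 5 under the ranking key.  Separately, the union of all genes
significant at `alpha` across the top `elite_size` chromosomes is formed
into one chromosome and injected unchanged into the next generation.  The
elite size is not dictated anywhere; the default of 10 (10% of the default
population of 100) is large enough to pool significant genes discovered in
different chromosomes and small enough that noise-gene false positives
(≈5% of inspected noise genes per fit) do not dominate the union.  When no
gene in the elite is significant, the top-ranked chromosome is carried
forward instead.

**Variation.** Two-point crossover with probability 0.8: cut points
`i < j` drawn uniformly, child 1 = parent 1's lateral segments around
parent 2's central segment, child 2 the complement; chromosomes shorter
than 3 genes are copied through.  Mutation flips each gene independently
with probability 0.1; an all-zero result gets one random gene restored.

**Stopping.** The run stops when the generation budget (default 30) is
spent or the best chromosome reaches accuracy 1 and error 0.

**Defaults.** 30 generations, population 100, tournament 5, crossover
0.8, mutation 0.1, significance 0.05 — the configuration of the study the
selector reimplements.

**Determinism.** All randomness flows from one `numpy` Generator seeded
by `GaConfig.seed`; fitness evaluations are memoized per gene vector
within a run.  Repeated runs with the same seed produce bit-identical
populations, history and best chromosome.

## Evaluation

The structured dataset (selected columns + labels) is scored with four
classifiers — SVM-RBF, SVM-linear, k-NN, and ordinary least squares on
the 0/1 labels thresholded at 0.5 — under stratified k-fold
cross-validation with k = 10, so each fold is a 90/10 train/test split;
no further hold-out is taken.  Hyperparameters are grid-searched inside
the training folds only, over C ∈ [10⁻⁴, 10³], γ ∈ [10⁻⁵, 10] and
k ∈ {1..10}.  The C and γ grids are log-spaced with `grid_points` values
across the full range (default 8); a per-decade grid over seven decades
would multiply the cost of every fold for no measurable gain on these
low-dimensional feature sets.  Sensitivity and accuracy are percent-scale
confusion ratios over the low/high workload tallies
(CLCW, CHCW, ILCW, IHCW): sensitivity = CLCW/(CLCW+IHCW)·100,
accuracy = (CLCW+CHCW)/total·100.

Two matched-size baselines support comparisons: mutual-information
ranking, using the package's own histogram plug-in estimator with
equal-frequency bins (discrete features fall back to one bin per value),
and projection onto leading principal components.  The MI estimator is
deliberately the simple plug-in, not a kNN estimator, so its behaviour is
transparent on the small synthetic problems it is tested on.

## Synthetic data

`generate_band_features` draws a two-state Gaussian feature table: each
column is Gaussian within a state (`noise_sd`, default 1), and informative
columns differ between states by `effect_size · noise_sd`, signed by band
type — Alpha/Beta/Gamma columns are elevated in the high-workload state,
Delta/Theta columns in the low-workload state, matching the physiology of
fast-wave activation under load and slow-wave activity at rest.  The
Gaussian-within-state assumption is the minimal model consistent with
mean ± SD descriptive reporting.  Defaults mirror the conditions of the
study the package emulates: 9 channels × 5 bands × 8210 samples, balanced
states, and — unless an explicit informative set is given — every
non-Theta column informative, so that Theta is the band the p ≤ 0.05
screen removes and the surviving search space has the familiar 36
columns.

`generate_raw_eeg` builds raw traces as sums of per-band sinusoids (one
frequency per band per channel, drawn uniformly inside the band with a
30% margin from the edges so a tone's spectral peak cannot leak into the
neighbouring band at the analysis window's 2 Hz bin width) plus white
noise.

What the generator does *not* emulate: 1/f background spectra, blink/EMG
artifacts, volume-conduction correlation between channels, non-
stationarity, or within-state temporal autocorrelation.  Tests passing on
this generator therefore demonstrate the correctness of the algorithms
and their behaviour under controlled signal-to-noise, not field
performance on real recordings.  In particular, the published classifier
accuracies of the original study were measured on undeposited human EEG
and are not reproduction targets.

## Problem sizes in the test and acceptance runs

The behavioural suites run at deliberately desk-scale sizes chosen as the
smallest problems on which the studied effects are unambiguous:
selector-vs-exhaustive comparisons use 8-column spaces at n = 500 over 10
seeds (enumeration of 255 subsets per seed); recovery experiments use the
36-column four-band space with 3 informative columns at effect size 2,
n = 2000, over 10 seeds, with a scaled GA (population 30, 8 generations —
the fitness cache makes further generations redundant at this problem
size).  Statistical acceptance thresholds (≥ 9/10 seeds within 95% of the
enumeration optimum; ≥ 8/10 seeds recovering all informative columns with
at most half the space selected) were fixed from these conditions before
the suites were finalized.

## Known limitations

- The fitness assesses on a single shared split; fold-averaged fitness
  would be less noisy but k-fold inside the GA multiplies runtime by k.
- Wald p-values are unreliable near separation; the ridge fallback
  deliberately reports NaN rather than misleading values, which makes the
  significant-gene merge conservative on strongly separable data.
- The gene-count and significance adaptation parameters act only as tie-
  break and elitism drivers; they carry no explicit weight in the fitness
  scalarization, so parsimony pressure is weak when accuracies differ.
- The interval-threshold labeler assumes the average band power is
  bimodal enough that the range midpoint separates states; on strongly
  skewed data the split can be badly unbalanced.
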
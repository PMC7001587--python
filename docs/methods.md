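# Methods

## The question and the measurement

When an autoencoder is trained to reconstruct two modalities of the same
category (an image of a digit and a spectrogram of the spoken digit), do
hidden units emerge that represent the category *regardless of the input
modality* — a shared representation? This package implements the full
analysis pipeline around that question: paired-dataset construction with
a label-mismatched control, bimodal autoencoder training at varying
encoder depth and with two fusion architectures, an information-theoretic
read-out of every hidden unit, a four-way selectivity typology, and a
frozen-encoder transfer task.

The core measurement is binned stimulus-specific single-cell
information. A unit's activation range [0, 1] is divided into `n_bins`
equal bins (10 by default) and a (category × bin) count table is
accumulated over test presentations. The information the unit carries
about category *s* is

    I(s, R) = Σ_r P(r|s) · log2( P(r|s) / P(r) )    [bits]

with P(r|s) the row-normalized conditional histogram and P(r) the pooled
marginal. This is the Kullback–Leibler divergence between the unit's
response distribution under *s* and its marginal response distribution;
it is non-negative and, under equal class priors, bounded by
log2(nCat) ≈ 3.32 bits for 10 digits. Probabilities are plug-in
empirical frequencies with no bias correction; the finite-sampling bias
floor is characterized empirically by a label-permutation null
(`shuffled_info_null`) rather than by analytic correction. Terms with
P(r|s) = 0 contribute 0; P(r) = 0 with P(r|s) > 0 cannot occur because
the marginal is the column sum of the same counts.

Bins are equal-width over the global sigmoid range [0, 1] (not per-unit
min–max), left-closed/right-open with the last bin closed at 1. Explicit
bin edges may be supplied instead; the three-bin worked example in the
test-suite uses its printed edges 0 / 0.33 / 0.67 / 1.

## Unit typology

A unit is *selective* for a digit in a modality when its information
about that digit, measured on the single-modality test subset, strictly
exceeds a per-modality threshold. Thresholds are the 80th percentile
(linear interpolation) of the pooled unit × digit information values of
a reference condition — the final encoding layer of the consistent-
trained network — and are then applied unchanged to every other
condition, recorded in all outputs for audit. Selective units are
classified as visual (only the visual digit set non-empty), auditory,
inconsistent (both non-empty, disjoint), or consistent (both non-empty,
intersecting — the shared representation). Units selective in neither
modality are reported as `non_selective` and sit outside the four-type
counts. The pooled-matrix reading of the percentile (over all
unit × digit values, not per-cell maxima) was one of two defensible
readings; it is fixed here and exposed via `percentile_threshold`.

## Networks and training

Both architectures use dense sigmoid layers of width 64 and identical
decoders: two parallel 3-layer paths, one per modality, ending in
sigmoid reconstruction layers at the modality's input dimension
(784 for 28×28 images and for 14×56 spectrograms). The *mixed-input*
encoder concatenates the two flattened inputs (1,568 values, row-major)
and passes them through 1–4 modality-combined sigmoid layers. The
*two-stage* encoder processes each modality through 3 separate layers
before a fourth, merged layer; it is trained end-to-end (not stagewise).

Training minimizes binary cross-entropy summed over both reconstruction
branches with AdaDelta at its standard settings (rho 0.95, eps 1e-6,
step size 1.0), full protocol 5,000 epochs, batch 128. Targets are
always the original arrays: the training set is tripled by
modality-dropout augmentation (one third visual-only, one third
audio-only, one third both, dropped inputs exactly zero), so the network
must reconstruct both modalities from one. The summed squared
reconstruction error is logged alongside as a monitoring metric.

Numerical choices: BCE is summed over features and averaged over the
batch. With a per-feature mean reduction, reconstruction gradients in
deep layers fall below AdaDelta's eps and the update degenerates to
bare-gradient steps that require hundreds of thousands of updates to
leave the mean-image solution; the per-sample sum reduction keeps
gradients inside AdaDelta's normalizing regime and is the package's
fixed convention. Weights use Glorot-uniform initialization, float32
arithmetic throughout; float32 sigmoids can saturate to exactly 0 or 1,
which the closed top bin absorbs. All randomness (initialization, batch
order, pairing, dropout masks) derives from explicit seeds via
independent tagged substreams, so every run is bit-reproducible on a
fixed platform.

## Synthetic data: what it emulates and what it does not

The generator replaces the original image/audio corpora with
class-structured arrays of the same shapes, ranges and per-class counts
(visual 28×28, 500 train / 50 test per digit; auditory 14×56, a
100-per-digit pool from 2 sub-prototype "speakers" split 50/50 into
train/test). Class identity is carried by sparse high-contrast smoothed
random prototypes (soft threshold at the field's 70th percentile, ~30%
of pixels bright), matching the near-binary sparse statistics of digit
images and spectrograms.

Within-class variability has two components with separate knobs:

* **structured deformation** (`variation_scale`, default 0.4;
  `n_variation_fields`, default 4): each sample shifts its prototype
  field along shared smooth basis patterns with Gaussian coefficients.
  This emulates reconstructable shape variation — different handwriting,
  different utterances — and is essential: purely unpredictable noise is
  discarded by the bottleneck, collapsing within-class activation
  variance and saturating the information estimate at its ceiling,
  which real data do not do.
* **pixel noise** (`noise_sd`, default 0.05): iid Gaussian, clipped to
  [0, 1].

What the generator does *not* emulate: stroke topology and correlated
digit geometry, speaker-specific spectro-temporal structure, and any
cross-modal correlation beyond the shared label. Passing tests therefore
show that the pipeline detects (or correctly fails to detect) shared
category structure injected through label-consistent pairing; they do
not certify accuracy values on natural images or audio.

Planted-activation fixtures bypass networks entirely: unit responses are
drawn from specified per-(digit, modality) bin distributions and mapped
to bin centers, so the exact information of every unit is available in
closed form and classifier recovery can be asserted with zero tolerance.

## Transfer evaluation

A supervised head — two dense layers of 64 rectified-linear units with
20% (inverted) dropout each, then a 10-way softmax — is trained with
categorical cross-entropy and the same AdaDelta settings on the frozen
final encoding layer, using labels from one single-modality condition
only. The encoder checksum is verified unchanged across head training.
Cross-modal transfer is top-1 accuracy on the other modality's test
subset; significance is judged against a label-shuffle null (the head
retrained on permuted labels, 95th percentile). Head epochs and batch
size are unspecified by the protocol and are configuration defaults
(desk 30 / full 100 epochs, batch 128).

## Execution profiles and problem sizes

Two profiles share identical topology and differ only in problem size.
`full` mirrors the study protocol (500/50 visual, 50 auditory per digit,
5,000 epochs, 10 replicates). `desk` — the default for the test suite
and replicated experiments — uses 10 train / 50 test visual variations
per digit, 10 auditory per digit, 150 epochs, batch 32, and 5 replicate
seeds; one network trains in roughly 8 s on a single CPU and the full
replicated experiment set completes in minutes. At this scale the
training-dependent findings are asserted *directionally* (orderings of
replicate means, null-exceedance) rather than against any full-scale
numbers: consistent-cell counts, accuracy curves, the 0.96/0.94-bit
thresholds and printed t/F statistics are stochastic outcomes of the
full 5,000-epoch protocol and are not reproduced at desk scale.

## Known limitations

* The plug-in information estimator is biased upward at small sample
  counts; compare against the shuffle null before interpreting small
  absolute values.
* AdaDelta's slow early ramp means very short trainings (a few hundred
  updates) may not leave the mean-image regime; the desk profile's
  epoch count was chosen above that region.
* The two-stage framework exposes concatenated per-modality streams
  (128 units) for layers 1–3 and the merged 64-unit code at layer 4;
  cross-layer comparisons between frameworks are therefore only
  meaningful at the final layer.
* `compare_groups` applies no multiple-comparison correction, matching
  the analysis protocol it implements.
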
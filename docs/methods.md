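# Methods

This note documents the models and procedures implemented in `virtualhic`,
their assumptions, the tunable parameters that matter, and the numerical
choices made where the design was genuinely open. It states no empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Problem setting

The package predicts 5-kb-resolution Hi-C contact maps from epigenomic
signal tracks and DNA sequence, and annotates each 5-kb bin with chromatin
states, in a single multi-task model. All contact values are on the
distance-stratified normalized scale: each matrix diagonal (one genomic
separation) is z-scored with its own mean and standard deviation, removing
the distance decay so that values are comparable across separations and
across data sources. Every loss and evaluation metric in the package
operates on this scale; raw counts are never modeled.

## Diagonal extraction

A training sample is the anti-diagonal stripe of contacts centered on a
genomic bin `c`: `target[t] = C[c−t, c+t]` for offsets `t = 1..100`, so one
sample covers genomic separations 10 kb–1 Mb, paired with a 200-bin (1-Mb)
feature window centered on `c`. This is the one geometry under which "100
values per diagonal", 1-Mb assembly tiles and a 195-diagonal denoiser loss
are mutually consistent. Samples containing zeros, NaNs or masked entries
in the target are discarded. Two consequences worth noting:

* stripes at integer centers reach only the even separations (an
  anti-diagonal with even index sum contains entries of one parity);
  assembled tiles therefore carry an explicit mask and downstream consumers
  (denoiser input, stitching) treat odd separations as missing rather than
  zero;
* the per-value distance weight is `w = 1 + min(relu(y), 10)/10`, i.e.,
  strong normalized contacts are up-weighted up to 2×. The weight function
  is pluggable.

A sample "has a peak" when any target value is ≥ 3.0 on the normalized
scale (the same ±3 threshold the interaction change score uses); training
sets are subsampled to a 1:2.5 peak:no-peak ratio, uniformly within
stratum, reproducibly by seed.

Tiles of 200×200 bins are assembled from predicted stripes by averaging
every value that maps to an entry, sliding at 0.5-Mb steps for denoiser
training and 0.75-Mb steps (0.25-Mb overlap) at prediction time, excluding
the first and last 2 Mb of each chromosome. Stitching averages overlapping
tile entries and propagates masks.

## Training objectives

The predictor's total objective is `HiCLoss + ChromHMMLoss`.

`HiCLoss` mixes per-sample distance-weighted L1/L2 sums
(`W_l1 = 0.1` on L1, `0.9` on L2), a batch-level weighted Pearson penalty
(weight 5) and a distance-stratified weighted correlation penalty
(weight 100). The batch correlation uses per-sample weighted means in a
single global ratio. The distance-stratified correlation is computed per
offset stratum — values sharing a genomic separation are correlated across
the batch — and the per-offset coefficients are averaged with their weight
mass. (The two correlation formulas are printed identically in the source
material; the per-offset reading is the only one that makes the second term
"distance-stratified", and it is the term that dominates the objective.)
Zero-variance correlation units contribute 0, i.e. the maximal penalty,
with a warning.

`ChromHMMLoss` is a per-label focal loss over the 13 chromatin states with
focusing parameter γ = 3.5 and per-state balance weights α_k = 1/f_k, the
unrescaled inverse of each state's genome-wide bin frequency (with a 1e-3
frequency floor). The weights are deliberately not normalized: rescaling
them to mean 1 starves rare states of positive-term gradient and, at
desk-scale training budgets, leaves the head predicting probabilities
below 0.5 for every label. Predicted probabilities are clipped to
`[1e-6, 1 − 1e-6]` before the logs. α multiplies the positive term only,
following the printed form.

The denoiser surrogate objective is a Charbonnier term
`mean sqrt(Δ² + ε²)` with ε = 1e-3 plus a diagonal-correlation term
`1 − (1/195) Σ_{d=4..198} cov/(σ_true σ_pred + ε)` over matrix diagonals
4–198 with population moments; the same ε = 1e-3 stabilizes both terms
(configurable separately).

Reference implementations of all objectives live in `virtualhic.losses`
(forward-only numpy); the differentiable versions used in training live in
`virtualhic.nn.tensor_losses` and are tested to agree with the references
to 1e-9, which are in turn tested against independent brute-force scalar
transcriptions.

## Chromatin-state vocabulary

The 25-state ROADMAP vocabulary collapses to 13 states: the three
promoter-flanking states merge, the seven transcription(-enhancer) states
merge, the three active-enhancer states merge, the three
weak/acetylated-enhancer states merge, and the remaining nine states pass
through. Output order is fixed (merged states first, by the numeric order
of their first member) so α vectors align across runs. Bin encoding uses
an any-overlap rule: a bin carries a state if ≥1 bp of the bin intersects
a segment of that state — the multi-label framing implies presence, not
dominance. Coordinates are 0-based half-open throughout, so a segment
starting exactly on a bin boundary labels only the right-hand bin.

## Predictor architecture

Two convolutional encoders (five conv → batchnorm → GELU → maxpool blocks
each) reduce the sequence (published scale: base-pair resolution, pools
5·5·5·5·8 = 5000) and the epigenetic tracks (25-bp resolution, pools
5·5·4·2·1 = 200) to one embedding per 5-kb bin; the validator accepts any
pool factorization whose product matches the input resolution. The
concatenated per-bin embeddings, plus sinusoidal positions, pass through a
pre-norm transformer encoder. Two heads follow:

* Hi-C head: for each offset `t`, the embeddings at the two endpoint bins
  of the contact `(c−t, c+t)` are concatenated and passed through a shared
  MLP to one value ("pair" mode, the default). A pooled variant (mean over
  the window, then an MLP to all 100 outputs) is available via
  `hic_head_mode="pooled"`, but mean pooling discards the positional
  information needed to resolve distance-specific outputs and did not train
  to useful accuracy at desk scale.
* state head: a per-bin MLP to 13 sigmoid outputs.

GELU uses the tanh approximation (the variant most transformer
implementations use); the exact-erf form is measurably slower on CPU and
numerically indistinguishable for training purposes.

The desk-scale configuration (used throughout the tests) divides all
channel widths by 8, consumes both inputs at 5-kb resolution (sequence as
per-bin base composition), uses a 2-layer, 2-head transformer, and float32
parameters. The published-scale configuration (64/128/128/256 filters,
base-pair sequence input) is expressible in the same `ModelConfig` and
validated by the same code, but is not trainable in minutes on one CPU and
is not exercised by the test suite.

## Training protocol

Adam with a warmup schedule: published-scale defaults are 5000 epochs
maximum, 30 warmup epochs at lr 1e-7 then 1e-5, early stopping with
patience 2000 on the validation weighted Pearson. Desk-scale defaults
compress this to tens of epochs, warmup 3 at 1e-4 then 1e-3 (optionally
cosine-annealed), patience 20, with three regularizers that matter at this
sample count:

* window-flip augmentation: reversing the feature window spatially maps
  bin `c−t` onto `c+t`, leaving the anti-diagonal target invariant (the
  per-bin states reverse with the window); each training window is flipped
  with probability 0.5;
* Gaussian input noise on the track windows (sd 0.25 on the z-scored
  scale), which penalizes window-fingerprint memorization;
* decoupled weight decay (1e-4).

Without them, a desk-scale model trained on a few hundred overlapping 1-Mb
windows of one chromosome memorizes window identities and transfers no
per-offset signal to a held-out chromosome.

The early-stopping/selection criterion is a validation Pearson
correlation; `TrainConfig.val_metric` chooses between the pooled weighted
Pearson and the distance-stratified weighted correlation (the objective's
dominant term). The recovery experiment uses the latter, which tracks
held-out per-offset performance much more closely than the pooled
coefficient.

The denoiser is a reduced multi-scale residual network: 2 residual groups
of 2 multi-resolution blocks (a full-resolution and an average-pooled
half-resolution conv path, summed), with a global input residual whose
final convolution is zero-initialized — the untrained model is exactly the
identity, so training can only improve on its input. Because assembled
tiles carry data only on even separations, masked entries are filled by
valid-neighbor interpolation (never zeros) on the way into the network,
and re-masked on the way out. Training uses Adam at 3e-4; the patience
counter follows the validation diagonal-correlation term (the stated
protocol) while the restored weights are the best by the full validation
surrogate loss — the diagonal term alone is scale-invariant and would
happily keep weights that corrupt magnitudes. Desk scale uses 8 channels
and up to 80 epochs.

## Evaluation metrics

Pearson and Spearman correlations are computed over jointly valid entries
of the upper triangle (including the main diagonal); Spearman uses average
ranks. The distance-stratified correlation is one Pearson per diagonal;
diagonals with fewer than 3 valid entries or zero variance are omitted
with a warning. O/E correlation divides each matrix by its own per-distance
mean contact before correlating jointly valid entries. SSIM follows the
single-window definition — means, variances and covariance over all
jointly valid entries — with C1 = (0.01·L)², C2 = (0.03·L)². L is the
joint observed data range of both matrices: defining L from one argument
would break the symmetry SSIM(X,Y) = SSIM(Y,X), which we consider part of
the metric's contract. A sliding-window SSIM (scikit-image) is available
as an explicitly different estimator.

Per-diagonal z-normalization treats a diagonal as degenerate when its
standard deviation is below 1e-12 relative to its mean magnitude, mapping
it to zero — an exactly constant diagonal stored in floating point
otherwise produces spurious ±1 values from rounding noise.

The percentile-rank partition buckets scored 1-Mb regions into quartile
bands labeled PR99 (top), PR75, PR50, PR25; ties at a cut-point fall into
the lower band.

## Synthetic data

The generator produces the coupled inputs the pipeline assumes, at desk
scale (default: two 10-Mb chromosomes of 5-kb bins):

* contact maps: `(1+d)^(−1)` distance decay, multiplied by planted TAD
  blocks (sizes 50–150 bins, boosts 1.5–2.5) and Gaussian corner-loop
  bumps (strengths 2–4 at ~70% of TADs), times multiplicative Gaussian
  noise `(1+ε)`, ε ~ N(0, 0.1), then per-diagonal z-normalized.
  Multiplicative noise keeps the per-diagonal signal-to-noise ratio
  distance-independent, which is how noise behaves on the normalized scale
  consumed downstream; additive noise on the raw decay scale would drown
  all long-range structure.
* tracks (nominally 25-bp resolution, bin-level signals upsampled by
  repetition): a boundary track with Gaussian bumps at TAD boundaries, an
  anchor track with bumps at loop anchors, an activity track correlated
  0.9 with the map's row mean, plus smoothed-noise tracks — all
  standardized at bin level so that with no planted structure every
  informative track is distributionally indistinguishable from a noise
  track.
* states: deterministic thresholds of the tracks (active enhancer =
  activity > 1, weak enhancer = activity in (0.3, 1], promoter/Tx from
  their tracks, quiescent where nothing else), so state prediction has a
  clean ceiling;
* sequence: i.i.d. uniform background with a 14-bp CTCF-like consensus
  planted at 1e-4 per bp, positions logged for recovery tests.

What the generator does not emulate: raw Hi-C count statistics (sampling
noise, coverage biases, unmappable regions), compartment-scale structure,
sequence-driven chromatin structure (tracks, not sequence, carry the
coupling), realistic state co-occurrence grammar, and replicate-level
variability. Passing tests therefore demonstrate that the pipeline's
machinery — extraction, objectives, training loop, metrics, analytics —
behaves correctly on data with the assumed statistical structure, not that
the model architecture reaches any particular accuracy on real chromatin.

## Desk-scale recovery experiment

`virtualhic.experiments.synthetic_recovery` trains the desk-scale
predictor on synthetic chromosome 1 (stride-1 extraction, peak-balanced,
~900 training windows, 26 epochs) and evaluates on held-out chromosome 2.
Validation is disjoint by chromosome: a separate 5-Mb validation
chromosome, generated with a distinct seed (hence a distinct TAD/loop
layout) but the training chromosome's z-score transform, drives early
stopping and calibrates per-label state decision thresholds. Evaluation
details:

* predictions are flip-averaged at test time (the window and its spatial
  reversal are equally valid views of the same anti-diagonal target;
  averaging them cancels orientation-specific error);
* the Hi-C readout is the per-offset Pearson correlation of predicted vs
  true stripe values across evaluation centers, averaged over offsets;
* state calls are per genomic bin: probabilities from the central half of
  every window covering a bin (the positions with bilateral context) are
  averaged, then thresholded with the validation-calibrated per-label
  thresholds; accuracy is reported per label against the deterministic
  truth.

Problem sizes (10-Mb chromosomes, ~26 epochs) are chosen so the experiment
completes in minutes on one CPU.

## Interpretation procedures

* Motif PWMs: positions where a first-layer sequence-encoder kernel's
  activation (post-batchnorm, post-GELU by default; stage configurable)
  exceeds 2 are extended ±7 bases; base frequencies over these 15-mers
  form one PWM per kernel. Sites within 7 bp of a sequence edge are
  dropped; kernels with no sites yield uniform PWMs flagged support = 0.
  PWMs export to MEME minimal format.
* Integrated gradients: trapezoid-rule path integral from an all-zero
  baseline, 64 steps by default, attributing a scalar target — the summed
  Hi-C output, or a chromatin-state logit (pre-sigmoid; logits keep the
  completeness identity meaningful) — to the epigenetic input tracks.
  The completeness identity Σ IG ≈ F(x) − F(0) holds to quadrature error.
* Gene importance: mean attribution within promoter ±0.25 Mb, averaged
  over tracks; differential tables subtract one condition from another;
  rankings export as two-column `.rnk` files sorted descending with ties
  broken by gene id.

## Chromatin analytics

* Promoter hubness: mean contact between the promoter bin and all valid
  bins within ±0.25 Mb ("mean" mode, default) or the count of such bins
  above a threshold ("count" mode). Both readings of "average number of
  interactions" are exposed because the phrase is ambiguous.
* Interaction change score: per bin, the number of offsets in a ±15-bin
  window — excluding offsets {−1, 0, +1} — where the contact difference
  strictly exceeds +3 or falls below −3; the attainable maximum is 28.
* Region permutation test: the observed statistic is the proportion of
  differentially-expressed genes whose ±0.6-Mb extended span intersects
  the intersection of the top-k regions by interaction change and by
  enhancer difference (k defaults to the top decile and is always logged);
  the null shuffles which regions carry the top labels;
  p = (1 + #null ≥ obs)/(1 + n_perm). The permutation p-value is discrete;
  calibration checks should use enough genes/permutations that the p grid
  is fine.
* Quartile association: bins are split into quartiles of their row-mean
  contact value (sizes differing by at most 1); per-bin active-enhancer
  indicators are compared between adjacent quartiles and bottom-vs-top
  with two-sided Mann-Whitney tests.
* Tissue dendrogram: per 1-Mb region, the feature is the L1 distance
  between a tissue's sub-matrix and the across-tissue mean sub-matrix;
  tissues are clustered with average linkage on Euclidean distances
  between feature vectors (linkage and metric are choices; nothing is
  prescribed), serialized as Newick.
* In-silico perturbation: insertions, deletions and duplications edit the
  sequence and every track jointly; coordinates must align to the track
  resolution so the two stay in register, and re-running prediction on the
  edited inputs constitutes the experiment.

## Numerical and engineering choices

* The neural models run on an in-repo reverse-mode autodiff engine over
  numpy (`virtualhic.nn`): conv layers as kernel-position loops over BLAS
  contractions, gradient-ownership tracking to avoid defensive copies,
  float32 model parameters (float64 everywhere else). Gradients are
  verified against central differences in the test suite.
* Determinism: every stochastic component (generator, sampling, model
  init, shuffling, augmentation, permutation tests) is seeded through
  `numpy.random.default_rng`; model evaluation uses batchnorm running
  statistics, so prediction is deterministic.
* Z-score statistics for tracks are fit on training data only and stored
  in checkpoints so prediction reuses the training transform.
* Asymmetric input matrices are symmetrized by averaging with a warning;
  asymmetry beyond 10% of the matrix magnitude is an error.
* Contact-map I/O writes a minimal single-resolution cooler-compatible
  HDF5 layout via h5py (plus dense `.npz`/TSV); multi-resolution and
  `.hic` containers are out of scope.

## Known limitations

* Odd genomic separations are never covered by integer-center stripes
  (see above); real-data deployments wanting full coverage would need
  half-offset stripe families, which the tile mask design accommodates.
* The desk-scale model's held-out accuracy is bounded by what ~900
  overlapping windows of one synthetic chromosome can teach; the recovery
  experiment is a pipeline integration check, not an architecture
  benchmark.
* The engine is CPU-only and single-threaded beyond BLAS; published-scale
  training is out of scope.
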
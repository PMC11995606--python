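# Methods

## Model and rationale

`cfpri` treats early preeclampsia screening as a regression problem: map a
maternal-plasma cfRNA expression profile restricted to a small panel of
selected indicators onto a per-indicator PE-probability vector, and
summarise that vector by its mean — the Preeclamptic Risk Index (PRI).
The clinical anchors are PRI = 1 for a diagnosed preeclamptic pregnancy
and PRI = 0 for a normotensive one; the calculated PRI of an observed
sample interpolates between these anchors through the min–max position of
each indicator's abundance within its observed range.

The design is deliberately distribution-free at the selection stage (no
parametric tests, no multiple-testing machinery): a gene is informative
exactly when its NP and PE abundance *ranges* barely overlap and its group
means differ by a material fold. This favours robustly shifted indicators
over marginally significant ones, at the cost of ignoring covariance
between genes.

## Indicator selection

Per gene, with NP values a and PE values b (both groups non-empty):

* min/max/mean per group, zero flags (any exact 0), the overlap rate
  `|[max(min a, min b), min(max a, max b)]| / min(|range a|, |range b|)`
  (Szymkiewicz–Simpson on intervals, so a range nested inside the other
  counts as full overlap), and the fold (larger group mean ÷ smaller;
  1 when both are 0, +∞ when only the smaller is 0).

Rules, all required, evaluated in input gene order:

1. not (zeros in both groups) — a gene silent (or dropout-prone) in both
   groups cannot push the index either way. A strict `all_zero` variant
   drops only genes identically zero everywhere; the literal
   both-groups-contain-zero reading is the default.
2. overlap rate < 1 — fully overlapping ranges carry no direction.
3. overlap rate < 0.6 (configurable).
4. fold ≥ 1.5, optionally ≤ an upper bound. The fold criterion is treated
   as a floor by default because observed panels are naturally described
   by a fold *range*; a band variant (`fold_max`) is available.

Genes with exactly tied group means have no direction and are excluded
with a logged reason. Panel size is monotone: raising the overlap
threshold or lowering the fold floor can only add genes (asserted by a
sweep test). `threshold_sweep` tabulates panel size across a config grid,
since the thresholds that reproduce any particular published panel size
are a tuning choice, not a derivable constant.

## Dataset generation and probability targets

For each selected indicator the generation envelope is the global
[min, max] over both groups (optionally re-fitted on a seeded random 30%
subsample of the real samples, leaving all real samples untouched for
final evaluation; the generated matrices remain fully synthetic unless
`include_real` is set). Columns are generated independently:

* `truncated_gaussian` (default): mean at the envelope midpoint, sd =
  range × 1/6 so the bounds sit at ≈3σ; out-of-range draws are rejected
  and redrawn. The 1/6 fraction is a choice — the generator's only fixed
  inputs are the envelope and the count — and a `uniform` alternative is
  provided for sensitivity analysis.
* degenerate envelopes (lo = hi) produce constant columns.

Probability targets are the direction-aware min–max transform computed
over the matrix being transformed (generated matrices use their own
min/max; the calculated PRI of real data uses the real min/max). A
constant column maps to the uninformative value 0.5, logged rather than
raised. Consequences worth knowing:

* each generated dataset attains y = 0 and y = 1 exactly once per
  non-degenerate column;
* the transform is invariant to positive per-column affine rescaling;
* two matrices of different size transform slightly differently because
  their observed extremes differ — this is why the vector-MAE measured on
  a separately generated validation matrix is a little larger than the
  held-out-split validation loss.

Default sizes follow the reference protocol: M = 8000 training and
Q = 500 validation profiles ([M, N] sample-major layout, with a lossless
[1, N, M] channel-major conversion); the scaled test/acceptance runs use
M = 2000, Q = 200 so the full pipeline fits in minutes on one CPU.

## Network

All three architectures map an N-vector to an N-vector in [0, 1] and are
trained identically (Adam, lr 5 × 10⁻⁴, MAE loss, batch 16, validation
split 0.05; 500 epochs at full scale, 50 in the scaled runs), so the
model comparison is a pure architecture swap.

**Pyramid network (default).** Per-position batch norm on the input →
strided 1-D convolution (128 channels, stride 5) with ReLU → pyramid
pooling: for each bin b in {1, 2, 3, 6} (pruned to the feature length),
adaptive max-pool to b bins, 1×1 convolution (128/⌈bins⌉ channels), ReLU,
transposed-convolution upsampling back to the feature length; branch
outputs are concatenated with the untouched feature map → batch norm →
3-kernel convolution fusion with ReLU and dropout 0.25 → transposed
convolution restoring length N → per-position dense head (1×1
convolution, 128 channels, ReLU) → 1×1 convolution to one channel →
logistic squash. **CNN** is the same backbone without pyramid branches;
**MLP** is dense(128)–ReLU–dropout–dense(128)–ReLU–dense(N)–squash.

Numerical/structural choices that required a decision:

* **Kernels are one-dimensional** (length 3): the inputs are 1 × N
  profile vectors, not images, so a "3 × 3" kernel degenerates to length 3.
* **The strided feature extractor widens its kernel to the stride**
  (length 5 at stride 5). A stride-5/kernel-3 convolution skips two of
  every five input positions outright; because each probability target
  depends only on its own input position, skipped positions are
  unpredictable and impose an error floor (~0.05 MAE at N ≈ 17–29,
  observed as a hard training plateau). Kernel = stride is the standard
  patch-embedding resolution of this conflict; stride-1 convolutions keep
  kernel 3.
* **Input normalisation is per indicator position.** Indicator abundances
  span ~3 decades; batch norm over the N positions (rather than a single
  joint channel) gives each indicator a unit-scale input, which the
  stride-5 extractor needs to converge within 50 epochs.
* **Restoration to length N** uses a transposed convolution with kernel =
  stride + remainder and a fixed centre crop; a kernel narrower than the
  stride would leave output positions fed only by the bias.
* **Output squashing.** The hidden activations are ReLU but the targets
  are probabilities; the final layer is a logistic squash by default (a
  hard clamp is available). Predictions are therefore in (0, 1) and can
  approach but not exactly reach the anchors.
* **Pyramid bins** {1, 2, 3, 6} follow the canonical pyramid-pooling
  design; bins exceeding the post-stride feature length are pruned with a
  warning (at N ≈ 17–29 and stride 5 the feature length is 4–6, so the
  6-bin is usually pruned).
* **Determinism.** One seed drives weight init, the validation split,
  shuffling and dropout through independent substreams; single-threaded
  runs reproduce histories bit for bit. Training aborts on non-finite
  loss with a learning-rate hint.
* The MAE gradient uses the sign subgradient (0 at exactly zero error).

## Evaluation

Two error families are reported under distinct names and never conflated:
the vector-level MAE of probability predictions, and PRI-level signed
errors e_j = PRI_pred − PRI_truth summarised by max |e|, the
peak-to-valley error (max e − min e, invariant to a constant bias) and
mean |e|. Classification treats PE as positive: ROC by threshold sweep
over the scores with trapezoidal AUC (computed via scikit-learn, verified
in tests against exhaustive concordant-pair counting), and
precision/recall/F1 at a threshold resolved by Youden's J by default
(smallest threshold on ties; midpoint-of-group-means and fixed
thresholds available). With no positive calls, precision is 0 by logged
convention. `compare_models` refuses to tabulate reports that scored
different sample sets.

## Cohort simulator

The simulator emulates exactly the statistical structure the selection
rules assume, and nothing else:

* gene-level log-means are Gaussian (sd 2.0 in natural log, ≈3 decades of
  abundance); within-group abundances are log-normal;
* background genes share parameters across groups (sd 0.5), so their
  ranges overlap essentially fully;
* 20 of 200 genes (defaults) receive a multiplicative group-mean shift
  drawn uniformly from fold 1.5–2.5, up or down in PE with equal
  probability;
* the within-group log-sd of a differential gene is derived from a target
  raw-scale overlap rate (default 0.4) by inverting the overlap of the
  ranges exp(μ ± a·s) and exp(μ + ln f ± a·s), with a = 2.1 the expected
  extreme of 25–60 standard normal draws. Working on the raw scale
  matters: a log-scale approximation drifts badly at large folds because
  the lognormal's upper tail stretches the ranges. Realised overlaps are
  approximate (sampling noise), so recovery tests assert bands
  (recall/precision ≥ 0.8), not exact counts. A fixed `diff_log_sd`
  override decouples effect size from spread, which is what makes
  recall provably monotone in the fold floor;
* 5% of background genes get zeros injected into both groups (dropout),
  exercising rule 1.

What the simulator does **not** model — and hence what passing tests do
not establish about real cohorts: inter-gene correlation, library-size
and batch effects, sequencing noise models, gestational-age drift within
a window, or any real gene identities. Separating simulated groups
(AUC ≈ 1) is far easier than the real clinical problem; the simulator's
job is to verify the pipeline's mechanics and contracts, not its clinical
performance.

## Problem sizes and limitations

The test suite and the acceptance script run the pipeline at M = 2000,
Q = 200, 50 epochs on a 200-gene cohort (about two minutes per trained
network on one CPU); full-scale defaults (M = 8000, Q = 500, 500 epochs)
are the published protocol and run unchanged, just longer. Known
limitations: per-indicator independence in generation understates real
covariance, so the network never learns cross-indicator structure; the
min–max transform ties the probability scale to observed extremes, making
the calculated PRI sensitive to single extreme samples; and the selection
rules are threshold heuristics whose panel size must be tuned against the
final index separation rather than derived.
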
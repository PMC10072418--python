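# Methods

## Problem and model

`wsimil` classifies whole-slide histopathology images (WSIs) into binary
recurrence-risk categories (low/high, following the Oncotype DX convention of
a cutoff at score 25) using only slide-level labels. A WSI is far too large
to classify directly and patch-level labels do not exist, so the pipeline has
two weakly supervised stages.

**Stage 1 — patch scorer and discriminative sampling.** Every tumor-region
patch inherits its slide's label and a small CNN is trained on this noisy
patch classification task (binary cross-entropy, Adam). For a patch `x` with
predicted probability `p = σ(f_θ(x))`, the discrimination score is

    DS(x) = |p − 0.5| / 0.5  ∈ [0, 1].

Patches the scorer pushes confidently toward either class are discriminative;
patches near the decision boundary are not. Each slide's patches are ranked
by DS (per slide, not by a global threshold — DS distributions differ between
slides) and the top K are embedded with the scorer's feature trunk into a
K × D bag. Ties in DS are broken by row-major patch coordinates so selection
is deterministic.

**Stage 2 — gated attention MIL.** The bag `{x_k}` is pooled with gated
attention

    a_k = softmax_k( wᵀ ( tanh(V x_kᵀ) ⊙ sigm(U x_kᵀ) ) ),
    M   = Σ_k a_k x_k,

and the meta-instance `M` is classified by a single fully connected layer
with a sigmoid; a slide is called high-risk iff the probability is ≥ 0.5.
`V` and `U` (L × D) are stored weight-normalized — each row as a positive
scale times a unit direction — which stabilizes optimization; the effective
matrices are reconstructed on every forward pass, so the reparameterization
holds exactly after every optimizer step. Attention weights are non-negative
and sum to one per bag, making predictions invariant to instance permutation
and yielding per-patch attention maps for interpretability.

## Implementation notes

The neural components are implemented directly in numpy with analytic
gradients (`wsimil.nn` for the convolutional scorer; closed-form expressions
for the attention/classifier stage in `wsimil.mil`), keeping the package
dependency-light and the gradients auditable — the test suite checks every
layer and the full bag loss against central finite differences (relative
error ≤ 1e−4; the attention softmax is also checked against an element-wise
extended-precision evaluation to 1e−6). MIL computations run in float64; the
scorer in float32. Softmax uses max-subtraction; binary cross-entropy uses
the softplus form to avoid overflow.

Two scorer backbones are defined. `small_cnn` (default) is a three-conv-block
network — stride-2 3×3 convolution, then two same-padded 3×3 convolutions,
each followed by ReLU and 2×2 max pooling, then global average pooling —
with a 64-dimensional embedding and a two-layer head. It trains on a CPU in
seconds and is what all tests use. `paper_backbone` names the configuration
used with real cohorts (an ImageNet-pretrained ResNet50 truncated after its
third residual stage, 1024-dimensional embeddings, attention width L = 512);
it requires pretrained weights the package does not bundle, so constructing
it raises with an explanatory message. Pixel inputs are normalized as
`(x/255 − 0.5)/0.25` uniformly.

Training schedules: the estimator defaults follow the reference protocol
(Adam, learning rate 2e−4, up to 150 epochs, early-stopping patience 15; the
scorer monitors training accuracy, the MIL stage validation accuracy under
the hold-out protocol and training accuracy under leave-two-out CV). The
*pipeline* (`wsimil.pipeline`) substitutes desk-scale schedules appropriate
for the synthetic cohorts it runs on: scorer learning rate 1e−3, at most 16
epochs, patience 5, 48 sampled patches per training slide; MIL learning rate
3e−3 with the standard patience-15 stopping. These are the package's own
choices for its problem sizes, stated here so runs are reproducible.

**Early-stopping checkpoint rule.** A strict improvement of the monitored
accuracy resets patience; ties never do. Among epochs tied at the best
accuracy, the checkpoint is the one with the lowest monitor loss. With small
validation sets (a handful of slides) accuracy is extremely coarse, and
keeping the *first* epoch that touches the ceiling routinely freezes an
undertrained model; the loss tie-break selects among equally accurate models
without changing when training stops.

## Synthetic cohorts

The simulator (`wsimil.synthetic`) generates the statistical structure the
method assumes, not realistic histology. A slide is a regular mosaic of
square patches with a background margin; the ROI polygon (GeoJSON, 0-based
pixel coordinates) covers exactly the inner cells, so tiling recovers the
generative lattice and oracle tests can be exact. Patch kinds:

* `discriminative_positive`: Poisson(8) anti-aliased brown discs (radius
  5–10 % of the patch side) on a textured pink canvas — a cartoon of densely
  stained proliferating cells. Present only in positive slides, at fraction
  `positive_instance_fraction` (default 0.3) of ROI patches.
* `discriminative_negative`: same construction with Poisson(2) discs.
* `nondiscriminative`: the Poisson rate itself is drawn uniformly between
  the two class densities, giving intermediate, label-uninformative
  appearance. This matters: if ambiguous patches were instead sampled from
  the two class rates bimodally, a negative slide would contain patches
  pixel-identical to positive evidence, the scorer would (correctly, given
  appearance) rank them top-K, and sampling would actively mislead — a
  different phenomenon from the label-noise one this simulator models.
* `background`: bright blob-free canvas outside the ROI.

The density gap (8 vs 2 expected blobs) and noise (Gaussian, sd 6) are
simulator parameters, not claims about biology. Per-slide RNG streams are
derived as `SeedSequence([seed, slide_index])`, so slides are reproducible
independently of generation order; the label CSV, ROI GeoJSON, and a
ground-truth sidecar (`patch_truth.csv`, per-cell kinds) are written
alongside the images. The sidecar exists only for oracle tests — the
pipeline never reads it. Synthetic covariates (a continuous risk score
consistent with the label cutoff, and a tumor grade drawn with
label-dependent frequencies) support the subgroup error-rate analysis.

What passing on this simulator shows: the pipeline can recover slide labels
from bag structure alone, sampling removes ambiguous instances, and attention
concentrates on label-carrying instances. What it does not show: robustness
to stain variation, scanner artefacts, morphological heterogeneity, or any
claim about real tissue — the cohorts are caricatures with a single,
perfectly planted signal.

## Evaluation protocols

`kfold_holdout` balances the cohort by seeded downsampling of the majority
class, holds out a stratified test set (default 20 %) shared by all folds,
and draws `n_folds` independent stratified train/validation splits of the
remainder (validation fraction 0.1, at least one slide per class). Hold-out
metrics are computed per fold model and aggregated as mean ± sample sd, not
by ensembling. `ltocv` pairs slides across classes after a seeded shuffle:
one fold per pair, validation = one slide per class, no hold-out.

Metrics: AUC (rank-based), accuracy, per-class recall, macro-F1 (macro chosen
because the protocol reports symmetric per-class accuracies; per-class F1 is
available from the confusion counts). Bootstrap aggregation resamples
*slides* from the pooled predictions (percentile method, B = 2000 by
default); resamples that lose a class are redrawn because AUC is undefined on
them.

**Attention interpretability measurement.** `attention_truth_gap` compares
mean attention on dense (`discriminative_positive`) versus sparse
(`discriminative_negative`) instances within positive slides, averaged over
slides whose bag contains both. Ambiguous (`nondiscriminative`) instances
are excluded from the contrast: their sidecar kind does not determine their
appearance, so they belong to neither side of the oracle. A positive gap
means trained attention concentrates on the instances that carry the label
signal. Note that at very small K the sampled bags become nearly pure and
the within-bag attention ordering is only weakly constrained by training —
the gap is a meaningful diagnostic, not a guarantee, and is therefore
assessed across independently seeded runs.

**Heatmaps.** `render_heatmap` paints each patch's attention weight over its
footprint at a downsampled resolution (default 32×), averages overlapping
footprints, leaves unsampled regions at zero, and optionally
contrast-stretches by clipping at the 1st/99th percentile of footprint values
and min–max rescaling to [0, 1] (skipped when degenerate).

## Numerical and degenerate-input conventions

* Probabilities outside [0, 1] passed to the DS function are errors, as are
  single-class training sets (degenerate BCE/AUC), empty manifests, empty
  polygon lists, out-of-bounds patch windows, and attention vectors off the
  simplex beyond 1e−6.
* An ROI smaller than one patch tiles to an empty list (not an error).
* A slide with fewer than K patches contributes all of them; the shortfall is
  logged. `K = None` disables sampling entirely (every ROI patch in the bag).
* Patch-grid inclusion uses the patch *center* (configurable stride; default
  non-overlapping). The center rule tolerates boundary patches and keeps
  tiling exactly invertible on the synthetic mosaics.
* `patience = 0` stops after exactly one epoch; `patience ≥ max_epochs` is
  rejected.

## Known limitations

* The numpy scorer is CPU-bound and meant for desk-scale experiments; real
  gigapixel cohorts need the pretrained-backbone configuration and an
  accelerator, which this package deliberately does not ship.
* Bags are embedded once and persisted (HDF5); the scorer is not fine-tuned
  through the MIL stage.
* Validation-accuracy early stopping is coarse when validation sets are tiny;
  the loss tie-break mitigates but does not remove this.
* The simulator's planted signal is one-dimensional (blob density); it cannot
  probe texture- or context-dependent discrimination.
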
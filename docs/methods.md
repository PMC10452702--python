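# Methods

This note records the model, the algorithms, the parameter choices and the
numerical decisions behind `dropcell`. Everything here is implemented in the
package; nothing relies on external data or services.

## Problem

Droplet microfluidics encapsulates cells in picoliter water-in-oil droplets.
Downstream assays need to know, per droplet, whether it is empty, holds a
single cell, or holds multiple cells — and ideally where the cells sit.
`dropcell` implements a two-stage recognizer for brightfield micrographs of
densely packed (adherent) droplets:

1. **Stage 1 — detection.** An adaptive-scale template matcher proposes
   bounding circles for every droplet in the frame.
2. **Stage 2 — counting and classification.** A small two-branch
   convolutional network scores each proposed patch: one branch classifies
   droplet vs. clutter, the other regresses a cell **density map** whose
   integral is the cell count and whose maxima are cell locations.

The counting branch is *weakly supervised*: training labels are only the
per-droplet categories 0, 1, or "at least 2" cells — never counts above two
and never cell positions. Counts above two and cell locations emerge from
the density-map structure of the loss.

A Poisson module provides the encapsulation statistics used to design and
check loading experiments.

## Synthetic data generator (`synthgen`)

No imaging data ships with the package; a seeded generator renders frames
with the structure the recognizers rely on:

- Droplet diameters: truncated normal (default mean 22 px, CV 8 %).
- Packing: rejection sampling; two centers may be no closer than
  (r₁+r₂)(1−`max_overlap`), default `max_overlap` = 0.15, which produces
  adherent, slightly overlapping droplets as in dense monolayers.
- Appearance: bright oil background (grey level 200), dark rim (annulus of
  width 2 px, contrast −90), slightly darkened interior (−30), cells as
  Gaussian dark blobs (σ = d/4, contrast −80, diameters 4–8 px) placed
  uniformly inside 0.8 × radius, Gaussian sensor noise (σ = 4 grey levels).
- Loading: per-droplet cell counts are i.i.d. Poisson(λ), default λ = 0.5.

Placement, loading and noise use independent sub-streams of a single
`SeedSequence`, so the i-th droplet's load does not depend on how many
placement retries its neighbours needed; the same config and seed always
render the identical frame.

**What the generator does not emulate:** refraction and lensing through the
droplet interface, illumination gradients, debris, focus drift, satellite
droplets, or cell morphology beyond an isotropic blob. Scores obtained on
this generator measure the pipeline's geometric and statistical behaviour,
not transfer to any particular microscope.

Patch datasets for training are extracted at 2.4 × radius crops, resampled
to 32 × 32, with category quotas and a stratified 4:1:1 train/val/test
split. Background (non-droplet) windows are sampled from droplet-free
regions of the same frames.

## Stage 1: adaptive-scale template matching (`astm`)

1. **Foreground.** Otsu threshold on the frame; droplets are dark on bright
   oil, so foreground = below threshold; holes are filled. A separation
   sanity check (foreground/background mean gap ≥ 4 pooled SDs) rejects
   frames with no bimodal structure instead of hallucinating circles.
2. **Response.** For a circular template of diameter r (a rasterized disk),
   the response at each pixel is the fraction of foreground under the
   template — computed as an FFT convolution with the normalized disk,
   clipped to [0, 1]. A pure per-pixel implementation is kept as a testing
   oracle and verified to agree pointwise.
3. **Accept and shrink.** At the current scale, all connected plateaus with
   response ≥ σ = 0.98 are accepted (response-weighted centroid), erased
   from the foreground, and the same scale is re-searched. When nothing
   further is accepted, the scale shrinks to max-response × r, clamped to
   at most 0.95 × r per step so a high plateau cannot stall the schedule,
   down to a minimum radius of 8 px.
4. **Radius refinement.** The multiplicative shrink schedule can step over
   the true diameter, leaving an accepted circle at an undershot scale.
   Each accepted circle is therefore grown (step 0.25 px, cap 1.6 ×) while
   its foreground coverage stays ≥ σ. This is a pure augmentation of the
   accept step; no threshold changes.
5. **Non-maximum suppression** on circle IoU (threshold 0.3) merges
   duplicate proposals across scales.

## Stage 2: weakly supervised counting network (`wscnet`)

**Architecture** (exactly seven 3 × 3 convolutions, 5 127 parameters,
input 32 × 32 grey patch in [0, 1], NHWC):

- trunk: conv 1→8, 8→12, 12→12, 12→12, each followed by ReLU;
- counting head: conv 12→8, 8→8, 8→1, ReLU after each including the last,
  producing a non-negative density map D at input resolution;
- classification head: global average pool of the 12 trunk channels →
  per-feature standardization → linear 12→2 (droplet vs. clutter logits).

**Loss.** With D_sum = ΣD and D_max = max D, the truncated count is

    f(D) = D_sum                 if D_sum < 2
         = 2 + γ·D_sum           otherwise,       γ = 0.001

so labels y ∈ {0, 1, 2} (2 ≡ "at least two") can supervise unbounded
counts: beyond 2 the slope γ is small enough that any D_sum ≥ 2 is nearly
equally compatible with y = 2. The regularizer ψ = max(D_max − 1, 0)
discourages any single pixel from holding more than one cell's worth of
density, which forces multi-cell mass to spread into separate modes — this
is what makes localization and counts above 2 emerge without labels for
them. Per-patch counting loss: L_count = (f(D) − y)² + ψ, applied to
droplet patches only. Classification uses softmax cross-entropy L_class on
droplet-vs-clutter. Total: L = L_class + ω·L_count with ω = 1.

**Inference.** A proposal's patch is scored; if classified as droplet, its
category is argmin_k (D_sum − k)² over k ∈ {0, 1, 2} (ties toward the
smaller k), the integer count is ⌊D_sum + 0.5⌋, and cell locations are the
top-k density maxima under a 3-px minimum separation, mapped back to frame
coordinates through the crop transform.

### Numerical and optimization choices

The network is implemented directly on NumPy (float32, NHWC) with manual
backprop: convolution as nine shifted matrix products against views of the
padded input (benchmarked faster than im2col at these channel counts on
one CPU), in-place ReLU, Adam. All layers are dtype-agnostic so the
gradient check runs in float64 against central finite differences.

Three choices depart from a naive joint-training reading and are
optimization necessities, verified empirically:

1. **Small initialization of the final head convolution** (weights × 0.05,
   bias 10⁻³) so the initial D_sum is ≈ 1 rather than in the hundreds.
   Otherwise every patch starts deep in the truncated branch where the
   gradient slope is γ = 0.001 and counting never trains.
2. **Feature standardization before the linear readout.** Pooled trunk
   features have large offsets and tiny variance; a plain linear readout is
   so ill-conditioned that first-order methods stall at the class prior.
   A per-feature standardization (batch statistics during training, running
   averages at inference, no learned affine) fixes the conditioning.
3. **Two-phase training with a detached classification gradient.** The
   classification gradient stops at the pooling, so the trunk is shaped by
   the counting objective alone; after the counting phase (early stopping
   on validation loss, patience 3, learning-rate halving) the
   standardization statistics and linear readout are fit on the frozen
   pooled features. Jointly propagating both losses into the 12-channel
   trunk let the standardization-amplified classification gradient collapse
   the density output to a constant. The architecture and loss definitions
   are unchanged; only the schedule differs.

Defaults: γ = 0.001, ω = 1, Adam lr 10⁻⁴, batch 1024, ≤ 30 epochs. The
desk-scale benchmark preset uses 12 000 patches, batch 256, lr 10⁻³ and
20 epochs so it trains in minutes on one CPU; 32 × 32 patches (droplets are
14–40 px across, so a 2.4 r crop loses nothing at 32 px and costs ~4× less
than 64 px).

## Poisson encapsulation statistics (`poisson`)

Cell-per-droplet counts follow ρ_k = λᵏ e^{−λ}/k!. The module provides the
pmf; the empty/single/multicell rates and the conditional single-cell rate
ρ₁/(1 − ρ₀); the estimator λ̂ = −ln(1 − M/N) from N droplets of which M
contain ≥ 1 cell; and the physical operating point λ = c·(4/3)πR³ for cell
concentration c and droplet radius R (with explicit unit conversion,
cells/mL and µm). Useful identities: the single-cell fraction is maximized
at λ = 1 where it equals 1/e ≈ 36.78 % with a ≥ 2-cell ("covalence")
probability of 26.42 %; at λ ≈ 0.26 single-cell loading exceeds 20 % while
multicell stays under 3 %.

## Evaluation (`metrics`, `benchmark`)

- **Circle IoU** is computed analytically (lens areas), detections matched
  one-to-one to truth greedily by descending IoU above a threshold θ.
- **Detection:** precision/recall/F1 at θ = 0.5 and recall at the stricter
  θ = 0.8, pooled over frames.
- **Recognition:** category-aware F1 — a matched droplet with the wrong
  category counts as a false positive for the predicted category *and* a
  false negative for the true one; headline score is the mean F1 over
  empty/single/multiple.
- **Localization:** predicted density maxima matched greedily to true cell
  centroids within a valid-area radius (10 px in frame coordinates,
  converted through the patch crop scale); precision/recall on held-out
  multicell patches.
- **Counting:** mean relative error, excluding (and reporting) zero-truth
  droplets.
- **Poisson fit:** RSS against the model curves and a χ² goodness-of-fit
  with right-tail pooling to a minimum expected count of 5.

The seeded desk-scale benchmark (`dropcell.benchmark`) renders 640 × 480
frames of ~150 adherent droplets (diameter 22 px, CV 8 %, overlap 0.15) and
drives the full pipeline; it is what the acceptance script and the
acceptance tests run.

## Limitations

- Scores are on synthetic frames; the generator's realism bounds what they
  say about any real microscope (see above for what is not emulated).
- The detector assumes dark droplets on a brighter background with a
  roughly bimodal histogram; frames failing the separation check return no
  proposals rather than guessing.
- Counting is supervised only up to "at least two"; integer counts above ~4
  in one droplet get increasingly approximate as modes merge.
- Training is single-threaded NumPy: desk scale takes minutes, but the
  full-scale defaults (batch 1024, 30 epochs, large patch sets) take
  correspondingly longer.
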
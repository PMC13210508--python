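# Methods

This note records the modelling assumptions, parameter choices and
numerical conventions behind `persal`, and what the synthetic-data tests
do and do not establish about real recordings.

## Saliency-map construction

A gaze sample is one tracker reading; every sample counts once (no
duration weighting, no saccade/fixation segmentation).  Binocular readings
are merged per field by the arithmetic mean of the available eyes — the
rule is symmetric, and with one eye missing the other passes through.
Missing values are explicit (`NaN`/`None`), never sentinel zeros, because
(0, 0) is a valid top-left coordinate.  Samples with neither eye valid are
dropped and counted; a log that loses every sample is retained but flagged
so callers can exclude the subject, mirroring the usual completeness
screens in eye-tracking studies.

Counts are convolved with a truncated 2-D Gaussian, kernel 168 px and
σ = 24 px at full 1920×1080 capture — the SALICON convention, motivated by
a ≈24 px foveal radius at that viewing geometry.  An even kernel has no
centre pixel and shifts the map by half a pixel, so an even requested size
is rounded up to the next odd size (168 → 169); the half tail beyond
±3.5 σ that the truncation removes biases the moment-recovered width by
≈ −0.07 px, well inside the ±0.5 px tolerance we quote.  Boundary handling
is zero padding: gaze cannot land off-screen, so there is nothing to
reflect or wrap.  Maps are divided by their maximum (peak = 1; an all-zero
grid stays zero); sum-normalization is available for distribution-style
metrics.  When maps are built directly at reduced resolution, σ and kernel
scale with the same factor (σ = 6 at 1/4), keeping the physical smoothing
constant; smoothing-then-resizing and building-at-scale are both
supported, with smooth-then-resize the default order.

## Interest from pupil dilation

Raw diameters (mm) are z-scored with the population SD over all of a
subject's samples pooled across images, so a dilation on one image stands
out against the subject's whole session.  Per-day pooling is a config
switch, not auto-detected: the two-centre histogram/QQ shape that
motivates it is a diagnostic a human should confirm
(`interest.save_pupil_diagnostics` draws it).

The anomaly test is two-sided: z² ≥ χ²₁(1 − α), i.e. |z| ≥ 1.645 at
α = 0.10, |z| ≥ 2.576 at α = 0.01.  The Mahalanobis distance of a scalar
is |z|, so no covariance machinery is involved.  Only the dilation side
labels interest.

Aggregation over the ~300 samples of a presentation is the one genuinely
open design point.  A single-sample exceedance criterion cannot work: under
the null the chance that at least one of 300 samples crosses the 10%-level
threshold is 1 − 0.95³⁰⁰ ≈ 1, so every image would be labelled interesting.
The default is therefore *sustained* dilation — at least 10% of samples
above threshold — which has a per-image null false-positive rate near zero
(the null exceedance fraction is ≈ 0.05 with binomial SD ≈ 0.013) while a
2.5 SD dilation over 40% of the presentation pushes the fraction to ≈ 0.3.
`any` and `mean` aggregations remain available; `mean` is insensitive to
window-limited dilations and `any` is vacuous at this sampling rate, and
the windowed synthetic generator keeps the three distinguishable in tests.

## Model

The encoder is the 13-conv/4-pool VGG16 stack (3×3, pad 1, ReLU); the
decoder mirrors it with nearest-neighbour 2× upsampling and ends in a
1-channel 1×1 convolution with ReLU, so predicted maps are non-negative
and MSE against [0, 1] targets is interpretable.  There is no adversarial
component.  `channel_scale` multiplies every layer depth, so a 1/8-width
instance (C = 64) runs the identical graph as the full C = 512 model.

The user-encoding mechanism maps I_n (length M) through a Linear layer to
a 1×C token, then `enc_layers` pre-norm Transformer encoder blocks
(self-attention over the single token is the identity up to the value
path; with zero blocks the post-Linear and post-encoder probes coincide).
Fusion uses `dec_layers` pre-norm Transformer decoder blocks: optional
self-attention among the (W·H) image tokens, cross-attention with the user
token as the sole key/value, and a 4×C feed-forward.  With one key the
softmax is constant 1 whether logits are scaled by √d_k (default) or d_k
(config `logit_scale`), so the choice is observationally irrelevant here;
we keep the standard √d_k.  No positional embeddings by default — position
is carried by the residual stream — with learned embeddings behind a flag.

Initialization: He-scaled normals for convolutions with a small positive
bias (0.01), truncated normals (SD 0.02) for Transformer weights.  Two
numerical choices matter at narrow widths and are deliberate: the positive
conv bias and a near-flat output head (weights ×0.1, bias 0.1).  Without
them the all-ReLU stack can start, or collapse into, a dead state in which
the output is exactly constant and no gradient flows; with them every
output unit is alive at step 0 and the head first learns the base rate.
Max-pool backward routes gradient to the first maximum on ties.

## Training

Stage defaults are the full-scale settings: universal — Adam, lr 1e-5,
batch 32; personalized — AdamW, lr 1e-6, decoupled weight decay 0.05,
batch 1, each sample visited 8× per epoch (with 8 subjects × 1000 images
this equals each image appearing once per subject).  Validation runs once
per epoch; early stopping fires after `patience` = 5 consecutive
non-improving evaluations, and the checkpoint holds the best-validation
weights, so a run lasts at most (argmin epoch + patience) epochs.
The train/validation split stratifies positives and negatives inside every
subject, equalizing each subject's count of 1-labelled training images up
to rounding; 8000 pairs at 0.8 give 6400/1600.  Training is bit-for-bit
reproducible under a fixed seed in single-threaded execution.

Desk-scale profile: the package's own tiny runs (tests, CLI defaults) use
128×128 stimuli at 1/4 scale (32×32 model I/O), `channel_scale` 1/8,
1 encoder / 1 decoder block, 4 heads, lr 1e-3 (universal) / 3e-4
(personalized), batch 2 / 1, replication 1.  The width is the smallest at
which the universal stage reliably learns image-dependent structure
(validation MSE ≈ 0.02 against ≈ 0.07 for the best constant map); at 1/16
width the ReLU stack collapses to the constant solution.  The learning
rates compensate for the few optimization steps a 12-image corpus
provides; the full-scale values remain the defaults of `TrainConfig`.

Transfer initialization copies encoder and decoder weights from a trained
universal model; the user-encoding mechanism keeps its fresh weights and
nothing is frozen.  Immediately after transfer the bypass diagnostic
(`enc_output_tap`, decoder applied directly to encoder output) is
bit-identical to the universal model's prediction.  The transfer test
measures epochs-to-target where the target (0.06) sits between the
constant-output plateau (≈ 0.11) and the converged level (≈ 0.05), and
counts the initial validation evaluation as epoch 0: a transferred model
already below target needs zero personalized epochs, which is precisely
the initialization advantage being claimed.

## Metrics

NSS standardizes the map to mean 0, population SD 1 and averages at
fixated cells; a constant map scores 0 by convention, and NSS is invariant
to positive affine rescaling of the map.  CC is the Pearson correlation
over cells (undefined, reported NaN, for a constant map).  The AUC
variants follow the MIT/Tuebingen benchmark definitions: positives are map
values at fixations; AUC-Borji negatives are uniform-random cells;
shuffled-AUC negatives are fixation locations pooled from other images, so
a purely centre-biased map scores ≈ 0.5.  Each split's AUC is the
Mann-Whitney statistic with ties counted ½ (computed via average ranks,
identical to exhaustive pairwise counting); 100 splits and
n_neg = n_fixations per split by default, all seeded.  Fixation sets are
raw deduplicated in-bounds gaze cells, not smoothed maps.

## Synthetic worlds

The generator's defaults are the study conditions: 8 subjects, 1000
images, 300 samples over 5 s, 1920×1080 frames.  Gaze is a mixture of a
central Gaussian (σ = min(W, H)/5, weight 1.5) and per-object Gaussians
(σ = 0.35 × object radius) weighted by base salience (U[0.5, 1.5]) plus
the subject's interest in the object's category; objects (2–4 per image)
are placed with a centre-concentrated prior, giving the central bias on
both the composition and the gaze side.  Each subject strongly prefers 1–2
of 8 categories (weight 2.5 vs 0.1 background); a subject is *planted
interested* in an image when their maximum category weight there exceeds
1.0.  Pupils are N(baseline, 0.2 mm) with per-subject baselines in
[3.0, 4.0] mm; planted interest adds a 2.5 SD dilation over a contiguous
40% window at a random position.  The 2.5 SD effect size is a
detectability choice at α = 0.10, not a claim about human physiology.
Binocular pairs are the sampled point plus independent 2 px jitter per
eye.  Stimuli are procedural (category-coloured geometric objects on a
low-frequency textured background): the models consume only pixel arrays,
and procedural objects give exact ground-truth layouts for free.

What the synthetic corpus does *not* emulate: saccade dynamics, blinks and
tracking dropouts, microsaccades, pupil light reflexes or slow drifts
within a day, photorealistic image statistics, and any correlation between
image content and pupil response beyond the planted interest signal.
Passing tests therefore establish that the pipeline recovers the structure
it assumes when that structure is present — calibration, recovery,
monotonicity, transfer — not that real recordings satisfy those
assumptions.

## Known limitations

- Training at full width (C = 512) on real SALICON-scale data is out of
  reach of the numpy engine; the architecture is faithful but the package
  is designed for desk-scale instances and method-level analysis.
- The sustained-dilation fraction (0.10) is a fixed default; a principled
  per-subject calibration (e.g. controlling the per-image false-positive
  rate) is future work.
- Screen-to-image coordinate mapping supports only a linear rescale; no
  homographies or calibration-drift correction.
- The shuffled-AUC negative pool is "all other images in the evaluation
  set"; pool size and composition are configurable but no attempt is made
  to match fixation counts per image.
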
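# persal — personalized saliency maps from gaze and pupillometry

`persal` predicts *where a particular person will look* in an image, given
only the image and a compact representation of that person's interests
derived from their pupil dilations.  It is aimed at researchers in visual
attention, psychophysiology and human-computer interaction who work with
eye-tracker recordings (gaze coordinates + pupil diameters) and want to go
beyond population-level ("universal") saliency models.

## What it computes

**Saliency maps.**  Gaze samples for one subject viewing one image are
binned into a fixation-count grid and convolved with a truncated 2-D
Gaussian (default kernel 168 px, σ = 24 px at full 1920×1080 capture),
then divided by the peak so values lie in [0, 1].  One subject's counts
give a *personalized* saliency map (PSM); pooling all subjects' counts
gives a *universal* saliency map (USM).

**Interest vectors from pupillometry.**  Pupil diameter dilates with
interest, but its baseline is idiosyncratic, so diameters are z-scored per
subject (optionally per recording day, which removes between-day baseline
drift).  A sample is anomalous when its squared Mahalanobis distance — for
a scalar, z² — exceeds the χ²(1) quantile at 1 − α (α = 0.10 by default;
a_sq ≈ 2.7055).  An image is labelled *interesting* (entry 1) when the
dilation is sustained: at least 10% of the ~300 samples of its 5-second
presentation cross the upper threshold.  Constriction never labels
interest.  Over M images this yields the binary user characteristic vector
I_n ∈ {0,1}^(1×M) for subject n.

**The model.**  A VGG16-style convolutional encoder (13 conv layers,
4 max-poolings → feature grid = input/16, C channels) and a mirrored
decoder (4 upsamplings, final 1-channel ReLU) are trained with MSE to
predict the USM.  The personalized model adds a *user-encoding mechanism*:
I_n is mapped by a Linear layer to a single 1×C token
(T_enc_in = I_n W_encᵀ), refined by a stack of Transformer encoder blocks,
and supplied as key/value context to Transformer decoder blocks whose
queries are the (W·H)×C image-feature tokens:

    Attention(Q, K, V) = softmax(QKᵀ / √d_k) V,   d_k = C / heads

Because there is exactly one key, each softmax weight is identically 1 and
the attention output broadcasts the projected user value to every image
token; personalization enters purely through this broadcast and the
residual stream.  Personalized training starts from the trained universal
model's encoder/decoder weights (transfer initialization) and uses AdamW
with batch size 1; early stopping halts after 5 non-improving validation
epochs.  The full-scale optimum is 4 encoder blocks, 9 decoder blocks and
256 heads at C = 512.

The neural stack runs on a compact numpy reverse-mode autodiff engine
(`persal.autodiff`, `persal.nn`) written for exactly this architecture; a
`channel_scale` knob runs the identical graph at desk scale (e.g. C = 64).

**Evaluation.**  NSS, CC, AUC-Borji and shuffled AUC (negatives drawn from
other images' fixations, which cancels the central bias) in
`persal.metrics`, each validated against brute-force oracles.

**Synthetic data.**  No human recordings ship with the package.
`persal.synth` generates worlds with the statistical structure the method
assumes: centre-biased gaze mixtures over procedurally placed objects,
per-subject category preferences, 300 binocular samples per 5-second
presentation, Gaussian pupil baselines with interest-driven dilation
(default 2.5 SD over a 40% sub-window) and optional per-day baseline
shifts — 8 subjects × 1000 images by default, with planted ground truth
for every quantity the pipeline estimates.

## Worked example

```bash
persal simulate --out corpus --subjects 4 --images 12 \
    --width 256 --height 256 --map-scale 0.25 --seed 7
persal train-usm --out usm.npz --subjects 4 --images 12 --image-size 128 --seed 7
persal train-psm --out psm.npz --usm-init usm.npz \
    --subjects 4 --images 12 --image-size 128 --max-epochs 6 --seed 7
persal eval --maps corpus/maps --gaze corpus/gaze.csv --out metrics.csv --scale 0.25
```

prints

```
wrote corpus: 4 subjects x 12 images -> corpus
best val loss 0.04370 after 10 epochs
best val loss 0.03540 after 6 epochs
                sAUC     AUC-B       NSS
subject_id
subj0       0.683325  0.851362  1.845354
subj1       0.723556  0.863129  1.938434
subj2       0.694830  0.858256  1.918878
subj3       0.699905  0.856891  1.948580
mean        0.700404  0.857410  1.912812
```

The two training lines are the universal stage and the personalized stage
started from it (`--usm-init`); the personalized model reaches a lower
validation MSE than the universal baseline it inherits.  The table scores
each subject's measured PSM against that subject's own fixations: AUC-B
(uniform-random negatives) is high because the maps are built from those
very fixations, while sAUC is distinctly lower because its negatives come
from *other images'* fixations, discounting the credit a map earns from
the shared central bias.  NSS ≈ 1.9 means fixated cells sit about 1.9 map
standard deviations above the map mean.

The same pipeline is available as library calls (`persal.synth.build_corpus`,
`persal.train.train_stage`, `persal.metrics`); `persal describe` prints the
encoder/decoder layer tables.

## Layout

| module | contents |
| --- | --- |
| `persal.gaze_io` | gaze-log CSV I/O, binocular merging |
| `persal.saliency` | count grids, Gaussian smoothing, USM aggregation, resizing |
| `persal.interest` | standardization, χ² anomaly test, interest vectors, similarity |
| `persal.autodiff` / `persal.nn` | numpy reverse-mode autodiff and NN blocks |
| `persal.model` | universal + personalized saliency models, checkpoints |
| `persal.train` | training loops, early stopping, splits, transfer init |
| `persal.metrics` | NSS, CC, AUC-Borji, shuffled AUC, map cosine |
| `persal.synth` | synthetic worlds, gaze/pupil simulators, corpus builder |
| `persal.cli` | `persal simulate / train-usm / train-psm / eval / describe` |

See `docs/methods.md` for the modelling assumptions, parameter defaults and
known limitations.
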
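# Methods

## Overview

`snpdraw` chains three models: an image-compressing convolutional
autoencoder, a SNP-to-embedding regressor, and the composition of the
regressor with the frozen decoder, which turns a genotype's SNP dosages
into a drawn fruit image. Everything downstream of the images is
agnostic to where they came from; the bundled simulator exists so the
full chain can be trained and validated without restricted field data.

## Fruit renderer and simulated genetics

A fruit silhouette is a superellipse (exponent 2.5) whose per-row
half-width profile is multiplied by a linear vertical taper and an
optional sinusoidal lobing term:

- the **fruit shape index** (FSI = height/width) is set exactly by the
  pixel dimensions of the silhouette (the larger dimension occupies 70%
  of the canvas by default);
- the **shoulder ratio** (SR) is realised by solving the taper
  coefficient c = (SR − 1) / (0.8 (SR + 1)), calibrated at the same 10%
  inset rows where the measurement is taken — the symmetric superellipse
  factor cancels there, so the round trip is analytic;
- lobing is a bounded (≤ 20%) sinusoidal modulation of the width
  profile; it perturbs the outline without changing the bounding-box
  metrics.

Rendering is a pure function of the shape parameters: identical
parameters give bit-identical images. Degenerate parameters (a
silhouette thinner than 15% of the canvas, or a taper that would pinch
the outline to zero width) raise instead of clipping silently.

The population simulator draws allele dosages under Hardy–Weinberg
equilibrium (allele frequencies uniform on 0.15–0.85 unless supplied).
The genotype-to-phenotype map is purely additive on allele counts:
FSI_g = baseline + Σ_j a_j (c_gj − 2p_j), centred at the Hardy–Weinberg
expectation so the baseline is the population mean; the additive
variance is the classical Σ 2 p (1−p) a², which a Monte-Carlo test
verifies. Dosages are stored on the 0/0.5/1 scale (AA/Aa/aa); effects
are per-allele. Each image adds independent Normal(0, env_sd)
environmental noise to its genotype's mean FSI (default env_sd = 0.04;
within-genotype shape variance of real orchards is not characterised, so
this knob is a simulator convention, not a biological claim). Default
effect sizes are rescaled so the additive genetic standard deviation of
FSI is ≈ 0.11, giving a genotype-mean heritability near 0.97 with four
images per genotype — a deliberately favourable signal for desk-scale
experiments. Per-image FSI is truncated to the renderer's working range
(0.62–1.55); with the default architecture truncation is rare.

By default genetics acts on FSI only and SR is constant; SR variation
can be enabled per genotype (`sr_sd`). This reflects that the
height/width ratio is the headline metric while conicity is harder to
carry through mean embeddings.

## Autoencoder

Encoder: stride-2 3×3 convolutions (ReLU), flatten, leaky-ReLU dense
layers, then a dense bottleneck with sigmoid activation, so every
embedding coordinate lies in [0, 1]. Decoder: the mirror image (dense
stack reversed, transposed convolutions with output paddings solved from
the recorded encoder size chain), final sigmoid. Two profiles:

| profile | input | convs (filters) | dense | embedding |
|---|---|---|---|---|
| full scale | 300 px | 6 (16,32,48,64,96,128) | 8192/4096/2048 | 64 |
| desk scale | 64–96 px | 4 (8,16,32,64) | 1024/512/256 | 64 |

Two numerical guards stabilise the bottleneck. A parameter-free
LayerNorm standardises the features entering the bottleneck layer, and a
parameter-free BatchNorm on the bottleneck pre-activation forces the
code to vary across each training batch. Without them, short training
runs on small datasets can collapse: the decoder wins the race to a
mean-image solution, the latent saturates at the sigmoid rails, and the
embedding becomes constant. BatchNorm inference statistics are
recalibrated with one exact full-training-set pass after training, since
exponential running averages lag badly over a few hundred steps.
Remaining initialisation choices: He for conv/ReLU stages, Xavier for
the sigmoid bottleneck, and the decoder's output bias starts at the
logit of the training set's per-channel mean intensity so the first
epochs are spent on image structure rather than on the background level.

Training: reconstruction loss selectable among `mse` (default for
self-contained runs), `ssim` (global, single-window SSIM with analytic
gradient), and `perceptual` (sum of L1 distances over feature maps of a
frozen extractor — no pretrained weights ship with the package, so an
extractor must be supplied; otherwise a clear error advises the
self-contained losses). Optimizers: SGD with momentum 0.9 (full-scale
default, learning rate 0.01, batch 32, 35 epochs) or Adam. The
**desk-scale recipe** used by the tests and the acceptance script is
Adam at 3e-3, batch 8, a cosine learning-rate decay to one tenth, and
vertical-stretch augmentation (random 0.85–1.15 rescale of half the
images per step). The higher rate and smaller batches compensate for the
small number of gradient steps (≈25 per epoch at 180 images); the cosine
tail quietens late-epoch noise so the training curve descends smoothly;
the augmentation widens the range of aspect ratios the representation
covers, which matters when a held-out genotype's shape falls outside the
small training set's range. Augmentation only affects autoencoder
fitting — prediction targets are always computed from unaugmented
images.

Per-genotype targets are the element-wise arithmetic means of the
genotype's image embeddings; decoding a mean embedding gives the
genotype's *decoded mean image*, the phenometric reference for
prediction quality. Validation targets always come from the frozen
encoder applied to held-out images; the compressor is never retrained.

## Embedding predictor and assembly

A two-layer network (n_SNPs → 300 sigmoid → 64 sigmoid) trained with
MAE loss and SGD (momentum 0.9). Full-scale defaults follow the
reference regime: learning rate 0.05, up to 1000 epochs,
reduce-on-plateau (factor 0.5, patience 10), early stopping on
validation MAE (patience 25, min-delta 1e-4) with best-weights restore.
The desk profile (`desk_predictor_spec`) raises the rate to 0.2, uses
batch 8, caps at 600 epochs and lengthens both patiences — with ~45
training genotypes an epoch is only six gradient steps, so the
full-scale schedule freezes the rate before anything is learned. Dense
layers use LeCun initialisation (std 1/√fan_in): sigmoid units need
order-one pre-activations even when the SNP input is only 10 wide, which
fan-in+fan-out scaling underestimates.

Assembly is pure composition — the predictor's 64-vector feeds the
decoder directly, dimensions are checked, and no weights change. Drawing
validates that the genotype row covers the panel with dosages in
{0, 0.5, 1} and is deterministic in inference mode.

## Shape metrics

Silhouettes are extracted by greyscale conversion, Otsu thresholding
(64-bin histogram, with a mid-range fallback when the split lands inside
a bimodal background, e.g. native canvas vs resize padding), largest
connected component, hole filling. FSI is the bounding-box height/width
ratio. The "width at the most top and bottom points" of a fruit is
geometrically degenerate (extreme rows have near-zero width), so SR is
measured at a configurable inset — default 10% of the height — from each
end; this inset is an interpretation of the conventional definition and
is recorded in reports. The five shape classes (flat, flat-globose,
globose, oval, oblong) come from left-closed FSI intervals at four
configurable cut points, default 0.85 / 0.95 / 1.05 / 1.20; published
class boundaries vary, so every report echoes the thresholds used.

## Evaluation

- **Embedding MAE**: mean |prediction − target| over genotypes × dims.
- **Null threshold**: for each of n (default 10,000) replicate datasets,
  draw one value per genotype from Normal(μ_g, σ_g) and record the MAE
  of the draws against the μ_g; report mean ± sd of the replicate MAEs.
  σ_g is the within-genotype standard deviation estimated from images.
  With equal σ = s the boundary mean converges to the half-normal mean
  s√(2/π), which calibrates the implementation. Note that in the
  simulator the within-genotype variance is small relative to the
  genetic variance, so this boundary is much stricter at desk scale than
  in field data.
- **Wasserstein distances** (first order, via the sorted-quantile
  formulation) compare predicted, decoded-mean, and original-image
  metric distributions.
- **Confusion analysis**: fixed 5-class order, accuracy = trace/total,
  macro F averaged over the classes present in the true labels (class
  imbalance is the motivating concern, so absent classes must not
  inflate the average).
- **Batteries**: repeated retrainings with fresh random panels; Welch's
  unequal-variance t test compares batteries (the group variances
  genuinely differ), with a paired variant when batteries share seeds.
- **Panel ladder**: augmented (targeted core + random fill) vs fully
  random panels across a size ladder, fresh panels and initialisations
  per model, medians and IQRs per cell.

## Desk-scale study conditions

Tests and the acceptance script run one fixed configuration: 50
genotypes × 4 images at 64 px (≈180 training images after the 90/10
genotype-level stratified split), 10 causal + 140 neutral SNPs,
autoencoder trained 30 epochs (a 15-epoch checkpoint is assessed
separately), predictor batteries of 10 paired models, dilution 10×
with 5 runs per arm. The genotype-level split is stratified by the
five-class shape category of each genotype's mean FSI; a stratum with a
single genotype goes to train with a logged warning. Shape-retention
rates are measured on a 96 px twin of the pipeline because at 64 px an
FSI difference of 0.05 corresponds to roughly two pixels of silhouette
extent and the per-image check would mostly measure quantization.

What passing these tests shows — and does not show. The simulator
produces clean, centred, single-fruit images with purely additive
genetics, no linkage disequilibrium, no genotype-environment
interaction, and generous heritability. Success here demonstrates that
the pipeline's plumbing, losses, statistics and comparisons behave as
specified, and that the targeted-vs-random contrast is recovered when a
genetic signal genuinely exists; it does not certify performance on
field images, real LD structure, or weakly heritable traits.

## Known limitations

- The perceptual reconstruction loss requires an externally supplied
  feature extractor; the packaged losses are MSE and global SSIM.
- Mean embeddings symmetrise asymmetric fruit, so SR signal survives
  averaging poorly; SR results are reported but FSI is the reliable
  metric.
- The NumPy networks are CPU-bound; the full-scale 300 px profile
  builds and runs forward/backward correctly but training it to
  convergence is only practical on the desk profiles.
- VCF input is restricted to biallelic sites with complete GT fields;
  missing calls must be imputed (per-SNP mean, rounded to the dosage
  grid) or cleaned upstream.
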
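# Methods

## Problem setting

The package differentiates benign from malignant findings in 2-D grayscale
regions of interest (ROIs): hypoechoic breast lesions in ultrasound (one
slice per case) and lung nodules in CT (an ordered stack of axial slices
with anisotropic resolution — in-plane spacing well below the slice
thickness, which in clinical scans spans roughly 0.6–5 mm). A binary lesion
mask accompanies every slice; masks are treated as given outlines, and no
segmentation is performed anywhere in the package.

## The SDAE classifier

### Patch preparation

Each ROI is the mask's bounding box expanded by a 15 % margin, bilinearly
resized to 28×28 and min-max normalised to [0,1] per patch (a constant
patch maps to zeros). Resizing destroys absolute size and shape, which are
diagnostically meaningful, so three auxiliary scalars are carried along:
scale_x = width/28, scale_y = height/28, and the width/height aspect ratio.
They are z-scored with training-fold statistics before entering the network
(raw values of 1–20 would dominate sigmoid pre-activations). Aspect ratio
is defined width/height; interpolation is bilinear — both are deliberate
fixed conventions, since rank-order results do not hinge on them.

### Denoising autoencoder layer

Corruption is masking noise: exactly ⌊ν·d⌋ distinct coordinates, drawn
uniformly without replacement, are set to zero. The exact count (rather
than i.i.d. Bernoulli masking) makes the corruption fraction deterministic
and the layer easier to test; masking-to-zero is the canonical choice for
this architecture. Encoder and decoder are sigmoid layers with tied
weights (the decoder uses Wᵀ), and the objective is the mean elementwise
cross-entropy between the clean input and the reconstruction, with the
reconstruction clipped to [1e−7, 1−1e−7] so the loss is always finite.
Gradients are analytic; inside the clipped saturation region the analytic
formula follows the unclipped objective (the clip exists only to guard the
logarithm). Weights initialise uniform in ±4√(6/(d_in+d_hidden)), biases
at zero; training is plain mini-batch SGD (defaults: learning rate 0.1,
batch 20, 15 epochs, ν = 0.3) driven by one explicit seeded generator —
there is no global random state anywhere in the package.

### Stacking and supervised fine-tuning

Layer 1 (784→200) trains on patch vectors; layer 2 (200→100) trains on the
*clean* layer-1 codes, applying its own corruption internally — an open
design point resolved in favour of the cleaner, more common convention.
The supervised network is patch (784) + auxiliary (3) → 200 → 100 →
softmax-2. The auxiliary inputs reach hidden layer 1 through a weight
block initialised to zero, and the softmax head starts from small seeded
uniform noise, so at the first fine-tuning step the hidden representation
is exactly the pretrained one. Fine-tuning is full backpropagation
(defaults: learning rate 0.05, batch 20, 100 epochs, no weight decay).
Class index 0 is benign, 1 is malignant; a tie at p = 0.5 resolves to
benign, trading sensitivity for specificity at the decision boundary —
an arbitrary but documented convention.

Hidden-unit patterns are reconstructed for inspection: layer-1 patterns
are the encoder weight rows reshaped to 28×28; a layer-2 pattern is the
weighted sum of all layer-1 patterns with that unit's weights, taking every
first-layer neuron as active; all patterns are min-max normalised.

## Slice strategies and voting

SINGLE represents a nodule by its middle slice, index ⌊(n−1)/2⌋ (lower
middle for even n). ALL trains on every member slice of the training
nodules in a seeded random permutation and classifies a test nodule by
majority vote: malignant iff strictly more than half the slice calls are
malignant, so an exact half is benign. Voting uses hard labels; for
case-level AUC under ALL the mean slice malignancy score serves as the
case score, since a count-based vote yields no ranking.

## Texture baselines

**GLCM.** Images are uniformly quantised to 16 gray levels; co-occurrence
matrices at distance 1 and angles {0°, 45°, 90°, 135°} are symmetrised and
normalised. Fourteen Haralick statistics are computed (energy, contrast,
correlation, variance, inverse difference moment, sum average/variance/
entropy, entropy, difference variance/entropy, the two information measures
of correlation, and the maximal correlation coefficient), with natural
logarithms and explicit conventions for degenerate marginals (zero marginal
variance → correlation 0; empty entropies → information measures 0). The
12-feature subset used by the RANK stack drops the information measure 2
and the maximal correlation coefficient, the two numerically most fragile
statistics.

**Ranklet.** At every position of an even-sided window the pixels are
mid-ranked; for each Haar-like orientation (vertical, horizontal, diagonal
quadrant split) the response is 2U/(n_T n_C) − 1, where U is the
Mann-Whitney count of treatment-greater-than-control pairs with ties
counting one half. Responses lie in [−1,1] and are exactly invariant to
any strictly increasing intensity transform, which is what makes the stack
robust to speckle. Ranklets are computed on the pre-resize ROI (rank
statistics depend on resolution); windows default to sides 4 and 8, with
windows larger than the ROI skipped.

**Sub-band decomposition.** The CURVE stack runs on a pluggable
decomposition; the default is a 2-level separable db2 wavelet with
periodization (7 bands on a 28×28 patch, perfect reconstruction to 1e−8).
A callable plugin can substitute any other band decomposition. The number
of scales and orientations is configurable; the defaults are a deliberate,
compact choice.

**Selection and classification.** RANK features pass through bootstrap
selection: in each of B = 30 resamples features are ranked by
single-feature AUC (max of AUC and 1−AUC) and the top k = 8 recorded;
features present in ≥ τ·B of the top-k sets (τ = 0.5, at least one) are
kept, ordered by frequency. All baselines share one SVM stage (RBF kernel,
C = 1, gamma = "scale", training-fold standardisation, constant columns
dropped with a warning) so that method comparisons differ only in their
feature stacks. MORPH is inherently case-level — the lung features pool
over all member slices — so it ignores the SINGLE/ALL switch.

## Morphology

The mask's moment-matched ellipse uses the population covariance of
foreground pixel-centre coordinates; axis length = 4√(eigenvalue), the
same convention as `skimage.measure.regionprops`. Area is the pixel count
times the pixel area; lung volume is Σ slice area × thickness — an
approximation whose error grows with slice thickness. The lung "maximum
major diameter" is the maximum of the per-slice ellipse major axes, a
slice-wise reading chosen because fully 3-D measurements are unreliable at
coarse, variable slice thickness.

## Evaluation protocol

Folds are drawn at case level (never slice level — every member slice of a
case stays on one side of every split, and the harness asserts this at run
time). Ten repetitions of stratified 10-fold partitions are drawn with
rejection to guarantee pairwise-distinct partitions; stratification keeps
class balance stable at the small case counts used here. The same fold
plan is reused by every method. Six metrics are computed per fold; ratios
with empty denominators are reported as missing and excluded from that
metric's mean, never imputed as zero. AUC is the tie-corrected rank
statistic (Mann-Whitney U/(n₁n₂)). Bland-Altman limits are mean ± 1.96 ×
sample sd (ddof = 1) of the paired per-fold differences; method contrasts
use the two-sided pooled-variance two-sample t-test, with p = 1 by
convention when both samples are identical constants.

## Synthetic data

The generator emulates the statistical structure the classifiers rely on,
not the imaging physics.

*Ultrasound* (64 px, 0.15 mm/px): a star-convex lesion r(θ) = r₀(1 + a Σₖ
cₖ cos(kθ+φₖ)), harmonics k = 2–7, radius r₀ uniform in 0.18–0.32 of the
image side, hypoechoic interior (0.32 vs 0.65 background envelope) with a
smoothed intra-lesion texture field, multiplicative unit-mean Rayleigh
speckle (strength 0.6), logarithmic compression to 8 bits, and posterior
shadowing below the lesion with probability 0.3. The class signal is the
boundary-irregularity amplitude a (benign 0.08, malignant 0.30 — a
spiculation proxy) and the texture contrast (0.05 vs 0.15).

*CT* (48 px, 0.7 mm/px, 1.5 mm slices, 3–9 slices per case): a lobulated
ellipsoid with in-plane radius uniform in 2.5–6 mm (benign) or 4–9 mm
(malignant, reflecting the size–malignancy association), irregularity 0.05
vs 0.25, z-semi-axis sized so every sampled slice cuts the nodule, slices
placed so the middle slice sits at the equator and carries the maximal
cross-section. Masks are the exact analytic boundary cross-sections —
the stand-in for expert manual outlines.

These choices were fixed once as plausible effect sizes for the two
modalities. What passing tests show is that the pipelines recover a known,
constructed class signal end to end with correct bookkeeping; they do not
show clinical-grade performance, because the phantoms lack real acoustic
artefacts, anatomy, scanner variation and the overlap of real benign and
malignant appearance distributions.

## Problem sizes and numerical choices

The bundled studies run at desk scale, chosen so the complete suite and the
reproduction script each finish in minutes on one CPU: the ultrasound
holdout study uses 400 training and 100 test cases per class per seed, ten
seeds; the CT comparison uses 25 cases per class through the full 10×10
fold protocol with the two fast baselines. Reconstruction clipping at
1e−7, the SMO tolerance of the SVM stage (1e−3, which makes decision
scores reproducible only to about that order under sample reordering), and
the exact-count corruption are the main numerical conventions. Degenerate
inputs are rejected loudly (empty masks, one-pixel ROIs, single-class
training sets, odd ranklet windows) rather than silently repaired.

## Known limitations

The phantom generator is statistical, not physical; absolute metric values
on it do not transfer to clinical data. The SDAE is plain SGD without
momentum, dropout or weight decay, and the architecture is fixed at two
hidden layers (200, 100) unless configured otherwise. The curvelet-family
transform proper is not implemented; the decomposition slot is pluggable.
Running the SDAE inside the full 100-fold protocol is supported but slow at
default epochs; the bundled CT comparison therefore uses the baseline
methods, and the SDAE is evaluated in the seeded holdout study.
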
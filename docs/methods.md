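# Methods

`vctdbt` is a virtual-clinical-trial (VCT) toolchain for digital breast
tomosynthesis (DBT): it simulates a population of compressed-breast
phantoms, images them under three scanning geometries, reconstructs by
unfiltered simple backprojection, trains a multi-task 3D U-Net to segment
adipose/dense tissue and the 3D breast outline, and scores the results
slice-wise as a function of distance to the central reconstruction plane.
This note documents the models, the defaults, and the design choices.

## Phantom model

A phantom is a three-class voxel volume (0 = air, 1 = adipose, 2 = dense)
on an isotropic grid. Axes: `x` left–right (tube travel), `y`
posteroanterior with the chest wall at `y = 0`, `z` vertical with the
breast support at `z = 0` and the compression paddle at `z = CBT`.

**Outline.** The compressed breast is modelled parametrically: every
z-slice footprint is a half-ellipse attached to the chest wall, with flat
contact bands against paddle and support and a curved free surface (the
"convex hull") in between. The semi-axes grow from their contact-band
values by `bulge_mm * g(z)`, where `g` is a superelliptic profile that is
0 in the contact bands and 1 at mid-thickness:

    g(z) = (1 - |z - z_mid|^k / h^k)^(1/k),   h = half free thickness.

Defaults: `contact_fraction = 0.4` (40% of the thickness in flat contact,
split evenly), `curvature_exponent k = 4`, `bulge ~ 8-14% of CBT`. The
blunt profile (high `k`, generous curved band) matches the appearance of
compressed-breast outlines: nearly vertical at mid-thickness with rounded
corners near paddle and support. A pointier profile (k ~ 2) makes the
mid-thickness rim so thin that unfiltered backprojection under-values it,
moving the outline segmentation error from the extreme slices to the
central ones; the blunt profile is both more realistic and necessary for
the extreme-slice artifact pattern to dominate, so it is a load-bearing
choice.

**Population.** Compressed breast thickness (CBT) and volumetric breast
density (%VBD) are clinically summarised by median and interquartile
values (CBT 60.50 (51.50, 69.50) mm; %VBD 12.75 (8.40, 20.00)). Both are
sampled from log-normal distributions calibrated to the median and the
IQR ratio — log-normals because both quantities are positive and
right-skewed — and CBT is capped at 85 mm, the upper limit of compression
models for these outlines. Because of the cap, the simulated CBT
distribution is slightly below the clinical one, which is the expected
behaviour, not an error. Secondary outline parameters scale with CBT with
mild jitter (chest–nipple distance ~ 1.6–1.9 CBT, width ~ 2.0–2.4 CBT).

**Internal composition.** Dense tissue is placed by a seeded octree block
fill: the tissue bounding box is subdivided into octants; whole blocks
between `min_block_mm` and `8 * min_block_mm` across are switched to
dense, in random order, until the dense fraction is within ±0.5
percentage points of the target %VBD (blocks that would overshoot are
subdivided further). This deliberately reproduces only the coarse,
blocky structure of an octree density model; Cooper's ligaments, skin,
lesions, and parenchymal texture are out of scope, mirroring the
simplified three-class ground truth of the study design.

## Acquisition geometries

Three source trajectories above the breast, with a flat detector 25 mm
below the support (width-to-height pixel-count ratio 0.79):

* **conventional (I)** — 15 sources on a left–right line spanning ±7.5°;
* **T (II)** — 8 LR sources plus 7 posteroanterior (PA) sources (15
  total); the PA stem extends from the centre of the LR bar over the
  breast toward the nipple (the tube cannot travel behind the patient),
  spanning the same total angular range. PA motion is the scanning
  freedom unique to next-generation tomosynthesis prototypes;
* **XWR (III)** — 91 sources on a 738 mm arc pivoting at the breast
  support, spanning ±45°, at 6× total exposure.

The source height for the linear scans (620 mm) is a typical DBT
magnification geometry; the angular range is interpreted as the angle
subtended at the detector-centre pivot, so the linear travel is
`±sid·tan(7.5°)`. Sources sit above the chest wall (`y = 0`), as in
clinical craniocaudal positioning — centering them over the detector
instead would push chest-wall tissue off the detector's front edge.
The T legs are ordered LR first, then PA; the legs share no duplicate
central projection (7 + 8 = 15).

## Projection and reconstruction

Projections are monoenergetic line integrals at a 20 keV effective
energy, computed by incremental Siddon traversal (exact for
piecewise-constant volumes), one ray per detector pixel centre. Linear
attenuation defaults are ICRU-44-based breast tissue values at 20 keV:
adipose 0.0456 /mm, fibroglandular 0.0802 /mm, air 0. Optional Poisson
noise converts line integrals to transmitted counts at a configurable
fluence; the headline analyses are noiseless since they are driven by
geometry, not quantum noise.

Reconstruction is **unfiltered simple backprojection**: each voxel takes
the mean, over sources, of the bilinearly interpolated detector value at
the source–voxel ray's intersection with the detector plane, normalised
by the number of sources whose detector contains the intersection
(voxels seen by no source are zero and flagged in a coverage mask). No
filtering is applied on purpose: the limited-angle artifacts — the
out-of-plane smear quantified by `zpsf_width` (z-profile FWHM of a point
reconstruction) and the false boundaries in the convex-hull region — are
the object of study, and filtering would mask them.

## Losses

The Tversky index of class c weights false negatives and false positives
asymmetrically (α = 0.7, β = 0.3):

    TI_c = (Σ p_ic g_ic + ε) / (Σ p_ic g_ic + α Σ (1-p_ic) g_ic + β Σ p_ic (1-g_ic) + ε)

and the focal Tversky loss is `FTL = Σ_c (1 − TI_c)^γ` with γ = 3/4,
ε = 1e-6 for numerical stability. The combined dual-task loss adds to the
three-class tissue FTL (loss 1) a binary air/tissue FTL (loss 2) computed
on merged channels (tissue probability = adipose + dense), weighted by
`lambda_outline` (default 1, an unweighted sum). Loss 1 sums over all
three classes by default (a config switch restricts it to
adipose + dense) so that the air channel receives gradient in every
configuration. The summation domain N is the whole volume per batch item.
Analytic gradients with respect to the probabilities are provided for the
numpy trainer and are verified against finite differences in the tests.

## Segmenter

A compact 3D U-Net written directly in numpy: per resolution level one
3×3×3 convolution (im2col matrix product) → instance normalization →
leaky ReLU (slope 0.01), 2× average pooling, nearest-neighbour
upsampling with skip concatenation, and a 1×1×1 convolution to three
logits; softmax over channels. Instance normalization and leaky
activations follow the reference full-resolution 3D U-Net design and are
what keep training stable at the protocol's learning rate. Defaults:
depth 2, 8 base channels, whole-volume inference (an optional patch size
with 50%-overlap averaging is available). The backward pass is
hand-derived and validated by finite-difference gradient checks.

Training protocol: Adam with learning rate 0.01, batch size 2 (gradients
averaged across the batch), an 80/20 train/validation split by phantom,
checkpoints every 5 epochs with the best validation-Dice snapshot
retained as the returned model. Reconstructions are z-scored per volume
before entering the network. Inputs of different shapes are handled
natively (the network is fully convolutional; volumes are zero-padded to
multiples of `2^depth` and cropped after).

## Evaluation

Per slice and class, one-vs-rest confusion counts yield Jaccard, Dice,
precision, recall, accuracy, and the Jaccard distance `1 − J` (the
disjunct volume normalised by the union, used for breast-outline
errors). The signed slice distance `d = (z − z_central)·voxel` is
negative toward the support. Slices pooled across phantoms of different
thickness are split into 10 equal-count bins of `d` (counts equal ±1),
each labelled by its mean `d`; slices whose ratio metrics are undefined
(empty union) are excluded from bin means and counted in a QC column.
Model comparisons use the Kruskal–Wallis omnibus test and pairwise
Wilcoxon–Mann–Whitney tests (exact for small tie-free samples); raw
p-values are reported, with an optional Holm correction that is off by
default. Accuracy colormaps render correct air/adipose/dense as
blue/gray/white, any error involving air as red, and the remaining
errors (adipose↔dense confusions, i.e. dense FP or FN) as yellow; in a
three-class problem those categories are exhaustive, so no separate
adipose-error colour exists.

## The four-model study

Models map to fixed (geometry, loss) pairs: I₁ = (conventional, loss 1),
I₁&₂ = (conventional, loss 1&2), II₁&₂ = (T, loss 1&2),
III₁&₂ = (XWR, loss 1&2). The loss comparison is I₁ vs I₁&₂; the
geometry comparison is I₁&₂ vs II₁&₂ vs III₁&₂. All four models share
the training seed and protocol so the comparisons are controlled.

**Problem sizes.** The package's study defaults are desk-scale: 3 mm
voxels, 5 training + 6 evaluation phantoms, a 52×66-pixel detector at
4 mm pitch, 12 epochs, depth-2/8-channel U-Net. These sizes were chosen
so a full four-model study runs in a few minutes on one CPU core; the
full-scale values (550 phantoms at 0.1 mm, 0.085 mm reconstructions,
551×701×T inputs, full nnU-Net) are accepted in configuration but are
cluster/GPU territory. At desk scale only the *direction* of the
published rankings is meaningful, never the magnitudes: the published
Dice values and the ~99% outline improvements of the T geometry arise
from full-resolution training on hundreds of phantoms built with a
proprietary compression model and a commercial reconstruction, none of
which the surrogate reproduces. The direction of the loss effect (the
combined loss lowers the outline error) and of the T geometry's outline
advantage do emerge in most seeds. The XWR arc's tissue-segmentation
advantage is the least stable direction at this scale: with short
training the dense class is far from converged, the four arms' tissue
Jaccards sit within seed-to-seed noise of each other, and XWR is best or
tied rather than clearly ahead — so that directional check can fail at
desk scale without indicating a defect.

## What the synthetic data does and does not show

The generator emulates: population-matched CBT/%VBD distributions, the
three-zone compressed outline (paddle contact, convex hull, support
contact), blocky octree density structure, cone-beam acquisition with
the three NGT trajectories, and unfiltered backprojection with its
characteristic artifacts (bottom-heavy outline errors from the small
support–detector gap, out-of-plane smear shrinking with angular range).
It does not emulate: anatomical texture and ligaments, polyenergetic
spectra, scatter, detector blur/noise transfer, compression mechanics,
or reader behaviour. Passing tests therefore demonstrate the internal
consistency of the method and the geometry-driven artifact physics, not
clinical performance.

## Numerical choices

* Tie-breaks: per-voxel argmax resolves ties toward the lower class
  index (air < adipose < dense).
* `fill_tissue` warns and keeps the closest achievable fill when the
  ±0.5 pp density tolerance is unreachable at the block granularity.
* Backprojection samples the detector bilinearly and tolerates a
  half-pixel overhang at the detector edges (nearest-pixel
  extrapolation) so chest-wall voxels remain covered.
* `zpsf_width` interpolates the half-maximum crossings linearly and
  rejects flat profiles.
* Mask resampling is nearest-neighbour (labels stay categorical);
  intensity downsampling is local mean pooling; equal pitches return
  bit-identical copies.
* All randomness flows from explicit seeds; the experiment runner fans a
  master seed out to per-stage seeds via SHA-256 and records them in the
  run manifest.
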
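# Methods

## Problem

After definitive chemoradiotherapy for locally advanced hepatocellular
carcinoma (HCC), treatment response is assessed on follow-up CT by RECIST
1.1: the change in the target lesion's longest axial diameter classifies the
case as complete/partial response, stable or progressive disease.  Measuring
that diameter requires a tumor contour on the follow-up scan, which is the
hard part: treated HCC is radiologically heterogeneous (necrosis, scarring,
peritumoral inflammation on a cirrhotic background), and a segmentation
model trained across patients often fails on an unseen patient's follow-up
image.

`idolseg` implements a two-stage strategy around that failure.  A
*generalized* 3D fully convolutional DenseNet is trained on a cohort of
{CT, contour} pairs from both time points.  For each evaluation patient the
generalized weights are then *intentionally overfitted* to that patient's
own pre-treatment pair {CT_pre, Tumor_pre} — repeated and perturbed to form
a patient-specific training stream — and the resulting *personalized* model
segments the same patient's follow-up CT_post.  Predicted masks feed the
RECIST geometry (longest axial diameter from a binary mask), response
classification, and agreement statistics (Dice, concordance tables, exact
McNemar, paired tests).

## Network

The segmentation backbone is a 3D, single-channel, two-class FC-DenseNet
("Tiramisu" layout): initial 3x3x3 convolution, encoder blocks of 2, 3, 4
and 5 dense layers with a 7-layer bottleneck, growth rate 12, mirrored
decoder with skip concatenations, and a 1x1x1 classifier; softmax over the
two class channels.  Each dense layer is ReLU -> 3x3x3 conv (growth-rate new
channels) -> dropout (rate 0.2 while training).  Transition-down is a
width-preserving 1x1x1 conv + dropout + max pooling; transition-up is
nearest-neighbour upsampling + width-preserving 3x3x3 conv.

Design points the architecture description leaves open, resolved here:

- **Anisotropy-safe pooling.** In-plane axes always pool by 2 (input x/y
  must be divisible by 16 for the default 4-stage encoder); the axial axis
  pools only while its current extent is even, so thin stacks never
  collapse.  The factors used on the way down are replayed in reverse on
  the way up, keeping the network fully convolutional across input sizes.
- **No normalization layers.**  Batch statistics are degenerate at batch
  size 1; the input is normalized outside the network instead (below).
- **Initialization.** He-normal, seeded; two builds from the same config
  and seed are bit-identical.

The numerics are a small reverse-mode autodiff engine written on numpy
(`_autograd.py`): same-padded 3D convolution implemented as one GEMM per
kernel offset with shifted accumulation (an explicit im2col at these sizes
is memory-bandwidth bound), max-pool/upsample/concat/dropout, fused
log-softmax, and Adam.  Gradients of every operator are covered by
finite-difference checks in the test suite.

## Loss

The training objective combines cross-entropy, *dual* cross-entropy and a
soft-Dice term:

    L = w_ce * CE + w_dce * DCE + w_dice * (1 - softDice)

    CE       = mean_v [ -log p(true class) ]
    DCE      = CE + lambda * mean_v [ -log(1 - p(wrong class)) ]
    softDice = (2 * sum p_fg y + eps) / (sum p_fg + sum y + eps)

with default weights w_ce = w_dce = w_dice = 1, lambda = 1, eps = 1.  Dual
cross-entropy is realized as the CE plus a wrong-class penalty
-log(1 - p_wrong) with weight lambda (reducing to plain CE at lambda = 0);
for two softmax classes the penalty coincides with CE numerically, but the
form is kept general and configurable.  Probabilities inside logs are
floored at 1e-7; the training path evaluates CE through a fused log-softmax
so the gradient with respect to the logits is the bounded (onehot - p) even
where p underflows.  The clamp used on the probability route passes its
gradient straight through: a hard-gated clamp silences the learning signal
exactly at confidently-wrong voxels, which measurably prevented recovery
from an all-background collapse during development.

## Optimization

Adam (0.9/0.999), batch size 1, polynomially decaying learning rate
lr(t) = lr0 (1 - t/T)^p with lr0 = 1e-3, p = 0.9, floored at 1e-8.
Augmentation is random brightness scaling (x0.9-1.1 on raw intensities,
before windowing) and uniform random cropping.  Both time points of every
training case enter the sample pool as independent samples.

**Input normalization.** Volumes are clipped to a fixed soft-tissue window
(default -100 to 300 CT-like units) and mapped linearly onto [-1, 1].  The
map depends on the window alone: a training crop and the full inference
volume land on identical scales.  (A per-volume z-score was tried first and
rejected: its statistics shift with the tissue composition of the crop, and
a model trained on crops then mis-segments whole volumes outright.)

## Patient-specific adaptation

Adaptation copies the generalized model (never mutating it) and continues
training for a fixed number of epochs on perturbed repetitions of the prior
pair only; the *final* epoch's weights are used — no early stopping or
best-checkpoint selection.  Hyperparameters (optimizer, schedule formula,
loss, cropping) are inherited from the generalized stage; the schedule
restarts, with t counting adaptation epochs (a continued-decay alternative
is available via `restart_schedule=False`).  Defaults: 350 epochs, 20
repetitions per epoch.

The perturbation family: in-plane rotation ±10°, translation ±5 in-plane /
±2 axial voxels, isotropic scale 0.9-1.1, brightness 0.9-1.1, additive
Gaussian noise with sd = 2% of the processed window width.  The noise is
deliberately scaled to the window the network sees, not to the raw volume
range — the raw range is dominated by air at -1000 and would yield noise
larger than the tissue contrasts.  Geometric amplitudes are expressed in
voxels and implicitly assume clinical resolution, where ±5 voxels is a few
percent of a tumor diameter; on coarse desk-scale grids the same voxel
counts are a large fraction of the tumor, blur the boundary supervision,
and bias the adapted model toward dilation — tests on coarse grids scale
the amplitudes accordingly.

With zero adaptation epochs the personalized model equals the generalized
one (identity limit, regression-tested).

## Synthetic phantom cohort

No clinical images ship with the package; a generator produces paired
pre/post portal-venous-like phantoms with exact ground truth:

- **Geometry.** An ellipsoidal liver (default semiaxes 38 x 32 x 58 mm)
  inside a body ellipsoid on air background; the tumor is a union of
  ellipsoid lobes (default 2) sampled inside the liver.  Default grid
  64 x 64 x 24 voxels at 1.4 x 1.4 x 6.0 mm spacing — the ~0.23
  in-plane/axial anisotropy of clinical portal-venous liver CT at a
  quarter of its resolution, so that training runs in minutes on a CPU.
- **Response.** Between time points the tumor's semiaxes scale by a shrink
  factor s (cohort default: uniform on [0.45, 1.05], i.e. diameter changes
  of -55% to +5%, the band clinical responses span); the liver contracts
  mildly (x0.95) about its center and the tumor center moves with it.  The
  true response class follows from s by the RECIST rule.
- **Appearance.** Class means in CT-like units (air -1000, body 40, liver
  110, tumor hypodense below liver, edema between the two); band-limited
  multiplicative texture over the parenchyma stands in for cirrhotic
  coarseness, a weaker texture makes the tumor heterogeneous, plus white
  Gaussian noise (sd 5).  Between patients the liver mean jitters (sd 8)
  and the tumor-liver contrast is drawn uniformly from 12 to 55 units —
  from near-isodense, barely conspicuous lesions to obvious ones.  That
  conspicuity spread is the clinically documented reason a cohort-trained
  model degrades on unseen patients, and without it a desk-scale cohort is
  trivially easy and the generalized model leaves adaptation nothing to
  improve.
- **The edema ring.** After treatment a ring of intermediate intensity
  (default 1.5 mm, one in-plane voxel) surrounds the tumor, *excluded* from
  the ground-truth mask.  It models peritumoral inflammatory change and
  deliberately plants the known failure mode of patient-adapted models:
  having never seen the post-treatment tissue class, they tend to include
  it, over-segmenting outward.  The thickness is calibrated so the induced
  overestimation is on the scale reported clinically (tens of percent of
  volume, ~10% of diameter) — a thicker ring on desk-scale tumors would
  multiply mask volume several-fold and impose an overestimation ceiling no
  faithful adaptation could clear.

Everything derives deterministically from the seed; the post mask is the
exact voxelization of the rescaled tumor shape, so measured post diameters
track s x (pre diameter) to within voxel quantization (~1.4 mm per
endpoint).

What the phantoms do **not** model: DICOM/HU calibration, partial-volume
blur, TACE artifacts, vessels, diffuse portal-vein tumor thrombus,
multi-phase acquisition, inter-scan registration error.  Passing desk-scale
tests therefore demonstrates the *mechanics and direction* of the method —
not clinical DSC levels, which depend on image complexity the phantoms do
not carry.

## RECIST geometry and statistics

The longest axial diameter of a mask is computed per axial slice from the
largest 8-connected in-plane component: the maximum pairwise distance
between voxel centers under the in-plane spacing (dx may differ from dy),
maximized over slices.  The implementation enumerates convex-hull vertices
(the maximum of a finite point set is attained there) and falls back to all
pairs for tiny or collinear components; it is tested for exact agreement
against a brute-force all-pairs oracle.  Ties break toward the lower slice
index, then the lexicographically smaller endpoint pair.  An empty mask
measures 0 mm.

Classification: CR if the lesion disappears; PR if the diameter change is
<= -30%; PD if >= +20% *and* >= 5 mm absolute; SD otherwise; boundaries
inclusive.  Concordance over {PR, SD} yields sensitivity (PR as positive
class), specificity, their mean as the balanced-accuracy AUC (the AUC a
single 2x2 table determines), and the exact binomial McNemar test on the
discordant cells.  Paired series get a two-sided paired t, an
exact-where-feasible Wilcoxon signed-rank, and Spearman's rho with average
ranks (scipy implementations).

## Reproduction fixtures

Three CSVs transcribe the published per-case validation tables: 14
validation-case DSCs (generalized model on CT_pre and CT_post, personalized
model on CT_post), 14 diameter/percent-change/response rows, and the 2x2
manual-vs-predicted concordance counts.  `recompute_summaries` recomputes
every summary these tables determine and pairs each with its published
value: the DSC column means (0.61/0.53/0.63), post-treatment diameter means
(88.4 and 97.6 mm), their 9.2 mm mean difference, the paired-t p (0.032),
all 28 response labels, the (3,1,0,10) concordance counts, sensitivity
0.75 / specificity 1.00 / AUC 0.875 / McNemar p = 1.00.

Two published summaries are arithmetically inconsistent with their own
per-case columns (the pre-treatment mean diameter, printed 118.2 vs 120.2
recomputed, and the mean percent reduction, printed 19.9% vs 18.3%
recomputed); the report computes and flags them rather than asserting
equality.  Response labels are reproduced from the *printed* percent
columns, rounded to one decimal, not from percent changes recomputed from
the printed diameters — the two disagree for several cases and the printed
percent column is the one the printed labels follow from; recomputed
percent changes are reported separately.

## Desk-scale experiment

`run_desk_experiment` is the end-to-end analogue of the clinical
comparison at CPU scale: a 6-train/3-validation phantom cohort; a reduced
network (encoder blocks 2-3 with a 4-layer bottleneck, growth rate 8, first
conv 16) trained 16 epochs on random 32 x 32 x 16 crops; 25 adaptation
epochs x 4 repetitions per validation case.  These sizes are the package's
working point for minutes-scale runs; the full-size defaults remain
available.  Reported per validation case and in the mean: generalized-model
DSC on CT_pre and CT_post, personalized-model DSC on CT_post, and predicted
vs true post mask volumes.  At the shipped settings the personalized model
improves the post-treatment mean DSC over the generalized model while
over- (not under-) segmenting around the edema ring, reproducing the
direction of both published findings.

## Numerical conventions and edge cases

- Dice of two empty masks is 1.0; empty-vs-nonempty is 0.0 (models that
  output nothing must be scoreable).
- Mask binarization is `p >= threshold` (inclusive; 0.5 equals two-class
  argmax with foreground ties).
- Percent change requires a positive baseline diameter; a lesion appearing
  from nothing is flagged, not classified (new-lesion semantics are out of
  scope).
- Concordance outside {PR, SD} raises (the 2x2 statistics are undefined);
  an all-PR or all-SD manual column leaves the undefined rate as None.
- Wilcoxon on all-zero differences is flagged None rather than computed.
- Non-finite training loss aborts with epoch/sample context.
- Activations and weights are float32; losses are accumulated in float32
  and reported as floats.

## Limitations

- Clinical DSC magnitudes are not reproducible from this repository — no
  image data is published; only table statistics and desk-scale directions
  are testable.
- The phantom's appearance model is simple (piecewise-constant classes +
  texture + noise); absolute DSC values on phantoms overstate what the same
  pipeline achieves on real CT.
- Two-class segmentation of a single dominant lesion; multi-lesion
  sum-of-diameters RECIST, new-lesion detection and mRECIST viable-core
  measurement are out of scope.
- Pre and post volumes are processed in their own frames; no inter-scan
  registration is attempted.
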
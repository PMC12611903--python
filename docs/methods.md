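# Methods

## The problem

Brain arteriovenous malformations (bAVMs) treated with stereotactic
radiosurgery (SRS) require a precisely contoured target (the nidus) so that
a steep dose gradient can spare adjacent eloquent tissue — in particular
white-matter (WM) tracts reconstructed from DTI tractography.  `avmseg`
implements a two-stage automatic segmentation of the nidus from
co-registered multimodal volumes (CT-like, TOF-MRA-like, T2-like, plus the
tract mask as an input channel), together with the geometric and dosimetric
evaluation machinery needed to judge whether an automatic contour is
clinically interchangeable with a manual one.

Because clinical bAVM imaging is not redistributable, the package ships a
synthetic phantom generator that reproduces the *structure* of the problem
— a bright compact irregular lesion, diffuse perilesional signal, a curved
tract passing within a few voxels of the lesion, noise, and a conformal
dose peak — so the entire pipeline is exercisable and testable end to end.

## Cascade

**Stage 1 (detection).** A standard 4-level 2D U-Net runs independently on
every axial slice of the multi-channel stack; per-pixel foreground
probabilities are thresholded at 0.5 (configurable) and restacked into a
coarse 3D mask.  The mass center of that mask (mean foreground index,
rounded half-up per axis) anchors a fixed-size cubic ROI — 128 voxels per
side at clinical resolution, 32 in the desk-scale experiments.  Boxes are
half-open `[start, start+size)` with `start = center − size//2`, clamped
into the grid; grids smaller than the ROI are symmetrically zero-padded
first, and all of this is recorded in an `ROIBox` so that ROI-space
predictions map back to the full grid exactly (crop∘paste is an identity on
the box support).  An empty coarse detection falls back to the grid center
with a warning; inference never aborts.

**Stage 2 (segmentation).** A U-shaped 3D encoder–decoder over the ROI.
Each level is an *attentional block*: two convolutional sublayers
(depthwise-separable by default: a k³ per-channel spatial filter followed
by a 1³ pointwise channel mixer), each with instance normalization and a
rectifier, refined by channel attention then spatial attention, applied as
Hadamard products:

    V_c(F) = σ( MLP(AvgPool(F)) + MLP(MaxPool(F)) )
    V_s(F) = σ( conv_k([ChanAvg(F) ; ChanMax(F)]) )
    block(F) = V_s(F₁) ⊙ F₁,   F₁ = V_c(F) ⊙ F

The MLP is shared between the two pooled vectors: two affine maps (W0, W1)
with a rectifier between and a bottleneck of `channels / mlp_reduction`
(default 8).  The spatial-attention kernel defaults to 7 (the usual CBAM
choice).  Downsampling is factor-2 max pooling; the decoder mirrors the
encoder with transposed-convolution upsampling (kernel 2, stride 2;
nearest-neighbor available) and skip concatenation.  The head is a 1³
convolution to two channels followed by tanh, polarizing lesion vs normal
tissue; the predicted mask is the per-voxel argmax with ties broken to
background.

`use_attention=False` removes both attention modules (the ablation
variant); `use_depthwise=False` swaps separable convolutions for standard
ones, yielding a strictly larger parameter count (a k=3, 16→32 layer has
944 vs 13 824 weights).

## Training objective

Soft confusion counts over foreground probabilities p and binary target t,
TP = Σp·t, FP = Σp·(1−t), FN = Σ(1−p)·t, define

    L_IoU  = 1 − (TP+ε)/(TP+FP+FN+ε)
    L_Dice = 1 − (2TP+ε)/(2TP+FP+FN+ε)
    L      = (L_IoU + L_Dice)/2,      ε = 1e−5.

ε keeps the empty/empty case finite (loss 0).  Dice ≥ IoU for any counts,
so L_Dice ≤ L_IoU and the compound loss lies between them.  For the
two-channel tanh head the training probability is the affine map
p = (o₁ − o₀ + 2)/4: it is exactly argmax-consistent (p = 0.5 at the tie)
and reaches 0 and 1 at full polarization, which a sigmoid of the channel
difference cannot (tanh bounds would cap p at σ(±2) ≈ 0.88/0.12 and floor
the loss through background false-positive mass).

Both stages use Adam with first-moment coefficient β₁ = 0.5 (the
"momentum 0.5" reading), β₂ = 0.999, and a halve-on-plateau schedule: the
learning rate is multiplied by 0.5 whenever the validation compound loss
has not reached a new minimum for `plateau_patience` (default 10)
consecutive epochs, so the rate is always lr₀/2^k.  A validation split
(`val_fraction`, default 0.1 of the training cases) drives the plateau
criterion.  The detector is trained first; the segmenter is then trained on
ROIs cropped around the *ground-truth* mass center (teacher forcing) — the
detector's center is used only at inference.

**Learning rate and scale.**  The clinical-scale default is lr₀ = 2e−4
over 300 epochs.  The desk-scale phantom experiment (below) performs
roughly 64× fewer optimizer updates (30 epochs × ~12 batches vs 300 epochs
× >150 cases), and Adam's per-step displacement is bounded by the learning
rate, so total parameter travel scales like lr₀ × n_updates.  The
experiment therefore scales the initial rate by the update-count ratio,
`DESK_SCALE_LR0 = 1e−2`, keeping optimizer, β₁ and the plateau schedule
unchanged.  With the clinical rate at desk scale the loss provably cannot
leave the vicinity of its initialization.

**Augmentation.** Random rotation (±15°, random axis pair), flips and
zoom (0.9–1.1) applied identically to every channel and mask (linear
interpolation for images, nearest-neighbor for masks).  At training time
the detector uses flips only, and the segmenter applies the full transform
on a margin-padded ROI crop rather than the whole grid; both choices cut
interpolation cost without changing what the transform does to the sample.

## Phantoms

`PhantomParams` defaults define the standard study phantom: 64³ voxels at
1 mm isotropic spacing, nidus semi-axes drawn from 5–9 voxels with a
smooth low-order directional perturbation of amplitude 0.3 (at amplitude 0
the lesion is an exact ellipsoid, keeping its voxel volume analytically
checkable), a tube of radius 2 voxels swept along a quadratic Bézier curve
whose closest approach is aimed inside a 2-voxel surface gap from the
nidus, per-channel contrasts (MRA 20→100, T2 30→65, CT 40→55 arbitrary
units) with Gaussian noise SDs of 5/4/3, and a dose grid: prescription
(20 Gy, the low end of typical bAVM SRS prescriptions) on the 1-voxel
dilated nidus with Gaussian falloff (σ = 2 voxels), normalized to peak at
the prescription.  Per-case seeds derive from a master seed through
`SeedSequence`, so datasets are bit-reproducible; the train share of an
n-case dataset is `round(n·ratio)` (191 cases at 0.8 give the conventional
153:38 partition).

What the phantoms do **not** model: vascular trees and feeders, anatomy
outside the lesion, MR/CT physics (bias fields, partial volume, motion),
registration error between channels, and beam-level dosimetry.  Passing
the end-to-end tests therefore demonstrates that the pipeline is
implemented correctly and can learn a high-contrast volumetric target —
not that it reaches clinical accuracy on patient data.

## Evaluation

Overlap metrics come from voxel confusion counts: DSC, sensitivity and the
recall-weighted F2 = 5TP/(5TP+4FP+FN).  Both masks empty is scored 1.0 by
convention and flagged; an empty prediction scores 0 with distance metrics
reported as NaN and flagged.  Surfaces are foreground voxels with at least
one six-connected background neighbor (the grid edge counts as
background), taken at voxel centers in millimetres, so anisotropic spacing
is honored.  The directed Hausdorff distance is h(A,B) = max_a min_b ‖a−b‖;
HD is the symmetric max.  The quantity reported as **MSD** is the mean of
the two directed Hausdorff values, (h(A,B)+h(B,A))/2 — deliberately *not*
the conventional all-point average surface distance, which is available
separately as `average_surface_distance` to avoid conflation.

**WMT** measures how differently two competing contours take up a WM
tract: |‖A∩WM‖/‖A‖ − ‖B∩WM‖/‖B‖|.  The normalizer is the contour volume by
default; dividing by the tract volume instead is exposed as an option,
since the fraction's denominator is a genuine modeling choice.

Dosimetry: cumulative DVHs (fraction of a structure receiving at least
each dose level); Dq by the higher-rank sorted-voxel convention without
interpolation (the largest level received by at least q% of voxels — 100
voxels dosed 1..100 Gy give D95 = 6 Gy); VxGy as a fraction internally,
percent at the CLI; coverage = 100·|TV∩PIV|/|TV|, CI = |PIV|/|TV| and
nCI = |PIV|·|TV|/|TV∩PIV|² (Paddick-style inverse; ≥ 1 whenever defined,
undefined and flagged when the isodose misses the target); and the
coefficient of determination of an ordinary least-squares fit for
endpoint-series concordance.  Dose grids are assumed co-registered to the
mask grid; resampling is out of scope.

## Numerical engine

The networks run on a compact reverse-mode automatic-differentiation
engine written on NumPy (`avmseg.nn`), float32 throughout, single-CPU,
fully deterministic for fixed seeds.  Convolutions use three routes chosen
by shape: 1³ pointwise kernels as BLAS channel-mixing matmuls; all other
2D/3D kernels through direct loop kernels JIT-compiled with numba
(vectorized over the contiguous fastest axis; no im2col window
materialization); and a cached-column GEMV path for 2D depthwise filters.
Gradient correctness of every primitive — standard/depthwise/transposed
convolutions, pooling, attention reductions, instance norm — is verified
against central finite differences in the test suite.  Max reductions
route gradients to the first argmax (deterministic tie-break); the
plateau scheduler counts strictly-improving epochs with best initialized
to +∞.

## Desk-scale experiment

`run_phantom_experiment(master_seed)` is the package's standard
end-to-end study: 30 phantom cases at 64³ split 24:6, a width-8 detector
trained 20 epochs (flips only, batch = 8 slices of one case, half of them
lesion-bearing), and width-8, 4-level segmenters on 32³ ROIs trained 30
epochs (batch 2) — once with attention, once ablated, sharing the
detector and its per-case detections.  Problem sizes were chosen so the
full experiment runs in minutes on a single CPU while still exercising
every stage; the acceptance checks run it for three master seeds and pool
the 18 held-out cases.  Typical results: median held-out DSC ≈ 0.97 for
both variants (the phantom task is easy enough that the ablation gap, a
clinical effect, is not resolvable at this scale — the check is
directional, attention ≥ ablated − 0.05).

`scripts/acceptance.py` runs one such experiment per given seed and adds
the dosimetric layer: target Dmean agreement between auto and manual
contours under the case dose; synthetic per-contour "plans" (the phantom
dose model applied to each contour) compared through the tract's Dmean and
V1Gy series (R² across cases); and coverage/CI/nCI of the auto-contour
plan against the manual target, prescribing at the isodose level that
covers 95 % of that target — the usual radiosurgical prescription
convention.

## Known limitations

* The engine is CPU-NumPy; clinical-resolution training (128³ ROIs,
  hundreds of epochs) is out of its intended range.
* Phantom realism is structural, not physical (see above); absolute
  metric values on phantoms say nothing about clinical performance.
* The decoder places attention blocks symmetrically to the encoder and
  channel widths double per level; the architecture leaves both
  configurable since finer placement details are a design freedom.
* Registration, tractography reconstruction and treatment-plan
  optimization are consumed as inputs, never computed.
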
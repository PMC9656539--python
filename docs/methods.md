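# Methods

This package segments the five pulmonary lobes of a thoracic CT scan by
registering an annotated atlas to the scan and pulling the atlas lobe
annotation through the estimated deformation.  The registration is
deliberately *fissure-aided*: the pulmonary fissures are extracted first
and their similarity enters the registration loss with the same weight as
the lung intensity similarity, because intensity alone aligns the lung
outline well but leaves the faint fissure sheets — the actual lobe
borders — uncorrected.

## Prerequisite segmentations

**Lung segmentation** is classical region growing.  Airspace is the
6-connected flood fill of voxels below a fixed threshold (default
−500 HU) from two seed points, found by expanding a spherical search
around two atlas-space anchor positions (defaults at the expected lung
centres, fractions (0.28, 0.5, 0.5) and (0.72, 0.5, 0.5) of the grid).
The airway tree, when present, is removed by explosion-controlled region
growing: a trachea seed is identified as the most superior small,
circular, air-density (≤ −950 HU mean) airspace cross-section that
persists over a few slices, and the growing threshold is stepped upward
in 10 HU increments until the grown volume jumps by more than a factor of
2 in one step (a leak); the last safe region, dilated by one voxel, is
subtracted.  Volumes without a trachea-like component (our phantoms, by
default) are passed through unchanged with a warning.  The two lungs are
separated by connected components (with erosion + nearest-component
reassignment if they touch) and assigned left/right by centroid position
along the image x axis; each lung is finally closed with a spherical
structuring element (radius 3 voxels) so vessels and small defects do not
punch holes in the mask.

**Fissure extraction** uses the Hessian sheet-similarity model.  At scale
σ (Gaussian derivatives, default 1 mm, reflective boundaries) the Hessian
eigenvalues are ordered |λ1| ≤ |λ2| ≤ |λ3|.  A bright sheet on dark
parenchyma has λ3 strongly negative with eigenvector e3 normal to the
sheet, and λ1, λ2 ≈ 0.  Each voxel is scored

    S = F_structure · F_sheet,
    F_structure = Θ(−λ3) · exp(−(|λ3| − α)⁶ / β⁶),
    F_sheet     = exp(−λ2⁶ / γ⁶),

with α = 50, β = 35, γ = 25 on the HU scale and S > 0.1 defining
candidate voxels.  Two printed-form details required a decision:

* With the Θ gate forcing λ3 < 0 and α = +50, the literal exponent
  (λ3 − α)⁶/β⁶ is at least (50/35)⁶ ≈ 8.5 for every admissible λ3, so the
  literal structure term is never larger than ~2·10⁻⁴ and the filter
  would fire nowhere.  We therefore evaluate the term on the eigenvalue
  magnitude, exp(−(|λ3| − α)⁶/β⁶), which makes α the expected sheet
  curvature.  The literal reading stays available behind
  `literal_structure_term=True`.
* Eigenvectors are defined only up to sign, so the orientation-coherence
  test between neighbouring candidates uses the absolute inner product
  |e3(a)·e3(b)| ≥ 0.95 by default; a strict signed mode is selectable.

Candidates are grouped by union–find over 26-neighbour pairs that pass
the coherence test, and components with more than `min_component_size`
voxels survive (default 100, suited to 32–64 voxel desk grids; ~1000 is
appropriate on clinical ~1 mm grids).  Everything runs per lung on the HU
image restricted to the lung mask, with the exterior filled by the lung
median intensity so the lung border itself does not respond; α = 50
implies an HU-like scale, so the filter sees unnormalised HU values.
Candidates are additionally restricted to the lung eroded by
`border_erosion` voxels (default 2): partial-volume smear at the
lung/soft-tissue interface is itself a bright sheet and is otherwise
detected as fissure — on a warped phantom this single restriction raised
detection precision from 0.43 to 1.0 at unchanged recall.

## Registration

A compact convolutional encoder-decoder maps the 4-channel stack
(fixed CT, fixed fissure, moving CT, moving fissure) to a dense
displacement field φ in voxel units on the fixed grid, pull convention:
moved(i) = moving(i + φ(i)) with trilinear sampling and clamp-to-edge
out-of-bounds handling.  The loss is

    L = MSE(f_CT, m_CT∘φ) + MSE(f_f, m_f∘φ) + λ·Reg(φ),
    Reg(φ) = (1/3) Σ_axes mean_i Σ_components G_axis[φ](i)²,

with forward differences G (the difference off the last slice is taken as
zero) and λ = 0.01 by default.  The smoothness penalty is stated for a
scalar field; we apply it to each of the three displacement components
and sum before the mean, the standard diffusion regulariser.  Setting the
fissure weight to 0 recovers the plain intensity + smoothness loss used
as the ablation baseline.

CT channels are clamped to [−1000, −200] HU and mapped linearly to [0, 1]
— a window spanning air to the upper end of parenchyma that keeps both
the lung outline and fissures visible.  The fissure channels need more
care, and three choices proved essential (each was validated by checking
that the fissure MSE evaluated at the *known true field* of a phantom
pair drops well below its value at the identity — with naive channels
the two were equal, i.e. the term carried no alignment signal):

* **Symmetric extraction.**  The atlas fissure channel is produced by
  running the same automatic detector on the atlas CT, not by using an
  annotation mask.  Detector output has a characteristic thickness; a
  1-voxel annotation against a several-voxel detection creates a width
  mismatch that no deformation can reduce.
* **Gaussian smoothing** of both channels (default 2 mm), widening the
  capture range of the MSE around the thin sheets.
* **Mass normalisation.**  The smoothed channels are scaled to equal
  total mass and then jointly rescaled so the larger peak is 1.
  Per-channel peak normalisation lets any residual thickness difference
  dominate the MSE.

The network is implemented in numpy with a small reverse-mode autodiff
core (`lobereg._autodiff`): 3×3×3 convolutions (zero padding, evaluated
as 27 shifted BLAS matmuls), leaky ReLU (slope 0.2), 2× average-pool
downsampling, nearest-neighbour upsampling with skip concatenation and
1×1×1 channel mixing in the decoder, and a zero-initialised head so the
initial warp is exactly the identity.  Default widths are (8, 16, 16)
encoder channels over three levels and 8 decoder channels.  Optimisation
is Adam with a linearly decaying learning rate (0.04 → 0.004 over the
default 300 iterations); training is deterministic for a fixed seed and
aborts with the iteration index if the loss becomes non-finite.

Because a single CPU-scale instance optimisation at 64³ converges slowly
from scratch, `train` supports a coarse-to-fine schedule
(`coarse_iters` > 0): the same weights are first trained on the 2×
average-pooled pair, where one optimisation step is ~8× cheaper and one
coarse voxel spans two fine voxels, then training continues at full
resolution.  Convolution weights are resolution-agnostic, so the coarse
phase is a warm start, not a separate model.  The network can be trained
on one pair (instance optimisation, the default in the pipeline) or on a
list of pairs visited round-robin.

## Lobe transfer and post-processing

The atlas lobe annotation is pulled through φ with nearest-neighbour
sampling (labels are never interpolated).  Post-processing enforces the
two properties that define a "reasonable" lobe map: labels must lie
inside the subject's own lung segmentation, and every lung voxel must
carry a label of the anatomically correct side (RU/RM/RL in the right
lung, LU/LL in the left).  Warped labels outside the lungs are cleared;
unlabeled or wrong-side lung voxels are reassigned to the label of the
nearest valid labeled voxel by Euclidean distance transform, each lung
handled independently.  The result exactly partitions the lung mask —
no holes and no out-of-lung labels.  Evaluation is the Dice coefficient
2|X∩GT|/(|X|+|GT|) per lobe, computed on the atlas-aligned grid;
empty-vs-empty is defined as 1.0 (vacuous agreement).

Affine pre-alignment of a subject onto the atlas grid is a translation +
anisotropic scaling matching the first and second moments of the
sub-threshold (< −200 HU) foreground, followed by trilinear resampling
onto the atlas grid; `--prealigned` bypasses the moment matching.  The
pipeline treats this as black-box preprocessing, so a deliberately simple
method keeps it dependency-free and exactly testable.

## The synthetic phantom

The phantom emulates what the method needs from a thoracic CT: a
soft-tissue body (+40 HU, in −1000 HU air) containing two ellipsoidal
lungs (−900 HU), each split into lobes by gently rippled oblique cutting
surfaces (ripple amplitude 1.5 voxels, so the sheet normals vary and the
orientation-coherence rule is exercised nontrivially), thin bright
fissure sheets rendered with a Gaussian cross-profile (FWHM = 1 mm) so
the integrated contrast is independent of surface obliquity, optional
bright tube distractors (vessels), and Gaussian noise (default SD
15 HU).  Default grid 64³ at 1 mm spacing.

The fissure contrast is calibrated to the sheet filter: a one-voxel sheet
of contrast c on −900 HU parenchyma produces λ3 ≈ −0.4·c at σ = 1 mm, so
the default sheet intensity −775 HU (c = 125) puts |λ3| ≈ 50 = α at the
sheet centre, the peak of F_structure.  A much brighter sheet (e.g.
−650 HU) would overshoot the structure band and be *rejected* by the
filter — the similarity model is intensity-scale sensitive by design.

Subjects are produced by warping the atlas bundle through a known smooth
displacement field: white-noise 3-vectors smoothed at a correlation scale
(default 8 voxels), tapered smoothly to exact zero in a 2-voxel border
band, rescaled to a peak magnitude (default 3 voxels) and rejected (new
derived seed) if the Jacobian determinant of identity + field is not
positive everywhere.  Intensities warp trilinearly, masks and labels by
nearest neighbour.

When a *pair* is generated (`make_phantom_pair`), the noise-free anatomy
is warped and the atlas and subject then receive independent noise
realisations.  Warping the noisy atlas directly would deform the noise
pattern coherently with the anatomy, handing the intensity loss a dense
correspondence cue that does not exist between a real subject and an
atlas acquired separately; the literal warp-the-noisy-atlas construction
remains available via `independent_noise=False`.

A variant field for ablation studies (`make_fissure_targeted_field`)
windows the field to the lung interior and normalises it so the peak
displacement *on the fissure voxels* equals the requested amplitude:
fissures move while the lung outline stays put, so the intensity term
alone carries almost no registration signal and the contribution of the
fissure term is isolated.  The ablation is scored as the Dice of the
warped atlas fissure mask against the subject's true fissures with both
masks dilated by one voxel: a one-voxel-thin sheet resampled by nearest
neighbour shifts in half-voxel quanta, so undilated thin-sheet Dice is
dominated by rounding and can even reward leaving the sheet unmoved; the
one-voxel dilation makes the overlap reflect actual alignment.

What the phantom does *not* model: airway trees (the bronchial-removal
step is exercised by a synthetic test tube only), emphysema/COPD texture,
incomplete fissures (beyond an optional erase-a-disk switch), anisotropic
voxels in the default spec, and the intensity inhomogeneities of real
scanners.  Passing phantom tests therefore demonstrates the correctness
of the mechanics (filters, optimisation, label transfer) under the
geometry and contrast assumptions stated above, not clinical-grade
robustness.

## Problem sizes and numerical choices

All shipped experiments run on one CPU at desk scale: 64³ grids for the
end-to-end experiments, 32³–48³ for unit and ablation tests.  The
end-to-end run uses the coarse-to-fine schedule (150 coarse + 250 fine
iterations) within the 500-iteration budget.  Other fixed choices:
reflective boundaries for all image-processing convolutions, zero padding
inside the network, clamp-to-edge sampling in the warper, strict
inequality at the S > 0.1 candidate threshold, components larger than
(strictly) `min_component_size` kept, Dice of empty-vs-empty defined
as 1.0, and 0-based voxel indices with displacement in voxel units
throughout.  Grid sizes must be divisible by 2^levels for the
pool/upsample path; volumes of at least 8 voxels per axis are assumed
everywhere.

## Known limitations

* The similarity model needs the fissure contrast within the F_structure
  band; heavily calcified or faint fissures fall outside it.
* Instance optimisation spends minutes per pair on a CPU; the
  architecture supports training a reusable model over many pairs, but no
  pretrained weights ship with the package.
* The moment-based affine is adequate for initial positioning only; it
  has no rotation component.
* Dice is the only shipped metric; surface distances are out of scope.
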
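"""Synthetic thorax phantoms with ground truth for every pipeline stage.

The phantom is a soft-tissue cylinder containing two ellipsoidal lungs of
parenchymal intensity.  Each lung is split into lobes by gently rippled
oblique cutting surfaces (left: one oblique fissure -> LU/LL; right:
oblique + near-horizontal -> RU/RM/RL), and the fissures themselves are
rendered as thin bright sheets whose contrast is calibrated so that the
Hessian sheet filter's |lambda3| at the sheet centre sits near the
structure-term centre alpha = 50 (a one-voxel sheet needs ~125 HU of
contrast at sigma = 1 mm, hence the -775 HU default on -900 HU
parenchyma).  Optional bright tubes act as vessel distractors.  Subjects
are produced from the atlas phantom by a known smooth displacement field,
so registration accuracy can be scored against ground truth.

Default grid is 64^3 at 1 mm isotropic spacing; geometry is specified as
fractions of the grid so smaller desk-scale grids stay valid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core_image import DisplacementField, LabelMap, Volume
from .lobe_transfer import Atlas
from .lung_seg import LungMask
from .registration import spatial_transform

__all__ = [
    "PhantomSpec",
    "PhantomPair",
    "make_atlas_phantom",
    "make_smooth_field",
    "make_fissure_targeted_field",
    "make_subject_phantom",
    "make_phantom_pair",
    "jacobian_determinant",
    "erase_fissure_disk",
]

AIR_HU = -1000.0


@dataclass
class PhantomSpec:
    shape: tuple[int, int, int] = (64, 64, 64)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    lung_hu: float = -900.0
    body_hu: float = 40.0
    #: calibrated so the sheet-centre |lambda3| at sigma=1mm is ~50 (= alpha)
    fissure_hu: float = -775.0
    fissure_thickness: float = 1.0  # mm
    ripple_amplitude: float = 1.5  # voxels, <= 2
    noise_sd: float = 15.0  # HU
    vessel_count: int = 0
    vessel_hu: float = -300.0
    vessel_radius: float = 1.3  # voxels
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.lung_hu < self.fissure_hu < self.body_hu):
            raise ValueError("need lung_hu < fissure_hu < body_hu")
        if min(self.shape) < 16:
            raise ValueError("phantom grid must be at least 16 voxels per axis")
        if self.noise_sd < 0 or self.fissure_thickness <= 0:
            raise ValueError("noise_sd must be >= 0 and fissure_thickness > 0")


@dataclass
class PhantomPair:
    """Atlas bundle, deformed subject bundle, and the true field mapping
    subject-grid voxels into the atlas (pull convention:
    ``subject(i) = atlas(i + phi(i))``)."""

    atlas: Atlas
    subject: Atlas
    true_field: DisplacementField


# geometric layout as fractions of the grid
_BODY_RADIUS = 0.46
_LUNG_CENTER_X = {"right": 0.30, "left": 0.70}
_LUNG_SEMI = (0.16, 0.27, 0.36)
_OBLIQUE_Z = 0.50
_OBLIQUE_SLOPE_Y = 0.55
_HORIZ_Z = 0.64
_HORIZ_SLOPE_Y = 0.10


def _grids(shape):
    return np.meshgrid(*(np.arange(s, dtype=np.float64) for s in shape), indexing="ij")


def make_atlas_phantom(spec: PhantomSpec | None = None) -> Atlas:
    """Build the annotated atlas phantom (CT + fissure mask + lobe labels +
    lung masks).  Deterministic for a fixed seed."""
    spec = spec or PhantomSpec()
    nx, ny, nz = spec.shape
    x, y, z = _grids(spec.shape)
    rng = np.random.default_rng(spec.seed)

    body = (((x - 0.5 * nx) / (_BODY_RADIUS * nx)) ** 2 + ((y - 0.5 * ny) / (_BODY_RADIUS * ny)) ** 2) <= 1.0
    body &= (z >= 0.02 * nz) & (z <= 0.98 * nz)

    lungs = {}
    for side in ("right", "left"):
        cx = _LUNG_CENTER_X[side] * nx
        sx, sy, sz = _LUNG_SEMI[0] * nx, _LUNG_SEMI[1] * ny, _LUNG_SEMI[2] * nz
        lungs[side] = (
            ((x - cx) / sx) ** 2 + ((y - 0.5 * ny) / sy) ** 2 + ((z - 0.5 * nz) / sz) ** 2
        ) <= 1.0
    if not (lungs["right"].any() and lungs["left"].any()):
        raise ValueError("lung geometry does not fit inside the grid")

    amp = spec.ripple_amplitude
    ripple1 = amp * np.sin(2 * np.pi * x / (nx / 2.0)) * np.cos(2 * np.pi * y / (ny / 2.0))
    ripple2 = 0.6 * amp * np.cos(2 * np.pi * x / (nx / 2.0)) * np.sin(2 * np.pi * y / (ny / 2.0))

    # signed (approximately normalised) distances to the cutting surfaces
    obl_norm = float(np.sqrt(1.0 + _OBLIQUE_SLOPE_Y**2))
    g = _OBLIQUE_Z * nz + _OBLIQUE_SLOPE_Y * (y - 0.5 * ny) + ripple1
    d_obl = (z - g) / obl_norm
    h = _HORIZ_Z * nz + _HORIZ_SLOPE_Y * (y - 0.5 * ny) + ripple2
    d_hor = (z - h) / float(np.sqrt(1.0 + _HORIZ_SLOPE_Y**2))

    labels = np.zeros(spec.shape, dtype=np.int16)
    labels[lungs["left"]] = np.where(d_obl[lungs["left"]] < 0, 5, 4)  # LL / LU
    right = lungs["right"]
    labels[right] = np.where(
        d_obl[right] < 0, 3, np.where(d_hor[right] < 0, 2, 1)  # RL / RM / RU
    )

    thick_vox = spec.fissure_thickness / float(np.mean(spec.spacing))
    half = thick_vox / 2.0
    fissure = np.zeros(spec.shape, dtype=bool)
    both_lungs = lungs["left"] | lungs["right"]
    fissure |= (np.abs(d_obl) <= half) & both_lungs
    fissure |= (np.abs(d_hor) <= half) & (d_obl > 2.0) & right

    ct = np.where(body, spec.body_hu, AIR_HU)
    ct[both_lungs] = spec.lung_hu

    # bright sheets with a Gaussian cross-profile (FWHM = fissure thickness)
    # so the integrated contrast, hence the Hessian response, is independent
    # of the local surface obliquity
    sig_t = thick_vox / 2.355
    contrast = spec.fissure_hu - spec.lung_hu
    sheet = np.exp(-(d_obl**2) / (2 * sig_t**2)) * both_lungs
    sheet_h = np.exp(-(d_hor**2) / (2 * sig_t**2)) * ((d_obl > 2.0) & right)
    ct += contrast * np.maximum(sheet, sheet_h)

    if spec.vessel_count:
        vessel = np.zeros(spec.shape, dtype=bool)
        pts = np.stack([x, y, z], axis=-1)
        for k in range(spec.vessel_count):
            side = "right" if k % 2 == 0 else "left"
            c = np.array([_LUNG_CENTER_X[side] * nx, 0.5 * ny, 0.5 * nz])
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            rel = pts - c
            d2 = (rel**2).sum(-1) - (rel @ u) ** 2
            vessel |= (d2 <= spec.vessel_radius**2) & lungs[side]
        vessel &= ~fissure  # keep fissure ground truth clean
        ct[vessel] = spec.vessel_hu

    if spec.noise_sd > 0:
        ct = ct + rng.normal(0.0, spec.noise_sd, size=spec.shape)

    return Atlas(
        ct=Volume(ct, spec.spacing),
        fissure=fissure,
        lobes=LabelMap(labels, spec.spacing),
        lungs=LungMask(left=lungs["left"], right=lungs["right"]),
    )


def jacobian_determinant(field: DisplacementField) -> np.ndarray:
    """Per-voxel determinant of the Jacobian of (identity + field),
    central finite differences."""
    vec = field.vectors
    J = np.empty(field.grid_shape + (3, 3))
    for a in range(3):
        for b in range(3):
            J[..., a, b] = np.gradient(vec[a], axis=b) + (1.0 if a == b else 0.0)
    return np.linalg.det(J)


def make_smooth_field(
    shape,
    amplitude: float,
    scale: float,
    seed: int = 0,
    require_positive_jacobian: bool = True,
) -> DisplacementField:
    """Smooth random displacement field with peak magnitude ``amplitude``.

    White-noise 3-vectors are Gaussian-smoothed at width ``scale``
    (voxels), zeroed in a 2-voxel border band, and rescaled so the maximum
    displacement magnitude equals ``amplitude`` exactly.  If the folding
    check (Jacobian determinant of identity + field > 0) fails, the field
    is regenerated from the next derived seed.
    """
    if amplitude < 0:
        raise ValueError("amplitude must be >= 0")
    if scale <= 0:
        raise ValueError("scale must be > 0")
    shape = tuple(int(s) for s in shape)
    if amplitude == 0:
        return DisplacementField(np.zeros((3,) + shape))
    for attempt in range(8):
        rng = np.random.default_rng(seed + 1000 * attempt)
        vec = rng.normal(size=(3,) + shape)
        vec = np.stack([ndimage.gaussian_filter(v, scale, mode="reflect") for v in vec])
        # taper smoothly to exact zero in a 2-voxel border band so the
        # windowing itself cannot fold the transform
        taper = 6.0
        window = np.ones(shape)
        for ax, n in enumerate(shape):
            dist = np.minimum(np.arange(n), np.arange(n)[::-1]).astype(np.float64)
            ramp = np.clip((dist - 2.0) / taper, 0.0, 1.0)
            ramp = 0.5 - 0.5 * np.cos(np.pi * ramp)  # smooth-step
            sl = [None, None, None]
            sl[ax] = slice(None)
            window *= ramp[tuple(sl)]
        vec *= window
        mag = np.sqrt((vec**2).sum(axis=0)).max()
        if mag == 0:
            continue
        vec *= amplitude / mag
        field = DisplacementField(vec)
        if not require_positive_jacobian or jacobian_determinant(field).min() > 0:
            return field
    raise RuntimeError("could not generate a fold-free field; lower amplitude or raise scale")


def make_fissure_targeted_field(
    atlas: Atlas,
    amplitude: float = 3.0,
    scale: float = 8.0,
    seed: int = 0,
) -> DisplacementField:
    """Smooth field confined to the lung interior: it displaces the
    fissures while leaving the lung outline (and the body) essentially
    unchanged.  Useful for isolating what the fissure similarity term
    contributes to registration, since intensity similarity of the lung
    outline carries no signal for such a deformation."""
    interior = ndimage.distance_transform_edt(atlas.lungs.both)
    window = np.clip((interior - 2.0) / 4.0, 0.0, 1.0)
    window = ndimage.gaussian_filter(window, 2.0, mode="reflect")
    for attempt in range(8):
        base = make_smooth_field(atlas.ct.shape, amplitude, scale, seed=seed + 1000 * attempt,
                                 require_positive_jacobian=False)
        vec = base.vectors * window
        # "displaces the fissures by amplitude": normalise by the peak
        # magnitude over the fissure voxels, not over the whole grid
        mag_f = np.sqrt((vec**2).sum(axis=0))[atlas.fissure].max()
        if mag_f == 0:
            continue
        vec = vec * (amplitude / mag_f)
        field = DisplacementField(vec)
        if jacobian_determinant(field).min() > 0:
            return field
    raise RuntimeError("fissure-targeted field folded; lower amplitude or raise scale")


def make_subject_phantom(atlas: Atlas, field: DisplacementField) -> Atlas:
    """Deform an atlas bundle by ``field``: intensities are pulled with
    trilinear interpolation, masks and labels with nearest-neighbour."""
    if field.grid_shape != atlas.ct.shape:
        raise ValueError(f"field grid {field.grid_shape} != atlas grid {atlas.ct.shape}")
    nn = lambda a: spatial_transform(a, field, mode="nearest")
    return Atlas(
        ct=spatial_transform(atlas.ct, field, mode="trilinear"),
        fissure=nn(atlas.fissure.astype(np.int8)).astype(bool),
        lobes=LabelMap(nn(atlas.lobes.labels), atlas.lobes.spacing, atlas.lobes.origin),
        lungs=LungMask(left=nn(atlas.lungs.left.astype(np.int8)).astype(bool),
                       right=nn(atlas.lungs.right.astype(np.int8)).astype(bool)),
    )


def make_phantom_pair(
    spec: PhantomSpec | None = None,
    amplitude: float = 3.0,
    scale: float = 8.0,
    field_seed: int = 0,
    independent_noise: bool = True,
) -> PhantomPair:
    """Atlas phantom + deformed subject + the true field.

    With ``independent_noise`` (the default) the noise-free anatomy is
    warped and atlas and subject then receive *independent* noise
    realisations of ``spec.noise_sd``, emulating two separate
    acquisitions: a real subject shares anatomy with an atlas, never the
    scanner noise.  With ``independent_noise=False`` the subject is the
    literal warp of the noisy atlas (the noise pattern deforms with the
    anatomy, which leaks correspondence information an intensity loss can
    exploit)."""
    spec = spec or PhantomSpec()
    field = make_smooth_field(spec.shape, amplitude, scale, seed=field_seed)
    if not independent_noise or spec.noise_sd == 0:
        atlas = make_atlas_phantom(spec)
        subject = make_subject_phantom(atlas, field)
        return PhantomPair(atlas=atlas, subject=subject, true_field=field)
    clean_spec = PhantomSpec(**{**vars(spec), "noise_sd": 0.0})
    clean = make_atlas_phantom(clean_spec)
    atlas = make_atlas_phantom(spec)  # same anatomy, noise from spec.seed
    subject = make_subject_phantom(clean, field)
    rng = np.random.default_rng(spec.seed + 7919)
    subject.ct = subject.ct.like(subject.ct.data + rng.normal(0.0, spec.noise_sd, spec.shape))
    return PhantomPair(atlas=atlas, subject=subject, true_field=field)


def erase_fissure_disk(fissure: np.ndarray, center, radius: float) -> np.ndarray:
    """Remove a disk of fissure voxels around ``center`` (voxel coords) —
    a crude model of an incomplete fissure."""
    x, y, z = _grids(fissure.shape)
    c = np.asarray(center, dtype=np.float64)
    d2 = (x - c[0]) ** 2 + (y - c[1]) ** 2 + (z - c[2]) ** 2
    return np.asarray(fissure, dtype=bool) & (d2 > radius**2)
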
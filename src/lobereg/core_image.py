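"""Volume data model, NIfTI I/O and shared preprocessing transforms.

Conventions used throughout the package
---------------------------------------
* Array axis order is ``(x, y, z)`` and maps one-to-one onto NIfTI voxel
  indices ``(i, j, k)``.  Axis 0 runs patient right -> left, axis 2 runs
  inferior -> superior.
* Voxel indices are 0-based integers; displacement fields are expressed in
  voxel units on the fixed-image grid.
* All convolutions (Gaussian smoothing, Hessian derivatives) use reflective
  boundary handling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage

__all__ = [
    "Volume",
    "LabelMap",
    "DisplacementField",
    "LOBE_PALETTE",
    "read_volume",
    "write_volume",
    "read_labels",
    "write_labels",
    "clamp_normalize",
    "gaussian_smooth",
    "resample",
    "affine_prealign",
]

#: Lobe label palette: right upper/middle/lower, left upper/lower.
LOBE_PALETTE = {0: "background", 1: "RU", 2: "RM", 3: "RL", 4: "LU", 5: "LL"}


@dataclass
class Volume:
    """A scalar 3D image with voxel spacing (mm) and physical origin."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected 3D volume, got {self.data.ndim}D")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite voxels")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive values, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def like(self, data: np.ndarray) -> "Volume":
        """New Volume on this grid with different voxel data."""
        return Volume(data, self.spacing, self.origin)


@dataclass
class LabelMap:
    """Integer labels on a Volume grid plus a label -> name palette."""

    labels: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    palette: dict = field(default_factory=lambda: dict(LOBE_PALETTE))

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError(f"expected 3D label map, got {self.labels.ndim}D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            self.labels = np.rint(self.labels).astype(np.int16)
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape


@dataclass
class DisplacementField:
    """Per-voxel 3-vector displacements, voxel units, on the fixed grid.

    ``vectors`` has shape ``(3, nx, ny, nz)``; component c at voxel i is the
    displacement added to i before sampling the moving image (pull
    convention: ``moved(i) = moving(i + phi(i))``).
    """

    vectors: np.ndarray

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=np.float64)
        if self.vectors.ndim != 4 or self.vectors.shape[0] != 3:
            raise ValueError(
                f"displacement field must have shape (3, nx, ny, nz), got {self.vectors.shape}"
            )
        if not np.all(np.isfinite(self.vectors)):
            raise ValueError("displacement field contains non-finite values")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.vectors.shape[1:]

    def max_magnitude(self) -> float:
        return float(np.sqrt((self.vectors**2).sum(axis=0)).max())


# ---------------------------------------------------------------------------
# NIfTI I/O
# ---------------------------------------------------------------------------


def _affine(spacing, origin) -> np.ndarray:
    aff = np.diag(list(spacing) + [1.0])
    aff[:3, 3] = origin
    return aff


def read_volume(path) -> Volume:
    """Read a 3D NIfTI image (.nii / .nii.gz)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"expected 3D volume, got {data.ndim}D in {path.name}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    origin = tuple(float(t) for t in img.affine[:3, 3])
    return Volume(np.asarray(data, dtype=np.float64), spacing, origin)


def write_volume(v: Volume, path) -> None:
    img = nib.Nifti1Image(np.asarray(v.data, dtype=np.float64), _affine(v.spacing, v.origin))
    img.header.set_zooms(v.spacing)
    nib.save(img, str(path))


def write_field(phi: DisplacementField, path, spacing=(1.0, 1.0, 1.0)) -> None:
    """Write a displacement field as a 4D NIfTI with the 3 components last."""
    arr = np.moveaxis(phi.vectors, 0, -1)
    img = nib.Nifti1Image(arr.astype(np.float64), _affine(spacing, (0, 0, 0)))
    nib.save(img, str(path))


def read_field(path) -> DisplacementField:
    img = nib.load(str(path))
    arr = np.asarray(img.dataobj)
    if arr.ndim != 4 or arr.shape[-1] != 3:
        raise ValueError(f"expected a (nx, ny, nz, 3) field, got shape {arr.shape}")
    return DisplacementField(np.moveaxis(arr, -1, 0))


def read_labels(path) -> LabelMap:
    v = read_volume(path)
    return LabelMap(np.rint(v.data).astype(np.int16), v.spacing, v.origin)


def write_labels(lm: LabelMap, path) -> None:
    img = nib.Nifti1Image(lm.labels.astype(np.int16), _affine(lm.spacing, lm.origin))
    img.header.set_zooms(lm.spacing)
    nib.save(img, str(path))


# ---------------------------------------------------------------------------
# Preprocessing transforms
# ---------------------------------------------------------------------------


def clamp_normalize(v: Volume, lo: float = -1000.0, hi: float = -200.0) -> Volume:
    """Clamp intensities to ``[lo, hi]`` HU and map linearly onto [0, 1].

    The default window [-1000, -200] HU spans air to the upper end of lung
    parenchyma, which keeps both the lung outline and the faint fissure
    sheets visible to the intensity-similarity loss.
    """
    if lo >= hi:
        raise ValueError(f"need lo < hi, got lo={lo}, hi={hi}")
    out = (np.clip(v.data, lo, hi) - lo) / (hi - lo)
    return v.like(out)


def gaussian_smooth(v: Volume, sigma: float) -> Volume:
    """Gaussian smoothing with physical width ``sigma`` in mm.

    ``sigma=0`` returns the input unchanged.  Boundaries are handled by
    reflection, which preserves the total image sum.
    """
    if sigma < 0:
        raise ValueError(f"sigma must be >= 0, got {sigma}")
    if sigma == 0:
        return v.like(v.data.copy())
    sig_vox = [sigma / s for s in v.spacing]
    return v.like(ndimage.gaussian_filter(np.asarray(v.data, dtype=np.float64), sig_vox, mode="reflect"))


def resample(
    moving: Volume,
    out_shape: tuple[int, int, int],
    matrix: np.ndarray,
    offset: np.ndarray,
    order: int = 1,
    spacing=None,
    origin=None,
    cval: float | None = None,
) -> Volume:
    """Sample ``moving`` at coordinates ``matrix @ i + offset`` for every
    output voxel index i (trilinear for order=1, nearest for order=0).

    The identity transform reproduces the input exactly at grid points.
    Out-of-bounds samples take the nearest edge value unless ``cval`` is
    given.
    """
    mode = "nearest" if cval is None else "constant"
    kw = {} if cval is None else {"cval": cval}
    out = ndimage.affine_transform(
        np.asarray(moving.data, dtype=np.float64),
        np.asarray(matrix, dtype=np.float64),
        offset=np.asarray(offset, dtype=np.float64),
        output_shape=tuple(out_shape),
        order=order,
        mode=mode,
        **kw,
    )
    return Volume(out, spacing or moving.spacing, origin or moving.origin)


def _foreground_moments(data: np.ndarray, hu_threshold: float):
    fg = data < hu_threshold
    n = int(fg.sum())
    if n == 0:
        raise ValueError("no foreground voxels below threshold; cannot compute moments")
    idx = np.argwhere(fg).astype(np.float64)
    centroid = idx.mean(axis=0)
    sd = idx.std(axis=0)
    if np.any(sd == 0):
        raise ValueError("degenerate foreground (zero extent along an axis)")
    return centroid, sd


def affine_prealign(
    subject: Volume,
    atlas: Volume,
    hu_threshold: float = -200.0,
    prealigned: bool = False,
):
    """Align a subject scan to the atlas grid by matching foreground moments.

    Foreground is the sub-threshold (airspace + parenchyma) region.  The
    transform is a per-axis translation + anisotropic scaling that maps the
    atlas foreground centroid/spread onto the subject's, after which the
    subject is resampled onto the atlas grid.  With ``prealigned=True`` the
    moments step is skipped and the subject is only resampled (identity
    mapping) onto the atlas grid.

    Returns ``(aligned_volume, params)`` where params holds the recovered
    per-axis ``scale`` and ``translation`` (subject voxel units).
    """
    if prealigned:
        params = {"scale": (1.0, 1.0, 1.0), "translation": (0.0, 0.0, 0.0), "prealigned": True}
        aligned = resample(
            subject, atlas.shape, np.eye(3), np.zeros(3), order=1,
            spacing=atlas.spacing, origin=atlas.origin,
        )
        return aligned, params

    if np.ptp(subject.data) == 0 or np.ptp(atlas.data) == 0:
        raise ValueError("constant image: affine moments are undefined")
    c_sub, sd_sub = _foreground_moments(subject.data, hu_threshold)
    c_atl, sd_atl = _foreground_moments(atlas.data, hu_threshold)
    scale = sd_sub / sd_atl  # atlas index -> subject index stretch
    offset = c_sub - scale * c_atl
    aligned = resample(
        subject, atlas.shape, np.diag(scale), offset, order=1,
        spacing=atlas.spacing, origin=atlas.origin,
    )
    params = {
        "scale": tuple(float(s) for s in scale),
        "translation": tuple(float(t) for t in (c_sub - c_atl)),
        "prealigned": False,
    }
    return aligned, params
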
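"""Left/right lung segmentation by threshold region growing.

The procedure is the classic three-step pipeline: (1) fixed-threshold
region growing from automatically detected seed points segments the
pulmonary airspace; (2) the bronchial tree is removed by
explosion-controlled region growing from a trachea seed; (3) morphological
closing fills vessels and small defects inside each lung.

All masks are boolean arrays on the input volume grid; flood fills use
6-connectivity, component analysis for left/right assignment uses the
image x axis (axis 0, patient right -> left: the right lung has the
smaller x centroid).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core_image import Volume

__all__ = [
    "LungMask",
    "grow_airspace",
    "detect_lung_seeds",
    "separate_bronchi",
    "close_lung",
    "segment_lungs",
    "lungs_to_labels",
    "labels_to_lungs",
]

log = logging.getLogger(__name__)

#: Fixed airspace threshold (HU) separating parenchyma from soft tissue.
AIRSPACE_THRESHOLD = -500.0

#: Explosion control for bronchial growing: stop when the grown volume more
#: than doubles over one threshold step.
EXPLOSION_FACTOR = 2.0
BRONCHI_THRESHOLD_STEP = 10.0

#: Default closing radius (voxels) — large enough to swallow vessels,
#: small enough not to bridge the two lungs.
CLOSING_RADIUS = 3

_STRUCT6 = ndimage.generate_binary_structure(3, 1)


@dataclass
class LungMask:
    """Disjoint binary masks for the left and right lung."""

    left: np.ndarray
    right: np.ndarray

    def __post_init__(self) -> None:
        self.left = np.asarray(self.left, dtype=bool)
        self.right = np.asarray(self.right, dtype=bool)
        if self.left.shape != self.right.shape:
            raise ValueError("left/right masks must share a grid")
        if np.any(self.left & self.right):
            raise ValueError("left and right lung masks overlap")

    @property
    def both(self) -> np.ndarray:
        return self.left | self.right

    @property
    def shape(self):
        return self.left.shape


def lungs_to_labels(lungs: LungMask) -> np.ndarray:
    """Integer lung label map: 1 = left, 2 = right."""
    out = np.zeros(lungs.shape, dtype=np.int16)
    out[lungs.left] = 1
    out[lungs.right] = 2
    return out


def labels_to_lungs(labels: np.ndarray) -> LungMask:
    labels = np.asarray(labels)
    return LungMask(left=labels == 1, right=labels == 2)


def _ball(radius: int) -> np.ndarray:
    r = int(radius)
    ax = np.arange(-r, r + 1)
    x, y, z = np.meshgrid(ax, ax, ax, indexing="ij")
    return (x * x + y * y + z * z) <= r * r


def grow_airspace(v: Volume, seeds, threshold: float = AIRSPACE_THRESHOLD) -> np.ndarray:
    """6-connected flood fill of ``{intensity < threshold}`` from seed voxels."""
    below = v.data < threshold
    for s in seeds:
        s = tuple(int(c) for c in s)
        if not below[s]:
            raise ValueError(f"seed {s} has intensity {v.data[s]:.0f} >= threshold {threshold}")
    lab, _ = ndimage.label(below, structure=_STRUCT6)
    wanted = {lab[tuple(int(c) for c in s)] for s in seeds}
    mask = np.isin(lab, sorted(wanted))
    if not mask.any():
        raise ValueError("region growing produced an empty mask")
    return mask


def detect_lung_seeds(
    v: Volume,
    threshold: float = AIRSPACE_THRESHOLD,
    anchors=None,
    max_radius_frac: float = 0.35,
):
    """Find one sub-threshold voxel per lung near two atlas-space anchors.

    Anchors default to fractional positions (0.28, 0.5, 0.5) and
    (0.72, 0.5, 0.5) of the grid — the expected right/left lung centres in
    atlas-aligned coordinates.  The search expands spherically around each
    anchor and returns the closest airspace voxel (lexicographic
    tie-break), so the result is deterministic.
    """
    shape = np.array(v.shape)
    if anchors is None:
        anchors = [(0.28, 0.5, 0.5), (0.72, 0.5, 0.5)]
    max_radius = max_radius_frac * float(shape.min())
    below = v.data < threshold
    coords = np.argwhere(below)
    seeds = []
    for frac in anchors:
        anchor = np.array(frac) * (shape - 1)
        if coords.size == 0:
            raise ValueError("no airspace voxel in the volume")
        d2 = ((coords - anchor) ** 2).sum(axis=1)
        order = np.lexsort((coords[:, 2], coords[:, 1], coords[:, 0], d2))
        best = coords[order[0]]
        if d2[order[0]] > max_radius**2:
            raise ValueError(
                f"no airspace voxel within radius {max_radius:.0f} of anchor {tuple(anchor)}"
            )
        seeds.append(tuple(int(c) for c in best))
    return seeds


def explosion_stop(volumes, factor: float = EXPLOSION_FACTOR) -> int:
    """Index of the last safe entry in a grown-volume sequence.

    The sequence holds the region size at successive (rising) thresholds;
    growth beyond ``factor`` times the previous size signals an airway leak
    and the previous threshold is the last safe one.
    """
    volumes = list(volumes)
    for i in range(1, len(volumes)):
        if volumes[i] > factor * volumes[i - 1]:
            return i - 1
    return len(volumes) - 1


#: a trachea candidate must be close to pure air, well below parenchyma
TRACHEA_HU_MAX = -950.0


def _find_trachea_seed(airspace: np.ndarray, v: Volume):
    """Most superior compact circular air-density cross-section, if any.

    To avoid mistaking a lung apex for the trachea the candidate must be
    (a) small and roughly circular, (b) near pure air intensity, and
    (c) persistent: a component of similar area must exist at the same
    (x, y) location three slices further down.
    """
    nz = airspace.shape[2]
    max_area = 0.02 * airspace.shape[0] * airspace.shape[1]
    for z in range(nz - 1, max(nz - int(0.4 * nz) - 1, -1), -1):
        sl = airspace[:, :, z]
        lab, n = ndimage.label(sl)
        for i in range(1, n + 1):
            comp = lab == i
            area = int(comp.sum())
            if not (4 <= area <= max_area):
                continue
            idx = np.argwhere(comp)
            extent = idx.max(axis=0) - idx.min(axis=0) + 1
            fill = area / float(extent[0] * extent[1])
            aspect = extent.min() / float(extent.max())
            if fill <= 0.6 or aspect <= 0.5:
                continue
            if float(v.data[:, :, z][comp].mean()) > TRACHEA_HU_MAX:
                continue
            cx, cy = idx.mean(axis=0)
            ci, cj = int(round(cx)), int(round(cy))
            zd = z - 3
            if zd < 0 or not airspace[ci, cj, zd]:
                continue
            lab_d, _ = ndimage.label(airspace[:, :, zd])
            area_d = int((lab_d == lab_d[ci, cj]).sum())
            if area_d > 2.5 * area:  # lung apices widen quickly; airways do not
                continue
            return (ci, cj, z)
    return None


def separate_bronchi(airspace: np.ndarray, v: Volume) -> np.ndarray:
    """Remove the airway tree by explosion-controlled region growing.

    A trachea seed is searched in the most superior slices; the airway
    region is grown with the threshold stepped upward until the grown
    volume jumps by more than the explosion factor, and the last safe
    region is subtracted.  Volumes without a trachea-like component (e.g.
    phantoms without airways) are returned unchanged with a warning.
    """
    if not airspace.any():
        raise ValueError("empty airspace mask")
    seed = _find_trachea_seed(airspace, v)
    if seed is None:
        log.warning("no trachea-like component found; airspace returned unchanged")
        return airspace

    base = float(v.data[seed])
    thresholds = base + BRONCHI_THRESHOLD_STEP * np.arange(1, 40)
    regions, volumes = [], []
    for t in thresholds:
        below = (v.data < t) & airspace
        lab, _ = ndimage.label(below, structure=_STRUCT6)
        if lab[seed] == 0:
            continue
        reg = lab == lab[seed]
        regions.append(reg)
        volumes.append(int(reg.sum()))
        if len(volumes) >= 2 and volumes[-1] > EXPLOSION_FACTOR * volumes[-2]:
            break
    if not regions:
        log.warning("bronchial growing never captured the seed; airspace unchanged")
        return airspace
    safe = explosion_stop(volumes)
    airways = ndimage.binary_dilation(regions[safe], structure=_STRUCT6)
    return airspace & ~airways


def close_lung(mask: np.ndarray, radius: int = CLOSING_RADIUS) -> np.ndarray:
    """Morphological closing with a spherical element; output contains input."""
    if not mask.any():
        raise ValueError("empty mask")
    ball = _ball(radius)
    padded = np.pad(mask, radius)
    closed = ndimage.binary_closing(padded, structure=ball)
    closed = closed[radius:-radius, radius:-radius, radius:-radius]
    return closed | mask


def _split_left_right(mask: np.ndarray):
    """Split airspace into two lungs; erode if they touch."""
    lab, n = ndimage.label(mask, structure=_STRUCT6)
    if n >= 2:
        sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
        keep = np.argsort(sizes)[-2:] + 1
        comp_a = lab == keep[0]
        comp_b = lab == keep[1]
    else:
        # single component: erode until it splits, then reassign by
        # nearest eroded component
        eroded = mask
        for _ in range(20):
            eroded = ndimage.binary_erosion(eroded, structure=_STRUCT6)
            lab, n = ndimage.label(eroded, structure=_STRUCT6)
            if n >= 2:
                break
        if n < 2:
            raise ValueError("could not separate two lungs")
        sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
        keep = np.argsort(sizes)[-2:] + 1
        core = np.where(np.isin(lab, keep), lab, 0)
        # grow both cores back out within the original mask
        _, idx = ndimage.distance_transform_edt(core == 0, return_indices=True)
        assigned = core[tuple(idx)]
        comp_a = (assigned == keep[0]) & mask
        comp_b = (assigned == keep[1]) & mask
    cx_a = np.argwhere(comp_a)[:, 0].mean()
    cx_b = np.argwhere(comp_b)[:, 0].mean()
    # axis 0 runs patient right -> left: smaller x centroid is the right lung
    if cx_a < cx_b:
        return comp_b, comp_a
    return comp_a, comp_b


def segment_lungs(
    v: Volume,
    threshold: float = AIRSPACE_THRESHOLD,
    closing_radius: int = CLOSING_RADIUS,
    anchors=None,
) -> LungMask:
    """Full lung segmentation: seeds -> airspace growing -> bronchial
    removal -> left/right split -> per-lung closing."""
    seeds = detect_lung_seeds(v, threshold=threshold, anchors=anchors)
    airspace = grow_airspace(v, seeds, threshold=threshold)
    airspace = separate_bronchi(airspace, v)
    if not airspace.any():
        raise ValueError("airspace empty after bronchial separation")
    left, right = _split_left_right(airspace)
    left = close_lung(left, radius=closing_radius)
    right = close_lung(right, radius=closing_radius)
    overlap = left & right
    if overlap.any():  # closing can bridge the gap; give overlap to the nearer lung
        left = left & ~overlap
        right = right & ~overlap
    return LungMask(left=left, right=right)
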
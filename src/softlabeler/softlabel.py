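"""Soft-label generation from hard masks via superpixels and boundary distance.

The hard binary mask is refined into a per-pixel lesion-membership
probability ("soft label").  Superpixels that lie entirely inside or
outside the lesion keep their hard 1/0 values; superpixels that straddle
the lesion contour have every pixel remapped through a distance-based
membership function:

* on the contour:       f = 1/2
* interior, distance d: f = 1/2 * (1 + d / (1 + d))   in (1/2, 1)
* exterior, distance d: f = 1/2 * (1 - d / (1 + d))   in (0, 1/2)

where ``d`` is the Euclidean distance (in pixels) to the nearest contour
point.  The contour is the set of lesion pixels with at least one
4-connected background neighbour, so the contour belongs to the lesion and
thresholding the soft label at 0.5 (ties -> lesion) recovers the hard mask
exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum

import numpy as np
from scipy import ndimage

from .errors import DegenerateMaskError, DimensionError, InvalidParameterError
from .superpixel import SlicParams, SuperpixelMap, slic_segment

__all__ = [
    "RegionRelation",
    "BoundarySet",
    "DistanceField",
    "SoftLabel",
    "extract_boundary",
    "distance_to_boundary",
    "membership_value",
    "classify_superpixels",
    "generate_soft_label",
]

# Per-pixel position flags relative to the lesion contour.
ON_CONTOUR = 0
INTERIOR = 1
EXTERIOR = -1

# Provenance flags for SoftLabel pixels.
KEPT_HARD = 0
REMAPPED = 1


class RegionRelation(IntEnum):
    """Relation of one superpixel to the lesion contour."""

    OUTSIDE = 0       # all background
    INSIDE = 1        # all lesion
    INTERSECTING = 2  # contains both classes


@dataclass
class BoundarySet:
    """Lesion contour pixels: lesion pixels with a 4-connected background
    neighbour. Empty iff the mask is constant."""

    points: np.ndarray  # (n, 2) array of (row, col) coordinates

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class DistanceField:
    """Per-pixel Euclidean distance to the nearest contour point, plus the
    position flag (on-contour / interior / exterior)."""

    d: np.ndarray      # (H, W) float, >= 0; exactly 0 on the contour
    inside: np.ndarray  # (H, W) int in {ON_CONTOUR, INTERIOR, EXTERIOR}


@dataclass
class SoftLabel:
    """Per-pixel lesion membership probability in [0, 1]."""

    p: np.ndarray           # (H, W) float in [0, 1]
    provenance: np.ndarray  # (H, W) int in {KEPT_HARD, REMAPPED}

    def threshold(self) -> np.ndarray:
        """Recover the hard mask: p >= 0.5 is lesion (contour ties included)."""
        return (self.p >= 0.5).astype(np.uint8)


def _check_binary(mask: np.ndarray) -> np.ndarray:
    mask = np.asarray(mask)
    vals = np.unique(mask)
    if not np.isin(vals, (0, 1)).all():
        raise InvalidParameterError("mask must be binary (values 0/1)")
    return mask.astype(bool)


def _boundary_mask(mask: np.ndarray) -> np.ndarray:
    """Lesion pixels with >= 1 four-connected background neighbour."""
    m = mask.astype(bool)
    # A lesion pixel is on the contour iff some 4-neighbour inside the image
    # is background; border_value=1 keeps an all-lesion mask contour-free.
    eroded = ndimage.binary_erosion(
        m, structure=ndimage.generate_binary_structure(2, 1), border_value=1)
    return m & ~eroded


def extract_boundary(mask: np.ndarray) -> BoundarySet:
    """Extract the lesion contour point set from a binary mask.

    Returns an empty set for constant masks (no lesion, or no background);
    downstream operations treat that as a degenerate input.
    """
    m = _check_binary(mask)
    bnd = _boundary_mask(m)
    pts = np.argwhere(bnd)
    return BoundarySet(points=pts)


def distance_to_boundary(mask: np.ndarray) -> DistanceField:
    """Euclidean distance from every pixel to the nearest contour point.

    Uses the exact Euclidean distance transform; ``d`` is zero exactly on
    contour pixels and positive elsewhere.
    """
    m = _check_binary(mask)
    bnd = _boundary_mask(m)
    if not bnd.any():
        raise DegenerateMaskError("mask has no lesion contour")
    d = ndimage.distance_transform_edt(~bnd)
    inside = np.where(m, INTERIOR, EXTERIOR).astype(np.int8)
    inside[bnd] = ON_CONTOUR
    return DistanceField(d=np.asarray(d, dtype=float), inside=inside)


def membership_value(d, region_flag):
    """Distance-to-membership mapping.

    Parameters
    ----------
    d:
        Distance(s) to the contour in pixels, >= 0. Scalar or array.
    region_flag:
        ``ON_CONTOUR`` (0), ``INTERIOR`` (1) or ``EXTERIOR`` (-1);
        scalar or array broadcastable against ``d``.

    Returns
    -------
    Membership probability: exactly 0.5 on the contour, in (0.5, 1)
    inside, in (0, 0.5) outside, monotone in ``d`` on each branch.
    """
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise InvalidParameterError("distance must be non-negative")
    flag = np.asarray(region_flag)
    ratio = d / (1.0 + d)
    out = 0.5 * (1.0 + np.sign(flag) * ratio)
    if out.ndim == 0:
        return float(out)
    return out


def classify_superpixels(spmap: SuperpixelMap, mask: np.ndarray) -> np.ndarray:
    """Classify every superpixel as outside / inside / intersecting.

    A region is ``INTERSECTING`` iff it touches the lesion contour — it
    contains a contour pixel, or both lesion and background pixels (for a
    connected region the former implies the latter's closure; both tests
    are kept so the classification never depends on region connectivity).
    Otherwise it is ``INSIDE`` (all lesion, contour-free) or ``OUTSIDE``
    (all background).

    Returns an array of :class:`RegionRelation` values indexed by region id.
    """
    m = _check_binary(mask)
    if spmap.labels.shape != m.shape:
        raise DimensionError(
            f"superpixel map {spmap.labels.shape} vs mask {m.shape}")
    lab = spmap.labels.ravel()
    lesion_px = np.bincount(lab, weights=m.ravel(), minlength=spmap.n_regions)
    total_px = np.bincount(lab, minlength=spmap.n_regions)
    contour_px = np.bincount(lab, weights=_boundary_mask(m).ravel(),
                             minlength=spmap.n_regions)
    mixed = (lesion_px > 0) & (lesion_px < total_px)
    rel = np.full(spmap.n_regions, RegionRelation.OUTSIDE, dtype=np.int8)
    rel[lesion_px == total_px] = RegionRelation.INSIDE
    rel[(contour_px > 0) | mixed] = RegionRelation.INTERSECTING
    return rel


def generate_soft_label(image: np.ndarray, mask: np.ndarray,
                        params: SlicParams | None = None, seed: int = 0,
                        spmap: SuperpixelMap | None = None) -> SoftLabel:
    """Convert a hard mask into a soft label using superpixel structure.

    Pixels of superpixels that do not touch the contour keep their hard
    0/1 values; pixels of contour-intersecting superpixels are remapped
    through :func:`membership_value` of the global distance field.

    Parameters
    ----------
    image, mask:
        RGB raster and its binary ground-truth mask (same spatial shape).
    params, seed:
        SLIC settings used when ``spmap`` is not supplied.
    spmap:
        Optional precomputed superpixel map (skips the SLIC run).
    """
    m = _check_binary(mask)
    image = np.asarray(image)
    if image.shape[:2] != m.shape:
        raise DimensionError(f"image {image.shape[:2]} vs mask {m.shape}")
    if not m.any() or m.all():
        raise DegenerateMaskError(
            "mask must contain at least one lesion and one background pixel")

    if spmap is None:
        spmap = slic_segment(image, params, seed)
    elif spmap.labels.shape != m.shape:
        raise DimensionError(
            f"superpixel map {spmap.labels.shape} vs mask {m.shape}")

    rel = classify_superpixels(spmap, m)
    field = distance_to_boundary(m)

    p = m.astype(float)
    remap = (rel[spmap.labels] == RegionRelation.INTERSECTING)
    p[remap] = membership_value(field.d[remap], field.inside[remap])

    provenance = np.where(remap, REMAPPED, KEPT_HARD).astype(np.int8)
    return SoftLabel(p=p, provenance=provenance)
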
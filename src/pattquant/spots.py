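"""Spot extraction: from a binary dark/light map to a cleaned set of spots.

The raw dark mask is segmented into 8-connected components, small
components (< 350 px by default) are discarded as stray pixels, holes
inside each component are filled, and the contours are smoothed by
morphological closing followed by opening.  Spots are classified as
*interior* (no pixel 8-adjacent to the mask boundary or image border) or
*boundary*; a region "qualifies" as patterned when it carries enough
interior spots (>= 4 for limbs, >= 6 for trunk and tail, no minimum for
the head).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .imaging import BinaryPattern, BodyPart, RegionImage

__all__ = [
    "Spot",
    "SpotSet",
    "MIN_SPOT_PX",
    "QUALIFY_MIN_INTERIOR",
    "label_components",
    "filter_min_size",
    "fill_holes",
    "smooth_contours",
    "classify_interior",
    "extract_spots",
    "classify_patterned",
    "equivalent_ellipse",
    "spot_thickness",
]

#: Minimum spot area in pixels (~0.5 mm^2 at the photographic scale used).
MIN_SPOT_PX = 350

#: Minimum number of interior spots for a region to count as patterned.
QUALIFY_MIN_INTERIOR = {"limb": 4, "trunk": 6, "tail": 6, "head": 0}

_SQUARE3 = np.ones((3, 3), dtype=bool)  # 8-connectivity / 3x3 structuring element


@dataclass
class Spot:
    """One connected melanistic component with its geometry."""

    pixels: np.ndarray  # (n, 2) int array of (row, col)
    area_px: int
    area_cm2: float
    centroid: Tuple[float, float]
    major_axis_px: float
    minor_axis_px: float
    orientation: float
    thickness_d: int
    interior: bool
    mean_green: float


@dataclass
class SpotSet:
    """All spots of one region plus the qualifying decision."""

    spots: List[Spot]
    pattern: BinaryPattern
    qualifying: bool = False

    @property
    def n_all(self) -> int:
        return len(self.spots)

    @property
    def n_interior(self) -> int:
        return sum(1 for s in self.spots if s.interior)

    def interior_spots(self) -> List[Spot]:
        return [s for s in self.spots if s.interior]

    def union_mask(self) -> np.ndarray:
        out = np.zeros(self.pattern.mask.shape, dtype=bool)
        for s in self.spots:
            out[s.pixels[:, 0], s.pixels[:, 1]] = True
        return out


def label_components(dark: np.ndarray) -> List[np.ndarray]:
    """Maximal 8-connected components of a boolean image.

    Returns a list of (n, 2) pixel-coordinate arrays ordered by the
    component's first pixel in row-major scan order (top-most, then
    left-most), so the output is deterministic.
    """
    dark = np.asarray(dark, dtype=bool)
    labels, n = ndimage.label(dark, structure=_SQUARE3)
    comps = []
    for idx in ndimage.value_indices(labels, ignore_value=0).values():
        rows, cols = idx
        comps.append(np.column_stack([rows, cols]).astype(np.intp))
    comps.sort(key=lambda c: (int(c[0, 0]), int(c[0, 1])))
    return comps


def filter_min_size(
    components: Sequence[np.ndarray], min_spot_px: int = MIN_SPOT_PX
) -> List[np.ndarray]:
    """Keep components whose pixel count is >= ``min_spot_px`` (inclusive)."""
    if min_spot_px < 1:
        raise ValueError("min_spot_px must be >= 1")
    return [c for c in components if len(c) >= min_spot_px]


def _to_mask(component: np.ndarray, shape: Tuple[int, int]) -> np.ndarray:
    m = np.zeros(shape, dtype=bool)
    m[component[:, 0], component[:, 1]] = True
    return m


def _to_pixels(mask: np.ndarray) -> np.ndarray:
    rows, cols = np.nonzero(mask)
    return np.column_stack([rows, cols]).astype(np.intp)


def fill_holes(component: np.ndarray, shape: Tuple[int, int]) -> np.ndarray:
    """Fill enclosed background holes of one component.

    Background is flooded 4-connectedly from the image border; pixels not
    reached are holes and are added to the component.  Idempotent.
    """
    comp = _to_mask(np.asarray(component), shape)
    filled = ndimage.binary_fill_holes(comp)  # 4-connected background flood
    return _to_pixels(filled)


def smooth_contours(dark: np.ndarray, iterations: int = 2) -> np.ndarray:
    """Morphological closing then opening with a 3x3 square element.

    Removes granular effects at spot edges without changing the overall
    shape; ``iterations = 0`` is the identity.
    """
    if iterations < 0:
        raise ValueError("iterations must be >= 0")
    if iterations == 0:
        return np.asarray(dark, dtype=bool).copy()
    dark = np.asarray(dark, dtype=bool)
    # closing: dilate then erode; border treated as background for dilation
    # and foreground for erosion so image-edge spots are not eaten away
    out = ndimage.binary_dilation(dark, _SQUARE3, iterations=iterations)
    out = ndimage.binary_erosion(out, _SQUARE3, iterations=iterations, border_value=1)
    # opening: erode then dilate
    out = ndimage.binary_erosion(out, _SQUARE3, iterations=iterations, border_value=1)
    out = ndimage.binary_dilation(out, _SQUARE3, iterations=iterations)
    return out


def classify_interior(component: np.ndarray, mask: np.ndarray) -> bool:
    """True iff no component pixel is 8-adjacent to out-of-mask or border."""
    comp = _to_mask(np.asarray(component), mask.shape)
    rows = np.asarray(component)[:, 0]
    cols = np.asarray(component)[:, 1]
    h, w = mask.shape
    if rows.min() == 0 or cols.min() == 0 or rows.max() == h - 1 or cols.max() == w - 1:
        return False
    grown = ndimage.binary_dilation(comp, _SQUARE3)
    return not np.any(grown & ~mask)


def equivalent_ellipse(component: np.ndarray) -> Tuple[float, float, float]:
    """Axes of the ellipse with the same normalized second moments.

    Uses the pixel coordinates' central second moments with the standard
    +1/12 per-pixel correction; returns (major, minor, orientation) where
    the axes are full lengths 4*sqrt(eigenvalue) in pixels and orientation
    is the major-axis angle in radians (counter-clockwise from the row
    axis).  Degenerate (collinear) components have the minor axis floored
    at the one-pixel equivalent.
    """
    pts = np.asarray(component, dtype=float)
    if len(pts) < 1:
        raise ValueError("component must contain at least one pixel")
    c = pts.mean(axis=0)
    d = pts - c
    cov = d.T @ d / len(pts) + np.eye(2) / 12.0
    evals, evecs = np.linalg.eigh(cov)  # ascending
    lam2, lam1 = float(evals[0]), float(evals[1])
    one_px = 4.0 * np.sqrt(1.0 / 12.0)
    major = 4.0 * np.sqrt(lam1)
    minor = max(4.0 * np.sqrt(max(lam2, 0.0)), one_px)
    v = evecs[:, 1]
    orientation = float(np.arctan2(v[1], v[0]))
    return major, minor, orientation


def spot_thickness(component: np.ndarray, shape: Optional[Tuple[int, int]] = None) -> int:
    """Erosion steps (4-connected cross element) until the spot disappears.

    The cross element makes the count track the spot's inscribed radius:
    a disk of radius r vanishes after ~r erosions, so the elongation
    EL = area / (2 d^2) of a disk is ~pi/2.
    """
    pts = np.asarray(component)
    if shape is None:
        r0, c0 = pts[:, 0].min(), pts[:, 1].min()
        local = pts - [r0, c0]
        shape = (int(local[:, 0].max()) + 1, int(local[:, 1].max()) + 1)
        m = _to_mask(local, shape)
    else:
        m = _to_mask(pts, shape)
    d = 0
    while m.any():
        m = ndimage.binary_erosion(m, border_value=0)  # cross element
        d += 1
    return d


def classify_patterned(n_interior: int, body_part: BodyPart) -> bool:
    """Does this region carry enough interior spots to count as patterned?"""
    return n_interior >= QUALIFY_MIN_INTERIOR[BodyPart(body_part).part_type]


def extract_spots(
    pattern: BinaryPattern,
    image: Optional[RegionImage] = None,
    min_spot_px: int = MIN_SPOT_PX,
    smooth_iterations: int = 2,
) -> SpotSet:
    """Full spot pipeline for one binarized region.

    label -> size filter -> per-component hole filling -> contour smoothing
    on the union -> relabel -> size filter -> interior classification and
    per-spot geometry.  ``image`` supplies the original green values for
    the spot-intensity statistics; when omitted, mean_green is NaN.
    """
    if image is not None and image.mask.shape != pattern.mask.shape:
        raise ValueError("pattern and image must share shape")
    shape = pattern.mask.shape
    comps = filter_min_size(label_components(pattern.dark), min_spot_px)
    union = np.zeros(shape, dtype=bool)
    for comp in comps:
        filled = fill_holes(comp, shape)
        union[filled[:, 0], filled[:, 1]] = True
    union &= pattern.mask
    union = smooth_contours(union, smooth_iterations) & pattern.mask
    comps = filter_min_size(label_components(union), min_spot_px)

    green = image.channel("G") if image is not None else None
    scale2 = pattern.cm_per_pixel**2
    spots = []
    for comp in comps:
        major, minor, orient = equivalent_ellipse(comp)
        mg = float(green[comp[:, 0], comp[:, 1]].mean()) if green is not None else float("nan")
        spots.append(
            Spot(
                pixels=comp,
                area_px=len(comp),
                area_cm2=len(comp) * scale2,
                centroid=(float(comp[:, 0].mean()), float(comp[:, 1].mean())),
                major_axis_px=major,
                minor_axis_px=minor,
                orientation=orient,
                thickness_d=spot_thickness(comp),
                interior=classify_interior(comp, pattern.mask),
                mean_green=mg,
            )
        )
    ss = SpotSet(spots=spots, pattern=pattern)
    ss.qualifying = classify_patterned(ss.n_interior, pattern.body_part)
    return ss
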
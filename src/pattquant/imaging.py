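"""Binarization of body-region photographs into melanistic dark/light maps.

A region photograph (one body part of one gecko, restricted to a hand-cut
mask) is thresholded with a robust-background / Niblack rule computed over
the whole region: a pixel is called dark when its green value falls below
T = mu - k*sigma, clamped to a global floor of 60 (on the 0-255 scale) and,
for the trunk, capped at 108.  The Niblack factor k depends on the body
part (0.85 for limbs, trunk and tail; 0.50 for the head, which carries a
larger melanistic fraction).

Shadow-prone parts (limbs and trunk) additionally get a lighting
flattening step (a least-squares illumination plane removed from the green
channel) and have pixels flagged as shadow/glare excluded from the
threshold statistics.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "BodyPart",
    "RegionImage",
    "ThresholdReport",
    "BinaryPattern",
    "DegenerateRegionError",
    "NIBLACK_K",
    "THRESHOLD_FLOOR",
    "TRUNK_CAP",
    "region_stats",
    "artifact_mask",
    "compute_threshold",
    "binarize",
]


class DegenerateRegionError(ValueError):
    """Raised when a region has too few usable pixels for statistics."""


class BodyPart(str, enum.Enum):
    """The seven analyzed body regions."""

    FL = "FL"  # front left leg
    FR = "FR"  # front right leg
    BL = "BL"  # back left leg
    BR = "BR"  # back right leg
    HD = "HD"  # head
    TR = "TR"  # trunk
    TA = "TA"  # tail

    @property
    def part_type(self) -> str:
        """Morphological class: 'limb', 'head', 'trunk' or 'tail'."""
        if self in (BodyPart.FL, BodyPart.FR, BodyPart.BL, BodyPart.BR):
            return "limb"
        return {"HD": "head", "TR": "trunk", "TA": "tail"}[self.value]

    @property
    def is_leg(self) -> bool:
        return self.part_type == "limb"


#: Niblack factor k in T = mu - k*sigma, per morphological class.
NIBLACK_K = {"limb": 0.85, "head": 0.50, "trunk": 0.85, "tail": 0.85}

#: Global lower bound on the threshold (0-255 scale): pixels this dark are
#: invariably melanistic, so T never drops below it.
THRESHOLD_FLOOR = 60.0

#: Upper bound applied to the trunk only, guarding against sparse patterns
#: whose high region mean would otherwise inflate the threshold.
TRUNK_CAP = 108.0

_CHANNEL_INDEX = {"R": 0, "G": 1, "B": 2}


@dataclass
class RegionImage:
    """An RGB photograph restricted to one body-region mask.

    Parameters
    ----------
    pixels : (H, W, 3) uint8 array
        8-bit RGB values.
    mask : (H, W) bool array
        True inside the analyzed region.
    body_part : BodyPart
    gecko_id : str
    replicate : int
        Independent photograph number (1-based).
    cm_per_pixel : float
        Length scale of the photograph (cm per pixel side).
    """

    pixels: np.ndarray
    mask: np.ndarray
    body_part: BodyPart
    gecko_id: str = ""
    replicate: int = 1
    cm_per_pixel: float = 1.0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        self.mask = np.asarray(self.mask, dtype=bool)
        self.body_part = BodyPart(self.body_part)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("pixels must be an H x W x 3 array")
        if self.mask.shape != self.pixels.shape[:2]:
            raise ValueError("mask shape must match pixels")
        if not self.mask.any():
            raise ValueError("mask has no pixels")
        if self.pixels.min() < 0 or self.pixels.max() > 255:
            raise ValueError("channel values must be in [0, 255]")
        if not (self.cm_per_pixel > 0):
            raise ValueError("cm_per_pixel must be positive")
        if self.replicate < 1:
            raise ValueError("replicate must be >= 1")

    def channel(self, name: str) -> np.ndarray:
        """One color channel as float (H, W)."""
        return self.pixels[:, :, _CHANNEL_INDEX[name]].astype(float)


@dataclass
class ThresholdReport:
    """Provenance of one binarization threshold."""

    mu: float
    sigma: float
    k: float
    floor: float = THRESHOLD_FLOOR
    cap: Optional[float] = None
    T: float = 0.0
    n_excluded_shadow: int = 0
    n_excluded_glare: int = 0


@dataclass
class BinaryPattern:
    """Final black-on-white spot map for one region."""

    dark: np.ndarray
    mask: np.ndarray
    cm_per_pixel: float
    report: ThresholdReport
    body_part: BodyPart
    gecko_id: str = ""
    replicate: int = 1

    def __post_init__(self) -> None:
        self.dark = np.asarray(self.dark, dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        self.body_part = BodyPart(self.body_part)
        if self.dark.shape != self.mask.shape:
            raise ValueError("dark and mask must share shape")
        if np.any(self.dark & ~self.mask):
            raise ValueError("dark pixels must lie inside the mask")


def region_stats(image: RegionImage, channel: str, used: Optional[np.ndarray] = None):
    """Mean and population standard deviation of one channel over ``used``.

    ``used`` defaults to the full region mask and must be a subset of it.
    """
    if used is None:
        used = image.mask
    used = np.asarray(used, dtype=bool)
    if np.any(used & ~image.mask):
        raise ValueError("used pixels must be a subset of the region mask")
    vals = image.channel(channel)[used]
    if vals.size < 2:
        raise DegenerateRegionError(
            f"region statistics need >= 2 pixels, got {vals.size}"
        )
    return float(vals.mean()), float(vals.std())


def artifact_mask(image: RegionImage):
    """Flag shadow and glare pixels per the body-part-specific rules.

    Limbs: shadow where G < muG - 0.3*sigmaG, glare where G > muG + 0.3*sigmaG.
    Trunk: shadow where B < muB - 0.85*sigmaB, no glare rule.
    Head and tail: no artifact rules (both sets empty).

    Statistics are taken over the full region mask.
    """
    shape = image.mask.shape
    shadow = np.zeros(shape, dtype=bool)
    glare = np.zeros(shape, dtype=bool)
    ptype = image.body_part.part_type
    if ptype == "limb":
        mu, sigma = region_stats(image, "G")
        g = image.channel("G")
        shadow = (g < mu - 0.3 * sigma) & image.mask
        glare = (g > mu + 0.3 * sigma) & image.mask
    elif ptype == "trunk":
        mu, sigma = region_stats(image, "B")
        b = image.channel("B")
        shadow = (b < mu - 0.85 * sigma) & image.mask
    return shadow, glare


def compute_threshold(mu: float, sigma: float, body_part: BodyPart) -> ThresholdReport:
    """Clamp the Niblack value mu - k*sigma to [floor, cap] for this part."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    body_part = BodyPart(body_part)
    ptype = body_part.part_type
    k = NIBLACK_K[ptype]
    cap = TRUNK_CAP if ptype == "trunk" else None
    t = max(mu - k * sigma, THRESHOLD_FLOOR)
    if cap is not None:
        t = min(t, cap)
    return ThresholdReport(mu=mu, sigma=sigma, k=k, cap=cap, T=float(t))


def _fit_illumination_plane(values: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Least-squares plane a + b*row + c*col over mask pixels, returned with
    its mask-mean removed (so subtracting it preserves the region mean)."""
    rows, cols = np.nonzero(mask)
    a = np.column_stack([np.ones(rows.size), rows, cols])
    coef, *_ = np.linalg.lstsq(a, values[rows, cols], rcond=None)
    rr, cc = np.indices(mask.shape)
    plane = coef[0] + coef[1] * rr + coef[2] * cc
    plane -= plane[mask].mean()
    if np.ptp(plane[mask]) < 1e-6:  # numerically flat: leave the image alone
        return np.zeros_like(plane)
    return plane


def binarize(image: RegionImage) -> BinaryPattern:
    """Full thresholding pipeline for one region photograph.

    1. Flag shadow/glare pixels (``artifact_mask`` rules, raw channels).
    2. For shadow-prone parts (limbs, trunk) remove a least-squares
       illumination plane from the green channel, then re-flag on the
       flattened image.
    3. Recompute (mu, sigma) of green over mask minus flagged pixels and
       derive T with ``compute_threshold``.
    4. dark = {G < T} within the mask.

    The flagged pixels are excluded from the threshold statistics only;
    the shadows themselves are neutralized by the illumination
    flattening, so melanistic pixels (which any brightness-based shadow
    rule inevitably also flags) are never barred from the dark set.
    """
    ptype = image.body_part.part_type
    g = image.channel("G")
    mask = image.mask
    if mask.sum() < 2:
        raise DegenerateRegionError("region must contain >= 2 pixels")

    shadow, glare = artifact_mask(image)

    if ptype in ("limb", "trunk"):
        g = g - _fit_illumination_plane(g, mask)
        if ptype == "limb":
            # re-flag on the flattened green field
            vals = g[mask]
            mu0, s0 = float(vals.mean()), float(vals.std())
            shadow = (g < mu0 - 0.3 * s0) & mask
            glare = (g > mu0 + 0.3 * s0) & mask

    used = mask & ~shadow & ~glare
    if used.sum() < 2:
        used = mask  # fall back: flags swallowed the whole region
    vals = g[used]
    mu, sigma = float(vals.mean()), float(vals.std())
    report = compute_threshold(mu, sigma, image.body_part)
    report.n_excluded_shadow = int((shadow & mask).sum())
    report.n_excluded_glare = int((glare & mask).sum())

    dark = (g < report.T) & mask
    return BinaryPattern(
        dark=dark,
        mask=mask,
        cm_per_pixel=image.cm_per_pixel,
        report=report,
        body_part=image.body_part,
        gecko_id=image.gecko_id,
        replicate=image.replicate,
    )
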
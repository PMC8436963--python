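"""The fourteen pattern indices describing one region's spot pattern.

Each qualifying region is summarized by a point in a 14-dimensional
"pattern space":

======  =============================================================
FM      fraction of melanistic area (dark / total mask pixels)
SS/SSD  mean / sd of major axis length of interior spots (cm)
EE/EED  mean / sd of major:minor axis ratio of interior spots
PL      peak length: characteristic pattern wavelength (cm), from the
        radially averaged 2-D power spectrum of the binary field
MD/MDD  mean / sd over all spots of the mean centroid distance to the
        closest three other spots (cm)
SA/SAD  mean / sd of interior spot areas (cm^2)
SI/SID  mean / sd of the green values over pooled pixels of all spots
EL/ELD  mean / sd of spot elongation area / (2 d^2) for interior spots,
        where d is the number of erosion steps until the spot vanishes
======  =============================================================

Index values whose defining spot class is empty (or, for PL and MD,
undefined) are reported as NaN, never as silent zeros.  Dispersion
indices use the sample (n-1) standard deviation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, fields
from typing import List, Optional, Sequence

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .imaging import BinaryPattern, BodyPart, RegionImage
from .spots import SpotSet

__all__ = [
    "INDEX_NAMES",
    "PatternIndices",
    "peak_length",
    "nearest_neighbor_stats",
    "compute_indices",
    "average_replicates",
]

#: Canonical ordering of the 14 indices (columns of every table/vector).
INDEX_NAMES = [
    "FM", "SS", "SSD", "EE", "EED", "PL", "MD",
    "MDD", "SA", "SAD", "SI", "SID", "EL", "ELD",
]


@dataclass
class PatternIndices:
    """The 14-value descriptor of one region (or a replicate average)."""

    FM: float
    SS: float
    SSD: float
    EE: float
    EED: float
    PL: float
    MD: float
    MDD: float
    SA: float
    SAD: float
    SI: float
    SID: float
    EL: float
    ELD: float
    n_all: float = 0
    n_interior: float = 0
    qualifying: bool = False
    gecko_id: str = ""
    body_part: Optional[BodyPart] = None
    replicate: Optional[int] = None
    averaged: bool = False

    def as_vector(self) -> np.ndarray:
        """The 14 indices as a float vector in canonical order."""
        return np.array([getattr(self, n) for n in INDEX_NAMES], dtype=float)


def _sample_sd(values: np.ndarray) -> float:
    return float(np.std(values, ddof=1)) if len(values) >= 2 else 0.0


def peak_length(pattern: BinaryPattern) -> float:
    """Characteristic wavelength of the pattern, in cm.

    The binary field (1 = dark) is cropped to the mask bounding box,
    out-of-mask pixels are set to the in-mask mean, the mean is removed and
    the field zero-padded to the next power-of-two square N.  The 2-D FFT
    power spectrum is averaged over integer-radius annuli; the peak radius
    r* gives PL = (N / r*) * cm_per_pixel.  Returns NaN for uniform
    (spotless or all-dark) fields.
    """
    dark = pattern.dark[pattern.mask]
    if not dark.any() or dark.all():
        return float("nan")
    rows, cols = np.nonzero(pattern.mask)
    r0, r1 = rows.min(), rows.max() + 1
    c0, c1 = cols.min(), cols.max() + 1
    field = pattern.dark[r0:r1, c0:c1].astype(float)
    m = pattern.mask[r0:r1, c0:c1]
    mean = field[m].mean()
    field = np.where(m, field, mean) - mean
    n = 1 << int(np.ceil(np.log2(max(field.shape))))
    padded = np.zeros((n, n))
    padded[: field.shape[0], : field.shape[1]] = field
    power = np.abs(np.fft.fft2(padded)) ** 2
    fr = np.fft.fftfreq(n) * n
    rad = np.sqrt(fr[:, None] ** 2 + fr[None, :] ** 2)
    ann = np.rint(rad).astype(int)
    half = n // 2
    counts = np.bincount(ann.ravel(), minlength=half + 1)[1 : half + 1]
    sums = np.bincount(ann.ravel(), weights=power.ravel(), minlength=half + 1)[1 : half + 1]
    with np.errstate(invalid="ignore", divide="ignore"):
        radial = sums / counts
    r_star = int(np.nanargmax(radial)) + 1
    return (n / r_star) * pattern.cm_per_pixel


def nearest_neighbor_stats(
    centroids: Sequence, k: int = 3, cm_per_pixel: float = 1.0
):
    """Mean (MD) and sample sd (MDD) of per-spot mean distances to the
    closest ``min(k, n-1)`` other spot centroids, in cm.

    Returns (NaN, NaN) when fewer than two centroids exist.
    """
    pts = np.asarray(centroids, dtype=float)
    if len(pts) < 2:
        return float("nan"), float("nan")
    dist = squareform(pdist(pts))
    k_eff = min(k, len(pts) - 1)
    np.fill_diagonal(dist, np.inf)
    nearest = np.sort(dist, axis=1)[:, :k_eff]
    per_spot = nearest.mean(axis=1) * cm_per_pixel
    return float(per_spot.mean()), _sample_sd(per_spot)


def compute_indices(
    spotset: SpotSet,
    pattern: BinaryPattern,
    image: Optional[RegionImage] = None,
    ee_convention: str = "ratio",
) -> PatternIndices:
    """All 14 indices for one region.

    ``ee_convention`` selects the spot-shape measure: ``"ratio"`` (default,
    major/minor axis ratio >= 1) or ``"eccentricity"``
    (sqrt(1 - (minor/major)^2) in [0, 1)).
    """
    if image is not None and image.mask.shape != pattern.mask.shape:
        raise ValueError("pattern and image must share shape")
    if ee_convention not in ("ratio", "eccentricity"):
        raise ValueError("ee_convention must be 'ratio' or 'eccentricity'")
    scale = pattern.cm_per_pixel
    nan = float("nan")

    all_spots = spotset.spots
    interior = spotset.interior_spots()

    fm = sum(s.area_px for s in all_spots) / pattern.mask.sum()

    if interior:
        majors = np.array([s.major_axis_px for s in interior]) * scale
        if ee_convention == "ratio":
            shapes = np.array([s.major_axis_px / s.minor_axis_px for s in interior])
        else:
            shapes = np.array(
                [np.sqrt(1 - (s.minor_axis_px / s.major_axis_px) ** 2) for s in interior]
            )
        areas = np.array([s.area_cm2 for s in interior])
        elong = np.array([s.area_px / (2 * s.thickness_d**2) for s in interior])
        ss, ssd = float(majors.mean()), _sample_sd(majors)
        ee, eed = float(shapes.mean()), _sample_sd(shapes)
        sa, sad = float(areas.mean()), _sample_sd(areas)
        el, eld = float(elong.mean()), _sample_sd(elong)
    else:
        ss = ssd = ee = eed = sa = sad = el = eld = nan

    pl = peak_length(pattern) if all_spots else nan
    md, mdd = nearest_neighbor_stats(
        [s.centroid for s in all_spots], cm_per_pixel=scale
    )

    if all_spots and image is not None:
        green = image.channel("G")
        pooled = np.concatenate(
            [green[s.pixels[:, 0], s.pixels[:, 1]] for s in all_spots]
        )
        si, sid = float(pooled.mean()), _sample_sd(pooled)
    elif all_spots and not np.isnan(all_spots[0].mean_green):
        mg = np.array([s.mean_green for s in all_spots])
        w = np.array([s.area_px for s in all_spots], dtype=float)
        si, sid = float(np.average(mg, weights=w)), nan
    else:
        si = sid = nan

    return PatternIndices(
        FM=float(fm), SS=ss, SSD=ssd, EE=ee, EED=eed, PL=pl, MD=md, MDD=mdd,
        SA=sa, SAD=sad, SI=si, SID=sid, EL=el, ELD=eld,
        n_all=spotset.n_all, n_interior=spotset.n_interior,
        qualifying=spotset.qualifying,
        gecko_id=pattern.gecko_id, body_part=pattern.body_part,
        replicate=pattern.replicate,
    )


def average_replicates(replicates: Sequence[PatternIndices]) -> PatternIndices:
    """Per-index arithmetic mean over repeated measurements of one region.

    Indices missing (NaN) in some replicates are averaged over the
    non-missing ones, with a warning.  The result is flagged qualifying
    only when every replicate qualifies.
    """
    reps = list(replicates)
    if not reps:
        raise ValueError("need at least one replicate")
    ids = {(r.gecko_id, r.body_part) for r in reps}
    if len(ids) > 1:
        raise ValueError("replicates must come from one gecko and body part")
    mat = np.array([r.as_vector() for r in reps])
    if np.isnan(mat).any() and not np.isnan(mat).all(axis=0).any():
        warnings.warn(
            "some indices missing in a subset of replicates; "
            "averaging over the non-missing ones",
            stacklevel=2,
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        means = np.nanmean(mat, axis=0)
    out = PatternIndices(
        **dict(zip(INDEX_NAMES, (float(v) for v in means))),
        n_all=float(np.mean([r.n_all for r in reps])),
        n_interior=float(np.mean([r.n_interior for r in reps])),
        qualifying=all(r.qualifying for r in reps),
        gecko_id=reps[0].gecko_id,
        body_part=reps[0].body_part,
        replicate=None,
        averaged=True,
    )
    return out
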
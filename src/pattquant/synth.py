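"""Synthetic region images and cohorts with known ground truth.

The generator emulates the photographic data the pipeline assumes: dark
elliptical spots on a lighter, noisy skin background inside an irregular
region mask, with optional shadow gradients and glare, and replicate-level
repositioning jitter.  Spot centers sit on a jittered hexagonal lattice so
a true characteristic wavelength exists (for a lattice with
nearest-neighbour spacing a, the first ring of the reciprocal lattice lies
at wavelength (sqrt(3)/2) * a, the row spacing; the truth record carries
both numbers).  Non-overlap is enforced by per-spot rejection so the true
spot count and areas are unambiguous.

Cohorts mimic the structure of a real study: a per-gecko latent
("genetic") parameter vector drawn from a multivariate normal, body-part
offsets (larger spots on head and tail than on the legs), independent
per-body-part developmental noise, and small rigid translations plus fresh
pixel noise per replicate photograph.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage

from .imaging import BinaryPattern, BodyPart, RegionImage, ThresholdReport

__all__ = [
    "SyntheticSpec",
    "CohortSpec",
    "Cohort",
    "PackingError",
    "make_mask",
    "generate_pattern",
    "render_image",
    "generate_cohort",
]


class PackingError(RuntimeError):
    """Raised when spots cannot be placed without overlap."""


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic region image."""

    shape: Tuple[int, int] = (130, 170)
    mask_kind: str = "ellipse"  # "rectangle" | "ellipse" | "limb"
    spacing: float = 40.0  # hexagonal lattice nearest-neighbour spacing, px
    jitter: float = 0.1  # center jitter as a fraction of spacing
    semi_major_mean: float = 14.0  # px; spot semi-major axis, lognormal
    semi_major_logsd: float = 0.08
    axis_ratio_mean: float = 1.3  # major/minor, lognormal >= 1
    axis_ratio_logsd: float = 0.08
    bg_green: float = 180.0
    bg_green_sd: float = 8.0
    spot_green: float = 45.0
    spot_green_sd: float = 8.0
    bg_red: float = 150.0
    spot_red: float = 70.0
    bg_blue: float = 120.0
    spot_blue: float = 112.0  # spots nearly invisible in blue
    channel_sd: float = 8.0
    shadow_amplitude: float = 0.0  # linear left-to-right darkening, intensity units
    shadow_blue: bool = True  # shadows darken the blue channel too
    glare_amplitude: float = 0.0  # brightening bump, intensity units
    glare_radius_frac: float = 0.18
    cm_per_pixel: float = 0.004
    body_part: BodyPart = BodyPart.TA
    gecko_id: str = "synthetic"
    replicate: int = 1
    seed: int = 0

    @property
    def wavelength_px(self) -> float:
        """Spectral characteristic wavelength of the lattice (row spacing)."""
        return self.spacing * np.sqrt(3) / 2


def make_mask(shape: Tuple[int, int], kind: str = "ellipse") -> np.ndarray:
    """A body-region mask: rectangle, inscribed ellipse, or a limb-like
    tapered polygonal outline."""
    h, w = shape
    if kind == "rectangle":
        m = np.zeros(shape, dtype=bool)
        m[2 : h - 2, 2 : w - 2] = True
        return m
    rr, cc = np.indices(shape)
    if kind == "ellipse":
        cy, cx = (h - 1) / 2, (w - 1) / 2
        return ((rr - cy) / (h / 2 - 1)) ** 2 + ((cc - cx) / (w / 2 - 1)) ** 2 <= 1.0
    if kind == "limb":
        # tapered tube: half-height shrinks linearly from 0.95 to 0.55
        cy = (h - 1) / 2
        half = (h / 2 - 2) * (0.95 - 0.4 * cc / (w - 1))
        return (np.abs(rr - cy) <= half) & (cc >= 2) & (cc <= w - 3)
    raise ValueError(f"unknown mask kind {kind!r}")


def _hex_lattice(shape: Tuple[int, int], spacing: float, phase: Tuple[float, float]):
    """Hexagonal lattice points covering the image, row spacing sqrt(3)/2*a."""
    h, w = shape
    dy = spacing * np.sqrt(3) / 2
    pts = []
    row = 0
    y = phase[0] % dy
    while y < h:
        x0 = (phase[1] + (spacing / 2 if row % 2 else 0.0)) % spacing
        x = x0
        while x < w:
            pts.append((y, x))
            x += spacing
        y += dy
        row += 1
    return np.array(pts) if pts else np.empty((0, 2))


def _rasterize_ellipse(shape, center, a, b, theta) -> np.ndarray:
    """Boolean mask of a filled ellipse (semi-axes a >= b, angle theta)."""
    h, w = shape
    r0 = max(int(np.floor(center[0] - a)), 0)
    r1 = min(int(np.ceil(center[0] + a)) + 1, h)
    c0 = max(int(np.floor(center[1] - a)), 0)
    c1 = min(int(np.ceil(center[1] + a)) + 1, w)
    out = np.zeros(shape, dtype=bool)
    if r0 >= r1 or c0 >= c1:
        return out
    rr, cc = np.mgrid[r0:r1, c0:c1]
    dy = rr - center[0]
    dx = cc - center[1]
    u = dy * np.cos(theta) + dx * np.sin(theta)
    v = -dy * np.sin(theta) + dx * np.cos(theta)
    out[r0:r1, c0:c1] = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    return out


def generate_pattern(
    spec: SyntheticSpec,
    center_offset: Tuple[float, float] = (0.0, 0.0),
) -> Tuple[BinaryPattern, dict]:
    """Rasterize a jittered-hexagonal spot pattern inside a region mask.

    Returns the ground-truth binary pattern and a truth record (realized
    per-spot geometry, lattice spacing and spectral wavelength).  Spots
    whose candidate placement collides with an already placed spot are
    re-drawn up to 100 times; persistent collision raises PackingError.
    ``center_offset`` shifts every spot center rigidly (replicate jitter).
    Fully deterministic in ``spec.seed``.
    """
    mask = make_mask(spec.shape, spec.mask_kind)
    phase_rng = np.random.default_rng(
        np.random.SeedSequence(entropy=spec.seed, spawn_key=(0,))
    )
    phase = phase_rng.uniform(0, spec.spacing, size=2)
    sites = _hex_lattice(spec.shape, spec.spacing, (phase[0], phase[1]))
    dark = np.zeros(spec.shape, dtype=bool)
    occupied = np.zeros(spec.shape, dtype=bool)  # dilated to keep spots apart
    centers, majors, minors, thetas, areas = [], [], [], [], []
    max_jit = spec.jitter * spec.spacing
    for i, site in enumerate(sites):
        site = site + np.asarray(center_offset)
        if not (0 <= site[0] < spec.shape[0] and 0 <= site[1] < spec.shape[1]):
            continue
        if not mask[int(site[0]), int(site[1])]:
            continue
        # per-site generator keyed off the region seed: spot parameters are
        # identical across replicate re-rasterizations of the same region
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=spec.seed, spawn_key=(1, i))
        )
        placed = False
        for _ in range(100):
            jit = rng.uniform(-max_jit, max_jit, size=2)
            c = site + jit
            a = spec.semi_major_mean * rng.lognormal(0.0, spec.semi_major_logsd)
            q = max(spec.axis_ratio_mean * rng.lognormal(0.0, spec.axis_ratio_logsd), 1.0)
            b = a / q
            theta = rng.uniform(0, np.pi)
            ell = _rasterize_ellipse(spec.shape, c, a, b, theta)
            if not ell.any():
                continue
            if not (ell & occupied).any():
                placed = True
                break
        if not placed:
            raise PackingError(
                "could not place a non-overlapping spot after 100 rejections; "
                "increase the lattice spacing or shrink the spots"
            )
        dark |= ell
        # gap of >= 5 px between spots: a 2-iteration morphological closing
        # (dilation radius 2 from each side) can never merge two spots
        occupied |= ndimage.binary_dilation(ell, np.ones((3, 3), bool), iterations=4)
        centers.append(tuple(c))
        majors.append(a)
        minors.append(b)
        thetas.append(theta)
        areas.append(ell)  # masks for now; reduced to per-spot stats below
    dark &= mask
    # per-spot truth after clipping to the region mask
    areas_in_mask = []
    interior_flags = []
    for ell in areas:
        clipped = ell & mask
        areas_in_mask.append(int(clipped.sum()))
        grown = ndimage.binary_dilation(clipped, np.ones((3, 3), bool))
        interior_flags.append(bool(clipped.any()) and not bool((grown & ~mask).any()))
    areas = areas_in_mask
    report = ThresholdReport(mu=0.0, sigma=0.0, k=0.0, T=float("nan"))
    pattern = BinaryPattern(
        dark=dark,
        mask=mask,
        cm_per_pixel=spec.cm_per_pixel,
        report=report,
        body_part=spec.body_part,
        gecko_id=spec.gecko_id,
        replicate=spec.replicate,
    )
    from .spots import MIN_SPOT_PX  # local import avoids a module cycle

    interior_areas = [a for a, flag in zip(areas, interior_flags) if flag]
    interior_ratios = [
        maj / mi for maj, mi, flag in zip(majors, minors, interior_flags) if flag
    ]
    truth = {
        "n_spots": len(centers),
        "n_detectable": sum(a >= MIN_SPOT_PX for a in areas),
        "n_interior": sum(interior_flags),
        "centers": centers,
        "semi_major": majors,
        "semi_minor": minors,
        "orientation": thetas,
        "areas_px": areas,
        "interior": interior_flags,
        "spacing_px": spec.spacing,
        "wavelength_px": spec.wavelength_px,
        "wavelength_cm": spec.wavelength_px * spec.cm_per_pixel,
        # truth for the measurable quantities: interior spots for SA/EE,
        # size-filtered spots for FM (the pipeline discards fragments
        # below the minimum spot size)
        "mean_area_cm2": float(np.mean(interior_areas)) * spec.cm_per_pixel**2
        if interior_areas else float("nan"),
        "mean_axis_ratio": float(np.mean(interior_ratios))
        if interior_ratios else float("nan"),
        "fm": float(dark.sum() / mask.sum()),
        "fm_filtered": float(
            sum(a for a in areas if a >= MIN_SPOT_PX) / mask.sum()
        ),
    }
    return pattern, truth


def render_image(
    pattern: BinaryPattern,
    spec: SyntheticSpec,
    rng: Optional[np.random.Generator] = None,
) -> RegionImage:
    """Render a ground-truth pattern as a noisy RGB photograph."""
    rng = np.random.default_rng(spec.seed + 1) if rng is None else rng
    h, w = pattern.mask.shape
    dark = pattern.dark

    def channel(bg, spot, bg_sd, spot_sd):
        vals = rng.normal(bg, bg_sd, size=(h, w))
        vals[dark] = rng.normal(spot, spot_sd, size=int(dark.sum()))
        return vals

    g = channel(spec.bg_green, spec.spot_green, spec.bg_green_sd, spec.spot_green_sd)
    r = channel(spec.bg_red, spec.spot_red, spec.channel_sd, spec.channel_sd)
    b = channel(spec.bg_blue, spec.spot_blue, spec.channel_sd, spec.channel_sd)

    if spec.shadow_amplitude > 0:
        ramp = spec.shadow_amplitude * (1.0 - np.arange(w) / (w - 1))
        g -= ramp[None, :]
        r -= ramp[None, :]
        if spec.shadow_blue:
            b -= ramp[None, :]
    if spec.glare_amplitude > 0:
        cy, cx = h * 0.3, w * 0.7
        rr, cc = np.indices((h, w))
        rad = spec.glare_radius_frac * min(h, w)
        bump = spec.glare_amplitude * np.exp(
            -((rr - cy) ** 2 + (cc - cx) ** 2) / (2 * rad**2)
        )
        g += bump
        r += bump
        b += bump

    pixels = np.stack(
        [np.clip(c, 0, 255).round() for c in (r, g, b)], axis=2
    ).astype(np.uint8)
    return RegionImage(
        pixels=pixels,
        mask=pattern.mask,
        body_part=pattern.body_part,
        gecko_id=pattern.gecko_id,
        replicate=pattern.replicate,
        cm_per_pixel=pattern.cm_per_pixel,
    )


#: Per-body-part geometry of the default cohort: region shape plus
#: multiplicative offsets on spot size and lattice spacing (head and tail
#: carry larger, wider-spaced spots than the legs).
PART_GEOMETRY: Dict[str, dict] = {
    "limb": {"shape": (130, 170), "size": 1.0, "spacing": 0.92, "mask": "limb"},
    "trunk": {"shape": (170, 230), "size": 1.0, "spacing": 1.0, "mask": "ellipse"},
    "head": {"shape": (150, 170), "size": 1.15, "spacing": 1.15, "mask": "ellipse"},
    "tail": {"shape": (120, 280), "size": 1.15, "spacing": 1.12, "mask": "ellipse"},
}


@dataclass
class CohortSpec:
    """Parameters of a synthetic study cohort.

    Per gecko a latent vector (log spot size, log lattice spacing, spot
    intensity offset) is drawn from a multivariate normal with standard
    deviations ``genetic_sd`` and correlation ``genetic_corr`` between the
    two log-scale components.  Each body part then receives independent
    developmental noise (``dev_sd`` scaled by ``dev_scale``) on the same
    latent components, and each replicate photograph a rigid sub-pixel
    translation up to ``replicate_shift`` px plus fresh pixel noise.
    """

    n_geckos: int = 25
    parts: Tuple[str, ...] = ("FL", "FR", "BL", "BR", "HD", "TR", "TA")
    n_replicates: int = 4
    base_semi_major: float = 14.0
    base_spacing: float = 44.0
    shape_scale: float = 1.0  # multiplies the region dimensions
    #: latent components: (log spot size, log lattice spacing,
    #: spot intensity offset, log axis ratio)
    genetic_sd: Tuple[float, float, float, float] = (0.20, 0.10, 8.0, 0.08)
    genetic_corr: float = 0.5  # between log size and log spacing
    dev_sd: Tuple[float, float, float, float] = (0.05, 0.03, 3.0, 0.02)
    dev_scale: float = 1.0
    replicate_shift: float = 3.0
    cm_per_pixel: float = 0.004
    seed: int = 0


@dataclass
class Cohort:
    """In-memory synthetic dataset: images plus ground truth."""

    spec: CohortSpec
    images: List[RegionImage]
    metadata: pd.DataFrame  # one row per image
    truth: pd.DataFrame  # one row per (gecko, part)
    latents: pd.DataFrame  # one row per gecko


def _latent_cov(spec: CohortSpec) -> np.ndarray:
    s1, s2, s3, s4 = spec.genetic_sd
    cov = np.diag([s1**2, s2**2, s3**2, s4**2])
    cov[0, 1] = cov[1, 0] = spec.genetic_corr * s1 * s2
    return cov


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Generate the full cohort of region images with ground truth."""
    root = np.random.SeedSequence(spec.seed)
    latent_rng = np.random.default_rng(root.spawn(1)[0])
    latents = latent_rng.multivariate_normal(
        np.zeros(4), _latent_cov(spec), size=spec.n_geckos
    )
    dev = latent_rng.normal(
        0.0,
        np.asarray(spec.dev_sd) * spec.dev_scale,
        size=(spec.n_geckos, len(spec.parts), 4),
    )
    images: List[RegionImage] = []
    meta_rows = []
    truth_rows = []
    for gi in range(spec.n_geckos):
        gecko = f"g{gi + 1:03d}"
        for pi, part in enumerate(spec.parts):
            bp = BodyPart(part)
            geom = PART_GEOMETRY[bp.part_type]
            lat = latents[gi] + dev[gi, pi]
            region_seed = int(
                np.random.SeedSequence(
                    entropy=spec.seed, spawn_key=(1, gi, pi)
                ).generate_state(1)[0]
                % (2**31)
            )
            spacing = spec.base_spacing * geom["spacing"] * np.exp(lat[1])
            semi_major = spec.base_semi_major * geom["size"] * np.exp(lat[0])
            # packing feasibility: a gecko with unusually large spots also
            # gets a wider lattice so neighbours keep the enforced gap
            spacing = max(spacing, 2.0 * (semi_major + 4.5))
            shape = tuple(
                int(round(s * spec.shape_scale)) for s in geom["shape"]
            )
            sspec = SyntheticSpec(
                shape=shape,
                mask_kind=geom["mask"],
                spacing=spacing,
                semi_major_mean=semi_major,
                spot_green=float(np.clip(45.0 + lat[2], 20.0, 90.0)),
                axis_ratio_mean=float(max(1.3 * np.exp(lat[3]), 1.0)),
                cm_per_pixel=spec.cm_per_pixel,
                body_part=bp,
                gecko_id=gecko,
                seed=region_seed,
            )
            # one set of spot parameters per region; replicates re-rasterize
            # the same ellipses at a rigid sub-pixel offset
            truth = None
            for rep in range(1, spec.n_replicates + 1):
                offset = (
                    (0.0, 0.0)
                    if rep == 1
                    else tuple(
                        np.random.default_rng(
                            np.random.SeedSequence(
                                entropy=spec.seed, spawn_key=(2, gi, pi, rep)
                            )
                        ).uniform(-spec.replicate_shift, spec.replicate_shift, 2)
                    )
                )
                rspec = replace(sspec, replicate=rep)
                pattern, t = generate_pattern(rspec, center_offset=offset)
                if rep == 1:
                    truth = t
                render_rng = np.random.default_rng(
                    np.random.SeedSequence(entropy=spec.seed, spawn_key=(3, gi, pi, rep))
                )
                image = render_image(pattern, rspec, rng=render_rng)
                images.append(image)
                meta_rows.append(
                    {
                        "gecko_id": gecko,
                        "body_part": bp.value,
                        "replicate": rep,
                        "cm_per_pixel": spec.cm_per_pixel,
                    }
                )
            truth_rows.append(
                {
                    "gecko_id": gecko,
                    "body_part": bp.value,
                    "n_spots": truth["n_spots"],
                    "n_detectable": truth["n_detectable"],
                    "n_interior": truth["n_interior"],
                    "mean_area_cm2": truth["mean_area_cm2"],
                    "mean_axis_ratio": truth["mean_axis_ratio"],
                    "wavelength_cm": truth["wavelength_cm"],
                    "fm": truth["fm"],
                    "fm_filtered": truth["fm_filtered"],
                }
            )
    return Cohort(
        spec=spec,
        images=images,
        metadata=pd.DataFrame(meta_rows),
        truth=pd.DataFrame(truth_rows),
        latents=pd.DataFrame(
            latents,
            columns=["log_size", "log_spacing", "intensity", "log_axis_ratio"],
        ).assign(gecko_id=[f"g{i + 1:03d}" for i in range(spec.n_geckos)]),
    )
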
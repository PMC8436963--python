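"""Shared fixtures and small builders for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from pattquant.imaging import BinaryPattern, BodyPart, RegionImage, ThresholdReport


def make_region(
    green,
    mask=None,
    body_part="TA",
    red=None,
    blue=None,
    cm_per_pixel=0.01,
    gecko_id="t",
    replicate=1,
):
    """Build a RegionImage from a green-channel array (other channels
    default to copies of green)."""
    g = np.asarray(green, dtype=np.uint8)
    if mask is None:
        mask = np.ones(g.shape, dtype=bool)
    r = g if red is None else np.asarray(red, dtype=np.uint8)
    b = g if blue is None else np.asarray(blue, dtype=np.uint8)
    return RegionImage(
        pixels=np.stack([r, g, b], axis=2),
        mask=np.asarray(mask, dtype=bool),
        body_part=BodyPart(body_part),
        gecko_id=gecko_id,
        replicate=replicate,
        cm_per_pixel=cm_per_pixel,
    )


def make_pattern(dark, mask=None, cm_per_pixel=0.01, body_part="TA", gecko_id="t",
                 replicate=1):
    """Wrap a boolean dark image as a BinaryPattern with a dummy report."""
    dark = np.asarray(dark, dtype=bool)
    if mask is None:
        mask = np.ones(dark.shape, dtype=bool)
    return BinaryPattern(
        dark=dark,
        mask=np.asarray(mask, dtype=bool),
        cm_per_pixel=cm_per_pixel,
        report=ThresholdReport(mu=0.0, sigma=0.0, k=0.0, T=float("nan")),
        body_part=BodyPart(body_part),
        gecko_id=gecko_id,
        replicate=replicate,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
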
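"""Pattern indices: equivalent-ellipse geometry, thickness, peak length,
nearest-neighbour statistics, the full 14-index computation and replicate
averaging — checked against independent brute-force oracles."""

import numpy as np
import pytest

from pattquant.indices import (
    INDEX_NAMES,
    average_replicates,
    compute_indices,
    nearest_neighbor_stats,
    peak_length,
)
from pattquant.spots import equivalent_ellipse, extract_spots, spot_thickness
from pattquant.synth import SyntheticSpec, generate_pattern

from conftest import make_pattern, make_region


# ---------------------------------------------------------------- oracles

def oracle_axes(points):
    """Equivalent-ellipse axes via the explicit 2x2 eigenvalue formula."""
    pts = np.asarray(points, float)
    d = pts - pts.mean(axis=0)
    sxx = (d[:, 0] ** 2).mean() + 1 / 12
    syy = (d[:, 1] ** 2).mean() + 1 / 12
    sxy = (d[:, 0] * d[:, 1]).mean()
    tr, det = sxx + syy, sxx * syy - sxy**2
    disc = np.sqrt(max(tr**2 / 4 - det, 0.0))
    lam1, lam2 = tr / 2 + disc, tr / 2 - disc
    return 4 * np.sqrt(lam1), 4 * np.sqrt(max(lam2, 0.0))


def oracle_erosion_steps(mask):
    """Erosion count with an explicit 4-neighbourhood scan."""
    m = np.asarray(mask, bool).copy()
    m = np.pad(m, 1, constant_values=False)
    steps = 0
    while m.any():
        nxt = m.copy()
        rows, cols = np.nonzero(m)
        for r, c in zip(rows, cols):
            if not (m[r - 1, c] and m[r + 1, c] and m[r, c - 1] and m[r, c + 1]):
                nxt[r, c] = False
        m = nxt
        steps += 1
    return steps


def oracle_knn_mean(centroids, k=3):
    pts = np.asarray(centroids, float)
    per_spot = []
    for i in range(len(pts)):
        d = sorted(
            np.hypot(*(pts[i] - pts[j])) for j in range(len(pts)) if j != i
        )
        per_spot.append(np.mean(d[: min(k, len(pts) - 1)]))
    return np.array(per_spot)


def raster_disk(radius):
    n = 2 * radius + 5
    rr, cc = np.indices((n, n))
    return np.argwhere((rr - n // 2) ** 2 + (cc - n // 2) ** 2 <= radius**2)


# --------------------------------------------------------------- geometry

class TestEquivalentEllipse:
    def test_disk_axes_match_diameter(self):
        major, minor, _ = equivalent_ellipse(raster_disk(20))
        assert major == pytest.approx(40, rel=0.02)
        assert minor == pytest.approx(40, rel=0.02)

    def test_axis_aligned_ellipse(self):
        rr, cc = np.indices((70, 70))
        pts = np.argwhere(((rr - 35) / 30) ** 2 + ((cc - 35) / 10) ** 2 <= 1)
        major, minor, _ = equivalent_ellipse(pts)
        assert major == pytest.approx(60, rel=0.02)
        assert minor == pytest.approx(20, rel=0.02)

    def test_rotation_by_90_degrees_preserves_axes(self):
        rr, cc = np.indices((70, 70))
        pts = np.argwhere(((rr - 35) / 25) ** 2 + ((cc - 35) / 12) ** 2 <= 1)
        rot = pts[:, ::-1]  # swap rows/cols
        a0 = equivalent_ellipse(pts)[:2]
        a1 = equivalent_ellipse(rot)[:2]
        assert a0 == pytest.approx(a1, rel=1e-12)

    def test_matches_oracle_on_random_blobs(self, rng):
        for _ in range(30):
            pts = np.argwhere(rng.random((25, 25)) < 0.3)
            if len(pts) < 2:
                continue
            major, minor, _ = equivalent_ellipse(pts)
            om, on = oracle_axes(pts)
            assert major == pytest.approx(om, rel=1e-9)
            assert minor == pytest.approx(max(on, 4 * np.sqrt(1 / 12)), rel=1e-9)

    def test_single_pixel_minor_floor(self):
        major, minor, _ = equivalent_ellipse(np.array([[3, 3]]))
        assert minor == pytest.approx(4 * np.sqrt(1 / 12))
        assert major == pytest.approx(minor)


class TestSpotThickness:
    def test_single_pixel(self):
        assert spot_thickness(np.array([[0, 0]])) == 1

    def test_square_20(self):
        rr, cc = np.indices((20, 20))
        assert spot_thickness(np.stack([rr.ravel(), cc.ravel()], 1)) == 10

    def test_disk_thickness_and_elongation(self):
        pts = raster_disk(10)
        d = spot_thickness(pts)
        assert abs(d - 10) <= 1
        el = len(pts) / (2 * d**2)
        assert el == pytest.approx(np.pi / 2, rel=0.2)  # digitization of d

    def test_matches_erosion_oracle(self, rng):
        from pattquant.spots import label_components

        for _ in range(15):
            img = rng.random((20, 20)) < 0.6
            for comp in label_components(img):
                m = np.zeros(img.shape, bool)
                m[comp[:, 0], comp[:, 1]] = True
                assert spot_thickness(comp) == oracle_erosion_steps(m)


class TestPeakLength:
    def test_vertical_stripes_period_32(self):
        dark = np.zeros((64, 64), bool)
        for c0 in range(0, 64, 32):
            dark[:, c0 : c0 + 16] = True
        pl = peak_length(make_pattern(dark, cm_per_pixel=0.01))
        assert pl == pytest.approx(32 * 0.01, rel=1e-9)

    def test_hex_lattice_wavelength(self):
        spec = SyntheticSpec(seed=1, body_part="HD", shape=(160, 180))
        pat, truth = generate_pattern(spec)
        pl = peak_length(pat)
        assert pl == pytest.approx(truth["wavelength_cm"], rel=0.10)

    def test_scale_linearity(self):
        spec = SyntheticSpec(seed=2, body_part="TA")
        pat, _ = generate_pattern(spec)
        pl1 = peak_length(pat)
        pat2 = make_pattern(pat.dark, pat.mask, cm_per_pixel=2 * pat.cm_per_pixel)
        assert peak_length(pat2) == pytest.approx(2 * pl1, rel=1e-12)

    def test_uniform_fields_are_undefined(self):
        assert np.isnan(peak_length(make_pattern(np.zeros((8, 8), bool))))
        assert np.isnan(peak_length(make_pattern(np.ones((8, 8), bool))))


class TestNearestNeighborStats:
    def test_four_corners(self):
        s = 10.0
        pts = [(0, 0), (0, s), (s, 0), (s, s)]
        md, mdd = nearest_neighbor_stats(pts, cm_per_pixel=1.0)
        expected = (2 * s + s * np.sqrt(2)) / 3
        assert md == pytest.approx(expected, rel=1e-12)
        assert mdd == pytest.approx(0.0, abs=1e-9)

    def test_two_spots_fall_back_to_k1(self):
        md, mdd = nearest_neighbor_stats([(0, 0), (0, 7)], cm_per_pixel=1.0)
        assert md == 7.0 and mdd == 0.0

    def test_single_spot_undefined(self):
        md, mdd = nearest_neighbor_stats([(1, 1)])
        assert np.isnan(md) and np.isnan(mdd)

    def test_matches_brute_force(self, rng):
        for _ in range(20):
            pts = rng.random((10, 2)) * 50
            md, mdd = nearest_neighbor_stats(pts, cm_per_pixel=0.5)
            per = oracle_knn_mean(pts) * 0.5
            assert md == pytest.approx(per.mean(), rel=1e-12)
            assert mdd == pytest.approx(per.std(ddof=1), rel=1e-9)


# ----------------------------------------------------- full index vectors

def _square_spot_pattern():
    """One 20x20 spot inside a 100x100 mask (FM = 0.04)."""
    dark = np.zeros((100, 100), bool)
    dark[40:60, 40:60] = True
    return make_pattern(dark, cm_per_pixel=0.01, body_part="HD")


class TestComputeIndices:
    def test_fm_is_area_ratio(self):
        pat = _square_spot_pattern()
        ss = extract_spots(pat, None)
        idx = compute_indices(ss, pat)
        assert idx.FM == pytest.approx(400 / 10000)

    def test_spot_intensity_from_original_pixels(self):
        pat = _square_spot_pattern()
        g = np.full((100, 100), 200, dtype=np.uint8)
        g[pat.dark] = 42
        img = make_region(g, body_part="HD", cm_per_pixel=0.01)
        ss = extract_spots(pat, img)
        idx = compute_indices(ss, pat, img)
        assert idx.SI == 42.0
        assert idx.SID == 0.0

    def test_identical_disks_have_unit_ellipticity(self):
        dark = np.zeros((150, 150), bool)
        rr, cc = np.indices((150, 150))
        for cy, cx in [(35, 35), (35, 105), (105, 35), (105, 105), (70, 70)]:
            dark |= (rr - cy) ** 2 + (cc - cx) ** 2 <= 12**2
        pat = make_pattern(dark, cm_per_pixel=0.01, body_part="HD")
        ss = extract_spots(pat, None, min_spot_px=100)
        idx = compute_indices(ss, pat)
        assert idx.EE == pytest.approx(1.0, abs=0.03)
        assert idx.EED == pytest.approx(0.0, abs=0.03)
        # rasterization undercounts the continuous disk area slightly
        assert idx.SA == pytest.approx(np.pi * 12**2 * 0.01**2, rel=0.05)

    def test_missing_when_no_interior_spots(self):
        dark = np.zeros((60, 60), bool)
        dark[0:25, 0:25] = True  # touches the border: boundary spot
        pat = make_pattern(dark, body_part="HD")
        ss = extract_spots(pat, None, min_spot_px=100)
        idx = compute_indices(ss, pat)
        assert ss.n_all == 1 and ss.n_interior == 0
        for name in ("SS", "EE", "SA", "EL"):
            assert np.isnan(getattr(idx, name))
        assert not np.isnan(idx.FM)

    def test_scale_covariance(self):
        spec = SyntheticSpec(seed=4, body_part="HD", shape=(150, 170))
        pat, _ = generate_pattern(spec)
        ss = extract_spots(pat, None)
        idx1 = compute_indices(ss, pat)
        pat2 = make_pattern(pat.dark, pat.mask, cm_per_pixel=2 * pat.cm_per_pixel,
                            body_part="HD")
        ss2 = extract_spots(pat2, None)
        idx2 = compute_indices(ss2, pat2)
        for name in ("SS", "SSD", "PL", "MD", "MDD"):
            assert getattr(idx2, name) == pytest.approx(2 * getattr(idx1, name), rel=1e-9)
        for name in ("SA", "SAD"):
            assert getattr(idx2, name) == pytest.approx(4 * getattr(idx1, name), rel=1e-9)
        for name in ("FM", "EE", "EED", "SI", "SID", "EL", "ELD"):
            a, b = getattr(idx1, name), getattr(idx2, name)
            if np.isnan(a):
                assert np.isnan(b)
            else:
                assert b == pytest.approx(a, rel=1e-12)

    def test_rotation_invariance(self):
        spec = SyntheticSpec(seed=5, body_part="HD", shape=(150, 150))
        pat, _ = generate_pattern(spec)
        rot = make_pattern(np.rot90(pat.dark).copy(), np.rot90(pat.mask).copy(),
                           cm_per_pixel=pat.cm_per_pixel, body_part="HD")
        idx1 = compute_indices(extract_spots(pat, None), pat)
        idx2 = compute_indices(extract_spots(rot, None), rot)
        for name in INDEX_NAMES:
            a, b = getattr(idx1, name), getattr(idx2, name)
            if np.isnan(a):
                assert np.isnan(b)
            elif name in ("SI", "SID"):
                continue  # no image attached
            else:
                assert b == pytest.approx(a, rel=1e-6)

    def test_ee_eccentricity_convention(self):
        spec = SyntheticSpec(seed=6, body_part="HD", shape=(140, 160))
        pat, _ = generate_pattern(spec)
        ss = extract_spots(pat, None)
        ratio = compute_indices(ss, pat, ee_convention="ratio").EE
        ecc = compute_indices(ss, pat, ee_convention="eccentricity").EE
        assert ratio >= 1.0
        assert 0.0 <= ecc < 1.0


class TestAverageReplicates:
    def _make(self, fm, gecko="g", part="HD", rep=1, **kw):
        vals = {n: 1.0 for n in INDEX_NAMES}
        vals["FM"] = fm
        vals.update(kw)
        from pattquant.indices import PatternIndices
        return PatternIndices(**vals, n_all=5, n_interior=5, qualifying=True,
                              gecko_id=gecko, body_part="HD", replicate=rep)

    def test_single_replicate_is_identity(self):
        r = self._make(0.25)
        avg = average_replicates([r])
        assert avg.FM == 0.25 and avg.averaged

    def test_mean_of_four(self):
        reps = [self._make(v, rep=i + 1) for i, v in enumerate([0.1, 0.2, 0.3, 0.4])]
        assert average_replicates(reps).FM == pytest.approx(0.25)

    def test_missing_value_skipped_with_warning(self):
        reps = [self._make(0.2, rep=1), self._make(0.4, rep=2, SS=float("nan"))]
        with pytest.warns(UserWarning):
            avg = average_replicates(reps)
        assert avg.FM == pytest.approx(0.3)
        assert avg.SS == pytest.approx(1.0)  # mean over the single present value

    def test_mixed_geckos_rejected(self):
        with pytest.raises(ValueError):
            average_replicates([self._make(0.1, gecko="a"), self._make(0.2, gecko="b")])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            average_replicates([])
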
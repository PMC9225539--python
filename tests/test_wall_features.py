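"""Feature extraction: histogram, GLCM (with brute-force oracle), shape,
polar thickness and boundary similarity."""

import math

import numpy as np
import pytest

from bladderwall.imaging import N_FEATURES
from bladderwall.wall_features import (
    ContourRadii,
    DEFAULT_OFFSETS,
    GLCM_FEATURE_ORDER,
    WallRegion,
    boundary_similarity_features,
    contour_radii,
    extract_all,
    glcm_features,
    glcm_matrix,
    glcm_stats,
    histogram_features,
    shape_features,
    to_polar,
    wall_thickness_feature,
)
from conftest import make_image


def region_from(pixels, mask=None, contours=False):
    pixels = np.asarray(pixels, dtype=float)
    if mask is None:
        mask = np.ones_like(pixels, dtype=bool)
    dummy = np.array([[0.0, 0.0], [0.0, 1.0], [1.0, 1.0], [0.0, 0.0]])
    return WallRegion(image=make_image(pixels), wall_mask=mask,
                      inner_contour=dummy, outer_contour=dummy)


# ---------------------------------------------------------------------------
# histogram
# ---------------------------------------------------------------------------

class TestHistogram:
    def test_three_point_set(self):
        f = histogram_features(region_from([[1.0, 2.0, 3.0]]))
        assert f[0] == 2.0                      # mean
        assert abs(f[1] - 2.0 / 3.0) < 1e-12    # population variance
        assert abs(f[2] - 1.5) < 1e-12          # kurtosis (2/3) / (4/9)
        assert abs(f[3]) < 1e-12                # skewness of a symmetric set

    def test_constant_region_conventions(self):
        g = 64
        f = histogram_features(region_from(np.full((4, 4), float(g))))
        assert f[1] == 0.0 and f[2] == 0.0 and f[3] == 0.0
        assert abs(f[4] - (256 - g) / 256) < 1e-12


# ---------------------------------------------------------------------------
# GLCM
# ---------------------------------------------------------------------------

def brute_force_glcm(pixels, mask, levels, offsets):
    """Independent pair-enumeration co-occurrence matrix."""
    vals = pixels[mask]
    lo, hi = vals.min(), vals.max()
    if hi > lo:
        q = np.clip(((pixels - lo) / (hi - lo) * levels).astype(int), 0, levels - 1)
    else:
        q = np.zeros(pixels.shape, int)
    counts = np.zeros((levels, levels))
    rows, cols = pixels.shape
    for r in range(rows):
        for c in range(cols):
            if not mask[r, c]:
                continue
            for dr, dc in offsets:
                r2, c2 = r + dr, c + dc
                if 0 <= r2 < rows and 0 <= c2 < cols and mask[r2, c2]:
                    counts[q[r, c], q[r2, c2]] += 1
                    counts[q[r2, c2], q[r, c]] += 1
    return counts / counts.sum()


def brute_force_stats(p):
    """Each of the 20 texture statistics as an explicit double loop."""
    n = p.shape[0]
    px = [sum(p[i, j] for j in range(n)) for i in range(n)]
    py = [sum(p[i, j] for i in range(n)) for j in range(n)]
    mu_x = sum(i * px[i] for i in range(n))
    mu_y = sum(j * py[j] for j in range(n))
    sd_x = math.sqrt(sum((i - mu_x) ** 2 * px[i] for i in range(n)))
    sd_y = math.sqrt(sum((j - mu_y) ** 2 * py[j] for j in range(n)))
    p_sum = [0.0] * (2 * n - 1)
    p_diff = [0.0] * n
    for i in range(n):
        for j in range(n):
            p_sum[i + j] += p[i, j]
            p_diff[abs(i - j)] += p[i, j]
    out = {}
    out["autocorrelation"] = sum(i * j * p[i, j] for i in range(n) for j in range(n))
    out["contrast"] = sum((i - j) ** 2 * p[i, j] for i in range(n) for j in range(n))
    if sd_x > 0 and sd_y > 0:
        out["correlation"] = sum(
            (i - mu_x) * (j - mu_y) * p[i, j] for i in range(n) for j in range(n)
        ) / (sd_x * sd_y)
    else:
        out["correlation"] = 1.0
    out["cluster_prominence"] = sum(
        (i + j - mu_x - mu_y) ** 4 * p[i, j] for i in range(n) for j in range(n))
    out["cluster_shade"] = sum(
        (i + j - mu_x - mu_y) ** 3 * p[i, j] for i in range(n) for j in range(n))
    out["dissimilarity"] = sum(abs(i - j) * p[i, j] for i in range(n) for j in range(n))
    out["energy"] = sum(p[i, j] ** 2 for i in range(n) for j in range(n))
    hxy = -sum(p[i, j] * math.log2(p[i, j]) for i in range(n) for j in range(n) if p[i, j] > 0)
    out["entropy"] = hxy
    out["homogeneity"] = sum(p[i, j] / (1 + abs(i - j)) for i in range(n) for j in range(n))
    out["max_probability"] = max(p[i, j] for i in range(n) for j in range(n))
    out["variance"] = sum((i - mu_x) ** 2 * p[i, j] for i in range(n) for j in range(n))
    sa = sum(k * p_sum[k] for k in range(2 * n - 1))
    out["sum_average"] = sa
    out["sum_variance"] = sum((k - sa) ** 2 * p_sum[k] for k in range(2 * n - 1))
    out["sum_entropy"] = -sum(v * math.log2(v) for v in p_sum if v > 0)
    mu_d = sum(k * p_diff[k] for k in range(n))
    out["difference_variance"] = sum((k - mu_d) ** 2 * p_diff[k] for k in range(n))
    out["difference_entropy"] = -sum(v * math.log2(v) for v in p_diff if v > 0)
    hx = -sum(v * math.log2(v) for v in px if v > 0)
    hy = -sum(v * math.log2(v) for v in py if v > 0)
    hxy1 = -sum(p[i, j] * math.log2(px[i] * py[j])
                for i in range(n) for j in range(n) if p[i, j] > 0 and px[i] * py[j] > 0)
    hxy2 = -sum(px[i] * py[j] * math.log2(px[i] * py[j])
                for i in range(n) for j in range(n) if px[i] * py[j] > 0)
    denom = max(hx, hy)
    out["imc1"] = (hxy - hxy1) / denom if denom > 0 else 0.0
    out["imc2"] = math.sqrt(max(0.0, 1.0 - 2.0 ** (-2.0 * (hxy2 - hxy))))
    out["inverse_difference_normalized"] = sum(
        p[i, j] / (1 + abs(i - j) / n) for i in range(n) for j in range(n))
    out["inverse_difference_moment"] = sum(
        p[i, j] / (1 + (i - j) ** 2) for i in range(n) for j in range(n))
    return out


class TestGLCM:
    def test_hand_enumerated_two_level_matrix(self):
        region = region_from([[0.0, 0.0], [1.0, 1.0]])
        p = glcm_matrix(region, levels=2, offsets=((0, 1),))
        np.testing.assert_allclose(p, [[0.5, 0.0], [0.0, 0.5]])

    def test_constant_region_single_entry(self):
        p = glcm_matrix(region_from(np.full((4, 4), 9.0)), levels=8, offsets=((0, 1),))
        assert p[0, 0] == 1.0 and p.sum() == 1.0

    def test_matrix_normalized_and_symmetric(self, rng):
        px = rng.integers(0, 256, size=(12, 12)).astype(float)
        mask = rng.random((12, 12)) > 0.3
        p = glcm_matrix(region_from(px, mask), levels=8)
        assert abs(p.sum() - 1.0) < 1e-12
        np.testing.assert_allclose(p, p.T, atol=1e-15)

    def test_matrix_matches_pair_enumeration(self, rng):
        px = rng.integers(0, 256, size=(10, 10)).astype(float)
        mask = rng.random((10, 10)) > 0.25
        p = glcm_matrix(region_from(px, mask), levels=6)
        expected = brute_force_glcm(px, mask, 6, DEFAULT_OFFSETS)
        np.testing.assert_allclose(p, expected, atol=1e-12)

    def test_degenerate_region_error(self):
        mask = np.zeros((5, 5), bool)
        mask[0, 0] = True
        mask[4, 4] = True  # no co-occurring pair at distance 1
        with pytest.raises(ValueError, match="pairs"):
            glcm_matrix(region_from(np.arange(25.0).reshape(5, 5), mask))

    def test_two_entry_matrix_statistics(self):
        stats = glcm_stats(np.array([[0.5, 0.0], [0.0, 0.5]]))
        assert stats["energy"] == 0.5
        assert stats["entropy"] == 1.0  # one bit
        assert stats["contrast"] == 0.0

    def test_constant_region_statistics(self):
        vec = glcm_features(region_from(np.full((5, 5), 7.0)))
        stats = dict(zip(GLCM_FEATURE_ORDER, vec))
        assert stats["max_probability"] == 1.0
        assert stats["entropy"] == 0.0
        assert stats["contrast"] == 0.0
        assert stats["energy"] == 1.0

    @pytest.mark.parametrize("size", [8, 12, 16])
    def test_all_twenty_match_brute_force(self, size):
        rng = np.random.default_rng(size)
        px = rng.integers(0, 256, size=(size, size)).astype(float)
        mask = rng.random((size, size)) > 0.2
        region = region_from(px, mask)
        p = glcm_matrix(region, levels=8)
        got = glcm_stats(p)
        expected = brute_force_stats(p)
        for name in GLCM_FEATURE_ORDER:
            assert abs(got[name] - expected[name]) < 1e-9, name


# ---------------------------------------------------------------------------
# shape
# ---------------------------------------------------------------------------

class TestShape:
    def test_disk_limits(self):
        yy, xx = np.mgrid[0:32, 0:32]
        disk = (yy - 16) ** 2 + (xx - 16) ** 2 <= 100
        area, perim, circ, ecc, sol, roundness, ratio, theta, eqd = shape_features(disk, 1.0)
        assert 0.9 <= circ <= 1.1
        assert ratio >= 0.95
        assert sol >= 0.95
        assert ecc <= 0.2

    def test_rectangle_moments(self):
        mask = np.zeros((40, 40), bool)
        mask[15:25, 10:30] = True  # 10 rows x 20 cols
        feats = shape_features(mask, 1.0)
        ratio, theta = feats[6], feats[7]
        assert abs(ratio - 0.5) <= 0.05
        assert abs(theta) <= 0.05  # long axis along x (columns)

    def test_spacing_scaling_law(self):
        yy, xx = np.mgrid[0:32, 0:32]
        disk = (yy - 16) ** 2 + (xx - 16) ** 2 <= 90
        f1 = shape_features(disk, 1.0)
        f2 = shape_features(disk, 2.0)
        assert abs(f2[0] - 4 * f1[0]) < 1e-9       # area x4
        assert abs(f2[1] - 2 * f1[1]) < 1e-9       # perimeter x2
        for k in (2, 3, 4, 5, 6, 7):               # dimensionless unchanged
            assert abs(f2[k] - f1[k]) < 1e-9

    def test_multi_component_error(self):
        mask = np.zeros((20, 20), bool)
        mask[2:5, 2:5] = True
        mask[10:14, 10:14] = True
        with pytest.raises(ValueError, match="component"):
            shape_features(mask)


# ---------------------------------------------------------------------------
# polar map
# ---------------------------------------------------------------------------

class TestPolar:
    def test_distance_image_gives_radius(self):
        yy, xx = np.mgrid[0:64, 0:64]
        img = make_image(np.hypot(yy - 32, xx - 32))
        pm = to_polar(img, (32, 32), n_theta=90, r_max=25)
        rr = np.broadcast_to(pm.r_grid[:, None], pm.intensities.shape)
        assert np.max(np.abs(pm.intensities - rr)) <= 0.5

    def test_theta_zero_ray_is_image_row(self):
        rng = np.random.default_rng(0)
        px = rng.random((33, 33)) * 100
        pm = to_polar(make_image(px), (16, 16), n_theta=360, r_max=15)
        np.testing.assert_allclose(pm.intensities[:, 0], px[16, 16:32], atol=1e-9)

    def test_rotation_permutes_theta(self):
        rng = np.random.default_rng(1)
        px = rng.random((41, 41)) * 100
        n_theta = 360
        pm = to_polar(make_image(px), (20, 20), n_theta=n_theta, r_max=18)
        rot = np.rot90(px, k=-1)  # 90 degrees: (y, x) -> (x, N-1-y)
        pm_rot = to_polar(make_image(rot), (20, 20), n_theta=n_theta, r_max=18)
        shifted = np.roll(pm.intensities, n_theta // 4, axis=1)
        np.testing.assert_allclose(pm_rot.intensities, shifted, atol=1e-6)

    def test_out_of_bounds_flagged(self):
        pm = to_polar(make_image(np.ones((21, 21))), (10, 10), n_theta=8, r_max=50)
        assert pm.out_of_bounds


# ---------------------------------------------------------------------------
# contour radii / thickness / boundary similarity
# ---------------------------------------------------------------------------

def circle_contour(cy, cx, r, n=400):
    th = np.linspace(0, 2 * np.pi, n)
    return np.column_stack([cy + r * np.sin(th), cx + r * np.cos(th)])


class TestContourRadii:
    def test_concentric_circles(self):
        radii = contour_radii(circle_contour(50, 50, 20), circle_contour(50, 50, 25),
                              (50, 50), 360)
        assert np.all(np.abs(radii.r_inner - 20) <= 0.5)
        assert np.all(np.abs(radii.r_outer - 25) <= 0.5)
        assert len(radii.theta_grid) == 360
        assert np.allclose(np.diff(radii.theta_grid), radii.theta_grid[1])

    def test_axis_aligned_ellipse(self):
        th = np.linspace(0, 2 * np.pi, 720)
        ellipse = np.column_stack([50 + 20 * np.sin(th), 50 + 30 * np.cos(th)])
        radii = contour_radii(circle_contour(50, 50, 5), ellipse, (50, 50), 360)
        assert abs(radii.r_outer[0] - 30) <= 0.5          # theta = 0
        assert abs(radii.r_outer[90] - 20) <= 0.5         # theta = pi/2


class TestThickness:
    def test_concentric_circles_mm(self):
        radii = contour_radii(circle_contour(50, 50, 20), circle_contour(50, 50, 25),
                              (50, 50), 360)
        assert abs(wall_thickness_feature(radii, 1.0) - 5.0) <= 0.5

    def test_identical_contours_zero(self):
        c = circle_contour(40, 40, 15)
        radii = contour_radii(c, c, (40, 40), 180)
        assert wall_thickness_feature(radii) <= 1e-9

    def test_sinusoidal_profile_mean(self):
        th = np.linspace(0, 2 * np.pi, 720)
        outer = np.column_stack([50 + (25 + 2 * np.sin(th)) * np.sin(th),
                                 50 + (25 + 2 * np.sin(th)) * np.cos(th)])
        radii = contour_radii(circle_contour(50, 50, 20), outer, (50, 50), 360)
        assert abs(wall_thickness_feature(radii, 1.0) - 5.0) <= 0.5

    def test_negative_thickness_error(self):
        radii = ContourRadii(theta_grid=np.linspace(0, 2 * np.pi, 8, endpoint=False),
                             r_inner=np.full(8, 10.0), r_outer=np.full(8, 9.0))
        with pytest.raises(ValueError, match="negative"):
            wall_thickness_feature(radii)


class TestBoundarySimilarity:
    def test_concentric_circles_all_five(self):
        th = np.linspace(0, 2 * np.pi, 360, endpoint=False)
        radii = ContourRadii(theta_grid=th, r_inner=np.full(360, 20.0),
                             r_outer=np.full(360, 25.0))
        f35, f36, f37, f38, f39 = boundary_similarity_features(radii)
        assert abs(f35 - 2 * np.pi * 5) <= 0.01
        assert f36 == 9000.0
        assert f37 == 1800.0
        assert f38 == 5.0
        assert f39 == 5.0

    def test_identical_curves_zero(self):
        th = np.linspace(0, 2 * np.pi, 360, endpoint=False)
        radii = ContourRadii(theta_grid=th, r_inner=np.full(360, 20.0),
                             r_outer=np.full(360, 20.0))
        assert np.all(boundary_similarity_features(radii) == 0.0)

    def test_abs_sine_profile(self):
        th = np.linspace(0, 2 * np.pi, 3600, endpoint=False)
        radii = ContourRadii(theta_grid=th, r_inner=np.full_like(th, 20.0),
                             r_outer=20.0 + np.abs(np.sin(th)))
        f = boundary_similarity_features(radii)
        assert abs(f[4] - 1.0) <= 0.01           # max distance
        assert abs(f[3] - 2 / np.pi) <= 0.01     # mean of |sin|


# ---------------------------------------------------------------------------
# extract_all
# ---------------------------------------------------------------------------

class TestExtractAll:
    def _region(self, sample):
        return WallRegion(image=sample.image, wall_mask=sample.wall_mask,
                          inner_contour=sample.inner_contour,
                          outer_contour=sample.outer_contour,
                          outer_mask=sample.outer_mask)

    def test_length_and_finiteness(self, noisy_phantom):
        vec = extract_all(self._region(noisy_phantom))
        assert vec.shape == (N_FEATURES,)
        assert np.all(np.isfinite(vec))

    def test_deterministic(self, noisy_phantom):
        region = self._region(noisy_phantom)
        np.testing.assert_array_equal(extract_all(region), extract_all(region))

    def test_thickness_feature_recovers_truth(self, clean_phantom):
        vec = extract_all(self._region(clean_phantom))
        assert abs(vec[34] - clean_phantom.spec.wall_thickness_mean) <= 1.0
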
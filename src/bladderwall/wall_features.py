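"""The 40-feature characterization vector of a segmented bladder wall.

Five families are concatenated in canonical order (see
``imaging.FEATURE_NAMES``):

* f0-f4   first-order histogram statistics of the wall pixels;
* f5-f24  twenty GLCM (Haralick/Soh/Clausi) texture statistics computed on
          a mask-restricted, symmetric, offset-accumulated co-occurrence
          matrix;
* f25-f33 nine shape/orientation descriptors of the outer mask;
* f34     mean wall thickness in mm, measured in polar coordinates as
          r_outer(theta) - r_inner(theta) around the bladder centroid;
* f35-f39 five similarity statistics between the inner and outer radius
          curves on a common angular grid.

All intensity features are computed from the original (non-denoised)
image; only the masks/contours come from the segmentation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import measure

from .imaging import GrayImage, N_FEATURES

__all__ = [
    "WallRegion",
    "FeatureConfig",
    "PolarMap",
    "ContourRadii",
    "histogram_features",
    "glcm_matrix",
    "glcm_features",
    "GLCM_FEATURE_ORDER",
    "shape_features",
    "to_polar",
    "contour_radii",
    "wall_thickness_feature",
    "thickness_extras",
    "boundary_similarity_features",
    "extract_all",
]

DEFAULT_OFFSETS: tuple[tuple[int, int], ...] = ((0, 1), (-1, 1), (-1, 0), (-1, -1))
"""Distance-1 offsets at 0, 45, 90 and 135 degrees."""


@dataclass(frozen=True)
class WallRegion:
    """Everything the extractor needs for one image."""

    image: GrayImage
    wall_mask: np.ndarray
    inner_contour: np.ndarray   # (N, 2) ordered (row, col)
    outer_contour: np.ndarray
    outer_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not np.asarray(self.wall_mask, dtype=bool).any():
            raise ValueError("wall mask is empty")

    @property
    def spacing(self) -> float:
        return float(np.mean(self.image.spacing))


@dataclass(frozen=True)
class FeatureConfig:
    glcm_levels: int = 32
    glcm_offsets: tuple[tuple[int, int], ...] = DEFAULT_OFFSETS
    n_theta: int = 360


# ---------------------------------------------------------------------------
# f0-f4: histogram features
# ---------------------------------------------------------------------------

def histogram_features(region: WallRegion) -> np.ndarray:
    """Mean, population variance, kurtosis, skewness and the area under the
    normalized cumulative 256-bin histogram of the wall pixels.

    Kurtosis is the raw fourth standardized moment (3 for a Gaussian);
    zero-variance regions report kurtosis = skewness = 0 by convention.
    """
    x = region.image.pixels[np.asarray(region.wall_mask, dtype=bool)].astype(np.float64)
    mean = float(x.mean())
    var = float(np.mean((x - mean) ** 2))
    if var > 0:
        kurt = float(np.mean((x - mean) ** 4) / var**2)
        skew = float(np.mean((x - mean) ** 3) / var**1.5)
    else:
        kurt = skew = 0.0
    counts, _ = np.histogram(np.clip(x, 0, 255), bins=256, range=(0, 256))
    cum = np.cumsum(counts) / x.size
    return np.array([mean, var, kurt, skew, float(cum.mean())])


# ---------------------------------------------------------------------------
# f5-f24: GLCM texture
# ---------------------------------------------------------------------------

def glcm_matrix(
    region: WallRegion,
    levels: int = 32,
    offsets: tuple[tuple[int, int], ...] = DEFAULT_OFFSETS,
) -> np.ndarray:
    """Mask-restricted symmetric co-occurrence matrix, normalized to sum 1.

    Intensities are quantized to ``levels`` equal bins over the wall's own
    min-max range; a pair is counted only when both pixels lie inside the
    wall mask, in both directions, accumulated over all offsets.
    """
    if levels < 2:
        raise ValueError("levels must be >= 2")
    mask = np.asarray(region.wall_mask, dtype=bool)
    px = region.image.pixels.astype(np.float64)
    vals = px[mask]
    lo, hi = float(vals.min()), float(vals.max())
    if hi > lo:
        q = np.minimum((px - lo) / (hi - lo) * levels, levels - 1).astype(np.int64)
        q = np.clip(q, 0, levels - 1)
    else:
        q = np.zeros_like(px, dtype=np.int64)

    counts = np.zeros((levels, levels), dtype=np.float64)
    rows, cols = mask.shape
    for dr, dc in offsets:
        r0s, r0e = max(0, -dr), min(rows, rows - dr)
        c0s, c0e = max(0, -dc), min(cols, cols - dc)
        a_mask = mask[r0s:r0e, c0s:c0e]
        b_mask = mask[r0s + dr:r0e + dr, c0s + dc:c0e + dc]
        both = a_mask & b_mask
        a = q[r0s:r0e, c0s:c0e][both]
        b = q[r0s + dr:r0e + dr, c0s + dc:c0e + dc][both]
        np.add.at(counts, (a, b), 1.0)
        np.add.at(counts, (b, a), 1.0)
    total = counts.sum()
    if total < 2:
        raise ValueError("wall region has too few co-occurring pixel pairs for texture")
    return counts / total


GLCM_FEATURE_ORDER: tuple[str, ...] = (
    "autocorrelation",
    "contrast",
    "correlation",
    "cluster_prominence",
    "cluster_shade",
    "dissimilarity",
    "energy",
    "entropy",
    "homogeneity",
    "max_probability",
    "variance",
    "sum_average",
    "sum_variance",
    "sum_entropy",
    "difference_variance",
    "difference_entropy",
    "imc1",
    "imc2",
    "inverse_difference_normalized",
    "inverse_difference_moment",
)


def glcm_stats(p: np.ndarray) -> dict[str, float]:
    """The 20 texture statistics of a normalized co-occurrence matrix.

    Standard Haralick/Soh/Clausi definitions with base-2 logarithms.
    Conventions for degenerate (single-entry) matrices: correlation = 1,
    IMC1 = 0, IMC2 = 0.
    """
    n = p.shape[0]
    i = np.arange(n, dtype=np.float64)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mu_x = float((i * px).sum())
    mu_y = float((i * py).sum())
    sd_x = math.sqrt(float(((i - mu_x) ** 2 * px).sum()))
    sd_y = math.sqrt(float(((i - mu_y) ** 2 * py).sum()))

    diff = np.abs(ii - jj)
    with np.errstate(divide="ignore", invalid="ignore"):
        logp = np.where(p > 0, np.log2(np.where(p > 0, p, 1.0)), 0.0)

    # sum / difference distributions p_{x+y}, p_{|x-y|}
    ks = np.arange(2 * n - 1, dtype=np.float64)
    p_sum = np.zeros(2 * n - 1)
    np.add.at(p_sum, (ii + jj).astype(int).ravel(), p.ravel())
    kd = np.arange(n, dtype=np.float64)
    p_diff = np.zeros(n)
    np.add.at(p_diff, diff.astype(int).ravel(), p.ravel())

    out: dict[str, float] = {}
    out["autocorrelation"] = float((ii * jj * p).sum())
    out["contrast"] = float(((ii - jj) ** 2 * p).sum())
    if sd_x > 0 and sd_y > 0:
        out["correlation"] = float(((ii - mu_x) * (jj - mu_y) * p).sum() / (sd_x * sd_y))
    else:
        out["correlation"] = 1.0
    out["cluster_prominence"] = float(((ii + jj - mu_x - mu_y) ** 4 * p).sum())
    out["cluster_shade"] = float(((ii + jj - mu_x - mu_y) ** 3 * p).sum())
    out["dissimilarity"] = float((diff * p).sum())
    out["energy"] = float((p**2).sum())
    hxy = float(-(p * logp).sum())
    out["entropy"] = hxy
    out["homogeneity"] = float((p / (1.0 + diff)).sum())
    out["max_probability"] = float(p.max())
    out["variance"] = float(((ii - mu_x) ** 2 * p).sum())
    sum_avg = float((ks * p_sum).sum())
    out["sum_average"] = sum_avg
    out["sum_variance"] = float(((ks - sum_avg) ** 2 * p_sum).sum())
    out["sum_entropy"] = float(-(p_sum[p_sum > 0] * np.log2(p_sum[p_sum > 0])).sum())
    mu_d = float((kd * p_diff).sum())
    out["difference_variance"] = float(((kd - mu_d) ** 2 * p_diff).sum())
    out["difference_entropy"] = float(-(p_diff[p_diff > 0] * np.log2(p_diff[p_diff > 0])).sum())

    hx = float(-(px[px > 0] * np.log2(px[px > 0])).sum())
    hy = float(-(py[py > 0] * np.log2(py[py > 0])).sum())
    pxy_outer = np.outer(px, py)
    valid = (p > 0) & (pxy_outer > 0)
    hxy1 = float(-(p[valid] * np.log2(pxy_outer[valid])).sum())
    valid2 = pxy_outer > 0
    hxy2 = float(-(pxy_outer[valid2] * np.log2(pxy_outer[valid2])).sum())
    denom = max(hx, hy)
    out["imc1"] = float((hxy - hxy1) / denom) if denom > 0 else 0.0
    arg = 1.0 - 2.0 ** (-2.0 * (hxy2 - hxy))
    out["imc2"] = float(math.sqrt(max(arg, 0.0)))
    out["inverse_difference_normalized"] = float((p / (1.0 + diff / n)).sum())
    out["inverse_difference_moment"] = float((p / (1.0 + diff**2)).sum())
    return out


def glcm_features(region: WallRegion, cfg: FeatureConfig = FeatureConfig()) -> np.ndarray:
    p = glcm_matrix(region, cfg.glcm_levels, cfg.glcm_offsets)
    stats = glcm_stats(p)
    return np.array([stats[name] for name in GLCM_FEATURE_ORDER])


# ---------------------------------------------------------------------------
# f25-f33: shape and orientation of the outer mask
# ---------------------------------------------------------------------------

def shape_features(outer_mask: np.ndarray, spacing: float = 1.0) -> np.ndarray:
    """Nine morphological descriptors of the (single-component) outer mask.

    area (mm^2), perimeter (mm), circularity 4*pi*A/P^2, eccentricity,
    solidity, roundness 4A/(pi*major^2), axis ratio minor/major,
    orientation of the major axis from the +x (column) axis in
    (-pi/2, pi/2], equivalent diameter (mm).
    """
    mask = np.asarray(outer_mask, dtype=bool)
    _, n_comp = ndimage.label(mask)
    if n_comp != 1:
        raise ValueError(f"outer mask must be a single connected component (found {n_comp})")
    props = measure.regionprops(mask.astype(np.uint8))[0]
    area_px = float(props.area)
    perim_px = float(props.perimeter)
    area = area_px * spacing**2
    perimeter = perim_px * spacing
    circularity = 4 * math.pi * area_px / perim_px**2 if perim_px > 0 else 0.0
    # solidity from the convex hull of pixel centers (the rasterized convex
    # image overestimates the hull area for small near-convex shapes)
    pts = np.column_stack(np.nonzero(mask)).astype(float)
    try:
        from scipy.spatial import ConvexHull

        hull_area = ConvexHull(pts).volume
        solidity = min(1.0, area_px / hull_area) if hull_area > 0 else 1.0
    except Exception:
        solidity = float(props.solidity)
    major = float(props.axis_major_length)
    minor = float(props.axis_minor_length)
    roundness = 4 * area_px / (math.pi * major**2) if major > 0 else 0.0
    axis_ratio = minor / major if major > 0 else 1.0
    # orientation from central moments, measured from the column (x) axis
    mu = measure.moments_central(mask.astype(np.float64))
    mu20 = mu[0, 2]  # variance along columns (x)
    mu02 = mu[2, 0]
    mu11 = -mu[1, 1]  # row axis points down; flip to y-up convention
    theta = 0.5 * math.atan2(2 * mu11, mu20 - mu02)
    if theta <= -math.pi / 2:
        theta += math.pi
    elif theta > math.pi / 2:
        theta -= math.pi
    equiv_diam = math.sqrt(4 * area_px / math.pi) * spacing
    return np.array([
        area, perimeter, circularity, float(props.eccentricity),
        solidity, roundness, axis_ratio, theta, equiv_diam,
    ])


# ---------------------------------------------------------------------------
# polar representation, f34 thickness, f35-f39 boundary similarity
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PolarMap:
    center: tuple[float, float]      # (Cx, Cy) = (col, row)
    theta_grid: np.ndarray
    r_grid: np.ndarray
    intensities: np.ndarray          # shape (len(r_grid), len(theta_grid))
    out_of_bounds: bool = False


def to_polar(image: GrayImage, center: tuple[float, float], n_theta: int = 360,
             r_max: float | None = None) -> PolarMap:
    """Resample the image onto a polar grid around ``center`` = (Cx, Cy).

    ``Ip(r, theta) = I(Cx + r cos theta, Cy + r sin theta)`` by bilinear
    interpolation; samples falling outside the image are filled with 0 and
    flagged via ``out_of_bounds``.
    """
    rows, cols = image.shape
    cx, cy = center
    if not (0 <= cx <= cols - 1 and 0 <= cy <= rows - 1):
        raise ValueError(f"center {center} outside image of shape {image.shape}")
    if r_max is None:
        r_max = float(min(cx, cols - 1 - cx, cy, rows - 1 - cy))
    theta = np.linspace(0.0, 2 * np.pi, n_theta, endpoint=False)
    r = np.arange(0.0, float(r_max) + 1.0)
    rr, tt = np.meshgrid(r, theta, indexing="ij")
    x = cx + rr * np.cos(tt)
    y = cy + rr * np.sin(tt)
    oob = bool((x < 0).any() or (x > cols - 1).any() or (y < 0).any() or (y > rows - 1).any())
    vals = ndimage.map_coordinates(
        image.pixels.astype(np.float64), [y.ravel(), x.ravel()],
        order=1, mode="constant", cval=0.0,
    ).reshape(rr.shape)
    return PolarMap(center=(float(cx), float(cy)), theta_grid=theta, r_grid=r,
                    intensities=vals, out_of_bounds=oob)


@dataclass(frozen=True)
class ContourRadii:
    theta_grid: np.ndarray
    r_inner: np.ndarray
    r_outer: np.ndarray
    n_multivalued: int = 0   # angles with multiple radial crossings


def _radii_by_ray(contour: np.ndarray, center: tuple[float, float],
                  theta: np.ndarray, take: str) -> tuple[np.ndarray, int]:
    """Radial distance to a closed contour along each ray from ``center``.

    Intersects every ray with every contour segment; non-star-shaped
    contours yield several crossings per angle — ``take`` picks the
    outermost ('max') or innermost ('min') and the extra crossings are
    counted.
    """
    cy, cx = center
    pts = np.asarray(contour, dtype=np.float64)
    if not np.allclose(pts[0], pts[-1]):
        pts = np.vstack([pts, pts[0]])
    # segment endpoints relative to center, in (x, y)
    p = np.column_stack([pts[:-1, 1] - cx, pts[:-1, 0] - cy])
    q = np.column_stack([pts[1:, 1] - cx, pts[1:, 0] - cy])
    d = q - p
    radii = np.empty(len(theta))
    extra = 0
    for k, th in enumerate(theta):
        ux, uy = math.cos(th), math.sin(th)
        # solve p + t d = s (ux, uy): cross products give t and s
        denom = d[:, 0] * uy - d[:, 1] * ux
        with np.errstate(divide="ignore", invalid="ignore"):
            t = (p[:, 1] * ux - p[:, 0] * uy) / denom
            s = np.where(np.abs(ux) > np.abs(uy),
                         (p[:, 0] + t * d[:, 0]) / ux,
                         (p[:, 1] + t * d[:, 1]) / uy)
        hit = (np.abs(denom) > 1e-12) & (t >= 0) & (t < 1) & (s > 0)
        ss = s[hit]
        if ss.size == 0:
            radii[k] = np.nan
            continue
        if ss.size > 1:
            extra += 1
        radii[k] = ss.max() if take == "max" else ss.min()
    # fill rare misses by periodic interpolation over valid neighbours
    if np.isnan(radii).any():
        good = ~np.isnan(radii)
        if not good.any():
            raise ValueError("contour does not enclose the center")
        radii = np.interp(theta, theta[good], radii[good], period=2 * np.pi)
    return radii, extra


def contour_radii(inner_contour: np.ndarray, outer_contour: np.ndarray,
                  center: tuple[float, float], n_theta: int = 360) -> ContourRadii:
    """Both contours as r(theta) on a common uniform angular grid.

    ``center`` is (row, col) — normally the centroid of the region the
    outer contour encloses.  For non-star-shaped contours the outermost
    crossing is kept for the outer curve and the innermost for the inner
    curve, with the number of multivalued angles recorded.
    """
    theta = np.linspace(0.0, 2 * np.pi, n_theta, endpoint=False)
    r_in, extra_in = _radii_by_ray(inner_contour, center, theta, take="min")
    r_out, extra_out = _radii_by_ray(outer_contour, center, theta, take="max")
    return ContourRadii(theta_grid=theta, r_inner=r_in, r_outer=r_out,
                        n_multivalued=extra_in + extra_out)


def wall_thickness_feature(radii: ContourRadii, spacing: float = 1.0) -> float:
    """f34: mean of (r_outer - r_inner) over theta, scaled to mm."""
    d = radii.r_outer - radii.r_inner
    if (d < 0).any():
        raise ValueError("negative pointwise wall thickness: outer contour inside inner")
    return float(d.mean() * spacing)


def thickness_extras(radii: ContourRadii, spacing: float = 1.0) -> dict[str, float]:
    """Non-canonical extras: min/max/SD of the thickness profile (mm)."""
    d = (radii.r_outer - radii.r_inner) * spacing
    return {"min": float(d.min()), "max": float(d.max()), "sd": float(d.std())}


def boundary_similarity_features(radii: ContourRadii) -> np.ndarray:
    """f35-f39 from d(theta) = r_outer - r_inner on the common grid.

    f35 |trapezoidal area difference over the full period|, f36 sum of
    squared differences, f37 sum of absolute differences, f38 mean
    absolute difference, f39 maximum absolute difference.
    """
    th = np.append(radii.theta_grid, 2 * np.pi)
    r_out = np.append(radii.r_outer, radii.r_outer[0])
    r_in = np.append(radii.r_inner, radii.r_inner[0])
    f35 = abs(float(np.trapezoid(r_out, th) - np.trapezoid(r_in, th)))
    d = np.abs(radii.r_outer - radii.r_inner)
    return np.array([f35, float((d**2).sum()), float(d.sum()), float(d.mean()), float(d.max())])


def extract_all(region: WallRegion, cfg: FeatureConfig = FeatureConfig()) -> np.ndarray:
    """Concatenate all five families into the canonical 40-vector."""
    outer_mask = region.outer_mask
    if outer_mask is None:
        raise ValueError("shape features require the outer mask")
    try:
        hist = histogram_features(region)
    except Exception as exc:
        raise RuntimeError(f"histogram features failed: {exc}") from exc
    try:
        glcm = glcm_features(region, cfg)
    except Exception as exc:
        raise RuntimeError(f"GLCM features failed: {exc}") from exc
    try:
        shape = shape_features(outer_mask, region.spacing)
    except Exception as exc:
        raise RuntimeError(f"shape features failed: {exc}") from exc
    try:
        cy, cx = ndimage.center_of_mass(np.asarray(outer_mask, dtype=float))
        radii = contour_radii(region.inner_contour, region.outer_contour, (cy, cx), cfg.n_theta)
        thickness = wall_thickness_feature(radii, region.spacing)
        boundary = boundary_similarity_features(radii)
    except Exception as exc:
        raise RuntimeError(f"polar/boundary features failed: {exc}") from exc
    vec = np.concatenate([hist, glcm, shape, [thickness], boundary])
    assert vec.size == N_FEATURES
    if not np.all(np.isfinite(vec)):
        bad = int(np.flatnonzero(~np.isfinite(vec))[0])
        raise RuntimeError(f"non-finite feature f{bad}")
    return vec
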
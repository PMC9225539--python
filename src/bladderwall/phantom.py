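"""Synthetic bladder-slice phantoms with exact ground truth.

A phantom emulates a T2-weighted sagittal slice through a filled bladder:
a bright urine lumen, a dark muscular wall ring of controllable thickness,
irregularity and diverticula, and a bright peri-vesical surround, plus
additive Gaussian noise.  Exact inner/outer masks and contours are produced
alongside, so segmentation and feature recovery can be scored against a
known truth.

The wall is defined in polar coordinates around the phantom centre:

    r_inner(theta) = base_inner_radius
    r_outer(theta) = r_inner(theta) + t(theta)
    t(theta) = mean + sd * smooth_noise(theta) + diverticulum bumps

``smooth_noise`` is a low-order random Fourier series (unit RMS), so the
thickness varies smoothly around the ring; diverticula are Gaussian bumps
in theta whose amplitude always exceeds ``irregularity_amplitude`` so they
are countable as distinct outpouchings.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from skimage import measure

from .imaging import GrayImage

__all__ = ["PhantomSpec", "PhantomSample", "generate_phantom", "generate_cohort"]

_SMOOTH_HARMONICS = (2, 3, 4, 5)  # low-order ripple of the thickness profile
_DIVERTICULUM_WIDTH_RAD = 0.22    # angular sigma of a diverticulum bump


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, contrast and noise of one synthetic bladder slice.

    Intensities follow the T2 ordering: lumen (urine) and surround
    (peri-vesical fat) bright, wall (detrusor) dark.
    """

    image_size: int = 128
    pixel_spacing: float = 1.0            # mm / px, isotropic
    center: tuple[float, float] | None = None   # (row, col); default = centre
    base_inner_radius: float = 22.0       # px
    wall_thickness_mean: float = 5.0      # px
    wall_thickness_sd: float = 0.0        # px, RMS of the smooth ripple
    irregularity_amplitude: float = 0.0   # px, extra radial perturbation
    n_diverticula: int = 0
    lumen_intensity: float = 220.0
    wall_intensity: float = 60.0
    surround_intensity: float = 170.0
    noise_sigma: float = 0.0              # gray levels
    label: int = 0                        # 0 = non-severe, 1 = severe
    seed: int = 0

    def __post_init__(self) -> None:
        if self.wall_thickness_mean < 1:
            raise ValueError("wall_thickness_mean must be >= 1 px")
        if not (self.lumen_intensity > self.wall_intensity):
            raise ValueError("T2 contrast requires lumen brighter than wall")
        if not (self.surround_intensity > self.wall_intensity):
            raise ValueError("T2 contrast requires surround brighter than wall")
        for name in ("lumen_intensity", "wall_intensity", "surround_intensity"):
            v = getattr(self, name)
            if not (0 <= v <= 255):
                raise ValueError(f"{name}={v} outside [0, 255]")
        if self.base_inner_radius <= 0:
            raise ValueError("base_inner_radius must be positive")
        if self.n_diverticula < 0:
            raise ValueError("n_diverticula must be >= 0")


@dataclass(frozen=True)
class PhantomSample:
    """A rendered phantom with its exact ground truth."""

    image: GrayImage
    inner_mask: np.ndarray
    outer_mask: np.ndarray
    inner_contour: np.ndarray   # (N, 2) ordered (row, col) points
    outer_contour: np.ndarray
    label: int
    spec: PhantomSpec
    thickness_profile: np.ndarray = field(repr=False, default=None)  # t(theta) on theta_grid
    theta_grid: np.ndarray = field(repr=False, default=None)

    @property
    def wall_mask(self) -> np.ndarray:
        return self.outer_mask & ~self.inner_mask


def _diverticulum_amplitude(spec: PhantomSpec) -> float:
    # must clear the smooth-ripple + irregularity band so bumps are countable
    return spec.irregularity_amplitude + 2.0 * spec.wall_thickness_sd + 3.0


def _thickness_profile(spec: PhantomSpec, theta: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Evaluate t(theta); consumes a fixed number of draws for determinism."""
    t = np.full_like(theta, float(spec.wall_thickness_mean))
    amps = rng.standard_normal(len(_SMOOTH_HARMONICS))
    phases = rng.uniform(0, 2 * np.pi, len(_SMOOTH_HARMONICS))
    if spec.wall_thickness_sd > 0 or spec.irregularity_amplitude > 0:
        ripple = np.zeros_like(theta)
        for a, ph, k in zip(amps, phases, _SMOOTH_HARMONICS):
            ripple += a * np.cos(k * theta + ph)
        rms = np.sqrt(np.mean(ripple**2)) or 1.0
        ripple /= rms
        t = t + (spec.wall_thickness_sd + spec.irregularity_amplitude) * ripple
    if spec.n_diverticula:
        # spread bump centres apart so each stays a distinct local maximum
        centers = (np.arange(spec.n_diverticula) * 2 * np.pi / spec.n_diverticula
                   + rng.uniform(0, 2 * np.pi / (2 * spec.n_diverticula), spec.n_diverticula))
        amp = _diverticulum_amplitude(spec)
        for c in centers:
            d = np.angle(np.exp(1j * (theta - c)))  # wrapped angular distance
            t = t + amp * np.exp(-0.5 * (d / _DIVERTICULUM_WIDTH_RAD) ** 2)
    return np.maximum(t, 1.0)


def generate_phantom(spec: PhantomSpec) -> PhantomSample:
    """Render one phantom slice; deterministic for a fixed ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    n = spec.image_size
    center = spec.center or ((n - 1) / 2.0, (n - 1) / 2.0)
    cy, cx = center

    theta_grid = np.linspace(0.0, 2 * np.pi, 720, endpoint=False)
    t_profile = _thickness_profile(spec, theta_grid, rng)
    r_inner_g = np.full_like(theta_grid, spec.base_inner_radius)
    r_outer_g = r_inner_g + t_profile

    r_out_max = float(r_outer_g.max())
    if (cy - r_out_max < 1 or cx - r_out_max < 1
            or cy + r_out_max > n - 2 or cx + r_out_max > n - 2):
        raise ValueError(
            f"outer contour (max radius {r_out_max:.1f} px) exceeds image bounds "
            f"for image_size={n}; enlarge the image or shrink the bladder"
        )

    rows, cols = np.mgrid[0:n, 0:n]
    dy = rows - cy
    dx = cols - cx
    r = np.hypot(dx, dy)
    theta = np.mod(np.arctan2(dy, dx), 2 * np.pi)

    # per-pixel outer radius by periodic linear interpolation of t(theta)
    t_pix = np.interp(theta, theta_grid, t_profile, period=2 * np.pi)
    inner_mask = r <= spec.base_inner_radius
    outer_mask = r <= spec.base_inner_radius + t_pix

    image = np.full((n, n), spec.surround_intensity, dtype=np.float64)
    image[outer_mask] = spec.wall_intensity
    image[inner_mask] = spec.lumen_intensity
    if spec.noise_sigma > 0:
        image = image + rng.normal(0.0, spec.noise_sigma, image.shape)
        image = np.clip(image, 0.0, 255.0)

    inner_contour = _largest_contour(inner_mask)
    outer_contour = _largest_contour(outer_mask)
    return PhantomSample(
        image=GrayImage(image, (spec.pixel_spacing, spec.pixel_spacing)),
        inner_mask=inner_mask,
        outer_mask=outer_mask,
        inner_contour=inner_contour,
        outer_contour=outer_contour,
        label=spec.label,
        spec=spec,
        thickness_profile=t_profile,
        theta_grid=theta_grid,
    )


def _largest_contour(mask: np.ndarray) -> np.ndarray:
    contours = measure.find_contours(mask.astype(float), 0.5)
    if not contours:
        raise ValueError("mask has no contour")
    return max(contours, key=len)


def generate_cohort(
    n_per_class: int,
    spec_class0: PhantomSpec,
    spec_class1: PhantomSpec,
    seed: int = 0,
) -> list[PhantomSample]:
    """Generate a balanced two-class cohort of ``2 * n_per_class`` phantoms.

    Per-sample seeds are spawned reproducibly from the master ``seed``; the
    class templates fix everything except the random ripple/diverticulum
    placement and the noise realization.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(2 * n_per_class)]
    samples: list[PhantomSample] = []
    for i in range(n_per_class):
        samples.append(generate_phantom(replace(spec_class0, label=0, seed=child_seeds[2 * i])))
        samples.append(generate_phantom(replace(spec_class1, label=1, seed=child_seeds[2 * i + 1])))
    return samples
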
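"""Image and table I/O for the bladder-wall pipeline.

Clinical slices arrive as single-frame grayscale DICOM carrying the pixel
spacing in its tags; synthetic phantoms and intermediate masks travel as
8-bit PNG (or TIFF) with the spacing supplied alongside.  Feature tables are
plain CSV with a fixed 42-column schema (``id``, ``f0`` … ``f39``,
``label``) so that every downstream stage can rely on one canonical feature
ordering.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image as PILImage

__all__ = [
    "GrayImage",
    "FEATURE_NAMES",
    "N_FEATURES",
    "read_image",
    "write_image",
    "write_mask",
    "read_mask",
    "write_contour",
    "read_contour",
    "write_feature_table",
    "read_feature_table",
    "feature_table",
]


@dataclass(frozen=True)
class GrayImage:
    """A 2-D grayscale slice with physical pixel spacing.

    Parameters
    ----------
    pixels : ndarray, shape (rows, cols)
        Scalar intensities (float or integer); must be finite.
    spacing : tuple of float
        ``(row_mm, col_mm)`` physical size of one pixel in millimetres.
    """

    pixels: np.ndarray
    spacing: tuple[float, float] = (1.0, 1.0)

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValueError(f"expected a 2-D image, got shape {px.shape}")
        if not np.all(np.isfinite(px)):
            raise ValueError("image contains non-finite pixel values")
        if not (self.spacing[0] > 0 and self.spacing[1] > 0):
            raise ValueError(f"pixel spacing must be positive, got {self.spacing}")
        object.__setattr__(self, "pixels", px)
        object.__setattr__(self, "spacing", (float(self.spacing[0]), float(self.spacing[1])))

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


# Canonical feature catalog: the 40-entry vector every extractor emits, in
# fixed order.  Families: f0-f4 first-order histogram, f5-f24 GLCM texture,
# f25-f33 shape/orientation of the outer mask, f34 polar wall thickness,
# f35-f39 inner/outer boundary similarity.  The membership of the GLCM and
# shape blocks is this package's own catalog (documented in docs/methods.md).
FEATURE_NAMES: tuple[str, ...] = (
    # f0-f4: histogram
    "hist_mean",
    "hist_variance",
    "hist_kurtosis",
    "hist_skewness",
    "hist_cum_area",
    # f5-f24: GLCM texture
    "glcm_autocorrelation",
    "glcm_contrast",
    "glcm_correlation",
    "glcm_cluster_prominence",
    "glcm_cluster_shade",
    "glcm_dissimilarity",
    "glcm_energy",
    "glcm_entropy",
    "glcm_homogeneity",
    "glcm_max_probability",
    "glcm_variance",
    "glcm_sum_average",
    "glcm_sum_variance",
    "glcm_sum_entropy",
    "glcm_difference_variance",
    "glcm_difference_entropy",
    "glcm_imc1",
    "glcm_imc2",
    "glcm_inverse_difference_normalized",
    "glcm_inverse_difference_moment",
    # f25-f33: shape/orientation
    "shape_area_mm2",
    "shape_perimeter_mm",
    "shape_circularity",
    "shape_eccentricity",
    "shape_solidity",
    "shape_roundness",
    "shape_axis_ratio",
    "shape_orientation_rad",
    "shape_equivalent_diameter_mm",
    # f34: polar wall thickness
    "wall_thickness_mean_mm",
    # f35-f39: boundary similarity
    "boundary_area_difference",
    "boundary_sum_squared_difference",
    "boundary_sum_absolute_difference",
    "boundary_mean_distance",
    "boundary_max_distance",
)
N_FEATURES = len(FEATURE_NAMES)
assert N_FEATURES == 40

_FEATURE_COLUMNS = [f"f{i}" for i in range(N_FEATURES)]
_TABLE_COLUMNS = ["id", *_FEATURE_COLUMNS, "label"]


def read_image(path: str | Path, spacing_override: tuple[float, float] | None = None) -> GrayImage:
    """Read a single-frame grayscale image from DICOM, PNG or TIFF.

    For DICOM, the pixel spacing is taken from the ``PixelSpacing`` (or
    ``ImagerPixelSpacing``) tag; `spacing_override` wins when given.  For
    PNG/TIFF an override (or JSON sidecar written by :func:`write_image`)
    is required, else spacing defaults to 1 mm with a configuration error
    when strictness matters upstream.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    suffix = path.suffix.lower()
    if suffix in {".dcm", ".dicom", ""}:
        return _read_dicom(path, spacing_override)
    return _read_raster(path, spacing_override)


def _read_dicom(path: Path, spacing_override) -> GrayImage:
    import pydicom

    ds = pydicom.dcmread(str(path))
    if int(getattr(ds, "NumberOfFrames", 1) or 1) > 1:
        raise ValueError(f"{path}: multi-frame DICOM is not supported")
    if int(getattr(ds, "SamplesPerPixel", 1) or 1) != 1:
        raise ValueError(f"{path}: color DICOM is not supported")
    pixels = ds.pixel_array.astype(np.float64)
    if pixels.ndim != 2:
        raise ValueError(f"{path}: expected a single 2-D frame, got shape {pixels.shape}")
    if spacing_override is not None:
        spacing = (float(spacing_override[0]), float(spacing_override[1]))
    else:
        tag = getattr(ds, "PixelSpacing", None) or getattr(ds, "ImagerPixelSpacing", None)
        if tag is None:
            raise ValueError(f"{path}: no pixel-spacing tag and no spacing override given")
        spacing = (float(tag[0]), float(tag[1]))
    return GrayImage(pixels, spacing)


def _read_raster(path: Path, spacing_override) -> GrayImage:
    with PILImage.open(path) as im:
        if im.mode not in {"L", "I", "I;16", "F"}:
            if im.mode in {"RGB", "RGBA", "P"}:
                raise ValueError(f"{path}: color input is not supported (mode {im.mode})")
            im = im.convert("F")
        pixels = np.asarray(im, dtype=np.float64)
    spacing = spacing_override
    if spacing is None:
        sidecar = path.with_suffix(path.suffix + ".json")
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
            spacing = tuple(meta.get("spacing_mm", (1.0, 1.0)))
        else:
            spacing = (1.0, 1.0)
    return GrayImage(pixels, (float(spacing[0]), float(spacing[1])))


def write_image(image: GrayImage, path: str | Path, sidecar: bool = True) -> Path:
    """Write an 8-bit PNG (values clipped/rounded to [0, 255]) plus a JSON
    sidecar carrying the pixel spacing."""
    path = Path(path)
    arr = np.clip(np.rint(image.pixels), 0, 255).astype(np.uint8)
    PILImage.fromarray(arr, mode="L").save(path)
    if sidecar:
        meta = {"spacing_mm": list(image.spacing)}
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps(meta, sort_keys=True) + "\n"
        )
    return path


def write_mask(mask: np.ndarray, path: str | Path) -> Path:
    """Write a binary mask as an 8-bit PNG (foreground 255)."""
    path = Path(path)
    arr = np.where(np.asarray(mask, dtype=bool), 255, 0).astype(np.uint8)
    PILImage.fromarray(arr, mode="L").save(path)
    return path


def read_mask(path: str | Path) -> np.ndarray:
    with PILImage.open(path) as im:
        return np.asarray(im) > 127


def write_contour(contour: np.ndarray, path: str | Path) -> Path:
    """Write an ordered contour as a two-column CSV ``x,y`` (x = column)."""
    path = Path(path)
    pts = np.asarray(contour, dtype=float)
    with open(path, "w") as fh:
        fh.write("x,y\n")
        for row, col in pts:
            fh.write(f"{col!r},{row!r}\n")
    return path


def read_contour(path: str | Path) -> np.ndarray:
    df = pd.read_csv(path)
    return np.column_stack([df["y"].to_numpy(float), df["x"].to_numpy(float)])


def feature_table(ids, vectors, labels) -> pd.DataFrame:
    """Assemble a canonical feature table from per-image 40-vectors."""
    rows = []
    for i, vec, lab in zip(ids, vectors, labels, strict=True):
        vals = np.asarray(vec, dtype=float).ravel()
        if vals.size != N_FEATURES:
            raise ValueError(f"row {i!r}: expected {N_FEATURES} features, got {vals.size}")
        rows.append([i, *vals, int(lab)])
    return pd.DataFrame(rows, columns=_TABLE_COLUMNS)


def write_feature_table(table: pd.DataFrame, path: str | Path) -> Path:
    """Write a feature table as CSV with shortest-round-trip float text."""
    _validate_table(table)
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(",".join(_TABLE_COLUMNS) + "\n")
        for _, row in table.iterrows():
            cells = [str(row["id"])]
            cells += [repr(float(row[c])) for c in _FEATURE_COLUMNS]
            cells.append(str(int(row["label"])))
            fh.write(",".join(cells) + "\n")
    return path


def read_feature_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    _validate_table(df)
    return df[_TABLE_COLUMNS]


def _validate_table(df: pd.DataFrame) -> None:
    missing = [c for c in _TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"feature table is missing column(s): {', '.join(missing)}")
    extra = [c for c in df.columns if c not in _TABLE_COLUMNS]
    if extra:
        raise ValueError(f"feature table has unexpected column(s): {', '.join(extra)}")
    feats = df[_FEATURE_COLUMNS]
    if feats.isna().any().any():
        bad = [c for c in _FEATURE_COLUMNS if feats[c].isna().any()]
        raise ValueError(f"feature table has missing values in: {', '.join(bad)}")
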
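"""Calibrated image, mask and centroid I/O.

Every reader/writer in the package shares one coordinate convention:
physical micrometres, origin at the centre of the top-left pixel, x rightward
(columns), y downward (rows). Pixel index (col, row) maps to
(col * pixel_size, row * pixel_size) um. Anatomical orientation (which way is
dorsal) is carried in sidecar JSON metadata, never inferred from pixels.

Formats: single-channel 8/16-bit TIFF or PNG for images, 0/255 8-bit TIFF/PNG
for masks, CSV with columns ``id, x_um, y_um`` for centroid tables, JSON for
sidecar metadata.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import tifffile
from skimage import io as _skio

__all__ = [
    "CalibratedImage",
    "CentroidSet",
    "FormatError",
    "CalibrationError",
    "SchemaError",
    "read_image",
    "write_image",
    "read_mask_image",
    "write_mask_image",
    "read_centroids",
    "write_centroids",
    "read_sidecar",
    "write_sidecar",
]


class FormatError(ValueError):
    """Input file has an unsupported layout (e.g. multi-channel image)."""


class CalibrationError(ValueError):
    """Physical pixel size missing or unusable."""


class SchemaError(ValueError):
    """Tabular input is missing required columns."""


@dataclass(frozen=True)
class CalibratedImage:
    """2-D intensity grid with a physical pixel size in um/pixel."""

    pixels: np.ndarray
    pixel_size: float

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise FormatError(f"expected a 2-D single-channel image, got shape {px.shape}")
        if not (self.pixel_size > 0):
            raise CalibrationError(f"pixel_size must be > 0, got {self.pixel_size}")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self):
        return self.pixels.shape

    @property
    def extent_um(self):
        """(width_um, height_um) spanned by pixel centres plus one pixel."""
        h, w = self.pixels.shape
        return (w * self.pixel_size, h * self.pixel_size)


@dataclass(frozen=True)
class CentroidSet:
    """Cell positions in physical um with provenance.

    ``label`` records where the points came from: generator ground truth
    (``truth``), the detector (``detected``) or an emulated human annotator
    (``counter_A``/``counter_B``).
    """

    x: np.ndarray
    y: np.ndarray
    label: str = "detected"
    source_id: str = ""
    ids: Optional[np.ndarray] = None
    extra: Optional[pd.DataFrame] = None

    _LABELS = ("truth", "detected", "counter_A", "counter_B")

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float).ravel()
        y = np.asarray(self.y, dtype=float).ravel()
        if x.shape != y.shape:
            raise ValueError("x and y must have equal length")
        if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
            raise ValueError("centroid coordinates must be finite")
        if self.label not in self._LABELS:
            raise ValueError(f"label must be one of {self._LABELS}")
        ids = self.ids
        if ids is None:
            ids = np.arange(x.size)
        else:
            ids = np.asarray(ids).ravel()
            if ids.shape != x.shape:
                raise ValueError("ids must match coordinate length")
            if len(np.unique(ids)) != ids.size:
                raise ValueError("centroid ids must be unique")
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)
        object.__setattr__(self, "ids", ids)

    def __len__(self) -> int:
        return int(self.x.size)

    @property
    def points(self) -> np.ndarray:
        """(n, 2) array of (x, y) in um."""
        return np.column_stack([self.x, self.y])

    def with_label(self, label: str, source_id: Optional[str] = None) -> "CentroidSet":
        return replace(
            self, label=label, source_id=self.source_id if source_id is None else source_id
        )


def _as_single_channel(arr: np.ndarray, path) -> np.ndarray:
    arr = np.squeeze(arr)
    if arr.ndim != 2:
        raise FormatError(
            f"{path}: expected single-channel 2-D image, got shape {arr.shape}"
        )
    return arr


def _tiff_pixel_size(path: Path) -> Optional[float]:
    """Pixel size in um/px from TIFF resolution tags or ImageJ metadata."""
    with tifffile.TiffFile(str(path)) as tf:
        page = tf.pages[0]
        tags = page.tags
        if "XResolution" in tags:
            num, den = tags["XResolution"].value
            unit = tags.get("ResolutionUnit")
            unit = getattr(unit, "value", None) if unit is not None else None
            unit = getattr(unit, "value", unit)  # enum -> int
            if num > 0 and den > 0:
                px_per_unit = num / den
                if unit == 3:  # centimetre
                    return 1e4 / px_per_unit
                if unit == 2:  # inch
                    return 25400.0 / px_per_unit
                # unit "none": conventionally px per um in this package
                return 1.0 / px_per_unit
        ij = tf.imagej_metadata
        if ij and "spacing" in ij and ij.get("unit") in ("um", "micron", "µm"):
            return float(ij["spacing"])
    return None


def read_image(path, pixel_size_override: Optional[float] = None) -> CalibratedImage:
    """Read a single-channel TIFF/PNG as a :class:`CalibratedImage`.

    Pixel size comes from TIFF resolution metadata unless
    ``pixel_size_override`` (um/pixel) is given; a file with neither raises
    :class:`CalibrationError`. Multi-channel images are rejected.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        arr = tifffile.imread(str(path))
        meta_px = _tiff_pixel_size(path)
    elif suffix == ".png":
        arr = _skio.imread(str(path))
        meta_px = None
    else:
        raise FormatError(f"unsupported image format: {path.name}")
    arr = _as_single_channel(arr, path)
    pixel_size = pixel_size_override if pixel_size_override is not None else meta_px
    if pixel_size is None:
        raise CalibrationError(
            f"{path}: no pixel size in metadata and no override supplied"
        )
    return CalibratedImage(pixels=arr, pixel_size=float(pixel_size))


def write_image(image: CalibratedImage, path) -> Path:
    """Write a calibrated image as TIFF with resolution metadata (px/cm)."""
    path = Path(path)
    px_per_cm = 1e4 / image.pixel_size
    tifffile.imwrite(
        str(path),
        np.asarray(image.pixels),
        resolution=(px_per_cm, px_per_cm),
        resolutionunit="CENTIMETER",
    )
    return path


def write_mask_image(mask: np.ndarray, pixel_size: float, path) -> Path:
    """Write a boolean mask as 0/255 8-bit TIFF with calibration metadata."""
    arr = (np.asarray(mask, dtype=bool) * np.uint8(255))
    return write_image(CalibratedImage(arr, pixel_size), path)


def read_mask_image(path, pixel_size_override: Optional[float] = None):
    """Read a mask image; any nonzero pixel is foreground.

    Returns ``(boolean array, pixel_size)``.
    """
    img = read_image(path, pixel_size_override)
    return np.asarray(img.pixels) != 0, img.pixel_size


_REQUIRED_COLS = ("id", "x_um", "y_um")


def read_centroids(path, label: str = "detected") -> CentroidSet:
    """Read a centroid CSV (columns ``id, x_um, y_um``; extras preserved)."""
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in _REQUIRED_COLS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    extra_cols = [c for c in df.columns if c not in _REQUIRED_COLS]
    extra = df[extra_cols].copy() if extra_cols else None
    return CentroidSet(
        x=df["x_um"].to_numpy(float),
        y=df["y_um"].to_numpy(float),
        ids=df["id"].to_numpy(),
        label=label,
        source_id=path.stem,
        extra=extra,
    )


def write_centroids(centroids: CentroidSet, path) -> Path:
    """Write a centroid set as CSV; coordinates kept to 6 decimals."""
    path = Path(path)
    df = pd.DataFrame(
        {
            "id": centroids.ids,
            "x_um": np.round(centroids.x, 6),
            "y_um": np.round(centroids.y, 6),
        }
    )
    if centroids.extra is not None:
        for c in centroids.extra.columns:
            df[c] = centroids.extra[c].to_numpy()
    df.to_csv(path, index=False)
    return path


def write_sidecar(meta: dict, path) -> Path:
    """Write sidecar metadata (preset, dpi, seed, ONH, orientation) as JSON."""
    path = Path(path)
    with open(path, "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True, default=_jsonable)
    return path


def read_sidecar(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
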
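"""File I/O and shared spatial types.

All modules use one coordinate frame: ``x`` is the column index, ``y`` the
row index, both 0-based, with pixel centers at integer coordinates.  Masks
are pixel sets (a pixel is in or out; no sub-pixel geometry).

On-disk formats
---------------
* grayscale images: PNG (8- or 16-bit) or single-frame DICOM (read only),
* landmark sets: PTS text files (16 ordered points per vertebral body),
* binary masks: 8-bit PNG, nonzero = foreground,
* trained models: a JSON container with base64-embedded numeric arrays
  (portable and diffable, no pickle).
"""

from __future__ import annotations

import base64
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np

logger = logging.getLogger(__name__)

N_LANDMARKS = 16


class FormatError(ValueError):
    """An on-disk artifact could not be parsed in its declared format."""


class ValidationError(ValueError):
    """Parsed content violates a domain invariant (e.g. wrong point count)."""


@dataclass
class GrayImage:
    """A 2D grayscale image with physical pixel spacing.

    Parameters
    ----------
    pixels
        2D float array of non-negative intensities.
    spacing
        ``(row_mm, col_mm)`` physical size of one pixel.
    source_id
        Free-text provenance tag (file path, phantom seed, ...).
    """

    pixels: np.ndarray
    spacing: tuple[float, float] = (1.0, 1.0)
    source_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2 or self.pixels.shape[0] < 2 or self.pixels.shape[1] < 2:
            raise ValidationError("image must be 2D with at least 2 rows and 2 columns")
        if not np.all(np.isfinite(self.pixels)):
            raise ValidationError("image intensities must be finite")
        if self.spacing[0] <= 0 or self.spacing[1] <= 0:
            raise ValidationError("pixel spacing components must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class LandmarkSet:
    """Ordered set of exactly 16 sub-pixel (x, y) points outlining one vertebral body."""

    points: np.ndarray
    frame: str = ""

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.shape != (N_LANDMARKS, 2):
            raise ValidationError(
                f"a landmark set has exactly {N_LANDMARKS} (x, y) points, "
                f"got shape {self.points.shape}"
            )
        if not np.all(np.isfinite(self.points)):
            raise ValidationError("landmark coordinates must be finite")

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class BoundingBox:
    """Axis-aligned detection box: top-left corner (x, y), size, and a score."""

    x: float
    y: float
    width: float
    height: float
    score: float = 0.0

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValidationError("bounding box width and height must be positive")

    @property
    def area(self) -> float:
        return self.width * self.height

    def as_dict(self) -> dict:
        return {
            "x": self.x,
            "y": self.y,
            "width": self.width,
            "height": self.height,
            "score": self.score,
        }


def iou(a: BoundingBox, b: BoundingBox) -> float:
    """Intersection-over-union of two boxes."""
    x0 = max(a.x, b.x)
    y0 = max(a.y, b.y)
    x1 = min(a.x + a.width, b.x + b.width)
    y1 = min(a.y + a.height, b.y + b.height)
    if x1 <= x0 or y1 <= y0:
        return 0.0
    inter = (x1 - x0) * (y1 - y0)
    return inter / (a.area + b.area - inter)


@dataclass
class BinaryMask:
    """Boolean pixel set with the spacing of its reference image."""

    pixels: np.ndarray
    spacing: tuple[float, float] = (1.0, 1.0)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=bool)
        if self.pixels.ndim != 2:
            raise ValidationError("mask must be 2D")
        if self.spacing[0] <= 0 or self.spacing[1] <= 0:
            raise ValidationError("pixel spacing components must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def area_px(self) -> int:
        return int(self.pixels.sum())


# ---------------------------------------------------------------------------
# DICOM
# ---------------------------------------------------------------------------

def read_dicom_slice(path: str | Path) -> GrayImage:
    """Read a single-frame DICOM slice into a :class:`GrayImage`.

    Pixel values are rescaled by RescaleSlope/RescaleIntercept when present.
    Spacing comes from PixelSpacing; if the tag is absent, (1.0, 1.0) mm is
    assumed and a warning is logged.
    """
    import pydicom

    path = Path(path)
    try:
        ds = pydicom.dcmread(path)
        pixels = ds.pixel_array.astype(float)
    except Exception as exc:  # pragma: no cover - exercised via FormatError path
        raise FormatError(f"cannot read DICOM pixel data from {path}: {exc}") from exc
    if pixels.ndim != 2:
        raise FormatError(f"{path}: expected a single-frame 2D DICOM slice")

    slope = float(getattr(ds, "RescaleSlope", 1.0))
    intercept = float(getattr(ds, "RescaleIntercept", 0.0))
    pixels = pixels * slope + intercept

    if "PixelSpacing" in ds:
        spacing = (float(ds.PixelSpacing[0]), float(ds.PixelSpacing[1]))
    else:
        logger.warning("%s: PixelSpacing absent, assuming 1.0 x 1.0 mm", path)
        spacing = (1.0, 1.0)
    return GrayImage(pixels=pixels, spacing=spacing, source_id=str(path))


# ---------------------------------------------------------------------------
# PTS landmark files
# ---------------------------------------------------------------------------

def write_pts(landmarks: LandmarkSet, path: str | Path) -> None:
    """Write a landmark set in PTS text format.

    Layout::

        version: 1
        n_points: 16
        {
        x y
        ...
        }
    """
    path = Path(path)
    lines = ["version: 1", f"n_points: {len(landmarks)}", "{"]
    for x, y in landmarks.points:
        lines.append(f"{x:.12g} {y:.12g}")
    lines.append("}")
    path.write_text("\n".join(lines) + "\n")


def read_pts(path: str | Path) -> LandmarkSet:
    """Read a PTS landmark file (see :func:`write_pts` for the layout)."""
    path = Path(path)
    raw = [ln.strip() for ln in path.read_text().splitlines() if ln.strip()]
    if len(raw) < 4 or not raw[0].startswith("version:"):
        raise FormatError(f"{path}: missing PTS header")
    if not raw[1].startswith("n_points:"):
        raise FormatError(f"{path}: missing n_points declaration")
    try:
        n = int(raw[1].split(":", 1)[1])
    except ValueError as exc:
        raise FormatError(f"{path}: unparseable n_points") from exc
    if n != N_LANDMARKS:
        raise ValidationError(f"{path}: n_points is {n}, expected {N_LANDMARKS}")
    if raw[2] != "{" or raw[-1] != "}":
        raise FormatError(f"{path}: point block must be brace-delimited")
    body = raw[3:-1]
    if len(body) != n:
        raise ValidationError(f"{path}: declared {n} points but found {len(body)}")
    pts = []
    for ln in body:
        tokens = ln.split()
        if len(tokens) != 2:
            raise FormatError(f"{path}: expected 'x y' per line, got {ln!r}")
        try:
            pts.append((float(tokens[0]), float(tokens[1])))
        except ValueError as exc:
            raise FormatError(f"{path}: non-numeric coordinate in {ln!r}") from exc
    return LandmarkSet(points=np.array(pts), frame=str(path))


# ---------------------------------------------------------------------------
# PNG images and masks
# ---------------------------------------------------------------------------

def read_image(path: str | Path, spacing: tuple[float, float] = (1.0, 1.0)) -> GrayImage:
    """Read a grayscale PNG into a :class:`GrayImage`."""
    path = Path(path)
    try:
        arr = np.asarray(iio.imread(path))
    except Exception as exc:
        raise FormatError(f"cannot read image {path}: {exc}") from exc
    if arr.ndim == 3:
        arr = arr[..., 0]
    return GrayImage(pixels=arr.astype(float), spacing=spacing, source_id=str(path))


def write_image(image: GrayImage, path: str | Path) -> None:
    """Write a grayscale image as 16-bit PNG, linearly scaled to the full range."""
    px = image.pixels
    lo, hi = float(px.min()), float(px.max())
    scale = 65535.0 / (hi - lo) if hi > lo else 0.0
    out = np.round((px - lo) * scale).astype(np.uint16)
    iio.imwrite(Path(path), out)


def read_mask(path: str | Path, spacing: tuple[float, float] = (1.0, 1.0)) -> BinaryMask:
    """Read a PNG mask; any nonzero pixel is foreground."""
    path = Path(path)
    try:
        arr = np.asarray(iio.imread(path))
    except Exception as exc:
        raise FormatError(f"cannot read mask {path}: {exc}") from exc
    if arr.ndim == 3:
        arr = arr[..., 0]
    return BinaryMask(pixels=arr != 0, spacing=spacing)


def write_mask(mask: BinaryMask, path: str | Path) -> None:
    """Write a mask as 8-bit PNG (foreground = 255)."""
    iio.imwrite(Path(path), mask.pixels.astype(np.uint8) * 255)


# ---------------------------------------------------------------------------
# JSON model container
# ---------------------------------------------------------------------------

def _encode_array(arr: np.ndarray) -> dict:
    arr = np.ascontiguousarray(arr)
    return {
        "__ndarray__": base64.b64encode(arr.tobytes()).decode("ascii"),
        "dtype": str(arr.dtype),
        "shape": list(arr.shape),
    }


def _decode_array(obj: dict) -> np.ndarray:
    data = base64.b64decode(obj["__ndarray__"])
    return np.frombuffer(data, dtype=np.dtype(obj["dtype"])).reshape(obj["shape"]).copy()


def _encode(obj):
    if isinstance(obj, np.ndarray):
        return _encode_array(obj)
    if isinstance(obj, (np.floating, np.integer, np.bool_)):
        return obj.item()
    if isinstance(obj, dict):
        return {k: _encode(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_encode(v) for v in obj]
    return obj


def _decode(obj):
    if isinstance(obj, dict):
        if "__ndarray__" in obj:
            return _decode_array(obj)
        return {k: _decode(v) for k, v in obj.items()}
    if isinstance(obj, list):
        return [_decode(v) for v in obj]
    return obj


def save_model_json(payload: dict, path: str | Path) -> None:
    """Serialize a nested dict of scalars/arrays as a JSON model container."""
    Path(path).write_text(json.dumps(_encode(payload), indent=1, sort_keys=True))


def load_model_json(path: str | Path) -> dict:
    """Load a JSON model container written by :func:`save_model_json`."""
    try:
        return _decode(json.loads(Path(path).read_text()))
    except json.JSONDecodeError as exc:
        raise FormatError(f"{path}: not a valid JSON model container") from exc
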
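"""Radiograph, lung-mask and manifest I/O.

Supports the headerless JSRT raw dialect (unsigned 16-bit big-endian,
12-bit dynamic range), ordinary lossless rasters (PNG/TIFF) via imageio,
single-channel raster lung masks, and a CSV manifest mapping image id to
image path, optional mask path and label.

Conventions: intensities are normalized to [0, 1]; grids are row-major
with a top-left origin; boxes are half-open ``[r0, r1) x [c0, c1)``;
labels are case-insensitive on input and canonical lowercase internally.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

logger = logging.getLogger(__name__)

#: Maximum value of the 12-bit JSRT dynamic range.
JSRT_MAXVAL = 4095

LABELS = ("cancer", "normal")


@dataclass
class ChestImage:
    """One radiograph: normalized pixels, optional lung mask, label, id.

    Parameters
    ----------
    id : str
        Non-empty identifier, unique within a manifest.
    pixels : ndarray of float, shape (H, W)
        Intensities in [0, 1], row-major, origin top-left.
    mask : ndarray of {0, 1} or None
        Binary lung-field mask of the same shape (1 = lung).
    label : {"cancer", "normal", "unknown"}
    """

    id: str
    pixels: np.ndarray
    mask: np.ndarray | None = None
    label: str = "unknown"

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("ChestImage id must be non-empty")
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValidationError(f"pixels must be 2-D, got shape {self.pixels.shape}")
        if self.pixels.min() < 0 or self.pixels.max() > 1:
            raise ValidationError("pixel intensities must lie in [0, 1]")
        if self.mask is not None:
            self.mask = np.asarray(self.mask)
            if self.mask.shape != self.pixels.shape:
                raise ValidationError(
                    f"mask shape {self.mask.shape} != pixels shape {self.pixels.shape}"
                )
            vals = np.unique(self.mask)
            if not np.isin(vals, (0, 1)).all():
                raise ValidationError("mask must contain only {0, 1}")
            self.mask = self.mask.astype(np.uint8)
        if self.label not in ("cancer", "normal", "unknown"):
            raise ValidationError(f"unknown label {self.label!r}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]


@dataclass
class ManifestRecord:
    id: str
    image_path: str
    mask_path: str | None
    label: str


@dataclass
class Manifest:
    """An ordered list of (id, image path, mask path, label) records."""

    records: list[ManifestRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    @property
    def labels(self) -> list[str]:
        return [r.label for r in self.records]

    def label_counts(self) -> dict[str, int]:
        counts = {lab: 0 for lab in LABELS}
        for r in self.records:
            counts[r.label] = counts.get(r.label, 0) + 1
        return counts

    def validate(self) -> None:
        ids = self.ids
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate manifest ids: {dupes}")
        bad = [r.id for r in self.records if r.label not in LABELS]
        if bad:
            raise ValidationError(f"labels outside {LABELS} for rows: {bad}")

    def to_csv(self, path: str | os.PathLike) -> None:
        df = pd.DataFrame(
            {
                "id": [r.id for r in self.records],
                "image": [r.image_path for r in self.records],
                "mask": [r.mask_path or "" for r in self.records],
                "label": [r.label for r in self.records],
            }
        )
        df.to_csv(path, index=False)


def read_jsrt_raw(
    path: str | os.PathLike,
    width: int = 2048,
    height: int = 2048,
    invert: bool = False,
) -> ChestImage:
    """Read a headerless JSRT-style raw radiograph.

    The file must contain exactly ``width * height`` unsigned 16-bit
    big-endian samples with 12-bit dynamic range; intensities are divided
    by 4095 and clipped to [0, 1]. ``invert`` flips the LUT (4095 - v)
    before normalization, for inverted-LUT copies of the dataset.
    """
    path = Path(path)
    expected = width * height * 2
    actual = path.stat().st_size
    if actual != expected:
        raise FormatError(
            f"{path}: expected {expected} bytes for {width}x{height} 16-bit raw, "
            f"got {actual}"
        )
    raw = np.fromfile(path, dtype=">u2").reshape(height, width)
    if invert:
        raw = JSRT_MAXVAL - np.minimum(raw, JSRT_MAXVAL)
    pixels = np.clip(raw.astype(np.float64) / JSRT_MAXVAL, 0.0, 1.0)
    return ChestImage(id=path.stem, pixels=pixels)


def write_jsrt_raw(image: ChestImage, path: str | os.PathLike) -> None:
    """Write ``image`` in the headerless JSRT raw dialect.

    Pixels are quantized as ``round(pixels * 4095)`` and stored as
    unsigned 16-bit big-endian; ``read_jsrt_raw`` inverts this to within
    one quantization step (1/4095).
    """
    quantized = np.round(np.asarray(image.pixels) * JSRT_MAXVAL).astype(">u2")
    quantized.tofile(Path(path))


def read_image(path: str | os.PathLike) -> ChestImage:
    """Read a PNG/TIFF raster and rescale intensities to [0, 1].

    Integer images are divided by the dtype's max value; multi-channel
    inputs are converted to luminance (ITU-R BT.709 weights).
    """
    path = Path(path)
    try:
        arr = iio.imread(path)
    except Exception as exc:  # imageio raises format-specific errors
        raise FormatError(f"{path}: unreadable raster ({exc})") from exc
    dtype = arr.dtype
    if arr.ndim == 3:
        arr = arr[..., :3] @ np.array([0.2126, 0.7152, 0.0722])
    if np.issubdtype(dtype, np.integer):
        pixels = arr.astype(np.float64) / np.iinfo(dtype).max
    else:
        pixels = arr.astype(np.float64)
    return ChestImage(id=path.stem, pixels=np.clip(pixels, 0.0, 1.0))


def read_mask(path: str | os.PathLike, shape: tuple[int, int] | None = None) -> np.ndarray:
    """Read a single-channel raster lung mask as a {0, 1} grid.

    Any nonzero pixel maps to 1. If ``shape`` differs from the raster's
    shape, the mask is resampled by nearest neighbor, provided the aspect
    ratios agree to within 1%.
    """
    path = Path(path)
    try:
        arr = iio.imread(path)
    except Exception as exc:
        raise FormatError(f"{path}: unreadable raster ({exc})") from exc
    if arr.ndim == 3:
        arr = arr[..., 0]
    mask = (arr != 0).astype(np.uint8)
    if shape is not None and mask.shape != tuple(shape):
        src_ar = mask.shape[0] / mask.shape[1]
        dst_ar = shape[0] / shape[1]
        if abs(src_ar - dst_ar) / dst_ar > 0.01:
            raise FormatError(
                f"{path}: mask aspect ratio {src_ar:.4f} differs from requested "
                f"{dst_ar:.4f} by more than 1%"
            )
        rows = (np.arange(shape[0]) * mask.shape[0] / shape[0]).astype(int)
        cols = (np.arange(shape[1]) * mask.shape[1] / shape[1]).astype(int)
        mask = mask[np.ix_(rows, cols)]
    if mask.sum() == 0:
        logger.warning("%s: mask is empty (no lung field)", path)
    return mask


def load_manifest(path: str | os.PathLike) -> Manifest:
    """Load a dataset manifest CSV with columns ``id,image,mask,label``.

    The mask column is optional. Labels are case-folded; rows whose label
    is outside {cancer, normal} raise a :class:`ValidationError` listing
    the offenders, as do duplicate ids.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str).fillna("")
    required = {"id", "image", "label"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: manifest missing columns {sorted(missing)}")
    has_mask = "mask" in df.columns
    records = []
    for _, row in df.iterrows():
        mask_path = row["mask"] if has_mask and row.get("mask") else None
        records.append(
            ManifestRecord(
                id=str(row["id"]),
                image_path=str(row["image"]),
                mask_path=mask_path,
                label=str(row["label"]).strip().lower(),
            )
        )
    manifest = Manifest(records)
    manifest.validate()
    counts = manifest.label_counts()
    logger.info("manifest %s: %d records (%s)", path, len(manifest), counts)
    return manifest


def images_from_manifest(manifest: Manifest) -> list[ChestImage]:
    """Load every record of a manifest into memory (image + mask)."""
    images = []
    for rec in manifest.records:
        image = read_image(rec.image_path)
        if rec.mask_path:
            image.mask = read_mask(rec.mask_path, image.shape)
        image.id = rec.id
        image.label = rec.label
        images.append(image)
    return images


def manifest_from_images(images: Iterable[ChestImage]) -> Manifest:
    """Build an in-memory manifest (empty paths) from loaded images."""
    return Manifest(
        [ManifestRecord(id=im.id, image_path="", mask_path=None, label=im.label) for im in images]
    )
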
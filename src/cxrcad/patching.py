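"""Overlapping-patch extraction over the lung fields.

Each radiograph is resized so its long side equals a working resolution
(default 1024), tiled by a dense overlapping grid of square patches
(default 256 px with 25% overlap), and the fixed number of candidates
with the highest lung-field coverage is kept (default 11 patches per
image, the count at which patch-based training saturates). Ties are
broken by row-major grid order so extraction is deterministic.

Boxes are half-open ``(r0, c0, r1, c1)`` in working-resolution
coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import resize as _sk_resize

from .errors import GeometryError, ValidationError
from .image_io import ChestImage

Box = tuple[int, int, int, int]


@dataclass(frozen=True)
class PatchConfig:
    """Geometry of patch extraction.

    ``overlap_ratio`` is the fraction of the patch side shared between
    adjacent patches; the grid stride is ``round(patch_size * (1 -
    overlap_ratio))``. With the defaults (1024 working resolution,
    256-px patches, 25% overlap) a square image yields a 5 x 5 = 25
    candidate grid from which the top ``n_patches`` by lung fraction are
    kept.
    """

    n_patches: int = 11
    overlap_ratio: float = 0.25
    patch_size: int = 256
    working_resolution: int = 1024

    def __post_init__(self) -> None:
        if self.n_patches < 1:
            raise ValidationError("n_patches must be >= 1")
        if not (0 <= self.overlap_ratio < 1):
            raise ValidationError("overlap_ratio must lie in [0, 1)")
        if self.patch_size < 8:
            raise ValidationError("patch_size must be >= 8")


@dataclass
class Patch:
    """A square sub-image with its provenance and lung coverage."""

    parent_id: str
    box: Box
    pixels: np.ndarray
    lung_fraction: float
    label: str


def candidate_grid(
    image_shape: tuple[int, int], patch_size: int, overlap_ratio: float
) -> list[Box]:
    """Enumerate the dense overlapping grid of candidate boxes.

    Anchors run 0, stride, 2*stride, ... along each axis with a final
    anchor clamped so the last patch ends exactly at the image edge;
    the Cartesian product is returned in row-major order.
    """
    h, w = image_shape
    if patch_size > h or patch_size > w:
        raise GeometryError(f"patch {patch_size} exceeds image shape {image_shape}")
    stride = int(round(patch_size * (1 - overlap_ratio)))
    stride = max(stride, 1)

    def anchors(dim: int) -> list[int]:
        xs = list(range(0, dim - patch_size + 1, stride))
        if xs[-1] != dim - patch_size:
            xs.append(dim - patch_size)
        return xs

    return [
        (r, c, r + patch_size, c + patch_size) for r in anchors(h) for c in anchors(w)
    ]


def lung_fraction(box: Box, mask: np.ndarray) -> float:
    """Fraction of pixels inside ``box`` that are lung (mask == 1)."""
    r0, c0, r1, c1 = box
    if r0 < 0 or c0 < 0 or r1 > mask.shape[0] or c1 > mask.shape[1]:
        raise GeometryError(f"box {box} outside mask bounds {mask.shape}")
    return float(np.mean(mask[r0:r1, c0:c1]))


def resize_to_working(image: ChestImage, working_resolution: int) -> ChestImage:
    """Resize pixels (bilinear) and mask (nearest) so the long side
    equals ``working_resolution``; aspect ratio is preserved."""
    h, w = image.shape
    scale = working_resolution / max(h, w)
    new_shape = (int(round(h * scale)), int(round(w * scale)))
    if new_shape == image.shape:
        return image
    pixels = _sk_resize(image.pixels, new_shape, order=1, anti_aliasing=scale < 1)
    mask = None
    if image.mask is not None:
        mask = _sk_resize(
            image.mask.astype(float), new_shape, order=0, anti_aliasing=False
        ).astype(np.uint8)
    return ChestImage(
        id=image.id, pixels=np.clip(pixels, 0, 1), mask=mask, label=image.label
    )


def extract_patches(image: ChestImage, config: PatchConfig) -> list[Patch]:
    """Extract the ``config.n_patches`` candidates best covering the lungs.

    The image and mask are brought to the working resolution, the full
    candidate grid is scored by lung fraction, and the top-N candidates
    are returned in row-major grid order (stable under ties). Patches
    inherit the image label. If the grid has fewer than N candidates,
    all are returned.
    """
    if image.mask is None:
        raise ValidationError(
            f"{image.id}: patch extraction needs a lung mask; supply one or use the "
            "synthetic generator"
        )
    working = resize_to_working(image, config.working_resolution)
    boxes = candidate_grid(working.shape, config.patch_size, config.overlap_ratio)
    fractions = np.array([lung_fraction(b, working.mask) for b in boxes])
    n = min(config.n_patches, len(boxes))
    if n < config.n_patches:
        import logging

        logging.getLogger(__name__).warning(
            "%s: grid has only %d candidates (< %d requested)",
            image.id,
            len(boxes),
            config.n_patches,
        )
    # stable sort keeps row-major order among equal fractions
    order = np.argsort(-fractions, kind="stable")[:n]
    keep = np.sort(order)  # report patches in grid order
    patches = []
    for idx in keep:
        r0, c0, r1, c1 = boxes[idx]
        patches.append(
            Patch(
                parent_id=image.id,
                box=boxes[idx],
                pixels=working.pixels[r0:r1, c0:c1].copy(),
                lung_fraction=float(fractions[idx]),
                label=image.label,
            )
        )
    return patches
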
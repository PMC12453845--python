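"""Phantom chest radiographs with lung masks and labels.

The generator emulates the gross intensity structure of a posteroanterior
chest radiograph: two dark elliptical lung fields on a brighter
mediastinum/soft-tissue background, periodic rib shading inside the
lungs, an optional bright (radiopaque) circular nodule of controlled
contrast and radius inside a lung field, optional low-frequency clutter
outside the lungs, and additive Gaussian noise. The matching lung mask
is the union of the two ellipses and the label is ``cancer`` iff a
nodule was drawn.

All randomness is driven by ``PhantomSpec.seed`` through independent
`numpy.random.SeedSequence` child streams for noise, clutter and nodule
placement, so toggling ``with_nodule`` changes pixels only inside the
nodule disk.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, replace
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from scipy import ndimage

from .errors import PlacementError, ValidationError
from .image_io import ChestImage, Manifest, ManifestRecord, write_jsrt_raw  # noqa: F401

__all__ = [
    "PhantomSpec",
    "generate_phantom",
    "generate_cohort",
    "generate_cohort_images",
    "write_jsrt_raw",
]


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one phantom radiograph.

    Intensities are on the normalized [0, 1] scale. Defaults model a
    well-exposed film: soft tissue at 0.65, aerated lung at 0.30, rib
    shading of amplitude 0.05, sensor noise sigma 0.02. The default
    nodule radius (28 px on a 512-px grid, scaled with image size)
    corresponds to a ~2 cm nodule on a ~35 cm field of view; its
    contrast of 0.30 makes it clearly radiopaque against lung.
    """

    seed: int = 0
    size: tuple[int, int] = (512, 512)
    background_level: float = 0.65
    lung_level: float = 0.30
    rib_amplitude: float = 0.05
    noise_sigma: float = 0.02
    background_texture: float = 0.0
    with_nodule: bool = False
    nodule_contrast: float = 0.30
    nodule_radius: float | None = None
    nodule_center: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.lung_level < self.background_level <= 1):
            raise ValidationError("require 0 <= lung_level < background_level <= 1")
        if self.noise_sigma < 0:
            raise ValidationError("noise_sigma must be >= 0")
        if self.lung_level + self.nodule_contrast > 1:
            raise ValidationError("lung_level + nodule_contrast must be <= 1")
        if self.with_nodule and self.radius_px <= 0:
            raise ValidationError("nodule_radius must be > 0 when with_nodule")

    @property
    def radius_px(self) -> float:
        if self.nodule_radius is not None:
            return float(self.nodule_radius)
        return 28.0 * min(self.size) / 512.0


def _lung_mask(size: tuple[int, int]) -> np.ndarray:
    """Union of two ellipses standing in for the left/right lung fields."""
    h, w = size
    rr, cc = np.mgrid[0:h, 0:w]
    mask = np.zeros(size, dtype=np.uint8)
    for ccol in (0.31 * w, 0.69 * w):
        ell = ((rr - 0.52 * h) / (0.32 * h)) ** 2 + ((cc - ccol) / (0.155 * w)) ** 2 <= 1.0
        mask |= ell.astype(np.uint8)
    return mask


def _place_nodule(mask: np.ndarray, radius: float, rng: np.random.Generator) -> tuple[int, int]:
    """Uniformly sample a center whose whole disk fits inside the lung field."""
    interior = ndimage.distance_transform_edt(mask) >= radius
    rows, cols = np.nonzero(interior)
    if rows.size == 0:
        raise PlacementError(f"no lung position admits a nodule of radius {radius}")
    k = rng.integers(rows.size)
    return int(rows[k]), int(cols[k])


def generate_phantom(spec: PhantomSpec) -> ChestImage:
    """Render one phantom radiograph from ``spec``.

    Returns a :class:`ChestImage` whose mask is the union of the two
    lung ellipses and whose label is ``cancer`` iff ``spec.with_nodule``.
    Deterministic: the same spec yields bit-identical pixels and mask.

    Raises
    ------
    PlacementError
        If an explicit ``nodule_center`` lies outside the lung mask.
    """
    h, w = spec.size
    ss = np.random.SeedSequence(spec.seed)
    noise_rng, clutter_rng, place_rng = (np.random.default_rng(s) for s in ss.spawn(3))

    mask = _lung_mask(spec.size)
    pixels = np.full(spec.size, spec.background_level, dtype=np.float64)
    pixels[mask == 1] = spec.lung_level

    if spec.rib_amplitude:
        rows = np.arange(h)[:, None]
        ribs = spec.rib_amplitude * np.sin(2 * np.pi * rows / (h / 9.0))
        pixels += np.broadcast_to(ribs, spec.size) * mask

    if spec.background_texture:
        blobs = ndimage.gaussian_filter(clutter_rng.standard_normal(spec.size), sigma=min(h, w) / 16)
        blobs *= spec.background_texture / max(blobs.std(), 1e-12)
        pixels += blobs * (1 - mask)

    if spec.with_nodule:
        radius = spec.radius_px
        if spec.nodule_center is not None:
            r0, c0 = spec.nodule_center
            if not (0 <= r0 < h and 0 <= c0 < w) or mask[r0, c0] == 0:
                raise PlacementError(f"nodule center {spec.nodule_center} outside the lung field")
        else:
            r0, c0 = _place_nodule(mask, radius, place_rng)
        rr, cc = np.mgrid[0:h, 0:w]
        disk = (rr - r0) ** 2 + (cc - c0) ** 2 <= radius**2
        pixels[disk] += spec.nodule_contrast

    if spec.noise_sigma:
        pixels += noise_rng.normal(0.0, spec.noise_sigma, spec.size)

    return ChestImage(
        id=f"phantom-{spec.seed}",
        pixels=np.clip(pixels, 0.0, 1.0),
        mask=mask,
        label="cancer" if spec.with_nodule else "normal",
    )


def _image_seed(cohort_seed: int, index: int) -> int:
    """Deterministic per-image seed below 2**31."""
    return int(np.random.SeedSequence((cohort_seed, index)).generate_state(1)[0] % (2**31))


def generate_cohort_images(
    n_cancer: int,
    n_normal: int,
    seed: int,
    base_spec: PhantomSpec | None = None,
) -> list[ChestImage]:
    """Generate an in-memory cohort of labelled phantoms.

    Per-image seeds are derived deterministically from ``seed`` and the
    image index, so cohorts are reproducible and images independent.
    ``base_spec`` carries every non-seed, non-label parameter.
    """
    if n_cancer < 0 or n_normal < 0:
        raise ValidationError("cohort counts must be >= 0")
    base = base_spec or PhantomSpec()
    images = []
    for i in range(n_cancer + n_normal):
        with_nodule = i < n_cancer
        spec = replace(base, seed=_image_seed(seed, i), with_nodule=with_nodule, nodule_center=None)
        image = generate_phantom(spec)
        image.id = f"ph{i:04d}_{'cancer' if with_nodule else 'normal'}"
        images.append(image)
    return images


def generate_cohort(
    n_cancer: int,
    n_normal: int,
    seed: int,
    out_dir: str | os.PathLike,
    base_spec: PhantomSpec | None = None,
) -> Manifest:
    """Write a phantom cohort to ``out_dir`` and return its manifest.

    Each image is stored as a 16-bit grayscale PNG next to an 8-bit mask
    PNG, plus ``manifest.csv`` compatible with
    :func:`cxrcad.image_io.load_manifest`. Two runs with the same
    arguments produce byte-identical files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    records = []
    for image in generate_cohort_images(n_cancer, n_normal, seed, base_spec):
        img_path = out_dir / f"{image.id}.png"
        mask_path = out_dir / f"{image.id}_mask.png"
        iio.imwrite(img_path, np.round(image.pixels * 65535).astype(np.uint16))
        iio.imwrite(mask_path, (image.mask * 255).astype(np.uint8))
        records.append(
            ManifestRecord(
                id=image.id,
                image_path=str(img_path),
                mask_path=str(mask_path),
                label=image.label,
            )
        )
    manifest = Manifest(records)
    manifest.validate()
    manifest.to_csv(out_dir / "manifest.csv")
    return manifest
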
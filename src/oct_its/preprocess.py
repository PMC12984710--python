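"""Deterministic preprocessing and stochastic training-time augmentation.

Every image entering a model passes resize → per-image standardization.
Training images may additionally pass a stochastic augmentation chain
(random crop → horizontal flip → rotation → affine translate+shear); the
:class:`Pipeline` records which role (train / val / test) each batch was
prepared for and whether it was augmented, so leakage of augmentation into
evaluation data is auditable.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.transform import resize as _sk_resize

__all__ = ["AugmentConfig", "Pipeline", "resize", "normalize", "augment"]


@dataclass(frozen=True)
class AugmentConfig:
    """Augmentation magnitudes.

    Defaults are deliberately small so that class-defining anatomy (band
    deformation, subretinal blob) survives every transform.
    """

    crop_scale_range: tuple[float, float] = (0.85, 1.0)
    hflip_probability: float = 0.5
    rotation_range_deg: float = 15.0
    translate_fraction: float = 0.1
    shear_deg: float = 10.0
    enabled: bool = True

    def validate(self) -> None:
        lo, hi = self.crop_scale_range
        if not (0.0 < lo <= hi <= 1.0):
            raise ValueError("crop_scale_range must satisfy 0 < low <= high <= 1")
        if not (0.0 <= self.hflip_probability <= 1.0):
            raise ValueError("hflip_probability must be in [0, 1]")
        for name in ("rotation_range_deg", "translate_fraction", "shear_deg"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def resize(image: np.ndarray, target: tuple[int, int]) -> np.ndarray:
    """Bilinear resize to ``target`` (height, width).

    Bilinear interpolation keeps every output value inside the input range.
    """
    image = np.asarray(image, dtype=float)
    if image.size == 0:
        raise ValueError("cannot resize an empty image")
    th, tw = target
    if th < 1 or tw < 1:
        raise ValueError(f"target dimensions must be >= 1, got {target}")
    if image.shape == (th, tw):
        return image.copy()
    return _sk_resize(
        image, (th, tw), order=1, mode="edge", anti_aliasing=False,
        preserve_range=True,
    )


def normalize(image: np.ndarray) -> np.ndarray:
    """Per-image standardization to zero mean and unit variance.

    A constant image has no scale; it maps to all zeros with a warning
    rather than dividing by a vanishing standard deviation.
    """
    image = np.asarray(image, dtype=float)
    centered = image - image.mean()
    sd = centered.std()
    if sd < 1e-12:
        warnings.warn("normalize: constant image, returning zeros", stacklevel=2)
        return np.zeros_like(image)
    return centered / sd


def augment(
    image: np.ndarray,
    config: AugmentConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Apply the stochastic chain crop → flip → rotate → translate+shear.

    The random draws happen in a fixed order regardless of whether a stage
    acts, so a given generator state always yields the same output. Stages
    whose drawn magnitude is exactly zero are skipped, making the chain an
    exact identity (or exact mirror) in degenerate configurations.
    """
    config.validate()
    image = np.asarray(image, dtype=float)
    if not config.enabled:
        return image.copy()
    h, w = image.shape
    out = image

    # 1. random crop, resized back to the original frame
    scale = float(rng.uniform(*config.crop_scale_range))
    ch, cw = max(1, round(scale * h)), max(1, round(scale * w))
    top = int(rng.integers(0, h - ch + 1))
    left = int(rng.integers(0, w - cw + 1))
    if (ch, cw) != (h, w):
        out = resize(out[top : top + ch, left : left + cw], (h, w))

    # 2. horizontal flip
    if float(rng.uniform()) < config.hflip_probability:
        out = out[:, ::-1].copy()

    # 3. rotation, reflect padding to avoid black-corner artifacts
    angle = float(rng.uniform(-config.rotation_range_deg, config.rotation_range_deg))
    if angle != 0.0:
        out = ndimage.rotate(out, angle, reshape=False, order=1, mode="reflect")

    # 4. affine translation + shear
    ty = float(rng.uniform(-config.translate_fraction, config.translate_fraction)) * h
    tx = float(rng.uniform(-config.translate_fraction, config.translate_fraction)) * w
    shear = math.tan(math.radians(
        float(rng.uniform(-config.shear_deg, config.shear_deg))
    ))
    if ty != 0.0 or tx != 0.0 or shear != 0.0:
        # output (r, c) sampled at input (r + ty, shear*r + c + tx)
        matrix = np.array([[1.0, 0.0], [shear, 1.0]])
        out = ndimage.affine_transform(
            out, matrix, offset=(ty, tx), order=1, mode="reflect"
        )
    return out


class Pipeline:
    """Preprocessing front-end with an audit log.

    ``transform`` turns a list of image records into the (n, h, w) float
    tensor a classifier consumes. Augmentation is applied only when
    ``role == "train"`` and a config with ``enabled=True`` is supplied; every
    call appends an audit entry, so tests can assert that validation and test
    data were never augmented.
    """

    def __init__(
        self,
        image_size: tuple[int, int] = (64, 64),
        augment_config: AugmentConfig | None = None,
    ) -> None:
        self.image_size = tuple(image_size)
        self.augment_config = augment_config
        self.log: list[dict] = []

    def transform(
        self,
        records,
        role: str,
        rng: np.random.Generator | None = None,
    ) -> np.ndarray:
        if role not in ("train", "val", "test", "unlabeled"):
            raise ValueError(f"unknown pipeline role: {role!r}")
        do_augment = (
            role == "train"
            and self.augment_config is not None
            and self.augment_config.enabled
        )
        if do_augment and rng is None:
            raise ValueError("augmentation requested but no rng supplied")
        images = []
        for rec in records:
            img = resize(rec.pixels, self.image_size)
            if do_augment:
                img = augment(img, self.augment_config, rng)
            images.append(normalize(img))
        self.log.append({"role": role, "n": len(images), "augmented": bool(do_augment)})
        if not images:
            h, w = self.image_size
            return np.empty((0, h, w))
        return np.stack(images)
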
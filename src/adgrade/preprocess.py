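"""Grayscaling, min-max normalization, classical augmentation, stratified split.

Augmentation applies an affine transform family — rotation, translation,
shear, zoom, horizontal flip — in a fixed order with parameters drawn
uniformly from signed ranges, the standard training-set augmentation recipe
for medical grayscale images. The split is a per-class (stratified) shuffle
with a floor rule on the training count, matching dataset-accounting tables
where training gets floor(fraction * N_c) of each class.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import AffineTransform, warp

from .synthetic_mri import ImageDataset

_LUMA = np.array([0.299, 0.587, 0.114])  # ITU-R BT.601


class UnsupportedFormatError(ValueError):
    pass


class InvalidInputError(ValueError):
    pass


class InvalidSplitError(ValueError):
    pass


class InvalidLabelError(ValueError):
    pass


@dataclass(frozen=True)
class AugmentConfig:
    """Signed ranges of the affine transform family.

    Defaults follow the wide augmentation recipe: ±30° rotation, ±30%
    shifts/shear/zoom, random horizontal flips. ``brightness_jitter_frac``
    (off by default) adds a uniform ±fraction intensity offset.
    """

    rotation_range_deg: float = 30.0
    width_shift_frac: float = 0.30
    height_shift_frac: float = 0.30
    shear_frac: float = 0.30
    zoom_frac: float = 0.30
    horizontal_flip: bool = True
    brightness_jitter_frac: float = 0.0

    def __post_init__(self):
        for name in (
            "rotation_range_deg",
            "width_shift_frac",
            "height_shift_frac",
            "shear_frac",
            "zoom_frac",
            "brightness_jitter_frac",
        ):
            if getattr(self, name) < 0:
                raise InvalidInputError(f"{name} must be >= 0")


@dataclass(frozen=True)
class SplitSpec:
    train_fraction: float = 0.80
    seed: int = 0
    stratified: bool = True

    def __post_init__(self):
        if not 0.0 < self.train_fraction <= 1.0:
            raise InvalidSplitError(
                f"train_fraction must lie in (0, 1], got {self.train_fraction}"
            )


def to_grayscale(image: np.ndarray) -> np.ndarray:
    """Reduce a (H, W) or (H, W, 3) image to one channel (BT.601 weights)."""
    image = np.asarray(image, dtype=np.float64)
    if image.ndim == 2:
        return image
    if image.ndim == 3 and image.shape[2] == 1:
        return image[:, :, 0]
    if image.ndim == 3 and image.shape[2] == 3:
        return image @ _LUMA
    raise UnsupportedFormatError(f"expected 1 or 3 channels, got shape {image.shape}")


def minmax_normalize(image: np.ndarray) -> np.ndarray:
    """(x - min) / (max - min); constant images map to all zeros."""
    image = np.asarray(image, dtype=np.float64)
    if not np.isfinite(image).all():
        raise InvalidInputError("image contains NaN or infinite values")
    lo, hi = image.min(), image.max()
    if hi == lo:
        return np.zeros_like(image)
    return (image - lo) / (hi - lo)


def _affine_params(config: AugmentConfig, rng: np.random.Generator) -> dict:
    return {
        "rotation_deg": rng.uniform(-config.rotation_range_deg, config.rotation_range_deg),
        "shift_x": rng.uniform(-config.width_shift_frac, config.width_shift_frac),
        "shift_y": rng.uniform(-config.height_shift_frac, config.height_shift_frac),
        "shear": rng.uniform(-config.shear_frac, config.shear_frac),
        "zoom": 1.0 + rng.uniform(-config.zoom_frac, config.zoom_frac),
        "flip": bool(rng.random() < 0.5) if config.horizontal_flip else False,
        "brightness": (
            rng.uniform(-config.brightness_jitter_frac, config.brightness_jitter_frac)
            if config.brightness_jitter_frac > 0
            else 0.0
        ),
    }


def apply_affine(image: np.ndarray, params: dict) -> np.ndarray:
    """Deterministically apply one drawn transform (exposed for oracle tests).

    Order is rotation -> shift -> shear -> zoom -> flip, all about the image
    center; out-of-frame pixels take nearest-edge values. Shifts are
    fractions of the image side; shear is the off-diagonal affine factor.
    """
    h, w = image.shape
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    center = np.array([cx, cy])

    def centered(tf: AffineTransform) -> np.ndarray:
        t1 = AffineTransform(translation=-center)
        t2 = AffineTransform(translation=center)
        return t2.params @ tf.params @ t1.params

    m = np.eye(3)
    m = centered(AffineTransform(rotation=np.deg2rad(params["rotation_deg"]))) @ m
    m = (
        AffineTransform(
            translation=(params["shift_x"] * w, params["shift_y"] * h)
        ).params
        @ m
    )
    m = centered(AffineTransform(shear=np.arctan(params["shear"]))) @ m
    m = centered(AffineTransform(scale=params["zoom"])) @ m
    out = warp(
        image,
        np.linalg.inv(m),
        order=1,
        mode="edge",
        preserve_range=True,
    )
    if params["flip"]:
        out = out[:, ::-1]
    if params["brightness"]:
        lo, hi = image.min(), image.max()
        out = np.clip(out + params["brightness"], lo, hi)
    return out


def augment(image: np.ndarray, config: AugmentConfig, seed: int) -> np.ndarray:
    """One random augmentation of ``image``; shape and value range preserved."""
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2:
        raise UnsupportedFormatError("augment expects a 2-D image")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return apply_affine(image, _affine_params(config, rng))


def stratified_split(
    dataset: ImageDataset, spec: SplitSpec
) -> tuple[ImageDataset, ImageDataset]:
    """Per-class split: train gets floor(train_fraction * N_c), rest to test."""
    rng = np.random.default_rng(spec.seed)
    labels = dataset.labels
    train_idx, test_idx = [], []
    if spec.stratified:
        groups = [np.flatnonzero(labels == c) for c in range(len(dataset.class_names))]
    else:
        groups = [np.arange(len(labels))]
    for idx in groups:
        idx = idx.copy()
        rng.shuffle(idx)
        n_train = int(np.floor(spec.train_fraction * len(idx)))
        train_idx.extend(idx[:n_train])
        test_idx.extend(idx[n_train:])
    return dataset.subset(np.sort(train_idx)), dataset.subset(np.sort(test_idx))


def class_counts(dataset: ImageDataset) -> tuple[int, ...]:
    """Histogram of labels over the dataset's classes."""
    k = len(dataset.class_names)
    labels = dataset.labels
    if len(labels) and (labels.min() < 0 or labels.max() >= k):
        raise InvalidLabelError(f"labels must lie in 0..{k - 1}")
    return tuple(int((labels == c).sum()) for c in range(k))


__all__ = [
    "AugmentConfig",
    "SplitSpec",
    "UnsupportedFormatError",
    "InvalidInputError",
    "InvalidSplitError",
    "InvalidLabelError",
    "to_grayscale",
    "minmax_normalize",
    "apply_affine",
    "augment",
    "stratified_split",
    "class_counts",
]
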
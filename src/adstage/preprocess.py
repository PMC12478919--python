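"""Slice selection, per-slice normalization, augmentation, and stratified splits.

The preprocessing contract mirrors a standard 2D MRI classification recipe:
keep the middle 40% of axial slices (the anatomy-rich band), resize each to
224 x 224, min-max normalize per slice, expand each class by small random
rotations (within ±7 degrees) composed with zooms (within ±10%), and split
60/20/20 stratified by class. Augmentation is intended for the training
split only; augmenting before splitting would leak near-duplicates of a
training slice into the test set.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass

import numpy as np
from skimage.transform import AffineTransform, resize, warp

from .phantom import DatasetManifest


class PreprocessParameterError(ValueError):
    """Raised for invalid preprocessing parameters."""


@dataclass(frozen=True)
class AugmentPolicy:
    """Random rotation/zoom policy; limits are the half-widths of the
    uniform draws (degrees and zoom fraction respectively)."""

    rotation_limit: float = 7.0
    zoom_limit: float = 0.10
    seed: int = 42

    def __post_init__(self):
        if self.rotation_limit < 0:
            raise PreprocessParameterError("rotation_limit must be >= 0")
        if not 0.0 <= self.zoom_limit < 1.0:
            raise PreprocessParameterError("zoom_limit must be in [0, 1)")


@dataclass(frozen=True)
class SplitRatios:
    train: float = 0.60
    val: float = 0.20
    test: float = 0.20

    def __post_init__(self):
        for name, v in (("train", self.train), ("val", self.val), ("test", self.test)):
            if not 0.0 < v < 1.0:
                raise PreprocessParameterError(f"{name} ratio must be in (0, 1)")
        if abs(self.train + self.val + self.test - 1.0) > 1e-9:
            raise PreprocessParameterError("ratios must sum to 1")


def select_middle_slices(n_slices: int, fraction: float = 0.4) -> range:
    """Zero-based contiguous indices of the middle ``fraction`` of slices.

    The count is round-half-up of ``fraction * n_slices`` (at least 1) and
    the window is floor-centered.
    """
    if n_slices < 1:
        raise PreprocessParameterError("n_slices must be >= 1")
    if not 0.0 < fraction <= 1.0:
        raise PreprocessParameterError("fraction must be in (0, 1]")
    k = max(1, math.floor(fraction * n_slices + 0.5))
    start = (n_slices - k) // 2
    return range(start, start + k)


def normalize_slice(image: np.ndarray, out_size: int = 224) -> np.ndarray:
    """Resize to ``out_size`` square and min-max scale to [0, 1].

    A constant slice has no intensity range and maps to all zeros.
    """
    arr = np.asarray(image, dtype=np.float64)
    if arr.size == 0:
        raise PreprocessParameterError("empty image")
    if arr.shape != (out_size, out_size):
        arr = resize(arr, (out_size, out_size), order=1, mode="constant",
                     anti_aliasing=False, preserve_range=True)
    lo, hi = arr.min(), arr.max()
    if hi - lo < 1e-12:
        return np.zeros((out_size, out_size), dtype=np.float32)
    return ((arr - lo) / (hi - lo)).astype(np.float32)


def _rotate_zoom(image: np.ndarray, angle_deg: float, zoom: float) -> np.ndarray:
    """Rotate about the center, then zoom about the center; bilinear, zero fill."""
    h, w = image.shape
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    to_origin = AffineTransform(translation=(-cx, -cy))
    rot = AffineTransform(rotation=np.deg2rad(angle_deg))
    zm = AffineTransform(scale=(zoom, zoom))
    back = AffineTransform(translation=(cx, cy))
    tform = to_origin + rot + zm + back
    return warp(image, tform.inverse, order=1, mode="constant", cval=0.0,
                preserve_range=True).astype(np.float32)


def augment_to_count(images: list[np.ndarray], policy: AugmentPolicy,
                     target: int) -> list[np.ndarray]:
    """Expand a class to exactly ``target`` images.

    All originals are kept (first, in order); the remaining ``target - n``
    images are random rotation+zoom transforms, with source images cycled in
    order so every original contributes nearly equally.
    """
    n = len(images)
    if n < 1:
        raise PreprocessParameterError("need at least one image")
    if target < n:
        raise PreprocessParameterError("target below current count; "
                                       "augmentation never subsamples")
    rng = np.random.default_rng(policy.seed)
    out = [np.asarray(im, dtype=np.float32) for im in images]
    for i in range(target - n):
        src = out[i % n]
        angle = rng.uniform(-policy.rotation_limit, policy.rotation_limit)
        zoom = rng.uniform(1.0 - policy.zoom_limit, 1.0 + policy.zoom_limit)
        out.append(_rotate_zoom(src, angle, zoom))
    return out


def split_sizes(n: int, ratios: SplitRatios) -> tuple[int, int, int]:
    """(train, val, test) counts for one class: round-half-up of the val/test
    ratios, remainder to train."""
    n_val = math.floor(ratios.val * n + 0.5)
    n_test = math.floor(ratios.test * n + 0.5)
    n_train = n - n_val - n_test
    if n_train < 1 or n_val < 1 or n_test < 1:
        raise PreprocessParameterError(f"class of size {n} too small to split")
    return n_train, n_val, n_test


def split_dataset(manifest: DatasetManifest, ratios: SplitRatios,
                  seed: int = 42) -> DatasetManifest:
    """Stratified train/val/test assignment; returns a new manifest with the
    ``split`` field set on every record."""
    out = copy.deepcopy(manifest)
    rng = np.random.default_rng(seed)
    by_class: dict[str, list[int]] = {}
    for i, rec in enumerate(out.records):
        by_class.setdefault(rec.label, []).append(i)
    for label, idxs in sorted(by_class.items()):
        if len(idxs) < 3:
            raise PreprocessParameterError(f"class {label} has < 3 records")
        n_train, n_val, n_test = split_sizes(len(idxs), ratios)
        order = rng.permutation(len(idxs))
        for rank, j in enumerate(order):
            rec = out.records[idxs[j]]
            if rank < n_train:
                rec.split = "train"
            elif rank < n_train + n_val:
                rec.split = "val"
            else:
                rec.split = "test"
    return out
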
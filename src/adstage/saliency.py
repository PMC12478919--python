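"""Gradient saliency maps, overlay rendering, and regional quantification.

A saliency map is the per-pixel magnitude of the gradient of a class score
with respect to the input slice — the first-order answer to "which pixels
move this class's score". Gradients are taken through the differentiable
softmax head (backbone -> multi-scale head -> linear layer): the SVM's sign
decision has zero gradient almost everywhere, so it cannot be the saliency
path; asking for saliency of an SVM raises and points at the head instead.

For presentation the map is Gaussian-blurred, optionally combined with a
Sobel edge map of the slice, tinted in the predicted class's color
(AD -> red, MCI -> blue, CN -> green) and alpha-composited over the
grayscale slice. For quantification each map is divided into four equal
quadrants (Region 1 = top-left, 2 = top-right, 3 = bottom-left,
4 = bottom-right) and the mean saliency per region is averaged over each
class's samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from skimage.filters import sobel

from .classification import CLASSES, MultiScaleHead, extract_features

CLASS_COLOR_CHANNEL = {"AD": 0, "MCI": 2, "CN": 1}   # red / blue / green

REGION_COLUMNS = ("Region 1", "Region 2", "Region 3", "Region 4")


class SaliencyInputError(ValueError):
    """Raised for invalid saliency inputs."""


class UnsupportedModelError(TypeError):
    """Raised when saliency is requested for a non-differentiable model."""


class DifferentiableClassifier:
    """Backbone + multi-scale head as one differentiable scorer.

    Exposes class logits and the gradient of any class score with respect
    to the input pixels, which is what gradient saliency needs.
    """

    def __init__(self, backbone, head: MultiScaleHead):
        self.backbone = backbone
        self.head = head

    def forward(self, images: np.ndarray) -> np.ndarray:
        fmap = extract_features(self.backbone, images)
        if fmap.ndim == 3:
            fmap = fmap[None]
        return self.head.forward(fmap, training=False)

    def predict(self, images: np.ndarray) -> np.ndarray:
        logits = self.forward(images)
        return np.array([CLASSES[i] for i in logits.argmax(axis=1)])

    def input_gradient(self, image: np.ndarray, target_class: str) -> np.ndarray:
        """d(score of target class) / d(input pixels), shape (H, W, C_in)."""
        if target_class not in CLASSES:
            raise SaliencyInputError(f"unknown class {target_class!r}")
        arr = np.asarray(image, dtype=np.float32)
        if arr.ndim == 2:
            arr = arr[..., None]
        x = np.repeat(arr[None], self.backbone.in_channels, axis=3) \
            if arr.shape[-1] != self.backbone.in_channels else arr[None]
        fmap = self.backbone.forward(x, training=False)
        self.head.forward(fmap, training=False)
        dlogits = np.zeros((1, self.head.n_classes), dtype=np.float32)
        dlogits[0, CLASSES.index(target_class)] = 1.0
        dfmap = self.head.backward(dlogits)
        dx = self.backbone.backward(dfmap)
        return dx[0]


def compute_saliency(model, image: np.ndarray, target_class: str) -> np.ndarray:
    """Normalized gradient-magnitude saliency map for one slice.

    The map is ``|d score / d pixel|`` taken as the maximum over input
    channels, divided by its own maximum (an all-zero map stays zero), so
    values are comparable within one image.
    """
    if not hasattr(model, "input_gradient"):
        raise UnsupportedModelError(
            "model does not expose input gradients (an SVM decision has zero "
            "gradient almost everywhere); compute saliency through the "
            "differentiable softmax head (DifferentiableClassifier) instead")
    grad = model.input_gradient(image, target_class)
    sal = np.abs(grad).max(axis=-1)
    peak = sal.max()
    if peak > 0:
        sal = sal / peak
    return sal.astype(np.float32)


def render_overlay(saliency: np.ndarray, image: np.ndarray, predicted_class: str,
                   blur_sigma: float = 2.0, edge_on: bool = True,
                   alpha: float = 0.6) -> np.ndarray:
    """RGB overlay: blurred saliency (optionally sharpened with a Sobel edge
    map of the slice) tinting the predicted class's color channel over the
    grayscale slice. With zero saliency, no blur and no edges the output is
    the slice replicated to RGB."""
    sal = np.asarray(saliency, dtype=np.float32)
    img = np.asarray(image, dtype=np.float32)
    if sal.shape != img.shape:
        raise SaliencyInputError("saliency and image shapes differ")
    if predicted_class not in CLASS_COLOR_CHANNEL:
        raise SaliencyInputError(f"unknown class {predicted_class!r}")
    tint = gaussian_filter(sal, blur_sigma) if blur_sigma > 0 else sal.copy()
    if edge_on:
        edges = sobel(img)
        peak = edges.max()
        if peak > 0:
            edges = edges / peak
        tint = np.clip(tint + 0.5 * edges, 0.0, 1.0)
    rgb = np.repeat(img[..., None], 3, axis=2)
    ch = CLASS_COLOR_CHANNEL[predicted_class]
    rgb[..., ch] = img + alpha * tint * (1.0 - img)
    return np.clip(rgb, 0.0, 1.0)


def region_means(saliency: np.ndarray) -> np.ndarray:
    """Mean saliency of the four quadrants, row-major from top-left."""
    h, w = saliency.shape
    h2, w2 = h // 2, w // 2
    return np.array([
        saliency[:h2, :w2].mean(), saliency[:h2, w2:].mean(),
        saliency[h2:, :w2].mean(), saliency[h2:, w2:].mean(),
    ])


def region_quantification(saliency_maps, labels) -> pd.DataFrame:
    """Class x quadrant table of mean saliency.

    Each cell is the mean over pixels of the quadrant and over all the
    class's samples. Classes with no samples are simply absent from the
    table (missing, not zero). Rows follow the canonical class order.
    """
    maps = [np.asarray(m, dtype=np.float64) for m in saliency_maps]
    labels = list(labels)
    if len(maps) != len(labels):
        raise SaliencyInputError("one label per saliency map required")
    shapes = {m.shape for m in maps}
    if len(shapes) > 1:
        raise SaliencyInputError("all saliency maps must share one shape")
    rows = {}
    for cls in CLASSES:
        cls_maps = [m for m, l in zip(maps, labels) if l == cls]
        if not cls_maps:
            continue
        rows[cls] = np.mean([region_means(m) for m in cls_maps], axis=0)
    table = pd.DataFrame.from_dict(rows, orient="index",
                                   columns=list(REGION_COLUMNS))
    table.index.name = "Class"
    return table
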
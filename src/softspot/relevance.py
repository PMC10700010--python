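"""Saliency maps: Grad-CAM, guided backpropagation, guided Grad-CAM.

Grad-CAM at a convolutional layer: the gradient of the target-class logit
with respect to each feature-map channel is averaged over space to give a
channel weight; the map is the ReLU of the weight-summed channels, computed
at the layer's spatial resolution, bilinearly upsampled to image size and
max-normalised to [0, 1].

Guided backpropagation: the input gradient of the class logit, where every
ReLU's backward pass zeroes the gradient wherever the forward activation or
the incoming gradient is negative; reduced per pixel to the maximum absolute
channel gradient.

Guided Grad-CAM: the elementwise product of the two, combining Grad-CAM's
class-discriminative localisation with pixel-level sharpness.

Choosing a shallower convolutional layer trades class-level abstraction for
a finer relevance grid — useful when the deepest layer's map is too coarse
to pin down small surface features.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from skimage.transform import resize

from . import nn
from .classifier import resolve_layer

__all__ = ["RelevanceMap", "grad_cam", "guided_backprop", "guided_grad_cam"]


@dataclass
class RelevanceMap:
    values: np.ndarray  # H x W, nonnegative, max-normalised to [0, 1]
    method: str
    layer_name: str
    target_class: int


def _prep(image: np.ndarray) -> np.ndarray:
    x = np.asarray(image, dtype=np.float32)
    if x.ndim != 3 or x.shape[2] != 3:
        raise ValueError("expected an H x W x 3 image")
    return np.ascontiguousarray(x.transpose(2, 0, 1))[None]


def _normalize(v: np.ndarray) -> np.ndarray:
    m = v.max()
    return v / m if m > 0 else v


def grad_cam(model: nn.Sequential, image: np.ndarray, target_class: int,
             layer_name: str) -> RelevanceMap:
    """Class-activation map at ``layer_name`` (alias or concrete name)."""
    lname = resolve_layer(model, layer_name)
    x = _prep(image)
    model.forward(x, keep=True)
    acts = model.activation(lname)  # (1, C, h, w)
    grads = model.backward_from_logit(target_class, layer_name=lname)
    if not np.isfinite(grads).all():
        raise FloatingPointError("non-finite gradients in Grad-CAM")
    weights = grads.mean(axis=(2, 3))  # (1, C) spatial-mean gradients
    cam = np.maximum((weights[:, :, None, None] * acts).sum(axis=1), 0.0)[0]
    h, w = image.shape[:2]
    cam_up = resize(cam.astype(np.float64), (h, w), order=1, mode="edge",
                    anti_aliasing=False, preserve_range=True)
    return RelevanceMap(_normalize(np.maximum(cam_up, 0.0)), "grad_cam",
                        lname, target_class)


def grad_cam_raw(model: nn.Sequential, image: np.ndarray, target_class: int,
                 layer_name: str) -> np.ndarray:
    """Grad-CAM at the layer's native resolution, before upsampling."""
    lname = resolve_layer(model, layer_name)
    model.forward(_prep(image), keep=True)
    acts = model.activation(lname)
    grads = model.backward_from_logit(target_class, layer_name=lname)
    weights = grads.mean(axis=(2, 3))
    return np.maximum((weights[:, :, None, None] * acts).sum(axis=1), 0.0)[0]


def guided_backprop(model: nn.Sequential, image: np.ndarray,
                    target_class: int) -> np.ndarray:
    """Per-pixel magnitude (max |channel gradient|) of the guided gradient."""
    x = _prep(image)
    model.forward(x, keep=True)
    if not model.has_relu:
        warnings.warn("model has no ReLU layers; guided backprop reduces to "
                      "the plain input gradient", stacklevel=2)
    g = model.backward_from_logit(target_class, layer_name=None, guided=True)
    if not np.isfinite(g).all():
        raise FloatingPointError("non-finite gradients in guided backprop")
    return np.abs(g[0]).max(axis=0)  # (H, W)


def guided_grad_cam(model: nn.Sequential, image: np.ndarray, target_class: int,
                    layer_name: str) -> RelevanceMap:
    """Elementwise product of upsampled Grad-CAM and guided-backprop maps."""
    cam = grad_cam(model, image, target_class, layer_name)
    gb = guided_backprop(model, image, target_class)
    return RelevanceMap(_normalize(cam.values * gb), "guided_grad_cam",
                        cam.layer_name, target_class)
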
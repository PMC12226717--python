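"""Region- and pixel-level attribution for the CNN tiers.

GradCAM++ produces a region-level heatmap from the activations and
gradients of a named convolutional layer; Guided Backprop produces a
pixel-level map from input gradients with the guided ReLU rule
(gradients pass only where both the forward activation and the
incoming gradient are positive); their normalized elementwise product
is the overlay.  All maps are normalized to [0, 1] and resized to the
input raster's spatial size.
"""

from __future__ import annotations

from contextlib import contextmanager
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core.types import ClinicalRecord, ImageBundle, SeverityStage
from .fusion import FreezeMissingNet, M3VFNet, _standardize, _to_plane
from .nn import Module, Tensor, guided_relu_mode

__all__ = ["SaliencyMap", "gradcam_pp", "guided_backprop", "overlay",
           "gradcam_weights"]


@dataclass
class SaliencyMap:
    heatmap: np.ndarray          # H x W in [0, 1]
    level: str                   # "region" | "pixel" | "overlay"
    target_class: int

    def __post_init__(self) -> None:
        self.heatmap = np.asarray(self.heatmap, dtype=float)
        if self.heatmap.min() < -1e-12 or self.heatmap.max() > 1 + 1e-12:
            raise ValueError("saliency heatmap must lie in [0, 1]")


def _normalize01(m: np.ndarray) -> np.ndarray:
    lo, hi = float(m.min()), float(m.max())
    if hi == lo:
        return np.zeros_like(m)
    return (m - lo) / (hi - lo)


def _resolve_layer(net: Module, layer):
    if isinstance(layer, Module):
        return layer
    obj = net
    for part in layer.split("."):
        obj = getattr(obj, part)
    if not isinstance(obj, Module):
        raise ValueError(f"{layer!r} does not name a module")
    return obj


@contextmanager
def _capture_output(layer: Module):
    """Temporarily hook a layer's forward to record its output tensor."""
    store = {}
    orig = layer.forward

    def hooked(*args, **kwargs):
        out = orig(*args, **kwargs)
        store["out"] = out[0] if isinstance(out, tuple) else out
        return out

    object.__setattr__(layer, "forward", hooked)
    try:
        yield store
    finally:
        object.__setattr__(layer, "forward", orig)


def _build_run(net, bundle: ImageBundle, record: ClinicalRecord, target_class: int,
               modality: str, mean, std):
    """Closure running one sample through the net; returns (score, input)."""
    X = record.feature_vector()[None, :]
    if mean is not None:
        X = _standardize(X, np.asarray(mean), np.asarray(std))

    if isinstance(net, M3VFNet):
        images = {}
        target_tensor = None
        for m in net.image_streams:
            img = bundle.get(m)
            if img is None:
                raise ValueError(f"modality {m!r} absent; saliency needs the raster")
            t = Tensor(_to_plane(img)[None, None], requires_grad=True)
            images[m] = t
            if m == modality:
                target_tensor = t
        if target_tensor is None:
            raise ValueError(f"modality {modality!r} is not an input stream of this net")

        def run():
            net.eval()
            proba = net(images, X)
            return proba[0, int(target_class)], target_tensor

        return run

    if isinstance(net, FreezeMissingNet):
        from .core.types import MODALITIES
        images, target_tensor = [], None
        for m in MODALITIES:
            img = bundle.get(m)
            if img is None:
                raise ValueError(f"modality {m!r} absent; saliency needs the raster")
            t = Tensor(_to_plane(img)[None, None], requires_grad=True)
            images.append(t)
            if m == modality:
                target_tensor = t
        presence = np.ones((1, 3), dtype=bool)

        def run():
            net.eval()
            p = net(images, presence, X)[0]
            score = p if int(target_class) == 1 else 1.0 - p
            return score, target_tensor

        return run

    raise TypeError(f"unsupported network type {type(net)}")


def _default_layer(net, modality: str) -> str:
    # last conv layer of the relevant branch
    if isinstance(net, M3VFNet):
        return f"branch_{modality}.conv1x1"
    return f"branch_{modality}.block3"


def gradcam_weights(activation: np.ndarray, grad: np.ndarray,
                    eps: float = 1e-12) -> np.ndarray:
    """GradCAM++ channel weights from first/second/third-order gradient terms.

    ``activation``/``grad`` are (C, H, W); returns the length-C weight
    vector  w_c = sum_ij alpha_c^ij * relu(grad_c^ij)  with
    alpha = grad^2 / (2 grad^2 + sum_kl A_c * grad^3).
    """
    g2 = grad ** 2
    g3 = grad ** 3
    denom = 2.0 * g2 + activation.sum(axis=(1, 2), keepdims=True) * g3
    alpha = np.where(np.abs(denom) > eps, g2 / np.where(np.abs(denom) > eps, denom, 1.0), 0.0)
    return (alpha * np.maximum(grad, 0.0)).sum(axis=(1, 2))


def gradcam_pp(net, bundle: ImageBundle, record: ClinicalRecord, target_class,
               layer=None, modality: str = "global",
               mean=None, std=None) -> SaliencyMap:
    """Region-level GradCAM++ heatmap for one sample.

    ``layer`` names a convolutional layer (dot path into the net, e.g.
    ``"branch_global.block3"``); default is the last conv of the
    attributed branch.  The weighted activation sum is ReLU-ed,
    bilinearly upsampled to the raster size and min-max normalized.
    """
    target_class = int(target_class)
    layer_mod = _resolve_layer(net, layer or _default_layer(net, modality))
    run = _build_run(net, bundle, record, target_class, modality, mean, std)
    with _capture_output(layer_mod) as store:
        score, _ = run()
        score.backward()
    act = store["out"]
    if act.ndim != 4:
        raise ValueError("target layer must produce a spatial (N,C,H,W) map")
    if act.grad is None:
        cam = np.zeros(act.shape[2:])
    else:
        A, G = act.data[0], act.grad[0]
        w = gradcam_weights(A, G)
        cam = np.maximum((w[:, None, None] * A).sum(axis=0), 0.0)
    raster = bundle.get(modality)
    H, W = _to_plane(raster).shape
    cam = ndimage.zoom(cam, (H / cam.shape[0], W / cam.shape[1]), order=1)
    return SaliencyMap(_normalize01(cam), "region", target_class)


def guided_backprop(net, bundle: ImageBundle, record: ClinicalRecord, target_class,
                    modality: str = "global", mean=None, std=None) -> SaliencyMap:
    """Pixel-level guided-backprop map (|input gradient|, normalized)."""
    target_class = int(target_class)
    run = _build_run(net, bundle, record, target_class, modality, mean, std)
    with guided_relu_mode():
        score, inp = run()
        score.backward()
    g = np.zeros(inp.shape) if inp.grad is None else np.abs(inp.grad)
    return SaliencyMap(_normalize01(g[0, 0]), "pixel", target_class)


def overlay(region: SaliencyMap, pixel: SaliencyMap) -> SaliencyMap:
    """Elementwise product of region and pixel maps, renormalized to [0,1]."""
    if region.heatmap.shape != pixel.heatmap.shape:
        raise ValueError(
            f"size mismatch: {region.heatmap.shape} vs {pixel.heatmap.shape}")
    prod = region.heatmap * pixel.heatmap
    return SaliencyMap(_normalize01(prod), "overlay", region.target_class)
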
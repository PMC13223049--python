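"""Image augmentation: offline balancing ops and train-time ops.

Two parameter regimes are used, matching how the training data were built:

* **offline** (balancing the training split): rotation up to +/-15 degrees,
  brightness/contrast jitter of 10%, zoom up to 20%;
* **train-time** (applied on the fly, at the widely used detection-framework
  defaults): horizontal flip p=0.5, color jitter of 40%/70%/70% with hue
  factor 0.015 (order as conventionally listed: brightness, contrast,
  saturation, hue), random rectangle erasure p=0.4, translation up to 10% of
  each dimension.

Saturation/hue jitter is a near no-op on single-channel ultrasound (frames
are replicated to three channels, jittered, and collapsed back); it is kept
for fidelity to the stated parameter set. Geometric ops use bilinear
interpolation with zero fill — the background of a B-mode frame is black, so
reflection padding would invent tissue.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.color import hsv2rgb, rgb2hsv

from ._seeds import rng_for


@dataclass(frozen=True)
class AugmentParams:
    """Magnitudes and probabilities for both regimes."""

    max_rotation: float = 15.0  # degrees, either direction (offline)
    brightness_jitter: float = 0.10
    contrast_jitter: float = 0.10
    saturation_jitter: float = 0.70
    hue_jitter: float = 0.015
    max_zoom: float = 0.20  # offline only
    hflip_prob: float = 0.5  # train-time
    erase_prob: float = 0.4  # train-time
    erase_area_range: tuple[float, float] = (0.02, 0.20)  # fraction of image area
    erase_aspect_range: tuple[float, float] = (0.3, 3.3)
    translate_frac: float = 0.10  # train-time

    def __post_init__(self):
        for p in (self.hflip_prob, self.erase_prob):
            if not (0.0 <= p <= 1.0):
                raise ValueError("probabilities must be in [0, 1]")
        for j in (
            self.brightness_jitter,
            self.contrast_jitter,
            self.saturation_jitter,
            self.hue_jitter,
            self.max_zoom,
            self.translate_frac,
        ):
            if j < 0:
                raise ValueError("jitters must be >= 0")
        if not (0.0 <= self.max_rotation <= 180.0):
            raise ValueError("max_rotation must be in [0, 180] degrees")


TRAIN_TIME_DEFAULTS = AugmentParams(brightness_jitter=0.40, contrast_jitter=0.70)


def _to_u8(img: np.ndarray) -> np.ndarray:
    return np.clip(np.round(img), 0, 255).astype(np.uint8)


def _zoom_keep_dims(img: np.ndarray, factor: float) -> np.ndarray:
    h, w = img.shape
    z = ndimage.zoom(img.astype(float), factor, order=1, prefilter=False)
    out = np.zeros((h, w), dtype=float)
    zh, zw = z.shape
    if factor >= 1.0:  # center crop
        r0, c0 = (zh - h) // 2, (zw - w) // 2
        out = z[r0 : r0 + h, c0 : c0 + w]
    else:  # center pad
        r0, c0 = (h - zh) // 2, (w - zw) // 2
        out[r0 : r0 + zh, c0 : c0 + zw] = z
    return out


def offline_augment(image: np.ndarray, params: AugmentParams | None = None, seed: int = 0) -> np.ndarray:
    """One offline (balancing) augmentation draw: rotation, brightness/contrast, zoom.

    Rotation angle ~ U(-max_rotation, +max_rotation) (counterclockwise about
    the image center), brightness/contrast gains ~ U(1-j, 1+j), zoom factor
    ~ U(1-z, 1+z); output dimensions equal input dimensions and values are
    clipped to the 8-bit range.
    """
    p = params or AugmentParams()
    rng = rng_for(seed, "offline")
    img = np.asarray(image).astype(float)
    if img.size == 0:
        raise ValueError("empty image")
    theta = rng.uniform(-p.max_rotation, p.max_rotation)
    if theta != 0.0:
        img = ndimage.rotate(img, theta, reshape=False, order=1, mode="constant", cval=0.0)
    b = rng.uniform(1 - p.brightness_jitter, 1 + p.brightness_jitter)
    c = rng.uniform(1 - p.contrast_jitter, 1 + p.contrast_jitter)
    img = (img * b - img.mean() * b) * c + img.mean() * b
    z = rng.uniform(1 - p.max_zoom, 1 + p.max_zoom)
    if abs(z - 1.0) > 1e-12:
        img = _zoom_keep_dims(img, z)
    return _to_u8(img)


def train_time_augment(
    image: np.ndarray,
    params: AugmentParams | None = None,
    seed: int = 0,
    return_info: bool = False,
):
    """One train-time augmentation draw: hflip, color jitter, random erasure, translation.

    With ``return_info=True`` also returns a dict recording which ops fired
    and the erased rectangle (row0, col0, h, w), for diagnostics.
    """
    p = params if params is not None else TRAIN_TIME_DEFAULTS
    rng = rng_for(seed, "train-time")
    img = np.asarray(image).astype(float)
    if img.size == 0:
        raise ValueError("empty image")
    info: dict = {"hflip": False, "erase": None}

    if rng.random() < p.hflip_prob:
        img = img[:, ::-1].copy()
        info["hflip"] = True

    # color jitter on a 3-channel replica so saturation/hue are defined
    b = rng.uniform(1 - p.brightness_jitter, 1 + p.brightness_jitter)
    c = rng.uniform(1 - p.contrast_jitter, 1 + p.contrast_jitter)
    s = rng.uniform(max(0.0, 1 - p.saturation_jitter), 1 + p.saturation_jitter)
    hshift = rng.uniform(-p.hue_jitter, p.hue_jitter)
    rgb = np.repeat((np.clip(img, 0, 255) / 255.0)[..., None], 3, axis=-1)
    rgb = np.clip(rgb * b, 0, 1)
    mean = rgb.mean()
    rgb = np.clip((rgb - mean) * c + mean, 0, 1)
    if p.saturation_jitter > 0 or p.hue_jitter > 0:
        hsv = rgb2hsv(rgb)
        hsv[..., 1] = np.clip(hsv[..., 1] * s, 0, 1)
        hsv[..., 0] = (hsv[..., 0] + hshift) % 1.0
        rgb = hsv2rgb(hsv)
    img = rgb.mean(axis=-1) * 255.0

    if rng.random() < p.erase_prob:
        h, w = img.shape
        for _ in range(10):  # rejection-sample a rectangle that fits
            area = rng.uniform(*p.erase_area_range) * h * w
            aspect = np.exp(rng.uniform(np.log(p.erase_aspect_range[0]), np.log(p.erase_aspect_range[1])))
            eh = int(round(np.sqrt(area * aspect)))
            ew = int(round(np.sqrt(area / aspect)))
            if 0 < eh <= h and 0 < ew <= w:
                r0 = int(rng.integers(0, h - eh + 1))
                c0 = int(rng.integers(0, w - ew + 1))
                img[r0 : r0 + eh, c0 : c0 + ew] = 0.0
                info["erase"] = (r0, c0, eh, ew)
                break

    if p.translate_frac > 0:
        h, w = img.shape
        dr = int(round(rng.uniform(-p.translate_frac, p.translate_frac) * h))
        dc = int(round(rng.uniform(-p.translate_frac, p.translate_frac) * w))
        if dr or dc:
            out = np.zeros_like(img)
            r0s, r0d = (0, dr) if dr >= 0 else (-dr, 0)
            c0s, c0d = (0, dc) if dc >= 0 else (-dc, 0)
            hh, ww = h - abs(dr), w - abs(dc)
            out[r0d : r0d + hh, c0d : c0d + ww] = img[r0s : r0s + hh, c0s : c0s + ww]
            img = out
        info["translate"] = (dr, dc)

    out = _to_u8(img)
    return (out, info) if return_info else out
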
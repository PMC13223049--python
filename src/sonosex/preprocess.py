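"""Frame preprocessing: overlay stripping, specimen ROI extraction, zero-padding,
filename parsing, and automated quality filtering.

The acquisition device burns a border and a metadata text band into every
frame; those are stripped first so no classifier can read the label off the
overlay. The specimen is then isolated by binarizing at a fixed low intensity
threshold (default 5 on the 0-255 scale — the imaging background is uniformly
dark), taking the connected foreground component whose enclosed (hole-filled)
area is largest, and cropping to its axis-aligned bounding box. Crops are
finally zero-padded to common dimensions.

Quality filtering automates three visual exclusion criteria with conservative
numeric detectors: (a) echo ghosts — a shifted duplicate of the specimen from
shell reverberation; (b) missing gonad/gland anatomy; (c) incomplete capture
of the animal. Detectors never see the sex label.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage
from skimage import measure

from .naming import FilenameError, FrameMeta, format_filename, parse_filename  # noqa: F401 (re-export)

DEFAULT_THRESHOLD = 5


class EmptySpecimenError(ValueError):
    """No pixel above the binarization threshold: the frame has no usable specimen."""


@dataclass(frozen=True)
class BoundingBox:
    """0-based, inclusive origin with explicit height/width."""

    row0: int
    col0: int
    height: int
    width: int

    def __post_init__(self):
        if self.height < 1 or self.width < 1:
            raise ValueError("bounding box must have height >= 1 and width >= 1")
        if self.row0 < 0 or self.col0 < 0:
            raise ValueError("bounding box origin must be non-negative")

    @property
    def slices(self) -> tuple[slice, slice]:
        return (slice(self.row0, self.row0 + self.height), slice(self.col0, self.col0 + self.width))


def _as_gray(image: np.ndarray) -> np.ndarray:
    img = np.asarray(image)
    if img.ndim == 3:
        img = np.asarray(Image.fromarray(img).convert("L"))
    if img.dtype != np.uint8:
        img = np.clip(img, 0, 255).astype(np.uint8)
    return img


def strip_overlay(
    image: np.ndarray,
    border_spec: tuple[int, int, int, int] | int | str = "auto",
    text_band: int = 0,
) -> np.ndarray:
    """Remove the device overlay border (and metadata text band) from a frame.

    ``border_spec`` is either explicit margins (top, bottom, left, right), one
    margin for all sides, or ``"auto"``: detect the maximal constant-valued
    frame and remove it. A constant ring at background level (below the ROI
    threshold) is the dark imaging field, not an overlay, and is left alone.
    ``text_band`` additional rows are removed from the top (where the device
    prints acquisition metadata).
    """
    img = _as_gray(image)
    H, W = img.shape
    if border_spec == "auto":
        v = img[0, 0]
        if v <= DEFAULT_THRESHOLD:
            return img
        k = 0
        while k < (min(H, W) - 1) // 2:
            ring_ok = (
                np.all(img[k, k : W - k] == v)
                and np.all(img[H - 1 - k, k : W - k] == v)
                and np.all(img[k : H - k, k] == v)
                and np.all(img[k : H - k, W - 1 - k] == v)
            )
            if not ring_ok:
                break
            k += 1
        top = bottom = left = right = k
    else:
        if isinstance(border_spec, int):
            top = bottom = left = right = border_spec
        else:
            top, bottom, left, right = border_spec
    top += text_band
    if top + bottom >= H or left + right >= W:
        raise ValueError("overlay margins consume the entire image")
    return img[top : H - bottom, left : W - right]


def extract_roi(
    image: np.ndarray, threshold: int = DEFAULT_THRESHOLD
) -> tuple[BoundingBox, np.ndarray]:
    """Locate the specimen and crop to it.

    Foreground = pixels strictly greater than ``threshold``. Connected
    foreground components (8-connectivity) are ranked by their hole-filled
    area — the area enclosed by each outermost contour — and the largest is
    taken as the specimen; ties break on the lexicographically smallest
    (row0, col0). Returns the bounding box and the original image cropped
    to it.
    """
    img = _as_gray(image)
    mask = img > threshold
    if not mask.any():
        raise EmptySpecimenError("no pixel above threshold; empty specimen")
    labels = measure.label(mask, connectivity=2)
    best = None
    for p in measure.regionprops(labels):
        minr, minc, maxr, maxc = p.bbox
        key = (-int(p.area_filled), minr, minc)
        if best is None or key < best[0]:
            best = (key, BoundingBox(minr, minc, maxr - minr, maxc - minc))
    box = best[1]
    return box, img[box.slices]


def zero_pad(
    image: np.ndarray, target_h: int, target_w: int, anchor: str = "center"
) -> np.ndarray:
    """Embed ``image`` in a zero canvas of (target_h, target_w).

    ``anchor`` places the original pixels at ``"center"`` (offsets floored)
    or ``"topleft"``; every added pixel is exactly 0.
    """
    img = _as_gray(image)
    h, w = img.shape
    if target_h < h or target_w < w:
        raise ValueError(f"target ({target_h}x{target_w}) smaller than image ({h}x{w})")
    out = np.zeros((target_h, target_w), dtype=img.dtype)
    if anchor == "center":
        r0, c0 = (target_h - h) // 2, (target_w - w) // 2
    elif anchor == "topleft":
        r0, c0 = 0, 0
    else:
        raise ValueError(f"unknown anchor {anchor!r}")
    out[r0 : r0 + h, c0 : c0 + w] = img
    return out


# ---------------------------------------------------------------------------
# quality filtering


@dataclass(frozen=True)
class QualityRuleSet:
    """Enable flags and detector thresholds for the three exclusion criteria.

    Thresholds are deliberately conservative (defects must be unambiguous to
    fire; borderline frames are retained):

    * ``ghost_peak_min`` — criterion (a): a shifted specimen copy duplicates
      the speckle pattern, so the normalized autocorrelation of the
      high-pass-filtered frame shows a secondary peak at the ghost offset.
    * ``contrast_ratio_min`` — criterion (b): with gonad/gland anatomy
      present, the bright tail of the speckle-smoothed foreground clearly
      exceeds its median; a featureless specimen is near-homogeneous.
    * ``min_borders_touched`` — criterion (c): an incompletely captured
      specimen runs off the edge of the field of view.
    """

    check_ghost: bool = True
    check_anatomy: bool = True
    check_capture: bool = True
    ghost_peak_min: float = 0.21
    contrast_ratio_min: float = 1.22
    min_borders_touched: int = 2
    foreground_threshold: int = DEFAULT_THRESHOLD


def detect_echo_ghost(image: np.ndarray, rules: QualityRuleSet) -> tuple[bool, float]:
    """Criterion (a): secondary autocorrelation peak of the high-passed frame."""
    img = _as_gray(image).astype(float)
    hp = img - ndimage.gaussian_filter(img, 5.0)
    hp -= hp.mean()
    denom = float((hp * hp).sum())
    if denom <= 0:
        return False, 0.0
    F = np.fft.rfft2(hp)
    ac = np.fft.irfft2(F * np.conj(F), s=hp.shape) / denom
    ac = np.fft.fftshift(ac)
    cr, cc = np.array(ac.shape) // 2
    rr, cc2 = np.ogrid[: ac.shape[0], : ac.shape[1]]
    far = (rr - cr) ** 2 + (cc2 - cc) ** 2 > 8**2
    peak = float(ac[far].max()) if far.any() else 0.0
    return peak >= rules.ghost_peak_min, peak


def detect_missing_anatomy(image: np.ndarray, rules: QualityRuleSet) -> tuple[bool, float]:
    """Criterion (b): bright-tail / median ratio of the speckle-smoothed foreground."""
    img = _as_gray(image).astype(float)
    fg_mask = img > rules.foreground_threshold
    if fg_mask.sum() < 20:
        return True, 0.0
    smooth = ndimage.gaussian_filter(img, 2.5)
    fg = smooth[fg_mask]
    ratio = float(np.quantile(fg, 0.99) / max(np.median(fg), 1.0))
    return ratio < rules.contrast_ratio_min, ratio


def detect_incomplete_capture(image: np.ndarray, rules: QualityRuleSet) -> tuple[bool, int]:
    """Criterion (c): foreground touching too many image borders."""
    img = _as_gray(image)
    mask = img > rules.foreground_threshold
    touched = int(mask[0, :].any()) + int(mask[-1, :].any()) + int(mask[:, 0].any()) + int(mask[:, -1].any())
    return touched >= rules.min_borders_touched, touched


def filter_quality(
    manifest: pd.DataFrame,
    rules: QualityRuleSet | None = None,
    loader=None,
    images: list[np.ndarray] | None = None,
    root: str | os.PathLike | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition a manifest into (kept, excluded) by the automated criteria.

    Detectors run on overlay-stripped, *uncropped* frames (criterion (c)
    concerns the acquisition field of view). Provide the frames either as a
    ``loader(path) -> array`` callable, a parallel ``images`` list, or a
    ``root`` directory of PNGs. Excluded rows carry the fired criterion codes
    in a ``qc_codes`` column. Sex labels are never consulted.
    """
    rules = rules or QualityRuleSet()
    if manifest.empty:
        empty = manifest.copy()
        return empty, empty.assign(qc_codes=pd.Series(dtype=str))
    if loader is None:
        if images is not None:
            frames = dict(zip(manifest["path"], images))
            loader = frames.__getitem__
        elif root is not None:
            base = os.fspath(root)
            loader = lambda p: np.asarray(Image.open(os.path.join(base, p)).convert("L"))  # noqa: E731
        else:
            raise ValueError("provide one of loader=, images=, or root=")
    codes = []
    for path in manifest["path"]:
        img = loader(path)
        fired = []
        if rules.check_ghost and detect_echo_ghost(img, rules)[0]:
            fired.append("a")
        if rules.check_anatomy and detect_missing_anatomy(img, rules)[0]:
            fired.append("b")
        if rules.check_capture and detect_incomplete_capture(img, rules)[0]:
            fired.append("c")
        codes.append(";".join(fired))
    codes = pd.Series(codes, index=manifest.index, name="qc_codes")
    kept = manifest.loc[codes == ""].copy()
    excluded = manifest.loc[codes != ""].copy()
    excluded["qc_codes"] = codes[codes != ""]
    return kept, excluded


def preprocess_frame(
    image: np.ndarray,
    border_spec="auto",
    text_band: int = 0,
    threshold: int = DEFAULT_THRESHOLD,
) -> tuple[np.ndarray, BoundingBox]:
    """Convenience: strip overlay then crop to the specimen ROI."""
    stripped = strip_overlay(image, border_spec, text_band)
    box, crop = extract_roi(stripped, threshold)
    return crop, box


def pad_to_common(images: list[np.ndarray], target: tuple[int, int] | None = None) -> list[np.ndarray]:
    """Zero-pad a batch of crops to shared dimensions (default: batch-wise maxima)."""
    if not images:
        return []
    if target is None:
        target = (max(i.shape[0] for i in images), max(i.shape[1] for i in images))
    return [zero_pad(i, *target) for i in images]
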
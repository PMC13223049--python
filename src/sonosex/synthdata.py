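"""Synthetic abalone ultrasound phantoms.

Annotated multi-frame B-mode data of individually identified abalone are not
generally available, so this module generates labeled
stand-ins with the statistical structure the downstream analysis relies on:

* a near-black background under a bright specimen ellipse (the animal's
  cross-section), so fixed low-threshold binarization isolates the specimen;
* a cone-shaped digestive gland inside the specimen, enveloped by a thin
  high-echogenicity gonad band — the anatomy that carries the sex signal;
* multiplicative gamma speckle inside the specimen (the standard ultrasound
  noise idealization: unit mean, variance 1/shape);
* several frames per individual sharing one latent anatomy (``PhantomSpec``)
  and differing only by small probe-repositioning jitter and fresh speckle —
  which is exactly what makes image-level train/test splitting leak;
* sex-linked differences in band geometry and texture (females: thicker band
  with a darker core and stronger internal texture; males: thinner, brighter,
  more homogeneous), with a single ``effect_size`` dial; at 0 the sexes are
  statistically identical and no classifier should beat chance on unseen
  individuals;
* optional acquisition defects — echo ghosts, suppressed gonad anatomy,
  truncated field of view — plus a burned-in device overlay border with a
  pseudo-text band, so quality filtering and overlay stripping are exercised.

All randomness flows from one integer seed through per-(individual, frame)
counter-based streams; identical calls are bit-identical.
"""

from __future__ import annotations

import dataclasses
import datetime
import math
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage

from ._seeds import child_seed, rng_for
from .naming import SEXES, SIZE_CLASSES, FrameMeta, format_filename

BACKGROUND_LEVEL = 1.0  # strictly below the ROI threshold default of 5
OVERLAY_BORDER_VALUE = 40
OVERLAY_TEXT_VALUE = 210


# ---------------------------------------------------------------------------
# latent anatomy


@dataclass(frozen=True)
class PhantomSpec:
    """Latent per-individual anatomy and texture; all of an individual's frames render from this."""

    individual_id: str
    sex: str
    size_class: str
    canvas_h: int
    canvas_w: int
    ellipse_center: tuple[float, float]  # (row, col) px
    ellipse_axes: tuple[float, float]  # semi-axes (row, col) px
    cone_apex: tuple[float, float]  # (row, col) px
    cone_axis_angle: float  # radians; direction from apex toward the gland base
    cone_half_angle: float  # radians
    band_thickness_frac: float  # of the minor semi-axis, in (0, 0.5)
    band_echogenicity_mean: float  # 0-255
    gland_echogenicity_mean: float  # 0-255
    tissue_echogenicity_mean: float  # 0-255
    band_core_darkening: float  # fraction removed from the band core
    band_texture_contrast: float  # amplitude of within-band multiplicative texture
    speckle_shape: float | None  # gamma shape; None = noise off
    frame_jitter_scale: float
    texture_seed: int

    def __post_init__(self):
        if self.sex not in SEXES:
            raise ValueError(f"sex must be one of {SEXES}")
        if self.size_class not in SIZE_CLASSES:
            raise ValueError(f"size_class must be one of {SIZE_CLASSES}")
        if not (0.0 < self.band_thickness_frac < 0.5):
            raise ValueError("band_thickness_frac must lie strictly in (0, 0.5)")
        for name in ("band_echogenicity_mean", "gland_echogenicity_mean", "tissue_echogenicity_mean"):
            v = getattr(self, name)
            if not (0.0 <= v <= 255.0):
                raise ValueError(f"{name} must be in [0, 255]")
        if self.band_echogenicity_mean <= BACKGROUND_LEVEL:
            raise ValueError("band echogenicity must exceed the background level")
        if min(self.ellipse_axes) <= 0:
            raise ValueError("degenerate specimen ellipse (zero axis)")
        if self.speckle_shape is not None and not (self.speckle_shape > 0):
            raise ValueError("speckle_shape must be positive (or None for noise off)")


@dataclass(frozen=True)
class ArtifactProfile:
    """Acquisition defects and device overlay injected into a rendered frame."""

    echo_ghost: bool = False
    ghost_offset: tuple[int, int] = (18, 24)  # (rows, cols)
    ghost_gain: float = 0.45
    truncate_fov: bool = False
    truncate_frac: float = 0.5  # fraction of the specimen extent pushed off-frame
    suppress_gonad: bool = False
    overlay_border: bool = False
    border_px: int = 12
    text_band_px: int = 8

    def __post_init__(self):
        if not (0.0 <= self.truncate_frac <= 0.9):
            raise ValueError("truncate_frac must be in [0, 0.9]")
        if self.border_px < 0 or self.text_band_px < 0:
            raise ValueError("overlay dimensions must be non-negative")

    @property
    def defect_codes(self) -> str:
        codes = []
        if self.echo_ghost:
            codes.append("a")
        if self.suppress_gonad:
            codes.append("b")
        if self.truncate_fov:
            codes.append("c")
        return ";".join(codes)


_CLEAN = ArtifactProfile()


def _pair(mean: float, sd: float) -> tuple[float, float]:
    return (mean, sd)


@dataclass(frozen=True)
class PopulationParams:
    """Population distributions of anatomy parameters, with sex-conditional offsets.

    Each anatomical parameter is drawn from a normal with the given
    (mean, sd); sex offsets are multiplied by ``effect_size``, so
    ``effect_size=0`` makes the female and male populations identical.
    Defaults are chosen so a typical frame qualitatively matches a B-mode
    abalone cross-section: bright thin gonad band (~170) over a mid-gray
    gland (~105) and darker coelomic tissue (~55) on a black background.
    """

    effect_size: float = 1.0
    center_row_frac: tuple[float, float] = _pair(0.50, 0.02)
    center_col_frac: tuple[float, float] = _pair(0.50, 0.02)
    ax_row_frac: tuple[float, float] = _pair(0.30, 0.02)  # of canvas height
    ax_col_frac: tuple[float, float] = _pair(0.36, 0.02)  # of canvas width
    small_size_scale: float = 0.78  # small size class shrinks the specimen
    cone_half_angle: tuple[float, float] = _pair(0.50, 0.05)
    band_thickness_frac: tuple[float, float] = _pair(0.13, 0.015)
    band_thickness_sex_offset: float = 0.045  # F +, M - (x effect_size)
    band_echogenicity: tuple[float, float] = _pair(170.0, 8.0)
    band_echogenicity_sex_offset: float = 14.0  # M +, F - (x effect_size)
    gland_echogenicity: tuple[float, float] = _pair(105.0, 8.0)
    gland_echogenicity_sex_offset: float = 0.0  # M +, F - (x effect_size)
    tissue_echogenicity: tuple[float, float] = _pair(55.0, 5.0)
    tissue_echogenicity_sex_offset: float = 0.0  # M +, F - (x effect_size)
    band_core_darkening: tuple[float, float] = _pair(0.05, 0.02)
    band_core_darkening_female_extra: float = 0.22  # x effect_size
    band_texture_contrast: tuple[float, float] = _pair(0.05, 0.015)
    band_texture_contrast_female_extra: float = 0.15  # x effect_size
    speckle_shape: tuple[float, float] = _pair(9.0, 1.0)
    frame_jitter_scale: float = 1.0

    def __post_init__(self):
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if isinstance(v, tuple):
                if v[1] <= 0:
                    raise ValueError(f"{f.name}: spread must be positive")


def sample_individual(
    sex: str,
    size_class: str,
    population_params: PopulationParams | None = None,
    seed: int = 0,
    index: int = 0,
    canvas: tuple[int, int] = (128, 128),
    individual_id: str | None = None,
) -> PhantomSpec:
    """Draw one individual's latent anatomy from the population.

    Identical (sex, size_class, seed, index) always yields the identical
    spec — the anatomy is the animal, not the frame.
    """
    if sex not in SEXES:
        raise ValueError(f"sex must be one of {SEXES}, got {sex!r}")
    if size_class not in SIZE_CLASSES:
        raise ValueError(f"size_class must be one of {SIZE_CLASSES}, got {size_class!r}")
    pop = population_params or PopulationParams()
    rng = rng_for(seed, "individual", sex, size_class, index)
    H, W = canvas
    e = pop.effect_size
    sgn = 1.0 if sex == "F" else -1.0

    def draw(p):
        return rng.normal(p[0], p[1])

    scale = 1.0 if size_class == "large" else pop.small_size_scale
    a_r = max(6.0, draw(pop.ax_row_frac) * H * scale)
    a_c = max(6.0, draw(pop.ax_col_frac) * W * scale)
    cr = draw(pop.center_row_frac) * H
    cc = draw(pop.center_col_frac) * W
    theta = rng.normal(0.0, 0.25)
    d = (math.sin(theta), math.cos(theta))
    apex = (cr - 0.55 * a_r * d[0], cc - 0.55 * a_c * d[1])
    thick = draw(pop.band_thickness_frac) + sgn * pop.band_thickness_sex_offset * e
    thick = float(np.clip(thick, 0.02, 0.45))
    band_echo = float(np.clip(draw(pop.band_echogenicity) - sgn * pop.band_echogenicity_sex_offset * e, 20, 255))
    gland_echo = float(
        np.clip(draw(pop.gland_echogenicity) - sgn * pop.gland_echogenicity_sex_offset * e, 10, 255)
    )
    tissue_echo = float(
        np.clip(draw(pop.tissue_echogenicity) - sgn * pop.tissue_echogenicity_sex_offset * e, 5, 255)
    )
    core_dark = draw(pop.band_core_darkening)
    texture = draw(pop.band_texture_contrast)
    if sex == "F":
        core_dark += pop.band_core_darkening_female_extra * e
        texture += pop.band_texture_contrast_female_extra * e
    core_dark = float(np.clip(core_dark, 0.0, 0.8))
    texture = float(np.clip(texture, 0.0, 0.8))
    speckle = float(max(1.5, draw(pop.speckle_shape)))
    if individual_id is None:
        individual_id = f"{sex}{size_class[0].upper()}{index:03d}"
    return PhantomSpec(
        individual_id=individual_id,
        sex=sex,
        size_class=size_class,
        canvas_h=H,
        canvas_w=W,
        ellipse_center=(float(cr), float(cc)),
        ellipse_axes=(float(a_r), float(a_c)),
        cone_apex=(float(apex[0]), float(apex[1])),
        cone_axis_angle=float(theta),
        cone_half_angle=float(max(0.15, draw(pop.cone_half_angle))),
        band_thickness_frac=thick,
        band_echogenicity_mean=band_echo,
        gland_echogenicity_mean=gland_echo,
        tissue_echogenicity_mean=tissue_echo,
        band_core_darkening=core_dark,
        band_texture_contrast=texture,
        speckle_shape=speckle,
        frame_jitter_scale=pop.frame_jitter_scale,
        texture_seed=int(rng.integers(0, 2**31 - 1)),
    )


# ---------------------------------------------------------------------------
# rendering


def _frame_jitter(spec: PhantomSpec, frame_index: int, seed: int) -> tuple[np.ndarray, float]:
    rng = rng_for(seed, "jitter", spec.individual_id, frame_index)
    d_center = rng.normal(0.0, 1.5, size=2) * spec.frame_jitter_scale
    d_angle = rng.normal(0.0, 0.04) * spec.frame_jitter_scale
    return d_center, float(d_angle)


def phantom_masks(
    spec: PhantomSpec, frame_index: int = 0, seed: int = 0, jitter: bool = True
) -> dict[str, np.ndarray]:
    """Boolean anatomy masks (specimen / gland / band / band_core / tissue / background)
    at the geometry of a particular frame (including its jitter)."""
    if min(spec.ellipse_axes) <= 0:
        raise ValueError("degenerate specimen ellipse (zero axis)")
    H, W = spec.canvas_h, spec.canvas_w
    if jitter:
        d_center, d_angle = _frame_jitter(spec, frame_index, seed)
    else:
        d_center, d_angle = np.zeros(2), 0.0
    cr, cc = spec.ellipse_center[0] + d_center[0], spec.ellipse_center[1] + d_center[1]
    ar, ac = spec.ellipse_axes
    theta = spec.cone_axis_angle + d_angle
    apex = (spec.cone_apex[0] + d_center[0], spec.cone_apex[1] + d_center[1])

    rr, col = np.mgrid[0:H, 0:W].astype(float)
    ellipse = ((rr - cr) / ar) ** 2 + ((col - cc) / ac) ** 2 <= 1.0

    vr, vc = rr - apex[0], col - apex[1]
    norm = np.hypot(vr, vc)
    with np.errstate(invalid="ignore", divide="ignore"):
        cosang = (vr * math.sin(theta) + vc * math.cos(theta)) / np.where(norm == 0, 1.0, norm)
    gland = ellipse & (cosang >= math.cos(spec.cone_half_angle)) & (norm > 0.5)

    thick_px = max(1.0, spec.band_thickness_frac * min(ar, ac))
    dist = ndimage.distance_transform_edt(~gland)
    band = ellipse & ~gland & (dist <= thick_px)
    band_core = band & (dist <= thick_px / 2.0)
    tissue = ellipse & ~gland & ~band
    return {
        "specimen": ellipse,
        "gland": gland,
        "band": band,
        "band_core": band_core,
        "tissue": tissue,
        "background": ~ellipse,
    }


def noiseless_phantom(
    spec: PhantomSpec,
    frame_index: int = 0,
    artifacts: ArtifactProfile | None = None,
    seed: int = 0,
) -> np.ndarray:
    """The deterministic (speckle-free) phantom for one frame, as float64.

    ``suppress_gonad`` acts here: both the gonad band and the digestive gland
    render at plain tissue echogenicity with no core/texture structure, i.e.
    the identifiable anatomy is absent and the specimen is featureless.
    """
    art = artifacts or _CLEAN
    m = phantom_masks(spec, frame_index, seed)
    H, W = spec.canvas_h, spec.canvas_w
    img = np.full((H, W), BACKGROUND_LEVEL, dtype=float)
    img[m["tissue"]] = spec.tissue_echogenicity_mean
    if art.suppress_gonad:
        img[m["gland"]] = spec.tissue_echogenicity_mean
        img[m["band"]] = spec.tissue_echogenicity_mean
    else:
        img[m["gland"]] = spec.gland_echogenicity_mean
        img[m["band"]] = spec.band_echogenicity_mean
        if spec.band_texture_contrast > 0:
            trng = rng_for(spec.texture_seed, "band-texture")
            fieldn = ndimage.gaussian_filter(trng.standard_normal((H, W)), 3.0)
            fieldn /= max(fieldn.std(), 1e-9)
            img[m["band"]] *= np.clip(1.0 + spec.band_texture_contrast * fieldn[m["band"]], 0.2, 1.8)
        if spec.band_core_darkening > 0:
            img[m["band_core"]] *= 1.0 - spec.band_core_darkening
    img = ndimage.gaussian_filter(img, 1.0)
    img[m["background"]] = BACKGROUND_LEVEL  # keep the background strictly sub-threshold
    return img


def _shift_zero(img: np.ndarray, dr: int, dc: int, fill: float) -> np.ndarray:
    out = np.full_like(img, fill)
    H, W = img.shape
    r0s, r0d = (0, dr) if dr >= 0 else (-dr, 0)
    c0s, c0d = (0, dc) if dc >= 0 else (-dc, 0)
    h = H - abs(dr)
    w = W - abs(dc)
    if h > 0 and w > 0:
        out[r0d : r0d + h, c0d : c0d + w] = img[r0s : r0s + h, c0s : c0s + w]
    return out


def render_frame(
    spec: PhantomSpec,
    frame_index: int = 0,
    artifacts: ArtifactProfile | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Render one 8-bit grayscale frame of an individual.

    Speckle is multiplicative gamma noise (unit mean, shape
    ``spec.speckle_shape``) applied inside the specimen only; artifacts are
    applied last, overlay outermost.
    """
    if frame_index < 0:
        raise ValueError("frame_index must be >= 0")
    art = artifacts or _CLEAN
    img = noiseless_phantom(spec, frame_index, art, seed)
    m = phantom_masks(spec, frame_index, seed)
    if spec.speckle_shape is not None and np.isfinite(spec.speckle_shape):
        srng = rng_for(seed, "speckle", spec.individual_id, frame_index)
        k = spec.speckle_shape
        noise = srng.gamma(shape=k, scale=1.0 / k, size=img.shape)
        img = np.where(m["specimen"], img * noise, img)

    if art.echo_ghost:
        dr, dc = art.ghost_offset
        if abs(dr) >= spec.canvas_h or abs(dc) >= spec.canvas_w:
            raise ValueError("ghost offset exceeds canvas")
        ghost = _shift_zero(np.where(m["specimen"], img, 0.0), dr, dc, 0.0)
        img = img + art.ghost_gain * ghost

    if art.truncate_fov and art.truncate_frac > 0:
        # push part of the specimen past the bottom-right corner so that the
        # foreground touches two image borders (incomplete capture)
        cr, cc = spec.ellipse_center
        ar, ac = spec.ellipse_axes
        dr = int(math.ceil(spec.canvas_h - (cr + ar))) + max(1, int(art.truncate_frac * ar))
        dc = int(math.ceil(spec.canvas_w - (cc + ac))) + max(1, int(art.truncate_frac * ac))
        img = _shift_zero(img, dr, dc, BACKGROUND_LEVEL)

    img = np.clip(img, 0, 255)

    if art.overlay_border and art.border_px > 0:
        b = art.border_px
        if 2 * b >= min(img.shape):
            raise ValueError("overlay border consumes the entire frame")
        img[:b, :] = OVERLAY_BORDER_VALUE
        img[-b:, :] = OVERLAY_BORDER_VALUE
        img[:, :b] = OVERLAY_BORDER_VALUE
        img[:, -b:] = OVERLAY_BORDER_VALUE
        t = art.text_band_px
        if t > 0:
            orng = rng_for(seed, "overlay-text", spec.individual_id, frame_index)
            band = img[b : b + t, b:-b]
            # blocky pseudo-text: bright glyph-like cells on a dark strip
            cells = orng.random((t // 2 + 1, band.shape[1] // 3 + 1)) < 0.45
            glyphs = np.kron(cells, np.ones((2, 3)))[: band.shape[0], : band.shape[1]]
            band[:] = np.where(glyphs > 0, OVERLAY_TEXT_VALUE, 12)

    return np.round(img).astype(np.uint8)


# ---------------------------------------------------------------------------
# dataset generation


@dataclass(frozen=True)
class DatasetConfig:
    """Field-shaped dataset layout: individuals per sex and size class, uneven
    frames per individual, defect rates, and the device overlay.

    Defaults describe a filtered large-animal cohort: 22 individuals per sex,
    5-12 frames each (uneven), with roughly a third of raw frames carrying a
    quality defect.
    """

    n_per_sex: int = 22
    size_classes: tuple[str, ...] = ("large",)
    frames_min: int = 5
    frames_max: int = 12
    canvas: tuple[int, int] = (128, 128)
    locations: tuple[str, ...] = ("BML",)
    start_date: datetime.date = datetime.date(2024, 3, 1)
    ghost_rate: float = 0.18
    suppress_rate: float = 0.08
    truncate_rate: float = 0.08
    overlay_border_px: int = 12
    overlay_text_px: int = 8
    population: PopulationParams = field(default_factory=PopulationParams)

    def __post_init__(self):
        if self.n_per_sex <= 0 or self.frames_min <= 0 or self.frames_max < self.frames_min:
            raise ValueError("counts must be positive and frames_max >= frames_min")
        for r in (self.ghost_rate, self.suppress_rate, self.truncate_rate):
            if not (0.0 <= r <= 1.0):
                raise ValueError("defect rates must be probabilities")


MANIFEST_COLUMNS = [
    "path",
    "individual_id",
    "location",
    "sex",
    "size_class",
    "date",
    "quality_pass",
    "defect_codes",
]


def generate_frames(
    config: DatasetConfig | None = None, seed: int = 0
) -> tuple[list[np.ndarray], pd.DataFrame]:
    """Generate a dataset in memory: (frames, manifest).

    The manifest has one row per frame (columns ``MANIFEST_COLUMNS`` plus
    ``frame_index``); ``path`` is the canonical filename. ``quality_pass``
    is the ground-truth flag: True iff no defect was injected.
    """
    cfg = config or DatasetConfig()
    frames: list[np.ndarray] = []
    rows: list[dict] = []
    idx_counter = 0
    for size_class in cfg.size_classes:
        for sex in SEXES:
            for i in range(cfg.n_per_sex):
                spec = sample_individual(
                    sex, size_class, cfg.population, seed=seed, index=i, canvas=cfg.canvas
                )
                irng = rng_for(seed, "frames-of", spec.individual_id)
                n_frames = int(irng.integers(cfg.frames_min, cfg.frames_max + 1))
                location = cfg.locations[idx_counter % len(cfg.locations)]
                date = cfg.start_date + datetime.timedelta(days=idx_counter)
                for f in range(n_frames):
                    drng = rng_for(seed, "defects", spec.individual_id, f)
                    art = ArtifactProfile(
                        echo_ghost=bool(drng.random() < cfg.ghost_rate),
                        suppress_gonad=bool(drng.random() < cfg.suppress_rate),
                        truncate_fov=bool(drng.random() < cfg.truncate_rate),
                        overlay_border=cfg.overlay_border_px > 0,
                        border_px=cfg.overlay_border_px,
                        text_band_px=cfg.overlay_text_px,
                    )
                    img = render_frame(spec, f, art, seed=seed)
                    meta = FrameMeta(spec.individual_id, location, sex, size_class, date, f)
                    frames.append(img)
                    rows.append(
                        {
                            "path": format_filename(meta),
                            "individual_id": spec.individual_id,
                            "location": location,
                            "sex": sex,
                            "size_class": size_class,
                            "date": date.isoformat(),
                            "frame_index": f,
                            "quality_pass": art.defect_codes == "",
                            "defect_codes": art.defect_codes,
                        }
                    )
                idx_counter += 1
    manifest = pd.DataFrame(rows, columns=MANIFEST_COLUMNS + ["frame_index"])
    return frames, manifest


def generate_dataset(
    config: DatasetConfig | None = None, out_dir: str | os.PathLike = ".", seed: int = 0
) -> pd.DataFrame:
    """Render a dataset to ``out_dir`` as PNGs plus ``manifest.csv``; returns the manifest."""
    frames, manifest = generate_frames(config, seed)
    out = os.fspath(out_dir)
    os.makedirs(out, exist_ok=True)
    for img, path in zip(frames, manifest["path"]):
        Image.fromarray(img, mode="L").save(os.path.join(out, path))
    manifest.to_csv(os.path.join(out, "manifest.csv"), index=False)
    return manifest
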
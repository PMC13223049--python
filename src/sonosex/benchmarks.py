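"""Standard synthetic benchmark conditions.

These fix the experimental conditions used throughout the test suite and
documentation, so every claim about pipeline behaviour refers to one named,
reproducible setting:

* **zero-effect null** — female and male populations identical; any
  classifier beating chance on unseen individuals indicates leakage.
* **linear effect** — purely photometric dimorphism (global echogenicity
  shifts, identical geometry), the kind of signal a linear pixel-space model
  can represent.
* **strong geometry effect** — a large, clean band-thickness dimorphism with
  no compensating brightness difference; the recovery benchmark for the
  convolutional models.
* **speckle contrast** — heavy speckle with a weak textural sex effect, the
  regime where channel compression is argued to help; used for the
  reverse-vs-forward family comparison.

The cohort shape (14 individuals per sex, 5 frames each, 2 validation and 4
test individuals per sex) keeps unseen-individual evaluation meaningful at
desk scale while staying small enough for CPU runs.
"""

from __future__ import annotations

from .synthdata import DatasetConfig, PopulationParams

COHORT = dict(
    n_per_sex=14,
    frames_min=5,
    frames_max=5,
    canvas=(96, 96),
    ghost_rate=0.0,
    suppress_rate=0.0,
    truncate_rate=0.0,
    overlay_border_px=0,
    overlay_text_px=0,
)

N_VAL_PER_SEX = 2
N_TEST_PER_SEX = 4


def zero_effect_config(**overrides) -> DatasetConfig:
    """Sexes statistically identical; the null for leakage checks."""
    kw = {**COHORT, "population": PopulationParams(effect_size=0.0), **overrides}
    return DatasetConfig(**kw)


def linear_effect_config(**overrides) -> DatasetConfig:
    """Photometric-only dimorphism: males uniformly more echogenic.

    Geometry (band thickness, core, texture) is sex-independent, so the
    class signal is a global intensity shift — linear in pixel space.
    """
    # offsets ~5x the population sd of each echogenicity parameter, so the
    # photometric shift dominates anatomical variability
    pop = PopulationParams(
        effect_size=1.0,
        band_thickness_sex_offset=0.0,
        band_echogenicity_sex_offset=40.0,
        gland_echogenicity_sex_offset=25.0,
        tissue_echogenicity_sex_offset=18.0,
        band_core_darkening_female_extra=0.0,
        band_texture_contrast_female_extra=0.0,
    )
    kw = {**COHORT, "population": pop, **overrides}
    return DatasetConfig(**kw)


def strong_geometry_config(**overrides) -> DatasetConfig:
    """Large, clean band-thickness dimorphism (females' gonad band several
    times thicker), with photometric parameters sex-independent so the
    geometric signal is not masked by brightness compensation."""
    pop = PopulationParams(
        effect_size=2.5,
        band_echogenicity_sex_offset=0.0,
        band_core_darkening_female_extra=0.0,
        band_texture_contrast_female_extra=0.0,
    )
    kw = {**COHORT, "population": pop, **overrides}
    return DatasetConfig(**kw)


def speckle_contrast_config(**overrides) -> DatasetConfig:
    """High-speckle, weak-texture sex effect: the noisy regime for the
    forward-vs-reverse family comparison."""
    pop = PopulationParams(
        effect_size=1.5,
        band_echogenicity_sex_offset=0.0,
        band_core_darkening_female_extra=0.0,
        band_texture_contrast_female_extra=0.0,
        speckle_shape=(4.0, 0.5),
    )
    kw = {**COHORT, "population": pop, **overrides}
    return DatasetConfig(**kw)
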
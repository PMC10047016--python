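"""Configuration objects for the synthetic CEM cohort and pipeline runs.

A contrast-enhanced mammography (CEM) exam yields two co-registered
grayscale images per finding: a low-energy image reflecting radiographic
tissue density (the *density* channel) and a recombined image reflecting
iodine uptake (the *contrast* channel).  The synthetic cohort generator
emulates the statistical structure of a 159-finding diagnostic CEM cohort:
a benign / high-risk / atypia / malignant pathology mix, malignant lesions
whose intensity is more concentrated around the center of mass than benign
ones, background parenchymal texture, and clinical covariates with a
configurable age-malignancy odds ratio.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Mapping

from .errors import ConfigurationError

#: Finding-level pathology classes, in canonical order.
CLASS_LABELS = ("benign", "high_risk", "atypia", "malignant")

#: Image channels of a CEM exam.
CHANNELS = ("density", "contrast")

#: Full scale of the 16-bit intensity range used for generated images.
FULL_SCALE = 65535.0

# Class mix of the reference 159-finding cohort (benign 70, high-risk 10,
# atypia 8, malignant 71).
DEFAULT_CLASS_MIX: Mapping[str, float] = {
    "benign": 70 / 159,
    "high_risk": 10 / 159,
    "atypia": 8 / 159,
    "malignant": 71 / 159,
}

#: Fraction of malignant findings that are invasive (51 of 71).
DEFAULT_INVASIVE_FRACTION = 51 / 71


def _table_fractions(counts: Mapping[str, int]) -> dict[str, float]:
    total = sum(counts.values())
    return {k: v / total for k, v in counts.items()}


@dataclass(frozen=True)
class CovariateParams:
    """Distributions of the clinical and demographic covariates.

    Ages are drawn from class-conditional normals with common standard
    deviation; the malignant-class mean is shifted so that the log-odds of
    malignancy is exactly linear in age with slope
    ``log(age_or_per_year)`` (equal-variance normal discriminant identity:
    ``slope = (mu_mal - mu_other) / sd**2``).  Menopausal status is a
    noisy threshold of age.  The remaining categoricals are drawn
    independently of class.
    """

    age_mean_nonmalignant: float = 52.0
    age_sd: float = 12.0
    age_min: float = 18.0
    age_max: float = 100.0
    menopause_age_threshold: float = 51.5
    menopause_noise_sd: float = 3.0
    history_prob: float = 60 / 159
    race_probs: Mapping[str, float] = field(
        default_factory=lambda: _table_fractions(
            {
                "White": 125,
                "Black": 23,
                "Asian or Pacific Islander": 4,
                "Other Race or Race Not Recorded": 7,
            }
        )
    )
    density_probs: Mapping[str, float] = field(
        default_factory=lambda: _table_fractions(
            {
                "Fatty": 10,
                "Scattered": 69,
                "Heterogeneously Dense": 58,
                "Extremely Dense": 22,
            }
        )
    )
    bpe_probs: Mapping[str, float] = field(
        default_factory=lambda: _table_fractions(
            {"Minimal": 117, "Moderate": 36, "Marked": 6}
        )
    )
    finding_category_probs: Mapping[str, float] = field(
        default_factory=lambda: _table_fractions(
            {
                "Mass": 64,
                "Asymmetry": 45,
                "Calcifications": 32,
                "Architectural Distortion": 9,
                "Non-Mass Enhancement": 8,
                "Solitary Dilated Duct": 1,
            }
        )
    )

    def __post_init__(self) -> None:
        for name in ("race_probs", "density_probs", "bpe_probs", "finding_category_probs"):
            probs = getattr(self, name)
            if abs(sum(probs.values()) - 1.0) > 1e-9:
                raise ConfigurationError(f"{name} must sum to 1")
        if not 0 <= self.history_prob <= 1:
            raise ConfigurationError("history_prob must be in [0, 1]")
        if self.age_sd <= 0:
            raise ConfigurationError("age_sd must be positive")


@dataclass(frozen=True)
class CohortConfig:
    """All parameters of the synthetic CEM cohort generator.

    Lesions have an isotropic radial intensity profile
    ``amplitude * exp(-decay * r)`` on top of a low-frequency background
    field plus i.i.d. Gaussian noise.  The profile is parameterized by the
    *total integrated lesion mass* rather than the peak amplitude
    (``amplitude = mass * decay**2 / (2*pi)``), so a faster decay means the
    same lesion burden concentrated closer to the center — the ordering
    observed for malignant versus benign findings.  Invasive malignancies
    receive an extra decay increment on the density channel only.

    Parameters
    ----------
    n_findings
        Number of findings in the cohort.
    class_mix
        Proportions over the four pathology classes.
    invasive_fraction
        Fraction of malignant findings flagged invasive.
    exact_mix
        If True (default), class counts are allocated deterministically by
        largest remainder so a 159-finding cohort reproduces the reference
        70/10/8/71 split exactly; if False they are drawn multinomially.
    image_size
        Side length of the square ROI in pixels.
    decay_benign, decay_malignant, decay_invasive_extra
        Radial decay rates (1/pixel).  Benign, high-risk and atypia
        findings share ``decay_benign``.
    decay_jitter_sd
        Standard deviation of the per-case, per-channel lognormal jitter
        applied to the class decay rate.  Independent jitter across
        channels makes the two channels carry partially independent
        signal.
    lesion_mass
        Total integrated lesion intensity on the density channel.
    contrast_snr
        Ratio of lesion enhancement amplitude (at the benign decay) to the
        background-enhancement texture amplitude on the contrast channel.
    background_mean, contrast_background_mean
        Flat background levels per channel (intensity units; full scale is
        65535).
    background_texture_amplitude, contrast_texture_amplitude
        Standard deviation of the low-frequency background texture per
        channel; on the contrast channel it is further scaled by the
        case's background parenchymal enhancement (BPE) category.
    noise_sd
        Additive Gaussian pixel noise standard deviation.
    anisotropy
        Axis stretch factor of the lesion kernel (1 = isotropic).
    age_or_per_year
        Odds ratio linking one year of age to malignancy.
    """

    n_findings: int = 159
    class_mix: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_CLASS_MIX))
    invasive_fraction: float = DEFAULT_INVASIVE_FRACTION
    exact_mix: bool = True
    image_size: int = 300
    decay_benign: float = 0.04
    decay_malignant: float = 0.08
    decay_invasive_extra: float = 0.04
    decay_jitter_sd: float = 0.35
    anisotropy: float = 1.0
    lesion_mass: float = 2.5e7
    contrast_snr: float = 4.0
    background_mean: float = 0.20 * FULL_SCALE
    contrast_background_mean: float = 0.08 * FULL_SCALE
    background_texture_amplitude: float = 3000.0
    contrast_texture_amplitude: float = 1500.0
    texture_correlation_frac: float = 0.125
    bpe_texture_factors: Mapping[str, float] = field(
        default_factory=lambda: {"Minimal": 1.0, "Moderate": 1.6, "Marked": 2.6}
    )
    noise_sd: float = 1500.0
    center_jitter_frac: float = 0.10
    age_or_per_year: float = 1.07
    covariate_params: CovariateParams = field(default_factory=CovariateParams)
    seed: int = 0

    def __post_init__(self) -> None:
        if set(self.class_mix) != set(CLASS_LABELS):
            raise ConfigurationError(
                f"class_mix must have exactly the keys {CLASS_LABELS}"
            )
        if abs(sum(self.class_mix.values()) - 1.0) > 1e-9:
            raise ConfigurationError("class_mix must sum to 1")
        if min(self.class_mix.values()) < 0:
            raise ConfigurationError("class_mix proportions must be non-negative")
        for name in ("decay_benign", "decay_malignant"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if self.decay_invasive_extra < 0:
            raise ConfigurationError("decay_invasive_extra must be non-negative")
        if self.decay_malignant <= self.decay_benign:
            raise ConfigurationError(
                "decay_malignant must exceed decay_benign (malignant lesions "
                "are more centrally concentrated)"
            )
        if self.n_findings < 2:
            raise ConfigurationError("n_findings must be at least 2")
        if self.image_size < 16:
            raise ConfigurationError("image_size must be at least 16 pixels")
        if not 0 <= self.invasive_fraction <= 1:
            raise ConfigurationError("invasive_fraction must be in [0, 1]")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be non-negative")
        if self.contrast_snr <= 0:
            raise ConfigurationError("contrast_snr must be positive")
        if self.anisotropy <= 0:
            raise ConfigurationError("anisotropy must be positive")
        if self.age_or_per_year <= 0:
            raise ConfigurationError("age_or_per_year must be positive")

    @property
    def age_malignant_shift(self) -> float:
        """Age-mean shift of the malignant class implied by the odds ratio."""
        p = self.covariate_params
        return math.log(self.age_or_per_year) * p.age_sd**2

    def lesion_total_mass(self, channel: str) -> float:
        """Total integrated lesion intensity for a channel."""
        if channel == "density":
            return self.lesion_mass
        if channel == "contrast":
            # contrast_snr fixes the benign-decay peak amplitude relative
            # to the background texture amplitude
            amplitude = self.contrast_snr * self.contrast_texture_amplitude
            return amplitude * 2.0 * math.pi / self.decay_benign**2
        raise ConfigurationError(f"unknown channel {channel!r}")

    def replace(self, **kwargs) -> "CohortConfig":
        """Return a copy with the given fields replaced."""
        return dataclasses.replace(self, **kwargs)


@dataclass(frozen=True)
class RunConfig:
    """Parameters of a full simulate-to-report pipeline run."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    n_bands: int = 32
    cv_folds: int = 5
    cv_reps: int = 5
    tasks: tuple[str, ...] = ("malignant_vs_benign", "invasive_vs_noninvasive")
    feature_sets: tuple[str, ...] = ("density", "contrast", "concatenated")
    include_atypia_as_benign: bool = False
    make_figures: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_bands < 2:
            raise ConfigurationError("n_bands must be at least 2")
        if self.cv_folds < 2 or self.cv_reps < 1:
            raise ConfigurationError("cv_folds >= 2 and cv_reps >= 1 required")
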
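"""Synthetic CEM cohort generator.

Every downstream stage of the pipeline (ingestion, radial features,
classification, clinical models) is exercised on cohorts produced here,
since real CEM image archives are not publicly deposited.  The generator
emulates the three statistical structures the analysis relies on:

* malignant lesions concentrate their intensity closer to the center of
  mass than benign lesions (class-dependent radial decay rate, with
  invasive malignancies decaying faster still on the density channel);
* images carry low-frequency background parenchymal texture — scaled by
  the BPE category on the contrast channel — plus Gaussian pixel noise;
* covariates with a configurable log-linear age-malignancy link and a
  menopausal status driven by age.

Identical :class:`~cemradial.config.CohortConfig` objects (same seed)
produce bit-identical cohorts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .config import CHANNELS, CLASS_LABELS, FULL_SCALE, CohortConfig
from .errors import ConfigurationError, DataError
from .ingest import Case

try:  # tifffile is a hard dependency; import here for the writer
    import tifffile
except ImportError as exc:  # pragma: no cover
    raise ImportError("cemradial requires tifffile for image IO") from exc

_CONTOUR_VERTICES = 64


@dataclass
class SyntheticCohort:
    """A generated cohort: cases, the config used, and a file manifest."""

    cases: list[Case]
    config_used: CohortConfig
    manifest: pd.DataFrame


def _largest_remainder_counts(mix: dict[str, float], n: int) -> dict[str, int]:
    """Deterministic integer allocation of n items to proportions."""
    raw = {k: mix[k] * n for k in CLASS_LABELS}
    counts = {k: int(math.floor(v)) for k, v in raw.items()}
    remainder = n - sum(counts.values())
    order = sorted(CLASS_LABELS, key=lambda k: raw[k] - counts[k], reverse=True)
    for k in order[:remainder]:
        counts[k] += 1
    return counts


def draw_class_labels(
    config: CohortConfig, rng: np.random.Generator
) -> tuple[list[str], list[bool]]:
    """Draw per-finding class labels and invasive flags.

    With ``exact_mix`` the class counts follow a largest-remainder
    allocation of the configured proportions (and the invasive count is
    ``round(invasive_fraction * n_malignant)``); otherwise both are drawn
    from the corresponding multinomial/binomial.  The case order is
    shuffled either way.
    """
    n = config.n_findings
    if config.exact_mix:
        counts = _largest_remainder_counts(dict(config.class_mix), n)
    else:
        p = [config.class_mix[k] for k in CLASS_LABELS]
        drawn = rng.multinomial(n, p)
        counts = dict(zip(CLASS_LABELS, (int(v) for v in drawn)))
    labels: list[str] = []
    for k in CLASS_LABELS:
        labels.extend([k] * counts[k])
    n_mal = counts["malignant"]
    if config.exact_mix:
        n_inv = int(round(config.invasive_fraction * n_mal))
    else:
        n_inv = int(rng.binomial(n_mal, config.invasive_fraction)) if n_mal else 0
    invasive_pool = [True] * n_inv + [False] * (n_mal - n_inv)
    rng.shuffle(invasive_pool)
    order = rng.permutation(n)
    labels = [labels[i] for i in order]
    inv_iter = iter(invasive_pool)
    invasive = [next(inv_iter) if lab == "malignant" else False for lab in labels]
    return labels, invasive


def generate_covariates(
    class_labels: list[str],
    params: CohortConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Draw the clinical/demographic covariate table for given labels.

    Age is drawn from class-conditional equal-variance normals whose mean
    shift encodes ``age_or_per_year`` exactly on the log-odds scale;
    menopausal status thresholds age plus noise; the remaining categories
    are independent of class.
    """
    if len(class_labels) == 0:
        raise DataError("class_labels must be non-empty")
    for lab in class_labels:
        if lab not in CLASS_LABELS:
            raise ConfigurationError(f"unknown class label {lab!r}")
    cp = params.covariate_params
    n = len(class_labels)
    is_mal = np.array([lab == "malignant" for lab in class_labels])
    means = np.where(
        is_mal,
        cp.age_mean_nonmalignant + params.age_malignant_shift,
        cp.age_mean_nonmalignant,
    )
    age = rng.normal(means, cp.age_sd)
    age = np.clip(age, cp.age_min, cp.age_max)
    meno_noise = rng.normal(0.0, cp.menopause_noise_sd, size=n)
    menopause = np.where(
        age + meno_noise > cp.menopause_age_threshold, "post", "pre"
    )
    race = rng.choice(
        list(cp.race_probs), size=n, p=list(cp.race_probs.values())
    )
    history = rng.random(n) < cp.history_prob
    density = rng.choice(
        list(cp.density_probs), size=n, p=list(cp.density_probs.values())
    )
    bpe = rng.choice(list(cp.bpe_probs), size=n, p=list(cp.bpe_probs.values()))
    finding = rng.choice(
        list(cp.finding_category_probs),
        size=n,
        p=list(cp.finding_category_probs.values()),
    )
    return pd.DataFrame(
        {
            "class": class_labels,
            "age": np.round(age, 3),
            "race": race,
            "history": history,
            "menopause": menopause,
            "density_category": density,
            "bpe": bpe,
            "finding_category": finding,
        }
    )


def _class_decay(
    config: CohortConfig, class_label: str, channel: str, invasive: bool
) -> float:
    if class_label not in CLASS_LABELS:
        raise ConfigurationError(f"unknown class label {class_label!r}")
    if channel not in CHANNELS:
        raise ConfigurationError(f"unknown channel {channel!r}")
    if class_label != "malignant":
        return config.decay_benign
    decay = config.decay_malignant
    if invasive and channel == "density":
        # invasive disease shows up in the density channel only
        decay += config.decay_invasive_extra
    return decay


def _elliptic_radius(
    shape: tuple[int, int], center: tuple[float, float], anisotropy: float
) -> np.ndarray:
    rows = np.arange(shape[0], dtype=float)[:, None]
    cols = np.arange(shape[1], dtype=float)[None, :]
    dy = (rows - center[0]) * anisotropy
    dx = (cols - center[1]) / anisotropy
    return np.hypot(dy, dx)


def _background_field(
    size: int,
    mean: float,
    amplitude: float,
    correlation_frac: float,
    rng: np.random.Generator,
) -> np.ndarray:
    field = np.full((size, size), mean, dtype=float)
    if amplitude > 0:
        noise = rng.standard_normal((size, size))
        sigma = max(correlation_frac * size, 1.0)
        smooth = ndimage.gaussian_filter(noise, sigma=sigma, mode="reflect")
        sd = smooth.std()
        if sd > 0:
            field += amplitude * smooth / sd
    return field


def _half_max_contour(
    center: tuple[float, float], decay: float, anisotropy: float, size: int
) -> np.ndarray:
    """Half-maximum isocontour of the noiseless lesion kernel (an ellipse)."""
    rho = math.log(2.0) / decay
    theta = np.linspace(0.0, 2.0 * math.pi, _CONTOUR_VERTICES, endpoint=False)
    x = center[1] + rho * anisotropy * np.cos(theta)
    y = center[0] + (rho / anisotropy) * np.sin(theta)
    x = np.clip(x, 0.0, size - 1.0)
    y = np.clip(y, 0.0, size - 1.0)
    return np.column_stack([x, y])


def generate_lesion_image(
    class_label: str,
    channel: str,
    params: CohortConfig,
    rng: np.random.Generator,
    invasive: bool = False,
    bpe: str = "Minimal",
    center: tuple[float, float] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Generate one ROI image and its lesion contour.

    The lesion kernel has radial profile ``amplitude * exp(-decay * r)``
    with amplitude fixed by the channel's total lesion mass, placed at a
    jittered interior point on a textured background; pixel noise is
    added and the result is clipped to the 16-bit range and quantized.
    The two channels of a CEM exam are co-registered, so when generating
    a case the same ``center`` must be passed for both channels; without
    it a jittered interior point is drawn from ``rng``.

    Returns
    -------
    image : uint16 ndarray of shape (image_size, image_size)
    contour : (64, 2) float array of (x, y) vertices approximating the
        lesion's half-maximum isocontour.
    """
    size = params.image_size
    decay = _class_decay(params, class_label, channel, invasive)
    decay *= math.exp(rng.normal(0.0, params.decay_jitter_sd))
    if center is None:
        jitter = params.center_jitter_frac * size
        center = (
            size / 2.0 + rng.uniform(-jitter, jitter),
            size / 2.0 + rng.uniform(-jitter, jitter),
        )
    mass = params.lesion_total_mass(channel)
    amplitude = mass * decay**2 / (2.0 * math.pi)
    r = _elliptic_radius((size, size), center, params.anisotropy)
    lesion = amplitude * np.exp(-decay * r)
    if channel == "density":
        bg_mean = params.background_mean
        bg_amp = params.background_texture_amplitude
    else:
        bg_mean = params.contrast_background_mean
        factor = params.bpe_texture_factors.get(bpe, 1.0)
        bg_amp = params.contrast_texture_amplitude * factor
    image = _background_field(
        size, bg_mean, bg_amp, params.texture_correlation_frac, rng
    )
    image += lesion
    if params.noise_sd > 0:
        image += rng.normal(0.0, params.noise_sd, size=(size, size))
    image = np.clip(image, 0.0, FULL_SCALE)
    image = np.rint(image).astype(np.uint16)
    contour = _half_max_contour(center, decay, params.anisotropy, size)
    return image, contour


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Generate a full synthetic cohort from a configuration.

    The seed stream is split per stage and per case, so regeneration with
    the same config is bit-identical and independent of how the caller
    consumes the cohort.
    """
    base = np.random.SeedSequence(config.seed)
    ss_labels, ss_cov, ss_cases = base.spawn(3)
    rng_labels = np.random.default_rng(ss_labels)
    labels, invasive = draw_class_labels(config, rng_labels)
    rng_cov = np.random.default_rng(ss_cov)
    covariates = generate_covariates(labels, config, rng_cov)
    case_seeds = ss_cases.spawn(config.n_findings)
    cases: list[Case] = []
    rows = []
    for i, (lab, inv) in enumerate(zip(labels, invasive)):
        rng = np.random.default_rng(case_seeds[i])
        cov = covariates.iloc[i]
        jitter = config.center_jitter_frac * config.image_size
        center = (
            config.image_size / 2.0 + rng.uniform(-jitter, jitter),
            config.image_size / 2.0 + rng.uniform(-jitter, jitter),
        )
        density, contour = generate_lesion_image(
            lab, "density", config, rng, invasive=inv, bpe=cov["bpe"], center=center
        )
        contrast, _ = generate_lesion_image(
            lab, "contrast", config, rng, invasive=inv, bpe=cov["bpe"], center=center
        )
        case_id = f"case_{i:04d}"
        size = config.image_size
        case = Case(
            case_id=case_id,
            density_image=density,
            contrast_image=contrast,
            contour=contour,
            box=(0, 0, size - 1, size - 1),
            class_label=lab,
            invasive_flag=inv if lab == "malignant" else None,
            age=float(cov["age"]),
            race=str(cov["race"]),
            history=bool(cov["history"]),
            menopause=str(cov["menopause"]),
            density_category=str(cov["density_category"]),
            bpe=str(cov["bpe"]),
            finding_category=str(cov["finding_category"]),
        )
        cases.append(case)
        rows.append(
            {
                "case_id": case_id,
                "density_path": f"images/{case_id}_density.tif",
                "contrast_path": f"images/{case_id}_contrast.tif",
                "contour_path": f"contours/{case_id}.csv",
                "class": lab,
                "invasive_flag": (inv if lab == "malignant" else ""),
                "age": float(cov["age"]),
                "race": str(cov["race"]),
                "history": bool(cov["history"]),
                "menopause": str(cov["menopause"]),
                "density_category": str(cov["density_category"]),
                "bpe": str(cov["bpe"]),
                "finding_category": str(cov["finding_category"]),
                "box": f"0;0;{size - 1};{size - 1}",
            }
        )
    manifest = pd.DataFrame(rows)
    return SyntheticCohort(cases=cases, config_used=config, manifest=manifest)


def _config_echo(config: CohortConfig) -> str:
    """Serialize a CohortConfig as a flat TOML-style key/value document."""
    lines = ["[cohort]"]
    import dataclasses

    for f in dataclasses.fields(config):
        value = getattr(config, f.name)
        if isinstance(value, (int, float, bool)):
            lines.append(f"{f.name} = {value!r}")
        elif isinstance(value, str):
            lines.append(f'{f.name} = "{value}"')
        elif isinstance(value, dict):
            lines.append(f"[cohort.{f.name}]")
            for k, v in value.items():
                lines.append(f'"{k}" = {v!r}')
        else:  # nested dataclass
            lines.append(f"[cohort.{f.name}]")
            for g in dataclasses.fields(value):
                v = getattr(value, g.name)
                if isinstance(v, dict):
                    lines.append(f"[cohort.{f.name}.{g.name}]")
                    for k, vv in v.items():
                        lines.append(f'"{k}" = {vv!r}')
                else:
                    lines.append(f"{g.name} = {v!r}")
    return "\n".join(lines) + "\n"


def write_cohort(cohort: SyntheticCohort, out_dir: Path | str) -> Path:
    """Write a cohort to disk and return the manifest path.

    Layout: ``images/*.tif`` (16-bit grayscale TIFF), ``contours/*.csv``
    (columns x,y in 0-based pixel units), ``manifest.csv``, and
    ``config.toml`` echoing the generator configuration.  Round-trip
    reads reproduce pixel values exactly.
    """
    out = Path(out_dir)
    try:
        (out / "images").mkdir(parents=True, exist_ok=True)
        (out / "contours").mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise DataError(f"cannot create output directory {out}: {exc}") from exc
    for case, (_, row) in zip(cohort.cases, cohort.manifest.iterrows()):
        tifffile.imwrite(out / row["density_path"], case.density_image)
        tifffile.imwrite(out / row["contrast_path"], case.contrast_image)
        pd.DataFrame(case.contour, columns=["x", "y"]).to_csv(
            out / row["contour_path"], index=False
        )
    manifest_path = out / "manifest.csv"
    cohort.manifest.to_csv(manifest_path, index=False)
    (out / "config.toml").write_text(_config_echo(cohort.config_used))
    return manifest_path
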
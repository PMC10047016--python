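"""Radial-distribution features around a lesion's center of mass.

The core quantitative feature: concentric equal-width annuli (bands) are
laid around the intensity-weighted center of mass of the contour-masked
density image, each pixel is assigned to the band containing its
center-to-center distance, band masses are summed and divided by the
band's empirical pixel area, and the per-area profile is rescaled to unit
sum.  Malignant lesions concentrate intensity in the innermost bands.

The center is computed once from the density channel and reused for the
contrast channel, so the two histograms are spatially aligned and can be
concatenated into a single feature vector.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import DataError, DegenerateInputError
from .ingest import Case, ContourMask, rasterize_contour

logger = logging.getLogger(__name__)


@dataclass
class RadialHistogram:
    """Area-normalized radial intensity distribution of one image.

    Attributes
    ----------
    values
        Length-B non-negative vector summing to 1 (after area
        normalization and unit-sum rescaling).  Bands whose empirical
        area is zero get value 0.
    band_edges
        B+1 strictly increasing radii in pixels, starting at 0.
    center
        (row, col) continuous center the bands were drawn around.
    channel
        "density" or "contrast".
    total_mass
        Raw summed intensity before any normalization.
    """

    values: np.ndarray
    band_edges: np.ndarray
    center: tuple[float, float]
    channel: str
    total_mass: float

    @property
    def n_bands(self) -> int:
        return len(self.values)


def center_of_mass(image: np.ndarray, mask: ContourMask | np.ndarray) -> tuple[float, float]:
    """Intensity-weighted mean pixel coordinate over masked pixels.

    Raises :class:`DegenerateInputError` when the masked intensity sum is
    zero.
    """
    image = np.asarray(image, dtype=float)
    m = mask.mask if isinstance(mask, ContourMask) else np.asarray(mask, dtype=bool)
    if m.shape != image.shape:
        raise DataError("mask shape does not match image shape")
    total = float(image[m].sum())
    if total <= 0:
        raise DegenerateInputError("masked region has zero total intensity")
    rows, cols = np.nonzero(m)
    weights = image[rows, cols]
    return (
        float(np.dot(weights, rows) / total),
        float(np.dot(weights, cols) / total),
    )


def _r_max(shape: tuple[int, int], center: tuple[float, float]) -> float:
    h, w = shape
    corners = [(0.0, 0.0), (0.0, w - 1.0), (h - 1.0, 0.0), (h - 1.0, w - 1.0)]
    return max(np.hypot(center[0] - r, center[1] - c) for r, c in corners)


def radial_histogram(
    image: np.ndarray,
    center: tuple[float, float],
    n_bands: int,
    channel: str = "density",
    r_max: float | None = None,
    mask: np.ndarray | None = None,
    normalize: str = "area_unit_sum",
) -> RadialHistogram:
    """Histogram of intensity over concentric bands around ``center``.

    Band edges partition ``[0, r_max]`` into ``n_bands`` equal-width
    half-open intervals (the last band is closed); ``r_max`` defaults to
    the distance from the center to the farthest image-corner pixel, so
    every pixel lands in a band.  Per-band mass is divided by the band's
    empirical pixel count, which handles boundary clipping of the annuli;
    with ``normalize="area_unit_sum"`` (default) the per-area profile is
    then rescaled to unit sum, with ``"area"`` it is returned as-is.

    Empty bands (zero pixels) get value 0 and are logged at WARNING
    level, so band counts exceeding the radial extent in pixels degrade
    gracefully rather than failing.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise DataError("image must be 2-D")
    if n_bands < 2:
        raise DataError("n_bands must be at least 2")
    h, w = image.shape
    if not (0 <= center[0] <= h - 1 and 0 <= center[1] <= w - 1):
        raise DataError(f"center {center} outside image bounds")
    if normalize not in ("area_unit_sum", "area"):
        raise DataError(f"unknown normalization {normalize!r}")
    if r_max is None:
        r_max = _r_max(image.shape, center)
    if r_max <= 0:
        raise DataError("r_max must be positive")
    rows = np.arange(h, dtype=float)[:, None]
    cols = np.arange(w, dtype=float)[None, :]
    dist = np.hypot(rows - center[0], cols - center[1])
    if mask is not None:
        sel = np.asarray(mask, dtype=bool)
        if sel.shape != image.shape:
            raise DataError("mask shape does not match image shape")
    else:
        sel = np.ones_like(dist, dtype=bool)
    width = r_max / n_bands
    idx = np.floor(dist / width).astype(int)
    # the closed last band: pixels exactly at r_max (and, in masked or
    # fixed-r_max mode, anything beyond) fold into band B-1 only if they
    # are within r_max
    within = sel & (dist <= r_max)
    idx = np.clip(idx, 0, n_bands - 1)
    flat_idx = idx[within]
    mass = np.bincount(flat_idx, weights=image[within], minlength=n_bands)
    area = np.bincount(flat_idx, minlength=n_bands).astype(float)
    empty = area == 0
    if empty.any():
        logger.warning(
            "%d of %d radial bands are empty (r_max=%.2f px)",
            int(empty.sum()),
            n_bands,
            r_max,
        )
    values = np.zeros(n_bands, dtype=float)
    np.divide(mass, area, out=values, where=~empty)
    total_mass = float(mass.sum())
    if normalize == "area_unit_sum":
        s = values.sum()
        if s > 0:
            values = values / s
    edges = np.linspace(0.0, r_max, n_bands + 1)
    return RadialHistogram(
        values=values,
        band_edges=edges,
        center=(float(center[0]), float(center[1])),
        channel=channel,
        total_mass=total_mass,
    )


def concatenate_histograms(
    h_density: RadialHistogram, h_contrast: RadialHistogram
) -> np.ndarray:
    """Concatenate density and contrast histograms (density block first).

    No renormalization across blocks; each block retains its own unit
    sum.  Raises on mismatched band counts.
    """
    if h_density.n_bands != h_contrast.n_bands:
        raise DataError(
            f"band count mismatch: {h_density.n_bands} vs {h_contrast.n_bands}"
        )
    return np.concatenate([h_density.values, h_contrast.values])


def class_average_profile(
    histograms: Sequence[RadialHistogram], labels: Sequence[int]
) -> tuple[np.ndarray, np.ndarray]:
    """Unweighted per-bin mean profile for the negative and positive class.

    Returns ``(mean_negative, mean_positive)``; raises when either class
    is empty.
    """
    labels = np.asarray(labels, dtype=int)
    if len(histograms) != len(labels):
        raise DataError("histograms and labels must have equal length")
    values = np.array([h.values for h in histograms])
    out = []
    for cls in (0, 1):
        sel = labels == cls
        if not sel.any():
            raise DataError(f"class {cls} has no histograms")
        out.append(values[sel].mean(axis=0))
    return out[0], out[1]


@dataclass
class FeatureMatrix:
    """Per-case radial-histogram features for one feature set.

    ``X`` has one row per case and B columns for a single channel or 2B
    for the concatenated set (density block first).
    """

    X: np.ndarray
    y: np.ndarray
    case_ids: list[str]
    feature_set: str
    n_bands: int

    def __post_init__(self) -> None:
        if np.isnan(self.X).any():
            raise DataError("feature matrix contains missing values")
        if len(self.X) != len(self.y) or len(self.X) != len(self.case_ids):
            raise DataError("rows, labels and case_ids must align")


def case_histograms(
    case: Case,
    n_bands: int,
    mask_restricted: bool = False,
    normalize: str = "area_unit_sum",
) -> dict[str, RadialHistogram]:
    """Both channels' radial histograms for one case.

    The center of mass is computed from the contour-masked density image
    and reused for the contrast channel.  By default the histogram
    support is the full rectangular ROI (the contour is only used for the
    center); ``mask_restricted=True`` limits it to the contour interior.
    """
    cmask = rasterize_contour(case.contour, case.shape)
    center = center_of_mass(case.density_image, cmask)
    support = cmask.mask if mask_restricted else None
    return {
        "density": radial_histogram(
            case.density_image, center, n_bands, channel="density",
            mask=support, normalize=normalize,
        ),
        "contrast": radial_histogram(
            case.contrast_image, center, n_bands, channel="contrast",
            mask=support, normalize=normalize,
        ),
    }


def build_feature_matrix(
    cases: Sequence[Case],
    labels: Sequence[int],
    feature_set: str,
    n_bands: int,
    mask_restricted: bool = False,
) -> FeatureMatrix:
    """Assemble the per-case feature matrix for one feature set.

    ``feature_set`` is "density", "contrast" or "concatenated".
    """
    if feature_set not in ("density", "contrast", "concatenated"):
        raise DataError(f"unknown feature set {feature_set!r}")
    rows = []
    for case in cases:
        hists = case_histograms(case, n_bands, mask_restricted=mask_restricted)
        if feature_set == "concatenated":
            rows.append(concatenate_histograms(hists["density"], hists["contrast"]))
        else:
            rows.append(hists[feature_set].values)
    return FeatureMatrix(
        X=np.array(rows),
        y=np.asarray(labels, dtype=int),
        case_ids=[c.case_id for c in cases],
        feature_set=feature_set,
        n_bands=n_bands,
    )
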
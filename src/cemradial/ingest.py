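"""Reading and validating CEM cases: image pairs, contours, metadata.

Pixel coordinate convention throughout the package: 0-based row/column
indices with pixel centers at integer coordinates.  Contours are closed
simple polygons in (x, y) = (column, row) order, boundary-inclusive for
point-in-polygon tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import shapely
import tifffile
from shapely.geometry import Polygon

from .config import CLASS_LABELS
from .errors import DataError, InsufficientDataError

TASKS = ("malignant_vs_benign", "invasive_vs_noninvasive")

# Dichotomizations used by the clinical models: race collapses to White
# vs. all other races, breast density to dense vs. non-dense, background
# parenchymal enhancement to minimal/moderate vs. marked.
_DENSE_LEVELS = {
    "Fatty": False,
    "Scattered": False,
    "Heterogeneously Dense": True,
    "Extremely Dense": True,
}
_BPE_MARKED = {"Minimal": False, "Moderate": False, "Marked": True}
_MENOPAUSE_LEVELS = ("pre", "post")


@dataclass
class Case:
    """One finding: paired ROI images, annotation, label and covariates."""

    case_id: str
    density_image: np.ndarray
    contrast_image: np.ndarray
    contour: np.ndarray  # (n_vertices, 2) float, columns (x, y)
    box: tuple[int, int, int, int]  # (row0, col0, row1, col1), inclusive
    class_label: str
    invasive_flag: bool | None
    age: float
    race: str
    history: bool
    menopause: str  # "pre" | "post"
    density_category: str
    bpe: str
    finding_category: str | None = None

    def __post_init__(self) -> None:
        self.density_image = np.asarray(self.density_image)
        self.contrast_image = np.asarray(self.contrast_image)
        if self.density_image.ndim != 2:
            raise DataError(f"{self.case_id}: images must be 2-D")
        if self.density_image.shape != self.contrast_image.shape:
            raise DataError(
                f"{self.case_id}: channel shape mismatch "
                f"{self.density_image.shape} vs {self.contrast_image.shape}"
            )
        if np.min(self.density_image) < 0 or np.min(self.contrast_image) < 0:
            raise DataError(f"{self.case_id}: negative intensities")
        if self.class_label not in CLASS_LABELS:
            raise DataError(
                f"{self.case_id}: unknown class_label {self.class_label!r}"
            )
        if (self.class_label == "malignant") != (self.invasive_flag is not None):
            raise DataError(
                f"{self.case_id}: invasive_flag must be present iff malignant"
            )
        self.contour = np.asarray(self.contour, dtype=float)
        if self.contour.ndim != 2 or self.contour.shape[1] != 2:
            raise DataError(f"{self.case_id}: contour must be (n, 2)")
        h, w = self.density_image.shape
        xs, ys = self.contour[:, 0], self.contour[:, 1]
        if xs.min() < 0 or ys.min() < 0 or xs.max() > w - 1 or ys.max() > h - 1:
            raise DataError(f"{self.case_id}: contour vertices out of image bounds")
        if self.race not in ("White",) and not isinstance(self.race, str):
            raise DataError(f"{self.case_id}: race must be a string")
        if self.menopause not in _MENOPAUSE_LEVELS:
            raise DataError(
                f"{self.case_id}: unknown menopause level {self.menopause!r}"
            )
        if self.density_category not in _DENSE_LEVELS:
            raise DataError(
                f"{self.case_id}: unknown density_category "
                f"{self.density_category!r}"
            )
        if self.bpe not in _BPE_MARKED:
            raise DataError(f"{self.case_id}: unknown bpe level {self.bpe!r}")

    # -- covariate dichotomizations used by the regression models --------
    @property
    def race_other(self) -> bool:
        return self.race != "White"

    @property
    def dense(self) -> bool:
        return _DENSE_LEVELS[self.density_category]

    @property
    def bpe_marked(self) -> bool:
        return _BPE_MARKED[self.bpe]

    @property
    def post_menopausal(self) -> bool:
        return self.menopause == "post"

    @property
    def shape(self) -> tuple[int, int]:
        return self.density_image.shape


@dataclass
class ContourMask:
    """Boolean inclusion mask of a contour on the image pixel grid."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if not self.mask.any():
            raise DataError("contour mask contains no pixels")

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())


def rasterize_contour(contour: np.ndarray, shape: tuple[int, int]) -> ContourMask:
    """Rasterize a closed polygon onto a pixel grid.

    A pixel belongs to the mask when its center (integer coordinates) lies
    strictly inside or on the polygon boundary.

    Parameters
    ----------
    contour
        ``(n, 2)`` array of (x, y) vertices; the polygon closes itself.
    shape
        Image shape ``(rows, cols)``.
    """
    contour = np.asarray(contour, dtype=float)
    if contour.ndim != 2 or contour.shape[1] != 2 or len(contour) < 3:
        raise DataError("contour must have at least 3 (x, y) vertices")
    poly = Polygon(contour)
    if poly.area == 0 or not poly.is_valid:
        raise DataError("degenerate or self-intersecting contour polygon")
    h, w = shape
    # restrict the point-in-polygon test to the polygon bounding box
    minx, miny, maxx, maxy = poly.bounds
    c0 = max(int(np.floor(minx)), 0)
    c1 = min(int(np.ceil(maxx)), w - 1)
    r0 = max(int(np.floor(miny)), 0)
    r1 = min(int(np.ceil(maxy)), h - 1)
    mask = np.zeros(shape, dtype=bool)
    if c1 >= c0 and r1 >= r0:
        cols, rows = np.meshgrid(np.arange(c0, c1 + 1), np.arange(r0, r1 + 1))
        pts = shapely.points(cols.ravel(), rows.ravel())
        inside = shapely.covers(poly, pts).reshape(rows.shape)
        mask[r0 : r1 + 1, c0 : c1 + 1] = inside
    return ContourMask(mask)


def _parse_bool(value) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    if isinstance(value, (int, np.integer, float)):
        return bool(int(value))
    s = str(value).strip().lower()
    if s in ("true", "1", "yes"):
        return True
    if s in ("false", "0", "no"):
        return False
    raise DataError(f"cannot parse boolean value {value!r}")


def read_contour(path: Path) -> np.ndarray:
    df = pd.read_csv(path)
    if not {"x", "y"}.issubset(df.columns):
        raise DataError(f"{path}: contour file must have columns x,y")
    return df[["x", "y"]].to_numpy(dtype=float)


def read_case(manifest_row: Mapping, base_dir: Path | str) -> Case:
    """Build a validated :class:`Case` from one manifest row.

    Image and contour paths in the row are resolved relative to
    ``base_dir``.  Raises :class:`DataError` on missing files, channel
    shape mismatch, unknown category levels, or a malignant case without
    an invasive flag.
    """
    base = Path(base_dir)
    row = dict(manifest_row)
    case_id = str(row["case_id"])
    paths = {}
    for key in ("density_path", "contrast_path", "contour_path"):
        p = base / str(row[key])
        if not p.exists():
            raise DataError(f"case {case_id}: missing file {p}")
        paths[key] = p
    density = tifffile.imread(paths["density_path"])
    contrast = tifffile.imread(paths["contrast_path"])
    contour = read_contour(paths["contour_path"])
    class_label = str(row["class"])
    invasive: bool | None = None
    if class_label == "malignant":
        raw = row.get("invasive_flag")
        if raw is None or (isinstance(raw, float) and np.isnan(raw)) or str(raw) == "":
            raise DataError(f"case {case_id}: malignant case lacks invasive_flag")
        invasive = _parse_bool(raw)
    h = density.shape[0]
    w = density.shape[1] if density.ndim == 2 else 0
    box = row.get("box", (0, 0, h - 1, w - 1))
    if isinstance(box, str):
        box = tuple(int(v) for v in box.split(";"))
    return Case(
        case_id=case_id,
        density_image=density,
        contrast_image=contrast,
        contour=contour,
        box=tuple(box),
        class_label=class_label,
        invasive_flag=invasive,
        age=float(row["age"]),
        race=str(row["race"]),
        history=_parse_bool(row["history"]),
        menopause=str(row["menopause"]),
        density_category=str(row["density_category"]),
        bpe=str(row["bpe"]),
        finding_category=str(row["finding_category"])
        if "finding_category" in row
        else None,
    )


def validate_manifest(manifest_path: Path | str) -> pd.DataFrame:
    """Check that every file referenced by a manifest exists.

    Returns the manifest table; raises :class:`DataError` naming the first
    case with a missing file.
    """
    manifest_path = Path(manifest_path)
    df = pd.read_csv(manifest_path)
    base = manifest_path.parent
    for _, row in df.iterrows():
        for key in ("density_path", "contrast_path", "contour_path"):
            p = base / str(row[key])
            if not p.exists():
                raise DataError(
                    f"case {row['case_id']}: manifest references missing file {p}"
                )
    return df


def read_cohort(manifest_path: Path | str) -> list[Case]:
    """Read every case listed in a manifest CSV."""
    manifest_path = Path(manifest_path)
    df = validate_manifest(manifest_path)
    return [read_case(row, manifest_path.parent) for _, row in df.iterrows()]


@dataclass
class ExclusionLog:
    """Record of which cases a task filter kept and dropped."""

    task: str
    n_input: int
    n_retained: int
    dropped: dict[str, int] = field(default_factory=dict)


def task_label(case: Case, task: str) -> int:
    """Binary outcome of a case under a classification task (1 = positive)."""
    if task == "malignant_vs_benign":
        return 1 if case.class_label == "malignant" else 0
    if task == "invasive_vs_noninvasive":
        return 1 if case.invasive_flag else 0
    raise DataError(f"unknown task {task!r}")


def exclusion_filter(
    cases: Sequence[Case],
    task: str,
    include_atypia_as_benign: bool = False,
) -> tuple[list[Case], np.ndarray, ExclusionLog]:
    """Apply a task's inclusion rule and return cases, labels and a log.

    Task ``malignant_vs_benign`` keeps benign (negative) and malignant
    (positive) findings, dropping high-risk and — by default — atypia
    findings; ``include_atypia_as_benign=True`` instead pools atypia with
    the benign class.  Task ``invasive_vs_noninvasive`` keeps malignant
    findings only, positive = invasive.
    """
    if task not in TASKS:
        raise DataError(f"unknown task {task!r}; expected one of {TASKS}")
    kept: list[Case] = []
    dropped: dict[str, int] = {}
    for case in cases:
        if task == "malignant_vs_benign":
            keep = case.class_label in ("benign", "malignant") or (
                include_atypia_as_benign and case.class_label == "atypia"
            )
        else:
            keep = case.class_label == "malignant"
        if keep:
            kept.append(case)
        else:
            dropped[case.class_label] = dropped.get(case.class_label, 0) + 1
    labels = np.array([task_label(c, task) for c in kept], dtype=int)
    for value, name in ((1, "positive"), (0, "negative")):
        if int(np.sum(labels == value)) < 2:
            raise InsufficientDataError(
                f"task {task}: fewer than 2 {name} cases after exclusion"
            )
    log = ExclusionLog(
        task=task, n_input=len(cases), n_retained=len(kept), dropped=dropped
    )
    return kept, labels, log
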
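"""Shared domain types: severity grades, lesion classes, masks, manifests."""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class ValidationError(ValueError):
    """Input violates a structural contract (bad grade label, bounds, ...)."""


class IntegrityError(ValidationError):
    """A table violates an internal invariant (e.g. rl_count != ma + hma)."""


class SeverityGrade(enum.IntEnum):
    """ICDR severity grade restricted to the non-proliferative range.

    Proliferative DR is deliberately not representable: manifests carrying a
    ``proliferative`` label are rejected at parse time.
    """

    NO_DR = 0
    MILD = 1
    MODERATE = 2
    SEVERE = 3

    @property
    def label(self) -> str:
        return _GRADE_LABELS[self]

    @classmethod
    def from_label(cls, label: str) -> "SeverityGrade":
        try:
            return _GRADE_LOOKUP[str(label).strip()]
        except KeyError:
            raise ValidationError(
                f"unknown severity grade label {label!r}; "
                f"expected one of {sorted(set(_GRADE_LOOKUP))}"
            ) from None


_GRADE_LABELS = {
    SeverityGrade.NO_DR: "no_DR",
    SeverityGrade.MILD: "mild",
    SeverityGrade.MODERATE: "moderate",
    SeverityGrade.SEVERE: "severe",
}
_GRADE_LOOKUP = {
    "no_DR": SeverityGrade.NO_DR,
    "no_dr": SeverityGrade.NO_DR,
    "mild": SeverityGrade.MILD,
    "mild_NPDR": SeverityGrade.MILD,
    "moderate": SeverityGrade.MODERATE,
    "moderate_NPDR": SeverityGrade.MODERATE,
    "severe": SeverityGrade.SEVERE,
    "severe_NPDR": SeverityGrade.SEVERE,
}

GRADES = tuple(SeverityGrade)


def as_grade(value) -> SeverityGrade:
    """Coerce an int, label string or member to :class:`SeverityGrade`."""
    if isinstance(value, SeverityGrade):
        return value
    if isinstance(value, str):
        return SeverityGrade.from_label(value)
    return SeverityGrade(int(value))


class LesionClass(str, enum.Enum):
    """Lesion classes stored on disk.  Red lesions (RL = MA + Hma) are always
    derived downstream and never read from a file."""

    MA = "MA"
    HMA = "Hma"
    HE = "HE"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value

    @classmethod
    def from_name(cls, name: str) -> "LesionClass":
        for member in cls:
            if member.value.lower() == str(name).strip().lower():
                return member
        raise ValidationError(f"unknown lesion class {name!r}")


#: measures usable in summaries/tests: the three stored classes, the derived
#: red-lesion count and the hard-exudate area.
MEASURES = ("MA", "Hma", "RL", "HE", "HE_area")

#: count-table column associated with each measure
MEASURE_COLUMNS = {
    "MA": "ma_count",
    "Hma": "hma_count",
    "RL": "rl_count",
    "HE": "he_count",
    "HE_area": "he_area_px",
}

#: canonical column order of the counts CSV
COUNT_COLUMNS = (
    "dataset_id",
    "image_id",
    "grade",
    "ma_count",
    "hma_count",
    "rl_count",
    "he_count",
    "he_area_px",
    "he_area_fraction",
)


@dataclass
class LesionMask:
    """One binary raster for one lesion class of one image."""

    image_id: str
    lesion_class: LesionClass
    pixels: np.ndarray  # 2D bool

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValidationError(
                f"mask for {self.image_id!r} must be 2D, got shape {self.pixels.shape}"
            )
        if self.pixels.size == 0:
            raise ValidationError(f"mask for {self.image_id!r} has zero area")
        self.pixels = self.pixels.astype(bool)

    @property
    def height(self) -> int:
        return int(self.pixels.shape[0])

    @property
    def width(self) -> int:
        return int(self.pixels.shape[1])

    @property
    def foreground_pixels(self) -> int:
        return int(self.pixels.sum())


@dataclass
class LesionMapping:
    """Point annotations of individual lesions for one image.

    ``entries`` holds ``(lesion_class, x, y)`` with x = column, y = row,
    0-based, origin top-left.  ``height``/``width`` are optional declared
    image bounds; when present every centroid must fall inside them.
    """

    image_id: str
    entries: list[tuple[LesionClass, float, float]] = field(default_factory=list)
    height: int | None = None
    width: int | None = None

    def count(self, lesion_class: LesionClass | None = None) -> int:
        if lesion_class is None:
            return len(self.entries)
        return sum(1 for cls, _, _ in self.entries if cls == lesion_class)

    def centroids(self, lesion_class: LesionClass) -> np.ndarray:
        """(n, 2) array of (x, y) for one class."""
        pts = [(x, y) for cls, x, y in self.entries if cls == lesion_class]
        return np.asarray(pts, dtype=float).reshape(-1, 2)


MANIFEST_COLUMNS = ("dataset_id", "image_id", "grade", "ma_mask", "hma_mask", "he_mask")

MASK_PATH_COLUMNS = {
    LesionClass.MA: "ma_mask",
    LesionClass.HMA: "hma_mask",
    LesionClass.HE: "he_mask",
}


@dataclass
class DatasetManifest:
    """Validated table mapping image ids to grades and mask paths.

    ``frame`` has the manifest CSV columns; ``grade`` holds
    :class:`SeverityGrade` members and absent mask paths are ``None``.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in MANIFEST_COLUMNS if c not in self.frame.columns]
        if missing:
            raise ValidationError(f"manifest missing columns: {missing}")
        dup = self.frame.duplicated(subset=["dataset_id", "image_id"])
        if dup.any():
            offending = self.frame.loc[dup, ["dataset_id", "image_id"]]
            raise ValidationError(
                "duplicate (dataset_id, image_id) pairs in manifest: "
                + ", ".join(f"{d}/{i}" for d, i in offending.itertuples(index=False))
            )
        path_cols = list(MASK_PATH_COLUMNS.values())
        no_mask = self.frame[path_cols].isna().all(axis=1)
        if no_mask.any():
            offending = self.frame.loc[no_mask, "image_id"].tolist()
            raise ValidationError(f"manifest rows without any mask path: {offending}")

    def __len__(self) -> int:
        return len(self.frame)

    def __iter__(self):
        return self.frame.itertuples(index=False)

    def mask_path(self, row, lesion_class: LesionClass):
        value = getattr(row, MASK_PATH_COLUMNS[lesion_class])
        return None if value is None or (isinstance(value, float) and np.isnan(value)) else value
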
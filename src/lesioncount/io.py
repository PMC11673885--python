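"""Reading and writing masks, lesion-mapping XML, manifests and count tables.

File formats
------------
* masks: PNG or TIFF, one raster per lesion class per image, filename
  convention ``<image_id>_<MA|Hma|HE>.png``;
* manifest CSV: ``dataset_id,image_id,grade,ma_mask,hma_mask,he_mask``
  (empty cell = mask not annotated for that class);
* lesion-mapping XML: ``<image id="..."><lesion class="MA" x="12.0" y="30.5"/>...``;
* counts CSV: ``dataset_id,image_id,grade,ma_count,hma_count,rl_count,
  he_count,he_area_px,he_area_fraction`` (empty cell = missing).
"""

from __future__ import annotations

import os
import xml.etree.ElementTree as ET
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from lesioncount.types import (
    COUNT_COLUMNS,
    as_grade,
    MANIFEST_COLUMNS,
    DatasetManifest,
    IntegrityError,
    LesionClass,
    LesionMapping,
    LesionMask,
    SeverityGrade,
    ValidationError,
)

#: grayscale intensities strictly above this become foreground; guards
#: against antialiased exports of nominally binary masks
GRAY_THRESHOLD = 127


def read_mask(path: str | os.PathLike, lesion_class: LesionClass) -> LesionMask:
    """Load a binary lesion mask from a PNG/TIFF file.

    Grayscale rasters are binarized at intensity > 127; RGB(A) rasters are
    collapsed by any-color-channel-nonzero.  The image id is the filename
    stem with a trailing ``_<class>`` suffix stripped if present.
    """
    path = Path(path)
    try:
        with Image.open(path) as img:
            arr = np.asarray(img)
    except FileNotFoundError:
        raise
    except OSError as exc:
        raise OSError(f"cannot read mask file {path}: {exc}") from exc
    if arr.ndim == 3:
        channels = arr[..., :3] if arr.shape[2] >= 3 else arr
        pixels = (channels != 0).any(axis=2)
    elif arr.ndim == 2:
        pixels = arr > GRAY_THRESHOLD if arr.dtype != bool else arr
    else:
        raise ValidationError(f"mask file {path} has unsupported shape {arr.shape}")
    image_id = path.stem
    suffix = f"_{lesion_class.value}"
    if image_id.endswith(suffix):
        image_id = image_id[: -len(suffix)]
    return LesionMask(image_id=image_id, lesion_class=lesion_class, pixels=pixels)


def write_mask(mask: LesionMask, path: str | os.PathLike) -> None:
    """Write a mask as an 8-bit PNG/TIFF with foreground = 255."""
    arr = np.where(mask.pixels, 255, 0).astype(np.uint8)
    Image.fromarray(arr, mode="L").save(path)


def read_lesion_xml(path: str | os.PathLike) -> LesionMapping:
    """Parse a per-image XML file of individual lesion centroids.

    Raises :class:`ValidationError` listing every entry whose centroid lies
    outside the image bounds declared on the ``<image>`` element (bounds are
    optional; without them no range check is performed).
    """
    path = Path(path)
    try:
        root = ET.parse(path).getroot()
    except ET.ParseError as exc:
        raise ET.ParseError(f"malformed lesion XML {path}: {exc}") from exc
    if root.tag != "image":
        raise ValidationError(f"{path}: expected root element <image>, got <{root.tag}>")
    image_id = root.get("id", path.stem)
    height = root.get("height")
    width = root.get("width")
    mapping = LesionMapping(
        image_id=image_id,
        height=int(height) if height is not None else None,
        width=int(width) if width is not None else None,
    )
    offending = []
    for elem in root.iter("lesion"):
        cls = LesionClass.from_name(elem.get("class", ""))
        x = float(elem.get("x"))
        y = float(elem.get("y"))
        if mapping.width is not None and not (0 <= x <= mapping.width - 1):
            offending.append((cls.value, x, y))
        elif mapping.height is not None and not (0 <= y <= mapping.height - 1):
            offending.append((cls.value, x, y))
        mapping.entries.append((cls, x, y))
    if offending:
        raise ValidationError(
            f"{path}: {len(offending)} lesion centroid(s) outside bounds "
            f"{mapping.width}x{mapping.height}: {offending}"
        )
    return mapping


def write_lesion_xml(mapping: LesionMapping, path: str | os.PathLike) -> None:
    root = ET.Element("image", id=mapping.image_id)
    if mapping.height is not None:
        root.set("height", str(mapping.height))
    if mapping.width is not None:
        root.set("width", str(mapping.width))
    for cls, x, y in mapping.entries:
        ET.SubElement(root, "lesion", {"class": cls.value, "x": repr(x), "y": repr(y)})
    ET.indent(root)
    ET.ElementTree(root).write(path, encoding="unicode")


def read_manifest(path: str | os.PathLike) -> DatasetManifest:
    """Read and validate a dataset manifest CSV.

    Grade labels are mapped to :class:`SeverityGrade`; an unknown label
    (e.g. ``proliferative``) raises :class:`ValidationError` naming the row.
    Empty mask-path cells become ``None`` ("not annotated"), never an error.
    """
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in MANIFEST_COLUMNS if c not in frame.columns]
    if missing:
        raise ValidationError(f"manifest {path} missing columns: {missing}")
    grades = []
    for idx, label in enumerate(frame["grade"]):
        try:
            grades.append(SeverityGrade.from_label(label))
        except ValidationError as exc:
            raise ValidationError(f"manifest {path} row {idx}: {exc}") from None
    frame = frame.copy()
    frame["grade"] = grades
    for col in ("ma_mask", "hma_mask", "he_mask"):
        frame[col] = frame[col].replace("", None)
    base = Path(path).parent
    for col in ("ma_mask", "hma_mask", "he_mask"):
        frame[col] = [
            str(base / p) if p is not None and not os.path.isabs(p) else p
            for p in frame[col]
        ]
    return DatasetManifest(frame=frame.reset_index(drop=True))


def write_manifest(manifest: DatasetManifest, path: str | os.PathLike,
                   relative_to: str | os.PathLike | None = None) -> None:
    frame = manifest.frame.copy()
    frame["grade"] = [as_grade(g).label for g in frame["grade"]]
    if relative_to is not None:
        base = Path(relative_to)
        for col in ("ma_mask", "hma_mask", "he_mask"):
            frame[col] = [
                os.path.relpath(p, base) if p is not None else None for p in frame[col]
            ]
    frame = frame.sort_values(["dataset_id", "image_id"], kind="mergesort")
    frame.to_csv(path, index=False, na_rep="")


def _normalize_counts(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in COUNT_COLUMNS if c not in table.columns]
    if missing:
        raise ValidationError(f"count table missing columns: {missing}")
    return table


def validate_counts(table: pd.DataFrame) -> None:
    """Enforce count-table invariants: non-negative counts, rl = ma + hma."""
    _normalize_counts(table)
    for col in ("ma_count", "hma_count", "rl_count", "he_count", "he_area_px"):
        values = pd.to_numeric(table[col], errors="coerce")
        if (values.dropna() < 0).any():
            raise IntegrityError(f"negative values in {col}")
    ma = pd.to_numeric(table["ma_count"], errors="coerce")
    hma = pd.to_numeric(table["hma_count"], errors="coerce")
    rl = pd.to_numeric(table["rl_count"], errors="coerce")
    both = ma.notna() & hma.notna()
    bad = both & (rl != ma + hma)
    if bad.any():
        ids = table.loc[bad, "image_id"].tolist()
        raise IntegrityError(f"rl_count != ma_count + hma_count for rows: {ids[:10]}")


def write_counts(table: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write a count table as CSV (deterministic row order, empty = missing).

    Refuses to write a table violating the ``rl = ma + hma`` invariant.
    """
    validate_counts(table)
    out = table.loc[:, list(COUNT_COLUMNS)].copy()
    out["grade"] = [as_grade(g).label for g in out["grade"]]
    for col in ("ma_count", "hma_count", "rl_count", "he_count", "he_area_px"):
        out[col] = pd.to_numeric(out[col], errors="coerce").astype("Int64")
    out = out.sort_values(["dataset_id", "image_id"], kind="mergesort")
    out.to_csv(path, index=False, na_rep="")


def read_counts(path: str | os.PathLike) -> pd.DataFrame:
    """Read a counts CSV back into the canonical in-memory form."""
    table = pd.read_csv(path)
    _normalize_counts(table)
    table["grade"] = [SeverityGrade.from_label(g) for g in table["grade"]]
    for col in ("ma_count", "hma_count", "rl_count", "he_count", "he_area_px"):
        table[col] = pd.to_numeric(table[col], errors="coerce").astype(float)
    table["he_area_fraction"] = pd.to_numeric(table["he_area_fraction"], errors="coerce")
    validate_counts(table)
    return table.reset_index(drop=True)
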
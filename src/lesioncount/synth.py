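"""Synthetic data: planted-lesion masks and severity-calibrated count tables.

Two generators stand in for the four study datasets:

* :func:`generate_mask` plants filled disks (optionally overlapping) in a
  binary raster and emits the matching centroid ground truth, giving the
  counting kernel a fixture with exact known answers;
* :func:`generate_count_table` draws per-image lesion counts from
  zero-inflated negative-binomial severity profiles whose per-grade means
  are calibrated to published per-stratum averages, over a four-dataset
  cohort with heterogeneous sizes, grade mixtures and annotation coverage.

Everything is driven by ``numpy.random.default_rng`` seeds and fully
reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from lesioncount import io
from lesioncount.types import (
    GRADES,
    DatasetManifest,
    LesionClass,
    LesionMapping,
    LesionMask,
    SeverityGrade,
    ValidationError,
)


class PackingError(RuntimeError):
    """Requested lesions cannot be placed in the raster."""


@dataclass(frozen=True)
class SeverityProfile:
    """Count distribution of one lesion class at one severity grade.

    Counts are zero-inflated negative binomial: with probability
    ``zero_inflation`` the draw is 0, otherwise NB with the stated mean and
    size parameter (``dispersion``; smaller = more overdispersed).
    ``target_mean`` is the unconditional mean.
    """

    grade: SeverityGrade
    lesion: LesionClass
    target_mean: float
    dispersion: float = 6.0
    zero_inflation: float = 0.0

    def __post_init__(self) -> None:
        if self.target_mean < 0:
            raise ValidationError("target_mean must be >= 0")
        if self.dispersion <= 0:
            raise ValidationError("dispersion must be > 0")
        if not (0.0 <= self.zero_inflation <= 1.0):
            raise ValidationError("zero_inflation must be in [0, 1]")

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.target_mean == 0:
            return np.zeros(n, dtype=int)
        nb_mean = self.target_mean / (1.0 - self.zero_inflation)
        k = self.dispersion
        draws = rng.negative_binomial(k, k / (k + nb_mean), size=n)
        if self.zero_inflation > 0:
            draws[rng.random(n) < self.zero_inflation] = 0
        return draws.astype(int)


#: (grade, lesion) -> (mean, dispersion, zero_inflation).  Means follow the
#: published per-grade averages; hemorrhages and hard exudates are absent by
#: clinical definition below moderate.  MA/Hma dispersions are moderate so
#: the IQR filter trims little mass; HE is deliberately much wider.
_PROFILE_TABLE = {
    (SeverityGrade.NO_DR, LesionClass.MA): (1.0, 1.0, 0.3),
    (SeverityGrade.NO_DR, LesionClass.HMA): (0.0, 6.0, 0.0),
    (SeverityGrade.NO_DR, LesionClass.HE): (0.0, 6.0, 0.0),
    (SeverityGrade.MILD, LesionClass.MA): (4.3, 10.0, 0.0),
    (SeverityGrade.MILD, LesionClass.HMA): (0.0, 6.0, 0.0),
    (SeverityGrade.MILD, LesionClass.HE): (0.0, 6.0, 0.0),
    (SeverityGrade.MODERATE, LesionClass.MA): (14.2, 8.0, 0.0),
    (SeverityGrade.MODERATE, LesionClass.HMA): (8.7, 8.0, 0.0),
    (SeverityGrade.MODERATE, LesionClass.HE): (30.0, 1.0, 0.0),
    (SeverityGrade.SEVERE, LesionClass.MA): (53.1, 8.0, 0.0),
    (SeverityGrade.SEVERE, LesionClass.HMA): (51.1, 8.0, 0.0),
    (SeverityGrade.SEVERE, LesionClass.HE): (58.2, 1.0, 0.0),
}


def default_severity_profiles() -> dict[tuple[SeverityGrade, LesionClass], SeverityProfile]:
    """Default calibration: one profile per (grade, lesion class)."""
    return {
        key: SeverityProfile(
            grade=key[0], lesion=key[1],
            target_mean=mean, dispersion=disp, zero_inflation=zi,
        )
        for key, (mean, disp, zi) in _PROFILE_TABLE.items()
    }


#: per-class plausible radius ranges (px); only relative scales matter
LESION_RADII = {
    LesionClass.MA: (2, 5),
    LesionClass.HMA: (4, 12),
    LesionClass.HE: (5, 15),
}


@dataclass(frozen=True)
class MaskSpec:
    """Recipe for one planted-lesion mask."""

    height: int = 256
    width: int = 256
    n_lesions: int = 10
    radius_range: tuple[int, int] = (4, 8)
    overlap_fraction: float = 0.0
    lesion_class: LesionClass = LesionClass.MA
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_lesions < 0:
            raise ValidationError("n_lesions must be >= 0")
        if not (0.0 <= self.overlap_fraction <= 1.0):
            raise ValidationError("overlap_fraction must be in [0, 1]")
        rmin, rmax = self.radius_range
        if not (1 <= rmin <= rmax):
            raise ValidationError(f"bad radius_range {self.radius_range}")


_MAX_PLACEMENT_TRIES = 2000


def _draw_disk(pixels: np.ndarray, cy: float, cx: float, r: int) -> None:
    h, w = pixels.shape
    y0, y1 = max(0, int(cy - r)), min(h, int(cy + r) + 1)
    x0, x1 = max(0, int(cx - r)), min(w, int(cx + r) + 1)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    pixels[y0:y1, x0:x1] |= (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2


def generate_mask(spec: MaskSpec) -> tuple[LesionMask, LesionMapping]:
    """Plant ``n_lesions`` filled disks; return the mask and its ground truth.

    ``ceil(overlap_fraction * n)`` lesions are placed to intersect a
    previously placed neighbor: the center separation is kept below the sum
    of radii but at or above ``0.8 * (r1 + r2)`` (and above the larger
    radius), so each lesion of the pair keeps its own distance-transform
    maximum.  The rest are pairwise disjoint.  Raises :class:`PackingError`
    when placement keeps failing.
    """
    rng = np.random.default_rng(spec.seed)
    pixels = np.zeros((spec.height, spec.width), dtype=bool)
    mapping = LesionMapping(
        image_id=f"synthetic_{spec.seed}", height=spec.height, width=spec.width
    )
    if spec.n_lesions == 0:
        return (
            LesionMask(mapping.image_id, spec.lesion_class, pixels),
            mapping,
        )
    rmin, rmax = spec.radius_range
    if spec.height <= 2 * rmax + 2 or spec.width <= 2 * rmax + 2:
        raise PackingError(
            f"raster {spec.height}x{spec.width} too small for radius {rmax}"
        )
    n_overlap = math.ceil(spec.overlap_fraction * spec.n_lesions)
    n_disjoint = spec.n_lesions - n_overlap
    placed: list[tuple[float, float, int]] = []  # (cy, cx, r)

    def try_place_disjoint(r: int) -> tuple[float, float] | None:
        for _ in range(_MAX_PLACEMENT_TRIES):
            cy = rng.uniform(r + 1, spec.height - r - 2)
            cx = rng.uniform(r + 1, spec.width - r - 2)
            # +2 keeps even 8-connected components separate
            if all(
                (cy - py) ** 2 + (cx - px) ** 2 > (r + pr + 2) ** 2
                for py, px, pr in placed
            ):
                return cy, cx
        return None

    for _ in range(n_disjoint):
        r = int(rng.integers(rmin, rmax + 1))
        pos = try_place_disjoint(r)
        if pos is None:
            raise PackingError(
                f"cannot place {spec.n_lesions} disjoint radius<={rmax} disks "
                f"in {spec.height}x{spec.width}"
            )
        placed.append((*pos, r))

    for _ in range(n_overlap):
        r = int(rng.integers(rmin, rmax + 1))
        if not placed:
            pos = try_place_disjoint(r)
            if pos is None:
                raise PackingError("cannot seed overlap chain")
            placed.append((*pos, r))
            continue
        done = False
        for _ in range(_MAX_PLACEMENT_TRIES):
            py, px, pr = placed[int(rng.integers(len(placed)))]
            hi = pr + r - 1
            # shallow intersection: deep engulfment is visually ambiguous
            # and not a fair target for any splitting method
            lo = min(max(max(pr, r) + 1, 0.8 * (pr + r)), hi)
            if hi < max(pr, r) + 1:
                continue
            sep = rng.uniform(lo, hi)
            angle = rng.uniform(0, 2 * np.pi)
            cy = py + sep * np.sin(angle)
            cx = px + sep * np.cos(angle)
            if not (r + 1 <= cy <= spec.height - r - 2 and r + 1 <= cx <= spec.width - r - 2):
                continue
            # keep the pair isolated from everyone else
            if all(
                (cy - qy) ** 2 + (cx - qx) ** 2 > (r + qr + 2) ** 2
                for qy, qx, qr in placed
                if (qy, qx, qr) != (py, px, pr)
            ):
                placed.append((cy, cx, r))
                done = True
                break
        if not done:
            raise PackingError("cannot place overlapping lesion; relax the spec")

    for cy, cx, r in placed:
        _draw_disk(pixels, cy, cx, r)
        mapping.entries.append((spec.lesion_class, float(cx), float(cy)))
    return LesionMask(mapping.image_id, spec.lesion_class, pixels), mapping


_DEFAULT_SIZES = {
    "dataset1": 144,
    "dataset2": 586,
    "dataset3": 1395,
    "dataset4": 50,
}

#: default grade mixtures: dataset2 lacks no-DR annotations, dataset4 only
#: carries moderate/severe — emulating the heterogeneous coverage of public
#: collections; moderate dominates overall.
_DEFAULT_MIX = {
    "dataset1": {SeverityGrade.NO_DR: 0.20, SeverityGrade.MILD: 0.25,
                 SeverityGrade.MODERATE: 0.35, SeverityGrade.SEVERE: 0.20},
    "dataset2": {SeverityGrade.MILD: 0.20, SeverityGrade.MODERATE: 0.55,
                 SeverityGrade.SEVERE: 0.25},
    "dataset3": {SeverityGrade.NO_DR: 0.15, SeverityGrade.MILD: 0.25,
                 SeverityGrade.MODERATE: 0.45, SeverityGrade.SEVERE: 0.15},
    "dataset4": {SeverityGrade.MODERATE: 0.60, SeverityGrade.SEVERE: 0.40},
}

ALL_CLASSES = frozenset(LesionClass)

#: dataset3-like members show a marginal but real hemorrhage presence at the
#: mild grade (the other datasets stay null there, keeping the no-DR vs mild
#: comparison non-significant within them)
_DEFAULT_OVERRIDES = {
    ("dataset3", SeverityGrade.MILD, LesionClass.HMA): (0.5, 1.0, 0.0),
}


@dataclass(frozen=True)
class CohortSpec:
    """Recipe for a multi-dataset synthetic cohort.

    ``annotated`` maps (dataset_id, grade) to the lesion classes carrying
    masks/counts there; missing keys mean "all classes annotated".
    ``profile_overrides`` maps (dataset_id, grade, lesion) to
    (mean, dispersion, zero_inflation) triples replacing the global profile
    for that dataset's stratum.  ``outlier_rate`` is the fraction of records
    planted with an extreme MA or Hma count (>= 5x the stratum mean).
    """

    sizes: dict = field(default_factory=lambda: dict(_DEFAULT_SIZES))
    grade_mix: dict = field(default_factory=lambda: {k: dict(v) for k, v in _DEFAULT_MIX.items()})
    annotated: dict = field(default_factory=dict)
    profile_overrides: dict = field(default_factory=lambda: dict(_DEFAULT_OVERRIDES))
    outlier_rate: float = 0.0
    #: share of severe records emulating clinically-severe images with a low
    #: microaneurysm count (extensive hemorrhage / IRMA cases); half of them
    #: are low on hemorrhages too
    severe_low_ma_fraction: float = 0.04
    seed: int = 0
    image_height: int = 760
    image_width: int = 760

    def __post_init__(self) -> None:
        if any(n < 0 for n in self.sizes.values()):
            raise ValidationError("dataset sizes must be >= 0")
        if not (0.0 <= self.outlier_rate <= 1.0):
            raise ValidationError("outlier_rate must be in [0, 1]")
        for ds, mix in self.grade_mix.items():
            total = sum(mix.values())
            if mix and abs(total - 1.0) > 1e-9:
                raise ValidationError(f"grade mixture of {ds} sums to {total}, not 1")

    def scaled(self, factor: int) -> "CohortSpec":
        return replace(self, sizes={k: int(v * factor) for k, v in self.sizes.items()})

    def classes_for(self, dataset_id: str, grade: SeverityGrade) -> frozenset:
        return frozenset(self.annotated.get((dataset_id, grade), ALL_CLASSES))


def _apportion(n: int, mix: dict, order) -> dict:
    """Largest-remainder apportionment of n rows across grades (deterministic)."""
    shares = {g: n * mix.get(g, 0.0) for g in order}
    counts = {g: int(math.floor(s)) for g, s in shares.items()}
    leftover = n - sum(counts.values())
    remainders = sorted(order, key=lambda g: (-(shares[g] - counts[g]), int(g)))
    for g in remainders[:leftover]:
        counts[g] += 1
    return counts


#: mean squared radius per class, for converting HE counts to areas
def _mean_disk_area(lesion: LesionClass) -> float:
    rmin, rmax = LESION_RADII[lesion]
    # E[r^2] for r ~ U{rmin..rmax}
    rr = np.arange(rmin, rmax + 1)
    return float(np.pi * (rr**2).mean())


def generate_count_table(
    profiles: dict | None = None,
    cohort: CohortSpec = CohortSpec(),
    seed: int | None = None,
) -> tuple[pd.DataFrame, list[tuple[str, str]]]:
    """Draw a full cohort count table; return it with planted-outlier ids.

    Counts are drawn independently per lesion class from the stratum's
    profile; RL = MA + Hma; HE area is the summed area of ``he_count``
    random-radius disks.  Outliers are planted on MA or Hma at
    ``max(5 * stratum mean, 20)`` plus noise, guaranteed above the stratum's
    upper IQR bound for the default profiles.
    """
    profiles = profiles if profiles is not None else default_severity_profiles()
    rng = np.random.default_rng(cohort.seed if seed is None else seed)
    he_unit_area = _mean_disk_area(LesionClass.HE)
    frames = []
    outlier_ids: list[tuple[str, str]] = []
    for dataset_id in sorted(cohort.sizes):
        n = cohort.sizes[dataset_id]
        mix = cohort.grade_mix.get(dataset_id, {})
        per_grade = _apportion(n, mix, GRADES)
        idx = 0
        for grade in GRADES:
            m = per_grade.get(grade, 0)
            if m == 0:
                continue
            annotated = cohort.classes_for(dataset_id, grade)
            image_ids = [f"{dataset_id}_img{idx + i:05d}" for i in range(m)]
            idx += m
            cols: dict[str, np.ndarray] = {}
            for lesion in (LesionClass.MA, LesionClass.HMA, LesionClass.HE):
                override = cohort.profile_overrides.get((dataset_id, grade, lesion))
                if override is not None:
                    mean_, disp_, zi_ = override
                    profile = SeverityProfile(grade, lesion, mean_, disp_, zi_)
                else:
                    profile = profiles[(grade, lesion)]
                draws = profile.sample(rng, m).astype(float)
                if lesion not in annotated:
                    draws = np.full(m, np.nan)
                cols[lesion.value] = draws
            ma, hma, he = cols["MA"], cols["Hma"], cols["HE"]
            if grade == SeverityGrade.SEVERE and cohort.severe_low_ma_fraction > 0:
                n_low = int(round(cohort.severe_low_ma_fraction * m))
                if n_low and LesionClass.MA in annotated:
                    low_idx = rng.choice(m, size=n_low, replace=False)
                    low = SeverityProfile(grade, LesionClass.MA, 6.0, 2.0)
                    ma[low_idx] = low.sample(rng, n_low)
                    both_low = low_idx[rng.random(n_low) < 0.7]
                    if len(both_low) and LesionClass.HMA in annotated:
                        low_h = SeverityProfile(grade, LesionClass.HMA, 20.0, 2.0)
                        hma[both_low] = low_h.sample(rng, len(both_low))
            if cohort.outlier_rate > 0:
                n_out = int(round(cohort.outlier_rate * m))
                if n_out:
                    chosen = rng.choice(m, size=n_out, replace=False)
                    for i in chosen:
                        candidates = [
                            (LesionClass.MA, ma),
                            (LesionClass.HMA, hma),
                        ]
                        candidates = [(c, a) for c, a in candidates if c in annotated]
                        if not candidates:
                            continue
                        lesion, arr = candidates[int(rng.integers(len(candidates)))]
                        mean = profiles[(grade, lesion)].target_mean
                        arr[i] = max(5.0 * mean, 20.0) + rng.poisson(max(mean, 1.0))
                        outlier_ids.append((dataset_id, image_ids[i]))
            rl = ma + hma
            he_area = np.full(m, np.nan)
            he_frac = np.full(m, np.nan)
            known_he = ~np.isnan(he)
            for i in np.flatnonzero(known_he):
                c = int(he[i])
                if c == 0:
                    area = 0.0
                else:
                    # lognormal jitter keeps areas positive and overdispersed
                    area = float(np.round(c * he_unit_area * rng.lognormal(0.0, 0.25)))
                he_area[i] = area
                he_frac[i] = area / (cohort.image_height * cohort.image_width)
            frames.append(
                pd.DataFrame(
                    {
                        "dataset_id": dataset_id,
                        "image_id": image_ids,
                        "grade": [grade] * m,
                        "ma_count": ma,
                        "hma_count": hma,
                        "rl_count": rl,
                        "he_count": he,
                        "he_area_px": he_area,
                        "he_area_fraction": he_frac,
                    }
                )
            )
    if not frames:
        table = pd.DataFrame(
            columns=[
                "dataset_id", "image_id", "grade", "ma_count", "hma_count",
                "rl_count", "he_count", "he_area_px", "he_area_fraction",
            ]
        )
    else:
        table = pd.concat(frames, ignore_index=True)
    return table, outlier_ids


def generate_dataset(
    cohort: CohortSpec,
    out_dir,
    profiles: dict | None = None,
    mask_size: int = 448,
    overlap_fraction: float = 0.0,
) -> Path:
    """Write a complete runnable input: masks, XML ground truth, manifest.

    Per-image lesion counts are drawn from the severity profiles, then each
    annotated class gets a mask with exactly that many planted lesions plus
    a matching XML centroid file.  Returns the manifest path.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "masks").mkdir(exist_ok=True)
    (out_dir / "xml").mkdir(exist_ok=True)
    table, _ = generate_count_table(profiles, cohort)
    rng = np.random.default_rng(cohort.seed + 1)
    rows = []
    for row in table.itertuples(index=False):
        entry = {
            "dataset_id": row.dataset_id,
            "image_id": row.image_id,
            "grade": row.grade,
            "ma_mask": None,
            "hma_mask": None,
            "he_mask": None,
        }
        # masks of one image share dimensions; grow the raster when the
        # drawn counts would not pack into the default size
        demand = 0.0
        for lesion, count in (
            (LesionClass.MA, row.ma_count),
            (LesionClass.HMA, row.hma_count),
            (LesionClass.HE, row.he_count),
        ):
            if count is not None and not (isinstance(count, float) and np.isnan(count)):
                rmax = LESION_RADII[lesion][1]
                demand = max(demand, 3.0 * int(count) * np.pi * (rmax + 2) ** 2)
        side = max(mask_size, int(math.ceil(math.sqrt(demand))))
        combined = LesionMapping(image_id=row.image_id, height=side, width=side)
        for lesion, count, col in (
            (LesionClass.MA, row.ma_count, "ma_mask"),
            (LesionClass.HMA, row.hma_count, "hma_mask"),
            (LesionClass.HE, row.he_count, "he_mask"),
        ):
            if count is None or (isinstance(count, float) and np.isnan(count)):
                continue
            spec = MaskSpec(
                height=side,
                width=side,
                n_lesions=int(count),
                radius_range=LESION_RADII[lesion],
                overlap_fraction=overlap_fraction,
                lesion_class=lesion,
                seed=int(rng.integers(2**31)),
            )
            mask, mapping = generate_mask(spec)
            mask_path = out_dir / "masks" / f"{row.image_id}_{lesion.value}.png"
            io.write_mask(mask, mask_path)
            entry[col] = str(mask_path)
            combined.entries.extend(
                (lesion, x, y) for _, x, y in mapping.entries
            )
        io.write_lesion_xml(combined, out_dir / "xml" / f"{row.image_id}.xml")
        rows.append(entry)
    manifest = DatasetManifest(frame=pd.DataFrame(rows))
    manifest_path = out_dir / "manifest.csv"
    io.write_manifest(manifest, manifest_path, relative_to=out_dir)
    return manifest_path
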
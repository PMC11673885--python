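"""Stage orchestration: count -> filter -> stats -> classify.

Every stage is a pure function of (inputs, config); a run directory gets
the counts, filter report, summaries, test results, weighted summaries,
classifier report and figures, plus a run-manifest JSON with the seed,
config hash and per-stage row counts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from lesioncount import io, plots
from lesioncount.classify import ClassifierConfig, build_features, train_classifier
from lesioncount.counting import (
    CountingParams,
    combine_red_lesions,
    count_lesions,
    measure_he_area,
)
from lesioncount.filtering import filter_outliers
from lesioncount.stats import pairwise_frame, summarize_all, weighted_summary_frame
from lesioncount.types import DatasetManifest, LesionClass

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything a full run needs; serializable to/from a YAML mapping."""

    counting: CountingParams = field(default_factory=CountingParams)
    stratify: str = "dataset_grade"
    quantile_method: str = "linear"
    ci_method: str = "t"
    pairs: str = "adjacent"
    features: tuple[str, ...] = ("MA", "Hma", "HE")
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    filtering_enabled: bool = True
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "counting": dataclasses.asdict(self.counting),
            "stratify": self.stratify,
            "quantile_method": self.quantile_method,
            "ci_method": self.ci_method,
            "pairs": self.pairs,
            "features": list(self.features),
            "classifier": dataclasses.asdict(self.classifier),
            "filtering_enabled": self.filtering_enabled,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        counting = CountingParams(**data.pop("counting", {}))
        classifier = ClassifierConfig(**data.pop("classifier", {}))
        features = tuple(data.pop("features", ("MA", "Hma", "HE")))
        return cls(counting=counting, classifier=classifier, features=features, **data)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def count_manifest(
    manifest: DatasetManifest, params: CountingParams = CountingParams()
) -> pd.DataFrame:
    """Count lesions for every manifest row; absent masks yield missing counts."""
    rows = []
    for row in manifest:
        counts: dict[str, float | None] = {}
        he_area = he_frac = None
        for lesion in LesionClass:
            path = manifest.mask_path(row, lesion)
            if path is None:
                counts[lesion.value] = None
                continue
            mask = io.read_mask(path, lesion)
            counts[lesion.value] = count_lesions(mask, params)
            if lesion == LesionClass.HE:
                he_area, he_frac = measure_he_area(mask)
        rows.append(
            {
                "dataset_id": row.dataset_id,
                "image_id": row.image_id,
                "grade": row.grade,
                "ma_count": counts["MA"],
                "hma_count": counts["Hma"],
                "rl_count": combine_red_lesions(counts["MA"], counts["Hma"]),
                "he_count": counts["HE"],
                "he_area_px": he_area,
                "he_area_fraction": he_frac,
            }
        )
    table = pd.DataFrame(rows)
    for col in ("ma_count", "hma_count", "rl_count", "he_count", "he_area_px"):
        table[col] = pd.to_numeric(table[col], errors="coerce").astype(float)
    return table


def run_pipeline(
    config: PipelineConfig,
    out_dir,
    manifest_path=None,
    counts_path=None,
) -> Path:
    """Run count -> filter -> stats -> classify, writing all artifacts.

    Provide either a manifest (masks are counted) or a precomputed counts
    CSV.  Returns the output directory.
    """
    if (manifest_path is None) == (counts_path is None):
        raise ValueError("provide exactly one of manifest_path or counts_path")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stage_rows: dict[str, int] = {}

    if manifest_path is not None:
        logger.info("stage count: reading %s", manifest_path)
        manifest = io.read_manifest(manifest_path)
        table = count_manifest(manifest, config.counting)
    else:
        logger.info("stage count: loading precomputed counts %s", counts_path)
        table = io.read_counts(counts_path)
    io.write_counts(table, out_dir / "counts.csv")
    stage_rows["count"] = len(table)

    if config.filtering_enabled:
        filtered, report = filter_outliers(
            table, stratify=config.stratify, quantile_method=config.quantile_method
        )
        report.to_frame().to_csv(out_dir / "filter_report.csv", index=False)
        logger.info(
            "stage filter: %d -> %d rows (%.1f%% excluded)",
            report.n_before, report.n_after, 100 * report.excluded_fraction,
        )
    else:
        filtered = table
        logger.info("stage filter: disabled")
    io.write_counts(filtered, out_dir / "counts_filtered.csv")
    stage_rows["filter"] = len(filtered)

    summaries = summarize_all(filtered, ci_method=config.ci_method, seed=config.seed)
    summaries.to_csv(out_dir / "summaries.csv", index=False)
    weighted = weighted_summary_frame(filtered, ci_method=config.ci_method, seed=config.seed)
    weighted.to_csv(out_dir / "weighted_summaries.csv", index=False)
    tests = pairwise_frame(filtered, pairs=config.pairs)
    tests.to_csv(out_dir / "pairwise_tests.csv", index=False)
    stage_rows["stats"] = len(summaries)
    plots.severity_plot(summaries, out_dir / "severity_by_dataset.png")
    plots.severity_plot(weighted, out_dir / "severity_weighted.png")

    feats = build_features(filtered, features=config.features)
    model, report = train_classifier(feats, config.classifier)
    model.save(out_dir / "classifier.json")
    report.to_frame().to_csv(out_dir / "classifier_report.csv")
    plots.confusion_plot(report, out_dir / "confusion.png")
    stage_rows["classify"] = report.n_train + report.n_test
    logger.info(
        "stage classify: accuracy %.3f on %d held-out rows", report.accuracy, report.n_test
    )

    run_manifest = {
        "seed": config.seed,
        "config_hash": config.digest(),
        "config": config.to_dict(),
        "stage_rows": stage_rows,
        "versions": {
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    with open(out_dir / "run_manifest.json", "w") as fh:
        json.dump(run_manifest, fh, indent=1)
    return out_dir
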
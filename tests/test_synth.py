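import dataclasses

import numpy as np
import pandas as pd
import pytest

from lesioncount import io
from lesioncount.counting import count_lesions
from lesioncount.synth import (
    CohortSpec,
    MaskSpec,
    PackingError,
    SeverityProfile,
    default_severity_profiles,
    generate_count_table,
    generate_dataset,
    generate_mask,
)
from lesioncount.types import GRADES, LesionClass, SeverityGrade, ValidationError


class TestProfiles:
    def test_calibration_constants(self):
        profiles = default_severity_profiles()
        assert profiles[(SeverityGrade.MILD, LesionClass.MA)].target_mean == 4.3
        assert profiles[(SeverityGrade.MODERATE, LesionClass.MA)].target_mean == 14.2
        assert profiles[(SeverityGrade.SEVERE, LesionClass.MA)].target_mean == 53.1
        assert profiles[(SeverityGrade.MODERATE, LesionClass.HMA)].target_mean == 8.7
        assert profiles[(SeverityGrade.SEVERE, LesionClass.HMA)].target_mean == 51.1
        assert profiles[(SeverityGrade.MODERATE, LesionClass.HE)].target_mean == 30.0
        assert profiles[(SeverityGrade.SEVERE, LesionClass.HE)].target_mean == 58.2

    def test_absent_by_definition(self):
        profiles = default_severity_profiles()
        assert profiles[(SeverityGrade.MILD, LesionClass.HMA)].target_mean == 0
        assert profiles[(SeverityGrade.MILD, LesionClass.HE)].target_mean == 0
        assert profiles[(SeverityGrade.NO_DR, LesionClass.HMA)].target_mean == 0
        # no-DR microaneurysms are negligible but not structurally zero
        assert profiles[(SeverityGrade.NO_DR, LesionClass.MA)].target_mean <= 1.0

    def test_he_dispersion_wider(self):
        profiles = default_severity_profiles()
        assert (
            profiles[(SeverityGrade.MODERATE, LesionClass.HE)].dispersion
            < profiles[(SeverityGrade.MODERATE, LesionClass.MA)].dispersion
        )

    def test_monotone_calibration(self):
        profiles = default_severity_profiles()
        for lesion in (LesionClass.MA, LesionClass.HMA):
            means = [profiles[(g, lesion)].target_mean for g in GRADES]
            # nondecreasing everywhere, strictly increasing once present
            assert all(b >= a for a, b in zip(means, means[1:]))
            present = [m for m in means if m > 0]
            assert all(b > a for a, b in zip(present, present[1:]))
        rl_means = [
            profiles[(g, LesionClass.MA)].target_mean
            + profiles[(g, LesionClass.HMA)].target_mean
            for g in GRADES
        ]
        assert all(b > a for a, b in zip(rl_means, rl_means[1:]))

    def test_zero_mean_draws_zero(self, rng):
        p = default_severity_profiles()[(SeverityGrade.MILD, LesionClass.HMA)]
        assert (p.sample(rng, 1000) == 0).all()

    def test_validation(self):
        with pytest.raises(ValidationError):
            SeverityProfile(SeverityGrade.MILD, LesionClass.MA, -1.0)
        with pytest.raises(ValidationError):
            SeverityProfile(SeverityGrade.MILD, LesionClass.MA, 1.0, dispersion=0)


class TestGenerateCountTable:
    def test_empty_cohort(self):
        cohort = CohortSpec(sizes={"d": 0}, grade_mix={"d": {}})
        table, outliers = generate_count_table(cohort=cohort)
        assert len(table) == 0 and outliers == []

    def test_law_of_large_numbers_moderate_ma(self):
        cohort = CohortSpec(
            sizes={"dataset1": 10_000},
            grade_mix={"dataset1": {SeverityGrade.MODERATE: 1.0}},
            seed=21,
        )
        table, _ = generate_count_table(cohort=cohort)
        assert table["ma_count"].mean() == pytest.approx(14.2, rel=0.02)

    def test_default_fig_pattern_sizes(self):
        table, _ = generate_count_table(cohort=CohortSpec(seed=1))
        sizes = table["dataset_id"].value_counts().to_dict()
        assert sizes == {
            "dataset1": 144, "dataset2": 586, "dataset3": 1395, "dataset4": 50,
        }

    def test_rl_is_sum(self):
        table, _ = generate_count_table(cohort=CohortSpec(seed=2))
        both = table["ma_count"].notna() & table["hma_count"].notna()
        assert (
            table.loc[both, "rl_count"]
            == table.loc[both, "ma_count"] + table.loc[both, "hma_count"]
        ).all()

    def test_reproducible(self):
        a, oa = generate_count_table(cohort=CohortSpec(seed=9))
        b, ob = generate_count_table(cohort=CohortSpec(seed=9))
        pd.testing.assert_frame_equal(a, b)
        assert oa == ob

    def test_different_seeds_differ(self):
        a, _ = generate_count_table(cohort=CohortSpec(seed=1))
        b, _ = generate_count_table(cohort=CohortSpec(seed=2))
        assert not a["ma_count"].equals(b["ma_count"])

    def test_mild_strata_definitionally_null(self):
        table, _ = generate_count_table(cohort=CohortSpec(seed=3))
        mild = table[table["grade"] == SeverityGrade.MILD]
        assert (mild["he_count"].dropna() == 0).all()
        # hemorrhages null at mild except the dataset3-like marginal presence
        other = mild[mild["dataset_id"] != "dataset3"]
        assert (other["hma_count"].dropna() == 0).all()

    def test_no_dr_negligible(self):
        table, _ = generate_count_table(cohort=CohortSpec(seed=4))
        no_dr = table[table["grade"] == SeverityGrade.NO_DR]
        assert no_dr["ma_count"].mean() < 2.0
        assert (no_dr["hma_count"].dropna() == 0).all()

    def test_planted_outliers_extreme(self):
        cohort = CohortSpec(outlier_rate=0.1, seed=5)
        table, outliers = generate_count_table(cohort=cohort)
        assert 0.05 < len(outliers) / len(table) < 0.15
        indexed = table.set_index(["dataset_id", "image_id"])
        for key in outliers:
            row = indexed.loc[key]
            assert max(row["ma_count"], row["hma_count"]) >= 20

    def test_annotation_gaps_are_missing(self):
        cohort = dataclasses.replace(
            CohortSpec(seed=6),
            annotated={("dataset4", SeverityGrade.MODERATE): frozenset({LesionClass.HE})},
        )
        table, _ = generate_count_table(cohort=cohort)
        sub = table[
            (table["dataset_id"] == "dataset4") & (table["grade"] == SeverityGrade.MODERATE)
        ]
        assert sub["ma_count"].isna().all()
        assert sub["he_count"].notna().all()
        assert sub["rl_count"].isna().all()


class TestGenerateMask:
    def test_zero_lesions(self):
        mask, mapping = generate_mask(MaskSpec(n_lesions=0, seed=0))
        assert mask.foreground_pixels == 0
        assert mapping.count() == 0

    def test_disjoint_count_exact(self):
        mask, mapping = generate_mask(MaskSpec(n_lesions=12, overlap_fraction=0.0, seed=1))
        assert mapping.count() == 12
        assert count_lesions(mask) == 12

    def test_overlap_merges_components_watershed_recovers(self):
        mask, mapping = generate_mask(
            MaskSpec(n_lesions=12, overlap_fraction=0.5, radius_range=(4, 8), seed=3)
        )
        from lesioncount.counting import CountingParams, count_components

        assert count_components(mask, CountingParams()).n_instances < 12
        assert count_lesions(mask) == 12

    def test_centroids_in_bounds(self):
        mask, mapping = generate_mask(MaskSpec(n_lesions=20, seed=4))
        for _, x, y in mapping.entries:
            assert 0 <= x < mask.width
            assert 0 <= y < mask.height

    def test_mask_bytes_reproducible(self):
        a, _ = generate_mask(MaskSpec(n_lesions=10, overlap_fraction=0.3, seed=5))
        b, _ = generate_mask(MaskSpec(n_lesions=10, overlap_fraction=0.3, seed=5))
        np.testing.assert_array_equal(a.pixels, b.pixels)

    def test_infeasible_packing_raises(self):
        with pytest.raises(PackingError):
            generate_mask(MaskSpec(height=40, width=40, n_lesions=200, radius_range=(4, 8)))

    def test_validation(self):
        with pytest.raises(ValidationError):
            MaskSpec(n_lesions=-1)
        with pytest.raises(ValidationError):
            MaskSpec(overlap_fraction=1.5)


@pytest.fixture(scope="module")
def tiny_dataset(tmp_path_factory):
    out = tmp_path_factory.mktemp("cohort")
    cohort = dataclasses.replace(
        CohortSpec(seed=11),
        sizes={"dataset1": 2, "dataset4": 2},
    )
    return generate_dataset(cohort, out), out


class TestGenerateDataset:
    def test_smoke_outputs_exist(self, tiny_dataset):
        manifest_path, out = tiny_dataset
        manifest = io.read_manifest(manifest_path)
        assert len(manifest) == 4
        assert sorted(p.name for p in (out / "xml").iterdir())

    def test_counts_match_planted_ground_truth(self, tiny_dataset):
        manifest_path, out = tiny_dataset
        manifest = io.read_manifest(manifest_path)
        for row in manifest:
            mapping = io.read_lesion_xml(out / "xml" / f"{row.image_id}.xml")
            for lesion in LesionClass:
                path = manifest.mask_path(row, lesion)
                if path is None:
                    continue
                mask = io.read_mask(path, lesion)
                # disjoint planting: counting is exact
                assert count_lesions(mask) == mapping.count(lesion)

    def test_same_seed_byte_identical_manifest(self, tmp_path):
        cohort = dataclasses.replace(CohortSpec(seed=12), sizes={"dataset1": 3})
        p1 = generate_dataset(cohort, tmp_path / "a")
        p2 = generate_dataset(cohort, tmp_path / "b")
        assert p1.read_text() == p2.read_text()
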
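import numpy as np
import pandas as pd
import pytest

from lesioncount.types import SeverityGrade


def make_counts(rows):
    """Build a count table from (dataset_id, image_id, grade, ma, hma, he) tuples.

    rl is derived; he_area defaults to 10x the HE count.
    """
    records = []
    for dataset_id, image_id, grade, ma, hma, he in rows:
        rl = None if ma is None or hma is None else ma + hma
        records.append(
            {
                "dataset_id": dataset_id,
                "image_id": image_id,
                "grade": grade if isinstance(grade, SeverityGrade) else SeverityGrade(grade),
                "ma_count": ma,
                "hma_count": hma,
                "rl_count": rl,
                "he_count": he,
                "he_area_px": None if he is None else he * 10,
                "he_area_fraction": None if he is None else he * 10 / 1e5,
            }
        )
    columns = [
        "dataset_id", "image_id", "grade", "ma_count", "hma_count",
        "rl_count", "he_count", "he_area_px", "he_area_fraction",
    ]
    table = pd.DataFrame(records, columns=columns)
    for col in ("ma_count", "hma_count", "rl_count", "he_count", "he_area_px"):
        table[col] = pd.to_numeric(table[col], errors="coerce").astype(float)
    return table


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def two_group_table():
    """Two datasets, two grades, small and fully hand-checkable."""
    rows = []
    for i, v in enumerate([1, 2, 3]):
        rows.append(("d1", f"a{i}", 1, v, 0, 0))
    for i, v in enumerate([4, 5, 6]):
        rows.append(("d1", f"b{i}", 2, v, 1, 2))
    return make_counts(rows)
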
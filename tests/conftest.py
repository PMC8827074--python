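import pandas as pd
import pytest

from pgdvoc import (
    FeatureTable,
    SyntheticSpec,
    generate_cohort,
    normalize_areas,
    validate_sample_meta,
)


@pytest.fixture(scope="session")
def cohort17():
    """Default study-shaped synthetic cohort, seed 17 (table, meta, records)."""
    return generate_cohort(SyntheticSpec(seed=17))


@pytest.fixture(scope="session")
def norm17(cohort17):
    table, meta, records = cohort17
    return normalize_areas(table), meta, records


@pytest.fixture()
def toy_table():
    """3 samples x 2 features with simple integer areas."""
    areas = pd.DataFrame(
        [[2.0, 3.0], [0.0, 5.0], [1.0, 1.0]],
        index=["s1", "s2", "s3"],
        columns=["fA", "fB"],
    )
    areas.index.name = "sample_id"
    return FeatureTable(areas)


def make_meta(rows):
    """Helper: build validated metadata from (sample, patient, matrix, window, grade)."""
    return validate_sample_meta(
        pd.DataFrame(
            rows,
            columns=["sample_id", "patient_id", "matrix_type", "time_window", "pgd_grade"],
        )
    )


@pytest.fixture()
def paired_meta():
    """Four patients, each with a BALF/BBA early pair; two PGD3."""
    rows = []
    for i, grade in enumerate([3, 3, 0, 1], start=1):
        for m in ("BALF", "BBA"):
            rows.append([f"p{i}-{m}", f"p{i}", m, "early", grade])
    return make_meta(rows)
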
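import numpy as np
import pandas as pd
import pytest

from microcensus import (
    OtuTable,
    build_null,
    cohort_spec,
    fit_reference,
    select_top_features,
    synth_cohort,
)


@pytest.fixture(scope="session")
def small_cohort():
    """Desk-scale synthetic cohort: 200 hosts x 50 taxa."""
    return synth_cohort(cohort_spec(n0=200, p=50, seed=42))


@pytest.fixture(scope="session")
def small_table(small_cohort):
    return small_cohort.table


@pytest.fixture(scope="session")
def small_model(small_table):
    features = select_top_features(small_table, 30)
    return fit_reference(small_table, features)


@pytest.fixture(scope="session")
def small_census(small_model, small_table):
    return build_null(small_model, small_table, N=60, B=400, seed=7)


@pytest.fixture
def tiny_table():
    """A 3-sample, 3-taxon relative table with hand-checkable numbers."""
    data = pd.DataFrame(
        [[0.5, 0.3, 0.2], [0.2, 0.5, 0.3], [0.3, 0.2, 0.5]],
        index=["s1", "s2", "s3"],
        columns=["A", "B", "C"],
    )
    return OtuTable(data, is_relative=True)


@pytest.fixture
def counts_table():
    data = pd.DataFrame(
        [[10, 20, 70], [40, 40, 20], [5, 90, 5]],
        index=["s1", "s2", "s3"],
        columns=["A", "B", "C"],
        dtype=float,
    )
    return OtuTable(data, is_relative=False)
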
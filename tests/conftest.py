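import numpy as np
import pandas as pd
import pytest

from urostab.cohort_io import (
    OtuCountTable,
    build_paired_cohort,
    parse_metadata_frame,
)
from urostab.synthetic import SyntheticConfig


def make_metadata_frame(rows):
    """rows: list of dicts with canonical metadata columns."""
    return pd.DataFrame(rows)


def make_cohort(counts: dict[str, dict[str, int]], meta_rows, taxonomy=None):
    """Build a PairedCohort from {sample_id: {otu_id: count}} and metadata rows."""
    table = OtuCountTable(
        pd.DataFrame.from_dict(counts, orient="index").fillna(0).astype(np.int64),
        taxonomy=taxonomy,
    )
    samples, subjects = parse_metadata_frame(pd.DataFrame(meta_rows))
    return build_paired_cohort(table, samples, subjects)


def default_meta_row(subject, sample, timepoint, **overrides):
    row = dict(
        subject_id=subject,
        sample_id=sample,
        timepoint=timepoint,
        method="MSU",
        sex="M",
        age=60,
        cancer=0,
        stones=0,
        interval_months=12,
    )
    row.update(overrides)
    return row


@pytest.fixture
def three_subject_cohort():
    """Three subjects with distinctive overlap structure.

    A: identical samples; B: partially overlapping; C: disjoint samples.
    """
    counts = {
        "A1": {"o1": 50, "o2": 50},
        "A2": {"o1": 50, "o2": 50},
        "B1": {"o1": 30, "o2": 30, "o3": 40},
        "B2": {"o1": 20, "o4": 80},
        "C1": {"o5": 100},
        "C2": {"o6": 100},
    }
    meta = [
        default_meta_row("A", "A1", 1, interval_months=5, sex="F", age=55),
        default_meta_row("A", "A2", 2, interval_months=5, sex="F", age=55),
        default_meta_row("B", "B1", 1, interval_months=20, cancer=1),
        default_meta_row("B", "B2", 2, interval_months=20, cancer=1),
        default_meta_row("C", "C1", 1, interval_months=35, method="catheter"),
        default_meta_row("C", "C2", 2, interval_months=35),
    ]
    return make_cohort(counts, meta)


@pytest.fixture
def small_synthetic_config():
    """Down-scaled generator settings for fast integration tests."""
    return SyntheticConfig(
        n_subjects=16,
        global_pool_size=400,
        subject_pool_mean=50.0,
        subject_pool_sd=25.0,
        depth_mean=3000.0,
        depth_sd=1200.0,
        depth_min=1000,
    )


def random_count_vector(rng, size=30, max_count=20, ensure_positive=True):
    v = rng.integers(0, max_count, size=size)
    if ensure_positive and v.sum() == 0:
        v[rng.integers(0, size)] = 1
    return v
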
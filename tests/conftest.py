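import numpy as np
import pandas as pd
import pytest

from actidx import (
    CATEGORIES,
    aggregate_to_windows,
    extract_features,
    generate_cohort,
    paper_like_cohort,
)
from actidx.ingest import WindowSeries


def build_window_series(counts, subject_id="T0", window_length=15,
                        start="2024-01-01 22:00:00", fracs=None,
                        wear=None, sit_to_stand=None, step_count=None):
    """WindowSeries from raw per-window arrays (defaults: all sitting,
    full wear, no events)."""
    counts = np.asarray(counts, dtype=float)
    n = len(counts)
    data = pd.DataFrame({
        "window_start": pd.date_range(start, periods=n,
                                      freq=f"{window_length}min"),
        "wear_frac": np.ones(n) if wear is None else np.asarray(wear, float),
        "count_sum": counts,
        "sit_to_stand": np.zeros(n) if sit_to_stand is None
        else np.asarray(sit_to_stand, float),
        "step_count": np.zeros(n) if step_count is None
        else np.asarray(step_count, float),
    })
    for c in CATEGORIES:
        data[f"frac_{c}"] = 0.0
    if fracs is None:
        data["frac_sitting"] = 1.0
    else:
        for c, v in fracs.items():
            data[f"frac_{c}"] = v
    return WindowSeries(subject_id, window_length, data)


@pytest.fixture
def make_windows():
    return build_window_series


@pytest.fixture(scope="session")
def small_cohort():
    """A small two-group synthetic cohort reused across tests:
    (window series list, manifest, feature table)."""
    cfg = paper_like_cohort(days=4, seed=11, sizes={"AD": 8, "DLB": 8})
    series, manifest = generate_cohort(cfg)
    windows = [aggregate_to_windows(s) for s in series]
    table = extract_features(windows, manifest)
    return windows, manifest, table
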
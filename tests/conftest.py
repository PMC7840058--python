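import numpy as np
import pandas as pd
import pytest

from rsfperm.dataset_io import (
    ALL_COLUMNS,
    CONTINUOUS_ATTRIBUTES,
    AnalysisDataset,
)


def make_dataset(rows: list[dict]) -> AnalysisDataset:
    """Build an AnalysisDataset from partial row dicts (missing attribute
    cells become NaN)."""
    frame = pd.DataFrame(rows)
    for col in ALL_COLUMNS:
        if col not in frame.columns:
            frame[col] = np.nan
    frame = frame[list(ALL_COLUMNS)]
    return AnalysisDataset(frame=frame)


def site_row(record_id, role="control", behavior="none", region="eastern_nevada", **attrs):
    row = {
        "record_id": record_id,
        "role": role,
        "behavior": behavior,
        "region": region,
        "latitude": 39.0,
        "longitude": -116.0,
    }
    row.update(attrs)
    return row


@pytest.fixture(scope="session")
def small_study():
    """A reduced synthetic study shared by slower tests."""
    from rsfperm.simulate import BehaviorSpec, RegionSpec, SyntheticTruth, generate_study
    from rsfperm.simulate import default_attribute_means, default_covariance

    cov = default_covariance()
    means = default_attribute_means()
    truth = SyntheticTruth(
        regions={
            "eastern_nevada": RegionSpec(120, {**means, "elevation": 2100.0}, cov, (0.0, 0.0)),
            "southern_idaho": RegionSpec(60, {**means, "elevation": 1750.0}, cov, (150_000.0, 0.0)),
            "central_nevada": RegionSpec(50, {**means, "elevation": 2000.0}, cov, (300_000.0, 0.0)),
        },
        behaviors={
            "caching": BehaviorSpec(
                used_counts={"eastern_nevada": 15, "southern_idaho": 20, "central_nevada": 15},
                beta={"elevation": -0.6, "slope": -0.8, "distance_to_road": -0.8},
            ),
            "foraging": BehaviorSpec(
                used_counts={"southern_idaho": 12, "central_nevada": 14},
                beta={"slope": -0.5, "grass_cover": -0.5},
            ),
        },
        random_intercept_sd=0.5,
        missingness_rate=0.01,
        seed=42,
    )
    return generate_study(truth)
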
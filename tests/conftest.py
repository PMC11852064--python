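import numpy as np
import pandas as pd
import pytest

from dalbapk import (
    PKParameters,
    Regimen,
    StudyDataset,
    dalbavancin_reference_model,
)


@pytest.fixture(scope="session")
def typical_params() -> PKParameters:
    """Published typical adult values."""
    return PKParameters(cl=0.0273, v1=3.6, q=0.0225, v2=6.4)


@pytest.fixture(scope="session")
def reference_model():
    return dalbavancin_reference_model()


@pytest.fixture(scope="session")
def two_dose_regimen() -> Regimen:
    """1500 mg / 30 min infusions at day 0 and day 7."""
    return Regimen.from_times([0.0, 168.0], 1500.0)


def make_dataset(records: list[dict]) -> StudyDataset:
    return StudyDataset(pd.DataFrame(records))


@pytest.fixture()
def toy_dataset() -> StudyDataset:
    """Three subjects, one dose each, two observations each.

    Observed values were drawn once from the generative model at the
    reference parameters and frozen.
    """
    rows = []
    obs = {
        1: [(12.0, 310.2), (300.0, 33.1)],
        2: [(12.0, 265.9), (300.0, 41.7)],
        3: [(12.0, 410.8), (300.0, 28.4)],
    }
    weights = {1: 60.0, 2: 85.0, 3: 72.0}
    for sid, pairs in obs.items():
        rows.append(
            {"ID": sid, "TIME": 0.0, "EVID": 1, "AMT": 1500.0, "DUR": 0.5,
             "DV": np.nan, "WT": weights[sid]}
        )
        for t, dv in pairs:
            rows.append(
                {"ID": sid, "TIME": t, "EVID": 0, "AMT": np.nan, "DUR": np.nan,
                 "DV": dv, "WT": weights[sid]}
            )
    return make_dataset(rows)
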
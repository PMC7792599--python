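import warnings

import numpy as np
import pandas as pd
import pytest

from rehablearn.cohort_synth import fixture_experiment
from rehablearn.preprocess import (
    apply_normalizer,
    fit_normalizer,
    smote_balance,
)
from rehablearn.schema_io import (
    FTSTS_DIFFICULTY,
    TUG_DIFFICULTY,
    RehabDataset,
)

# the height-derivation drift report and the SMOTE leakage note are
# expected chatter in fixtures; tests that check them do so explicitly
warnings.filterwarnings("ignore", message="recomputed BMI moments")


def make_dataset(rows, taxonomy=None, test_type="TUG", provenance="synthetic"):
    """Small helper: build a RehabDataset from a list of row dicts."""
    frame = pd.DataFrame(rows)
    taxonomies = {} if taxonomy is None else {taxonomy.axis: taxonomy}
    return RehabDataset(
        frame=frame,
        taxonomies=taxonomies,
        test_type=test_type,
        provenance=provenance,
    )


def demo_rows(n, rng=None, label_col=None, label=0):
    """n physically consistent feature rows (BMI identity holds)."""
    rng = rng or np.random.default_rng(0)
    rows = []
    for _ in range(n):
        h = float(rng.uniform(1.5, 1.9))
        w = float(rng.uniform(55, 95))
        rows.append(
            {
                "completion_time_s": float(rng.uniform(5, 20)),
                "age_y": float(rng.uniform(20, 80)),
                "height_m": h,
                "weight_kg": w,
                "bmi": w / h**2,
                "sex": int(rng.integers(2)),
                **({label_col: label} if label_col else {}),
            }
        )
    return rows


@pytest.fixture(scope="session")
def ftsts_fixture_raw():
    return fixture_experiment("FTSTS", seed=3)


@pytest.fixture(scope="session")
def tug_fixture_raw():
    return fixture_experiment("TUG", seed=3)


@pytest.fixture(scope="session")
def ftsts_balanced_normalized(ftsts_fixture_raw):
    ds, _ = smote_balance(ftsts_fixture_raw, "difficulty", seed=5)
    return apply_normalizer(ds, fit_normalizer(ds))


@pytest.fixture(scope="session")
def tug_balanced_normalized(tug_fixture_raw):
    ds, _ = smote_balance(tug_fixture_raw, "difficulty", seed=5)
    return apply_normalizer(ds, fit_normalizer(ds))
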
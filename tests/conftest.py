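import numpy as np
import pandas as pd
import pytest

import kneeoa as k


@pytest.fixture(scope="session")
def table2():
    return k.load_fixture("table2")


@pytest.fixture(scope="session")
def table5():
    return k.load_fixture("table5")


@pytest.fixture(scope="session")
def synthetic_cohort():
    """One default-condition synthetic cohort, shared across tests."""
    return k.generate_cohort(k.GeneratorParams(seed=11))


@pytest.fixture(scope="session")
def model2_fit(synthetic_cohort):
    return k.fit_model(synthetic_cohort, k.MODEL_II)


def make_cohort(n_alleles, labels, sex=None, age=None, bmi=None):
    """Tiny hand-built cohort from per-subject risk-allele counts and
    0/1 case labels; clinical columns default to constants."""
    n_alleles = np.asarray(n_alleles)
    labels = np.asarray(labels)
    m = len(n_alleles)
    d1 = np.minimum(n_alleles, 2)
    d2 = np.minimum(n_alleles - d1, 2)
    d3 = n_alleles - d1 - d2
    df = pd.DataFrame({
        "subject_id": [f"s{i}" for i in range(m)],
        "status": np.where(labels == 1, "case", "control"),
        "sex": 2 if sex is None else sex,
        "age": 70.0 if age is None else age,
        "height": np.nan, "weight": np.nan,
        "bmi": 23.0 if bmi is None else bmi,
        "dosage_aspn": d1, "dosage_gdf5": d2, "dosage_dvwa": d3,
    })
    return k.CohortTable(df, "test cohort")


@pytest.fixture
def tiny_cohort():
    return make_cohort([0, 3, 6, 1, 2, 5], [1, 1, 1, 0, 0, 0])
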
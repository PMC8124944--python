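import pandas as pd
import pytest

from mirpanel import CohortConfig, generate_cohort, generate_standard_curve_plate, quantify_cohort


@pytest.fixture(scope="session")
def tiny_config():
    return CohortConfig(
        n_benign_discovery=30,
        n_malignant_discovery=20,
        n_benign_validation=30,
        n_malignant_validation=20,
        n_normal=10,
        n_mirnas=40,
        n_expressed=30,
        seed=7,
    )


@pytest.fixture(scope="session")
def tiny_cohort(tiny_config):
    ct, annotations, truth = generate_cohort(tiny_config)
    standards, _ = generate_standard_curve_plate(tiny_config)
    return ct, annotations, truth, standards


@pytest.fixture(scope="session")
def noiseless_config():
    return CohortConfig(
        n_benign_discovery=12,
        n_malignant_discovery=8,
        n_benign_validation=12,
        n_malignant_validation=8,
        n_normal=5,
        n_mirnas=25,
        n_expressed=18,
        ct_noise_sd=0.0,
        hemolysis_fraction=0.0,
        seed=11,
    )


@pytest.fixture(scope="session")
def noiseless_cohort(noiseless_config):
    ct, annotations, truth = generate_cohort(noiseless_config)
    standards, _ = generate_standard_curve_plate(noiseless_config)
    return ct, annotations, truth, standards


@pytest.fixture(scope="session")
def tiny_expression(tiny_cohort):
    ct, annotations, truth, standards = tiny_cohort
    expression, curves, recovery, collapsed = quantify_cohort(ct, standards)
    return expression, curves, recovery, collapsed


def labels_from_annotations(annotations) -> pd.Series:
    return pd.Series({a.sample_id: a.diagnosis for a in annotations})
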
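import pytest
from hypothesis import HealthCheck, settings

import glycoprm as g

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def panel():
    return g.load_verification_panel()


@pytest.fixture(scope="session")
def study_dataset():
    """Full verification-design dataset: 163 subjects, duplicate runs."""
    return g.generate_dataset(seed=0)


@pytest.fixture(scope="session")
def study_matrix(study_dataset, panel):
    """QC-filtered, normalized matrix of the study-design dataset."""
    cohort, runs, truth = study_dataset
    retained, report = g.qc_filter(runs)
    matrix = g.assemble_matrix(retained, cohort, panel)
    return matrix, report, truth


@pytest.fixture(scope="session")
def feature_columns(panel):
    from glycoprm.prm import CLINICAL_COLUMNS

    return list(panel["peptide_id"]) + CLINICAL_COLUMNS
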
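import pandas as pd
import pytest

from lipidmrm.ingest import assemble_matrix, profiles_from_table
from lipidmrm.reference import discriminative_transitions
from lipidmrm.scan_library import synthetic_screening_methods
from lipidmrm.synthetic_data import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def methods():
    return synthetic_screening_methods()


@pytest.fixture(scope="session")
def method_pos(methods):
    return methods[0]


@pytest.fixture(scope="session")
def method_neg(methods):
    return methods[1]


@pytest.fixture(scope="session")
def reference_panel() -> pd.DataFrame:
    return discriminative_transitions()


@pytest.fixture(scope="session")
def cohort_matrix(method_pos):
    """Default-design positive-mode cohort (36 samples), seed 11."""
    table = generate_cohort(CohortConfig(seed=11), method_pos)
    return assemble_matrix(profiles_from_table(table, method_pos))


@pytest.fixture(scope="session")
def cohort_matrix_neg(method_neg):
    table = generate_cohort(CohortConfig(seed=12), method_neg)
    return assemble_matrix(profiles_from_table(table, method_neg))
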
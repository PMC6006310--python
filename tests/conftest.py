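import numpy as np
import pandas as pd
import pytest

from grscohort.cohort_io import GenotypeMatrix, PhenotypeTable, SNPPanel, make_panel_record
from grscohort.simulate import make_fixture_suite


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    """Deterministic on-disk fixture: 20 samples x 5 SNPs in every format."""
    out = tmp_path_factory.mktemp("fixture")
    make_fixture_suite(out, seed=7)
    return out


@pytest.fixture
def tiny_panel():
    return SNPPanel(
        [
            make_panel_record("rs0001", "GENE1", "A", 1.5),
            make_panel_record("rs0002", "GENE2", "C", 2.0),
            make_panel_record("rs0003", "GENE3", "G", 0.8),
        ]
    )


@pytest.fixture
def tiny_matrix():
    # 4 samples x 3 SNPs; one missing call for sample s4
    data = pd.DataFrame(
        {
            "rs0001": [2.0, 1.0, 0.0, 1.0],
            "rs0002": [1.0, 1.0, 1.0, 0.0],
            "rs0003": [0.0, 2.0, 1.0, np.nan],
        },
        index=["s1", "s2", "s3", "s4"],
    )
    return GenotypeMatrix(data)


@pytest.fixture
def tiny_phenotypes():
    frame = pd.DataFrame(
        {
            "af_status": ["case", "case", "control", "control"],
            "af_subtype": ["permanent", "non-permanent", "none", "none"],
            "sex_male": [1.0, 0.0, 1.0, 0.0],
            "age": [70.0, 65.0, 72.0, 68.0],
        },
        index=["s1", "s2", "s3", "s4"],
    )
    return PhenotypeTable(frame)
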
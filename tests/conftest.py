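import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from leanscan import GenotypePanel, PhenotypeTable
from leanscan.io import default_snp_meta


@pytest.fixture
def tiny_panel():
    """3 subjects x 2 SNPs with one missing call."""
    calls = np.array([[0, 2], [1, -1], [2, 0]], dtype=np.int8)
    return GenotypePanel(
        np.array(["A", "B", "C"], dtype=object),
        np.array(["rs1", "rs2"], dtype=object),
        calls,
        default_snp_meta(["rs1", "rs2"]),
    )


@pytest.fixture
def tiny_pheno():
    data = pd.DataFrame(
        {
            "lean_mass_pct": [34.2, 33.8, 34.5],
            "age_years": [60.0, 65.0, 70.0],
            "fat_mass_pct": [31.0, 32.0, 30.5],
            "bmd": [0.95, 1.01, 0.99],
        },
        index=pd.Index(["A", "B", "C"], name="subject_id"),
    )
    return PhenotypeTable(data)
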
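import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from gastrukit.containers import CellMatrix
from gastrukit.synthetic import (
    default_cohort_spec,
    default_time_program,
    generate_species_pair,
)

MASTER_SEED = 7  # the study conditions for the parameter-recovery simulation


@pytest.fixture(scope="session")
def species_pair():
    """Default two-species cohort: 6 stages x 5 individuals, shared program."""
    program = default_time_program(seed=MASTER_SEED)
    cmA, cmB, omap = generate_species_pair(
        program,
        default_cohort_spec("speciesA"),
        default_cohort_spec("speciesB"),
        seed=MASTER_SEED,
    )
    return program, cmA, cmB, omap


@pytest.fixture
def tiny_cm():
    """3 genes x 4 cells over two individuals, hand-checkable."""
    counts = sp.csr_matrix(
        np.array(
            [
                [1, 2, 0, 3],
                [0, 4, 5, 0],
                [2, 0, 1, 1],
            ]
        )
    )
    genes = pd.Index(["SOX2", "TBX6", "PAX3"], name="gene_id")
    meta = pd.DataFrame(
        {
            "individual_id": ["g1", "g1", "g2", "g2"],
            "cell_type": ["NMP", "somite", "NMP", "somite"],
            "stage_label": ["t0"] * 4,
            "stage_value": [0.0] * 4,
            "species": ["human"] * 4,
            "model": ["gastruloid"] * 4,
        },
        index=pd.Index(["c1", "c2", "c3", "c4"], name="cell_id"),
    )
    return CellMatrix(counts, genes, meta)
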
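import numpy as np
import pandas as pd
import pytest

from priorblup import (
    GenotypeMatrix,
    PhenotypeTable,
    SimConfig,
    simulate_population,
)


@pytest.fixture(scope="session")
def small_population():
    """A 300 x 800 simulated population with 5 QTL, shared across tests."""
    cfg = SimConfig.scaled_down(
        300, 800, n_qtl=5, qtl_variance_fraction=0.5, h2_target=0.3, seed=11
    )
    return simulate_population(cfg)


@pytest.fixture
def tiny_geno():
    """Hand-built 4-sample x 3-marker matrix (no missing calls)."""
    dosages = np.array(
        [[0, 1, 0], [2, 1, 0], [1, 2, 0], [1, 0, 0]], dtype=np.int8
    )
    markers = pd.DataFrame(
        {
            "chrom": [1, 1, 2],
            "id": ["m1", "m2", "m3"],
            "cm": 0.0,
            "pos": [100, 5000, 300],
            "a1": "A",
            "a2": "G",
        }
    )
    return GenotypeMatrix(dosages, markers, ["s1", "s2", "s3", "s4"])


def make_pheno(sample_ids, traits, herd=None, birth=None):
    n = len(sample_ids)
    return PhenotypeTable(
        pd.DataFrame(
            {
                "sample_id": sample_ids,
                "trait": traits,
                "herd": herd if herd is not None else ["H1"] * n,
                "birth_type": birth if birth is not None else ["1"] * n,
            }
        )
    )
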
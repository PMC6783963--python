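import numpy as np
import pandas as pd
import pytest

from oleakit.data_model import GenotypeTable, QuantitativeMatrix


@pytest.fixture
def toy_genotypes() -> GenotypeTable:
    """Five samples, two loci, one half-missing call and one full blank."""
    alleles = np.array(
        [
            [[140, 144], [200, 200]],
            [[140, 140], [200, 204]],
            [[144, 144], [0, 0]],
            [[140, 144], [204, 204]],
            [[142, 144], [200, 204]],
        ]
    )
    missing = np.array(
        [
            [False, False],
            [False, False],
            [False, True],
            [False, False],
            [False, False],
        ]
    )
    return GenotypeTable(["S1", "S2", "S3", "S4", "S5"], ["L1", "L2"], alleles, missing)


@pytest.fixture
def fatty_site_means() -> QuantitativeMatrix:
    """One row per collection site holding the reference mean oil profile."""
    from oleakit.synthetic_data import DEFAULT_FATTY_MEANS

    sites = ["CE", "CM", "OIR", "OSE"]
    data = {
        acid: [by_site[s][0] for s in sites] for acid, by_site in DEFAULT_FATTY_MEANS.items()
    }
    return QuantitativeMatrix(pd.DataFrame(data, index=pd.Index(sites, name="sample_id")), percent=True)
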
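import numpy as np
import pandas as pd
import pytest

from plastinet.design import make_design


@pytest.fixture(scope="session")
def design2():
    """The 4-condition x 2-replicate factorial layout."""
    return make_design(2)


@pytest.fixture(scope="session")
def design3():
    return make_design(3)


@pytest.fixture(scope="session")
def design5():
    return make_design(5)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240)


@pytest.fixture()
def toy_annotation():
    """Two genes on one chromosome with a clear gap between them."""
    return pd.DataFrame(
        {
            "gene_id": ["geneA", "geneB"],
            "chrom": ["chr1", "chr1"],
            "start": [10_000, 40_000],
            "end": [12_000, 43_000],
            "strand": ["+", "-"],
        }
    )
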
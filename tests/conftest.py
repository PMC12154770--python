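import numpy as np
import pytest

from grene.panel import generate_founder_panel


@pytest.fixture(scope="session")
def small_panel():
    """30 accessions x 600 SNPs on 3 chromosomes, moderate LD."""
    return generate_founder_panel(
        n_accessions=30, n_snps=600, n_chroms=3, ld_decay=15.0, seed=101
    )


@pytest.fixture(scope="session")
def tiny_panel():
    """10 accessions x 60 SNPs; quick structural checks."""
    return generate_founder_panel(
        n_accessions=10, n_snps=60, n_chroms=2, ld_decay=5.0, seed=7
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
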
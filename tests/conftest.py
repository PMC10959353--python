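import numpy as np
import pytest

from mobiloscope.synthetic_data import build_genome, make_family_panel


@pytest.fixture(scope="session")
def small_families():
    """Two families with 120-bp LTRs and ~1 kb elements, for fast tests."""
    return make_family_panel(2, ltr_len=120, internal_len=800, seed=101)


@pytest.fixture(scope="session")
def small_genome(small_families):
    fams = small_families
    return build_genome(
        fams,
        {fams[0].name: 3, fams[1].name: 2},
        chrom_len=60_000,
        tsd_len=5,
        divergence=0.0,
        seed=102,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
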
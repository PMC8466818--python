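import numpy as np
import pytest

from cansynth.simulate import (
    FamilyConfig,
    make_paper_fixture,
    make_template_panel,
    simulate_gene_family,
)


@pytest.fixture(scope="session")
def family():
    """Seeded two-clade synthetic family (10 CBCAS-like + 10 THCAS-like)."""
    return simulate_gene_family(FamilyConfig(seed=42))


@pytest.fixture(scope="session")
def panel():
    """Synthetic three-gene template panel carrying the published primer sites."""
    return make_template_panel(seed=0)


@pytest.fixture(scope="session")
def fixture_bundle():
    return make_paper_fixture()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
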
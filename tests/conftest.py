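import pytest

from circpanel.junctions import build_references
from circpanel.primers import design_panel
from circpanel.simulate import make_synthetic_heart_panel, make_toy_genome


@pytest.fixture(scope="session")
def toy2():
    """Two planted three-exon genes (one +, one - strand) and their panel."""
    genome, panel = make_toy_genome(n_targets=2, exon_len=200, seed=1)
    return genome, panel


@pytest.fixture(scope="session")
def heart63():
    """Synthetic 63-circRNA / 50-host-gene panel collapsing to 52 groups."""
    genome, panel = make_synthetic_heart_panel(seed=20)
    return genome, panel


@pytest.fixture(scope="session")
def heart_design(heart63):
    genome, panel = heart63
    result = design_panel(panel, genome)
    assert not result.failures, result.failures
    return result


@pytest.fixture(scope="session")
def heart_refs(heart63, heart_design):
    genome, panel = heart63
    return build_references(panel, heart_design.primers, genome)


@pytest.fixture(scope="session")
def toy2_refs(toy2):
    genome, panel = toy2
    result = design_panel(panel, genome)
    assert not result.failures, result.failures
    return result.primers, build_references(panel, result.primers, genome)
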
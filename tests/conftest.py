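import pytest

import bcrcsf as b


@pytest.fixture(scope="session")
def library():
    return b.toy_library()


@pytest.fixture(scope="session")
def default_sim(library):
    """The default simulated repertoire (cells, truths), shared read-only."""
    cfg = b.SimConfig(seed=42)
    return b.simulate_repertoire(library, cfg)


@pytest.fixture(scope="session")
def fitted(library, default_sim):
    """Fitted results on the default repertoire, shared read-only."""
    cells, _ = default_sim
    return b.RepertoireAnalysis(cells, library).fit()
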
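import numpy as np
import pytest

import thermoniche as tn


@pytest.fixture()
def table1():
    return tn.load_table1_fixture()


@pytest.fixture()
def species_table():
    """The 23 study species (outgroup excluded)."""
    return tn.load_table1_fixture(include_outgroup=False)


@pytest.fixture()
def rng():
    return np.random.default_rng(20170721)


@pytest.fixture()
def tree8():
    """Fixed 8-tip bifurcating tree with varied branch lengths."""
    return tn.read_newick(
        "(((A:0.5,B:1.2):0.8,(C:0.3,D:0.9):1.1):0.4,((E:0.7,F:0.2):0.6,(G:1.5,H:0.4):0.9):1.3);"
    )
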
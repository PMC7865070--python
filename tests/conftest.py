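import pytest

from olpiphy import synthdata as sd
from olpiphy import treekit as tk


@pytest.fixture(scope="session")
def jc():
    return tk.SubstModel(n_states=4)


@pytest.fixture(scope="session")
def quartet_alignment(jc):
    """2000 sites simulated on a quartet with a long internal branch."""
    tree = tk.read_tree("((A:0.1,B:0.1):0.5,C:0.1,D:0.1);")
    aln = sd.simulate_alignment(tree, jc, 2000, seed=11)
    return aln.rows


@pytest.fixture(scope="session")
def ten_taxon_tree():
    return tk.read_tree(
        "(((A:0.06,B:0.06):0.04,(C:0.06,D:0.06):0.04):0.04,"
        "((E:0.06,F:0.06):0.04,(G:0.06,H:0.06):0.04):0.04,"
        "(I:0.06,J:0.06):0.06);"
    )
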
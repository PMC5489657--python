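import numpy as np
import pytest

import bogwater as bw


@pytest.fixture(scope="session")
def sim():
    """One scaled-down simulated survey shared across the suite."""
    cfg = bw.small_config(seed=11)
    table, metadata, tree, truth = bw.simulate_timeseries(cfg)
    return {"config": cfg, "table": table, "metadata": metadata,
            "tree": tree, "truth": truth}


@pytest.fixture(scope="session")
def rarefied(sim):
    table, report = bw.rarefy(bw.filter_rare_otus(sim["table"]),
                              depth=2500, seed=11)
    return table, report


@pytest.fixture()
def tiny_table():
    counts = np.array([[5, 0, 1],
                       [2, 3, 0],
                       [0, 4, 4],
                       [1, 1, 1]])
    return bw.OtuTable(counts, ["s1", "s2", "s3", "s4"],
                       ["otuA", "otuB", "otuC"])


@pytest.fixture()
def cherry_tree():
    """((A:1,B:1):1,C:2); — the hand-computable UniFrac example."""
    import io
    from skbio import TreeNode
    return TreeNode.read(io.StringIO("((A:1,B:1):1,C:2);"))
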
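import numpy as np
import pandas as pd
import pytest

from mircoreg.motifs import RegGraph


@pytest.fixture
def hand_ct_table() -> pd.DataFrame:
    """One case and one control sample; target at Ct 30, references at 25/27.

    Noise-free: delta Ct is 30 - 26 = 4 in both samples.
    """
    rows = []
    for sample, group in [("s1", "case"), ("s2", "control")]:
        for mirna, ct in [("miR-x", 30.0), ("ref-a", 25.0), ("ref-b", 27.0)]:
            for rep in (1, 2, 3):
                rows.append(
                    {"sample": sample, "group": group, "mirna": mirna,
                     "replicate": rep, "ct": ct}
                )
    return pd.DataFrame(rows)


def make_graph(tm=(), mt=(), tg=(), mg=()) -> RegGraph:
    """Build a RegGraph from edge lists: TF->miRNA, miRNA->TF, TF->gene, miRNA->gene."""
    g = RegGraph()
    for t, m in list(tm) + [(t, m) for m, t in mt]:
        g.add_node(t, "TF")
        g.add_node(m, "miRNA")
    for t, x in tg:
        g.add_node(t, "TF")
        g.add_node(x, "gene")
    for m, x in mg:
        g.add_node(m, "miRNA")
        g.add_node(x, "gene")
    for t, m in tm:
        g.add_edge(t, m)
    for m, t in mt:
        g.add_edge(m, t)
    for t, x in tg:
        g.add_edge(t, x)
    for m, x in mg:
        g.add_edge(m, x)
    return g


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260928)
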
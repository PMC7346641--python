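"""Shared fixtures: tiny hand-built networks and a small synthetic cohort.

All data are generated programmatically; nothing is read from disk except
files the tests themselves write into tmp_path.
"""

import networkx as nx
import pytest

from hgtnet.data_model import HGTEvent, HGTNetwork
from hgtnet.synthetic_cohort import CohortConfig, generate_cohort


def make_network(sample_id: str, edges, nodes=()) -> HGTNetwork:
    """Build a network from (u, v) or (u, v, weight) tuples."""
    g = nx.Graph()
    g.add_nodes_from(nodes)
    for e in edges:
        if len(e) == 2:
            g.add_edge(e[0], e[1], weight=1)
        else:
            g.add_edge(e[0], e[1], weight=e[2])
    return HGTNetwork(sample_id=sample_id, graph=g)


@pytest.fixture
def path_network():
    """a — b — c."""
    return make_network("p3", [("a", "b"), ("b", "c")])


@pytest.fixture
def events_tsv(tmp_path):
    """Well-formed 3-row event table; one row needs side swapping."""
    p = tmp_path / "events.tsv"
    p.write_text(
        "sample_id\tgenome_a\tpos_a\tgenome_b\tpos_b\n"
        "s1\tgA\t150\tgB\t550\n"
        "s1\tgB\t550\tgA\t150\n"
        "s2\tgC\t10\tgA\t99\n"
    )
    return p


@pytest.fixture(scope="session")
def small_cohort():
    """Desk-scale mother-child cohort shared across test modules."""
    return generate_cohort(CohortConfig(seed=11, n_families=4))


@pytest.fixture(scope="session")
def small_cohort_dir(small_cohort, tmp_path_factory):
    d = tmp_path_factory.mktemp("cohort")
    small_cohort.write(d)
    return d
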
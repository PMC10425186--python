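import networkx as nx
import pytest

from usnap import SnapshotGraphSet, SyntheticSpec, generate


def make_set(*edge_lists, labels=None):
    """Snapshot set from plain edge lists (one list per snapshot)."""
    return SnapshotGraphSet([nx.Graph(e) for e in edge_lists], labels or [])


@pytest.fixture
def tiny_set():
    """T=3 with u=2 intended: S1={(A,B)}, S2={(A,B),(B,C)}, S3={}."""
    return make_set([("A", "B")], [("A", "B"), ("B", "C")], [])


@pytest.fixture
def identical_path_set():
    """Two identical snapshots of the path A-B-C: every weight collapses to 1."""
    path = [("A", "B"), ("B", "C")]
    return make_set(path, path)


@pytest.fixture
def planted_two_regions():
    """Planted 6- and 5-cliques unique to snapshot 1 over a shared background."""
    spec = SyntheticSpec(seed=1, n_planted_regions=2, n_planted=(6, 5),
                         n_background=20)
    snaps, truth = generate(spec)
    return snaps, truth
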
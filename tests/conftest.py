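import numpy as np
import pytest

from katzlda.fixtures import FixtureSpec, generate_inputs
from katzlda.network import AssociationNetwork, network_from_pairs


@pytest.fixture
def toy_pairs():
    # dedup fixture: 5 rows, 4 distinct pairs
    return [("L1", "D1"), ("L1", "D1"), ("L2", "D1"), ("L2", "D2"), ("L3", "D2")]


@pytest.fixture
def toy_net(toy_pairs):
    return network_from_pairs(toy_pairs)


@pytest.fixture
def toy_table(tmp_path, toy_pairs):
    path = tmp_path / "associations.tsv"
    path.write_text("lncrna_id\tdisease_id\tevidence\n" + "".join(
        f"{l}\t{d}\tPMID:{i}\n" for i, (l, d) in enumerate(toy_pairs)))
    return path


@pytest.fixture(scope="session")
def small_bundle():
    """One small planted-signal study condition shared across tests."""
    return generate_inputs(FixtureSpec(nl=24, nd=16, density=0.12, n_blocks=4,
                                       dag_depth=3, seed=11))


def random_bipartite(rng, nl, nd, density=0.3):
    adjacency = (rng.random((nl, nd)) < density).astype(np.int8)
    if not adjacency.any():
        adjacency[rng.integers(nl), rng.integers(nd)] = 1
    ids_l = tuple(f"L{i}" for i in range(nl))
    ids_d = tuple(f"D{j}" for j in range(nd))
    return AssociationNetwork(ids_l, ids_d, adjacency)
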
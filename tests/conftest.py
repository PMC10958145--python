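import numpy as np
import pytest

from selconv.aamodels import jtt
from selconv.synthetic import ScenarioConfig, build_dataset, gpx6_scenario
from selconv.trees import EXCHANGE, INHERITED, SEC, PhyloTree

#: fixed 10-taxon tagged tree used for calibration-style simulations:
#: three internal EXCHANGE branches, each with INHERITED descendants.
TEN_TAXON_NEWICK = (
    "(((a:0.05,b:0.05)ab:0.04,(c:0.05,d:0.05)cd:0.04)abcd:0.03,"
    "((e:0.05,f:0.05)ef:0.04,((g:0.05,h:0.05)gh:0.04,(i:0.05,j:0.05)"
    "ij:0.04)ghij:0.03)efij:0.03)root;"
)


def tag_tree(tree: PhyloTree, exchange_names) -> PhyloTree:
    for b in tree.branches:
        tree.tags[b] = SEC
    for name in exchange_names:
        b = tree.node_by_name(name)
        tree.tags[b] = EXCHANGE
        for d in tree.subtree_nodes(b):
            if d != b:
                tree.tags[d] = INHERITED
    tree.validate_tags()
    return tree


@pytest.fixture(scope="session")
def ten_taxon_tree() -> PhyloTree:
    return tag_tree(PhyloTree.from_newick(TEN_TAXON_NEWICK, is_path=False),
                    ("ab", "ef", "gh"))


@pytest.fixture(scope="session")
def jtt_model():
    return jtt()


@pytest.fixture(scope="session")
def gpx6_dataset():
    """One realisation of the packaged 22-mammal preset (with injection)."""
    return build_dataset(gpx6_scenario(seed=42))


@pytest.fixture(scope="session")
def plain_dataset(ten_taxon_tree):
    """Neutral-structure dataset: equal omega in all branch classes."""
    cfg = ScenarioConfig(
        tree=ten_taxon_tree.copy(),
        omegas={SEC: 0.2, EXCHANGE: 0.2, INHERITED: 0.2},
        domain_lengths={"A": 100}, catalytic_site=50, kappa=2.5,
        n_focal_changes=0, n_injected=0, seed=9,
    )
    return build_dataset(cfg)
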
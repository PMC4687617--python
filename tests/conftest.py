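import pytest

import phylocontrasts as pc
from phylocontrasts.evaluation import pair_trait_experiment, single_trait_experiment

# 5-tip fixture whose PIC ancestral states and contrasts were frozen from an
# independent reference implementation (R ape: ace method="pic" and pic()).
ORACLE_NEWICK = "(((A:1.0,B:2.0):0.5,C:1.5):0.75,(D:1.25,E:0.25):2.0);"
ORACLE_TIPS = {"A": 1.2, "B": -0.4, "C": 2.1, "D": 0.3, "E": -1.0}
# keyed by descendant tip sets, order-free
ORACLE_ANCESTRAL = {
    frozenset("AB"): 0.6666667,
    frozenset("ABC"): 1.2937500,
    frozenset("DE"): -0.7833333,
    frozenset("ABCDE"): 0.4856628,
}
ORACLE_CONTRASTS = {
    frozenset("AB"): 0.9237604,
    frozenset("ABC"): -0.8777338,
    frozenset("DE"): 1.0614456,
    frozenset("ABCDE"): 1.0925084,
}


@pytest.fixture(scope="session")
def oracle_tree():
    return pc.read_tree(ORACLE_NEWICK)


@pytest.fixture(scope="session")
def yule100():
    """The fixed 100-tip pure-birth surrogate tree used by the experiments."""
    return pc.simulate_tree(100, seed=1)


@pytest.fixture(scope="session")
def single200(yule100):
    """Single-trait bias experiment, 200 geometric-BM replicates."""
    return single_trait_experiment(yule100, n_traits=200, sigma2=1.0, seed=1)


@pytest.fixture(scope="session")
def pidc_highres(yule100):
    """PIDC-only bias run with enough replicates to resolve a +/-0.05 band.

    The worst-node Monte-Carlo standard error must sit well below the band
    half-width; 6000 replicates put it near 0.015 on this tree.
    """
    return single_trait_experiment(
        yule100, n_traits=6000, sigma2=1.0, seed=1, methods=("PIDC",)
    )


@pytest.fixture(scope="session")
def pairs100(yule100):
    """Slope-recovery experiment: 100 correlated pairs, beta swept 0 to 1."""
    return pair_trait_experiment(yule100, n_pairs=100, seed=1)


def tipset(tree, node):
    """Frozen-oracle helper: the set of tip labels descending from a node."""
    out = set()
    stack = [node]
    while stack:
        v = stack.pop()
        if tree.is_tip[v]:
            out.add(tree.labels[v])
        else:
            stack.extend(tree.children[v])
    return frozenset(out)
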
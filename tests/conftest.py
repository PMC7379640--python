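import numpy as np
import pytest

import phylopaths as pp
from phylopaths.tree import PhyloCovariance


@pytest.fixture
def toy_tree():
    """((A:1,B:1):1,C:2); — ultrametric, height 2."""
    return pp.Phylogeny.from_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def star_cov():
    """Identity covariance on 40 tips: no phylogenetic structure."""
    n = 40
    return PhyloCovariance([f"s{i}" for i in range(n)], np.eye(n))


@pytest.fixture
def small_dataset():
    """An 80-species synthetic dataset from the default generating model."""
    cfg = pp.default_config(seed=11, n_species=80)
    tree = pp.simulate_tree(80, seed=11)
    data = pp.simulate_traits(tree, cfg)
    return data, pp.vcv(tree)


def phylo_noise(cov, rng):
    """A Brownian draw on the tree's correlation structure."""
    corr = cov.correlation()
    L = np.linalg.cholesky(corr + 1e-12 * np.eye(len(corr)))
    return L @ rng.standard_normal(len(corr))
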
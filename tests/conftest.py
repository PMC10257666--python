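import numpy as np
import pytest

from pulsegcn.simulate import SimConfig, simulate_reference, simulate_tree
from pulsegcn.tree import parse_tree

BASIC_NEWICK = "((A:2,B:2):1,C:3);"


@pytest.fixture
def basic_tree():
    return parse_tree(BASIC_NEWICK)


@pytest.fixture(scope="session")
def reference300():
    """Medium synthetic reference under the default study conditions:
    tree, true branch-group assignment, generating model, integer traits."""
    return simulate_reference(SimConfig(n_tips=300, seed=11))


def simulate_bm(tree, sigma2=1.0, root=10.0, seed=0):
    """Exact Brownian-motion tip values (Gaussian increment per branch)."""
    rng = np.random.default_rng(seed)
    value = np.empty(tree.n_nodes)
    value[tree.root] = root
    for node in tree.postorder[::-1]:
        if node == tree.root:
            continue
        value[node] = value[tree.parent[node]] + \
            rng.normal(0.0, np.sqrt(sigma2 * tree.lengths[node]))
    return {tree.labels[t]: float(value[t]) for t in tree.tip_ids}


@pytest.fixture(scope="session")
def bm_tree_traits():
    """50-tip tree with continuous BM traits (sigma2 = 1), for Gaussian
    oracles.  Branches shorter than a few expected jumps of the lambda=1e4
    comparison regime are lengthened: below that scale the compound-Poisson
    process is genuinely not Brownian and no equivalence is expected."""
    tree = simulate_tree(50, 0.4, seed=21)
    nonroot = np.arange(tree.n_nodes) != tree.root
    tree.lengths[nonroot] = np.maximum(tree.lengths[nonroot], 2e-3)
    return tree, simulate_bm(tree, 1.0, 10.0, seed=22)


def phylo_covariance(tree):
    """Independent oracle: phylogenetic covariance matrix (shared root-to-
    MRCA path length) built from explicit root-to-tip paths."""
    tips = tree.tip_ids
    paths = {}
    for t in tips:
        path = []
        node = int(t)
        while node != tree.root:
            path.append(node)
            node = int(tree.parent[node])
        paths[int(t)] = path
    n = len(tips)
    V = np.zeros((n, n))
    for i, a in enumerate(tips):
        for j, b in enumerate(tips):
            shared = set(paths[int(a)]) & set(paths[int(b)])
            V[i, j] = sum(tree.lengths[s] for s in shared)
    return tips, V


def reml_loglik_bm(tree, traits, sigma2, sigma2_eps=0.0):
    """Matrix-based restricted (contrast) log-likelihood of BM + tip noise:
    the Gaussian density of the data integrated over the unknown root value
    with a flat prior.  Independent of the recursion it checks."""
    tips, V = phylo_covariance(tree)
    x = np.array([traits[tree.labels[t]] for t in tips])
    n = len(x)
    C = sigma2 * V + sigma2_eps * np.eye(n)
    Ci = np.linalg.inv(C)
    one = np.ones(n)
    denom = one @ Ci @ one
    mu = (one @ Ci @ x) / denom
    r = x - mu
    sign, logdet = np.linalg.slogdet(C)
    assert sign > 0
    return -0.5 * ((n - 1) * np.log(2 * np.pi) + logdet + np.log(denom)
                   + r @ Ci @ r)
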
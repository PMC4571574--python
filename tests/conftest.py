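import numpy as np
import pytest

from rootward.likelihood import Alignment
from rootward.models import NRParameters
from rootward.trees import parse_newick, random_rooted_tree


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def jc_params():
    """Jukes–Cantor as the zero-perturbation NR special case."""
    return NRParameters(pi=np.ones(4) / 4, kappa=1.0)


@pytest.fixture
def five_taxon_tree():
    return parse_newick(
        "(((A:0.1,B:0.2):0.15,C:0.3):0.1,(D:0.25,E:0.05):0.2);")


def random_alignment(labels, n_sites, rng, alphabet="ACGT"):
    return Alignment(list(labels),
                     ["".join(rng.choice(list(alphabet), n_sites))
                      for _ in labels])


def random_nr_params(rng, nonreversible=True, n_categories=1):
    return NRParameters(
        pi=rng.dirichlet(np.ones(4) * 5),
        kappa=float(rng.uniform(1.0, 4.0)),
        eps_r=rng.normal(0.0, 0.3, 6),
        eps_n=rng.normal(0.0, 0.3, 12) if nonreversible else np.zeros(12),
        sigma_r=0.3, sigma_n=0.3 if nonreversible else 0.0,
        alpha=float(rng.uniform(0.4, 2.0)),
        n_categories=n_categories)


def random_hb_params(tree, rng, equal_compositions=False, n_categories=1):
    from rootward.models import HBParameters
    root_children = {c.id for c in tree.root.children}
    alr_root = rng.normal(0.0, 0.4, 3)
    branch_alr = {
        nd.id: (alr_root.copy() if equal_compositions
                else alr_root + rng.normal(0.0, 0.5, 3))
        for nd in tree.edges() if nd.id not in root_children}
    return HBParameters(rho=rng.exponential(1.0, 6), alr_root=alr_root,
                        branch_alr=branch_alr, s=0.5,
                        alpha=float(rng.uniform(0.4, 2.0)),
                        n_categories=n_categories)


def random_tree(n, rng, mean_bl=0.2):
    return random_rooted_tree([f"t{i}" for i in range(n)], rng, mean_bl)
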
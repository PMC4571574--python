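import math

import numpy as np
import pytest
from scipy.stats import dirichlet, expon, norm

from conftest import random_alignment, random_hb_params, random_nr_params, random_tree
from rootward.inference import (ChainSample, McmcOptions, PriorSpec, _State,
                                draw_parameters_from_prior, log_prior, propose,
                                run_mcmc)
from rootward.likelihood import Alignment
from rootward.models import HBParameters, NRParameters, alr_inverse
from rootward.trees import parse_newick, root_split_of


def literal_nr_log_prior(params, tree, spec):
    """Independent term-by-term transcription of the NR prior (scipy only)."""
    lp = sum(expon.logpdf(nd.length, scale=spec.branch_length_mean)
             for nd in tree.edges())
    lp += dirichlet.logpdf(params.pi[:3], spec.dirichlet_pi)  # density over pi
    lp += np.log(params.pi).sum()                             # alr Jacobian
    lp += norm.logpdf(math.log(params.kappa), scale=spec.log_kappa_sd)
    lp += expon.logpdf(params.sigma_r, scale=spec.sigma_r_mean)
    lp += norm.logpdf(params.eps_r, scale=params.sigma_r).sum()
    lp += expon.logpdf(params.sigma_n, scale=spec.sigma_n_mean)
    lp += norm.logpdf(params.eps_n, scale=params.sigma_n).sum()
    lp += expon.logpdf(params.alpha, scale=spec.alpha_mean)
    return float(lp)


def literal_hb_log_prior(params, tree, spec):
    """Independent transcription of the HB prior, walking the tree by hand."""
    lp = sum(expon.logpdf(nd.length, scale=spec.branch_length_mean)
             for nd in tree.edges())
    lp += expon.logpdf(params.rho, scale=spec.rho_mean).sum()
    lp += norm.logpdf(params.alr_root, scale=spec.alr_root_sd).sum()
    lp += expon.logpdf(params.s, scale=spec.s_mean)
    lp += expon.logpdf(params.alpha, scale=spec.alpha_mean)
    root_children = {c.id for c in tree.root.children}
    for nd in tree.edges():
        if nd.id in root_children:
            continue
        parent = nd.parent
        parent_a = (params.alr_root if parent.parent is None
                    or parent.id in root_children
                    else params.branch_alr[parent.id])
        lp += norm.logpdf(params.branch_alr[nd.id] - parent_a,
                          scale=params.s).sum()
    return float(lp)


class TestLogPrior:
    def test_nr_matches_literal_transcription(self, rng):
        spec = PriorSpec()
        for _ in range(5):
            tree = random_tree(5, rng, mean_bl=0.1)
            params = draw_parameters_from_prior(spec, tree, "NR", rng)
            assert log_prior(params, tree, spec) == pytest.approx(
                literal_nr_log_prior(params, tree, spec), abs=1e-10)

    def test_hb_matches_literal_transcription(self, rng):
        spec = PriorSpec()
        for _ in range(5):
            tree = random_tree(6, rng, mean_bl=0.1)
            params = draw_parameters_from_prior(spec, tree, "HB", rng)
            assert log_prior(params, tree, spec) == pytest.approx(
                literal_hb_log_prior(params, tree, spec), abs=1e-10)

    def test_nr_mode_eps_terms(self, rng):
        # with eps = 0 the eps blocks contribute the Gaussian densities at 0
        spec = PriorSpec()
        tree = random_tree(4, rng, mean_bl=0.1)
        p = NRParameters(pi=np.ones(4) / 4, kappa=1.0, sigma_r=0.3,
                         sigma_n=0.2, alpha=1.0)
        base = log_prior(p, tree, spec)
        expected_eps = (6 * norm.logpdf(0.0, scale=0.3)
                        + 12 * norm.logpdf(0.0, scale=0.2))
        stripped = literal_nr_log_prior(p, tree, spec) - expected_eps
        assert base - stripped == pytest.approx(expected_eps, abs=1e-10)

    def test_hb_equal_alr_drift_at_zero(self, rng):
        spec = PriorSpec()
        tree = random_tree(5, rng, mean_bl=0.1)
        params = random_hb_params(tree, rng, equal_compositions=True)
        n_drift = len(params.branch_alr)
        lp = log_prior(params, tree, spec)
        without_drift = lp - n_drift * 3 * norm.logpdf(0.0, scale=params.s)
        assert np.isfinite(without_drift)

    def test_out_of_support_is_minus_infinity(self, rng):
        spec = PriorSpec()
        tree = random_tree(4, rng, mean_bl=0.1)
        p = NRParameters(pi=np.ones(4) / 4, kappa=1.0, sigma_r=0.0,
                         eps_r=np.full(6, 0.1))
        assert log_prior(p, tree, spec) == -math.inf
        bad_tree = tree.copy()
        bad_tree.edges()[0].length = -0.1
        ok = NRParameters(pi=np.ones(4) / 4, kappa=1.0)
        assert log_prior(ok, bad_tree, spec) == -math.inf


class TestDrawFromPrior:
    def test_sigma_moments(self):
        rng = np.random.default_rng(1)
        spec = PriorSpec()
        tree = random_tree(4, rng, mean_bl=0.1)
        draws = [draw_parameters_from_prior(spec, tree, "NR", rng).sigma_r
                 for _ in range(10_000)]
        se = 0.25 / math.sqrt(10_000)
        assert abs(np.mean(draws) - 0.25) < 3 * se

    def test_degenerate_drift_pins_compositions_to_root(self, rng):
        spec = PriorSpec(s_mean=1e-9)
        tree = random_tree(6, rng, mean_bl=0.1)
        p = draw_parameters_from_prior(spec, tree, "HB", rng)
        for a in p.branch_alr.values():
            assert np.allclose(a, p.alr_root, atol=1e-6)

    def test_tiny_sigma_pins_eps_near_zero(self, rng):
        spec = PriorSpec(sigma_r_mean=1e-12, sigma_n_mean=1e-12)
        tree = random_tree(4, rng, mean_bl=0.1)
        p = draw_parameters_from_prior(spec, tree, "NR", rng)
        assert np.allclose(p.eps_r, 0.0, atol=1e-9)
        assert np.allclose(p.eps_n, 0.0, atol=1e-9)

    def test_hb_composition_count(self, rng):
        spec = PriorSpec()
        for n in (3, 5, 8):
            tree = random_tree(n, rng, mean_bl=0.1)
            p = draw_parameters_from_prior(spec, tree, "HB", rng)
            assert len(p.branch_alr) == 2 * n - 4


def _state_for(tree, params, aln=None):
    from rootward.likelihood import tree_log_likelihood
    ll = 0.0 if aln is None else tree_log_likelihood(aln, tree, params)
    return _State(tree, params, ll, log_prior(params, tree, PriorSpec()))


class TestMoves:
    def test_brlen_multiplier_hastings_ratio(self, rng):
        tree = random_tree(5, rng)
        params = random_nr_params(rng)
        state = _state_for(tree, params)
        opts = McmcOptions()
        for _ in range(20):
            new_tree, _, log_hr = propose(state, "brlen", PriorSpec(), opts, rng)
            changed = [(a.length, b.length) for a, b in
                       zip(tree.postorder(), new_tree.postorder())
                       if a.length != b.length]
            assert len(changed) == 1
            old, new = changed[0]
            assert log_hr == pytest.approx(math.log(new / old), abs=1e-12)

    @pytest.mark.parametrize("move", ["nni", "reroot"])
    def test_topology_moves_preserve_structure(self, rng, move):
        opts = McmcOptions()
        for _ in range(30):
            tree = random_tree(6, rng)
            params = random_hb_params(tree, rng)
            state = _state_for(tree, params)
            out = propose(state, move, PriorSpec(), opts, rng)
            assert out is not None
            new_tree, new_params, _ = out
            new_tree.validate()
            assert new_tree.leaf_labels == tree.leaf_labels
            assert len(new_tree.edges()) == 2 * 6 - 2
            # HB dimension stays fixed: 2n-4 branch compositions
            assert len(new_params.branch_alr) == 2 * 6 - 4
            assert math.isfinite(log_prior(new_params, new_tree, PriorSpec()))

    def test_scalar_walks_leave_tree_untouched(self, rng):
        tree = random_tree(4, rng)
        params = random_nr_params(rng)
        state = _state_for(tree, params)
        opts = McmcOptions()
        for move in ("pi", "kappa", "alpha", "eps_r", "eps_n",
                     "sigma_r", "sigma_n"):
            new_tree, new_params, _ = propose(state, move, PriorSpec(), opts, rng)
            assert new_tree is tree
            assert new_params is not params


class TestRunMcmc:
    def test_bit_reproducible_given_seed(self, rng):
        aln = random_alignment(["a", "b", "c", "d"], 30, rng)
        opts = McmcOptions(chain_length=300, burn_in=0.2, thin=3, seed=42)
        r1 = run_mcmc(aln, "random", opts, "NR", n_categories=2)
        r2 = run_mcmc(aln, "random", opts, "NR", n_categories=2)
        assert [s.log_likelihood for s in r1.samples] == \
               [s.log_likelihood for s in r2.samples]
        assert [s.tree.newick() for s in r1.samples] == \
               [s.tree.newick() for s in r2.samples]

    def test_different_seeds_differ(self, rng):
        aln = random_alignment(["a", "b", "c", "d"], 30, rng)
        r1 = run_mcmc(aln, "random", McmcOptions(chain_length=200, seed=1),
                      "NR", n_categories=1)
        r2 = run_mcmc(aln, "random", McmcOptions(chain_length=200, seed=2),
                      "NR", n_categories=1)
        assert [s.log_likelihood for s in r1.samples] != \
               [s.log_likelihood for s in r2.samples]

    def test_acceptance_rates_reported_per_move(self, rng):
        aln = Alignment(["a", "b", "c", "d"], [""] * 4)
        run = run_mcmc(aln, "random", McmcOptions(chain_length=500, seed=0),
                       "HB", n_categories=1)
        rates = run.acceptance_rates()
        assert {"brlen", "nni", "reroot", "comp", "s"} <= set(rates)
        # flat likelihood: symmetric walks accept at high rates
        assert rates["comp"] > 0.5

    def test_invalid_init_rejected(self, rng):
        aln = random_alignment(["a", "b", "c"], 10, rng)
        tree = random_tree(3, rng)
        tree = parse_newick("((a:0.1,b:0.1):0.1,c:0.1);")
        params = NRParameters(pi=np.ones(4) / 4, kappa=1.0, sigma_r=0.0,
                              eps_r=np.full(6, 1.0))
        bad = ChainSample(0, tree, params, 0.0, 0.0)
        with pytest.raises(ValueError, match="prior"):
            run_mcmc(aln, bad, McmcOptions(chain_length=10), "NR")

    def test_hb_composition_dimension_invariant_along_chain(self, rng):
        aln = random_alignment(["a", "b", "c", "d", "e"], 20, rng)
        run = run_mcmc(aln, "random",
                       McmcOptions(chain_length=400, burn_in=0.0, thin=1,
                                   seed=3),
                       "HB", n_categories=1)
        for s in run.samples:
            s.tree.validate()
            assert len(s.params.branch_alr) == 2 * 5 - 4
            root_children = {c.id for c in s.tree.root.children}
            assert not (set(s.params.branch_alr) & root_children)


class TestPosteriorSanity:
    def test_empty_alignment_posterior_equals_prior_for_kappa(self):
        """With no data the chain must reproduce the prior; log kappa is an
        exact standard normal."""
        aln = Alignment(list("abcd"), [""] * 4)
        run = run_mcmc(aln, "random",
                       McmcOptions(chain_length=8000, burn_in=0.1, thin=8,
                                   seed=8),
                       "NR", n_categories=1)
        lk = np.array([math.log(s.params.kappa) for s in run.samples])
        # tolerance ~3 Monte-Carlo s.e. given the chain's autocorrelation
        assert abs(lk.mean()) < 0.15
        assert abs(lk.std() - 1.0) < 0.15

    def test_chain_finds_high_likelihood_region(self, rng):
        # identical sequences: posterior should shrink branch lengths
        aln = Alignment(list("abcd"), ["ACGTACGTACGTACGT"] * 4)
        run = run_mcmc(aln, "random",
                       McmcOptions(chain_length=800, burn_in=0.5, seed=5),
                       "NR", n_categories=1)
        mean_bl = np.mean([np.mean([nd.length for nd in s.tree.edges()])
                           for s in run.samples])
        assert mean_bl < 0.05
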
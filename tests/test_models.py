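import numpy as np
import pytest
from scipy.linalg import null_space

from conftest import random_hb_params, random_tree
from rootward.models import (ORDERED_PAIR_INDEX, PAIR_INDEX, TRANSITION_PAIRS,
                             NRParameters, alr, alr_inverse,
                             discrete_gamma_rates, gc_content,
                             gtr_rate_matrix, hb_branch_matrices,
                             hky_rate_matrix, nr_rate_matrix,
                             spectral_propagator, stationary_distribution,
                             transition_probabilities)

UNIFORM = np.ones(4) / 4


def detailed_balance_residual(rm):
    pi, q = rm.stationary, rm.matrix
    flux = pi[:, None] * q
    return np.max(np.abs(flux - flux.T))


class TestHKY:
    def test_uniform_kappa_one_is_jukes_cantor(self):
        rm = hky_rate_matrix(UNIFORM, 1.0)
        off = rm.matrix[~np.eye(4, dtype=bool)]
        assert np.allclose(off, 1 / 3)
        assert np.allclose(np.diag(rm.matrix), -1.0)

    def test_stationary_distribution_is_pi(self, rng):
        for _ in range(5):
            pi = rng.dirichlet(np.ones(4) * 3)
            rm = hky_rate_matrix(pi, float(rng.uniform(0.5, 5)))
            assert np.allclose(stationary_distribution(rm), pi, atol=1e-10)

    def test_transition_transversion_ratio_preserved(self):
        rm = hky_rate_matrix(np.array([0.1, 0.2, 0.3, 0.4]), 2.0)
        # q_AG/q_AC = (0.3*2)/0.2 = 3 regardless of normalization
        assert rm.matrix[0, 2] / rm.matrix[0, 1] == pytest.approx(3.0)

    @pytest.mark.parametrize("bad_kappa", [0.0, -1.0])
    def test_rejects_nonpositive_kappa(self, bad_kappa):
        with pytest.raises(ValueError):
            hky_rate_matrix(UNIFORM, bad_kappa)


class TestGTR:
    def test_unit_exchangeabilities_uniform_is_jc(self):
        rm = gtr_rate_matrix(np.ones(6), UNIFORM)
        assert np.allclose(rm.matrix[~np.eye(4, dtype=bool)], 1 / 3)

    def test_detailed_balance(self, rng):
        for _ in range(10):
            rm = gtr_rate_matrix(rng.exponential(1, 6),
                                 rng.dirichlet(np.ones(4) * 2))
            assert detailed_balance_residual(rm) < 1e-14

    def test_transition_biased_gtr_equals_hky(self):
        # rho = (AC,AG,AT,CG,CT,GT) = (1,2,1,1,2,1) doubles the transitions
        gtr = gtr_rate_matrix(np.array([1, 2, 1, 1, 2, 1.0]), UNIFORM)
        hky = hky_rate_matrix(UNIFORM, 2.0)
        assert np.allclose(gtr.matrix, hky.matrix, atol=1e-12)


class TestNR:
    def test_zero_perturbations_recover_hky(self, rng):
        pi = rng.dirichlet(np.ones(4) * 4)
        p = NRParameters(pi=pi, kappa=2.7)
        assert np.allclose(nr_rate_matrix(p).matrix,
                           hky_rate_matrix(pi, 2.7).matrix, atol=1e-12)

    def test_reversible_perturbations_keep_detailed_balance(self, rng):
        for _ in range(10):
            p = NRParameters(pi=rng.dirichlet(np.ones(4) * 4),
                             kappa=float(rng.uniform(0.5, 4)),
                             eps_r=rng.normal(0, 0.5, 6), sigma_r=0.5)
            assert detailed_balance_residual(nr_rate_matrix(p)) < 1e-12

    def test_nonreversible_perturbations_break_detailed_balance(self, rng):
        broken = 0
        for _ in range(50):
            p = NRParameters(pi=rng.dirichlet(np.ones(4) * 4),
                             kappa=2.0, eps_r=rng.normal(0, 0.3, 6),
                             eps_n=rng.normal(0, 0.3, 12),
                             sigma_r=0.3, sigma_n=0.3)
            if detailed_balance_residual(nr_rate_matrix(p)) > 1e-6:
                broken += 1
        assert broken == 50

    def test_matches_literal_formula_oracle(self):
        rng = np.random.default_rng(4)
        pi = rng.dirichlet(np.ones(4) * 4)
        kappa, eps_r, eps_n = 2.5, rng.normal(0, 0.4, 6), rng.normal(0, 0.4, 12)

        # independent literal construction of the two-perturbation matrix
        q = np.zeros((4, 4))
        for i in range(4):
            for j in range(4):
                if i == j:
                    continue
                k_ij = kappa if (i, j) in TRANSITION_PAIRS else 1.0
                pair = (min(i, j), max(i, j))
                q[i, j] = (pi[j] * k_ij * np.exp(eps_r[PAIR_INDEX[pair]])
                           * np.exp(eps_n[ORDERED_PAIR_INDEX[(i, j)]]))
        np.fill_diagonal(q, -q.sum(axis=1))
        v = null_space(q.T)[:, 0]
        v = v / v.sum()
        q_norm = q / (-(v * np.diag(q)).sum())

        rm = nr_rate_matrix(NRParameters(pi=pi, kappa=kappa, eps_r=eps_r,
                                         eps_n=eps_n, sigma_r=0.4, sigma_n=0.4))
        assert np.allclose(rm.matrix, q_norm, atol=1e-12)
        assert detailed_balance_residual(rm) > 1e-4


class TestStationaryDistribution:
    def test_jukes_cantor_uniform(self, jc_params):
        rm = nr_rate_matrix(jc_params)
        assert np.allclose(stationary_distribution(rm), UNIFORM, atol=1e-12)

    def test_matches_null_space_oracle_for_nonreversible(self, rng):
        for _ in range(20):
            q = rng.exponential(1.0, (4, 4))
            np.fill_diagonal(q, 0.0)
            np.fill_diagonal(q, -q.sum(axis=1))
            v = stationary_distribution(q)
            ref = null_space(q.T)[:, 0]
            ref = ref / ref.sum()
            assert np.allclose(v, ref, atol=1e-10)
            assert np.max(np.abs(v @ q)) < 1e-10


class TestTransitionProbabilities:
    def test_zero_time_is_identity(self, rng):
        rm = gtr_rate_matrix(rng.exponential(1, 6), rng.dirichlet(np.ones(4)))
        assert np.allclose(transition_probabilities(rm, 0.0), np.eye(4))

    def test_jc_long_time_limit(self, jc_params):
        p = transition_probabilities(nr_rate_matrix(jc_params), 200.0)
        assert np.allclose(p, 0.25, atol=1e-12)

    def test_jc_closed_form_diagonal(self, jc_params):
        rm = nr_rate_matrix(jc_params)
        for t in (0.01, 0.3, 1.0, 2.5):
            p = transition_probabilities(rm, t)
            expect = 0.25 + 0.75 * np.exp(-4 * t / 3)
            assert np.allclose(np.diag(p), expect, atol=1e-12)

    def test_rows_are_distributions(self, rng):
        for _ in range(5):
            q = rng.exponential(1.0, (4, 4))
            np.fill_diagonal(q, 0.0)
            np.fill_diagonal(q, -q.sum(axis=1))
            p = transition_probabilities(q, float(rng.uniform(0, 3)))
            assert np.allclose(p.sum(axis=1), 1.0, atol=1e-12)
            assert np.all(p >= 0) and np.all(p <= 1)

    def test_negative_time_rejected(self, jc_params):
        with pytest.raises(ValueError):
            transition_probabilities(nr_rate_matrix(jc_params), -0.1)

    def test_chapman_kolmogorov(self, rng):
        for _ in range(10):
            q = rng.exponential(1.0, (4, 4))
            np.fill_diagonal(q, 0.0)
            np.fill_diagonal(q, -q.sum(axis=1))
            s, t = rng.uniform(0, 5, 2)
            ps, pt = transition_probabilities(q, s), transition_probabilities(q, t)
            pst = transition_probabilities(q, s + t)
            assert np.allclose(ps @ pt, pst, atol=1e-9)

    def test_spectral_propagator_matches_expm(self, rng):
        for _ in range(10):
            q = rng.exponential(1.0, (4, 4))
            np.fill_diagonal(q, 0.0)
            np.fill_diagonal(q, -q.sum(axis=1))
            ts = rng.uniform(0, 3, 5)
            fast = spectral_propagator(q)(ts)
            for k, t in enumerate(ts):
                assert np.allclose(fast[k], transition_probabilities(q, t),
                                   atol=1e-9)


class TestDiscreteGamma:
    def test_single_category_is_unit_rate(self):
        assert discrete_gamma_rates(0.7, 1).rates == pytest.approx([1.0])

    def test_large_alpha_concentrates_at_one(self):
        # extreme-quartile conditional means sit at ~±1.27/sqrt(alpha)
        rates = discrete_gamma_rates(1e7, 4).rates
        assert np.allclose(rates, 1.0, atol=1e-3)
        spread6 = np.abs(discrete_gamma_rates(1e6, 4).rates - 1.0).max()
        assert spread6 < 1.5e-3

    def test_alpha_one_two_categories_closed_form(self):
        # conditional means of Exp(1) below/above its median:
        # (1 - (1+ln2)/2)/0.5 and its mirror about the mean
        rates = discrete_gamma_rates(1.0, 2).rates
        assert rates[0] == pytest.approx(0.30685281944, abs=1e-8)
        assert rates[1] == pytest.approx(1.69314718056, abs=1e-8)

    @pytest.mark.parametrize("alpha,k", [(0.2, 4), (1.0, 4), (5.0, 8), (0.5, 2)])
    def test_mean_is_exactly_one_and_rates_increase(self, alpha, k):
        rates = discrete_gamma_rates(alpha, k).rates
        assert rates.mean() == pytest.approx(1.0, abs=1e-12)
        assert np.all(np.diff(rates) > 0)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            discrete_gamma_rates(0.0, 4)
        with pytest.raises(ValueError):
            discrete_gamma_rates(1.0, 0)


class TestCompositions:
    def test_gc_content_examples(self):
        assert gc_content(UNIFORM) == pytest.approx(0.5)
        assert gc_content(np.array([0.1, 0.4, 0.3, 0.2])) == pytest.approx(0.7)

    def test_gc_monotone_in_pi_g(self):
        base = np.array([0.3, 0.25, 0.2, 0.25])
        shifted = np.array([0.25, 0.25, 0.25, 0.25])
        assert gc_content(shifted) > gc_content(base)

    def test_alr_round_trip(self, rng):
        for _ in range(10):
            pi = rng.dirichlet(np.ones(4))
            assert np.allclose(alr_inverse(alr(pi)), pi, atol=1e-12)


class TestHBBranchMatrices:
    @pytest.mark.parametrize("n,expected_free", [(3, 2), (5, 6), (6, 8)])
    def test_composition_counts(self, n, expected_free, rng):
        tree = random_tree(n, rng)
        params = random_hb_params(tree, rng)
        assert len(params.branch_alr) == expected_free == 2 * n - 4
        mats = hb_branch_matrices(params, tree)
        assert len(mats) == 2 * n - 2

    def test_root_adjacent_edges_share_root_composition(self, rng):
        tree = random_tree(5, rng)
        params = random_hb_params(tree, rng)
        mats = hb_branch_matrices(params, tree)
        for child in tree.root.children:
            assert np.allclose(mats[child.id].stationary, params.pi_root)

    def test_equal_compositions_collapse_to_single_gtr(self, rng):
        tree = random_tree(5, rng)
        params = random_hb_params(tree, rng, equal_compositions=True)
        mats = hb_branch_matrices(params, tree)
        ref = next(iter(mats.values())).matrix
        for rm in mats.values():
            assert np.allclose(rm.matrix, ref, atol=1e-12)

    def test_mismatched_compositions_rejected(self, rng):
        tree = random_tree(5, rng)
        params = random_hb_params(tree, rng)
        params.branch_alr.pop(next(iter(params.branch_alr)))
        with pytest.raises(ValueError, match="mismatch"):
            hb_branch_matrices(params, tree)


class TestRateMatrixInvariants:
    def test_rows_sum_to_zero_and_unit_mean_rate(self, rng):
        for _ in range(20):
            which = rng.integers(3)
            if which == 0:
                rm = hky_rate_matrix(rng.dirichlet(np.ones(4) * 2),
                                     float(rng.uniform(0.5, 5)))
            elif which == 1:
                rm = gtr_rate_matrix(rng.exponential(1, 6),
                                     rng.dirichlet(np.ones(4) * 2))
            else:
                p = NRParameters(pi=rng.dirichlet(np.ones(4) * 2), kappa=2.0,
                                 eps_r=rng.normal(0, 0.3, 6),
                                 eps_n=rng.normal(0, 0.3, 12),
                                 sigma_r=0.3, sigma_n=0.3)
                rm = nr_rate_matrix(p)
            assert np.max(np.abs(rm.matrix.sum(axis=1))) < 1e-12
            pi_star = stationary_distribution(rm)
            assert -(pi_star * np.diag(rm.matrix)).sum() == pytest.approx(
                1.0, abs=1e-10)
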
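"""Priors and Metropolis–Hastings MCMC over rooted trees and model parameters.

The posterior is ∝ likelihood × prior over (rooted topology, branch lengths,
substitution-model parameters).  The prior is hierarchical:

* **NR** — π ~ Dirichlet(1,1,1,1); log κ ~ Normal(0,1); ε_R | σ_R iid
  Normal(0, σ_R²) (6 values), ε_N | σ_N iid Normal(0, σ_N²) (12 values);
  σ_R, σ_N ~ Exponential(mean 0.25); α ~ Exponential(mean 1).  Large σ_R
  signals GTR-like (reversible) departures from HKY85, large σ_N signals
  non-reversibility — the quantity that carries root information.
* **HB** — ρ: 6 iid Exponential(mean 1) (scale-free, mean-normalized when
  used); compositions in alr coordinates with a_root ~ Normal(0, 5²·I₃) and a
  first-order random walk along the tree, a_b | a_parent ~ Normal(a_parent,
  s²·I₃), so neighbouring edges share more information than distant ones;
  s ~ Exponential(mean 0.5); α ~ Exponential(mean 1).
* Branch lengths iid Exponential(mean 0.1); rooted topology uniform over
  rooted binary topologies (a constant, omitted from log densities).

All hyperparameters are fields of :class:`PriorSpec`.  Because the NR chain
moves π in alr coordinates, the Dirichlet term carries the alr Jacobian
Σ_i log π_i; the HB composition prior is *defined* on alr coordinates, so no
Jacobian applies there.

The move kernel is a random scan over: branch-length multipliers, rooted NNI,
root repositioning (slide along the root edge or re-root on a uniformly
chosen edge), and random-walk updates of the scalar/vector parameters on
unconstrained scales.  Under topology and root moves the HB per-branch
compositions travel with their physical edges; an edge that becomes
root-adjacent surrenders its composition and an edge that stops being
root-adjacent draws a fresh one from its conditional prior, with both
densities entering the Hastings ratio, so the dimension stays fixed at
2n−4 vectors plus the root composition.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple, Union

import numpy as np
from scipy.special import gammaln

from .likelihood import Alignment, tree_log_likelihood
from .models import PAIR_INDEX, HBParameters, NRParameters, alr_inverse
from .trees import (MERGED_EDGE, Node, RootedTree, nni_candidates,
                    random_rooted_tree, reroot_at_edge, rooted_nni,
                    root_split_of)

__all__ = ["PriorSpec", "McmcOptions", "ChainSample", "McmcRun",
           "log_prior", "run_mcmc", "propose", "draw_parameters_from_prior",
           "nj_midpoint_tree"]

logger = logging.getLogger("rootward")

_LOG_2PI = math.log(2.0 * math.pi)


def _norm_logpdf(x, sd) -> float:
    x = np.asarray(x, dtype=float)
    return float(-0.5 * np.sum((x / sd) ** 2) - x.size * (math.log(sd) + 0.5 * _LOG_2PI))


def _expon_logpdf(x, mean) -> float:
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        return -math.inf
    rate = 1.0 / mean
    return float(x.size * math.log(rate) - rate * np.sum(x))


# ----------------------------------------------------------------------- spec


@dataclass
class PriorSpec:
    """Hyperparameters of the hierarchical prior (see module docstring)."""

    dirichlet_pi: np.ndarray = field(default_factory=lambda: np.ones(4))
    log_kappa_sd: float = 1.0
    sigma_r_mean: float = 0.25
    sigma_n_mean: float = 0.25
    alpha_mean: float = 1.0
    branch_length_mean: float = 0.1
    rho_mean: float = 1.0
    alr_root_sd: float = 5.0
    s_mean: float = 0.5

    def __post_init__(self):
        self.dirichlet_pi = np.asarray(self.dirichlet_pi, dtype=float)
        for name in ("log_kappa_sd", "sigma_r_mean", "sigma_n_mean",
                     "alpha_mean", "branch_length_mean", "rho_mean",
                     "alr_root_sd", "s_mean"):
            if not (getattr(self, name) > 0):
                raise ValueError(f"{name} must be positive")
        if self.dirichlet_pi.shape != (4,) or np.any(self.dirichlet_pi <= 0):
            raise ValueError("dirichlet_pi must be 4 positive concentrations")

    def to_dict(self) -> dict:
        return {"dirichlet_pi": [float(x) for x in self.dirichlet_pi],
                **{k: float(getattr(self, k)) for k in
                   ("log_kappa_sd", "sigma_r_mean", "sigma_n_mean", "alpha_mean",
                    "branch_length_mean", "rho_mean", "alr_root_sd", "s_mean")}}


DEFAULT_PROPOSAL_SCALES = {
    "brlen": 1.0,        # multiplier tuning lambda
    "pi": 0.15,          # alr random-walk sd
    "kappa": 0.25,       # log-scale walk sd
    "alpha": 0.35,
    "eps_rel": 0.5,      # eps walk sd = eps_rel*sigma + eps_min
    "eps_min": 0.02,
    "sigma": 1.5,        # multiplier lambda for sigma_R / sigma_N / s
    "comp": 0.2,         # HB alr composition walk sd
    "rho": 0.3,          # log-scale walk sd per component
    "root_comp": 0.3,    # sd of the root-composition jump inside reroot
}

DEFAULT_MOVE_WEIGHTS_NR = {
    "brlen": 0.40, "nni": 0.10, "reroot": 0.10,
    "pi": 0.06, "kappa": 0.06, "alpha": 0.05,
    "eps_r": 0.06, "eps_n": 0.06,
    "sigma_r": 0.03, "sigma_n": 0.03,
    "sigma_r_joint": 0.025, "sigma_n_joint": 0.025,
    "sigma_r_refresh": 0.025, "sigma_n_refresh": 0.025,
    "alpha_refresh": 0.02, "kappa_refresh": 0.02, "kappa_ridge": 0.03,
}

DEFAULT_MOVE_WEIGHTS_HB = {
    "brlen": 0.40, "nni": 0.10, "reroot": 0.10,
    "comp": 0.16, "rho": 0.08, "alpha": 0.05,
    "s": 0.06, "s_joint": 0.05, "s_refresh": 0.03,
    "alpha_refresh": 0.02,
}


@dataclass
class McmcOptions:
    """Chain-control settings; every tunable is recorded here for the trace."""

    chain_length: int = 10_000       # number of sweeps
    burn_in: float = 0.25            # fraction of chain_length, or int count
    thin: int = 10                   # keep every thin-th sweep
    moves_per_sweep: int = 6         # elementary proposals per sweep
    seed: int = 0
    proposal_scales: Dict[str, float] = field(default_factory=dict)
    move_weights: Dict[str, float] = field(default_factory=dict)
    sample_topology: bool = True
    log_every: int = 100

    def __post_init__(self):
        if self.chain_length <= 0 or self.thin <= 0 or self.moves_per_sweep <= 0:
            raise ValueError("chain_length, thin and moves_per_sweep must be positive")

    @property
    def burn_in_iterations(self) -> int:
        if isinstance(self.burn_in, float) and 0 <= self.burn_in < 1:
            return int(self.burn_in * self.chain_length)
        return int(self.burn_in)


@dataclass
class ChainSample:
    """One retained MCMC draw — the unit of every posterior summary."""

    iteration: int
    tree: RootedTree
    params: Union[NRParameters, HBParameters]
    log_likelihood: float
    log_prior: float


@dataclass
class McmcRun:
    samples: List[ChainSample]
    acceptance: Dict[str, Tuple[int, int]]    # move -> (accepted, proposed)
    options: McmcOptions
    model: str

    def acceptance_rates(self) -> Dict[str, float]:
        return {k: (a / p if p else float("nan"))
                for k, (a, p) in self.acceptance.items()}


# ---------------------------------------------------------------------- prior


def _parent_alr(params: HBParameters, tree: RootedTree, node) -> np.ndarray:
    """alr vector of the adjacent edge on the root side of ``node``'s edge."""
    parent = node.parent
    if parent.parent is None or parent.id not in params.branch_alr:
        return params.alr_root
    return params.branch_alr[parent.id]


def _branch_length_log_prior(tree: RootedTree, spec: PriorSpec) -> float:
    lengths = np.array([nd.length for nd in tree.edges()])
    if np.any(lengths <= 0) or not np.all(np.isfinite(lengths)):
        return -math.inf
    return _expon_logpdf(lengths, spec.branch_length_mean)


def log_prior(params: Union[NRParameters, HBParameters], tree: RootedTree,
              spec: PriorSpec) -> float:
    """Joint log prior density of (parameters, branch lengths) given the spec.

    The uniform rooted-topology prior contributes a constant and is omitted.
    Out-of-support states return −inf (auto-reject in the sampler).
    """
    lp = _branch_length_log_prior(tree, spec)
    if lp == -math.inf:
        return lp

    if isinstance(params, NRParameters):
        pi = params.pi
        c = spec.dirichlet_pi
        # Dirichlet density plus the alr Jacobian (the chain moves in alr space)
        lp += float(np.sum((c - 1.0) * np.log(pi))
                    + gammaln(c.sum()) - np.sum(gammaln(c)))
        lp += float(np.sum(np.log(pi)))
        lp += _norm_logpdf(math.log(params.kappa), spec.log_kappa_sd)
        for sigma, eps, mean in ((params.sigma_r, params.eps_r, spec.sigma_r_mean),
                                 (params.sigma_n, params.eps_n, spec.sigma_n_mean)):
            if sigma < 0:
                return -math.inf
            if sigma == 0.0:
                # degenerate limit: point mass at eps = 0
                if np.any(eps != 0.0):
                    return -math.inf
                lp += _expon_logpdf(0.0, mean)
            else:
                lp += _expon_logpdf(sigma, mean)
                lp += _norm_logpdf(eps, sigma)
        lp += _expon_logpdf(params.alpha, spec.alpha_mean)
        return lp

    # HB
    if params.s <= 0:
        return -math.inf
    lp += _expon_logpdf(params.rho, spec.rho_mean)
    lp += _norm_logpdf(params.alr_root, spec.alr_root_sd)
    lp += _expon_logpdf(params.s, spec.s_mean)
    lp += _expon_logpdf(params.alpha, spec.alpha_mean)
    root_children = {c.id for c in tree.root.children}
    expected = {nd.id for nd in tree.edges()} - root_children
    if expected != set(params.branch_alr):
        raise ValueError("HB composition vectors do not match the tree's edges")
    for nd in tree.edges():
        if nd.id in root_children:
            continue
        lp += _norm_logpdf(params.branch_alr[nd.id] - _parent_alr(params, tree, nd),
                           params.s)
    return lp


def draw_parameters_from_prior(spec: PriorSpec, tree: RootedTree, model: str,
                               rng: np.random.Generator,
                               n_categories: int = 4
                               ) -> Union[NRParameters, HBParameters]:
    """Exact draw from the prior, including the HB along-tree composition walk."""
    alpha = rng.exponential(spec.alpha_mean)
    if model == "NR":
        sigma_r = rng.exponential(spec.sigma_r_mean)
        sigma_n = rng.exponential(spec.sigma_n_mean)
        return NRParameters(
            pi=rng.dirichlet(spec.dirichlet_pi),
            kappa=math.exp(rng.normal(0.0, spec.log_kappa_sd)),
            eps_r=rng.normal(0.0, sigma_r, 6) if sigma_r > 0 else np.zeros(6),
            eps_n=rng.normal(0.0, sigma_n, 12) if sigma_n > 0 else np.zeros(12),
            sigma_r=sigma_r, sigma_n=sigma_n,
            alpha=alpha, n_categories=n_categories)
    if model != "HB":
        raise ValueError(f"unknown model {model!r}")
    s = rng.exponential(spec.s_mean)
    alr_root = rng.normal(0.0, spec.alr_root_sd, 3)
    root_children = {c.id for c in tree.root.children}
    branch_alr: Dict[int, np.ndarray] = {}
    for nd in tree.preorder():
        if nd.parent is None or nd.id in root_children:
            continue
        parent = nd.parent
        base = (alr_root if parent.parent is None or parent.id not in branch_alr
                else branch_alr[parent.id])
        branch_alr[nd.id] = base + rng.normal(0.0, s, 3)
    return HBParameters(rho=rng.exponential(spec.rho_mean, 6),
                        alr_root=alr_root, branch_alr=branch_alr,
                        s=s, alpha=alpha, n_categories=n_categories)


# ---------------------------------------------------------------------- moves
#
# Each move returns (new_tree, new_params, log_hastings_ratio) or None when
# the proposal is structurally impossible; the MH core turns an out-of-support
# proposal (log prior = -inf) into a rejection.

Proposal = Optional[Tuple[RootedTree, Union[NRParameters, HBParameters], float]]


def _multiplier(rng, lam: float) -> float:
    return math.exp(lam * (rng.random() - 0.5))


def _move_brlen(state, prior, scales, rng) -> Proposal:
    tree = state.tree.copy()
    edges = tree.edges()
    nd = edges[rng.integers(len(edges))]
    m = _multiplier(rng, scales["brlen"])
    nd.length *= m
    return tree, state.params, math.log(m)


def _move_nni(state, prior, scales, rng) -> Proposal:
    cands = nni_candidates(state.tree)
    if not cands:
        return None
    v_id, which = cands[rng.integers(len(cands))]
    new_tree = rooted_nni(state.tree, v_id, which)
    params = state.params
    log_hr = 0.0
    if isinstance(params, HBParameters):
        v_old = state.tree.node(v_id)
        if v_old.parent is state.tree.root:
            # c becomes root-adjacent (surrenders its alr); w stops being
            # root-adjacent (fresh conditional-prior draw).
            c = v_old.children[which]
            w = next(x for x in state.tree.root.children if x is not v_old)
            params = params.copy()
            old_a = params.branch_alr.pop(c.id)
            log_hr += _norm_logpdf(old_a - params.alr_root, params.s)
            new_a = params.alr_root + rng.normal(0.0, params.s, 3)
            params.branch_alr[w.id] = new_a
            log_hr -= _norm_logpdf(new_a - params.alr_root, params.s)
    return new_tree, params, log_hr


def _move_reroot(state, prior, scales, rng) -> Proposal:
    tree = state.tree
    edges = tree.edges()
    x = edges[rng.integers(len(edges))]
    frac = rng.random()
    if not (0.0 < frac < 1.0):   # pragma: no cover - measure-zero draw
        return None
    new_tree, info = reroot_at_edge(tree, x.id, frac)
    params = state.params
    if info.slide:
        return new_tree, params, 0.0
    log_hr = math.log(info.split_length / info.merged_length)
    if isinstance(params, HBParameters):
        params = params.copy()
        old_alr = params.branch_alr
        # Root composition jumps with the root: propose a_root' around the
        # composition of the edge being rooted on; the reverse move recentres
        # on the merged edge's (freshly drawn) composition.
        tau = scales["root_comp"]
        centre_fwd = (old_alr[x.id] if x.id in old_alr else params.alr_root)
        new_root_alr = centre_fwd + rng.normal(0.0, tau, 3)
        log_hr -= _norm_logpdf(new_root_alr - centre_fwd, tau)
        old_root_alr = params.alr_root
        params.alr_root = new_root_alr
        new_root_children = {c.id for c in new_tree.root.children}
        new_balr: Dict[int, np.ndarray] = {}
        used = set()
        pending = []
        for nd in new_tree.preorder():
            if nd.parent is None or nd.id in new_root_children:
                continue
            orig = info.edge_origin[nd.id]
            if orig != MERGED_EDGE and orig in old_alr:
                new_balr[nd.id] = old_alr[orig]
                used.add(orig)
            else:
                pending.append(nd)
        # fresh conditional-prior draws, parents first (preorder guarantees it)
        tmp = HBParameters(params.rho, params.alr_root, new_balr, params.s,
                           params.alpha, params.n_categories)
        for nd in pending:
            base = _parent_alr(tmp, new_tree, nd)
            draw = base + rng.normal(0.0, params.s, 3)
            new_balr[nd.id] = draw
            log_hr -= _norm_logpdf(draw - base, params.s)
        # reverse-move draws for the compositions we discarded
        discarded = set(old_alr) - used
        assert len(discarded) == len(pending), "reroot composition bookkeeping"
        for did in discarded:
            nd_old = state.tree.node(did)
            base = _parent_alr(state.params, state.tree, nd_old)
            log_hr += _norm_logpdf(old_alr[did] - base, state.params.s)
        # reverse root-composition proposal recentres on the merged edge
        centre_rev = new_balr[info.merged_child_id]
        log_hr += _norm_logpdf(old_root_alr - centre_rev, tau)
        params.branch_alr = new_balr
    return new_tree, params, log_hr


def _move_pi(state, prior, scales, rng) -> Proposal:
    params = state.params.copy()
    a = np.log(params.pi[:3] / params.pi[3]) + rng.normal(0.0, scales["pi"], 3)
    params.pi = alr_inverse(a)
    return state.tree, params, 0.0


def _move_kappa(state, prior, scales, rng) -> Proposal:
    params = state.params.copy()
    params.kappa = math.exp(math.log(params.kappa)
                            + rng.normal(0.0, scales["kappa"]))
    return state.tree, params, 0.0


def _move_alpha(state, prior, scales, rng) -> Proposal:
    params = state.params.copy()
    m = math.exp(rng.normal(0.0, scales["alpha"]))
    params.alpha *= m
    return state.tree, params, math.log(m)


def _eps_scale(sigma: float, scales) -> float:
    return scales["eps_rel"] * sigma + scales["eps_min"]


def _move_eps(which: str):
    def move(state, prior, scales, rng) -> Proposal:
        params = state.params.copy()
        vec = params.eps_r if which == "r" else params.eps_n
        sigma = params.sigma_r if which == "r" else params.sigma_n
        i = rng.integers(len(vec))
        vec[i] += rng.normal(0.0, _eps_scale(sigma, scales))
        return state.tree, params, 0.0
    return move


def _move_sigma(which: str):
    def move(state, prior, scales, rng) -> Proposal:
        params = state.params.copy()
        m = _multiplier(rng, scales["sigma"])
        if which == "r":
            params.sigma_r *= m
        else:
            params.sigma_n *= m
        return state.tree, params, math.log(m)
    return move


def _move_sigma_joint(which: str):
    """Rescale sigma together with its eps block (funnel-friendly)."""
    def move(state, prior, scales, rng) -> Proposal:
        params = state.params.copy()
        m = _multiplier(rng, scales["sigma"])
        if which == "r":
            params.sigma_r *= m
            params.eps_r *= m
            dim = 1 + 6
        else:
            params.sigma_n *= m
            params.eps_n *= m
            dim = 1 + 12
        return state.tree, params, dim * math.log(m)
    return move


def _move_comp(state, prior, scales, rng) -> Proposal:
    params = state.params.copy()
    keys = list(params.branch_alr)
    i = rng.integers(len(keys) + 1)
    if i == len(keys):
        params.alr_root = params.alr_root + rng.normal(0.0, scales["comp"], 3)
    else:
        k = keys[i]
        params.branch_alr[k] = params.branch_alr[k] + rng.normal(
            0.0, scales["comp"], 3)
    return state.tree, params, 0.0


def _move_rho(state, prior, scales, rng) -> Proposal:
    params = state.params.copy()
    i = rng.integers(6)
    m = math.exp(rng.normal(0.0, scales["rho"]))
    params.rho[i] *= m
    return state.tree, params, math.log(m)


def _move_s(state, prior, scales, rng) -> Proposal:
    params = state.params.copy()
    m = _multiplier(rng, scales["sigma"])
    params.s *= m
    return state.tree, params, math.log(m)


def _move_s_joint(state, prior, scales, rng) -> Proposal:
    """Rescale s together with all edge-to-edge composition increments."""
    params = state.params.copy()
    tree = state.tree
    m = _multiplier(rng, scales["sigma"])
    devs = {nd.id: params.branch_alr[nd.id] - _parent_alr(params, tree, nd)
            for nd in tree.edges() if nd.id in params.branch_alr}
    params.s *= m
    new_balr: Dict[int, np.ndarray] = {}
    tmp = HBParameters(params.rho, params.alr_root, new_balr, params.s,
                       params.alpha, params.n_categories)
    for nd in tree.preorder():
        if nd.id in devs:
            new_balr[nd.id] = _parent_alr(tmp, tree, nd) + m * devs[nd.id]
    params.branch_alr = new_balr
    return state.tree, params, (1 + 3 * len(devs)) * math.log(m)


def _move_kappa_ridge(state, prior, scales, rng) -> Proposal:
    """Slide along the kappa–eps_R ridge: multiply kappa by m and subtract
    log m from the two transition-pair eps_R entries (AG, CT).

    The rate matrix — hence the likelihood — is unchanged; only the prior
    decides acceptance.  Without this move the chain cannot traverse the
    ridge on which kappa and exp(eps) trade off, and kappa's marginal
    under-disperses.  In the sampler's working coordinates (log kappa, eps)
    this is a symmetric translation, so the Hastings ratio is zero.
    """
    params = state.params.copy()
    step = scales["kappa"] * 4.0 * (rng.random() - 0.5)
    params.kappa *= math.exp(step)
    params.eps_r[PAIR_INDEX[(0, 2)]] -= step   # AG
    params.eps_r[PAIR_INDEX[(1, 3)]] -= step   # CT
    return state.tree, params, 0.0


def _move_kappa_refresh(state, prior, scales, rng) -> Proposal:
    """Independence proposal of kappa from its log-normal prior."""
    params = state.params.copy()
    old = math.log(params.kappa)
    new = rng.normal(0.0, prior.log_kappa_sd)
    params.kappa = math.exp(new)
    log_hr = _norm_logpdf(old, prior.log_kappa_sd) - _norm_logpdf(
        new, prior.log_kappa_sd)
    return state.tree, params, log_hr


def _move_alpha_refresh(state, prior, scales, rng) -> Proposal:
    """Independence proposal of alpha from its exponential prior."""
    params = state.params.copy()
    old = params.alpha
    params.alpha = rng.exponential(prior.alpha_mean)
    log_hr = _expon_logpdf(old, prior.alpha_mean) - _expon_logpdf(
        params.alpha, prior.alpha_mean)
    return state.tree, params, log_hr


def _move_sigma_refresh(which: str):
    """Independence proposal of a whole (sigma, eps) block from its prior.

    The proposal density cancels the matching prior terms, so acceptance
    reduces to the likelihood ratio; this cuts straight across the
    sigma–eps funnel that random walks traverse slowly.
    """
    def move(state, prior, scales, rng) -> Proposal:
        params = state.params.copy()
        mean = prior.sigma_r_mean if which == "r" else prior.sigma_n_mean
        k = 6 if which == "r" else 12
        new_sigma = rng.exponential(mean)
        new_eps = rng.normal(0.0, new_sigma, k)
        if which == "r":
            old_sigma, old_eps = params.sigma_r, params.eps_r
            params.sigma_r, params.eps_r = new_sigma, new_eps
        else:
            old_sigma, old_eps = params.sigma_n, params.eps_n
            params.sigma_n, params.eps_n = new_sigma, new_eps
        log_hr = (_expon_logpdf(old_sigma, mean) + _norm_logpdf(old_eps, old_sigma)
                  - _expon_logpdf(new_sigma, mean) - _norm_logpdf(new_eps, new_sigma))
        return state.tree, params, log_hr
    return move


def _move_s_refresh(state, prior, scales, rng) -> Proposal:
    """Independence proposal of (s, all branch compositions) from the prior
    conditional on the root composition; the HB analogue of the sigma
    refresh moves."""
    params = state.params.copy()
    tree = state.tree
    old_s = params.s
    old_balr = params.branch_alr
    log_hr = _expon_logpdf(old_s, prior.s_mean)
    for nd in tree.edges():
        if nd.id in old_balr:
            log_hr += _norm_logpdf(old_balr[nd.id]
                                   - _parent_alr(params, tree, nd), old_s)
    new_s = rng.exponential(prior.s_mean)
    new_balr: Dict[int, np.ndarray] = {}
    params.s = new_s
    params.branch_alr = new_balr
    log_hr -= _expon_logpdf(new_s, prior.s_mean)
    for nd in tree.preorder():
        if nd.parent is None or nd.id not in old_balr:
            continue
        base = _parent_alr(params, tree, nd)
        draw = base + rng.normal(0.0, new_s, 3)
        new_balr[nd.id] = draw
        log_hr -= _norm_logpdf(draw - base, new_s)
    return state.tree, params, log_hr


_MOVES = {
    "brlen": _move_brlen,
    "nni": _move_nni,
    "reroot": _move_reroot,
    "pi": _move_pi,
    "kappa": _move_kappa,
    "alpha": _move_alpha,
    "eps_r": _move_eps("r"),
    "eps_n": _move_eps("n"),
    "sigma_r": _move_sigma("r"),
    "sigma_n": _move_sigma("n"),
    "sigma_r_joint": _move_sigma_joint("r"),
    "sigma_n_joint": _move_sigma_joint("n"),
    "comp": _move_comp,
    "rho": _move_rho,
    "s": _move_s,
    "s_joint": _move_s_joint,
    "alpha_refresh": _move_alpha_refresh,
    "kappa_refresh": _move_kappa_refresh,
    "kappa_ridge": _move_kappa_ridge,
    "sigma_r_refresh": _move_sigma_refresh("r"),
    "sigma_n_refresh": _move_sigma_refresh("n"),
    "s_refresh": _move_s_refresh,
}


@dataclass
class _State:
    tree: RootedTree
    params: Union[NRParameters, HBParameters]
    log_likelihood: float
    log_prior: float


def propose(state: _State, move: str, prior: PriorSpec, opts: McmcOptions,
            rng: np.random.Generator) -> Proposal:
    """Apply one named move; returns (tree, params, log Hastings ratio)."""
    scales = {**DEFAULT_PROPOSAL_SCALES, **opts.proposal_scales}
    return _MOVES[move](state, prior, scales, rng)


# ------------------------------------------------------------ heuristic start


def nj_midpoint_tree(aln: Alignment, min_length: float = 1e-4) -> RootedTree:
    """Heuristic starting tree: neighbour joining on Jukes–Cantor-corrected
    p-distances, rooted at the midpoint of the longest leaf-to-leaf path.

    NJ starts are the standard way to avoid spending the early chain on
    basic topology search; midpoint rooting gives the root moves a sensible
    starting basin.  Non-positive NJ branch lengths are clamped to
    ``min_length``.  Requires at least four taxa and a non-empty alignment.
    """
    from skbio import DistanceMatrix
    from skbio.tree import nj as _nj

    if aln.n_taxa < 4 or aln.n_sites == 0:
        raise ValueError("NJ start needs >= 4 taxa and a non-empty alignment")
    codes, weights = aln.patterns()
    codes = np.where(codes == 4, 3, codes)        # U -> T
    plain = codes <= 3                            # unambiguous ACGT
    n = aln.n_taxa
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            valid = plain[i] & plain[j]
            tot = float(weights[valid].sum())
            p = (float(weights[valid & (codes[i] != codes[j])].sum()) / tot
                 if tot else 0.0)
            p = min(p, 0.7499)                    # JC correction domain
            dist[i, j] = dist[j, i] = max(-0.75 * math.log(1 - 4 * p / 3),
                                          min_length)
    sk_tree = _nj(DistanceMatrix(dist, aln.labels)).root_at_midpoint()

    nodes: Dict[int, Node] = {}
    counter = [0]

    def conv(sk_node):
        nd = Node(counter[0], label=(sk_node.name if sk_node.is_tip() else None))
        nodes[nd.id] = nd
        counter[0] += 1
        if sk_node.length is not None:
            nd.length = max(float(sk_node.length), min_length)
        for child in sk_node.children:
            nd.add_child(conv(child))
        return nd

    root = conv(sk_tree)
    root.length = None
    tree = RootedTree(root, nodes, counter[0])
    tree.validate()
    return tree


# ----------------------------------------------------------------------- core


def run_mcmc(aln: Alignment, init, opts: McmcOptions, model: str,
             spec: Optional[PriorSpec] = None, n_categories: int = 4) -> McmcRun:
    """Random-scan Metropolis–Hastings targeting the rooted-tree posterior.

    ``init`` is either the string ``"random"`` (random rooted topology,
    branch lengths and parameters drawn from the prior) or a
    :class:`ChainSample` to continue from.  One sweep applies one move drawn
    from the weighted move mixture.  Given the same ``(seed, options)``, the
    sampled chain is bit-reproducible.
    """
    if model not in ("NR", "HB"):
        raise ValueError(f"model must be 'NR' or 'HB', got {model!r}")
    spec = spec if spec is not None else PriorSpec()
    rng = np.random.default_rng(opts.seed)

    if init == "random":
        tree = random_rooted_tree(sorted(aln.labels), rng, spec.branch_length_mean)
        params = draw_parameters_from_prior(spec, tree, model, rng, n_categories)
    elif init == "nj-midpoint":
        tree = nj_midpoint_tree(aln)
        params = draw_parameters_from_prior(spec, tree, model, rng, n_categories)
    elif isinstance(init, ChainSample):
        tree = init.tree.copy()
        params = init.params.copy()
    else:
        raise ValueError("init must be 'random', 'nj-midpoint' or a ChainSample")

    lp = log_prior(params, tree, spec)
    if lp == -math.inf:
        raise ValueError("initial state has zero prior density")
    ll = tree_log_likelihood(aln, tree, params)
    if not math.isfinite(ll):
        raise ValueError("initial state has non-finite likelihood")
    state = _State(tree, params, ll, lp)

    weights = dict(DEFAULT_MOVE_WEIGHTS_NR if model == "NR"
                   else DEFAULT_MOVE_WEIGHTS_HB)
    weights.update(opts.move_weights)
    if not opts.sample_topology:
        weights.pop("nni", None)
        weights.pop("reroot", None)
    if aln.n_taxa == 2:                      # a cherry has no NNI neighbours
        weights.pop("nni", None)
    names = sorted(weights)
    probs = np.array([weights[n] for n in names], dtype=float)
    probs /= probs.sum()

    accepted = {n: 0 for n in names}
    proposed = {n: 0 for n in names}
    samples: List[ChainSample] = []
    burn = opts.burn_in_iterations
    scales = {**DEFAULT_PROPOSAL_SCALES, **opts.proposal_scales}

    cum = np.cumsum(probs)
    for it in range(opts.chain_length):
        for _ in range(opts.moves_per_sweep):
            name = names[int(np.searchsorted(cum, rng.random()))]
            proposed[name] += 1
            out = _MOVES[name](state, spec, scales, rng)
            if out is None:
                continue
            new_tree, new_params, log_hr = out
            new_lp = log_prior(new_params, new_tree, spec)
            if new_lp > -math.inf:
                try:
                    new_ll = tree_log_likelihood(aln, new_tree, new_params)
                except ArithmeticError:
                    new_ll = -math.inf
                log_accept = (new_ll + new_lp) - (state.log_likelihood
                                                  + state.log_prior) + log_hr
                if log_accept >= 0 or math.log(rng.random()) < log_accept:
                    state = _State(new_tree, new_params, new_ll, new_lp)
                    accepted[name] += 1
        if it >= burn and (it - burn) % opts.thin == 0:
            samples.append(ChainSample(it, state.tree.copy(),
                                       state.params.copy(),
                                       state.log_likelihood, state.log_prior))
        if opts.log_every and (it + 1) % opts.log_every == 0:
            logger.debug("sweep %d logL %.3f logPrior %.3f root %s",
                         it + 1, state.log_likelihood, state.log_prior,
                         root_split_of(state.tree))

    return McmcRun(samples=samples,
                   acceptance={n: (accepted[n], proposed[n]) for n in names},
                   options=opts, model=model)
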
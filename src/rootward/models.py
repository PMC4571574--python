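"""Nucleotide substitution models: HKY85, GTR, and the two root-identifying
extensions NR and HB.

Everything uses the fixed state order **A, C, G, T** (files, vectors,
matrices).  A rate matrix Q has non-negative off-diagonals and zero row sums;
"normalized" means the expected substitution rate at stationarity is one,
−Σ_i π*_i q_ii = 1 with π* the matrix's own stationary distribution, so that
branch lengths are expected substitutions per site under the actual process.

The NR model starts from HKY85 and multiplies each off-diagonal rate by two
perturbation factors, exp(ε_R) for the unordered pair (a reversible, GTR-like
departure) and exp(ε_N) for the ordered pair (a fully non-reversible
departure).  The hierarchical standard deviations σ_R and σ_N that control
the size of these perturbations live in :mod:`rootward.inference`; here the ε
values are plain parameters.  The exponential placement keeps rates positive
for unconstrained Gaussian ε.

The HB model keeps a single set of GTR exchangeabilities but gives every
branch not adjacent to the root its own composition vector; the root and its
two adjacent branches share the root composition.  Each branch's rate matrix
is normalized under its own composition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Dict, Optional

import numpy as np
from scipy.linalg import expm
from scipy.special import gammainc
from scipy.stats import gamma as gamma_dist

from .trees import RootedTree

__all__ = [
    "NUCLEOTIDES",
    "TRANSITION_PAIRS",
    "PAIR_INDEX",
    "ORDERED_PAIRS",
    "RateMatrix",
    "NRParameters",
    "HBParameters",
    "GammaRates",
    "validate_composition",
    "validate_exchangeabilities",
    "alr",
    "alr_inverse",
    "gc_content",
    "hky_rate_matrix",
    "gtr_rate_matrix",
    "nr_rate_matrix",
    "hb_branch_matrices",
    "stationary_distribution",
    "transition_probabilities",
    "discrete_gamma_rates",
    "spectral_propagator",
]

NUCLEOTIDES = ("A", "C", "G", "T")

#: transitions are the purine<->purine and pyrimidine<->pyrimidine changes
TRANSITION_PAIRS = frozenset({(0, 2), (2, 0), (1, 3), (3, 1)})  # A<->G, C<->T

#: unordered pairs in the fixed order (AC, AG, AT, CG, CT, GT)
PAIR_INDEX = {(0, 1): 0, (0, 2): 1, (0, 3): 2, (1, 2): 3, (1, 3): 4, (2, 3): 5}

#: ordered pairs (i, j), i != j, row-major
ORDERED_PAIRS = [(i, j) for i in range(4) for j in range(4) if i != j]
ORDERED_PAIR_INDEX = {p: k for k, p in enumerate(ORDERED_PAIRS)}


def validate_composition(pi) -> np.ndarray:
    """Check and return a composition vector (π_A, π_C, π_G, π_T)."""
    pi = np.asarray(pi, dtype=float)
    if pi.shape != (4,):
        raise ValueError(f"composition must have 4 entries, got shape {pi.shape}")
    if np.any(pi <= 0.0) or np.any(pi >= 1.0):
        raise ValueError(f"composition entries must lie in (0,1): {pi}")
    if abs(pi.sum() - 1.0) > 1e-12:
        raise ValueError(f"composition must sum to 1, got {pi.sum()!r}")
    return pi


def validate_exchangeabilities(rho) -> np.ndarray:
    """Check a 6-vector of exchangeabilities (AC, AG, AT, CG, CT, GT) and
    return it normalized to mean 1 (the scale is not identifiable)."""
    rho = np.asarray(rho, dtype=float)
    if rho.shape != (6,):
        raise ValueError(f"exchangeabilities must have 6 entries, got {rho.shape}")
    if np.any(rho <= 0.0):
        raise ValueError(f"exchangeabilities must be positive: {rho}")
    return rho / rho.mean()


def alr(pi) -> np.ndarray:
    """Additive log-ratio coordinates (log π_A/π_T, log π_C/π_T, log π_G/π_T)."""
    pi = validate_composition(pi)
    return np.log(pi[:3] / pi[3])


def alr_inverse(a) -> np.ndarray:
    """Composition vector from alr coordinates (reference nucleotide T)."""
    a = np.asarray(a, dtype=float)
    if a.shape != (3,):
        raise ValueError(f"alr vector must have 3 entries, got {a.shape}")
    e = np.exp(np.concatenate([a, [0.0]]))
    return e / e.sum()


def gc_content(pi) -> float:
    """π_G + π_C — the statistic whose branch-wise posterior mean explains
    which root the models prefer."""
    pi = validate_composition(pi)
    return float(pi[1] + pi[2])


# ------------------------------------------------------------------- matrices


@dataclass(frozen=True)
class RateMatrix:
    """A 4×4 instantaneous rate matrix with its stationary distribution."""

    matrix: np.ndarray
    stationary: np.ndarray
    normalized: bool = True

    def __post_init__(self):
        q = self.matrix
        if q.shape != (4, 4):
            raise ValueError("rate matrix must be 4x4")
        off = q[~np.eye(4, dtype=bool)]
        if np.any(off < 0):
            raise ValueError("negative off-diagonal rate")
        if np.max(np.abs(q.sum(axis=1))) > 1e-12:
            raise ValueError("rate matrix rows must sum to 0")


def _finalize(q_off: np.ndarray, stationary: Optional[np.ndarray] = None,
              normalize: bool = True) -> RateMatrix:
    """Fill the diagonal, optionally rescale to mean rate 1 under the matrix's
    own stationary distribution."""
    q = np.array(q_off, dtype=float)
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    pi_star = _stationary_of(q) if stationary is None else np.asarray(stationary, float)
    if normalize:
        mu = -float(np.dot(pi_star, np.diag(q)))
        if mu <= 0:
            raise ValueError("degenerate rate matrix (zero total rate)")
        q = q / mu
    return RateMatrix(matrix=q, stationary=pi_star, normalized=normalize)


def _stationary_of(q: np.ndarray) -> np.ndarray:
    # Solve v Q = 0, sum(v) = 1 by replacing one equation with the constraint.
    a = np.vstack([q.T[:3], np.ones(4)])
    b = np.array([0.0, 0.0, 0.0, 1.0])
    v = np.linalg.solve(a, b)
    if np.any(v <= 0):
        raise ValueError("rate matrix has no positive stationary distribution "
                         "(reducible or degenerate)")
    return v


def hky_rate_matrix(pi, kappa: float) -> RateMatrix:
    """HKY85: q_ij = κ·π_j for transitions, π_j for transversions."""
    pi = validate_composition(pi)
    if not (kappa > 0):
        raise ValueError(f"kappa must be positive, got {kappa}")
    q = np.tile(pi, (4, 1))
    for i, j in TRANSITION_PAIRS:
        q[i, j] *= kappa
    return _finalize(q, stationary=pi)


def gtr_rate_matrix(rho, pi) -> RateMatrix:
    """General time-reversible model: q_ij = ρ_{ij}·π_j, stationary at π."""
    rho = validate_exchangeabilities(rho)
    pi = validate_composition(pi)
    r = np.zeros((4, 4))
    for (i, j), k in PAIR_INDEX.items():
        r[i, j] = r[j, i] = rho[k]
    return _finalize(r * pi[None, :], stationary=pi)


@dataclass
class NRParameters:
    """Parameter block of the stationary non-reversible (NR) model.

    ``eps_r`` (6, by unordered pair) and ``eps_n`` (12, by ordered pair) are
    the reversible and non-reversible perturbations; ``sigma_r``/``sigma_n``
    are their hierarchical standard deviations (σ = 0 pins the ε at 0).
    ``alpha``/``n_categories`` control discrete-gamma rate variation across
    sites (K = 1 disables it).
    """

    pi: np.ndarray
    kappa: float
    eps_r: np.ndarray = field(default_factory=lambda: np.zeros(6))
    eps_n: np.ndarray = field(default_factory=lambda: np.zeros(12))
    sigma_r: float = 0.0
    sigma_n: float = 0.0
    alpha: float = 1.0
    n_categories: int = 1

    def __post_init__(self):
        self.pi = validate_composition(self.pi)
        self.eps_r = np.asarray(self.eps_r, dtype=float)
        self.eps_n = np.asarray(self.eps_n, dtype=float)
        if not (self.kappa > 0):
            raise ValueError("kappa must be positive")
        if self.eps_r.shape != (6,) or self.eps_n.shape != (12,):
            raise ValueError("eps_r must have 6 entries and eps_n 12")
        if self.sigma_r < 0 or self.sigma_n < 0:
            raise ValueError("sigma_r and sigma_n must be non-negative")
        if not (self.alpha > 0) or self.n_categories < 1:
            raise ValueError("alpha must be positive and n_categories >= 1")

    def copy(self) -> "NRParameters":
        return NRParameters(self.pi.copy(), self.kappa, self.eps_r.copy(),
                            self.eps_n.copy(), self.sigma_r, self.sigma_n,
                            self.alpha, self.n_categories)


_KAPPA_MASK = np.zeros((4, 4), dtype=bool)
for _i, _j in TRANSITION_PAIRS:
    _KAPPA_MASK[_i, _j] = True
_EPS_R_IDX = np.zeros((4, 4), dtype=int)
for (_i, _j), _k in PAIR_INDEX.items():
    _EPS_R_IDX[_i, _j] = _EPS_R_IDX[_j, _i] = _k
_EPS_N_IDX = np.zeros((4, 4), dtype=int)
for (_i, _j), _k in ORDERED_PAIR_INDEX.items():
    _EPS_N_IDX[_i, _j] = _k
_OFFDIAG = ~np.eye(4, dtype=bool)


def _nr_generator(p: NRParameters):
    """(Q, stationary) for the NR model without object overhead (hot path)."""
    q = np.where(_KAPPA_MASK, p.kappa, 1.0) * p.pi[None, :]
    q = q * np.exp(p.eps_r[_EPS_R_IDX] + p.eps_n[_EPS_N_IDX])
    q[~_OFFDIAG] = 0.0
    np.fill_diagonal(q, -q.sum(axis=1))
    pi_star = _stationary_of(q)
    q /= -float(np.dot(pi_star, np.diag(q)))
    return q, pi_star


def nr_rate_matrix(p: NRParameters) -> RateMatrix:
    """NR rate matrix: HKY85 rates times exp(ε_R) and exp(ε_N) factors,
    normalized under its own stationary distribution."""
    q, pi_star = _nr_generator(p)
    return RateMatrix(matrix=q, stationary=pi_star, normalized=True)


@dataclass
class HBParameters:
    """Parameter block of the branch-heterogeneous (HB) model.

    Compositions are stored in alr coordinates: ``alr_root`` for the root and
    its two adjacent branches, and ``branch_alr`` keyed by edge (child-node
    id) for each of the 2n−4 remaining branches.  ``s`` is the standard
    deviation of the edge-to-edge composition random walk, which shares
    information between neighbouring branches; ``rho`` the shared GTR
    exchangeabilities (scale-free; normalized to mean 1 when used).
    """

    rho: np.ndarray
    alr_root: np.ndarray
    branch_alr: Dict[int, np.ndarray]
    s: float
    alpha: float = 1.0
    n_categories: int = 1

    def __post_init__(self):
        self.rho = np.asarray(self.rho, dtype=float)
        self.alr_root = np.asarray(self.alr_root, dtype=float)
        if self.rho.shape != (6,) or np.any(self.rho <= 0):
            raise ValueError("rho must be 6 positive values")
        if self.alr_root.shape != (3,):
            raise ValueError("alr_root must have 3 entries")
        if not (self.s > 0):
            raise ValueError("s must be positive")
        if not (self.alpha > 0) or self.n_categories < 1:
            raise ValueError("alpha must be positive and n_categories >= 1")

    @property
    def pi_root(self) -> np.ndarray:
        return alr_inverse(self.alr_root)

    def composition_for_edge(self, child_id: int) -> np.ndarray:
        if child_id in self.branch_alr:
            return alr_inverse(self.branch_alr[child_id])
        return self.pi_root

    def copy(self) -> "HBParameters":
        return HBParameters(self.rho.copy(), self.alr_root.copy(),
                            {k: v.copy() for k, v in self.branch_alr.items()},
                            self.s, self.alpha, self.n_categories)


def hb_branch_matrices(p: HBParameters, tree: RootedTree) -> Dict[int, RateMatrix]:
    """Per-edge GTR matrices for the HB model, keyed by edge (child id).

    Root-adjacent edges share the root composition; every other edge uses its
    own.  Raises if the parameter block does not provide exactly one alr
    vector per non-root-adjacent edge.
    """
    root_children = {c.id for c in tree.root.children}
    needed = {nd.id for nd in tree.edges()} - root_children
    if needed != set(p.branch_alr):
        raise ValueError(
            f"composition/edge mismatch: edges need {sorted(needed)}, "
            f"parameters provide {sorted(p.branch_alr)}")
    out: Dict[int, RateMatrix] = {}
    for nd in tree.edges():
        out[nd.id] = gtr_rate_matrix(p.rho, p.composition_for_edge(nd.id))
    return out


# ------------------------------------------------------- linear-algebra layer


def stationary_distribution(q_or_matrix) -> np.ndarray:
    """The unique probability vector v with v·Q = 0 (Q irreducible)."""
    q = q_or_matrix.matrix if isinstance(q_or_matrix, RateMatrix) else np.asarray(
        q_or_matrix, dtype=float)
    v = _stationary_of(q)
    if np.max(np.abs(v @ q)) > 1e-10:
        raise ValueError("stationary solve did not converge (degenerate Q?)")
    return v


def transition_probabilities(q_or_matrix, t: float) -> np.ndarray:
    """P(t) = exp(Qt) via scipy's scaling-and-squaring Padé expm.

    Robust for any generator, including the non-reversible NR matrices whose
    eigenvalues may be complex.  The MCMC hot path uses
    :func:`spectral_propagator` instead and falls back to this routine.
    """
    if t < 0:
        raise ValueError(f"time must be non-negative, got {t}")
    q = q_or_matrix.matrix if isinstance(q_or_matrix, RateMatrix) else np.asarray(
        q_or_matrix, dtype=float)
    p = expm(q * t)
    return np.clip(p, 0.0, 1.0)


def spectral_propagator(q_or_matrix):
    """Return a function ts -> stacked exp(Q·ts) using one eigendecomposition.

    Falls back to Padé expm per time point when the eigenvector matrix is
    ill-conditioned (near-defective Q).
    """
    q = q_or_matrix.matrix if isinstance(q_or_matrix, RateMatrix) else np.asarray(
        q_or_matrix, dtype=float)
    lam, vec = np.linalg.eig(q)
    use_spectral = True
    try:
        vinv = np.linalg.inv(vec)
        if np.linalg.cond(vec) > 1e8:
            use_spectral = False
    except np.linalg.LinAlgError:  # pragma: no cover - defective matrices
        use_spectral = False

    if use_spectral:
        def prop(ts):
            ts = np.atleast_1d(np.asarray(ts, dtype=float))
            e = np.exp(lam[None, :] * ts[:, None])            # (T,4)
            p = np.einsum("ij,tj,jk->tik", vec, e, vinv).real
            return np.clip(p, 0.0, 1.0)
    else:  # pragma: no cover - exercised only for pathological matrices
        def prop(ts):
            ts = np.atleast_1d(np.asarray(ts, dtype=float))
            return np.stack([np.clip(expm(q * t), 0.0, 1.0) for t in ts])

    return prop


# -------------------------------------------------------------- gamma rates


@dataclass(frozen=True)
class GammaRates:
    """K equal-probability rate categories with mean rate exactly 1."""

    rates: np.ndarray

    @property
    def n_categories(self) -> int:
        return len(self.rates)


@lru_cache(maxsize=512)
def _discrete_gamma_cached(alpha: float, k: int) -> tuple:
    edges = gamma_dist.ppf(np.arange(1, k) / k, a=alpha, scale=1.0 / alpha)
    edges = np.concatenate([[0.0], edges, [np.inf]])
    upper = np.where(np.isinf(edges[1:]), 1.0,
                     gammainc(alpha + 1.0, alpha * edges[1:]))
    lower = gammainc(alpha + 1.0, alpha * edges[:-1])
    rates = np.clip(k * (upper - lower), 0.0, None)
    rates /= rates.mean()
    return tuple(rates)


def discrete_gamma_rates(alpha: float, n_categories: int) -> GammaRates:
    """Discretized Gamma(shape α, mean 1) rate-across-sites distribution.

    Categories are the K equal-probability quantile bands; each category rate
    is the conditional mean of its band (computed with the incomplete-gamma
    identity ∫ x g_α(x) dx = F_{α+1}), then renormalized so the mean is
    exactly 1.  Category means (not medians) keep the average rate unbiased.
    """
    if not (alpha > 0):
        raise ValueError(f"alpha must be positive, got {alpha}")
    if n_categories < 1:
        raise ValueError(f"need at least one category, got {n_categories}")
    k = int(n_categories)
    if k == 1:
        return GammaRates(rates=np.ones(1))
    # quantile band edges of Gamma(shape=alpha, scale=1/alpha); cached since
    # MCMC revisits alpha values after rejected moves
    return GammaRates(rates=np.array(_discrete_gamma_cached(float(alpha), k)))
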
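"""Alignment container and rooted-tree log-likelihoods.

The pruning (post-order) recursion runs from the tips to the root with
transition probabilities oriented root→tips: each edge contributes
P = exp(Q_edge · t · r_k) for discrete-gamma category rate r_k, with a single
Q under NR and branch-specific GTR matrices under HB.  The root state is
drawn from the stationary distribution of Q (NR) or the root composition
(HB).  Gaps and IUPAC ambiguity codes are marginalized (a gap contributes
partial likelihood 1 in every state).

Per-pattern rescaling is applied at every internal node, with the log offsets
accumulated exactly, so deep trees cannot underflow.  Site patterns are
compressed once per alignment and cached, as is the per-taxon table of leaf
state vectors — this makes :func:`tree_log_likelihood` cheap enough to sit in
the Metropolis–Hastings hot loop without a separate engine object.

:func:`brute_force_log_likelihood` recomputes the same quantity by explicit
summation over all internal-node state assignments (and scipy's Padé expm
rather than the spectral path), serving as an independent oracle for trees of
up to 7 taxa.
"""

from __future__ import annotations

import itertools
from typing import Dict, Sequence, Union

import numpy as np

from . import models
from .models import HBParameters, NRParameters
from .trees import RootedTree

__all__ = ["Alignment", "AmbiguityError", "tree_log_likelihood",
           "brute_force_log_likelihood"]


class AmbiguityError(ValueError):
    """An alignment character outside the IUPAC nucleotide alphabet."""


def _build_state_table() -> Dict[str, np.ndarray]:
    def vec(*states):
        v = np.zeros(4)
        for s in states:
            v["ACGT".index(s)] = 1.0
        return v

    table = {
        "A": vec("A"), "C": vec("C"), "G": vec("G"), "T": vec("T"),
        "U": vec("T"),
        "R": vec("A", "G"), "Y": vec("C", "T"), "S": vec("C", "G"),
        "W": vec("A", "T"), "K": vec("G", "T"), "M": vec("A", "C"),
        "B": vec("C", "G", "T"), "D": vec("A", "G", "T"),
        "H": vec("A", "C", "T"), "V": vec("A", "C", "G"),
        "N": vec("A", "C", "G", "T"), "-": vec("A", "C", "G", "T"),
        "?": vec("A", "C", "G", "T"), "X": vec("A", "C", "G", "T"),
    }
    return table


_STATE_TABLE = _build_state_table()
_CODE_OF = {ch: k for k, ch in enumerate(_STATE_TABLE)}
_VECTORS = np.stack([_STATE_TABLE[ch] for ch in _STATE_TABLE])  # (n_codes, 4)


class Alignment:
    """A multiple nucleotide alignment with cached site-pattern compression."""

    def __init__(self, labels: Sequence[str], sequences: Sequence[str]) -> None:
        labels = list(labels)
        sequences = [s.upper() for s in sequences]
        if len(labels) != len(sequences):
            raise ValueError("labels and sequences differ in number")
        if len(set(labels)) != len(labels):
            dup = sorted({l for l in labels if labels.count(l) > 1})
            raise ValueError(f"duplicate taxon labels: {dup}")
        if any(not l for l in labels):
            raise ValueError("empty taxon label")
        lengths = {len(s) for s in sequences}
        if len(lengths) > 1:
            bad = min(sequences, key=len)
            raise ValueError(
                f"ragged alignment: sequence for "
                f"{labels[sequences.index(bad)]!r} has length {len(bad)}")
        for label, seq in zip(labels, sequences):
            for col, ch in enumerate(seq):
                if ch not in _CODE_OF:
                    raise AmbiguityError(
                        f"illegal character {ch!r} in {label!r} at column {col + 1}")
        self.labels = labels
        self.sequences = sequences
        self.n_taxa = len(labels)
        self.n_sites = lengths.pop() if lengths else 0
        self._patterns = None
        self._leaf_partials: Dict[str, np.ndarray] = {}

    @property
    def label_set(self) -> frozenset:
        return frozenset(self.labels)

    # ------------------------------------------------------------ compression

    def patterns(self):
        """(codes, weights): unique site columns and their multiplicities."""
        if self._patterns is None:
            if self.n_sites == 0:
                self._patterns = (np.zeros((self.n_taxa, 0), dtype=np.uint8),
                                  np.zeros(0))
            else:
                codes = np.array(
                    [[_CODE_OF[ch] for ch in seq] for seq in self.sequences],
                    dtype=np.uint8)
                uniq, counts = np.unique(codes, axis=1, return_counts=True)
                self._patterns = (uniq, counts.astype(float))
        return self._patterns

    def leaf_partials(self, label: str) -> np.ndarray:
        """(4, n_patterns) indicator/ambiguity vectors for one taxon."""
        if label not in self._leaf_partials:
            codes, _ = self.patterns()
            row = self.labels.index(label)
            self._leaf_partials[label] = _VECTORS[codes[row]].T.copy()
        return self._leaf_partials[label]

    def take(self, labels: Sequence[str]) -> "Alignment":
        """Sub-alignment (or re-ordering) restricted to the given taxa."""
        idx = [self.labels.index(l) for l in labels]
        return Alignment([self.labels[i] for i in idx],
                         [self.sequences[i] for i in idx])

    def __eq__(self, other) -> bool:
        return (isinstance(other, Alignment)
                and self.labels == other.labels
                and self.sequences == other.sequences)

    def __repr__(self) -> str:  # pragma: no cover
        return f"Alignment({self.n_taxa} taxa, {self.n_sites} sites)"


ModelParameters = Union[NRParameters, HBParameters]


def _hb_matrices_batch(params: HBParameters, tree: RootedTree, edges):
    """Vectorized per-edge GTR generators for the HB model.

    Equivalent to :func:`rootward.models.hb_branch_matrices` (asserted in the
    test suite) but builds the (E,4,4) stack without per-edge Python objects;
    this sits inside the MCMC hot loop.
    """
    root_children = {c.id for c in tree.root.children}
    needed = {e.id for e in edges} - root_children
    if needed != set(params.branch_alr):
        raise ValueError(
            f"composition/edge mismatch: edges need {sorted(needed)}, "
            f"parameters provide {sorted(params.branch_alr)}")
    alrs = np.stack([params.branch_alr[e.id] if e.id in params.branch_alr
                     else params.alr_root for e in edges])               # (E,3)
    expa = np.exp(np.concatenate([alrs, np.zeros((len(edges), 1))], axis=1))
    pis = expa / expa.sum(axis=1, keepdims=True)                         # (E,4)
    rho = params.rho / params.rho.mean()
    r = np.zeros((4, 4))
    for (i, j), k in models.PAIR_INDEX.items():
        r[i, j] = r[j, i] = rho[k]
    qs = r[None, :, :] * pis[:, None, :]
    mu = np.einsum("ei,ij,ej->e", pis, r, pis)       # expected rate before diag
    qs = qs / mu[:, None, None]
    d = np.arange(4)
    qs[:, d, d] = 0.0
    qs[:, d, d] = -qs.sum(axis=2)
    return qs, pis


def _edge_propagators(tree: RootedTree, params: ModelParameters, rates: np.ndarray):
    """P-matrices per (edge, category) plus the root state distribution.

    Returns ``(pmats, root_dist)`` where ``pmats[child_id]`` has shape
    (K, 4, 4).  NR uses one spectral decomposition for the shared Q; HB uses
    a batched symmetric eigendecomposition over the per-edge GTR matrices.
    """
    edges = tree.edges()
    k = len(rates)
    if isinstance(params, NRParameters):
        q, pi_star = models._nr_generator(params)
        prop = models.spectral_propagator(q)
        ts = np.array([[e.length * r for r in rates] for e in edges])  # (E,K)
        flat = prop(ts.reshape(-1)).reshape(len(edges), k, 4, 4)
        pmats = {e.id: flat[i] for i, e in enumerate(edges)}
        return pmats, pi_star

    # HB: batched reversible propagation, one symmetric eigh over all edges.
    qs, pis = _hb_matrices_batch(params, tree, edges)
    d = np.sqrt(pis)
    sym = d[:, :, None] * qs / d[:, None, :]
    sym = 0.5 * (sym + np.transpose(sym, (0, 2, 1)))   # enforce exact symmetry
    lam, w = np.linalg.eigh(sym)                                         # (E,4),(E,4,4)
    ts = np.array([[e.length * r for r in rates] for e in edges])        # (E,K)
    expt = np.exp(lam[:, None, :] * ts[:, :, None])                      # (E,K,4)
    a = w / d[:, :, None]                     # D^{-1/2} W
    b = np.transpose(w, (0, 2, 1)) * d[:, None, :]   # W^T D^{1/2}
    p = np.einsum("eij,ekj,ejl->ekil", a, expt, b)
    p = np.clip(p, 0.0, 1.0)
    pmats = {e.id: p[i] for i, e in enumerate(edges)}
    return pmats, params.pi_root


def tree_log_likelihood(aln: Alignment, tree: RootedTree,
                        params: ModelParameters) -> float:
    """Log-likelihood of a rooted tree under the NR or HB model.

    Sites are independent; each site averages over the K equal-weight
    discrete-gamma categories.  Raises on a taxon mismatch between alignment
    and tree, or if the result is non-finite despite rescaling.
    """
    if aln.label_set != tree.leaf_labels:
        raise ValueError(
            f"alignment taxa {sorted(aln.label_set)} != tree leaves "
            f"{sorted(tree.leaf_labels)}")
    if aln.n_sites == 0:
        return 0.0
    gr = models.discrete_gamma_rates(params.alpha, params.n_categories)
    rates = gr.rates
    k = len(rates)
    pmats, root_dist = _edge_propagators(tree, params, rates)

    _, weights = aln.patterns()
    n_pat = len(weights)
    partials: Dict[int, np.ndarray] = {}
    log_scale = np.zeros(n_pat)
    for node in tree.postorder():
        if node.is_leaf:
            continue
        acc = np.ones((k, 4, n_pat))
        for child in node.children:
            p = pmats[child.id]
            if child.is_leaf:
                acc *= np.einsum("kij,jp->kip", p, aln.leaf_partials(child.label))
            else:
                acc *= np.einsum("kij,kjp->kip", p, partials.pop(child.id))
        m = acc.max(axis=(0, 1))
        if np.any(m <= 0.0) or not np.all(np.isfinite(m)):
            bad = int(np.argmin(m))
            raise ArithmeticError(
                f"non-finite partial likelihood at site pattern {bad}")
        acc /= m
        log_scale += np.log(m)
        partials[node.id] = acc

    site_by_cat = np.einsum("i,kip->kp", root_dist, partials[tree.root.id])
    site = site_by_cat.mean(axis=0)
    if np.any(site <= 0.0):
        bad = int(np.argmin(site))
        raise ArithmeticError(f"zero site likelihood at pattern {bad}")
    return float(np.dot(weights, np.log(site) + log_scale))


# ---------------------------------------------------------------- brute force


def brute_force_log_likelihood(aln: Alignment, tree: RootedTree,
                               params: ModelParameters) -> float:
    """Oracle: the same log-likelihood by exhaustive enumeration of all
    4^(n−1) internal-node state assignments (≤ 7 taxa).

    Deliberately shares no code with the pruning path: transition matrices
    come from scipy's Padé expm and the sum is a literal transcription of the
    model's generative definition.
    """
    if aln.label_set != tree.leaf_labels:
        raise ValueError("alignment taxa do not match tree leaves")
    n = tree.n_leaves
    if n > 7:
        raise ValueError(f"brute force limited to 7 taxa, got {n}")
    if aln.n_sites == 0:
        return 0.0

    rates = models.discrete_gamma_rates(params.alpha, params.n_categories).rates
    if isinstance(params, NRParameters):
        rm = models.nr_rate_matrix(params)
        root_dist = rm.stationary
        q_of = {e.id: rm.matrix for e in tree.edges()}
    else:
        mats = models.hb_branch_matrices(params, tree)
        root_dist = params.pi_root
        q_of = {e.id: mats[e.id].matrix for e in tree.edges()}

    internals = [nd for nd in tree.postorder() if not nd.is_leaf]
    index_of = {nd.id: i for i, nd in enumerate(internals)}
    _, weights = aln.patterns()
    n_pat = len(weights)

    site_total = np.zeros(n_pat)
    for rate in rates:
        pmat = {eid: models.transition_probabilities(q, tree.node(eid).length * rate)
                for eid, q in q_of.items()}
        cat_sum = np.zeros(n_pat)
        for assign in itertools.product(range(4), repeat=len(internals)):
            term = np.full(n_pat, root_dist[assign[index_of[tree.root.id]]])
            for nd in tree.postorder():
                if nd.parent is None:
                    continue
                a_par = assign[index_of[nd.parent.id]]
                p = pmat[nd.id]
                if nd.is_leaf:
                    term = term * (p[a_par] @ aln.leaf_partials(nd.label))
                else:
                    term = term * p[a_par, assign[index_of[nd.id]]]
            cat_sum += term
        site_total += cat_sum / len(rates)
    return float(np.dot(weights, np.log(site_total)))
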
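"""Posterior summaries: root-split tables, majority-rule consensus, branch GC
ranking, standardized marginal likelihoods, and empirical composition spread.

Two distinct root summaries matter and can disagree.  The *root-split
posterior* is a marginal summary: the relative frequency of each canonical
taxon bipartition induced by the sampled root, averaging over everything else
in the tree.  The *majority-rule consensus* is a conditional summary built
recursively from the leaves: it contains precisely the clades (rooted:
descendant leaf-sets) with posterior support above 0.5, so its root position
depends on the plausibility of sub-clades and need not coincide with the
modal root split.  Rooted clades — not unrooted bipartitions — define
consensus identity here, because the root position is the estimand.

The *standardized marginal likelihood* of a scalar parameter (used for the
perturbation standard deviations σ_R and σ_N) is the posterior density
divided by the prior density — the weight of evidence the data carry for
each parameter value; values near zero at σ = 0 are evidence against the
reversible (or HKY-like) restriction.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.stats import gaussian_kde

from .inference import ChainSample
from .likelihood import Alignment
from .models import HBParameters, gc_content
from .trees import Node, RootedTree, RootSplit, TreeError, root_split_of

__all__ = [
    "RootSplitPosterior",
    "ConsensusTree",
    "MarginalLikelihoodCurve",
    "root_split_posterior",
    "majority_rule_consensus",
    "rank_branches_by_gc",
    "standardized_marginal_likelihood",
    "empirical_composition_sd",
]


@dataclass
class RootSplitPosterior:
    """Canonical root splits with their posterior probabilities, sorted
    in decreasing order of support."""

    probabilities: Dict[RootSplit, float]
    n_samples: int

    def __post_init__(self):
        total = sum(self.probabilities.values())
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"root-split probabilities sum to {total}")

    @property
    def modal_split(self) -> RootSplit:
        return next(iter(self.probabilities))

    def as_rows(self) -> List[Tuple[str, float, float]]:
        """(split, probability, cumulative) rows for the TSV table."""
        rows, cum = [], 0.0
        for split, p in self.probabilities.items():
            cum += p
            rows.append((str(split), p, cum))
        return rows


def root_split_posterior(samples: Sequence[ChainSample]) -> RootSplitPosterior:
    """Relative frequency of each canonical root split in the chain."""
    if not samples:
        raise ValueError("need at least one sample")
    counts = Counter(root_split_of(s.tree) for s in samples)
    n = len(samples)
    probs = {split: c / n for split, c in
             sorted(counts.items(), key=lambda kv: (-kv[1], str(kv[0])))}
    return RootSplitPosterior(probabilities=probs, n_samples=n)


# ------------------------------------------------------------------ consensus


@dataclass
class ConsensusTree:
    """Majority-rule consensus with clade supports and mean branch lengths.

    The root may sit on a polytomy when no root-adjacent clade clears 0.5.
    """

    tree: RootedTree
    supports: Dict[frozenset, float]

    def newick(self) -> str:
        return self.tree.newick(include_supports=True)


def majority_rule_consensus(samples: Sequence[ChainSample]) -> ConsensusTree:
    """The rooted tree containing exactly the clades with support > 0.5.

    Clade supports above one half are pairwise compatible, so they nest into
    a unique rooted tree (with polytomies where support is lacking).  Branch
    lengths are posterior means over the samples containing the clade; ties
    at exactly 0.5 are excluded.
    """
    if not samples:
        raise ValueError("need at least one sample")
    taxa = samples[0].tree.leaf_labels
    n = len(samples)
    counts: Counter = Counter()
    length_sums: Dict[frozenset, float] = defaultdict(float)
    for s in samples:
        if s.tree.leaf_labels != taxa:
            raise ValueError("samples have inconsistent taxon sets")
        for nd in s.tree.edges():
            clade = s.tree.clade(nd)
            counts[clade] += 1
            length_sums[clade] += nd.length

    majority = {clade: c / n for clade, c in counts.items() if c / n > 0.5}
    # leaf clades always have support 1 (guard for degenerate inputs)
    for label in taxa:
        majority.setdefault(frozenset((label,)), 1.0)

    root_clade = frozenset(taxa)
    node_of: Dict[frozenset, Node] = {root_clade: Node(0)}
    for i, clade in enumerate(sorted(majority, key=lambda c: (len(c), sorted(c)))):
        nd = Node(i + 1)
        if len(clade) == 1:
            nd.label = next(iter(clade))
        else:
            nd.label = "%.3f" % majority[clade]
        nd.length = length_sums[clade] / counts[clade] if counts.get(clade) else 1.0
        node_of[clade] = nd

    # nest each clade under its minimal strict superset (clades above 0.5
    # support are pairwise compatible, so this nesting is well defined)
    for clade, nd in node_of.items():
        if clade == root_clade:
            continue
        supersets = [c for c in node_of if len(c) > len(clade) and clade < c]
        node_of[min(supersets, key=len)].add_child(nd)

    root = node_of[root_clade]
    tree = RootedTree(root, {nd.id: nd for nd in node_of.values()},
                      len(node_of) + 1)
    return ConsensusTree(tree=tree,
                         supports={c: p for c, p in majority.items() if len(c) > 1})


def rank_branches_by_gc(samples: Sequence[ChainSample],
                        reference: ConsensusTree
                        ) -> List[Tuple[frozenset, Optional[float]]]:
    """Reference edges ordered by decreasing posterior mean GC content.

    For each reference clade, the mean is taken over the samples containing
    that clade of the GC content of the matching edge's composition
    (root-adjacent edges contribute the root composition).  Rank 1 is the
    most GC-rich branch; edges matched by no sample carry ``None`` and sort
    last.  Ties break on canonical clade order.
    """
    ref_clades = [reference.tree.clade(nd) for nd in reference.tree.edges()]
    sums: Dict[frozenset, float] = defaultdict(float)
    hits: Dict[frozenset, int] = defaultdict(int)
    wanted = set(ref_clades)
    for s in samples:
        if not isinstance(s.params, HBParameters):
            raise ValueError("branch GC ranking needs HB samples")
        tree = s.tree
        for nd in tree.edges():
            clade = tree.clade(nd)
            if clade in wanted:
                sums[clade] += gc_content(s.params.composition_for_edge(nd.id))
                hits[clade] += 1
    out = []
    for clade in ref_clades:
        mean = sums[clade] / hits[clade] if hits[clade] else None
        out.append((clade, mean))
    out.sort(key=lambda cm: (cm[1] is None, -(cm[1] or 0.0),
                             sorted(cm[0])))
    return out


# --------------------------------------------------------------- sigma curves


@dataclass
class MarginalLikelihoodCurve:
    """Posterior/prior density ratio of a non-negative scalar on a grid."""

    grid: np.ndarray
    ratio: np.ndarray

    def __post_init__(self):
        if np.any(self.ratio < 0):
            raise ValueError("density ratio cannot be negative")


def standardized_marginal_likelihood(sigma_samples: Sequence[float],
                                     prior_density: Callable[[np.ndarray], np.ndarray],
                                     n_grid: int = 512,
                                     ) -> MarginalLikelihoodCurve:
    """Posterior density (reflected KDE) divided by the prior density.

    The posterior density of the non-negative parameter is estimated with a
    Gaussian KDE (Silverman bandwidth) reflected at zero, evaluated on a
    uniform grid over [0, 1.1·max(sample)].  Values well above 1 mark
    parameter regions the data support relative to the prior; a ratio near 0
    at σ = 0 is evidence against the restricted (σ = 0) model.  Density
    ratios are unstable where both densities vanish (the far tail), so read
    the curve where the prior has appreciable mass.
    """
    x = np.asarray(sigma_samples, dtype=float)
    if len(x) < 100:
        raise ValueError(f"need at least 100 samples, got {len(x)}")
    if np.any(x < 0):
        raise ValueError("samples must be non-negative")
    if np.ptp(x) == 0.0:
        raise ValueError("degenerate all-equal sample")
    kde = gaussian_kde(x, bw_method="silverman")
    grid = np.linspace(0.0, 1.1 * float(x.max()), n_grid)
    posterior = kde(grid) + kde(-grid)          # boundary reflection at 0
    prior = np.asarray(prior_density(grid), dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(prior > 0, posterior / np.where(prior > 0, prior, 1.0),
                         np.inf)
    return MarginalLikelihoodCurve(grid=grid, ratio=ratio)


# ------------------------------------------------------------ composition sd


def empirical_composition_sd(aln: Alignment) -> Dict[str, float]:
    """Across-taxon standard deviation of each nucleotide's proportion.

    Proportions are computed per taxon among unambiguous, non-gap sites only,
    then the sample standard deviation (n−1 divisor) is taken across taxa.
    Large values flag compositional heterogeneity that stationary models
    cannot absorb.
    """
    if aln.n_taxa < 2:
        raise ValueError("need at least 2 taxa")
    props = np.empty((aln.n_taxa, 4))
    for i, (label, seq) in enumerate(zip(aln.labels, aln.sequences)):
        counts = np.array([seq.count("A"), seq.count("C"), seq.count("G"),
                           seq.count("T") + seq.count("U")], dtype=float)
        total = counts.sum()
        if total == 0:
            raise ValueError(f"taxon {label!r} has no unambiguous sites")
        props[i] = counts / total
    sds = props.std(axis=0, ddof=1)
    return dict(zip("ACGT", map(float, sds)))
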
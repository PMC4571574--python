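"""Generative counterparts of the NR and HB models.

Simulation draws, per site, a discrete-gamma rate category, a root state from
the model's root distribution (the stationary distribution of Q under NR, the
root composition under HB), and then propagates states root→tips through
exp(Q_edge · t · r).  No indel process is modelled: the data the models are
fit to are pre-aligned, so gaps only enter through real alignments.

The :func:`gc_shift_simulation` scenario is the standard recovery fixture: a
balanced six-taxon tree whose two root-side subtrees evolve toward low
(GC 0.3) and high (GC 0.7) composition, with a uniform composition at the
root — exactly the kind of compositional shift that lets a non-stationary
model locate the root.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Tuple, Union

import numpy as np

from . import models
from .inference import PriorSpec, draw_parameters_from_prior
from .likelihood import Alignment
from .models import HBParameters, NRParameters
from .trees import RootedTree, parse_newick

__all__ = ["SimulationSpec", "simulate_alignment", "draw_parameters_from_prior",
           "gc_shift_simulation"]


@dataclass
class SimulationSpec:
    """Ground truth for one simulated alignment."""

    tree: RootedTree
    model: str                       # "NR" | "HB"
    params: Union[NRParameters, HBParameters]
    n_sites: int
    seed: int

    def __post_init__(self):
        if self.model not in ("NR", "HB"):
            raise ValueError(f"model must be 'NR' or 'HB', got {self.model!r}")
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        expected = NRParameters if self.model == "NR" else HBParameters
        if not isinstance(self.params, expected):
            raise ValueError(f"{self.model} simulation needs {expected.__name__}")
        self.tree.validate()


def _categorical_rows(probs: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One draw per row from row-wise categorical distributions."""
    cum = np.cumsum(probs, axis=1)
    cum[:, -1] = 1.0
    u = rng.random(len(probs))
    return (u[:, None] > cum).sum(axis=1)


def simulate_alignment(spec: SimulationSpec,
                       return_truth: bool = False):
    """Simulate an alignment under the spec; bit-reproducible given its seed.

    With ``return_truth`` also returns the per-site rate-category assignments
    and root states (for exact diagnostics).
    """
    rng = np.random.default_rng(spec.seed)
    tree = spec.tree
    params = spec.params
    rates = models.discrete_gamma_rates(params.alpha, params.n_categories).rates
    k = len(rates)

    if spec.model == "NR":
        rm = models.nr_rate_matrix(params)
        root_dist = rm.stationary
        q_of = {e.id: rm.matrix for e in tree.edges()}
    else:
        mats = models.hb_branch_matrices(params, tree)
        root_dist = params.pi_root
        q_of = {e.id: mats[e.id].matrix for e in tree.edges()}

    n = spec.n_sites
    cats = rng.integers(0, k, size=n)
    site_rates = rates[cats]
    root_states = _categorical_rows(np.tile(root_dist, (n, 1)), rng)

    states: Dict[int, np.ndarray] = {tree.root.id: root_states}
    for nd in tree.preorder():
        if nd.parent is None:
            continue
        prop = models.spectral_propagator(q_of[nd.id])
        pk = prop(nd.length * rates)                      # (K,4,4)
        parent_states = states[nd.parent.id]
        probs = pk[cats, parent_states, :]                # (n,4)
        states[nd.id] = _categorical_rows(probs, rng)

    letters = np.array(list("ACGT"))
    labels = [leaf.label for leaf in tree.leaves()]
    seqs = ["".join(letters[states[leaf.id]]) for leaf in tree.leaves()]
    aln = Alignment(labels, seqs)
    if return_truth:
        return aln, {"categories": cats, "root_states": root_states}
    return aln


# ------------------------------------------------------------------ scenarios


def gc_shift_simulation(seed: int,
                        n_sites: int = 1000,
                        gc_low: float = 0.3,
                        gc_high: float = 0.7,
                        scaffold_fraction: float = 0.25,
                        branch_length: float = 0.2,
                        root_edge_length: float = 0.4,
                        rho: Tuple[float, ...] = (1.0, 2.0, 1.0, 1.0, 2.0, 1.0),
                        ) -> SimulationSpec:
    """Six-taxon HB scenario with a compositional shift across the root.

    The tree places a low-GC cherry (L1, L2) on one side of the root and
    four high-GC taxa (R1–R4, two cherries) on the other; the true root
    split is L1,L2 | R1,R2,R3,R4.  Pendant branches evolve at GC ``gc_low``
    (left) or ``gc_high`` (right), the internal scaffold carries a mild
    shift in the same direction (``scaffold_fraction`` of the way from 0.5),
    and the root composition is uniform.  G and C (resp. A and T) are kept
    equal, so each composition is determined by its GC content alone.
    Exchangeabilities default to a mild transition bias.

    Two design points matter for identifiability.  Anchoring the extreme
    compositions at the tips (scaffold only mildly graded) means an
    off-centre rooting must spend extra drift steps re-deriving the
    scaffold.  And making the true root split a *cherry* split puts the
    truth where compositional root attraction points anyway — the root of a
    compositionally shifted clade — rather than one edge away from it.
    """
    bl = branch_length
    newick = (f"((L1:{bl},L2:{bl}):{root_edge_length},"
              f"((R1:{bl},R2:{bl}):{bl},(R3:{bl},R4:{bl}):{bl})"
              f":{root_edge_length});")
    tree = parse_newick(newick)
    tree.validate()

    def comp(gc: float) -> np.ndarray:
        return np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])

    left_labels = tree.clade(tree.root.children[0])
    branch_alr: Dict[int, np.ndarray] = {}
    root_children = {c.id for c in tree.root.children}
    for nd in tree.edges():
        if nd.id in root_children:
            continue
        gc_tip = gc_low if tree.clade(nd) <= left_labels else gc_high
        gc = gc_tip if nd.is_leaf else 0.5 + scaffold_fraction * (gc_tip - 0.5)
        branch_alr[nd.id] = models.alr(comp(gc))
    params = HBParameters(rho=np.asarray(rho, dtype=float),
                          alr_root=models.alr(np.ones(4) / 4),
                          branch_alr=branch_alr, s=0.5,
                          alpha=1.0, n_categories=1)
    return SimulationSpec(tree=tree, model="HB", params=params,
                          n_sites=n_sites, seed=seed)
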
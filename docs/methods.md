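# Methods

## The rooting problem

Under a stationary, time-reversible substitution model the likelihood of a
phylogeny is the same wherever the root is placed (the "pulley principle"),
so standard Bayesian and ML phylogenetics produce unrooted trees and the root
is added afterwards from an outgroup — with the familiar risk of long-branch
attraction when the outgroup is distant or compositionally divergent.
`rootward` implements two substitution models whose likelihoods *do* depend
on the root, so that the root position is a parameter inferred jointly with
everything else:

* **NR** — stationary and branch-homogeneous but **non-reversible**.  The
  instantaneous rate matrix starts from HKY85,
  `q_ij = π_j·κ^[ij is a transition]`, and multiplies each off-diagonal rate
  by two perturbation factors, `exp(ε_R{ij})` on the six unordered pairs
  (a reversible, GTR-like departure) and `exp(ε_N(i,j))` on the twelve
  ordered pairs (the general non-reversible departure).  The perturbations
  are exponentiated so that unconstrained Gaussian ε keep rates positive.
  Their hierarchical standard deviations σ_R and σ_N are inferred: large
  σ_R means the data prefer GTR-like exchangeabilities over HKY85; large
  σ_N means detectable non-reversibility — the signal that carries root
  information.  The root state distribution is the matrix's own stationary
  distribution.
* **HB** — reversible within each branch but **non-stationary**: every
  branch not adjacent to the root has its own composition vector π_b (GTR
  with shared exchangeabilities ρ and branch-specific frequencies), while
  the root and its two adjacent branches share a root composition.  Root
  information comes from evidence of compositional drift along the tree.

Both models use discrete-gamma rate variation across sites (K equal-weight
categories of a mean-one Gamma(α), category means renormalized to mean
exactly 1; K = 1 disables it; default K = 4).

Rate matrices are always normalized to one expected substitution per site
*under their own stationary distribution*, so branch lengths mean expected
substitutions per site under the actual process (for NR this is not the
parametrization π).

## Likelihood

Felsenstein pruning on the rooted tree, root→tips transition matrices
`P = exp(Q_edge·t·r_k)` per rate category.  Site patterns are compressed
once per alignment; IUPAC ambiguity codes are marginalized and gaps treated
as fully missing; per-pattern rescaling with exact log offsets is applied at
every internal node, so deep trees cannot underflow.  The hot path uses
spectral decompositions (a symmetric eigendecomposition per GTR edge,
batched over edges for HB; a single general eigendecomposition for NR, with
a Padé `expm` fallback for near-defective matrices).  An independent oracle,
`brute_force_log_likelihood`, recomputes the same quantity by summation over
all 4^(n−1) internal state assignments using scipy's `expm`, and the test
suite holds the two routes to 1e−8 agreement on random instances.

## Priors

* NR: π ~ Dirichlet(1,1,1,1); log κ ~ Normal(0,1); ε_R|σ_R ~ N(0,σ_R²)⁶,
  ε_N|σ_N ~ N(0,σ_N²)¹²; σ_R, σ_N ~ Exponential(mean 0.25);
  α ~ Exponential(mean 1).
* HB: ρ ~ iid Exponential(mean 1), interpreted up to scale (the likelihood
  is invariant to the overall scale of ρ because of mean-rate
  normalization; reported values are mean-normalized).  Compositions live in
  additive-log-ratio coordinates `a = (log π_A/π_T, log π_C/π_T,
  log π_G/π_T)`: a_root ~ N(0, 5²·I₃) and, walking away from the root, each
  edge's coordinates follow a Gaussian random walk
  `a_b | a_parent ~ N(a_parent, s²·I₃)` with s ~ Exponential(mean 0.5) — so
  neighbouring branches share more information than distant ones.
* Branch lengths iid Exponential(mean 0.1); rooted topology uniform over
  rooted binary topologies.

All hyperparameters are `PriorSpec` fields.  Because the NR chain moves π in
alr coordinates, the Dirichlet term carries the alr Jacobian Σ log π_i; the
HB composition prior is defined directly on alr coordinates, so none is
needed there.  The log-prior implementation is checked term by term against
an independent scipy transcription.

## MCMC

Random-scan Metropolis–Hastings.  One *sweep* applies `moves_per_sweep`
(default 6) proposals drawn from a weighted move mixture — roughly one per
move family per sweep.  Moves:

* branch-length multipliers (Hastings log m);
* rooted NNI (an involution; Hastings 0 except for HB composition
  bookkeeping below);
* root repositioning: slide within the current root edge, or re-root on a
  uniformly chosen edge at a uniform split point (Hastings
  log(ℓ_target/ℓ_merged) from the split/merge length densities);
* random walks on unconstrained scales: alr(π), log κ, log α, ε components
  (walk scale proportional to the current σ), log σ and log s multipliers,
  per-branch alr compositions, log ρ components;
* joint scale moves ((σ, ε) and (s, composition increments) rescaled
  together, Jacobian (1+d)·log m) and prior-block *refresh* moves
  (independence proposals of (σ, ε), (s, all branch compositions), α, κ
  from their priors; proposal densities cancel the matching prior terms, so
  acceptance is the likelihood ratio).  The refreshes are what let the
  chain traverse the funnel-shaped hierarchy geometry; plain random walks
  have integrated autocorrelation times in the thousands there.
* a κ-ridge move for NR: κ and exp(ε_R) on the two transition pairs enter
  the likelihood only through their product, so a symmetric translation in
  (log κ, ε_AG, ε_CT) — likelihood-invariant, Hastings 0 — is needed for
  κ's marginal to disperse correctly.  Credible-interval calibration on
  prior-drawn truths was the test that caught both the need for this move
  and an early Hastings-ratio bug in it.

Under topology and root moves, HB compositions travel with their physical
edges (edge identity = stable node ids).  An edge that becomes root-adjacent
surrenders its composition; an edge that stops being root-adjacent draws a
fresh one from its conditional prior; both densities enter the Hastings
ratio, keeping the dimension fixed at 2n−4 vectors plus the root
composition.  The re-rooting move additionally recentres the root
composition on the composition of the edge being rooted on (reverse move
recentres on the merged edge), which is what makes root jumps across
compositionally distinct regions acceptably probable.

Given (seed, options) the chain is bit-reproducible; acceptance rates are
tracked per move.

## Posterior summaries

* **Root-split posterior** — relative frequency of the canonical bipartition
  induced by the sampled root; a *marginal* summary.
* **Majority-rule consensus** — exactly the rooted clades (descendant
  leaf-sets, not unrooted bipartitions — the root is the estimand) with
  support > 0.5, nested into a tree (polytomies where support is lacking),
  branch lengths = clade-conditional posterior means.  A *conditional*
  summary: its root can differ from the modal root split, and the test suite
  constructs a fixture exhibiting exactly that disagreement.
* **Branch GC ranking** — per consensus edge, the clade-conditional
  posterior mean of π_G+π_C (root composition for root-adjacent edges),
  in decreasing order.
* **Standardized marginal likelihood** — posterior density (Gaussian KDE,
  Silverman bandwidth, reflected at 0) divided by the prior density of σ_R,
  σ_N or s on a 512-point grid over [0, 1.1·max].  The ratio is read where
  the prior has appreciable mass; in the far tail a density ratio estimated
  from finite samples is 0/0-unstable (with 10⁴ draws the expected kernel
  mass near the grid end is far below one sample), so the calibration
  property (curve ≈ 1 under prior sampling) is asserted where the prior
  density exceeds 10% of its maximum — there the sup-deviation is ≈ 0.12 at
  10⁴ draws.
* **Empirical composition spread** — per-nucleotide across-taxon standard
  deviation (n−1 divisor) of proportions among unambiguous, non-gap sites;
  a quick screen for data that a stationary model cannot absorb.

## Simulator and study conditions

`simulate_alignment` draws, per site, a rate category, a root state from the
model's root distribution, and propagates states root→tips; it is seeded and
bit-reproducible, and can return the category/root-state ground truth.  No
indel process is modelled (the models address pre-aligned data).

The benchmark scenario `gc_shift_simulation` is a six-taxon tree with a
low-GC cherry (L1, L2) on one side of the root and four high-GC taxa
(two cherries, R1–R4) on the other (pendant and internal branches 0.2,
root-adjacent branches 0.4 substitutions/site), a GC shift of 0.3 vs 0.7
between the root-side subtrees, 1000 sites, uniform root composition, and a
mild transition bias (ρ_AG = ρ_CT = 2).  Two placement choices matter for
identifiability, both found by measuring converged posteriors over candidate
configurations:

* The extreme compositions sit on the *pendant* branches, with the internal
  scaffold only mildly graded (GC 0.45/0.55).  If the whole subtree sits at
  the extreme composition, the true central rooting and an off-centre
  rooting explain the data at the *same* total composition-drift cost — the
  Gaussian random-walk prior charges squared step sizes, and an off-centre
  root gains a fused central edge as an extra stepping stone — so pendant
  rootings can genuinely out-score the truth.  Tip-anchored extremes make
  off-centre rootings pay extra scaffold steps.
* The true root split is a *cherry* split.  Compositional root attraction
  points at the root of a compositionally shifted clade; a 2+4 design puts
  the truth exactly there instead of one edge away.

Even so, the margin between the true root and its one-edge neighbours is
modest at 1000 sites: across simulated replicates roughly a quarter of data
realizations yield a converged posterior whose modal root split is an
adjacent rooting (long-chain checks show these are posterior properties,
not sampler failures).  The recovery experiment (10 replicates, 20 000
sweeps each, neighbour-joining/midpoint starting trees) therefore recovers
the true root in *most but not all* replicates.  This is a real limitation
of Gaussian composition-drift priors worth knowing when reading rooted
trees inferred from single-gene-scale alignments; the margin grows with
site count.

## Scaled-down experiment sizes

The recovery experiments run at sizes a laptop handles comfortably: root
recovery uses 10 replicates × 20 000 sweeps (six taxa, 1000 sites),
starting each chain from the neighbour-joining topology rooted at its
midpoint (`run_mcmc(..., init="nj-midpoint")`, built on scikit-bio's NJ) —
the standard way to avoid spending the early chain on basic topology
search;
interval calibration uses 20 replicates of eight-taxon, 1000-site NR data
with 2000-sweep chains initialized at the simulation truth — initialization
at truth is standard for calibration checks (it removes burn-in failures
without biasing a converged chain); with random starts some replicates stall
in wrong topologies within this budget and the compensating parameter
estimates spoil the check.  Prior-recovery chains use 20 000 sweeps on an
empty alignment.

## Numerical notes and edge cases

* Stationary distributions solve vQ = 0 with the sum constraint replacing
  one equation; residual checked to 1e−10.
* `transition_probabilities` clips O(1e−16) negative entries from the
  spectral/Padé reconstruction to 0.
* Discrete-gamma category means use the incomplete-gamma identity
  ∫ x g_α(x) dx = F_{α+1}; the cache keyed by (α, K) matters because MCMC
  revisits α values after rejections.
* Degenerate inputs: σ = 0 is honoured as a point mass (finite prior only if
  the corresponding ε are exactly 0); empty alignments are valid and give
  log-likelihood 0 (used by the prior-recovery tests); ties at exactly 0.5
  are excluded from the consensus.
* GC-content ties in the branch ranking break on canonical clade order;
  edges matched by no sample are flagged absent and sort last.

## Known limitations

* Single chain, no parallel tempering: on multimodal root posteriors
  (distinct rootings separated by composition reorganizations) a single
  chain can need many sweeps to cross between modes; heuristic starts and
  the composition-aware re-rooting move mitigate but do not remove this.
* The Gaussian composition-drift prior prefers gradual gradients; abrupt
  symmetric shifts can make off-centre roots competitive (see above).
* No partitioned models, no invariant-sites category, no across-site
  composition mixtures, and nucleotides only.
* Marginal-likelihood model comparison (Bayes factors) is out of scope; the
  standardized-marginal-likelihood curve is a within-model evidence summary,
  not a model-choice statistic.
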
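# Methods

## The model

A binary character evolves independently along each branch of a rooted,
time-calibrated tree under a 2-state continuous-time Markov chain with
instantaneous rates q01 (0 -> 1, "origin" of the derived state) and q10
(1 -> 0, "reversal"), both in expected changes per lineage per Ma.  The
transition matrix is closed-form,

    P00(t) = pi0 + pi1 e^{-st},  P01(t) = pi1 (1 - e^{-st}),
    s = q01 + q10,  pi1 = q01 / s,

so no matrix exponential is ever approximated.  Mk1 is the q01 = q10
submodel (k = 1 free parameter); Mk2 is unconstrained (k = 2).  The model
assumes rate constancy within the scope it is fitted to — the full tree, or
one partition — and independence among characters; characters are analysed
one column at a time.

Tip observations are state sets: a determinate cell licenses one state, a
missing (`?`/`-`) or polymorphic (`{01}`/`(01)`) cell licenses both, i.e.
contributes partial likelihood 1 for each allowed state.  Missing and
polymorphic cells are distinguished only by *rescoring* (below), not by the
likelihood.

## Likelihood and fitting

Likelihoods use Felsenstein pruning over a postorder-indexed tree.  Partial
likelihoods are rescaled at every internal node and the log factors
accumulated, so matrices with >1000 taxa cannot underflow.  Polytomies are
handled natively (a node combines any number of children).

Mk1 fitting is a 31-point log-spaced scan of q over [1e-10, 100] followed by
bounded Brent refinement in the bracketing interval; the 1-D profile is
smooth and this is robust to the flat ridges of near-invariant characters.
Mk2 fitting runs L-BFGS-B on log rates from five fixed starting points
(symmetric 1e-4/1e-3/1e-2 and the two asymmetric corners 1e-2/1e-4) plus the
Mk1 optimum; the best of the six local optima is reported.  A fitted rate
within 1e-3 log units of a bound sets `bound_hit` — this matters for rare
states with no observed reversals, where the Mk2 reversal rate can run away
along a likelihood ridge; the fit is reported and flagged, never suppressed.
Convergence is at the optimizer's default tolerances tightened to
ftol = 1e-12; rates should be read to about 4 significant figures.

### Root prior

The root state prior is flat (0.5/0.5) by default, with stationary or fixed
priors available.  Under Mk1 flat equals stationary, so all Mk1 results are
prior-independent; Mk2 results record which prior was used (the pipeline
manifest logs it).  This was a genuinely open design choice; flat was chosen
because it keeps the two models maximally comparable.

## Marginal ancestral states

For each node the marginal probability of each state given *all* tips is
computed by combining the inside (postorder) partials with an outside
(preorder) pass — algebraically identical to re-rooting at every node — and
normalizing per node, so each node's two probabilities sum to 1 exactly.
This is marginal, not joint, reconstruction, matching the per-node
"proportional relative likelihoods" that comparative studies tabulate.

Support categories: strong for p >= 0.90, moderate 0.61–0.89, weak
<= 0.60, and "equivocal" reserved for p = 0.5 within a tolerance of 1e-3.
Because published categories are printed to two decimals, the gaps are
closed by half-open intervals at 0.605 and 0.895.  Model-to-model change
counts compare argmax states and exclude equivocal nodes by default (an
optional flag counts them as differing from any determinate state).

## The censored partition test

The tree is split into named partitions — clades or grades, specified as
explicit tip lists so grades pose no problem — and each partition is pruned
to the MRCA-rooted induced subtree (degree-2 nodes suppressed, lengths
summed).  An independent model is fitted per subtree; the composite
log-likelihood is the sum and its parameter count the sum of the per-part
k.  This is the "censored" construction: the backbone edges connecting
partitions belong to no partition, so the full-tree and composite
likelihoods are not computed on identical edge sets.  The comparison is
nevertheless made by AIC, exactly as the censored approach prescribes, and
every output table carries this caveat.  Stems of clade partitions are not
retained (subtrees start at the crown MRCA).

Named internal nodes whose descendants span more than one partition cannot
be reconstructed on any subtree and are reported as *lost*.  A partition
with no determinate tip for a character is flagged degenerate and enters
the composite with lnL = 0 and k = 0 (its tip pattern has probability 1
under any model).

AIC verdicts: dAIC < 2 "indistinguishable", 2–10 "better", >= 10 "very
different".  Per-partition best-model selection requires Mk2 to beat Mk1 by
at least 2 AIC units (ties go to the smaller model).  The Mk2 symmetry
ratio min(q01,q10)/max(q01,q10) is reported per fit.

## Fixed-rate sweeps

Reconstructions are recomputed with the Mk1 rate imposed (k = 0; the AIC of
an imposed rate is just -2 lnL) over a grid, by default {0.0001, 0.001,
0.01, 0.1} per Ma, with a dense log-spaced mode (40 points/decade) for
curve plots.  As q grows all marginals converge to 0.5/0.5 — the high
transition rate equilibrium, detected when every tracked node is within
1e-3 of 0.5.  A node's curve is classified `state_switch_dip` if its argmax
state differs between any two grid points (its probability curve crosses
0.5 before settling there), else `monotone_convergence`.  At low imposed
rates the most-likely state coincides with the Fitch state at unambiguous
nodes, which the tests assert on simulations.

## Parsimony origins and reversals

Change counting is equal-cost Sankoff DP, the polytomy-safe generalization
of Fitch; missing and polymorphic tips carry the full state set.  Branch
lengths are ignored and polytomies are treated as hard.  Per-node MPR state
sets (states realized in at least one most-parsimonious reconstruction) are
computed with an inside/outside pass; a node with set {0, 1} is equivocal.

Origins/reversals bounds use the two uniform resolutions of equivocal
nodes: all-derived and all-ancestral.  For binary characters each
resolution realizes exactly the Fitch length (the implementation verifies
this at run time and raises otherwise), so with length L and origin counts
o the reversal counts are L - o and the additive identity
min_o + max_r = max_o + min_r = L holds by construction.  The reported
min/max are additionally computed by an exact lexicographic DP over all
MPRs, which agrees with the resolutions on every enumerated case in the
test suite; the result object labels which resolution produced which bound
rather than hard-coding a direction.  Origins are counted on edges only; a
derived root state is visible in the labelings but not counted as an
origin.  Per-partition breakdowns assign each change to the partition of
the child node of its edge, with cross-partition (backbone) edges reported
separately so totals are conserved.

## bladj calibration

Input branch lengths are ignored; ages are fixed at the constrained named
nodes (the root must be one; tips are at age 0) and each maximal chain of m
unconstrained nodes between fixed ages A (ancestor) and D (descendant)
receives ages A - i (A - D)/(m + 1).  Fixed nodes are processed
oldest-first and, below each, chains are spaced against fixed descendants
in age order and nearest-first, so nodes shared between paths get
deterministic ages; this follows the published bladj behaviour where its
tie-breaking is under-documented.  Constraint violations (a constrained
descendant older than its constrained ancestor, an unconstrained root, an
unknown name) raise errors naming the offenders.  Equal ages would create
zero-length edges; these are perturbed by 1e-6 Ma with a warning because
downstream optimization prefers positive durations.  The output is
ultrametric to floating-point accuracy.

## Synthetic data

The generator emulates the *structure* the analysis assumes: five named
partitions on a short ladder backbone (root at 140 Ma, backbone nodes at
130/125/120 Ma, partition crowns at 0.8x their attachment age), pure-birth
(Yule) subtrees conditioned on tip count and rescaled to their crown age,
characters evolved forward edge-by-edge under partition-specific Mk
regimes with backbone edges following a designated regime, and exact-count
seeded missing (5%) and polymorphic (2%) cell degradation.  Default sizes
are 150/280/120/340/340 tips (1230 total), with the two superclades
carrying most of the diversity, and default regimes span 1e-4 to 1.5e-2
changes/Ma mixing symmetric and asymmetric partitions — the rate magnitudes
typical of conserved floral traits on a clade this age.  One global seed
expands through fixed counters (tree 0, character i 10+i, degradation 100),
so components are independently reproducible.

What the generator does *not* emulate: extinction (pure birth suffices for
ultrametric shape), trait-dependent diversification, phylogenetic error,
non-random missingness (real missing data concentrates in perianth-less
families), or correlated characters.  Passing tests therefore demonstrate
correctness of the machinery and statistical behaviour under the model's
own assumptions, not robustness to their violation.

## Problem sizes and tolerances in the tests

Enumeration oracles check pruning, marginals and parsimony exactly (1e-9)
on random trees of up to 6 tips, where brute force over all state
assignments is feasible.  Statistical checks use sizes chosen to keep the
suite fast while leaving comfortable margins: rate recovery at 1000 tips
(50 replicates, >= 90% within a factor 2 of truth for q* of 0.001 and
0.01), heterogeneity detection at 5 x 100 tips with a 100x contrast
(>= 95% AIC wins), and shared scaled-down bundles of ~260 tips for
pipeline-level tests.  The acceptance script runs the pipeline at the full
default 1230-tip conditions.

## Known limitations

- Binary characters only; no k > 2 states, no hidden-rate models, no
  Bayesian sampling, no stochastic character mapping.
- The partition scheme is a priori; there is no automatic rate-shift
  detection.
- The censored comparison discards backbone edges, so a small part of the
  data never informs the partitioned composite.
- Mk2 estimates for rare states with unobserved reversals are boundary-
  prone; `bound_hit` must be checked before interpreting such rates.
- bladj ages are even-spacing interpolations, not divergence-time
  estimates.
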
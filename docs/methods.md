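# Methods

This document defines the models and procedures implemented by
`fragminer`, the parameter defaults, and the reasoning behind them.

## Molecular graph model

Molecules are heavy-atom labeled graphs: atoms carry (element, formal
charge, aromatic flag), bonds carry one of `single | double | triple |
aromatic`. Hydrogens are implicit and never stored. A **fragment** is a
connected, bond-induced subgraph with at least one bond.

Fragment identity is a **canonical key** computed by iterative
neighborhood-color refinement followed by individualization with
exhaustive branching on the first non-singleton color cell; the key is
the lexicographically smallest serialization (atom labels in color
order plus the sorted edge list). This is exact — equal keys hold if
and only if the labeled graphs are isomorphic — and is validated in the
tests against `networkx.is_isomorphic` on randomized fragment pairs.
Subgraph embedding uses the VF2 monomorphism iterator with label and
bond-order matching; embeddings are reported as bond-id sets, so
matches are bond-induced and automorphic repeats collapse.

## Mining

See the README for the search-tree construction (subID, PRN, registry
pruning, antimonotone threshold cut). Definitions fixed here:

- **popularity** of a subID = number of distinct molecule ids among its
  components (not the component count).
- **PRN test**: compares molecule-support *sets*, not popularities. A
  child that trades one supporting molecule for another changes the
  support set at equal popularity; such a node is still maximal for its
  own support and must be reported.
- **registry**: all visited subID strings. Since a subID (the complete
  embedding list) identifies the fragment class exactly, pruning any
  revisited node is output-preserving, and the visited-node count drops
  on every library in which some fragment is reachable from two
  parents.
- **FFID collapse**: reports are grouped by supporting-molecule
  multiset; inside one group a fragment nested in a larger fragment is
  dropped, mutually non-nested fragments all stay.
- **aromatic integrity filter**: a fragment is discarded when, in a
  supporting molecule, it contains an aromatic bond whose smallest
  all-aromatic ring is not fully inside the matched bond set; partial
  aromatic rings are not meaningful chemical substructures.

Defaults: popularity threshold `t = 2` (the smallest value for which
"frequent" is non-trivial; `t = 1` is rejected because every molecule
would report itself), fragment growth cap `max_edges = 20` (bounds
worst-case growth on pathological inputs; no fragment in any test
library reaches it).

Correctness is established two ways: a proof sketch (child subIDs are
complete embedding lists by induction, so the PRN test is exactly the
"dominated by an equal-support superfragment" test, and antimonotonicity
guarantees every reportable fragment is reached), and an empirical
check against `exhaustive_maximal_frequent`, an independent brute-force
implementation, over randomized libraries.

## Activity preprocessing

IC50 values are read in nM. Classification labels: 0 (inactive) iff
IC50 > 10,000 nM, else 1; all rows kept. Regression: rows above
10,000 nM are removed and pIC50 = −log10(IC50 [M]) = 9 − log10(IC50
[nM]) is computed for the rest. Non-positive IC50 values are rejected
rows (warned, not fatal). Salt stripping keeps the connected component
with the most heavy atoms (ties: bond count, then smallest canonical
key); duplicates are removed by post-strip canonical identity, keeping
the first occurrence.

## Descriptors

The substructure dictionary (SSD) orders fragments by descending
library frequency with canonical-key tie-break. The descriptor matrix
is binary: `L[i, j] = 1` iff dictionary fragment *i* embeds in compound
*j*. Before modeling, fragments present in **less than 5%** of the
library are dropped (fraction exactly at the floor is kept); rare
fragments produce near-constant columns that destabilize the logistic
Hessian. A second, count-based filter (`frequency_tuning_subset`)
returns the descending frequency curve so a regression-specific cutoff
can be chosen at its flattening point.

## Classification: ridge logistic regression (RLR)

Model: P(y=1|x) = σ(Wᵀx), no intercept (binary presence vectors; the
all-zero vector is a meaningful "no dictionary fragment" baseline).
Objective: penalized log-likelihood

    J(W) = Σᵢ [ yᵢ Wᵀxᵢ − log(1 + exp(Wᵀxᵢ)) ] − ‖W‖² / (2σ²)

i.e. a Gaussian prior with standard deviation σ (default σ = 1, a weak
prior appropriate for ±O(1) logits from binary features). J is strictly
concave; it is maximized by Newton's method with step halving
(gradient `Xᵀ(y−p) − W/σ²`, Hessian `Xᵀdiag(p(1−p))X + I/σ²`),
converging when the gradient norm drops below 1e-6 (at most 100
iterations). The fit is tested to agree with an independent BFGS
optimization of the same objective to 1e-4 on the weights.

Evaluation: **random sub-sampling cross-validation** — each repeat
partitions the samples into 3 random subsets, trains on 2 and
evaluates on the held-out one (a 2:1 train/validation ratio); 10
repeats are averaged. Metrics: sensitivity, specificity, accuracy at
the 0.5 threshold, and rank-based ROC AUC. Degenerate splits (a class
missing from either side) are redrawn.

## Regression: RBF-kernel SVR

ε-insensitive support vector regression with kernel
k(x, x′) = exp(−‖x−x′‖² / (2σ²)). Defaults: kernel width
σ = √(n_features/2) (makes the typical squared distance between binary
descriptor vectors, which is O(n_features), give kernel values in a
responsive mid-range), box constraint C = 10, ε = 0.1 (half the planted
noise scale). The quadratic program is solved by scikit-learn's SVR
(libsvm) with γ = 1/(2σ²); predictions are re-implemented from the
stored dual expansion so serialized models are self-contained. A
constant training target short-circuits to predicting the constant.
Evaluation: seeded 5-fold cross-validation reporting fold-averaged MSE
and Pearson correlation; `grid_search_svr` picks hyperparameters by CV
MSE with deterministic tie-breaks.

## Privileged fragments

For fragment *i* in a focused library of T molecules: f_i = molecules
containing it, a_i = active molecules containing it, and

    PFI_i = f_i · a_i / T.

Significance: each fragment's active-molecule counts (A = a_i,
B = actives − a_i) are compared against its presence counts in a
**background library** (C matched, D unmatched) with the one-tailed
Fisher exact test P(a ≥ A) under the hypergeometric null, computed via
`scipy.stats.hypergeom.sf` and verified against exact rational
arithmetic to 1e-12. P-values are Benjamini–Hochberg adjusted; the
election keeps fragments with q < α (default α = 0.05) and ranks them
by descending PFI with canonical-key tie-break. In production use the
background is a large general-purpose collection; the synthetic
generator provides one by re-running with a 5% active prevalence.

## Combination rules

For every unordered pair of privileged fragments present in an active
molecule, the pair of embeddings with the most intimate relation casts
the molecule's single vote:

- **merge** — embeddings share an atom;
- **direct** — a bond joins an atom of each;
- **linker** — otherwise: the bonds on a shortest path between the two
  atom sets, path ties broken by the smallest linker canonical key.

A molecule containing exactly one privileged fragment votes
**standalone**. Votes aggregate by (pair, relation, linker identity)
into records sorted by descending support.

## Synthetic benchmark generator

Molecules are assembled from a 30-template catalog (6 aromatic
six-rings, 6 aromatic five-rings, 8 aliphatic rings, 10 chain/branched
functional groups) joined by 1–3 carbon linkers, with optional
methyl/ethyl decoration. Valence is enforced throughout (C4/N3/O2/S6;
aromatic bonds count 1.5, aromatic N/O/S accept exactly their two ring
bonds). Catalog design keeps planted fragments detectable: no plain
carbon-chain templates (linkers cannot counterfeit a template) and no
carbonyl-carbon attachment points (joins cannot accidentally extend a
planted group into a different one).

Activity model: actives carry ≥ 1 of the configured causal fragments;
pIC50 = baseline (5.5) + Σ planted effects + N(0, noise_sd), IC50 =
10^(9−pIC50) capped at the 10,000 nM cutoff; inactives draw IC50
log-uniformly from (10⁴, 10⁶] nM, forcing label 0. Planted combination
rules join a named fragment pair directly or through a fixed-length
carbon linker in a configurable fraction of actives. Everything is
driven by one `random.Random(seed)`; reruns are byte-identical, and a
manifest records per-molecule ground truth (planted fragments, rule,
pIC50) sufficient to recompute every quantity the tests assert.

Limits: molecules are small (tens of heavy atoms), rings never fuse,
stereochemistry and tautomers are out of scope, and pyrrole-type ring
N–H is materialized only at the RDKit conversion boundary.

## Problem sizes and budgets

Defaults were chosen so every documented workflow runs on one CPU in
minutes: benchmark libraries of 80–600 molecules, brute-force-oracle
libraries of ≤ 25 molecules × ≤ 10 bonds, a 200-molecule focused
library with a ≥ 100-molecule background for election. The full test
suite runs in ≈ 4 minutes; the end-to-end pipeline on 120 molecules in
≈ 4 minutes.

## Numerical choices

Logistic probabilities use `scipy.special.expit` and
`log(1+e^z) = logaddexp(0, z)` for overflow safety; Newton curvature
weights are floored at 1e-12; BH adjustment uses a reverse cumulative
minimum; kernel distances are clipped at 0 before exponentiation.
Cross-validation uses `numpy.random.default_rng` throughout, so all
reported metrics are exactly reproducible from the seed.
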
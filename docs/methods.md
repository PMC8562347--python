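# Methods

## Model

`msctree` performs Bayesian inference of a rooted species tree `S` from
multi-locus sequence alignments under the multispecies coalescent (MSC).
The model has three layers:

1. **Species tree.** A rooted, binary, ultrametric tree over `s` species
   with divergence times `tau_j` (node ages) and population-size
   parameters `theta_j = 4 N_j mu` for every contemporary and ancestral
   population. Both are measured in expected substitutions per site.
2. **Gene trees.** Each locus `i` carries a coalescent genealogy `G_i`
   embedded in the species tree: within a population with parameter
   `theta`, each pair of lineages coalesces at rate `2/theta`; lineages
   that fail to coalesce are handed to the parent population at its
   `tau`. Sequences therefore split no later than species ("sequences
   split before species"), and the MSC density of `(G_i | S, tau, theta)`
   factorizes over populations into `2/theta` per coalescent event and
   `exp(-n(n-1) dt / theta)` per inter-event interval. The density is
   over labeled histories (each event names the joining pair), so no
   extra combinatorial factor appears and the familiar 1/3 probability
   per 3-taxon gene-tree topology emerges by integration.
3. **Sequences.** Each alignment follows JC69 on its gene tree
   (stationary frequencies 1/4), evaluated by the pruning algorithm with
   site-pattern compression. Loci are independent, so the likelihood is a
   product over loci.

Priors: independent Gamma(shape, rate) on every `theta`; Gamma on the
root age `tau_0`; non-root ages uniform given `tau_0` over the region the
topology allows; and either a uniform prior on labeled histories
("Prior 0") or on rooted topologies ("Prior 1").

### Topology prior bookkeeping

The conditionally-uniform non-root age density is implemented with a
normalizing constant shared across topologies, `tau_0^-(s-2)`. With a
common constant, integrating the ages contributes the number of labeled
histories `h(T)` to each topology's marginal probability. The
Metropolis-Hastings topology factor is therefore 1 under Prior 0 and
`h(T)/h(T*)` under Prior 1, while the *reported* topology prior (used
when converting marginal likelihoods to posteriors) is proportional to
`h(T)` under Prior 0 and constant under Prior 1. Prior-recovery tests pin
this down: at `s = 4`, Prior 1 yields 1/15 per topology and Prior 0
yields 2/18 per balanced and 1/18 per caterpillar topology.

## MCMC

One iteration is a full sweep: every `theta` (sliding window on the log
scale), every `tau` (rubber-band), per locus one coalescent-node age
resample and one gene-tree SPR (prior-only runs, and A00 runs with
`gene_all_ages`, resample *every* node age per locus — free when the
likelihood is 1 and worthwhile for dense parameter estimation), and one
global mixing move that scales
all ages and thetas by a common factor with Jacobian `c^D`. In species
tree search mode (A01) each iteration then attempts one transmodel move:
SPR with probability 0.6, nodeslider otherwise (configurable). A00 mode
skips the transmodel moves. Iteration counts are not comparable to
programs with thinner iterations.

The rubber-band move interpolates gene-tree node ages in the three
populations adjacent to the moved divergence between the moved boundary
and the fixed neighboring boundaries; for the root the window is
one-sided and ages in the root population shift rigidly (Jacobian 1).
Step sizes are auto-tuned into an acceptance window of [0.2, 0.5] during
burn-in only, and frozen afterwards to preserve detailed balance.

### Coordinated SPR

An internal branch `X-Y` is selected with probability proportional to
`1/sqrt(branch length)` (short branches preferred), one daughter `A` of
`Y` with probability 1/2, and a regraft target `C` among branches that
survive pruning (excluding `B`, the sibling) and cover `tau_Y`, with
probability proportional to `1/c_i`, where `c_i` counts nodes on the path
`A-Z-C_i` (`Z` = MRCA of `A` and `C_i`; the minimum `c_i = 4` recovers
NNI). No age changes anywhere. Gene trees are re-embedded by pruning
every *moved node* — a node in a population on the path `Y..Z` (exclusive
of `Z`) with exactly one all-`A` daughter — and regrafting it at its
unchanged age onto a uniformly chosen skeleton branch alive at that age
in the population the `A` lineage then occupies. The Hastings ratio
combines branch selection (computed on `S` forward and on the proposed
`S*` in reverse), target selection on both trees, and per-moved-node
target counts.

Two implementation details matter for exactness and are enforced by
scripted round-trip tests (`|log R_fwd + log R_rev| = 0` to 1e-9, state
restored bit-for-bit):

* **All-A target exclusion.** A skeleton branch whose descendants are
  all from clade-`A` species can survive below a non-moved node above
  `Z`. Regrafting a moved node onto it would merge two all-`A` subtrees,
  and the reverse move's moved-node rule could not undo the proposal.
  Such branches are excluded from the target set, symmetrically in both
  directions.
* **Chained moved nodes.** The skeleton-side child of a moved node can
  itself be a moved node; skeleton construction bypasses the whole chain
  and each member regrafts independently (several pruned subtrees may
  re-chain onto one skeleton branch, ordered by age).

### Nodeslider (Expand/Shrink)

A fair coin picks the direction. Expand slides node `Y` (with clade `A`)
rootward: `tau_Y* = tau_X + Exponential(mean = expand_ratio * tau_X)`,
clade-`A` ages rescale by `r = tau_Y*/tau_Y`, and `Y-A` reattaches on the
unique ancestral branch covering `tau_Y*` (becoming the new root when
`tau_Y*` exceeds the old root age; at `s = 3` every accepted move changes
the root). Shrink slides `Y` into the clade of its daughter `C`:
`tau_Y = tau_C * u^(1/lambda)` from the power density with
`lambda = log(shrink_ratio)/log(1 - shrink_ratio)` (21.85 at the 0.1
default, placing 90% of the mass within 10% below `tau_C`), reattaching
on one of the `G(tau_Y)` branches of clade `C` alive at that age. Gene
trees follow with the same moved-node rule but *no* age window: every
node with exactly one all-`A` daughter is pruned, its subtree ages
multiplied by `r`, and regrafted at `t* = t r` onto a skeleton branch in
population `Y`-or-ancestor of the proposed tree. An all-`A` locus simply
rescales every age. The acceptance ratio is the species factor
(selection probabilities and the two age densities, reverse weights on
the proposed tree), one global Jacobian `r^m` with `m` counting *every*
rescaled age (species-tree clade-`A` internals plus all gene-tree
rescalings, including all-`A` loci), root-age prior terms
`g(tau_0*)/g(tau_0) * (tau_0*/tau_0)^-(s-2)` when the root age changes,
the topology-prior factor, and the MSC and likelihood ratios.

The Expand age density is defined operationally: the excess
`tau_Y* - tau_X` is exponential with mean `expand_ratio * tau_X`, and the
same density appears in the acceptance ratio.

### Population labels are derived data

Given node ages and the species tree, the population of every gene-tree
node is uniquely determined (the smallest population ancestral to both
children's populations whose age interval covers the node age). The
moves therefore recompute labels canonically instead of tracking the
per-class relabelling rules node by node; the results coincide with
those rules, which is asserted on a hand-built fixture.

## Marginal likelihood

For a fixed species tree the log marginal likelihood is computed by path
sampling over the power posterior (prior x likelihood^beta), treating
gene trees as parameters, with K-point Gauss-Legendre quadrature over
`beta` (default K = 16; smallest beta 0.0053). Per-beta chains are
independently seeded A00 runs with the log-likelihood multiplied by
`beta` in every acceptance ratio; the two smallest-beta chains draw twice
the samples because they are the noisiest. Monte-Carlo error is
estimated by batch means (20 batches) and propagated through the
quadrature weights. Posterior probabilities of candidate trees multiply
`exp(log_ml)` by the topology prior (labeled-history counts under
Prior 0).

## Simulator

The simulator is the package's synthetic-data generator: hierarchical
coalescent simulation of gene trees (exponential waiting times at rate
`n(n-1)/theta` per population) and JC69 sequence evolution (with
probability `e^(-4d/3)` copy the parent state, else draw uniformly). The
16-species study trees provide a standard benchmark design: every
internode interval equal to `theta`, root age `15 theta` (caterpillar,
"asymmetric") or `4 theta` (fully balanced, "symmetric"), two sequences
per species per locus. What the generator does **not** emulate: rate
variation among sites or loci, substitution models beyond JC69,
migration/introgression, sequencing error, or alignment uncertainty -
recovery results on simulated data therefore speak to the sampler's
correctness and statistical efficiency, not to robustness against those
real-data complications.

## Test and acceptance-run sizing

Distributional tests (prior recovery, KS checks) are the primary
validation: with the likelihood fixed at 1, the chains must reproduce
the analytic priors. Two practical points:

* MCMC output is autocorrelated; naive chi-square/KS p-values on thinned
  traces are anti-conservative. Categorical goodness-of-fit tests
  deflate the chi-square statistic by the batch-means variance-inflation
  estimate, which keeps the test calibrated without requiring
  independent samples.
* Proposal steps tuned for data-informed posteriors mix far too slowly
  on diffuse priors; prior-recovery runs use prior-scale steps
  (acceptance in roughly [0.2, 0.6]).

Desk-scale sizes used by the default suite and `scripts/acceptance.py`:
prior recovery at `s = 3..5` with 6,000-8,000 samples thinned by 3-4;
species-tree recovery on 5-species datasets of 10 loci x 500 sites
(theta = 0.01, internode = theta, two sequences per species) with chains
of ~2,800 sweeps; the 3-species transmodel-versus-path-sampling
comparison with K = 16 chains of 1,500-3,000 samples each. The
full 16-species, 50-replicate, 200,000-iteration benchmark design is a
cluster-scale computation; the suite verifies the 16-species machinery
end to end and substitutes the 5-species analogue for the quantitative
recovery checks.

## Numerical choices

* Ultrametricity tolerance on Newick input: relative 1e-6; ages stored
  exactly thereafter.
* Internal branch lengths are floored at 1e-30 before the
  `1/sqrt(b)` selection weights (floating-point age ties occur even
  though exact ties have measure zero).
* Gene-tree age intervals are half-open `[lower, upper)`; a node whose
  age equals a population boundary belongs to the upper population.
* Pruning likelihood uses per-node rescaling with log-scaler
  accumulation; deterministic and traversal-order independent. All-gap
  and `N` sites are fully ambiguous partials of ones; other IUPAC codes
  are indicator vectors.
* MAP ties are broken by canonical-Newick lexicographic order
  (documented as arbitrary). Canonical Newick orders children by their
  lexicographically smallest descendant tip.
* ESS of the log-likelihood is deliberately not used as a convergence
  diagnostic for transmodel runs; agreement of topology posteriors
  across independent runs from different starting trees is the shipped
  diagnostic.

## Known limitations

* JC69 only; no among-site or among-locus rate variation; strict clock.
* No species-delimitation modes; the species assignment (Imap) is fixed.
* Single-threaded; the path-sampling driver runs its K chains serially.
* Gene-tree proposals recompute the full per-locus likelihood rather
  than updating partials along the changed path; adequate at the tested
  scales, the dominant cost at hundreds of sequences per locus.
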
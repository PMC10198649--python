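# Methods

## The problem

Partition models and edge-length (GHOST) mixture models are the two
standard ways of accommodating heterotachy — variation of the
evolutionary process across sites and lineages — in phylogenetic
maximum likelihood.  Practitioners choose among them with information
criteria, almost always AIC (`-2 lnL + 2q`) or BIC.  AIC is an
estimator of the relative expected Kullback–Leibler divergence (rEKL)
of a fitted model from the generating process, and its unbiasedness
rests on regularity conditions that fail when parameters sit near the
boundary of parameter space — in phylogenetics, when edges carry few
expected substitutions.  This package reproduces, as a tested and fully
self-contained pipeline, a simulation study of how AIC and BIC behave
when ranking two partition families (P-UEL, P-LEL) and two GHOST
mixture families (M-UGP, M-LGP) under standard and short-edge
("nonstandard") conditions and under increasing mispartitioning, using
an exact simulation estimator of rEKL over the full site-pattern space.

## Generating process

Data are 8-taxon, 2×1000-site alignments simulated under a two-block
unlinked-edge-length GTR partition model: block k evolves on tree T_k
under GTR model M_k, and the blocks are concatenated.  The two GTR
models are fixed (rates relative to G↔T = 1, order A↔C, A↔G, A↔T, C↔G,
C↔T; frequencies A, C, G, T):

    block 1: rates (1.56, 3.20, 4.02, 1.32, 0.90), freqs (0.28, 0.34, 0.19, 0.19)
    block 2: rates (1.17, 2.41, 1.79, 2.65, 2.99), freqs (0.17, 0.30, 0.37, 0.16)

Rate matrices are normalised to one expected substitution per site per
unit edge length.  Three edge-length regimes share one topology:

- **standard** — every edge length is drawn once per study arm from
  Exp(mean 0.06), rejection-resampled until > 0.005, so each edge
  expects more than 5 substitutions per 1000-site block;
- **mild** — tree 1 has all 13 edges at 0.005 (exactly 5 expected
  substitutions per block per edge); tree 2 mixes 0.005 and 0.001;
- **extreme** — both trees mix 0.005 and 0.001.

The study topology is the balanced tree ((a,b),(c,d)) | ((e,f),(g,h)).
The source study shows its trees only graphically, so the short-edge
trees here place the 0.005 ("long") edges on two non-sister tips plus
the internal path between them — tips {a, c} for tree D, tips {e, g}
for tree E — making the long edges non-monophyletic (a long-branch-
attraction shape), with 0.001 everywhere else.  The topology and edge
placement are configuration items (`partmix.simulate.base_topology`),
and conclusions that depend on the exact placement (e.g. topology
recovery percentages under the extreme regime) should be read as
qualitative.

**Mispartitioning.**  A proportion p ∈ {0, 0.05, …, 0.5} of sites is
drawn uniformly from each block and the *fitted-block labels* of the
two draws are exchanged; sequence content and the sites' true origins
are untouched and both fitted blocks keep exactly 1000 sites.  The full
design is 11 proportions × 100 replicates per condition; the default
desk-scale preset is 3 proportions × 20 replicates.

The simulator draws the root state from the stationary frequencies and
propagates along edges with exact GTR transition matrices; its output
distribution is cross-validated in the tests against the
pruning-computed exact pattern distribution (chi-square goodness of
fit).  It emulates iid sites with no rate variation, indels, or
ambiguity codes — matching the fitted models, so these tests say
nothing about robustness to such features in real data.

## Fitted models

All four families are special cases of a generalised mixture in which
site i has per-class weights α_ik over (tree, GTR) classes:

- **P-UEL** (42 parameters): per-block tree and GTR; the likelihood
  separates and the blocks are fitted independently.
- **P-LEL** (30): one shared tree, per-block GTR.  Because time and
  rate cannot be disentangled on a shared tree, block 2 carries a free
  relative-rate scalar (equivalently, its G↔T rate is freed) — the
  "ninth" GTR parameter.
- **M-UGP** (43): one topology, two classes with their own edge
  lengths and GTRs, one free mixture weight applied to every site.
- **M-LGP** (35): as M-UGP with a single shared GTR.

Parameter accounting per family: each GTR contributes 5 + 3, each edge
set 2N−3 = 13, the mixture weight 1, the P-LEL scalar 1.

**Optimisation.**  Likelihoods are computed by Felsenstein pruning,
vectorised over the unique site patterns of the alignment with
per-pattern log-space rescaling.  All parameters are optimised jointly
by bounded L-BFGS-B on transformed coordinates: log edge lengths, log
exchangeabilities, softmax frequencies, logit mixture weight.  (An
EM-style alternation for the mixture weight would reach the same
stationary points; the joint update is simpler and was adopted after
checking both give identical optima on test problems.)  Bounds mirror
common ML phylogenetics practice — edge lengths in [1e-6, 10] expected
substitutions, exchangeabilities in [0.01, 100], frequencies and
weights at least ~1e-4 — and they matter scientifically here: under
short-edge conditions many estimates pin at the boundary, and the floor
keeps the fitted site-pattern distribution non-degenerate, which the
rEKL measure (below) sees directly.  Convergence uses L-BFGS-B's
relative-ftol at 1e-9 (≈ 1e-5 log-likelihood units at this data size).

Each fit runs a configurable number of restarts: one initialised from
the generating parameters when available (otherwise a neutral
Jukes–Cantor-like point), one neutral, further ones randomised.  A
stability study showed truth-initialised fits reach the same optimum as
cold multi-restart fits on these problem sizes, so the pipeline default
is 2 restarts (the library default is 3); the best restart wins, which
also guarantees the fitted lnL is never below the generating-parameter
lnL at 0% swap.  Mixture classes are reported with the larger weight
first; complex families are warm-started from their nested family's
solution inside the pipeline, which enforces the nesting inequalities
lnL(M-UGP) ≥ lnL(M-LGP) and lnL(P-UEL) ≥ lnL(P-LEL) replicate by
replicate.

Topology is fixed to the generating topology by default (the study's
regimes recover it essentially always except in the extreme arm, and
the bias quantities do not involve search).  Exhaustive enumeration
((2n−5)!! topologies) and NNI hill climbing from a neighbour-joining
start are provided for search experiments.

## rEKL, Bias(AIC), and BIC

Because sites are iid given the model, the expected predictive
log-likelihood of a fitted model collapses to a sum over the 4^8 =
65,536 site patterns, and the package computes it exactly — no pattern
sampling.  With p*_j the exact pattern distribution of generating
block j and p̂_l^k the fitted distribution of component k on replicate
l, the estimators over c replicates are

    rEKL_partition = −2 · mean_l Σ_k Σ_h ( Σ_j n_k^j p*_j(h) ) ln p̂_l^k(h)
    rEKL_mixture   = −2 · mean_l Σ_h n ( ½p*_1 + ½p*_2 )(h) ln ( α̂1 p̂_l^1 + α̂2 p̂_l^2 )(h)

where n_k^j counts the sites assigned to fitted block k whose true
origin is j (at proportion p: 1000(1−p) own-origin, 1000p other), and
n = 2000.  The composition weights make the partition rEKL respond to
mispartitioning; the published expansion of this estimator weights each
fitted block by the combined mass of both blocks, which double-counts
and is proportion-independent — it is retained as `mode="literal"` for
audit.  The mixture rEKL never uses block labels, so mixture biases are
identical across mispartitioning levels by construction.

    Bias(AIC) = rEKL − E(AIC),

with E(AIC) the mean AIC over the same c replicates and the Monte-Carlo
standard error computed from the paired per-replicate differences.  By
Gibbs' inequality rEKL is bounded below by the generating process's
pattern entropy; the bound is exposed (`plug_in_rekl_bound`) and
property-tested.

BIC is conventional for mixtures (`−2 lnL + q ln 2000`).  For partition
models each block's unique parameters are penalised by the log of that
block's size and shared parameters by ln n:
`−2 lnL + Σ_k q_k ln n_k + q_c ln n`, with (q_1, q_2; q_c) = (21, 21; 0)
for P-UEL and (8, 9; 13) for P-LEL; with one block this reduces exactly
to the conventional BIC (property-tested).

## Performance measures

The Kuhner–Felsenstein branch score between two trees is the root of
the summed squared edge-length differences over the union of their
bipartitions (absent bipartitions contribute length zero); it is a
metric, and the metric axioms are property-tested.  The matching rules:
a P-LEL shared tree is scored against both generating trees and the two
scores averaged; P-UEL blocks match their generating blocks; mixture
classes are scored under both class-to-tree assignments, each as an
α̂-weighted average (a plain mean is available — the weighting was an
open choice), and the minimum is taken, with ties broken to the
identity assignment.  Topology recovery means unrooted Robinson–Foulds
distance zero.  Parameter errors are signed element-wise differences of
frequencies (4) and exchangeabilities (6, under the shared G↔T = 1
normalisation) per component, with mixture classes matched by the
branch-score-minimising allocation.

## Numerical and design notes

- Pattern probabilities are exact to pruning round-off; conservation
  (Σ_h p(h) = 1) holds to 1e-8 over all 65,536 patterns and pruning is
  verified against exhaustive summation over internal states on small
  trees.
- Fitted pattern probabilities are floored at 1e-300 inside the rEKL
  logarithm; with the optimiser's bounds this floor is never active in
  practice.
- The per-replicate Bias(AIC) differences have a standard deviation of
  roughly 100 AIC units (dominated by the shared sampling noise of the
  data log-likelihood), so a desk-scale arm with c = 20 carries a
  Monte-Carlo SE of ~15–25 AIC units; the acceptance checks use the
  paired SE computed per arm.
- Everything downstream of a seed is deterministic: random streams are
  derived from the experiment seed with fixed integer spawn keys per
  (condition, proportion, replicate, family), so identical seeds give
  byte-identical outputs and families see the same alignments.

## Known limitations

- The exact short-edge tree shapes of the source study are unknown
  (published only as figures); quantities that depend on them — most
  visibly the extreme-arm topology-recovery percentage — are
  qualitative here.
- Desk-scale replicate counts (c = 20 per arm in the acceptance
  script, against 100 in the full design) leave Monte-Carlo error of
  ~15–25 AIC units on bias estimates; the full-scale preset
  (`ExperimentConfig.full_scale()`) reproduces the complete design when
  given the time.
- Exact ML optimisation bounds the reproducible range of Bias(AIC):
  the optimism E[lnL̂ − lnL(θ*)] of a correctly specified q-parameter
  fit is ≈ q/2 under regularity (verified here: 20.98 vs q/2 = 21 for
  P-UEL under the standard condition), so bias values near −2q — as
  published for the most complex families under short-edge conditions —
  imply near-zero optimism and are not attainable by a fully converged
  ML fit; this package's properly-optimised P-UEL/M-UGP biases under
  the mild regime are correspondingly less negative than the published
  ones, while the simpler families' biases reproduce within Monte-Carlo
  error.  The criterion-ordering results (AIC vs BIC vs rEKL winners)
  do not depend on this.
- No rate-across-sites variation, ambiguity codes, gaps, more than two
  blocks/classes, or non-reversible models.
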
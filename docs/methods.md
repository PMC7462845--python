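# Methods

`plastorate` implements the comparative-genomics analysis that links
substitution rates of plastid protein-coding genes to plastome
rearrangement in diatoms: codon-level dN/dS estimation, exact inversion
distances on signed gene-order permutations, in-frame indel counting, and
the correlation stage tying rates to rearrangement and to plastome
features. This note records the models, the numerical choices, and what
the synthetic-data generator does and does not emulate.

## Substitution-rate estimation

### Pairwise counting (NG86)

For a pair of gap-free, codon-aligned sequences the Nei–Gojobori (1986)
method counts synonymous (S) and nonsynonymous (N) sites and differences
(Sd, Nd), computes the proportions pS = Sd/S and pN = Nd/N, and corrects
each with the Jukes–Cantor formula d = −(3/4)·ln(1 − 4p/3); ω = dN/dS.

Conventions, since the method leaves them open:

* **Stop codons.** Every single-base change that would create a stop codon
  is excluded from both the site and the difference counts. Each excluded
  change removes 1/3 of a site, so a codon's s + n may be less than 3
  (e.g. tryptophan TGG, with two stop-adjacent changes, contributes
  s = 0, n = 7/3); the total shortfall is reported on the estimate. For
  codon pairs differing at k ∈ {2,3} positions, Sd and Nd are averaged over
  all k! mutational orderings, skipping orderings that pass through a stop
  codon; in the rare case that every ordering is blocked, the average falls
  back to all orderings with a flag.
* **Sites** are averaged over the two sequences; Sd/Nd are additive over
  codons, so concatenated genes decompose exactly into per-gene counts.
* **Undefined values.** pS ≥ 3/4 makes dS undefined (saturation) and
  dS = 0 makes ω undefined; both are reported as missing with a flag, never
  coerced to 0, and downstream correlation code drops them pairwise with a
  logged count.

The pairwise estimator is deliberately a counting method with no
transition/transversion correction. At κ > 1 it is known to be biased;
the ω = 1 calibration in the tests therefore simulates at κ = 1 — the
regime the estimator is designed for — while realistic scenarios keep
κ = 2. The calibration pair uses a divergence of 0.3 substitutions per
codon site path length: at much lower divergence the mean of the dN/dS
*ratio* is inflated a few percent purely by sampling noise in the dS
denominator, which would test the ratio's small-sample distribution rather
than the estimator.

### Single-ω maximum likelihood (GY94 "model 0")

The Goldman–Yang (1994) codon model on the 61 sense codons:
q_ij = 0 for multi-position changes and otherwise proportional to π_j,
multiplied by κ for transitions and by ω for nonsynonymous changes, scaled
so the expected rate at stationarity is 1. Codon frequencies default to
F3×4 computed from the alignment (F61 or uniform can be passed as `pi`).
The likelihood on a fixed rooted tree is computed by Felsenstein pruning
over site patterns compressed with multiplicities; transition matrices
come from an eigendecomposition of the symmetrised reversible generator
(D^{1/2} Q D^{−1/2}), with rows of exp(Qt) clipped at 0 and renormalised
against round-off.

`fit_m0` maximises over (κ, ω, tree_scale) with L-BFGS-B in log-parameter
space, bounds κ ∈ [0.01, 100], ω ∈ [10⁻⁴, 20], scale ∈ [10⁻⁶, 10³], from
three starts (κ, ω) = (1, 0.1), (2, 0.5), (5, 1). Branch-length
*proportions* are fixed to the input tree and only a global scale is
optimised — a deliberate simplification of per-branch optimisation,
recorded in the fit's flags. Identical sequences drive the scale to its
lower bound and are flagged rather than erroring.

On simulated data (8 ultrametric taxa, 500 codons, ω = 0.2, κ = 2) the fit
recovers ω with a median relative error of about 6–8% over 20 replicates,
and recovers the photosynthesis < ribosomal ω ordering essentially always.

### Likelihood-ratio arithmetic

Nested site-model comparisons (M7 beta vs M8 beta+ω>1) reduce here to the
statistic 2·(lnL₁ − lnL₀) against the χ² upper tail with the stated
degrees of freedom (2 for M7 vs M8). The heavy numerical fitting of those
site models is out of scope; published log-likelihood pairs are inputs.
A negative statistic is reported as-is with p = 1 and a warning.

## Rearrangement distances

A plastome's gene order (one inverted-repeat copy removed) is a signed
permutation of locally collinear blocks. The minimum reversal distance is
computed exactly with the Hannenhalli–Pevzner formula
d = (n+1) − c + h + f on the breakpoint graph of the permutation framed by
0 and n+1: c counts alternating cycles; h counts hurdles (minimal
unoriented components, plus the greatest unoriented component when its
span contains all others); f = 1 exactly when the hurdles are odd in
number and every one is a superhurdle (deleting it would not reduce the
hurdle count). Orientation of a gray edge is read off the parity of its
endpoint positions; components are connected components of the
gray-edge interleaving graph over nontrivial cycles.

Correctness is established against an independent breadth-first-search
oracle over the reversal graph: exhaustively for all signed permutations
with n ≤ 5 (3,840 at n = 5) and n = 6, and on seeded random pairs at
n = 7. Fortresses cannot occur at those sizes, so the fortress branch is
exercised by a constructed three-superhurdle permutation
(2,4,3,5,1, 6, 8,10,9,11,7, 12, 14,16,15,17,13), whose distance of 16 was
additionally verified by exhibiting a 16-step sorting sequence.

Chromosomes are treated as linear with fixed framing, matching how
linearised single-copy orders are published; a circular mode (minimising
over rotations and the whole-molecule flip) sits behind a flag.
Gene-order identity grouping uses exact signed-sequence equality (an
option relaxes this up to whole-molecule reversal). On the bundled
40-taxon order table this yields 14 taxa sharing their order with at least
one other, in six groups, and the full 40×40 inversion matrix computes in
well under a second.

## Indel counting

Indels are counted per taxon against a designated reference (the outgroup
in the published design): within each gene, an event is a maximal run of
gap characters in either row of the pairwise slice — taxon-row runs are
deletions, reference-row runs insertions. Columns gapped in both rows
(typically a third taxon's insertion) carry no information about the pair
and are stripped first, with a logged count. A gene is *intact* for a
taxon when every run length in both rows is divisible by 3; frameshifted
genes are excluded from that taxon's total only. The per-taxon total is
the event count summed over intact genes, which is invariant to gene
order. A per-column counting mode exists behind a flag; adjacent insertion
and deletion runs count as two events.

## Correlation stage

Two surfaces:

* **Focal-taxon tests.** Given an all-vs-all pairwise rate matrix (dN, dS
  or ω) and the pairwise inversion matrix, each focal taxon i is tested by
  Pearson correlation over {(rate(i,j), iv(i,j)) : j ≠ i}, with the
  two-sided p from t = r·√((n−2)/(1−r²)). Significance for the per-focal
  counts is called on the raw p at α = 0.05, with Bonferroni-adjusted
  values (family = one test per focal taxon, per rate type) reported
  alongside. Using an all-vs-all pairwise matrix is an interpretation:
  per-focal correlations require per-pair rates, which outgroup-relative
  rates alone cannot supply.
* **Rate-vs-feature regressions.** Outgroup-relative rates against
  plastome features (size, indel total, IR/LSC/SSC lengths) both by
  Pearson test and by PGLS under a Brownian-motion covariance
  V_ij = shared root-to-MRCA path length on the tree with the outgroup
  pruned. PGLS is the closed form β = (XᵀV⁻¹X)⁻¹XᵀV⁻¹y via Cholesky
  whitening, σ² = residual quadratic form/(n−k), t-based p-values; with
  V = I it reproduces OLS to machine precision. No Pagel's λ is estimated;
  a fixed λ multiplier on the off-diagonal is available. A singular V
  receives a 10⁻¹⁰ diagonal jitter, logged. Rank-deficient designs error
  with the collinear column names.

## Synthetic data

The generator produces the joint structure the analysis assumes: a rooted
ultrametric tree (Yule by default; star or fixed newick available) with
root-to-tip depth 0.05 substitutions per codon site; i.i.d. lognormal
per-branch rate multipliers with log-sd τ = 0.6 (emulating strong lineage
effects such as a single dramatically accelerated lineage); codon
alignments evolved under group-specific ω (photosynthesis 0.05,
ribosomal/RNA-polymerase 0.3, κ = 2) over a reduced 12-gene plastome-like
complement; reversal histories on a 42-block signed permutation; and
in-frame indel events of length 3/6/9 nt (70/20/10%).

Rearrangement and indel intensities couple to the branch multiplier m
through Poisson(rate · b · (coupling·m + (1−coupling))): coupling = 1
makes structural churn fully rate-proportional, coupling = 0 makes it
depend on branch length only. Defaults λ_inv = 60 and μ_indel = 200 per
unit rate-weighted branch length give a handful of inversions and on the
order of ten indel events per lineage at the default depth, comparable to
the rearrangement levels seen across diatom plastomes. Reversal intervals
are uniform (no hotspots), matching the null model implicit in
reversal-distance analysis. Every stochastic call takes a mandatory seed
and is a pure function of (arguments, seed); bundles are byte-reproducible.

### Why the size/power calibration uses a star tree

On a structured tree, pairwise rates *and* pairwise inversion counts both
grow with the shared path length between two taxa, so even with
coupling = 0 the focal-taxon Pearson test has a confounded, non-null
target — which is precisely why the feature regressions use PGLS. The
calibration scenario (`calibration_config`) therefore uses a star tree
with equal depths and a single ω class: there, at coupling = 0, a focal
taxon's rates (driven by its partners' multipliers) and inversion counts
(driven by its partners' Poisson draws) are exactly independent.

A second structural fact matters for interpreting the null: within one
replicate the 40 focal tests share their per-partner components (partner
j contributes the same m_j to every rate(i,j) and the same reversal count
K_j to every iv(i,j)), so their correlation statistics are strongly
dependent — close to 40 copies of a single draw. The false-positive
*fraction* over replicates is therefore compared to the binomial band at
the replicate level (the independent unit), not at the per-test level.
At the defaults the decoupled scenario sits near the nominal 5% and the
fully coupled one flags >90% of focal taxa.

What the generator does **not** emulate: base-composition heterogeneity
across lineages, rearrangement hotspots, IR expansion/contraction,
foreign-DNA insertion, alignment error, and ortholog-selection ambiguity.
Passing tests on synthetic data show the estimators and the correlation
machinery behave as designed under the stated model, not that real
plastome data satisfy that model.

## Problem sizes used in tests

Simulation-based checks run at reduced but statistically adequate sizes
chosen once: 20 replicates for estimator-recovery and size/power checks,
1,000-codon neutral pairs, 500-codon 8-taxon fits, 40-taxon single-gene
(300-codon) calibration scenarios. The exhaustive reversal-distance
validation covers every signed permutation to n = 6 and seeded samples at
n = 7, where the BFS oracle's state space (645,120 states) is still
enumerable.

## Known limitations

* `fit_m0` optimises one global branch scale, not per-branch lengths; on
  data whose true branch proportions differ from the input tree the ω
  estimate absorbs some misfit.
* The NG86 fallback for fully stop-blocked codon pairs (all orderings pass
  through stops) counts through-stop steps as nonsynonymous; such pairs
  are flagged and vanishingly rare in real coding alignments.
* The M7/M8 machinery itself (beta-distributed ω fitting, Bayes Empirical
  Bayes site identification) is not implemented; only the LRT arithmetic
  on supplied log-likelihoods is.
* Inversion distance treats the gene order as a single linear chromosome;
  translocation/transposition and DCJ distances are out of scope.
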
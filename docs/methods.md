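# Methods

`karyorec` reconstructs, for every internal node of a rooted binary species
phylogeny, a *monoploid* ancestral genome — at most one copy of each gene
family, organised into linear contigs and then into `x` chromosomes — from
the chromosomal gene orders of the extant genomes, and estimates the basic
chromosome number `x` statistically. This note records the model, the
numerical choices, and what the simulation-based tests do and do not show.

## Model and pipeline

**Gene families.** All reasoning is at the level of gene families (small
sets of homologs across the input genomes). Families with more than 10
members in any one genome are excluded — beyond that size, homology
assignment is too ambiguous and the matching graph fills with spurious
joins. Families present in a single genome are also dropped: they can never
support an adjacency shared across an ancestral node.

**Generalized adjacencies.** Two genes are generalized-adjacent when at most
`gap_max = 7` retained genes separate them on a chromosome. An adjacency
joins oriented gene *extremities* (5' head / 3' tail), so strandedness is
preserved. For an ancestral node, an adjacency is *phylogenetically
informative* when at least one leaf genome in each of the node's two child
subtrees carries it; its weight is the number of supporting leaves below the
node, plus 0.5 when a genome outside the subtree also carries it (outgroup
corroboration as a tie-break). Gap length does not enter the weight: a
gapped adjacency is a unit of evidence, not a distance.

**Contigs by maximum-weight matching.** The informative adjacencies form a
graph over family extremities; a maximum-weight matching selects a
conflict-free subset, and adding each family's implicit head–tail edge turns
the matched components into linear runs — the ancestral contigs. Matching
guarantees monoploidy by construction. Because co-optimal matchings are
abundant, we sample `n_samples` (default 100; 50 and lower for small runs)
optima by perturbing each edge weight with an i.i.d. uniform(0, δ) jitter,
δ = 1e-6 × the smallest nonzero weight. Weights are quantised in steps of
0.5, and total jitter cannot bridge that quantum on any realistic instance,
so every sample is an exact optimum; the jitter only randomises the
tie-breaking. Matchings are solved per connected component (an exact
decomposition; components correspond roughly to ancestral chromosomes),
which keeps the blossom algorithm fast on large instances. Rare cycles
(closed matched loops) are linearised by deleting the cycle's minimum-weight
matched edge — the least evidence sacrificed. Samples are highly similar in
practice; the acceptance script reports the mean pairwise fraction of shared
matched edges.

**g-mers and co-occurrence.** Contig lengths are extremely skewed, and long
contigs — spliced from several true chromosomes — dominate and distort any
clustering built on whole contigs. Every contig of length L > g is therefore
cut into ⌊L/g⌋ pieces of length `g = 20`; a remainder r ≥ ⌈g/2⌉ stands
alone, a smaller one is appended to the last piece (no piece exceeds
g + ⌈g/2⌉ − 1, so unit lengths vary by at most 3× and the length bias is
gone). The longest `max_units = 500` units are clustered. Each unit is
matched against every extant chromosome: it matches where at least
max(2, 0.3·|unit|) of its families have a gene (tolerant to fractionation;
the absolute floor of 2 blocks single-gene hits), with the median position
of the matched genes recorded as an anchor. The co-occurrence matrix C
counts, over (genome, chromosome) pairs, how often two units match the same
chromosome — a genome with several matching chromosomes contributes several
counts. C is smoothed by correlation: S[u,v] is the Pearson correlation of
rows u and v of C excluding columns u and v (constant rows correlate 0), and
D = 1 − S is the clustering distance. Units are clustered by complete
linkage; the flat cut at k clusters is polished, k fixed, by iteratively
reassigning any unit whose mean distance to its own cluster exceeds
(1 + 0.1)× its mean distance to the nearest other cluster. A PCA route
(project C onto the fewest components reaching 70% variance, cap 10; Ward on
the scores) provides an independent clustering for consistency checks.

**Gap statistic and the estimate of x.** For each matching sample, the
clustering is scored over k = 2..`k_max` (default 20) with the gap
statistic: W_k = Σ_r D_r/(2 n_r) (D_r the sum of pairwise Euclidean
distances among feature rows within cluster r, features being rows of S),
and gap(k) = mean_b log W*_kb − log W_k over B = 50 null replicates drawn
uniformly from the per-feature bounding box and clustered by the same
complete-linkage procedure. log(W + 1e-12) guards exact-duplicate feature
rows. Because samples differ in how cleanly they cluster, only the best are
kept: samples ranking in the top 10 gap values for at least two of
k = 4..10 (ties kept; top-10-by-mean-gap as fallback).

The estimate reads the *increments* Δ(k) = gap(k) − gap(k−1) of the mean
profile over the selected samples. A least-squares line is fitted to Δ(k)
on the overfitting regime k = 12..20, and x is the largest k < 12 whose
increment exceeds the line's prediction *by more than 2·√(s_k² + s_{k−1}²)*,
where s_k is the gap statistic's Monte-Carlo dispersion. The margin is the
package's operationalisation of a "visible" departure from the noise trend:
with a strict inequality, symmetric fit residuals make a spurious exceedance
near-certain on structureless data, whereas the s_k scale calibrates the
test to the null fluctuation of Δ at each k (fit-residual scatter is the
fallback for profiles without stored dispersions). If no increment clears
the margin the estimate is flagged as "no structure" and x = 2 is reported.
Points inside the fitted window are never candidates — they exceed their own
fit only by noise. Two published alternatives (two-line intersection,
maximum-curvature "kneedle") are deliberately not implemented as defaults;
both are known to be unstable on concave gap curves.

**Chromosome assembly.** At the chosen x, each contig follows the majority
cluster of its g-mers (ties: the first g-mer). Within a cluster, the matrix
P[i,j] counts (genome, chromosome) occurrences where contig i's anchor
precedes contig j's; the Linear Ordering Problem — the permutation
maximising respected precedences — is solved exactly by exhaustive search
for ≤ 8 contigs and by a greedy-plus-local-search heuristic (net-score
initialisation; best-improvement swaps and relocations) above that. A
contig is flipped when the majority of its matched occurrences run against
its stored orientation (sign of the position correlation per occurrence).
Chromosome labels are arbitrary; every comparison against truth is
label-invariant.

**Evaluation.** *Coherence*: per descendant chromosome, the largest
fraction of its ancestor-placed families drawn from a single ancestral
chromosome, averaged over chromosomes (families the ancestor does not place
are excluded from the denominator; the inclusive variant is a config
switch). *Coverage*: families placed. *Choppiness*: paint each extant gene
with its family's ancestral chromosome colour, merge runs of one colour
(unpainted genes do not break runs), and count segments spanning strictly
more than 300 kb. Cross-reconstruction comparisons map families through
ortholog pairs (majority vote on conflicts) and flag row/column maxima of
the shared-family matrix; clustering-method comparisons additionally report
the adjusted Rand index.

## Simulator

The simulator provides ground truth for every stage. A root genome of
`x_true` chromosomes × `genes_per_chromosome` single-copy families evolves
along a rooted tree; per branch, event counts are Poisson(rate × length)
and events apply in random order: inversions (uniform segment, signs
flipped), reciprocal translocations (uniform internal cut points, tails
exchanged), fusions/fissions, duplications (family size capped at 10, the
pipeline's own filter), losses. Flagged branches undergo whole-genome
duplication followed by fractionation (each duplicate pair loses one copy
with probability 1 − retention, survivor uniform). Coordinates are
synthesised last — lognormal gene lengths (≈3 kb) and intergenic gaps
(≈10 kb) — so that painted segments reach the >300 kb scale at ~25
consecutive genes. A fraction of genes can be emitted without family labels
to mimic unannotated content. Everything is reproducible from one seed.

What the simulator does *not* emulate: transposon turnover, tandem arrays,
unequal branch lengths within the default balanced tree, gene-conversion
homogenisation, and assembly errors. Passing tests therefore demonstrate
algorithmic correctness and statistical calibration on clean rearrangement
histories, not robustness to annotation noise in real genomes.

## Problem sizes used in the tests

The test and acceptance runs use simulations of ~500–1000 genes over 6
leaves (identity recovery: 9 × 60 genes, 10 matching samples; parameter
recovery: ~1000 genes, 20 samples, 3 seeds × x_true ∈ {7, 9, 11}), chosen
so the full suite runs on one CPU in minutes while exercising every stage
at its defaults (gap_max 7, g 20, B 50, k_max 20, fit window 12–20,
top-10/≥2 sample selection).

Two regimes deserve honesty about what they show. At ~1000 genes each
ancestral chromosome yields only ~5 clustering units, so the gap curve is
noisy and the increment rule's resolution is limited; recovery of x to ±1
is reliable at x_true = 9 but degrades toward x_true = 11 (too few units
per block) and, in the other direction, internal-branch translocations
create genuine derived co-occurrence blocks that the rule may count on top
of the ancestral ones. The second effect follows from the simulator's
geometry: translocation cut points are uniform, so exchanged tails average
half a chromosome, and a single such event on an internal branch leaves a
large block that co-occurs one way in half the leaves and the other way in
the rest — real cluster structure by any measure, and scale-independent (we
verified it persists at ~3000 genes). Averaging gap profiles over several g
values (`g_sweep`) smooths sample noise but cannot remove such blocks.
These are identifiability ceilings of chromosome-number inference whenever
large shared rearrangements are frequent relative to chromosome count, not
implementation defects.

## Known limitations

* The adjacency weight (support count + 0.5 outgroup bonus) is a documented
  substitute for the original pipeline's weighting, which is not restated
  in full anywhere we could implement from.
* "Taking account of ordering" enters only through anchors for contig
  ordering, not the co-occurrence counts themselves.
* The LOP instance (precedence counts) is reconstructed from anchors;
  normalisation variants are possible.
* Estimates of x inherit the ±2-style uncertainty of inflection detection
  on noisy gap curves; the reported slope/intercept and increments allow
  re-reading the decision.
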
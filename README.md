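# karyorec

Reconstruction of ancestral **monoploid karyotypes** — gene content, gene
order and the basic chromosome number *x* — for every internal node of a
species phylogeny, from the chromosomal gene orders of extant genomes.

The package is aimed at comparative genomicists studying clades (a plant
order, an animal subkingdom) with several annotated chromosome-level
genomes. It takes per-genome gene coordinates (GFF3), a gene→family map (or
raw homologous gene pairs from which families are built as connected
components), and a rooted binary Newick tree, and produces for each
ancestral node a set of ordered chromosomes of gene families, together with
quality statistics and chromosome "paintings" of the extant genomes.

## Method in brief

1. **Generalized adjacencies.** Two genes are adjacent if ≤ 7 retained genes
   separate them. An adjacency joins oriented gene extremities (5' *head*,
   3' *tail*). For an ancestral node, adjacencies supported on both sides of
   the node's bipartition are *phylogenetically informative*; their weight is
   the supporting-leaf count (+0.5 for outgroup corroboration).
2. **Contigs by maximum-weight matching (mwm).** A matching in the extremity
   graph selects a conflict-free, maximum-evidence set of adjacencies; with
   the implicit head–tail edges, matched components are linear ancestral
   *contigs*, each family appearing at most once (monoploidy). Because many
   matchings tie at the optimum, *n* samples (100 or 50 in full runs) are
   drawn by infinitesimal weight perturbation.
3. **g-mers and clustering.** Contigs are cut into pieces of length *g* = 20
   (*g*-mers) to remove the long-contig bias, matched against extant
   chromosomes, and clustered (complete linkage on a correlation-smoothed
   chromosomal co-occurrence matrix; dynamic-cut polishing; a PCA + Ward
   alternative for cross-checking).
4. **Gap statistic → x.** Each sample's clustering is scored over
   k = 2..20 with the gap statistic, gap(k) = E[log W*_k] − log W_k; the
   best samples are retained (top-10 gap values for ≥ 2 of k = 4..10); a
   line fitted to the increments Δ(k) on k = 12..20 models overfitting
   noise, and **x is the largest k below the window whose increment exceeds
   the line significantly**. Averaging profiles over several g values
   stabilises the trend (`g_sweep`).
5. **Chromosomes.** At the chosen x, contigs follow the majority cluster of
   their g-mers and are ordered along each chromosome by a Linear Ordering
   Problem on observed anchor precedences (exact for ≤ 8 contigs).
   Evaluation reports *coherence*, *coverage* and *choppiness* (> 300 kb
   painted segments).

A full account, with all parameters and their defaults, is in
[docs/methods.md](docs/methods.md).

## Worked example

Simulate a 6-genome clade descending unchanged from a 9-chromosome,
540-gene monoploid ancestor, then reconstruct it:

```sh
karyorec simulate --out sim --x-true 9 --genes-per-chromosome 60 \
    --leaves 6 --seed 1
karyorec run-all --genomes sim --tree sim/tree.nwk --out run \
    --samples 10 --seed 1
```

which prints (abridged):

```
INFO karyorec: 6 genomes, 540 families after filtering, 5 ancestors
Ancestor 1: x=9, coverage=540 families
Ancestor 2: x=9, coverage=540 families
...
```

`x=9` is the estimated basic chromosome number (correct by construction
here), and `coverage=540` says every gene family was placed. The run
directory contains, per ancestor, the sampled contigs
(`contigs_A1.tsv`), gap profiles (`gap_profiles_A1.tsv`), the karyotype
(`karyotype_A1.tsv`: chromosome, position, signed family), a BED9 painting
of every extant genome in ancestral colours (`painting_A1.bed`), and
`quality.tsv` with per-descendant coherence (1.0 here), coverage and
choppiness (9 segments per genome — one block per conserved chromosome).
With rearrangements in the history the same pipeline yields noisier
clusters, and the gap-statistic machinery (sample selection, g-averaging,
the significance margin on increments) is what keeps the x estimate stable.

Individual stages (`adjacencies`, `contigs`, `gapstat`, `cluster`,
`assemble`, `evaluate`) re-run from the cached artifacts of earlier stages,
and everything is reproducible from one seed.

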
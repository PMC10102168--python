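"""Generalized (gapped) gene adjacencies and their phylogenetic filtering.

Two genes on a chromosome are *generalized-adjacent* when at most ``gap_max``
retained genes lie between them (default 7).  An adjacency joins two gene
*extremities*: the 5' end (head) or 3' end (tail) of a family's oriented gene.
For a pair of genes (i, j) with i left of j, the adjacency joins the
right-facing extremity of i (tail on '+', head on '-') to the left-facing
extremity of j (head on '+', tail on '-').

For each ancestral node of the phylogeny, an adjacency is *phylogenetically
informative* when it is observed in at least one leaf genome of each of the
node's two child subtrees — evidence that it predates the split.  Its weight
is the number of supporting leaves below the node, plus 0.5 when at least one
genome outside the subtree also carries it (outgroup corroboration, used as a
tie-break).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .genome_io import Genome, Phylogeny

HEAD = "head"  # 5' extremity
TAIL = "tail"  # 3' extremity

Extremity = tuple[str, str]  # (family_id, HEAD|TAIL)


def right_extremity(family_id: str, strand: str) -> Extremity:
    return (family_id, TAIL if strand == "+" else HEAD)


def left_extremity(family_id: str, strand: str) -> Extremity:
    return (family_id, HEAD if strand == "+" else TAIL)


def adjacency_key(ea: Extremity, eb: Extremity) -> tuple[Extremity, Extremity]:
    """Canonical unordered representation of an extremity pair."""
    return (ea, eb) if ea <= eb else (eb, ea)


@dataclass
class GeneralizedAdjacency:
    ext_a: Extremity
    ext_b: Extremity
    min_gap: int
    support: set[str] = field(default_factory=set)
    weight: float = 0.0

    @property
    def key(self) -> tuple[Extremity, Extremity]:
        return adjacency_key(self.ext_a, self.ext_b)


@dataclass
class NodeAdjacencySet:
    ancestor_id: int
    adjacencies: list[GeneralizedAdjacency] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.adjacencies)


def extract_adjacencies(genome: Genome, gap_max: int = 7) -> dict[
        tuple[Extremity, Extremity], int]:
    """All gapped adjacencies of one genome: canonical extremity pair -> min gap.

    Gaps count retained (family-filtered) genes only, so the genome should be
    restricted to the filtered family set first.  Pairs whose two genes belong
    to the same family are skipped: they cannot contribute to a monoploid
    linear reconstruction.
    """
    out: dict[tuple[Extremity, Extremity], int] = {}
    for genes in genome.chromosomes.values():
        n = len(genes)
        for i in range(n):
            gi = genes[i]
            for j in range(i + 1, min(n, i + gap_max + 2)):
                gj = genes[j]
                if gi.family_id == gj.family_id:
                    continue
                key = adjacency_key(right_extremity(gi.family_id, gi.strand),
                                    left_extremity(gj.family_id, gj.strand))
                gap = j - i - 1
                if key not in out or gap < out[key]:
                    out[key] = gap
    return out


def extract_all(genomes: Mapping[str, Genome], gap_max: int = 7) -> dict[
        str, dict[tuple[Extremity, Extremity], int]]:
    return {name: extract_adjacencies(g, gap_max) for name, g in genomes.items()}


def informative_adjacencies(
    leaf_adjacencies: Mapping[str, Mapping[tuple[Extremity, Extremity], int]],
    phylogeny: Phylogeny,
    ancestor_id: int,
) -> NodeAdjacencySet:
    """Adjacencies informative for one ancestral node, with weights.

    ``leaf_adjacencies`` maps genome name -> extract_adjacencies output.
    """
    if ancestor_id not in phylogeny.ancestors:
        raise ValueError(f"unknown ancestor id {ancestor_id} (leaves have none)")
    left, right = phylogeny.child_leaf_sets(ancestor_id)
    subtree = left | right
    outside = set(leaf_adjacencies) - subtree

    keys: set = set()
    for name in subtree:
        keys.update(leaf_adjacencies[name].keys())

    node_set = NodeAdjacencySet(ancestor_id)
    for key in sorted(keys):
        support = {name for name in leaf_adjacencies
                   if key in leaf_adjacencies[name]}
        if not (support & left and support & right):
            continue
        weight = float(len(support & subtree))
        if support & outside:
            weight += 0.5
        min_gap = min(leaf_adjacencies[name][key] for name in support)
        node_set.adjacencies.append(
            GeneralizedAdjacency(key[0], key[1], min_gap, support, weight)
        )
    return node_set


def dump_adjacencies(node_sets: Iterable[NodeAdjacencySet], path) -> None:
    """Write adjacency sets as TSV."""
    with open(path, "w") as fh:
        fh.write("ancestor_id\tfamily_a\tend_a\tfamily_b\tend_b\t"
                 "min_gap\tweight\tsupport\n")
        for ns in node_sets:
            for adj in ns.adjacencies:
                fh.write(
                    f"{ns.ancestor_id}\t{adj.ext_a[0]}\t{adj.ext_a[1]}\t"
                    f"{adj.ext_b[0]}\t{adj.ext_b[1]}\t{adj.min_gap}\t"
                    f"{adj.weight}\t{','.join(sorted(adj.support))}\n"
                )
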
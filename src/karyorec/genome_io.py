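"""Genome, gene-family and phylogeny input/output.

The data model is deliberately small: a genome is a set of chromosomes, each an
ordered list of oriented genes labelled with a gene-family identifier.  All
downstream reconstruction works on family labels, not sequences — "gene" is
used in the broad sense of a family of homologous genes across the input
genomes.

External formats:

* GFF3 with ``gene`` features carrying a mandatory ``ID`` attribute;
* family map TSV: ``gene_id<TAB>family_id``;
* homologous-pair TSV (SynMap-style): ``gene_id<TAB>gene_id``, from which
  families are built as connected components;
* rooted binary Newick trees whose leaf labels are the genome names.

Coordinates are 1-based inclusive externally (GFF convention); the order index
of a gene within its chromosome is the 0-based rank by start coordinate.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import dendropy

logger = logging.getLogger(__name__)

STRANDS = ("+", "-")


@dataclass(frozen=True)
class Gene:
    """An oriented, family-labelled gene on a chromosome."""

    gene_id: str
    family_id: str
    chromosome_id: str
    start_bp: int
    end_bp: int
    strand: str

    def __post_init__(self) -> None:
        if self.start_bp < 1 or self.end_bp < self.start_bp:
            raise ValueError(
                f"gene {self.gene_id}: invalid coordinates "
                f"[{self.start_bp}, {self.end_bp}]"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"gene {self.gene_id}: unknown strand {self.strand!r}")


@dataclass
class Genome:
    """A named genome: chromosome_id -> genes sorted by start coordinate."""

    name: str
    chromosomes: dict[str, list[Gene]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for chrom, genes in self.chromosomes.items():
            genes.sort(key=lambda g: g.start_bp)
            starts = [g.start_bp for g in genes]
            if len(set(starts)) != len(starts):
                raise ValueError(f"{self.name}/{chrom}: duplicate start coordinates")
            for g in genes:
                if g.gene_id in seen:
                    raise ValueError(f"{self.name}: duplicate gene_id {g.gene_id}")
                seen.add(g.gene_id)

    @property
    def n_genes(self) -> int:
        return sum(len(v) for v in self.chromosomes.values())

    def genes(self) -> Iterable[Gene]:
        for genes in self.chromosomes.values():
            yield from genes

    def families(self) -> set[str]:
        return {g.family_id for g in self.genes()}

    def restrict_to_families(self, keep: set[str]) -> "Genome":
        """Copy of the genome containing only genes whose family is in ``keep``."""
        chroms = {
            c: [g for g in genes if g.family_id in keep]
            for c, genes in self.chromosomes.items()
        }
        return Genome(self.name, {c: gs for c, gs in chroms.items() if gs})


@dataclass
class GeneFamilyTable:
    """family_id -> genome name -> member gene ids."""

    members: dict[str, dict[str, list[str]]] = field(default_factory=dict)
    n_dropped_size: int = 0
    n_dropped_single_genome: int = 0

    def family_ids(self) -> set[str]:
        return set(self.members)

    def genomes_of(self, family_id: str) -> set[str]:
        return set(self.members[family_id])

    def __len__(self) -> int:
        return len(self.members)


# ---------------------------------------------------------------------------
# GFF3 + family map reading/writing
# ---------------------------------------------------------------------------

def _parse_gff_attributes(attr: str) -> dict[str, str]:
    out = {}
    for part in attr.strip().split(";"):
        if not part:
            continue
        key, _, val = part.partition("=")
        out[key.strip()] = val.strip()
    return out


def read_genome(gff_path: str | Path, family_map_path: str | Path,
                name: str | None = None) -> Genome:
    """Read a genome from a gene-feature GFF3 plus a gene→family TSV.

    Genes without a family assignment are dropped (count logged).  Duplicate
    gene ids and unknown strands are errors.
    """
    gff_path = Path(gff_path)
    fam: dict[str, str] = {}
    with open(family_map_path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            gid, fid = line.split("\t")[:2]
            fam[gid] = fid

    chroms: dict[str, list[Gene]] = {}
    seen: set[str] = set()
    n_unassigned = 0
    with open(gff_path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise ValueError(f"{gff_path}: malformed GFF3 line: {line!r}")
            seqid, _, ftype, start, end, _, strand, _, attrs = fields[:9]
            if ftype != "gene":
                continue
            gid = _parse_gff_attributes(attrs).get("ID")
            if gid is None:
                raise ValueError(f"{gff_path}: gene feature without ID attribute")
            if gid in seen:
                raise ValueError(f"{gff_path}: duplicate gene id {gid}")
            seen.add(gid)
            if gid not in fam:
                n_unassigned += 1
                continue
            chroms.setdefault(seqid, []).append(
                Gene(gid, fam[gid], seqid, int(start), int(end), strand)
            )
    if n_unassigned:
        logger.warning("%s: dropped %d genes with no family assignment",
                       gff_path.name, n_unassigned)
    return Genome(name or gff_path.stem, chroms)


def write_genome(genome: Genome, gff_path: str | Path,
                 family_map_path: str | Path | None = None) -> None:
    """Write a genome back out as gene-feature GFF3 (+ optional family TSV)."""
    with open(gff_path, "w") as fh:
        fh.write("##gff-version 3\n")
        for chrom in sorted(genome.chromosomes):
            for g in genome.chromosomes[chrom]:
                fh.write(
                    f"{chrom}\tkaryorec\tgene\t{g.start_bp}\t{g.end_bp}\t."
                    f"\t{g.strand}\t.\tID={g.gene_id}\n"
                )
    if family_map_path is not None:
        with open(family_map_path, "w") as fh:
            for g in sorted(genome.genes(), key=lambda g: g.gene_id):
                fh.write(f"{g.gene_id}\t{g.family_id}\n")


# ---------------------------------------------------------------------------
# Gene families
# ---------------------------------------------------------------------------

def build_families_from_pairs(pair_tsv: str | Path,
                              genomes: Mapping[str, Genome]) -> GeneFamilyTable:
    """Build gene families as connected components of a homologous-pair graph.

    ``pair_tsv`` holds syntenically validated homologous gene pairs, two gene
    ids per line (orthologs between genomes, paralogs within one).  Self-pairs
    are ignored with a warning.  The resulting components are named
    ``F000001`` ... in order of their smallest member gene id.
    """
    import networkx as nx

    graph: nx.Graph = nx.Graph()
    with open(pair_tsv) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            a, b = line.split("\t")[:2]
            if a == b:
                logger.warning("ignoring self-pair %s", a)
                continue
            graph.add_edge(a, b)

    gene_owner = {g.gene_id: gname
                  for gname, genome in genomes.items() for g in genome.genes()}

    components = sorted((sorted(c) for c in nx.connected_components(graph)),
                        key=lambda c: c[0])
    table = GeneFamilyTable()
    for i, comp in enumerate(components, start=1):
        fid = f"F{i:06d}"
        per_genome: dict[str, list[str]] = {}
        for gid in comp:
            owner = gene_owner.get(gid)
            if owner is None:
                continue
            per_genome.setdefault(owner, []).append(gid)
        if per_genome:
            table.members[fid] = per_genome
    return table


def families_from_map(genomes: Mapping[str, Genome]) -> GeneFamilyTable:
    """Collect a family table from the family labels already on the genes."""
    table = GeneFamilyTable()
    for gname, genome in genomes.items():
        for g in genome.genes():
            table.members.setdefault(g.family_id, {}).setdefault(gname, []).append(
                g.gene_id
            )
    return table


def filter_families(table: GeneFamilyTable,
                    max_family_size: int = 10) -> GeneFamilyTable:
    """Keep small, phylogenetically informative families.

    Drops families with more than ``max_family_size`` members in any single
    genome (large families carry too much homology ambiguity) and families
    present in fewer than two genomes (they can never support an adjacency
    shared across an ancestral node).  Idempotent.
    """
    out = GeneFamilyTable()
    for fid, per_genome in table.members.items():
        if any(len(v) > max_family_size for v in per_genome.values()):
            out.n_dropped_size += 1
            continue
        if len(per_genome) < 2:
            out.n_dropped_single_genome += 1
            continue
        out.members[fid] = {g: list(v) for g, v in per_genome.items()}
    if out.n_dropped_size or out.n_dropped_single_genome:
        logger.info("filter_families: dropped %d oversized, %d single-genome",
                    out.n_dropped_size, out.n_dropped_single_genome)
    return out


# ---------------------------------------------------------------------------
# Phylogeny
# ---------------------------------------------------------------------------

@dataclass
class Phylogeny:
    """A rooted binary tree over the input genomes.

    Internal nodes are numbered ``Ancestor 1 .. A`` in preorder from the root
    (the root is Ancestor 1); the numbering is emitted alongside any output so
    it can be matched to published figures, whose numbering is arbitrary.
    """

    tree: dendropy.Tree
    ancestors: dict[int, dendropy.Node] = field(default_factory=dict)

    @property
    def n_ancestors(self) -> int:
        return len(self.ancestors)

    def leaves(self, ancestor_id: int) -> set[str]:
        node = self.ancestors[ancestor_id]
        return {lf.taxon.label for lf in node.leaf_iter()}

    def child_leaf_sets(self, ancestor_id: int) -> tuple[set[str], set[str]]:
        node = self.ancestors[ancestor_id]
        left, right = node.child_nodes()
        return ({lf.taxon.label for lf in left.leaf_iter()},
                {lf.taxon.label for lf in right.leaf_iter()})

    def all_leaves(self) -> set[str]:
        return {lf.taxon.label for lf in self.tree.leaf_node_iter()}

    def ancestor_table(self) -> list[tuple[int, str]]:
        """(ancestor_id, comma-joined sorted leaf labels) for reporting."""
        return [(aid, ",".join(sorted(self.leaves(aid))))
                for aid in sorted(self.ancestors)]


def read_phylogeny(newick: str | Path, genome_names: Iterable[str]) -> Phylogeny:
    """Read a rooted binary Newick tree and check its leaves against genomes.

    Non-binary internal nodes are rejected: each reconstruction depends on the
    bipartition at its node, so trees must arrive fully resolved.
    """
    newick = str(newick)
    if Path(newick).exists():
        tree = dendropy.Tree.get(path=newick, schema="newick")
    else:
        tree = dendropy.Tree.get(data=newick, schema="newick")
    tree.is_rooted = True

    leaf_labels = {lf.taxon.label for lf in tree.leaf_node_iter()}
    names = set(genome_names)
    if leaf_labels != names:
        missing = sorted(names - leaf_labels)
        extra = sorted(leaf_labels - names)
        raise ValueError(
            f"tree leaves do not match genomes; missing from tree: {missing}, "
            f"not a genome: {extra}"
        )

    phylo = Phylogeny(tree)
    aid = 0
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            continue
        nchild = len(node.child_nodes())
        if nchild != 2:
            raise ValueError(
                f"internal node with {nchild} children; only binary trees are "
                "accepted — resolve polytomies before input"
            )
        aid += 1
        node.label = f"Ancestor {aid}"
        phylo.ancestors[aid] = node
    return phylo


def filtered_genomes(genomes: Mapping[str, Genome],
                     table: GeneFamilyTable) -> dict[str, Genome]:
    """Restrict every genome to the families retained in ``table``."""
    keep = table.family_ids()
    return {name: g.restrict_to_families(keep) for name, g in genomes.items()}
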
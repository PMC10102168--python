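"""Genome evolution simulator providing ground truth for the pipeline.

A monoploid root genome of ``x_true`` chromosomes of unique single-copy gene
families evolves along a rooted tree.  On each branch, event counts are drawn
Poisson(rate × branch length) per event type and applied in random order:

* inversion — a uniform random segment of one chromosome is reversed with
  sign flips;
* reciprocal translocation — internal cut points on two chromosomes, tails
  exchanged;
* fusion / fission — chromosomes joined or split;
* gene duplication — a gene copied to a random position (family size capped
  at 10, matching the pipeline's family filter);
* gene loss — a random gene deleted.

Branches can additionally carry a whole-genome duplication: every chromosome
is doubled, then fractionation deletes one member of each duplicate pair with
probability 1 − ``fractionation_retention`` (the survivor chosen uniformly).

Base-pair coordinates are synthesised last from lognormal gene-length and
intergenic-spacing distributions (≈3 kb genes, ≈10 kb spacing), so painting
and choppiness — which need > 300 kb spans — are exercised realistically.
The same seed always reproduces byte-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np

from .genome_io import Gene, Genome

SignedGene = tuple[str, int]  # (family_id, +1|-1)
SimGenome = list[list[SignedGene]]  # chromosomes of signed families

EVENT_TYPES = ("inversion", "translocation", "fusion", "fission",
               "duplication", "loss")


@dataclass
class SimConfig:
    x_true: int = 9
    genes_per_chromosome: int = 60
    tree_newick: str | None = None      # default: balanced tree over n_leaves
    n_leaves: int = 6
    branch_length: float = 1.0          # used by the default balanced tree
    inversion_rate: float = 0.0
    translocation_rate: float = 0.0
    fusion_rate: float = 0.0
    fission_rate: float = 0.0
    duplication_rate: float = 0.0
    loss_rate: float = 0.0
    wgd_branches: frozenset[str] = frozenset()
    fractionation_retention: float = 0.2
    max_family_size: int = 10
    gene_len_meanlog: float = math.log(3000.0)
    gene_len_sdlog: float = 0.4
    spacing_meanlog: float = math.log(10000.0)
    spacing_sdlog: float = 0.6
    unannotated_fraction: float = 0.0   # genes emitted without a family label
    seed: int = 0

    def rate(self, event: str) -> float:
        return getattr(self, f"{event}_rate")


@dataclass
class SimTruth:
    """Genomes at every node, the per-branch event log, and the family map."""

    config: SimConfig
    node_genomes: dict[str, SimGenome] = field(default_factory=dict)
    ancestor_ids: dict[str, int] = field(default_factory=dict)  # node -> id
    event_log: list[tuple[str, str, dict]] = field(default_factory=list)
    tree_newick: str = ""

    def genome_of(self, node: str | int) -> SimGenome:
        if isinstance(node, int):
            rev = {v: k for k, v in self.ancestor_ids.items()}
            if node not in rev:
                raise KeyError(f"unknown ancestor id {node}")
            node = rev[node]
        if node not in self.node_genomes:
            raise KeyError(f"unknown node {node}")
        return self.node_genomes[node]

    def event_counts(self, branch: str) -> dict[str, int]:
        counts = {e: 0 for e in EVENT_TYPES}
        for br, ev, _ in self.event_log:
            if br == branch and ev in counts:
                counts[ev] += 1
        return counts


def balanced_newick(n_leaves: int, branch_length: float = 1.0) -> str:
    """A caterpillar-free, roughly balanced binary tree over L1..Ln."""
    labels = [f"L{i + 1}" for i in range(n_leaves)]

    def build(lo: int, hi: int) -> str:
        if hi - lo == 1:
            return f"{labels[lo]}:{branch_length}"
        mid = (lo + hi + 1) // 2
        return f"({build(lo, mid)},{build(mid, hi)}):{branch_length}"

    inner = build(0, n_leaves)
    # strip the root's own branch length
    return inner.rsplit(":", 1)[0] + ";"


def _root_genome(config: SimConfig) -> SimGenome:
    fid = 0
    genome: SimGenome = []
    for _ in range(config.x_true):
        chrom = []
        for _ in range(config.genes_per_chromosome):
            fid += 1
            chrom.append((f"F{fid:05d}", +1))
        genome.append(chrom)
    return genome


def _copy(genome: SimGenome) -> SimGenome:
    return [list(ch) for ch in genome]


def _pick_gene(genome: SimGenome, rng: np.random.Generator) -> tuple[int, int]:
    sizes = np.array([len(ch) for ch in genome])
    flat = int(rng.integers(0, sizes.sum()))
    for ci, s in enumerate(sizes):
        if flat < s:
            return ci, flat
        flat -= s
    raise AssertionError


def _apply_event(genome: SimGenome, event: str, rng: np.random.Generator,
                 config: SimConfig) -> dict:
    if event == "inversion":
        ci, _ = _pick_gene(genome, rng)
        n = len(genome[ci])
        i, j = sorted(rng.integers(0, n, size=2))
        genome[ci][i:j + 1] = [(f, -s) for f, s in reversed(genome[ci][i:j + 1])]
        return {"chrom": ci, "span": (int(i), int(j))}
    if event == "translocation":
        eligible = [i for i, ch in enumerate(genome) if len(ch) >= 2]
        if len(eligible) < 2:
            return {"skipped": True}
        ca, cb = rng.choice(eligible, size=2, replace=False)
        pa = int(rng.integers(1, len(genome[ca])))
        pb = int(rng.integers(1, len(genome[cb])))
        ta, tb = genome[ca][pa:], genome[cb][pb:]
        genome[ca] = genome[ca][:pa] + tb
        genome[cb] = genome[cb][:pb] + ta
        return {"chroms": (int(ca), int(cb)), "cuts": (pa, pb)}
    if event == "fusion":
        if len(genome) < 2:
            return {"skipped": True}
        ca, cb = rng.choice(len(genome), size=2, replace=False)
        tail = genome[cb]
        if rng.random() < 0.5:
            tail = [(f, -s) for f, s in reversed(tail)]
        genome[int(ca)] = genome[int(ca)] + tail
        del genome[int(cb)]
        return {"chroms": (int(ca), int(cb))}
    if event == "fission":
        eligible = [i for i, ch in enumerate(genome) if len(ch) >= 2]
        if not eligible:
            return {"skipped": True}
        ci = int(rng.choice(eligible))
        pos = int(rng.integers(1, len(genome[ci])))
        genome.append(genome[ci][pos:])
        genome[ci] = genome[ci][:pos]
        return {"chrom": ci, "cut": pos}
    if event == "duplication":
        ci, gi = _pick_gene(genome, rng)
        fam, sign = genome[ci][gi]
        count = sum(1 for ch in genome for f, _ in ch if f == fam)
        if count >= config.max_family_size:
            return {"skipped": True, "family": fam}
        cj, _ = _pick_gene(genome, rng)
        pos = int(rng.integers(0, len(genome[cj]) + 1))
        genome[cj].insert(pos, (fam, int(rng.choice([-1, 1]))))
        return {"family": fam, "to": (int(cj), pos)}
    if event == "loss":
        ci, gi = _pick_gene(genome, rng)
        fam = genome[ci][gi][0]
        del genome[ci][gi]
        if not genome[ci] and len(genome) > 1:
            del genome[ci]
        return {"family": fam, "chrom": ci}
    raise ValueError(f"unknown event {event}")


def _apply_wgd(genome: SimGenome, rng: np.random.Generator,
               config: SimConfig) -> None:
    doubled = _copy(genome) + _copy(genome)
    n = len(genome)
    n_genes = sum(len(ch) for ch in genome)
    # per original gene decide the fate of its duplicate pair
    keep_both = rng.random(n_genes) < config.fractionation_retention
    keep_first = rng.integers(0, 2, size=n_genes)  # survivor if not both
    drop_a: list[set[int]] = [set() for _ in range(n)]
    drop_b: list[set[int]] = [set() for _ in range(n)]
    gidx = 0
    for ci in range(n):
        for gi in range(len(genome[ci])):
            if not keep_both[gidx]:
                (drop_b if keep_first[gidx] else drop_a)[ci].add(gi)
            gidx += 1
    for ci in range(n):
        doubled[ci] = [g for i, g in enumerate(doubled[ci])
                       if i not in drop_a[ci]]
        doubled[n + ci] = [g for i, g in enumerate(doubled[n + ci])
                           if i not in drop_b[ci]]
    genome[:] = [ch for ch in doubled if ch]


def simulate(config: SimConfig) -> SimTruth:
    """Evolve the root genome down the tree; returns full ground truth."""
    if config.x_true < 1:
        raise ValueError("x_true must be >= 1")
    if not 0.0 <= config.fractionation_retention <= 1.0:
        raise ValueError("fractionation_retention must be in [0, 1]")
    newick = config.tree_newick or balanced_newick(config.n_leaves,
                                                   config.branch_length)
    tree = dendropy.Tree.get(data=newick, schema="newick")
    tree.is_rooted = True

    truth = SimTruth(config, tree_newick=newick)
    ss = np.random.SeedSequence(config.seed)

    # name nodes: leaves keep labels, internal nodes get Ancestor ids preorder
    aid = 0
    node_name: dict[dendropy.Node, str] = {}
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            node_name[node] = node.taxon.label
        else:
            aid += 1
            name = f"A{aid}"
            node_name[node] = name
            truth.ancestor_ids[name] = aid

    preorder = list(tree.preorder_node_iter())
    streams = ss.spawn(len(preorder))
    root = preorder[0]
    truth.node_genomes[node_name[root]] = _root_genome(config)

    for node, sub in zip(preorder, streams):
        if node is root:
            continue
        rng = np.random.default_rng(sub)
        parent = truth.node_genomes[node_name[node.parent_node]]
        genome = _copy(parent)
        branch = node_name[node]
        t = node.edge.length if node.edge.length is not None else 1.0

        if branch in config.wgd_branches:
            _apply_wgd(genome, rng, config)
            truth.event_log.append((branch, "wgd", {}))

        events: list[str] = []
        for ev in EVENT_TYPES:
            lam = config.rate(ev) * t
            if lam > 0:
                events.extend([ev] * int(rng.poisson(lam)))
        rng.shuffle(events)
        for ev in events:
            detail = _apply_event(genome, ev, rng, config)
            truth.event_log.append((branch, ev, detail))
        truth.node_genomes[branch] = genome
    return truth


def _assign_coordinates(name: str, sim_genome: SimGenome,
                        rng: np.random.Generator, config: SimConfig) -> Genome:
    chroms: dict[str, list[Gene]] = {}
    gid = 0
    for ci, chrom in enumerate(sim_genome):
        genes: list[Gene] = []
        pos = 1
        for fam, sign in chrom:
            length = max(200, int(rng.lognormal(config.gene_len_meanlog,
                                                config.gene_len_sdlog)))
            gap = max(50, int(rng.lognormal(config.spacing_meanlog,
                                            config.spacing_sdlog)))
            gid += 1
            genes.append(Gene(f"{name}_g{gid:05d}", fam, f"chr{ci + 1}",
                              pos, pos + length - 1, "+" if sign > 0 else "-"))
            pos += length + gap
        chroms[f"chr{ci + 1}"] = genes
    return Genome(name, chroms)


def leaf_genomes(truth: SimTruth) -> dict[str, Genome]:
    """Leaf genomes with synthesised bp coordinates (deterministic)."""
    config = truth.config
    ss = np.random.SeedSequence((config.seed, 0xC00D))
    leaves = sorted(n for n in truth.node_genomes if not n.startswith("A"))
    out = {}
    for name, sub in zip(leaves, ss.spawn(len(leaves))):
        rng = np.random.default_rng(sub)
        out[name] = _assign_coordinates(name, truth.node_genomes[name],
                                        rng, config)
    return out


def truth_labels(truth: SimTruth, node: str | int) -> dict[str, int]:
    """family -> true chromosome index at a node (first occurrence wins)."""
    genome = truth.genome_of(node)
    labels: dict[str, int] = {}
    for ci, chrom in enumerate(genome):
        for fam, _ in chrom:
            labels.setdefault(fam, ci)
    return labels


def write_inputs(truth: SimTruth, outdir: str | Path) -> dict[str, Path]:
    """Emit the pipeline's input files: per-leaf GFF3 + family TSV, Newick,
    and truth files (per-node orders, event log)."""
    from .genome_io import write_genome

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    config = truth.config
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 0xFA)))
    for name, genome in leaf_genomes(truth).items():
        gff = outdir / f"{name}.gff3"
        fam = outdir / f"{name}.families.tsv"
        write_genome(genome, gff, None)
        with open(fam, "w") as fh:
            for g in sorted(genome.genes(), key=lambda g: g.gene_id):
                if (config.unannotated_fraction > 0
                        and rng.random() < config.unannotated_fraction):
                    continue
                fh.write(f"{g.gene_id}\t{g.family_id}\n")
        paths[name] = gff
    tree_path = outdir / "tree.nwk"
    tree_path.write_text(truth.tree_newick + "\n")
    paths["tree"] = tree_path
    with open(outdir / "truth_events.tsv", "w") as fh:
        fh.write("branch\tevent\tdetail\n")
        for br, ev, detail in truth.event_log:
            fh.write(f"{br}\t{ev}\t{detail}\n")
    with open(outdir / "truth_orders.tsv", "w") as fh:
        fh.write("node\tchromosome\tposition\tsigned_family\n")
        for node in sorted(truth.node_genomes):
            for ci, chrom in enumerate(truth.node_genomes[node]):
                for pos, (fam, sign) in enumerate(chrom):
                    fh.write(f"{node}\t{ci}\t{pos}\t"
                             f"{'+' if sign > 0 else '-'}{fam}\n")
    return paths
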
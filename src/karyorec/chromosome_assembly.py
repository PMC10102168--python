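"""From unit clusters to ordered ancestral chromosomes.

Each cluster of units defines the contig content of one ancestral chromosome
(a contig follows the majority cluster of its g-mers).  Contigs are then laid
along the chromosome by a Linear Ordering Problem: P[i, j] counts the
(genome, chromosome) occurrences where contig i's anchor precedes contig j's,
and we seek the permutation maximising the sum of precedence counts it
respects.  LOP is NP-hard; instances here are small, so exhaustive search is
used up to n = 8 and a greedy-plus-local-search heuristic above that.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import permutations

import numpy as np

from .contig_assembly import Contig
from .genome_io import Genome
from .gmer_clustering import Gmer, match_unit_to_chromosomes

logger = logging.getLogger(__name__)


@dataclass
class AncestorKaryotype:
    ancestor_id: int
    chromosomes: list[list[Contig]]
    sample_index: int = -1
    g: int = 0
    k: int = 0

    @property
    def x(self) -> int:
        return len(self.chromosomes)

    def chromosome_families(self, i: int) -> list[tuple[str, int]]:
        return [fam for contig in self.chromosomes[i] for fam in contig.families]

    def family_to_chromosome(self) -> dict[str, int]:
        return {f: i for i in range(self.x)
                for f, _ in self.chromosome_families(i)}

    @property
    def n_families(self) -> int:
        return sum(len(c) for chrom in self.chromosomes for c in chrom)


def units_to_contig_clusters(units: list[Gmer],
                             labels: np.ndarray) -> dict[int, int]:
    """Assign each contig the majority cluster of its g-mers.

    Ties go to the cluster of the contig's first g-mer.
    """
    by_contig: dict[int, list[tuple[int, int]]] = {}
    for unit, lab in zip(units, labels):
        by_contig.setdefault(unit.contig_id, []).append((unit.start, int(lab)))
    out: dict[int, int] = {}
    for cid, pairs in by_contig.items():
        pairs.sort()
        votes: dict[int, int] = {}
        for _, lab in pairs:
            votes[lab] = votes.get(lab, 0) + 1
        best = max(votes.values())
        tied = [lab for lab, v in votes.items() if v == best]
        out[cid] = pairs[0][1] if len(tied) > 1 else tied[0]
    return out


def contig_matches(contig: Contig, genomes: dict[str, Genome], tau: float = 0.3
                   ) -> dict[tuple[str, str], float]:
    """(genome, chromosome) -> anchor for a whole contig (treated as a unit)."""
    unit = Gmer(-1, 0, list(contig.families))
    m: dict[tuple[str, str], float] = {}
    for gname, genome in genomes.items():
        for chrom, anchor in match_unit_to_chromosomes(unit, genome, tau).items():
            m[(gname, chrom)] = anchor
    return m


def precedence_counts(matches: list[dict[tuple[str, str], float]]) -> np.ndarray:
    """P[i, j] = occurrences where contig i's anchor precedes contig j's."""
    n = len(matches)
    P = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            shared = set(matches[i]) & set(matches[j])
            for key in shared:
                ai, aj = matches[i][key], matches[j][key]
                if ai < aj:
                    P[i, j] += 1
                elif aj < ai:
                    P[j, i] += 1
                else:
                    logger.debug("equal anchors for contigs %d,%d on %s", i, j, key)
    return P


def _lop_score(P: np.ndarray, order: list[int]) -> int:
    return int(sum(P[order[i], order[j]]
                   for i in range(len(order)) for j in range(i + 1, len(order))))


def lop_exact(P: np.ndarray) -> list[int]:
    """Exhaustive LOP optimum (first-found among ties); n ≤ ~9 only."""
    n = P.shape[0]
    best, best_score = list(range(n)), _lop_score(P, list(range(n)))
    for perm in permutations(range(n)):
        s = _lop_score(P, list(perm))
        if s > best_score:
            best, best_score = list(perm), s
    return best


def lop_heuristic(P: np.ndarray) -> list[int]:
    """Greedy net-score initialisation + best-improvement local search.

    Moves: pairwise swaps and single-element relocations, applied while any
    improves the score.
    """
    n = P.shape[0]
    net = P.sum(axis=1) - P.sum(axis=0)
    order = sorted(range(n), key=lambda i: (-net[i], i))
    score = _lop_score(P, order)
    improved = True
    while improved:
        improved = False
        best_gain, best_order = 0, None
        for i in range(n):
            for j in range(i + 1, n):
                cand = order.copy()
                cand[i], cand[j] = cand[j], cand[i]
                gain = _lop_score(P, cand) - score
                if gain > best_gain:
                    best_gain, best_order = gain, cand
        for i in range(n):
            for j in range(n):
                if i == j:
                    continue
                cand = order.copy()
                item = cand.pop(i)
                cand.insert(j, item)
                gain = _lop_score(P, cand) - score
                if gain > best_gain:
                    best_gain, best_order = gain, cand
        if best_order is not None:
            order, score = best_order, score + best_gain
            improved = True
    return order


def lop_order(P: np.ndarray, exact_threshold: int = 8) -> list[int]:
    """Permutation maximising respected precedences (exact for small n)."""
    n = P.shape[0]
    if n <= 1:
        return list(range(n))
    if n <= exact_threshold:
        return lop_exact(P)
    return lop_heuristic(P)


def _orientation_vote(contig: Contig,
                      genomes: dict[str, Genome], tau: float = 0.3) -> int:
    """+1 if the contig mostly runs forward along matched chromosomes, else -1.

    For every matched (genome, chromosome), the direction is the sign of the
    correlation between contig position and chromosomal position of the
    contig's families.  Ties keep the orientation as-is (+1).
    """
    if len(contig) < 2:
        return +1
    pos_in_contig = {f: i for i, (f, _) in enumerate(contig.families)}
    votes = 0
    for genome in genomes.values():
        for chrom, genes in genome.chromosomes.items():
            idx, bp = [], []
            fam_bp: dict[str, list[int]] = {}
            for gene in genes:
                if gene.family_id in pos_in_contig:
                    fam_bp.setdefault(gene.family_id, []).append(gene.start_bp)
            if len(fam_bp) < max(2.0, tau * len(contig)):
                continue
            for f, bps in fam_bp.items():
                idx.append(pos_in_contig[f])
                bp.append(float(np.median(bps)))
            if len(idx) < 2:
                continue
            r = np.corrcoef(idx, bp)[0, 1]
            if np.isnan(r) or r == 0:
                continue
            votes += 1 if r > 0 else -1
    return -1 if votes < 0 else +1


def build_karyotype(contigs: list[Contig],
                    contig_clusters: dict[int, int],
                    genomes: dict[str, Genome],
                    ancestor_id: int,
                    tau: float = 0.3,
                    sample_index: int = -1, g: int = 0) -> AncestorKaryotype:
    """Order each cluster's contigs with the LOP and emit the karyotype.

    Contigs are flipped when the majority of their matched occurrences run
    against their stored orientation.  Monoploidy (each family at most once in
    the whole karyotype) is verified.
    """
    clusters: dict[int, list[int]] = {}
    for cid, lab in contig_clusters.items():
        clusters.setdefault(lab, []).append(cid)

    chromosomes: list[list[Contig]] = []
    for lab in sorted(clusters):
        cids = sorted(clusters[lab])
        matches = [contig_matches(contigs[c], genomes, tau) for c in cids]
        P = precedence_counts(matches)
        order = lop_order(P)
        chrom: list[Contig] = []
        for idx in order:
            contig = contigs[cids[idx]]
            if _orientation_vote(contig, genomes, tau) < 0:
                contig = contig.reversed_()
            chrom.append(contig)
        chromosomes.append(chrom)

    karyo = AncestorKaryotype(ancestor_id, chromosomes, sample_index, g,
                              k=len(chromosomes))
    seen: set[str] = set()
    for i in range(karyo.x):
        for f, _ in karyo.chromosome_families(i):
            if f in seen:
                raise ValueError(f"family {f} placed twice — monoploidy violated")
            seen.add(f)
    return karyo


def dump_karyotype(karyo: AncestorKaryotype, path) -> None:
    with open(path, "w") as fh:
        fh.write("ancestor_id\tchromosome\tposition\tsigned_family\tsource_contig\n")
        for ci, chrom in enumerate(karyo.chromosomes):
            pos = 0
            for contig_idx, contig in enumerate(chrom):
                for f, s in contig.families:
                    sign = "+" if s > 0 else "-"
                    fh.write(f"{karyo.ancestor_id}\t{ci}\t{pos}\t{sign}{f}\t"
                             f"{contig_idx}\n")
                    pos += 1
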
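"""Reconstruction quality: coherence, coverage, choppiness, painting, and
cross-reconstruction comparisons.

* **Coherence** — for each descendant chromosome, the maximum proportion of
  its (ancestor-placed) gene families coming from a single ancestral
  chromosome, averaged over chromosomes; 1.0 means a clean one-to-many
  chromosome correspondence.
* **Coverage** — the number of gene families placed in the reconstruction.
* **Choppiness** — paint every extant gene with the colour of the ancestral
  chromosome holding its family, merge runs of one colour into segments, and
  count segments spanning more than 300 kb.  More rearrangement between the
  ancestor and the descendant means more, shorter segments.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from .chromosome_assembly import AncestorKaryotype
from .genome_io import Genome

logger = logging.getLogger(__name__)

# fixed palette for BED9 output (cycled when x exceeds its length)
_PALETTE = ["230,25,75", "60,180,75", "255,225,25", "0,130,200", "245,130,48",
            "145,30,180", "70,240,240", "240,50,230", "210,245,60", "128,0,0",
            "0,128,128", "170,110,40"]


@dataclass
class PaintedSegment:
    genome: str
    chromosome: str
    start_bp: int
    end_bp: int
    color: int        # ancestral chromosome index
    gene_count: int

    @property
    def span(self) -> int:
        return self.end_bp - self.start_bp + 1


def _chromosome_family_sets(obj: Genome | AncestorKaryotype) -> dict[object, set[str]]:
    if isinstance(obj, AncestorKaryotype):
        return {i: {f for f, _ in obj.chromosome_families(i)} for i in range(obj.x)}
    return {c: {g.family_id for g in genes} for c, genes in obj.chromosomes.items()}


def coherence(descendant: Genome | AncestorKaryotype,
              ancestor: AncestorKaryotype) -> float:
    """Average, over descendant chromosomes, of the largest fraction of their
    ancestor-placed families drawn from one ancestral chromosome.

    Families the ancestor does not place are excluded from the denominator;
    descendant chromosomes sharing no family with the ancestor are skipped.
    """
    anc_sets = _chromosome_family_sets(ancestor)
    placed = set().union(*anc_sets.values()) if anc_sets else set()
    vals = []
    for chrom, fams in _chromosome_family_sets(descendant).items():
        present = fams & placed
        if not present:
            logger.debug("chromosome %s shares no family with ancestor", chrom)
            continue
        best = max(len(present & a) for a in anc_sets.values())
        vals.append(best / len(present))
    return float(np.mean(vals)) if vals else float("nan")


def coverage(ancestor: AncestorKaryotype) -> int:
    """Number of gene families placed in the reconstruction."""
    return ancestor.n_families


def paint(genome: Genome, ancestor: AncestorKaryotype,
          min_segment_bp: int = 300_000) -> tuple[list[PaintedSegment], int]:
    """Colour extant genes by ancestral chromosome and merge same-colour runs.

    Genes whose family is not in the ancestor stay uncoloured and do not break
    runs.  Returns (segments, choppiness), choppiness counting only segments
    spanning strictly more than ``min_segment_bp``.
    """
    color_of = ancestor.family_to_chromosome()
    segments: list[PaintedSegment] = []
    for chrom, genes in genome.chromosomes.items():
        run_color, run_start, run_end, run_count = None, 0, 0, 0
        for gene in genes:
            col = color_of.get(gene.family_id)
            if col is None:
                continue
            if col == run_color:
                run_end, run_count = gene.end_bp, run_count + 1
            else:
                if run_color is not None:
                    segments.append(PaintedSegment(genome.name, chrom, run_start,
                                                   run_end, run_color, run_count))
                run_color, run_start, run_end, run_count = (
                    col, gene.start_bp, gene.end_bp, 1)
        if run_color is not None:
            segments.append(PaintedSegment(genome.name, chrom, run_start,
                                           run_end, run_color, run_count))
    choppiness = sum(1 for s in segments if s.span > min_segment_bp)
    return segments, choppiness


def write_bed9(segments: Iterable[PaintedSegment], path) -> None:
    """Painted segments as BED9 (0-based half-open, itemRgb per ancestral
    chromosome)."""
    with open(path, "w") as fh:
        for s in segments:
            start0, end = s.start_bp - 1, s.end_bp
            rgb = _PALETTE[s.color % len(_PALETTE)]
            fh.write(f"{s.chromosome}\t{start0}\t{end}\tanc_chr{s.color}\t"
                     f"{s.gene_count}\t.\t{start0}\t{end}\t{rgb}\n")


def _maxima_table(M: pd.DataFrame) -> pd.DataFrame:
    """Flag row maxima, column maxima and cells that are both ('green')."""
    flags = pd.DataFrame("", index=M.index, columns=M.columns)
    for a in M.index:
        row = M.loc[a]
        if row.max() > 0:
            flags.loc[a, row.idxmax()] += "R"
    for b in M.columns:
        col = M[b]
        if col.max() > 0:
            flags.loc[col.idxmax(), b] += "C"
    return flags.map(lambda v: "green" if v == "RC" else
                     ("row_max" if v == "R" else ("col_max" if v == "C" else "")))


def compare_ancestors(karyo_a: AncestorKaryotype, karyo_b: AncestorKaryotype,
                      family_links: Mapping[str, str]
                      ) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Chromosome-level correspondence of two independent reconstructions.

    ``family_links`` maps A-side family ids to B-side family ids (built from
    ortholog pairs by :func:`map_families`).  Returns (shared-count matrix,
    maxima flags, summary) where summary records families of each side without
    a placed counterpart.
    """
    b_chrom = karyo_b.family_to_chromosome()
    M = pd.DataFrame(0, index=[f"A{i}" for i in range(karyo_a.x)],
                     columns=[f"B{j}" for j in range(karyo_b.x)])
    unmatched_a = 0
    for i in range(karyo_a.x):
        for f, _ in karyo_a.chromosome_families(i):
            counterpart = family_links.get(f)
            if counterpart is None or counterpart not in b_chrom:
                unmatched_a += 1
                continue
            M.loc[f"A{i}", f"B{b_chrom[counterpart]}"] += 1
    linked_b = {v for v in family_links.values()}
    unmatched_b = sum(1 for f in b_chrom if f not in linked_b)
    if int(M.values.sum()) == 0:
        logger.warning("compare_ancestors: no mapped families")
    summary = {"unmatched_a": unmatched_a, "unmatched_b": unmatched_b,
               "n_green": int((_maxima_table(M) == "green").values.sum())}
    return M, _maxima_table(M), summary


def map_families(ortholog_pairs: Iterable[tuple[str, str]],
                 gene_to_family_a: Mapping[str, str],
                 gene_to_family_b: Mapping[str, str]) -> dict[str, str]:
    """A-family -> B-family via ortholog gene pairs, majority vote on conflict."""
    votes: dict[str, dict[str, int]] = {}
    for ga, gb in ortholog_pairs:
        fa, fb = gene_to_family_a.get(ga), gene_to_family_b.get(gb)
        if fa is None or fb is None:
            continue
        votes.setdefault(fa, {})[fb] = votes.setdefault(fa, {}).get(fb, 0) + 1
    return {fa: max(sorted(v), key=v.get) for fa, v in votes.items()}


def compare_clusterings(labels_a: np.ndarray, labels_b: np.ndarray
                        ) -> tuple[pd.DataFrame, pd.DataFrame, float]:
    """Contingency of two unit clusterings + maxima flags + adjusted Rand."""
    la, lb = np.asarray(labels_a), np.asarray(labels_b)
    M = pd.crosstab(pd.Series(la, name="hier"), pd.Series(lb, name="pca"))
    ari = float(adjusted_rand_score(la, lb))
    return M, _maxima_table(M), ari


def quality_report(ancestor: AncestorKaryotype,
                   descendants: Mapping[str, Genome],
                   g: int, min_segment_bp: int = 300_000) -> pd.DataFrame:
    """Per-descendant coherence/coverage/choppiness table for one ancestor."""
    rows = []
    for name, genome in descendants.items():
        _, chop = paint(genome, ancestor, min_segment_bp)
        rows.append({"ancestor": ancestor.ancestor_id, "g": g,
                     "sample": ancestor.sample_index, "descendant": name,
                     "coherence": coherence(genome, ancestor),
                     "coverage": coverage(ancestor), "choppiness": chop})
    return pd.DataFrame(rows)
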
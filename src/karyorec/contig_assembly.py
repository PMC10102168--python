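"""Ancestral contigs from sampled maximum-weight matchings.

The candidate adjacencies of an ancestral node form a graph whose vertices are
gene-family extremities and whose edges are weighted adjacencies.  A matching
in this graph selects a conflict-free set of adjacencies: each extremity joins
at most one neighbour, so adding the implicit intra-gene head–tail edge of
every family turns the matched components into simple paths (and occasionally
cycles) — the monoploid ancestral *contigs*, each family appearing at most
once overall.

Because very many matchings share the maximum weight, we do not report one
solution: each sample perturbs every edge weight by an i.i.d. uniform(0, δ)
jitter, δ = 1e-6 × the smallest nonzero weight, and solves the perturbed
problem exactly (networkx blossom algorithm).  The jitter is far below the
0.5 quantum of the weights, so every sample is an exact optimum of the
unperturbed problem, while the random tie-breaking explores the optimum set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .adjacencies import HEAD, TAIL, Extremity, NodeAdjacencySet, adjacency_key

Edge = tuple[Extremity, Extremity]


@dataclass
class Contig:
    """An ordered run of signed ancestral gene families."""

    families: list[tuple[str, int]]  # (family_id, +1|-1)

    def __len__(self) -> int:
        return len(self.families)

    def signed_ids(self) -> list[str]:
        return [("+" if s > 0 else "-") + f for f, s in self.families]

    def reversed_(self) -> "Contig":
        return Contig([(f, -s) for f, s in reversed(self.families)])

    def canonical(self) -> "Contig":
        rev = self.reversed_()
        return self if self.families <= rev.families else rev


@dataclass
class ContigSample:
    sample_index: int
    contigs: list[Contig]
    total_weight: float
    matched_edges: set[Edge] = field(default_factory=set)


def build_matching_graph(node_set: NodeAdjacencySet) -> nx.Graph:
    """Graph over family extremities; duplicate edges merged keeping max weight."""
    g = nx.Graph()
    for adj in node_set.adjacencies:
        a, b = adj.ext_a, adj.ext_b
        if a == b:
            continue
        g.add_node(a)
        g.add_node(b)
        if g.has_edge(a, b):
            g[a][b]["weight"] = max(g[a][b]["weight"], adj.weight)
        else:
            g.add_edge(a, b, weight=adj.weight)
    # every family contributes both extremities even if only one is used
    for fam in {v[0] for v in g.nodes}:
        g.add_node((fam, HEAD))
        g.add_node((fam, TAIL))
    return g


def _perturbed_copy(graph: nx.Graph, rng: np.random.Generator) -> nx.Graph:
    weights = [d["weight"] for _, _, d in graph.edges(data=True) if d["weight"] > 0]
    delta = 1e-6 * min(weights) if weights else 1e-6
    g = nx.Graph()
    g.add_nodes_from(graph.nodes)
    edges = sorted(graph.edges(data="weight"))  # fixed order for reproducibility
    jitter = rng.uniform(0.0, delta, size=len(edges))
    for (u, v, w), eps in zip(edges, jitter):
        g.add_edge(u, v, weight=w + eps, raw=w)
    return g


def matching_to_contigs(matching: set[Edge],
                        families: set[str],
                        perturbed_weight: dict[Edge, float] | None = None,
                        ) -> list[Contig]:
    """Convert one matching into monoploid linear contigs.

    Components of matched edges + intra-gene edges are paths or cycles; a
    cycle is linearised by deleting its minimum-(perturbed-)weight matched
    edge, sacrificing the least evidence.  Unmatched families become length-1
    contigs.  A gene traversed head→tail reads '+'.
    """
    used: set[Extremity] = set()
    partner: dict[Extremity, Extremity] = {}
    for u, v in matching:
        for e in (u, v):
            if e in used:
                raise ValueError(f"extremity {e} used twice — not a matching")
            used.add(e)
        partner[u] = v
        partner[v] = u

    def walk(start: Extremity) -> list[tuple[str, int]]:
        """Follow alternating intra-gene / matched edges from a free extremity."""
        seq = []
        ext = start
        while True:
            fam, end = ext
            seq.append((fam, +1 if end == HEAD else -1))
            other = (fam, TAIL if end == HEAD else HEAD)
            if other not in partner:
                return seq
            ext = partner[other]

    contigs: list[Contig] = []
    visited: set[str] = set()
    # paths: start from families with a free extremity
    for fam in sorted(families):
        for end in (HEAD, TAIL):
            ext = (fam, end)
            if fam in visited or ext in partner:
                continue
            seq = walk(ext)
            visited.update(f for f, _ in seq)
            contigs.append(Contig(seq).canonical())
            break

    # remaining components are cycles
    remaining = sorted(set(families) - visited)
    while remaining:
        fam = remaining[0]
        # collect the cycle's matched edges
        cycle_edges: list[Edge] = []
        ext = (fam, HEAD)
        fams_in_cycle: list[str] = []
        while True:
            f, end = ext
            fams_in_cycle.append(f)
            other = (f, TAIL if end == HEAD else HEAD)
            nxt = partner[other]
            cycle_edges.append(adjacency_key(other, nxt))
            if nxt[0] == fam and len(fams_in_cycle) >= 1 and nxt == (fam, HEAD):
                break
            ext = nxt
        wt = perturbed_weight or {}
        drop = min(cycle_edges, key=lambda e: (wt.get(e, 0.0), e))
        u, v = drop
        del partner[u]
        del partner[v]
        seq = walk(u)
        visited.update(f for f, _ in seq)
        contigs.append(Contig(seq).canonical())
        remaining = sorted(set(families) - visited)

    contigs.sort(key=lambda c: (-len(c), c.families))
    return contigs


def sample_mwm(graph: nx.Graph, n_samples: int = 100,
               seed: int | np.random.SeedSequence | None = 0) -> list[ContigSample]:
    """Sample maximum-weight matchings via seeded weight perturbation.

    Each sample draws its jitter from an independent RNG substream, solves the
    perturbed problem exactly, and reports the *unperturbed* total weight.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    streams = ss.spawn(n_samples)
    families = sorted({v[0] for v in graph.nodes})
    # matchings decompose over connected components (computed on the graph
    # plus intra-gene edges so a family's two extremities stay together);
    # solving per component is exact and much faster on large instances
    with_intra = graph.copy()
    for fam in families:
        with_intra.add_edge((fam, HEAD), (fam, TAIL))
    components = [sorted(c) for c in nx.connected_components(with_intra)]
    components.sort()
    samples = []
    for i, sub in enumerate(streams):
        rng = np.random.default_rng(sub)
        pg = _perturbed_copy(graph, rng)
        matching: set[Edge] = set()
        for comp in components:
            sub_g = pg.subgraph(comp)
            if sub_g.number_of_edges() == 0:
                continue
            matching.update(adjacency_key(u, v)
                            for u, v in nx.max_weight_matching(sub_g))
        total = sum(pg[u][v]["raw"] for u, v in matching)
        pw = {adjacency_key(u, v): d["weight"] for u, v, d in pg.edges(data=True)}
        contigs = matching_to_contigs(matching, set(families), pw)
        samples.append(ContigSample(i, contigs, total, matching))
    return samples


def sample_similarity(sample_i: ContigSample, sample_j: ContigSample) -> float:
    """Shared matched edges / size of the smaller matching (1.0 if both empty)."""
    a, b = sample_i.matched_edges, sample_j.matched_edges
    if not a and not b:
        return 1.0
    denom = min(len(a), len(b))
    if denom == 0:
        return 0.0
    return len(a & b) / denom


def dump_contigs(samples: list[ContigSample], ancestor_id: int, path) -> None:
    with open(path, "w") as fh:
        fh.write("ancestor_id\tsample_index\tcontig_id\tposition\tsigned_family\n")
        for s in samples:
            for cid, contig in enumerate(s.contigs):
                for pos, sf in enumerate(contig.signed_ids()):
                    fh.write(f"{ancestor_id}\t{s.sample_index}\t{cid}\t{pos}\t{sf}\n")
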
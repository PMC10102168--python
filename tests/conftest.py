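"""Shared fixtures: tiny hand-built genomes and a cached identity-simulation
pipeline run (descendants identical to the ancestor) reused across tests."""

from __future__ import annotations

import numpy as np
import pytest

from karyorec.evolver_sim import SimConfig, leaf_genomes, simulate
from karyorec.genome_io import (Gene, Genome, families_from_map,
                                filter_families, filtered_genomes,
                                read_phylogeny)
from karyorec.pipeline import RunConfig, run_ancestor


def make_genome(name: str, chromosomes: list[list[str]],
                spacing: int = 10_000, gene_len: int = 2_000) -> Genome:
    """Build a genome from signed family tokens, e.g. [["+a", "-b"], ["+c"]].

    Gene ids are synthesised; coordinates are evenly spaced so every gene run
    spans predictable distances.
    """
    chroms = {}
    gid = 0
    for ci, toks in enumerate(chromosomes):
        genes = []
        pos = 1
        for tok in toks:
            strand, fam = tok[0], tok[1:]
            gid += 1
            genes.append(Gene(f"{name}_g{gid}", fam, f"chr{ci + 1}", pos,
                              pos + gene_len - 1, strand))
            pos += gene_len + spacing
        chroms[f"chr{ci + 1}"] = genes
    return Genome(name, chroms)


@pytest.fixture(scope="session")
def identity_sim():
    """Zero-rate simulation: 6 leaves identical to an x=9, 540-gene ancestor."""
    cfg = SimConfig(x_true=9, genes_per_chromosome=60, n_leaves=6, seed=1)
    truth = simulate(cfg)
    genomes = leaf_genomes(truth)
    table = filter_families(families_from_map(genomes), cfg.max_family_size)
    gset = filtered_genomes(genomes, table)
    phylo = read_phylogeny(truth.tree_newick, genomes.keys())
    return truth, gset, phylo


@pytest.fixture(scope="session")
def identity_run(identity_sim):
    """Root-ancestor reconstruction of the identity simulation (10 samples)."""
    truth, gset, phylo = identity_sim
    cfg = RunConfig(n_samples=10, B=50, seed=1)
    return truth, gset, phylo, cfg, run_ancestor(gset, phylo, 1, cfg)


@pytest.fixture(scope="session")
def rearranged_sim():
    """Moderately rearranged simulation (inversions + translocations)."""
    cfg = SimConfig(x_true=7, genes_per_chromosome=60, n_leaves=6,
                    inversion_rate=5.0, translocation_rate=1.0, seed=7)
    truth = simulate(cfg)
    genomes = leaf_genomes(truth)
    table = filter_families(families_from_map(genomes), cfg.max_family_size)
    gset = filtered_genomes(genomes, table)
    phylo = read_phylogeny(truth.tree_newick, genomes.keys())
    return truth, gset, phylo


class _RecoveryTally:
    """Collects x estimates across the parameter-recovery grid so the hit
    rate can be asserted once over all runs."""

    def __init__(self):
        self.results: dict[tuple[int, int], int] = {}

    def record(self, x_true: int, seed: int, x_hat: int) -> None:
        self.results[(x_true, seed)] = x_hat


@pytest.fixture(scope="session")
def recovery_tally():
    return _RecoveryTally()


def random_weighted_graph(rng: np.random.Generator, n_families: int,
                          n_edges: int, max_weight: int = 10):
    """Random extremity graph with integer weights (for matching oracles)."""
    import networkx as nx

    from karyorec.adjacencies import HEAD, TAIL

    g = nx.Graph()
    fams = [f"f{i}" for i in range(n_families)]
    for fam in fams:
        g.add_node((fam, HEAD))
        g.add_node((fam, TAIL))
    nodes = sorted(g.nodes)
    for _ in range(n_edges):
        i, j = rng.integers(0, len(nodes), size=2)
        u, v = nodes[int(i)], nodes[int(j)]
        if u == v or u[0] == v[0] or g.has_edge(u, v):
            continue
        g.add_edge(u, v, weight=int(rng.integers(1, max_weight + 1)))
    return g


def exhaustive_max_matching_weight(graph) -> float:
    """Brute-force maximum-weight matching by recursion over edges."""
    edges = [(u, v, d["weight"]) for u, v, d in graph.edges(data=True)]

    def best(i: int, used: frozenset) -> float:
        if i == len(edges):
            return 0.0
        u, v, w = edges[i]
        skip = best(i + 1, used)
        if u in used or v in used:
            return skip
        return max(skip, w + best(i + 1, used | {u, v}))

    return best(0, frozenset())
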
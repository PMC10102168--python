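"""Genome/family/phylogeny I-O and the family-size filter."""

import numpy as np
import pytest

from karyorec.evolver_sim import SimConfig, leaf_genomes, simulate
from karyorec.genome_io import (GeneFamilyTable, build_families_from_pairs,
                                families_from_map, filter_families,
                                read_genome, read_phylogeny, write_genome)

from conftest import make_genome


def _write_gff(path, rows):
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for seqid, start, end, strand, gid in rows:
            fh.write(f"{seqid}\tsrc\tgene\t{start}\t{end}\t.\t{strand}\t.\t"
                     f"ID={gid}\n")


def _write_map(path, pairs):
    with open(path, "w") as fh:
        for gid, fid in pairs:
            fh.write(f"{gid}\t{fid}\n")


class TestReadGenome:
    def test_genes_sorted_by_coordinate(self, tmp_path):
        gff = tmp_path / "g.gff3"
        fam = tmp_path / "g.tsv"
        # deliberately out of order in the file
        _write_gff(gff, [("chr1", 500, 700, "+", "g2"),
                         ("chr1", 10, 200, "+", "g1"),
                         ("chr1", 900, 950, "-", "g3")])
        _write_map(fam, [("g1", "fa"), ("g2", "fb"), ("g3", "fc")])
        genome = read_genome(gff, fam)
        assert [g.gene_id for g in genome.chromosomes["chr1"]] == ["g1", "g2", "g3"]
        assert [g.strand for g in genome.chromosomes["chr1"]] == ["+", "+", "-"]

    def test_gene_missing_from_family_map_is_dropped(self, tmp_path):
        gff = tmp_path / "g.gff3"
        fam = tmp_path / "g.tsv"
        _write_gff(gff, [("chr1", 10, 20, "+", "g1"), ("chr1", 30, 40, "+", "g2")])
        _write_map(fam, [("g1", "fa")])
        genome = read_genome(gff, fam)
        assert genome.n_genes == 1
        assert genome.chromosomes["chr1"][0].gene_id == "g1"

    def test_duplicate_gene_id_rejected(self, tmp_path):
        gff = tmp_path / "g.gff3"
        fam = tmp_path / "g.tsv"
        _write_gff(gff, [("chr1", 10, 20, "+", "g1"), ("chr1", 30, 40, "+", "g1")])
        _write_map(fam, [("g1", "fa")])
        with pytest.raises(ValueError, match="duplicate gene id"):
            read_genome(gff, fam)

    def test_unknown_strand_rejected(self, tmp_path):
        gff = tmp_path / "g.gff3"
        fam = tmp_path / "g.tsv"
        _write_gff(gff, [("chr1", 10, 20, "?", "g1")])
        _write_map(fam, [("g1", "fa")])
        with pytest.raises(ValueError, match="strand"):
            read_genome(gff, fam)

    def test_simulator_round_trip(self, tmp_path):
        """write_genome → read_genome preserves order, strands and families."""
        truth = simulate(SimConfig(x_true=3, genes_per_chromosome=25,
                                   n_leaves=4, inversion_rate=2.0, seed=5))
        for name, genome in leaf_genomes(truth).items():
            gff = tmp_path / f"{name}.gff3"
            fam = tmp_path / f"{name}.tsv"
            write_genome(genome, gff, fam)
            back = read_genome(gff, fam, name)
            assert set(back.chromosomes) == set(genome.chromosomes)
            for chrom in genome.chromosomes:
                orig = genome.chromosomes[chrom]
                got = back.chromosomes[chrom]
                assert [(g.family_id, g.strand, g.start_bp) for g in got] == \
                       [(g.family_id, g.strand, g.start_bp) for g in orig]


class TestFamilies:
    def test_pairs_transitive_closure(self, tmp_path):
        p = tmp_path / "pairs.tsv"
        p.write_text("a\tb\nb\tc\n")
        gs = {"G": make_genome("G", [["+a", "+b", "+c"]])}
        # gene ids in make_genome are synthesised; remap to a/b/c
        gs["G"].chromosomes["chr1"] = [
            g.__class__(fam, fam, g.chromosome_id, g.start_bp, g.end_bp, "+")
            for g, fam in zip(gs["G"].chromosomes["chr1"], "abc")]
        table = build_families_from_pairs(p, gs)
        assert len(table) == 1
        members = next(iter(table.members.values()))
        assert sorted(members["G"]) == ["a", "b", "c"]

    def test_empty_pair_file(self, tmp_path):
        p = tmp_path / "pairs.tsv"
        p.write_text("")
        assert len(build_families_from_pairs(p, {})) == 0

    def test_components_match_union_find_oracle(self, tmp_path):
        rng = np.random.default_rng(42)
        genes = [f"g{i}" for i in range(50)]
        pairs = [(genes[int(a)], genes[int(b)])
                 for a, b in rng.integers(0, 50, size=(60, 2)) if a != b]
        p = tmp_path / "pairs.tsv"
        p.write_text("".join(f"{a}\t{b}\n" for a, b in pairs))
        gs = {"G": make_genome("G", [[f"+x{i}" for i in range(50)]])}
        gs["G"].chromosomes["chr1"] = [
            g.__class__(gid, gid, g.chromosome_id, g.start_bp, g.end_bp, "+")
            for g, gid in zip(gs["G"].chromosomes["chr1"], genes)]
        table = build_families_from_pairs(p, gs)

        # independent union-find
        parent = {g: g for g in genes}

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for a, b in pairs:
            parent[find(a)] = find(b)
        oracle = {}
        for g in genes:
            oracle.setdefault(find(g), set()).add(g)
        oracle_comps = {frozenset(v) for v in oracle.values() if len(v) > 1}
        got = {frozenset(m["G"]) for m in table.members.values()}
        assert got == oracle_comps

    def test_families_partition_genes(self, tmp_path):
        rng = np.random.default_rng(3)
        genes = [f"g{i}" for i in range(30)]
        pairs = [(genes[int(a)], genes[int(b)])
                 for a, b in rng.integers(0, 30, size=(25, 2)) if a != b]
        p = tmp_path / "pairs.tsv"
        p.write_text("".join(f"{a}\t{b}\n" for a, b in pairs))
        gs = {"G": make_genome("G", [[f"+q{i}" for i in range(30)]])}
        gs["G"].chromosomes["chr1"] = [
            g.__class__(gid, gid, g.chromosome_id, g.start_bp, g.end_bp, "+")
            for g, gid in zip(gs["G"].chromosomes["chr1"], genes)]
        table = build_families_from_pairs(p, gs)
        all_members = [g for m in table.members.values() for g in m["G"]]
        assert len(all_members) == len(set(all_members))


class TestFilterFamilies:
    def _table(self, spec):
        t = GeneFamilyTable()
        for fid, per_genome in spec.items():
            t.members[fid] = {g: [f"{fid}_{g}_{i}" for i in range(n)]
                              for g, n in per_genome.items()}
        return t

    def test_oversized_family_dropped(self):
        t = self._table({"f1": {"A": 11, "B": 1}, "f2": {"A": 10, "B": 1}})
        out = filter_families(t, max_family_size=10)
        assert set(out.members) == {"f2"}
        assert out.n_dropped_size == 1

    def test_single_copy_in_many_genomes_retained(self):
        t = self._table({"f1": {c: 1 for c in "ABCDEF"}})
        assert set(filter_families(t).members) == {"f1"}

    def test_single_genome_family_dropped(self):
        t = self._table({"f1": {"A": 2}, "f2": {"A": 1, "B": 1}})
        out = filter_families(t)
        assert set(out.members) == {"f2"}
        assert out.n_dropped_single_genome == 1

    def test_idempotent(self):
        t = self._table({"f1": {"A": 11, "B": 1}, "f2": {"A": 3, "B": 2},
                         "f3": {"A": 4}})
        once = filter_families(t)
        twice = filter_families(once)
        assert once.members == twice.members


class TestReadPhylogeny:
    def test_internal_node_count(self):
        phylo = read_phylogeny("((A,B),(C,D));", ["A", "B", "C", "D"])
        assert phylo.n_ancestors == 3

    def test_preorder_numbering(self):
        phylo = read_phylogeny("((A,B),C);", ["A", "B", "C"])
        assert phylo.leaves(1) == {"A", "B", "C"}  # root = Ancestor 1
        assert phylo.leaves(2) == {"A", "B"}

    def test_nonbinary_rejected(self):
        with pytest.raises(ValueError, match="binary"):
            read_phylogeny("(A,B,C);", ["A", "B", "C"])

    def test_leaf_mismatch_lists_difference(self):
        with pytest.raises(ValueError, match="missing"):
            read_phylogeny("((A,B),C);", ["A", "B", "D"])

    def test_child_leaf_sets_bipartition(self):
        phylo = read_phylogeny("((A,B),(C,D));", ["A", "B", "C", "D"])
        left, right = phylo.child_leaf_sets(1)
        assert {frozenset(left), frozenset(right)} == \
               {frozenset({"A", "B"}), frozenset({"C", "D"})}
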
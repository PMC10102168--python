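"""g-mer cutting, co-occurrence, smoothing and clustering."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import adjusted_rand_score

from karyorec.contig_assembly import Contig
from karyorec.gmer_clustering import (Gmer, cooccurrence, correlation_smooth,
                                      cut_gmers, cut_k, dynamic_cut,
                                      hier_cluster, match_all,
                                      match_unit_to_chromosomes, pca_cluster,
                                      select_units)

from conftest import make_genome


def contig(n, prefix="f"):
    return Contig([(f"{prefix}{i}", 1) for i in range(n)])


class TestCutGmers:
    def test_exact_multiples(self):
        units = cut_gmers([contig(100)], g=20)
        assert [len(u) for u in units] == [20] * 5

    def test_short_contig_passes_through(self):
        units = cut_gmers([contig(15)], g=20)
        assert [len(u) for u in units] == [15]

    def test_small_remainder_merged_into_last_piece(self):
        # L=47, g=20: r=7 < 10, appended to the last full piece
        units = cut_gmers([contig(47)], g=20)
        assert [len(u) for u in units] == [20, 27]

    def test_large_remainder_stands_alone(self):
        # L=52, g=20: r=12 >= 10 forms its own piece
        units = cut_gmers([contig(52)], g=20)
        assert [len(u) for u in units] == [20, 20, 12]

    def test_g_below_two_rejected(self):
        with pytest.raises(ValueError):
            cut_gmers([contig(5)], g=1)

    @pytest.mark.parametrize("L", [1, 7, 19, 20, 21, 29, 30, 31, 47, 60, 101])
    def test_reassembly_and_length_bound(self, L):
        """Concatenating a contig's g-mers in order reproduces the contig;
        no piece exceeds g + ceil(g/2) - 1."""
        g = 20
        c = Contig([(f"x{i}", 1 if i % 3 else -1) for i in range(L)])
        units = cut_gmers([c], g=g)
        rebuilt = [fam for u in units for fam in u.families]
        assert rebuilt == c.families
        assert all(len(u) <= g + math.ceil(g / 2) - 1 for u in units)
        assert all(len(u) >= 1 for u in units)


@settings(deadline=None, max_examples=80, derandomize=True)
@given(L=st.integers(min_value=1, max_value=250),
       g=st.integers(min_value=2, max_value=50))
def test_gmer_cutting_reassembles_for_any_length(L, g):
    """For arbitrary contig length and piece size: ordered concatenation
    reproduces the contig, piece lengths are bounded, and the piece count
    follows the floor/remainder rule."""
    c = Contig([(f"x{i}", 1 if i % 2 else -1) for i in range(L)])
    units = cut_gmers([c], g=g)
    assert [fam for u in units for fam in u.families] == c.families
    assert all(len(u) <= g + math.ceil(g / 2) - 1 for u in units)
    if L <= g:
        assert len(units) == 1
    else:
        r = L % g
        expected = L // g + (1 if r >= math.ceil(g / 2) else 0)
        assert len(units) == expected


class TestSelectUnits:
    def test_under_limit_keeps_all(self):
        units = cut_gmers([contig(100)], 20)
        assert len(select_units(units, 500)) == 5

    def test_equal_lengths_tie_break_by_contig_and_start(self):
        units = [Gmer(cid, s, [(f"f{cid}_{s}_{i}", 1) for i in range(20)])
                 for cid in range(30) for s in (0, 20)]
        kept = select_units(units, 10)
        assert [(u.contig_id, u.start) for u in kept] == \
               [(c, s) for c in range(5) for s in (0, 20)]

    def test_mixed_lengths_sorted_by_length_first(self):
        rng = np.random.default_rng(0)
        units = [Gmer(i, 0, [(f"f{i}_{j}", 1) for j in range(int(L))])
                 for i, L in enumerate(rng.integers(5, 30, size=40))]
        kept = select_units(units, 15)
        expected = sorted(units, key=lambda u: (-len(u), u.contig_id, u.start))[:15]
        assert [(u.contig_id, u.start) for u in kept] == \
               [(u.contig_id, u.start) for u in expected]


class TestMatching:
    def test_unit_on_single_chromosome(self):
        genome = make_genome("A", [[f"+f{i}" for i in range(20)],
                                   ["+z1", "+z2", "+z3"]])
        unit = Gmer(0, 0, [(f"f{i}", 1) for i in range(20)])
        assert set(match_unit_to_chromosomes(unit, genome)) == {"chr1"}

    def test_even_split_matches_both(self):
        genome = make_genome("A", [[f"+f{i}" for i in range(10)],
                                   [f"+f{i}" for i in range(10, 20)]])
        unit = Gmer(0, 0, [(f"f{i}", 1) for i in range(20)])
        assert set(match_unit_to_chromosomes(unit, genome, tau=0.3)) == \
               {"chr1", "chr2"}

    def test_threshold_floor_blocks_single_hits(self):
        genome = make_genome("A", [["+f0", "+q1", "+q2"]])
        unit = Gmer(0, 0, [("f0", 1), ("other", 1), ("other2", 1)])
        assert match_unit_to_chromosomes(unit, genome) == {}

    def test_batched_matching_equals_per_unit_reference(self):
        rng = np.random.default_rng(6)
        fams = [f"f{i}" for i in range(30)]
        genomes = {f"G{i}": make_genome(
            f"G{i}", [[f"+{rng.choice(fams)}" for _ in range(12)]
                      for _ in range(3)]) for i in range(3)}
        units = [Gmer(i, 0, [(f, 1)
                             for f in rng.choice(fams, 8, replace=False)])
                 for i in range(10)]
        batched = match_all(units, genomes)
        for unit, got in zip(units, batched):
            expected = {}
            for gname, genome in genomes.items():
                for chrom, anchor in match_unit_to_chromosomes(
                        unit, genome).items():
                    expected[(gname, chrom)] = anchor
            assert got == expected

    def test_matches_equal_brute_force_recount(self):
        rng = np.random.default_rng(2)
        fams = [f"f{i}" for i in range(40)]
        chroms = [[f"+{rng.choice(fams)}" for _ in range(15)] for _ in range(4)]
        genome = make_genome("A", chroms)
        unit = Gmer(0, 0, [(f, 1) for f in rng.choice(fams, 12, replace=False)])
        got = match_unit_to_chromosomes(unit, genome, tau=0.3)
        need = max(2, 0.3 * 12)
        for ci, toks in enumerate(chroms):
            present = {t[1:] for t in toks} & unit.family_set
            assert ((f"chr{ci + 1}" in got) == (len(present) >= need))


class TestCooccurrence:
    def test_shared_chromosome_counts_per_genome(self):
        genomes = {f"G{i}": make_genome(f"G{i}", [["+a1", "+a2", "+b1", "+b2"]])
                   for i in range(4)}
        units = [Gmer(0, 0, [("a1", 1), ("a2", 1)]),
                 Gmer(1, 0, [("b1", 1), ("b2", 1)])]
        C = cooccurrence(match_all(units, genomes))
        assert C[0, 1] == 4  # both match the single chromosome in 4 genomes

    def test_never_sharing_gives_zero(self):
        genomes = {"G": make_genome("G", [["+a1", "+a2"], ["+b1", "+b2"]])}
        units = [Gmer(0, 0, [("a1", 1), ("a2", 1)]),
                 Gmer(1, 0, [("b1", 1), ("b2", 1)])]
        C = cooccurrence(match_all(units, genomes))
        assert C[0, 1] == 0

    def test_one_genome_can_contribute_twice(self):
        # both units' families present on two chromosomes of one genome
        genomes = {"G": make_genome("G", [["+a1", "+a2", "+b1", "+b2"],
                                          ["+a1", "+a2", "+b1", "+b2"]])}
        units = [Gmer(0, 0, [("a1", 1), ("a2", 1)]),
                 Gmer(1, 0, [("b1", 1), ("b2", 1)])]
        C = cooccurrence(match_all(units, genomes))
        assert C[0, 1] == 2

    def test_symmetric_nonnegative_with_match_counts_on_diagonal(self):
        rng = np.random.default_rng(4)
        fams = [f"f{i}" for i in range(30)]
        genomes = {f"G{i}": make_genome(
            f"G{i}", [[f"+{rng.choice(fams)}" for _ in range(10)]
                      for _ in range(3)]) for i in range(3)}
        units = [Gmer(i, 0, [(f, 1) for f in rng.choice(fams, 8, replace=False)])
                 for i in range(6)]
        matches = match_all(units, genomes)
        C = cooccurrence(matches)
        assert np.array_equal(C, C.T)
        assert (C >= 0).all()
        assert np.array_equal(np.diag(C), [len(m) for m in matches])


class TestCorrelationSmooth:
    def test_identical_rows_fully_similar(self):
        C = np.array([[2., 2., 1., 0.], [2., 2., 1., 0.],
                      [1., 1., 3., 0.], [0., 0., 0., 1.]])
        S, D = correlation_smooth(C)
        assert S[0, 1] == pytest.approx(1.0)
        assert D[0, 1] == pytest.approx(0.0)

    def test_anticorrelated_rows_maximally_distant(self):
        C = np.array([[3., 0., 3., 0.], [0., 3., 0., 3.],
                      [3., 0., 9., 0.], [0., 3., 0., 9.]])
        S, D = correlation_smooth(C)
        assert S[0, 1] == pytest.approx(-1.0)
        assert D[0, 1] == pytest.approx(2.0)

    def test_matches_direct_leave_two_out_correlation(self):
        rng = np.random.default_rng(9)
        C = rng.integers(0, 6, size=(10, 10)).astype(float)
        C = (C + C.T) / 2
        S, _ = correlation_smooth(C)
        for u in range(10):
            for v in range(10):
                if u == v:
                    assert S[u, v] == 1.0
                    continue
                cols = [c for c in range(10) if c not in (u, v)]
                x, y = C[u, cols], C[v, cols]
                if x.std() == 0 or y.std() == 0:
                    expected = 0.0
                else:
                    expected = np.corrcoef(x, y)[0, 1]
                assert S[u, v] == pytest.approx(expected, abs=1e-9)

    def test_constant_rows_correlate_zero(self):
        C = np.full((4, 4), 5.0)
        S, D = correlation_smooth(C)
        assert S[0, 1] == 0.0
        assert D[0, 1] == 1.0

    def test_tiny_input_identity(self):
        S, D = correlation_smooth(np.ones((2, 2)))
        assert np.array_equal(S, np.eye(2))


class TestHierCluster:
    def _block_distance(self, sizes, within=0.1, between=1.0, seed=0):
        n = sum(sizes)
        labels = np.repeat(np.arange(len(sizes)), sizes)
        rng = np.random.default_rng(seed)
        D = np.where(labels[:, None] == labels[None, :], within, between)
        D = D + rng.uniform(0, 0.01, (n, n))
        D = (D + D.T) / 2
        np.fill_diagonal(D, 0)
        return D, labels

    def test_two_tight_blocks_recovered(self):
        D, truth = self._block_distance([6, 6])
        labels = cut_k(hier_cluster(D), 2)
        assert adjusted_rand_score(truth, labels) == 1.0

    def test_cut_at_n_gives_singletons(self):
        D, _ = self._block_distance([4, 4])
        labels = cut_k(hier_cluster(D), 8)
        assert len(set(labels)) == 8

    def test_cut_beyond_n_rejected(self):
        D, _ = self._block_distance([3, 3])
        with pytest.raises(ValueError):
            cut_k(hier_cluster(D), 7)

    def test_matches_naive_complete_linkage_oracle(self):
        """Flat cuts at every k agree with a naive O(n^3) agglomeration."""
        rng = np.random.default_rng(12)
        n = 12
        D = rng.uniform(0.1, 2.0, size=(n, n))
        D = (D + D.T) / 2
        np.fill_diagonal(D, 0)

        clusters = [frozenset([i]) for i in range(n)]
        naive_partitions = {n: set(clusters)}
        while len(clusters) > 1:
            best = None
            for i in range(len(clusters)):
                for j in range(i + 1, len(clusters)):
                    d = max(D[a, b] for a in clusters[i] for b in clusters[j])
                    if best is None or d < best[0]:
                        best = (d, i, j)
            _, i, j = best
            merged = clusters[i] | clusters[j]
            clusters = [c for idx, c in enumerate(clusters)
                        if idx not in (i, j)] + [merged]
            naive_partitions[len(clusters)] = set(clusters)

        tree = hier_cluster(D)
        for k in range(2, n + 1):
            labels = cut_k(tree, k)
            got = set()
            for lab in set(labels):
                got.add(frozenset(np.where(labels == lab)[0].tolist()))
            assert got == naive_partitions[k], f"partition mismatch at k={k}"


class TestDynamicCut:
    def test_well_separated_fixed_point(self):
        D = np.where(np.arange(8)[:, None] // 4 == np.arange(8)[None, :] // 4,
                     0.1, 1.0).astype(float)
        np.fill_diagonal(D, 0)
        labels = np.array([0] * 4 + [1] * 4)
        assert np.array_equal(dynamic_cut(labels, D), labels)

    def test_planted_outlier_reassigned(self):
        # unit 0 labelled 0 but sits at distance 0.1 from cluster 1
        n = 9
        D = np.ones((n, n))
        np.fill_diagonal(D, 0)
        for i in range(1, 5):
            for j in range(1, 5):
                D[i, j] = 0.1 if i != j else 0
        for i in range(5, 9):
            for j in range(5, 9):
                D[i, j] = 0.1 if i != j else 0
        for j in range(5, 9):
            D[0, j] = D[j, 0] = 0.1  # near cluster 1
        labels = np.array([0] + [0] * 4 + [1] * 4)
        out = dynamic_cut(labels, D)
        assert out[0] == 1
        assert np.array_equal(out[1:], labels[1:])

    def test_k_preserved_on_random_instances(self):
        rng = np.random.default_rng(8)
        for _ in range(50):
            n = int(rng.integers(6, 20))
            k = int(rng.integers(2, 5))
            D = rng.uniform(0, 1, (n, n))
            D = (D + D.T) / 2
            np.fill_diagonal(D, 0)
            labels = rng.integers(0, k, n)
            labels[:k] = np.arange(k)  # ensure all clusters non-empty
            out = dynamic_cut(labels, D)
            assert set(out) == set(labels)


class TestPcaCluster:
    def test_planted_blobs_in_high_dimension(self):
        rng = np.random.default_rng(3)
        latent_centers = rng.uniform(-10, 10, size=(3, 2))
        embed = rng.normal(size=(2, 50))
        X, truth = [], []
        for ci, c in enumerate(latent_centers):
            pts = c + rng.normal(0, 0.3, size=(15, 2))
            X.append(pts @ embed)
            truth += [ci] * 15
        X = np.vstack(X) + rng.normal(0, 0.05, size=(45, 50))
        labels = pca_cluster(X, k=3)
        assert adjusted_rand_score(truth, labels) == 1.0

    def test_k_one_single_cluster(self):
        X = np.random.default_rng(0).normal(size=(10, 5))
        assert set(pca_cluster(X, k=1)) == {0}

    def test_zero_variance_collapses_to_one_cluster(self):
        X = np.ones((6, 4))
        assert set(pca_cluster(X, k=3)) == {0}
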
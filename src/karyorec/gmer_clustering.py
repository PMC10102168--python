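"""g-mer decomposition, chromosomal co-occurrence and clustering.

Raw contig lengths are extremely variable, and long contigs — spliced from
several true chromosomes via mis-joined adjacencies — co-occur with everything,
biasing the clustering towards a few oversized clusters.  Cutting every contig
of length L into ~L/g pieces of length g ("g-mers", default g = 20) removes
the length signal entirely: all clustering units are commensurate.

Units are matched against the chromosomes of the extant genomes; the
co-occurrence matrix counts, over (genome, chromosome) pairs, how often two
units hit the same chromosome.  The matrix is smoothed by correlating unit
rows (two units that co-occur with the *same* partners are similar even if
they rarely co-occur directly), clustered by complete linkage on 1 − r, and
the flat cut is polished by a dynamic reassignment pass.  A PCA + Ward route
is provided as an independent alternative.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import cut_tree, linkage
from scipy.spatial.distance import squareform
from sklearn.decomposition import PCA

from .contig_assembly import Contig
from .genome_io import Genome

logger = logging.getLogger(__name__)


@dataclass
class Gmer:
    """A slice of a contig used as a clustering unit."""

    contig_id: int
    start: int  # slice start within the contig (gene index)
    families: list[tuple[str, int]]  # signed, as in Contig

    def __len__(self) -> int:
        return len(self.families)

    @property
    def family_set(self) -> set[str]:
        return {f for f, _ in self.families}


def cut_gmers(contigs: list[Contig], g: int = 20) -> list[Gmer]:
    """Cut contigs into ⌊L/g⌋ pieces of length g; a remainder r < ⌈g/2⌉ is
    appended to the last piece, otherwise it stands alone.  Contigs with
    L ≤ g pass through whole."""
    if g < 2:
        raise ValueError("g must be >= 2")
    half = math.ceil(g / 2)
    units: list[Gmer] = []
    for cid, contig in enumerate(contigs):
        L = len(contig)
        if L <= g:
            units.append(Gmer(cid, 0, list(contig.families)))
            continue
        n_full = L // g
        r = L % g
        bounds = [i * g for i in range(n_full)]
        if r >= half:
            bounds.append(n_full * g)
        bounds.append(L)
        for s, e in zip(bounds, bounds[1:]):
            units.append(Gmer(cid, s, contig.families[s:e]))
    return units


def select_units(units: list[Gmer], max_units: int = 500) -> list[Gmer]:
    """Keep the ``max_units`` longest units (ties by contig id, then start)."""
    ranked = sorted(units, key=lambda u: (-len(u), u.contig_id, u.start))
    return ranked[:max_units]


def match_unit_to_chromosomes(unit: Gmer, genome: Genome, tau: float = 0.3
                              ) -> dict[str, float]:
    """Chromosomes of ``genome`` the unit matches, with an anchor position.

    A unit matches a chromosome when at least max(2, τ·|unit|) of its member
    families have a gene there (τ = 0.3 tolerates fractionation while the
    absolute floor of 2 blocks single-gene hits).  The anchor is the median
    start coordinate of the matching genes, used later for ordering.
    """
    fams = unit.family_set
    need = max(2.0, tau * len(unit))
    out: dict[str, float] = {}
    for chrom, genes in genome.chromosomes.items():
        hit_fams: set[str] = set()
        positions: list[int] = []
        for gene in genes:
            if gene.family_id in fams:
                hit_fams.add(gene.family_id)
                positions.append(gene.start_bp)
        if len(hit_fams) >= need:
            out[chrom] = float(np.median(positions))
    return out


def match_all(units: list[Gmer], genomes: dict[str, Genome], tau: float = 0.3
              ) -> list[dict[tuple[str, str], float]]:
    """Per unit: (genome, chromosome) -> anchor.

    Equivalent to :func:`match_unit_to_chromosomes` per unit and genome, but
    batched through a family-presence matrix so large unit sets stay fast.
    """
    columns = [(gname, chrom) for gname in sorted(genomes)
               for chrom in sorted(genomes[gname].chromosomes)]
    col_index = {c: i for i, c in enumerate(columns)}
    fams = sorted({f for u in units for f in u.family_set})
    fam_index = {f: i for i, f in enumerate(fams)}

    presence = np.zeros((len(fams), len(columns)), dtype=np.uint8)
    starts: dict[tuple[int, int], list[int]] = {}
    for gname in sorted(genomes):
        for chrom, genes in genomes[gname].chromosomes.items():
            ci = col_index[(gname, chrom)]
            for gene in genes:
                fi = fam_index.get(gene.family_id)
                if fi is None:
                    continue
                presence[fi, ci] = 1
                starts.setdefault((fi, ci), []).append(gene.start_bp)

    matches: list[dict[tuple[str, str], float]] = []
    for unit in units:
        rows = [fam_index[f] for f in unit.family_set]
        counts = presence[rows].sum(axis=0)
        need = max(2.0, tau * len(unit))
        m: dict[tuple[str, str], float] = {}
        for ci in np.nonzero(counts >= need)[0]:
            pos = [p for fi in rows for p in starts.get((fi, int(ci)), ())]
            m[columns[int(ci)]] = float(np.median(pos))
        matches.append(m)
    return matches


def cooccurrence(matches: list[dict[tuple[str, str], float]],
                 columns: list[tuple[str, str]] | None = None) -> np.ndarray:
    """Symmetric count matrix: C[u, v] = #(genome, chromosome) matched by both.

    The diagonal holds each unit's total match count.  A genome contributes
    once per shared chromosome, so it can contribute twice or more.
    """
    if columns is None:
        cols = sorted({key for m in matches for key in m})
    else:
        cols = columns
    col_index = {c: i for i, c in enumerate(cols)}
    M = np.zeros((len(matches), max(len(cols), 1)), dtype=float)
    for u, m in enumerate(matches):
        for key in m:
            M[u, col_index[key]] = 1.0
    return M @ M.T


def correlation_smooth(C: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-correlation smoothing: S[u,v] = Pearson r of rows u and v of C,
    excluding columns u and v; D = 1 − S clipped to [0, 2].

    Constant (zero-variance) rows correlate 0 with everything; the diagonal
    of S is 1.  With fewer than 3 units there is nothing to correlate and the
    identity similarity is returned.
    """
    n = C.shape[0]
    if n < 3:
        S = np.eye(n)
        return S, np.clip(1.0 - S, 0.0, 2.0)
    m = n - 2  # columns entering each pairwise correlation
    T1 = C.sum(axis=1)
    T2 = (C ** 2).sum(axis=1)
    G = C @ C.T
    Cd = np.diag(C)

    # sums over columns != u, v for the pair (u, v), fully vectorised
    sx = T1[:, None] - Cd[:, None] - C            # Σ C[u, ·]
    sy = T1[None, :] - C.T - Cd[None, :]          # Σ C[v, ·]
    sxx = T2[:, None] - Cd[:, None] ** 2 - C ** 2
    syy = T2[None, :] - C.T ** 2 - Cd[None, :] ** 2
    # subtract the two excluded columns from Σ C[u,·]C[v,·]:
    #   column u contributes C[u,u]·C[v,u]; column v contributes C[u,v]·C[v,v]
    sxy = G - Cd[:, None] * C.T - C * Cd[None, :]

    varx = sxx - sx ** 2 / m
    vary = syy - sy ** 2 / m
    cov = sxy - sx * sy / m
    denom = np.sqrt(np.clip(varx, 0.0, None) * np.clip(vary, 0.0, None))
    with np.errstate(invalid="ignore", divide="ignore"):
        S = np.where(denom > 1e-12, cov / np.where(denom > 1e-12, denom, 1.0), 0.0)
    S = np.clip((S + S.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(S, 1.0)
    D = np.clip(1.0 - S, 0.0, 2.0)
    np.fill_diagonal(D, 0.0)
    return S, D


def hier_cluster(D: np.ndarray) -> np.ndarray:
    """Complete-linkage dendrogram (scipy linkage matrix) of a distance matrix."""
    condensed = squareform(np.asarray(D, dtype=float), checks=False)
    return linkage(condensed, method="complete")


def cut_k(tree: np.ndarray, k: int) -> np.ndarray:
    """Cut the dendrogram into exactly k clusters (labels 0..k-1)."""
    n = tree.shape[0] + 1
    if k > n:
        raise ValueError(f"cannot cut {n} units into {k} clusters")
    return cut_tree(tree, n_clusters=k).ravel()


def dynamic_cut(labels: np.ndarray, D: np.ndarray, eta: float = 0.1,
                max_iter: int = 20) -> np.ndarray:
    """Polish a flat cut without changing k.

    A unit is reassigned to its nearest other cluster when its average
    distance to its own cluster exceeds (1 + η) times its average distance to
    that cluster.  Reassignments that would empty a cluster are skipped;
    iterate to a fixed point (at most ``max_iter`` passes).
    """
    labels = np.asarray(labels).copy()
    n = len(labels)
    ks = np.unique(labels)
    for _ in range(max_iter):
        changed = False
        for u in range(n):
            own = labels[u]
            if np.sum(labels == own) <= 1:
                continue  # would empty its cluster
            avg = {}
            for c in ks:
                mask = labels == c
                mask_u = mask.copy()
                mask_u[u] = False
                if not mask_u.any():
                    continue
                avg[c] = D[u, mask_u].mean()
            if own not in avg:
                continue
            others = {c: v for c, v in avg.items() if c != own}
            if not others:
                continue
            best = min(others, key=lambda c: (others[c], c))
            if avg[own] > (1.0 + eta) * others[best]:
                labels[u] = best
                changed = True
        if not changed:
            break
    return labels


def pca_cluster(C: np.ndarray, k: int, var_target: float = 0.7,
                max_dims: int = 10) -> np.ndarray:
    """PCA + Ward alternative clustering of the co-occurrence matrix.

    Rows of C are centred and projected onto the fewest principal components
    reaching ``var_target`` of the variance (capped at ``max_dims``); Ward
    hierarchical clustering of the scores is cut at k.
    """
    n = C.shape[0]
    if n < k:
        raise ValueError(f"cannot form {k} clusters from {n} units")
    X = np.asarray(C, dtype=float)
    if np.allclose(X.var(axis=0), 0.0):
        logger.warning("pca_cluster: zero-variance matrix, single cluster")
        return np.zeros(n, dtype=int)
    pca = PCA(n_components=min(max_dims, n - 1, X.shape[1]))
    scores = pca.fit_transform(X)
    cum = np.cumsum(pca.explained_variance_ratio_)
    ndim = int(np.searchsorted(cum, var_target) + 1)
    ndim = min(ndim, scores.shape[1])
    Z = linkage(scores[:, :ndim], method="ward")
    return cut_tree(Z, n_clusters=k).ravel()
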
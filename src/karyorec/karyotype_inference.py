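"""Gap statistics and estimation of the basic chromosome number x.

For each matching sample, the clustering of its units is scored over
k = 2..k_max with the gap statistic: the log within-cluster dispersion of the
real data is compared to its expectation under a no-structure null (B uniform
draws from the bounding box of the features, clustered the same way).  The gap
curve rises steeply while extra clusters capture real chromosomes, then bends
into a slow noisy trend of overfitting.

x is read off the *increments* Δ(k) = gap(k) − gap(k−1): a least-squares line
is fitted to the increments in the noise regime (k = 12..20 by default) and x
is the largest k below that window whose increment exceeds the line's
prediction.  Because samples differ in how cleanly they cluster, the estimate
uses only the best samples: those ranking in the top 10 gap values for at
least two of k = 4..10.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .gmer_clustering import cut_k, hier_cluster

logger = logging.getLogger(__name__)

LOG_EPS = 1e-12


@dataclass
class GapProfile:
    sample_index: int
    ks: np.ndarray                 # k = 2..k_max
    gap: np.ndarray                # gap(k)
    se: np.ndarray                 # Monte-Carlo standard error of the null term
    B: int

    def gap_at(self, k: int) -> float:
        return float(self.gap[int(np.where(self.ks == k)[0][0])])


@dataclass
class XEstimate:
    x: int
    slope: float
    intercept: float
    ks: np.ndarray                 # k values of the increments (3..k_max)
    increments: np.ndarray
    selected_samples: list[int] = field(default_factory=list)
    null_flag: bool = False        # True when no increment exceeded the line


def _within_dispersion(dist: np.ndarray, labels: np.ndarray) -> float:
    """W = Σ_r D_r / (2 n_r), D_r the sum of pairwise distances in cluster r."""
    w = 0.0
    for c in np.unique(labels):
        idx = np.where(labels == c)[0]
        if len(idx) < 2:
            continue
        sub = dist[np.ix_(idx, idx)]
        w += sub.sum() / (2.0 * len(idx))  # sub double-counts pairs
    return w / 2.0


def gap_statistic(features: np.ndarray, k_max: int = 20, B: int = 50,
                  rng: np.random.Generator | int | None = 0,
                  labels_by_k: dict[int, np.ndarray] | None = None,
                  sample_index: int = 0) -> GapProfile:
    """Gap statistic over k = 2..k_max for one feature matrix.

    ``features`` are the unit feature vectors (rows of the smoothed similarity
    matrix in the pipeline).  Real-data labels per k may be supplied (e.g. from
    the correlation-distance dendrogram); otherwise complete linkage on
    Euclidean distances is used, which is also how every null replicate is
    clustered.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    X = np.asarray(features, dtype=float)
    n = X.shape[0]
    k_max = min(k_max, n)
    ks = np.arange(2, k_max + 1)
    if len(ks) == 0:
        raise ValueError("need at least 2 units")

    dist = squareform(pdist(X), checks=False)
    if labels_by_k is None:
        tree = hier_cluster(dist)
        labels_by_k = {k: cut_k(tree, k) for k in ks}
    logW = np.array([np.log(_within_dispersion(dist, labels_by_k[k]) + LOG_EPS)
                     for k in ks])

    from scipy.cluster.hierarchy import cut_tree

    lo, hi = X.min(axis=0), X.max(axis=0)
    logWstar = np.empty((B, len(ks)))
    for b in range(B):
        ref = rng.uniform(lo, hi, size=X.shape)
        rdist = squareform(pdist(ref), checks=False)
        rtree = hier_cluster(rdist)
        rlabels = cut_tree(rtree, n_clusters=ks)  # one pass for all k
        for j in range(len(ks)):
            logWstar[b, j] = np.log(
                _within_dispersion(rdist, rlabels[:, j]) + LOG_EPS)

    gap = logWstar.mean(axis=0) - logW
    se = logWstar.std(axis=0, ddof=1) * np.sqrt(1.0 + 1.0 / B)
    return GapProfile(sample_index, ks, gap, se, B)


def mean_profile(profiles: list[GapProfile],
                 indices: list[int] | None = None) -> GapProfile:
    """Mean gap curve over (selected) samples."""
    chosen = profiles if indices is None else [
        p for p in profiles if p.sample_index in set(indices)]
    if not chosen:
        raise ValueError("no profiles to average")
    ks = chosen[0].ks
    gap = np.mean([p.gap for p in chosen], axis=0)
    se = np.mean([p.se for p in chosen], axis=0) / np.sqrt(len(chosen))
    return GapProfile(-1, ks, gap, se, chosen[0].B)


def average_profiles(profiles: list[GapProfile]) -> GapProfile:
    """Average gap curves from several analyses (e.g. different g values or
    different ancestors of one clade).

    The increments of a single analysis fluctuate considerably; averaging
    parallel curves — whose piece-length choice g has little systematic
    effect — is the standard way to stabilise the trend before locating the
    inflection.  Dispersions combine as the rms reduced by √m.
    """
    if not profiles:
        raise ValueError("no profiles to average")
    ks = profiles[0].ks
    for p in profiles[1:]:
        if not np.array_equal(p.ks, ks):
            raise ValueError("profiles cover different k ranges")
    m = len(profiles)
    gap = np.mean([p.gap for p in profiles], axis=0)
    se = np.sqrt(np.mean([p.se ** 2 for p in profiles], axis=0) / m)
    return GapProfile(-1, ks, gap, se, profiles[0].B)


def select_best_samples(profiles: list[GapProfile], top_n: int = 10,
                        k_lo: int = 4, k_hi: int = 10,
                        min_appearances: int = 2) -> list[int]:
    """Samples appearing in the top ``top_n`` gap values for at least
    ``min_appearances`` of k = k_lo..k_hi (ties at the cutoff kept).

    Falls back, with a warning, to the ``top_n`` samples by mean gap if the
    rule selects nothing.
    """
    counts: dict[int, int] = {p.sample_index: 0 for p in profiles}
    for k in range(k_lo, k_hi + 1):
        if k not in profiles[0].ks:
            continue
        gaps = np.array([p.gap_at(k) for p in profiles])
        order = np.sort(gaps)[::-1]
        cutoff = order[min(top_n, len(order)) - 1]
        for p, gk in zip(profiles, gaps):
            if gk >= cutoff:
                counts[p.sample_index] += 1
    selected = sorted(i for i, c in counts.items() if c >= min_appearances)
    if not selected:
        logger.warning("best-sample rule selected nothing; "
                       "falling back to top %d by mean gap", top_n)
        means = {p.sample_index: float(np.mean(p.gap)) for p in profiles}
        selected = sorted(sorted(means, key=means.get, reverse=True)[:top_n])
    return selected


def estimate_x(profile: GapProfile, fit_lo: int = 12, fit_hi: int = 20,
               selected_samples: list[int] | None = None,
               noise_z: float = 2.0) -> XEstimate:
    """Largest k whose gap increment significantly exceeds the noise trend.

    Δ(k) = gap(k) − gap(k−1) is computed for k = 3..k_max; an OLS line
    Δ ~ k is fitted on the overfitting regime k = fit_lo..fit_hi (shrunk with
    a warning if the profile is shorter); x is the largest k in [3, fit_lo)
    with Δ(k) above the line's prediction by more than ``noise_z`` times the
    fit's residual standard deviation — an increment merely fluctuating at
    the trend's own noise level is not an inflection.  With no exceedance the
    null flag is raised and x = 2.
    """
    ks = profile.ks
    k_max = int(ks[-1])
    if k_max < fit_hi:
        logger.warning("k_max=%d < fit_hi=%d; shrinking fit window", k_max, fit_hi)
        fit_hi = k_max
    if fit_hi - fit_lo < 1:
        raise ValueError("fit window too small for a line fit")
    dk = ks[1:]
    delta = np.diff(profile.gap)

    fit_mask = (dk >= fit_lo) & (dk <= fit_hi)
    slope, intercept = np.polyfit(dk[fit_mask], delta[fit_mask], 1)
    resid = delta[fit_mask] - (slope * dk[fit_mask] + intercept)
    dof = max(int(fit_mask.sum()) - 2, 1)
    sigma_resid = float(np.sqrt((resid ** 2).sum() / dof))

    # per-k scale of Δ under the no-structure null: the gap statistic's own
    # Monte-Carlo dispersion s_k, propagated to the increment (falls back to
    # the fit's residual scatter when the profile carries no dispersions)
    se = np.asarray(profile.se, dtype=float)
    if np.all(se == 0):
        margin = np.full(len(dk), sigma_resid)
    else:
        margin = np.sqrt(se[1:] ** 2 + se[:-1] ** 2)

    x, null_flag = 2, True
    for k, d, m in zip(dk, delta, margin):
        if 3 <= k < fit_lo and d > slope * k + intercept + noise_z * m:
            x, null_flag = int(k), False
    if null_flag:
        logger.warning("no increment exceeded the fitted line; "
                       "no clustering structure detected (x flagged)")
    return XEstimate(x, float(slope), float(intercept), dk, delta,
                     selected_samples or [], null_flag)


def increment_plot_data(profiles_by_run: dict[str, GapProfile],
                        offset_step: float = 0.01):
    """Tidy table (run, k, increment, offset increment) for transition plots,
    each run vertically displaced by ``offset_step``."""
    import pandas as pd

    rows = []
    for i, (run, prof) in enumerate(profiles_by_run.items()):
        dk = prof.ks[1:]
        delta = np.diff(prof.gap)
        for k, d in zip(dk, delta):
            rows.append({"run": run, "k": int(k), "increment": float(d),
                         "offset_increment": float(d + i * offset_step)})
    return pd.DataFrame(rows)


def dump_profiles(profiles: list[GapProfile], path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_index\tk\tgap\tse\n")
        for p in profiles:
            for k, g, s in zip(p.ks, p.gap, p.se):
                fh.write(f"{p.sample_index}\t{k}\t{g:.6f}\t{s:.6f}\n")
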
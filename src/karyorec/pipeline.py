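"""End-to-end orchestration: inputs → adjacencies → contigs → clustering →
gap statistics → x → karyotypes → evaluation.

Every stage writes a plain-text artifact into the run directory and can be
re-run from the cached upstream artifacts, so a deleted downstream file is
reproduced byte-identically under the same seed.  One top-level seed drives
everything; per-ancestor and per-sample RNG substreams are derived from it
deterministically.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import adjacencies as adj
from . import chromosome_assembly as casm
from . import contig_assembly as ctg
from . import evaluation as ev
from . import gmer_clustering as gmc
from . import karyotype_inference as ki
from .genome_io import (GeneFamilyTable, Genome, Phylogeny, families_from_map,
                        filter_families, filtered_genomes, read_genome,
                        read_phylogeny)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All tunables, defaulting to the study's stated values."""

    gap_max: int = 7
    max_family_size: int = 10
    n_samples: int = 100
    g: int = 20
    g_sweep: tuple[int, ...] = ()
    tau: float = 0.3
    max_units: int = 500
    k_max: int = 20
    B: int = 50
    fit_lo: int = 12
    fit_hi: int = 20
    top_n: int = 10
    k_lo: int = 4
    k_hi: int = 10
    min_appearances: int = 2
    eta: float = 0.1
    min_segment_bp: int = 300_000
    seed: int = 0
    x_override: int | None = None   # force k instead of the gap estimate

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {k: v for k, v in data.items() if k in cls.__dataclass_fields__}
        unknown = set(data) - set(known)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "g_sweep" in known:
            known["g_sweep"] = tuple(known["g_sweep"])
        return cls(**known)


@dataclass
class SampleClustering:
    """Per-sample clustering state reused by several stages."""

    units: list[gmc.Gmer]
    C: np.ndarray
    S: np.ndarray
    D: np.ndarray
    tree: np.ndarray
    labels_by_k: dict[int, np.ndarray]


@dataclass
class AncestorResult:
    ancestor_id: int
    samples: list[ctg.ContigSample]
    profiles: list[ki.GapProfile]
    selected: list[int]
    x_estimate: ki.XEstimate
    best_sample: int
    unit_labels: np.ndarray
    clustering: SampleClustering
    karyotype: casm.AncestorKaryotype

    @property
    def x(self) -> int:
        return self.karyotype.x


def load_inputs(gff_paths: dict[str, str | Path],
                family_paths: dict[str, str | Path],
                newick: str | Path,
                max_family_size: int = 10
                ) -> tuple[dict[str, Genome], GeneFamilyTable, Phylogeny]:
    """Read genomes + family maps + tree; filter families; restrict genomes."""
    genomes = {name: read_genome(gff_paths[name], family_paths[name], name)
               for name in sorted(gff_paths)}
    table = filter_families(families_from_map(genomes), max_family_size)
    phylo = read_phylogeny(newick, genomes.keys())
    return filtered_genomes(genomes, table), table, phylo


def cluster_sample(sample: ctg.ContigSample, genomes: dict[str, Genome],
                   config: RunConfig) -> SampleClustering:
    units = gmc.select_units(gmc.cut_gmers(sample.contigs, config.g),
                             config.max_units)
    matches = gmc.match_all(units, genomes, config.tau)
    C = gmc.cooccurrence(matches)
    S, D = gmc.correlation_smooth(C)
    tree = gmc.hier_cluster(D)
    kmax = min(config.k_max, len(units))
    labels_by_k = {k: gmc.cut_k(tree, k) for k in range(2, kmax + 1)}
    return SampleClustering(units, C, S, D, tree, labels_by_k)


def node_samples(genomes: dict[str, Genome], phylo: Phylogeny,
                 ancestor_id: int, config: RunConfig,
                 leaf_adj: dict | None = None) -> list[ctg.ContigSample]:
    """Stage: informative adjacencies → matching graph → sampled contigs."""
    ss = np.random.SeedSequence((config.seed, ancestor_id))
    mwm_ss, _ = ss.spawn(2)
    if leaf_adj is None:
        leaf_adj = adj.extract_all(genomes, config.gap_max)
    node_set = adj.informative_adjacencies(leaf_adj, phylo, ancestor_id)
    graph = ctg.build_matching_graph(node_set)
    return ctg.sample_mwm(graph, config.n_samples, mwm_ss)


def node_profiles(samples: list[ctg.ContigSample],
                  genomes: dict[str, Genome], ancestor_id: int,
                  config: RunConfig
                  ) -> tuple[list[ki.GapProfile], list[SampleClustering]]:
    """Stage: per-sample clustering + gap profile (RNG substreams derived
    from the run seed and ancestor id, so cached contigs resume exactly)."""
    ss = np.random.SeedSequence((config.seed, ancestor_id))
    _, gap_ss = ss.spawn(2)
    profiles: list[ki.GapProfile] = []
    clusterings: list[SampleClustering] = []
    for sample, sub in zip(samples, gap_ss.spawn(len(samples))):
        sc = cluster_sample(sample, genomes, config)
        clusterings.append(sc)
        profiles.append(ki.gap_statistic(
            sc.S, k_max=config.k_max, B=config.B,
            rng=np.random.default_rng(sub), labels_by_k=sc.labels_by_k,
            sample_index=sample.sample_index))
    return profiles, clusterings


def sweep_profile(samples: list[ctg.ContigSample],
                  genomes: dict[str, Genome], ancestor_id: int,
                  config: RunConfig) -> ki.GapProfile:
    """Mean-of-best gap profile averaged over the g values in ``g_sweep``.

    Contigs (and hence the matching cost) are shared across g; only the
    clustering and gap statistics are recomputed per piece length.  The
    average stabilises the increment trend before the inflection is read.
    """
    import dataclasses

    per_g = []
    for g in config.g_sweep:
        cfg_g = dataclasses.replace(config, g=g, g_sweep=())
        profiles, _ = node_profiles(samples, genomes, ancestor_id, cfg_g)
        sel = ki.select_best_samples(profiles, config.top_n, config.k_lo,
                                     config.k_hi, config.min_appearances)
        per_g.append(ki.mean_profile(profiles, sel))
    return ki.average_profiles(per_g)


def node_assemble(samples: list[ctg.ContigSample],
                  profiles: list[ki.GapProfile],
                  genomes: dict[str, Genome], ancestor_id: int,
                  config: RunConfig,
                  clusterings: list[SampleClustering] | None = None
                  ) -> AncestorResult:
    """Stage: select best samples, estimate x, cut + polish the best sample's
    clustering, and assemble the karyotype.

    With a non-empty ``g_sweep`` the x estimate comes from the g-averaged
    profile (the clade-level trend); sample selection and the final assembly
    always use the primary g.
    """
    selected = ki.select_best_samples(profiles, config.top_n, config.k_lo,
                                      config.k_hi, config.min_appearances)
    if config.g_sweep:
        mprof = sweep_profile(samples, genomes, ancestor_id, config)
    else:
        mprof = ki.mean_profile(profiles, selected)
    xest = ki.estimate_x(mprof, config.fit_lo, config.fit_hi, selected)
    x = config.x_override or xest.x

    by_index = {p.sample_index: p for p in profiles}
    best = max(selected,
               key=lambda i: (by_index[i].gap_at(x) if x in by_index[i].ks
                              else -np.inf, -i))
    sc = (clusterings[best] if clusterings is not None
          else cluster_sample(samples[best], genomes, config))
    labels = gmc.dynamic_cut(gmc.cut_k(sc.tree, x), sc.D, config.eta)
    contig_clusters = casm.units_to_contig_clusters(sc.units, labels)
    # contigs not represented among the selected units (shorter than the
    # max_units cutoff) stay out of the karyotype
    karyo = casm.build_karyotype(samples[best].contigs, contig_clusters,
                                 genomes, ancestor_id, config.tau, best,
                                 config.g)
    return AncestorResult(ancestor_id, samples, profiles, selected, xest,
                          best, labels, sc, karyo)


def run_ancestor(genomes: dict[str, Genome], phylo: Phylogeny,
                 ancestor_id: int, config: RunConfig,
                 leaf_adj: dict | None = None) -> AncestorResult:
    """Full reconstruction of one ancestral node."""
    samples = node_samples(genomes, phylo, ancestor_id, config, leaf_adj)
    profiles, clusterings = node_profiles(samples, genomes, ancestor_id, config)
    return node_assemble(samples, profiles, genomes, ancestor_id, config,
                         clusterings)


def run_all(genomes: dict[str, Genome], phylo: Phylogeny, config: RunConfig,
            outdir: str | Path | None = None) -> dict[int, AncestorResult]:
    """Reconstruct every ancestral node; a failing node does not stop the
    others (failures are re-raised jointly at the end)."""
    leaf_adj = adj.extract_all(genomes, config.gap_max)
    results: dict[int, AncestorResult] = {}
    failures: dict[int, Exception] = {}
    for aid in sorted(phylo.ancestors):
        try:
            results[aid] = run_ancestor(genomes, phylo, aid, config, leaf_adj)
            logger.info("ancestor %d: x=%d (%d samples, %d selected)", aid,
                        results[aid].x, config.n_samples,
                        len(results[aid].selected))
        except Exception as exc:  # noqa: BLE001 — per-node isolation
            logger.error("ancestor %d failed: %s", aid, exc)
            failures[aid] = exc
    if outdir is not None:
        write_artifacts(results, genomes, phylo, config, outdir)
    if failures:
        raise RuntimeError(
            "ancestors failed: "
            + "; ".join(f"{aid}: {e}" for aid, e in failures.items()))
    return results


def evaluate_run(results: dict[int, AncestorResult],
                 genomes: dict[str, Genome], phylo: Phylogeny,
                 config: RunConfig):
    """Quality table: each ancestor scored against its immediate descendants
    (extant leaves use their real chromosomes; internal children use their own
    reconstruction from this run)."""
    import pandas as pd

    frames = []
    node_of = {id(node): aid for aid, node in phylo.ancestors.items()}
    for aid, res in results.items():
        node = phylo.ancestors[aid]
        rows = []
        for child in node.child_nodes():
            if child.is_leaf():
                name = child.taxon.label
                genome = genomes[name]
                _, chop = ev.paint(genome, res.karyotype, config.min_segment_bp)
                rows.append({"ancestor": aid, "descendant": name,
                             "kind": "extant",
                             "coherence": ev.coherence(genome, res.karyotype),
                             "choppiness": chop})
            else:
                child_aid = node_of[id(child)]
                if child_aid in results:
                    rows.append({"ancestor": aid,
                                 "descendant": f"Ancestor {child_aid}",
                                 "kind": "ancestral",
                                 "coherence": ev.coherence(
                                     results[child_aid].karyotype,
                                     res.karyotype),
                                 "choppiness": np.nan})
        df = pd.DataFrame(rows)
        df["coverage"] = ev.coverage(res.karyotype)
        df["g"] = config.g
        df["x"] = res.x
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def load_contigs(path: str | Path) -> tuple[int, list[ctg.ContigSample]]:
    """Read a contigs TSV back into ContigSamples (content only: matched
    edges and total weight are not round-tripped)."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    aid = int(df["ancestor_id"].iloc[0]) if len(df) else -1
    samples = []
    for sidx, sdf in df.groupby("sample_index"):
        contigs = []
        for _, cdf in sdf.groupby("contig_id"):
            cdf = cdf.sort_values("position")
            fams = [(sf[1:], +1 if sf[0] == "+" else -1)
                    for sf in cdf["signed_family"]]
            contigs.append(ctg.Contig(fams))
        contigs.sort(key=lambda c: (-len(c), c.families))
        samples.append(ctg.ContigSample(int(sidx), contigs, float("nan")))
    return aid, samples


def load_profiles(path: str | Path) -> list[ki.GapProfile]:
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    profiles = []
    for sidx, sdf in df.groupby("sample_index"):
        sdf = sdf.sort_values("k")
        profiles.append(ki.GapProfile(int(sidx), sdf["k"].to_numpy(),
                                      sdf["gap"].to_numpy(),
                                      sdf["se"].to_numpy(), B=0))
    return profiles


def write_artifacts(results: dict[int, AncestorResult],
                    genomes: dict[str, Genome], phylo: Phylogeny,
                    config: RunConfig, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "config.json", "w") as fh:
        json.dump(asdict(config), fh, indent=2, default=list)
    with open(outdir / "ancestors.tsv", "w") as fh:
        fh.write("ancestor_id\tleaves\n")
        for aid, leaves in phylo.ancestor_table():
            fh.write(f"{aid}\t{leaves}\n")
    report = {}
    for aid, res in results.items():
        ctg.dump_contigs(res.samples, aid, outdir / f"contigs_A{aid}.tsv")
        ki.dump_profiles(res.profiles, outdir / f"gap_profiles_A{aid}.tsv")
        casm.dump_karyotype(res.karyotype, outdir / f"karyotype_A{aid}.tsv")
        segs = []
        for name, genome in genomes.items():
            s, _ = ev.paint(genome, res.karyotype, config.min_segment_bp)
            segs.extend(s)
        ev.write_bed9(segs, outdir / f"painting_A{aid}.bed")
        report[aid] = {
            "x": res.x, "null_flag": res.x_estimate.null_flag,
            "selected_samples": res.selected, "best_sample": res.best_sample,
            "slope": res.x_estimate.slope,
            "intercept": res.x_estimate.intercept,
        }
    with open(outdir / "x_estimates.json", "w") as fh:
        json.dump(report, fh, indent=2)
    evaluate_run(results, genomes, phylo, config).to_csv(
        outdir / "quality.tsv", sep="\t", index=False)
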
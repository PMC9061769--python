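"""End-to-end orchestration over a dataset directory.

Stages (``simulate``, ``cluster``, ``abundance``, ``link-hosts``,
``ecology``, ``network``, ``biogeo``, ``pathfit``) consume and produce
files in one dataset directory, so each can be re-run independently; the
dependency closure of a requested stage subset is computed, and missing
upstream outputs raise a dependency error naming the stage. One global
seed is fanned out to stable per-stage seed streams.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from amdvir import __version__, biogeo
from amdvir.abundance import AbundanceMatrix, build_abundance_matrix
from amdvir.align import read_tabular_hits
from amdvir.clustering import cluster_viral_populations, dereplicate_prokaryote_genomes
from amdvir.ecology import lifestyle_ratio_trend, summarize_lineages
from amdvir.io import (
    read_depth_tsv,
    read_fasta,
    read_links_tsv,
    write_links_tsv,
)
from amdvir.linkage import (
    aggregate_population_links,
    detect_crispr_arrays,
    find_homology_hits,
    link_by_genome_homology,
    link_by_prophage_origin,
    match_spacers,
)
from amdvir.network import (
    barber_modularity_brim,
    build_network,
    extract_subnetwork,
    nodf,
    richness_structure_regression,
)
from amdvir.pathmodel import fit_path_model
from amdvir.records import Cluster
from amdvir.synthetic import SimulationConfig, simulate_dataset, write_dataset

logger = logging.getLogger(__name__)

STAGES = [
    "simulate",
    "cluster",
    "abundance",
    "link-hosts",
    "ecology",
    "network",
    "biogeo",
    "pathfit",
]

DEPENDENCIES: dict[str, list[str]] = {
    "simulate": [],
    "cluster": [],
    "abundance": [],
    "link-hosts": ["cluster"],
    "ecology": ["abundance", "link-hosts"],
    "network": ["abundance", "link-hosts"],
    "biogeo": ["abundance"],
    "pathfit": [],
}


def stage_seed(global_seed: int, stage: str) -> int:
    """Stable per-stage seed below 2^31, derived by hashing the stage name."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2**31)


def dependency_closure(stages: list[str]) -> list[str]:
    """Requested stages plus their transitive dependencies, pipeline order."""
    needed: set[str] = set()

    def visit(s: str) -> None:
        if s in needed:
            return
        for dep in DEPENDENCIES[s]:
            visit(dep)
        needed.add(s)

    for s in stages:
        if s not in DEPENDENCIES:
            raise ValueError(f"unknown stage {s!r}")
        visit(s)
    return [s for s in STAGES if s in needed]


def _require(path: Path, stage: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(
            f"stage {stage!r} requires {path.name}, which is missing from "
            f"{path.parent} — run its upstream stage first"
        )
    return path


def _clusters_from_tsv(path: Path) -> list[Cluster]:
    df = pd.read_csv(path, sep="\t")
    groups: dict[str, list[str]] = {}
    for row in df.itertuples(index=False):
        groups.setdefault(row.representative, []).append(row.member)
    return [Cluster(representative=r, members=m) for r, m in sorted(groups.items())]


def _clusters_to_tsv(clusters: list[Cluster], path: Path) -> None:
    rows = [(m, c.representative) for c in clusters for m in sorted(c.members)]
    pd.DataFrame(rows, columns=["member", "representative"]).to_csv(
        path, sep="\t", index=False
    )


def run_pipeline(
    data_dir: str | Path,
    stages: list[str] | None = None,
    seed: int = 0,
    sim_config: SimulationConfig | None = None,
    n_restarts: int = 10,
) -> dict:
    """Run the requested stages (default: all) over ``data_dir``.

    Returns the report bundle (also written to ``report.json`` in the
    directory). Identical directory contents and seed give identical
    outputs.
    """
    out = Path(data_dir)
    requested = dependency_closure(stages or STAGES)
    report: dict = {
        "version": __version__,
        "seed": seed,
        "stages": requested,
    }

    if "simulate" in requested:
        cfg = sim_config or SimulationConfig(seed=stage_seed(seed, "simulate"))
        dataset = simulate_dataset(cfg)
        write_dataset(dataset, out)
        report["simulate"] = {
            "n_samples": len(dataset.virus_abund.samples),
            "n_viral_genomes": len(dataset.sequences.viruses),
            "n_host_genomes": len(dataset.sequences.hosts),
            "n_true_links": len(dataset.truth.link_pairs()),
        }

    if "cluster" in requested:
        viruses = read_fasta(_require(out / "viruses.fasta", "cluster"), "viral")
        hosts = read_fasta(_require(out / "hosts.fasta", "cluster"), "prokaryotic")
        quality = pd.read_csv(_require(out / "host_quality.tsv", "cluster"), sep="\t")
        qmap = quality.set_index("genome")
        for h in hosts:
            h.completeness = float(qmap.loc[h.id, "completeness"])
            h.contamination = float(qmap.loc[h.id, "contamination"])
        votus = cluster_viral_populations(viruses)
        pops = dereplicate_prokaryote_genomes(hosts)
        _clusters_to_tsv(votus, out / "votu_clusters.tsv")
        _clusters_to_tsv(pops, out / "host_populations.tsv")
        report["cluster"] = {
            "n_viral_genomes": len(viruses),
            "n_votus": len(votus),
            "n_host_genomes": len(hosts),
            "n_host_populations": len(pops),
        }

    if "abundance" in requested:
        tracks = read_depth_tsv(_require(out / "depth_tracks.tsv", "abundance"))
        meta = pd.read_csv(
            _require(out / "metadata.tsv", "abundance"), sep="\t", index_col=0
        )
        libs = meta["library_size"].to_dict()
        for s in libs:
            tracks.setdefault(s, {})
        matrix = build_abundance_matrix(tracks, libs)
        matrix.write_tsv(out / "abundance_computed.tsv")
        report["abundance"] = {
            "n_entities": len(matrix.entities),
            "n_samples": len(matrix.samples),
        }

    if "link-hosts" in requested:
        viruses = read_fasta(_require(out / "viruses.fasta", "link-hosts"), "viral")
        hosts = read_fasta(_require(out / "hosts.fasta", "link-hosts"), "prokaryotic")
        votus = _clusters_from_tsv(_require(out / "votu_clusters.tsv", "link-hosts"))
        pops = _clusters_from_tsv(_require(out / "host_populations.tsv", "link-hosts"))
        binning = pd.read_csv(_require(out / "binning.tsv", "link-hosts"), sep="\t")
        scaffold_to_host = dict(zip(binning["scaffold"], binning["host_genome"]))

        prov_path = out / "provenance.tsv"
        if prov_path.exists():
            prov = pd.read_csv(prov_path, sep="\t")
            vmap = {v.id: v for v in viruses}
            for row in prov.itertuples(index=False):
                if row.virus in vmap:
                    vmap[row.virus].source_scaffold = row.source_scaffold
                    vmap[row.virus].source_interval = (int(row.start), int(row.end))

        hits_path = out / "planted_hits.tsv"
        if hits_path.exists():
            hits = read_tabular_hits(hits_path)
        else:
            hits = find_homology_hits(viruses, hosts, min_hit_length=1000)
        # hits may reference scaffolds; translate to host genome ids
        homology = {
            (v, scaffold_to_host.get(s, s))
            for v, s in link_by_genome_homology(hits)
        }
        spacers = []
        for h in hosts:
            scaffold = next(
                (s for s, g in scaffold_to_host.items() if g == h.id), h.id
            )
            spacers.extend(detect_crispr_arrays(scaffold, h.sequence))
        spacer_host = dict(scaffold_to_host)
        crispr = {
            (virus, spacer_host.get(sp.host_scaffold, sp.host_scaffold))
            for sp, virus in match_spacers(spacers, viruses)
        }
        prophage = link_by_prophage_origin(viruses, scaffold_to_host)
        links = aggregate_population_links(
            {"homology": homology, "crispr": crispr, "prophage": prophage},
            votus,
            pops,
        )
        write_links_tsv(links, out / "links.tsv")
        report["link-hosts"] = {
            "n_links": len(links),
            "n_linked_votus": len({l.virus_population for l in links}),
            "n_linked_host_populations": len({l.host_population for l in links}),
        }

    abundance_split = None
    if {"ecology", "network", "biogeo"} & set(requested):
        matrix = AbundanceMatrix.read_tsv(
            _require(out / "abundance_computed.tsv", "ecology")
        )
        pops = _clusters_from_tsv(_require(out / "host_populations.tsv", "ecology"))
        host_reps = {c.representative for c in pops}
        hdf = matrix.to_frame().loc[[e for e in matrix.entities if e in host_reps]]
        vdf = matrix.to_frame().loc[[e for e in matrix.entities if e not in host_reps]]
        abundance_split = (
            AbundanceMatrix.from_frame(vdf, matrix.library_sizes),
            AbundanceMatrix.from_frame(hdf, matrix.library_sizes),
        )

    if "ecology" in requested:
        virus_abund, host_abund = abundance_split
        links = read_links_tsv(_require(out / "links.tsv", "ecology"))
        tax = pd.read_csv(_require(out / "host_taxonomy.tsv", "ecology"), sep="\t")
        phylum_map = dict(zip(tax["host_population"], tax["phylum"]))
        lifestyles = {}
        ls_path = out / "lifestyles.tsv"
        if ls_path.exists():
            ls = pd.read_csv(ls_path, sep="\t")
            lifestyles = dict(zip(ls["virus_population"], ls["lifestyle"]))
        summaries = summarize_lineages(
            virus_abund, host_abund, links, phylum_map, lifestyles
        )
        lineage_rows = {
            s.phylum: {
                "n_host_populations": s.n_host_populations,
                "n_virus_populations": s.n_virus_populations,
                "mean_log10_vhr": s.mean_log10_vhr,
                "pearson_r": s.abundance_correlation[0] if s.abundance_correlation else np.nan,
                "pearson_p": s.abundance_correlation[1] if s.abundance_correlation else np.nan,
                "host_range_mean": s.host_range_mean,
                "viral_range_mean": s.viral_range_mean,
            }
            for s in summaries
        }
        pd.DataFrame.from_dict(lineage_rows, orient="index").to_csv(
            out / "lineage_summary.tsv", sep="\t", index_label="phylum"
        )
        eco_report = {"lineages": lineage_rows}
        if lifestyles:
            trend = lifestyle_ratio_trend(
                virus_abund, lifestyles, host_abund.to_frame().sum(axis=0)
            )
            eco_report["lifestyle_slopes"] = {
                cls: {"slope": s, "p": p} for cls, (s, p) in trend["slopes"].items()
            }
        report["ecology"] = eco_report

    if "network" in requested:
        virus_abund, host_abund = abundance_split
        links = read_links_tsv(_require(out / "links.tsv", "network"))
        meta_net = build_network(links)
        vdf, hdf = virus_abund.to_frame(), host_abund.to_frame()
        rows = []
        net_seed = stage_seed(seed, "network")
        for s in virus_abund.samples:
            pv = [v for v in meta_net.virus_nodes if v in vdf.index and vdf.loc[v, s] > 0]
            ph = [h for h in meta_net.host_nodes if h in hdf.index and hdf.loc[h, s] > 0]
            sub = extract_subnetwork(meta_net, pv, ph)
            prok_rich = int((hdf[s] > 0).sum())
            vir_rich = int((vdf[s] > 0).sum())
            if sub.n_edges == 0:
                rows.append((s, prok_rich, vir_rich, np.nan, np.nan))
                continue
            q = barber_modularity_brim(sub, n_restarts=n_restarts, seed=net_seed).q
            A, _, _ = sub.active_matrix()
            nd = nodf(A).nodf if (A.shape[0] >= 2 or A.shape[1] >= 2) else np.nan
            rows.append((s, prok_rich, vir_rich, q, nd))
        per_sample = pd.DataFrame(
            rows,
            columns=["sample", "prok_richness", "viral_richness", "modularity", "nestedness"],
        ).set_index("sample")
        per_sample.to_csv(out / "network_per_sample.tsv", sep="\t")
        reg = richness_structure_regression(
            per_sample[["modularity", "nestedness"]],
            per_sample[["prok_richness", "viral_richness"]],
        )
        report["network"] = {
            "meta_edges": meta_net.n_edges,
            "regressions": reg.to_dict(orient="records"),
        }

    if "biogeo" in requested:
        virus_abund, host_abund = abundance_split
        meta = pd.read_csv(out / "metadata.tsv", sep="\t", index_col=0)
        coords = meta[["lat", "lon"]]
        geo = biogeo.geographic_distance(coords)
        vcomm = biogeo.transform(virus_abund.to_frame().T, "hellinger")
        hcomm = biogeo.transform(host_abund.to_frame().T, "hellinger")
        vbc = biogeo.dissimilarity(vcomm, "bray_curtis")
        hbc = biogeo.dissimilarity(hcomm, "bray_curtis")
        r, p = biogeo.mantel_test(hbc, vbc, seed=stage_seed(seed, "biogeo"))
        fit = biogeo.ddr_fit(geo, vbc)
        pcoa_coords, evals = biogeo.pcoa(vbc)
        pcoa_coords.to_csv(out / "pcoa_viral.tsv", sep="\t", index_label="sample")
        prok_rich = (host_abund.to_frame() > 0).sum(axis=0)
        vir_rich = (virus_abund.to_frame() > 0).sum(axis=0)
        from scipy import stats as _stats

        rr = _stats.pearsonr(prok_rich, vir_rich)
        report["biogeo"] = {
            "mantel_r": r,
            "mantel_p": p,
            "ddr": {
                "overall_slope": fit.overall_slope,
                "local_slope": fit.local_slope,
                "regional_slope": fit.regional_slope,
                "p_values": fit.p_values,
                "adjusted_r2": fit.adjusted_r2,
            },
            "richness_pearson_r": float(rr.statistic),
            "richness_pearson_p": float(rr.pvalue),
        }

    if "pathfit" in requested:
        meta = pd.read_csv(_require(out / "metadata.tsv", "pathfit"), sep="\t", index_col=0)
        spec_text = _require(out / "path_model.txt", "pathfit").read_text()
        model = fit_path_model(meta, spec_text)
        report["pathfit"] = model.to_dict()

    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True, default=float) + "\n")
    return report
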
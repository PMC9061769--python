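"""Synthetic AMD viral-community generator with planted ground truth.

The generator builds a complete, internally consistent dataset emulating
the objects the pipeline consumes in the field:

* **sequences** — prokaryotic host genomes (pairs of replicate genomes at
  ~1% divergence, to exercise dereplication) carrying planted prophages,
  CRISPR arrays whose spacers copy viral segments, and >= 2.5 kb shared
  segments; viral genomes in clusters (a random ancestor plus one mutated
  copy per configured divergence level, substitutions only, so expected
  ANI is exactly 100 x (1 - divergence));
* **ecology** — lognormal host abundances thinned by a latitudinal
  richness gradient and an exponential spatial kernel (calibrated
  numerically against the requested distance-decay slope), viral
  abundances tied to linked hosts through planted lineage-specific
  virus-host abundance ratios (VHRs), uniform-depth tracks and library
  sizes that reproduce those abundances through the coverage pipeline,
  and metadata drawn from a configurable recursive path DAG;
* **a truth table** — intended vOTU membership at the clustering
  threshold, all true virus-host pairs with their evidence, lifestyles,
  the structural path coefficients, and the *achieved* noise-free VHRs
  and distance-decay slope (stored rather than assumed exact).

Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from amdvir import biogeo
from amdvir.abundance import AbundanceMatrix, DepthTrack
from amdvir.align import AlignmentHit
from amdvir.records import GenomeRecord
from amdvir import io as amdio

_BASES = np.array(list("ACGT"))
_OTHER = {b: [c for c in "ACGT" if c != b] for b in "ACGT"}


def _default_path_coefficients() -> dict[tuple[str, str], float]:
    # a 7-variable recursive DAG shaped like the drivers model:
    # latitude acts through climate and prokaryotic richness on viral richness
    return {
        ("lat", "MAT"): -0.6,
        ("lat", "MAP"): -0.32,
        ("lat", "prok_richness"): -0.42,
        ("MAT", "prok_richness"): 0.3,
        ("Fe", "prok_richness"): 0.25,
        ("prok_richness", "viral_richness"): 0.86,
        ("MAT", "viral_richness"): 0.2,
        ("pH", "viral_richness"): -0.2,
    }


@dataclass
class SimulationConfig:
    """Study-condition parameters of the synthetic community."""

    seed: int = 0
    n_sites: int = 18
    samples_per_site: int = 5
    n_host_phyla: int = 4
    hosts_per_phylum: int = 3
    viruses_per_host: int = 2
    genome_length_range: tuple[int, int] = (10_000, 20_000)
    divergence_levels: tuple[float, ...] = (0.0, 0.03, 0.10)
    planted_vhr_per_phylum: dict[str, float] | None = None
    prophage_fraction: float = 0.3
    crispr_fraction: float = 0.5
    generalist_extra_links: int = 2
    ddr_slope: float = -0.10
    lat_richness_gradient: float = 1.0
    path_coefficients: dict[tuple[str, str], float] = field(
        default_factory=_default_path_coefficients
    )
    noise_sd: float = 0.1
    n_background_viruses: int = 6
    n_background_hosts: int = 2
    p_virulent: float = 0.5
    lifestyle_assortment: float = 0.9
    site_jitter_km: float = 0.3
    depth_scale: float = 1000.0
    votu_ani_threshold: float = 95.0
    host_replicate_divergence: float = 0.01

    def __post_init__(self) -> None:
        if self.genome_length_range[0] < 10_000:
            raise ValueError("genome_length_range minimum must be >= 10,000 bp")
        for name in ("prophage_fraction", "crispr_fraction", "p_virulent",
                     "lifestyle_assortment"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]: {v}")
        for d in self.divergence_levels:
            if d < 0 or d >= 0.5:
                raise ValueError(
                    f"divergence {d} implies ANI at or below 50%: "
                    "clusters would be indistinguishable from background"
                )
            if d >= 0.45:
                warnings.warn(
                    "divergence close to 0.5: clusters barely distinguishable "
                    "from background",
                    stacklevel=2,
                )
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    def phyla(self) -> list[str]:
        return [f"Phylum_{chr(65 + i)}" for i in range(self.n_host_phyla)]

    def vhr_map(self) -> dict[str, float]:
        if self.planted_vhr_per_phylum is not None:
            return dict(self.planted_vhr_per_phylum)
        values = np.geomspace(1.0, 10.0, self.n_host_phyla)
        return dict(zip(self.phyla(), (float(v) for v in values)))


@dataclass
class TruthTable:
    """Planted ground truth of a synthetic dataset."""

    votu_membership: dict[str, str]
    host_membership: dict[str, str]
    links: set[tuple[str, str, str]]  # (virus_pop, host_pop, evidence)
    lifestyles: dict[str, str]
    path_coefficients: dict[tuple[str, str], float]
    vhr: dict[str, float]  # achieved noise-free per-phylum VHR (ratio scale)
    planted_vhr: dict[str, float]
    ddr_slope: float | None  # achieved on the noise-free viral community
    phylum_of_host: dict[str, str]
    prophage_coords: dict[str, tuple[str, int, int]]
    presence_rank: dict[str, int] = field(default_factory=dict)

    def link_pairs(self) -> set[tuple[str, str]]:
        return {(v, h) for v, h, _ in self.links}

    def to_json(self) -> str:
        payload = {
            "votu_membership": self.votu_membership,
            "host_membership": self.host_membership,
            "links": sorted(list(l) for l in self.links),
            "lifestyles": self.lifestyles,
            "path_coefficients": {f"{a}->{b}": v for (a, b), v in self.path_coefficients.items()},
            "vhr": self.vhr,
            "planted_vhr": self.planted_vhr,
            "ddr_slope": self.ddr_slope,
            "phylum_of_host": self.phylum_of_host,
            "prophage_coords": {k: list(v) for k, v in self.prophage_coords.items()},
            "presence_rank": self.presence_rank,
        }
        return json.dumps(payload, indent=2, sort_keys=True)


@dataclass
class SequenceSet:
    """Output of :func:`simulate_sequences`."""

    hosts: list[GenomeRecord]
    viruses: list[GenomeRecord]
    scaffold_to_host: dict[str, str]
    planted_hits: list[AlignmentHit]
    truth: TruthTable
    virus_pop_of_cluster: dict[str, list[str]]  # population -> member genomes
    host_pop_phylum: dict[str, str]


@dataclass
class SyntheticDataset:
    config: SimulationConfig
    sequences: SequenceSet
    host_abund: AbundanceMatrix
    virus_abund: AbundanceMatrix
    metadata: pd.DataFrame
    depth_tracks: dict[str, dict[str, DepthTrack]]
    truth: TruthTable


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, length)])


def _mutate(seq: str, divergence: float, rng: np.random.Generator) -> str:
    """Substitute exactly round(divergence x L) positions (no indels)."""
    n = int(round(divergence * len(seq)))
    if n == 0:
        return seq
    positions = rng.choice(len(seq), size=n, replace=False)
    out = list(seq)
    for p in positions:
        out[p] = _OTHER[out[p]][rng.integers(0, 3)]
    return "".join(out)


def _make_hit(virus_id: str, scaffold: str, vstart: int, vend: int,
              hstart: int, hend: int, pident: float = 100.0) -> AlignmentHit:
    length = vend - vstart
    matches = round(length * pident / 100)
    return AlignmentHit(
        query=virus_id, subject=scaffold, pident=pident, length=length,
        mismatch=length - matches, gapopen=0, qstart=vstart, qend=vend,
        sstart=hstart, send=hend, evalue=0.0, bitscore=2.0 * matches,
    )


def simulate_sequences(config: SimulationConfig) -> SequenceSet:
    """Generate host and viral genomes with planted linkage evidence.

    Every (host, virus-cluster) pair receives at least one line of
    evidence: a prophage with probability ``prophage_fraction``, a CRISPR
    spacer with probability ``crispr_fraction`` (both may co-occur), and a
    >= 2.5 kb shared segment whenever neither was drawn. One virus per
    phylum is a generalist with extra planted links into the rarest hosts
    of other phyla (the nested generalism gradient). Truth links are
    verified against the constructed sequences, so every recorded CRISPR
    link corresponds to an exact protospacer copy.
    """
    rng = np.random.default_rng([config.seed, 1])
    lo, hi = config.genome_length_range
    phyla = config.phyla()
    ani_floor_div = (100.0 - config.votu_ani_threshold) / 100.0

    votu_membership: dict[str, str] = {}
    host_membership: dict[str, str] = {}
    links: set[tuple[str, str, str]] = set()
    prophage_coords: dict[str, tuple[str, int, int]] = {}
    phylum_of_host: dict[str, str] = {}
    virus_pop_members: dict[str, list[str]] = {}

    # --- viral clusters -----------------------------------------------------
    cluster_seqs: dict[str, list[tuple[str, str, float]]] = {}  # pop -> [(id, seq, div)]
    host_of_cluster: dict[str, str] = {}
    for p, phylum in enumerate(phyla):
        for h in range(config.hosts_per_phylum):
            host_pop = f"host_p{p}_{h}.0"
            phylum_of_host[host_pop] = phylum
            for v in range(config.viruses_per_host):
                base = f"v_p{p}_{h}_{v}"
                length = int(rng.integers(lo, hi + 1))
                ancestor = _random_seq(rng, length)
                members = [(f"{base}.0", ancestor, 0.0)]
                for k, div in enumerate(config.divergence_levels, start=1):
                    members.append((f"{base}.{k}", _mutate(ancestor, div, rng), div))
                pop = f"{base}.0"
                cluster_seqs[pop] = members
                host_of_cluster[pop] = host_pop
                for mid, _, div in members:
                    votu_membership[mid] = pop if div <= ani_floor_div else mid
                virus_pop_members[pop] = [m[0] for m in members]

    # --- choose evidence per (host, cluster) --------------------------------
    # insertion plans per host population: (kind, cluster_pop, payload info)
    plans: dict[str, list[dict]] = {hp: [] for hp in phylum_of_host}
    for pop, members in cluster_seqs.items():
        host_pop = host_of_cluster[pop]
        got_prophage = rng.random() < config.prophage_fraction
        got_crispr = rng.random() < config.crispr_fraction
        if got_prophage:
            plans[host_pop].append({"kind": "prophage", "pop": pop})
        if got_crispr:
            plans[host_pop].append({"kind": "crispr", "pop": pop})
        if not got_prophage and not got_crispr:
            plans[host_pop].append({"kind": "segment", "pop": pop})

    # --- nested generalism: one generalist virus per phylum -----------------
    host_pops = sorted(phylum_of_host)
    # make each phylum's first host common (low rank) so generalist cores
    # persist in species-poor samples
    cores = [f"host_p{p}_0.0" for p in range(config.n_host_phyla)]
    others = [hp for hp in host_pops if hp not in cores]
    order = list(rng.permutation(cores)) + list(rng.permutation(others))
    presence_rank = {hp: i for i, hp in enumerate(order)}
    rare_hosts = sorted(host_pops, key=lambda hp: -presence_rank[hp])
    for p, phylum in enumerate(phyla):
        gen_pop = f"v_p{p}_0_0.0"
        targets = [hp for hp in rare_hosts if phylum_of_host[hp] != phylum]
        for hp in targets[: config.generalist_extra_links]:
            plans[hp].append({"kind": "segment", "pop": gen_pop})

    # --- assemble host genomes with insertions ------------------------------
    hosts: list[GenomeRecord] = []
    viruses: list[GenomeRecord] = []
    scaffold_to_host: dict[str, str] = {}
    planted_hits: list[AlignmentHit] = []
    provirus_info: dict[str, tuple[str, int, int]] = {}

    for host_pop in sorted(plans):
        bg_len = int(rng.integers(lo, hi + 1))
        bg = _random_seq(rng, bg_len)
        inserts = []
        for plan in plans[host_pop]:
            pos = int(rng.integers(500, bg_len - 500))
            inserts.append((pos, plan))
        inserts.sort(key=lambda t: t[0])
        pieces: list[str] = []
        cursor = 0
        offset = 0
        scaffold = f"{host_pop[:-2]}.scf"
        for pos, plan in inserts:
            pieces.append(bg[cursor:pos])
            pop = plan["pop"]
            members = cluster_seqs[pop]
            anc_id, anc_seq, _ = members[0]
            start = pos + offset
            if plan["kind"] == "prophage":
                payload = anc_seq
                provirus_info[anc_id] = (scaffold, start, start + len(payload))
                links.add((pop, host_pop, "prophage"))
                self_hit = (0, len(anc_seq))
                _record_homology_truth(
                    links, planted_hits, members, votu_membership, host_pop,
                    scaffold, self_hit, start,
                )
            elif plan["kind"] == "segment":
                seg_len = 3000
                a = int(rng.integers(0, len(anc_seq) - seg_len))
                payload = anc_seq[a : a + seg_len]
                _record_homology_truth(
                    links, planted_hits, members, votu_membership, host_pop,
                    scaffold, (a, a + seg_len), start,
                )
            else:  # crispr
                payload = _crispr_payload(
                    rng, members, votu_membership, host_pop, links
                )
            pieces.append(payload)
            offset += len(payload)
            cursor = pos
        pieces.append(bg[cursor:])
        base_seq = "".join(pieces)

        compl0 = float(90 + rng.uniform(0, 9))
        cont0 = float(rng.uniform(0, 1))
        compl1 = float(50 + rng.uniform(0, 30))
        cont1 = float(rng.uniform(0, 5))
        g0 = GenomeRecord(
            id=host_pop, sequence=base_seq, kind="prokaryotic",
            completeness=compl0, contamination=cont0,
        )
        rep_seq = _mutate(base_seq, config.host_replicate_divergence, rng)
        g1 = GenomeRecord(
            id=host_pop[:-2] + ".1", sequence=rep_seq, kind="prokaryotic",
            completeness=compl1, contamination=cont1,
        )
        hosts.extend([g0, g1])
        host_membership[g0.id] = host_pop
        host_membership[g1.id] = host_pop
        scaffold_to_host[scaffold] = host_pop

    # --- background genomes --------------------------------------------------
    for i in range(config.n_background_viruses):
        vid = f"bg_virus_{i}"
        seq = _random_seq(rng, int(rng.integers(lo, hi + 1)))
        viruses.append(GenomeRecord(id=vid, sequence=seq, kind="viral"))
        votu_membership[vid] = vid
    for i in range(config.n_background_hosts):
        hid = f"bg_host_{i}.0"
        seq = _random_seq(rng, int(rng.integers(lo, hi + 1)))
        hosts.append(
            GenomeRecord(
                id=hid, sequence=seq, kind="prokaryotic",
                completeness=float(60 + rng.uniform(0, 30)),
                contamination=float(rng.uniform(0, 5)),
            )
        )
        host_membership[hid] = hid
        scaffold_to_host[f"{hid[:-2]}.scf"] = hid

    # viral genome records (proviruses carry provenance)
    for pop, members in cluster_seqs.items():
        for mid, seq, _ in members:
            src = provirus_info.get(mid)
            viruses.append(
                GenomeRecord(
                    id=mid, sequence=seq, kind="viral",
                    source_scaffold=src[0] if src else None,
                    source_interval=(src[1], src[2]) if src else None,
                )
            )
    viruses.sort(key=lambda g: g.id)
    hosts.sort(key=lambda g: g.id)
    prophage_coords.update(provirus_info)

    truth = TruthTable(
        votu_membership=votu_membership,
        host_membership=host_membership,
        links=links,
        lifestyles={},
        path_coefficients=dict(config.path_coefficients),
        vhr={},
        planted_vhr=config.vhr_map(),
        ddr_slope=None,
        phylum_of_host=phylum_of_host,
        prophage_coords=prophage_coords,
        presence_rank=presence_rank,
    )
    return SequenceSet(
        hosts=hosts,
        viruses=viruses,
        scaffold_to_host=scaffold_to_host,
        planted_hits=planted_hits,
        truth=truth,
        virus_pop_of_cluster=virus_pop_members,
        host_pop_phylum=phylum_of_host,
    )


def _record_homology_truth(links, planted_hits, members, votu_membership,
                           host_pop, scaffold, region, host_start) -> None:
    """Record homology truth links for every vOTU among cluster members.

    The planted segment is shared (at the member's divergence) by all
    members of the cluster, so members promoted to their own vOTU by high
    divergence still genuinely share >= 2.5 kb with the host.
    """
    a, b = region
    for mid, _, div in members:
        pident = 100.0 * (1 - div)
        if pident >= 70.0 and (b - a) >= 2500:
            links.add((votu_membership[mid], host_pop, "homology"))
        # one tabular hit per member, at the member's divergence (what a
        # nucleotide search of all viral genomes against the host would find)
        planted_hits.append(
            _make_hit(mid, scaffold, a, b, host_start, host_start + (b - a),
                      pident=round(pident, 2))
        )


def _crispr_payload(rng, members, votu_membership, host_pop, links) -> str:
    """Build a CRISPR array payload: 4 identical repeats, 3 distinct spacers,
    one spacer an exact copy of a viral segment."""
    anc_id, anc_seq, _ = members[0]
    rep_len = int(rng.integers(25, 41))
    repeat = _random_seq(rng, rep_len)
    spacer_lens = [int(rng.integers(30, 41)) for _ in range(3)]
    proto_idx = int(rng.integers(0, 3))
    spacers = []
    sp_len = spacer_lens[proto_idx]
    a = int(rng.integers(0, len(anc_seq) - sp_len))
    proto = anc_seq[a : a + sp_len]
    for i, L in enumerate(spacer_lens):
        if i == proto_idx:
            spacers.append(proto)
        else:
            spacers.append(_random_seq(rng, L))
    while len(set(spacers)) != 3:  # vanishingly unlikely; regenerate
        spacers = [proto if i == proto_idx else _random_seq(rng, L)
                   for i, L in enumerate(spacer_lens)]
    # truth: the spacer matches any member whose protospacer region is intact
    for mid, seq, _ in members:
        if seq[a : a + sp_len] == proto:
            links.add((votu_membership[mid], host_pop, "crispr"))
    parts = [repeat]
    for sp in spacers:
        parts.append(sp)
        parts.append(repeat)
    return "".join(parts)


# ---------------------------------------------------------------------------
# ecology


def _expected_abundances(
    config: SimulationConfig,
    seqs: SequenceSet,
    rng: np.random.Generator,
    decay_length_km: float,
    site_lat: np.ndarray,
    samples: list[str],
    sample_site: np.ndarray,
    dist_site: np.ndarray,
    base_host: dict[str, float],
    home_site: dict[str, int],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Noise-free expected host and virus abundance matrices (pops x samples)."""
    host_pops = sorted(seqs.host_pop_phylum)
    n_samples = len(sample_site)
    abs_lat = np.abs(site_lat)
    lat_min = abs_lat.min()
    n_hosts = len(host_pops)
    richness = np.clip(
        np.round(n_hosts - config.lat_richness_gradient * (abs_lat - lat_min)),
        2, n_hosts,
    ).astype(int)

    H = np.zeros((n_hosts, n_samples))
    for i, hp in enumerate(host_pops):
        rank = seqs.truth.presence_rank[hp]
        for s in range(n_samples):
            site = sample_site[s]
            if rank < richness[site]:
                H[i, s] = base_host[hp] * np.exp(
                    -dist_site[home_site[hp], site] / decay_length_km
                )
    hostdf = pd.DataFrame(H, index=host_pops, columns=samples)

    # viruses: abundance flows from linked hosts through the planted VHRs
    pair_links: dict[str, list[str]] = {}
    n_vlinks: dict[str, int] = {}
    for v, h in seqs.truth.link_pairs():
        pair_links.setdefault(v, []).append(h)
        n_vlinks[h] = n_vlinks.get(h, 0) + 1
    vhr = config.vhr_map()
    virus_pops = sorted(pair_links)
    V = np.zeros((len(virus_pops), n_samples))
    for i, vp in enumerate(virus_pops):
        for h in pair_links[vp]:
            phylum = seqs.host_pop_phylum[h]
            V[i] += vhr[phylum] * hostdf.loc[h].to_numpy() / n_vlinks[h]
    virusdf = pd.DataFrame(V, index=virus_pops, columns=samples)
    return hostdf, virusdf


def simulate_ecology(config: SimulationConfig, seqs: SequenceSet) -> SyntheticDataset:
    """Generate abundances, depth tracks, metadata and finalize the truth.

    Host abundances are lognormal bases modulated by an exponential
    spatial kernel (the kernel length is calibrated on the noise-free
    expectation so the viral distance-decay slope approximates
    ``config.ddr_slope``; the achieved slope is stored in the truth
    table) and a latitudinal richness gradient over nested presence
    ranks. Virus abundance = planted VHR x linked-host abundance x
    lognormal noise. Depth tracks are uniform at depth = abundance x
    depth_scale x library-size factor, so the coverage pipeline recovers
    the abundances up to integer rounding.
    """
    rng = np.random.default_rng([config.seed, 2])
    n_sites, k = config.n_sites, config.samples_per_site
    site_lat = rng.uniform(22.0, 30.0, n_sites)
    site_lon = rng.uniform(101.0, 113.0, n_sites)
    sample_site = np.repeat(np.arange(n_sites), k)
    samples = [f"S{t:02d}_{r}" for t in range(n_sites) for r in range(k)]
    jdeg = config.site_jitter_km / 111.19
    lat = site_lat[sample_site] + rng.normal(0, jdeg, len(samples))
    lon = site_lon[sample_site] + rng.normal(0, jdeg, len(samples))
    coords = pd.DataFrame({"lat": lat, "lon": lon}, index=samples)
    geo = biogeo.geographic_distance(coords)
    site_coords = pd.DataFrame({"lat": site_lat, "lon": site_lon},
                               index=[f"site{t}" for t in range(n_sites)])
    dist_site = biogeo.geographic_distance(site_coords).values

    host_pops = sorted(seqs.host_pop_phylum)
    base_host = {hp: float(np.exp(rng.normal(0, 1))) for hp in host_pops}
    home_site = {hp: int(rng.integers(0, n_sites)) for hp in host_pops}

    # calibrate the kernel length against the requested distance-decay slope
    # the last grid point effectively disables the kernel (flat decay)
    lambdas = np.append(np.geomspace(20, 2000, 12), 1e8)
    best = (np.inf, lambdas[0], None, None, None)
    for lam in lambdas:
        H, V = _expected_abundances(
            config, seqs, rng, lam, site_lat, samples, sample_site, dist_site,
            base_host, home_site,
        )
        slope = _viral_ddr_slope(V, geo)
        score = abs(slope - config.ddr_slope) if np.isfinite(slope) else np.inf
        if score < best[0]:
            best = (score, lam, H, V, slope)
    _, lam, hostdf, virusdf, achieved_slope = best

    # background viruses: independent lognormal bases with the same kernel
    bg_rows = {}
    for g in seqs.viruses:
        if g.id.startswith("bg_virus_"):
            b = float(np.exp(rng.normal(0, 1))) * 0.5
            home = int(rng.integers(0, n_sites))
            bg_rows[g.id] = b * np.exp(-dist_site[home, sample_site] / lam)
    if bg_rows:
        virusdf = pd.concat([virusdf, pd.DataFrame(bg_rows, index=samples).T])
        virusdf = virusdf.sort_index()

    # achieved noise-free per-phylum VHR
    vhr_achieved: dict[str, float] = {}
    pair_links = seqs.truth.link_pairs()
    for phylum in sorted(set(seqs.host_pop_phylum.values())):
        hs = [h for h, ph in seqs.host_pop_phylum.items() if ph == phylum]
        vs = sorted({v for v, h in pair_links if h in hs})
        if not vs:
            continue
        hsum = hostdf.loc[hs].sum(axis=0).to_numpy()
        vsum = virusdf.loc[vs].sum(axis=0).to_numpy()
        ok = (hsum > 0) & (vsum > 0)
        if ok.any():
            vhr_achieved[phylum] = float(
                10 ** np.mean(np.log10(vsum[ok] / hsum[ok]))
            )

    # noise and matrices
    noise = lambda shape: np.exp(rng.normal(0, config.noise_sd, shape))  # noqa: E731
    libs = np.round(1e6 * np.exp(rng.normal(0, 0.2, len(samples))))
    host_vals = hostdf.to_numpy() * noise(hostdf.shape)
    virus_vals = virusdf.to_numpy() * noise(virusdf.shape)

    # depth tracks reproducing the abundances through the coverage formula
    lengths = {g.id: len(g) for g in seqs.hosts + seqs.viruses}
    mean_lib = libs.mean()
    tracks: dict[str, dict[str, DepthTrack]] = {s: {} for s in samples}
    for df_vals, index in ((host_vals, list(hostdf.index)), (virus_vals, list(virusdf.index))):
        for i, entity in enumerate(index):
            for j, s in enumerate(samples):
                depth = int(round(df_vals[i, j] * config.depth_scale * libs[j] / mean_lib))
                if depth > 0:
                    tracks[s][entity] = DepthTrack(
                        entity, np.full(lengths[entity], depth, dtype=np.int32)
                    )

    host_abund = AbundanceMatrix(
        list(hostdf.index), samples, host_vals * config.depth_scale, libs
    )
    virus_abund = AbundanceMatrix(
        list(virusdf.index), samples, virus_vals * config.depth_scale, libs
    )

    # metadata from the path DAG (lat observed from the geometry)
    metadata = _simulate_metadata(config, coords, rng)
    metadata["site"] = [f"site{t}" for t in sample_site]
    metadata["library_size"] = libs

    # lifestyles: assortative labelling plants the virulent-with-abundance trend
    lifestyles = _assign_lifestyles(config, virus_abund, host_abund, rng)

    truth = seqs.truth
    truth.vhr = vhr_achieved
    truth.ddr_slope = achieved_slope
    truth.lifestyles = lifestyles

    return SyntheticDataset(
        config=config,
        sequences=seqs,
        host_abund=host_abund,
        virus_abund=virus_abund,
        metadata=metadata,
        depth_tracks=tracks,
        truth=truth,
    )


def _viral_ddr_slope(virusdf: pd.DataFrame, geo: biogeo.DistanceMatrix) -> float:
    comm = virusdf.T  # samples x populations
    if (comm.sum(axis=1) == 0).any() or comm.shape[1] < 2:
        return np.nan
    hel = biogeo.transform(comm, "hellinger")
    bc = biogeo.dissimilarity(hel, "bray_curtis")
    fit = biogeo.ddr_fit(geo, bc)
    return fit.overall_slope


def _simulate_metadata(
    config: SimulationConfig, coords: pd.DataFrame, rng: np.random.Generator
) -> pd.DataFrame:
    edges = list(config.path_coefficients)
    variables: list[str] = []
    for a, b in edges:
        for v in (a, b):
            if v not in variables:
                variables.append(v)
    parents = {v: [] for v in variables}
    for a, b in edges:
        parents[b].append(a)
    from graphlib import TopologicalSorter

    ts = TopologicalSorter({v: set(parents[v]) for v in variables})
    order = list(ts.static_order())
    n = len(coords)
    data: dict[str, np.ndarray] = {}
    lat = coords["lat"].to_numpy()
    for v in order:
        if not parents[v]:
            if v == "lat":
                z = np.abs(lat)
                data[v] = (z - z.mean()) / z.std()
            else:
                data[v] = rng.standard_normal(n)
        else:
            mean = sum(
                config.path_coefficients[(u, v)] * data[u] for u in parents[v]
            )
            data[v] = mean + config.noise_sd * rng.standard_normal(n)
    out = pd.DataFrame(data, index=coords.index)
    if "lat" in out.columns:  # keep the observed coordinate, expose the z-score
        out = out.rename(columns={"lat": "lat_z"})
    out.insert(0, "lon", coords["lon"])
    out.insert(0, "lat", coords["lat"])
    return out


def _assign_lifestyles(
    config: SimulationConfig,
    virus_abund: AbundanceMatrix,
    host_abund: AbundanceMatrix,
    rng: np.random.Generator,
) -> dict[str, str]:
    v = virus_abund.to_frame()
    total_v = v.sum(axis=0)
    prok = host_abund.to_frame().sum(axis=0).to_numpy()
    scores = {}
    for entity in v.index:
        rel = np.where(total_v > 0, v.loc[entity] / total_v.replace(0, np.nan), 0.0)
        rel = np.nan_to_num(rel)
        scores[entity] = float(np.corrcoef(rel, prok)[0, 1]) if np.std(rel) > 0 else 0.0
    ranked = sorted(scores, key=lambda e: -scores[e])
    n_vir = int(round(config.p_virulent * len(ranked)))
    labels = {}
    for i, entity in enumerate(ranked):
        intended = "virulent" if i < n_vir else "temperate"
        if rng.random() < config.lifestyle_assortment:
            labels[entity] = intended
        else:
            labels[entity] = "virulent" if rng.random() < config.p_virulent else "temperate"
    return labels


def simulate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Convenience wrapper: sequences then ecology."""
    return simulate_ecology(config, simulate_sequences(config))


def _exogenous_variables(coefficients) -> list[tuple[str, str]]:
    """All free covariance pairs among exogenous variables of the DAG."""
    effects = {b for _, b in coefficients}
    variables: list[str] = []
    for a, b in coefficients:
        for v in (a, b):
            if v not in variables:
                variables.append(v)
    exog = sorted(v for v in variables if v not in effects)
    return [(a, b) for i, a in enumerate(exog) for b in exog[i + 1 :]]


# ---------------------------------------------------------------------------
# serialization


def write_dataset(dataset: SyntheticDataset, out_dir: str | Path) -> dict:
    """Write the dataset to ``out_dir`` and return the checksum manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seqs = dataset.sequences
    amdio.write_fasta(seqs.hosts, out / "hosts.fasta")
    amdio.write_fasta(seqs.viruses, out / "viruses.fasta")
    from amdvir.align import write_tabular_hits

    write_tabular_hits(seqs.planted_hits, out / "planted_hits.tsv")
    dataset.host_abund.write_tsv(out / "abundance_hosts.tsv")
    dataset.virus_abund.write_tsv(out / "abundance_viruses.tsv")
    amdio.write_depth_tsv(dataset.depth_tracks, out / "depth_tracks.tsv")
    dataset.metadata.to_csv(out / "metadata.tsv", sep="\t", index_label="sample",
                            float_format="%.6g")
    pd.DataFrame(
        sorted(seqs.scaffold_to_host.items()), columns=["scaffold", "host_genome"]
    ).to_csv(out / "binning.tsv", sep="\t", index=False)
    prov = [
        (g.id, g.source_scaffold, g.source_interval[0], g.source_interval[1])
        for g in seqs.viruses
        if g.source_scaffold is not None
    ]
    pd.DataFrame(
        prov, columns=["virus", "source_scaffold", "start", "end"]
    ).to_csv(out / "provenance.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            (g.id, round(g.completeness, 3), round(g.contamination, 3))
            for g in seqs.hosts
        ],
        columns=["genome", "completeness", "contamination"],
    ).to_csv(out / "host_quality.tsv", sep="\t", index=False)
    pd.DataFrame(
        sorted(seqs.host_pop_phylum.items()), columns=["host_population", "phylum"]
    ).to_csv(out / "host_taxonomy.tsv", sep="\t", index=False)
    pd.DataFrame(
        sorted(dataset.truth.lifestyles.items()), columns=["virus_population", "lifestyle"]
    ).to_csv(out / "lifestyles.tsv", sep="\t", index=False)
    spec_lines = [
        f"{a} -> {b}" for a, b in sorted(dataset.config.path_coefficients)
    ]
    exog = _exogenous_variables(dataset.config.path_coefficients)
    spec_lines += [f"{a} ~~ {b}" for a, b in exog]
    (out / "path_model.txt").write_text("\n".join(spec_lines) + "\n")
    (out / "truth.json").write_text(dataset.truth.to_json() + "\n")
    files = [p for p in out.iterdir() if p.name != "manifest.json"]
    return amdio.write_manifest(files, out / "manifest.json")
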
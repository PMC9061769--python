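"""Genome and protein clustering.

Viral genomes are clustered into vOTUs (species-level viral populations) at
95% average nucleotide identity (ANI) and 85% aligned fraction (AF) of the
shorter sequence. Prokaryotic genomes are dereplicated into populations by
single-linkage grouping at 97% ANI / 70% AF, the representative being the
member maximizing completeness - 4 x contamination. Predicted proteins are
clustered greedily at 60% identity / 80% coverage of the shorter sequence
(the "protein clusters", PCs, used as functional units downstream).
"""

from __future__ import annotations

from collections import defaultdict
from typing import Iterable, Mapping, Sequence

import edlib

from amdvir.align import seed_extend_hits
from amdvir.records import AlignmentHit, AniResult, Cluster, GenomeRecord

VIRAL_MIN_LENGTH = 10_000


def _subject_interval(h: AlignmentHit) -> tuple[int, int]:
    lo, hi = sorted((h.sstart, h.send))
    return lo, hi


def _merge_add(covered: list[tuple[int, int]], iv: tuple[int, int]) -> tuple[int, list[tuple[int, int]]]:
    """Add an interval to a merged set; return novel bp and the new set."""
    lo, hi = iv
    novel = hi - lo
    out = []
    for a, b in covered:
        if b < lo or a > hi:
            out.append((a, b))
        else:
            novel -= min(b, hi) - max(a, lo)
            lo, hi = min(a, lo), max(b, hi)
    novel = max(novel, 0)
    out.append((lo, hi))
    out.sort()
    return novel, out


def compute_ani_af(
    a: GenomeRecord,
    b: GenomeRecord,
    hits: Sequence[AlignmentHit] | None = None,
) -> AniResult:
    """Pairwise ANI and aligned fraction of the shorter sequence.

    ANI is the alignment-length-weighted mean percent identity over
    non-redundant hit intervals (hits processed best-score first; only the
    novel coverage each contributes on the shorter sequence is counted).
    AF is the merged coverage of the shorter sequence in percent. A pair
    with no hits yields ``AniResult(0, 0)``.
    """
    a_is_shorter = (len(a), a.id) <= (len(b), b.id)
    short, other = (a, b) if a_is_shorter else (b, a)
    if hits is None:
        hits = seed_extend_hits(short.id, short.sequence, other.id, other.sequence)
    rel = []
    for h in hits:
        if h.query == short.id and h.subject == other.id:
            rel.append((h, (h.qstart, h.qend)))
        elif h.query == other.id and h.subject == short.id:
            rel.append((h, _subject_interval(h)))
        elif h.query == h.subject == short.id == other.id:
            rel.append((h, (h.qstart, h.qend)))
    if not rel:
        return AniResult(0.0, 0.0)
    rel.sort(key=lambda t: (-t[0].bitscore, t[1]))
    covered: list[tuple[int, int]] = []
    wsum = 0.0
    wid = 0.0
    for h, iv in rel:
        novel, covered = _merge_add(covered, iv)
        if novel > 0:
            wsum += novel
            wid += novel * h.pident
    total = sum(b - a for a, b in covered)
    ani = wid / wsum if wsum else 0.0
    af = min(100.0, 100.0 * total / len(short))
    return AniResult(ani, af)


def _canonical_order(genomes: Iterable[GenomeRecord]) -> list[GenomeRecord]:
    return sorted(genomes, key=lambda g: (-len(g), g.id))


def _hits_by_pair(hits: Sequence[AlignmentHit] | None) -> dict[frozenset[str], list[AlignmentHit]] | None:
    if hits is None:
        return None
    table: dict[frozenset[str], list[AlignmentHit]] = defaultdict(list)
    for h in hits:
        table[frozenset((h.query, h.subject))].append(h)
    return table


def _pair_ani(
    a: GenomeRecord,
    b: GenomeRecord,
    hit_table: dict[frozenset[str], list[AlignmentHit]] | None,
) -> AniResult:
    if hit_table is None:
        return compute_ani_af(a, b)
    return compute_ani_af(a, b, hit_table.get(frozenset((a.id, b.id)), []))


def cluster_viral_populations(
    genomes: Sequence[GenomeRecord],
    ani_min: float = 95.0,
    af_min: float = 85.0,
    hits: Sequence[AlignmentHit] | None = None,
    linkage: str = "centroid",
) -> list[Cluster]:
    """Cluster viral genomes into vOTUs at ANI >= ``ani_min`` and
    AF >= ``af_min``.

    The default is greedy centroid clustering: genomes are processed longest
    first (ties broken lexicographically by id) and each joins the first
    existing representative meeting both thresholds, else founds a new
    cluster. ``linkage="single"`` instead groups connected components of the
    threshold graph, with the longest member as representative. Externally
    computed tabular hits may be supplied; otherwise the built-in aligner is
    used.
    """
    for g in genomes:
        if len(g) < VIRAL_MIN_LENGTH:
            raise ValueError(
                f"viral genome {g.id!r} is {len(g)} bp, below the "
                f"{VIRAL_MIN_LENGTH} bp clustering floor"
            )
    ordered = _canonical_order(genomes)
    table = _hits_by_pair(hits)
    if linkage == "centroid":
        clusters: list[Cluster] = []
        reps: list[GenomeRecord] = []
        for g in ordered:
            for cl, rep in zip(clusters, reps):
                r = _pair_ani(g, rep, table)
                if r.ani >= ani_min and r.af_smaller >= af_min:
                    cl.members.append(g.id)
                    break
            else:
                clusters.append(Cluster(representative=g.id, members=[g.id]))
                reps.append(g)
        return clusters
    if linkage == "single":
        return _single_linkage(
            ordered, table, ani_min, af_min,
            rep_key=lambda g: (-len(g), g.id),
        )
    raise ValueError(f"unknown linkage {linkage!r}")


def _single_linkage(
    ordered: list[GenomeRecord],
    table: dict[frozenset[str], list[AlignmentHit]] | None,
    ani_min: float,
    af_min: float,
    rep_key,
) -> list[Cluster]:
    parent = {g.id: g.id for g in ordered}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, a in enumerate(ordered):
        for b in ordered[i + 1 :]:
            if find(a.id) == find(b.id):
                continue
            r = _pair_ani(a, b, table)
            if r.ani >= ani_min and r.af_smaller >= af_min:
                parent[find(b.id)] = find(a.id)
    groups: dict[str, list[GenomeRecord]] = defaultdict(list)
    for g in ordered:
        groups[find(g.id)].append(g)
    clusters = []
    for members in groups.values():
        rep = min(members, key=rep_key)
        clusters.append(
            Cluster(representative=rep.id, members=sorted(m.id for m in members))
        )
    clusters.sort(key=lambda c: c.representative)
    return clusters


def dereplicate_prokaryote_genomes(
    genomes: Sequence[GenomeRecord],
    ani_min: float = 97.0,
    af_min: float = 70.0,
    hits: Sequence[AlignmentHit] | None = None,
) -> list[Cluster]:
    """Group prokaryotic genomes into populations (single linkage at
    ANI >= 97 / AF >= 70); the representative maximizes
    completeness - 4 x contamination (ties: lexicographic id).

    Inputs are expected to be pre-filtered to >= 50% completeness and
    < 10% contamination; missing quality fields raise ``ValueError``.
    """
    for g in genomes:
        if g.completeness is None or g.contamination is None:
            raise ValueError(f"genome {g.id!r} lacks completeness/contamination")
    ordered = _canonical_order(genomes)
    table = _hits_by_pair(hits)
    return _single_linkage(
        ordered, table, ani_min, af_min,
        rep_key=lambda g: (-g.quality_score, g.id),
    )


def cluster_proteins(
    proteins: Mapping[str, str] | Sequence[tuple[str, str]],
    id_min: float = 60.0,
    cov_min: float = 80.0,
) -> list[Cluster]:
    """Greedy longest-first protein clustering (cd-hit style).

    A protein joins the first representative with global percent identity
    >= ``id_min`` over an alignment covering >= ``cov_min`` percent of the
    shorter sequence. The resulting clusters are the protein clusters (PCs)
    counted as functional units downstream.
    """
    items = list(proteins.items()) if isinstance(proteins, Mapping) else list(proteins)
    items.sort(key=lambda t: (-len(t[1]), t[0]))
    clusters: list[Cluster] = []
    reps: list[tuple[str, str]] = []
    for pid, seq in items:
        for cl, (rid, rseq) in zip(clusters, reps):
            ident, cov = _protein_identity(seq, rseq)
            if ident >= id_min and cov >= cov_min:
                cl.members.append(pid)
                break
        else:
            clusters.append(Cluster(representative=pid, members=[pid]))
            reps.append((pid, seq))
    return clusters


def _protein_identity(a: str, b: str) -> tuple[float, float]:
    """Percent identity and coverage of the shorter sequence.

    The shorter sequence is aligned as an infix of the longer (end gaps on
    the longer sequence are free), so coverage of the shorter is complete
    whenever an alignment exists; identity charges every edit against the
    shorter sequence's length.
    """
    short, long_ = (a, b) if len(a) <= len(b) else (b, a)
    res = edlib.align(short, long_, mode="HW", task="distance")
    ident = 100.0 * max(0, len(short) - res["editDistance"]) / len(short)
    return ident, 100.0
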
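"""Virus-host linkage by three lines of evidence.

1. **Genome homology** — local alignment hits between viral and prokaryotic
   genomes passing E-value <= 1e-3, bit score >= 50, alignment length
   >= 2.5 kb, identity >= 70%.
2. **Prophage origin** — a provirus is linked to the population containing
   the scaffold it was excised from (provenance, not re-detection).
3. **CRISPR spacers** — spacers recovered from host scaffolds must match a
   viral genome exactly over their whole length (either strand); this is the
   zero-mismatch reading of a BLASTn search at E <= 1e-10, which at spacer
   lengths >= 20 bp reduces to exact substring search.

Genome-level pairs are then aggregated to population level through the
vOTU / host-population clusterings, with evidence flags unioned and support
counting the distinct genome-level pairs behind each population pair.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from typing import Iterable, Mapping, Sequence

from amdvir.align import reverse_complement, seed_extend_hits
from amdvir.records import AlignmentHit, Cluster, GenomeRecord, SpacerRecord

logger = logging.getLogger(__name__)

# CRT-like bounds for the minimal exact-repeat CRISPR detector
REPEAT_MIN, REPEAT_MAX = 19, 47
SPACER_MIN, SPACER_MAX = 20, 58
MIN_REPEATS = 3

HOMOLOGY_MAX_EVALUE = 1e-3
HOMOLOGY_MIN_BITSCORE = 50.0
HOMOLOGY_MIN_LENGTH = 2500
HOMOLOGY_MIN_IDENTITY = 70.0


def detect_crispr_arrays(scaffold_id: str, sequence: str) -> list[SpacerRecord]:
    """Find CRISPR arrays as >= 3 consecutive exact repeats (19-47 bp) whose
    gaps (spacers) are 20-58 bp and mutually distinct; returns the spacers
    in array order. Scaffolds without arrays yield an empty list.
    """
    n = len(sequence)
    if n < 150:
        return []
    seed = REPEAT_MIN
    # periods between consecutive repeat starts achievable under the bounds
    period_lo = seed + SPACER_MIN
    period_hi = REPEAT_MAX + SPACER_MAX
    spacers: list[SpacerRecord] = []
    array_index = 0
    i = 0
    while i < n - 2 * seed - SPACER_MIN:
        word = sequence[i : i + seed]
        # chain occurrences of the seed word at plausible periods
        starts = [i]
        while True:
            prev = starts[-1]
            nxt = sequence.find(word, prev + period_lo, min(n, prev + period_hi + seed))
            if nxt == -1:
                break
            starts.append(nxt)
        if len(starts) < MIN_REPEATS:
            i += 1
            continue
        # the seed may carry a junk prefix when the flanking spacers happen to
        # agree on their last bases; extend the chain with an inner core word
        # so copies with divergent flanks are not dropped, then refine the
        # repeat boundary by unanimity across all copies
        off = 2
        core_len = seed - off
        core = sequence[i + off : i + off + core_len]
        while True:
            prev = starts[-1]
            lo = prev + period_lo - off
            hi = min(n, prev + period_hi + seed)
            pos = sequence.find(core, lo + off, hi)
            if pos == -1 or pos - off <= prev:
                break
            starts.append(pos - off)
        dl, rep_len = _unanimous_window(sequence, starts, off, off + core_len)
        starts = [st + dl for st in starts]
        rep_len = min(rep_len, REPEAT_MAX)
        rep_len = min(rep_len, min(b - a for a, b in zip(starts, starts[1:])) - SPACER_MIN)
        gaps = [(a + rep_len, b) for a, b in zip(starts, starts[1:])]
        if rep_len < REPEAT_MIN or not all(
            SPACER_MIN <= b - a <= SPACER_MAX for a, b in gaps
        ):
            i += 1
            continue
        seqs = [sequence[a:b] for a, b in gaps]
        if len(set(seqs)) != len(seqs):  # spacers must be mutually distinct
            i += 1
            continue
        for a, b in gaps:
            spacers.append(
                SpacerRecord(
                    host_scaffold=scaffold_id,
                    array_index=array_index,
                    spacer_seq=sequence[a:b],
                    position=(a, b),
                )
            )
        array_index += 1
        i = starts[-1] + rep_len
    return spacers


def _unanimous_window(seq: str, starts: list[int], anchor_lo: int, anchor_hi: int) -> tuple[int, int]:
    """Maximal contiguous column window, containing the anchor columns, on
    which ALL chained copies agree. Returns (left offset, window length)."""
    n = len(seq)
    ref = starts[0]
    others = starts[1:]

    def agree(c: int) -> bool:
        if ref + c < 0 or any(st + c >= n or st + c < 0 for st in starts):
            return False
        ch = seq[ref + c]
        return all(seq[st + c] == ch for st in others)

    left = anchor_lo
    while left > 0 and agree(left - 1):
        left -= 1
    right = anchor_hi
    limit = anchor_lo + REPEAT_MAX + 4
    while right < limit and agree(right):
        right += 1
    return left, right - left


def match_spacers(
    spacers: Sequence[SpacerRecord],
    viral_genomes: Sequence[GenomeRecord],
    both_strands: bool = True,
) -> list[tuple[SpacerRecord, str]]:
    """Exact full-length spacer -> protospacer matches against viral genomes.

    A hit requires the spacer (or, by default, its reverse complement) to
    occur verbatim in the viral genome; spacers shorter than 20 bp are
    rejected with a warning since they cannot support the matching
    stringency.
    """
    usable = []
    for sp in spacers:
        if len(sp.spacer_seq) < 20:
            logger.warning(
                "spacer %s:%d (%d bp) below 20 bp; skipped",
                sp.host_scaffold, sp.array_index, len(sp.spacer_seq),
            )
        else:
            usable.append(sp)
    hits = []
    for virus in viral_genomes:
        seq = virus.sequence
        for sp in usable:
            if sp.spacer_seq in seq or (
                both_strands and reverse_complement(sp.spacer_seq) in seq
            ):
                hits.append((sp, virus.id))
    return hits


def find_homology_hits(
    viral_genomes: Sequence[GenomeRecord],
    host_genomes: Sequence[GenomeRecord],
    min_hit_length: int = 1000,
) -> list[AlignmentHit]:
    """Search viral genomes against host genomes with the built-in aligner.

    A convenience for self-contained runs; hits produced by an external
    BLASTn search (12-column tabular) can be used instead.
    """
    out: list[AlignmentHit] = []
    for v in viral_genomes:
        for h in host_genomes:
            out.extend(
                seed_extend_hits(
                    v.id, v.sequence, h.id, h.sequence, min_hit_length=min_hit_length
                )
            )
    return out


def link_by_genome_homology(hits: Iterable[AlignmentHit]) -> set[tuple[str, str]]:
    """(virus genome, host genome) pairs whose best hit passes all four
    homology thresholds; one pair per (virus, host) regardless of hit count."""
    pairs = set()
    for h in hits:
        if (
            h.evalue <= HOMOLOGY_MAX_EVALUE
            and h.bitscore >= HOMOLOGY_MIN_BITSCORE
            and h.length >= HOMOLOGY_MIN_LENGTH
            and h.pident >= HOMOLOGY_MIN_IDENTITY
        ):
            pairs.add((h.query, h.subject))
    return pairs


def link_by_prophage_origin(
    viral_genomes: Sequence[GenomeRecord],
    scaffold_to_host: Mapping[str, str],
) -> set[tuple[str, str]]:
    """Link each provirus to the host genome owning its source scaffold.

    ``scaffold_to_host`` maps scaffold id -> host genome id (the binning).
    Proviruses whose source scaffold is unbinned produce a warning, no link.
    """
    pairs = set()
    for v in viral_genomes:
        if v.source_scaffold is None:
            continue
        host = scaffold_to_host.get(v.source_scaffold)
        if host is None:
            logger.warning(
                "provirus %s: source scaffold %s not assigned to any host genome",
                v.id, v.source_scaffold,
            )
            continue
        pairs.add((v.id, host))
    return pairs


def aggregate_population_links(
    genome_pairs: Mapping[str, Iterable[tuple[str, str]]],
    votu_clusters: Sequence[Cluster],
    host_populations: Sequence[Cluster],
) -> list["VirusHostLink"]:
    """Map genome-level (virus, host) pairs to population-level links.

    ``genome_pairs`` maps evidence type ("homology", "prophage", "crispr")
    to its genome-level pairs. Evidence flags are unioned per population
    pair; support counts the distinct genome-level pairs behind it.
    """
    from amdvir.records import VirusHostLink

    virus_pop = {m: c.representative for c in votu_clusters for m in c.members}
    host_pop = {m: c.representative for c in host_populations for m in c.members}
    evidence: dict[tuple[str, str], set[str]] = defaultdict(set)
    supports: dict[tuple[str, str], set[tuple[str, str]]] = defaultdict(set)
    for ev, pairs in genome_pairs.items():
        for vg, hg in pairs:
            if vg not in virus_pop:
                raise ValueError(f"virus genome {vg!r} missing from vOTU clustering")
            if hg not in host_pop:
                raise ValueError(f"host genome {hg!r} missing from population clustering")
            key = (virus_pop[vg], host_pop[hg])
            evidence[key].add(ev)
            supports[key].add((vg, hg))
    links = [
        VirusHostLink(
            virus_population=v,
            host_population=h,
            evidence=frozenset(evidence[(v, h)]),
            support=len(supports[(v, h)]),
        )
        for v, h in sorted(evidence)
    ]
    return links


def links_to_frame(links: Sequence["VirusHostLink"]):
    import pandas as pd

    return pd.DataFrame(
        {
            "virus_population": [l.virus_population for l in links],
            "host_population": [l.host_population for l in links],
            "evidence": [",".join(sorted(l.evidence)) for l in links],
            "support": [l.support for l in links],
        }
    )
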
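"""Built-in pairwise nucleotide alignment.

Two regimes are covered, mirroring what BLAST-style tools would report for
the genome comparisons the pipeline needs:

* near-identical full-length pairs (the vOTU clustering case): a single
  global alignment scores the whole pair;
* partial homology (a provirus inside a host scaffold, a shared gene
  cassette): exact k-mer seeds on a common diagonal are chained and extended
  with an X-drop rule, then rescored with a global alignment of the spanned
  subregions.

The module emits :class:`~amdvir.records.AlignmentHit` rows compatible with
the 12-column tabular alignment format, so externally produced hit files can
be swapped in transparently.
"""

from __future__ import annotations

from collections import defaultdict
from functools import lru_cache
from pathlib import Path

import edlib

from amdvir.records import AlignmentHit

_COMPLEMENT = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _edlib_identity(a: str, b: str) -> tuple[float, int]:
    """Percent identity and alignment length of a global alignment."""
    res = edlib.align(a, b, mode="NW", task="distance")
    aln_len = max(len(a), len(b))  # substitution-dominated; gaps extend this
    matches = aln_len - res["editDistance"]
    return 100.0 * matches / aln_len, aln_len


def _hit_from_region(
    qname: str,
    sname: str,
    qseq: str,
    sseq: str,
    qs: int,
    qe: int,
    ss: int,
    se: int,
) -> AlignmentHit:
    pident, aln_len = _edlib_identity(qseq[qs:qe], sseq[ss:se])
    matches = round(aln_len * pident / 100.0)
    mismatch = aln_len - matches
    bitscore = max(0.0, 2.0 * matches - 3.0 * mismatch)
    evalue = len(qseq) * len(sseq) * 2.0 ** (-min(bitscore, 1000.0))
    return AlignmentHit(
        query=qname,
        subject=sname,
        pident=round(pident, 2),
        length=aln_len,
        mismatch=mismatch,
        gapopen=0,
        qstart=qs,
        qend=qe,
        sstart=ss,
        send=se,
        evalue=evalue,
        bitscore=round(bitscore, 1),
    )


def seed_extend_hits(
    qname: str,
    qseq: str,
    sname: str,
    sseq: str,
    *,
    k: int = 21,
    min_anchors: int = 2,
    min_hit_length: int = 100,
    both_strands: bool = True,
) -> list[AlignmentHit]:
    """Find local alignment hits between two sequences.

    Exact ``k``-mer matches falling on a common diagonal are grouped; each
    group spanning at least ``min_anchors`` seeds defines a candidate region
    that is extended outward with an X-drop rule (match +1, mismatch -2,
    stop 12 below the running maximum) and rescored globally. Random
    uniform sequence essentially never shares a 21-mer, so background pairs
    return no hits.
    """
    if len(qseq) < k or len(sseq) < k:
        return []
    index = _kmer_index(sseq, k)

    hits: list[AlignmentHit] = []
    for strand_seq, minus in ((qseq, False), (reverse_complement(qseq), True)) if both_strands else ((qseq, False),):
        diagonals: dict[int, list[tuple[int, int]]] = defaultdict(list)
        for i in range(len(strand_seq) - k + 1):
            for j in index.get(strand_seq[i : i + k], ()):
                diagonals[i - j].append((i, j))
        for anchors in diagonals.values():
            if len(anchors) < min_anchors:
                continue
            anchors.sort()
            qs = anchors[0][0]
            qe = anchors[-1][0] + k
            ss = anchors[0][1]
            se = anchors[-1][1] + k
            qs, ss = _xdrop_left(strand_seq, sseq, qs, ss)
            qe, se = _xdrop_right(strand_seq, sseq, qe, se)
            if qe - qs < min_hit_length:
                continue
            hit = _hit_from_region(qname, sname, strand_seq, sseq, qs, qe, ss, se)
            if minus:
                n = len(qseq)
                hit = AlignmentHit(
                    query=qname,
                    subject=sname,
                    pident=hit.pident,
                    length=hit.length,
                    mismatch=hit.mismatch,
                    gapopen=hit.gapopen,
                    qstart=n - qe,
                    qend=n - qs,
                    sstart=se,  # reversed => minus strand in tabular terms
                    send=ss,
                    evalue=hit.evalue,
                    bitscore=hit.bitscore,
                )
            hits.append(hit)
    hits.sort(key=lambda h: (-h.bitscore, h.qstart, h.sstart))
    return hits


@lru_cache(maxsize=128)
def _kmer_index(seq: str, k: int) -> dict[str, list[int]]:
    index: dict[str, list[int]] = defaultdict(list)
    for i in range(len(seq) - k + 1):
        index[seq[i : i + k]].append(i)
    index.default_factory = None
    return index


def _xdrop_left(q: str, s: str, qi: int, si: int, xdrop: int = 12) -> tuple[int, int]:
    score = best = 0
    bq, bs = qi, si
    while qi > 0 and si > 0:
        qi -= 1
        si -= 1
        score += 1 if q[qi] == s[si] else -2
        if score > best:
            best, bq, bs = score, qi, si
        elif best - score > xdrop:
            break
    return bq, bs


def _xdrop_right(q: str, s: str, qi: int, si: int, xdrop: int = 12) -> tuple[int, int]:
    score = best = 0
    bq, bs = qi, si
    while qi < len(q) and si < len(s):
        score += 1 if q[qi] == s[si] else -2
        qi += 1
        si += 1
        if score > best:
            best, bq, bs = score, qi, si
        elif best - score > xdrop:
            break
    return bq, bs


# ---------------------------------------------------------------------------
# 12-column tabular I/O (1-based inclusive coordinates on disk)


def read_tabular_hits(path: str | Path) -> list[AlignmentHit]:
    hits = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 12:
                raise ValueError(f"{path}:{lineno}: expected 12 columns, got {len(parts)}")
            try:
                q, s = parts[0], parts[1]
                pident = float(parts[2])
                length, mism, gapo = (int(x) for x in parts[3:6])
                qs, qe, ss, se = (int(x) for x in parts[6:10])
                ev, bit = float(parts[10]), float(parts[11])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed hit row: {exc}") from exc
            if ss <= se:
                ss0, se0 = ss - 1, se
            else:  # minus strand: keep reversed, shift to 0-based half-open
                ss0, se0 = ss, se - 1
            hits.append(
                AlignmentHit(q, s, pident, length, mism, gapo, qs - 1, qe, ss0, se0, ev, bit)
            )
    return hits


def write_tabular_hits(hits: list[AlignmentHit], path: str | Path) -> None:
    with open(path, "w") as fh:
        for h in hits:
            if h.sstart <= h.send:
                ss, se = h.sstart + 1, h.send
            else:
                ss, se = h.sstart, h.send + 1
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        h.query, h.subject, h.pident, h.length, h.mismatch,
                        h.gapopen, h.qstart + 1, h.qend, ss, se,
                        f"{h.evalue:.2e}", h.bitscore,
                    )
                )
                + "\n"
            )
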
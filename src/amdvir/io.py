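"""File I/O helpers: FASTA, uniform-depth tracks, links and metadata TSVs."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from amdvir.abundance import DepthTrack
from amdvir.records import GenomeRecord, VirusHostLink


def write_fasta(records: Iterable[GenomeRecord] | Mapping[str, str], path: str | Path) -> None:
    if isinstance(records, Mapping):
        seqs = [SeqRecord(Seq(s), id=i, description="") for i, s in records.items()]
    else:
        seqs = [SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records]
    SeqIO.write(seqs, str(path), "fasta")


def read_fasta(path: str | Path, kind: str = "viral") -> list[GenomeRecord]:
    return [
        GenomeRecord(id=rec.id, sequence=str(rec.seq).upper(), kind=kind)
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def read_fasta_dict(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_depth_tsv(
    tracks_per_sample: Mapping[str, Mapping[str, DepthTrack]], path: str | Path
) -> None:
    """Write depth tracks in a compact uniform-depth encoding.

    One row per (sample, entity) with the entity length and its constant
    per-base depth; suitable for the synthetic generator, whose tracks are
    uniform by construction.
    """
    rows = []
    for sample in sorted(tracks_per_sample):
        for entity in sorted(tracks_per_sample[sample]):
            t = tracks_per_sample[sample][entity]
            depths = np.unique(t.depth)
            if len(depths) != 1:
                raise ValueError(
                    f"track {entity}/{sample} is not uniform; use per-base output"
                )
            rows.append((sample, entity, len(t.depth), int(depths[0])))
    pd.DataFrame(rows, columns=["sample", "entity", "length", "depth"]).to_csv(
        path, sep="\t", index=False
    )


def read_depth_tsv(path: str | Path) -> dict[str, dict[str, DepthTrack]]:
    df = pd.read_csv(path, sep="\t")
    out: dict[str, dict[str, DepthTrack]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(row.sample, {})[row.entity] = DepthTrack(
            row.entity, np.full(int(row.length), int(row.depth), dtype=np.int32)
        )
    return out


def write_links_tsv(links: Sequence[VirusHostLink], path: str | Path) -> None:
    from amdvir.linkage import links_to_frame

    links_to_frame(links).to_csv(path, sep="\t", index=False)


def read_links_tsv(path: str | Path) -> list[VirusHostLink]:
    df = pd.read_csv(path, sep="\t")
    return [
        VirusHostLink(
            virus_population=row.virus_population,
            host_population=row.host_population,
            evidence=frozenset(str(row.evidence).split(",")),
            support=int(row.support),
        )
        for row in df.itertuples(index=False)
    ]


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(paths: Sequence[Path], out_path: str | Path) -> dict:
    manifest = {p.name: file_sha256(p) for p in sorted(paths)}
    with open(out_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
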
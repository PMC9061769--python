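"""Coverage-based abundance.

Read alignments are filtered at >= 95% nucleotide identity over >= 75% of
the read length; per-base depth is summarized by the trimmed mean
("tpmean": the lowest and highest 5% of positions removed); and abundance
is normalized for sequencing effort as

    abundance(entity, sample)
        = tpmean(entity, sample) / reads(sample) * mean_over_samples(reads)

so that jointly doubling a library's reads and depths leaves its abundances
unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class ReadAlignment:
    """One read's alignment to an entity."""

    read_id: str
    entity: str
    read_length: int
    aligned_length: int
    percent_identity: float
    start: int  # 0-based position of the alignment on the entity

    def __post_init__(self) -> None:
        if self.read_length is None or self.read_length <= 0:
            raise ValueError(f"read {self.read_id!r} missing/invalid read length")


@dataclass
class DepthTrack:
    """Per-base depth over one entity."""

    entity: str
    depth: np.ndarray

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth)
        if (self.depth < 0).any():
            raise ValueError(f"negative depth in track for {self.entity!r}")


def filter_read_alignments(
    alignments: Sequence[ReadAlignment],
    min_identity: float = 95.0,
    min_aligned_fraction: float = 0.75,
) -> list[ReadAlignment]:
    """Keep alignments with identity >= 95% covering >= 75% of the read."""
    return [
        a
        for a in alignments
        if a.percent_identity >= min_identity
        and a.aligned_length >= min_aligned_fraction * a.read_length
    ]


def depth_from_alignments(
    alignments: Sequence[ReadAlignment],
    entity_lengths: Mapping[str, int],
    prefiltered: bool = False,
) -> dict[str, DepthTrack]:
    """Pile filtered alignments into per-base depth tracks."""
    if not prefiltered:
        alignments = filter_read_alignments(alignments)
    tracks = {
        e: np.zeros(entity_lengths[e], dtype=np.int64) for e in entity_lengths
    }
    for a in alignments:
        d = tracks.get(a.entity)
        if d is None:
            raise ValueError(f"alignment to unknown entity {a.entity!r}")
        end = min(a.start + a.aligned_length, len(d))
        d[a.start : end] += 1
    return {e: DepthTrack(e, d) for e, d in tracks.items()}


def tpmean_coverage(track: DepthTrack | np.ndarray, trim: float = 0.05) -> float:
    """Trimmed-mean depth: drop floor(trim * L) lowest and highest positions."""
    if trim < 0 or trim >= 0.5:
        raise ValueError(f"trim must be in [0, 0.5): {trim}")
    depth = track.depth if isinstance(track, DepthTrack) else np.asarray(track)
    if depth.size == 0:
        raise ValueError("empty depth vector")
    k = int(np.floor(trim * depth.size))
    if k == 0:
        return float(depth.mean())
    s = np.sort(depth)
    return float(s[k:-k].mean())


@dataclass
class AbundanceMatrix:
    """Entities x samples normalized coverages, with library sizes."""

    entities: list[str]
    samples: list[str]
    values: np.ndarray
    library_sizes: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.library_sizes = np.asarray(self.library_sizes, dtype=float)
        if self.values.shape != (len(self.entities), len(self.samples)):
            raise ValueError("abundance matrix shape mismatch")
        if self.library_sizes.shape != (len(self.samples),):
            raise ValueError("library_sizes length mismatch")
        if (self.values < 0).any():
            raise ValueError("negative abundances")
        if (self.library_sizes <= 0).any():
            raise ValueError("library sizes must be positive")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.entities, columns=self.samples)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, library_sizes: np.ndarray | None = None) -> "AbundanceMatrix":
        if library_sizes is None:
            library_sizes = np.ones(df.shape[1])
        return cls(list(df.index), list(df.columns), df.to_numpy(float), library_sizes)

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="entity", float_format="%.6g")

    @classmethod
    def read_tsv(cls, path: str | Path, library_sizes: np.ndarray | None = None) -> "AbundanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls.from_frame(df, library_sizes)


def build_abundance_matrix(
    tracks_per_sample: Mapping[str, Mapping[str, DepthTrack]],
    library_sizes: Mapping[str, float],
    trim: float = 0.05,
) -> AbundanceMatrix:
    """Assemble the normalized abundance matrix from per-sample depth tracks.

    ``tracks_per_sample`` maps sample -> entity -> DepthTrack. Entities
    absent from a sample get abundance 0.
    """
    samples = sorted(tracks_per_sample)
    if set(samples) != set(library_sizes):
        raise ValueError("sample sets of tracks and library sizes differ")
    entities = sorted({e for t in tracks_per_sample.values() for e in t})
    libs = np.array([library_sizes[s] for s in samples], dtype=float)
    mean_lib = libs.mean()
    values = np.zeros((len(entities), len(samples)))
    for j, s in enumerate(samples):
        for i, e in enumerate(entities):
            track = tracks_per_sample[s].get(e)
            if track is not None:
                values[i, j] = tpmean_coverage(track, trim) / libs[j] * mean_lib
    return AbundanceMatrix(entities, samples, values, libs)


def rollup(
    matrix: AbundanceMatrix,
    membership: Mapping[str, str],
    mode: str = "sum",
) -> AbundanceMatrix:
    """Roll entity abundances up to clusters.

    ``mode="sum"`` adds member values (protein-cluster abundance = sum of
    member-gene abundances); ``mode="representative"`` takes the value of
    the cluster representative, where ``membership`` maps representative ->
    representative as well (population abundance = representative-genome
    abundance).
    """
    df = matrix.to_frame()
    if mode == "sum":
        groups = pd.Series({e: membership[e] for e in matrix.entities if e in membership})
        out = df.loc[groups.index].groupby(groups).sum()
    elif mode == "representative":
        reps = sorted(set(membership.values()))
        missing = [r for r in reps if r not in df.index]
        if missing:
            raise ValueError(f"representatives absent from matrix: {missing[:3]}")
        out = df.loc[reps]
    else:
        raise ValueError(f"unknown rollup mode {mode!r}")
    return AbundanceMatrix(list(out.index), matrix.samples, out.to_numpy(float), matrix.library_sizes)
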
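"""Core record types shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass
class GenomeRecord:
    """A viral or prokaryotic genome sequence with provenance and quality.

    Parameters
    ----------
    id : str
        Unique identifier.
    sequence : str
        Nucleotide sequence (ACGT alphabet expected).
    kind : {"viral", "prokaryotic"}
    source_scaffold : str, optional
        For proviruses: the scaffold the genome was excised from.
    source_interval : tuple of (int, int), optional
        0-based half-open coordinates of the provirus on its source scaffold.
    completeness, contamination : float, optional
        CheckM-style quality estimates in percent, [0, 100].
    lifestyle : {"virulent", "temperate", "unknown"}
    """

    id: str
    sequence: str
    kind: str = "viral"
    source_scaffold: str | None = None
    source_interval: tuple[int, int] | None = None
    completeness: float | None = None
    contamination: float | None = None
    lifestyle: str = "unknown"

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise ValueError(f"genome {self.id!r} has empty sequence")
        if self.kind not in ("viral", "prokaryotic"):
            raise ValueError(f"unknown genome kind {self.kind!r}")
        for attr in ("completeness", "contamination"):
            v = getattr(self, attr)
            if v is not None and not 0 <= v <= 100:
                raise ValueError(f"{attr} of {self.id!r} outside [0, 100]: {v}")
        if self.lifestyle not in ("virulent", "temperate", "unknown"):
            raise ValueError(f"unknown lifestyle {self.lifestyle!r}")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def quality_score(self) -> float:
        """Dereplication quality, completeness - 4 x contamination."""
        if self.completeness is None or self.contamination is None:
            raise ValueError(f"genome {self.id!r} lacks quality estimates")
        return self.completeness - 4.0 * self.contamination


@dataclass
class AniResult:
    """Pairwise average nucleotide identity and aligned fraction.

    ``ani`` is the alignment-length-weighted mean percent identity over
    non-redundant aligned intervals; ``af_smaller`` is the percent of the
    shorter sequence covered by (merged) alignments. Both live in [0, 100]
    and are symmetric in the pair.
    """

    ani: float
    af_smaller: float

    def __post_init__(self) -> None:
        if not (0 <= self.ani <= 100 and 0 <= self.af_smaller <= 100):
            raise ValueError(f"ANI/AF outside [0, 100]: {self}")


@dataclass
class Cluster:
    """A genome (or protein) cluster with a designated representative."""

    representative: str
    members: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.representative not in self.members:
            raise ValueError(
                f"representative {self.representative!r} not among members"
            )


@dataclass(frozen=True)
class AlignmentHit:
    """A local alignment hit in 12-column tabular (BLAST outfmt 6) terms.

    Coordinates are stored 0-based half-open; the tabular reader/writer
    converts from/to the format's 1-based inclusive convention. ``qstart`` <
    ``qend`` always; subject coordinates may be reversed for minus-strand
    hits (as in the tabular format).
    """

    query: str
    subject: str
    pident: float
    length: int
    mismatch: int
    gapopen: int
    qstart: int
    qend: int
    sstart: int
    send: int
    evalue: float
    bitscore: float


@dataclass
class VirusHostLink:
    """A population-level virus-host pair with its evidence."""

    virus_population: str
    host_population: str
    evidence: frozenset[str]
    support: int

    _ALLOWED = frozenset({"homology", "prophage", "crispr"})

    def __post_init__(self) -> None:
        self.evidence = frozenset(self.evidence)
        if not self.evidence:
            raise ValueError("evidence set must be non-empty")
        if not self.evidence <= self._ALLOWED:
            raise ValueError(f"unknown evidence type(s): {self.evidence - self._ALLOWED}")
        if self.support < 1:
            raise ValueError("support must be >= 1")


@dataclass(frozen=True)
class SpacerRecord:
    """A CRISPR spacer extracted from a host scaffold."""

    host_scaffold: str
    array_index: int
    spacer_seq: str
    position: tuple[int, int]  # 0-based half-open on the scaffold

    def __post_init__(self) -> None:
        if len(self.spacer_seq) < 15:
            raise ValueError("spacer shorter than 15 bp")
        s, e = self.position
        if not 0 <= s < e:
            raise ValueError(f"bad spacer interval {self.position}")
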
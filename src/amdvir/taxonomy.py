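"""Lowest-common-ancestor taxonomy for viral genomes.

Each annotated protein carries a reference lineage (ordered ranks, root to
leaf). A genome is assigned the deepest taxon supported by more than a
configurable fraction of its annotated proteins, walking up ranks until the
support test passes (majority-rule LCA). With ``min_fraction=1.0`` this
reduces to the strict LCA of all protein lineages.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence


@dataclass(frozen=True)
class Lineage:
    """An ordered root-to-leaf taxonomic path, e.g.
    ``Lineage((("order", "Caudovirales"), ("family", "Myoviridae")))``."""

    ranks: tuple[tuple[str, str], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        names = [r for r, _ in self.ranks]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate rank names in {names}")

    @classmethod
    def from_string(cls, text: str, rank_names: Sequence[str] | None = None) -> "Lineage":
        taxa = [t for t in text.split(";") if t]
        if rank_names is None:
            rank_names = [f"rank{i}" for i in range(len(taxa))]
        return cls(tuple(zip(rank_names, taxa)))

    def __str__(self) -> str:
        return ";".join(t for _, t in self.ranks) or "unclassified"

    @property
    def depth(self) -> int:
        return len(self.ranks)

    def prefix(self, depth: int) -> "Lineage":
        return Lineage(self.ranks[:depth])

    @property
    def is_unclassified(self) -> bool:
        return not self.ranks


def lowest_common_ancestor(lineages: Sequence[Lineage]) -> Lineage:
    """Deepest lineage prefix shared by all inputs (empty -> unclassified)."""
    if not lineages:
        raise ValueError("lowest_common_ancestor requires a non-empty list")
    depth = 0
    minimum = min(l.depth for l in lineages)
    first = lineages[0]
    while depth < minimum and all(
        l.ranks[depth] == first.ranks[depth] for l in lineages
    ):
        depth += 1
    return first.prefix(depth)


def classify_genome(
    protein_hits: Mapping[str, Lineage],
    min_fraction: float = 0.5,
) -> Lineage:
    """Majority-rule LCA over per-protein best-hit lineages.

    The assignment is the deepest taxon whose support exceeds
    ``min_fraction`` of annotated proteins at every rank along the path;
    genomes with no annotated proteins are unclassified.
    """
    if not 0 < min_fraction <= 1:
        raise ValueError(f"min_fraction must be in (0, 1]: {min_fraction}")
    lineages = [l for l in protein_hits.values() if not l.is_unclassified]
    if not lineages:
        return Lineage()
    n = len(lineages)
    max_depth = max(l.depth for l in lineages)
    assigned = Lineage()
    for depth in range(1, max_depth + 1):
        counts = Counter(l.prefix(depth).ranks for l in lineages if l.depth >= depth)
        if not counts:
            break
        best, support = counts.most_common(1)[0]
        # the winning path must extend the shallower assignment
        # unanimous support always passes, so min_fraction=1 is strict LCA
        if (support == n or support > min_fraction * n) and best[: assigned.depth] == assigned.ranks:
            assigned = Lineage(best)
        else:
            break
    return assigned
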
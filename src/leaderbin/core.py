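"""Shared domain containers.

Coordinates are 0-based, half-open throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence

import numpy as np


@dataclass(frozen=True)
class MarkerLocus:
    """One copy of a universal single-copy marker family on a genome."""

    family_id: int
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid marker interval [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class Genome:
    """A synthetic reference genome with planted single-copy marker loci."""

    id: str
    sequence: str
    markers: list[MarkerLocus] = field(default_factory=list)
    gc_target: float = 0.5

    def __len__(self) -> int:
        return len(self.sequence)

    def validate(self) -> None:
        L = len(self.sequence)
        ivals = sorted((m.start, m.end) for m in self.markers)
        for (s, e) in ivals:
            if e > L:
                raise ValueError(f"marker [{s},{e}) exceeds genome length {L}")
        for (_, e1), (s2, _) in zip(ivals, ivals[1:]):
            if s2 < e1:
                raise ValueError("marker intervals overlap")
        fams = [m.family_id for m in self.markers]
        if len(fams) != len(set(fams)):
            raise ValueError("duplicate marker family on a single genome")


@dataclass
class Contig:
    """A contig with optional provenance on its source genome.

    ``depths`` holds the mean per-base depth of the contig in each of the
    S samples (length-S vector; may be empty when depths are unknown).
    """

    id: str
    sequence: str
    provenance: Optional[tuple[str, int, int]] = None  # (genome_id, start, end)
    depths: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def __len__(self) -> int:
        return len(self.sequence)


class ContigSet:
    """An ordered collection of contigs, the unit of all evaluation stages."""

    def __init__(self, contigs: Sequence[Contig] = ()):  # noqa: D107
        self.contigs: list[Contig] = list(contigs)

    def __len__(self) -> int:
        return len(self.contigs)

    def __iter__(self) -> Iterator[Contig]:
        return iter(self.contigs)

    def __getitem__(self, i: int) -> Contig:
        return self.contigs[i]

    def add(self, contig: Contig) -> None:
        self.contigs.append(contig)

    @property
    def ids(self) -> list[str]:
        return [c.id for c in self.contigs]

    def total_length(self) -> int:
        return sum(len(c) for c in self.contigs)

    def lengths(self) -> np.ndarray:
        return np.array([len(c) for c in self.contigs], dtype=np.int64)

    def n_samples(self) -> int:
        return 0 if not self.contigs else int(self.contigs[0].depths.size)

    def subset(self, ids: Sequence[str]) -> "ContigSet":
        wanted = set(ids)
        return ContigSet([c for c in self.contigs if c.id in wanted])

    def validate_provenance(self, genomes: dict[str, Genome]) -> None:
        for c in self.contigs:
            if c.provenance is None:
                continue
            gid, s, e = c.provenance
            if gid not in genomes:
                raise ValueError(f"contig {c.id}: unknown source genome {gid}")
            if not (0 <= s < e <= len(genomes[gid])):
                raise ValueError(f"contig {c.id}: provenance [{s},{e}) outside {gid}")
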
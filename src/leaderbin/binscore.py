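"""Bin quality estimation, scoring, and reference-bin selection.

Completeness C is the fraction of universal single-copy marker families
with at least one fully contained copy in a bin; redundancy R is the
fraction present in two or more copies (the marker-based contamination
signal). A is the bin's mean coverage depth in its origin sample and
A_max the depth of the most abundant bin in that sample. Bins are scored

    score = w_c * C - w_r * R + w_a * (A / A_max)

with default weights (1, 1, 10): abundance dominates, so among complete
and clean candidate bins the most abundant community members are selected
as internal references — the leaderboard principle.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from . import _seq
from .core import ContigSet, Genome

HIGH_QUALITY = "high_quality_draft"
MEDIUM = "medium"
FAIL = "fail"


@dataclass(frozen=True)
class ScoreWeights:
    """Weights of the bin score; defaults (1, 1, 10)."""

    w_c: float = 1.0
    w_r: float = 1.0
    w_a: float = 10.0

    def __post_init__(self) -> None:
        if not all(np.isfinite(w) and w >= 0 for w in (self.w_c, self.w_r, self.w_a)):
            raise ValueError("weights must be finite and >= 0")


@dataclass
class BinQuality:
    bin_id: str
    C: float
    R: float
    A: float
    A_max: float = float("nan")
    score: float = field(default=float("nan"))
    tier: str = FAIL


def marker_copy_counts(bin_contigs: ContigSet, genomes: Mapping[str, Genome]) -> Counter:
    """Count fully contained marker copies per family, via provenance.

    A marker copy counts when its genomic interval lies entirely within
    a contig's source interval on the same genome.
    """
    counts: Counter = Counter()
    by_genome: dict[str, list] = {gid: sorted(g.markers, key=lambda m: m.start)
                                  for gid, g in genomes.items()}
    for contig in bin_contigs:
        if contig.provenance is None:
            continue
        gid, s, e = contig.provenance
        for m in by_genome.get(gid, ()):
            if m.start >= s and m.end <= e:
                counts[m.family_id] += 1
            elif m.start >= e:
                break
    return counts


def completeness(bin_contigs: ContigSet, genomes: Mapping[str, Genome],
                 m_markers: int) -> float:
    """Fraction of marker families with >= 1 fully contained copy."""
    if m_markers <= 0:
        raise ValueError("m_markers must be > 0")
    counts = marker_copy_counts(bin_contigs, genomes)
    return sum(1 for v in counts.values() if v >= 1) / m_markers


def redundancy(bin_contigs: ContigSet, genomes: Mapping[str, Genome],
               m_markers: int) -> float:
    """Fraction of marker families present in >= 2 copies."""
    if m_markers <= 0:
        raise ValueError("m_markers must be > 0")
    counts = marker_copy_counts(bin_contigs, genomes)
    return sum(1 for v in counts.values() if v >= 2) / m_markers


def bin_abundance(bin_contigs: ContigSet, origin_sample: int) -> float:
    """Length-weighted mean contig depth in the origin sample."""
    if len(bin_contigs) == 0:
        raise ValueError("empty bin has no abundance")
    lens = bin_contigs.lengths().astype(float)
    depths = np.array([c.depths[origin_sample] for c in bin_contigs])
    return float((lens * depths).sum() / lens.sum())


def score_bin(q: BinQuality, w: ScoreWeights = ScoreWeights()) -> float:
    """w_c·C − w_r·R + w_a·(A/A_max)."""
    if not (q.A_max > 0):
        raise ValueError("A_max must be > 0")
    return w.w_c * q.C - w.w_r * q.R + w.w_a * (q.A / q.A_max)


def quality_tier(C: float, contamination: float) -> str:
    """MAG quality tier with strict boundaries.

    high-quality draft: C > 0.90 and contamination < 0.05;
    medium: C > 0.70 and contamination < 0.10; otherwise fail.
    """
    if C > 0.90 and contamination < 0.05:
        return HIGH_QUALITY
    if C > 0.70 and contamination < 0.10:
        return MEDIUM
    return FAIL


def select_reference_bins(
    bins: Sequence[BinQuality],
    k: int = 5,
    min_completeness: float = 0.85,
) -> tuple[list[str], bool]:
    """Top-``k`` bin ids by score among bins with C > ``min_completeness``.

    Ties are broken by higher completeness, then lexicographic bin id.
    Returns (selected ids, short_flag); short_flag is True when fewer
    than ``k`` bins pass the completeness filter.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    eligible = [b for b in bins if b.C > min_completeness]
    ranked = sorted(eligible, key=lambda b: (-b.score, -b.C, b.bin_id))
    return [b.bin_id for b in ranked[:k]], len(eligible) < k


def assess_bins(
    assignment: Mapping[str, str],
    contigs: ContigSet,
    genomes: Mapping[str, Genome],
    m_markers: int,
    origin_sample: int = 0,
    weights: ScoreWeights = ScoreWeights(),
) -> list[BinQuality]:
    """Full quality table for a bin assignment (contig_id -> bin_id).

    Computes C, R, A per bin, sets A_max to the largest bin abundance in
    the origin sample, then scores and tiers every bin. Contamination
    for the tier is taken to be R (marker-redundancy based).
    """
    by_bin: dict[str, ContigSet] = {}
    by_id = {c.id: c for c in contigs}
    for cid, bid in assignment.items():
        by_bin.setdefault(bid, ContigSet()).add(by_id[cid])
    quals = []
    for bid in sorted(by_bin):
        cs = by_bin[bid]
        quals.append(BinQuality(
            bin_id=bid,
            C=completeness(cs, genomes, m_markers),
            R=redundancy(cs, genomes, m_markers),
            A=bin_abundance(cs, origin_sample),
        ))
    a_max = max((q.A for q in quals), default=0.0)
    for q in quals:
        q.A_max = a_max
        q.score = score_bin(q, weights) if a_max > 0 else float("nan")
        q.tier = quality_tier(q.C, q.R)
    return quals


def detect_markers_kmer(
    contigs: ContigSet,
    marker_db: Mapping[int, str],
    k: int = 31,
    min_kmer_fraction: float = 0.5,
) -> Counter:
    """Exact k-mer marker detector for contigs without provenance.

    For external FASTA input: a marker family is counted once per contig
    on which at least ``min_kmer_fraction`` of the family sequence's
    canonical k-mers occur. Only suitable when bin sequences match the
    marker database near-exactly.
    """
    counts: Counter = Counter()
    db = {fam: set(_seq.canonical_kmer_codes(_seq.encode(s), k).tolist())
          for fam, s in marker_db.items()}
    for contig in contigs:
        if len(contig) < k:
            continue
        kmers = set(_seq.canonical_kmer_codes(_seq.encode(contig.sequence), k).tolist())
        for fam, fam_kmers in db.items():
            if not fam_kmers:
                continue
            if len(fam_kmers & kmers) / len(fam_kmers) >= min_kmer_fraction:
                counts[fam] += 1
    return counts
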
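"""ANI-based bin dereplication with quality-winner selection.

Bins pooled across binning runs are compared by MinHash (bottom-sketch)
Jaccard similarity converted to ANI through the Mash distance relation

    ANI = 1 + (1/k) * ln(2J / (1 + J)),   clamped to [0, 1].

Two-stage single-linkage clustering (coarse groups at the primary ANI
threshold, replicate clusters at the secondary threshold — 90%/99%
defaults) collapses replicates; within each cluster the winner maximizes
completeness − 5 × contamination, with ties broken by larger total bin
length, then lexicographic bin id. Winner origins (which binning
protocol produced the best representative) are then tallied.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from . import _seq, binscore
from .core import ContigSet

QUALITY_CONTAMINATION_WEIGHT = 5.0


@dataclass(frozen=True)
class AniEstimate:
    bin_a: str
    bin_b: str
    jaccard: float
    ani: float


@dataclass(frozen=True)
class WinnerRecord:
    cluster_id: str
    winner_bin: str
    winner_origin: str
    quality: float


def bin_sketch(bin_contigs: ContigSet, k: int = 21, sketch_size: int = 5000) -> np.ndarray:
    """Bottom-``sketch_size`` MinHash sketch of a bin's canonical k-mers."""
    if len(bin_contigs) == 0:
        raise ValueError("cannot sketch an empty bin")
    hashes = []
    for c in bin_contigs:
        codes = _seq.canonical_kmer_codes(_seq.encode(c.sequence), k)
        if codes.size:
            hashes.append(_seq.splitmix64(codes))
    if not hashes:
        return np.empty(0, dtype=np.uint64)
    all_h = np.unique(np.concatenate(hashes))
    return all_h[:sketch_size]


def _jaccard_from_sketches(sa: np.ndarray, sb: np.ndarray, sketch_size: int) -> float:
    merged = np.unique(np.concatenate([sa, sb]))[:sketch_size]
    if merged.size == 0:
        return 0.0
    shared = np.intersect1d(merged, np.intersect1d(sa, sb, assume_unique=True),
                            assume_unique=True)
    return shared.size / merged.size


def ani_from_jaccard(j: float, k: int) -> float:
    """Mash-relation ANI estimate, clamped to [0, 1]."""
    if j <= 0:
        return 0.0
    if j >= 1:
        return 1.0
    return float(min(max(1.0 + np.log(2 * j / (1 + j)) / k, 0.0), 1.0))


def sketch_ani(
    bin_a: ContigSet,
    bin_b: ContigSet,
    k: int = 21,
    sketch_size: int = 5000,
    ids: tuple[str, str] = ("a", "b"),
) -> AniEstimate:
    """Estimate ANI between two bins from bottom sketches."""
    sa = bin_sketch(bin_a, k, sketch_size)
    sb = bin_sketch(bin_b, k, sketch_size)
    j = _jaccard_from_sketches(sa, sb, sketch_size)
    return AniEstimate(ids[0], ids[1], j, ani_from_jaccard(j, k))


class _UnionFind:
    def __init__(self, items: Sequence[str]):
        self.parent = {x: x for x in items}

    def find(self, x: str) -> str:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: str, b: str) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            # deterministic: smaller id becomes the root
            lo, hi = sorted((ra, rb))
            self.parent[hi] = lo


def _single_linkage(ids: Sequence[str], ani: Mapping[frozenset, float],
                    threshold: float) -> list[list[str]]:
    uf = _UnionFind(ids)
    for pair, a in ani.items():
        if a >= threshold:
            x, y = sorted(pair)
            uf.union(x, y)
    groups: dict[str, list[str]] = {}
    for i in ids:
        groups.setdefault(uf.find(i), []).append(i)
    return [sorted(groups[r]) for r in sorted(groups)]


def pairwise_ani(bins: Mapping[str, ContigSet], k: int = 21,
                 sketch_size: int = 5000) -> dict[frozenset, float]:
    """All-pairs sketch ANI over a collection of bins."""
    ids = sorted(bins)
    sketches = {i: bin_sketch(bins[i], k, sketch_size) for i in ids}
    out: dict[frozenset, float] = {}
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            j = _jaccard_from_sketches(sketches[a], sketches[b], sketch_size)
            out[frozenset((a, b))] = ani_from_jaccard(j, k)
    return out


def cluster_bins(
    bins: Mapping[str, ContigSet],
    primary_ani: float = 0.90,
    secondary_ani: float = 0.99,
    k: int = 21,
    sketch_size: int = 5000,
) -> list[list[str]]:
    """Two-stage single-linkage dereplication clustering.

    Coarse groups form at ``primary_ani``; replicate clusters form
    within each group at ``secondary_ani``. Returns sorted clusters of
    bin ids. Invariant to input order.
    """
    if not (0 < primary_ani <= 1 and 0 < secondary_ani <= 1):
        raise ValueError("ANI thresholds must be in (0, 1]")
    if not bins:
        return []
    ani = pairwise_ani(bins, k, sketch_size)
    clusters: list[list[str]] = []
    for group in _single_linkage(sorted(bins), ani, primary_ani):
        sub = {frozenset(p): v for p, v in ani.items()
               if all(m in group for m in p)}
        clusters.extend(_single_linkage(group, sub, secondary_ani))
    return sorted(clusters)


def pick_winner(
    cluster: Sequence[tuple[str, float, float, int]],
    origins: Mapping[str, str],
    cluster_id: str = "cluster0",
) -> WinnerRecord:
    """Pick the cluster winner by quality = C − 5 × contamination.

    ``cluster`` rows are (bin_id, completeness, contamination,
    total_length). Ties break by larger total length, then
    lexicographic bin id.
    """
    if not cluster:
        raise ValueError("empty cluster")
    best = sorted(
        cluster,
        key=lambda r: (-(r[1] - QUALITY_CONTAMINATION_WEIGHT * r[2]), -r[3], r[0]),
    )[0]
    quality = best[1] - QUALITY_CONTAMINATION_WEIGHT * best[2]
    return WinnerRecord(cluster_id=cluster_id, winner_bin=best[0],
                        winner_origin=origins.get(best[0], "unknown"),
                        quality=quality)


def tally_origins(
    winners: Sequence[WinnerRecord],
    qualities: Mapping[str, tuple[float, float]] | None = None,
) -> dict[str, dict[str, int]]:
    """Count winning-bin origins over all clusters and over HQ clusters.

    ``qualities`` maps bin id to (completeness, contamination) and is
    used to decide the high-quality-draft filter; when omitted, the HQ
    tally is empty.
    """
    total = Counter(w.winner_origin for w in winners)
    hq: Counter = Counter()
    if qualities is not None:
        for w in winners:
            c, cont = qualities[w.winner_bin]
            if binscore.quality_tier(c, cont) == binscore.HIGH_QUALITY:
                hq[w.winner_origin] += 1
    return {"all": dict(sorted(total.items())), "high_quality": dict(sorted(hq.items()))}
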
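"""Reference-based assembly evaluation.

Assembly contigs are aligned to reference contig sets (the internal,
long-read-derived reference bins) and summarized with the standard
reference-evaluation metrics: genome fraction, mismatch and indel rates
per 100 kbp, largest contig, total length above thresholds, and N50.

Alignment strategy: exact 21-mer seeds on both strands locate, for each
(contig, reference contig) pair, a candidate window and strand; the
window is then aligned with banded global/semi-global edit distance
(edlib) and the extended CIGAR provides exact mismatch and indel counts
for the reported alignment. One best alignment block is kept per
(contig, reference contig) pair; a contig may align to several
reference contigs.

Ambiguous bases (N) never seed and never count as matches.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import edlib
import numpy as np

from . import _seq
from .core import ContigSet

_CIG_NUM = b"0123456789"


@dataclass
class AlignmentBlock:
    """One gapped alignment of an assembly contig to a reference contig."""

    contig_id: str
    ref_id: str
    ref_start: int
    ref_end: int  # half-open on the reference
    contig_start: int
    contig_end: int
    strand: str  # '+' or '-'
    matches: int
    mismatches: int
    insertions: int  # bases present in the contig, absent from the reference
    deletions: int   # reference bases absent from the contig

    @property
    def identity(self) -> float:
        cols = self.matches + self.mismatches + self.insertions + self.deletions
        return self.matches / cols if cols else 0.0

    @property
    def aligned_ref_bases(self) -> int:
        return self.ref_end - self.ref_start


@dataclass
class EvalReport:
    """Per-reference evaluation summary."""

    ref_name: str
    genome_fraction: float  # percent
    mismatches_per_100kb: float
    indels_per_100kb: float
    largest_contig: int
    total_len_ge: dict[int, int]
    n50: int
    aligned_bp: int
    n_contigs: int

    def to_dict(self) -> dict:
        d = {
            "ref_name": self.ref_name,
            "genome_fraction": self.genome_fraction,
            "mismatches_per_100kb": self.mismatches_per_100kb,
            "indels_per_100kb": self.indels_per_100kb,
            "largest_contig": self.largest_contig,
            "n50": self.n50,
            "aligned_bp": self.aligned_bp,
            "n_contigs": self.n_contigs,
        }
        for t in sorted(self.total_len_ge):
            d[f"total_len_ge_{t}"] = self.total_len_ge[t]
        return d


def _parse_cigar(cigar: str) -> list[tuple[int, str]]:
    ops = []
    num = 0
    for ch in cigar:
        if ch.isdigit():
            num = num * 10 + ord(ch) - 48
        else:
            ops.append((num, ch))
            num = 0
    return ops


class _RefIndex:
    """Sorted-array exact k-mer index over a reference contig set."""

    def __init__(self, reference: ContigSet, k: int, max_occ: int = 100):
        self.k = k
        self.ref_ids = reference.ids
        self.ref_seqs = [c.sequence for c in reference]
        codes_all, ridx_all, pos_all = [], [], []
        for i, c in enumerate(reference):
            pos, vals = _seq.kmer_codes(_seq.encode(c.sequence), k)
            codes_all.append(vals)
            ridx_all.append(np.full(pos.size, i, dtype=np.int32))
            pos_all.append(pos.astype(np.int64))
        codes = np.concatenate(codes_all) if codes_all else np.empty(0, np.uint64)
        order = np.argsort(codes, kind="stable")
        self.codes = codes[order]
        self.ridx = np.concatenate(ridx_all)[order] if ridx_all else np.empty(0, np.int32)
        self.pos = np.concatenate(pos_all)[order] if pos_all else np.empty(0, np.int64)
        # mask out seeds occurring too often (repeats)
        uniq, starts, counts = np.unique(self.codes, return_index=True, return_counts=True)
        bad = counts > max_occ
        if bad.any():
            keep = np.ones(self.codes.size, dtype=bool)
            for s, c in zip(starts[bad], counts[bad]):
                keep[s:s + c] = False
            self.codes, self.ridx, self.pos = self.codes[keep], self.ridx[keep], self.pos[keep]

    def hits(self, query_codes: np.ndarray, query_pos: np.ndarray):
        """(ref_idx, ref_pos, query_pos) arrays of exact seed matches."""
        left = np.searchsorted(self.codes, query_codes, side="left")
        right = np.searchsorted(self.codes, query_codes, side="right")
        n = right - left
        has = n > 0
        if not has.any():
            return (np.empty(0, np.int32), np.empty(0, np.int64), np.empty(0, np.int64))
        idx = np.concatenate([np.arange(l, r) for l, r in zip(left[has], right[has])])
        qp = np.repeat(query_pos[has], n[has])
        return self.ridx[idx], self.pos[idx], qp


def map_contigs(
    contigs: ContigSet,
    reference: ContigSet,
    k: int = 21,
    min_identity: float = 0.95,
    min_len: int = 500,
    min_seeds: int = 2,
) -> list[AlignmentBlock]:
    """Align assembly contigs >= ``min_len`` bp to a reference contig set.

    For each (contig, reference contig) pair the seed matches define an
    overlapping segment on both sequences; the segment is extended to
    the available sequence ends and aligned semi-globally (banded edit
    distance) inside a padded reference window. Blocks with identity
    below ``min_identity`` are discarded; one best block is kept per
    pair, on the strand with stronger seed support. A contig may align
    to several reference contigs.
    """
    if not (11 <= k <= 31):
        raise ValueError("k must be in [11, 31]")
    if len(reference) == 0:
        raise ValueError("empty reference")
    index = _RefIndex(reference, k)
    blocks: list[AlignmentBlock] = []
    for contig in contigs:
        if len(contig) < min_len:
            continue
        candidates: dict[int, tuple[int, str, int, int, int, int]] = {}
        for strand in "+-":
            seq = contig.sequence if strand == "+" else _seq.revcomp(contig.sequence)
            qpos, qcodes = _seq.kmer_codes(_seq.encode(seq), k)
            ridx, rpos, qp = index.hits(qcodes, qpos)
            for ri in np.unique(ridx):
                m = ridx == ri
                n_seeds = int(m.sum())
                if n_seeds < min_seeds:
                    continue
                prev = candidates.get(int(ri))
                if prev is None or n_seeds > prev[0]:
                    candidates[int(ri)] = (
                        n_seeds, strand,
                        int(qp[m].min()), int(qp[m].max()) + k,
                        int(rpos[m].min()), int(rpos[m].max()) + k,
                    )
        for ri, (n_seeds, strand, qs, qe, rs, re) in sorted(candidates.items()):
            seq = contig.sequence if strand == "+" else _seq.revcomp(contig.sequence)
            ref_seq = index.ref_seqs[ri]
            lq, lr = len(seq), len(ref_seq)
            # extend the seed span to the available ends on both sequences
            ext_l = min(qs, rs)
            ext_r = min(lq - qe, lr - re)
            sub_q = seq[qs - ext_l: qe + ext_r]
            pad = max(len(sub_q) // 50, 50)  # indel drift slack
            lo = max(rs - ext_l - pad, 0)
            hi = min(re + ext_r + pad, lr)
            max_ed = max(200, len(sub_q) // 10)
            res = edlib.align(sub_q, ref_seq[lo:hi], mode="HW", task="path",
                              k=max_ed)
            if res["editDistance"] < 0 or not res.get("locations"):
                continue
            start, end = res["locations"][0]
            matches = mism = ins = dels = 0
            for n, op in _parse_cigar(res["cigar"]):
                if op == "=":
                    matches += n
                elif op == "X":
                    mism += n
                elif op == "I":
                    ins += n
                elif op == "D":
                    dels += n
            q_lo = qs - ext_l
            q_hi = qe + ext_r
            if strand == "-":  # report on the original contig orientation
                q_lo, q_hi = lq - q_hi, lq - q_lo
            block = AlignmentBlock(
                contig_id=contig.id,
                ref_id=index.ref_ids[ri],
                ref_start=lo + start,
                ref_end=lo + end + 1,
                contig_start=q_lo,
                contig_end=q_hi,
                strand=strand,
                matches=matches,
                mismatches=mism,
                insertions=ins,
                deletions=dels,
            )
            if block.identity >= min_identity:
                blocks.append(block)
    return blocks


def genome_fraction(blocks: Sequence[AlignmentBlock], reference: ContigSet) -> float:
    """Percent of reference bases covered by >= 1 alignment block."""
    total = reference.total_length()
    if total == 0:
        return 0.0
    by_ref: dict[str, list[tuple[int, int]]] = {}
    for b in blocks:
        by_ref.setdefault(b.ref_id, []).append((b.ref_start, b.ref_end))
    ref_lens = {c.id: len(c) for c in reference}
    covered = 0
    for rid, ivals in by_ref.items():
        if rid not in ref_lens:
            continue
        L = ref_lens[rid]
        last_end = 0
        for s, e in sorted(ivals):
            s, e = max(s, last_end), min(e, L)
            if e > s:
                covered += e - s
                last_end = e
            last_end = max(last_end, min(e, L))
    return 100.0 * covered / total


def error_rates(blocks: Sequence[AlignmentBlock]) -> tuple[float, float]:
    """(mismatches, indel bases) per 100 kbp of aligned reference bases.

    An indel run of length L counts as L events; insertion and deletion
    bases both count.
    """
    aligned = sum(b.aligned_ref_bases for b in blocks)
    if aligned <= 0:
        raise ValueError("zero aligned bases: error rates undefined")
    mism = sum(b.mismatches for b in blocks)
    indels = sum(b.insertions + b.deletions for b in blocks)
    return 1e5 * mism / aligned, 1e5 * indels / aligned


def contiguity_stats(
    contigs: ContigSet,
    thresholds: Sequence[int] = (3000, 5000, 10000, 50000),
) -> tuple[int, dict[int, int], int]:
    """(largest contig, total length >= each threshold, N50).

    N50 is the largest length L such that contigs of length >= L sum to
    at least half the total assembly length.
    """
    if len(contigs) == 0:
        raise ValueError("empty contig set")
    lens = np.sort(contigs.lengths())[::-1]
    total = int(lens.sum())
    cum = np.cumsum(lens)
    n50 = int(lens[np.searchsorted(cum, total / 2, side="left")])
    totals = {int(t): int(lens[lens >= t].sum()) for t in thresholds}
    return int(lens[0]), totals, n50


def evaluate_assembly(
    assembly: ContigSet,
    reference: ContigSet,
    ref_name: str,
    k: int = 21,
    min_identity: float = 0.95,
    min_len: int = 500,
    thresholds: Sequence[int] = (3000, 5000, 10000, 50000),
) -> EvalReport:
    """Full evaluation of one assembly against one reference bin."""
    blocks = map_contigs(assembly, reference, k=k, min_identity=min_identity,
                         min_len=min_len)
    gf = genome_fraction(blocks, reference)
    if blocks:
        mism, ind = error_rates(blocks)
        aligned = sum(b.aligned_ref_bases for b in blocks)
    else:
        mism = ind = 0.0
        aligned = 0
    aligned_ids = sorted({b.contig_id for b in blocks})
    if aligned_ids:
        aligned_contigs = assembly.subset(aligned_ids)
        largest, totals, n50 = contiguity_stats(aligned_contigs, thresholds)
        n_contigs = len(aligned_contigs)
    else:
        largest, totals, n50, n_contigs = 0, {int(t): 0 for t in thresholds}, 0, 0
    return EvalReport(
        ref_name=ref_name,
        genome_fraction=gf,
        mismatches_per_100kb=mism,
        indels_per_100kb=ind,
        largest_contig=largest,
        total_len_ge=totals,
        n50=n50,
        aligned_bp=aligned,
        n_contigs=n_contigs,
    )


def fraction_vs_abundance(
    assembly: ContigSet,
    tslr_contigs: ContigSet,
    depth_proxy: Optional[Sequence[float]] = None,
    k: int = 21,
    min_identity: float = 0.95,
    min_len: int = 500,
) -> list[tuple[str, float, float]]:
    """Per-reference-contig genome fraction paired with a depth proxy.

    Uses individual long-read contigs (rather than bins) as references;
    ``depth_proxy`` defaults to each reference contig's mean depth over
    its samples. Returns (ref_contig_id, depth, fraction_percent) rows,
    suitable for abundance-stratified recovery curves.
    """
    if depth_proxy is None:
        depth_proxy = [float(c.depths.mean()) if c.depths.size else 0.0
                       for c in tslr_contigs]
    blocks = map_contigs(assembly, tslr_contigs, k=k, min_identity=min_identity,
                         min_len=min_len)
    by_ref: dict[str, list[AlignmentBlock]] = {}
    for b in blocks:
        by_ref.setdefault(b.ref_id, []).append(b)
    rows = []
    for c, depth in zip(tslr_contigs, depth_proxy):
        single = ContigSet([c])
        frac = genome_fraction(by_ref.get(c.id, []), single)
        rows.append((c.id, float(depth), frac))
    return rows
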
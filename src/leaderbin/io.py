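"""Readers, writers, read subsampling, cost matching, seed derivation.

Formats: FASTA (80-column wrap), paired FASTQ, tab-separated tables with
a header row ('.' decimal, UTF-8), JSON run manifests. All writers emit
byte-stable output so reports can be regression-tested verbatim.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .core import Contig, ContigSet, Genome, MarkerLocus
from .simdata import AbundanceMatrix

FASTA_WIDTH = 80
FLOAT_FORMAT = "%.6g"


# ---------------------------------------------------------------- seeds

def derive_seed(master_seed: int, stage: str) -> int:
    """Stable per-stage seed below 2^31, derived from the master seed."""
    digest = hashlib.blake2b(f"{master_seed}:{stage}".encode(), digest_size=4).digest()
    return int.from_bytes(digest, "big") % (2 ** 31)


# ---------------------------------------------------------------- FASTA

def write_fasta(path: str | Path, records: Iterable[tuple[str, str]]) -> None:
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), FASTA_WIDTH):
                fh.write(seq[i:i + FASTA_WIDTH] + "\n")


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


# ------------------------------------------------------------- contig IO

def write_contigset(cs: ContigSet, fasta_path: str | Path,
                    tsv_path: str | Path) -> None:
    """FASTA + provenance/depth TSV for a contig set.

    TSV columns: contig_id, genome_id, start, end, depth_s1..depth_sS;
    contigs without provenance write '.' and -1 coordinates.
    """
    write_fasta(fasta_path, ((c.id, c.sequence) for c in cs))
    n_s = cs.n_samples()
    rows = []
    for c in cs:
        gid, s, e = c.provenance if c.provenance else (".", -1, -1)
        row = {"contig_id": c.id, "genome_id": gid, "start": s, "end": e}
        for i in range(n_s):
            row[f"depth_s{i + 1}"] = c.depths[i]
        rows.append(row)
    pd.DataFrame(rows).to_csv(tsv_path, sep="\t", index=False,
                              float_format=FLOAT_FORMAT)


def read_contigset(fasta_path: str | Path,
                   tsv_path: Optional[str | Path] = None) -> ContigSet:
    seqs = dict(read_fasta(fasta_path))
    meta = {}
    if tsv_path is not None:
        df = pd.read_csv(tsv_path, sep="\t")
        depth_cols = [c for c in df.columns if c.startswith("depth_s")]
        for _, r in df.iterrows():
            prov = None
            if r["genome_id"] != "." and int(r["start"]) >= 0:
                prov = (str(r["genome_id"]), int(r["start"]), int(r["end"]))
            meta[str(r["contig_id"])] = (prov, np.array([float(r[c]) for c in depth_cols]))
    cs = ContigSet()
    for cid, seq in seqs.items():
        prov, depths = meta.get(cid, (None, np.zeros(0)))
        cs.add(Contig(id=cid, sequence=seq, provenance=prov, depths=depths))
    return cs


def write_genomes(genomes: Sequence[Genome], fasta_path: str | Path,
                  marker_tsv: str | Path) -> None:
    write_fasta(fasta_path, ((g.id, g.sequence) for g in genomes))
    rows = [{"genome_id": g.id, "family_id": m.family_id,
             "start": m.start, "end": m.end}
            for g in genomes for m in g.markers]
    pd.DataFrame(rows, columns=["genome_id", "family_id", "start", "end"]).to_csv(
        marker_tsv, sep="\t", index=False)


def read_genomes(fasta_path: str | Path, marker_tsv: str | Path) -> list[Genome]:
    markers: dict[str, list[MarkerLocus]] = {}
    df = pd.read_csv(marker_tsv, sep="\t")
    for _, r in df.iterrows():
        markers.setdefault(str(r["genome_id"]), []).append(
            MarkerLocus(int(r["family_id"]), int(r["start"]), int(r["end"])))
    return [Genome(id=rid, sequence=seq, markers=markers.get(rid, []))
            for rid, seq in read_fasta(fasta_path)]


def write_abundance(ab: AbundanceMatrix, path: str | Path) -> None:
    df = pd.DataFrame(ab.values, index=ab.genome_ids,
                      columns=[f"s{i + 1}" for i in range(ab.n_samples)])
    df.index.name = "genome_id"
    df.to_csv(path, sep="\t", float_format="%.10g")


def read_abundance(path: str | Path) -> AbundanceMatrix:
    df = pd.read_csv(path, sep="\t", index_col="genome_id")
    return AbundanceMatrix(values=df.to_numpy(), genome_ids=list(df.index),
                           sigma_log=float("nan"), rho=float("nan"))


# ---------------------------------------------------------------- reads

@dataclass
class PairedRead:
    id: str
    seq1: str
    qual1: str
    seq2: str
    qual2: str


class ReadSet:
    """Paired short-read records; mates stay paired through all ops."""

    def __init__(self, pairs: Sequence[PairedRead] = ()):  # noqa: D107
        self.pairs = list(pairs)

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self):
        return iter(self.pairs)


def read_fastq_pairs(path1: str | Path, path2: str | Path) -> ReadSet:
    r1 = list(SeqIO.parse(str(path1), "fastq"))
    r2 = list(SeqIO.parse(str(path2), "fastq"))
    if len(r1) != len(r2):
        raise ValueError("mate files differ in read count")
    pairs = []
    for a, b in zip(r1, r2):
        qa = "".join(chr(q + 33) for q in a.letter_annotations["phred_quality"])
        qb = "".join(chr(q + 33) for q in b.letter_annotations["phred_quality"])
        pairs.append(PairedRead(a.id, str(a.seq), qa, str(b.seq), qb))
    return ReadSet(pairs)


def write_fastq_pairs(reads: ReadSet, path1: str | Path, path2: str | Path) -> None:
    with open(path1, "w") as f1, open(path2, "w") as f2:
        for p in reads:
            f1.write(f"@{p.id}/1\n{p.seq1}\n+\n{p.qual1}\n")
            f2.write(f"@{p.id}/2\n{p.seq2}\n+\n{p.qual2}\n")


def subsample_pairs(reads: ReadSet, n: int, seed: int = 0) -> ReadSet:
    """Uniform sample of ``n`` read pairs without replacement.

    Reservoir sampling keeps mates synchronized; asking for at least as
    many pairs as exist returns the input unchanged. Sampled pairs are
    emitted in their original order.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    if n >= len(reads):
        return reads
    rng = np.random.default_rng(seed)
    reservoir: list[int] = []
    for i in range(len(reads)):
        if i < n:
            reservoir.append(i)
        else:
            j = int(rng.integers(0, i + 1))
            if j < n:
                reservoir[j] = i
    return ReadSet([reads.pairs[i] for i in sorted(reservoir)])


# ----------------------------------------------------------- cost match

def cost_matched_reads(reads_a: int, bases_per_pair_a: int,
                       bases_per_pair_b: int, price_ratio_a_over_b: float) -> int:
    """Platform-B read count purchasable for platform A's sequencing cost.

    With a per-gigabase price ratio of 1.44 (HiSeq2500 PE250 over
    HiSeq4000 PE150), one million 2×250 bp pairs buys 2.4 million
    2×150 bp pairs.
    """
    if reads_a < 0:
        raise ValueError("reads_a must be >= 0")
    if bases_per_pair_a <= 0 or bases_per_pair_b <= 0 or price_ratio_a_over_b <= 0:
        raise ValueError("bases per pair and price ratio must be > 0")
    return round(reads_a * bases_per_pair_a * price_ratio_a_over_b / bases_per_pair_b)


# ------------------------------------------------------------- manifest

def write_json(obj: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_json(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def write_blocks_bed(blocks, path: str | Path) -> None:
    """BED of covered reference intervals (sorted, 0-based half-open)."""
    rows = sorted((b.ref_id, b.ref_start, b.ref_end, b.contig_id) for b in blocks)
    with open(path, "w") as fh:
        for rid, s, e, cid in rows:
            fh.write(f"{rid}\t{s}\t{e}\t{cid}\n")
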
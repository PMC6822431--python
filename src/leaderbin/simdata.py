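"""Synthetic multi-sample metagenome generation.

This module produces every input the downstream pipeline consumes:

* reference genomes carrying one copy of each universal single-copy
  marker family (the stand-in for HMM-detected marker genes);
* cross-sample abundance matrices with log-normal spread and optional
  AR(1) temporal autocorrelation;
* per-base coverage fields with chemistry presets — ``uniform``
  (ligation-like libraries) versus ``transposase`` (GC-dependent bias
  plus coverage-dropout windows, emulating tagmentation unevenness);
* short-read-style assemblies, emulated as coverage-threshold
  fragmentation with substitution/indel injection;
* long-read-style (synthetic long read) reference contigs: a full
  tiling of each genome at a low substitution error rate.

Marker presence/absence downstream is resolved through the provenance
annotations carried by every emitted contig, which keeps completeness
and redundancy estimates exact and deterministic.

All operations are bit-reproducible given their explicit integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np

from . import _seq
from .core import Contig, ContigSet, Genome, MarkerLocus

MARKER_DIVERGENCE = 0.05  # per-base divergence of each genome's marker copies


@dataclass
class AbundanceMatrix:
    """G×S relative-abundance matrix; columns (samples) sum to one."""

    values: np.ndarray
    genome_ids: list[str]
    sigma_log: float
    rho: float

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


@dataclass
class CoverageField:
    """Per-base expected depth for one genome in one sample."""

    genome_id: str
    depth: np.ndarray
    bias_profile: str = "uniform"

    def mean(self) -> float:
        return float(self.depth.mean())


def _marker_family_sequences(m_markers: int, marker_len: int, gc: float,
                             rng: np.random.Generator) -> list[str]:
    return [_seq.random_sequence(marker_len, gc, rng) for _ in range(m_markers)]


def generate_genomes(
    n_genomes: int,
    length: int,
    m_markers: int = 40,
    marker_len: int = 300,
    gc: float | Sequence[float] = 0.5,
    seed: int = 0,
) -> list[Genome]:
    """Generate ``n_genomes`` synthetic genomes with planted markers.

    Each genome carries exactly one copy of each of the ``m_markers``
    marker families. Family sequences are shared canonical sequences,
    mutated at 5% divergence per genome, and planted at disjoint
    positions (one per equal-width slot).

    ``gc`` may be a scalar or one target per genome.
    """
    if n_genomes < 1:
        raise ValueError("n_genomes must be >= 1")
    if m_markers > 0 and length < m_markers * marker_len * 10:
        raise ValueError(
            f"length {length} too small: need >= {m_markers * marker_len * 10} "
            f"for {m_markers} markers of {marker_len} bp"
        )
    gcs = [float(gc)] * n_genomes if np.isscalar(gc) else [float(g) for g in gc]
    if len(gcs) != n_genomes:
        raise ValueError("gc must be scalar or one value per genome")
    rng = np.random.default_rng(seed)
    canon = _marker_family_sequences(m_markers, marker_len, float(np.mean(gcs)), rng)
    genomes = []
    for i in range(n_genomes):
        seq = np.frombuffer(
            _seq.random_sequence(length, gcs[i], rng).encode(), dtype=np.uint8
        ).copy()
        markers: list[MarkerLocus] = []
        if m_markers > 0:
            slot = length // m_markers
            for fam in range(m_markers):
                offset = int(rng.integers(0, slot - marker_len + 1))
                start = fam * slot + offset
                copy, _ = _seq.mutate_substitutions(canon[fam], MARKER_DIVERGENCE, rng)
                seq[start:start + marker_len] = np.frombuffer(copy.encode(), dtype=np.uint8)
                markers.append(MarkerLocus(fam, start, start + marker_len))
        g = Genome(id=f"g{i:03d}", sequence=seq.tobytes().decode(), markers=markers,
                   gc_target=gcs[i])
        g.validate()
        genomes.append(g)
    return genomes


def composition_twin(genome: Genome, seed: int = 0) -> Genome:
    """A genome with matching tetranucleotide statistics but unrelated sequence.

    The sequence is re-sampled from a 3rd-order Markov chain estimated on
    the input, which preserves 4-mer frequencies in expectation while
    destroying long-range identity. The same marker families are planted
    afresh (each copied from the input's marker and mutated at 5%
    divergence) at slot positions, so marker-based completeness and
    redundancy remain measurable on the twin.
    """
    rng = np.random.default_rng(seed)
    codes = _seq.encode(genome.sequence)
    L = codes.size
    if L < 4:
        return Genome(id=genome.id + "_twin", sequence=genome.sequence,
                      markers=list(genome.markers), gc_target=genome.gc_target)
    # transition counts: 64 contexts x 4 successors
    ctx = codes[:-3] * 16 + codes[1:-2] * 4 + codes[2:-1]
    counts = np.zeros((64, 4), dtype=np.float64)
    np.add.at(counts, (ctx, codes[3:]), 1.0)
    base_freq = np.bincount(codes, minlength=4).astype(float)
    base_freq /= base_freq.sum()
    row_sums = counts.sum(axis=1, keepdims=True)
    probs = np.where(row_sums > 0, counts / np.maximum(row_sums, 1), base_freq)
    out = np.empty(L, dtype=np.uint8)
    out[:3] = codes[:3]
    u = rng.random(L - 3)
    cum = probs.cumsum(axis=1)
    c = int(out[0]) * 16 + int(out[1]) * 4 + int(out[2])
    for i in range(3, L):
        nxt = int(np.searchsorted(cum[c], u[i - 3], side="right"))
        nxt = min(nxt, 3)
        out[i] = nxt
        c = (c % 16) * 4 + nxt
    seq = np.frombuffer(_seq.decode(out).encode(), dtype=np.uint8).copy()
    markers: list[MarkerLocus] = []
    m = len(genome.markers)
    if m > 0:
        slot = L // m
        for j, src in enumerate(sorted(genome.markers, key=lambda x: x.family_id)):
            mlen = src.length
            offset = int(rng.integers(0, max(slot - mlen, 0) + 1))
            start = j * slot + offset
            copy, _ = _seq.mutate_substitutions(
                genome.sequence[src.start:src.end], MARKER_DIVERGENCE, rng)
            seq[start:start + mlen] = np.frombuffer(copy.encode(), dtype=np.uint8)
            markers.append(MarkerLocus(src.family_id, start, start + mlen))
    twin = Genome(id=genome.id + "_twin", sequence=seq.tobytes().decode(),
                  markers=markers, gc_target=genome.gc_target)
    twin.validate()
    return twin


def sample_abundances(
    n_genomes: int,
    n_samples: int,
    sigma_log: float = 1.0,
    rho: float = 0.0,
    seed: int = 0,
    genome_ids: Optional[Sequence[str]] = None,
) -> AbundanceMatrix:
    """Log-normal abundances with AR(1) autocorrelation across samples.

    Per genome, latent log-abundances follow a stationary AR(1) process
    over the sample axis with marginal standard deviation ``sigma_log``
    and lag-1 autocorrelation ``rho``. Columns are normalized to sum to 1.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if sigma_log < 0:
        raise ValueError("sigma_log must be >= 0")
    if not (0 <= rho <= 1):
        raise ValueError("rho must be in [0, 1]")
    rng = np.random.default_rng(seed)
    x = np.zeros((n_genomes, n_samples))
    x[:, 0] = rng.normal(0.0, sigma_log, size=n_genomes)
    innov_sd = sigma_log * np.sqrt(max(1.0 - rho * rho, 0.0))
    for s in range(1, n_samples):
        x[:, s] = rho * x[:, s - 1] + rng.normal(0.0, innov_sd, size=n_genomes)
    vals = np.exp(x)
    vals /= vals.sum(axis=0, keepdims=True)
    ids = list(genome_ids) if genome_ids is not None else [f"g{i:03d}" for i in range(n_genomes)]
    return AbundanceMatrix(values=vals, genome_ids=ids, sigma_log=sigma_log, rho=rho)


def simulate_coverage(
    genome: Genome,
    abundance: float,
    total_depth: float,
    bias_profile: str = "uniform",
    seed: int = 0,
    gc_sensitivity: float = 3.0,
    dropout_fraction: float = 0.05,
    dropout_window: int = 2000,
    dropout_factor: float = 0.05,
    gc_window: int = 200,
) -> CoverageField:
    """Per-base expected depth for one genome in one sample.

    ``uniform``: constant expectation ``abundance * total_depth`` with
    Poisson per-base noise. ``transposase``: the same expectation
    modulated by a GC-dependent factor (windows deviating from the
    genome mean GC are penalized, strength ``gc_sensitivity``) and by
    randomly placed dropout windows at ``dropout_factor`` of the local
    expectation, covering ``dropout_fraction`` of the genome; the
    combined bias factor is renormalized to mean one so the requested
    mean depth is preserved in expectation.
    """
    if abundance < 0:
        raise ValueError("abundance must be >= 0")
    if total_depth <= 0:
        raise ValueError("total_depth must be > 0")
    L = len(genome)
    lam = abundance * total_depth
    rng = np.random.default_rng(seed)
    if bias_profile == "uniform":
        if lam == 0:
            return CoverageField(genome.id, np.zeros(L), "uniform")
        return CoverageField(genome.id, rng.poisson(lam, L).astype(float), "uniform")
    if bias_profile != "transposase":
        raise ValueError(f"unknown bias profile: {bias_profile!r}")
    codes = _seq.encode(genome.sequence)
    is_gc = np.isin(codes, (1, 2)).astype(float)
    n_win = max(L // gc_window, 1)
    trimmed = is_gc[: n_win * gc_window].reshape(n_win, -1).mean(axis=1)
    gc_local = np.repeat(trimmed, gc_window)[:L]
    if gc_local.size < L:  # tail window inherits the last full window
        gc_local = np.concatenate([gc_local, np.full(L - gc_local.size, trimmed[-1])])
    factor = np.exp(-gc_sensitivity * np.abs(gc_local - is_gc.mean()) * 2)
    n_drop = int(np.ceil(dropout_fraction * L / dropout_window))
    starts = rng.integers(0, max(L - dropout_window, 1), size=n_drop)
    for s in starts:
        factor[s:s + dropout_window] *= dropout_factor
    factor /= factor.mean()
    if lam == 0:
        return CoverageField(genome.id, np.zeros(L), "transposase")
    return CoverageField(genome.id, rng.poisson(lam * factor).astype(float), "transposase")


def smooth_depth(depth: np.ndarray, window: int) -> np.ndarray:
    """Edge-corrected moving average of a per-base depth array."""
    if window <= 1:
        return depth
    kernel = np.ones(window)
    return np.convolve(depth, kernel, mode="same") / np.convolve(
        np.ones_like(depth), kernel, mode="same")


def _contig_runs(pooled: np.ndarray, break_depth: float, min_contig: int) -> list[tuple[int, int]]:
    """Maximal runs with depth >= break_depth and length >= min_contig."""
    ok = pooled >= break_depth
    if not ok.any():
        return []
    edges = np.flatnonzero(np.diff(np.concatenate(([0], ok.view(np.int8), [0]))))
    return [(int(s), int(e)) for s, e in zip(edges[::2], edges[1::2]) if e - s >= min_contig]


def emulate_assembly(
    genome: Genome,
    field: CoverageField | Sequence[CoverageField],
    break_depth: float = 2.0,
    sub_rate: float = 0.0,
    indel_rate: float = 0.0,
    min_contig: int = 500,
    seed: int = 0,
    id_prefix: Optional[str] = None,
    smooth_window: int = 1,
) -> ContigSet:
    """Emulate a short-read assembly by coverage-threshold fragmentation.

    The genome is cut wherever pooled expected depth falls below
    ``break_depth``; surviving runs of at least ``min_contig`` bp are
    emitted as contigs with substitutions and indels injected at the
    stated per-base rates. Provenance records the source interval, and
    per-sample mean depths are computed from the field(s).

    ``field`` may be a single :class:`CoverageField` (one sample) or a
    sequence of fields (one per sample; fragmentation then uses the
    pooled, summed depth — the co-assembly convention).

    ``smooth_window`` > 1 applies a moving average to the pooled depth
    before thresholding, modelling breakage at read-length scale rather
    than at single anomalous bases; 1 (default) thresholds the raw field.
    """
    if not (0 <= sub_rate <= 0.1 and 0 <= indel_rate <= 0.1):
        raise ValueError("error rates must be in [0, 0.1]")
    if min_contig < 1:
        raise ValueError("min_contig must be >= 1")
    fields = [field] if isinstance(field, CoverageField) else list(field)
    pooled = smooth_depth(np.sum([f.depth for f in fields], axis=0), smooth_window)
    rng = np.random.default_rng(seed)
    prefix = id_prefix if id_prefix is not None else f"{genome.id}_c"
    out = ContigSet()
    for idx, (s, e) in enumerate(_contig_runs(pooled, break_depth, min_contig)):
        seq = genome.sequence[s:e]
        if sub_rate > 0 or indel_rate > 0:
            seq, _, _, _ = _seq.mutate(seq, sub_rate, indel_rate, rng)
        depths = np.array([float(f.depth[s:e].mean()) for f in fields])
        out.add(Contig(id=f"{prefix}{idx:04d}", sequence=seq,
                       provenance=(genome.id, s, e), depths=depths))
    return out


def emulate_tslr_bins(
    genomes: Sequence[Genome],
    segment_len_range: tuple[int, int] = (3000, 10000),
    error_rate: float = 0.001,
    seed: int = 0,
    depths: Optional[Mapping[str, np.ndarray]] = None,
    depth_noise: bool = False,
) -> dict[str, ContigSet]:
    """Emulate synthetic-long-read reference contigs for each genome.

    Each genome is tiled end-to-end by segments with lengths drawn
    uniformly from ``segment_len_range`` (the final segment is truncated
    at the genome end), and substitutions are injected at ``error_rate``
    — the sub-0.1% error regime of synthetic long reads.

    ``depths`` optionally supplies a per-genome length-S mean-depth
    vector copied onto every segment; with ``depth_noise`` the per-
    segment value is Poisson-resampled around that mean (total base
    count over the segment), emulating read-mapping depth estimation.
    """
    if not (0 <= error_rate <= 0.01):
        raise ValueError("error_rate must be in [0, 0.01]")
    lo, hi = segment_len_range
    if not (0 < lo <= hi):
        raise ValueError("invalid segment length range")
    rng = np.random.default_rng(seed)
    out: dict[str, ContigSet] = {}
    for g in genomes:
        cs = ContigSet()
        pos = 0
        idx = 0
        L = len(g)
        base_depth = None if depths is None else np.asarray(depths[g.id], dtype=float)
        while pos < L:
            seg_len = int(rng.integers(lo, hi + 1))
            end = min(pos + seg_len, L)
            seq = g.sequence[pos:end]
            if error_rate > 0:
                seq, _ = _seq.mutate_substitutions(seq, error_rate, rng)
            if base_depth is None:
                d = np.zeros(0)
            elif depth_noise:
                n = end - pos
                d = rng.poisson(np.maximum(base_depth, 0) * n) / n
            else:
                d = base_depth.copy()
            cs.add(Contig(id=f"{g.id}_t{idx:04d}", sequence=seq,
                          provenance=(g.id, pos, end), depths=d))
            pos = end
            idx += 1
        out[g.id] = cs
    return out


def community_depths(abundance: AbundanceMatrix, total_depth: float) -> dict[str, np.ndarray]:
    """Expected mean depth per genome per sample: abundance × total depth."""
    return {gid: abundance.values[i] * total_depth
            for i, gid in enumerate(abundance.genome_ids)}
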
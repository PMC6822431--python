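"""Low-level nucleotide-sequence utilities shared across modules.

Sequences are plain Python strings over {A,C,G,T} (N tolerated on input,
never matched). Internally most routines work on uint8 code arrays with
A=0, C=1, G=2, T=3; code 255 marks ambiguous bases.
"""

from __future__ import annotations

import numpy as np

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

_ENCODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENCODE[_b] = _i
    _ENCODE[ord(chr(_b).lower())] = _i

_COMPLEMENT = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")


def encode(seq: str) -> np.ndarray:
    """Encode a sequence string to uint8 codes (255 for non-ACGT)."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode("ascii")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def gc_fraction(seq: str) -> float:
    codes = encode(seq)
    valid = codes != 255
    if not valid.any():
        return 0.0
    return float(np.isin(codes[valid], (1, 2)).mean())


def random_sequence(length: int, gc: float, rng: np.random.Generator) -> str:
    """I.i.d. sequence with expected GC content ``gc``."""
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return decode(rng.choice(4, size=length, p=p).astype(np.uint8))


def mutate_substitutions(seq: str, rate: float, rng: np.random.Generator) -> tuple[str, int]:
    """Inject substitutions at per-base ``rate``; returns (sequence, count).

    Only defined for unambiguous {A,C,G,T} sequences (simulator output).
    """
    codes = encode(seq)
    pos = np.flatnonzero(rng.random(codes.size) < rate)
    if pos.size:
        codes = codes.copy()
        codes[pos] = (codes[pos] + rng.integers(1, 4, size=pos.size)) % 4
    return decode(codes), int(pos.size)


def mutate(
    seq: str,
    sub_rate: float,
    indel_rate: float,
    rng: np.random.Generator,
) -> tuple[str, int, int, int]:
    """Inject substitutions and indels at per-base rates.

    The indel rate is split evenly between single-base insertions and
    deletions. Returns (mutated sequence, n_sub, n_ins, n_del).
    """
    codes = encode(seq)
    n = codes.size
    u = rng.random(n)
    sub_pos = np.flatnonzero(u < sub_rate)
    if sub_pos.size:
        codes = codes.copy()
        codes[sub_pos] = (codes[sub_pos] + rng.integers(1, 4, size=sub_pos.size)) % 4
    if indel_rate > 0:
        v = rng.random(n)
        del_mask = v < indel_rate / 2
        ins_mask = (v >= indel_rate / 2) & (v < indel_rate)
        n_del = int(del_mask.sum())
        n_ins = int(ins_mask.sum())
        # repeat-count trick: deleted bases contribute 0 copies, insertion
        # sites 2 (original base + a random base appended after it)
        counts = np.ones(n, dtype=np.intp)
        counts[del_mask] = 0
        counts[ins_mask] = 2
        out = np.repeat(codes, counts)
        if n_ins:
            # positions of the duplicated slots in the output array
            ends = np.cumsum(counts)
            ins_out = ends[ins_mask] - 1
            out[ins_out] = rng.integers(0, 4, size=n_ins).astype(np.uint8)
        codes = out
    else:
        n_ins = n_del = 0
    return decode(codes), int(sub_pos.size), n_ins, n_del


def kmer_codes(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """2-bit packed k-mer codes at every valid position.

    Returns (positions, uint64 codes); windows containing non-ACGT bases
    are dropped. Requires k <= 31.
    """
    n = codes.size
    if n < k:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.uint64)
    valid = codes != 255
    c = np.where(valid, codes, 0).astype(np.uint64)
    weights = (4 ** np.arange(k - 1, -1, -1, dtype=np.uint64))
    win = np.lib.stride_tricks.sliding_window_view(c, k)
    vals = win @ weights
    ok = np.lib.stride_tricks.sliding_window_view(valid, k).all(axis=1)
    pos = np.flatnonzero(ok)
    return pos, vals[pos]


def revcomp_codes(vals: np.ndarray, k: int) -> np.ndarray:
    """Reverse-complement of packed k-mer codes."""
    out = np.zeros_like(vals)
    v = vals.copy()
    for _ in range(k):
        out = (out << np.uint64(2)) | (np.uint64(3) - (v & np.uint64(3)))
        v >>= np.uint64(2)
    return out


def canonical_kmer_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Canonical (strand-collapsed) packed k-mer codes of a sequence."""
    _, vals = kmer_codes(codes, k)
    return np.minimum(vals, revcomp_codes(vals, k))


def splitmix64(x: np.ndarray) -> np.ndarray:
    """Stable 64-bit mixing function (for MinHash sketches)."""
    z = x + np.uint64(0x9E3779B97F4A7C15)
    z = (z ^ (z >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
    z = (z ^ (z >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
    return z ^ (z >> np.uint64(31))
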
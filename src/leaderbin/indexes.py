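"""Combinatorial dual-index (i7/i5) plate design with rotation.

A plate of n wells (default 384) assigns i7 index w to well w and i5
index (w + plate_ordinal) mod n — a cyclic rotation per plate. Within
any plate all i7s, all i5s and all (i7, i5) pairs are distinct, which
guards against barcode-swap misassignment; across consecutive plates
every pair recurs only after n plates, i.e. n² libraries (147,456 for
the full 384-index set).
"""

from __future__ import annotations

import string
from dataclasses import dataclass
from typing import Optional


@dataclass
class IndexPlate:
    plate_ordinal: int
    wells: list[tuple[str, int, int]]  # (well_label, i7_id, i5_id)


def well_label(w: int, n_cols: int = 24) -> str:
    """Row-major plate well label: A1..P24 for a 384-well plate."""
    row, col = divmod(w, n_cols)
    letters = string.ascii_uppercase
    prefix = letters[row] if row < 26 else letters[row // 26 - 1] + letters[row % 26]
    return f"{prefix}{col + 1}"


def build_plate(plate_ordinal: int, n: int = 384) -> IndexPlate:
    """Dual-index assignment for one plate under the rotation scheme."""
    if n <= 0:
        raise ValueError("n must be >= 1")
    if plate_ordinal < 0:
        raise ValueError("plate_ordinal must be >= 0")
    n_cols = 24 if n % 24 == 0 else n
    wells = [(well_label(w, n_cols), w, (w + plate_ordinal) % n) for w in range(n)]
    return IndexPlate(plate_ordinal=plate_ordinal, wells=wells)


def pair_recurrence_period(n_i7: int, n_i5: int) -> int:
    """Number of libraries between recurrences of any (i7, i5) pair.

    Under the cyclic rotation with equal index counts n, a pair recurs
    after exactly n plates of n wells = n_i7 × n_i5 libraries.
    """
    if n_i7 < 1 or n_i5 < 1:
        raise ValueError("index counts must be >= 1")
    if n_i7 != n_i5:
        raise ValueError("rotation scheme is defined for equal i7/i5 counts")
    return n_i7 * n_i5


def plate_rows(plate: IndexPlate, i7_seqs: Optional[dict[int, str]] = None,
               i5_seqs: Optional[dict[int, str]] = None) -> list[dict]:
    """Plate-sheet rows (well, i7_id, i5_id, optional sequences)."""
    rows = []
    for label, i7, i5 in plate.wells:
        row = {"well": label, "i7_id": i7, "i5_id": i5}
        if i7_seqs is not None:
            row["i7_seq"] = i7_seqs.get(i7, "")
        if i5_seqs is not None:
            row["i5_seq"] = i5_seqs.get(i5, "")
        rows.append(row)
    return rows
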
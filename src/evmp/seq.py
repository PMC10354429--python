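"""Promoter sequence data model, one-hot codec and library I/O.

Synthetic promoter libraries are collections of mutagenesis-derived variants
of a single *base promoter*, each with an experimentally measured strength
(log Fluorescence/OD600).  Sequences live over the five-letter alphabet
``A, T, C, G, B`` where ``B`` (blank) serves three roles: right-padding to a
library-wide fixed length, gap rendering after alignment, and masking in the
mutation representations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: Fixed alphabet order; feature/channel indices are stable under this order.
ALPHABET: tuple[str, ...] = ("A", "T", "C", "G", "B")
BLANK = "B"
#: One-hot channel count (four bases plus blank).
N_CHANNELS = 5

_CHAR_TO_INDEX = {c: i for i, c in enumerate(ALPHABET)}

#: Default library-wide padded length.
DEFAULT_PAD_LENGTH = 85


class AlphabetError(ValueError):
    """A sequence contains a character outside {A, T, C, G, B}."""


class LibraryJoinError(ValueError):
    """FASTA ids and strength-table ids do not match up."""


def validate_sequence(sequence: str, seq_id: str = "<sequence>") -> None:
    """Raise :class:`AlphabetError` naming the id and 0-based position of the
    first character outside the closed alphabet."""
    for pos, char in enumerate(sequence):
        if char not in _CHAR_TO_INDEX:
            raise AlphabetError(
                f"record {seq_id!r}: invalid character {char!r} at position {pos}"
            )


def pad(sequence: str, length: int) -> str:
    """Right-pad with ``B`` to ``length``; never alters existing characters."""
    if len(sequence) > length:
        raise ValueError(
            f"sequence of length {len(sequence)} exceeds pad length {length}"
        )
    return sequence + BLANK * (length - len(sequence))


def strip_blank(sequence: str) -> str:
    """Strip trailing ``B`` padding (inverse of :func:`pad` when the original
    had no trailing blanks)."""
    return sequence.rstrip(BLANK)


@dataclass(frozen=True)
class Promoter:
    """A promoter sequence with an optional strength label.

    Parameters
    ----------
    id : str
        Unique identifier within a library.
    sequence : str
        Upper-case sequence over ``{A, T, C, G, B}``.
    strength : float, optional
        Promoter strength on the log scale (log Fluorescence/OD600).
    """

    id: str
    sequence: str
    strength: Optional[float] = None

    def __post_init__(self) -> None:
        validate_sequence(self.sequence, self.id)
        if self.strength is not None and not math.isfinite(self.strength):
            raise ValueError(f"record {self.id!r}: strength must be finite")

    def __len__(self) -> int:
        return len(self.sequence)

    def padded(self, length: int) -> "Promoter":
        return replace(self, sequence=pad(self.sequence, length))


def one_hot(sequence: str) -> np.ndarray:
    """One-hot encode a sequence as a ``(len, 5)`` float matrix.

    Row ``i`` is the unit vector of ``sequence[i]`` under the channel order
    ``(A, T, C, G, B)``; every row sums to 1.
    """
    validate_sequence(sequence)
    mat = np.zeros((len(sequence), N_CHANNELS))
    for i, char in enumerate(sequence):
        mat[i, _CHAR_TO_INDEX[char]] = 1.0
    return mat


def decode_one_hot(matrix: np.ndarray) -> str:
    """Exact inverse of :func:`one_hot` on its image."""
    matrix = np.asarray(matrix)
    if matrix.ndim != 2 or matrix.shape[1] != N_CHANNELS:
        raise ValueError(f"expected a (n, {N_CHANNELS}) matrix, got {matrix.shape}")
    return "".join(ALPHABET[int(j)] for j in matrix.argmax(axis=1))


@dataclass
class PromoterLibrary:
    """A base promoter plus an ordered list of labelled variants, all padded
    to a common length ``pad_length``."""

    base: Promoter
    variants: list[Promoter] = field(default_factory=list)
    pad_length: int = DEFAULT_PAD_LENGTH

    def __post_init__(self) -> None:
        ids = [v.id for v in self.variants]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate variant ids: {dupes}")
        for p in [self.base, *self.variants]:
            if len(p) != self.pad_length:
                raise ValueError(
                    f"record {p.id!r} has length {len(p)}, expected padded "
                    f"length {self.pad_length}"
                )

    def __len__(self) -> int:
        return len(self.variants)

    @property
    def labeled(self) -> bool:
        return all(v.strength is not None for v in self.variants)

    def strengths(self) -> np.ndarray:
        if not self.labeled:
            raise ValueError("library contains unlabeled variants")
        return np.array([v.strength for v in self.variants])


def _read_strength_table(path: Path) -> dict[str, Optional[float]]:
    # Two-column (id, strength) text; delimiter (comma/tab) auto-detected.
    if not Path(path).read_text().strip():
        return {}
    df = pd.read_csv(path, sep=None, engine="python", header=None, dtype=str,
                     skip_blank_lines=True)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (id, strength)")
    rows = df.iloc[:, :2].values.tolist()
    # Tolerate a header row whose second field is not numeric.
    if rows and rows[0][1] is not None:
        try:
            float(rows[0][1])
        except ValueError:
            rows = rows[1:]
    table: dict[str, Optional[float]] = {}
    for rid, raw in rows:
        if raw is None or (isinstance(raw, float) and math.isnan(raw)) or raw == "":
            table[str(rid)] = None
            continue
        table[str(rid)] = float(raw)
    return table


def read_library(
    fasta_path: str | Path,
    strength_table_path: str | Path | None,
    pad_length: int = DEFAULT_PAD_LENGTH,
    *,
    base_id: str | None = None,
    allow_unlabeled: bool = False,
) -> PromoterLibrary:
    """Read a promoter library from FASTA plus a two-column strength table.

    The base promoter is the record named by ``base_id``, or the first FASTA
    record otherwise; it needs no strength entry.  All sequences are
    upper-cased and right-padded with ``B`` to ``pad_length``.  Strength ids
    must match FASTA ids exactly (a :class:`LibraryJoinError` lists orphans);
    variants missing from the table are only allowed with
    ``allow_unlabeled=True``.
    """
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if not records:
        raise ValueError(f"{fasta_path}: no FASTA records")
    table: dict[str, Optional[float]] = {}
    if strength_table_path is not None:
        table = _read_strength_table(Path(strength_table_path))

    promoters: list[Promoter] = []
    for rec in records:
        seq = str(rec.seq).upper()
        validate_sequence(seq, rec.id)
        promoters.append(Promoter(rec.id, pad(seq, pad_length)))

    fasta_ids = {p.id for p in promoters}
    if base_id is None:
        base_id = promoters[0].id
    elif base_id not in fasta_ids:
        raise LibraryJoinError(f"base id {base_id!r} not present in FASTA")

    orphans = sorted(set(table) - fasta_ids)
    if orphans:
        raise LibraryJoinError(f"strength-table ids absent from FASTA: {orphans}")

    base = next(p for p in promoters if p.id == base_id)
    if base.id in table and table[base.id] is not None:
        base = replace(base, strength=table[base.id])

    variants = []
    for p in promoters:
        if p.id == base_id:
            continue
        strength = table.get(p.id)
        if strength is None and not allow_unlabeled:
            raise LibraryJoinError(
                f"variant {p.id!r} has no strength entry "
                "(pass allow_unlabeled=True to permit)"
            )
        variants.append(replace(p, strength=strength))
    return PromoterLibrary(base=base, variants=variants, pad_length=pad_length)


def write_library(
    lib: PromoterLibrary,
    fasta_path: str | Path,
    table_path: str | Path,
) -> None:
    """Write FASTA + strength table such that :func:`read_library` round-trips
    sequences, ids and strengths exactly (strengths via ``repr`` full
    precision; unlabeled variants get an empty strength field)."""
    records = [SeqRecord(Seq(p.sequence), id=p.id, description="")
               for p in [lib.base, *lib.variants]]
    SeqIO.write(records, str(fasta_path), "fasta")
    with open(table_path, "w") as fh:
        fh.write("id\tstrength\n")
        if lib.base.strength is not None:
            fh.write(f"{lib.base.id}\t{lib.base.strength!r}\n")
        for p in lib.variants:
            value = "" if p.strength is None else repr(float(p.strength))
            fh.write(f"{p.id}\t{value}\n")


def hamming(a: str, b: str) -> int:
    """Number of mismatching positions between equal-length strings."""
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal lengths")
    return sum(x != y for x, y in zip(a, b))
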
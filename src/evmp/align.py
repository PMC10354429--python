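"""Alignment, mutation-site extraction and the k-mer mutation format.

A synthetic promoter S' is re-expressed, relative to a base promoter S, as
the pair <S, M(S, S')> where M(S, S') is the set of k-length windows of S'
centred on each mutation site ("extended vision": k > 1).  The pair is
equivalent to S' — ``reconstruct`` recovers the variant exactly — which is
the testable contract of the whole data-processing step.

Coordinates are 0-based positions in the aligned, B-padded coordinate
system.  Gaps introduced by alignment are rendered as ``B`` so that indels
stay expressible in the five-letter one-hot alphabet.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np

from .seq import BLANK, Promoter, pad, validate_sequence


class ConsistencyError(ValueError):
    """Overlapping k-mer windows disagree about a position."""


@dataclass(frozen=True)
class AlignmentParams:
    """Needleman–Wunsch scoring; ``match > mismatch`` and ``gap <= 0``."""

    match: float = 1.0
    mismatch: float = -1.0
    gap: float = -2.0

    def __post_init__(self) -> None:
        if not self.match > self.mismatch:
            raise ValueError("match score must exceed mismatch score")
        if self.gap > 0:
            raise ValueError("gap score must be non-positive")


@dataclass(frozen=True)
class Alignment:
    a: str
    b: str
    score: float


@dataclass(frozen=True)
class MutationSite:
    """A single position where variant and base differ (substitution, or an
    indel rendered as B on one side)."""

    position: int
    base_char: str
    variant_char: str

    def __post_init__(self) -> None:
        if self.base_char == self.variant_char:
            raise ValueError("a mutation site requires differing characters")
        if self.position < 0:
            raise ValueError("position must be non-negative")


@dataclass(frozen=True)
class KmerMutation:
    """The k-length window of the variant centred on one mutation site.

    The window covers indices ``[position - k//2, position + k - k//2 - 1]``
    of the variant; indices outside the sequence read as ``B`` so every
    window has length exactly k.
    """

    site: MutationSite
    k: int
    window: str

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if len(self.window) != self.k:
            raise ValueError(f"window {self.window!r} does not have length k={self.k}")
        validate_sequence(self.window)

    @property
    def start(self) -> int:
        """First (possibly negative) variant index covered by the window."""
        return self.site.position - self.k // 2

    def indices(self) -> range:
        return range(self.start, self.start + self.k)


@dataclass(frozen=True)
class EVMPRecord:
    """One variant in <base, k-mer mutations> form.

    ``mutations`` are sorted by ascending site position and, overlaid on
    ``base.sequence``, reproduce the (aligned, padded) variant exactly.
    """

    base: Promoter
    mutations: tuple[KmerMutation, ...]
    variant_id: str
    k: int
    strength: Optional[float] = None

    def __post_init__(self) -> None:
        positions = [m.site.position for m in self.mutations]
        if positions != sorted(positions):
            object.__setattr__(
                self,
                "mutations",
                tuple(sorted(self.mutations, key=lambda m: m.site.position)),
            )
        for m in self.mutations:
            if m.k != self.k:
                raise ValueError("all windows in a record must share k")
        if self.strength is not None and not math.isfinite(self.strength):
            raise ValueError("strength must be finite")

    @property
    def n_sites(self) -> int:
        return len(self.mutations)

    @property
    def length(self) -> int:
        return len(self.base)

    def variant_sequence(self) -> str:
        return reconstruct(self.base.sequence, self.mutations)


def global_align(a: str, b: str, params: AlignmentParams = AlignmentParams()) -> Alignment:
    """Optimal Needleman–Wunsch global alignment of two sequences.

    Deterministic traceback: at score ties prefer the diagonal move, then the
    vertical (gap in ``b``), then the horizontal (gap in ``a``).  Gaps are
    rendered as ``B`` in both output strings.
    """
    if not a or not b:
        raise ValueError("global_align requires non-empty sequences")
    validate_sequence(a)
    validate_sequence(b)
    n, m = len(a), len(b)
    score = np.empty((n + 1, m + 1))
    score[0, :] = np.arange(m + 1) * params.gap
    score[:, 0] = np.arange(n + 1) * params.gap
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            sub = params.match if a[i - 1] == b[j - 1] else params.mismatch
            score[i, j] = max(
                score[i - 1, j - 1] + sub,
                score[i - 1, j] + params.gap,
                score[i, j - 1] + params.gap,
            )
    out_a: list[str] = []
    out_b: list[str] = []
    i, j = n, m
    while i > 0 or j > 0:
        if i > 0 and j > 0:
            sub = params.match if a[i - 1] == b[j - 1] else params.mismatch
            if score[i, j] == score[i - 1, j - 1] + sub:
                out_a.append(a[i - 1])
                out_b.append(b[j - 1])
                i, j = i - 1, j - 1
                continue
        if i > 0 and score[i, j] == score[i - 1, j] + params.gap:
            out_a.append(a[i - 1])
            out_b.append(BLANK)
            i -= 1
            continue
        out_a.append(BLANK)
        out_b.append(b[j - 1])
        j -= 1
    return Alignment("".join(reversed(out_a)), "".join(reversed(out_b)),
                     float(score[n, m]))


def extract_sites(base_aligned: str, variant_aligned: str) -> list[MutationSite]:
    """One :class:`MutationSite` per differing position, ascending order.
    Substitutions and B-rendered indels are treated alike."""
    if len(base_aligned) != len(variant_aligned):
        raise ValueError(
            f"aligned lengths differ: {len(base_aligned)} vs {len(variant_aligned)}"
        )
    return [
        MutationSite(i, x, y)
        for i, (x, y) in enumerate(zip(base_aligned, variant_aligned))
        if x != y
    ]


def kmer_window(variant: str, position: int, k: int) -> str:
    """The k-length window of ``variant`` centred at ``position`` (left-heavy
    for even k); indices outside ``[0, len)`` read as ``B``."""
    start = position - k // 2
    return "".join(
        variant[i] if 0 <= i < len(variant) else BLANK
        for i in range(start, start + k)
    )


def kmer_mutations(
    variant: str, sites: Sequence[MutationSite], k: int
) -> list[KmerMutation]:
    """One :class:`KmerMutation` per site; overlapping windows are emitted
    independently, never merged."""
    if k < 1:
        raise ValueError("k must be >= 1")
    for site in sites:
        if not 0 <= site.position < len(variant):
            raise ValueError(f"site position {site.position} out of bounds")
    return [KmerMutation(site, k, kmer_window(variant, site.position, k))
            for site in sites]


def reconstruct(base: str, mutations: Iterable[KmerMutation]) -> str:
    """Invert the k-mer decomposition: overlay every window on ``base``.

    Positions outside any window keep the base character; covered positions
    take the window character.  Overlapping windows must agree
    (:class:`ConsistencyError` names the first conflicting position).
    """
    chars = list(base)
    assigned: dict[int, str] = {}
    for mut in mutations:
        for offset, char in zip(mut.indices(), mut.window):
            if offset < 0 or offset >= len(chars):
                continue
            if offset in assigned and assigned[offset] != char:
                raise ConsistencyError(
                    f"overlapping windows disagree at position {offset}: "
                    f"{assigned[offset]!r} vs {char!r}"
                )
            assigned[offset] = char
            chars[offset] = char
    return "".join(chars)


def make_record(
    base: Promoter,
    variant: Promoter,
    k: int,
    pad_length: int,
    params: AlignmentParams = AlignmentParams(),
) -> EVMPRecord:
    """Full data-processing step for one variant: align to the base, render
    gaps as B, pad both to ``pad_length``, extract sites and k-mer windows.

    Equal-length pairs (substitution-only libraries) skip the aligner, which
    then provably acts as the identity.
    """
    base_seq = base.sequence.rstrip(BLANK)
    var_seq = variant.sequence.rstrip(BLANK)
    if len(base_seq) == len(var_seq):
        aligned_base, aligned_var = base_seq, var_seq
    else:
        aln = global_align(base_seq, var_seq, params)
        aligned_base, aligned_var = aln.a, aln.b
    aligned_base = pad(aligned_base, pad_length)
    aligned_var = pad(aligned_var, pad_length)
    sites = extract_sites(aligned_base, aligned_var)
    muts = kmer_mutations(aligned_var, sites, k)
    return EVMPRecord(
        base=Promoter(base.id, aligned_base, base.strength),
        mutations=tuple(muts),
        variant_id=variant.id,
        k=k,
        strength=variant.strength,
    )


def receptive_field(record: EVMPRecord) -> float:
    """Fraction of promoter positions covered by at least one k-mer window
    (the VarEncoder's receptive field), in [0, 1]."""
    L = record.length
    covered: set[int] = set()
    for mut in record.mutations:
        covered.update(i for i in mut.indices() if 0 <= i < L)
    return len(covered) / L


def suggest_k(promoter_length: int, mean_mutation_count: float) -> int:
    """Heuristic window size k = l / alpha (rounded, floored at 1), chosen so
    that k-mer windows of the alpha average mutation sites tile the promoter
    without excessive overlap."""
    if mean_mutation_count <= 0:
        raise ValueError("mean mutation count must be positive")
    return max(1, int(math.floor(promoter_length / mean_mutation_count + 0.5)))


# ---------------------------------------------------------------------------
# JSON-lines serialization (the on-disk EVMP format emitted by `evmp process`)

def record_to_dict(record: EVMPRecord) -> dict:
    return {
        "variant_id": record.variant_id,
        "base_id": record.base.id,
        "base_sequence": record.base.sequence,
        "base_strength": record.base.strength,
        "k": record.k,
        "mutations": [
            {"position": m.site.position, "base_char": m.site.base_char,
             "variant_char": m.site.variant_char, "window": m.window}
            for m in record.mutations
        ],
        "strength": record.strength,
    }


def record_from_dict(d: dict) -> EVMPRecord:
    k = int(d["k"])
    muts = tuple(
        KmerMutation(
            MutationSite(int(m["position"]), m["base_char"], m["variant_char"]),
            k,
            m["window"],
        )
        for m in d["mutations"]
    )
    return EVMPRecord(
        base=Promoter(d["base_id"], d["base_sequence"], d.get("base_strength")),
        mutations=muts,
        variant_id=d["variant_id"],
        k=k,
        strength=d.get("strength"),
    )


def write_records(records: Iterable[EVMPRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(json.dumps(record_to_dict(rec)) + "\n")


def read_records(path: str | Path) -> list[EVMPRecord]:
    with open(path) as fh:
        return [record_from_dict(json.loads(line)) for line in fh if line.strip()]
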
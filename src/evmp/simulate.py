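"""Synthetic mutant-library generator with a known ground-truth strength map.

Emulates the statistical structure of a mutagenesis-derived promoter
library: a fixed base promoter of ~80 nt, variants carrying 1–8 substitution
mutations with the mode at 2–4 per variant, and log-scale strengths spanning
two orders of magnitude on the raw scale.  The ground truth is an additive
per-(position, base) effect model with optional pairwise epistasis and
Gaussian measurement noise — the standard surrogate for a mutational
landscape whose true map is unknown.  Everything downstream is testable
against this generator because the label-generating process is recoverable
by direct table lookup.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .seq import BLANK, Promoter, PromoterLibrary, hamming, pad

_BASES = ("A", "T", "C", "G")

#: Mutation-count distribution over 1..8 with the mode at 2–4 mutations and
#: a thin tail to 8 (>99% of variants carry <= 8 sites).
DEFAULT_MUTATION_COUNT_PROBS: tuple[float, ...] = (
    0.10, 0.24, 0.26, 0.20, 0.09, 0.06, 0.03, 0.02
)


@dataclass
class LibrarySpec:
    """Generation parameters for a synthetic promoter mutant library.

    Parameters
    ----------
    base_length : int
        Unpadded base-promoter length (nt).
    n_variants : int
        Library size N.
    mutation_count_probs : sequence of float
        Probability of a variant carrying ``i+1`` mutations; must sum to 1.
    seed : int
        Seed for all randomness (base sequence, effects, mutations, noise).
    noise_sigma : float
        Gaussian measurement-noise s.d. in log-strength units.
    span_target : float
        Orders of magnitude the noiseless strengths span on the raw scale
        (log-scale range of the labels).
    intercept : float
        Base-promoter log strength.
    n_epistasis : int
        Number of pairwise-interaction terms (0 disables epistasis).
    epistasis_scale : float
        S.d. of the interaction effects, log units.
    pad_length : int
        Library-wide padded length L.
    """

    base_length: int = 80
    n_variants: int = 2000
    mutation_count_probs: Sequence[float] = DEFAULT_MUTATION_COUNT_PROBS
    seed: int = 0
    noise_sigma: float = 0.1
    span_target: float = 2.0
    intercept: float = 3.0
    n_epistasis: int = 0
    epistasis_scale: float = 0.1
    pad_length: int = 85

    def __post_init__(self) -> None:
        probs = np.asarray(self.mutation_count_probs, dtype=float)
        if probs.ndim != 1 or len(probs) == 0 or (probs < 0).any():
            raise ValueError("mutation_count_probs must be a non-negative vector")
        if not np.isclose(probs.sum(), 1.0):
            raise ValueError("mutation_count_probs must sum to 1")
        if self.n_variants <= 0:
            raise ValueError("n_variants must be positive")
        if self.base_length <= 0:
            raise ValueError("base_length must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        if self.base_length > self.pad_length:
            raise ValueError("base_length exceeds pad_length")

    @property
    def max_mutations(self) -> int:
        return len(tuple(self.mutation_count_probs))

    @property
    def mean_mutation_count(self) -> float:
        probs = np.asarray(self.mutation_count_probs, dtype=float)
        return float(np.dot(probs, np.arange(1, len(probs) + 1)))


@dataclass
class GroundTruth:
    """The label-generating map: ``strength(S') = intercept + sum of the
    per-(position, new base) effects of its mutations + active pairwise
    interactions`` (noise is added once at generation time, not here).

    ``effects`` has shape ``(base_length, 4)`` with channel order
    (A, T, C, G); the entry at the base's own character is 0.
    """

    base_sequence: str
    intercept: float
    effects: np.ndarray
    epistasis: list[tuple[tuple[int, str], tuple[int, str], float]] = field(
        default_factory=list
    )
    noise_sigma: float = 0.0

    def noiseless_strength(self, sequence: str) -> float:
        seq = sequence.rstrip(BLANK)
        if len(seq) != len(self.base_sequence):
            raise ValueError("sequence length does not match the base promoter")
        total = self.intercept
        muts: dict[int, str] = {}
        for pos, (x, y) in enumerate(zip(self.base_sequence, seq)):
            if x != y:
                total += self.effects[pos, _BASES.index(y)]
                muts[pos] = y
        for (p1, b1), (p2, b2), eff in self.epistasis:
            if muts.get(p1) == b1 and muts.get(p2) == b2:
                total += eff
        return float(total)


def generate_library(spec: LibrarySpec) -> tuple[PromoterLibrary, GroundTruth]:
    """Generate a seeded library plus its ground truth.

    Variants are substitution-only mutants of a random base promoter: the
    mutation count is drawn from ``spec.mutation_count_probs``, positions
    uniformly without replacement, and the new base uniformly over the three
    alternatives.  Per-(position, base) effects are drawn once from a
    zero-mean Gaussian and rescaled so the noiseless strengths span exactly
    ``span_target`` log units; labels then get N(0, noise_sigma) noise.
    Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    l = spec.base_length
    base_seq = "".join(rng.choice(_BASES, size=l))

    effects = rng.normal(0.0, 1.0, size=(l, 4))
    for pos, char in enumerate(base_seq):
        effects[pos, _BASES.index(char)] = 0.0

    counts = rng.choice(
        np.arange(1, spec.max_mutations + 1),
        size=spec.n_variants,
        p=np.asarray(spec.mutation_count_probs, dtype=float),
    )
    variant_muts: list[list[tuple[int, str]]] = []
    for c in counts:
        positions = rng.choice(l, size=int(c), replace=False)
        muts = []
        for pos in sorted(positions):
            alternatives = [b for b in _BASES if b != base_seq[pos]]
            muts.append((int(pos), alternatives[int(rng.integers(3))]))
        variant_muts.append(muts)

    raw = np.array([
        sum(effects[pos, _BASES.index(b)] for pos, b in muts)
        for muts in variant_muts
    ])
    spread = raw.max() - raw.min()
    scale = spec.span_target / spread if spread > 0 else 1.0
    effects *= scale
    raw *= scale

    epistasis: list[tuple[tuple[int, str], tuple[int, str], float]] = []
    if spec.n_epistasis > 0:
        for _ in range(spec.n_epistasis):
            p1, p2 = rng.choice(l, size=2, replace=False)
            b1 = _BASES[int(rng.integers(4))]
            b2 = _BASES[int(rng.integers(4))]
            eff = float(rng.normal(0.0, spec.epistasis_scale))
            epistasis.append(((int(p1), b1), (int(p2), b2), eff))

    truth = GroundTruth(base_seq, spec.intercept, effects, epistasis,
                        spec.noise_sigma)

    noise = rng.normal(0.0, spec.noise_sigma, size=spec.n_variants)
    width = len(str(spec.n_variants))
    variants = []
    for i, muts in enumerate(variant_muts):
        chars = list(base_seq)
        for pos, b in muts:
            chars[pos] = b
        seq = "".join(chars)
        strength = truth.noiseless_strength(seq) + noise[i]
        variants.append(
            Promoter(f"var_{i:0{width}d}", pad(seq, spec.pad_length),
                     float(strength))
        )
    base = Promoter("base", pad(base_seq, spec.pad_length), spec.intercept)
    lib = PromoterLibrary(base=base, variants=variants,
                          pad_length=spec.pad_length)
    return lib, truth


def generate_base_panel(
    base: Promoter,
    count: int,
    min_diff: int = 2,
    max_diff: int = 7,
    seed: int = 0,
) -> list[Promoter]:
    """``count`` alternative base promoters, each differing from ``base`` at
    between ``min_diff`` and ``max_diff`` positions (the augmentation panel).
    Deterministic given ``seed``."""
    base_seq = base.sequence.rstrip(BLANK)
    l = len(base_seq)
    if not (1 <= min_diff <= max_diff < l):
        raise ValueError(
            f"require 1 <= min_diff <= max_diff < {l}, got [{min_diff}, {max_diff}]"
        )
    if count < 1:
        raise ValueError("count must be positive")
    rng = np.random.default_rng(seed)
    panel = []
    for i in range(count):
        n_diff = int(rng.integers(min_diff, max_diff + 1))
        positions = rng.choice(l, size=n_diff, replace=False)
        chars = list(base_seq)
        for pos in positions:
            alternatives = [b for b in _BASES if b != chars[pos]]
            chars[pos] = alternatives[int(rng.integers(3))]
        panel.append(Promoter(f"panel_{i + 1:02d}",
                              pad("".join(chars), len(base.sequence))))
    return panel


@dataclass(frozen=True)
class LibrarySummary:
    mutation_count_histogram: dict[int, float]
    mean_mutation_count: float
    strength_span: Optional[float]
    n_variants: int


def library_summary(lib: PromoterLibrary) -> LibrarySummary:
    """Mutation-count histogram (proportions, vs the base), mean mutation
    count alpha, and the strength span in orders of magnitude (max - min of
    the log-scale labels; None when any variant is unlabeled)."""
    counts = [hamming(lib.base.sequence, v.sequence) for v in lib.variants]
    n = len(counts)
    hist = {c: counts.count(c) / n for c in sorted(set(counts))}
    span = None
    if lib.labeled and n > 0:
        strengths = lib.strengths()
        span = float(strengths.max() - strengths.min())
    return LibrarySummary(
        mutation_count_histogram=hist,
        mean_mutation_count=float(np.mean(counts)) if counts else 0.0,
        strength_span=span,
        n_variants=n,
    )
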
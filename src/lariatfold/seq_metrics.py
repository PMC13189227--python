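"""Nucleotide-composition statistics for structure-potential screening.

The central statistic is *maximum base pairing* (MBP): the largest fraction
of a sequence's positions that could be paired given only its nucleotide
composition, counting Watson–Crick A–U and C–G pairs plus the G–U wobble
pair.  MBP is 1.0 when complementary bases occur at equal frequency and
drops as the composition becomes unbalanced, so it measures how much
secondary structure a sequence could form *at best*, independent of any
folding prediction.

The closed form used throughout is

    MBP = 1 - [max(A - U, 0) + max(C - G, 0) + |max(U - A, 0) - max(G - C, 0)|]

with A, C, G, U the base proportions (T is treated as U).  An independent
combinatorial oracle (:func:`mbp_matching_oracle`) maximizes the number of
disjoint {A-U, C-G, G-U} pairs over the base multiset and is used to verify
the closed form.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

__all__ = [
    "NucleotideComposition",
    "ShuffleSet",
    "gc_content",
    "mbp",
    "mbp_matching_oracle",
    "shuffle_sequence",
    "kmer_fully_paired_prob",
    "kmer_fully_paired_prob_mc",
]

_UNAMBIGUOUS = frozenset("ACGU")


def _normalize(seq: str) -> str:
    """Uppercase and map T to U (RNA alphabet used internally)."""
    return seq.upper().replace("T", "U")


@dataclass(frozen=True)
class NucleotideComposition:
    """Base proportions of a sequence over the unambiguous alphabet.

    Fractions are computed over A/C/G/U only; ambiguous bases (N and other
    IUPAC codes) are excluded from both numerator and denominator.  ``length``
    is the count of unambiguous bases.
    """

    fracA: float
    fracC: float
    fracG: float
    fracU: float
    length: int

    def __post_init__(self) -> None:
        if self.length < 0:
            raise ValueError("length must be >= 0")
        fracs = (self.fracA, self.fracC, self.fracG, self.fracU)
        if any(f < 0 for f in fracs):
            raise ValueError("fractions must be >= 0")
        if self.length > 0 and abs(sum(fracs) - 1.0) > 1e-9:
            raise ValueError("fractions must sum to 1")

    @classmethod
    def from_sequence(cls, seq: str) -> "NucleotideComposition":
        if not seq:
            raise ValueError("empty sequence")
        s = _normalize(seq)
        counts = {b: 0 for b in "ACGU"}
        for ch in s:
            if ch in counts:
                counts[ch] += 1
        n = sum(counts.values())
        if n == 0:
            raise ValueError("sequence has no unambiguous (ACGTU) bases")
        return cls(
            fracA=counts["A"] / n,
            fracC=counts["C"] / n,
            fracG=counts["G"] / n,
            fracU=counts["U"] / n,
            length=n,
        )

    @classmethod
    def from_counts(cls, nA: int, nC: int, nG: int, nU: int) -> "NucleotideComposition":
        n = nA + nC + nG + nU
        if n == 0:
            raise ValueError("all counts are zero")
        return cls(nA / n, nC / n, nG / n, nU / n, n)


@dataclass(frozen=True)
class ShuffleSet:
    """A sequence together with seeded uniform permutations of it."""

    original: str
    shuffles: tuple[str, ...]
    seed: int = 0

    def __post_init__(self) -> None:
        ref = sorted(self.original)
        for s in self.shuffles:
            if sorted(s) != ref:
                raise ValueError("shuffle is not a permutation of the original")


def gc_content(seq: str) -> float:
    """G+C fraction over the unambiguous bases of ``seq``.

    Ambiguous characters are excluded from the denominator; a sequence with
    no unambiguous bases raises ``ValueError``.
    """
    if not seq:
        raise ValueError("empty sequence")
    s = _normalize(seq)
    n = gc = 0
    for ch in s:
        if ch in _UNAMBIGUOUS:
            n += 1
            if ch in "GC":
                gc += 1
    if n == 0:
        raise ValueError("sequence has no unambiguous (ACGTU) bases")
    return gc / n


def mbp(comp: NucleotideComposition) -> float:
    """Maximum-base-pairing fraction from the closed-form composition formula."""
    if comp.length == 0:
        raise ValueError("composition of length 0")
    a, c, g, u = comp.fracA, comp.fracC, comp.fracG, comp.fracU
    return 1.0 - (
        max(a - u, 0.0)
        + max(c - g, 0.0)
        + abs(max(u - a, 0.0) - max(g - c, 0.0))
    )


def mbp_matching_oracle(comp: NucleotideComposition) -> float:
    """MBP by explicit pair matching over the base multiset.

    Maximizes the number of disjoint pairs drawn from {A-U, C-G, G-U} by
    exhausting every split of G between C-G and G-U pairing; independent of
    the closed form and used to verify it.
    """
    if comp.length == 0:
        raise ValueError("composition of length 0")
    n = comp.length
    nA = round(comp.fracA * n)
    nC = round(comp.fracC * n)
    nG = round(comp.fracG * n)
    nU = round(comp.fracU * n)
    best = 0
    # x = G-U wobble pairs; remaining U pairs A, remaining G pairs C.
    for x in range(min(nG, nU) + 1):
        pairs = x + min(nA, nU - x) + min(nC, nG - x)
        best = max(best, pairs)
    return 2.0 * best / n


def shuffle_sequence(seq: str, n: int = 10, seed: int = 0) -> ShuffleSet:
    """``n`` seeded uniform permutations of ``seq`` (composition-preserving).

    This is a mononucleotide shuffle: each output is an independent uniform
    permutation of the input characters, so GC content and MBP are exactly
    invariant across the set.
    """
    if not seq:
        raise ValueError("empty sequence")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = random.Random(seed)
    out = []
    chars = list(seq)
    for _ in range(n):
        perm = chars[:]
        rng.shuffle(perm)
        out.append("".join(perm))
    return ShuffleSet(original=seq, shuffles=tuple(out), seed=seed)


def kmer_fully_paired_prob(comp: NucleotideComposition, k: int) -> float:
    """Probability that a random k-mer from this composition is fully paired.

    Under the independence interpretation each of the k positions pairs with
    probability MBP, giving MBP**k.  Sensor-relevant lengths are k = 17
    (OAS1), 22 (RIG-I) and 33 (PKR).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    return mbp(comp) ** k


def kmer_fully_paired_prob_mc(
    comp: NucleotideComposition, k: int, n_trials: int = 10000, seed: int = 0
) -> float:
    """Monte-Carlo alternative to :func:`kmer_fully_paired_prob`.

    Draws k bases i.i.d. from the composition and tests whether the drawn
    k-mer's own MBP equals 1 (all bases pairable); provided for sensitivity
    analysis of the closed-form independence assumption.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    rng = random.Random(seed)
    bases = "ACGU"
    weights = [comp.fracA, comp.fracC, comp.fracG, comp.fracU]
    hits = 0
    for _ in range(n_trials):
        draw = rng.choices(bases, weights=weights, k=k)
        sub = NucleotideComposition.from_sequence("".join(draw))
        if mbp_matching_oracle(sub) >= 1.0 - 1e-12:
            hits += 1
    return hits / n_trials
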
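"""Secondary-structure statistics: duplex stretches, sensor sites, MFE ensembles.

A predicted structure (dot-bracket) is decomposed into its maximal runs of
consecutively stacked base pairs ("dsRNA stretches"); any bulge, internal
loop, or junction ends a stretch.  The number of binding sites for a
cytosolic dsRNA sensor is then

    sites(sensor) = sum_i floor(length of stretch i / minimum duplex length)

with default minimum activating duplex lengths OAS1 = 17 bp, RIG-I = 22 bp,
PKR = 33 bp.

Folding is an injected contract: any callable mapping a sequence to a
:class:`FoldResult` works.  :class:`ViennaFolder` wires the ViennaRNA
(RNAfold) predictor when its Python bindings are importable;
:class:`MaxPairFolder` is a built-in deterministic Nussinov-style
pairing-maximization folder (minimum hairpin loop 3 nt, energy −1 per pair)
that keeps every statistic exercisable without an external predictor.  The
two produce different energies by design; absolute MFE values are therefore
predictor-dependent and only structure-derived statistics are portable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

from .seq_metrics import _normalize, shuffle_sequence

__all__ = [
    "SecondaryStructure",
    "DsRNAStretch",
    "SensorPanel",
    "FoldResult",
    "EnsembleDeviation",
    "DEFAULT_SENSOR_PANEL",
    "parse_dotbracket",
    "extract_stretches",
    "sensor_sites",
    "normalized_mfe",
    "ensemble_deviation",
    "count_sensor_sites_for_regions",
    "MaxPairFolder",
    "ViennaFolder",
]

#: Minimum activating duplex length per sensor, in base pairs.
DEFAULT_SENSOR_PANEL: dict[str, int] = {"OAS1": 17, "RIG-I": 22, "PKR": 33}

SensorPanel = Mapping[str, int]

_CAN_PAIR = frozenset({("A", "U"), ("U", "A"), ("C", "G"), ("G", "C"), ("G", "U"), ("U", "G")})


def can_pair(a: str, b: str) -> bool:
    """Watson–Crick or G–U wobble pairing between two (RNA) bases."""
    return (a, b) in _CAN_PAIR


@dataclass(frozen=True)
class SecondaryStructure:
    sequence: str
    dotbracket: str
    pairs: frozenset[tuple[int, int]]

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.dotbracket):
            raise ValueError("sequence and dot-bracket lengths differ")


@dataclass(frozen=True)
class DsRNAStretch:
    """A maximal run of stacked pairs (i,j),(i+1,j-1),...,(i+L-1,j-L+1)."""

    length_bp: int
    five_prime_start: int
    three_prime_end: int

    def __post_init__(self) -> None:
        if self.length_bp < 1:
            raise ValueError("length_bp must be >= 1")


@dataclass(frozen=True)
class FoldResult:
    structure: SecondaryStructure
    mfe: float  # kcal/mol (predictor-dependent scale)
    normalized_mfe: float  # kcal/mol per nt


@dataclass(frozen=True)
class EnsembleDeviation:
    """Observed MFE versus the mean over a shuffled ensemble.

    ``deviation = observed - mean(shuffled)``: negative means the observed
    sequence folds more stably than expected from its composition alone.
    """

    observed_mfe: float
    shuffled_mfes: tuple[float, ...]
    mean_shuffled_mfe: float
    deviation: float


Folder = Callable[[str], FoldResult]


def parse_dotbracket(db: str, seq: str) -> SecondaryStructure:
    """Recover the pair set of a dot-bracket string by stack matching."""
    if len(db) != len(seq):
        raise ValueError("dot-bracket and sequence lengths differ")
    stack: list[int] = []
    pairs = set()
    for i, ch in enumerate(db):
        if ch == "(":
            stack.append(i)
        elif ch == ")":
            if not stack:
                raise ValueError(f"unbalanced ')' at position {i}")
            pairs.add((stack.pop(), i))
        elif ch != ".":
            raise ValueError(f"invalid dot-bracket character {ch!r} at position {i}")
    if stack:
        raise ValueError(f"unmatched '(' at position {stack[-1]}")
    return SecondaryStructure(sequence=seq, dotbracket=db, pairs=frozenset(pairs))


def to_dotbracket(pairs: Iterable[tuple[int, int]], length: int) -> str:
    chars = ["."] * length
    for i, j in pairs:
        chars[i] = "("
        chars[j] = ")"
    return "".join(chars)


def extract_stretches(structure: SecondaryStructure) -> list[DsRNAStretch]:
    """Split a structure into its maximal contiguous duplex segments.

    A stretch is a run of consecutively stacked pairs; ANY departure from
    perfect stacking — a bulge on either strand, a mismatch, or a junction —
    terminates it.  The sum of 2*length_bp over stretches equals the number
    of paired positions.
    """
    pairs = set(structure.pairs)
    out: list[DsRNAStretch] = []
    for i, j in sorted(pairs):
        if (i - 1, j + 1) in pairs:
            continue  # not the outermost pair of a run
        length = 1
        while (i + length, j - length) in pairs:
            length += 1
        out.append(DsRNAStretch(length_bp=length, five_prime_start=i, three_prime_end=j))
    out.sort(key=lambda s: s.five_prime_start)
    return out


def sensor_sites(
    stretches: Sequence[DsRNAStretch], panel: SensorPanel = DEFAULT_SENSOR_PANEL
) -> dict[str, int]:
    """Per-sensor site counts: sum over stretches of floor(length / threshold)."""
    for name, thr in panel.items():
        if thr < 1:
            raise ValueError(f"sensor threshold for {name} must be >= 1")
    return {
        name: sum(s.length_bp // thr for s in stretches) for name, thr in panel.items()
    }


def normalized_mfe(mfe: float, length: int) -> float:
    """Free energy per nucleotide, for comparisons across region lengths."""
    if length < 1:
        raise ValueError("length must be >= 1")
    return mfe / length


def ensemble_deviation(
    seq: str, folder: Folder, n: int = 10, seed: int = 0, normalized: bool = False
) -> EnsembleDeviation:
    """Observed fold energy minus the mean over ``n`` composition shuffles.

    The shuffled ensemble is the null expectation from nucleotide composition
    alone; a negative deviation marks a sequence folding more stably than its
    shuffles (e.g. one carrying an inverted repeat).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    observed = folder(seq)
    obs = observed.normalized_mfe if normalized else observed.mfe
    shuffled = []
    for s in shuffle_sequence(seq, n=n, seed=seed).shuffles:
        r = folder(s)
        shuffled.append(r.normalized_mfe if normalized else r.mfe)
    mean = sum(shuffled) / len(shuffled)
    return EnsembleDeviation(
        observed_mfe=obs,
        shuffled_mfes=tuple(shuffled),
        mean_shuffled_mfe=mean,
        deviation=obs - mean,
    )


def count_sensor_sites_for_regions(
    sequences: Mapping[str, str],
    folder: Folder,
    panel: SensorPanel = DEFAULT_SENSOR_PANEL,
    max_length: int = 5000,
) -> tuple[list[dict], list[dict]]:
    """Fold each region once and tabulate per-sensor site counts.

    Regions longer than ``max_length`` nt (default 5,000, matching the cap
    used for genome-wide folding) are skipped and reported in the returned
    skip list.  Returns ``(rows, skipped)``; each row carries region id,
    length, mfe, normalized_mfe, stretch count and one column per sensor.
    """
    rows: list[dict] = []
    skipped: list[dict] = []
    for region_id, seq in sequences.items():
        if len(seq) > max_length:
            skipped.append(
                {"region_id": region_id, "length": len(seq), "reason": f"length > {max_length}"}
            )
            continue
        result = folder(seq)
        stretches = extract_stretches(result.structure)
        row = {
            "region_id": region_id,
            "length": len(seq),
            "mfe": result.mfe,
            "normalized_mfe": result.normalized_mfe,
            "n_stretches": len(stretches),
        }
        row.update(sensor_sites(stretches, panel))
        rows.append(row)
    return rows, skipped


class MaxPairFolder:
    """Deterministic pairing-maximization folder (Nussinov-style dynamic program).

    Maximizes the number of nested {A-U, C-G, G-U} pairs with a minimum
    hairpin loop of ``min_loop`` unpaired nt (default 3) and assigns a
    surrogate energy of ``pair_energy`` kcal/mol per pair (default −1).
    Traceback ties are broken deterministically (unpaired-i preferred, then
    smallest split), so identical inputs give identical structures.
    """

    def __init__(self, min_loop: int = 3, pair_energy: float = -1.0):
        self.min_loop = min_loop
        self.pair_energy = pair_energy

    def __call__(self, seq: str) -> FoldResult:
        import numpy as np

        s = _normalize(seq)
        n = len(s)
        if n == 0:
            raise ValueError("empty sequence")
        ml = self.min_loop
        # N[i, j]: max pairs in s[i..j]; bifurcation max vectorized over the
        # split point (splits with an unpairably short left part are covered
        # by the unpaired-i case, so k starts at i+ml+1).
        N = np.zeros((n, n), dtype=np.int32)
        for span in range(ml + 1, n):
            for i in range(n - span):
                j = i + span
                best = max(N[i + 1, j], N[i, j - 1])
                if can_pair(s[i], s[j]):
                    v = N[i + 1, j - 1] + 1
                    if v > best:
                        best = v
                k0 = i + ml + 1
                if k0 < j:
                    v = int((N[i, k0:j] + N[k0 + 1 : j + 1, j]).max())
                    if v > best:
                        best = v
                N[i, j] = best
        pairs: set[tuple[int, int]] = set()
        stack = [(0, n - 1)]
        while stack:
            i, j = stack.pop()
            if i >= j or j - i <= ml:
                continue
            target = N[i, j]
            if target == N[i + 1, j]:
                stack.append((i + 1, j))
            elif target == N[i, j - 1]:
                stack.append((i, j - 1))
            elif can_pair(s[i], s[j]) and target == N[i + 1, j - 1] + 1:
                pairs.add((i, j))
                stack.append((i + 1, j - 1))
            else:
                for k in range(i + ml + 1, j):
                    if target == N[i, k] + N[k + 1, j]:
                        stack.append((i, k))
                        stack.append((k + 1, j))
                        break
        db = to_dotbracket(pairs, n)
        structure = SecondaryStructure(sequence=s, dotbracket=db, pairs=frozenset(pairs))
        mfe = self.pair_energy * len(pairs)
        return FoldResult(structure=structure, mfe=mfe, normalized_mfe=mfe / n)


class ViennaFolder:
    """RNAfold-backed folder using the ViennaRNA Python bindings.

    Production adapter for thermodynamic MFE prediction; raises ImportError
    at construction if the bindings are unavailable.
    """

    def __init__(self) -> None:
        import RNA  # noqa: F401 — hard failure here, not at call time

        self._RNA = RNA

    def __call__(self, seq: str) -> FoldResult:
        s = _normalize(seq)
        db, mfe = self._RNA.fold(s)
        structure = parse_dotbracket(db, s)
        return FoldResult(structure=structure, mfe=float(mfe), normalized_mfe=float(mfe) / len(s))
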
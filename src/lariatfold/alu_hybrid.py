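"""Weighted sense/antisense Alu-pair hybridization sampling.

Cellular sense and antisense Alu transcripts can anneal in trans; the
distribution of duplexes such a mix can form is estimated by repeated
weighted sampling: draw one plus-strand and one minus-strand Alu (with
probabilities given by their relative representation), predict the
intermolecular hybrid, split it into dsRNA stretches, and count sensor
sites.  The default is 10,000 trials.

The hybridizer is an injected contract mapping a sequence pair to duplex
stretches.  :class:`MaxComplementHybridizer` is the built-in deterministic
choice: it slides one strand against the reverse complement of the other
(no gaps), keeps the offset with the most complementary positions, and
reads stretches off the runs of consecutive complementary pairs.
:class:`DuplexFolder` wires ViennaRNA's RNAduplex when available.
"""

from __future__ import annotations

import logging
import random
from collections import Counter
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np

from .seq_metrics import _normalize
from .structure_stats import (
    DEFAULT_SENSOR_PANEL,
    DsRNAStretch,
    SensorPanel,
    can_pair,
    sensor_sites,
)

logger = logging.getLogger(__name__)

__all__ = [
    "WeightedAluPool",
    "HybridTrial",
    "TrialSummary",
    "weights_from_counts",
    "run_trials",
    "MaxComplementHybridizer",
    "DuplexFolder",
]

Hybridizer = Callable[[str, str], list[DsRNAStretch]]


@dataclass(frozen=True)
class WeightedAluPool:
    """Alu sequences with sampling weights (relative representation)."""

    ids: tuple[str, ...]
    sequences: dict[str, str]
    weights: dict[str, float]

    def __post_init__(self) -> None:
        if not self.ids:
            raise ValueError("empty pool")
        w = [self.weights[i] for i in self.ids]
        if any(x < 0 for x in w):
            raise ValueError("weights must be >= 0")
        if abs(sum(w) - 1.0) > 1e-9:
            raise ValueError("weights must sum to 1")


@dataclass(frozen=True)
class HybridTrial:
    trial_index: int
    plus_id: str
    minus_id: str
    stretches: tuple[DsRNAStretch, ...]
    site_counts: dict[str, int]
    failed: bool = False


@dataclass
class TrialSummary:
    """Empirical per-sensor site-count distribution over successful trials."""

    n_trials: int
    n_failed: int
    counts_per_sensor: dict[str, list[int]]
    mean: dict[str, float]
    median: dict[str, float]
    quantiles: dict[str, dict[float, float]]
    draw_frequencies_plus: dict[str, float]
    draw_frequencies_minus: dict[str, float]


def weights_from_counts(counts: Mapping[str, float]) -> dict[str, float]:
    """Normalize per-member read counts into sampling weights."""
    if any(c < 0 for c in counts.values()):
        raise ValueError("counts must be >= 0")
    total = sum(counts.values())
    if total <= 0:
        raise ValueError("all counts are zero")
    return {k: c / total for k, c in counts.items()}


def pool_from_counts(sequences: Mapping[str, str], counts: Mapping[str, float]) -> WeightedAluPool:
    weights = weights_from_counts(counts)
    ids = tuple(sorted(sequences))
    return WeightedAluPool(ids=ids, sequences=dict(sequences), weights={i: weights[i] for i in ids})


class MaxComplementHybridizer:
    """Gap-free complementarity-maximization intermolecular hybridizer.

    Aligns ``plus`` against reverse-complemented ``minus`` at every offset,
    scores each offset by its number of complementary (A-U, C-G, G-U)
    positions via FFT-free one-hot correlation, and extracts maximal runs of
    consecutive complementary pairs at the best offset (smallest offset on
    ties).  Intermolecular pairing only; no intramolecular folding.
    """

    _BASES = "ACGU"

    def __call__(self, plus: str, minus: str) -> list[DsRNAStretch]:
        p = _normalize(plus)
        m = _normalize(minus)[::-1]  # antiparallel: reverse so index aligns with p
        if not p or not m:
            raise ValueError("empty sequence")
        onehot_p = {b: np.array([c == b for c in p], dtype=np.float64) for b in self._BASES}
        onehot_m = {b: np.array([c == b for c in m], dtype=np.float64) for b in self._BASES}
        # complementarity matrix over offsets via convolution per base pair
        score = np.zeros(len(p) + len(m) - 1)
        pair_map = [("A", "U"), ("U", "A"), ("C", "G"), ("G", "C"), ("G", "U"), ("U", "G")]
        for bp, bm in pair_map:
            score += np.convolve(onehot_p[bp], onehot_m[bm][::-1])
        # offset o aligns p[i] with m[i - o + len(m) - 1]... use argmax lag
        best_lag = int(np.argmax(score))  # smallest lag wins ties (argmax convention)
        shift = best_lag - (len(m) - 1)  # p[i] pairs m[i - shift]
        stretches: list[DsRNAStretch] = []
        run = 0
        run_start = 0
        for i in range(len(p)):
            j = i - shift
            ok = 0 <= j < len(m) and can_pair(p[i], m[j])
            if ok:
                if run == 0:
                    run_start = i
                run += 1
            elif run:
                stretches.append(
                    DsRNAStretch(length_bp=run, five_prime_start=run_start, three_prime_end=run_start + run - 1)
                )
                run = 0
        if run:
            stretches.append(
                DsRNAStretch(length_bp=run, five_prime_start=run_start, three_prime_end=run_start + run - 1)
            )
        return stretches


class DuplexFolder:
    """RNAduplex-backed hybridizer (ViennaRNA Python bindings).

    Parses the duplex structure into stretches on the paired positions of
    the two strands; raises ImportError at construction if unavailable.
    """

    def __init__(self) -> None:
        import RNA

        self._RNA = RNA

    def __call__(self, plus: str, minus: str) -> list[DsRNAStretch]:
        duplex = self._RNA.duplexfold(_normalize(plus), _normalize(minus))
        left, right = duplex.structure.split("&")
        # paired positions: k-th '(' in left pairs with k-th-from-last ')' in right
        opens = [i for i, c in enumerate(left) if c == "("]
        closes = [i for i, c in enumerate(right) if c == ")"]
        pairs = list(zip(opens, reversed(closes)))
        stretches: list[DsRNAStretch] = []
        run_start = None
        run = 0
        for idx, (i, j) in enumerate(pairs):
            if run and pairs[idx - 1] == (i - 1, j + 1):
                run += 1
            else:
                if run:
                    stretches.append(
                        DsRNAStretch(length_bp=run, five_prime_start=run_start, three_prime_end=run_start + run - 1)
                    )
                run_start = i
                run = 1
        if run:
            stretches.append(
                DsRNAStretch(length_bp=run, five_prime_start=run_start, three_prime_end=run_start + run - 1)
            )
        return stretches


def run_trials(
    pool_plus: WeightedAluPool,
    pool_minus: WeightedAluPool,
    hybridizer: Hybridizer,
    panel: SensorPanel = DEFAULT_SENSOR_PANEL,
    n: int = 10000,
    seed: int = 0,
) -> tuple[list[HybridTrial], TrialSummary]:
    """``n`` weighted with-replacement draws of (plus, minus) Alu pairs.

    Each sampled pair is hybridized (results cached per pair — the
    hybridizer contract is deterministic), its stretches scored against the
    sensor panel, and the empirical per-sensor distribution summarized.
    Hybridizer failures are recorded as failed trials and excluded from the
    summary.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = random.Random(seed)
    plus_ids = list(pool_plus.ids)
    minus_ids = list(pool_minus.ids)
    plus_w = [pool_plus.weights[i] for i in plus_ids]
    minus_w = [pool_minus.weights[i] for i in minus_ids]
    cache: dict[tuple[str, str], tuple[DsRNAStretch, ...] | None] = {}
    trials: list[HybridTrial] = []
    for t in range(n):
        pid = rng.choices(plus_ids, weights=plus_w, k=1)[0]
        mid = rng.choices(minus_ids, weights=minus_w, k=1)[0]
        key = (pid, mid)
        if key not in cache:
            try:
                cache[key] = tuple(hybridizer(pool_plus.sequences[pid], pool_minus.sequences[mid]))
            except Exception:
                logger.exception("hybridizer failed for pair %s / %s", pid, mid)
                cache[key] = None
        stretches = cache[key]
        if stretches is None:
            trials.append(HybridTrial(t, pid, mid, (), {}, failed=True))
        else:
            trials.append(HybridTrial(t, pid, mid, stretches, sensor_sites(stretches, panel)))
    ok = [tr for tr in trials if not tr.failed]
    counts_per_sensor = {name: [tr.site_counts[name] for tr in ok] for name in panel}
    qs = (0.05, 0.25, 0.5, 0.75, 0.95)
    summary = TrialSummary(
        n_trials=n,
        n_failed=n - len(ok),
        counts_per_sensor=counts_per_sensor,
        mean={s: float(np.mean(v)) if v else float("nan") for s, v in counts_per_sensor.items()},
        median={s: float(np.median(v)) if v else float("nan") for s, v in counts_per_sensor.items()},
        quantiles={
            s: {q: float(np.quantile(v, q)) if v else float("nan") for q in qs}
            for s, v in counts_per_sensor.items()
        },
        draw_frequencies_plus={
            i: c / n for i, c in Counter(tr.plus_id for tr in trials).items()
        },
        draw_frequencies_minus={
            i: c / n for i, c in Counter(tr.minus_id for tr in trials).items()
        },
    )
    return trials, summary
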
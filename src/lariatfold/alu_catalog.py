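"""Alu-content classification of gene regions.

Alu retroelement insertions are intersected with annotated regions (introns,
UTRs, exons) and each region is classified by its Alu content:

* ``NONE`` — no Alu assigned;
* ``SINGLE`` — exactly one Alu;
* ``MULTI_SAME`` — two or more, all inserted in the same orientation;
* ``IR`` — two or more with at least one pair in opposite orientations
  (inverted-repeat Alus, capable of intramolecular duplex formation).

Orientation is the element's annotated strand in genome coordinates; whether
a pair is inverted does not depend on the host gene's strand, so gene strand
is never used to flip it.
"""

from __future__ import annotations

import enum
import logging
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

__all__ = [
    "GenomicInterval",
    "AluInsertion",
    "AluCategory",
    "assign_alus_to_regions",
    "categorize",
    "category_proportions",
]


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open genomic interval with strand."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end})")
        if self.strand not in "+-":
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlap(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass(frozen=True)
class AluInsertion:
    interval: GenomicInterval
    element_strand: str

    def __post_init__(self) -> None:
        if self.element_strand not in "+-":
            raise ValueError(f"invalid element strand {self.element_strand!r}")


class AluCategory(enum.Enum):
    NONE = "NONE"
    SINGLE = "SINGLE"
    MULTI_SAME = "MULTI_SAME"
    IR = "IR"


def assign_alus_to_regions(
    regions: Mapping[str, GenomicInterval],
    alus: Sequence[AluInsertion],
    min_overlap_fraction: float = 0.5,
) -> dict[str, list[AluInsertion]]:
    """Assign each Alu to every region covering >= ``min_overlap_fraction`` of it.

    The fraction is of the Alu element's own length (default 0.5).  An Alu
    may be assigned to several overlapping regions; nested and overlapping
    Alus count as separate insertions.  Alus on chromosomes absent from the
    region set are logged and skipped.
    """
    if not (0 < min_overlap_fraction <= 1):
        raise ValueError("min_overlap_fraction must be in (0, 1]")
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for region_id, iv in regions.items():
        trees[iv.chrom].addi(iv.start, iv.end, region_id)
    assigned: dict[str, list[AluInsertion]] = {rid: [] for rid in regions}
    region_chroms = set(trees)
    for alu in alus:
        iv = alu.interval
        if iv.chrom not in region_chroms:
            logger.warning("Alu on unknown chromosome %s skipped", iv.chrom)
            continue
        for hit in trees[iv.chrom].overlap(iv.start, iv.end):
            region = regions[hit.data]
            if iv.overlap(region) >= min_overlap_fraction * len(iv):
                assigned[hit.data].append(alu)
    for rid in assigned:
        assigned[rid].sort(key=lambda a: (a.interval.start, a.interval.end, a.element_strand))
    return assigned


def categorize(insertions: Iterable[AluInsertion]) -> AluCategory:
    """Alu-content class of a region from its assigned insertions."""
    strands = [a.element_strand for a in insertions]
    if not strands:
        return AluCategory.NONE
    if len(strands) == 1:
        return AluCategory.SINGLE
    if len(set(strands)) == 1:
        return AluCategory.MULTI_SAME
    return AluCategory.IR


def category_proportions(
    categories_by_type: Mapping[str, Sequence[AluCategory]],
) -> dict[str, dict[AluCategory, float]]:
    """Per region type, the fraction of regions in each Alu category.

    Region types with no regions are omitted with a warning.  Fractions per
    type sum to 1.
    """
    out: dict[str, dict[AluCategory, float]] = {}
    for region_type, cats in categories_by_type.items():
        if not cats:
            logger.warning("region type %s has no regions; omitted", region_type)
            continue
        n = len(cats)
        out[region_type] = {c: sum(1 for x in cats if x == c) / n for c in AluCategory}
    return out
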
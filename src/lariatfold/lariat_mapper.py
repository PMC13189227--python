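"""Lariat-read identification and branchpoint calling.

During splicing the intron is excised as a lariat: a loop closed by a
2'-5' bond between the 5' splice site (5'SS) and the branchpoint.  A
sequencing read crossing that junction contains, in read order, intronic
sequence ending at the branchpoint followed by the first bases of the
intron — the two segments map to the genome in *inverted* order relative
to their order in the read.  The mapping procedure:

1. drop reads with >5% ambiguous characters;
2. drop reads that align end-to-end to the genome (a lariat junction read
   cannot, by construction);
3. find reads containing exactly one intron's first-20-nt 5'SS key, with
   no mismatches or indels (exact substring match);
4. trim the read to the prefix upstream of the 5'SS key; drop prefixes
   shorter than 20 nt;
5. re-map the prefix to the genome, keeping alignments with <=5
   mismatches, <=10% mismatch rate and at most one indel of <=3 nt;
6. restrict to alignments in the same gene as the 5'SS, placed downstream
   of the intron start (the inverted order expected of a lariat), and take
   the highest-scoring one; its final aligned base is the branchpoint.

The built-in aligner finds candidate loci with edlib (banded edit-distance
search in infix mode) and re-scores each candidate with an exhaustive
enumeration of single-indel placements under the mismatch constraints,
scored +1 match / -1 mismatch / -2 gap open / -1 per gap base.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import edlib
import numpy as np
from Bio.Seq import Seq

from .alu_catalog import GenomicInterval
from .structure_stats import (
    DEFAULT_SENSOR_PANEL,
    Folder,
    SensorPanel,
    extract_stretches,
    sensor_sites,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ReadRecord",
    "Intron",
    "FivePrimeIndex",
    "GenomeAligner",
    "Alignment",
    "LariatReadAlignment",
    "BranchpointCall",
    "LariatQuant",
    "MapperConfig",
    "filter_ambiguous",
    "genome_prefilter",
    "build_fiveprime_index",
    "locate_fiveprime",
    "trim_for_branchpoint",
    "align_branch_segment",
    "select_and_call",
    "map_lariats",
    "quantify",
    "fold_changes",
    "lariat_dsrna_sites",
]


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


@dataclass(frozen=True)
class ReadRecord:
    id: str
    sequence: str
    quality: str | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("empty read sequence")


@dataclass(frozen=True)
class Intron:
    intron_id: str
    gene_id: str
    interval: GenomicInterval  # strand = gene/transcription strand


@dataclass(frozen=True)
class IndexEntry:
    intron_id: str
    gene_id: str
    key: str  # first k intronic nt, transcription orientation
    intron: Intron


@dataclass
class FivePrimeIndex:
    """5'SS keys (first k nt of each intron, transcription orientation)."""

    k: int
    entries: dict[str, IndexEntry]  # intron id -> entry
    by_key: dict[str, list[IndexEntry]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.by_key:
            by_key: dict[str, list[IndexEntry]] = defaultdict(list)
            for e in self.entries.values():
                by_key[e.key].append(e)
            self.by_key = dict(by_key)


@dataclass(frozen=True)
class Alignment:
    """A genomic placement of a query under the constraint triple."""

    chrom: str
    start: int  # 0-based half-open, genome forward coordinates
    end: int
    strand: str  # strand the query matched in this placement
    mismatches: int
    indel_len: int  # 0 if gapless; >0 deletion-from-query, <0 insertion-in-query
    score: int


@dataclass(frozen=True)
class LariatReadAlignment:
    read_id: str
    intron_id: str
    fiveprime_offset: int  # position of the 5'SS key within the read
    alignment: Alignment


@dataclass(frozen=True)
class BranchpointCall:
    intron_id: str
    coordinate: int  # 0-based genomic position of the last aligned base
    supporting_reads: tuple[str, ...]


@dataclass
class LariatQuant:
    counts: dict[str, int]
    total_mapped: int
    normalized: dict[str, float]  # reads per million mapped


@dataclass(frozen=True)
class MapperConfig:
    """Defaults follow the published filter chain exactly."""

    max_ambiguous_fraction: float = 0.05
    key_length: int = 20
    min_prefix_length: int = 20
    max_mismatches: int = 5
    max_mismatch_rate: float = 0.10
    max_indel_length: int = 3
    match_score: int = 1
    mismatch_score: int = -1
    gap_open: int = -2
    gap_extend: int = -1
    search_revcomp_keys: bool = False  # stranded protocol: keys searched forward only
    # the length rule is applied to the retained prefix (the re-mapped part);
    # set False to apply it to the removed suffix instead
    prefix_rule_on_retained: bool = True


# ---------------------------------------------------------------------------
# built-in aligner


class GenomeAligner:
    """Desk-scale genomic aligner under the lariat constraint triple.

    Candidate loci come from edlib's infix edit-distance search with band
    ``max_mismatches + max_indel_length``; each candidate window is then
    re-scored by enumerating every placement of at most one indel of length
    <= ``max_indel_length`` and counting mismatches with vectorized
    comparisons.  Suitable for genomes up to the tens of megabases.
    """

    def __init__(self, genome: Mapping[str, str], config: MapperConfig = MapperConfig()):
        self.config = config
        self.genome = {c: s.upper() for c, s in genome.items()}
        self._arrays = {
            c: np.frombuffer(s.encode("ascii"), dtype=np.uint8)
            for c, s in self.genome.items()
        }

    # -- constrained verification ------------------------------------------

    def _verify_window(
        self, q: np.ndarray, t: np.ndarray, window_start: int, chrom: str, strand: str
    ) -> list[Alignment]:
        """All constraint-satisfying alignments of q anchored inside a window.

        ``t`` is the window slice of the chromosome array and ``window_start``
        its genomic offset.  Returns the best-scoring alignment per start
        position (gapless preferred on score ties).
        """
        cfg = self.config
        L = len(q)
        W = len(t)
        results: dict[int, Alignment] = {}

        def consider(aln: Alignment) -> None:
            prev = results.get(aln.start)
            if (
                prev is None
                or aln.score > prev.score
                or (aln.score == prev.score and abs(aln.indel_len) < abs(prev.indel_len))
            ):
                results[aln.start] = aln

        def admissible(mism: int, aligned_len: int) -> bool:
            return mism <= cfg.max_mismatches and mism <= cfg.max_mismatch_rate * aligned_len

        # gapless placements
        for a in range(0, W - L + 1):
            mism = int((q != t[a : a + L]).sum())
            if admissible(mism, L):
                score = (L - mism) * cfg.match_score + mism * cfg.mismatch_score
                consider(
                    Alignment(chrom, window_start + a, window_start + a + L, strand, mism, 0, score)
                )
        # exact gapless hit is unbeatable (any indel costs at least gap_open+1)
        if any(r.mismatches == 0 and r.indel_len == 0 for r in results.values()):
            return list(results.values())
        for d in range(1, cfg.max_indel_length + 1):
            # deletion from query: alignment spans L + d genomic bases;
            # the gap must be internal (an edge gap is a clip, not an indel)
            span = L + d
            for a in range(0, W - span + 1):
                for s in range(1, L):
                    mism = int((q[:s] != t[a : a + s]).sum()) + int(
                        (q[s:] != t[a + s + d : a + span]).sum()
                    )
                    if admissible(mism, L):
                        score = (
                            (L - mism) * cfg.match_score
                            + mism * cfg.mismatch_score
                            + cfg.gap_open
                            + d * cfg.gap_extend
                        )
                        consider(
                            Alignment(
                                chrom, window_start + a, window_start + a + span, strand, mism, d, score
                            )
                        )
            # insertion in query: d read bases unaligned, spans L - d genomic bases
            span = L - d
            if span < 2:
                continue
            for a in range(0, W - span + 1):
                for s in range(1, span):
                    mism = int((q[:s] != t[a : a + s]).sum()) + int(
                        (q[s + d :] != t[a + s : a + span]).sum()
                    )
                    if admissible(mism, span):
                        score = (
                            (span - mism) * cfg.match_score
                            + mism * cfg.mismatch_score
                            + cfg.gap_open
                            + d * cfg.gap_extend
                        )
                        consider(
                            Alignment(
                                chrom, window_start + a, window_start + a + span, strand, mism, -d, score
                            )
                        )
        return list(results.values())

    def find_alignments(self, query: str, both_strands: bool = True) -> list[Alignment]:
        """All admissible genomic placements of ``query`` (best per locus)."""
        cfg = self.config
        band = cfg.max_mismatches + cfg.max_indel_length
        out: list[Alignment] = []
        strands = ("+", "-") if both_strands else ("+",)
        for strand in strands:
            q = query.upper() if strand == "+" else revcomp(query.upper())
            q_arr = np.frombuffer(q.encode("ascii"), dtype=np.uint8)
            for chrom, target in self.genome.items():
                res = edlib.align(q, target, mode="HW", task="locations", k=band)
                if res["editDistance"] < 0:
                    continue
                t_arr = self._arrays[chrom]
                seen_windows: set[tuple[int, int]] = set()
                for st, en in res["locations"]:
                    ws = max(0, st - cfg.max_indel_length)
                    we = min(len(target), en + 1 + cfg.max_indel_length)
                    if (ws, we) in seen_windows:
                        continue
                    seen_windows.add((ws, we))
                    out.extend(self._verify_window(q_arr, t_arr[ws:we], ws, chrom, strand))
        # dedupe identical placements, keep deterministic order
        best: dict[tuple[str, str, int, int], Alignment] = {}
        for aln in out:
            key = (aln.chrom, aln.strand, aln.start, aln.end)
            prev = best.get(key)
            if prev is None or aln.score > prev.score:
                best[key] = aln
        return sorted(best.values(), key=lambda a: (a.chrom, a.start, a.end, a.strand))


# ---------------------------------------------------------------------------
# pipeline stages


def filter_ambiguous(
    reads: Iterable[ReadRecord], max_ambiguous_fraction: float = 0.05
) -> list[ReadRecord]:
    """Retain reads whose non-ACGT(U) fraction is <= the threshold (default 5%)."""
    kept = []
    for r in reads:
        s = r.sequence.upper()
        n_amb = sum(1 for ch in s if ch not in "ACGTU")
        if n_amb / len(s) <= max_ambiguous_fraction:
            kept.append(r)
    return kept


def genome_prefilter(reads: Iterable[ReadRecord], aligner: GenomeAligner) -> list[ReadRecord]:
    """Discard reads with an end-to-end genomic alignment; keep the rest.

    A read spanning the lariat's branchpoint junction cannot align
    contiguously, so genome-mappable reads are removed up front.
    """
    kept = []
    for r in reads:
        if not aligner.find_alignments(r.sequence, both_strands=True):
            kept.append(r)
    return kept


def build_fiveprime_index(
    introns: Iterable[Intron], genome: Mapping[str, str], k: int = 20
) -> FivePrimeIndex:
    """Index the first ``k`` intronic nt of each intron, transcription orientation.

    Minus-strand introns contribute the reverse complement of their last
    ``k`` genomic bases.  Introns shorter than ``k`` are skipped with a
    warning.
    """
    entries: dict[str, IndexEntry] = {}
    for intron in introns:
        iv = intron.interval
        if len(iv) < k:
            logger.warning("intron %s shorter than %d nt; skipped", intron.intron_id, k)
            continue
        chrom_seq = genome[iv.chrom]
        if iv.strand == "+":
            key = chrom_seq[iv.start : iv.start + k]
        else:
            key = revcomp(chrom_seq[iv.end - k : iv.end])
        entries[intron.intron_id] = IndexEntry(
            intron_id=intron.intron_id, gene_id=intron.gene_id, key=key.upper(), intron=intron
        )
    return FivePrimeIndex(k=k, entries=entries)


def locate_fiveprime(
    read: ReadRecord, index: FivePrimeIndex, search_revcomp: bool = False
) -> tuple[str, int] | None:
    """Exact-match search of every 5'SS key in the read.

    Returns ``(intron_id, offset)`` iff exactly one intron's key occurs at
    exactly one offset; two offsets of the same key, or keys of two introns,
    disqualify the read (mismatched or indel-bearing key occurrences never
    count: matching is exact).
    """
    k = index.k
    seqs = [read.sequence.upper()]
    if search_revcomp:
        seqs.append(revcomp(read.sequence.upper()))
    hits: list[tuple[str, int]] = []
    for seq in seqs[:1] if not search_revcomp else seqs:
        for off in range(0, len(seq) - k + 1):
            for entry in index.by_key.get(seq[off : off + k], ()):
                hits.append((entry.intron_id, off))
    if len(hits) != 1:
        return None
    return hits[0]


def trim_for_branchpoint(
    read: ReadRecord, hit: tuple[str, int], min_prefix_length: int = 20
) -> str | None:
    """The branch segment: read prefix upstream of the 5'SS key occurrence.

    Prefixes shorter than ``min_prefix_length`` nt (default 20) are
    discarded — too short to re-map confidently.
    """
    _, offset = hit
    prefix = read.sequence[:offset]
    if len(prefix) < min_prefix_length:
        return None
    return prefix


def align_branch_segment(
    prefix: str, aligner: GenomeAligner, read_id: str, hit: tuple[str, int]
) -> list[LariatReadAlignment]:
    """Genome-wide admissible placements of the branch segment."""
    intron_id, offset = hit
    return [
        LariatReadAlignment(read_id=read_id, intron_id=intron_id, fiveprime_offset=offset, alignment=a)
        for a in aligner.find_alignments(prefix, both_strands=True)
    ]


def _branch_end_coordinate(aln: Alignment, strand: str) -> int:
    """Genomic coordinate of the final aligned base in transcription orientation."""
    return aln.end - 1 if strand == "+" else aln.start


def select_and_call(
    candidates: Sequence[LariatReadAlignment],
    hit: tuple[str, int],
    index: FivePrimeIndex,
    genes: Mapping[str, GenomicInterval],
) -> tuple[str, int] | None:
    """Pick the branchpoint among candidate branch-segment placements.

    Candidates are restricted to the gene of the 5'SS hit, on that gene's
    transcription strand, with the expected inverted order (the segment's
    transcription-orientation end downstream of the intron 5'SS and inside
    the intron).  The highest score wins; ties break to the smallest
    genomic coordinate then lexicographic intron id.  Returns
    ``(intron_id, branchpoint_coordinate)`` or None.
    """
    intron_id, _ = hit
    entry = index.entries[intron_id]
    intron = entry.intron
    gene_iv = genes[entry.gene_id]
    usable: list[tuple[int, int, str, LariatReadAlignment]] = []
    for cand in candidates:
        a = cand.alignment
        if a.chrom != gene_iv.chrom or a.strand != gene_iv.strand:
            continue
        if not (gene_iv.start <= a.start and a.end <= gene_iv.end):
            continue
        bp = _branch_end_coordinate(a, gene_iv.strand)
        # inverted order: branchpoint strictly downstream of the intron 5'SS,
        # and inside the intron
        if gene_iv.strand == "+":
            if not (intron.interval.start < bp < intron.interval.end):
                continue
        else:
            if not (intron.interval.start <= bp < intron.interval.end - 1):
                continue
        usable.append((a.score, bp, cand.intron_id, cand))
    if not usable:
        return None
    usable.sort(key=lambda t: (-t[0], t[1], t[2]))
    _, bp, _, chosen = usable[0]
    return chosen.intron_id, bp


@dataclass
class MappingResult:
    calls: list[BranchpointCall]
    stage_counts: dict[str, int]
    per_read: dict[str, tuple[str, int]]  # read id -> (intron id, branchpoint)


def map_lariats(
    reads: Sequence[ReadRecord],
    genome: Mapping[str, str],
    introns: Sequence[Intron],
    genes: Mapping[str, GenomicInterval],
    config: MapperConfig = MapperConfig(),
) -> MappingResult:
    """Run the full lariat-mapping pipeline and aggregate branchpoint calls."""
    aligner = GenomeAligner(genome, config)
    index = build_fiveprime_index(introns, genome, k=config.key_length)
    stage_counts = {"input": len(reads)}
    stage1 = filter_ambiguous(reads, config.max_ambiguous_fraction)
    stage_counts["ambiguity_filtered"] = len(stage1)
    stage2 = genome_prefilter(stage1, aligner)
    stage_counts["genome_unaligned"] = len(stage2)
    per_read: dict[str, tuple[str, int]] = {}
    n_hit = n_prefix = 0
    support: dict[tuple[str, int], list[str]] = defaultdict(list)
    for read in stage2:
        hit = locate_fiveprime(read, index, config.search_revcomp_keys)
        if hit is None:
            continue
        n_hit += 1
        if config.prefix_rule_on_retained:
            prefix = trim_for_branchpoint(read, hit, config.min_prefix_length)
        else:
            prefix = read.sequence[: hit[1]]
            if len(read.sequence) - hit[1] < config.min_prefix_length:
                prefix = None
            elif not prefix:
                prefix = None
        if prefix is None:
            continue
        n_prefix += 1
        candidates = align_branch_segment(prefix, aligner, read.id, hit)
        call = select_and_call(candidates, hit, index, genes)
        if call is None:
            continue
        per_read[read.id] = call
        support[call].append(read.id)
    stage_counts["unique_fiveprime_hit"] = n_hit
    stage_counts["prefix_retained"] = n_prefix
    stage_counts["called"] = len(per_read)
    calls = [
        BranchpointCall(intron_id=i, coordinate=bp, supporting_reads=tuple(sorted(rids)))
        for (i, bp), rids in sorted(support.items())
    ]
    return MappingResult(calls=calls, stage_counts=stage_counts, per_read=per_read)


# ---------------------------------------------------------------------------
# quantification


def quantify(
    calls: Sequence[BranchpointCall], total_mapped: int, count_mode: str = "reads"
) -> LariatQuant:
    """Per-intron lariat counts, normalized per million mapped reads.

    ``count_mode='reads'`` counts supporting reads; ``'branchpoints'``
    counts distinct branchpoints per intron.
    """
    if total_mapped <= 0:
        raise ValueError("total_mapped must be > 0")
    counts: dict[str, int] = defaultdict(int)
    for call in calls:
        if count_mode == "reads":
            counts[call.intron_id] += len(call.supporting_reads)
        elif count_mode == "branchpoints":
            counts[call.intron_id] += 1
        else:
            raise ValueError(f"unknown count_mode {count_mode!r}")
    normalized = {i: c / total_mapped * 1e6 for i, c in counts.items()}
    return LariatQuant(counts=dict(counts), total_mapped=total_mapped, normalized=normalized)


def fold_changes(
    wt: LariatQuant, ko: LariatQuant, pseudocount: float = 0.0
) -> dict[str, tuple[float, bool]]:
    """Per-intron (KO + pc) / (WT + pc) on normalized counts.

    With the default pseudocount of 0, a zero WT denominator yields
    ``inf`` (flagged True); 0/0 yields ``nan`` (flagged).
    """
    out: dict[str, tuple[float, bool]] = {}
    for intron_id in sorted(set(wt.normalized) | set(ko.normalized)):
        num = ko.normalized.get(intron_id, 0.0) + pseudocount
        den = wt.normalized.get(intron_id, 0.0) + pseudocount
        if den == 0:
            out[intron_id] = (float("inf") if num > 0 else float("nan"), True)
        else:
            out[intron_id] = (num / den, False)
    return out


def lariat_dsrna_sites(
    calls: Sequence[BranchpointCall],
    genome: Mapping[str, str],
    introns: Mapping[str, Intron],
    folder: Folder,
    total_mapped: int,
    panel: SensorPanel = DEFAULT_SENSOR_PANEL,
) -> dict[str, float]:
    """Sensor-site tallies over called lariat introns, per million mapped reads.

    Each intron with at least one branchpoint call is folded once; its
    per-sensor site counts are summed over called introns and divided by
    ``total_mapped`` (scaled per million).
    """
    if total_mapped <= 0:
        raise ValueError("total_mapped must be > 0")
    called_introns = sorted({c.intron_id for c in calls})
    totals = {name: 0 for name in panel}
    for intron_id in called_introns:
        intron = introns[intron_id]
        iv = intron.interval
        seq = genome[iv.chrom][iv.start : iv.end]
        if iv.strand == "-":
            seq = revcomp(seq)
        result = folder(seq)
        for name, count in sensor_sites(extract_stretches(result.structure), panel).items():
            totals[name] += count
    return {name: c / total_mapped * 1e6 for name, c in totals.items()}
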
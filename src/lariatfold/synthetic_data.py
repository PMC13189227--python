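"""Synthetic genomes, reads and count tables with a fully known ground truth.

Everything the pipeline consumes can be generated here with its true
parameters recorded in a :class:`SyntheticLedger`: a background genome in
which no 20-mer repeats (so 5'SS keys and branch-segment loci are unique),
genes with annotated 5'UTR/exon/intron/3'UTR regions, Alu insertions of a
chosen category per intron built from the 282-nt consensus Alu element,
planted branchpoints, lariat-spanning reads with configurable noise, and
negative-binomial count tables with a planted J2-IP enrichment.

The uniqueness guarantee applies to the background sequence: planted Alu
copies are repetitive by construction (that is the point of the IR
category), so the post-hoc k-mer validator accepts a mask of the planted
Alu intervals.  Branchpoints are always planted in background sequence,
keeping branch-segment recovery exact.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .alu_catalog import AluCategory, AluInsertion, GenomicInterval
from .lariat_mapper import Intron, ReadRecord, revcomp

__all__ = [
    "ALU_CONSENSUS",
    "SyntheticLedger",
    "make_genome",
    "simulate_lariat_reads",
    "simulate_counts",
    "random_sequence",
    "validate_unique_kmers",
]

#: Consensus Alu element (DNA alphabet), 282 nt.
ALU_CONSENSUS = (
    "GGCCGGGCGCGGTGGCTCACGCCTGTAATCCCAGCACTTTGGGAGGCCGAGGCGGGCGGATCACCTGAGG"
    "TCAGGAGTTCGAGACCAGCCTGGCCAACATGGTGAAACCCCGTCTCTACTAAAAATACAAAAATTAGCCG"
    "GGCGTGGTGGCGGGCGCCTGTAATCCCAGCTACTCGGGAGGCTGAGGCAGGAGAATCGCTTGAACCCGGG"
    "AGGCGGAGGTTGCAGTGAGCCGAGATCGCGCCACTGCACTCCAGCCTGGGCGACAGAGCGAGACTCCGTCTC"
)

_BASES = "ACGT"


@dataclass
class SyntheticLedger:
    """Complete ground truth of one synthetic dataset."""

    seed: int
    chrom: str
    genome: dict[str, str]
    genes: dict[str, GenomicInterval]
    regions: dict[str, tuple[str, GenomicInterval]]  # id -> (region_type, interval)
    introns: list[Intron]
    alus: list[AluInsertion]
    alus_by_intron: dict[str, list[AluInsertion]]
    planted_categories: dict[str, AluCategory]  # intron id -> category
    branchpoints: dict[str, int]  # intron id -> genomic coordinate (0-based)
    count_params: dict = field(default_factory=dict)

    def to_json(self) -> str:
        def enc(o):
            if isinstance(o, GenomicInterval):
                return {"chrom": o.chrom, "start": o.start, "end": o.end, "strand": o.strand}
            if isinstance(o, AluInsertion):
                return {"interval": enc(o.interval), "element_strand": o.element_strand}
            if isinstance(o, Intron):
                return {"intron_id": o.intron_id, "gene_id": o.gene_id, "interval": enc(o.interval)}
            raise TypeError(type(o))

        payload = {
            "seed": self.seed,
            "chrom": self.chrom,
            "genome": self.genome,
            "genes": {g: enc(iv) for g, iv in self.genes.items()},
            "regions": {r: [t, enc(iv)] for r, (t, iv) in self.regions.items()},
            "introns": [enc(i) for i in self.introns],
            "alus": [enc(a) for a in self.alus],
            "alus_by_intron": {k: [enc(a) for a in v] for k, v in self.alus_by_intron.items()},
            "planted_categories": {k: v.value for k, v in self.planted_categories.items()},
            "branchpoints": self.branchpoints,
            "count_params": self.count_params,
        }
        return json.dumps(payload, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SyntheticLedger":
        d = json.loads(text)

        def iv(x):
            return GenomicInterval(x["chrom"], x["start"], x["end"], x["strand"])

        return cls(
            seed=d["seed"],
            chrom=d["chrom"],
            genome=d["genome"],
            genes={g: iv(x) for g, x in d["genes"].items()},
            regions={r: (t, iv(x)) for r, (t, x) in d["regions"].items()},
            introns=[Intron(x["intron_id"], x["gene_id"], iv(x["interval"])) for x in d["introns"]],
            alus=[AluInsertion(iv(x["interval"]), x["element_strand"]) for x in d["alus"]],
            alus_by_intron={
                k: [AluInsertion(iv(x["interval"]), x["element_strand"]) for x in v]
                for k, v in d["alus_by_intron"].items()
            },
            planted_categories={k: AluCategory(v) for k, v in d["planted_categories"].items()},
            branchpoints=d["branchpoints"],
            count_params=d["count_params"],
        )


_RC_TABLE = str.maketrans("ACGT", "TGCA")


def _rc(kmer: str) -> str:
    return kmer.translate(_RC_TABLE)[::-1]


class _UniqueBackgroundBuilder:
    """Builds a sequence whose every background k-mer is genome-unique.

    Both orientations of each k-mer are recorded, so gene blocks placed
    reverse-complemented keep the guarantee.  Fixed (Alu) segments are
    recorded but not constrained; background bases are re-drawn until the
    trailing k-mer is novel in both orientations.
    """

    def __init__(self, rng: random.Random, k: int = 20):
        self.rng = rng
        self.k = k
        self.chars: list[str] = []
        self.seen: set[str] = set()
        self._window = ""
        self._last_fixed_end = -(10**9)  # position one past the last fixed base

    def _push(self, base: str) -> None:
        self.chars.append(base)
        self._window = (self._window + base)[-(self.k - 1) :]

    def _record(self, kmer: str) -> None:
        self.seen.add(kmer)
        self.seen.add(_rc(kmer))

    def append_background(self, n: int) -> None:
        for _ in range(n):
            # a window overlapping a fixed (repeat) block shares up to k-1
            # bases with other copies of that block, so novelty there is
            # best-effort only; such windows are excluded by the validator's
            # repeat mask as well.
            in_junction = self.position - self._last_fixed_end < self.k - 1
            for _attempt in range(100):
                base = self.rng.choice(_BASES)
                if len(self._window) < self.k - 1:
                    break
                if self._window + base not in self.seen:
                    break
            else:
                if not in_junction:
                    raise RuntimeError("could not find a novel k-mer extension")
                base = self.rng.choice(_BASES)
            if len(self._window) == self.k - 1:
                self._record(self._window + base)
            self._push(base)

    def append_fixed(self, seq: str) -> None:
        for base in seq:
            if len(self._window) == self.k - 1:
                self._record(self._window + base)
            self._push(base)
        self._last_fixed_end = self.position

    @property
    def position(self) -> int:
        return len(self.chars)

    def sequence(self) -> str:
        return "".join(self.chars)


def _mutate(seq: str, rate: float, rng: random.Random) -> str:
    if rate <= 0:
        return seq
    out = []
    for ch in seq:
        if rng.random() < rate:
            out.append(rng.choice([b for b in _BASES if b != ch]))
        else:
            out.append(ch)
    return "".join(out)


def make_genome(
    seed: int,
    n_genes: int = 10,
    intron_length_range: tuple[int, int] = (800, 1200),
    alu_plan: Mapping[str, AluCategory] | AluCategory | None = None,
    exon_length: int = 150,
    utr5_length: int = 100,
    utr3_length: int = 200,
    intergenic: int = 500,
    spacer_length: int = 10,
    alu_mutation_rate: float = 0.0,
    branchpoint_offset: int = 30,
    minus_strand_fraction: float = 0.5,
    total_length: int | None = None,
    chrom: str = "chrS",
) -> SyntheticLedger:
    """Generate a genome of single-intron genes with planted Alu content.

    ``alu_plan`` maps intron ids (``"gene{n}.intron1"``) to target
    categories, or is a single category applied to every intron (default
    NONE).  Each gene is laid out in transcription order as
    5'UTR | exon1 | intron | exon2+3'UTR, with the intron's Alu insertions
    (consensus element, forward or inverted, optionally mutated at
    ``alu_mutation_rate`` per base) separated by background spacers.  The
    branchpoint is planted ``branchpoint_offset`` nt upstream of the intron
    3' end, always in background sequence.  ``total_length`` pads the
    chromosome with background to a fixed size.
    """
    rng = random.Random(seed)
    builder = _UniqueBackgroundBuilder(rng, k=20)
    genes: dict[str, GenomicInterval] = {}
    regions: dict[str, tuple[str, GenomicInterval]] = {}
    introns: list[Intron] = []
    alus: list[AluInsertion] = []
    alus_by_intron: dict[str, list[AluInsertion]] = {}
    planted: dict[str, AluCategory] = {}
    branchpoints: dict[str, int] = {}

    def plan_for(intron_id: str) -> AluCategory:
        if alu_plan is None:
            return AluCategory.NONE
        if isinstance(alu_plan, AluCategory):
            return alu_plan
        return alu_plan.get(intron_id, AluCategory.NONE)

    for g in range(n_genes):
        gene_id = f"gene{g + 1}"
        intron_id = f"{gene_id}.intron1"
        strand = "-" if rng.random() < minus_strand_fraction else "+"
        intron_len = rng.randint(*intron_length_range)
        category = plan_for(intron_id)
        n_alus = {"NONE": 0, "SINGLE": 1, "MULTI_SAME": 2, "IR": 2}[category.value]
        if category == AluCategory.IR:
            orientations = ["sense", "antisense"]
        elif category == AluCategory.MULTI_SAME:
            o = rng.choice(["sense", "antisense"])
            orientations = [o, o]
        elif category == AluCategory.SINGLE:
            orientations = [rng.choice(["sense", "antisense"])]
        else:
            orientations = []
        alu_total = n_alus * len(ALU_CONSENSUS) + max(0, n_alus - 1) * spacer_length
        margin_3p = max(branchpoint_offset + 20, 60)
        min_required = 25 + alu_total + margin_3p + 20
        if intron_len < min_required:
            raise ValueError(
                f"intron {intron_id}: length {intron_len} cannot hold plan "
                f"{category.value} (needs >= {min_required})"
            )

        builder.append_background(intergenic)
        gene_start = builder.position
        # transcription-order layout, built directly on the forward strand for
        # '+' genes; '-' genes are built then placed reverse-complemented.
        parts: list[tuple[str, str | int]] = [
            ("five_prime_utr", utr5_length),
            ("exon1", exon_length),
        ]
        # intron interior: 25 nt bg (covers the 20-nt 5'SS key), alus+spacers, 3' bg
        bg_3p = intron_len - 25 - alu_total
        intron_parts: list[tuple[str, str | int]] = [("bg", 25)]
        for idx, orient in enumerate(orientations):
            if idx > 0:
                intron_parts.append(("bg", spacer_length))
            element = ALU_CONSENSUS if orient == "sense" else revcomp(ALU_CONSENSUS)
            element = _mutate(element, alu_mutation_rate, rng)
            intron_parts.append((f"alu_{orient}", element))
        intron_parts.append(("bg", bg_3p))

        if strand == "+":
            # stream parts onto the genome, tracking offsets
            for name, spec in parts:
                start = builder.position
                builder.append_background(spec)  # utr5/exon1 are background
                regions[f"{gene_id}.{name}"] = (
                    "five_prime_utr" if name == "five_prime_utr" else "exon",
                    GenomicInterval(chrom, start, builder.position, strand),
                )
            intron_start = builder.position
            tx_alu_offsets: list[tuple[int, int, str]] = []
            for name, spec in intron_parts:
                if isinstance(spec, int):
                    builder.append_background(spec)
                else:
                    a_start = builder.position
                    builder.append_fixed(spec)
                    tx_alu_offsets.append((a_start, builder.position, name))
            intron_end = builder.position
            exon2_start = builder.position
            builder.append_background(exon_length)
            regions[f"{gene_id}.exon2"] = (
                "exon",
                GenomicInterval(chrom, exon2_start, builder.position, strand),
            )
            utr3_start = builder.position
            builder.append_background(utr3_length)
            regions[f"{gene_id}.three_prime_utr"] = (
                "three_prime_utr",
                GenomicInterval(chrom, utr3_start, builder.position, strand),
            )
            gene_end = builder.position
            bp = intron_end - 1 - branchpoint_offset
            gene_alus = [
                AluInsertion(
                    GenomicInterval(chrom, s, e, strand),
                    "+" if name.endswith("sense") and not name.endswith("antisense") else "-",
                )
                for s, e, name in tx_alu_offsets
            ]
        else:
            # build the transcription-orientation gene sequence off-genome,
            # then place its reverse complement.
            sub_rng = rng
            tx_builder = _UniqueBackgroundBuilder(sub_rng, k=20)
            tx_builder.seen = builder.seen  # share the uniqueness ledger
            offsets: dict[str, tuple[int, int]] = {}
            for name, spec in parts:
                start = tx_builder.position
                tx_builder.append_background(spec)
                offsets[name] = (start, tx_builder.position)
            tx_intron_start = tx_builder.position
            tx_alu_offsets = []
            for name, spec in intron_parts:
                if isinstance(spec, int):
                    tx_builder.append_background(spec)
                else:
                    a_start = tx_builder.position
                    tx_builder.append_fixed(spec)
                    tx_alu_offsets.append((a_start, tx_builder.position, name))
            tx_intron_end = tx_builder.position
            offsets["exon2"] = (tx_builder.position, tx_builder.position + exon_length)
            tx_builder.append_background(exon_length)
            offsets["three_prime_utr"] = (tx_builder.position, tx_builder.position + utr3_length)
            tx_builder.append_background(utr3_length)
            tx_seq = tx_builder.sequence()
            gene_len = len(tx_seq)
            builder.append_fixed(revcomp(tx_seq))
            gene_end = builder.position

            def to_genomic(tx_s: int, tx_e: int) -> tuple[int, int]:
                return gene_start + gene_len - tx_e, gene_start + gene_len - tx_s

            for name, (s, e) in offsets.items():
                gs, ge = to_genomic(s, e)
                rtype = (
                    "five_prime_utr"
                    if name == "five_prime_utr"
                    else "three_prime_utr"
                    if name == "three_prime_utr"
                    else "exon"
                )
                regions[f"{gene_id}.{name}"] = (rtype, GenomicInterval(chrom, gs, ge, strand))
            intron_start, intron_end = to_genomic(tx_intron_start, tx_intron_end)
            bp_tx = tx_intron_end - 1 - branchpoint_offset
            bp = gene_start + gene_len - 1 - bp_tx
            gene_alus = []
            for s, e, name in tx_alu_offsets:
                gs, ge = to_genomic(s, e)
                # sense-in-transcript element lands on the gene's genomic strand
                el = "-" if name.endswith("_sense") else "+"
                gene_alus.append(AluInsertion(GenomicInterval(chrom, gs, ge, el), el))

        iv = GenomicInterval(chrom, intron_start, intron_end, strand)
        genes[gene_id] = GenomicInterval(chrom, gene_start, gene_end, strand)
        regions[intron_id] = ("intron", iv)
        introns.append(Intron(intron_id, gene_id, iv))
        planted[intron_id] = category
        branchpoints[intron_id] = bp
        alus.extend(gene_alus)
        alus_by_intron[intron_id] = gene_alus

    builder.append_background(intergenic)
    if total_length is not None:
        if builder.position > total_length:
            raise ValueError(
                f"requested total_length {total_length} < laid-out length {builder.position}"
            )
        builder.append_background(total_length - builder.position)
    genome = {chrom: builder.sequence()}
    return SyntheticLedger(
        seed=seed,
        chrom=chrom,
        genome=genome,
        genes=genes,
        regions=regions,
        introns=introns,
        alus=alus,
        alus_by_intron=alus_by_intron,
        planted_categories=planted,
        branchpoints=branchpoints,
    )


def simulate_lariat_reads(
    ledger: SyntheticLedger,
    intron_id: str,
    n: int = 10,
    read_length: int = 120,
    mismatches: int = 0,
    indel: tuple[str, int] | None = None,
    seed: int = 0,
    branchpoint: int | None = None,
    prefix_length: int | None = None,
) -> tuple[list[ReadRecord], pd.DataFrame]:
    """Reads spanning a lariat branchpoint junction, with configurable noise.

    Each read is the ``read_length - 20`` genomic bases ending at the
    branchpoint (transcription orientation) followed by the intron's first
    20 nt — the inverted segment order of a true lariat read.  Substitution
    and indel noise (``indel=('ins'|'del', length)``) are applied only to
    the branch-segment prefix.  Returns the reads and a truth table of
    planted coordinates.
    """
    rng = random.Random(seed)
    intron = next(i for i in ledger.introns if i.intron_id == intron_id)
    iv = intron.interval
    chrom_seq = ledger.genome[iv.chrom]
    tx = chrom_seq[iv.start : iv.end]
    if iv.strand == "-":
        tx = revcomp(tx)
    bp = ledger.branchpoints[intron_id] if branchpoint is None else branchpoint
    if not (iv.start <= bp < iv.end):
        raise ValueError(f"branchpoint {bp} outside intron {intron_id}")
    bp_tx = (bp - iv.start) if iv.strand == "+" else (iv.end - 1 - bp)
    plen = (read_length - 20) if prefix_length is None else prefix_length
    if plen < 1:
        raise ValueError("read too short: prefix would be empty")
    if bp_tx - plen + 1 < 0:
        raise ValueError(
            f"infeasible geometry: prefix {plen} reaches upstream of intron start"
        )
    key = tx[:20]
    clean_prefix = tx[bp_tx - plen + 1 : bp_tx + 1]
    reads: list[ReadRecord] = []
    rows = []
    for r in range(n):
        prefix = list(clean_prefix)
        if mismatches:
            # substitutions are planted >=5 nt from the prefix edges and >=5 nt
            # apart: an edge or clustered substitution can be re-explained by an
            # alignment with a short indel, making the planted count ambiguous
            margin, min_sep = 5, 5
            eligible = range(margin, len(prefix) - margin)
            if len(eligible) < mismatches * min_sep:
                raise ValueError("prefix too short for requested mismatch count")
            while True:
                pos = sorted(rng.sample(eligible, mismatches))
                if all(b - a >= min_sep for a, b in zip(pos, pos[1:])):
                    break
            for p in pos:
                prefix[p] = rng.choice([b for b in _BASES if b != prefix[p]])
        prefix_s = "".join(prefix)
        if indel is not None:
            kind, length = indel
            if length < 1 or length >= len(prefix_s) - 1:
                raise ValueError("invalid indel length")
            # central placement: an edge indel is alignment-equivalent to a
            # shorter event, which would make the planted truth ambiguous
            lo = max(1, len(prefix_s) // 4)
            hi = min(len(prefix_s) - length - 1, 3 * len(prefix_s) // 4)
            at = rng.randint(lo, max(lo, hi))
            if kind == "del":
                prefix_s = prefix_s[:at] + prefix_s[at + length :]
            elif kind == "ins":
                ins = "".join(rng.choice(_BASES) for _ in range(length))
                prefix_s = prefix_s[:at] + ins + prefix_s[at:]
            else:
                raise ValueError(f"unknown indel kind {kind!r}")
        read_id = f"{intron_id}.lariat{r + 1}"
        seq = prefix_s + key
        reads.append(ReadRecord(id=read_id, sequence=seq, quality="I" * len(seq)))
        rows.append(
            {
                "read_id": read_id,
                "intron_id": intron_id,
                "branchpoint": bp,
                "prefix_length": len(prefix_s),
                "mismatches": mismatches,
                "indel": f"{indel[0]}{indel[1]}" if indel else "",
            }
        )
    return reads, pd.DataFrame(rows)


def simulate_background_reads(
    ledger: SyntheticLedger, n: int = 10, read_length: int = 120, seed: int = 0
) -> list[ReadRecord]:
    """Reads copied verbatim from the genome (prefilter fodder)."""
    rng = random.Random(seed)
    chrom = ledger.chrom
    seq = ledger.genome[chrom]
    reads = []
    for r in range(n):
        start = rng.randint(0, len(seq) - read_length)
        reads.append(
            ReadRecord(
                id=f"bg{r + 1}",
                sequence=seq[start : start + read_length],
                quality="I" * read_length,
            )
        )
    return reads


def simulate_counts(
    ledger: SyntheticLedger,
    expression: float | Mapping[str, float] = 100.0,
    ip_enrichment: float = 2.0,
    dispersion: float = 0.05,
    ip_noise_dispersion: float = 0.05,
    seed: int = 0,
    region_types: Sequence[str] = ("intron", "three_prime_utr"),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Total and J2-IP count tables with a planted IR enrichment.

    Total counts are gamma-Poisson (negative-binomial-style: mean
    ``expression * length/1e3``, variance ``mu + dispersion * mu^2``;
    dispersion 0 gives the exact mean).  IP coverage at IR-category regions
    is ``total * ip_enrichment * g`` with ``g`` mean-one gamma noise of
    variance ``ip_noise_dispersion`` (0 gives the deterministic limit), so
    the per-site IP/total ratio is an unbiased draw around the planted
    enrichment.  Parameters are recorded in ``ledger.count_params``.
    """
    if ip_enrichment < 0 or dispersion < 0 or ip_noise_dispersion < 0:
        raise ValueError("expression, enrichment and dispersions must be >= 0")
    rng = np.random.default_rng(seed)
    rows_total = []
    rows_ip = []
    intron_cats = ledger.planted_categories
    for region_id, (rtype, iv) in sorted(ledger.regions.items()):
        if rtype not in region_types:
            continue
        gene_id = region_id.split(".")[0]
        # a gene's UTR inherits the Alu category of its intron in this
        # simplified genome (one intron per gene, Alus planted intronically)
        cat = intron_cats.get(f"{gene_id}.intron1", AluCategory.NONE)
        expr = expression[region_id] if isinstance(expression, Mapping) else expression
        mu = expr * len(iv) / 1e3
        if dispersion > 0:
            lam = rng.gamma(shape=1.0 / dispersion, scale=mu * dispersion)
            total = float(rng.poisson(lam))
        else:
            total = mu
        factor = ip_enrichment if cat == AluCategory.IR else 1.0
        if ip_noise_dispersion > 0:
            g = rng.gamma(shape=1.0 / ip_noise_dispersion, scale=ip_noise_dispersion)
        else:
            g = 1.0
        ip = total * factor * g
        base = {
            "region_id": region_id,
            "region_type": rtype,
            "category": cat.value,
            "length": len(iv),
        }
        rows_total.append({**base, "count": total})
        rows_ip.append({**base, "count": ip})
    ledger.count_params = {
        "expression": expression if not isinstance(expression, Mapping) else dict(expression),
        "ip_enrichment": ip_enrichment,
        "dispersion": dispersion,
        "ip_noise_dispersion": ip_noise_dispersion,
        "seed": seed,
    }
    return pd.DataFrame(rows_total), pd.DataFrame(rows_ip)


def simulate_ir_coverage(
    n_sites: int,
    enrichment: float = 2.0,
    mean_coverage: float = 100.0,
    dispersion: float = 0.05,
    ip_noise_dispersion: float = 0.05,
    seed: int = 0,
) -> tuple[dict[str, float], dict[str, float]]:
    """Paired (IP, total) coverage at IR Alu sites, without a genome.

    Same noise model as :func:`simulate_counts` applied site-wise: total
    coverage is gamma-Poisson around ``mean_coverage``; IP coverage is
    ``total * enrichment`` times mean-one gamma noise.  Returns
    ``(ip_coverage, total_coverage)`` keyed by site id — the statistical
    skeleton of a J2-IP vs cytoplasmic-total comparison.
    """
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    rng = np.random.default_rng(seed)
    ip: dict[str, float] = {}
    total: dict[str, float] = {}
    for i in range(n_sites):
        if dispersion > 0:
            lam = rng.gamma(shape=1.0 / dispersion, scale=mean_coverage * dispersion)
            t = float(rng.poisson(lam))
        else:
            t = mean_coverage
        g = (
            rng.gamma(shape=1.0 / ip_noise_dispersion, scale=ip_noise_dispersion)
            if ip_noise_dispersion > 0
            else 1.0
        )
        site = f"site{i + 1}"
        total[site] = t
        ip[site] = t * enrichment * g
    return ip, total


def random_sequence(
    length: int,
    fractions: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25),
    seed: int = 0,
    alphabet: str = "ACGU",
) -> str:
    """Composition-controlled i.i.d. random sequence (A, C, G, U/T order)."""
    if length < 1:
        raise ValueError("length must be >= 1")
    rng = random.Random(seed)
    return "".join(rng.choices(alphabet, weights=fractions, k=length))


def validate_unique_kmers(
    genome: Mapping[str, str],
    k: int = 20,
    mask: Sequence[GenomicInterval] = (),
) -> list[str]:
    """Post-hoc check that no k-mer outside ``mask`` occurs twice.

    Returns the list of duplicated k-mers (empty means the guarantee
    holds).  Planted Alu intervals are passed as the mask: repeat copies
    are duplicates by construction.
    """
    masked: dict[str, list[tuple[int, int]]] = {}
    for iv in mask:
        masked.setdefault(iv.chrom, []).append((iv.start, iv.end))
    seen: set[str] = set()
    dups: set[str] = set()
    for chrom, seq in genome.items():
        intervals = sorted(masked.get(chrom, []))
        for i in range(len(seq) - k + 1):
            if any(s < i + k and i < e for s, e in intervals):
                continue
            kmer = seq[i : i + k]
            if kmer in seen:
                dups.add(kmer)
            seen.add(kmer)
    return sorted(dups)
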
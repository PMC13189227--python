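"""Shared file formats, run configuration and reproducible output headers.

Formats: FASTA/FASTQ (Biopython), BED6 (Alu annotations, strand required),
GTF-lite (tab-separated chrom / source / feature / 1-based start / end /
score / strand / frame / ``gene_id``+``region_id`` attributes, converted to
0-based half-open on read), Vienna dot-bracket files, SAM-subset ingestion
(pysam) and commented TSV tables.

Every table written here starts with a ``#`` header carrying the package
version, the seed and a hash of the run configuration; no timestamps are
embedded, so reruns with identical inputs are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import io
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import __version__
from .alu_catalog import AluInsertion, GenomicInterval
from .lariat_mapper import Intron, ReadRecord

logger = logging.getLogger(__name__)

GTF_FEATURES = {"gene", "intron", "three_prime_utr", "five_prime_utr", "exon"}


@dataclass(frozen=True)
class RunConfig:
    """Stage parameters with defaults matching the published analysis."""

    seed: int = 0
    max_ambiguous_fraction: float = 0.05
    key_length: int = 20
    min_prefix_length: int = 20
    max_mismatches: int = 5
    max_mismatch_rate: float = 0.10
    max_indel_length: int = 3
    n_shuffles: int = 10
    fold_max_length: int = 5000
    sensor_panel: tuple[tuple[str, int], ...] = (("OAS1", 17), ("RIG-I", 22), ("PKR", 33))
    n_hybrid_trials: int = 10000
    folder: str = "builtin"  # or "viennarna"
    hybridizer: str = "builtin"  # or "rnaduplex"

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def output_header(config: RunConfig, tool: str) -> str:
    return (
        f"# lariatfold {__version__} tool={tool} seed={config.seed} "
        f"config={config.config_hash()}\n"
    )


def write_tsv(df: pd.DataFrame, path: str | Path, config: RunConfig, tool: str) -> None:
    with open(path, "w") as fh:
        fh.write(output_header(config, tool))
        df.to_csv(fh, sep="\t", index=False)


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


# -- FASTA / FASTQ -----------------------------------------------------------


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fastq(path: str | Path) -> list[ReadRecord]:
    out = []
    for rec in SeqIO.parse(str(path), "fastq"):
        qual = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
        out.append(ReadRecord(id=rec.id, sequence=str(rec.seq).upper(), quality=qual))
    return out


def write_fastq(reads: Iterable[ReadRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            qual = r.quality or "I" * len(r.sequence)
            fh.write(f"@{r.id}\n{r.sequence}\n+\n{qual}\n")


# -- BED6 (Alu annotations) --------------------------------------------------


def read_bed6(path: str | Path) -> list[AluInsertion]:
    """BED6: chrom, start, end, name, score (ignored), strand (required)."""
    out = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValueError(f"{path}:{ln}: BED6 requires 6 columns (strand)")
            chrom, start, end, _name, _score, strand = fields[:6]
            out.append(
                AluInsertion(
                    interval=GenomicInterval(chrom, int(start), int(end), strand),
                    element_strand=strand,
                )
            )
    return out


def write_bed6(alus: Sequence[AluInsertion], path: str | Path, name: str = "Alu") -> None:
    with open(path, "w") as fh:
        for i, a in enumerate(alus, 1):
            iv = a.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}{i}\t0\t{a.element_strand}\n"
            )


# -- GTF-lite ----------------------------------------------------------------


@dataclass
class Annotations:
    genes: dict[str, GenomicInterval]
    regions: dict[str, tuple[str, GenomicInterval]]  # region id -> (type, interval)
    introns: list[Intron]


def _parse_attributes(text: str) -> dict[str, str]:
    attrs = {}
    for chunk in text.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        key, _, value = chunk.partition(" ")
        attrs[key] = value.strip().strip('"')
    return attrs


def read_gtf_lite(path: str | Path) -> Annotations:
    genes: dict[str, GenomicInterval] = {}
    regions: dict[str, tuple[str, GenomicInterval]] = {}
    introns: list[Intron] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"{path}:{ln}: expected 9 tab-separated columns")
            chrom, _source, feature, start, end, _score, strand, _frame, attr_text = fields
            if feature not in GTF_FEATURES:
                raise ValueError(f"{path}:{ln}: unknown feature {feature!r}")
            attrs = _parse_attributes(attr_text)
            iv = GenomicInterval(chrom, int(start) - 1, int(end), strand)
            gene_id = attrs.get("gene_id", "")
            region_id = attrs.get("region_id", gene_id)
            if feature == "gene":
                genes[gene_id] = iv
            else:
                regions[region_id] = (feature, iv)
                if feature == "intron":
                    introns.append(Intron(region_id, gene_id, iv))
    return Annotations(genes=genes, regions=regions, introns=introns)


def write_gtf_lite(
    genes: Mapping[str, GenomicInterval],
    regions: Mapping[str, tuple[str, GenomicInterval]],
    path: str | Path,
    source: str = "lariatfold",
) -> None:
    with open(path, "w") as fh:
        for gene_id, iv in sorted(genes.items()):
            fh.write(
                f"{iv.chrom}\t{source}\tgene\t{iv.start + 1}\t{iv.end}\t.\t{iv.strand}\t.\t"
                f'gene_id "{gene_id}"; region_id "{gene_id}";\n'
            )
        for region_id, (rtype, iv) in sorted(regions.items()):
            gene_id = region_id.split(".")[0]
            fh.write(
                f"{iv.chrom}\t{source}\t{rtype}\t{iv.start + 1}\t{iv.end}\t.\t{iv.strand}\t.\t"
                f'gene_id "{gene_id}"; region_id "{region_id}";\n'
            )


# -- Vienna dot-bracket files ------------------------------------------------


def read_vienna(path: str | Path) -> list[tuple[str, str, str, float | None]]:
    """Parse (id, sequence, dotbracket, mfe) records from a Vienna-style file."""
    out = []
    lines = [l.rstrip("\n") for l in open(path) if l.strip()]
    i = 0
    while i < len(lines):
        if not lines[i].startswith(">"):
            raise ValueError(f"{path}: expected '>' header at line {i + 1}")
        name = lines[i][1:].split()[0]
        seq = lines[i + 1].strip()
        struct_line = lines[i + 2].strip()
        mfe = None
        db = struct_line
        if "(" in struct_line and struct_line.rstrip().endswith(")"):
            # trailing " (mfe)" energy annotation
            lpar = struct_line.rfind(" (")
            if lpar != -1:
                try:
                    mfe = float(struct_line[lpar + 2 : -1].strip())
                    db = struct_line[:lpar].strip()
                except ValueError:
                    db = struct_line
        out.append((name, seq, db, mfe))
        i += 3
    return out


def write_vienna(
    records: Iterable[tuple[str, str, str, float | None]], path: str | Path
) -> None:
    with open(path, "w") as fh:
        for name, seq, db, mfe in records:
            fh.write(f">{name}\n{seq}\n{db}")
            if mfe is not None:
                fh.write(f" ({mfe:.2f})")
            fh.write("\n")


# -- SAM subset --------------------------------------------------------------


def unmapped_reads_from_sam(path: str | Path) -> list[ReadRecord]:
    """Unmapped records of a (plain-text) SAM file, for prefilter ingestion.

    Only QNAME, FLAG and SEQ are consulted; a record is kept iff the
    0x4 (unmapped) flag is set.
    """
    import pysam

    out = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for rec in sam.fetch(until_eof=True):
            if rec.is_unmapped and rec.query_sequence:
                out.append(ReadRecord(id=rec.query_name, sequence=rec.query_sequence.upper()))
    return out


def setup_logging(verbose: bool = False) -> None:
    logging.basicConfig(
        stream=sys.stderr,
        level=logging.DEBUG if verbose else logging.INFO,
        format="%(levelname)s %(name)s: %(message)s",
    )
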
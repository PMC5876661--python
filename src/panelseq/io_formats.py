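"""Readers and writers for the external formats the pipeline touches.

Coordinate conventions
----------------------
Internally everything is 1-based inclusive, matching VCF, the dominant
input format.  BED is the only 0-based half-open format in the pipeline
and the conversion happens here and nowhere else: a 1-based position
``pos`` becomes the BED interval ``(pos - 1, pos)``.

Count tables are plain TSV with the header
``chrom  pos  accession  A  C  G  T  other`` and 1-based positions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

BASES = ("A", "C", "G", "T")
COUNT_TABLE_COLUMNS = ["chrom", "pos", "accession", "A", "C", "G", "T", "other"]


class FormatError(ValueError):
    """Malformed input file."""


@dataclass
class GenomeSequence:
    """A reference genome held fully in memory.

    Chromosome order is preserved from the FASTA; sequences are uppercase
    strings over the alphabet {A, C, G, T, N}.
    """

    chrom_names: list[str]
    sequences: dict[str, str]

    def __post_init__(self) -> None:
        if len(set(self.chrom_names)) != len(self.chrom_names):
            raise FormatError("duplicate chromosome names")
        for name in self.chrom_names:
            seq = self.sequences[name]
            if not seq:
                raise FormatError(f"chromosome {name} has zero length")
            if set(seq) - set("ACGTN"):
                bad = sorted(set(seq) - set("ACGTN"))
                raise FormatError(f"chromosome {name}: invalid characters {bad}")

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(self.sequences[name]) for name in self.chrom_names}

    def base_at(self, chrom: str, pos: int) -> str:
        """Reference base at a 1-based position."""
        return self.sequences[chrom][pos - 1]

    def window(self, chrom: str, start: int, end: int) -> str:
        """Subsequence for the 1-based inclusive interval [start, end]."""
        if start < 1 or end > len(self.sequences[chrom]) or start > end:
            raise FormatError(f"window [{start}, {end}] not on {chrom}")
        return self.sequences[chrom][start - 1 : end]


@dataclass(frozen=True)
class VariantRecord:
    """One caller's call at one site for one accession."""

    chrom: str
    pos: int  # 1-based
    ref_allele: str
    alt_allele: str
    depth: int
    mapping_quality: float
    caller_id: str
    accession_id: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref_allele == self.alt_allele:
            raise ValueError("ref and alt alleles must differ")
        for allele in (self.ref_allele, self.alt_allele):
            if allele not in BASES:
                raise ValueError(f"allele {allele!r} is not a single base")
        if self.depth < 0 or self.mapping_quality < 0:
            raise ValueError("depth and mapping quality must be non-negative")

    @property
    def site(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref_allele, self.alt_allele)


@dataclass(frozen=True)
class SiteAlleleCounts:
    """Per-base read counts at one site in one accession's alignment."""

    chrom: str
    pos: int  # 1-based
    accession_id: str
    counts: tuple[int, int, int, int]  # A, C, G, T
    other: int = 0

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.counts) or self.other < 0:
            raise ValueError("allele counts must be non-negative")

    @property
    def depth(self) -> int:
        return sum(self.counts) + self.other

    def count(self, base: str) -> int:
        return self.counts[BASES.index(base)]

    def nonref_fraction(self, ref_base: str) -> float:
        """Fraction of reads disagreeing with the reference base (0 if no depth)."""
        depth = self.depth
        if depth == 0:
            return 0.0
        return (depth - self.count(ref_base)) / depth


@dataclass
class VcfParseStats:
    """Bookkeeping so that no record is silently dropped."""

    parsed: int = 0
    skipped_indel: int = 0
    skipped_symbolic: int = 0
    skipped_missing_annotation: int = 0
    input_records: int = 0

    @property
    def skipped(self) -> int:
        return (
            self.skipped_indel
            + self.skipped_symbolic
            + self.skipped_missing_annotation
        )


def read_fasta(path: str | Path) -> GenomeSequence:
    """Read a (multi-record) FASTA into a :class:`GenomeSequence`.

    Sequences are uppercased; record order is preserved.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    names = [rec.id for rec in records]
    sequences = {rec.id: str(rec.seq).upper() for rec in records}
    return GenomeSequence(chrom_names=names, sequences=sequences)


def write_fasta(genome: GenomeSequence, path: str | Path, width: int = 70) -> None:
    records = [
        SeqRecord(Seq(genome.sequences[name]), id=name, description="")
        for name in genome.chrom_names
    ]
    with open(path, "w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=width)
        writer.write_file(records)


# Per-caller VCF dialect: which per-record keys supply depth and mapping
# quality.  Callers emit heterogeneous annotations; DP/MQ are the common
# denominators and the default.
DEFAULT_DIALECT = {"depth_key": "DP", "mq_key": "MQ"}


def read_vcf_minimal(
    path: str | Path,
    caller_id: str,
    accession_id: str,
    dialect: dict | None = None,
) -> tuple[list[VariantRecord], VcfParseStats]:
    """Read SNP records from a VCF 4.x file.

    Only single-base REF/ALT records are kept.  Multi-allelic records are
    split into one record per alternate allele; indels and symbolic
    alleles are skipped and counted.  Records missing the depth or
    mapping-quality annotation are skipped and counted, never fatal.
    """
    dialect = dialect or DEFAULT_DIALECT
    depth_key = dialect.get("depth_key", "DP")
    mq_key = dialect.get("mq_key", "MQ")

    out: list[VariantRecord] = []
    stats = VcfParseStats()
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            stats.input_records += 1
            ref = (rec.ref or "").upper()
            alts = rec.alts or ()
            info = dict(rec.info)
            depth = info.get(depth_key)
            mq = info.get(mq_key)
            if depth is None or mq is None:
                stats.skipped_missing_annotation += 1
                continue
            emitted = False
            for alt in alts:
                alt = alt.upper()
                if alt.startswith("<") or alt == "*":
                    stats.skipped_symbolic += 1
                    continue
                if len(ref) != 1 or len(alt) != 1:
                    stats.skipped_indel += 1
                    continue
                if ref not in BASES or alt not in BASES:
                    stats.skipped_symbolic += 1
                    continue
                out.append(
                    VariantRecord(
                        chrom=rec.chrom,
                        pos=rec.pos,
                        ref_allele=ref,
                        alt_allele=alt,
                        depth=int(depth),
                        mapping_quality=float(mq),
                        caller_id=caller_id,
                        accession_id=accession_id,
                    )
                )
                emitted = True
            if emitted:
                stats.parsed += 1
            elif not alts:
                stats.skipped_symbolic += 1
    logger.info(
        "%s (%s/%s): %d records parsed, %d skipped",
        path,
        caller_id,
        accession_id,
        stats.parsed,
        stats.skipped,
    )
    return out, stats


VCF_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##INFO=<ID=MQ,Number=1,Type=Float,Description="Mapping quality">
{contigs}#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
"""


def write_vcf_minimal(
    records: Sequence[VariantRecord],
    path: str | Path,
    contig_lengths: dict[str, int] | None = None,
) -> None:
    """Write SNP records as a minimal uncompressed VCF 4.2 file."""
    contigs = ""
    if contig_lengths:
        contigs = "".join(
            f"##contig=<ID={name},length={length}>\n"
            for name, length in contig_lengths.items()
        )
    with open(path, "w") as fh:
        fh.write(VCF_HEADER.format(contigs=contigs))
        for rec in records:
            mq = rec.mapping_quality
            mq_str = f"{mq:g}"
            fh.write(
                f"{rec.chrom}\t{rec.pos}\t.\t{rec.ref_allele}\t{rec.alt_allele}"
                f"\t.\tPASS\tDP={rec.depth};MQ={mq_str}\n"
            )


def write_bed(intervals: Iterable[tuple], path: str | Path) -> None:
    """Write BED3/BED6 intervals (0-based half-open).

    Each interval is ``(chrom, start, end)`` or ``(chrom, start, end,
    name)``.  An empty list yields an empty file with a track header.
    """
    with open(path, "w") as fh:
        fh.write('track name="intervals"\n')
        for iv in intervals:
            chrom, start, end = iv[0], int(iv[1]), int(iv[2])
            if start < 0 or start >= end:
                raise FormatError(f"invalid BED interval {chrom}:{start}-{end}")
            rest = "\t".join(str(x) for x in iv[3:])
            fh.write(f"{chrom}\t{start}\t{end}" + (f"\t{rest}" if rest else "") + "\n")


def read_bed(path: str | Path) -> list[tuple]:
    """Read a BED file written by :func:`write_bed` (0-based half-open)."""
    out: list[tuple] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            if start < 0 or start >= end:
                raise FormatError(f"invalid BED interval {chrom}:{start}-{end}")
            out.append((chrom, start, end, *fields[3:]))
    return out


def pos_to_bed(pos: int) -> tuple[int, int]:
    """1-based position -> 0-based half-open single-base interval."""
    return pos - 1, pos


def bed_to_pos(start: int, end: int) -> int:
    """0-based half-open single-base interval -> 1-based position."""
    if end != start + 1:
        raise FormatError("interval does not span exactly one base")
    return start + 1


def write_count_table(counts: Sequence[SiteAlleleCounts], path: str | Path) -> None:
    rows = [
        {
            "chrom": c.chrom,
            "pos": c.pos,
            "accession": c.accession_id,
            "A": c.counts[0],
            "C": c.counts[1],
            "G": c.counts[2],
            "T": c.counts[3],
            "other": c.other,
        }
        for c in counts
    ]
    df = pd.DataFrame(rows, columns=COUNT_TABLE_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def read_count_table(path: str | Path) -> list[SiteAlleleCounts]:
    """Read a 1-based TSV allele-count table."""
    df = pd.read_csv(path, sep="\t")
    missing = set(COUNT_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    return [
        SiteAlleleCounts(
            chrom=str(row.chrom),
            pos=int(row.pos),
            accession_id=str(row.accession),
            counts=(int(row.A), int(row.C), int(row.G), int(row.T)),
            other=int(row.other),
        )
        for row in df.itertuples()
    ]
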
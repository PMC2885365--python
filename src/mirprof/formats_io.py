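"""Readers/writers for the pipeline's file formats and genome sequence access.

All genomic coordinates are 0-based half-open internally. GFF3 input
(1-based closed) is converted on read; BED-style output stays 0-based
half-open.
"""

from __future__ import annotations

import gzip
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqIO.FastaIO import SimpleFastaParser
from Bio.SeqRecord import SeqRecord

VALID_CATEGORIES = (
    "mature_miRNA",
    "ncRNA",
    "rRNA_mRNA",
    "exon",
    "intergenic",
    "intronic",
)

_SEQ_RE = re.compile(r"^[ACGTUN]+$")

COMPLEMENT = str.maketrans("ACGTUN", "TGCAAN")


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(COMPLEMENT)[::-1]


class ParseError(ValueError):
    """Raised when an input file does not conform to its format."""


@dataclass(frozen=True)
class TagFileRecord:
    """One unique read sequence with its observed frequency."""

    sequence: str
    frequency: int


@dataclass(frozen=True, order=True)
class GenomeRegion:
    """0-based half-open genomic interval on a strand."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self):
        if self.start < 0 or self.start >= self.end:
            raise ValueError(f"bad region {self.chrom}:{self.start}-{self.end}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class ReferenceSet:
    """A named, categorised collection of reference sequences."""

    name: str
    category: str
    records: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self):
        if self.category not in VALID_CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        ids = [r[0] for r in self.records]
        if len(ids) != len(set(ids)):
            raise ValueError(f"duplicate record ids in reference set {self.name!r}")


def _open_text(path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def read_tag_file(path) -> list[TagFileRecord]:
    """Read a two-column TSV of (sequence, frequency).

    An optional single header line is tolerated. Duplicate sequences are an
    error here: collapsing only happens after adapter trimming.
    """
    records: list[TagFileRecord] = []
    seen: set[str] = set()
    with _open_text(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ParseError(f"{path}:{lineno}: expected 2 columns, got {len(fields)}")
            seq, count = fields[0].strip().upper(), fields[1].strip()
            if (
                lineno == 1
                and not _SEQ_RE.match(seq)
                and not count.lstrip("-").isdigit()
            ):
                continue  # header line: neither column parses
            if not _SEQ_RE.match(seq):
                raise ParseError(f"{path}:{lineno}: invalid sequence {fields[0]!r}")
            try:
                freq = int(count)
            except ValueError:
                raise ParseError(f"{path}:{lineno}: non-integer count {count!r}") from None
            if freq < 1:
                raise ParseError(f"{path}:{lineno}: frequency must be >= 1, got {freq}")
            if seq in seen:
                raise ParseError(f"{path}:{lineno}: duplicate sequence {seq}")
            seen.add(seq)
            records.append(TagFileRecord(seq, freq))
    return records


def write_tag_file(records: Iterable[TagFileRecord], path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f"{rec.sequence}\t{rec.frequency}\n")


def read_fasta(path) -> list[tuple[str, str]]:
    """Read FASTA into (id, sequence) pairs; sequences validated as nucleotide.

    Validation runs on the raw sequence lines (Biopython quietly drops
    internal whitespace, which we treat as malformed input instead).
    """
    import io

    with _open_text(path) as fh:
        text = fh.read()
    for lineno, line in enumerate(text.splitlines(), start=1):
        stripped = line.strip()
        if stripped and not stripped.startswith(">") and any(c.isspace() for c in stripped):
            raise ParseError(f"{path}:{lineno}: whitespace inside sequence")
    out = []
    for title, seq in SimpleFastaParser(io.StringIO(text)):
        seq = seq.upper()
        name = title.split(None, 1)[0] if title else ""
        if not _SEQ_RE.match(seq):
            raise ParseError(f"{path}: record {name!r} has illegal characters")
        out.append((name, seq))
    return out


def write_fasta(records: Iterable[tuple[str, str]], path) -> None:
    recs = [SeqRecord(Seq(seq), id=name, description="") for name, seq in records]
    with open(path, "w") as fh:
        SeqIO.write(recs, fh, "fasta-2line")


def read_fastq_sequences(path) -> list[str]:
    """Raw read sequences from FASTQ; qualities are ignored."""
    with _open_text(path) as fh:
        return [str(rec.seq).upper() for rec in SeqIO.parse(fh, "fastq")]


def load_genome(path) -> dict[str, str]:
    """Load a (small) genome FASTA into a chromosome -> sequence mapping."""
    return dict(read_fasta(path))


def fetch_region(genome: Mapping[str, str], region: GenomeRegion) -> str:
    """Extract a region's sequence; minus-strand regions are reverse-complemented."""
    if region.chrom not in genome:
        raise KeyError(f"unknown chromosome {region.chrom!r}")
    chrom_seq = genome[region.chrom]
    if region.end > len(chrom_seq):
        raise ValueError(
            f"region {region.chrom}:{region.start}-{region.end} exceeds "
            f"chromosome length {len(chrom_seq)}"
        )
    seq = chrom_seq[region.start : region.end]
    return reverse_complement(seq) if region.strand == "-" else seq


@dataclass
class Gene:
    gene_id: str
    region: GenomeRegion
    exons: list[GenomeRegion] = field(default_factory=list)

    def introns(self) -> list[GenomeRegion]:
        exons = sorted(self.exons, key=lambda e: e.start)
        out = []
        for a, b in zip(exons, exons[1:]):
            if b.start > a.end:
                out.append(GenomeRegion(self.region.chrom, a.end, b.start, self.region.strand))
        return out


@dataclass
class GeneModel:
    """Gene/exon annotation supporting intergenic/intronic classification."""

    genes: list[Gene] = field(default_factory=list)

    def classify(self, chrom: str, start: int, end: int) -> str:
        """Classify an interval as intergenic / intronic / exon_overlap.

        exon_overlap covers any overlap with an exon or partial overlap with
        a gene boundary; such hits were already handled by the elimination
        cascade and are discarded from novel-miRNA consideration.
        """
        label = "intergenic"
        for gene in self.genes:
            g = gene.region
            if g.chrom != chrom or end <= g.start or start >= g.end:
                continue
            if any(start < e.end and end > e.start for e in gene.exons):
                return "exon_overlap"
            if any(start >= i.start and end <= i.end for i in gene.introns()):
                label = "intronic"
            else:
                return "exon_overlap"  # straddles gene boundary or exon edge
        return label


def read_gff(path) -> GeneModel:
    """Minimal GFF3 reader for gene/exon features (1-based closed -> half-open).

    Exons attach to genes by the Parent= attribute chain or, failing that,
    by coordinate containment.
    """
    genes: dict[str, Gene] = {}
    exon_rows = []
    with _open_text(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ParseError(f"{path}:{lineno}: expected 9 GFF columns")
            chrom, _, ftype, start, end, _, strand, _, attrs = fields
            start0, end0 = int(start) - 1, int(end)
            attr_map = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            if ftype == "gene":
                gid = attr_map.get("ID", f"gene{lineno}")
                genes[gid] = Gene(gid, GenomeRegion(chrom, start0, end0, strand))
            elif ftype == "exon":
                exon_rows.append(
                    (attr_map.get("Parent"), GenomeRegion(chrom, start0, end0, strand))
                )
    for parent, region in exon_rows:
        if parent in genes:
            genes[parent].exons.append(region)
            continue
        for gene in genes.values():
            g = gene.region
            if g.chrom == region.chrom and region.start >= g.start and region.end <= g.end:
                gene.exons.append(region)
                break
    return GeneModel(list(genes.values()))


def write_gff(model: GeneModel, path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gene in model.genes:
            g = gene.region
            fh.write(
                f"{g.chrom}\tmirprof\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={gene.gene_id}\n"
            )
            for i, e in enumerate(sorted(gene.exons, key=lambda e: e.start), start=1):
                fh.write(
                    f"{e.chrom}\tmirprof\texon\t{e.start + 1}\t{e.end}\t.\t{e.strand}\t.\t"
                    f"ID={gene.gene_id}.exon{i};Parent={gene.gene_id}\n"
                )
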
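"""Genomic file I/O and strand-aware context-window extraction.

All coordinates are 0-based, half-open internally.  SAM input (1-based) is
converted on read; BED12 is natively 0-based.  Context windows are centered
on a read 5'-end position and reverse-complemented for minus-strand sites so
that models always see the priming-proximal orientation.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import pandas as pd
import pysam
from Bio import SeqIO

__all__ = [
    "FormatError",
    "Genome",
    "GeneModel",
    "ReadStartSite",
    "read_fasta",
    "write_fasta",
    "read_gene_models",
    "write_gene_models",
    "read_read_starts",
    "write_read_starts",
    "reverse_complement",
    "extract_window",
]

_VALID_BASES = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass
class Genome:
    """Named contigs of nucleotide text over {A,C,G,T,N}, stored uppercase."""

    contigs: dict[str, str]

    def __post_init__(self) -> None:
        for name, seq in self.contigs.items():
            if not seq:
                raise FormatError(f"contig {name!r} is empty")
            bad = set(seq) - _VALID_BASES
            if bad:
                raise FormatError(
                    f"contig {name!r} contains illegal characters {sorted(bad)}"
                )

    def __getitem__(self, name: str) -> str:
        return self.contigs[name]

    def __contains__(self, name: str) -> bool:
        return name in self.contigs


@dataclass
class GeneModel:
    """A gene's strand and sorted, non-overlapping exon intervals.

    ``exons`` are (start, end) pairs in 0-based half-open genome coordinates.
    """

    gene_id: str
    contig: str
    strand: str
    exons: list[tuple[int, int]]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise FormatError(f"gene {self.gene_id}: bad strand {self.strand!r}")
        prev_end = None
        for start, end in self.exons:
            if end <= start:
                raise FormatError(
                    f"gene {self.gene_id}: empty/inverted exon ({start},{end})"
                )
            if prev_end is not None and start < prev_end:
                raise FormatError(
                    f"gene {self.gene_id}: exons unsorted or overlapping at {start}"
                )
            prev_end = end
        if not self.exons:
            raise FormatError(f"gene {self.gene_id}: no exons")

    @property
    def length(self) -> int:
        """Total exonic length (the FPKM gene length)."""
        return sum(end - start for start, end in self.exons)


@dataclass(frozen=True)
class ReadStartSite:
    """A (contig, pos, strand) read 5'-end locus with its read count."""

    contig: str
    pos: int
    strand: str
    count: int = 1

    def __post_init__(self) -> None:
        if self.count < 1:
            raise FormatError(f"site {self.contig}:{self.pos}: count {self.count} < 1")
        if self.strand not in ("+", "-"):
            raise FormatError(f"site {self.contig}:{self.pos}: bad strand")

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.contig, self.pos, self.strand)


def read_fasta(path: str | os.PathLike) -> Genome:
    """Read a (multi-)FASTA file into a :class:`Genome`.

    Lowercase is folded to uppercase; multi-line records are concatenated.
    Duplicate contig names, empty records and characters outside
    {A,C,G,T,N} raise :class:`FormatError`.
    """
    with open(path) as handle:
        for line in handle:
            if line.strip():
                if not line.startswith(">"):
                    raise FormatError(
                        f"{path}: first non-blank line is not a FASTA header: "
                        f"{line.strip()[:40]!r}"
                    )
                break
    contigs: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        name = record.id
        if name in contigs:
            raise FormatError(f"{path}: duplicate contig name {name!r}")
        seq = str(record.seq).upper()
        bad = set(seq) - _VALID_BASES
        if bad:
            offset = next(i for i, ch in enumerate(seq) if ch in bad)
            raise FormatError(
                f"{path}: record {name!r} has illegal character "
                f"{seq[offset]!r} at position {offset}"
            )
        if not seq:
            raise FormatError(f"{path}: record {name!r} is empty")
        contigs[name] = seq
    return Genome(contigs)


def write_fasta(genome: Genome, path: str | os.PathLike, width: int = 60) -> None:
    with open(path, "w") as out:
        for name, seq in genome.contigs.items():
            out.write(f">{name}\n")
            for i in range(0, len(seq), width):
                out.write(seq[i : i + width] + "\n")


def _parse_int_list(text: str, what: str, line_no: int) -> list[int]:
    try:
        return [int(x) for x in text.rstrip(",").split(",")]
    except ValueError as exc:
        raise FormatError(f"line {line_no}: bad {what} field {text!r}") from exc


def read_gene_models(path: str | os.PathLike) -> list[GeneModel]:
    """Read gene models from a BED12 file.

    Exon intervals are reconstructed from blockSizes/blockStarts (relative to
    chromStart) into 0-based half-open genome coordinates.
    """
    genes: list[GeneModel] = []
    with open(path) as handle:
        for line_no, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise FormatError(
                    f"line {line_no}: expected 12 BED fields, got {len(fields)}"
                )
            contig = fields[0]
            try:
                chrom_start, chrom_end = int(fields[1]), int(fields[2])
                block_count = int(fields[9])
            except ValueError as exc:
                raise FormatError(f"line {line_no}: non-integer coordinate") from exc
            name, strand = fields[3], fields[5]
            sizes = _parse_int_list(fields[10], "blockSizes", line_no)
            starts = _parse_int_list(fields[11], "blockStarts", line_no)
            if len(sizes) != block_count or len(starts) != block_count:
                raise FormatError(
                    f"line {line_no}: blockCount {block_count} does not match "
                    f"{len(sizes)} sizes / {len(starts)} starts"
                )
            exons = [
                (chrom_start + s, chrom_start + s + sz)
                for s, sz in zip(starts, sizes)
            ]
            if exons and exons[-1][1] != chrom_end:
                raise FormatError(
                    f"line {line_no}: last block ends at {exons[-1][1]}, "
                    f"chromEnd is {chrom_end}"
                )
            try:
                genes.append(GeneModel(name, contig, strand, exons))
            except FormatError as exc:
                raise FormatError(f"line {line_no}: {exc}") from exc
    return genes


def write_gene_models(genes: list[GeneModel], path: str | os.PathLike) -> None:
    with open(path, "w") as out:
        for g in genes:
            start = g.exons[0][0]
            end = g.exons[-1][1]
            sizes = ",".join(str(e - s) for s, e in g.exons)
            starts = ",".join(str(s - start) for s, _ in g.exons)
            out.write(
                "\t".join(
                    [
                        g.contig,
                        str(start),
                        str(end),
                        g.gene_id,
                        "0",
                        g.strand,
                        str(start),
                        str(end),
                        "0",
                        str(len(g.exons)),
                        sizes,
                        starts,
                    ]
                )
                + "\n"
            )


def _sites_from_sam(
    path: str | os.PathLike,
    min_mapq: int,
    unique_only: bool,
    read1_only: bool,
) -> list[ReadStartSite]:
    counts: dict[tuple[str, int, str], int] = {}
    with pysam.AlignmentFile(str(path), "r") as sam:
        for aln in sam:
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            if read1_only and aln.is_paired and not aln.is_read1:
                continue
            if unique_only:
                if aln.has_tag("NH"):
                    if aln.get_tag("NH") != 1:
                        continue
                elif aln.mapping_quality < min_mapq:
                    continue
            if aln.is_reverse:
                # 5' end of a reverse-strand read = rightmost aligned base
                key = (aln.reference_name, aln.reference_end - 1, "-")
            else:
                key = (aln.reference_name, aln.reference_start, "+")
            counts[key] = counts.get(key, 0) + 1
    return [ReadStartSite(c, p, s, n) for (c, p, s), n in counts.items()]


def _sites_from_tsv(path: str | os.PathLike) -> list[ReadStartSite]:
    df = pd.read_csv(path, sep="\t", dtype={"contig": str, "strand": str})
    required = {"contig", "pos", "strand", "count"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    if (df["count"] < 1).any():
        raise FormatError(f"{path}: counts must be >= 1")
    agg = df.groupby(["contig", "pos", "strand"], sort=False)["count"].sum()
    return [
        ReadStartSite(c, int(p), s, int(n)) for (c, p, s), n in agg.items()
    ]


def read_read_starts(
    path: str | os.PathLike,
    format: str | None = None,
    min_mapq: int = 255,
    unique_only: bool = True,
    read1_only: bool = False,
) -> list[ReadStartSite]:
    """Read aggregated read 5'-end sites from a SAM file or a read-start TSV.

    For SAM, each kept primary alignment contributes its 5'-end reference
    base: the leftmost aligned base for forward-strand alignments, the
    rightmost (via the CIGAR reference span) for reverse-strand ones.
    Uniqueness is judged by the NH tag when present, else by
    ``mapping quality >= min_mapq``.  Identical sites are aggregated with
    summed counts.
    """
    if format is None:
        format = "sam" if str(path).endswith(".sam") else "tsv"
    if format == "sam":
        return _sites_from_sam(path, min_mapq, unique_only, read1_only)
    if format == "tsv":
        return _sites_from_tsv(path)
    raise ValueError(f"unknown read-start format {format!r}")


def write_read_starts(sites: list[ReadStartSite], path: str | os.PathLike) -> None:
    """Write sites as the read-start TSV dialect (pos 0-based, header line)."""
    with open(path, "w") as out:
        out.write("contig\tpos\tstrand\tcount\n")
        for s in sites:
            out.write(f"{s.contig}\t{s.pos}\t{s.strand}\t{s.count}\n")


def reverse_complement(seq: str) -> str:
    """Reverse-complement a sequence over {A,C,G,T,N} (N maps to N)."""
    bad = set(seq) - _VALID_BASES
    if bad:
        raise ValueError(f"illegal characters in sequence: {sorted(bad)}")
    return seq.translate(_COMPLEMENT)[::-1]


def extract_window(
    genome: Genome, contig: str, pos: int, strand: str, w: int
) -> str | None:
    """Extract the 2w+1 context window centered on ``pos``.

    Returns ``genome[pos-w .. pos+w]`` inclusive; for minus-strand sites the
    reverse complement, so the model always sees the priming-proximal
    orientation.  Returns ``None`` when the window would leave the contig or
    contains an N.
    """
    if w < 0:
        raise ValueError("w must be >= 0")
    if contig not in genome:
        raise KeyError(f"unknown contig {contig!r}")
    seq = genome[contig]
    lo, hi = pos - w, pos + w + 1
    if lo < 0 or hi > len(seq):
        return None
    window = seq[lo:hi]
    if "N" in window:
        return None
    if strand == "-":
        window = reverse_complement(window)
    return window
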
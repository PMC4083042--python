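"""Readers/writers for the standard formats the pipeline touches, plus the
shared coordinate and sequence model.

Conventions
-----------
* Internal coordinates are always 0-based, half-open (``[start, end)``).
  GFF3 is converted from/to its native 1-based closed convention at the
  boundary; BED is already 0-based half-open.
* All sequences are uppercased and U is converted to T at parse time, so
  every downstream comparison is DNA-alphabet exact.
* Collapsed small-RNA libraries may be written/read as FASTA with
  count-suffixed headers (``name_x<count>``), the usual dialect for
  adapter-trimmed, collapsed sequencing output.
"""

from __future__ import annotations

import dataclasses
import gzip
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pandas as pd
from Bio import SeqIO

__all__ = [
    "GenomeSequence",
    "Interval",
    "AnnotationRecord",
    "CollapsedRead",
    "SmallRNALibrary",
    "ParseError",
    "read_fasta",
    "write_fasta",
    "read_smrna_library",
    "write_smrna_library",
    "read_annotation",
    "write_annotation",
    "write_table",
    "read_table",
    "revcomp",
    "FEATURE_CLASSES",
    "GFF3_TYPE_MAP",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: closed set of feature classes used throughout the pipeline
FEATURE_CLASSES = (
    "gene",
    "TE",
    "known_miRNA_locus",
    "rRNA",
    "tRNA",
    "snoRNA",
    "snRNA",
    "repeat",
    "other",
)

#: documented mapping from GFF3/BED type strings to internal feature classes
GFF3_TYPE_MAP = {
    "gene": "gene",
    "mrna": "gene",
    "protein_coding_gene": "gene",
    "transposable_element": "TE",
    "transposable_element_gene": "TE",
    "te": "TE",
    "retrotransposon": "TE",
    "mirna": "known_miRNA_locus",
    "mirna_primary_transcript": "known_miRNA_locus",
    "pre_mirna": "known_miRNA_locus",
    "rrna": "rRNA",
    "trna": "tRNA",
    "snorna": "snoRNA",
    "snrna": "snRNA",
    "repeat_region": "repeat",
    "repeat": "repeat",
    "dispersed_repeat": "repeat",
}


class ParseError(ValueError):
    """Raised for malformed input files; message names the offending line."""


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (A/C/G/T/N)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GenomeSequence:
    """A single reference chromosome/contig."""

    name: str
    seq: str

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass(frozen=True, order=True)
class Interval:
    """0-based half-open genomic interval. ``strand`` is '+', '-' or '.'."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Interval", max_gap: int = 0) -> bool:
        """True if the two intervals overlap or lie within ``max_gap`` bp."""
        if self.chrom != other.chrom:
            return False
        return self.start < other.end + max_gap and other.start < self.end + max_gap


@dataclass
class AnnotationRecord:
    """A genomic feature with a class drawn from :data:`FEATURE_CLASSES`."""

    feature_id: str
    interval: Interval
    feature_class: str
    attributes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.feature_class not in FEATURE_CLASSES:
            raise ValueError(f"unknown feature class {self.feature_class!r}")


@dataclass(frozen=True)
class CollapsedRead:
    """A unique small-RNA sequence with its copy number in one library."""

    seq: str
    count: int

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass
class SmallRNALibrary:
    """A collapsed small-RNA library plus parse tallies.

    ``total_reads`` (the clean-read total, i.e. the sum of kept copy
    numbers) is the RPM denominator used throughout the pipeline.
    """

    reads: list[CollapsedRead]
    n_input: int = 0
    n_out_of_range: int = 0
    n_rejected: int = 0

    @property
    def total_reads(self) -> int:
        return sum(r.count for r in self.reads)

    def __iter__(self) -> Iterator[CollapsedRead]:
        return iter(self.reads)

    def __len__(self) -> int:
        return len(self.reads)


# ---------------------------------------------------------------------------
# FASTA / FASTQ
# ---------------------------------------------------------------------------

def _open_text(path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def read_fasta(path) -> list[tuple[str, str]]:
    """Parse a (possibly gzipped) FASTA file into ``(name, seq)`` tuples.

    Sequences are uppercased and U converted to T; record order is
    preserved.  Malformed headers, empty sequences and duplicate names
    raise :class:`ParseError` naming the line number.
    """
    records: list[tuple[str, str]] = []
    seen: set[str] = set()
    name = None
    chunks: list[str] = []
    header_line = 0
    with _open_text(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                if name is not None:
                    _finish_fasta_record(records, seen, name, chunks, header_line)
                name = line[1:].split()[0] if len(line) > 1 else ""
                if not name:
                    raise ParseError(f"{path}: empty FASTA header at line {lineno}")
                header_line = lineno
                chunks = []
            else:
                if name is None:
                    raise ParseError(
                        f"{path}: sequence before first header at line {lineno}"
                    )
                chunks.append(line)
        if name is not None:
            _finish_fasta_record(records, seen, name, chunks, header_line)
    return records


def _finish_fasta_record(records, seen, name, chunks, lineno) -> None:
    seq = "".join(chunks).upper().replace("U", "T")
    if not seq:
        raise ParseError(f"empty sequence for record {name!r} at line {lineno}")
    if name in seen:
        raise ParseError(f"duplicate FASTA record name {name!r} at line {lineno}")
    seen.add(name)
    records.append((name, seq))


def write_fasta(records: Iterable[tuple[str, str]], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


_COUNT_SUFFIX = re.compile(r"_x(\d+)$")
_VALID_READ = re.compile(r"^[ACGT]+$")


def read_smrna_library(
    path,
    fmt: str = "fasta",
    min_len: int = 15,
    max_len: int = 35,
) -> SmallRNALibrary:
    """Read an adapter-trimmed small-RNA library and collapse identical reads.

    FASTA headers in the collapsed dialect ``name_x<count>`` contribute
    ``count`` copies; any other header contributes one copy.  FASTQ is read
    through Bio.SeqIO (qualities validated, then ignored).  Reads outside
    ``[min_len, max_len]`` nt are dropped into an out-of-range tally; reads
    with non-ACGT characters after U->T (including N) are rejected and
    tallied, since they cannot be exact-mapped.
    """
    counts: dict[str, int] = {}
    n_input = n_oor = n_rej = 0
    if fmt == "fasta":
        entries = ((n, s) for n, s in read_fasta(path))
    elif fmt == "fastq":
        with _open_text(path) as fh:
            entries = [
                (rec.id, str(rec.seq).upper().replace("U", "T"))
                for rec in SeqIO.parse(fh, "fastq")
            ]
    else:
        raise ValueError(f"unknown small-RNA library format {fmt!r}")
    for name, seq in entries:
        m = _COUNT_SUFFIX.search(name)
        copies = int(m.group(1)) if m else 1
        n_input += copies
        if not _VALID_READ.match(seq):
            n_rej += copies
            continue
        if not (min_len <= len(seq) <= max_len):
            n_oor += copies
            continue
        counts[seq] = counts.get(seq, 0) + copies
    reads = [CollapsedRead(seq, c) for seq, c in sorted(counts.items())]
    return SmallRNALibrary(reads, n_input=n_input, n_out_of_range=n_oor, n_rejected=n_rej)


def write_smrna_library(library: SmallRNALibrary, path) -> None:
    """Write a collapsed library as FASTA with ``read<i>_x<count>`` headers."""
    write_fasta(
        ((f"read{i}_x{r.count}", r.seq) for i, r in enumerate(library.reads, 1)),
        path,
    )


# ---------------------------------------------------------------------------
# Annotation (GFF3 / BED)
# ---------------------------------------------------------------------------

def _classify(type_str: str, attributes: dict) -> str:
    cls = GFF3_TYPE_MAP.get(type_str.lower())
    if cls is None:
        cls = attributes.get("feature_class")
    return cls if cls in FEATURE_CLASSES else "other"


def read_annotation(
    path,
    dialect: str = "gff3",
    chrom_sizes: dict[str, int] | None = None,
) -> list[AnnotationRecord]:
    """Read GFF3 (1-based closed) or BED (0-based half-open) annotation.

    Intervals are normalized to the internal 0-based half-open convention;
    the feature class comes from the GFF3 type column (or BED name prefix
    ``class:feature_id``) through :data:`GFF3_TYPE_MAP`, with unknown types
    mapped to ``other``.  If ``chrom_sizes`` is given, any interval that
    exceeds its chromosome raises :class:`ParseError` naming the record.
    """
    records: list[AnnotationRecord] = []
    with _open_text(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if dialect == "gff3":
                if len(fields) < 9:
                    raise ParseError(f"{path}: short GFF3 line {lineno}")
                chrom, _, ftype, start, end, _, strand, _, attr_str = fields[:9]
                attributes = dict(
                    kv.split("=", 1) for kv in attr_str.split(";") if "=" in kv
                )
                feature_id = attributes.get("ID", f"feature{lineno}")
                iv = Interval(chrom, int(start) - 1, int(end), strand if strand in "+-" else ".")
                cls = _classify(ftype, attributes)
            elif dialect == "bed":
                if len(fields) < 3:
                    raise ParseError(f"{path}: short BED line {lineno}")
                chrom, start, end = fields[:3]
                name = fields[3] if len(fields) > 3 else f"feature{lineno}"
                strand = fields[5] if len(fields) > 5 else "."
                if ":" in name:
                    cls_str, feature_id = name.split(":", 1)
                else:
                    cls_str, feature_id = "other", name
                attributes = {}
                iv = Interval(chrom, int(start), int(end), strand if strand in "+-" else ".")
                cls = _classify(cls_str, attributes)
            else:
                raise ValueError(f"unknown annotation dialect {dialect!r}")
            if chrom_sizes is not None:
                size = chrom_sizes.get(iv.chrom)
                if size is None or iv.end > size:
                    raise ParseError(
                        f"{path}: record {feature_id!r} (line {lineno}) exceeds "
                        f"chromosome {iv.chrom}"
                    )
            records.append(AnnotationRecord(feature_id, iv, cls, attributes))
    return records


#: reverse mapping used when emitting GFF3 type columns
_CLASS_TO_GFF3 = {
    "gene": "gene",
    "TE": "transposable_element",
    "known_miRNA_locus": "miRNA_primary_transcript",
    "rRNA": "rRNA",
    "tRNA": "tRNA",
    "snoRNA": "snoRNA",
    "snRNA": "snRNA",
    "repeat": "repeat_region",
    "other": "region",
}


def write_annotation(records: Sequence[AnnotationRecord], path) -> None:
    """Emit annotation as GFF3 (1-based closed at the boundary)."""
    ordered = sorted(records, key=lambda r: (r.interval.chrom, r.interval.start, r.feature_id))
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for rec in ordered:
            iv = rec.interval
            attrs = ";".join(
                [f"ID={rec.feature_id}"]
                + [f"{k}={v}" for k, v in sorted(rec.attributes.items()) if k != "ID"]
            )
            fh.write(
                "\t".join(
                    [
                        iv.chrom,
                        "smrnapipe",
                        _CLASS_TO_GFF3[rec.feature_class],
                        str(iv.start + 1),
                        str(iv.end),
                        ".",
                        iv.strand if iv.strand in "+-" else ".",
                        ".",
                        attrs,
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Generic tabular output
# ---------------------------------------------------------------------------

_SORT_KEYS = ("chrom", "start", "end", "feature_id", "locus_id", "gene_id", "name")


def _flatten(record) -> dict:
    if dataclasses.is_dataclass(record):
        out = {}
        for f in dataclasses.fields(record):
            value = getattr(record, f.name)
            if isinstance(value, Interval):
                out["chrom"] = value.chrom
                out["start"] = value.start
                out["end"] = value.end
                out["strand"] = value.strand
            elif isinstance(value, dict):
                out[f.name] = ";".join(f"{k}={v}" for k, v in sorted(value.items()))
            else:
                out[f.name] = value
        return out
    if isinstance(record, dict):
        return dict(record)
    raise TypeError(f"cannot tabulate record of type {type(record)!r}")


def write_table(records: Sequence, path) -> None:
    """Write a sequence of same-schema records as a header-ed TSV.

    Floats are rendered with 6 significant digits; rows are sorted into a
    deterministic order (genomic order where coordinates exist, then id).
    An empty sequence is not writable without a schema, so ``records`` may
    also be a DataFrame, which is written as-is (sorted the same way).
    """
    if isinstance(records, pd.DataFrame):
        df = records.copy()
    else:
        df = pd.DataFrame([_flatten(r) for r in records])
    keys = [k for k in _SORT_KEYS if k in df.columns]
    if keys and len(df):
        df = df.sort_values(keys, kind="mergesort")
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_table(path) -> pd.DataFrame:
    """Read back a :func:`write_table` TSV."""
    return pd.read_csv(path, sep="\t")
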
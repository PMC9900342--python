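"""Readers and writers for the plain-text formats the pipeline touches.

All genomic coordinates everywhere in this package are 0-based half-open
(BED convention).  FASTQ qualities are phred+33.  Expression matrices are
TSV with a header row of sample ids and the feature id in the first column;
floats are serialized with 17 significant digits, which round-trips IEEE
double precision exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd

VALID_BASES = frozenset("ACGTN")
FLOAT_FORMAT = "%.17g"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA sequence over {A,C,G,T,N}."""
    return seq.translate(_COMPLEMENT)[::-1]


class FormatError(ValueError):
    """Raised for malformed input files; the message names the offending line."""


@dataclass
class SequenceRecord:
    """A named sequence with optional phred qualities."""

    id: str
    sequence: str
    quality: Optional[list[int]] = None
    description: Optional[str] = None

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise ValueError(f"record {self.id!r}: empty sequence")
        if self.quality is not None and len(self.quality) != len(self.sequence):
            raise ValueError(
                f"record {self.id!r}: quality length {len(self.quality)} "
                f"!= sequence length {len(self.sequence)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True, order=True)
class GenomeInterval:
    """0-based half-open stranded genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start {self.start} on {self.chrom}")
        if self.end <= self.start:
            raise ValueError(
                f"empty or inverted interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomeInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, other: "GenomeInterval") -> bool:
        """True iff *other* lies entirely within this interval (strand ignored)."""
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )


@dataclass
class ExpressionMatrix:
    """Rectangular non-negative feature x sample table (counts or TPM)."""

    values: pd.DataFrame  # rows = features, columns = samples
    conditions: dict[str, str] = field(default_factory=dict)
    unit: str = "count"

    def __post_init__(self) -> None:
        if (self.values.values < 0).any():
            raise ValueError("expression values must be non-negative")
        if self.unit not in ("count", "TPM"):
            raise ValueError(f"unknown unit {self.unit!r}")
        if self.conditions:
            missing = [s for s in self.values.columns if s not in self.conditions]
            if missing:
                raise ValueError(f"samples without condition label: {missing}")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


# ---------------------------------------------------------------------------
# FASTA / FASTQ


def read_fasta(path) -> list[SequenceRecord]:
    """Parse a FASTA file; multi-line sequences are concatenated, case folded up."""
    path = Path(path)
    records: list[SequenceRecord] = []
    header: Optional[str] = None
    desc: Optional[str] = None
    chunks: list[str] = []
    header_line = 0

    def flush() -> None:
        if header is None:
            return
        seq = "".join(chunks)
        if not seq:
            raise FormatError(f"{path}:{header_line}: record {header!r} has no sequence")
        records.append(SequenceRecord(header, seq, description=desc))

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            if line.startswith(">"):
                flush()
                body = line[1:].strip()
                if not body:
                    raise FormatError(f"{path}:{lineno}: empty FASTA header")
                parts = body.split(None, 1)
                header = parts[0]
                desc = parts[1] if len(parts) > 1 else None
                header_line = lineno
                chunks = []
            else:
                if header is None:
                    raise FormatError(f"{path}:{lineno}: sequence before first header")
                seq = line.strip().upper()
                bad = set(seq) - VALID_BASES
                if bad:
                    raise FormatError(
                        f"{path}:{lineno}: illegal characters {sorted(bad)} in sequence"
                    )
                chunks.append(seq)
    flush()
    return records


def write_fasta(records: Iterable[SequenceRecord], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            head = rec.id if not rec.description else f"{rec.id} {rec.description}"
            fh.write(f">{head}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


def read_fastq(path) -> list[SequenceRecord]:
    """Parse a 4-line-record phred+33 FASTQ file."""
    path = Path(path)
    records: list[SequenceRecord] = []
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    while lines and not lines[-1]:
        lines.pop()
    if len(lines) % 4 != 0:
        raise FormatError(f"{path}: truncated FASTQ (line count {len(lines)} not a multiple of 4)")
    for i in range(0, len(lines), 4):
        head, seq, plus, qual = lines[i : i + 4]
        lineno = i + 1
        if not head.startswith("@"):
            raise FormatError(f"{path}:{lineno}: expected '@' header, got {head[:20]!r}")
        if not plus.startswith("+"):
            raise FormatError(f"{path}:{lineno + 2}: expected '+' separator")
        seq = seq.upper()
        bad = set(seq) - VALID_BASES
        if bad:
            raise FormatError(f"{path}:{lineno + 1}: illegal characters {sorted(bad)}")
        if len(seq) != len(qual):
            raise FormatError(
                f"{path}:{lineno + 3}: quality length {len(qual)} != sequence length {len(seq)}"
            )
        body = head[1:].strip()
        parts = body.split(None, 1)
        records.append(
            SequenceRecord(
                parts[0],
                seq,
                quality=[ord(c) - 33 for c in qual],
                description=parts[1] if len(parts) > 1 else None,
            )
        )
    return records


def write_fastq(records: Iterable[SequenceRecord], path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            qual = rec.quality
            if qual is None:
                qual = [40] * len(rec.sequence)
            fh.write(f"@{rec.id}\n{rec.sequence}\n+\n")
            fh.write("".join(chr(q + 33) for q in qual) + "\n")


# ---------------------------------------------------------------------------
# BED6


def read_bed(path) -> list[tuple[GenomeInterval, str, float]]:
    """Read a BED file (>=3 columns) as (interval, name, score) tuples."""
    path = Path(path)
    rows: list[tuple[GenomeInterval, str, float]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: fewer than 3 tab-separated columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinate") from exc
            name = fields[3] if len(fields) > 3 else "."
            score = float(fields[4]) if len(fields) > 4 and fields[4] != "." else 0.0
            strand = fields[5] if len(fields) > 5 else "+"
            try:
                interval = GenomeInterval(chrom, start, end, strand)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            rows.append((interval, name, score))
    return rows


def write_bed(rows: Iterable[tuple[GenomeInterval, str, float]], path) -> None:
    with open(path, "w") as fh:
        for interval, name, score in rows:
            score_s = FLOAT_FORMAT % score if score % 1 else str(int(score))
            fh.write(
                f"{interval.chrom}\t{interval.start}\t{interval.end}"
                f"\t{name}\t{score_s}\t{interval.strand}\n"
            )


# ---------------------------------------------------------------------------
# Expression matrices


def read_matrix(path, conditions: Optional[dict[str, str]] = None, unit: str = "count") -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.isna().any().any():
        raise FormatError(f"{path}: ragged rows or missing cells")
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric cell ({exc})") from exc
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return ExpressionMatrix(df, conditions=dict(conditions or {}), unit=unit)


def write_matrix(matrix: ExpressionMatrix, path) -> None:
    matrix.values.to_csv(path, sep="\t", float_format=FLOAT_FORMAT)


# ---------------------------------------------------------------------------
# Collapsed-read FASTA dialect (">name_x<multiplicity>")


def write_collapsed_fasta(reads, path) -> None:
    """Write collapsed reads as FASTA with multiplicity in the header."""
    with open(path, "w") as fh:
        for i, read in enumerate(reads, start=1):
            fh.write(f">seq{i}_x{read.multiplicity}\n{read.sequence}\n")


def read_collapsed_fasta(path, sample: str = "sample"):
    from .preprocess import CollapsedRead  # local import to avoid a cycle

    reads = []
    for rec in read_fasta(path):
        mult = 1
        if "_x" in rec.id:
            tail = rec.id.rsplit("_x", 1)[1]
            if tail.isdigit():
                mult = int(tail)
        reads.append(CollapsedRead(rec.sequence, mult, sample))
    return reads


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
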
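"""Readers, writers and elementary sequence operations.

Every genomic coordinate in this package is 1-based and inclusive on the
forward strand, the convention used when naming single positions such as a
transcription start site.  The single exception is BED6 output, which is
converted to 0-based half-open at the writer boundary.

RNA-derived input is normalized at ingestion: bases are uppercased and U is
converted to T so that read sequences compare directly against a DNA
reference.  ``N`` is a legal base but never counts as a match anywhere in the
package.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional

from Bio import SeqIO
from Bio.SeqIO.QualityIO import FastqGeneralIterator
from gffutils.feature import feature_from_line

NUCLEOTIDES = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class FormatError(ValueError):
    """A file does not conform to its declared format."""


class AlphabetError(ValueError):
    """A sequence contains characters outside {A, C, G, T, N}."""


def _normalize(bases: str) -> str:
    return bases.upper().replace("U", "T")


def _check_alphabet(bases: str, context: str = "sequence") -> None:
    bad = set(bases) - NUCLEOTIDES
    if bad:
        raise AlphabetError(
            f"illegal character(s) {sorted(bad)} in {context}; allowed: A,C,G,T,N"
        )


def reverse_complement(bases: str) -> str:
    """Watson-Crick reverse complement; N maps to N.

    Involution: ``reverse_complement(reverse_complement(s)) == s``.
    """
    _check_alphabet(bases)
    return bases.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class ReferenceSequence:
    """A named genome or locus sequence (uppercase A/C/G/T/N)."""

    name: str
    bases: str

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("ReferenceSequence.name must be non-empty")
        _check_alphabet(self.bases, context=f"reference {self.name!r}")

    @property
    def length(self) -> int:
        return len(self.bases)

    def __len__(self) -> int:
        return len(self.bases)

    def slice(self, start: int, end: int) -> str:
        """Subsequence at 1-based inclusive coordinates [start, end]."""
        if not (1 <= start <= end <= len(self.bases)):
            raise ValueError(
                f"slice [{start}, {end}] outside reference {self.name!r} "
                f"of length {len(self.bases)}"
            )
        return self.bases[start - 1 : end]


@dataclass(frozen=True)
class FeatureRecord:
    """One annotation feature, GFF3-style 1-based inclusive coordinates."""

    seq_name: str
    start: int
    end: int
    strand: str
    feature_type: str
    attributes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.start < 1 or self.start > self.end:
            raise ValueError(
                f"feature coordinates must satisfy 1 <= start <= end, "
                f"got [{self.start}, {self.end}]"
            )
        if not self.feature_type:
            raise ValueError("feature_type must be non-empty")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class SequenceRead:
    """One sequencing read; ``mate`` is 1/2 for paired data, None otherwise."""

    read_id: str
    bases: str
    qualities: Optional[str] = None
    mate: Optional[int] = None

    def __post_init__(self) -> None:
        if self.qualities is not None and len(self.qualities) != len(self.bases):
            raise FormatError(
                f"read {self.read_id!r}: quality string length "
                f"{len(self.qualities)} != sequence length {len(self.bases)}"
            )

    def __len__(self) -> int:
        return len(self.bases)


# ---------------------------------------------------------------------------
# FASTA


def _bad_sequence_line(path: Path, bad_chars: set) -> int:
    """Locate (1-based) the first sequence line containing an illegal char."""
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            if line.startswith(">"):
                continue
            if set(_normalize(line.strip())) & bad_chars:
                return lineno
    return 0


def read_fasta(path) -> list[ReferenceSequence]:
    """Parse a FASTA file into ReferenceSequence records.

    Bases are uppercased and U -> T.  Malformed input raises
    :class:`FormatError` naming the offending line where determinable.
    """
    path = Path(path)
    records = []
    with open(path) as handle:
        first = handle.read(1)
        if first and first != ">":
            raise FormatError(f"{path}: malformed FASTA header at line 1")
    for rec in SeqIO.parse(str(path), "fasta"):
        bases = _normalize(str(rec.seq))
        bad = set(bases) - NUCLEOTIDES
        if bad:
            lineno = _bad_sequence_line(path, bad)
            raise FormatError(
                f"{path}: illegal character(s) {sorted(bad)} at line {lineno}"
            )
        records.append(ReferenceSequence(name=rec.id, bases=bases))
    return records


def write_fasta(records: Iterable[ReferenceSequence], path, width: int = 70) -> None:
    path = Path(path)
    with open(path, "w") as handle:
        for rec in records:
            handle.write(f">{rec.name}\n")
            for i in range(0, len(rec.bases), width):
                handle.write(rec.bases[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# FASTQ


def read_fastq(path, mate: Optional[int] = None) -> Iterator[SequenceRead]:
    """Stream 4-line FASTQ records in file order.

    ``mate`` tags every read with a mate number for paired files; reads named
    ``...(/1|/2)`` carry their mate tag from the name when ``mate`` is None.
    """
    path = Path(path)
    with open(path) as handle:
        try:
            for title, seq, qual in FastqGeneralIterator(handle):
                read_id = title.split()[0]
                read_mate = mate
                if read_mate is None and read_id[-2:] in ("/1", "/2"):
                    read_mate = int(read_id[-1])
                    read_id = read_id[:-2]
                if len(seq) != len(qual):
                    raise FormatError(
                        f"{path}: read {read_id!r} sequence/quality length mismatch"
                    )
                yield SequenceRead(
                    read_id=read_id,
                    bases=_normalize(seq),
                    qualities=qual,
                    mate=read_mate,
                )
        except ValueError as exc:  # Biopython signals malformed records
            if isinstance(exc, FormatError):
                raise
            raise FormatError(f"{path}: {exc}") from exc


def write_fastq(reads: Iterable[SequenceRead], path) -> None:
    path = Path(path)
    with open(path, "w") as handle:
        for read in reads:
            qual = read.qualities or "I" * len(read.bases)
            name = read.read_id if read.mate is None else f"{read.read_id}/{read.mate}"
            handle.write(f"@{name}\n{read.bases}\n+\n{qual}\n")


# ---------------------------------------------------------------------------
# GFF3


def read_gff3(path) -> list[FeatureRecord]:
    """Parse a GFF3 file; comment/directive lines are skipped.

    Coordinates are kept 1-based inclusive exactly as in the file.
    """
    path = Path(path)
    features = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                if line.startswith("##FASTA"):
                    break
                continue
            try:
                feat = feature_from_line(line)
            except Exception as exc:
                raise FormatError(f"{path}: line {lineno}: {exc}") from exc
            if feat.start > feat.end:
                raise FormatError(
                    f"{path}: line {lineno}: start {feat.start} > end {feat.end}"
                )
            attributes = {k: v[0] if len(v) == 1 else list(v)
                          for k, v in feat.attributes.items()}
            features.append(
                FeatureRecord(
                    seq_name=feat.seqid,
                    start=feat.start,
                    end=feat.end,
                    strand=feat.strand if feat.strand in "+-" else ".",
                    feature_type=feat.featuretype,
                    attributes=attributes,
                )
            )
    return features


def write_gff3(features: Iterable[FeatureRecord], path, source: str = "circbact") -> None:
    path = Path(path)
    with open(path, "w") as handle:
        handle.write("##gff-version 3\n")
        for feat in features:
            attrs = ";".join(f"{k}={v}" for k, v in feat.attributes.items()) or "."
            handle.write(
                "\t".join(
                    [
                        feat.seq_name,
                        source,
                        feat.feature_type,
                        str(feat.start),
                        str(feat.end),
                        ".",
                        feat.strand,
                        ".",
                        attrs,
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# BED6 (written only; converts to 0-based half-open here and only here)


def write_bed6(intervals, path) -> None:
    """Write (seq_name, start_1based, end_1based, name, score, strand) rows."""
    path = Path(path)
    with open(path, "w") as handle:
        for seq_name, start, end, name, score, strand in intervals:
            handle.write(
                f"{seq_name}\t{start - 1}\t{end}\t{name}\t{score}\t{strand}\n"
            )
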
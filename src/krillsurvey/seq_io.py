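"""Sequence I/O and read quality control.

Thin, gzip-aware wrappers around Biopython's parsers that normalise
everything to a single lightweight :class:`SeqRecord`, plus the survey
read-quality filter: a read is discarded when more than 5% of its bases
are undetermined (N) or more than 20% have a Phred quality of 10 or
below. Both thresholds are strict inequalities, so boundary reads pass.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

from Bio import SeqIO as _BioSeqIO
from Bio.Seq import Seq as _BioSeq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

__all__ = [
    "SeqRecord",
    "QCParams",
    "FilterStats",
    "ParseError",
    "read_fastx",
    "write_fastx",
    "filter_reads",
    "read_genbank_reference",
]


@dataclass
class SeqRecord:
    """One nucleotide or protein sequence, optionally with Phred qualities."""

    id: str
    seq: str
    description: str = ""
    quals: Optional[list[int]] = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("record id must be non-empty")
        if not self.seq:
            raise ValueError(f"record {self.id!r}: sequence must be non-empty")
        if self.quals is not None and len(self.quals) != len(self.seq):
            raise ValueError(
                f"record {self.id!r}: {len(self.quals)} quality scores for "
                f"{len(self.seq)} bases"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class QCParams:
    """Read-filter thresholds (fractions in [0, 1], Phred score integer)."""

    max_n_fraction: float = 0.05
    low_qual_threshold: int = 10
    max_low_qual_fraction: float = 0.20

    def __post_init__(self) -> None:
        for name in ("max_n_fraction", "max_low_qual_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


@dataclass
class FilterStats:
    kept: int = 0
    dropped: int = 0
    clean_bases: int = 0
    dropped_n: int = 0
    dropped_quality: int = 0

    @property
    def total(self) -> int:
        return self.kept + self.dropped


class ParseError(ValueError):
    """Malformed FASTA/FASTQ input."""


def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def _sniff_format(path: str | Path) -> str:
    with _open_text(path) as fh:
        first = fh.read(1)
    if first == ">":
        return "fasta"
    if first == "@":
        return "fastq"
    raise ParseError(
        f"{path}: cannot auto-detect format (first byte {first!r}, expected '>' or '@')"
    )


def read_fastx(path: str | Path, format: str = "auto") -> Iterator[SeqRecord]:
    """Stream records from a FASTA or FASTQ file (plain or gzipped).

    Sequences are uppercased; FASTQ qualities are Phred+33 (Biopython's
    ``fastq`` parser, i.e. the Sanger/Illumina-1.8 encoding — other
    encodings are not guessed).
    """
    if format == "auto":
        format = _sniff_format(path)
    if format not in ("fasta", "fastq"):
        raise ValueError(f"unsupported format {format!r}")
    with _open_text(path) as fh:
        try:
            for i, rec in enumerate(_BioSeqIO.parse(fh, format)):
                if not rec.id:
                    raise ParseError(f"{path}: record {i + 1} has an empty header")
                quals = None
                if format == "fastq":
                    quals = list(rec.letter_annotations["phred_quality"])
                yield SeqRecord(
                    id=rec.id,
                    seq=str(rec.seq).upper(),
                    description=rec.description[len(rec.id) :].strip()
                    if rec.description.startswith(rec.id)
                    else rec.description,
                    quals=quals,
                )
        except ValueError as exc:  # Biopython signals malformed records this way
            if isinstance(exc, ParseError):
                raise
            raise ParseError(f"{path}: {exc}") from exc


def _to_bio(rec: SeqRecord) -> _BioSeqRecord:
    out = _BioSeqRecord(_BioSeq(rec.seq), id=rec.id, description=rec.description)
    if rec.quals is not None:
        out.letter_annotations["phred_quality"] = list(rec.quals)
    return out


def write_fastx(records: Iterable[SeqRecord], path: str | Path, format: str = "fasta") -> int:
    """Write records as FASTA or FASTQ (gzipped when the path ends in .gz).

    Returns the number of records written. FASTQ requires qualities.
    """
    if format not in ("fasta", "fastq"):
        raise ValueError(f"unsupported format {format!r}")
    n = 0
    with _open_text(path, "wt") as fh:
        for rec in records:
            if format == "fastq" and rec.quals is None:
                raise ValueError(f"record {rec.id!r} has no qualities; cannot write FASTQ")
            _BioSeqIO.write(_to_bio(rec), fh, format)
            n += 1
    return n


def filter_reads(
    reads: Iterable[SeqRecord],
    params: QCParams = QCParams(),
    stats: Optional[FilterStats] = None,
) -> Iterator[SeqRecord]:
    """Yield reads passing the N-fraction and low-quality-fraction filters.

    A read is dropped iff its N fraction exceeds ``max_n_fraction`` or the
    fraction of bases with quality <= ``low_qual_threshold`` exceeds
    ``max_low_qual_fraction`` (both strictly). Pass a :class:`FilterStats`
    to collect kept/dropped counts and the clean-base total; it is updated
    in place as the stream is consumed.
    """
    if stats is None:
        stats = FilterStats()
    for read in reads:
        n = len(read)
        n_frac = read.seq.count("N") / n
        if n_frac > params.max_n_fraction:
            stats.dropped += 1
            stats.dropped_n += 1
            continue
        if read.quals is None:
            raise ValueError(
                f"read {read.id!r} has no quality scores; quality filtering "
                "requires FASTQ input"
            )
        low = sum(1 for q in read.quals if q <= params.low_qual_threshold)
        if low / n > params.max_low_qual_fraction:
            stats.dropped += 1
            stats.dropped_quality += 1
            continue
        stats.kept += 1
        stats.clean_bases += n
        yield read


def read_genbank_reference(path: str | Path):
    """Parse the subset of a GenBank record the mitochondrial pipeline needs.

    Returns ``(seq, topology, cds_list)`` where ``cds_list`` holds
    ``(gene_name, [(start, end, strand), ...], translation)`` tuples with
    0-based half-open exon coordinates. Only CDS features carrying both a
    /gene and a /translation qualifier are kept; all other annotation is
    ignored.
    """
    rec = _BioSeqIO.read(str(path), "genbank")
    topology = rec.annotations.get("topology", "linear")
    cds = []
    for feat in rec.features:
        if feat.type != "CDS":
            continue
        gene = feat.qualifiers.get("gene", [None])[0]
        translation = feat.qualifiers.get("translation", [None])[0]
        if gene is None or translation is None:
            continue
        spans = [
            (int(part.start), int(part.end), int(part.strand or 1))
            for part in feat.location.parts
        ]
        cds.append((gene, spans, translation))
    return str(rec.seq).upper(), topology, cds
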
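"""Sequence I/O and elementary sequence statistics.

Reads and writes FASTA and 4-line FASTQ (gzip-transparent on input), with a
closed DNA alphabet {A, C, G, T, N}: sequences are uppercased on ingestion and
every other IUPAC ambiguity code is mapped to N.  All coordinates elsewhere in
the package are 0-based, half-open.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Iterator

from Bio.SeqIO.FastaIO import SimpleFastaParser
from Bio.SeqIO.QualityIO import FastqGeneralIterator

__all__ = [
    "SequenceRecord",
    "FormatError",
    "read_fasta",
    "read_fastq",
    "write_fasta",
    "write_fastq",
    "gc_percent",
    "at_percent",
    "reverse_complement",
]

_ALPHABET = set("ACGTN")

# uppercase + map any non-ACGT symbol (IUPAC ambiguity codes, gaps, ...) to N
_CLEAN = {}
for _i in range(256):
    _c = chr(_i).upper()
    _CLEAN[_i] = _c if _c in "ACGT" else "N"
_CLEAN_TABLE = str.maketrans(_CLEAN)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

ORIGIN_TAG = "origin="


class FormatError(ValueError):
    """Raised for malformed FASTA/FASTQ input."""


@dataclass
class SequenceRecord:
    """One named nucleotide sequence (genome, fragment, or read).

    ``qualities`` is carried verbatim and never interpreted.  ``origin_label``
    is a truth tag naming the source genome, set by the library simulator and
    round-tripped through FASTQ headers as ``origin=<genome_id>``.
    """

    id: str
    sequence: str
    qualities: str | None = None
    origin_label: str | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise FormatError(f"record {self.id!r}: empty sequence")
        if self.qualities is not None and len(self.qualities) != len(self.sequence):
            raise FormatError(
                f"record {self.id!r}: sequence length {len(self.sequence)} != "
                f"quality length {len(self.qualities)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


def clean_sequence(raw: str) -> str:
    """Uppercase and collapse the alphabet to {A,C,G,T,N}."""
    return raw.translate(_CLEAN_TABLE)


def _open_text(path: str | Path) -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_fasta(path: str | Path) -> Iterator[SequenceRecord]:
    """Stream records from a FASTA file (possibly gzipped).

    Sequences are uppercased; non-ACGTN characters become N.  A header without
    sequence raises :class:`FormatError` naming the record.
    """
    with _open_text(path) as handle:
        for title, seq in SimpleFastaParser(handle):
            rec_id = title.split()[0] if title.split() else title
            if not seq:
                raise FormatError(f"FASTA record {rec_id!r}: empty sequence")
            yield SequenceRecord(id=rec_id, sequence=clean_sequence(seq),
                                 origin_label=_parse_origin(title))


def read_fastq(path: str | Path) -> Iterator[SequenceRecord]:
    """Stream records from a 4-line FASTQ file (possibly gzipped).

    Enforces sequence/quality length equality; a truncated or mismatched
    record raises :class:`FormatError` with its 0-based record index.
    """
    with _open_text(path) as handle:
        index = 0
        try:
            for title, seq, qual in FastqGeneralIterator(handle):
                if len(seq) != len(qual):
                    raise FormatError(
                        f"FASTQ record {index} ({title.split()[0]!r}): "
                        f"sequence/quality length mismatch"
                    )
                if not seq:
                    raise FormatError(f"FASTQ record {index}: empty sequence")
                yield SequenceRecord(
                    id=title.split()[0],
                    sequence=clean_sequence(seq),
                    qualities=qual,
                    origin_label=_parse_origin(title),
                )
                index += 1
        except ValueError as exc:  # Biopython signals truncation/garbling
            if isinstance(exc, FormatError):
                raise
            raise FormatError(f"FASTQ record {index}: {exc}") from exc


def _parse_origin(title: str) -> str | None:
    for token in title.split()[1:]:
        if token.startswith(ORIGIN_TAG):
            return token[len(ORIGIN_TAG):]
    return None


def _title(record: SequenceRecord) -> str:
    if record.origin_label is not None:
        return f"{record.id} {ORIGIN_TAG}{record.origin_label}"
    return record.id


def write_fasta(records: Iterable[SequenceRecord], path: str | Path,
                width: int = 70) -> int:
    """Write records as FASTA; returns the number written."""
    n = 0
    with open(path, "w") as handle:
        for rec in records:
            handle.write(f">{_title(rec)}\n")
            for i in range(0, len(rec.sequence), width):
                handle.write(rec.sequence[i:i + width] + "\n")
            n += 1
    return n


def write_fastq(records: Iterable[SequenceRecord], path: str | Path) -> int:
    """Write records as 4-line FASTQ; records lacking qualities get 'I' bases."""
    n = 0
    with open(path, "w") as handle:
        for rec in records:
            qual = rec.qualities if rec.qualities is not None else "I" * len(rec)
            handle.write(f"@{_title(rec)}\n{rec.sequence}\n+\n{qual}\n")
            n += 1
    return n


def _as_sequence(item: SequenceRecord | str) -> str:
    return item.sequence if isinstance(item, SequenceRecord) else item


def gc_percent(records: Iterable[SequenceRecord | str] | SequenceRecord | str) -> float:
    """Pooled percent GC of one or more sequences.

    Computed as 100·(G+C)/(A+C+G+T); N is excluded from both numerator and
    denominator.  Raises ``ValueError`` if no unambiguous base is present.
    """
    if isinstance(records, (SequenceRecord, str)):
        records = [records]
    gc = 0
    acgt = 0
    for item in records:
        seq = _as_sequence(item)
        g = seq.count("G") + seq.count("C")
        gc += g
        acgt += g + seq.count("A") + seq.count("T")
    if acgt == 0:
        raise ValueError("GC content undefined: no unambiguous (A/C/G/T) bases")
    return 100.0 * gc / acgt


def at_percent(records: Iterable[SequenceRecord | str] | SequenceRecord | str) -> float:
    """Pooled percent AT, the complement of :func:`gc_percent` for N-free input."""
    if isinstance(records, (SequenceRecord, str)):
        records = [records]
    at = 0
    acgt = 0
    for item in records:
        seq = _as_sequence(item)
        a = seq.count("A") + seq.count("T")
        at += a
        acgt += a + seq.count("G") + seq.count("C")
    if acgt == 0:
        raise ValueError("AT content undefined: no unambiguous (A/C/G/T) bases")
    return 100.0 * at / acgt


def reverse_complement(sequence: str) -> str:
    """Reverse complement over {A,C,G,T,N} (N ↔ N)."""
    invalid = set(sequence) - _ALPHABET
    if invalid:
        raise ValueError(f"non-ACGTN characters in sequence: {sorted(invalid)}")
    return sequence.translate(_COMPLEMENT)[::-1]
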
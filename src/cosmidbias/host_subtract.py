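"""Exact-identity subtraction of host-genome and vector reads.

Large-insert libraries propagated in E. coli are sequenced together with
substantial host chromosomal DNA and vector backbone; both must be removed
before any compositional statistic (percent GC, promoter content, taxon
abundance).  This module removes a read iff its full sequence occurs exactly
— 100 % identity over the entire read length, on either strand — somewhere in
a reference.  This is the strictest reading of a "conservative criterion of
100 % identity": a local aligner could also drop reads with perfect partial
matches, so removal counts here are a lower bound on what partial-span
screens report.

References flagged circular (vectors, most bacterial chromosomes) are matched
across the origin junction.  Reads containing N are never removed, since N
cannot match any base at 100 % identity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .seqio import SequenceRecord, reverse_complement

__all__ = ["ReferenceIndex", "SubtractionReport", "subtract_reads",
           "build_reference_index"]


class ReferenceIndex:
    """Exact-window membership index over a set of reference sequences.

    Answers "does this ``read_length`` window occur anywhere in any reference,
    either strand?" exactly, via a hash set of all forward-strand windows
    (the query checks both the window and its reverse complement).
    """

    def __init__(
        self,
        references: Sequence[SequenceRecord],
        read_length: int,
        circular: Sequence[bool] | None = None,
    ) -> None:
        if read_length < 1:
            raise ValueError("read_length must be >= 1")
        if circular is None:
            circular = [False] * len(references)
        if len(circular) != len(references):
            raise ValueError("one circular flag per reference required")
        if references and all(len(r.sequence) < read_length for r in references):
            raise ValueError(
                f"read_length {read_length} exceeds every reference length"
            )
        self.read_length = read_length
        self.reference_ids = [r.id for r in references]
        self._windows: set[str] = set()
        for ref, circ in zip(references, circular):
            seq = ref.sequence
            if circ:
                # wrap so windows spanning the origin junction are indexed
                seq = seq + seq[: read_length - 1]
            for i in range(len(seq) - read_length + 1):
                self._windows.add(seq[i:i + read_length])

    def __contains__(self, window: str) -> bool:
        if len(window) != self.read_length or "N" in window:
            return False
        return window in self._windows or reverse_complement(window) in self._windows

    def __len__(self) -> int:
        return len(self._windows)


def build_reference_index(
    references: Sequence[SequenceRecord],
    read_length: int,
    circular: Sequence[bool] | None = None,
) -> ReferenceIndex:
    """Build an exact either-strand window index (see :class:`ReferenceIndex`)."""
    return ReferenceIndex(references, read_length, circular)


@dataclass
class SubtractionReport:
    """Read-level accounting of a subtraction run.

    A read matching several references is attributed to the earliest matching
    reference in the provided order (host before vector, by convention) and is
    counted exactly once, so the counts always sum to ``total_reads``.
    """

    total_reads: int = 0
    removed_by_reference: dict[str, int] = field(default_factory=dict)
    kept_reads: int = 0

    @property
    def removed_host(self) -> int:
        """Reads attributed to the first reference (the host genome)."""
        ids = list(self.removed_by_reference)
        return self.removed_by_reference[ids[0]] if ids else 0

    @property
    def removed_vector(self) -> int:
        """Reads attributed to any reference after the first (the vector(s))."""
        ids = list(self.removed_by_reference)
        return sum(self.removed_by_reference[i] for i in ids[1:])

    @property
    def removed_total(self) -> int:
        return sum(self.removed_by_reference.values())

    @property
    def removed_percent(self) -> float:
        if self.total_reads == 0:
            return 0.0
        return 100.0 * self.removed_total / self.total_reads


def subtract_reads(
    reads: Iterable[SequenceRecord],
    references: Sequence[SequenceRecord],
    circular_flags: Sequence[bool] | None = None,
) -> tuple[list[SequenceRecord], SubtractionReport]:
    """Remove reads that match a reference at 100 % identity over their full
    length, either strand.

    Mates of a pair are evaluated independently.  Reads of different lengths
    are handled by building one window index per observed length, on demand.
    Returns the kept reads (input order preserved) and a
    :class:`SubtractionReport`.
    """
    if circular_flags is None:
        circular_flags = [False] * len(references)
    report = SubtractionReport(
        removed_by_reference={r.id: 0 for r in references}
    )
    per_ref_indexes: dict[int, list[ReferenceIndex]] = {}

    def indexes_for(length: int) -> list[ReferenceIndex]:
        cached = per_ref_indexes.get(length)
        if cached is None:
            cached = [
                ReferenceIndex([ref], length, [circ])
                for ref, circ in zip(references, circular_flags)
                if len(ref.sequence) >= length
            ]
            per_ref_indexes[length] = cached
        return cached

    kept: list[SequenceRecord] = []
    for read in reads:
        report.total_reads += 1
        matched = None
        if "N" not in read.sequence:
            for index in indexes_for(len(read.sequence)):
                if read.sequence in index:
                    matched = index.reference_ids[0]
                    break
        if matched is None:
            kept.append(read)
            report.kept_reads += 1
        else:
            report.removed_by_reference[matched] += 1
    return kept, report
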
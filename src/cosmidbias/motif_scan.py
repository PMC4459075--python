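"""Sigma-factor consensus motif definitions, scanning, and background models.

A motif is a list of conserved blocks interleaved with bounded variable-length
spacers, e.g. the sigma-70 (rpoD) housekeeping consensus TTGACA·N15–19·TATAAT
(the −35 hexamer, a 15–19 nt spacer, and the −10 Pribnow box).  Conserved
positions are sets over {A,C,G,T} (a two-base set such as [A/T] is a
degenerate class); spacer positions match any base including N, while N never
satisfies a conserved position.

Matching semantics (documented prominently because they change the counts):
scanning is left-to-right and **leftmost**; at a given start the spacer is
**greedy** (the longest admissible spacer vector that completes a match is the
one reported, earlier spacers taking priority); matches are
**non-overlapping** — after a hit, scanning resumes immediately after its end.
One start yields at most one hit even when several spacer lengths would match.
Minus-strand hits are found by scanning the reverse complement and are
reported with strand "−" and coordinates on the forward sequence.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Literal, Sequence

import pandas as pd

from .seqio import SequenceRecord, reverse_complement

__all__ = [
    "SigmaFactorMotif",
    "MotifHit",
    "PromoterContentTable",
    "builtin_motifs",
    "parse_motif",
    "load_motifs",
    "scan_sequence",
    "scan_dataset",
    "expected_hits_per_mb",
    "hits_to_frame",
]

StrandMode = Literal["forward_only", "both"]

FORWARD_ONLY: StrandMode = "forward_only"
BOTH: StrandMode = "both"

_MAX_SPACER_RANGE = 32


PositionSet = frozenset
Block = tuple[PositionSet, ...]


@dataclass(frozen=True)
class SigmaFactorMotif:
    """A multi-block degenerate consensus with bounded variable spacers.

    ``blocks[i]`` is an ordered tuple of position-sets; ``spacers[i]`` is the
    inclusive (min, max) spacer length range between ``blocks[i]`` and
    ``blocks[i+1]``.  Two blocks and one spacer is the common case; a third
    block (second spacer) accommodates consensuses such as the Bacteroides
    primary sigma factor.
    """

    name: str
    blocks: tuple[Block, ...]
    spacers: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if len(self.blocks) < 2:
            raise ValueError(f"motif {self.name!r}: needs at least two blocks")
        if len(self.spacers) != len(self.blocks) - 1:
            raise ValueError(
                f"motif {self.name!r}: {len(self.blocks)} blocks require "
                f"{len(self.blocks) - 1} spacer ranges, got {len(self.spacers)}"
            )
        for block in self.blocks:
            if not block or any(not pos for pos in block):
                raise ValueError(f"motif {self.name!r}: empty block or position-set")
            for pos in block:
                if not pos <= frozenset("ACGT"):
                    raise ValueError(
                        f"motif {self.name!r}: position-set {set(pos)} not over ACGT"
                    )
        for lo, hi in self.spacers:
            if lo < 0 or hi < lo:
                raise ValueError(f"motif {self.name!r}: invalid spacer range ({lo},{hi})")
            if hi - lo > _MAX_SPACER_RANGE:
                raise ValueError(
                    f"motif {self.name!r}: spacer range width {hi - lo} exceeds "
                    f"{_MAX_SPACER_RANGE}"
                )

    @property
    def block_length(self) -> int:
        """Total number of conserved positions."""
        return sum(len(b) for b in self.blocks)

    @property
    def min_span(self) -> int:
        return self.block_length + sum(lo for lo, _ in self.spacers)

    @property
    def max_span(self) -> int:
        return self.block_length + sum(hi for _, hi in self.spacers)

    @property
    def n_spacer_combinations(self) -> int:
        return math.prod(hi - lo + 1 for lo, hi in self.spacers)

    def consensus_string(self) -> str:
        """Human-readable pattern, e.g. ``TTGACA N15-19 TATAAT``."""
        parts = []
        for i, block in enumerate(self.blocks):
            parts.append("".join(
                next(iter(p)) if len(p) == 1 else "[" + "/".join(sorted(p)) + "]"
                for p in block
            ))
            if i < len(self.spacers):
                lo, hi = self.spacers[i]
                parts.append(f"N{lo}" if lo == hi else f"N{lo}-{hi}")
        return " ".join(parts)


@dataclass(frozen=True)
class MotifHit:
    """One motif occurrence, with 0-based half-open forward-strand coordinates."""

    sequence_id: str
    motif_name: str
    strand: str  # "+" or "-"
    start: int
    end: int
    spacer_lengths: tuple[int, ...]
    matched_text: str  # as read along the matching strand


@dataclass
class PromoterContentTable:
    """Per-sample, per-motif hit counts normalized to hits per megabase."""

    sample_name: str
    hit_counts: dict[str, int]
    megabases_scanned: float
    strands: StrandMode = BOTH

    def __post_init__(self) -> None:
        if self.megabases_scanned <= 0:
            raise ValueError("megabases_scanned must be positive")

    @property
    def hits_per_mb(self) -> dict[str, float]:
        return {m: c / self.megabases_scanned for m, c in self.hit_counts.items()}

    def to_frame(self) -> pd.DataFrame:
        per_mb = self.hits_per_mb
        return pd.DataFrame(
            {
                "sample": self.sample_name,
                "motif": list(self.hit_counts),
                "hit_count": list(self.hit_counts.values()),
                "megabases_scanned": self.megabases_scanned,
                "hits_per_mb": [per_mb[m] for m in self.hit_counts],
            }
        )


_BLOCK_TOKEN = re.compile(r"([ACGT]|\[[ACGT](?:/[ACGT])+\])")
_SPACER_TOKEN = re.compile(r"^N(\d+)(?:[-–](\d+))?$")


def _parse_block(token: str) -> Block:
    pos_sets: list[PositionSet] = []
    rest = token
    while rest:
        m = _BLOCK_TOKEN.match(rest)
        if m is None:
            raise ValueError(f"cannot parse motif block {token!r}")
        sym = m.group(1)
        if sym.startswith("["):
            pos_sets.append(frozenset(sym[1:-1].split("/")))
        else:
            pos_sets.append(frozenset(sym))
        rest = rest[m.end():]
    return tuple(pos_sets)


def parse_motif(name: str, pattern: str) -> SigmaFactorMotif:
    """Build a motif from consensus notation.

    ``pattern`` alternates blocks and spacer tokens, whitespace-separated:
    ``"TTGACA N15-19 TATAAT"``.  Degenerate classes are written ``[A/T]``.
    """
    blocks: list[Block] = []
    spacers: list[tuple[int, int]] = []
    expect_block = True
    for token in pattern.split():
        spacer = _SPACER_TOKEN.match(token)
        if spacer is not None:
            if expect_block:
                raise ValueError(f"motif {name!r}: consecutive spacers in {pattern!r}")
            lo = int(spacer.group(1))
            hi = int(spacer.group(2)) if spacer.group(2) else lo
            spacers.append((lo, hi))
            expect_block = True
        else:
            if not expect_block:
                raise ValueError(f"motif {name!r}: consecutive blocks in {pattern!r}")
            blocks.append(_parse_block(token))
            expect_block = False
    return SigmaFactorMotif(name=name, blocks=tuple(blocks), spacers=tuple(spacers))


def builtin_motifs() -> list[SigmaFactorMotif]:
    """The five sigma-factor consensus patterns scanned by the pipeline.

    rpoD (sigma-70) is the constitutive housekeeping factor; rpoE (sigma-24),
    rpoH (sigma-32) and rpoN (sigma-54, GC-rich) are E. coli controls, and
    sigABfr is the Bacteroides primary sigma factor (not recognized by
    E. coli polymerase).
    """
    return [
        parse_motif("rpoD", "TTGACA N15-19 TATAAT"),
        parse_motif("rpoE", "GGAACTT N15-19 TCAAA"),
        parse_motif("rpoH", "TTG[A/T][A/T][A/T] N13-14 CCCCAT[A/T]T"),
        parse_motif("rpoN", "TGGCA N7 TGC"),
        parse_motif("sigABfr", "TTTG N19-21 TA N2 TTTG"),
    ]


def load_motifs(path: str | Path) -> list[SigmaFactorMotif]:
    """Load motifs from a two-column TSV (name, consensus pattern).

    Lines starting with ``#`` are comments.  Pattern syntax as in
    :func:`parse_motif`.
    """
    motifs = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 'name<TAB>pattern'")
            motifs.append(parse_motif(parts[0], parts[1]))
    return motifs


# --- scanning ---------------------------------------------------------------

_REGEX_CACHE: dict[tuple, re.Pattern] = {}


def _compiled(motif: SigmaFactorMotif) -> re.Pattern:
    key = (motif.blocks, motif.spacers)
    rx = _REGEX_CACHE.get(key)
    if rx is None:
        parts = []
        for i, block in enumerate(motif.blocks):
            for pos in block:
                if len(pos) == 1:
                    parts.append(next(iter(pos)))
                else:
                    parts.append("[" + "".join(sorted(pos)) + "]")
            if i < len(motif.spacers):
                lo, hi = motif.spacers[i]
                # greedy bounded repetition: backtracking prefers the longest
                # spacer that still completes the match, earlier spacers first
                parts.append("([ACGTN]{%d,%d})" % (lo, hi))
        rx = re.compile("".join(parts))
        _REGEX_CACHE[key] = rx
    return rx


def _scan_forward(sequence: str, motif: SigmaFactorMotif) -> Iterator[tuple[int, int, tuple[int, ...], str]]:
    rx = _compiled(motif)
    for m in rx.finditer(sequence):
        spacers = tuple(len(g) for g in m.groups())
        yield m.start(), m.end(), spacers, m.group(0)


def scan_sequence(
    record: SequenceRecord | str,
    motif: SigmaFactorMotif,
    strands: StrandMode = BOTH,
) -> list[MotifHit]:
    """All hits of ``motif`` in one sequence under the leftmost/greedy/
    non-overlapping semantics described in the module docstring.

    Returns hits sorted by (strand, start), plus strand first.  Minus-strand
    hits carry forward-sequence coordinates; their ``matched_text`` is the
    motif as read on the minus strand.
    """
    if isinstance(record, str):
        record = SequenceRecord(id="<anonymous>", sequence=record)
    seq = record.sequence
    hits = [
        MotifHit(record.id, motif.name, "+", s, e, sp, text)
        for s, e, sp, text in _scan_forward(seq, motif)
    ]
    if strands == BOTH:
        rc = reverse_complement(seq)
        L = len(seq)
        minus = [
            MotifHit(record.id, motif.name, "-", L - e, L - s, sp, text)
            for s, e, sp, text in _scan_forward(rc, motif)
        ]
        minus.sort(key=lambda h: h.start)
        hits.extend(minus)
    elif strands != FORWARD_ONLY:
        raise ValueError(f"unknown strand mode {strands!r}")
    return hits


def scan_dataset(
    records: Iterable[SequenceRecord],
    motifs: Sequence[SigmaFactorMotif] | None = None,
    strands: StrandMode = BOTH,
    sample_name: str = "sample",
) -> PromoterContentTable:
    """Count motif hits over a whole read/contig set, normalized per Mb.

    Each hit must lie wholly within a single record (reads are never joined).
    ``megabases_scanned`` is total bases / 1e6, counted once regardless of the
    strand mode.
    """
    if motifs is None:
        motifs = builtin_motifs()
    counts = {m.name: 0 for m in motifs}
    total_bases = 0
    for rec in records:
        total_bases += len(rec.sequence)
        for motif in motifs:
            counts[motif.name] += len(scan_sequence(rec, motif, strands))
    if total_bases == 0:
        raise ValueError(f"sample {sample_name!r}: zero bases scanned")
    return PromoterContentTable(
        sample_name=sample_name,
        hit_counts=counts,
        megabases_scanned=total_bases / 1e6,
        strands=strands,
    )


def expected_hits_per_mb(
    motif: SigmaFactorMotif,
    gc: float,
    strands: StrandMode = BOTH,
) -> float:
    """Expected motif hits per Mb of i.i.d. sequence at a given GC fraction.

    Under a background with P(A)=P(T)=(1−gc)/2 and P(G)=P(C)=gc/2, the
    per-position match probability is the number of admissible spacer-length
    combinations times the product over conserved positions of
    P(base ∈ position-set); the expectation per Mb multiplies by 1e6 and by 2
    when both strands are scanned.  Overlap and non-independence corrections
    are ignored (rare-motif regime), so this is an upper-tail-accurate
    approximation for sparse motifs, not an exact count distribution.
    """
    if not 0.0 < gc < 1.0:
        raise ValueError(f"gc must be in (0,1), got {gc}")
    base_p = {"A": (1 - gc) / 2, "T": (1 - gc) / 2, "G": gc / 2, "C": gc / 2}
    p = 1.0
    for block in motif.blocks:
        for pos in block:
            p *= sum(base_p[b] for b in pos)
    p *= motif.n_spacer_combinations
    factor = 2.0 if strands == BOTH else 1.0
    return p * 1e6 * factor


def hits_to_frame(hits: Iterable[MotifHit]) -> pd.DataFrame:
    """Tabulate hits (one row per hit) for TSV export."""
    rows = [
        {
            "sequence_id": h.sequence_id,
            "motif": h.motif_name,
            "strand": h.strand,
            "start": h.start,
            "end": h.end,
            "spacer_lengths": ",".join(map(str, h.spacer_lengths)),
            "matched_text": h.matched_text,
        }
        for h in hits
    ]
    return pd.DataFrame(
        rows,
        columns=["sequence_id", "motif", "strand", "start", "end",
                 "spacer_lengths", "matched_text"],
    )
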
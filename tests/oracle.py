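"""Independent brute-force motif-scanning oracle used by the tests.

Enumerates every (start, spacer-length-vector) candidate by direct per-position
set membership over numpy-coded sequences — no pattern engine involved — then
applies the same published match policy: leftmost start wins; at a start the
lexicographically largest spacer vector wins (greedy, earlier spacers take
priority); after a hit, scanning resumes at its end (non-overlapping).
"""

from __future__ import annotations

import itertools

import numpy as np

from cosmidbias.motif_scan import SigmaFactorMotif
from cosmidbias.seqio import reverse_complement


def _candidate_starts(codes: np.ndarray, motif: SigmaFactorMotif,
                      spacer_vector: tuple[int, ...]) -> np.ndarray:
    """All starts where the motif matches with exactly this spacer vector."""
    span = motif.block_length + sum(spacer_vector)
    n = codes.size - span + 1
    if n <= 0:
        return np.empty(0, dtype=int)
    ok = np.ones(n, dtype=bool)
    offset = 0
    for i, block in enumerate(motif.blocks):
        for pos_set in block:
            allowed = np.zeros(256, dtype=bool)
            for base in pos_set:
                allowed[ord(base)] = True
            ok &= allowed[codes[offset:offset + n]]
            offset += 1
        if i < len(spacer_vector):
            offset += spacer_vector[i]
    return np.nonzero(ok)[0]


def brute_force_scan(sequence: str, motif: SigmaFactorMotif
                     ) -> list[tuple[int, int, tuple[int, ...]]]:
    """Forward-strand hits as (start, end, spacer_vector) under the
    leftmost / greedy / non-overlapping policy."""
    codes = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
    spacer_vectors = list(itertools.product(
        *[range(lo, hi + 1) for lo, hi in motif.spacers]
    ))
    # candidates[start] -> list of matching spacer vectors
    candidates: dict[int, list[tuple[int, ...]]] = {}
    for vec in spacer_vectors:
        for start in _candidate_starts(codes, motif, vec):
            candidates.setdefault(int(start), []).append(vec)
    hits = []
    cursor = 0
    for start in sorted(candidates):
        if start < cursor:
            continue
        vec = max(candidates[start])  # lexicographic max = greedy
        end = start + motif.block_length + sum(vec)
        hits.append((start, end, vec))
        cursor = end
    return hits


def brute_force_scan_both(sequence: str, motif: SigmaFactorMotif
                          ) -> list[tuple[str, int, int, tuple[int, ...]]]:
    """Both-strand hits as (strand, start, end, spacer_vector) with minus-strand
    coordinates mapped onto the forward sequence."""
    out = [("+", s, e, v) for s, e, v in brute_force_scan(sequence, motif)]
    L = len(sequence)
    rc_hits = brute_force_scan(reverse_complement(sequence), motif)
    out.extend(sorted(("-", L - e, L - s, v) for s, e, v in rc_hits))
    return out
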
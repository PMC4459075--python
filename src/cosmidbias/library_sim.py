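"""Generative stand-in for large-insert library construction.

Emulates the wet-lab pipeline that turns a microbial community into a cosmid
library: community DNA is fragmented (a high-molecular-weight pool plus a
sheared-debris component), size-selected to a window (default ~40–70 kb),
cloned with a promoter-dependent loss model, and sequenced as short paired-end
reads (default 90 bases) carrying truth labels.

The clone-loss model is the package's hypothesis made operational: each
fragment carries k sigma-70 (rpoD) consensus promoter sites (counted on both
strands, since insert orientation in the vector is random), and survives
cloning independently with probability exp(−λ·k).  An independent per-promoter
hazard is the simplest monotone form in which constitutive transcription from
cloned inserts destabilizes the clone, and it makes λ identifiable from the
fragment truth table.

All stages are deterministic given the top-level seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import motif_scan, seqio
from .seqio import SequenceRecord, reverse_complement

__all__ = [
    "CommunityGenomeSpec",
    "CommunityGenome",
    "Fragment",
    "SimulationParams",
    "ExperimentResult",
    "generate_genome",
    "generate_community",
    "extract_crude",
    "size_select",
    "clone_library",
    "simulate_reads",
    "run_experiment",
    "write_experiment",
    "estimate_retention_rate",
    "STAGES",
]

logger = logging.getLogger(__name__)

STAGES = ("crude_extract", "size_selected", "cosmid_library")

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_RPOD = motif_scan.builtin_motifs()[0]
assert _RPOD.name == "rpoD"

_PLANT_UPSTREAM = "TTGACA"
_PLANT_DOWNSTREAM = "TATAAT"
_PLANT_SPACER_RANGE = (15, 19)


def _random_dna(rng: np.random.Generator, length: int, gc: float) -> str:
    """i.i.d. DNA with P(G)=P(C)=gc/2, P(A)=P(T)=(1−gc)/2."""
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    codes = rng.choice(4, size=length, p=p)
    return _BASES[codes].tobytes().decode("ascii")


@dataclass(frozen=True)
class CommunityGenomeSpec:
    """Generative parameters of one community member."""

    genome_id: str
    length: int
    gc_target: float
    planted_rpoD: int = 0
    relative_abundance: float = 1.0


@dataclass
class CommunityGenome:
    """A generated genome with its measured sigma-70 consensus content."""

    genome_id: str
    length: int
    gc_target: float
    planted_rpoD: int
    relative_abundance: float
    sequence: str
    measured_rpoD: int

    def as_record(self) -> SequenceRecord:
        return SequenceRecord(id=self.genome_id, sequence=self.sequence)


@dataclass
class Fragment:
    """A piece of community DNA; ``rpoD_count`` is the both-strand hit count
    on the fragment, computed lazily and cached (it drives clone retention)."""

    genome_id: str
    start: int
    end: int
    sequence: str
    _rpoD_count: int | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.end - self.start != len(self.sequence):
            raise ValueError("fragment coordinates inconsistent with sequence length")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def rpoD_count(self) -> int:
        if self._rpoD_count is None:
            self._rpoD_count = len(
                motif_scan.scan_sequence(self.sequence, _RPOD, motif_scan.BOTH)
            )
        return self._rpoD_count


@dataclass
class SimulationParams:
    """All generative knobs of the library-construction stand-in.

    Defaults follow the study conditions: a 40–70 kb size-selection window,
    90-base paired-end reads from ~350 bp sequencing templates, error-free
    reads, and a unit per-promoter clone-loss rate λ=1.  The crude extract
    mixes high-molecular-weight fragments with a sheared-debris component
    (the "heavy smear" seen on a gel of crude DNA).
    """

    seed: int
    community: tuple[CommunityGenomeSpec, ...]
    n_fragments: int = 2000
    debris_fraction: float = 0.3
    hmw_length_range: tuple[int, int] = (30_000, 100_000)
    debris_length_range: tuple[int, int] = (500, 10_000)
    size_select_range: tuple[int, int] = (40_000, 70_000)
    retention_rate: float = 1.0  # λ, per-rpoD-hit clone-loss rate
    reads_per_sample: int = 5000  # read pairs per sequenced stage
    read_length: int = 90
    mate_gap: int = 170  # template = 2*read_length + mate_gap ≈ 350 bp
    substitution_rate: float = 0.0

    def __post_init__(self) -> None:
        if not self.community:
            raise ValueError("community must contain at least one genome spec")
        if not 0.0 <= self.debris_fraction <= 1.0:
            raise ValueError("debris_fraction must be in [0,1]")
        if self.retention_rate < 0:
            raise ValueError("retention rate λ must be >= 0")
        for name in ("hmw_length_range", "debris_length_range", "size_select_range"):
            lo, hi = getattr(self, name)
            if lo <= 0 or hi < lo:
                raise ValueError(f"{name}: invalid range ({lo}, {hi})")
        total = sum(s.relative_abundance for s in self.community)
        if abs(total - 1.0) > 1e-6:
            raise ValueError(
                f"relative abundances must sum to 1 (got {total:.6f})"
            )


def generate_genome(
    genome_id: str,
    length: int,
    gc_target: float,
    planted_rpoD: int,
    rng: np.random.Generator | int,
) -> CommunityGenome:
    """Generate one genome: i.i.d. background at ``gc_target`` with
    ``planted_rpoD`` sigma-70 consensus sites overwritten at non-overlapping
    uniform positions, each on a random strand with a random 15–19 nt spacer.

    The returned genome records its *measured* (scanned, both-strand) rpoD
    count, which is >= the planted count because chance background hits and
    plant/background juxtapositions can add occurrences.
    """
    if length < 1000:
        raise ValueError("genome length must be >= 1000")
    if not 0.0 <= gc_target <= 1.0:
        raise ValueError("gc_target must be in [0,1]")
    rng = np.random.default_rng(rng) if isinstance(rng, int) else rng
    seq = bytearray(_random_dna(rng, length, gc_target), "ascii")

    max_site = len(_PLANT_UPSTREAM) + _PLANT_SPACER_RANGE[1] + len(_PLANT_DOWNSTREAM)
    placed: list[tuple[int, int]] = []
    max_attempts = max(1000, 200 * planted_rpoD)
    attempts = 0
    while len(placed) < planted_rpoD:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError(
                f"genome {genome_id!r}: could not place {planted_rpoD} "
                f"non-overlapping rpoD sites in {length} bases"
            )
        spacer_len = int(rng.integers(_PLANT_SPACER_RANGE[0],
                                      _PLANT_SPACER_RANGE[1] + 1))
        site = (_PLANT_UPSTREAM + _random_dna(rng, spacer_len, gc_target)
                + _PLANT_DOWNSTREAM)
        if rng.random() < 0.5:
            site = reverse_complement(site)
        pos = int(rng.integers(0, length - max_site + 1))
        span = (pos, pos + len(site))
        if any(s < span[1] and span[0] < e for s, e in placed):
            continue
        seq[span[0]:span[1]] = site.encode("ascii")
        placed.append(span)

    sequence = seq.decode("ascii")
    measured = len(motif_scan.scan_sequence(sequence, _RPOD, motif_scan.BOTH))
    return CommunityGenome(
        genome_id=genome_id,
        length=length,
        gc_target=gc_target,
        planted_rpoD=planted_rpoD,
        relative_abundance=1.0,
        sequence=sequence,
        measured_rpoD=measured,
    )


def generate_community(
    specs: Sequence[CommunityGenomeSpec],
    rng: np.random.Generator | int,
) -> list[CommunityGenome]:
    """Generate every genome of a community spec (abundances must sum to 1)."""
    rng = np.random.default_rng(rng) if isinstance(rng, int) else rng
    total = sum(s.relative_abundance for s in specs)
    if abs(total - 1.0) > 1e-6:
        raise ValueError(f"relative abundances must sum to 1 (got {total:.6f})")
    genomes = []
    for spec in specs:
        g = generate_genome(spec.genome_id, spec.length, spec.gc_target,
                            spec.planted_rpoD, rng)
        g.relative_abundance = spec.relative_abundance
        genomes.append(g)
    return genomes


def extract_crude(
    community: Sequence[CommunityGenome],
    params: SimulationParams,
    rng: np.random.Generator | int,
) -> list[Fragment]:
    """Fragment the community into a crude-extract pool.

    Each of ``params.n_fragments`` fragments picks its source genome with
    probability equal to the genome's relative abundance (its share of
    community DNA), then draws a length from the debris distribution with
    probability ``debris_fraction`` and from the high-molecular-weight
    distribution otherwise; the start is uniform and fragments are truncated
    at the genome end.
    """
    rng = np.random.default_rng(rng) if isinstance(rng, int) else rng
    weights = np.array([g.relative_abundance for g in community], dtype=float)
    weights /= weights.sum()
    genome_idx = rng.choice(len(community), size=params.n_fragments, p=weights)
    is_debris = rng.random(params.n_fragments) < params.debris_fraction
    fragments: list[Fragment] = []
    for gi, debris in zip(genome_idx, is_debris):
        genome = community[int(gi)]
        lo, hi = (params.debris_length_range if debris
                  else params.hmw_length_range)
        frag_len = int(rng.integers(lo, hi + 1))
        start = int(rng.integers(0, genome.length))
        end = min(start + frag_len, genome.length)
        fragments.append(
            Fragment(genome_id=genome.genome_id, start=start, end=end,
                     sequence=genome.sequence[start:end])
        )
    return fragments


def size_select(
    fragments: Iterable[Fragment],
    size_select_range: tuple[int, int] = (40_000, 70_000),
) -> list[Fragment]:
    """Keep exactly the fragments whose length lies in the closed window
    (default ~40–70 kb, the pulsed-field electrophoresis cut); order preserved."""
    lo, hi = size_select_range
    return [f for f in fragments if lo <= len(f) <= hi]


def clone_library(
    fragments: Sequence[Fragment],
    retention_rate: float,
    rng: np.random.Generator | int,
) -> tuple[list[Fragment], pd.DataFrame]:
    """Clone fragments with promoter-dependent loss.

    Each fragment survives independently with probability exp(−λ·k), where k
    is its both-strand rpoD consensus count and λ = ``retention_rate``.
    Returns the surviving fragments and a truth table (one row per input
    fragment: genome_id, start, end, length, k, survived).
    """
    if retention_rate < 0:
        raise ValueError("retention rate λ must be >= 0")
    rng = np.random.default_rng(rng) if isinstance(rng, int) else rng
    rows = []
    retained = []
    for frag in fragments:
        k = frag.rpoD_count
        p_survive = float(np.exp(-retention_rate * k))
        survived = bool(rng.random() < p_survive)
        rows.append(
            {"genome_id": frag.genome_id, "start": frag.start, "end": frag.end,
             "length": len(frag), "k": k, "survived": survived}
        )
        if survived:
            retained.append(frag)
    table = pd.DataFrame(
        rows, columns=["genome_id", "start", "end", "length", "k", "survived"]
    )
    return retained, table


def simulate_reads(
    fragments: Sequence[Fragment],
    reads_per_sample: int,
    read_length: int,
    rng: np.random.Generator | int,
    mate_gap: int = 170,
    substitution_rate: float = 0.0,
    id_prefix: str = "r",
) -> list[SequenceRecord]:
    """Error-free (by default) paired-end reads from a fragment pool.

    Pairs are sampled over fragments weighted by fragment length; the forward
    mate starts uniformly, the reverse mate is the reverse complement of the
    window ``mate_gap`` bases downstream (mates overlap if the fragment is
    shorter than the full template).  Each read's ``origin_label`` is the
    fragment's source genome.  Fragments shorter than ``read_length`` are
    skipped with a logged warning count.  Substitution noise is opt-in.
    """
    rng = np.random.default_rng(rng) if isinstance(rng, int) else rng
    eligible = [f for f in fragments if len(f) >= read_length]
    n_skipped = len(fragments) - len(eligible)
    if n_skipped:
        logger.warning("simulate_reads: skipped %d fragments shorter than "
                       "read length %d", n_skipped, read_length)
    if not eligible:
        raise ValueError("no fragment is at least one read length long")
    lengths = np.array([len(f) for f in eligible], dtype=float)
    choice = rng.choice(len(eligible), size=reads_per_sample,
                        p=lengths / lengths.sum())
    template_len = 2 * read_length + mate_gap
    reads: list[SequenceRecord] = []
    for i, fi in enumerate(choice):
        frag = eligible[int(fi)]
        tlen = min(len(frag), template_len)
        start = int(rng.integers(0, len(frag) - tlen + 1))
        template = frag.sequence[start:start + tlen]
        fwd = template[:read_length]
        rev = reverse_complement(template[-read_length:])
        if substitution_rate > 0.0:
            fwd = _mutate(fwd, substitution_rate, rng)
            rev = _mutate(rev, substitution_rate, rng)
        qual = "I" * read_length
        reads.append(SequenceRecord(id=f"{id_prefix}{i}/1", sequence=fwd,
                                    qualities=qual, origin_label=frag.genome_id))
        reads.append(SequenceRecord(id=f"{id_prefix}{i}/2", sequence=rev,
                                    qualities=qual, origin_label=frag.genome_id))
    return reads


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    hit = np.nonzero(rng.random(arr.size) < rate)[0]
    for i in hit:
        current = arr[i]
        options = [b for b in _BASES if b != current]
        arr[i] = options[int(rng.integers(0, len(options)))]
    return arr.tobytes().decode("ascii")


@dataclass
class ExperimentResult:
    """Everything the three-stage simulation produced, with truth tables."""

    params: SimulationParams
    community: list[CommunityGenome]
    fragments: dict[str, list[Fragment]]
    reads: dict[str, list[SequenceRecord]]
    fragment_table: pd.DataFrame  # cloning input: genome_id,start,end,length,k,survived
    abundance_truth: pd.DataFrame  # stage, genome_id, base_share_percent
    stage_seeds: dict[str, int]


def _base_shares(fragments: Sequence[Fragment],
                 genome_ids: Sequence[str]) -> dict[str, float]:
    totals = {g: 0 for g in genome_ids}
    for f in fragments:
        totals[f.genome_id] += len(f)
    grand = sum(totals.values())
    if grand == 0:
        return {g: 0.0 for g in genome_ids}
    return {g: 100.0 * t / grand for g, t in totals.items()}


def run_experiment(params: SimulationParams) -> ExperimentResult:
    """Run the full pipeline: community → crude extract → size selection →
    promoter-dependent cloning → paired-end reads for each sequenced stage.

    Deterministic given ``params.seed``; per-stage child seeds are derived
    from it and logged in the result.
    """
    master = np.random.default_rng(params.seed)
    stage_seeds = {
        name: int(master.integers(0, 2**31))
        for name in ("genomes", "crude", "clone",
                     "reads_crude_extract", "reads_size_selected",
                     "reads_cosmid_library")
    }

    community = generate_community(params.community,
                                   np.random.default_rng(stage_seeds["genomes"]))
    crude = extract_crude(community, params,
                          np.random.default_rng(stage_seeds["crude"]))
    selected = size_select(crude, params.size_select_range)
    if not selected:
        raise ValueError("size selection retained no fragments; widen "
                         "hmw_length_range or the selection window")
    library, fragment_table = clone_library(
        selected, params.retention_rate,
        np.random.default_rng(stage_seeds["clone"]))
    if not library:
        raise ValueError("no fragment survived cloning; lower retention_rate "
                         "or the planted promoter density")

    pools = {"crude_extract": crude, "size_selected": selected,
             "cosmid_library": library}
    reads = {
        stage: simulate_reads(
            pool, params.reads_per_sample, params.read_length,
            np.random.default_rng(stage_seeds[f"reads_{stage}"]),
            mate_gap=params.mate_gap,
            substitution_rate=params.substitution_rate,
            id_prefix=f"{stage}_",
        )
        for stage, pool in pools.items()
    }

    genome_ids = [g.genome_id for g in community]
    truth_rows = []
    for stage, pool in pools.items():
        shares = _base_shares(pool, genome_ids)
        for g in genome_ids:
            truth_rows.append({"stage": stage, "genome_id": g,
                               "base_share_percent": shares[g]})
    abundance_truth = pd.DataFrame(
        truth_rows, columns=["stage", "genome_id", "base_share_percent"]
    )

    return ExperimentResult(
        params=params,
        community=community,
        fragments=pools,
        reads=reads,
        fragment_table=fragment_table,
        abundance_truth=abundance_truth,
        stage_seeds=stage_seeds,
    )


def write_experiment(result: ExperimentResult, outdir: str | Path) -> dict[str, Path]:
    """Write one FASTQ per sequenced stage plus TSV truth tables and a seed
    log; returns a manifest of written paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Path] = {}
    for stage in STAGES:
        path = outdir / f"{stage}.fastq"
        seqio.write_fastq(result.reads[stage], path)
        manifest[f"reads_{stage}"] = path
    frag_path = outdir / "fragment_table.tsv"
    result.fragment_table.to_csv(frag_path, sep="\t", index=False)
    manifest["fragment_table"] = frag_path
    truth_path = outdir / "abundance_truth.tsv"
    result.abundance_truth.to_csv(truth_path, sep="\t", index=False)
    manifest["abundance_truth"] = truth_path
    genome_path = outdir / "community_genomes.fasta"
    seqio.write_fasta([g.as_record() for g in result.community], genome_path)
    manifest["community_genomes"] = genome_path
    seed_path = outdir / "seeds.tsv"
    with open(seed_path, "w") as fh:
        fh.write("stage\tseed\n")
        fh.write(f"master\t{result.params.seed}\n")
        for stage, seed in result.stage_seeds.items():
            fh.write(f"{stage}\t{seed}\n")
    manifest["seeds"] = seed_path
    return manifest


def estimate_retention_rate(fragment_table: pd.DataFrame) -> float:
    """Recover the clone-loss rate λ from a fragment truth table.

    Fragments are grouped by promoter count k; for each group with informative
    empirical survival (0 < p̂ < 1, k > 0), −log(p̂) is regressed on k through
    the origin with inverse-variance weights n·p̂/(1−p̂) (the delta-method
    variance of −log p̂ under binomial survival).  k = 0 fragments carry no
    information about λ; degenerate groups (all survived or none survived)
    have no finite variance estimate and are excluded.
    """
    required = {"k", "survived"}
    if not required <= set(fragment_table.columns):
        raise ValueError(f"fragment table needs columns {sorted(required)}")
    grouped = fragment_table.groupby("k")["survived"].agg(["mean", "count"])
    num = 0.0
    den = 0.0
    for k, row in grouped.iterrows():
        p_hat, n = float(row["mean"]), float(row["count"])
        if k == 0 or p_hat <= 0.0 or p_hat >= 1.0:
            continue
        w = n * p_hat / (1.0 - p_hat)
        y = -np.log(p_hat)
        num += w * k * y
        den += w * k * k
    if den == 0.0:
        raise ValueError("no informative k group (need fragments with k > 0 "
                         "and intermediate survival)")
    return num / den
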
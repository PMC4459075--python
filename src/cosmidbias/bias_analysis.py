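"""Per-genome library bias: fold changes, genome features, and correlations.

A taxon's library bias is its change in percent abundance between two
sequenced samples — cosmid-library abundance divided by crude-extract
abundance — reported as a fold change and its log10.  Genomes absent from one
sample get a sentinel instead of a fold change: CE_0 (zero in the crude
extract) or CL_0 (zero in the cosmid library), with CE_0 taking precedence
when both are zero.

Genome features considered as bias predictors are percent GC and the density
of sigma-70 (rpoD) consensus promoter sites per Mb: AT-rich genomes carry more
rpoD-consensus-like sequence purely by chance, so GC may act merely as a proxy
for constitutive-promoter content.  ``correlate_bias`` quantifies which
feature tracks the observed bias better.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy import stats

from . import motif_scan, seqio
from .seqio import SequenceRecord

__all__ = [
    "AbundanceProfile",
    "GenomeProfile",
    "BiasRecord",
    "CorrelationReport",
    "abundance_from_labels",
    "compute_bias",
    "genome_profile",
    "correlate_bias",
    "fragments_per_genome",
    "bias_to_frame",
]


@dataclass
class AbundanceProfile:
    """Per-genome percent abundance in one sample (sums to 100)."""

    sample_name: str
    abundances: dict[str, float]

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.abundances.values()):
            raise ValueError("abundances must be non-negative")
        total = sum(self.abundances.values())
        if self.abundances and abs(total - 100.0) > 1e-6:
            raise ValueError(f"abundances must sum to 100 (got {total:.6f})")


@dataclass(frozen=True)
class GenomeProfile:
    """Genome-level bias predictors: percent GC and rpoD consensus density."""

    genome_id: str
    genome_length: int
    gc: float  # percent
    rpoD_count: int  # both-strand consensus hits in the whole genome

    @property
    def rpoD_per_mb(self) -> float:
        return self.rpoD_count / (self.genome_length / 1e6)


SENTINEL_NONE = "none"
SENTINEL_CE0 = "CE_0"
SENTINEL_CL0 = "CL_0"


@dataclass(frozen=True)
class BiasRecord:
    """One genome's representation change between crude extract (CE) and
    cosmid library (CL); ``fold_change`` is defined only when both abundances
    are nonzero (sentinel ``none``)."""

    genome_id: str
    abundance_CE: float
    abundance_CL: float
    sentinel: str = SENTINEL_NONE

    @property
    def fold_change(self) -> float | None:
        if self.sentinel != SENTINEL_NONE:
            return None
        return self.abundance_CL / self.abundance_CE

    @property
    def log10_fold_change(self) -> float | None:
        fc = self.fold_change
        return None if fc is None else math.log10(fc)


def abundance_from_labels(
    reads: Iterable[SequenceRecord],
    sample_name: str = "sample",
) -> AbundanceProfile:
    """Percent abundance per genome from simulator truth labels.

    Stands in for read-based taxonomic profiling when every read carries an
    ``origin_label``; an unlabeled read is an error.
    """
    counts: dict[str, int] = {}
    total = 0
    for read in reads:
        if read.origin_label is None:
            raise ValueError(f"read {read.id!r} has no origin label")
        counts[read.origin_label] = counts.get(read.origin_label, 0) + 1
        total += 1
    if total == 0:
        raise ValueError("no reads supplied")
    return AbundanceProfile(
        sample_name=sample_name,
        abundances={g: 100.0 * c / total for g, c in counts.items()},
    )


def compute_bias(
    profile_CE: AbundanceProfile,
    profile_CL: AbundanceProfile,
) -> list[BiasRecord]:
    """Fold change of percent abundance (cosmid library / crude extract) per
    genome over the union of both profiles (a missing genome counts as 0)."""
    genomes = sorted(set(profile_CE.abundances) | set(profile_CL.abundances))
    records = []
    for g in genomes:
        ce = profile_CE.abundances.get(g, 0.0)
        cl = profile_CL.abundances.get(g, 0.0)
        if ce == 0.0:
            sentinel = SENTINEL_CE0  # takes precedence when both are zero
        elif cl == 0.0:
            sentinel = SENTINEL_CL0
        else:
            sentinel = SENTINEL_NONE
        records.append(BiasRecord(genome_id=g, abundance_CE=ce,
                                  abundance_CL=cl, sentinel=sentinel))
    return records


def genome_profile(genome: SequenceRecord) -> GenomeProfile:
    """Percent GC and both-strand rpoD consensus count of one genome."""
    rpod = motif_scan.builtin_motifs()[0]
    hits = motif_scan.scan_sequence(genome, rpod, motif_scan.BOTH)
    return GenomeProfile(
        genome_id=genome.id,
        genome_length=len(genome.sequence),
        gc=seqio.gc_percent(genome),
        rpoD_count=len(hits),
    )


@dataclass(frozen=True)
class CorrelationReport:
    """How well GC and rpoD density predict log10 library bias.

    Correlations are computed over sentinel-free records only; the excluded
    counts per sentinel class are reported so the censoring is visible.
    """

    n_used: int
    n_excluded_CE0: int
    n_excluded_CL0: int
    pearson_gc: float
    pearson_gc_p: float
    pearson_rpoD: float
    pearson_rpoD_p: float
    spearman_gc: float
    spearman_gc_p: float
    spearman_rpoD: float
    spearman_rpoD_p: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"predictor": "gc", "method": "pearson",
                 "r": self.pearson_gc, "p": self.pearson_gc_p},
                {"predictor": "gc", "method": "spearman",
                 "r": self.spearman_gc, "p": self.spearman_gc_p},
                {"predictor": "rpoD_per_mb", "method": "pearson",
                 "r": self.pearson_rpoD, "p": self.pearson_rpoD_p},
                {"predictor": "rpoD_per_mb", "method": "spearman",
                 "r": self.spearman_rpoD, "p": self.spearman_rpoD_p},
            ]
        )


def correlate_bias(
    bias_records: Sequence[BiasRecord],
    genome_profiles: Sequence[GenomeProfile] | Mapping[str, GenomeProfile],
) -> CorrelationReport:
    """Pearson and Spearman correlation of log10 fold change against genome
    percent GC and against rpoD consensus density per Mb.

    Sentinel records (zero abundance in either sample) are excluded — a fold
    change is undefined for them — and at least three usable records are
    required.
    """
    if not isinstance(genome_profiles, Mapping):
        genome_profiles = {p.genome_id: p for p in genome_profiles}
    log_fc, gcs, densities = [], [], []
    n_ce0 = n_cl0 = 0
    for rec in bias_records:
        if rec.sentinel == SENTINEL_CE0:
            n_ce0 += 1
            continue
        if rec.sentinel == SENTINEL_CL0:
            n_cl0 += 1
            continue
        profile = genome_profiles.get(rec.genome_id)
        if profile is None:
            raise KeyError(f"no genome profile for {rec.genome_id!r}")
        log_fc.append(rec.log10_fold_change)
        gcs.append(profile.gc)
        densities.append(profile.rpoD_per_mb)
    if len(log_fc) < 3:
        raise ValueError(
            f"need >= 3 sentinel-free records to correlate (got {len(log_fc)})"
        )
    p_gc = stats.pearsonr(log_fc, gcs)
    p_rp = stats.pearsonr(log_fc, densities)
    s_gc = stats.spearmanr(log_fc, gcs)
    s_rp = stats.spearmanr(log_fc, densities)
    return CorrelationReport(
        n_used=len(log_fc),
        n_excluded_CE0=n_ce0,
        n_excluded_CL0=n_cl0,
        pearson_gc=float(p_gc.statistic), pearson_gc_p=float(p_gc.pvalue),
        pearson_rpoD=float(p_rp.statistic), pearson_rpoD_p=float(p_rp.pvalue),
        spearman_gc=float(s_gc.statistic), spearman_gc_p=float(s_gc.pvalue),
        spearman_rpoD=float(s_rp.statistic), spearman_rpoD_p=float(s_rp.pvalue),
    )


def fragments_per_genome(genome_length: float, mean_insert_length: float) -> int:
    """How many library inserts tile one genome: genome length divided by the
    mean insert length, rounded to the nearest integer.

    E.g. a 2.25 Mb genome at ~28 kb mean insert is covered by ~80 fragments,
    so even a modest per-fragment promoter count exposes most of the genome to
    promoter-driven clone loss.
    """
    if genome_length <= 0 or mean_insert_length <= 0:
        raise ValueError("genome_length and mean_insert_length must be positive")
    return round(genome_length / mean_insert_length)


def bias_to_frame(records: Sequence[BiasRecord]) -> pd.DataFrame:
    """Tabulate bias records for TSV export (sentinels kept as labels)."""
    rows = []
    for r in records:
        rows.append({
            "genome_id": r.genome_id,
            "abundance_CE": r.abundance_CE,
            "abundance_CL": r.abundance_CL,
            "fold_change": r.fold_change if r.sentinel == SENTINEL_NONE else "",
            "log10_fold_change": (r.log10_fold_change
                                  if r.sentinel == SENTINEL_NONE else ""),
            "sentinel": r.sentinel,
        })
    return pd.DataFrame(rows, columns=["genome_id", "abundance_CE",
                                       "abundance_CL", "fold_change",
                                       "log10_fold_change", "sentinel"])
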
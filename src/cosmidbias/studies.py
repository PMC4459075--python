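"""Canonical synthetic studies of cloning bias, packaged as one-call analyses.

Each function sets up a simulated community under fixed, documented study
conditions, runs the library-construction pipeline end to end, and computes
one of the package's headline statistics:

* :func:`background_monte_carlo` — observed vs closed-form chance rate of the
  sigma-70 consensus on i.i.d. sequence.
* :func:`gc_shift_summary` — percent GC of the three sequenced stages, for a
  community where AT-rich genomes carry higher promoter density (the setting
  in which GC shifts emerge in the final library only when cloning loss is
  active).
* :func:`promoter_content_change` — per-motif hits-per-Mb change between crude
  extract and cosmid library (the promoter-content histogram comparison).
* :func:`bias_correlation_replicate` — a community with GC and promoter
  density drawn independently, asking whether library bias tracks rpoD
  consensus density better than GC.
* :func:`lambda_recovery` — recover the clone-loss rate λ from the fragment
  truth table.

Problem sizes are desk-scale (a few Mb of community sequence, hundreds to
thousands of fragments): large enough that the documented effects dominate
sampling noise, small enough that each study runs in seconds.
"""

from __future__ import annotations

import math

import numpy as np

from . import bias_analysis, library_sim, motif_scan, seqio
from .bias_analysis import CorrelationReport
from .library_sim import CommunityGenomeSpec, SimulationParams

__all__ = [
    "background_monte_carlo",
    "gc_gradient_params",
    "gc_shift_summary",
    "promoter_contrast_params",
    "promoter_content_change",
    "bias_correlation_replicate",
    "lambda_recovery",
]


def background_monte_carlo(
    seed: int,
    gc: float = 0.5,
    n_replicates: int = 100,
    length: int = 100_000,
) -> dict[str, float]:
    """Observed mean rpoD consensus hits per Mb on i.i.d. sequence vs the
    closed-form expectation (both strands).

    Returns observed mean, its standard error over replicates, and the
    analytic expectation.
    """
    rng = np.random.default_rng(seed)
    rpod = motif_scan.builtin_motifs()[0]
    rates = []
    for i in range(n_replicates):
        genome = library_sim.generate_genome(
            f"mc{i}", length, gc, planted_rpoD=0, rng=rng)
        rates.append(genome.measured_rpoD / (length / 1e6))
    rates = np.asarray(rates)
    return {
        "observed_mean": float(rates.mean()),
        "standard_error": float(rates.std(ddof=1) / math.sqrt(n_replicates)),
        "expected": motif_scan.expected_hits_per_mb(rpod, gc, motif_scan.BOTH),
    }


def gc_gradient_params(seed: int, retention_rate: float) -> SimulationParams:
    """Four genomes spanning 35–65 % GC whose planted rpoD density falls as GC
    rises (60, 40, 20, 0 sites/Mb) — the configuration in which GC acts as a
    proxy for promoter content.  Crude extract includes a sheared-debris
    component that size selection removes."""
    densities = {0.35: 60, 0.45: 40, 0.55: 20, 0.65: 0}
    community = tuple(
        CommunityGenomeSpec(f"gc{int(gc * 100)}", 300_000, gc,
                            planted_rpoD=int(d * 0.3),  # d sites/Mb on 0.3 Mb
                            relative_abundance=0.25)
        for gc, d in densities.items()
    )
    return SimulationParams(
        seed=seed, community=community, n_fragments=600, debris_fraction=0.35,
        debris_length_range=(500, 8_000), hmw_length_range=(35_000, 80_000),
        size_select_range=(40_000, 70_000), retention_rate=retention_rate,
        reads_per_sample=5_000, read_length=90,
    )


def gc_shift_summary(seed: int, retention_rate: float) -> dict[str, float]:
    """Percent GC of each sequenced stage under :func:`gc_gradient_params`.

    With λ = 0 all three stages agree within sampling error (fragmentation and
    size selection do not bias GC); with λ > 0 the cosmid library shifts
    GC-rich because AT-rich, promoter-dense fragments fail to clone.
    """
    result = library_sim.run_experiment(gc_gradient_params(seed, retention_rate))
    return {stage: seqio.gc_percent(result.reads[stage])
            for stage in library_sim.STAGES}


def promoter_contrast_params(seed: int,
                             retention_rate: float = 1.0) -> SimulationParams:
    """Six 2-Mb genomes at equal (38 %) GC, half with 150 planted rpoD
    sites/Mb and half with none: promoter content varies across taxa while GC
    does not, isolating the promoter-content signature in the library."""
    community = tuple(
        CommunityGenomeSpec(f"g{i}", 2_000_000, 0.38,
                            planted_rpoD=(300 if i < 3 else 0),
                            relative_abundance=1 / 6)
        for i in range(6)
    )
    return SimulationParams(
        seed=seed, community=community, n_fragments=2_000, debris_fraction=0.0,
        hmw_length_range=(40_000, 70_000), size_select_range=(40_000, 70_000),
        retention_rate=retention_rate, reads_per_sample=30_000, read_length=90,
    )


def promoter_content_change(seed: int, retention_rate: float = 1.0) -> dict:
    """Per-motif log10 change of hits-per-Mb, cosmid library vs crude extract,
    under :func:`promoter_contrast_params`.

    A 0.5 pseudocount stabilizes the ratio for the rare control motifs.
    Returns the two content tables and the change per motif; with λ = 1 the
    rpoD consensus is strongly depressed in the library while the four control
    sigma-factor consensuses move only by sampling noise.
    """
    result = library_sim.run_experiment(
        promoter_contrast_params(seed, retention_rate))
    tables = {
        stage: motif_scan.scan_dataset(result.reads[stage], sample_name=stage)
        for stage in ("crude_extract", "cosmid_library")
    }
    ce, cl = tables["crude_extract"], tables["cosmid_library"]
    change = {}
    for name in ce.hit_counts:
        rate_ce = (ce.hit_counts[name] + 0.5) / ce.megabases_scanned
        rate_cl = (cl.hit_counts[name] + 0.5) / cl.megabases_scanned
        change[name] = math.log10(rate_cl / rate_ce)
    return {"tables": tables, "log10_change": change}


def bias_correlation_replicate(seed: int) -> CorrelationReport:
    """One replicate of the bias-predictor comparison: ten 250-kb genomes with
    GC ~ U(0.40, 0.65) and planted rpoD density ~ U(0, 40)/Mb drawn
    independently, λ = 1.

    Abundances come from read truth labels; genome features from scanning the
    generated genomes.  Because clone loss is driven by promoter count, the
    log10 fold change should correlate strongly (negatively) with rpoD density
    per Mb and only incidentally with GC.
    """
    rng = np.random.default_rng(seed)
    specs = []
    for i in range(10):
        gc = float(rng.uniform(0.40, 0.65))
        density = float(rng.uniform(0, 40))
        specs.append(CommunityGenomeSpec(
            f"g{i}", 250_000, gc,
            planted_rpoD=int(round(density * 0.25)),
            relative_abundance=0.1))
    params = SimulationParams(
        seed=seed, community=tuple(specs), n_fragments=400,
        debris_fraction=0.0, hmw_length_range=(40_000, 70_000),
        size_select_range=(40_000, 70_000), retention_rate=1.0,
        reads_per_sample=10_000, read_length=90,
    )
    result = library_sim.run_experiment(params)
    profile_ce = bias_analysis.abundance_from_labels(
        result.reads["crude_extract"], "crude_extract")
    profile_cl = bias_analysis.abundance_from_labels(
        result.reads["cosmid_library"], "cosmid_library")
    records = bias_analysis.compute_bias(profile_ce, profile_cl)
    profiles = [bias_analysis.genome_profile(g.as_record())
                for g in result.community]
    return bias_analysis.correlate_bias(records, profiles)


def lambda_recovery(seed: int, retention_rate: float = 1.0,
                    n_fragments: int = 2_500) -> dict[str, float]:
    """Simulate cloning of ``n_fragments`` promoter-bearing fragments and
    recover λ from the fragment truth table.

    Uses one 400-kb genome with 300 planted sites/Mb and 6-kb fragments so the
    per-fragment count k spans several informative values.
    """
    rng = np.random.default_rng(seed)
    genome = library_sim.generate_genome("g", 400_000, 0.5, 120, rng)
    frag_len = 6_000
    fragments = []
    for _ in range(n_fragments):
        start = int(rng.integers(0, genome.length - frag_len))
        fragments.append(library_sim.Fragment(
            "g", start, start + frag_len,
            genome.sequence[start:start + frag_len]))
    _, table = library_sim.clone_library(fragments, retention_rate, rng)
    lam_hat = library_sim.estimate_retention_rate(table)
    return {"true_lambda": retention_rate, "estimated_lambda": lam_hat,
            "n_fragments": n_fragments}
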
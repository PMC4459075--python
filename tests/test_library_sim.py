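"""The library-construction simulator: genome generation, fragmentation,
size selection, promoter-dependent cloning, read simulation, determinism."""

import numpy as np
import pytest

from cosmidbias import library_sim, motif_scan
from cosmidbias.library_sim import (
    CommunityGenomeSpec,
    Fragment,
    SimulationParams,
    clone_library,
    estimate_retention_rate,
    extract_crude,
    generate_community,
    generate_genome,
    run_experiment,
    simulate_reads,
    size_select,
)
from cosmidbias.seqio import reverse_complement

RPOD = motif_scan.builtin_motifs()[0]


def small_params(**overrides):
    """A desk-scale parameter set used across tests."""
    defaults = dict(
        seed=11,
        community=(
            CommunityGenomeSpec("lowgc", 60_000, 0.35, planted_rpoD=6,
                                relative_abundance=0.5),
            CommunityGenomeSpec("highgc", 60_000, 0.6, planted_rpoD=0,
                                relative_abundance=0.5),
        ),
        n_fragments=300,
        debris_fraction=0.2,
        hmw_length_range=(8_000, 20_000),
        debris_length_range=(300, 2_000),
        size_select_range=(9_000, 18_000),
        retention_rate=1.0,
        reads_per_sample=400,
        read_length=90,
    )
    defaults.update(overrides)
    return SimulationParams(**defaults)


class TestGenerateGenome:
    def test_planted_count_exact_on_gc_only_background(self, rng):
        # gc_target 1 admits no chance hits (rpoD needs 10 A/T positions)
        g = generate_genome("g", 50_000, 1.0, 20, rng)
        assert g.measured_rpoD == 20
        assert g.planted_rpoD == 20

    def test_measured_at_least_planted(self, rng):
        g = generate_genome("g", 100_000, 0.35, 10, rng)
        assert g.measured_rpoD >= 10

    def test_realized_gc_within_binomial_bound(self, rng):
        length, gc = 200_000, 0.42
        g = generate_genome("g", length, gc, 0, rng)
        observed = (g.sequence.count("G") + g.sequence.count("C")) / length
        se = np.sqrt(gc * (1 - gc) / length)
        assert abs(observed - gc) < 3 * se

    def test_unplanted_genome_hit_count_near_background(self, rng):
        # ~0.6 hits/Mb at 50% GC: a 10 kb genome usually has zero hits
        counts = [generate_genome(f"g{i}", 10_000, 0.5, 0, rng).measured_rpoD
                  for i in range(20)]
        assert np.mean(counts) < 1.0

    def test_impossible_planting_density_errors(self, rng):
        with pytest.raises(RuntimeError):
            generate_genome("g", 1_000, 0.5, 200, rng)

    def test_deterministic_given_seed(self):
        a = generate_genome("g", 20_000, 0.45, 5, 123)
        b = generate_genome("g", 20_000, 0.45, 5, 123)
        assert a.sequence == b.sequence


class TestExtractCrudeAndSizeSelect:
    def test_debris_fraction_zero_no_short_fragments(self, rng):
        params = small_params(debris_fraction=0.0, n_fragments=100)
        community = generate_community(params.community, rng)
        frags = extract_crude(community, params, rng)
        # truncation at genome ends can shorten, but a fragment from the
        # hmw distribution starting early keeps its drawn length
        assert max(len(f) for f in frags) >= params.hmw_length_range[0]
        untruncated = [f for f in frags if f.end < 60_000]
        assert all(len(f) >= params.hmw_length_range[0] for f in untruncated)

    def test_debris_fraction_one_all_short(self, rng):
        params = small_params(debris_fraction=1.0,
                              debris_length_range=(500, 5_000), n_fragments=100)
        community = generate_community(params.community, rng)
        frags = extract_crude(community, params, rng)
        assert all(len(f) <= 5_000 for f in frags)

    def test_base_share_tracks_relative_abundance(self, rng):
        specs = (
            CommunityGenomeSpec("a", 40_000, 0.5, relative_abundance=0.7),
            CommunityGenomeSpec("b", 40_000, 0.5, relative_abundance=0.3),
        )
        params = small_params(community=specs, n_fragments=10_000,
                              debris_fraction=0.0,
                              hmw_length_range=(1_000, 2_000))
        community = generate_community(specs, rng)
        frags = extract_crude(community, params, rng)
        share_a = sum(len(f) for f in frags if f.genome_id == "a") / sum(
            len(f) for f in frags)
        se = np.sqrt(0.7 * 0.3 / 10_000)
        # fragment lengths are iid across genomes, so base share ~ count share
        assert abs(share_a - 0.7) < 4 * se

    def test_size_select_is_partition_by_length(self, rng):
        params = small_params()
        community = generate_community(params.community, rng)
        frags = extract_crude(community, params, rng)
        lo, hi = params.size_select_range
        selected = size_select(frags, params.size_select_range)
        rejected = [f for f in frags if f not in selected]
        assert all(lo <= len(f) <= hi for f in selected)
        assert all(not lo <= len(f) <= hi for f in rejected)
        assert len(selected) + len(rejected) == len(frags)

    @pytest.mark.parametrize("length,kept", [(50_000, True), (5_000, False),
                                             (40_000, True), (70_001, False)])
    def test_size_select_boundaries(self, length, kept):
        frag = Fragment("g", 0, length, "A" * length)
        assert bool(size_select([frag], (40_000, 70_000))) is kept


class TestCloneLibrary:
    def test_lambda_zero_retains_all(self, rng):
        frags = [Fragment("g", 0, 100, "C" * 100) for _ in range(50)]
        retained, table = clone_library(frags, 0.0, rng)
        assert len(retained) == 50
        assert table["survived"].all()

    def test_promoter_free_fragments_always_retained(self, rng):
        frags = [Fragment("g", 0, 200, "C" * 200) for _ in range(50)]
        retained, table = clone_library(frags, 5.0, rng)
        assert (table["k"] == 0).all()
        assert len(retained) == 50

    def test_retention_frequency_matches_exp_lambda_at_k1(self, rng):
        site = "TTGACA" + "G" * 17 + "TATAAT"
        frag_seq = "C" * 100 + site + "C" * 100
        frags = [Fragment("g", 0, len(frag_seq), frag_seq) for _ in range(800)]
        lam = 0.8
        retained, table = clone_library(frags, lam, rng)
        assert (table["k"] == 1).all()
        p_hat = table["survived"].mean()
        p = np.exp(-lam)
        se = np.sqrt(p * (1 - p) / 800)
        assert abs(p_hat - p) < 3 * se

    def test_conservation_retained_plus_lost(self, rng):
        frags = [Fragment("g", 0, 100, "C" * 100) for _ in range(30)]
        retained, table = clone_library(frags, 0.5, rng)
        assert len(table) == 30
        assert table["survived"].sum() == len(retained)


class TestSimulateReads:
    def _fragment(self, rng, length=5_000, gc=0.5):
        g = generate_genome("g1", max(length, 1000), gc, 0, rng)
        return g, Fragment("g1", 0, length, g.sequence[:length])

    def test_pair_count(self, rng):
        _, frag = self._fragment(rng)
        reads = simulate_reads([frag], 1000, 90, rng)
        assert len(reads) == 2000
        assert all(r.origin_label == "g1" for r in reads)

    def test_reads_are_exact_genome_substrings_error_free(self, rng):
        genome, frag = self._fragment(rng)
        for r in simulate_reads([frag], 100, 90, rng):
            assert (r.sequence in genome.sequence
                    or reverse_complement(r.sequence) in genome.sequence)

    def test_read_share_tracks_base_share_of_pool(self, rng):
        ga = generate_genome("a", 30_000, 0.5, 0, rng)
        gb = generate_genome("b", 10_000, 0.5, 0, rng)
        frags = [Fragment("a", 0, 30_000, ga.sequence),
                 Fragment("b", 0, 10_000, gb.sequence)]
        reads = simulate_reads(frags, 4000, 90, rng)
        share_a = sum(r.origin_label == "a" for r in reads) / len(reads)
        se = np.sqrt(0.75 * 0.25 / 4000)
        assert abs(share_a - 0.75) < 4 * se

    def test_short_fragments_skipped(self, rng, caplog):
        _, frag = self._fragment(rng)
        short = Fragment("g1", 0, 50, frag.sequence[:50])
        with caplog.at_level("WARNING"):
            reads = simulate_reads([frag, short], 100, 90, rng)
        assert len(reads) == 200
        assert "skipped 1 fragments" in caplog.text

    def test_substitution_noise_opt_in(self, rng):
        genome, frag = self._fragment(rng, length=4_000)
        noisy = simulate_reads([frag], 200, 90, rng, substitution_rate=0.05)
        mismatching = sum(
            r.sequence not in genome.sequence
            and reverse_complement(r.sequence) not in genome.sequence
            for r in noisy)
        assert mismatching > 100  # P(read untouched) = 0.95^90 ~ 0.01


class TestRunExperiment:
    def test_deterministic_given_seed(self):
        a = run_experiment(small_params(seed=77))
        b = run_experiment(small_params(seed=77))
        for stage in library_sim.STAGES:
            assert [(r.id, r.sequence) for r in a.reads[stage]] == [
                (r.id, r.sequence) for r in b.reads[stage]]
        assert a.fragment_table.equals(b.fragment_table)
        assert a.abundance_truth.equals(b.abundance_truth)

    def test_lambda_zero_library_matches_size_selected_abundance(self):
        result = run_experiment(small_params(seed=5, retention_rate=0.0,
                                             n_fragments=600,
                                             reads_per_sample=2000))
        truth = result.abundance_truth.pivot(index="genome_id", columns="stage",
                                             values="base_share_percent")
        # no cloning loss: library pool IS the size-selected pool
        assert np.allclose(truth["cosmid_library"], truth["size_selected"])

    def test_planted_density_ranks_library_abundance_inversely(self):
        specs = tuple(
            CommunityGenomeSpec(f"d{d}", 300_000, 0.5,
                                planted_rpoD=int(d * 0.3),  # d plants per Mb
                                relative_abundance=1 / 3)
            for d in (0, 10, 40)
        )
        params = small_params(seed=3, community=specs, n_fragments=900,
                              debris_fraction=0.0,
                              hmw_length_range=(40_000, 58_000),
                              size_select_range=(40_000, 58_000),
                              retention_rate=1.0, reads_per_sample=3000)
        result = run_experiment(params)
        truth = result.abundance_truth.pivot(index="genome_id", columns="stage",
                                             values="base_share_percent")
        lib = truth["cosmid_library"]
        assert lib["d0"] > lib["d10"] > lib["d40"]

    def test_fragment_table_schema_and_conservation(self):
        result = run_experiment(small_params(seed=9))
        table = result.fragment_table
        assert list(table.columns) == ["genome_id", "start", "end", "length",
                                       "k", "survived"]
        assert len(table) == len(result.fragments["size_selected"])
        assert table["survived"].sum() == len(result.fragments["cosmid_library"])

    def test_write_experiment_round_trips_reads(self, tmp_path):
        from cosmidbias import seqio

        result = run_experiment(small_params(seed=2, reads_per_sample=50))
        manifest = library_sim.write_experiment(result, tmp_path)
        back = list(seqio.read_fastq(manifest["reads_cosmid_library"]))
        assert len(back) == 100
        assert back[0].origin_label in {"lowgc", "highgc"}


class TestRetentionRateRecovery:
    def test_lambda_recovered_within_15_percent(self):
        rng = np.random.default_rng(42)
        genome = generate_genome("g", 400_000, 0.5, 120, rng)  # 300 plants/Mb
        frags = []
        for _ in range(2_500):
            start = int(rng.integers(0, genome.length - 6_000))
            frags.append(Fragment("g", start, start + 6_000,
                                  genome.sequence[start:start + 6_000]))
        lam = 1.0
        _, table = clone_library(frags, lam, rng)
        lam_hat = estimate_retention_rate(table)
        assert abs(lam_hat - lam) / lam < 0.15

    def test_no_informative_group_errors(self, rng):
        frags = [Fragment("g", 0, 100, "C" * 100) for _ in range(10)]
        _, table = clone_library(frags, 1.0, rng)
        with pytest.raises(ValueError, match="informative"):
            estimate_retention_rate(table)


class TestParamValidation:
    def test_abundances_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            small_params(community=(
                CommunityGenomeSpec("a", 10_000, 0.5, relative_abundance=0.6),
                CommunityGenomeSpec("b", 10_000, 0.5, relative_abundance=0.6),
            ))

    def test_negative_lambda_rejected(self):
        with pytest.raises(ValueError):
            small_params(retention_rate=-0.1)

    def test_debris_fraction_bounds(self):
        with pytest.raises(ValueError):
            small_params(debris_fraction=1.5)
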
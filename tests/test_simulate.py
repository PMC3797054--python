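"""Generator tests: determinism, paralog identity, capture models, libraries."""

import numpy as np
import pytest

from dualcap.seqs import encode, decode, revcomp
from dualcap.simulate import (ConfigurationError, SimConfig, SimulationError,
                              capture_probability_cap, capture_probability_dT,
                              mutate_to_identity, simulate_library,
                              simulate_transcriptome, tile_reads)


def hamming_identity(a: str, b: str) -> float:
    assert len(a) == len(b)
    return np.mean([x == y for x, y in zip(a, b)])


class TestMutateToIdentity:
    def test_identity_one_is_noop(self, rng):
        assert mutate_to_identity("ACGTACGTAC", 1.0, rng) == "ACGTACGTAC"

    def test_ten_percent_of_ten_is_one_substitution(self, rng):
        out = mutate_to_identity("ACGTACGTAC", 0.9, rng)
        assert sum(a != b for a, b in zip(out, "ACGTACGTAC")) == 1

    def test_exact_mismatch_count_at_093(self, rng):
        base = decode(rng.integers(0, 4, 100).astype(np.uint8))
        out = mutate_to_identity(base, 0.93, rng)
        assert sum(a != b for a, b in zip(out, base)) == 7

    def test_rejects_nonpositive_identity(self, rng):
        with pytest.raises(ValueError):
            mutate_to_identity("ACGT", 0.0, rng)


class TestCaptureModels:
    @pytest.mark.parametrize("tail,expected", [(10, 0.0), (17, 0.0)])
    def test_below_anchor_is_zero(self, tail, expected):
        assert capture_probability_dT(tail, 18, 30, 1.0) == expected

    def test_hyperbola_value(self):
        assert capture_probability_dT(47, 18, 30, 1.0) == pytest.approx(0.5)

    def test_monotone_and_bounded(self):
        probs = [capture_probability_dT(t, 18, 30, 0.9) for t in range(0, 400)]
        assert all(b >= a for a, b in zip(probs, probs[1:]))
        assert max(probs) <= 0.9

    def test_cap_capture_tail_independent(self):
        assert capture_probability_cap(True, 0.8) == 0.8
        assert capture_probability_cap(False, 0.8) == 0.0


class TestSimulateTranscriptome:
    def test_deterministic_under_seed(self, small_config):
        a = simulate_transcriptome(small_config)
        b = simulate_transcriptome(small_config)
        assert [t.sequence for t in a.pool] == [t.sequence for t in b.pool]
        assert a.genome.sequence == b.genome.sequence
        assert [t.abundance for t in a.pool] == [t.abundance for t in b.pool]

    def test_no_paralogs_when_fraction_zero(self):
        exp = simulate_transcriptome(SimConfig(n_genes=20, paralog_fraction=0.0,
                                               n_deadenylated=2,
                                               n_adenylated=2, seed=3))
        assert all(t.paralog_group is None for t in exp.pool)

    def test_paralog_identity_near_93(self):
        exp = simulate_transcriptome(SimConfig(n_genes=100,
                                               paralog_fraction=0.5, seed=7))
        groups = {}
        for t in exp.pool:
            if t.paralog_group:
                groups.setdefault(t.paralog_group, []).append(t.sequence)
        idents = [hamming_identity(a, b) for a, b in groups.values()]
        assert len(idents) == 50
        # observed mean within 3 sd of the configured 93.1%
        assert abs(np.mean(idents) - 0.931) < 3 * 0.0272
        assert all(0.85 < i < 0.995 for i in idents)

    def test_abundances_sum_to_one_and_states_share_them(self, small_experiment):
        assert sum(t.abundance for t in small_experiment.pool) == pytest.approx(1.0)

    def test_rejects_bad_config(self):
        with pytest.raises(ConfigurationError):
            simulate_transcriptome(SimConfig(n_genes=5))
        with pytest.raises(ConfigurationError):
            simulate_transcriptome(SimConfig(rrna_carryover=1.5))

    def test_genome_contains_each_transcript_verbatim(self, small_experiment):
        g = small_experiment.genome
        for tid, s, e in g.loci[:10]:
            t = next(t for t in small_experiment.pool if t.id == tid)
            assert g.sequence[s:e] == t.sequence

    def test_tier_sizes_step_down(self, small_experiment):
        sizes = [len(t) for t in small_experiment.annotation_tiers]
        assert sizes[0] > sizes[1] > sizes[2] > 0


class TestSimulateLibrary:
    def test_empty_capturable_pool_raises(self, small_experiment, small_config):
        pool = [t for t in small_experiment.pool][:20]
        for t in pool:
            t = t  # tails forced below anchor on a copy
        import dataclasses
        short = [dataclasses.replace(t, tail_M=5, tail_IF=5) for t in pool]
        with pytest.raises(SimulationError, match="empty capturable pool"):
            simulate_library(short, "M", "dT", small_config,
                             rrna=small_experiment.rrna)

    def test_noiseless_reads_are_exact_substrings(self, small_experiment):
        cfg = SimConfig(n_genes=60, n_reads=2000, error_rate=0.0,
                        duplicate_rate=0.0, rrna_carryover=0.0,
                        n_deadenylated=6, n_adenylated=4, seed=11)
        exp = simulate_transcriptome(cfg)
        lib = simulate_library(exp.pool, "M", "cap", cfg)
        by_id = {t.id: t.sequence for t in exp.pool}
        for i in range(0, len(lib), 97):
            seq = lib.sequence(i)
            src = by_id[lib.truth_id(i)]
            assert seq in src or revcomp(seq) in src

    def test_cap_counts_follow_abundance_binomially(self):
        cfg = SimConfig(n_genes=12, paralog_fraction=0.0, n_reads=100_000,
                        error_rate=0.0, duplicate_rate=0.0, rrna_carryover=0.0,
                        n_deadenylated=0, n_adenylated=0,
                        short_tail_fraction=0.0, coding_fraction=1.0,
                        ncrna_fraction=0.0, abundance_sigma=0.0, seed=5)
        exp = simulate_transcriptome(cfg)
        lib = simulate_library(exp.pool, "M", "cap", cfg)
        counts = np.bincount(lib.src[lib.src >= 0], minlength=len(exp.pool))
        # equal abundance, equal capture -> equal expected counts (within 5%)
        assert counts.max() / counts.min() < 1.15
        two = counts[0] / counts[1]
        assert abs(two - 1) < 0.05

    def test_all_reads_have_read_length(self, small_experiment, small_config):
        lib = simulate_library(small_experiment.pool, "IF", "cap", small_config,
                               rrna=small_experiment.rrna)
        assert lib.seqs.shape[1] == small_config.read_length

    def test_rrna_carryover_fraction(self, small_experiment):
        cfg = SimConfig(n_genes=60, n_reads=100_000, rrna_carryover=0.02,
                        duplicate_rate=0.0, seed=11)
        lib = simulate_library(small_experiment.pool, "M", "cap", cfg,
                               rrna=small_experiment.rrna)
        frac = float((lib.src < 0).mean())
        sd = np.sqrt(0.02 * 0.98 / len(lib))
        assert abs(frac - 0.02) < 3 * sd

    def test_fastq_roundtrip(self, tmp_path, small_experiment):
        cfg = SimConfig(n_genes=60, n_reads=500, seed=11)
        lib = simulate_library(small_experiment.pool, "M", "cap", cfg,
                               rrna=small_experiment.rrna)
        path = tmp_path / "lib.fq"
        lib.to_fastq(path)
        from dualcap.simulate import ReadSet
        back = ReadSet.from_fastq(path)
        assert np.array_equal(back.seqs, lib.seqs)

    def test_library_determinism(self, small_experiment, small_config):
        a = simulate_library(small_experiment.pool, "M", "dT", small_config,
                             rrna=small_experiment.rrna)
        b = simulate_library(small_experiment.pool, "M", "dT", small_config,
                             rrna=small_experiment.rrna)
        assert np.array_equal(a.seqs, b.seqs)


class TestTileReads:
    def test_tiling_covers_every_window(self, small_experiment):
        pool = small_experiment.pool[:3]
        tiled = tile_reads(pool, stride=1, both_strands=False)
        t0 = pool[0]
        starts = tiled.pos[tiled.src == 0]
        assert set(starts.tolist()) == set(range(len(t0.sequence) - 49))

    def test_both_strands_doubles(self, small_experiment):
        pool = small_experiment.pool[:3]
        single = tile_reads(pool, stride=2, both_strands=False)
        double = tile_reads(pool, stride=2, both_strands=True)
        assert len(double) == 2 * len(single)
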
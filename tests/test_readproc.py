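"""Preprocessing and quantification tests, with a brute-force aligner oracle."""

import numpy as np
import pytest

from dualcap.readproc import (PseudoAligner, alignment_rate, count_and_normalize,
                              dedupe_reads, filter_rrna, pseudo_align,
                              replicate_r2, AMBIGUOUS, UNALIGNED)
from dualcap.seqs import decode, encode, revcomp
from dualcap.simulate import SimConfig, simulate_library, simulate_transcriptome


def brute_force_loci(read: str, refs: list, max_mm: int = 2):
    """All-positions Hamming scan on both strands (independent oracle)."""
    out = []
    for ref_idx, (_rid, rseq) in enumerate(refs):
        for strand, q in (("+", read), ("-", revcomp(read))):
            for p in range(len(rseq) - len(q) + 1):
                mm = sum(a != b for a, b in zip(q, rseq[p:p + len(q)]))
                if mm <= max_mm:
                    out.append((ref_idx, p, strand, mm))
    return out


def brute_force_assign(read: str, refs: list, max_mm: int = 2):
    loci = brute_force_loci(read, refs, max_mm)
    if not loci:
        return UNALIGNED
    best = min(mm for _r, _p, _s, mm in loci)
    refs_at_best = {r for r, _p, _s, mm in loci if mm == best}
    return AMBIGUOUS if len(refs_at_best) > 1 else refs_at_best.pop()


class TestDedupe:
    def test_counts_and_first_occurrence(self):
        reads = ["ACGT" * 13, "ACGT" * 13, "TTTT" * 13, "ACGT" * 13]
        mats = np.vstack([encode(r[:50]) for r in reads])
        uniq, removed = dedupe_reads(mats)
        assert removed == 2
        assert uniq.shape[0] == 2
        assert decode(uniq[0]) == reads[0][:50]

    def test_all_distinct_unchanged(self, rng):
        mats = rng.integers(0, 4, (20, 50)).astype(np.uint8)
        uniq, removed = dedupe_reads(mats)
        assert removed == 0 and uniq.shape[0] == 20

    def test_reverse_complement_not_a_duplicate(self, rng):
        a = rng.integers(0, 4, 50).astype(np.uint8)
        mats = np.vstack([a, (3 - a)[::-1]])
        _uniq, removed = dedupe_reads(mats)
        assert removed == 0


class TestFilterRrna:
    def test_exact_substring_removed_and_3mm_kept(self, rng):
        rrna = decode(rng.integers(0, 4, 500).astype(np.uint8))
        clean = rrna[100:150]
        three = encode(clean).copy()
        three[[5, 20, 40]] = (three[[5, 20, 40]] + 1) % 4
        mats = np.vstack([encode(clean), three])
        kept, n, frac = filter_rrna(mats, [("r", rrna)])
        assert n == 1 and frac == 0.5
        assert decode(kept[0]) == decode(three)

    def test_carryover_fraction_recovered(self, small_experiment):
        cfg = SimConfig(n_genes=60, n_reads=100_000, rrna_carryover=0.02,
                        duplicate_rate=0.0, seed=11)
        lib = simulate_library(small_experiment.pool, "M", "cap", cfg,
                               rrna=small_experiment.rrna)
        _kept, _n, frac = filter_rrna(lib, small_experiment.rrna)
        sd = np.sqrt(0.02 * 0.98 / len(lib))
        assert abs(frac - 0.02) < 3 * sd + 0.002  # + small alignment slack


class TestPseudoAlign:
    def test_exact_unique_read(self, rng):
        refs = [("t1", decode(rng.integers(0, 4, 300).astype(np.uint8))),
                ("t2", decode(rng.integers(0, 4, 300).astype(np.uint8)))]
        read = refs[0][1][37:87]
        aln = pseudo_align([read], refs)
        assert aln.ref[0] == 0 and aln.pos[0] == 37 and aln.mismatches[0] == 0

    def test_two_paralog_hit_discarded_ambiguous(self, rng):
        base = decode(rng.integers(0, 4, 300).astype(np.uint8))
        refs = [("a", base), ("b", base[:150] + base[150:])]  # identical copy
        read = base[10:60]
        aln = pseudo_align([read], refs)
        assert aln.ref[0] == AMBIGUOUS

    def test_minus_strand_read(self, rng):
        ref = decode(rng.integers(0, 4, 200).astype(np.uint8))
        read = revcomp(ref[60:110])
        aln = pseudo_align([read], [("t", ref)])
        assert aln.ref[0] == 0 and aln.pos[0] == 60 and aln.strand[0] == 1

    def test_oracle_equivalence_random_reads(self, rng):
        """Seed-and-verify must agree with the all-positions Hamming scan."""
        refs = [(f"t{i}", decode(rng.integers(0, 4, 400).astype(np.uint8)))
                for i in range(5)]
        aligner = PseudoAligner(refs)
        reads, expect = [], []
        for trial in range(120):
            ref_i = int(rng.integers(0, 5))
            p = int(rng.integers(0, 350))
            read = encode(refs[ref_i][1][p:p + 50]).copy()
            n_mut = int(rng.integers(0, 4))  # up to 3 mutations
            pos = rng.choice(50, size=n_mut, replace=False)
            read[pos] = (read[pos] + rng.integers(1, 4, n_mut)) % 4
            if rng.random() < 0.5:
                read = (3 - read)[::-1]
            reads.append(decode(read))
        for r in reads:
            expect.append(brute_force_assign(r, refs))
        aln = aligner.align(np.vstack([encode(r) for r in reads]))
        assert aln.ref.tolist() == expect

    def test_noiseless_library_truth_recovery(self, small_experiment):
        cfg = SimConfig(n_genes=60, n_reads=20_000, error_rate=0.0,
                        duplicate_rate=0.0, rrna_carryover=0.0,
                        n_deadenylated=6, n_adenylated=4, seed=11)
        exp = simulate_transcriptome(cfg)
        lib = simulate_library(exp.pool, "M", "cap", cfg)
        aln = PseudoAligner(exp.pool).align(lib)
        m = aln.assigned
        assert m.mean() > 0.9
        assert (aln.ref[m] == lib.src[m]).mean() >= 0.99

    def test_short_reference_skipped_with_warning(self, rng):
        refs = [("short", "ACGTACGT"),
                ("long", decode(rng.integers(0, 4, 200).astype(np.uint8)))]
        read = refs[1][1][0:50]
        with pytest.warns(UserWarning, match="shorter than the read"):
            aln = pseudo_align([read], refs)
        assert aln.ref[0] == 1


class TestCounting:
    def _aln(self, refs, assignments):
        from dualcap.readproc import Alignments
        ref = np.array(assignments)
        n = ref.size
        return Alignments(ref=ref, pos=np.zeros(n, int), strand=np.zeros(n, np.int8),
                          mismatches=np.zeros(n, np.int8),
                          ref_ids=[i for i, _l in refs],
                          ref_lengths=dict(refs))

    def test_rpkm_formula(self):
        # 10 reads on a 1000-nt transcript with 1e6 mapped total -> RPKM 10.0
        refs = [("t1", 1000), ("filler", 500)]
        aln = self._aln(refs, [0] * 10 + [1] * (1_000_000 - 10))
        ct = count_and_normalize(aln, dict(refs))
        assert ct.rpkm("t1") == pytest.approx(10.0)

    def test_zero_count_transcript_present(self):
        refs = [("t1", 1000), ("t2", 500)]
        ct = count_and_normalize(self._aln(refs, [0, 0]), dict(refs))
        assert ct.raw("t2") == 0 and ct.rpkm("t2") == 0.0

    def test_scale_invariance(self):
        refs = [("t1", 1000), ("t2", 500)]
        a = count_and_normalize(self._aln(refs, [0] * 4 + [1] * 2), dict(refs))
        b = count_and_normalize(self._aln(refs, [0] * 8 + [1] * 4), dict(refs))
        assert np.allclose(a.table["rpkm"], b.table["rpkm"])

    def test_zero_total_raises(self):
        refs = [("t1", 1000)]
        with pytest.raises(ValueError):
            count_and_normalize(self._aln(refs, [UNALIGNED]), dict(refs))

    def test_counts_sum_to_total_mapped(self):
        refs = [("t1", 1000), ("t2", 500)]
        ct = count_and_normalize(self._aln(refs, [0, 1, 1, UNALIGNED, AMBIGUOUS]),
                                 dict(refs))
        assert ct.table["raw"].sum() == ct.total_mapped == 3


class TestReplicateR2:
    def _table(self, rpkms):
        import pandas as pd
        from dualcap.readproc import CountTable
        df = pd.DataFrame({"raw": np.ones(len(rpkms)), "rpkm": rpkms},
                          index=[f"t{i}" for i in range(len(rpkms))])
        return CountTable(table=df, total_mapped=100)

    def test_self_is_one(self):
        t = self._table([1.0, 5.0, 10.0, 0.0])
        assert replicate_r2(t, t) == pytest.approx(1.0)

    def test_doubling_is_still_one(self):
        a = self._table([1.0, 5.0, 10.0, 2.0])
        b = self._table([2.0, 10.0, 20.0, 4.0])
        assert replicate_r2(a, b) == pytest.approx(1.0, abs=1e-3)

    def test_too_few_shared_raises(self):
        a = self._table([1.0, 0.0])
        with pytest.raises(ValueError):
            replicate_r2(a, a)


class TestAlignmentRate:
    def test_full_reference_beats_subset(self, rng):
        cfg = SimConfig(n_genes=40, n_reads=5_000, error_rate=0.0,
                        duplicate_rate=0.0, rrna_carryover=0.0,
                        paralog_fraction=0.0, n_deadenylated=4,
                        n_adenylated=2, seed=21)
        exp = simulate_transcriptome(cfg)
        lib = simulate_library(exp.pool, "M", "cap", cfg)
        full = alignment_rate(lib, exp.pool)
        subset = alignment_rate(lib, exp.pool[:28])
        assert full >= 0.99
        assert subset < full
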
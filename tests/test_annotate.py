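"""ORF prediction (with brute-force oracle), UTR matching, paralog band,
genome-mapping filters."""

import re

import numpy as np
import pytest

from dualcap.annotate import (GenomeMapper, detect_paralogs, genome_map_filter,
                              longest_orf, orf_summary, utr_match)
from dualcap.scaffold import six_frame_translate
from dualcap.seqs import decode, revcomp


def brute_force_longest_orf(seq: str) -> int:
    """Independent oracle: regex over all six frame translations."""
    if len(seq) < 3:
        return 0
    best = 0
    for pep in six_frame_translate(seq):
        for m in re.finditer(r"M[^*]*", pep):
            best = max(best, len(m.group()))
    return best


class TestLongestOrf:
    def test_minimal_orf(self):
        r = longest_orf("ATGAAATAA")
        assert r.longest_orf_aa == 2 and r.frame == 1 and not r.open_ended

    def test_no_start_codon(self):
        # no ATG on either strand: avoid CAT (revcomp of ATG) too
        r = longest_orf("CCCCCCGGGGGG")
        assert r.longest_orf_aa == 0

    def test_open_ended_fragment(self):
        r = longest_orf("ATGGGG")
        assert r.longest_orf_aa == 2 and r.open_ended

    def test_too_short_reports_zero(self):
        assert longest_orf("AT").longest_orf_aa == 0

    def test_oracle_equivalence_random(self, rng):
        for _ in range(400):
            L = int(rng.integers(3, 120))
            seq = decode(rng.integers(0, 4, L).astype(np.uint8))
            assert longest_orf(seq).longest_orf_aa == \
                brute_force_longest_orf(seq), seq

    def test_monotone_under_codon_insertion(self, rng):
        """Appending non-stop codons before the stop never shortens the ORF."""
        core = "ATG" + "AAA" * 10
        prev = longest_orf(core + "TAA").longest_orf_aa
        for extra in range(1, 8):
            cur = longest_orf("ATG" + "AAA" * (10 + extra) + "TAA").longest_orf_aa
            assert cur > prev
            prev = cur

    def test_orf50_flag(self):
        assert longest_orf("ATG" + "GCT" * 49 + "TAA").has_orf50
        assert not longest_orf("ATG" + "GCT" * 48 + "TAA").has_orf50


class TestOrfSummary:
    def test_all_zero(self):
        from dualcap.annotate import OrfReport
        reports = [OrfReport(f"t{i}", 0) for i in range(5)]
        assert orf_summary(reports) == (0.0, 0.0, 0.0)

    def test_arithmetic(self):
        from dualcap.annotate import OrfReport
        reports = [OrfReport("a", 10), OrfReport("b", 50), OrfReport("c", 60)]
        frac_any, mean_aa, frac50 = orf_summary(reports)
        assert (frac_any, mean_aa) == (1.0, 40.0)
        assert frac50 == pytest.approx(2 / 3)

    def test_random_sequences_mostly_have_orfs(self, rng):
        """Random 500-mers nearly always contain some ATG-led frame."""
        reports = [longest_orf(decode(rng.integers(0, 4, 500).astype(np.uint8)))
                   for _ in range(300)]
        frac_any, mean_aa, _ = orf_summary(reports)
        assert frac_any >= 0.95
        assert mean_aa > 10


class TestUtrMatch:
    def test_verbatim_utr_fragment(self, rng):
        utr = decode(rng.integers(0, 4, 400).astype(np.uint8))
        assert utr_match(utr[100:300], [("u1", utr)]) is True

    def test_random_never_matches(self, rng):
        db = [(f"u{i}", decode(rng.integers(0, 4, 300).astype(np.uint8)))
              for i in range(10)]
        misses = sum(
            utr_match(decode(rng.integers(0, 4, 200).astype(np.uint8)), db)
            for _ in range(60))
        assert misses == 0

    def test_weak_similarity_rejected(self, rng):
        utr = decode(rng.integers(0, 4, 300).astype(np.uint8))
        # 60% identity over 50 nt: e-value far above 1e-30
        frag = list(utr[:50])
        for p in rng.choice(50, 20, replace=False):
            frag[p] = "ACGT"[("ACGT".index(frag[p]) + 1) % 4]
        query = "".join(frag) + decode(rng.integers(0, 4, 150).astype(np.uint8))
        assert utr_match(query, [("u1", utr)]) is False


class TestDetectParalogs:
    def _mutate(self, seq, n, rng, spread=True):
        codes = list(seq)
        pos = (np.linspace(5, len(seq) - 5, n).astype(int) if spread
               else rng.choice(len(seq), n, replace=False))
        for p in pos:
            codes[p] = "ACGT"[("ACGT".index(codes[p]) + 1) % 4]
        return "".join(codes)

    def test_93_percent_pair_flagged(self, rng):
        a = decode(rng.integers(0, 4, 100).astype(np.uint8))
        b = self._mutate(a, 7, rng)
        pairs, flag = detect_paralogs([("a", a), ("b", b)])
        assert flag and pairs[0][:2] == ("a", "b")
        assert 0.88 <= pairs[0][2] <= 0.995

    def test_identical_not_flagged(self, rng):
        a = decode(rng.integers(0, 4, 150).astype(np.uint8))
        pairs, flag = detect_paralogs([("a", a), ("b", a)])
        assert not flag and pairs == []

    def test_eighty_percent_not_flagged(self, rng):
        a = decode(rng.integers(0, 4, 200).astype(np.uint8))
        b = self._mutate(a, 40, rng)
        _pairs, flag = detect_paralogs([("a", a), ("b", b)])
        assert not flag

    def test_singleton_cluster_empty(self):
        assert detect_paralogs([("a", "ACGT" * 30)]) == ([], False)


def _toy_genome(rng, inserts, spacer=3000):
    """Concatenate inserts with random spacers; returns (genome, offsets)."""
    parts, offsets = [], []
    cursor = 0
    for ins in inserts:
        gap = decode(rng.integers(0, 4, spacer).astype(np.uint8))
        parts.append(gap)
        cursor += spacer
        offsets.append(cursor)
        parts.append(ins)
        cursor += len(ins)
    parts.append(decode(rng.integers(0, 4, spacer).astype(np.uint8)))
    return "".join(parts), offsets


class TestGenomeMapping:
    def test_verbatim_single_locus_kept(self, rng):
        tx = decode(rng.integers(0, 4, 1500).astype(np.uint8))
        genome, offs = _toy_genome(rng, [tx])
        kept, verdict = genome_map_filter(tx, genome)
        assert verdict == "mapped" and len(kept) == 1
        m = kept[0]
        assert m.identity == 1.0 and m.query_coverage == 1.0
        assert m.score == 1500 and m.locus[1] == offs[0]

    def test_three_copies_dropped_multilocus(self, rng):
        tx = decode(rng.integers(0, 4, 1500).astype(np.uint8))
        genome, _ = _toy_genome(rng, [tx, tx, tx])
        kept, verdict = genome_map_filter(tx, genome)
        assert verdict == "multi_locus" and kept == []

    def test_ninety_percent_decoy_unmapped(self, rng):
        tx = decode(rng.integers(0, 4, 1500).astype(np.uint8))
        decoy = list(tx)
        for p in rng.choice(1500, 150, replace=False):
            decoy[p] = "ACGT"[("ACGT".index(decoy[p]) + 1) % 4]
        genome, _ = _toy_genome(rng, ["".join(decoy)])
        kept, verdict = genome_map_filter(tx, genome)
        assert verdict == "unmapped" and kept == []

    def test_intron_within_limit_chained(self, rng):
        exon1 = decode(rng.integers(0, 4, 800).astype(np.uint8))
        exon2 = decode(rng.integers(0, 4, 800).astype(np.uint8))
        intron = decode(rng.integers(0, 4, 5000).astype(np.uint8))
        genome, _ = _toy_genome(rng, [exon1 + intron + exon2])
        kept, verdict = genome_map_filter(exon1 + exon2, genome)
        assert verdict == "mapped"
        assert kept[0].identity > 0.99 and kept[0].query_coverage == 1.0

    def test_oversized_intron_not_chained(self, rng):
        exon1 = decode(rng.integers(0, 4, 800).astype(np.uint8))
        exon2 = decode(rng.integers(0, 4, 800).astype(np.uint8))
        intron = decode(rng.integers(0, 4, 25_000).astype(np.uint8))
        genome, _ = _toy_genome(rng, [exon1 + intron + exon2])
        _kept, verdict = genome_map_filter(exon1 + exon2, genome)
        assert verdict == "unmapped"   # two half-coverage loci, neither passes

    def test_minus_strand_mapping(self, rng):
        tx = decode(rng.integers(0, 4, 1200).astype(np.uint8))
        genome, _ = _toy_genome(rng, [revcomp(tx)])
        kept, verdict = genome_map_filter(tx, genome)
        assert verdict == "mapped" and kept[0].strand == "-"

    def test_mapper_reuse_across_transcripts(self, rng):
        txs = [decode(rng.integers(0, 4, 1200).astype(np.uint8))
               for _ in range(3)]
        genome, _ = _toy_genome(rng, txs)
        mapper = GenomeMapper(genome)
        for tx in txs:
            kept, verdict = mapper.map(tx)
            assert verdict == "mapped" and kept[0].identity == 1.0
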
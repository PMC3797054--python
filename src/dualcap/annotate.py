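"""Triage of transcripts without protein orthologs.

Transcripts that found no homolog during scaffolding are characterised three
ways: coding potential (longest open reading frame over all six frames),
3'UTR origin (a high-stringency nucleotide match into a reference 3'UTR
set), and assembly fidelity (mapping back to the genome under strict
identity/coverage/score filters). A separate detector flags clusters whose
members sit in the ~93% pairwise-identity band characteristic of
allotetraploid paralog pairs, distinguishing them from same-gene redundancy
at ~100% identity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .homology import NucleotideSearch
from .scaffold import FRAME_LABELS, six_frame_translate
from .seqs import encode, revcomp_codes, window_keys


@dataclass
class OrfReport:
    transcript_id: str
    longest_orf_aa: int
    frame: int = 0            # +1..+3 / -1..-3; 0 when no ORF
    strand: str = "+"
    open_ended: bool = False  # ran to the sequence end without a stop

    @property
    def has_orf50(self) -> bool:
        return self.longest_orf_aa >= 50


def longest_orf(sequence, transcript_id: str = "") -> OrfReport:
    """Longest ATG-to-stop (or ATG-to-end) reading frame over six frames.

    The ORF starts at an ATG and runs to the first in-frame stop, or to the
    sequence end when no stop follows (assembly fragments routinely truncate
    reading frames, so open-ended ORFs count). Length in amino acids
    includes the initial M and excludes the stop. Ties prefer the + strand,
    then the lower frame number.
    """
    if hasattr(sequence, "sequence"):
        transcript_id = transcript_id or sequence.id
        sequence = sequence.sequence
    if len(sequence) < 3:
        return OrfReport(transcript_id, 0)
    best = OrfReport(transcript_id, 0)
    for label, pep in zip(FRAME_LABELS, six_frame_translate(sequence)):
        start = 0
        n = len(pep)
        while start < n:
            stop = pep.find("*", start)
            seg_end = n if stop < 0 else stop
            m = pep.find("M", start, seg_end)
            if m >= 0:
                aa = seg_end - m
                if aa > best.longest_orf_aa:
                    best = OrfReport(transcript_id, aa, label,
                                     "+" if label > 0 else "-",
                                     open_ended=stop < 0)
            if stop < 0:
                break
            start = stop + 1
    return best


def orf_summary(reports) -> tuple:
    """(fraction with any ORF, mean ORF length in aa, fraction >=50 aa)."""
    aa = np.array([r.longest_orf_aa for r in reports], dtype=float)
    if aa.size == 0:
        raise ValueError("no ORF reports")
    return (float((aa > 0).mean()), float(aa.mean()),
            float((aa >= 50).mean()))


def utr_match(transcript, utr_db, evalue_max: float = 1e-30,
              searcher: Optional[NucleotideSearch] = None) -> bool:
    """High-stringency nucleotide match of a transcript into a 3'UTR set."""
    seq = transcript.sequence if hasattr(transcript, "sequence") else transcript
    if searcher is None:
        if not utr_db:
            raise ValueError("UTR database is empty")
        searcher = NucleotideSearch(utr_db)
    return bool(searcher.search([("q", seq)], evalue_max=evalue_max))


def detect_paralogs(cluster_members, band=(0.88, 0.995)):
    """Flag member pairs whose best local identity falls in the paralog band.

    ``cluster_members`` is a list of (id, sequence) pairs (bare sequences
    get positional ids). Identity at ~100% is same-gene redundancy, not a
    paralog pair, hence the open top of the band. Returns
    (flagged_pairs, cluster_contains_collapsed_paralogs).
    """
    members = [(m.id, m.sequence) if hasattr(m, "sequence")
               else (m if isinstance(m, tuple) else (f"m{i}", m))
               for i, m in enumerate(cluster_members)]
    if len(members) < 2:
        return [], False
    lo, hi = band
    engine = NucleotideSearch(members)
    flagged = {}
    for h in engine.search(members):
        if h.query_id == h.subject_id:
            continue
        pair = tuple(sorted((h.query_id, h.subject_id)))
        ident = h.identity
        if lo <= ident <= hi:
            prev = flagged.get(pair)
            if prev is None or ident > prev:
                flagged[pair] = ident
    pairs = sorted((a, b, ident) for (a, b), ident in flagged.items())
    return pairs, bool(pairs)


# ---------------------------------------------------------------------------
# genome mapping
# ---------------------------------------------------------------------------

@dataclass
class GenomeMapping:
    transcript_id: str
    locus: tuple               # (genome record id, start, end) 0-based half-open
    strand: str
    identity: float
    query_coverage: float
    score: int
    n_loci_total: int


class GenomeMapper:
    """Seed-and-chain transcript-to-genome mapper with strict filters.

    Candidate loci are groups of exact seed-word hits on one strand whose
    genomic gaps never exceed the maximum intron size. Each locus is scored
    over per-diagonal ungapped blocks (gaps between blocks on a shared
    diagonal are compared directly, so a uniformly diverged copy is measured
    at its true identity). A mapping is kept only if it clears the identity,
    query-coverage and score floors, and the transcript is discarded
    entirely when more than ``max_loci`` candidate loci exist.
    """

    def __init__(self, genome, word: int = 31, max_intron: int = 20_000):
        if hasattr(genome, "sequence") and not hasattr(genome, "id"):
            records = [("genome", genome.sequence)]
        elif isinstance(genome, str):
            records = [("genome", genome)]
        else:
            records = [(r.id, r.sequence) if hasattr(r, "sequence") else r
                       for r in genome]
        if not records or not any(len(s) >= word for _i, s in records):
            raise ValueError("genome is empty or shorter than the seed word")
        self.word = word
        self.max_intron = max_intron
        self.rec_ids = [i for i, _s in records]
        codes = [encode(s) for _i, s in records]
        self._lens = np.array([c.size for c in codes], dtype=np.int64)
        self._offsets = np.concatenate([[0], np.cumsum(self._lens)[:-1]])
        self._big = np.concatenate(codes)
        keys, pos = [], []
        for off, ln in zip(self._offsets, self._lens):
            if ln < word:
                continue
            _hi, lo = window_keys(self._big[off:off + ln][None, :], word)
            keys.append(lo[0])
            pos.append(np.arange(off, off + ln - word + 1))
        keys = np.concatenate(keys)
        pos = np.concatenate(pos)
        order = np.argsort(keys, kind="stable")
        self._keys = keys[order]
        self._pos = pos[order]

    def _seed_hits(self, q: np.ndarray):
        _hi, lo = window_keys(q[None, :], self.word)
        keys = lo[0]
        a = np.searchsorted(self._keys, keys, side="left")
        b = np.searchsorted(self._keys, keys, side="right")
        counts = b - a
        qpos = np.repeat(np.arange(keys.size), counts)
        cum = np.cumsum(counts)
        flat = (np.arange(int(counts.sum())) - np.repeat(cum - counts, counts)
                + np.repeat(a, counts))
        return qpos, self._pos[flat]

    def _score_locus(self, q: np.ndarray, qpos, gpos):
        """Blockwise comparison of one candidate locus; returns metrics."""
        Lq = q.size
        diag = gpos - qpos
        blocks = []
        for d in np.unique(diag):
            sel = qpos[diag == d]
            blocks.append([int(sel.min()), int(sel.max()) + self.word, int(d)])
        blocks.sort()
        # extend blocks over uncovered query gaps (first to 0, last to Lq)
        blocks[0][0] = 0
        blocks[-1][1] = Lq
        for i in range(len(blocks) - 1):
            blocks[i][1] = max(blocks[i][1], blocks[i + 1][0])
            blocks[i + 1][0] = max(blocks[i + 1][0], blocks[i][1])
        matches = aligned = 0
        gmin, gmax = None, None
        for q0, q1, d in blocks:
            if q1 <= q0:
                continue
            g0, g1 = q0 + d, q1 + d
            g0c, g1c = max(g0, 0), min(g1, self._big.size)
            if g1c <= g0c:
                continue
            q0c, q1c = g0c - d, g1c - d
            matches += int((q[q0c:q1c] == self._big[g0c:g1c]).sum())
            aligned += q1c - q0c
            gmin = g0c if gmin is None else min(gmin, g0c)
            gmax = g1c if gmax is None else max(gmax, g1c)
        if aligned == 0:
            return None
        return dict(identity=matches / aligned, coverage=aligned / Lq,
                    score=2 * matches - aligned, gmin=gmin, gmax=gmax)

    def map(self, transcript, min_identity: float = 0.95,
            min_query_cov: float = 0.80, min_score: int = 1000,
            max_loci: int = 2):
        """Returns (kept mappings, verdict in {mapped, unmapped, multi_locus})."""
        tid = transcript.id if hasattr(transcript, "id") else "query"
        seq = transcript.sequence if hasattr(transcript, "sequence") else transcript
        q_fwd = encode(seq)
        loci = []
        for strand, q in (("+", q_fwd), ("-", revcomp_codes(q_fwd))):
            if q.size < self.word:
                continue
            qpos, gpos = self._seed_hits(q)
            if qpos.size == 0:
                continue
            order = np.argsort(gpos, kind="stable")
            qpos, gpos = qpos[order], gpos[order]
            # a new locus starts at an over-sized genomic gap, or where the
            # query coordinate resets (tandem copies within intron range)
            breaks = np.flatnonzero((np.diff(gpos) > self.max_intron)
                                    | (np.diff(qpos) < -self.word)) + 1
            for qp, gp in zip(np.split(qpos, breaks), np.split(gpos, breaks)):
                loci.append((strand, q, qp, gp))
        n_loci = len(loci)
        kept = []
        if n_loci > max_loci:
            return kept, "multi_locus"
        for strand, q, qp, gp in loci:
            m = self._score_locus(q, qp, gp)
            if m is None:
                continue
            rec = int(np.searchsorted(self._offsets, m["gmin"], side="right") - 1)
            mapping = GenomeMapping(
                tid, (self.rec_ids[rec], int(m["gmin"] - self._offsets[rec]),
                      int(m["gmax"] - self._offsets[rec])),
                strand, m["identity"], m["coverage"], m["score"], n_loci)
            if (m["identity"] >= min_identity and m["coverage"] >= min_query_cov
                    and m["score"] >= min_score):
                kept.append(mapping)
        return kept, ("mapped" if kept else "unmapped")


def genome_map_filter(transcript, genome, max_intron: int = 20_000,
                      min_identity: float = 0.95, min_query_cov: float = 0.80,
                      min_score: int = 1000, max_loci: int = 2):
    """One-shot wrapper around :class:`GenomeMapper` for a single transcript."""
    mapper = genome if isinstance(genome, GenomeMapper) else \
        GenomeMapper(genome, max_intron=max_intron)
    return mapper.map(transcript, min_identity, min_query_cov, min_score,
                      max_loci)
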
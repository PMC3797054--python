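"""Read preprocessing and quantification.

Exact-duplicate removal, rRNA filtering, transcriptome pseudo-alignment with
a fixed mismatch budget, per-transcript counting with RPKM normalisation
(reads per kilobase of transcript per million mapped reads), and replicate
correlation.

The aligner is a seed-and-verify ungapped mapper: a read is split into
``max_mismatches + 1`` disjoint seed segments, so whenever a locus is within
the mismatch budget at least one segment matches it exactly (pigeonhole);
every seed hit is then verified by a full Hamming comparison. All loci at the
minimal mismatch count are kept; a read whose minimal-score loci fall on more
than one distinct transcript is discarded as ambiguous.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterator, Optional

import numpy as np
import pandas as pd

from .seqs import encode, revcomp_codes, window_keys
from .simulate import ReadSet


@dataclass
class AlignmentRecord:
    """One resolved read placement on a reference transcript."""

    read_id: str
    transcript_id: str
    position: int          # 0-based start on the transcript sense strand
    strand: str            # '+' or '-'
    mismatches: int


UNALIGNED = -1
AMBIGUOUS = -2


@dataclass
class Alignments:
    """Columnar alignment results for a whole read set.

    ``ref`` holds the reference index per read, or the sentinels
    ``UNALIGNED`` / ``AMBIGUOUS``.
    """

    ref: np.ndarray
    pos: np.ndarray
    strand: np.ndarray      # 0 '+', 1 '-'
    mismatches: np.ndarray
    ref_ids: list
    ref_lengths: dict
    read_ids: Optional[list] = None

    def __len__(self) -> int:
        return self.ref.size

    @property
    def assigned(self) -> np.ndarray:
        return self.ref >= 0

    @property
    def n_assigned(self) -> int:
        return int(self.assigned.sum())

    @property
    def n_ambiguous(self) -> int:
        return int((self.ref == AMBIGUOUS).sum())

    @property
    def n_unaligned(self) -> int:
        return int((self.ref == UNALIGNED).sum())

    def records(self) -> Iterator[AlignmentRecord]:
        for i in np.flatnonzero(self.assigned):
            rid = self.read_ids[i] if self.read_ids else f"read{i:08d}"
            yield AlignmentRecord(rid, self.ref_ids[self.ref[i]],
                                  int(self.pos[i]),
                                  "+" if self.strand[i] == 0 else "-",
                                  int(self.mismatches[i]))


def _as_matrix(reads) -> np.ndarray:
    if isinstance(reads, ReadSet):
        return reads.seqs
    if isinstance(reads, np.ndarray):
        return reads
    return np.vstack([encode(s) for s in reads])


def _as_records(refs) -> list:
    if isinstance(refs, dict):
        return list(refs.items())
    out = []
    for r in refs:
        if isinstance(r, tuple):
            out.append(r)
        else:  # SimTranscript-like
            out.append((r.id, r.sequence))
    return out


def _expand_ranges(lo: np.ndarray, hi: np.ndarray):
    """Flatten [lo_i, hi_i) ranges: returns (owner_index, flat_position)."""
    counts = hi - lo
    total = int(counts.sum())
    owner = np.repeat(np.arange(lo.size), counts)
    cum = np.cumsum(counts)
    flat = np.arange(total) - np.repeat(cum - counts, counts) + np.repeat(lo, counts)
    return owner, flat


class PseudoAligner:
    """Ungapped seed-and-verify mapper over a transcript reference set."""

    def __init__(self, references, max_mismatches: int = 2):
        recs = _as_records(references)
        if not recs:
            raise ValueError("empty reference set")
        self.max_mismatches = int(max_mismatches)
        self.ref_ids = [i for i, _s in recs]
        self.ref_lengths = {i: len(s) for i, s in recs}
        codes = [encode(s) for _i, s in recs]
        self._lens = np.array([c.size for c in codes], dtype=np.int64)
        self._offsets = np.concatenate([[0], np.cumsum(self._lens)[:-1]])
        self._big = np.concatenate(codes)
        self._index_cache: dict[int, tuple] = {}

    def _seed_index(self, seed_len: int):
        if seed_len in self._index_cache:
            return self._index_cache[seed_len]
        keys_parts, pos_parts = [], []
        for off, ln in zip(self._offsets, self._lens):
            if ln < seed_len:
                continue
            _hi, lo = window_keys(self._big[off:off + ln][None, :], seed_len)
            keys_parts.append(lo[0])
            pos_parts.append(np.arange(off, off + ln - seed_len + 1))
        keys = np.concatenate(keys_parts)
        pos = np.concatenate(pos_parts)
        order = np.argsort(keys, kind="stable")
        result = (keys[order], pos[order])
        self._index_cache[seed_len] = result
        return result

    def _candidates(self, mat: np.ndarray):
        """All verified loci with mismatches <= budget, per oriented read."""
        n, read_len = mat.shape
        n_seg = self.max_mismatches + 1
        seed_len = read_len // n_seg
        if seed_len < 8:
            raise ValueError("reads too short for the seed scheme")
        if seed_len > 32:
            seed_len = 32
        offsets = [i * (read_len // n_seg) for i in range(n_seg)]
        skip = [i for i, ln in zip(self.ref_ids, self._lens) if ln < read_len]
        if skip:
            warnings.warn(f"{len(skip)} reference(s) shorter than the read "
                          f"length were skipped", stacklevel=3)
        sorted_keys, sorted_pos = self._seed_index(seed_len)

        both = np.concatenate([mat, revcomp_codes(mat)])  # rows n.. are '-'
        cand = {k: [] for k in ("read", "start", "strand", "mm")}
        for off in offsets:
            _hi, keys = window_keys(both[:, off:off + seed_len], seed_len)
            keys = keys[:, 0]
            lo = np.searchsorted(sorted_keys, keys, side="left")
            hi = np.searchsorted(sorted_keys, keys, side="right")
            owner, flat = _expand_ranges(lo, hi)
            start = sorted_pos[flat] - off
            ridx = np.searchsorted(self._offsets, start, side="right") - 1
            ok = ((start >= self._offsets[ridx])
                  & (start + read_len <= self._offsets[ridx] + self._lens[ridx]))
            owner, start = owner[ok], start[ok]
            # verify by full Hamming comparison, chunked for memory
            for c0 in range(0, owner.size, 1 << 20):
                sl = slice(c0, min(owner.size, c0 + (1 << 20)))
                o, s = owner[sl], start[sl]
                mm = (self._big[s[:, None] + np.arange(read_len)]
                      != both[o]).sum(axis=1)
                keep = mm <= self.max_mismatches
                cand["read"].append(o[keep] % n)
                cand["strand"].append((o[keep] >= n).astype(np.int8))
                cand["start"].append(s[keep])
                cand["mm"].append(mm[keep].astype(np.int8))
        read = np.concatenate(cand["read"])
        start = np.concatenate(cand["start"])
        strand = np.concatenate(cand["strand"])
        mm = np.concatenate(cand["mm"])
        # dedupe loci found by multiple seeds
        order = np.lexsort((strand, start, read))
        read, start, strand, mm = (a[order] for a in (read, start, strand, mm))
        if read.size:
            first = np.ones(read.size, bool)
            first[1:] = (np.diff(read) != 0) | (np.diff(start) != 0) \
                | (np.diff(strand) != 0)
            read, start, strand, mm = (a[first] for a in (read, start, strand, mm))
        return read, start, strand, mm

    def hit_mask(self, reads) -> np.ndarray:
        """Per-read flag: aligns anywhere within the mismatch budget."""
        mat = _as_matrix(reads)
        read, _s, _st, _mm = self._candidates(mat)
        mask = np.zeros(mat.shape[0], dtype=bool)
        mask[read] = True
        return mask

    def align(self, reads) -> Alignments:
        mat = _as_matrix(reads)
        n = mat.shape[0]
        read, start, strand, mm = self._candidates(mat)
        ref = np.full(n, UNALIGNED, dtype=np.int64)
        out_pos = np.zeros(n, dtype=np.int64)
        out_strand = np.zeros(n, dtype=np.int8)
        out_mm = np.zeros(n, dtype=np.int8)
        if read.size:
            ridx = np.searchsorted(self._offsets, start, side="right") - 1
            order = np.lexsort((start, strand, mm, read))
            read, start, strand, mm, ridx = (a[order] for a in
                                             (read, start, strand, mm, ridx))
            head = np.ones(read.size, bool)
            head[1:] = np.diff(read) != 0
            head_idx = np.flatnonzero(head)
            # best locus per read = group head (min mm, then '+', then pos)
            best_read = read[head_idx]
            ref[best_read] = ridx[head_idx]
            out_pos[best_read] = start[head_idx] - self._offsets[ridx[head_idx]]
            out_strand[best_read] = strand[head_idx]
            out_mm[best_read] = mm[head_idx]
            # ambiguity: a minimal-mismatch locus on a different transcript
            group = np.cumsum(head) - 1
            min_mm = mm[head_idx][group]
            best_ref = ridx[head_idx][group]
            amb_rows = (mm == min_mm) & (ridx != best_ref)
            ref[np.unique(read[amb_rows])] = AMBIGUOUS
        read_ids = ([reads.read_id(i) for i in range(n)]
                    if isinstance(reads, ReadSet) and n <= 100_000 else None)
        return Alignments(ref=ref, pos=out_pos, strand=out_strand,
                          mismatches=out_mm, ref_ids=self.ref_ids,
                          ref_lengths=dict(self.ref_lengths), read_ids=read_ids)


def pseudo_align(reads, reference_transcripts, max_mismatches: int = 2) -> Alignments:
    """Align reads to reference transcripts with a mismatch budget.

    Returns an :class:`Alignments` container; iterate ``.records()`` for
    per-read :class:`AlignmentRecord` objects.
    """
    return PseudoAligner(reference_transcripts, max_mismatches).align(reads)


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def dedupe_reads(reads):
    """Remove exact-sequence duplicates, keeping each first occurrence.

    Duplicates are defined on the raw sequence only; a read and its reverse
    complement are distinct. Returns (unique_reads, n_removed).
    """
    mat = _as_matrix(reads)
    n = mat.shape[0]
    if n == 0:
        return reads, 0
    hi, lo = window_keys(mat, mat.shape[1])
    hi, lo = hi[:, 0], lo[:, 0]
    order = np.lexsort((np.arange(n), lo, hi))
    hs, ls = hi[order], lo[order]
    head = np.ones(n, bool)
    head[1:] = (np.diff(hs) != 0) | (np.diff(ls) != 0)
    keep = np.sort(order[head])
    n_removed = n - keep.size
    if isinstance(reads, ReadSet):
        return reads.subset(keep), n_removed
    return mat[keep], n_removed


def filter_rrna(reads, rrna_ref, max_mismatches: int = 2):
    """Remove reads aligning to rRNA on either strand within the budget.

    Returns (kept_reads, rrna_count, rrna_fraction).
    """
    recs = _as_records(rrna_ref)
    if not recs:
        raise ValueError("rRNA reference is empty")
    mat = _as_matrix(reads)
    if mat.shape[0] == 0:
        return reads, 0, 0.0
    mask = PseudoAligner(recs, max_mismatches).hit_mask(mat)
    n_rrna = int(mask.sum())
    keep = np.flatnonzero(~mask)
    kept = reads.subset(keep) if isinstance(reads, ReadSet) else mat[keep]
    return kept, n_rrna, n_rrna / mat.shape[0]


# ---------------------------------------------------------------------------
# counting
# ---------------------------------------------------------------------------

@dataclass
class CountTable:
    """Per-transcript raw and RPKM-normalised counts for one library."""

    table: pd.DataFrame           # index: transcript; columns: raw, rpkm
    total_mapped: int
    total_unique: int = 0
    rrna_count: int = 0
    library: str = ""

    def raw(self, transcript_id: str) -> int:
        return int(self.table.at[transcript_id, "raw"])

    def rpkm(self, transcript_id: str) -> float:
        return float(self.table.at[transcript_id, "rpkm"])

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index_label="transcript")


def count_and_normalize(alignments: Alignments, reference_lengths=None,
                        **meta) -> CountTable:
    """Raw counts and RPKM per transcript; zero-count transcripts included."""
    lengths = reference_lengths or alignments.ref_lengths
    ids = list(lengths)
    id_to_row = {i: r for r, i in enumerate(ids)}
    assigned = alignments.ref[alignments.assigned]
    total = assigned.size
    if total == 0:
        raise ValueError("zero mapped reads; cannot normalise")
    raw = np.zeros(len(ids), dtype=np.int64)
    counts = np.bincount(assigned, minlength=len(alignments.ref_ids))
    for ref_row, c in enumerate(counts):
        if c:
            raw[id_to_row[alignments.ref_ids[ref_row]]] += c
    kb = np.array([lengths[i] for i in ids]) / 1000.0
    rpkm = raw / (kb * (total / 1e6))
    df = pd.DataFrame({"raw": raw, "rpkm": rpkm}, index=pd.Index(ids, name="transcript"))
    return CountTable(table=df, total_mapped=int(total), **meta)


def replicate_r2(table_a: CountTable, table_b: CountTable) -> float:
    """Squared Pearson correlation of log2(RPKM+1) over expressed transcripts."""
    a, b = table_a.table, table_b.table
    if not a.index.equals(b.index):
        raise ValueError("count tables cover different transcript universes")
    mask = (a["rpkm"] > 0) | (b["rpkm"] > 0)
    if int(mask.sum()) < 3:
        raise ValueError("fewer than 3 shared expressed transcripts")
    x = np.log2(a.loc[mask, "rpkm"].to_numpy() + 1.0)
    y = np.log2(b.loc[mask, "rpkm"].to_numpy() + 1.0)
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def alignment_rate(reads, reference, max_mismatches: int = 2,
                   ambiguous: str = "discard") -> float:
    """Fraction of reads aligning to the reference.

    ``ambiguous="discard"`` (default) counts only reads with a unique
    minimal-mismatch transcript — the quantification policy. For a
    deliberately redundant reference such as a multi-k merged assembly use
    ``ambiguous="count"``, which counts any read with at least one in-budget
    locus (best-hit reporting, the convention short-read aligners use when
    quoting % aligned).
    """
    mat = _as_matrix(reads)
    if mat.shape[0] == 0:
        return 0.0
    aligner = PseudoAligner(reference, max_mismatches)
    if ambiguous == "count":
        return float(aligner.hit_mask(mat).mean())
    if ambiguous != "discard":
        raise ValueError("ambiguous must be 'discard' or 'count'")
    aln = aligner.align(mat)
    return aln.n_assigned / mat.shape[0]


def library_stats(n_input: int, n_unique: int, rrna_count: int,
                  alignments: Alignments) -> dict:
    """Per-library accounting (rRNA %, alignment %, ambiguity, duplicates)."""
    n_nonrrna = n_unique - rrna_count
    return {
        "n_input": n_input,
        "n_unique": n_unique,
        "n_duplicates": n_input - n_unique,
        "rrna_count": rrna_count,
        "rrna_fraction": rrna_count / n_unique if n_unique else 0.0,
        "n_aligned": alignments.n_assigned,
        "n_ambiguous": alignments.n_ambiguous,
        "n_unaligned": alignments.n_unaligned,
        "alignment_rate": alignments.n_assigned / n_nonrrna if n_nonrrna else 0.0,
    }
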
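"""Seeded ungapped local alignment with Karlin-Altschul statistics.

A generic exact-word seed index plus a batched X-drop ungapped extension,
instantiated for protein space (BLOSUM62, 4-mer words — the translated
search used for homology scaffolding) and nucleotide space (+1/-1, both
strands — UTR matching, containment-free paralog identity, and truth-set
matching). Gapped alignment is out of scope; only threshold behaviour at
the pipeline's e-value cutoffs matters, so e-values use the standard
ungapped Karlin-Altschul form

    bits = (lambda * S - ln K) / ln 2,   E = m * n * 2^(-bits)

with published ungapped constants (BLOSUM62: lambda=0.3176, K=0.134;
+1/-1 nucleotide: lambda=ln 3 exactly, K=0.35).
"""

from __future__ import annotations

from dataclasses import dataclass
from math import log

import numpy as np

from .seqs import encode, revcomp_codes

SENTINEL_SCORE = -10_000


def poly_keys(codes: np.ndarray, w: int, base: int) -> np.ndarray:
    """Polynomial keys of every w-window of a 1-D code array."""
    r = codes.size - w + 1
    if r <= 0:
        return np.empty(0, dtype=np.uint64)
    key = np.zeros(r, dtype=np.uint64)
    c = codes.astype(np.uint64)
    for j in range(w):
        key = key * np.uint64(base) + c[j:j + r]
    return key


class SeedIndex:
    """Sorted-array exact-word index over concatenated records.

    Records are joined with sentinel codes so windows never span records;
    positions are global into the padded concatenation.
    """

    def __init__(self, records_codes: list, word: int, alphabet: int):
        self.word = word
        self.alphabet = alphabet
        sent = np.array([alphabet], dtype=np.uint8)
        parts, offsets = [sent], []
        cursor = 1
        for codes in records_codes:
            offsets.append(cursor)
            parts.append(codes)
            parts.append(sent)
            cursor += codes.size + 1
        self.big = np.concatenate(parts)
        self.offsets = np.array(offsets, dtype=np.int64)
        self.lengths = np.array([c.size for c in records_codes], dtype=np.int64)
        self.total_residues = int(self.lengths.sum())
        keys, pos = [], []
        for off, ln in zip(self.offsets, self.lengths):
            k = poly_keys(self.big[off:off + ln], word, alphabet + 1)
            keys.append(k)
            pos.append(np.arange(off, off + max(ln - word + 1, 0)))
        keys = np.concatenate(keys) if keys else np.empty(0, np.uint64)
        pos = np.concatenate(pos) if pos else np.empty(0, np.int64)
        order = np.argsort(keys, kind="stable")
        self.sorted_keys = keys[order]
        self.sorted_pos = pos[order]

    def record_of(self, gpos: np.ndarray) -> np.ndarray:
        return np.searchsorted(self.offsets, gpos, side="right") - 1

    def lookup(self, query_keys: np.ndarray):
        """All (query_window, db_position) seed pairs."""
        lo = np.searchsorted(self.sorted_keys, query_keys, side="left")
        hi = np.searchsorted(self.sorted_keys, query_keys, side="right")
        counts = hi - lo
        owner = np.repeat(np.arange(query_keys.size), counts)
        cum = np.cumsum(counts)
        flat = (np.arange(int(counts.sum())) - np.repeat(cum - counts, counts)
                + np.repeat(lo, counts))
        return owner, self.sorted_pos[flat]


def _extend_dir(Q, D, lut, qpos, dpos, qinit, direction, init_score, xdrop):
    """One-directional X-drop extension; returns (best_score, best_endpoint).

    The endpoint is the exclusive query end for rightward extension and the
    inclusive query start for leftward; the database index stays on the seed
    diagonal (di = dpos + (qi - qpos)).
    """
    best = init_score.astype(np.int64).copy()
    end = qinit.copy()
    idx = np.arange(qpos.size)
    cur = best.copy()
    step = 0
    while idx.size:
        if direction > 0:
            qi = qinit[idx] + step
        else:
            qi = qinit[idx] - 1 - step
        di = dpos[idx] + (qi - qpos[idx])
        ok = (qi >= 0) & (di >= 0) & (qi < Q.size) & (di < D.size)
        if not ok.all():
            idx, cur, qi, di = idx[ok], cur[ok], qi[ok], di[ok]
            if idx.size == 0:
                break
        cur = cur + lut[Q[qi], D[di]]
        imp = cur > best[idx]
        sel = idx[imp]
        best[sel] = cur[imp]
        end[sel] = qi[imp] + (1 if direction > 0 else 0)
        keep = (best[idx] - cur) <= xdrop
        idx, cur = idx[keep], cur[keep]
        step += 1
    return best, end


def batch_extend(Q: np.ndarray, D: np.ndarray, qpos: np.ndarray,
                 dpos: np.ndarray, word: int, lut: np.ndarray, xdrop: int):
    """Ungapped X-drop extension of seed pairs on their shared diagonal.

    Q and D are sentinel-padded code arrays; the LUT scores (q, d) code
    pairs, with sentinel rows at SENTINEL_SCORE so extensions stop hard at
    record boundaries. Returns (score, qstart, qend); database endpoints
    follow the diagonal (dstart = dpos - (qpos - qstart), ...).
    """
    n = qpos.size
    if n == 0:
        z = np.empty(0, np.int64)
        return z, z.copy(), z.copy()
    seed_score = np.zeros(n, dtype=np.int64)
    for j in range(word):
        seed_score += lut[Q[qpos + j], D[dpos + j]]
    best_r, qend = _extend_dir(Q, D, lut, qpos, dpos, qpos + word, +1,
                               seed_score, xdrop)
    best, qstart = _extend_dir(Q, D, lut, qpos, dpos, qpos.copy(), -1,
                               best_r, xdrop)
    return best, qstart, qend


# ---------------------------------------------------------------------------
# alphabets and scoring
# ---------------------------------------------------------------------------

AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"
AA_STOP = 20          # '*' in six-frame translations: hard break
AA_SENTINEL = 21

_AA_CODE = np.full(256, AA_STOP, dtype=np.uint8)
for _i, _a in enumerate(AA_ORDER):
    _AA_CODE[ord(_a)] = _i
_AA_CODE[ord("*")] = AA_STOP


def aa_encode(pep: str) -> np.ndarray:
    """Encode a peptide; unknown residues behave like stops (hard break)."""
    return _AA_CODE[np.frombuffer(pep.encode("ascii"), dtype=np.uint8)]


def _blosum62_lut() -> np.ndarray:
    from Bio.Align import substitution_matrices

    m = substitution_matrices.load("BLOSUM62")
    lut = np.full((AA_SENTINEL + 1, AA_SENTINEL + 1), SENTINEL_SCORE,
                  dtype=np.int64)
    for i, a in enumerate(AA_ORDER):
        for j, b in enumerate(AA_ORDER):
            lut[i, j] = int(m[a][b])
    return lut


BLOSUM62_LUT = _blosum62_lut()

NT_SENTINEL = 4
_NT_LUT = np.full((5, 5), SENTINEL_SCORE, dtype=np.int64)
for _i in range(4):
    for _j in range(4):
        _NT_LUT[_i, _j] = 1 if _i == _j else -1

# ungapped Karlin-Altschul constants
PROT_LAMBDA, PROT_K = 0.3176, 0.134
NT_LAMBDA, NT_K = log(3.0), 0.35


def bit_score(raw: float, lam: float, k: float) -> float:
    return (lam * raw - log(k)) / log(2.0)


def evalue(raw: float, m: int, n: int, lam: float, k: float) -> float:
    return float(m) * float(n) * 2.0 ** (-bit_score(raw, lam, k))


@dataclass
class LocalHit:
    """Best ungapped local alignment between one query and one subject."""

    query_id: str
    subject_id: str
    score: int
    bits: float
    evalue: float
    qstart: int
    qend: int
    sstart: int
    send: int
    strand: str = "+"      # nucleotide searches only; query strand
    frame: int = 0         # protein searches: query frame label

    @property
    def span(self) -> int:
        return self.qend - self.qstart

    @property
    def identity(self) -> float:
        """Fraction identical, exact for +1/-1 scoring."""
        if self.span == 0:
            return 0.0
        return (self.score + self.span) / (2 * self.span)


def _dedupe_diagonals(qrec, drec, qpos, dpos):
    diag = qpos - dpos
    order = np.lexsort((qpos, diag, drec, qrec))
    qr, dr, dg = qrec[order], drec[order], diag[order]
    head = np.ones(order.size, bool)
    head[1:] = (np.diff(qr) != 0) | (np.diff(dr) != 0) | (np.diff(dg) != 0)
    return order[head]


class _SearchBase:
    """Shared seed-lookup / extend / per-pair-best machinery."""

    lam: float
    k_const: float

    def _raw_hits(self, q_codes_list, max_hits=None):
        """Extend deduped seed pairs; returns columnar hit arrays."""
        idx = self.index
        sent = np.array([idx.alphabet], dtype=np.uint8)
        parts, qoffsets = [sent], []
        cursor = 1
        for codes in q_codes_list:
            qoffsets.append(cursor)
            parts.append(codes)
            parts.append(sent)
            cursor += codes.size + 1
        Q = np.concatenate(parts)
        qoffsets = np.array(qoffsets, dtype=np.int64)
        qkeys, qpos_parts = [], []
        for off, codes in zip(qoffsets, q_codes_list):
            keys = poly_keys(Q[off:off + codes.size], idx.word, idx.alphabet + 1)
            qkeys.append(keys)
            qpos_parts.append(np.arange(off, off + keys.size))
        if not qkeys:
            return None
        qkeys = np.concatenate(qkeys)
        qpos_all = np.concatenate(qpos_parts)
        owner, dpos = idx.lookup(qkeys)
        if owner.size == 0:
            return None
        qpos = qpos_all[owner]
        qrec = np.searchsorted(qoffsets, qpos, side="right") - 1
        drec = idx.record_of(dpos)
        keep = _dedupe_diagonals(qrec, drec, qpos, dpos)
        qpos, dpos, qrec, drec = qpos[keep], dpos[keep], qrec[keep], drec[keep]
        score, qstart, qend = batch_extend(Q, idx.big, qpos, dpos,
                                           idx.word, self.lut, self.xdrop)
        dstart = dpos - (qpos - qstart)
        # best alignment per (query record, db record)
        order = np.lexsort((-score, drec, qrec))
        head = np.ones(order.size, bool)
        head[1:] = (np.diff(qrec[order]) != 0) | (np.diff(drec[order]) != 0)
        sel = order[head]
        return dict(qrec=qrec[sel], drec=drec[sel], score=score[sel],
                    qstart=(qstart - qoffsets[qrec])[sel],
                    qend=(qend - qoffsets[qrec])[sel],
                    dstart=(dstart - idx.offsets[drec])[sel],
                    dend=(dstart - idx.offsets[drec] + (qend - qstart))[sel])


class ProteinSearch(_SearchBase):
    """Exact-4-mer seeded, BLOSUM62 ungapped translated-space search."""

    lam, k_const = PROT_LAMBDA, PROT_K

    def __init__(self, db, word: int = 4, xdrop: int = 20):
        self.db_ids = [i for i, _p in db]
        self.db_lengths = [len(p) for _i, p in db]
        self.index = SeedIndex([aa_encode(p) for _i, p in db], word,
                               alphabet=AA_SENTINEL)
        self.lut = BLOSUM62_LUT
        self.xdrop = xdrop

    def search_peptides(self, queries, evalue_max=None, query_space=None):
        """Best hit per (query peptide, db protein).

        ``query_space`` optionally maps query index -> the m term of the
        e-value search space (e.g. the total six-frame residue count of the
        originating contig); defaults to the peptide length.
        """
        ids = [i for i, _p in queries]
        raw = self._raw_hits([aa_encode(p) for _i, p in queries])
        hits = []
        if raw is None:
            return hits
        for qi, di, sc, qs, qe, ds, de in zip(
                raw["qrec"], raw["drec"], raw["score"], raw["qstart"],
                raw["qend"], raw["dstart"], raw["dend"]):
            m = query_space[qi] if query_space is not None else len(queries[qi][1])
            e = evalue(sc, m, self.index.total_residues, self.lam, self.k_const)
            if evalue_max is not None and e > evalue_max:
                continue
            hits.append(LocalHit(ids[qi], self.db_ids[di], int(sc),
                                 bit_score(sc, self.lam, self.k_const), e,
                                 int(qs), int(qe), int(ds), int(de)))
        return hits


class NucleotideSearch(_SearchBase):
    """Exact-word seeded, +1/-1 ungapped nucleotide search, both strands."""

    lam, k_const = NT_LAMBDA, NT_K

    def __init__(self, db, word: int = 14, xdrop: int = 30):
        recs = [(i, s) for i, s in db]
        self.db_ids = [i for i, _s in recs]
        self.db_lengths = [len(s) for _i, s in recs]
        self.index = SeedIndex([encode(s) for _i, s in recs], word, alphabet=4)
        self.lut = _NT_LUT
        self.xdrop = xdrop

    def search(self, queries, evalue_max=None):
        """Best hit per (query, db record); query coords on the + strand."""
        ids = [i for i, _s in queries]
        lens = [len(s) for _i, s in queries]
        codes = []
        for _i, s in queries:
            c = encode(s)
            codes.append(c)
            codes.append(revcomp_codes(c))
        raw = self._raw_hits(codes)
        best: dict[tuple, LocalHit] = {}
        if raw is None:
            return []
        for qi2, di, sc, qs, qe, ds, de in zip(
                raw["qrec"], raw["drec"], raw["score"], raw["qstart"],
                raw["qend"], raw["dstart"], raw["dend"]):
            qi, is_rc = divmod(int(qi2), 2)
            L = lens[qi]
            if is_rc:   # map coords back to the + strand
                qs, qe = L - qe, L - qs
            e = evalue(sc, L, self.index.total_residues, self.lam, self.k_const)
            if evalue_max is not None and e > evalue_max:
                continue
            hit = LocalHit(ids[qi], self.db_ids[di], int(sc),
                           bit_score(sc, self.lam, self.k_const), e,
                           int(qs), int(qe), int(ds), int(de),
                           strand="-" if is_rc else "+")
            key = (qi, di)
            if key not in best or hit.score > best[key].score:
                best[key] = hit
        return list(best.values())

    def best_per_query(self, queries, evalue_max=None):
        out: dict[str, LocalHit] = {}
        for h in self.search(queries, evalue_max):
            if h.query_id not in out or h.score > out[h.query_id].score:
                out[h.query_id] = h
        return out
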
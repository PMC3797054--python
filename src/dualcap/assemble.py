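"""Minimal multi-k de Bruijn unitig assembler and assembly merging.

The assembler builds a canonical de Bruijn graph (each k-mer identified with
its reverse complement, as the libraries are unstranded) over k-mers observed
at least ``min_count`` times, and emits unitigs — maximal non-branching
paths — in deterministic lexicographic order. Multi-k assembly pools the
unitig sets of a range of k values; the merge step removes every contig that
occurs verbatim (either strand) inside a strictly longer contig, at 100%
identity only, so near-identical paralog pairs are never collapsed.

k-mers are bit-packed (two bits per base) into (hi, lo) uint64 pairs; all
set operations are sorted-array based, which keeps the assembler vectorised
end to end except for the final unitig walk.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .seqs import (decode, encode, keys_to_bytes, revcomp, window_keys,
                   window_keys_lo, _shift_in)

K_ODD = tuple(range(17, 42, 2))    # "run A" grid
K_EVEN = tuple(range(20, 41, 2))   # "run B" grid


@dataclass
class Contig:
    id: str
    sequence: str
    source_library: str = ""
    assembler_run: str = ""
    k: int = 0

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class MergedAssembly:
    """A containment-free contig set with per-contig provenance."""

    contigs: list
    provenance: dict = field(default_factory=dict)  # contig id -> [run labels]

    def __len__(self) -> int:
        return len(self.contigs)

    def sequences(self) -> list:
        return [c.sequence for c in self.contigs]


def _as_matrices(reads) -> list:
    """Normalise read input to a list of (N, L) uint8 code matrices."""
    from .simulate import ReadSet

    if isinstance(reads, ReadSet):
        return [reads.seqs]
    if isinstance(reads, np.ndarray):
        return [reads] if reads.size else []
    by_len: dict[int, list] = {}
    for s in reads:
        codes = s if isinstance(s, np.ndarray) else encode(s)
        by_len.setdefault(len(codes), []).append(codes)
    return [np.vstack(v) for _l, v in sorted(by_len.items())]


def _runlength_sum(hi, lo, cnt):
    order = np.lexsort((lo, hi))
    hs, ls, cs = hi[order], lo[order], cnt[order]
    head = np.ones(hs.size, bool)
    head[1:] = (np.diff(hs) != 0) | (np.diff(ls) != 0)
    idx = np.flatnonzero(head)
    return hs[idx], ls[idx], np.add.reduceat(cs, idx)


def _value_counts(vals: np.ndarray):
    """Unique values + counts of a uint64 array via an in-place value sort."""
    vals = np.sort(vals, kind="stable")
    head = np.ones(vals.size, bool)
    head[1:] = np.diff(vals) != 0
    idx = np.flatnonzero(head)
    return vals[idx], np.add.reduceat(np.ones(vals.size, np.int64), idx)


def canonical_kmer_counts(reads, k: int, chunk_elems: int = 16_000_000):
    """Counts of canonical k-mers (min of forward / reverse complement)."""
    small = k <= 32
    acc_h, acc_l, acc_c = [], [], []
    for mat in _as_matrices(reads):
        n, length = mat.shape
        if length < k:
            continue
        r = length - k + 1
        rows = max(1, chunk_elems // r)
        for c0 in range(0, n, rows):
            sub = mat[c0:c0 + rows]
            rc = (3 - sub)[:, ::-1]
            if small:
                fl = window_keys_lo(sub, k)
                rl = window_keys_lo(rc, k)[:, ::-1]  # rc window j <-> fwd j
                cl = np.minimum(fl, rl).ravel()
                ul, cnt = _value_counts(cl)
                uh = np.zeros_like(ul)
            else:
                fh, fl = window_keys(sub, k)
                rh, rl = window_keys(rc, k)
                rh, rl = rh[:, ::-1], rl[:, ::-1]
                use_f = (fh < rh) | ((fh == rh) & (fl <= rl))
                ch = np.where(use_f, fh, rh).ravel()
                cl = np.where(use_f, fl, rl).ravel()
                uh, ul, cnt = _runlength_sum(ch, cl, np.ones(cl.size, np.int64))
            acc_h.append(uh)
            acc_l.append(ul)
            acc_c.append(cnt)
    if not acc_h:
        return (np.empty(0, np.uint64),) * 2 + (np.empty(0, np.int64),)
    return _runlength_sum(np.concatenate(acc_h), np.concatenate(acc_l),
                          np.concatenate(acc_c))


def _unpack_keys(hi: np.ndarray, lo: np.ndarray, k: int) -> np.ndarray:
    """Inverse of packing: (n, k) uint8 code matrix."""
    n = hi.size
    out = np.empty((n, k), dtype=np.uint8)
    w = min(k, 32)
    for j in range(w):
        out[:, k - 1 - j] = ((lo >> np.uint64(2 * j)) & np.uint64(3)).astype(np.uint8)
    for j in range(k - 32):
        out[:, k - 33 - j] = ((hi >> np.uint64(2 * j)) & np.uint64(3)).astype(np.uint8)
    return out


def _pack_rows(mat: np.ndarray):
    hi, lo = window_keys(mat, mat.shape[1])
    return hi[:, 0], lo[:, 0]


def build_unitigs(reads, k: int, min_count: int = 2, source_library: str = "",
                  assembler_run: str = "") -> list:
    """Assemble unitigs from the canonical de Bruijn graph at one k.

    A unitig extends through a k-mer junction only when the extension is
    unique in both directions; reverse-complement-palindromic k-mers (even k)
    are treated as junctions. Output order is lexicographic over the
    strand-canonical unitig sequences, so results are deterministic and
    independent of read order.
    """
    uh, ul, cnt = canonical_kmer_counts(reads, k)
    keep = cnt >= min_count
    uh, ul = uh[keep], ul[keep]
    n = int(uh.size)
    if n == 0:
        warnings.warn(f"no k-mer passed min_count={min_count} at k={k}")
        return []

    C = _unpack_keys(uh, ul, k)          # canonical orientation (o=0)
    R = (3 - C)[:, ::-1]                 # reverse complement  (o=1)
    rh, rl = _pack_rows(R)
    pal = (rh == uh) & (rl == ul)

    small = k <= 32
    to_key = (lambda hi, lo: lo) if small else keys_to_bytes
    keys_all = np.concatenate([to_key(uh, ul), to_key(rh, rl)])
    state_all = np.concatenate([np.arange(n) * 2, np.arange(n) * 2 + 1])
    order = np.argsort(keys_all, kind="stable")
    sorted_keys, sorted_state = keys_all[order], state_all[order]

    two_n = 2 * n
    outdeg = np.zeros(two_n, dtype=np.uint8)
    succ = np.full(two_n, -1, dtype=np.int64)
    succ_base = np.zeros(two_n, dtype=np.uint8)
    for o, (bh, bl) in ((0, (uh, ul)), (1, (rh, rl))):
        for b in range(4):
            nh, nl = _shift_in(bh, bl, np.full(n, b, np.uint8), k)
            qk = to_key(nh, nl)
            p = np.searchsorted(sorted_keys, qk, side="left")
            p_clip = np.minimum(p, two_n - 1)
            found = sorted_keys[p_clip] == qk
            src = np.flatnonzero(found) * 2 + o
            outdeg[src] += 1
            succ[src] = sorted_state[p_clip[found]]
            succ_base[src] = b

    node = np.arange(two_n) >> 1
    valid = (outdeg == 1) & (succ >= 0) & ~pal[node]
    tgt = np.where(valid, succ, 0)
    valid &= (outdeg[tgt ^ 1] == 1) & ~pal[tgt >> 1]
    link = np.where(valid, succ, -1)

    link_l = link.tolist()
    base_l = succ_base.tolist()
    visited = bytearray(n)
    seqs_out = []

    def walk(s: int) -> None:
        i = s >> 1
        visited[i] = 1
        bases = []
        cur = s
        while True:
            t = link_l[cur]
            if t < 0 or visited[t >> 1]:
                break
            bases.append(base_l[cur])
            visited[t >> 1] = 1
            cur = t
        start_codes = C[i] if s & 1 == 0 else R[i]
        seq = decode(start_codes) + decode(np.array(bases, dtype=np.uint8))
        rc = revcomp(seq)
        seqs_out.append(seq if seq <= rc else rc)

    has_pred = link[np.arange(two_n) ^ 1] >= 0
    for s in np.flatnonzero(~has_pred):
        if not visited[s >> 1]:
            walk(int(s))
    for i in range(n):                       # leftovers are cycles
        if not visited[i]:
            walk(2 * i)

    seqs_out.sort()
    return [Contig(id=f"u{idx:06d}", sequence=s, source_library=source_library,
                   assembler_run=assembler_run, k=k)
            for idx, s in enumerate(seqs_out)]


def assemble_multi_k(reads, k_list, min_count: int = 2,
                     source_library: str = "", run_label: str = "") -> list:
    """Union of per-k unitig sets, each contig tagged with its k."""
    if not k_list:
        raise ValueError("k_list must be nonempty")
    contigs = []
    for k in k_list:
        part = build_unitigs(reads, k, min_count=min_count,
                             source_library=source_library,
                             assembler_run=run_label or f"k{k}")
        for c in part:
            c.id = f"{source_library or 'asm'}_k{k}_{c.id}"
        contigs.extend(part)
    return contigs


# ---------------------------------------------------------------------------
# containment merge
# ---------------------------------------------------------------------------

def _as_contigs(contigs) -> list:
    out = []
    for i, c in enumerate(contigs):
        if isinstance(c, Contig):
            out.append(c)
        else:
            out.append(Contig(id=f"c{i:06d}", sequence=c))
    return out


def remove_contained(contigs, min_len: int = 100) -> MergedAssembly:
    """Drop short contigs, then contigs contained verbatim in longer ones.

    A contig is removed when it is an exact substring — on either strand —
    of a strictly longer contig (the 100%-identity merge rule: anything less
    identical, e.g. a ~93% paralog pair, is kept). Equal-length duplicates,
    including reverse-complement pairs, collapse to the lexicographically
    smaller sequence. The result is an antichain under substring order and
    the operation is idempotent.
    """
    pool = [c for c in _as_contigs(contigs) if len(c.sequence) >= min_len]
    # collapse exact duplicates (both strands) onto the canonical sequence
    groups: dict[str, list] = {}
    for c in pool:
        rc = revcomp(c.sequence)
        canon = c.sequence if c.sequence <= rc else rc
        groups.setdefault(canon, []).append(c)
    canon_seqs = sorted(groups)
    if not canon_seqs:
        return MergedAssembly(contigs=[], provenance={})

    codes = [encode(s) for s in canon_seqs]
    lens = np.array([c.size for c in codes], dtype=np.int64)
    offsets = np.concatenate([[0], np.cumsum(lens)[:-1]])
    big = np.concatenate(codes)
    w = int(min(32, lens.min()))
    key_parts, pos_parts = [], []
    for off, ln in zip(offsets, lens):
        _hi, lo = window_keys(big[off:off + ln][None, :], w)
        key_parts.append(lo[0])
        pos_parts.append(np.arange(off, off + ln - w + 1))
    keys = np.concatenate(key_parts)
    pos = np.concatenate(pos_parts)
    order = np.argsort(keys, kind="stable")
    sorted_keys, sorted_pos = keys[order], pos[order]

    def contained(ci: int) -> bool:
        c = codes[ci]
        for probe in (c, (3 - c)[::-1]):
            _hi, lo = window_keys(probe[:w][None, :], w)
            key = lo[0, 0]
            a = np.searchsorted(sorted_keys, key, side="left")
            b = np.searchsorted(sorted_keys, key, side="right")
            for p in sorted_pos[a:b]:
                host = int(np.searchsorted(offsets, p, side="right") - 1)
                if host == ci or lens[host] <= lens[ci]:
                    continue
                if p + lens[ci] > offsets[host] + lens[host]:
                    continue
                if np.array_equal(big[p:p + lens[ci]], probe):
                    return True
        return False

    kept_contigs, provenance = [], {}
    for idx, seq in enumerate(canon_seqs):
        if contained(idx):
            continue
        members = sorted(groups[seq], key=lambda c: c.id)
        rep = members[0]
        cid = f"ctg{len(kept_contigs):06d}"
        kept_contigs.append(Contig(id=cid, sequence=seq,
                                   source_library=rep.source_library,
                                   assembler_run=rep.assembler_run, k=rep.k))
        provenance[cid] = sorted({m.assembler_run or m.id for m in members})
    return MergedAssembly(contigs=kept_contigs, provenance=provenance)


def assembly_stats(merged) -> dict:
    """Length-class counts with strict thresholds (>100 bp ... >5 kb)."""
    contigs = merged.contigs if isinstance(merged, MergedAssembly) else _as_contigs(merged)
    lengths = [len(c.sequence) for c in contigs]
    return {f">{label}": sum(1 for ln in lengths if ln > cut)
            for label, cut in (("100bp", 100), ("0.5kb", 500),
                               ("1kb", 1000), ("5kb", 5000))}
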
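"""Tiered translated-homology scaffolding.

Assembled contigs are searched, in translated (six-frame) space, against a
ranked series of reference protein sets — a well-annotated set first, then a
gene-prediction set, then a cross-species protein set. Assignment is
sequential: a contig that passes the e-value threshold in tier 1 is claimed
by its best tier-1 reference and never reaches tier 2, even if a later tier
would score better. Contigs sharing a best reference form a cluster (the
"scaffold"), are renamed after it, and the fraction of the reference covered
by the union of their alignments summarises how complete the assembly is at
gene level.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .homology import NucleotideSearch, ProteinSearch
from .seqs import encode, revcomp_codes


def _codon_lut() -> np.ndarray:
    from Bio.Data import CodonTable

    table = CodonTable.unambiguous_dna_by_id[1]
    lut = np.full(64, ord("*"), dtype=np.uint8)
    order = "ACGT"
    for codon, aa in table.forward_table.items():
        i = (order.index(codon[0]) * 16 + order.index(codon[1]) * 4
             + order.index(codon[2]))
        lut[i] = ord(aa)
    return lut


_CODON_LUT = _codon_lut()


def translate_frame(codes: np.ndarray) -> str:
    """Translate a code array in frame 0 (standard code, stops as '*')."""
    n = codes.size // 3
    if n == 0:
        return ""
    c = codes[: 3 * n].reshape(n, 3).astype(np.int64)
    return _CODON_LUT[c[:, 0] * 16 + c[:, 1] * 4 + c[:, 2]].tobytes().decode()


def six_frame_translate(sequence: str) -> list:
    """Peptides of frames +1, +2, +3, -1, -2, -3 (stops rendered '*')."""
    if len(sequence) < 3:
        raise ValueError("sequence shorter than one codon")
    codes = encode(sequence)
    rc = revcomp_codes(codes)
    return [translate_frame(codes[f:]) for f in range(3)] + \
           [translate_frame(rc[f:]) for f in range(3)]


FRAME_LABELS = (1, 2, 3, -1, -2, -3)


@dataclass
class HomologyHit:
    """A translated-search match of a contig to a reference protein."""

    contig_id: str
    reference_id: str
    tier: int
    bit_score: float
    evalue: float
    query_range: tuple          # nt coords on the contig + strand
    reference_range: tuple      # aa coords on the reference
    frame: int                  # +1..+3 / -1..-3


@dataclass
class ScaffoldCluster:
    """A reference protein with the contigs assigned to it."""

    reference_id: str
    tier: int
    members: list = field(default_factory=list)   # (renamed, contig_id, ref_range)
    reference_length: int = 0

    @property
    def coverage_fraction(self) -> float:
        return reference_coverage([m[2] for m in self.members],
                                  self.reference_length)


def _frame_to_nt(frame: int, qs: int, qe: int, length: int) -> tuple:
    off = abs(frame) - 1
    a, b = off + 3 * qs, off + 3 * qe
    if frame > 0:
        return (a, b)
    return (length - b, length - a)


def translated_search(contigs, protein_db, evalue_max: float = 1e-10,
                      searcher: Optional[ProteinSearch] = None,
                      tier: int = 0) -> list:
    """Six-frame BLASTX-style search of contigs against a protein set.

    Seeds are exact peptide 4-mers, extended ungapped under BLOSUM62 with an
    X-drop; the e-value search space is (total six-frame residues of the
    contig) x (total database residues). The best hit per (contig,
    reference) is kept; hits are filtered at ``evalue_max``.
    """
    if isinstance(contigs, (tuple,)) and len(contigs) == 2 \
            and isinstance(contigs[1], str):
        contigs = [contigs]
    recs = [(c.id, c.sequence) if hasattr(c, "sequence") else (c[0], c[1])
            for c in contigs]
    if searcher is None:
        if not protein_db:
            raise ValueError("protein database is empty")
        searcher = ProteinSearch(protein_db)
    queries, qspace, meta = [], [], []
    for cid, seq in recs:
        if len(seq) < 3:
            continue
        frames = six_frame_translate(seq)
        total = sum(len(p) for p in frames)
        for label, pep in zip(FRAME_LABELS, frames):
            if len(pep) >= searcher.index.word:
                queries.append((f"{cid}||{label}", pep))
                qspace.append(total)
                meta.append((cid, label, len(seq)))
    hits = searcher.search_peptides(queries, evalue_max=evalue_max,
                                    query_space=np.array(qspace)
                                    if qspace else None)
    best: dict[tuple, HomologyHit] = {}
    meta_by_id = {q[0]: m for q, m in zip(queries, meta)}
    for h in hits:
        cid, frame, length = meta_by_id[h.query_id]
        hh = HomologyHit(cid, h.subject_id, tier, h.bits, h.evalue,
                         _frame_to_nt(frame, h.qstart, h.qend, length),
                         (h.sstart, h.send), frame)
        key = (cid, h.subject_id)
        prev = best.get(key)
        if prev is None or (hh.evalue, -hh.bit_score) < (prev.evalue,
                                                         -prev.bit_score):
            best[key] = hh
    return list(best.values())


def _best_hit(hits: list) -> HomologyHit:
    return min(hits, key=lambda h: (h.evalue, -h.bit_score, h.reference_id))


def tiered_scaffold(contigs, tiers, evalue_max: float = 1e-10):
    """Sequential assignment of contigs to ranked reference protein sets.

    Returns (clusters, unassigned_contig_ids). Tier-1 assignments are made
    before tiers 2-3 are consulted, so they cannot be changed by the content
    of later tiers. Cluster members are renamed ``<reference>.<n>``.
    """
    recs = [(c.id, c.sequence) if hasattr(c, "sequence") else (c[0], c[1])
            for c in contigs]
    remaining = list(recs)
    clusters: dict[tuple, ScaffoldCluster] = {}
    for tier_no, db in enumerate(tiers, start=1):
        if not remaining or not db:
            continue
        db_len = {i: len(p) for i, p in db}
        hits = translated_search(remaining, db, evalue_max, tier=tier_no)
        by_contig: dict[str, list] = {}
        for h in hits:
            by_contig.setdefault(h.contig_id, []).append(h)
        assigned = set()
        for cid, contig_hits in by_contig.items():
            best = _best_hit(contig_hits)
            key = (tier_no, best.reference_id)
            cluster = clusters.setdefault(
                key, ScaffoldCluster(best.reference_id, tier_no,
                                     reference_length=db_len[best.reference_id]))
            cluster.members.append((None, cid, best.reference_range))
            assigned.add(cid)
        remaining = [r for r in remaining if r[0] not in assigned]
    for cluster in clusters.values():
        cluster.members.sort(key=lambda m: m[1])
        cluster.members = [(f"{cluster.reference_id}.{n}", cid, rng)
                           for n, (_old, cid, rng)
                           in enumerate(cluster.members, start=1)]
    ordered = sorted(clusters.values(), key=lambda c: (c.tier, c.reference_id))
    return ordered, [r[0] for r in remaining]


def reference_coverage(ranges, reference_length: int) -> float:
    """Fraction of a reference covered by the union of aligned ranges."""
    if reference_length <= 0:
        return 0.0
    covered = 0
    last_end = None
    for start, end in sorted((max(0, s), min(reference_length, e))
                             for s, e in ranges):
        if last_end is None or start > last_end:
            covered += max(0, end - start)
            last_end = end
        elif end > last_end:
            covered += end - last_end
            last_end = end
    return covered / reference_length


def overlap_sets(assignments_by_pipeline: dict) -> dict:
    """Exclusive Venn-region counts over >=2 labelled reference-id sets."""
    labels = sorted(assignments_by_pipeline)
    if len(labels) < 2:
        raise ValueError("need at least 2 labelled sets")
    universe = set().union(*assignments_by_pipeline.values())
    regions: dict[tuple, int] = {}
    for item in universe:
        key = tuple(lb for lb in labels if item in assignments_by_pipeline[lb])
        regions[key] = regions.get(key, 0) + 1
    return regions


def nucleotide_homology(contig, reference_tx, min_identity: float = 0.80,
                        min_query_cov: float = 0.50) -> bool:
    """Ungapped-local-alignment homology call between two nucleotide seqs.

    True iff the best local alignment (either strand, +1/-1 scoring) reaches
    ``min_identity`` over its span and the span covers ``min_query_cov`` of
    the contig.
    """
    seq = contig.sequence if hasattr(contig, "sequence") else contig
    ref = reference_tx.sequence if hasattr(reference_tx, "sequence") else reference_tx
    hits = NucleotideSearch([("ref", ref)]).search([("q", seq)])
    return any(h.identity >= min_identity
               and h.span >= min_query_cov * len(seq) for h in hits)


def match_reference_set(contigs, references, min_identity: float = 0.80,
                        min_query_cov: float = 0.50) -> set:
    """Reference ids matched by any contig under the homology rule."""
    recs = [(c.id, c.sequence) if hasattr(c, "sequence") else (c[0], c[1])
            for c in contigs]
    refs = [(r.id, r.sequence) if hasattr(r, "sequence") else (r[0], r[1])
            for r in references]
    if not recs or not refs:
        return set()
    engine = NucleotideSearch(refs)
    matched = set()
    lens = {i: len(s) for i, s in recs}
    for h in engine.search(recs):
        if h.identity >= min_identity and h.span >= min_query_cov * lens[h.query_id]:
            matched.add(h.subject_id)
    return matched
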
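"""Synthetic dual-capture experiment generator.

Builds a toy transcriptome in the biological setting the pipeline targets: a
transcriptionally silent egg/early-embryo system in which per-transcript
abundance is constant between the mitotic (M) and interphase (IF) states and
only poly(A) tail lengths change; an allotetraploid-style paralog structure
(~93% nucleotide identity pairs); heavy rRNA background with a small
post-capture carryover; and two capture chemistries — oligo-dT, whose
efficiency rises with tail length and is zero below an 18-A anchor, and
5'-cap capture, which is tail-independent.

Everything downstream of this module (quantification, poly(A) calls,
assembly, scaffolding, triage) is validated against the ground truth emitted
here.
"""

from __future__ import annotations

import dataclasses
import itertools
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import seqs
from .seqs import decode, encode, revcomp_codes

STOP_CODONS = {"TAA", "TAG", "TGA"}
START_CODON = "ATG"


class ConfigurationError(ValueError):
    """Invalid simulation configuration."""


class SimulationError(RuntimeError):
    """A library cannot be simulated under the given conditions."""


@dataclass
class SimConfig:
    """Parameters of the synthetic experiment.

    Tail lengths are in nucleotides, fractions in [0, 1]. ``seed`` fully
    determines every output byte.
    """

    n_genes: int = 909
    paralog_fraction: float = 0.10
    paralog_identity_mean: float = 0.931
    paralog_identity_sd: float = 0.0272
    rrna_fraction_total: float = 0.95   # rRNA share of total RNA, pre-capture
    rrna_carryover: float = 0.02        # residual rRNA share post-capture
    read_length: int = 50
    n_reads: int = 2_000_000
    error_rate: float = 0.001
    duplicate_rate: float = 0.05
    anchor_len: int = 18
    dt_half_saturation: float = 30.0
    dt_pmax: float = 0.9
    pcap: float = 0.8
    seed: int = 1

    # transcript pool composition
    min_len: int = 200
    max_len: int = 3000
    abundance_sigma: float = 1.5
    coding_fraction: float = 0.85
    ncrna_fraction: float = 0.10        # remainder are utr_fragment (uncapped)
    n_deadenylated: int = 60            # planted tail_M=150 -> tail_IF=10
    n_adenylated: int = 40              # planted tail_M=10 -> tail_IF=150
    short_tail_fraction: float = 0.15   # tails < anchor in both states
    tail_planted_long: int = 150
    tail_short: int = 10
    tail_base_low: int = 60
    tail_base_high: int = 200
    tier_fractions: tuple = (0.70, 0.15, 0.10)
    intergenic_len: int = 500

    def __post_init__(self):
        self.tier_fractions = tuple(self.tier_fractions)

    def validate(self) -> None:
        fracs = dict(
            paralog_fraction=self.paralog_fraction,
            rrna_fraction_total=self.rrna_fraction_total,
            rrna_carryover=self.rrna_carryover,
            duplicate_rate=self.duplicate_rate,
            error_rate=self.error_rate,
            coding_fraction=self.coding_fraction,
            ncrna_fraction=self.ncrna_fraction,
            short_tail_fraction=self.short_tail_fraction,
        )
        for name, v in fracs.items():
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name}={v} outside [0, 1]")
        if self.n_genes < 10:
            raise ConfigurationError("n_genes must be >= 10")
        if self.coding_fraction + self.ncrna_fraction > 1.0:
            raise ConfigurationError("biotype fractions exceed 1")
        if not 0 < self.dt_pmax <= 1 or not 0 < self.pcap <= 1:
            raise ConfigurationError("capture maxima must be in (0, 1]")
        if self.dt_half_saturation <= 0:
            raise ConfigurationError("dt_half_saturation must be positive")
        if self.min_len < self.read_length:
            raise ConfigurationError("min_len shorter than read_length")


@dataclass
class SimTranscript:
    """A ground-truth transcript with per-state poly(A) tail lengths."""

    id: str
    gene_id: str
    paralog_group: Optional[str]
    sequence: str
    biotype: str                 # coding | ncRNA | utr_fragment
    abundance: float             # molar fraction; identical in both states
    tail_M: int
    tail_IF: int
    capped: bool
    cds_start: Optional[int] = None   # 0-based half-open CDS incl. stop codon
    cds_end: Optional[int] = None
    regulation: str = "none"     # planted truth: deadenylated | adenylated | none

    def tail(self, state: str) -> int:
        if state == "M":
            return self.tail_M
        if state == "IF":
            return self.tail_IF
        raise ValueError(f"unknown state {state!r}")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class GenomeRecord:
    """Toy genome: concatenated gene loci with intergenic spacers."""

    sequence: str
    loci: list  # (transcript_id, start, end), 0-based half-open


@dataclass
class SimulatedExperiment:
    """Full output of :func:`simulate_transcriptome`."""

    pool: list
    genome: GenomeRecord
    rrna: list                    # (id, sequence) records
    annotation_tiers: list        # three ranked lists of (protein_id, peptide)
    utr_db: list                  # (id, 3'UTR sequence) for annotated coding genes
    config: SimConfig = None

    def __iter__(self):  # allow tuple-style unpacking (pool, genome, rrna, tiers)
        return iter((self.pool, self.genome, self.rrna, self.annotation_tiers))


# ---------------------------------------------------------------------------
# capture models
# ---------------------------------------------------------------------------

def capture_probability_dT(tail_len: int, anchor_len: int = 18,
                           half_saturation: float = 30.0, pmax: float = 0.9) -> float:
    """Oligo-dT capture probability as a saturating function of tail length.

    Zero below the anchored-primer minimum (the oligo needs ``anchor_len``
    consecutive adenosines to prime), then a hyperbola rising to ``pmax``.
    """
    if tail_len < 0:
        raise ValueError("tail_len must be >= 0")
    if tail_len < anchor_len:
        return 0.0
    x = tail_len - anchor_len + 1
    return pmax * x / (x + half_saturation)


def capture_probability_cap(capped: bool, pcap: float = 0.8) -> float:
    """Cap-capture probability: tail-independent, zero for uncapped RNAs."""
    return pcap if capped else 0.0


def mutate_to_identity(sequence: str, target_identity: float, rng) -> str:
    """Substitute bases so the result has Hamming identity round(L*t)/L.

    Substitutions only (no indels), so identity arithmetic stays exact.
    """
    if not 0 < target_identity <= 1:
        raise ValueError("target_identity must be in (0, 1]")
    codes = encode(sequence).copy()
    n_sub = len(codes) - int(round(len(codes) * target_identity))
    if n_sub == 0:
        return sequence
    pos = rng.choice(len(codes), size=n_sub, replace=False)
    codes[pos] = (codes[pos] + rng.integers(1, 4, size=n_sub)) % 4
    return decode(codes)


# ---------------------------------------------------------------------------
# transcript pool
# ---------------------------------------------------------------------------

def _random_seq(rng, length: int) -> np.ndarray:
    return rng.integers(0, 4, size=length, dtype=np.uint8).astype(np.uint8)

_NONSTOP = [c for c in ("".join(b) for b in itertools.product("ACGT", repeat=3))
            if c not in STOP_CODONS]


def _coding_sequence(rng, length: int):
    """Random transcript with a planted 5'UTR / ORF / 3'UTR structure."""
    utr5 = max(10, int(round(0.10 * length)))
    n_codons = max(20, int(0.60 * length) // 3)  # incl. start, excl. stop
    cds_len = 3 * n_codons + 3
    utr3 = length - utr5 - cds_len
    if utr3 < 10:
        utr3 = 10
        length = utr5 + cds_len + utr3
    body = [START_CODON]
    body.extend(np.array(_NONSTOP)[rng.integers(0, len(_NONSTOP), n_codons - 1)])
    body.append(("TAA", "TAG", "TGA")[rng.integers(0, 3)])
    cds = "".join(body)
    seq = decode(_random_seq(rng, utr5)) + cds + decode(_random_seq(rng, utr3))
    return seq, utr5, utr5 + cds_len


def _truncated_normal(rng, mean, sd, low, high):
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if low < x < high:
            return x
    return min(max(mean, low + 1e-9), high - 1e-9)


def simulate_transcriptome(config: SimConfig) -> SimulatedExperiment:
    """Generate the ground-truth pool, toy genome, rRNA and annotation tiers.

    Deterministic under ``config.seed``. A ``paralog_fraction`` of genes get a
    partner transcript whose pairwise identity is drawn from a normal
    distribution truncated to (0.85, 0.995); annotation tiers hold proteins
    for ~70% / 15% / 10% of coding genes with ~5% absent from all tiers.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    n = config.n_genes
    lengths = rng.integers(config.min_len, config.max_len + 1, size=n)
    n_coding = int(round(config.coding_fraction * n))
    n_ncrna = int(round(config.ncrna_fraction * n))
    biotypes = (["coding"] * n_coding + ["ncRNA"] * n_ncrna
                + ["utr_fragment"] * (n - n_coding - n_ncrna))
    rng.shuffle(biotypes)

    pool: list[SimTranscript] = []
    for i in range(n):
        bt = biotypes[i]
        if bt == "coding":
            seq, cs, ce = _coding_sequence(rng, int(lengths[i]))
        else:
            seq, cs, ce = decode(_random_seq(rng, int(lengths[i]))), None, None
        pool.append(SimTranscript(
            id=f"tx{i:05d}", gene_id=f"g{i:05d}", paralog_group=None,
            sequence=seq, biotype=bt, abundance=0.0, tail_M=0, tail_IF=0,
            capped=(bt != "utr_fragment"), cds_start=cs, cds_end=ce))

    # paralog partners: separate genes in a shared family, diverged ~93%
    n_paralog = int(round(config.paralog_fraction * n))
    partner_of = rng.choice(n, size=n_paralog, replace=False) if n_paralog else []
    for j, gi in enumerate(sorted(int(x) for x in np.atleast_1d(partner_of))):
        base = pool[gi]
        ident = _truncated_normal(rng, config.paralog_identity_mean,
                                  config.paralog_identity_sd, 0.85, 0.995)
        group = f"pg{gi:05d}"
        base.paralog_group = group
        pool.append(SimTranscript(
            id=f"tx{n + j:05d}", gene_id=f"g{gi:05d}p", paralog_group=group,
            sequence=mutate_to_identity(base.sequence, ident, rng),
            biotype=base.biotype, abundance=0.0, tail_M=0, tail_IF=0,
            capped=base.capped, cds_start=base.cds_start, cds_end=base.cds_end))

    n_tx = len(pool)
    ab = rng.lognormal(mean=0.0, sigma=config.abundance_sigma, size=n_tx)
    ab /= ab.sum()
    for t, a in zip(pool, ab):
        t.abundance = float(a)

    # tail-length truth: planted regulation + a short-tail-in-both-states class
    base_tails = rng.integers(config.tail_base_low, config.tail_base_high + 1,
                              size=n_tx)
    for t, b in zip(pool, base_tails):
        t.tail_M = t.tail_IF = int(b)
    n_short = int(round(config.short_tail_fraction * n_tx))
    order = rng.permutation(n_tx)
    n_planted = config.n_deadenylated + config.n_adenylated
    if n_planted + n_short > n_tx:
        raise ConfigurationError("planted classes exceed pool size")
    coding_first = sorted(order, key=lambda i: pool[i].biotype != "coding")
    dead = coding_first[:config.n_deadenylated]
    aden = coding_first[config.n_deadenylated:n_planted]
    rest = [i for i in order if i not in set(coding_first[:n_planted])]
    short = rest[:n_short]
    for i in dead:
        pool[i].tail_M, pool[i].tail_IF = config.tail_planted_long, config.tail_short
        pool[i].regulation = "deadenylated"
    for i in aden:
        pool[i].tail_M, pool[i].tail_IF = config.tail_short, config.tail_planted_long
        pool[i].regulation = "adenylated"
    for i in short:
        pool[i].tail_M = pool[i].tail_IF = config.tail_short

    genome = _build_genome(pool, rng, config.intergenic_len)
    rrna = [("rRNA_18S", decode(_random_seq(rng, 1800))),
            ("rRNA_28S", decode(_random_seq(rng, 4000)))]
    tiers, utr_db = _build_annotation(pool, rng, config.tier_fractions)
    return SimulatedExperiment(pool=pool, genome=genome, rrna=rrna,
                               annotation_tiers=tiers, utr_db=utr_db,
                               config=config)


def _build_genome(pool, rng, spacer: int) -> GenomeRecord:
    parts, loci, cursor = [], [], 0
    for t in pool:
        gap = decode(_random_seq(rng, spacer))
        parts.append(gap)
        cursor += spacer
        parts.append(t.sequence)
        loci.append((t.id, cursor, cursor + len(t.sequence)))
        cursor += len(t.sequence)
    parts.append(decode(_random_seq(rng, spacer)))
    return GenomeRecord(sequence="".join(parts), loci=loci)


def translate_cds(seq: str) -> str:
    """Translate an in-frame CDS (standard code), truncating at the first stop."""
    from .scaffold import translate_frame
    pep = translate_frame(encode(seq))
    stop = pep.find("*")
    return pep if stop < 0 else pep[:stop]


def _build_annotation(pool, rng, tier_fractions):
    coding = [t for t in pool if t.biotype == "coding"]
    order = rng.permutation(len(coding))
    f1, f2, f3 = tier_fractions
    n1 = int(round(f1 * len(coding)))
    n2 = int(round(f2 * len(coding)))
    n3 = int(round(f3 * len(coding)))
    groups = (order[:n1], order[n1:n1 + n2], order[n1 + n2:n1 + n2 + n3])
    prefixes = ("ENS", "GEN", "UNI")
    tiers = []
    for prefix, idx in zip(prefixes, groups):
        tier = []
        for i in sorted(int(x) for x in idx):
            t = coding[i]
            pep = translate_cds(t.sequence[t.cds_start:t.cds_end - 3])
            if len(pep) >= 20:
                tier.append((f"{prefix}_{t.gene_id}", pep))
        tiers.append(tier)
    annotated = {coding[int(i)].id for g in groups for i in g}
    utr_db = [(f"utr3_{t.gene_id}", t.sequence[t.cds_end:])
              for t in coding if t.id in annotated and len(t.sequence) - t.cds_end >= 50]
    return tiers, utr_db


# ---------------------------------------------------------------------------
# read sets
# ---------------------------------------------------------------------------

@dataclass
class ReadSet:
    """A simulated library held columnar.

    ``seqs`` is an (N, read_length) uint8 code matrix; ``src`` indexes the
    transcript pool (negative values -1, -2, ... index rRNA records); ``pos``
    is the 0-based start of the sampled window on the source sense strand and
    ``strand`` is 0 (+) or 1 (-). Iteration yields the per-read tuples
    (read_id, sequence, truth_id, truth_pos).
    """

    seqs: np.ndarray
    src: np.ndarray
    pos: np.ndarray
    strand: np.ndarray
    state: str
    method: str
    pool_ids: list = field(default_factory=list)
    rrna_ids: list = field(default_factory=list)

    def __len__(self) -> int:
        return self.seqs.shape[0]

    @property
    def read_length(self) -> int:
        return self.seqs.shape[1]

    def read_id(self, i: int) -> str:
        return f"{self.method}_{self.state}_{i:08d}"

    def truth_id(self, i: int) -> str:
        s = int(self.src[i])
        return self.pool_ids[s] if s >= 0 else "rRNA"

    def sequence(self, i: int) -> str:
        return decode(self.seqs[i])

    def __iter__(self):
        for i in range(len(self)):
            yield (self.read_id(i), self.sequence(i), self.truth_id(i),
                   int(self.pos[i]))

    def subset(self, index) -> "ReadSet":
        return dataclasses.replace(
            self, seqs=self.seqs[index], src=self.src[index],
            pos=self.pos[index], strand=self.strand[index])

    @classmethod
    def concatenate(cls, readsets) -> "ReadSet":
        first = readsets[0]
        return dataclasses.replace(
            first,
            seqs=np.concatenate([r.seqs for r in readsets]),
            src=np.concatenate([r.src for r in readsets]),
            pos=np.concatenate([r.pos for r in readsets]),
            strand=np.concatenate([r.strand for r in readsets]),
            state="+".join(dict.fromkeys(r.state for r in readsets)),
            method="+".join(dict.fromkeys(r.method for r in readsets)))

    def to_fastq(self, path) -> None:
        """Write FASTQ with a fixed quality string (qualities are never used)."""
        qual = "I" * self.read_length
        with open(path, "w") as fh:
            for i in range(len(self)):
                fh.write(f"@{self.read_id(i)}\n{self.sequence(i)}\n+\n{qual}\n")

    @classmethod
    def from_fastq(cls, path, state: str = "NA", method: str = "NA") -> "ReadSet":
        from Bio.SeqIO.QualityIO import FastqGeneralIterator

        mats = []
        with open(path) as fh:
            for _title, seq, _q in FastqGeneralIterator(fh):
                mats.append(encode(seq))
        seqs_ = np.vstack(mats) if mats else np.zeros((0, 50), np.uint8)
        n = seqs_.shape[0]
        return cls(seqs=seqs_, src=np.full(n, -1, np.int32),
                   pos=np.zeros(n, np.int32), strand=np.zeros(n, np.int8),
                   state=state, method=method)


def _capture_weights(pool, state: str, method: str, config: SimConfig):
    w = np.empty(len(pool))
    for i, t in enumerate(pool):
        if method == "dT":
            w[i] = t.abundance * capture_probability_dT(
                t.tail(state), config.anchor_len,
                config.dt_half_saturation, config.dt_pmax)
        elif method == "cap":
            w[i] = t.abundance * capture_probability_cap(t.capped, config.pcap)
        else:
            raise ValueError(f"unknown capture method {method!r}")
    return w


def _sample_windows(big: np.ndarray, offsets: np.ndarray, lengths: np.ndarray,
                    which: np.ndarray, rng, read_len: int):
    """Gather read windows: uniform priming position, window clamped at 3' end."""
    L = lengths[which]
    u = (rng.random(which.size) * L).astype(np.int64)
    start = np.minimum(u, L - read_len)
    flat = offsets[which] + start
    mat = big[flat[:, None] + np.arange(read_len)]
    return mat, start.astype(np.int32)


def simulate_library(pool, state: str, method: str, config: SimConfig,
                     rng=None, rrna=None) -> ReadSet:
    """Simulate one single-end library under the given capture chemistry.

    Transcript sampling weight is abundance x capture probability; read start
    positions follow a uniform random-priming model; reads are unstranded
    (either strand with probability 0.5); substitution errors occur at
    ``error_rate`` per base; a ``duplicate_rate`` fraction of reads are
    verbatim PCR re-emissions, and ``rrna_carryover`` of reads come from the
    ``rrna`` records (required whenever carryover is nonzero).
    """
    if not pool:
        raise SimulationError("empty transcript pool")
    if rng is None:
        rng = np.random.default_rng(
            np.random.SeedSequence([config.seed, {"M": 0, "IF": 1}[state],
                                    {"dT": 0, "cap": 1}[method]]))
    w = _capture_weights(pool, state, method, config)
    if w.sum() <= 0:
        raise SimulationError("empty capturable pool")
    p = w / w.sum()

    R = config.read_length
    n_total = config.n_reads
    n_rrna = rng.binomial(n_total, config.rrna_carryover)
    n_dup = rng.binomial(n_total - n_rrna, config.duplicate_rate)
    n_base = n_total - n_rrna - n_dup

    big = np.concatenate([encode(t.sequence) for t in pool])
    lengths = np.array([len(t.sequence) for t in pool])
    offsets = np.concatenate([[0], np.cumsum(lengths)[:-1]])

    which = rng.choice(len(pool), size=n_base, p=p)
    mat, start = _sample_windows(big, offsets, lengths, which, rng, R)

    # rRNA carryover reads
    rrna_records = rrna
    if n_rrna and not rrna_records:
        raise SimulationError("rRNA carryover requested but no rRNA records "
                              "given; pass rrna=... or set rrna_carryover=0")
    if n_rrna:
        rlens = np.array([len(s) for _i, s in rrna_records])
        rbig = np.concatenate([encode(s) for _i, s in rrna_records])
        roff = np.concatenate([[0], np.cumsum(rlens)[:-1]])
        rp = rlens / rlens.sum()
        rwhich = rng.choice(len(rrna_records), size=n_rrna, p=rp)
        rmat, rstart = _sample_windows(rbig, roff, rlens, rwhich, rng, R)
        mat = np.concatenate([mat, rmat])
        start = np.concatenate([start, rstart])
        which = np.concatenate([which, -(rwhich.astype(np.int64) + 1)])

    # unstranded: flip half the reads to the minus strand
    strand = rng.integers(0, 2, size=mat.shape[0]).astype(np.int8)
    minus = strand == 1
    mat[minus] = revcomp_codes(mat[minus])

    # substitution errors (expected-count placement; collisions negligible)
    if config.error_rate > 0:
        n_err = rng.binomial(mat.size, config.error_rate)
        flat_idx = rng.integers(0, mat.size, size=n_err)
        shift = rng.integers(1, 4, size=n_err).astype(np.uint8)
        mat.reshape(-1)[flat_idx] = (mat.reshape(-1)[flat_idx] + shift) % 4

    # PCR duplicates: verbatim re-emissions of already-made reads
    if n_dup:
        copies = rng.integers(0, mat.shape[0], size=n_dup)
        mat = np.concatenate([mat, mat[copies]])
        start = np.concatenate([start, start[copies]])
        which = np.concatenate([which, which[copies]])
        strand = np.concatenate([strand, strand[copies]])

    return ReadSet(seqs=mat, src=which.astype(np.int32), pos=start,
                   strand=strand, state=state, method=method,
                   pool_ids=[t.id for t in pool],
                   rrna_ids=[i for i, _s in rrna_records] if n_rrna else [])


def tile_reads(pool, read_length: int = 50, stride: int = 1,
               both_strands: bool = True) -> ReadSet:
    """Deterministic error-free reads tiling every transcript.

    Used for assembler validation: every window position of every transcript
    is emitted (at the given stride, always including the final window), on
    both strands by default so every canonical k-mer is seen at least twice.
    """
    mats, srcs, poss = [], [], []
    for i, t in enumerate(pool):
        codes = encode(t.sequence)
        starts = list(range(0, len(codes) - read_length + 1, stride))
        if starts[-1] != len(codes) - read_length:
            starts.append(len(codes) - read_length)
        idx = np.asarray(starts)[:, None] + np.arange(read_length)
        mats.append(codes[idx])
        srcs.append(np.full(len(starts), i, np.int32))
        poss.append(np.asarray(starts, np.int32))
    mat = np.concatenate(mats)
    src = np.concatenate(srcs)
    pos = np.concatenate(poss)
    strand = np.zeros(mat.shape[0], np.int8)
    if both_strands:
        mat = np.concatenate([mat, revcomp_codes(mat)])
        src = np.concatenate([src, src])
        pos = np.concatenate([pos, pos])
        strand = np.concatenate([strand, np.ones_like(strand)])
    return ReadSet(seqs=mat, src=src, pos=pos, strand=strand,
                   state="NA", method="tiled", pool_ids=[t.id for t in pool])


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_truth_tsv(pool, path) -> None:
    import csv

    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["id", "gene_id", "paralog_group", "biotype", "abundance",
                    "tail_M", "tail_IF", "capped", "regulation"])
        for t in pool:
            w.writerow([t.id, t.gene_id, t.paralog_group or "", t.biotype,
                        f"{t.abundance:.6e}", t.tail_M, t.tail_IF,
                        int(t.capped), t.regulation])


def write_experiment(exp: SimulatedExperiment, outdir) -> None:
    """Persist pool/genome/rRNA/annotation tiers as FASTA and truth as TSV."""
    import os

    os.makedirs(outdir, exist_ok=True)
    seqs.write_fasta(os.path.join(outdir, "pool.fa"),
                     [(t.id, t.sequence) for t in exp.pool])
    seqs.write_fasta(os.path.join(outdir, "genome.fa"),
                     [("toy_genome", exp.genome.sequence)])
    seqs.write_fasta(os.path.join(outdir, "rrna.fa"), exp.rrna)
    for n, tier in enumerate(exp.annotation_tiers, start=1):
        seqs.write_fasta(os.path.join(outdir, f"tier{n}.fa"), tier)
    seqs.write_fasta(os.path.join(outdir, "utr3.fa"), exp.utr_db)
    write_truth_tsv(exp.pool, os.path.join(outdir, "truth.tsv"))
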
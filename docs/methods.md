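# Methods

`dualcap` re-creates, on fully synthetic data, a dual-capture RNA-seq
analysis of poly(A) tail-length regulation in a transcriptionally silent
cell-free system (mitotic vs interphase *Xenopus*-style egg extract), and
the de novo transcriptome workflow built on the same libraries: multi-k
assembly, 100%-identity containment merging, tiered translated-homology
scaffolding, and triage of unannotated transcripts. Every stage is
validated against the generator's ground truth.

## The measurement model

Two capture chemistries see the same RNA pool differently:

* **oligo-dT capture** — efficiency is a function of poly(A) tail length.
  We model it as a hard zero below an 18-nt anchor (an anchored oligo-dT
  primer needs ≥18 consecutive adenosines to anneal) followed by a
  saturating hyperbola:

      p_dT(ℓ) = 0                                   ℓ < a
      p_dT(ℓ) = p_max · x / (x + h),  x = ℓ − a + 1  otherwise

  with anchor `a = 18` nt, half-saturation `h = 30` nt and
  `p_max = 0.9`. This is the simplest monotone model consistent with
  anchored-oligo chemistry; all three parameters are exposed in
  `SimConfig`.

* **cap capture** — efficiency `p_cap = 0.8` for any capped RNA,
  independent of the tail; zero for uncapped RNAs. The true efficiency of
  cap pulldown as a function of cap state is not quantified anywhere we
  can anchor to, so `p_cap` is a free parameter; none of the pipeline's
  conclusions depend on its value because cap ratios are always M:IF
  ratios of the same transcript.

Because abundances are constant between states (transcriptional silence),
an M:IF change in the dT library with a flat cap ratio can only be a tail
change. The classifier applies a two-fold quadrant rule on
(dT ratio, cap ratio), with a cap-side change taking precedence as
cap-level regulation (decapping/recapping), and a ≥100-raw-read floor.

**Read floor side.** The floor requires ≥100 raw reads for both capture
methods. By default it is evaluated on the better-covered state
(`floor_side="either"`). A mitotic-only floor — the convention of a
deadenylation screen — makes adenylation calls structurally impossible
here, because a planted adenylated transcript (tail 10→150) has *exactly
zero* mitotic dT reads under the hard-anchor model; a symmetric classifier
needs a symmetric floor. `floor_side="mitotic"` restores the screen
convention.

**Sensitivity/precision denominators.** The floor is an abstention, not a
call: recovery statistics are computed over floor-passing transcripts, and
the number of planted transcripts lost to the floor is reported alongside
(`n_planted_low_coverage`). With log-normal abundances (σ = 1.5) roughly
10% of transcripts genuinely never reach 100 reads at 2×10⁶ reads per
library; no classifier could score them.

**Dispersion summaries** are the mean and population standard deviation
(ddof = 0) of finite M:IF ratios over floor-passing transcripts;
denominator dropouts (infinite ratios) are excluded, zeros are not.

## The synthetic experiment

Defaults (all in `SimConfig`): 909 genes, 10% with a paralog partner
(pairwise identity drawn from Normal(93.1%, 2.72%) truncated to
(85%, 99.5%)) → 1,000 transcripts of 200–3,000 nt; log-normal abundances
(σ = 1.5) summing to 1, identical across states; 60 planted deadenylated
transcripts (tail 150 → 10 nt), 40 planted adenylated (10 → 150), 15%
short-tailed in both states (< 18 nt, hence dT-invisible); coding (85%,
with a planted 5′UTR/ORF/3′UTR structure), ncRNA (10%) and uncapped
UTR-fragment (5%) biotypes; libraries of 2×10⁶ single-end 50-nt unstranded
reads with substitution errors at 10⁻³/base, 5% verbatim PCR duplicates
and 2% residual rRNA; a toy genome embedding every transcript once with
500-nt spacers; three ranked annotation tiers holding proteins for ~70%,
~15% and ~10% of coding genes (~5% in none). Read start positions are
uniform over all transcript positions with the 50-nt window clamped at the
3′ end (uniform priming, not uniform window placement). A fixed seed
determines every output byte.

What the generator does **not** emulate: splicing isoforms, fragment-size
selection, positional coverage bias, quality-score structure, indels
(neither in paralog divergence nor in sequencing error), partial
degradation, or abundance changes between states. Consequently, passing
tests demonstrate the pipeline's logic and thresholds under the stated
model — capture-bias arithmetic, merge semantics, homology thresholds —
not robustness to splice variants or indel-rich data.

## Preprocessing and quantification

Duplicates are exact-sequence duplicates (first occurrence kept; a read
and its reverse complement are distinct). rRNA reads are any that align to
either strand of the rRNA set within the mismatch budget. The
pseudo-aligner is ungapped seed-and-verify: a read is split into
`max_mismatches + 1` disjoint seed segments (16 nt for 50-nt reads and 2
mismatches), so by pigeonhole any in-budget locus is found by at least one
exact seed; each seed hit is verified by full Hamming comparison, all
minimal-mismatch loci are kept, and a read whose minimal loci span more
than one transcript is discarded as ambiguous (conservative; integer
counts). RPKM = raw / (kb × mapped/10⁶); replicate R² is the squared
Pearson correlation of log₂(RPKM + 1) over transcripts expressed in either
replicate.

`alignment_rate` has two policies: `discard` (unique-assignment, the
quantification default) and `count` (best-hit counting — any in-budget
locus). The `count` policy is used when quoting % aligned against the
multi-k merged assembly, which is deliberately redundant: overlapping
fragments of one gene from different k values survive a 100%-containment
merge, and discarding reads that hit two such fragments would understate
an assembly's coverage of the read pool.

## Assembly and merging

The assembler is a canonical de Bruijn unitig builder: k-mers are
identified with their reverse complements (libraries are unstranded),
counted with a `min_count = 2` floor (error pruning), and unitigs are
maximal paths with unique extension in both directions. Even-k
reverse-complement palindromic k-mers are junctions: a sequence containing
one cannot be spelled by a simple walk in the canonical graph (the classic
even-k pathology), so such positions break contigs at even k and are
recovered by odd-k runs — one of the reasons multi-k assembly helps.
Output is deterministic: unitigs are emitted strand-canonically (the
lexicographically smaller of sequence/reverse complement) in sorted order,
independent of read order.

The default grids are odd k = 17…41 and even k = 20…40. The merge drops
contigs < 100 nt, collapses exact duplicates (including reverse-complement
pairs) onto the lexicographically smaller sequence, and removes any contig
occurring verbatim (either strand) inside a strictly longer one — exact
substring only, so ~93%-identity paralog pairs are never collapsed. The
result is an antichain under substring order and the operation is
idempotent. Internally the merge uses a sorted word index with full
verification, equivalent to (and tested against) the quadratic both-strand
substring scan.

## Homology machinery

All homology stages share one engine: exact-word seeding, ungapped X-drop
extension, ungapped Karlin–Altschul statistics
(bits = (λS − ln K)/ln 2, E = m·n·2^(−bits)).

* Translated (BLASTX-style) search: six-frame translation, exact peptide
  4-mer seeds, BLOSUM62, X-drop 20, λ = 0.3176, K = 0.134 (published
  ungapped values); m = total six-frame residues of the contig, n = total
  database residues; hits kept at E ≤ 10⁻¹⁰, single best HSP per
  (contig, reference). Scaffolding is sequential over ranked tiers: a
  tier-1 pass claims the contig before tiers 2–3 are consulted; best hit
  ties break by e-value, bit score, then reference id.
* Nucleotide search: +1/−1 scoring (λ = ln 3 exactly, K = 0.35), exact
  14-mer seeds, X-drop 30, both strands. Identity over the aligned span is
  (score + span)/(2·span), exact under ±1 scoring. Used for the 80%
  identity / 50% query-coverage homology rule, 3′UTR matching at
  E ≤ 10⁻³⁰, and the ~93% paralog band (0.88–0.995, i.e. mean ± ~2 sd of
  the paralog identity distribution with 100% excluded so same-gene
  redundancy is not miscalled).
* Genome mapping: exact 31-mer seeds, loci split at genomic gaps > 20,000
  nt (maximum intron) or where the query coordinate resets (tandem
  copies); per-diagonal gap-filled block comparison gives identity, query
  coverage and score = matches − mismatches; filters: identity ≥ 95%,
  coverage ≥ 80%, score ≥ 1000, and rejection of transcripts with > 2
  candidate loci. Block-based, not a full spliced aligner — sufficient for
  filter semantics on toy genomes (score ≥ 1000 implies only ≥ ~1 kb
  queries can pass, as with the original BLAT-score filter).

ORF calling scans all six frames for ATG-to-stop segments; open-ended ORFs
(no stop before the sequence end) are counted because assembly fragments
routinely truncate reading frames — excluding them would bias lengths
down. Ties prefer the + strand, then the lower frame index. The
implementation is tested for exact agreement with a brute-force regex
enumeration.

## Problem sizes

The default experiment (1,000 transcripts, four 2×10⁶-read libraries) runs
end to end on one CPU. Assembler validation uses deterministic error-free
tiling reads at stride 8 (every k ≤ 41 window is still covered on both
strands, so unitig output is identical to stride-1 tiling at a quarter of
the cost). Library assemblies consume the first 150,000 unique non-rRNA
reads per capture method — enough for the combined-capture comparisons the
package makes; deeper input mainly adds low-abundance fragments.
Reconstruction statistics are quoted over transcripts that are repeat-free
at k = 17 (all canonical 17-mers unique in the pool): a transcript sharing
a ≥ 17-nt exact run with another — most paralog pairs — cannot be spelled
unambiguously by any assembler at that k, so it bounds the denominator,
not the assembler.

## Known limitations

Ungapped alignment throughout (no indels anywhere in the model, so exact
by construction on synthetic data; real data would need gapped extension).
Single best HSP per pair; no HSP chaining in translated space. The
dT-capture hard anchor makes below-anchor transcripts perfectly invisible,
which is sharper than reality and is why mitotic-side-only read floors
were generalised. Tail length is never estimated in absolute terms — the
method detects relative change only.
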
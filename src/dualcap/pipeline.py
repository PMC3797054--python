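"""End-to-end orchestration of the dual-capture analysis.

``run_all`` executes: simulate -> four libraries (M/IF x dT/cap) ->
preprocess/quantify -> poly(A) calls -> per-method multi-k assembly ->
containment merges (per library and combined) -> tiered scaffolding ->
triage of unassigned contigs -> truth evaluation. Everything is
deterministic under the embedded simulation seed, and every reported number
is recomputed from the stage outputs held in the returned report.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
import time
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import annotate as ann
from . import assemble as asm
from . import polya as pa
from . import readproc as rp
from . import scaffold as sc
from .simulate import (ReadSet, SimConfig, simulate_library,
                       simulate_transcriptome)

log = logging.getLogger("dualcap")

LIBRARIES = (("dT", "M"), ("dT", "IF"), ("cap", "M"), ("cap", "IF"))


@dataclass
class RunConfig:
    """Pipeline configuration; thresholds default to the study's values."""

    sim: SimConfig = field(default_factory=SimConfig)
    fold: float = 2.0
    floor: int = 100
    floor_side: str = "either"
    min_len: int = 100                  # containment-merge length filter
    k_odd: tuple = asm.K_ODD
    k_even: tuple = asm.K_EVEN
    min_count: int = 2
    max_assembly_reads: int = 250_000   # unique reads fed per assembly run
    evalue_scaffold: float = 1e-10
    evalue_utr: float = 1e-30
    paralog_band: tuple = (0.88, 0.995)
    homology_identity: float = 0.80
    homology_query_cov: float = 0.50
    run_polya: bool = True
    run_assembly: bool = True
    run_scaffold: bool = True
    run_annotate: bool = True
    outdir: Optional[str] = None

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "sim" in d and isinstance(d["sim"], dict):
            d["sim"] = SimConfig(**d["sim"])
        for key in ("k_odd", "k_even", "paralog_band"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


@dataclass
class RunReport:
    """Per-stage metrics plus the truth-evaluation block."""

    config: dict
    library_stats: dict = field(default_factory=dict)
    polya: dict = field(default_factory=dict)
    assembly: dict = field(default_factory=dict)
    scaffold: dict = field(default_factory=dict)
    annotate: dict = field(default_factory=dict)
    truth_eval: dict = field(default_factory=dict)

    def to_json(self, path=None) -> str:
        def default(o):
            if isinstance(o, (np.integer,)):
                return int(o)
            if isinstance(o, (np.floating,)):
                return float(o)
            if isinstance(o, tuple):
                return list(o)
            raise TypeError(type(o).__name__)

        text = json.dumps(dataclasses.asdict(self), indent=2, default=default,
                          sort_keys=True)
        if path:
            with open(path, "w") as fh:
                fh.write(text)
        return text


class StageError(RuntimeError):
    def __init__(self, stage: str, err: Exception):
        super().__init__(f"stage {stage!r} failed: {err}")
        self.stage = stage


def _stage(name):
    def deco(fn):
        def wrapped(*a, **kw):
            t0 = time.time()
            try:
                out = fn(*a, **kw)
            except Exception as err:  # noqa: BLE001 - re-tagged per contract
                raise StageError(name, err) from err
            log.info("stage %s done in %.1fs", name, time.time() - t0)
            return out
        return wrapped
    return deco


@_stage("quantify")
def quantify_library(lib: ReadSet, pool, rrna, max_mismatches: int = 2):
    """Dedupe, rRNA-filter, align and count one library."""
    uniq, _n_dup = rp.dedupe_reads(lib)
    kept, n_rrna, _frac = rp.filter_rrna(uniq, rrna, max_mismatches)
    aln = rp.PseudoAligner(pool, max_mismatches).align(kept)
    table = rp.count_and_normalize(aln, {t.id: len(t.sequence) for t in pool},
                                   total_unique=len(uniq), rrna_count=n_rrna,
                                   library=f"{lib.method}_{lib.state}")
    stats = rp.library_stats(len(lib), len(uniq), n_rrna, aln)
    return kept, aln, table, stats


def _planted(pool, regulation: str) -> set:
    return {t.id for t in pool if t.regulation == regulation}


def sens_prec(calls, pool, call_name: str, regulation: str) -> dict:
    """Sensitivity/precision over floor-passing transcripts.

    The read floor is an abstention: transcripts that never reached the
    coverage floor are reported separately, not scored against the
    classifier.
    """
    planted = _planted(pool, regulation)
    passing = set(calls.index[calls["floor_ok"]])
    called = set(calls.index[calls["call"] == call_name])
    tp = len(planted & called)
    denom_s = len(planted & passing)
    return {
        "sensitivity": tp / denom_s if denom_s else float("nan"),
        "precision": tp / len(called) if called else float("nan"),
        "n_planted": len(planted),
        "n_planted_low_coverage": len(planted - passing),
        "n_called": len(called),
    }


def evaluate_polya(calls, pool, fold: float = 2.0) -> dict:
    out = {
        "deadenylation": sens_prec(calls, pool, "deadenylation_candidate",
                                   "deadenylated"),
        "adenylation": sens_prec(calls, pool, "adenylation_candidate",
                                 "adenylated"),
    }
    # cap neutrality: stable transcripts should be called unchanged
    stable = {t.id for t in pool if t.regulation == "none"}
    passing = set(calls.index[calls["floor_ok"]])
    unchanged = set(calls.index[calls["call"] == "unchanged"])
    denom = stable & passing
    out["stable_called_unchanged"] = (len(denom & unchanged) / len(denom)
                                      if denom else float("nan"))
    return out


def run_all(config: RunConfig) -> RunReport:
    """Execute the full pipeline; deterministic under config.sim.seed."""
    report = RunReport(config=config.to_dict())
    exp = simulate_transcriptome(config.sim)

    libs, tables, alns, kept_reads = {}, {}, {}, {}
    for method, state in LIBRARIES:
        lib = simulate_library(exp.pool, state, method, config.sim,
                               rrna=exp.rrna)
        kept, aln, table, stats = quantify_library(lib, exp.pool, exp.rrna)
        key = f"{method}_{state}"
        libs[key], kept_reads[key], alns[key], tables[key] = lib, kept, aln, table
        report.library_stats[key] = stats

    if config.run_polya:
        calls = pa.call_polya(tables["dT_M"], tables["dT_IF"],
                              tables["cap_M"], tables["cap_IF"],
                              fold=config.fold, floor=config.floor,
                              floor_side=config.floor_side)
        dt_mean, dt_sd = pa.dispersion_summary(calls, "dT")
        cap_mean, cap_sd = pa.dispersion_summary(calls, "cap")
        ebias = pa.end_bias(alns["cap_M"])
        report.polya = {
            "n_floor_passing": int(calls["floor_ok"].sum()),
            "dispersion": {"dT": {"mean": dt_mean, "sd": dt_sd},
                           "cap": {"mean": cap_mean, "sd": cap_sd}},
            "end_bias_median_ratio": float(ebias["ratio"].median()),
            "class_counts": calls["call"].value_counts().to_dict(),
        }
        report.truth_eval["polya"] = evaluate_polya(calls, exp.pool,
                                                    config.fold)
        report.truth_eval["polya"]["tvn_flip_consistency"] = _tvn_check(
            calls, exp.pool)
        self_calls = calls
    else:
        self_calls = None

    merged = {}
    if config.run_assembly:
        for method in ("dT", "cap"):
            reads = ReadSet.concatenate([kept_reads[f"{method}_M"],
                                         kept_reads[f"{method}_IF"]])
            if len(reads) > config.max_assembly_reads:
                reads = reads.subset(np.arange(config.max_assembly_reads))
            contigs = (asm.assemble_multi_k(reads, config.k_odd,
                                            config.min_count, method, "odd")
                       + asm.assemble_multi_k(reads, config.k_even,
                                              config.min_count, method, "even"))
            merged[method] = asm.remove_contained(contigs, config.min_len)
        merged["combined"] = asm.remove_contained(
            merged["dT"].contigs + merged["cap"].contigs, config.min_len)
        matched = {m: sc.match_reference_set(merged[m].contigs, exp.pool,
                                             config.homology_identity,
                                             config.homology_query_cov)
                   for m in ("dT", "cap", "combined")}
        report.assembly = {
            "stats": {m: asm.assembly_stats(merged[m]) for m in merged},
            "n_contigs": {m: len(merged[m]) for m in merged},
            "truth_matched": {m: len(matched[m]) for m in matched},
            "venn_dT_cap": {"+".join(k): v for k, v in
                            sc.overlap_sets({"dT": matched["dT"],
                                             "cap": matched["cap"]}).items()},
        }
        report.truth_eval["assembly_recall"] = {
            m: len(matched[m]) / len(exp.pool) for m in matched}

    if config.run_scaffold and merged:
        clusters, unassigned = sc.tiered_scaffold(
            merged["combined"].contigs, exp.annotation_tiers,
            config.evalue_scaffold)
        tier_counts = {f"tier{t}": sum(1 for c in clusters if c.tier == t)
                       for t in (1, 2, 3)}
        n_members = sum(len(c.members) for c in clusters)
        report.scaffold = {
            "n_clusters": len(clusters),
            "tier_counts": tier_counts,
            "n_contigs_assigned": n_members,
            "n_unassigned": len(unassigned),
            "mean_tier1_coverage": float(np.mean(
                [c.coverage_fraction for c in clusters if c.tier == 1]))
            if tier_counts["tier1"] else 0.0,
        }
    else:
        clusters, unassigned = [], []

    if config.run_annotate and merged:
        by_id = {c.id: c for c in merged["combined"].contigs}
        orphan = [by_id[i] for i in unassigned]
        report.annotate = _annotate_orphans(orphan, exp, config)
        flagged = 0
        for c in clusters:
            members = [(m[1], by_id[m[1]].sequence) for m in c.members
                       if m[1] in by_id]
            if len(members) >= 2:
                _pairs, flag = ann.detect_paralogs(members,
                                                   config.paralog_band)
                flagged += int(flag)
        report.annotate["n_clusters_with_paralog_band_pairs"] = flagged

    if config.outdir:
        _write_outputs(config, exp, tables, self_calls, merged, clusters,
                       unassigned, report)
    return report


def _tvn_check(calls, pool) -> float:
    """Fraction of floor-passing TVN true->false flips with dT ratio > 1."""
    flips = [t.id for t in pool
             if pa.tvn_control(t, "M") and not pa.tvn_control(t, "IF")]
    ok = calls.loc[[f for f in flips if f in calls.index]]
    ok = ok[ok["floor_ok"]]
    if not len(ok):
        return float("nan")
    return float((ok["dt_ratio"] > 1).mean())


@_stage("annotate")
def _annotate_orphans(orphans, exp, config) -> dict:
    if not orphans:
        return {"n_unassigned": 0}
    reports = [ann.longest_orf(c.sequence, c.id) for c in orphans]
    frac_any, mean_aa, frac50 = ann.orf_summary(reports)
    utr_engine = None
    if exp.utr_db:
        from .homology import NucleotideSearch
        utr_engine = NucleotideSearch(exp.utr_db)
    n_utr = sum(ann.utr_match(c.sequence, exp.utr_db, config.evalue_utr,
                              searcher=utr_engine)
                for c in orphans) if utr_engine else 0
    mapper = ann.GenomeMapper(exp.genome.sequence)
    verdicts = {"mapped": 0, "unmapped": 0, "multi_locus": 0}
    for c in orphans:
        _kept, verdict = mapper.map(c.sequence)
        verdicts[verdict] += 1
    return {
        "n_unassigned": len(orphans),
        "orf": {"fraction_any": frac_any, "mean_aa": mean_aa,
                "fraction_orf50": frac50},
        "utr_match_fraction": n_utr / len(orphans),
        "genome_verdicts": verdicts,
    }


def _write_outputs(config, exp, tables, calls, merged, clusters, unassigned,
                   report) -> None:
    from . import simulate as sim
    from .seqs import write_fasta

    out = config.outdir
    os.makedirs(out, exist_ok=True)
    sim.write_experiment(exp, os.path.join(out, "truth"))
    for key, table in tables.items():
        table.to_tsv(os.path.join(out, f"counts_{key}.tsv"))
    if calls is not None:
        calls.to_csv(os.path.join(out, "polya_calls.tsv"), sep="\t",
                     index_label="transcript")
    for name, m in merged.items():
        write_fasta(os.path.join(out, f"assembly_{name}.fa"),
                    [(c.id, f"lib={c.source_library} run={c.assembler_run} "
                            f"k={c.k}", c.sequence) for c in m.contigs])
    if clusters:
        with open(os.path.join(out, "clusters.tsv"), "w") as fh:
            fh.write("reference\ttier\tcoverage\tmembers\n")
            for c in clusters:
                fh.write(f"{c.reference_id}\t{c.tier}\t"
                         f"{c.coverage_fraction:.3f}\t"
                         f"{','.join(m[0] for m in c.members)}\n")
    report.to_json(os.path.join(out, "report.json"))


def evaluate_against_truth(report: RunReport, truth_pool) -> dict:
    """Re-derive headline truth metrics from a report (id-keyed)."""
    if not report.truth_eval:
        raise ValueError("report carries no truth evaluation block")
    return report.truth_eval
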
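"""Dual-capture poly(A) regulation inference.

The central idea: with equal transcript abundance across cell-cycle states,
a mitotic:interphase (M:IF) abundance change seen in an oligo-dT library but
not in a cap-capture library is a change in poly(A) tail length, not in
abundance — dT capture efficiency depends on the tail, cap capture does not.
Each transcript's (dT ratio, cap ratio) pair is classified against a
two-fold quadrant rule; a cap-side change takes precedence and marks
cap-level (decapping/recapping) regulation instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .readproc import Alignments, CountTable

CLASSES = ("deadenylation_candidate", "adenylation_candidate",
           "cap_dependent_change", "unchanged", "low_coverage")


@dataclass
class PolyACall:
    transcript_id: str
    dt_ratio: float
    cap_ratio: float
    call: str


def mif_ratio(count_M: float, count_IF: float) -> float:
    """M:IF ratio of normalised counts; inf flags an IF dropout."""
    if count_M < 0 or count_IF < 0:
        raise ValueError("counts must be non-negative")
    if count_IF == 0:
        return float("inf") if count_M > 0 else float("nan")
    return count_M / count_IF


def classify_polya(dt_ratio: float, cap_ratio: float, fold: float = 2.0,
                   read_floor_ok: bool = True) -> str:
    """Quadrant classification of one transcript.

    Boundaries are inclusive toward the called class; a cap-side change
    outside [1/fold, fold] takes precedence over any poly(A) call.
    """
    if not read_floor_ok:
        return "low_coverage"
    if not (1.0 / fold <= cap_ratio <= fold):
        return "cap_dependent_change"
    if dt_ratio >= fold:
        return "deadenylation_candidate"
    if dt_ratio <= 1.0 / fold:
        return "adenylation_candidate"
    return "unchanged"


def _floor_ok(raw_m: np.ndarray, raw_if: np.ndarray, floor: int,
              side: str) -> np.ndarray:
    if side == "mitotic":
        return raw_m >= floor
    if side == "either":
        return np.maximum(raw_m, raw_if) >= floor
    raise ValueError(f"unknown floor side {side!r}")


def call_polya(dt_m: CountTable, dt_if: CountTable,
               cap_m: CountTable, cap_if: CountTable,
               fold: float = 2.0, floor: int = 100,
               floor_side: str = "either") -> pd.DataFrame:
    """Per-transcript M:IF ratios in both capture chemistries plus the call.

    The read floor must hold for both capture methods; ``floor_side`` chooses
    whether the raw-read floor is evaluated on the mitotic side only
    ("mitotic", the deadenylation-screen convention) or on the better-covered
    state ("either", default — symmetric, so adenylation is also callable).
    Ratios are on the RPKM scale so library depth cancels.
    """
    idx = dt_m.table.index
    for t in (dt_if, cap_m, cap_if):
        if not t.table.index.equals(idx):
            raise ValueError("count tables cover different transcript universes")
    floor_ok = (_floor_ok(dt_m.table["raw"].to_numpy(),
                          dt_if.table["raw"].to_numpy(), floor, floor_side)
                & _floor_ok(cap_m.table["raw"].to_numpy(),
                            cap_if.table["raw"].to_numpy(), floor, floor_side))
    with np.errstate(divide="ignore", invalid="ignore"):
        dt_ratio = dt_m.table["rpkm"].to_numpy() / dt_if.table["rpkm"].to_numpy()
        cap_ratio = cap_m.table["rpkm"].to_numpy() / cap_if.table["rpkm"].to_numpy()
    calls = [classify_polya(d, c, fold, ok)
             for d, c, ok in zip(dt_ratio, cap_ratio, floor_ok)]
    return pd.DataFrame({"dt_ratio": dt_ratio, "cap_ratio": cap_ratio,
                         "floor_ok": floor_ok, "call": calls}, index=idx)


def dispersion_summary(calls: pd.DataFrame, side: str):
    """(mean, sd) of finite M:IF ratios over floor-passing transcripts.

    ``side`` is "dT" or "cap". Infinite ratios (denominator dropouts) are
    excluded; the sd is the population standard deviation.
    """
    col = {"dT": "dt_ratio", "cap": "cap_ratio"}[side]
    r = calls.loc[calls["floor_ok"], col].to_numpy()
    r = r[np.isfinite(r)]
    if r.size < 10:
        raise ValueError("fewer than 10 floor-passing transcripts")
    return float(r.mean()), float(r.std(ddof=0))


def tvn_control(transcript, state: str) -> bool:
    """In-silico anchored-RT (TVN) primeability: tail >= 18 A in that state.

    The anchored primer (18 Ts followed by VN) requires a minimal 18-A tail,
    so a True->False flip between states marks deadenylation below the
    anchor.
    """
    return transcript.tail(state) >= 18


def end_bias(alignments: Alignments, reference_lengths=None) -> pd.DataFrame:
    """Read counts in the 5' and 3' quartiles of each transcript.

    A read is assigned by its 5'-most aligned base on the transcript sense
    strand; the ratio uses +1 pseudocounts. With uniform coverage the ratio
    clusters at 1; an excess on either side flags degraded or end-biased
    material.
    """
    lengths = reference_lengths or alignments.ref_lengths
    ids = list(lengths)
    rows = {i: r for r, i in enumerate(ids)}
    c5 = np.zeros(len(ids), dtype=np.int64)
    c3 = np.zeros(len(ids), dtype=np.int64)
    mask = alignments.assigned
    ref = alignments.ref[mask]
    pos = alignments.pos[mask]
    L = np.array([lengths[alignments.ref_ids[r]] for r in range(len(alignments.ref_ids))])
    if np.any(L < 8):
        raise ValueError("transcripts shorter than 8 nt are not quartile-assignable")
    q5 = pos < (L[ref] * 0.25)
    q3 = pos >= (L[ref] * 0.75)
    row_of_ref = np.array([rows[rid] for rid in alignments.ref_ids])
    np.add.at(c5, row_of_ref[ref[q5]], 1)
    np.add.at(c3, row_of_ref[ref[q3]], 1)
    ratio = (c5 + 1) / (c3 + 1)
    return pd.DataFrame({"count_5p": c5, "count_3p": c3, "ratio": ratio},
                        index=pd.Index(ids, name="transcript"))
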
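"""Scoring a call set against simulated truth.

A DEL/INS/DUP/INV call matches a truth event when the types agree, the
start coordinates are within 1 kbp, and the call size is within 0.5-2x
of the truth size; translocations require both breakpoints within 1 kbp.
Matching is one-to-one and greedy by ascending coordinate distance
(an optional multimatch mode allows one truth to absorb several calls).
Besides recall/precision/F1, the breakpoint-shift profile summarises how
exactly breakpoints were placed: counts over shifts of -100..+100 bp
(clamped into the end bins) and the fractions at exactly 0 and within
1 bp.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .calling import SVCall
from .simulator import TruthSV

SV_TYPES = ("DEL", "INS", "DUP", "INV", "TRA")


@dataclass
class Metrics:
    tp: int = 0
    fp: int = 0
    fn: int = 0

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else 0.0

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else 0.0

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if p + r else 0.0


@dataclass
class EvalResult:
    per_type: dict[str, Metrics]
    overall: Metrics
    matches: list[tuple[TruthSV, SVCall, int, float]]  # (truth, call, shift, size ratio)
    undefined_precision: bool = False

    def shift_histogram(self) -> dict[int, int]:
        hist: dict[int, int] = {k: 0 for k in range(-100, 101)}
        for _, _, shift, _ in self.matches:
            hist[max(-100, min(100, shift))] += 1
        return hist

    @property
    def exact_fraction(self) -> float:
        if not self.matches:
            return 0.0
        return sum(1 for m in self.matches if m[2] == 0) / len(self.matches)

    @property
    def within1_fraction(self) -> float:
        if not self.matches:
            return 0.0
        return sum(1 for m in self.matches if abs(m[2]) <= 1) / len(self.matches)


def _is_candidate(
    t: TruthSV, c: SVCall, max_shift: int, ins_dup_equiv: bool
) -> bool:
    if t.sv_type == "TRA" or c.sv_type == "TRA":
        if t.sv_type != c.sv_type:
            return False
        if t.chrom != c.chrom or t.chrom2 != c.chrom2:
            return False
        return (
            abs(t.pos - c.pos) <= max_shift and abs(t.pos2 - c.pos2) <= max_shift
        )
    types_ok = t.sv_type == c.sv_type or (
        ins_dup_equiv and {t.sv_type, c.sv_type} == {"INS", "DUP"}
    )
    if not types_ok or t.chrom != c.chrom:
        return False
    if abs(t.pos - c.pos) > max_shift:
        return False
    return 0.5 * t.size <= c.size <= 2 * t.size


def match_calls(
    truth: list[TruthSV],
    calls: list[SVCall],
    max_shift: int = 1000,
    min_size: Optional[int] = 45,
    multimatch: bool = False,
    ins_dup_equiv: bool = False,
) -> EvalResult:
    """Greedy one-to-one matching by ascending breakpoint distance."""
    if min_size is not None:
        truth = [t for t in truth if t.sv_type == "TRA" or t.size >= min_size]
        calls = [c for c in calls if c.sv_type == "TRA" or c.size >= min_size]
    pairs = []
    for ti, t in enumerate(truth):
        for ci, c in enumerate(calls):
            if _is_candidate(t, c, max_shift, ins_dup_equiv):
                pairs.append((abs(t.pos - c.pos), ti, ci))
    pairs.sort()
    t_used: set[int] = set()
    c_used: set[int] = set()
    matches = []
    for dist, ti, ci in pairs:
        if ci in c_used or (not multimatch and ti in t_used):
            continue
        t, c = truth[ti], calls[ci]
        shift = c.pos - t.pos
        ratio = c.size / t.size if t.size else 1.0
        matches.append((t, c, shift, ratio))
        t_used.add(ti)
        c_used.add(ci)
    per_type = {typ: Metrics() for typ in SV_TYPES}
    for ti, t in enumerate(truth):
        m = per_type[t.sv_type]
        if ti in t_used:
            m.tp += 1
        else:
            m.fn += 1
    for ci, c in enumerate(calls):
        if ci not in c_used:
            per_type[c.sv_type].fp += 1
    overall = Metrics(
        tp=sum(m.tp for m in per_type.values()),
        fp=sum(m.fp for m in per_type.values()),
        fn=sum(m.fn for m in per_type.values()),
    )
    return EvalResult(
        per_type,
        overall,
        matches,
        undefined_precision=(overall.tp + overall.fp == 0),
    )


def compute_metrics(result: EvalResult) -> dict[str, tuple[float, float, float]]:
    """(recall, precision, F1) per type plus 'overall'."""
    out = {
        typ: (m.recall, m.precision, m.f1) for typ, m in result.per_type.items()
    }
    out["overall"] = (
        result.overall.recall,
        result.overall.precision,
        result.overall.f1,
    )
    return out


def breakpoint_shift_profile(
    result: EvalResult,
) -> tuple[dict[int, int], float, float]:
    """Shift histogram (clamped to +-100) + exact / within-1bp fractions."""
    return result.shift_histogram(), result.exact_fraction, result.within1_fraction


def genotype_concordance(result: EvalResult) -> float:
    """Fraction of TP matches whose genotype agrees with truth zygosity."""
    if not result.matches:
        return 0.0
    ok = 0
    for t, c, _, _ in result.matches:
        want = "1/1" if t.zygosity == "hom" else "0/1"
        if c.genotype == want or (t.zygosity == "het" and c.genotype == "1/2"):
            ok += 1
    return ok / len(result.matches)
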
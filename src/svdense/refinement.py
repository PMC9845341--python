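"""Breakpoint refinement by consensus realignment.

For each cluster, windows of supporting reads spanning the provisional
breakpoint +- a 500 bp flank are combined into a consensus: a partial
order alignment backbone followed by two majority-pileup polish rounds.
The consensus — far more accurate than any single noisy read — is then
realigned to the local reference with an affine-gap fit alignment, and
the indel found there replaces the provisional (mean-of-signals)
breakpoint.  Any failure along the way (too few usable reads, an
unalignable consensus, no matching indel) falls back to the rounded mean
of the raw signals, flagged imprecise.

INV and TRA candidates keep their mean-of-signal coordinates: their
consensus would need orientation-aware alignment for little gain, since
their split-segment breakpoints are already anchor-defined.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import edlib
import numpy as np

from ._align import align_glocal, leftalign_del, leftalign_ins
from ._poa import poa_consensus
from .alignment_io import ReferenceGenome
from .clustering import SVCluster

FLANK = 500  # read-window flank on each side of the provisional breakpoint


class PoaFailure(Exception):
    pass


class RealignFailure(Exception):
    pass


@dataclass
class Consensus:
    seq: str
    n_reads: int
    region: tuple[str, int, int]


@dataclass
class RefinedBreakpoint:
    pos: int
    size: int
    end: int
    precise: bool
    ins_seq: Optional[str] = None


def _polish(cons: str, reads: list[str]) -> str:
    """One majority-vote pileup round of reads against the consensus."""
    n = len(cons)
    nr = len(reads)
    sub: list[dict[str, int]] = [{} for _ in range(n)]
    dels = np.zeros(n)
    cov = np.zeros(n)
    ins: list[dict[str, int]] = [{} for _ in range(n + 1)]
    for r in reads:
        res = edlib.align(r, cons, mode="NW", task="path")
        if res["editDistance"] < 0:
            continue
        ci = ri = num = 0
        pend: list[str] = []
        for ch in res["cigar"]:
            if ch.isdigit():
                num = num * 10 + ord(ch) - 48
                continue
            if ch in "=X":
                if pend:
                    s = "".join(pend)
                    ins[ci][s] = ins[ci].get(s, 0) + 1
                    pend = []
                for _ in range(num):
                    cov[ci] += 1
                    b = r[ri]
                    sub[ci][b] = sub[ci].get(b, 0) + 1
                    ci += 1
                    ri += 1
            elif ch == "D":  # gap in read: vote to delete this consensus base
                if pend:
                    s = "".join(pend)
                    ins[ci][s] = ins[ci].get(s, 0) + 1
                    pend = []
                for _ in range(num):
                    cov[ci] += 1
                    dels[ci] += 1
                    ci += 1
            elif ch == "I":  # extra read bases between consensus columns
                pend.append(r[ri : ri + num])
                ri += num
            num = 0
    out: list[str] = []
    for i in range(n):
        if ins[i]:
            seq, cnt = max(ins[i].items(), key=lambda kv: (kv[1], kv[0]))
            if cnt > nr / 2:
                out.append(seq)
        if dels[i] > cov[i] / 2:
            continue
        if sub[i]:
            out.append(max(sub[i].items(), key=lambda kv: (kv[1], kv[0]))[0])
        else:
            out.append(cons[i])
    return "".join(out)


def build_poa_consensus(
    read_windows: list[str],
    region: tuple[str, int, int] = ("", 0, 0),
    polish_rounds: int = 2,
) -> Consensus:
    """POA consensus of >= 2 read windows, with majority polish rounds."""
    windows = [w for w in read_windows if w]
    if len(windows) < 2:
        raise PoaFailure(f"{len(windows)} usable reads")
    cons = poa_consensus(windows, gap_open=-6, gap_ext=-2)
    for _ in range(polish_rounds):
        cons = _polish(cons, windows)
    if len(cons) < min(len(w) for w in windows) / 2:
        raise PoaFailure("consensus collapsed")
    return Consensus(cons, len(windows), region)


def realign_local(
    cons: Consensus,
    genome: ReferenceGenome,
    chrom: str,
    start: int,
    end: int,
    min_aligned_frac: float = 0.70,
    min_identity: float = 0.80,
):
    """Fit-align the consensus inside genome[chrom][start:end].

    Raises RealignFailure when fewer than 70% of consensus bases land in
    aligned columns or column identity is below 80%.
    """
    start = max(0, start)
    end = min(genome.lengths[chrom], end)
    window = genome.fetch(chrom, start, end)
    aln = align_glocal(cons.seq, window)
    aligned = sum(n for op, n in aln.cigar if op == "M")
    if aligned < min_aligned_frac * len(cons.seq):
        raise RealignFailure("consensus mostly unaligned")
    if aln.n_match < min_identity * aligned:
        raise RealignFailure("low identity")
    return aln, start, window


def _consensus_svs(
    aln, window: str, window_start: int, cons_seq: str, min_size: int = 30
) -> list[tuple[str, int, int, Optional[str]]]:
    """Indels in the consensus alignment, merged and left-normalised."""
    events: list[tuple[str, int, int, int]] = []  # (type, ref_pos, size, q_pos)
    ref = aln.ref_start
    q = 0
    for op, n in aln.cigar:
        if op == "M":
            ref += n
            q += n
        elif op == "I":
            if n >= min_size:
                events.append(("INS", ref, n, q))
            q += n
        else:
            if n >= min_size:
                events.append(("DEL", ref, n, q))
            ref += n
    merged: list[tuple[str, int, int, int]] = []
    for ev in events:
        if merged:
            prev = merged[-1]
            if prev[0] == ev[0]:
                gap = (
                    ev[1] - (prev[1] + prev[2]) if ev[0] == "DEL" else ev[3] - (prev[3] + prev[2])
                )
                if gap <= max(100, 0.5 * (prev[2] + ev[2])):
                    merged[-1] = (prev[0], prev[1], prev[2] + ev[2], prev[3])
                    continue
        merged.append(ev)
    out = []
    for typ, rpos, size, qpos in merged:
        if typ == "DEL":
            p = leftalign_del(window, rpos, size)
            out.append(("DEL", window_start + p, size, None))
        else:
            seq = cons_seq[qpos : qpos + size]
            p, seq = leftalign_ins(window, rpos, seq)
            out.append(("INS", window_start + p, size, seq))
    return out


def refine_breakpoints(
    cluster: SVCluster,
    genome: ReferenceGenome,
    flank: int = FLANK,
    max_reads: int = 8,
    max_event_size: int = 10000,
) -> RefinedBreakpoint:
    """Consensus-refined breakpoint for one cluster; mean-of-signals fallback."""
    prov_pos = cluster.mean_pos
    prov_size = cluster.mean_size
    fallback = _fallback(cluster, prov_pos, prov_size)
    if cluster.sv_type not in ("INS", "DEL") or prov_size > max_event_size:
        return fallback
    # unanimous evidence: every read reports the same breakpoint and size,
    # so the consensus route cannot move it — adopt it as precise
    if (
        len(cluster.members) >= 3
        and len({m.pos for m in cluster.members}) == 1
        and len({m.size for m in cluster.members}) == 1
    ):
        return RefinedBreakpoint(
            prov_pos,
            prov_size,
            prov_pos + (prov_size if cluster.sv_type == "DEL" else 0),
            True,
            fallback.ins_seq,
        )
    windows = []
    for m in cluster.members:
        w = m.read_window(flank)
        if w is not None:
            windows.append((m.read_id, w))
    windows.sort(key=lambda t: (-len(t[1]), t[0]))
    windows = [w for _, w in windows[:max_reads]]
    try:
        region_start = prov_pos - flank
        region_end = prov_pos + (prov_size if cluster.sv_type == "DEL" else 0) + flank
        cons = build_poa_consensus(
            windows, (cluster.chrom, region_start, region_end)
        )
        pad = 200
        aln, wstart, wseq = realign_local(
            cons, genome, cluster.chrom, region_start - pad, region_end + pad
        )
    except (PoaFailure, RealignFailure, KeyError):
        return fallback
    cands = [
        c
        for c in _consensus_svs(aln, wseq, wstart, cons.seq)
        if c[0] == cluster.sv_type
        and 0.5 * prov_size <= c[2] <= 2 * prov_size
        and abs(c[1] - prov_pos) <= flank
    ]
    if not cands:
        return fallback
    typ, pos, size, seq = min(cands, key=lambda c: abs(c[1] - prov_pos))
    end = pos + (size if typ == "DEL" else 0)
    return RefinedBreakpoint(pos, size, end, True, seq)


def _fallback(cluster: SVCluster, pos: int, size: int) -> RefinedBreakpoint:
    ins_seq = None
    if cluster.sv_type == "INS":
        seqs = [m.ins_seq for m in cluster.members if m.ins_seq]
        if seqs:
            ins_seq = min(seqs, key=lambda s: abs(len(s) - size))
    if cluster.sv_type == "INV":
        ends = [m.inv_end for m in cluster.members if m.inv_end is not None]
        end = int(np.floor(np.mean(ends) + 0.5)) if ends else pos + size
    elif cluster.sv_type in ("DEL", "DUP"):
        end = pos + size
    else:
        end = pos
    return RefinedBreakpoint(pos, size, end, False, ins_seq)
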
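"""Pairwise alignment primitives.

`align_glocal` is an affine-gap fit alignment: the query (a consensus or
contig) is aligned end-to-end while the reference window has free flanks.
It is the workhorse behind breakpoint refinement and duplication rescue.
A gap of length L costs ``gap_open + gap_ext * L``.

The DP is row-vectorised with numpy; the within-row ref-gap recurrence is
resolved with a running-maximum scan, so each query row costs a handful of
vector operations.  Traceback uses a packed uint8 pointer matrix.

`leftalign_del` / `leftalign_ins` shift indels to their leftmost
equivalent placement, the convention used for both simulated truth and
reported calls.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import edlib
import numpy as np

from ._seq import seq_to_codes

NEG = np.int32(-(10**9))


@dataclass
class GlocalAlignment:
    score: int
    cigar: list[tuple[str, int]]  # ops over query (M/I) and ref (M/D)
    ref_start: int
    ref_end: int
    n_match: int  # identical bases in M columns


def align_glocal(
    query: str,
    ref: str,
    match: int = 2,
    mismatch: int = -4,
    gap_open: int = -4,
    gap_ext: int = -2,
) -> GlocalAlignment:
    """Affine-gap alignment of full `query` against a window of `ref`.

    gap cost for length L is gap_open + L * gap_ext (both negative).
    """
    q = seq_to_codes(query)
    r = seq_to_codes(ref)
    m, n = len(q), len(r)
    if m == 0 or n == 0:
        raise ValueError("empty sequence")
    go = -(gap_open + gap_ext)  # positive cost of first gap base
    ge = -gap_ext

    Hprev = np.zeros(n + 1, dtype=np.int32)  # free ref prefix
    Iprev = np.full(n + 1, NEG, dtype=np.int32)
    ptr = np.zeros((m + 1, n + 1), dtype=np.uint8)
    karr = (np.arange(n + 1, dtype=np.int64) * ge).astype(np.int32)

    rmatch = np.where(r < 4, r, np.int8(-1))
    for i in range(1, m + 1):
        qi = q[i - 1]
        sc = np.where(rmatch == qi, np.int32(match), np.int32(mismatch))
        Mvec = Hprev[:-1] + sc
        Irow = np.maximum(Hprev - go, Iprev - ge)
        ibit = (Iprev - ge) > (Hprev - go)
        Hp = np.empty(n + 1, dtype=np.int32)
        Hp[0] = Irow[0]
        np.maximum(Mvec, Irow[1:], out=Hp[1:])
        # ref-consuming gap via scan:  D[j] = max_{k<j} Hp[k] - go - ge*(j-1-k)
        B = Hp + karr
        cb = np.maximum.accumulate(B)
        D = np.empty(n + 1, dtype=np.int32)
        D[0] = NEG
        D[1:] = cb[:-1] - go - (karr[1:] - np.int32(ge))
        dbit = np.zeros(n + 1, dtype=bool)
        dbit[1:] = (D[:-1] - ge) > (Hp[:-1] - go)
        Hrow = np.maximum(Hp, D)
        code = np.full(n + 1, 2, dtype=np.uint8)
        code[1:] = np.where(
            Hrow[1:] == Mvec, 0, np.where(Hrow[1:] == D[1:], 1, 2)
        ).astype(np.uint8)
        ptr[i] = code | (dbit.astype(np.uint8) << 2) | (ibit.astype(np.uint8) << 3)
        Hprev, Iprev = Hrow, Irow

    j = int(np.argmax(Hprev))
    score = int(Hprev[j])
    ref_end = j
    ops: list[str] = []
    i = m
    state = "H"
    while i > 0:
        p = ptr[i, j]
        if state == "H":
            c = p & 3
            if c == 0:
                ops.append("M")
                i -= 1
                j -= 1
            elif c == 1:
                state = "D"
            else:
                state = "I"
        elif state == "D":
            ops.append("D")
            ext = bool(p & 4)
            j -= 1
            if not ext:
                state = "H"
        else:  # I
            ops.append("I")
            ext = bool(p & 8)
            i -= 1
            if not ext:
                state = "H"
    ops.reverse()
    cigar: list[tuple[str, int]] = []
    for op in ops:
        if cigar and cigar[-1][0] == op:
            cigar[-1] = (op, cigar[-1][1] + 1)
        else:
            cigar.append((op, 1))
    # count exact matches in M columns
    n_match = 0
    qi = 0
    rj = j
    for op, ln in cigar:
        if op == "M":
            n_match += sum(
                1 for k in range(ln) if query[qi + k] == ref[rj + k]
            )
            qi += ln
            rj += ln
        elif op == "I":
            qi += ln
        else:
            rj += ln
    return GlocalAlignment(score, cigar, j, ref_end, n_match)


def leftalign_del(ref: str, pos: int, size: int, lower: int = 0) -> int:
    """Leftmost-equivalent start for deleting ref[pos:pos+size]."""
    while pos > lower and ref[pos - 1] == ref[pos + size - 1]:
        pos -= 1
    return pos


def leftalign_ins(
    ref: str, pos: int, ins_seq: str, lower: int = 0
) -> tuple[int, str]:
    """Leftmost-equivalent (pos, seq) for inserting ins_seq before ref[pos]."""
    s = list(ins_seq)
    while pos > lower and s and ref[pos - 1] == s[-1]:
        s.insert(0, s.pop())
        pos -= 1
    return pos, "".join(s)


def edlib_identity(query: str, target: str, mode: str = "HW") -> tuple[float, Optional[tuple[int, int]]]:
    """Best infix (mode HW) or global (NW) placement of query in target.

    Returns (identity approximated as 1 - edit_distance/len(query),
    (start, end) half-open location) or (0.0, None) when edlib finds
    nothing.
    """
    if not query or not target:
        return 0.0, None
    res = edlib.align(query, target, mode=mode, task="locations")
    ed = res["editDistance"]
    if ed < 0 or not res["locations"]:
        return 0.0, None
    s, e = res["locations"][0]
    return 1.0 - ed / len(query), (int(s), int(e) + 1)
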
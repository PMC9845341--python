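"""Insertions longer than the reads, recovered by local assembly.

No single read spans an insertion much longer than the read length, so
such events surface only as stacks of long (>= 200 bp) clipped ends on
both sides of the breakpoint.  Clip positions are clustered; when at
least N_supp reads are clipped on each side, the clipped reads are
assembled by greedy suffix-prefix overlap layout, and the single
resulting contig is anchored back to the reference around the breakpoint.
A call is emitted only when exactly one contig assembles, it lands within
1 kbp of the candidate breakpoint on the same chromosome, and the implied
insertion is at least 1 kbp — the filters that keep this aggressive path
precise.
"""

from __future__ import annotations

from dataclasses import dataclass
from statistics import median
from typing import Optional

import edlib

from .alignment_io import ReferenceGenome
from .calling import SVCall
from .signal_detection import ClipSignal


@dataclass
class ClipCluster:
    chrom: str
    region_start: int
    region_end: int
    left_members: list[ClipSignal]
    right_members: list[ClipSignal]

    @property
    def position(self) -> int:
        return int(median([c.pos for c in self.left_members + self.right_members]))


@dataclass
class Contig:
    seq: str
    n_reads: int
    source_region: tuple[str, int, int]


def find_clip_clusters(
    clips: list[ClipSignal], n_supp: int, window: int = 1000
) -> list[ClipCluster]:
    """Chain clips within `window`; keep regions with N_supp on each side."""
    by_chrom: dict[str, list[ClipSignal]] = {}
    for c in clips:
        by_chrom.setdefault(c.chrom, []).append(c)
    out = []
    for chrom in sorted(by_chrom):
        sig = sorted(by_chrom[chrom], key=lambda c: c.pos)
        group: list[ClipSignal] = []
        for c in sig + [None]:
            if group and (c is None or c.pos - group[-1].pos > window):
                left = [g for g in group if g.side == "left"]
                right = [g for g in group if g.side == "right"]
                if (
                    len({g.read_id for g in left}) >= n_supp
                    and len({g.read_id for g in right}) >= n_supp
                ):
                    out.append(
                        ClipCluster(
                            chrom, group[0].pos, group[-1].pos + 1, left, right
                        )
                    )
                group = []
            if c is not None:
                group.append(c)
    return out


def _suffix_prefix(
    a: str, b: str, probe: int, max_err: float
) -> Optional[tuple[float, int]]:
    """Overlap of a's suffix with b's prefix region.

    Returns (identity, end-of-overlap position in b) or None.  The probe
    is a's terminal `probe` bp, located as an infix of b.
    """
    if len(a) < probe or len(b) < probe:
        return None
    q = a[-probe:]
    res = edlib.align(q, b, mode="HW", task="locations", k=int(max_err * probe))
    if res["editDistance"] < 0 or not res["locations"]:
        return None
    s, e = res["locations"][0]
    ident = 1 - res["editDistance"] / probe
    return ident, int(e) + 1


def assemble_local(
    reads: list[tuple[str, str]],
    source_region: tuple[str, int, int] = ("", 0, 0),
    min_overlap: int = 1000,
    min_identity: float = 0.65,
    max_reads: int = 40,
) -> list[Contig]:
    """Greedy overlap-layout assembly of clipped reads.

    All-vs-all suffix/prefix overlaps (probe = min_overlap, banded edit
    distance), greedy chaining of the best extensions, containment
    absorption of leftover reads.  Reads are reference-oriented, so
    overlaps are plain suffix-prefix.
    """
    uniq: dict[str, str] = {}
    for rid, seq in reads:
        if seq and (rid not in uniq or len(seq) > len(uniq[rid])):
            uniq[rid] = seq
    items = sorted(uniq.items(), key=lambda kv: (-len(kv[1]), kv[0]))[:max_reads]
    if not items:
        return []
    ids = [rid for rid, _ in items]
    seqs = {rid: s for rid, s in items}
    max_err = 1 - min_identity
    edges = []  # (-identity, a, b, b_end)
    for a in ids:
        for b in ids:
            if a == b:
                continue
            hit = _suffix_prefix(seqs[a], seqs[b], min_overlap, max_err)
            if hit is None:
                continue
            ident, b_end = hit
            if len(seqs[b]) - b_end <= 0:
                continue  # no extension: b contained or non-extending
            edges.append((-ident, a, b, b_end))
    edges.sort()
    nxt: dict[str, tuple[str, int]] = {}
    has_prev: set[str] = set()

    def chain_head(x: str) -> str:
        seen = set()
        while x in nxt and x not in seen:
            seen.add(x)
            x = nxt[x][0]
        return x

    for negid, a, b, b_end in edges:
        if a in nxt or b in has_prev:
            continue
        if chain_head(b) == a:
            continue  # would close a cycle
        nxt[a] = (b, b_end)
        has_prev.add(b)
    contigs: list[Contig] = []
    used: set[str] = set()
    for rid in ids:
        if rid in has_prev or rid in used:
            continue
        seq = seqs[rid]
        n = 1
        used.add(rid)
        cur = rid
        while cur in nxt:
            b, b_end = nxt[cur]
            seq = seq + seqs[b][b_end:]
            used.add(b)
            n += 1
            cur = b
        contigs.append(Contig(seq, n, source_region))
    # greedy path cover leaves parallel chains over the same locus: merge
    # contigs by containment or suffix-prefix overlap until stable
    contigs.sort(key=lambda c: -len(c.seq))
    changed = True
    while changed and len(contigs) > 1:
        changed = False
        for i in range(len(contigs)):
            for j in range(len(contigs)):
                if i == j:
                    continue
                a, b = contigs[i], contigs[j]
                if len(b.seq) <= len(a.seq):
                    res = edlib.align(
                        b.seq, a.seq, mode="HW", task="distance",
                        k=int(max_err * len(b.seq)),
                    )
                    if res["editDistance"] >= 0:
                        a.n_reads += b.n_reads
                        contigs.pop(j)
                        changed = True
                        break
                hit = _suffix_prefix(a.seq, b.seq, min_overlap, max_err)
                if hit is not None and len(b.seq) - hit[1] > 0:
                    contigs[i] = Contig(
                        a.seq + b.seq[hit[1]:], a.n_reads + b.n_reads, a.source_region
                    )
                    contigs.pop(j)
                    changed = True
                    break
            if changed:
                break
    return contigs


def call_large_insertion(
    cluster: ClipCluster,
    contigs: list[Contig],
    genome: ReferenceGenome,
    anchor: int = 1000,
    search_flank: int = 50000,
    max_distance: int = 1000,
    min_ins_size: int = 1000,
    min_anchor_identity: float = 0.65,
) -> Optional[SVCall]:
    """Anchor the single contig near the breakpoint; emit the insertion.

    Filtered out when multiple contigs assembled, the contig anchors do
    not land within `max_distance` of the candidate breakpoint, or the
    implied insertion is shorter than 1 kbp.
    """
    if len(contigs) != 1:
        return None
    contig = contigs[0].seq
    if len(contig) < 2 * anchor + min_ins_size:
        return None
    bp = cluster.position
    L = genome.lengths[cluster.chrom]
    wstart = max(0, bp - search_flank)
    window = genome.fetch(cluster.chrom, wstart, min(L, bp + search_flank))
    k = int((1 - min_anchor_identity) * anchor)
    # the contig ends must anchor inside the local window (this is the
    # same-chromosome / not-too-far filter: a contig from elsewhere finds
    # no anchors here)
    pre = edlib.align(contig[:anchor], window, mode="HW", task="locations", k=k)
    suf = edlib.align(contig[-anchor:], window, mode="HW", task="locations", k=k)
    if (
        pre["editDistance"] < 0
        or suf["editDistance"] < 0
        or not pre["locations"]
        or not suf["locations"]
    ):
        return None
    # bracket the inserted sequence: locate the reference flanks of the
    # candidate breakpoint inside the contig
    lf = genome.fetch(cluster.chrom, max(0, bp - 2 * anchor), bp)
    rf = genome.fetch(cluster.chrom, bp, min(L, bp + 2 * anchor))
    kf = int((1 - min_anchor_identity) * len(lf))
    left = edlib.align(lf, contig, mode="HW", task="locations", k=kf)
    right = edlib.align(rf, contig, mode="HW", task="locations", k=kf)
    if (
        left["editDistance"] < 0
        or right["editDistance"] < 0
        or not left["locations"]
        or not right["locations"]
    ):
        return None
    gap_start = left["locations"][0][1] + 1
    gap_end = right["locations"][0][0]
    ins_size = gap_end - gap_start
    if ins_size < min_ins_size:
        return None
    n_reads = len({c.read_id for c in cluster.left_members + cluster.right_members})
    return SVCall(
        sv_type="INS",
        chrom=cluster.chrom,
        pos=bp,
        size=int(ins_size),
        end=bp,
        n_supp_reads=n_reads,
        precise=False,
    )
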
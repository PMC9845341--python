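"""End-to-end SV calling: signals -> clusters -> refinement -> calls.

`call_svs` accepts either a SAM/BAM path or an in-memory iterable of
per-read AlignmentRecord groups (the simulator's oracle output), so the
full caller can run hermetically inside tests.
"""

from __future__ import annotations

import bisect
import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from . import calling, clustering, large_insertion, refinement, signal_detection
from .alignment_io import AlignmentRecord, ReferenceGenome, read_alignments
from .calling import SVCall
from .signal_detection import ClipSignal, DepthProfile, RawSVSignal

log = logging.getLogger("svdense")


@dataclass
class CallerConfig:
    min_signal_size: int = 30
    min_sv_size: int = 45
    mapq_min: int = 20
    min_supp: Optional[int] = None  # override the depth-derived N_supp
    refine: bool = True
    assembly: bool = True
    rescue_dup: bool = True
    flank: int = 500
    poa_max_reads: int = 8
    local_depth_flank: int = 500
    emit_all: bool = False


def _group_by_read(
    records: Iterable[AlignmentRecord],
) -> Iterable[list[AlignmentRecord]]:
    by_read: dict[str, list[AlignmentRecord]] = {}
    for rec in records:
        by_read.setdefault(rec.read_id, []).append(rec)
    return by_read.values()


class _DepthIndex:
    """Read span index for local-depth queries (sorted starts/ends)."""

    def __init__(self) -> None:
        self.starts: dict[str, list[int]] = {}
        self.ends: dict[str, list[int]] = {}

    def add(self, chrom: str, start: int, end: int) -> None:
        self.starts.setdefault(chrom, []).append(start)
        self.ends.setdefault(chrom, []).append(end)

    def freeze(self) -> None:
        for c in self.starts:
            self.starts[c].sort()
            self.ends[c].sort()

    def depth(self, chrom: str, lo: int, hi: int) -> int:
        s = self.starts.get(chrom)
        if not s:
            return 0
        e = self.ends[chrom]
        return bisect.bisect_left(s, hi) - bisect.bisect_right(e, lo)


def call_svs(
    alignments: str | Iterable[Sequence[AlignmentRecord]],
    genome: ReferenceGenome,
    config: Optional[CallerConfig] = None,
) -> tuple[list[SVCall], DepthProfile]:
    """Run the full caller; returns all calls (check filter_status) + depth."""
    cfg = config or CallerConfig()
    if isinstance(alignments, str):
        groups = _group_by_read(read_alignments(alignments))
    else:
        groups = alignments

    signals: list[RawSVSignal] = []
    clips: list[ClipSignal] = []
    aligned_bases: dict[str, int] = {c: 0 for c in genome.lengths}
    depth_idx = _DepthIndex()
    for recs in groups:
        recs = [r for r in recs if not r.is_secondary]
        if not recs:
            continue
        segs = signal_detection.segments_of_read(recs)
        for rec in recs:
            aligned_bases[rec.chrom] = (
                aligned_bases.get(rec.chrom, 0) + rec.aligned_bases
            )
            depth_idx.add(rec.chrom, rec.ref_start, rec.ref_end)
            signals.extend(
                signal_detection.extract_intra_signals(rec, cfg.min_signal_size)
            )
            clips.extend(signal_detection.record_clip_signals(rec, segs))
        if len(segs) > 1:
            signals.extend(
                signal_detection.extract_split_signals(segs, cfg.min_signal_size)
            )
    depth_idx.freeze()
    profile = DepthProfile(aligned_bases, dict(genome.lengths))
    n_supp = cfg.min_supp if cfg.min_supp is not None else profile.n_supp
    log.info(
        "depth %.1fx, N_supp %d, %d raw signals, %d clip signals",
        profile.mean_depth, n_supp, len(signals), len(clips),
    )

    # cluster per type/chrom
    clusters: list[clustering.SVCluster] = []
    by_key: dict[tuple[str, str], list[RawSVSignal]] = {}
    tra: list[RawSVSignal] = []
    for s in signals:
        if s.sv_type == "TRA":
            tra.append(s)
        else:
            by_key.setdefault((s.sv_type, s.chrom), []).append(s)
    for key in sorted(by_key):
        clusters.extend(clustering.density_cluster(by_key[key], n_supp))
    clusters.extend(clustering.cluster_translocations(tra))

    split_clusters: list[clustering.SVCluster] = []
    for cl in clusters:
        split_clusters.extend(clustering.split_multiallele(cl))

    # group multi-allele siblings back together for joint reporting
    calls: list[SVCall] = []
    i = 0
    while i < len(split_clusters):
        cl = split_clusters[i]
        if cl.allele_index == 1 and i + 1 < len(split_clusters) and (
            split_clusters[i + 1].allele_index == 2
            and split_clusters[i + 1].summit_pos == cl.summit_pos
        ):
            calls.append(
                _make_call(cl, genome, cfg, sibling=split_clusters[i + 1])
            )
            i += 2
        else:
            calls.append(_make_call(cl, genome, cfg))
            i += 1

    # large-insertion module
    if cfg.assembly:
        ins_calls = _assembly_calls(clips, genome, n_supp)
        calls = _dedupe_assembly(calls, ins_calls)

    for c in calls:
        c.local_depth = depth_idx.depth(
            c.chrom,
            c.pos - cfg.local_depth_flank,
            c.pos + cfg.local_depth_flank,
        )
    calls = [
        c
        for c in calls
        if c.sv_type == "TRA" or c.size >= cfg.min_sv_size
    ]
    calls = calling.filter_candidates(
        calls, profile, mapq_min=cfg.mapq_min, min_supp=cfg.min_supp
    )
    if cfg.rescue_dup:
        for c in calls:
            if c.filter_status == "PASS":
                calling.rescue_duplication(c, genome)
    for c in calls:
        if c.filter_status == "PASS":
            c.genotype = calling.genotype_call(c)
    return calls, profile


def _make_call(
    cl: clustering.SVCluster,
    genome: ReferenceGenome,
    cfg: CallerConfig,
    sibling: Optional[clustering.SVCluster] = None,
) -> SVCall:
    if cfg.refine:
        rb = refinement.refine_breakpoints(
            cl, genome, flank=cfg.flank, max_reads=cfg.poa_max_reads
        )
    else:
        rb = refinement._fallback(cl, cl.mean_pos, cl.mean_size)
    mapqs = [m.mapq for m in cl.members]
    call = SVCall(
        sv_type=cl.sv_type,
        chrom=cl.chrom,
        pos=rb.pos,
        size=rb.size,
        end=rb.end,
        n_supp_reads=cl.read_support,
        precise=rb.precise,
        ins_seq=rb.ins_seq,
        mapq_mean=float(np.mean(mapqs)),
        member_ins_seqs=[m.ins_seq for m in cl.members if m.ins_seq],
    )
    if cl.sv_type == "TRA":
        call.chrom2 = cl.members[0].chrom2
        call.pos2 = int(np.median([m.pos2 for m in cl.members]))
        call.pos = int(np.median([m.pos for m in cl.members]))
        call.end = call.pos
    if sibling is not None:
        rb2 = (
            refinement.refine_breakpoints(
                sibling, genome, flank=cfg.flank, max_reads=cfg.poa_max_reads
            )
            if cfg.refine
            else refinement._fallback(sibling, sibling.mean_pos, sibling.mean_size)
        )
        call.allele_sizes = [rb.size, rb2.size]
        call.allele_supports = [cl.read_support, sibling.read_support]
        call.n_supp_reads = cl.read_support + sibling.read_support
    return call


def _assembly_calls(
    clips: list[ClipSignal], genome: ReferenceGenome, n_supp: int
) -> list[SVCall]:
    out = []
    for cluster in large_insertion.find_clip_clusters(clips, n_supp):
        reads = [
            (c.read_id, c.read_seq)
            for c in cluster.left_members + cluster.right_members
            if c.read_seq
        ]
        if len({r for r, _ in reads}) < n_supp:
            continue
        region = (cluster.chrom, cluster.region_start, cluster.region_end)
        contigs = large_insertion.assemble_local(reads, region)
        call = large_insertion.call_large_insertion(cluster, contigs, genome)
        if call is not None:
            out.append(call)
    return out


def _dedupe_assembly(
    calls: list[SVCall], ins_calls: list[SVCall]
) -> list[SVCall]:
    """Merge assembly insertions with overlapping split/intra calls.

    The assembly call's size wins; the higher support count is kept.
    """
    out = list(calls)
    for a in ins_calls:
        merged = False
        for c in out:
            if (
                c.sv_type == "INS"
                and c.chrom == a.chrom
                and abs(c.pos - a.pos) <= 1000
                and 0.5 * a.size <= c.size <= 2 * a.size
            ):
                c.size = a.size
                c.end = a.end
                c.n_supp_reads = max(c.n_supp_reads, a.n_supp_reads)
                merged = True
                break
        if not merged:
            out.append(a)
    return out
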
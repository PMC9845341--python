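"""Per-read raw SV signal extraction.

Two evidence channels feed the caller:

* intra-alignment: insertions/deletions contained in one CIGAR
  (I/D/N ops at or above ``min_signal_size``, with nearby same-type ops
  merged, since aligners fragment single events in noisy reads);
* inter-alignment (split reads): adjacent alignment segments of one read
  classified by chromosome, orientation and the read/reference gap
  arithmetic into DEL/INS/DUP/INV/TRA.

Alignments with >= 200 bp clipped ends are additionally recorded as clip
signals, the substrate of the large-insertion module, and the same scan
accumulates per-chromosome aligned bases for the depth estimate that
drives the adaptive support threshold N_supp = depth/10 + 2.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .alignment_io import AlignmentRecord, parse_cigar_string
from ._seq import revcomp

CLIP_MIN = 200  # minimum clipped-end length to count as a clipped alignment


@dataclass
class RawSVSignal:
    sv_type: str  # INS DEL DUP INV TRA
    chrom: str
    pos: int
    size: int
    read_id: str
    source: str  # intra | split
    ins_seq: Optional[str] = None
    mapq: int = 60
    chrom2: Optional[str] = None  # TRA only
    pos2: Optional[int] = None
    inv_end: Optional[int] = None
    # breakpoint offset within the record's (reference-oriented) sequence,
    # plus that sequence, for consensus window extraction
    read_offset: Optional[int] = None
    read_seq_ref: Optional[str] = None

    def read_window(self, flank: int) -> Optional[str]:
        """Reference-oriented read subsequence spanning the SV +- flank.

        Returns None when the read does not fully cover the window.
        """
        if self.read_offset is None or self.read_seq_ref is None:
            return None
        span = self.size if self.sv_type == "INS" else 0
        lo = self.read_offset - flank
        hi = self.read_offset + span + flank
        if lo < 0 or hi > len(self.read_seq_ref):
            return None
        return self.read_seq_ref[lo:hi]


@dataclass
class ClipSignal:
    chrom: str
    pos: int
    side: str  # left: clipped bases precede the aligned block on the reference
    read_id: str
    clip_len: int
    read_seq: Optional[str] = None  # full reference-oriented record sequence


@dataclass
class DepthProfile:
    per_chrom_aligned_bases: dict[str, int]
    chrom_lengths: dict[str, int]

    @property
    def mean_depth(self) -> float:
        total_len = sum(self.chrom_lengths.values())
        if total_len == 0:
            return 0.0
        return sum(self.per_chrom_aligned_bases.values()) / total_len

    @property
    def n_supp(self) -> int:
        return int(self.mean_depth // 10) + 2


@dataclass
class Segment:
    """One aligned block of a read in physical-read coordinates."""

    read_id: str
    chrom: str
    ref_start: int
    ref_end: int
    strand: str
    read_start: int  # physical read orientation
    read_end: int
    mapq: int
    record: Optional[AlignmentRecord] = None


def _merge_gap_ok(gap: int, combined: int, max_fixed: int = 100) -> bool:
    return gap <= max(max_fixed, 0.5 * combined)


def extract_intra_signals(
    rec: AlignmentRecord, min_signal_size: int = 30
) -> list[RawSVSignal]:
    """I/D/N CIGAR ops >= min_signal_size, with nearby same-type ops merged.

    Two candidate ops of one type merge when the gap between them is at
    most max(100 bp, half their combined size); the merged signal keeps
    the first op's breakpoint.
    """
    if rec.is_secondary or rec.mapq == 0:
        return []
    cands: list[tuple[str, int, int, int]] = []  # (type, ref_pos, size, read_pos)
    ref = rec.ref_start
    rd = 0
    for op, n in rec.cigar:
        if op in "M=X":
            ref += n
            rd += n
        elif op == "I":
            if n >= min_signal_size:
                cands.append(("INS", ref, n, rd))
            rd += n
        elif op in "DN":
            if n >= min_signal_size:
                cands.append(("DEL", ref, n, rd))
            ref += n
        elif op in "SH":
            rd += n
    out: list[RawSVSignal] = []
    for typ in ("INS", "DEL"):
        run: list[tuple[str, int, int, int]] = []
        run_size = 0
        for c in [c for c in cands if c[0] == typ]:
            if run:
                prev = run[-1]
                if typ == "DEL":
                    gap = c[1] - (prev[1] + prev[2])
                else:
                    gap = c[3] - (prev[3] + prev[2])
                if _merge_gap_ok(gap, run_size + c[2]):
                    run.append(c)
                    run_size += c[2]
                    continue
                out.append(_emit_intra(rec, typ, run))
                run = []
                run_size = 0
            run.append(c)
            run_size += c[2]
        if run:
            out.append(_emit_intra(rec, typ, run))
    out.sort(key=lambda s: s.pos)
    return out


def _emit_intra(
    rec: AlignmentRecord, typ: str, run: list[tuple[str, int, int, int]]
) -> RawSVSignal:
    pos = run[0][1]
    size = sum(c[2] for c in run)
    read_pos = run[0][3]
    ins_seq = None
    if typ == "INS" and rec.read_seq is not None:
        ins_seq = "".join(rec.read_seq[c[3] : c[3] + c[2]] for c in run)
    return RawSVSignal(
        sv_type=typ,
        chrom=rec.chrom,
        pos=pos,
        size=size,
        read_id=rec.read_id,
        source="intra",
        ins_seq=ins_seq,
        mapq=rec.mapq,
        read_offset=read_pos,
        read_seq_ref=rec.read_seq,
    )


def segments_of_read(records: Sequence[AlignmentRecord]) -> list[Segment]:
    """Aligned segments of one read in physical-read coordinates.

    Prefers actual supplementary records; falls back to SA-tag entries of
    the primary when supplementaries were not retained.
    """
    recs = [r for r in records if not r.is_secondary]
    if not recs:
        return []
    segs: list[Segment] = []
    seen: set[tuple[str, int, str]] = set()
    for r in recs:
        L = r.read_length
        if r.strand == "+":
            rs, re_ = r.left_clip, L - r.right_clip
        else:
            rs, re_ = r.right_clip, L - r.left_clip
        key = (r.chrom, r.ref_start, r.strand)
        seen.add(key)
        segs.append(
            Segment(r.read_id, r.chrom, r.ref_start, r.ref_end, r.strand, rs, re_, r.mapq, r)
        )
    # SA entries not represented by an actual record
    primary = next((r for r in recs if not r.is_supplementary), recs[0])
    L = primary.read_length
    for sa in primary.sa_segments:
        if (sa.chrom, sa.pos, sa.strand) in seen:
            continue
        cig = parse_cigar_string(sa.cigar)
        ref_span = sum(n for op, n in cig if op in "M=XDN")
        left = cig[0][1] if cig and cig[0][0] in "SH" else 0
        right = cig[-1][1] if len(cig) > 1 and cig[-1][0] in "SH" else 0
        if sa.strand == "+":
            rs, re_ = left, L - right
        else:
            rs, re_ = right, L - left
        segs.append(
            Segment(
                primary.read_id, sa.chrom, sa.pos, sa.pos + ref_span, sa.strand, rs, re_, sa.mapq
            )
        )
    segs.sort(key=lambda s: (s.read_start, s.read_end))
    return segs


def classify_split_pair(
    seg_a: Segment, seg_b: Segment, min_signal_size: int = 30
) -> Optional[RawSVSignal]:
    """Classify an adjacent split-read segment pair.

    Priority: different chromosomes -> TRA; different strands -> INV;
    otherwise DEL/INS/DUP from the read-gap/ref-gap arithmetic.  Pairs
    where both segments have MAPQ 0 are suppressed.
    """
    a, b = seg_a, seg_b
    if a.read_id != b.read_id:
        raise ValueError("split pair from different reads")
    if a.mapq == 0 and b.mapq == 0:
        return None
    mapq = min(a.mapq, b.mapq)
    if a.chrom != b.chrom:
        pa = a.ref_end if a.strand == "+" else a.ref_start
        pb = b.ref_start if b.strand == "+" else b.ref_end
        (c1, p1), (c2, p2) = sorted([(a.chrom, pa), (b.chrom, pb)])
        return RawSVSignal(
            "TRA", c1, p1, 0, a.read_id, "split", mapq=mapq, chrom2=c2, pos2=p2
        )
    if a.strand != b.strand:
        if a.strand == "+":
            s, e = sorted((a.ref_end, b.ref_end))
        else:
            s, e = sorted((a.ref_start, b.ref_start))
        if e - s < min_signal_size:
            return None
        return RawSVSignal(
            "INV", a.chrom, s, e - s, a.read_id, "split", mapq=mapq, inv_end=e
        )
    g = b.read_start - a.read_end
    if a.strand == "+":
        r = b.ref_start - a.ref_end
        junction = a.ref_end
        overlap_start = b.ref_start
    else:
        r = a.ref_start - b.ref_end
        junction = b.ref_end
        overlap_start = a.ref_start
    if r - g >= min_signal_size:
        return RawSVSignal(
            "DEL", a.chrom, junction, r - g, a.read_id, "split", mapq=mapq
        )
    if r < 0 and -r >= min_signal_size and -r >= g:
        # reference overlap dominates the read gap: tandem duplication
        return RawSVSignal(
            "DUP", a.chrom, overlap_start, -r, a.read_id, "split", mapq=mapq
        )
    if g - r >= min_signal_size:
        ins_seq = None
        offset = None
        seq_ref = None
        rec = a.record or b.record
        if rec is not None and rec.read_seq is not None and rec.read_length:
            L = rec.read_length
            if a.strand == "+":
                offset, hi = a.read_end, b.read_start
                seq_ref = _oriented_seq(rec)
            else:
                offset, hi = L - b.read_start, L - a.read_end
                seq_ref = _oriented_seq(rec)
            if seq_ref is not None and hi <= len(seq_ref):
                ins_seq = seq_ref[offset:hi][: g - r]
        return RawSVSignal(
            "INS",
            a.chrom,
            junction,
            g - r,
            a.read_id,
            "split",
            ins_seq=ins_seq,
            mapq=mapq,
            read_offset=offset,
            read_seq_ref=seq_ref,
        )
    if r < 0 and -r >= min_signal_size:
        return RawSVSignal(
            "DUP", a.chrom, overlap_start, -r, a.read_id, "split", mapq=mapq
        )
    return None


def _oriented_seq(rec: AlignmentRecord) -> Optional[str]:
    """Record sequence in reference-forward orientation of its chromosome."""
    return rec.read_seq


def extract_split_signals(
    segments: Sequence[Segment], min_signal_size: int = 30
) -> list[RawSVSignal]:
    segs = sorted(segments, key=lambda s: (s.read_start, s.read_end))
    out = []
    for a, b in zip(segs, segs[1:]):
        sig = classify_split_pair(a, b, min_signal_size)
        if sig is not None:
            out.append(sig)
    return out


def record_clip_signals(
    rec: AlignmentRecord,
    read_segments: Optional[Sequence[Segment]] = None,
    clip_min: int = CLIP_MIN,
) -> list[ClipSignal]:
    """Clipped ends >= clip_min bp, unless explained by another segment.

    A clip is explained when the same read has another aligned segment on
    that side in read coordinates (the clipped bases map elsewhere).
    """
    if rec.is_secondary or rec.mapq == 0:
        return []
    L = rec.read_length
    if rec.strand == "+":
        rs, re_ = rec.left_clip, L - rec.right_clip
    else:
        rs, re_ = rec.right_clip, L - rec.left_clip
    before_explained = after_explained = False
    if read_segments:
        for s in read_segments:
            if s.ref_start == rec.ref_start and s.chrom == rec.chrom and s.strand == rec.strand:
                continue
            if s.read_end <= rs + 50:
                before_explained = True
            if s.read_start >= re_ - 50:
                after_explained = True
    out: list[ClipSignal] = []
    # CIGAR clips are in reference orientation; the physical before/after
    # side that explains them depends on the record strand
    if rec.strand == "+":
        left_expl, right_expl = before_explained, after_explained
    else:
        left_expl, right_expl = after_explained, before_explained
    if rec.left_clip >= clip_min and not left_expl:
        out.append(
            ClipSignal(rec.chrom, rec.ref_start, "left", rec.read_id, rec.left_clip, rec.read_seq)
        )
    if rec.right_clip >= clip_min and not right_expl:
        out.append(
            ClipSignal(rec.chrom, rec.ref_end, "right", rec.read_id, rec.right_clip, rec.read_seq)
        )
    return out


def estimate_depth(
    alignments: Iterable[AlignmentRecord], chrom_lengths: dict[str, int]
) -> DepthProfile:
    """Average depth as aligned read bases over genome length."""
    per_chrom = {c: 0 for c in chrom_lengths}
    for rec in alignments:
        if rec.is_secondary:
            continue
        per_chrom[rec.chrom] = per_chrom.get(rec.chrom, 0) + rec.aligned_bases
    return DepthProfile(per_chrom, dict(chrom_lengths))
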
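import numpy as np
import pytest

from svdense._seq import random_seq
from svdense.alignment_io import AlignmentRecord
from svdense.signal_detection import (
    DepthProfile,
    Segment,
    classify_split_pair,
    estimate_depth,
    extract_intra_signals,
    extract_split_signals,
    record_clip_signals,
    segments_of_read,
)


def _rec(cigar, ref_start=10000, read_seq=None, mapq=60, strand="+", chrom="chr1"):
    from svdense.alignment_io import parse_cigar_string

    cig = parse_cigar_string(cigar)
    ref_span = sum(n for op, n in cig if op in "MDN")
    left = cig[0][1] if cig[0][0] in "SH" else 0
    right = cig[-1][1] if len(cig) > 1 and cig[-1][0] in "SH" else 0
    if read_seq is None:
        read_len = sum(n for op, n in cig if op in "MIS")
        read_seq = "A" * read_len
    return AlignmentRecord(
        read_id="r1", chrom=chrom, ref_start=ref_start,
        ref_end=ref_start + ref_span, strand=strand, mapq=mapq, cigar=cig,
        left_clip=left, right_clip=right, read_seq=read_seq,
    )


class TestIntraSignals:
    def test_insertion(self, rng):
        seq = random_seq(rng, 1100)
        rec = _rec("500M100I500M", read_seq=seq)
        (sig,) = extract_intra_signals(rec, 50)
        assert sig.sv_type == "INS" and sig.pos == 10500 and sig.size == 100
        assert sig.ins_seq == seq[500:600]

    def test_below_threshold(self):
        assert extract_intra_signals(_rec("500M40D500M"), 50) == []

    def test_merging_rule(self):
        # 60D + 70D separated by 30M: gap 30 <= max(100, 0.5*130) -> merged
        (sig,) = extract_intra_signals(_rec("200M60D30M70D200M"), 50)
        assert sig.sv_type == "DEL"
        assert sig.pos == 10200  # first D
        assert sig.size == 130

    def test_merging_vs_bruteforce_oracle(self, rng):
        """Merged output equals brute-force interval merging on random CIGARs."""
        for _ in range(50):
            ops = []
            for _k in range(rng.integers(1, 6)):
                ops.append(("M", int(rng.integers(1, 300))))
                ops.append(("D", int(rng.integers(30, 200))))
            ops.append(("M", 200))
            cigar = "".join(f"{n}{op}" for op, n in ops)
            sigs = extract_intra_signals(_rec(cigar), 30)
            # oracle: greedy left-to-right merge over the D intervals
            pos = 10000
            dels = []
            for op, n in ops:
                if op == "M":
                    pos += n
                else:
                    dels.append((pos, n))
                    pos += n
            merged = []
            for p, n in dels:
                if merged and p - (merged[-1][0] + merged[-1][1]) <= max(
                    100, 0.5 * (merged[-1][2] + n)
                ):
                    merged[-1] = (merged[-1][0], p + n - merged[-1][0], merged[-1][2] + n)
                else:
                    merged.append((p, n, n))
            assert [(s.pos, s.size) for s in sigs] == [
                (p, sz) for p, _, sz in merged
            ]

    def test_mapq0_suppressed(self):
        assert extract_intra_signals(_rec("500M100I500M", mapq=0), 50) == []


def _seg(chrom="chr1", rs=10000, re=20000, strand="+", qs=0, qe=10000, mapq=60, rid="r1"):
    return Segment(rid, chrom, rs, re, strand, qs, qe, mapq)


class TestSplitPair:
    def test_deletion(self):
        a = _seg(rs=10000, re=20000, qs=0, qe=10000)
        b = _seg(rs=20500, re=25000, qs=10000, qe=14500)
        sig = classify_split_pair(a, b, 30)
        assert sig.sv_type == "DEL" and sig.pos == 20000 and sig.size == 500

    def test_duplication_overlap(self):
        a = _seg(rs=10000, re=20000, qs=0, qe=10000)
        b = _seg(rs=19700, re=25000, qs=10000, qe=15300)
        sig = classify_split_pair(a, b, 30)
        assert sig.sv_type == "DUP" and sig.size == 300 and sig.pos == 19700

    def test_inversion(self):
        a = _seg(rs=10000, re=20000, strand="+", qs=0, qe=10000)
        b = _seg(rs=20000, re=20400, strand="-", qs=10000, qe=10400)
        sig = classify_split_pair(a, b, 30)
        assert sig.sv_type == "INV" and sig.pos == 20000 and sig.inv_end == 20400

    def test_translocation(self):
        a = _seg(chrom="chr1", rs=10000, re=20000, qs=0, qe=10000)
        b = _seg(chrom="chr5", rs=50000, re=55000, qs=10000, qe=15000)
        sig = classify_split_pair(a, b, 30)
        assert sig.sv_type == "TRA"
        assert (sig.chrom, sig.pos) == ("chr1", 20000)
        assert (sig.chrom2, sig.pos2) == ("chr5", 50000)

    def test_different_reads_rejected(self):
        with pytest.raises(ValueError):
            classify_split_pair(_seg(rid="a"), _seg(rid="b"), 30)

    def test_mapq0_both_suppressed(self):
        a = _seg(mapq=0)
        b = _seg(rs=25000, re=30000, qs=10000, qe=15000, mapq=0)
        assert classify_split_pair(a, b, 30) is None


class TestSplitSignals:
    def test_single_segment(self):
        assert extract_split_signals([_seg()], 30) == []

    def test_three_segment_inversion(self):
        # read A - inv(B) - C over reference [0,10k) [10k,12k) [12k,20k)
        segs = [
            _seg(rs=0, re=10000, strand="+", qs=0, qe=10000),
            _seg(rs=10000, re=12000, strand="-", qs=10000, qe=12000),
            _seg(rs=12000, re=20000, strand="+", qs=12000, qe=20000),
        ]
        sigs = extract_split_signals(segs, 30)
        assert len(sigs) == 2
        assert all(s.sv_type == "INV" for s in sigs)
        assert all((s.pos, s.inv_end) == (10000, 12000) for s in sigs)

    def test_three_segment_inversion_reverse_read(self):
        # same inversion seen by a reverse-sequenced read: segment order and
        # strands flip, breakpoints must not change
        segs = [
            _seg(rs=12000, re=20000, strand="-", qs=0, qe=8000),
            _seg(rs=10000, re=12000, strand="+", qs=8000, qe=10000),
            _seg(rs=0, re=10000, strand="-", qs=10000, qe=20000),
        ]
        sigs = extract_split_signals(segs, 30)
        assert len(sigs) == 2
        assert all((s.pos, s.inv_end) == (10000, 12000) for s in sigs)

    def test_two_segment_deletion(self):
        segs = [
            _seg(rs=0, re=10000, qs=0, qe=10000),
            _seg(rs=12000, re=15000, qs=10000, qe=13000),
        ]
        (sig,) = extract_split_signals(segs, 30)
        assert sig.sv_type == "DEL" and sig.size == 2000


class TestClipSignals:
    def test_left_clip(self):
        rec = _rec("250S1000M")
        (sig,) = record_clip_signals(rec)
        assert sig.side == "left" and sig.pos == 10000 and sig.clip_len == 250

    def test_below_threshold(self):
        assert record_clip_signals(_rec("150S1000M")) == []

    def test_both_sides(self):
        sigs = record_clip_signals(_rec("300S1000M400S"))
        assert [s.side for s in sigs] == ["left", "right"]

    def test_clip_explained_by_sibling_segment(self):
        rec = _rec("300S1000M")
        sibling = _seg(rs=50000, re=50290, qs=0, qe=290)
        mine = _seg(rs=10000, re=11000, qs=300, qe=1300)
        assert record_clip_signals(rec, [sibling, mine]) == []


class TestDepth:
    def test_arithmetic(self):
        recs = [_rec("1000M", ref_start=i * 1000, chrom="g") for i in range(10)]
        prof = estimate_depth(recs, {"g": 10000})
        assert prof.mean_depth == 1.0
        assert prof.n_supp == 2

    def test_nsupp_formula(self):
        assert DepthProfile({"g": 500000}, {"g": 10000}).n_supp == 7  # 50x
        assert DepthProfile({"g": 450000}, {"g": 10000}).n_supp == 6  # 45x

    def test_secondary_excluded(self):
        r = _rec("1000M", chrom="g")
        r.is_secondary = True
        assert estimate_depth([r], {"g": 1000}).mean_depth == 0.0


def test_homozygous_del_one_signal_per_spanning_read(small_errorfree_sim):
    """On error-free oracle alignments every read spanning a hom DEL yields
    exactly one DEL signal of the true size at the true position."""
    cfg, res, records = small_errorfree_sim
    hom_dels = [t for t in res.truth if t.sv_type == "DEL" and t.zygosity == "hom"]
    assert hom_dels
    t = hom_dels[0]
    per_read = {}
    for recs in records:
        for rec in recs:
            for s in extract_intra_signals(rec, 30):
                if s.sv_type == "DEL" and abs(s.pos - t.pos) < 1000:
                    per_read.setdefault(s.read_id, []).append(s)
    assert per_read
    for sigs in per_read.values():
        assert len(sigs) == 1
        assert sigs[0].pos == t.pos and sigs[0].size == t.size


def test_signal_size_floor(small_errorfree_sim):
    cfg, res, records = small_errorfree_sim
    for recs in records[:300]:
        for rec in recs:
            for s in extract_intra_signals(rec, 30):
                assert s.size >= 30
            for c in record_clip_signals(rec, segments_of_read(recs)):
                assert c.clip_len >= 200
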
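import numpy as np
import pytest

from svdense.calling import SVCall
from svdense.evaluation import (
    breakpoint_shift_profile,
    compute_metrics,
    genotype_concordance,
    match_calls,
)
from svdense.simulator import TruthSV


def _truth(typ="DEL", chrom="c1", pos=10000, size=500, zyg="het", **kw):
    return TruthSV(typ, chrom, pos, size, zyg, "1", **kw)


def _call(typ="DEL", chrom="c1", pos=10000, size=500, **kw):
    base = dict(sv_type=typ, chrom=chrom, pos=pos, size=size,
                end=pos + size, n_supp_reads=10, genotype="0/1")
    base.update(kw)
    return SVCall(**base)


class TestTpRules:
    def test_within_tolerances_is_tp(self):
        res = match_calls([_truth()], [_call(pos=10900, size=600)], min_size=None)
        assert res.overall.tp == 1

    def test_size_window_violation(self):
        res = match_calls([_truth()], [_call(pos=10000, size=1001)], min_size=None)
        assert res.overall.tp == 0 and res.overall.fp == 1 and res.overall.fn == 1

    def test_type_mismatch(self):
        res = match_calls([_truth()], [_call(typ="INS")], min_size=None)
        assert res.overall.tp == 0

    def test_shift_beyond_1kb(self):
        res = match_calls([_truth()], [_call(pos=11001)], min_size=None)
        assert res.overall.tp == 0

    def test_tra_both_breakpoints(self):
        t = _truth(typ="TRA", size=0, chrom2="c2", pos2=50000)
        good = _call(typ="TRA", size=0, chrom2="c2", pos2=50800)
        bad = _call(typ="TRA", size=0, chrom2="c2", pos2=51500)
        assert match_calls([t], [good], min_size=None).overall.tp == 1
        assert match_calls([t], [bad], min_size=None).overall.tp == 0

    def test_ins_dup_equiv_flag(self):
        t = _truth(typ="DUP")
        c = _call(typ="INS")
        assert match_calls([t], [c], min_size=None).overall.tp == 0
        assert match_calls([t], [c], min_size=None, ins_dup_equiv=True).overall.tp == 1


class TestMetrics:
    def test_arithmetic(self):
        truth = [_truth(pos=p) for p in (10000, 20000, 30000, 40000, 50000,
                                         60000, 70000, 80000, 90000, 100000)]
        calls = [_call(pos=p) for p in (10000, 20000, 30000, 40000, 50000,
                                        60000, 70000, 80000, 90000)] + [
            _call(pos=300000)
        ]
        res = match_calls(truth, calls, min_size=None)
        m = compute_metrics(res)["overall"]
        assert m == (0.9, 0.9, pytest.approx(0.9))

    def test_no_calls(self):
        res = match_calls([_truth()], [], min_size=None)
        assert res.undefined_precision
        assert compute_metrics(res)["overall"] == (0.0, 0.0, 0.0)

    def test_perfect(self):
        truth = [_truth(pos=p) for p in (10000, 20000)]
        calls = [_call(pos=p) for p in (10000, 20000)]
        assert compute_metrics(match_calls(truth, calls, min_size=None))["overall"] == (
            1.0, 1.0, 1.0
        )


class TestShiftProfile:
    def _matched(self, shifts):
        truth = [_truth(pos=10000 + 50000 * i) for i in range(len(shifts))]
        calls = [_call(pos=10000 + 50000 * i + s) for i, s in enumerate(shifts)]
        return match_calls(truth, calls, min_size=None)

    def test_all_exact(self):
        res = self._matched([0, 0, 0])
        _, exact, within1 = breakpoint_shift_profile(res)
        assert exact == 1.0 and within1 == 1.0

    def test_counting(self):
        res = self._matched([0, 0, 1, -3])
        hist, exact, within1 = breakpoint_shift_profile(res)
        assert exact == 0.5 and within1 == 0.75
        assert hist[0] == 2 and hist[1] == 1 and hist[-3] == 1

    def test_clamping(self):
        res = self._matched([250])
        hist, _, _ = breakpoint_shift_profile(res)
        assert hist[100] == 1


class TestMatchingProperties:
    def test_one_to_one(self, rng):
        truth = [_truth(pos=10000 + int(d)) for d in rng.integers(0, 500, 6)]
        calls = [_call(pos=10000 + int(d)) for d in rng.integers(0, 500, 8)]
        res = match_calls(truth, calls, min_size=None)
        assert len({id(m[0]) for m in res.matches}) == len(res.matches)
        assert len({id(m[1]) for m in res.matches}) == len(res.matches)
        assert res.overall.tp == len(res.matches)

    def test_permutation_invariance(self, rng):
        truth = [_truth(pos=int(p)) for p in rng.integers(10000, 500000, 10)]
        calls = [_call(pos=int(p + rng.integers(-800, 800)))
                 for p in [t.pos for t in truth]]
        a = compute_metrics(match_calls(truth, calls, min_size=None))
        perm = [calls[i] for i in rng.permutation(len(calls))]
        b = compute_metrics(match_calls(truth[::-1], perm, min_size=None))
        assert a == b

    def test_greedy_close_to_optimal_bipartite(self, rng):
        """Greedy TP counts equal maximum bipartite matching on >= 99% of
        small random instances (crowded loci may differ)."""
        import networkx as nx

        agree = 0
        n_trials = 300
        for _ in range(n_trials):
            truth = [_truth(pos=int(p)) for p in rng.integers(0, 60000, rng.integers(1, 11))]
            calls = [_call(pos=int(p)) for p in rng.integers(0, 60000, rng.integers(1, 11))]
            res = match_calls(truth, calls, min_size=None, max_shift=1000)
            g = nx.Graph()
            tn = [f"t{i}" for i in range(len(truth))]
            cn = [f"c{i}" for i in range(len(calls))]
            g.add_nodes_from(tn, bipartite=0)
            g.add_nodes_from(cn, bipartite=1)
            for i, t in enumerate(truth):
                for j, c in enumerate(calls):
                    if abs(t.pos - c.pos) <= 1000:
                        g.add_edge(f"t{i}", f"c{j}")
            mm = nx.algorithms.matching.max_weight_matching(g, maxcardinality=True)
            agree += res.overall.tp == len(mm)
        assert agree >= 0.99 * n_trials


def test_genotype_concordance_separate_from_tp():
    t = _truth(zyg="hom")
    c = _call(genotype="0/1")
    res = match_calls([t], [c], min_size=None)
    assert res.overall.tp == 1  # wrong genotype still a TP
    assert genotype_concordance(res) == 0.0
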
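import numpy as np
import pytest

from svdense._seq import revcomp
from svdense.alignment_io import ReferenceGenome
from svdense.simulator import (
    DEFAULT_COUNTS,
    SimConfig,
    SizeModel,
    TruthSV,
    apply_svs_to_genome,
    error_rng,
    read_truth_tsv,
    sample_sv_set,
    simulate,
    simulate_read_placements,
    write_truth_tsv,
)


class TestSampleSvSet:
    def test_default_composition(self):
        svs = sample_sv_set(SimConfig(seed=2))
        assert len(svs) == 22200
        by_type = {t: sum(1 for s in svs if s.sv_type == t) for t in DEFAULT_COUNTS}
        assert by_type == DEFAULT_COUNTS

    def test_het_hom_ratio_exact(self):
        cfg = SimConfig(
            chrom_lengths={"c1": 2_000_000}, counts={"DEL": 9}, seed=3
        )
        svs = sample_sv_set(cfg)
        zyg = [s.zygosity for s in svs]
        assert zyg.count("het") == 6 and zyg.count("hom") == 3

    def test_empty_counts(self):
        cfg = SimConfig(chrom_lengths={"c1": 100000}, counts={}, seed=1)
        assert sample_sv_set(cfg) == []

    def test_minimum_separation(self):
        cfg = SimConfig(
            chrom_lengths={"c1": 5_000_000}, counts={"DEL": 50, "INS": 50}, seed=4
        )
        svs = [s for s in sample_sv_set(cfg)]
        svs.sort(key=lambda s: s.pos)
        for a, b in zip(svs, svs[1:]):
            clear = 2 * max(a.size, b.size, 1000)
            assert b.pos - a.end >= clear


def _toy_genome(rng, n=10000):
    from svdense._seq import random_seq

    return ReferenceGenome({"c1": random_seq(rng, n), "c2": random_seq(rng, n)})


class TestApplySvs:
    def test_hom_deletion_lengths(self, rng):
        g = _toy_genome(rng)
        svs = [TruthSV("DEL", "c1", 4000, 500, "hom", "both")]
        haps, truth = apply_svs_to_genome(g, svs)
        for hap in (1, 2):
            assert haps.chroms[hap]["c1"].length == 9500

    def test_het_insertion_one_haplotype(self, rng):
        g = _toy_genome(rng)
        svs = [TruthSV("INS", "c1", 4000, 300, "het", "1", ins_seq="ACGT" * 75)]
        haps, truth = apply_svs_to_genome(g, svs)
        assert haps.chroms[1]["c1"].length == 10300
        assert haps.chroms[2]["c1"].length == 10000

    def test_inversion_is_revcomp(self, rng):
        g = _toy_genome(rng)
        s, e = 4000, 4600
        svs = [TruthSV("INV", "c1", s, e - s, "hom", "both")]
        haps, _ = apply_svs_to_genome(g, svs)
        hseq = haps.chroms[1]["c1"].seq
        ref = g.sequences["c1"]
        assert hseq[s:e] == revcomp(ref[s:e])
        assert hseq[:s] == ref[:s] and hseq[e:] == ref[e:]

    def test_liftover_inverse(self, rng):
        g = _toy_genome(rng)
        svs = [TruthSV("DEL", "c1", 3000, 400, "hom", "both")]
        haps, _ = apply_svs_to_genome(g, svs)
        hc = haps.chroms[1]["c1"]
        assert hc.liftover(2999) == ("c1", 2999, "+")
        assert hc.liftover(3000) == ("c1", 3400, "+")

    def test_translocation_swaps_tails(self, rng):
        g = _toy_genome(rng)
        svs = [TruthSV("TRA", "c1", 4000, 0, "hom", "both", chrom2="c2", pos2=6000)]
        haps, truth = apply_svs_to_genome(g, svs)
        a = haps.chroms[1]["c1"].seq
        assert a == g.sequences["c1"][:4000] + g.sequences["c2"][6000:]


class TestReads:
    def test_depth_within_two_percent(self, rng):
        g = _toy_genome(rng, 100000)
        haps, _ = apply_svs_to_genome(g, [])
        cfg = SimConfig(chrom_lengths={"c1": 100000, "c2": 100000}, depth=20,
                        mean_read_length=5000, seed=1)
        reads = simulate_read_placements(haps, cfg, np.random.default_rng(1))
        total = sum(r.end - r.start for r in reads)
        assert abs(total - 20 * 400000) <= 0.02 * 20 * 400000

    def test_error_free_reads_are_substrings(self):
        cfg = SimConfig(chrom_lengths={"c1": 50000}, counts={"DEL": 1},
                        depth=3, mean_read_length=5000, preset="perfect", seed=9)
        res = simulate(cfg)
        rng = error_rng(cfg)
        for recs in res.records(cfg, rng):
            for rec in recs:
                hseqs = [res.haplotypes.chroms[h]["c1"].seq for h in (1, 2)]
                s = rec.read_seq
                assert any(s in h or revcomp(s) in h for h in hseqs)

    def test_seeded_determinism(self):
        cfg = SimConfig(chrom_lengths={"c1": 80000}, counts={"DEL": 3, "INS": 3},
                        depth=5, mean_read_length=5000, preset="pacbio-clr", seed=42)
        def run():
            res = simulate(cfg)
            recs = [r for rs in res.records(cfg, error_rng(cfg)) for r in rs]
            return [(r.read_id, r.chrom, r.ref_start, tuple(r.cigar)) for r in recs], res.truth
        a, ta = run()
        b, tb = run()
        assert a == b and ta == tb


class TestOracleAlignments:
    def test_hom_deletion_yields_del_op(self):
        cfg = SimConfig(chrom_lengths={"c1": 60000},
                        counts={"DEL": 1}, het_fraction=0.0,
                        size_model=SizeModel(fixed_range=(500, 500)),
                        depth=8, mean_read_length=8000, preset="perfect", seed=3)
        res = simulate(cfg)
        t = res.truth[0]
        found = 0
        for recs in res.records(cfg, error_rng(cfg)):
            for rec in recs:
                if rec.ref_start < t.pos - 100 and rec.ref_end > t.pos + t.size + 100:
                    assert ("D", 500) in rec.cigar
                    found += 1
        assert found > 0

    def test_large_het_insertion_produces_clips(self):
        cfg = SimConfig(chrom_lengths={"c1": 200000},
                        counts={"INS": 1}, het_fraction=1.0,
                        size_model=SizeModel(fixed_range=(20000, 20000)),
                        depth=15, mean_read_length=9000, preset="perfect", seed=3)
        res = simulate(cfg)
        t = res.truth[0]
        clips = 0
        for recs in res.records(cfg, error_rng(cfg)):
            for rec in recs:
                near_bp = abs(rec.ref_end - t.pos) < 50 or abs(rec.ref_start - t.pos) < 50
                if near_bp and max(rec.left_clip, rec.right_clip) >= 200:
                    clips += 1
        assert clips >= 5

    def test_plain_region_pure_match(self):
        cfg = SimConfig(chrom_lengths={"c1": 30000}, counts={},
                        depth=5, mean_read_length=5000, preset="perfect", seed=3)
        res = simulate(cfg)
        for recs in res.records(cfg, error_rng(cfg)):
            for rec in recs:
                assert [op for op, n in rec.cigar] == ["M"]


def test_truth_tsv_round_trip(tmp_path):
    cfg = SimConfig(chrom_lengths={"c1": 200000, "c2": 200000},
                    counts={"DEL": 3, "INS": 3, "TRA": 1}, seed=6)
    svs = sample_sv_set(cfg)
    path = str(tmp_path / "t.tsv")
    write_truth_tsv(svs, path)
    back = read_truth_tsv(path)
    assert [(t.sv_type, t.chrom, t.pos, t.size, t.zygosity) for t in back] == [
        (t.sv_type, t.chrom, t.pos, t.size, t.zygosity) for t in svs
    ]
    for t, b in zip(svs, back):
        assert t.end == b.end
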
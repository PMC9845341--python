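import numpy as np
import pytest

from svdense.clustering import (
    SVCluster,
    cluster_translocations,
    compute_density,
    density_cluster,
    optimal_two_partition,
    split_multiallele,
)
from svdense.signal_detection import RawSVSignal


def _sig(pos, size=300, typ="DEL", rid=None, chrom="c1", pos2=None, chrom2=None):
    return RawSVSignal(
        typ, chrom, pos, size, rid or f"r{pos}_{np.random.randint(1e9)}",
        "intra", pos2=pos2, chrom2=chrom2,
    )


class TestDensity:
    def test_colocated(self):
        d = compute_density(np.array([100] * 5), 100)
        assert list(d) == [5] * 5

    def test_far_apart(self):
        d = compute_density(np.array([100, 1_000_100]), 100)
        assert list(d) == [1, 1]

    def test_counting(self):
        d = compute_density(np.array([100, 140, 180]), 100)
        assert d[1] == 3


class TestDensityCluster:
    def test_single_cluster(self):
        sigs = [_sig(5000, rid=f"r{i}") for i in range(10)]
        (cl,) = density_cluster(sigs, 7)
        assert len(cl.members) == 10

    def test_below_peak_threshold(self):
        sigs = [_sig(5000, rid=f"r{i}") for i in range(4)]
        assert density_cluster(sigs, 7) == []

    def test_two_separated_groups_match_gap_clustering(self):
        sigs = [_sig(5000, rid=f"a{i}") for i in range(10)] + [
            _sig(55000, rid=f"b{i}") for i in range(10)
        ]
        cls = density_cluster(sigs, 7)
        assert len(cls) == 2
        assert sorted(len(c.members) for c in cls) == [10, 10]

    def test_equals_single_linkage_on_separated_groups(self, rng):
        """With groups farther apart than any bandwidth, density clustering
        equals single-linkage gap clustering."""
        for _ in range(50):
            n_groups = int(rng.integers(1, 5))
            centers = np.cumsum(rng.integers(20000, 50000, n_groups))
            sigs, truth_groups = [], []
            for g, c in enumerate(centers):
                n = int(rng.integers(5, 12))
                # spread within half the base bandwidth so every member sees
                # the whole group in its density count
                poss = sorted(int(c + d) for d in rng.integers(-25, 26, n))
                truth_groups.append(n)
                sigs.extend(_sig(p, rid=f"g{g}_{i}") for i, p in enumerate(poss))
            cls = density_cluster(sigs, 5)
            expected = [n for n in truth_groups if n >= 5]
            assert sorted(len(c.members) for c in cls) == sorted(expected)

    def test_partition_and_window_disjointness(self, rng):
        sigs = [_sig(int(p), rid=f"r{i}") for i, p in enumerate(rng.integers(0, 100000, 200))]
        cls = density_cluster(sigs, 3)
        seen = set()
        for c in cls:
            for m in c.members:
                assert id(m) not in seen
                seen.add(id(m))
        wins = sorted((c.window_start, c.window_end) for c in cls)
        for (s1, e1), (s2, e2) in zip(wins, wins[1:]):
            assert e1 <= s2

    def test_nsupp_monotonicity(self, rng):
        sigs = [_sig(int(p), rid=f"r{i}") for i, p in enumerate(rng.integers(0, 50000, 150))]
        counts = [len(density_cluster(sigs, n)) for n in (2, 4, 6, 8, 10)]
        assert counts == sorted(counts, reverse=True)


class TestTranslocations:
    def _tra(self, pos, pos2, rid):
        return RawSVSignal("TRA", "c1", pos, 0, rid, "split", chrom2="c2", pos2=pos2)

    def test_tight_group(self, rng):
        sigs = [
            self._tra(10000 + int(d1), 90000 + int(d2), f"r{i}")
            for i, (d1, d2) in enumerate(zip(rng.integers(-50, 50, 8), rng.integers(-50, 50, 8)))
        ]
        (cl,) = cluster_translocations(sigs)
        assert len(cl.members) == 8

    def test_scattered_group_uses_wide_window(self, rng):
        # positions spread with sd ~350: still one cluster via the 800 bp window
        offs = [-600, -400, -200, 0, 200, 400, 600, 500]
        sigs = [self._tra(10000 + o, 90000 + o, f"r{i}") for i, o in enumerate(offs)]
        cls = cluster_translocations(sigs)
        assert len(cls) == 1

    def test_two_distant_groups(self):
        sigs = [self._tra(10000, 90000, f"a{i}") for i in range(5)] + [
            self._tra(10000, 1_090_000, f"b{i}") for i in range(5)
        ]
        cls = cluster_translocations(sigs)
        assert len(cls) == 2


def _cluster(sizes, typ="INS"):
    members = [_sig(1000, size=s, typ=typ, rid=f"r{i}") for i, s in enumerate(sizes)]
    return SVCluster(typ, "c1", 990, 1010, 1000, float(len(sizes)), members)


class TestMultiallele:
    def test_unimodal_single_allele(self):
        (cl,) = split_multiallele(_cluster([300] * 8))
        assert cl.allele_index == 0 and len(cl.members) == 8

    def test_bimodal_split(self):
        out = split_multiallele(_cluster([300] * 5 + [900] * 5))
        assert len(out) == 2
        assert out[0].allele_index == 1 and out[1].allele_index == 2
        assert np.mean([m.size for m in out[0].members]) == 300
        assert np.mean([m.size for m in out[1].members]) == 900

    def test_single_member_unchanged(self):
        (cl,) = split_multiallele(_cluster([400]))
        assert len(cl.members) == 1

    def test_outlier_shedding(self):
        out = split_multiallele(_cluster([300] * 10 + [10_000]))
        (cl,) = out
        assert 10_000 not in [m.size for m in cl.members]

    def test_inv_not_split(self):
        (cl,) = split_multiallele(_cluster([100] * 5 + [900] * 5, typ="INV"))
        assert cl.allele_index == 0


class TestTwoPartition:
    def test_matches_exhaustive_and_sklearn(self, rng):
        """1-D 2-means equals the optimal threshold split on every instance
        with <= 12 members (cross-checked against scikit-learn KMeans)."""
        from sklearn.cluster import KMeans

        def wcss(groups):
            return sum(
                float(((np.array(g) - np.mean(g)) ** 2).sum()) for g in groups if g
            )

        for _ in range(60):
            n = int(rng.integers(2, 13))
            xs = rng.integers(50, 5000, n).tolist()
            lo, hi = optimal_two_partition(xs)
            km = KMeans(n_clusters=2, n_init=10, random_state=0).fit(
                np.array(xs, dtype=float).reshape(-1, 1)
            )
            groups = [
                [x for x, l in zip(xs, km.labels_) if l == 0],
                [x for x, l in zip(xs, km.labels_) if l == 1],
            ]
            assert wcss([lo, hi]) <= wcss(groups) + 1e-6
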
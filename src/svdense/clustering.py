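"""Merging raw SV signals into candidate clusters.

INS/DEL/DUP/INV signals of one chromosome are clustered by signal
density: peaks at least N_supp high are processed from highest to lowest,
and each cluster window extends from the summit until the density drops
below 10% of the summit height (or the positional gap exceeds the
bandwidth).  The bandwidth adapts to the local median signal size, so
longer events — whose raw breakpoints scatter more — get wider windows.

Translocations use fixed 400/800 bp windows on both breakpoints, the
wider window for groups with larger positional spread.

A candidate whose member sizes are bimodal (Q3 >= 2*Q1) is split into two
alleles by optimal 1-D 2-means; otherwise size outliers are shed and a
single allele is kept.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from statistics import pstdev

import numpy as np

from .signal_detection import RawSVSignal


@dataclass
class SVCluster:
    sv_type: str
    chrom: str
    window_start: int
    window_end: int
    summit_pos: int
    summit_density: float
    members: list[RawSVSignal]
    allele_index: int = 0  # 0 single, 1/2 alleles of a multi-allele SV

    @property
    def read_support(self) -> int:
        return len({m.read_id for m in self.members})

    @property
    def mean_pos(self) -> int:
        return int(np.floor(np.mean([m.pos for m in self.members]) + 0.5))

    @property
    def mean_size(self) -> int:
        return int(np.floor(np.mean([m.size for m in self.members]) + 0.5))


def compute_density(positions: np.ndarray, bandwidth: int) -> np.ndarray:
    """Signal count within +-bandwidth/2 of each signal position."""
    positions = np.asarray(positions)
    half = bandwidth / 2
    hi = np.searchsorted(positions, positions + half, side="right")
    lo = np.searchsorted(positions, positions - half, side="left")
    return (hi - lo).astype(float)


def _adaptive_bandwidth(sizes: np.ndarray) -> int:
    return int(min(1000, max(100, 0.5 * float(np.median(sizes)))))


def density_cluster(
    signals: list[RawSVSignal],
    n_supp: int,
    base_bandwidth: int = 100,
    drop_fraction: float = 0.10,
) -> list[SVCluster]:
    """Density-peak clustering of one chromosome's signals of one type.

    Peaks are consumed from highest summit to lowest; each signal joins at
    most one cluster; peaks below n_supp are left unclustered.
    """
    if not signals:
        return []
    sig = sorted(signals, key=lambda s: s.pos)
    pos = np.array([s.pos for s in sig], dtype=np.int64)
    sizes = np.array([max(s.size, 1) for s in sig], dtype=np.int64)
    alive = np.ones(len(sig), dtype=bool)
    out: list[SVCluster] = []
    while True:
        idx = np.flatnonzero(alive)
        if len(idx) == 0:
            break
        p = pos[idx]
        dens = compute_density(p, base_bandwidth)
        k = int(np.argmax(dens))
        if dens[k] < n_supp:
            break
        summit = int(p[k])
        near = np.abs(p - summit) <= 500
        bw = _adaptive_bandwidth(sizes[idx][near])
        dens = compute_density(p, bw)
        k = int(np.argmax(dens))
        summit = int(p[k])
        summit_d = float(dens[k])
        if summit_d < n_supp:
            break
        thr = drop_fraction * summit_d
        lo = k
        while lo > 0 and dens[lo - 1] >= thr and p[lo] - p[lo - 1] <= bw:
            lo -= 1
        hi = k
        while hi + 1 < len(p) and dens[hi + 1] >= thr and p[hi + 1] - p[hi] <= bw:
            hi += 1
        take = idx[lo : hi + 1]
        members = [sig[i] for i in take]
        out.append(
            SVCluster(
                sv_type=members[0].sv_type,
                chrom=members[0].chrom,
                window_start=int(p[lo]),
                window_end=int(p[hi]) + 1,
                summit_pos=summit,
                summit_density=summit_d,
                members=members,
            )
        )
        alive[take] = False
    out.sort(key=lambda c: c.window_start)
    return out


def _chain_group(
    sigs: list[RawSVSignal], window: int
) -> list[list[RawSVSignal]]:
    groups: list[list[RawSVSignal]] = []
    cur: list[RawSVSignal] = []
    for s in sigs:
        if cur and (
            s.pos - cur[-1].pos > window or abs(s.pos2 - cur[-1].pos2) > window
        ):
            groups.append(cur)
            cur = []
        cur.append(s)
    if cur:
        groups.append(cur)
    return groups


def cluster_translocations(
    signals: list[RawSVSignal], sd_cutoff: int = 200
) -> list[SVCluster]:
    """Fixed-window clustering of TRA breakpoint pairs.

    Both breakpoints must co-locate within the window; 400 bp for tight
    groups (positional sd <= sd_cutoff), 800 bp for scattered ones.
    """
    by_pair: dict[tuple[str, str], list[RawSVSignal]] = {}
    for s in signals:
        by_pair.setdefault((s.chrom, s.chrom2), []).append(s)
    out: list[SVCluster] = []
    for (c1, c2), sigs in sorted(by_pair.items()):
        sigs.sort(key=lambda s: (s.pos, s.pos2))
        for prov in _chain_group(sigs, 800):
            sd = max(
                pstdev([s.pos for s in prov]) if len(prov) > 1 else 0.0,
                pstdev([s.pos2 for s in prov]) if len(prov) > 1 else 0.0,
            )
            window = 400 if sd <= sd_cutoff else 800
            for grp in _chain_group(prov, window):
                ps = [s.pos for s in grp]
                out.append(
                    SVCluster(
                        sv_type="TRA",
                        chrom=c1,
                        window_start=min(ps),
                        window_end=max(ps) + 1,
                        summit_pos=int(np.median(ps)),
                        summit_density=float(len(grp)),
                        members=grp,
                    )
                )
    return out


def optimal_two_partition(sizes: list[int]) -> tuple[list[int], list[int]]:
    """Optimal 1-D 2-partition (minimum within-cluster sum of squares).

    In one dimension the 2-means optimum is a threshold split of the
    sorted values, so exhaustive search over the n-1 splits is exact.
    """
    xs = np.sort(np.asarray(sizes, dtype=float))
    n = len(xs)
    csum = np.cumsum(xs)
    csq = np.cumsum(xs**2)
    best_k, best_cost = 1, np.inf
    for k in range(1, n):
        left = csq[k - 1] - csum[k - 1] ** 2 / k
        right = (csq[-1] - csq[k - 1]) - (csum[-1] - csum[k - 1]) ** 2 / (n - k)
        cost = left + right
        if cost < best_cost - 1e-9:
            best_cost, best_k = cost, k
    thr = xs[best_k - 1]
    lo = [int(x) for x in xs[:best_k]]
    hi = [int(x) for x in xs[best_k:]]
    return lo, hi


def split_multiallele(cluster: SVCluster) -> list[SVCluster]:
    """Q1/Q3 bimodality test and optimal 2-means allele separation.

    Applies to INS/DEL/DUP clusters; single-allele clusters shed size
    outliers beyond [Q1/2, 2*Q3].
    """
    if cluster.sv_type not in ("INS", "DEL", "DUP") or len(cluster.members) < 2:
        return [cluster]
    sizes = np.array([m.size for m in cluster.members], dtype=float)
    q1, q3 = np.percentile(sizes, [25, 75])
    if q3 < 2 * q1:
        keep = [
            m for m in cluster.members if q1 / 2 <= m.size <= 2 * q3
        ]
        if keep and len(keep) < len(cluster.members):
            cluster = SVCluster(
                cluster.sv_type,
                cluster.chrom,
                cluster.window_start,
                cluster.window_end,
                cluster.summit_pos,
                cluster.summit_density,
                keep,
                allele_index=0,
            )
        return [cluster]
    lo, hi = optimal_two_partition([m.size for m in cluster.members])
    thr = max(lo)
    low_members = [m for m in cluster.members if m.size <= thr]
    high_members = [m for m in cluster.members if m.size > thr]
    out = []
    for i, members in enumerate((low_members, high_members), start=1):
        if members:
            out.append(
                SVCluster(
                    cluster.sv_type,
                    cluster.chrom,
                    cluster.window_start,
                    cluster.window_end,
                    cluster.summit_pos,
                    cluster.summit_density,
                    members,
                    allele_index=i,
                )
            )
    return out
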
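"""Partial order alignment for consensus building.

Reads are aligned one after another to a growing DAG; matched bases fuse
into existing nodes (or into ring-mates — alternative bases aligned to the
same column), mismatches branch, and indels add or skip nodes.  The
consensus is the heaviest source-to-sink path, scoring node support plus
edge traversal counts, so on gap-free equal-length inputs it reduces to a
column-wise majority vote.

Alignment to the graph uses the same affine scheme as the pairwise module
(row-vectorised over the sequence, one row per graph node in topological
order); gap of length L costs gap_open + gap_ext * L.
"""

from __future__ import annotations

from collections import deque

import numpy as np

from ._seq import codes_to_seq, seq_to_codes

NEG = np.int32(-(10**9))


class PartialOrderGraph:
    def __init__(
        self,
        match: int = 2,
        mismatch: int = -4,
        gap_open: int = -2,
        gap_ext: int = -2,
    ):
        self.match = match
        self.mismatch = mismatch
        self.go = -(gap_open + gap_ext)  # positive cost, first gap base
        self.ge = -gap_ext
        self.bases: list[int] = []
        self.support: list[int] = []
        self.preds: list[list[int]] = []
        self.succs: list[list[int]] = []
        self.edge_w: dict[tuple[int, int], int] = {}
        self.ring: list[int] = []  # ring id per node (column of aligned alts)
        self.ring_members: dict[int, list[int]] = {}
        self.n_reads = 0

    # -- construction ------------------------------------------------
    def _new_node(self, base: int, ring_with: int | None = None) -> int:
        v = len(self.bases)
        self.bases.append(base)
        self.support.append(1)
        self.preds.append([])
        self.succs.append([])
        if ring_with is None:
            self.ring.append(v)
            self.ring_members[v] = [v]
        else:
            rid = self.ring[ring_with]
            self.ring.append(rid)
            self.ring_members[rid].append(v)
        return v

    def _add_edge(self, u: int, v: int) -> None:
        key = (u, v)
        if key in self.edge_w:
            self.edge_w[key] += 1
        else:
            self.edge_w[key] = 1
            self.succs[u].append(v)
            self.preds[v].append(u)

    def _topo_order(self) -> list[int]:
        indeg = [len(p) for p in self.preds]
        q = deque(v for v in range(len(self.bases)) if indeg[v] == 0)
        order = []
        while q:
            v = q.popleft()
            order.append(v)
            for w in self.succs[v]:
                indeg[w] -= 1
                if indeg[w] == 0:
                    q.append(w)
        return order

    def add_sequence(self, seq: str) -> None:
        codes = seq_to_codes(seq)
        if len(codes) == 0:
            raise ValueError("empty sequence")
        self.n_reads += 1
        if not self.bases:
            prev = None
            for b in codes:
                v = self._new_node(int(b))
                if prev is not None:
                    self._add_edge(prev, v)
                prev = v
            return
        pairs = self._align(codes)
        self._merge(codes, pairs)

    # -- graph alignment ---------------------------------------------
    def _align(self, codes: np.ndarray) -> list[tuple[int | None, int | None]]:
        order = self._topo_order()
        rank = {v: t for t, v in enumerate(order)}
        V = len(order)
        m = len(codes)
        go, ge = self.go, self.ge

        # score rows per base value against the sequence
        sc = np.where(
            codes[None, :] == np.arange(4, dtype=np.uint8)[:, None],
            np.int32(self.match),
            np.int32(self.mismatch),
        )
        row0 = np.empty(m + 1, dtype=np.int32)  # virtual start (leading seq gap)
        row0[0] = 0
        if m:
            row0[1:] = -(go + ge * np.arange(m, dtype=np.int32))
        karr = (np.arange(m + 1, dtype=np.int64) * ge).astype(np.int32)

        H = np.empty((V, m + 1), dtype=np.int32)
        E = np.empty((V, m + 1), dtype=np.int32)
        F = np.empty((V, m + 1), dtype=np.int32)
        for t, v in enumerate(order):
            ps = self.preds[v]
            if not ps:
                Hp = row0
                Ev = row0 - go
            else:
                r0 = rank[ps[0]]
                Hp = H[r0]
                Ev = np.maximum(Hp - go, E[r0] - ge)
                for p in ps[1:]:
                    rp = rank[p]
                    Hp = np.maximum(Hp, H[rp])
                    np.maximum(Ev, np.maximum(H[rp] - go, E[rp] - ge), out=Ev)
            srow = sc[self.bases[v]] if self.bases[v] < 4 else np.full(m, self.mismatch, np.int32)
            H0 = np.empty(m + 1, dtype=np.int32)
            H0[0] = Ev[0]
            np.maximum(Hp[:-1] + srow, Ev[1:], out=H0[1:])
            B = H0 + karr
            cb = np.maximum.accumulate(B)
            Fv = np.empty(m + 1, dtype=np.int32)
            Fv[0] = NEG
            Fv[1:] = cb[:-1] - go - (karr[1:] - np.int32(ge))
            H[t] = np.maximum(H0, Fv)
            E[t] = Ev
            F[t] = Fv

        # traceback from best sink at j = m
        sinks = [v for v in order if not self.succs[v]]
        best_v = max(sinks, key=lambda v: (H[rank[v], m], -v))
        pairs: list[tuple[int | None, int | None]] = []
        t = rank[best_v]
        v: int | None = best_v
        j = m
        state = "H"
        while v is not None:
            ps = self.preds[v]
            hval = H[t, j]
            if state == "H":
                if j > 0:
                    s = (
                        self.match
                        if self.bases[v] < 4 and codes[j - 1] == self.bases[v]
                        else self.mismatch
                    )
                    moved = False
                    if not ps and row0[j - 1] + s == hval:
                        pairs.append((v, j - 1))
                        j -= 1
                        # leading seq gap before alignment start
                        while j > 0:
                            j -= 1
                            pairs.append((None, j))
                        v = None
                        moved = True
                    else:
                        for p in ps:
                            if H[rank[p], j - 1] + s == hval:
                                pairs.append((v, j - 1))
                                v, t = p, rank[p]
                                j -= 1
                                moved = True
                                break
                    if moved:
                        continue
                if E[t, j] == hval:
                    state = "E"
                    continue
                state = "F"
                continue
            if state == "E":
                eval_ = E[t, j]
                pairs.append((v, None))
                if not ps and row0[j] - self.go == eval_:
                    while j > 0:
                        j -= 1
                        pairs.append((None, j))
                    v = None
                    continue
                nxt = None
                for p in ps:
                    rp = rank[p]
                    if H[rp, j] - self.go == eval_:
                        nxt, ns = p, "H"
                        break
                    if E[rp, j] - self.ge == eval_:
                        nxt, ns = p, "E"
                        break
                v, t, state = nxt, rank[nxt] if nxt is not None else 0, ns if nxt is not None else "H"
                continue
            # state F: seq[j-1] is an insertion relative to the graph
            fval = F[t, j]
            pairs.append((None, j - 1))
            if H[t, j - 1] - self.go == fval:
                state = "H"
            j -= 1
        pairs.reverse()
        return pairs

    def _merge(
        self, codes: np.ndarray, pairs: list[tuple[int | None, int | None]]
    ) -> None:
        last = None
        for v, j in pairs:
            if j is None:
                continue  # graph node skipped
            b = int(codes[j])
            node = None
            if v is not None:
                if self.bases[v] == b:
                    node = v
                    self.support[v] += 1
                else:
                    for alt in self.ring_members[self.ring[v]]:
                        if self.bases[alt] == b:
                            node = alt
                            self.support[alt] += 1
                            break
                    if node is None:
                        node = self._new_node(b, ring_with=v)
            else:
                node = self._new_node(b)
            if last is not None:
                self._add_edge(last, node)
            last = node

    # -- consensus ----------------------------------------------------
    def consensus(self) -> str:
        """Heaviest source-to-sink path by summed edge traversal counts.

        Edge weights (how many reads travelled u->v) rather than node
        support decide the path, so sparsely supported insertion detours
        cannot outscore the main bundle.
        """
        order = self._topo_order()
        best: dict[int, int] = {}
        back: dict[int, int | None] = {}
        for v in order:
            if not self.preds[v]:
                best[v] = 0
                back[v] = None
            else:
                u = max(
                    self.preds[v],
                    key=lambda u: (best[u] + self.edge_w[(u, v)], -u),
                )
                best[v] = best[u] + self.edge_w[(u, v)]
                back[v] = u
        sinks = [v for v in order if not self.succs[v]]
        v = max(sinks, key=lambda s: (best[s], -s))
        path = []
        while v is not None:
            path.append(self.bases[v])
            v = back[v]
        path.reverse()
        return codes_to_seq(np.array(path, dtype=np.uint8))


def poa_consensus(seqs: list[str], **scoring) -> str:
    """Consensus of ≥1 sequences via partial order alignment."""
    g = PartialOrderGraph(**scoring)
    for s in seqs:
        g.add_sequence(s)
    return g.consensus()
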
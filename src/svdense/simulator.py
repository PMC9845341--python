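"""Ground-truth SV simulation with oracle alignments.

The generator implants a configurable mix of deletions, insertions,
tandem duplications, inversions and reciprocal translocations into a
diploid pair of haplotypes (2:1 het:hom, heterozygotes randomly phased),
draws gamma-length reads at a per-haplotype target depth, applies a
preset per-base error model, and — the key testing device — emits
*oracle* alignments: SAM records whose CIGARs are composed from the known
read placement, the haplotype→reference block map, and the simulated
error edits.  This removes the external aligner from the loop, so every
caller stage can be exercised hermetically.

SV sizes follow a geometric-decay background plus Gaussian peaks at
~350 bp and ~6 kbp, mimicking the Alu/LINE peaks of human genomes.
Tandem duplications up to 2 kbp are represented in alignments as
insertion CIGAR ops (aligners absorb short extra copies into one
alignment); larger ones as split alignments whose segments overlap on
the reference — the two signatures real aligners produce.

Truth coordinates are left-normalised (indels shifted to their leftmost
equivalent placement), the same convention the caller reports.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field, replace
from typing import Iterator, Optional

import numpy as np

from ._align import leftalign_del, leftalign_ins
from ._seq import codes_to_seq, random_seq, revcomp, seq_to_codes
from .alignment_io import AlignmentRecord, ReferenceGenome, SASegment, cigar_to_string

DEFAULT_COUNTS = {"DEL": 10000, "INS": 10000, "DUP": 1000, "INV": 1000, "TRA": 200}

# approximate human chr1-22+X lengths (Mbp), used when only SV *placement*
# is needed and no sequence is materialised
HUMAN_LIKE_LENGTHS = {
    f"chr{i}": int(mb * 1e6)
    for i, mb in zip(
        list(range(1, 23)) + ["X"],
        [248, 242, 198, 190, 181, 171, 159, 145, 138, 134, 135, 133,
         114, 107, 102, 90, 83, 80, 59, 64, 47, 51, 156],
    )
}

ERROR_PRESETS = {
    # total per-base error rate, (mismatch, insertion, deletion) fractions
    "pacbio-clr": (0.15, (0.40, 0.30, 0.30)),
    "nanopore": (0.12, (0.25, 0.35, 0.40)),
    "hifi": (0.01, (0.50, 0.25, 0.25)),
    "perfect": (0.0, (0.0, 0.0, 0.0)),
}


@dataclass
class TruthSV:
    sv_type: str
    chrom: str
    pos: int
    size: int
    zygosity: str  # het | hom
    haplotype: str  # '1' | '2' | 'both'
    ins_seq: Optional[str] = None
    chrom2: Optional[str] = None  # TRA partner breakpoint
    pos2: Optional[int] = None

    @property
    def end(self) -> int:
        return self.pos + (self.size if self.sv_type in ("DEL", "DUP", "INV") else 0)


@dataclass
class SizeModel:
    weights: tuple[float, float, float] = (0.6, 0.3, 0.1)
    geo_mean: float = 300.0
    peaks: tuple[tuple[float, float], ...] = ((350.0, 30.0), (6000.0, 500.0))
    min_size: int = 50
    fixed_range: Optional[tuple[int, int]] = None  # overrides the mixture

    def sample(self, rng: np.random.Generator) -> int:
        if self.fixed_range is not None:
            lo, hi = self.fixed_range
            return int(rng.integers(lo, hi + 1))
        comp = rng.choice(3, p=self.weights)
        if comp == 0:
            return self.min_size + int(rng.geometric(1.0 / (self.geo_mean - self.min_size)))
        mu, sd = self.peaks[comp - 1]
        return max(self.min_size, int(round(rng.normal(mu, sd))))


@dataclass
class SimConfig:
    chrom_lengths: Optional[dict[str, int]] = None  # None -> human-like table
    counts: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_COUNTS))
    size_model: SizeModel = field(default_factory=SizeModel)
    het_fraction: float = 2.0 / 3.0  # 2:1 het:hom
    depth: float = 25.0  # per haplotype
    mean_read_length: int = 15000
    read_length_shape: float = 3.0
    min_read_length: int = 500
    preset: str = "pacbio-clr"
    seed: int = 1
    dup_split_threshold: int = 2000  # DUPs above: split-alignment signature

    def lengths(self) -> dict[str, int]:
        return self.chrom_lengths if self.chrom_lengths is not None else HUMAN_LIKE_LENGTHS


def synthetic_genome(cfg: SimConfig, rng: np.random.Generator) -> ReferenceGenome:
    return ReferenceGenome(
        {c: random_seq(rng, n) for c, n in cfg.lengths().items()}
    )


# ---------------------------------------------------------------- truth set


def sample_sv_set(cfg: SimConfig, rng: Optional[np.random.Generator] = None) -> list[TruthSV]:
    """Random SV set with exact per-type counts.

    Events are placed uniformly, no two closer than twice
    max(size, 1 kbp); zygosity is an exact round(2n/3) het split per type.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    lengths = cfg.lengths()
    chroms = list(lengths)
    weights = np.array([lengths[c] for c in chroms], dtype=float)
    weights /= weights.sum()
    occupied: dict[str, list[tuple[int, int, int]]] = {c: [] for c in chroms}

    def place(size: int, ref_span: int, middle: bool = False) -> tuple[str, int]:
        clear = 2 * max(size, 1000)
        for _ in range(5000):
            chrom = chroms[rng.choice(len(chroms), p=weights)]
            L = lengths[chrom]
            margin = ref_span + 5000
            lo, hi = (int(0.2 * L), int(0.8 * L)) if middle else (margin, L - margin)
            if hi <= lo:
                continue
            pos = int(rng.integers(lo, hi))
            occ = occupied[chrom]
            i = bisect.bisect_left(occ, (pos, 0, 0))
            ok = True
            for j in (i - 1, i):
                if 0 <= j < len(occ):
                    s2, e2, c2 = occ[j]
                    gap = max(s2 - (pos + ref_span), pos - e2)
                    if gap < max(clear, c2):
                        ok = False
                        break
            if ok:
                occ.insert(i, (pos, pos + ref_span, clear))
                return chrom, pos
        raise RuntimeError("could not place SV set; genome too crowded")

    svs: list[TruthSV] = []
    for typ in ("DEL", "INS", "DUP", "INV", "TRA"):
        n = cfg.counts.get(typ, 0)
        if n == 0:
            continue
        n_het = int(round(cfg.het_fraction * n))
        het_idx = set(rng.permutation(n)[:n_het].tolist())
        for i in range(n):
            zyg = "het" if i in het_idx else "hom"
            hap = "both" if zyg == "hom" else str(1 + int(rng.integers(2)))
            if typ == "TRA":
                c1, p1 = place(0, 0, middle=True)
                while True:
                    c2, p2 = place(0, 0, middle=True)
                    if c2 != c1:
                        break
                (c1, p1), (c2, p2) = sorted([(c1, p1), (c2, p2)])
                svs.append(TruthSV("TRA", c1, p1, 0, zyg, hap, chrom2=c2, pos2=p2))
                continue
            size = cfg.size_model.sample(rng)
            ref_span = 0 if typ == "INS" else size
            chrom, pos = place(size, ref_span)
            ins_seq = random_seq(rng, size) if typ == "INS" else None
            svs.append(TruthSV(typ, chrom, pos, size, zyg, hap, ins_seq=ins_seq))
    svs.sort(key=lambda s: (s.chrom, s.pos))
    return svs


# -------------------------------------------------- haplotype construction

# block kinds: ("M", ref_chrom, ref_start, ref_end, strand) | ("I", seq)
Block = tuple


@dataclass
class HaplotypeChrom:
    name: str
    blocks: list[Block]
    starts: list[int] = field(default_factory=list)  # hap coord of each block
    seq: str = ""

    def finalize(self, genome: ReferenceGenome) -> None:
        starts, parts, at = [], [], 0
        for b in self.blocks:
            starts.append(at)
            if b[0] == "M":
                _, c, s, e, st = b
                part = genome.fetch(c, s, e)
                if st == "-":
                    part = revcomp(part)
            else:
                part = b[1]
            parts.append(part)
            at += len(part)
        self.starts = starts
        self.seq = "".join(parts)

    @property
    def length(self) -> int:
        return len(self.seq)

    def liftover(self, pos: int) -> Optional[tuple[str, int, str]]:
        """Map a haplotype coordinate back to (ref_chrom, ref_pos, strand)."""
        i = bisect.bisect_right(self.starts, pos) - 1
        b = self.blocks[i]
        off = pos - self.starts[i]
        if b[0] == "I":
            return None
        _, c, s, e, st = b
        return (c, s + off, st) if st == "+" else (c, e - 1 - off, st)


class Haplotypes:
    """Two SV-modified haplotypes with per-chromosome block maps."""

    def __init__(self, chroms: dict[int, dict[str, HaplotypeChrom]]):
        self.chroms = chroms  # hap (1|2) -> name -> HaplotypeChrom


def _normalize_truth(genome: ReferenceGenome, svs: list[TruthSV]) -> list[TruthSV]:
    out = []
    for sv in svs:
        ref = genome.sequences[sv.chrom]
        if sv.sv_type == "DEL":
            sv = replace(sv, pos=leftalign_del(ref, sv.pos, sv.size))
        elif sv.sv_type == "INS":
            pos, seq = leftalign_ins(ref, sv.pos, sv.ins_seq)
            sv = replace(sv, pos=pos, ins_seq=seq)
        elif sv.sv_type == "DUP":
            sv = replace(sv, ins_seq=genome.fetch(sv.chrom, sv.pos, sv.pos + sv.size))
        out.append(sv)
    return out


def _split_at_ref(blocks: list[Block], ref_chrom: str, ref_pos: int) -> Optional[tuple[list[Block], list[Block]]]:
    for i, b in enumerate(blocks):
        if b[0] == "M" and b[1] == ref_chrom and b[4] == "+" and b[2] <= ref_pos < b[3]:
            left = blocks[:i] + ([("M", b[1], b[2], ref_pos, "+")] if ref_pos > b[2] else [])
            right = ([("M", b[1], ref_pos, b[3], "+")] if ref_pos < b[3] else []) + blocks[i + 1:]
            return left, right
    return None


def apply_svs_to_genome(
    genome: ReferenceGenome,
    svs: list[TruthSV],
    dup_split_threshold: int = 2000,
) -> tuple[Haplotypes, list[TruthSV]]:
    """Build both haplotypes; returns them plus the left-normalised truth."""
    svs = _normalize_truth(genome, svs)
    haps: dict[int, dict[str, HaplotypeChrom]] = {1: {}, 2: {}}
    dropped: set[int] = set()
    for hap in (1, 2):
        blocks_by_chrom: dict[str, list[Block]] = {}
        for chrom, L in genome.lengths.items():
            mine = [
                s
                for s in svs
                if s.chrom == chrom
                and s.sv_type != "TRA"
                and (s.haplotype == "both" or s.haplotype == str(hap))
            ]
            blocks: list[Block] = []
            cur = 0
            for sv in mine:
                if sv.pos > cur:
                    blocks.append(("M", chrom, cur, sv.pos, "+"))
                if sv.sv_type == "DEL":
                    cur = sv.pos + sv.size
                elif sv.sv_type == "INS":
                    blocks.append(("I", sv.ins_seq))
                    cur = sv.pos
                elif sv.sv_type == "DUP":
                    if sv.size <= dup_split_threshold:
                        blocks.append(("I", sv.ins_seq))
                        cur = sv.pos
                    else:
                        blocks.append(("M", chrom, sv.pos, sv.pos + sv.size, "+"))
                        cur = sv.pos
                elif sv.sv_type == "INV":
                    blocks.append(("M", chrom, sv.pos, sv.pos + sv.size, "-"))
                    cur = sv.pos + sv.size
            if cur < L:
                blocks.append(("M", chrom, cur, L, "+"))
            blocks_by_chrom[chrom] = blocks
        for k, sv in enumerate(svs):
            if sv.sv_type != "TRA" or not (
                sv.haplotype == "both" or sv.haplotype == str(hap)
            ):
                continue
            # earlier swaps may have moved the breakpoint region to another
            # haplotype chromosome: search every container
            key_a = key_b = None
            for key, blocks in blocks_by_chrom.items():
                if key_a is None and _split_at_ref(blocks, sv.chrom, sv.pos):
                    key_a = key
                if key_b is None and _split_at_ref(blocks, sv.chrom2, sv.pos2):
                    key_b = key
            if key_a is None or key_b is None or key_a == key_b:
                dropped.add(k)  # breakpoints collided on one molecule
                continue
            a_left, a_right = _split_at_ref(blocks_by_chrom[key_a], sv.chrom, sv.pos)
            b_left, b_right = _split_at_ref(blocks_by_chrom[key_b], sv.chrom2, sv.pos2)
            blocks_by_chrom[key_a] = a_left + b_right
            blocks_by_chrom[key_b] = b_left + a_right
        for chrom, blocks in blocks_by_chrom.items():
            hc = HaplotypeChrom(f"h{hap}_{chrom}", blocks)
            hc.finalize(genome)
            haps[hap][chrom] = hc
    truth = [sv for k, sv in enumerate(svs) if k not in dropped]
    return Haplotypes(haps), truth


# ----------------------------------------------------------------- reads


@dataclass
class SimRead:
    read_id: str
    hap: int
    chrom: str  # haplotype chromosome name (reference chrom label)
    start: int  # haplotype coordinates
    end: int
    reverse: bool


def simulate_read_placements(
    haps: Haplotypes, cfg: SimConfig, rng: np.random.Generator
) -> list[SimRead]:
    """Gamma-length reads at the per-haplotype target depth."""
    reads: list[SimRead] = []
    k = 0
    scale = cfg.mean_read_length / cfg.read_length_shape
    for hap in (1, 2):
        for chrom, hc in haps.chroms[hap].items():
            L = hc.length
            target = cfg.depth * L
            total = 0
            while total < target:
                n = max(1, int((target - total) / cfg.mean_read_length))
                lens = rng.gamma(cfg.read_length_shape, scale, size=n)
                lens = np.clip(lens, cfg.min_read_length, max(cfg.min_read_length, L)).astype(int)
                starts = rng.integers(0, np.maximum(1, L - lens))
                revs = rng.random(n) < 0.5
                for ln, st, rv in zip(lens, starts, revs):
                    reads.append(
                        SimRead(f"read{k:07d}", hap, chrom, int(st), int(st + ln), bool(rv))
                    )
                    k += 1
                    total += int(ln)
                    if total >= target:
                        break
    return reads


def _mutate_piece(
    codes: np.ndarray, rate: float, fracs: tuple[float, float, float], rng: np.random.Generator
) -> tuple[np.ndarray, list[tuple[str, int]]]:
    """Apply per-base errors; returns mutated codes + CIGAR fragments."""
    L = len(codes)
    if L == 0:
        return codes, []
    if rate <= 0:
        return codes, [("M", L)]
    pm, pi, pd = rate * fracs[0], rate * fracs[1], rate * fracs[2]
    u = rng.random(L)
    mm = u < pm
    dl = (u >= pm) & (u < pm + pd)
    ins = (u >= pm + pd) & (u < pm + pd + pi)
    sub = codes.copy()
    nmm = int(mm.sum())
    if nmm:
        sub[mm] = (sub[mm] + 1 + rng.integers(0, 3, nmm, dtype=np.uint8)) % 4
    ops = dl.astype(np.uint8)  # 0 = M, 1 = D
    ins_idx = np.flatnonzero(ins)
    if len(ins_idx):
        ins_bases = rng.integers(0, 4, len(ins_idx), dtype=np.uint8)
        ops_full = np.insert(ops, ins_idx + 1, np.uint8(2))
        seq_full = np.insert(sub, ins_idx + 1, ins_bases)
    else:
        ops_full, seq_full = ops, sub
    seq_out = seq_full[ops_full != 1]
    # run-length encode ops
    change = np.flatnonzero(np.diff(ops_full)) + 1
    bounds = np.concatenate(([0], change, [len(ops_full)]))
    frags = [
        ("MDI"[ops_full[bounds[i]]], int(bounds[i + 1] - bounds[i]))
        for i in range(len(bounds) - 1)
    ]
    return seq_out, frags


MAX_INTRA_GAP = 10000  # indels above this split the alignment record


def _read_pieces(hc: HaplotypeChrom, start: int, end: int) -> list[tuple]:
    """Blocks intersected with a haplotype interval: ('M', c, s, e, strand) / ('I', seq)."""
    pieces = []
    i = bisect.bisect_right(hc.starts, start) - 1
    while i < len(hc.blocks) and hc.starts[i] < end:
        b = hc.blocks[i]
        bstart = hc.starts[i]
        blen = (b[3] - b[2]) if b[0] == "M" else len(b[1])
        lo = max(start, bstart) - bstart
        hi = min(end, bstart + blen) - bstart
        if hi > lo:
            if b[0] == "M":
                _, c, s, e, st = b
                if st == "+":
                    pieces.append(("M", c, s + lo, s + hi, "+"))
                else:
                    pieces.append(("M", c, e - hi, e - lo, "-"))
            else:
                pieces.append(("I", b[1][lo:hi]))
        i += 1
    return pieces


def emit_oracle_alignments(
    haps: Haplotypes,
    reads: list[SimRead],
    cfg: SimConfig,
    rng: np.random.Generator,
    min_anchor: int = 30,
) -> Iterator[list[AlignmentRecord]]:
    """Per-read oracle SAM records composed from placement + error edits.

    Yields one list of records per read (primary first); reads with no
    mappable anchor (e.g. contained in a novel insertion) yield nothing.
    """
    rate, fracs = ERROR_PRESETS[cfg.preset]
    for rd in reads:
        hc = haps.chroms[rd.hap][rd.chrom]
        pieces = _read_pieces(hc, rd.start, rd.end)
        # mutate every piece; track read-coordinate extents (hap-forward)
        mut: list[tuple] = []  # (piece, cigar frags, read_lo, read_hi)
        parts: list[np.ndarray] = []
        at = 0
        hap_seq = hc.seq[rd.start : rd.end]
        off = 0
        for p in pieces:
            length = (p[3] - p[2]) if p[0] == "M" else len(p[1])
            codes = seq_to_codes(hap_seq[off : off + length])
            seq_out, frags = _mutate_piece(codes, rate, fracs, rng)
            parts.append(seq_out)
            mut.append((p, frags, at, at + len(seq_out)))
            at += len(seq_out)
            off += length
        if not mut:
            continue
        read_fwd = codes_to_seq(np.concatenate(parts)) if parts else ""
        total = len(read_fwd)
        if total == 0:
            continue
        # group pieces into alignment records
        groups: list[list[tuple]] = []
        cur: list[tuple] = []
        pending_ins: list[tuple] = []
        for item in mut:
            p = item[0]
            if p[0] == "I":
                if cur:
                    pending_ins.append(item)
                continue
            if not cur:
                cur = [item]
                pending_ins = []
                continue
            prev = cur[-1][0]
            ins_len = sum(it[3] - it[2] for it in pending_ins)
            compatible = prev[1] == p[1] and prev[4] == p[4] and ins_len <= MAX_INTRA_GAP
            if compatible:
                gap = (p[2] - prev[3]) if p[4] == "+" else (prev[2] - p[3])
                compatible = 0 <= gap <= MAX_INTRA_GAP
            if compatible:
                cur.extend(pending_ins)
                cur.append(item)
            else:
                groups.append(cur)
                cur = [item]
            pending_ins = []
        if cur:
            groups.append(cur)
        records: list[AlignmentRecord] = []
        for g in groups:
            mpieces = [it for it in g if it[0][0] == "M"]
            aligned = sum(
                n for it in mpieces for op, n in it[1] if op == "M"
            )
            if aligned < min_anchor:
                continue
            strand = mpieces[0][0][4]
            rd_lo = g[0][2]
            rd_hi = g[-1][3]
            # assemble hap-orientation cigar
            cig: list[tuple[str, int]] = []

            def push(op: str, n: int) -> None:
                if n <= 0:
                    return
                if cig and cig[-1][0] == op:
                    cig[-1] = (op, cig[-1][1] + n)
                else:
                    cig.append((op, n))

            prev_m = None
            for it in g:
                p, frags = it[0], it[1]
                if p[0] == "I":
                    push("I", it[3] - it[2])
                    continue
                if prev_m is not None:
                    gap = (p[2] - prev_m[3]) if strand == "+" else (prev_m[2] - p[3])
                    push("D", gap)
                for op, n in frags:
                    push(op, n)
                prev_m = p
            if strand == "+":
                ref_start = mpieces[0][0][2]
                ref_end = mpieces[-1][0][3]
                left, right = rd_lo, total - rd_hi
                stored = read_fwd
            else:
                ref_start = mpieces[-1][0][2]
                ref_end = mpieces[0][0][3]
                cig = cig[::-1]
                left, right = total - rd_hi, rd_lo
                stored = revcomp(read_fwd)
            full_cigar = (
                ([("S", left)] if left else []) + cig + ([("S", right)] if right else [])
            )
            final_strand = "-" if (strand == "-") != rd.reverse else "+"
            records.append(
                AlignmentRecord(
                    read_id=rd.read_id,
                    chrom=mpieces[0][0][1],
                    ref_start=ref_start,
                    ref_end=ref_end,
                    strand=final_strand,
                    mapq=60,
                    cigar=full_cigar,
                    left_clip=left,
                    right_clip=right,
                    read_seq=stored,
                    is_supplementary=False,
                )
            )
        if not records:
            continue
        primary = max(records, key=lambda r: r.aligned_bases)
        for r in records:
            r.is_supplementary = r is not primary
            r.sa_segments = [
                SASegment(o.chrom, o.ref_start, o.strand, cigar_to_string(o.cigar), o.mapq)
                for o in records
                if o is not r
            ]
        records.sort(key=lambda r: r.is_supplementary)
        yield records


# ------------------------------------------------------------ top level


@dataclass
class SimResult:
    genome: ReferenceGenome
    truth: list[TruthSV]
    haplotypes: Haplotypes
    reads: list[SimRead]

    def records(self, cfg: SimConfig, rng: np.random.Generator) -> Iterator[list[AlignmentRecord]]:
        return emit_oracle_alignments(self.haplotypes, self.reads, cfg, rng)


def simulate(cfg: SimConfig, genome: Optional[ReferenceGenome] = None) -> SimResult:
    """Genome + truth + haplotypes + read placements, fully seeded."""
    root = np.random.SeedSequence(cfg.seed)
    sg, ss, sr = [np.random.default_rng(s) for s in root.spawn(3)]
    if genome is None:
        genome = synthetic_genome(cfg, sg)
    cfg = replace(cfg, chrom_lengths=dict(genome.lengths))
    svs = sample_sv_set(cfg, ss)
    haps, truth = apply_svs_to_genome(genome, svs, cfg.dup_split_threshold)
    reads = simulate_read_placements(haps, cfg, sr)
    return SimResult(genome, truth, haps, reads)


def error_rng(cfg: SimConfig) -> np.random.Generator:
    """The dedicated error-model stream (4th child of the config seed)."""
    return np.random.default_rng(np.random.SeedSequence(cfg.seed).spawn(4)[3])


# ------------------------------------------------------------- truth IO


def write_truth_tsv(truth: list[TruthSV], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("#chrom\tpos\tend\tsv_type\tsize\tzygosity\thaplotype\tchrom2\tpos2\n")
        for t in truth:
            fh.write(
                f"{t.chrom}\t{t.pos}\t{t.end}\t{t.sv_type}\t{t.size}\t"
                f"{t.zygosity}\t{t.haplotype}\t{t.chrom2 or '.'}\t"
                f"{t.pos2 if t.pos2 is not None else '.'}\n"
            )


def write_truth_vcf(
    truth: list[TruthSV], chrom_lengths: dict[str, int], path: str
) -> None:
    """Ground truth as a minimal VCF 4.2 (symbolic ALTs, BND pairs for TRA)."""
    lines = [
        "##fileformat=VCFv4.2",
        "##source=svdense-simulator",
        '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">',
        '##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="SV length">',
        '##INFO=<ID=END,Number=1,Type=Integer,Description="End position">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    ]
    lines += [f"##contig=<ID={c},length={n}>" for c, n in chrom_lengths.items()]
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ttruth")
    order = {c: i for i, c in enumerate(chrom_lengths)}
    for k, t in enumerate(sorted(truth, key=lambda t: (order.get(t.chrom, 99), t.pos))):
        gt = "1/1" if t.zygosity == "hom" else "0/1"
        if t.sv_type == "TRA":
            lines.append(
                f"{t.chrom}\t{t.pos + 1}\ttruth_{k}a\tN\tN]{t.chrom2}:{t.pos2 + 1}]\t.\tPASS\t"
                f"SVTYPE=BND\tGT\t{gt}"
            )
            lines.append(
                f"{t.chrom2}\t{t.pos2 + 1}\ttruth_{k}b\tN\tN]{t.chrom}:{t.pos + 1}]\t.\tPASS\t"
                f"SVTYPE=BND\tGT\t{gt}"
            )
            continue
        svlen = -t.size if t.sv_type == "DEL" else t.size
        lines.append(
            f"{t.chrom}\t{t.pos + 1}\ttruth_{k}\tN\t<{t.sv_type}>\t.\tPASS\t"
            f"SVTYPE={t.sv_type};SVLEN={svlen};END={t.end + 1}\tGT\t{gt}"
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_truth_tsv(path: str) -> list[TruthSV]:
    out = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            c, p, e, typ, size, zyg, hap, c2, p2 = line.rstrip("\n").split("\t")
            out.append(
                TruthSV(
                    typ, c, int(p), int(size), zyg, hap,
                    chrom2=None if c2 == "." else c2,
                    pos2=None if p2 == "." else int(p2),
                )
            )
    return out
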
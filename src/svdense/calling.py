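"""Depth-adaptive filtering, genotyping, duplication rescue and VCF output.

Candidates must be supported by at least N_supp = depth/10 + 2 reads
(floored), carry adequate mapping quality, and — for multi-allele
candidates — each allele is filtered independently, demoting to a
single-allele call when only one survives.  Genotypes come from the ratio
of supporting reads to local depth (>= 0.75 -> homozygous).  Insertion
calls whose inserted sequences re-align to the +-1 kbp flanking region in
more than half of the supporting reads are re-typed as tandem
duplications.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import edlib

from .alignment_io import ReferenceGenome
from .signal_detection import DepthProfile


@dataclass
class SVCall:
    sv_type: str
    chrom: str
    pos: int
    size: int
    end: int
    n_supp_reads: int
    local_depth: float = 0.0
    genotype: str = "./."
    precise: bool = False
    ins_seq: Optional[str] = None
    mapq_mean: float = 60.0
    chrom2: Optional[str] = None
    pos2: Optional[int] = None
    allele_sizes: Optional[list[int]] = None
    allele_supports: Optional[list[int]] = None
    filter_status: str = "PASS"
    member_ins_seqs: list[str] = field(default_factory=list, repr=False)


def compute_nsupp(mean_depth: float) -> int:
    """Minimum supporting reads: floor(depth/10) + 2, never below 2."""
    return max(2, int(mean_depth // 10) + 2)


def filter_candidates(
    calls: list[SVCall],
    profile: DepthProfile,
    mapq_min: int = 20,
    min_supp: Optional[int] = None,
) -> list[SVCall]:
    """Depth-scaled support and MAPQ filters; per-allele for multi-allele SVs."""
    n_supp = min_supp if min_supp is not None else profile.n_supp
    out = []
    for c in calls:
        if c.allele_sizes is not None and c.allele_supports is not None:
            passing = [i for i, s in enumerate(c.allele_supports) if s >= n_supp]
            if len(passing) == 0:
                c.filter_status = "low_support"
            elif len(passing) == 1:
                i = passing[0]
                c.size = c.allele_sizes[i]
                c.n_supp_reads = c.allele_supports[i]
                c.end = c.pos + (c.size if c.sv_type in ("DEL", "DUP", "INV") else 0)
                c.allele_sizes = None
                c.allele_supports = None
                c.filter_status = "PASS"
            else:
                c.filter_status = "PASS"
        else:
            c.filter_status = "PASS" if c.n_supp_reads >= n_supp else "low_support"
        if c.filter_status == "PASS" and c.mapq_mean < mapq_min:
            c.filter_status = "low_mapq"
        out.append(c)
    return out


def genotype_call(call: SVCall, hom_ratio: float = 0.75) -> str:
    """Genotype from the supporting-read : local-depth ratio."""
    if call.allele_sizes is not None and call.allele_supports is not None:
        return "1/2"
    if call.local_depth <= 0:
        return "1/1"
    r = call.n_supp_reads / call.local_depth
    return "1/1" if r >= hom_ratio else "0/1"


def _aligns_back(ins_seq: str, window: str, min_identity: float = 0.80) -> bool:
    """>= 50% of the inserted bases locally alignable to the flank window.

    Long inserts are tested in <= 500 bp chunks (local-coverage
    approximation); a chunk counts when its best infix placement reaches
    the identity threshold.
    """
    if not ins_seq or not window:
        return False
    chunks = [ins_seq[i : i + 500] for i in range(0, len(ins_seq), 500)][:16]
    aligned = 0
    for ch in chunks:
        if len(ch) < 30:
            continue
        res = edlib.align(ch, window, mode="HW", task="distance")
        if res["editDistance"] >= 0 and 1 - res["editDistance"] / len(ch) >= min_identity:
            aligned += len(ch)
    return aligned >= 0.5 * len(ins_seq)


def rescue_duplication(
    call: SVCall, genome: ReferenceGenome, flank: int = 1000
) -> SVCall:
    """Re-type an INS as tandem DUP when inserted sequences match the flanks.

    Strictly more than half of the supporting reads' inserted sequences
    must align back to breakpoint +- flank.
    """
    if call.sv_type != "INS" or not call.member_ins_seqs:
        return call
    L = genome.lengths[call.chrom]
    window = genome.fetch(
        call.chrom, max(0, call.pos - flank), min(L, call.pos + flank)
    )
    n_aligned = sum(1 for s in call.member_ins_seqs if _aligns_back(s, window))
    if n_aligned > 0.5 * len(call.member_ins_seqs):
        call.sv_type = "DUP"
        call.end = call.pos + call.size
    return call


# ------------------------------------------------------------------ VCF

VCF_HEADER = """##fileformat=VCFv4.2
##source=svdense
##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">
##INFO=<ID=SVLEN,Number=.,Type=Integer,Description="SV length (negative for deletions)">
##INFO=<ID=END,Number=1,Type=Integer,Description="End position">
##INFO=<ID=SUPPORT,Number=1,Type=Integer,Description="Supporting reads">
##INFO=<ID=PRECISE,Number=0,Type=Flag,Description="Consensus-refined breakpoint">
##INFO=<ID=IMPRECISE,Number=0,Type=Flag,Description="Mean-of-signals breakpoint">
##INFO=<ID=CHR2,Number=1,Type=String,Description="Partner chromosome (TRA)">
##INFO=<ID=MATEID,Number=1,Type=String,Description="Mate breakend">
##FILTER=<ID=low_support,Description="Fewer than N_supp supporting reads">
##FILTER=<ID=low_mapq,Description="Mean mapping quality below threshold">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
"""


def write_vcf(
    calls: Iterable[SVCall],
    genome_lengths: dict[str, int],
    out_path: str,
    emit_all: bool = False,
) -> None:
    order = {c: i for i, c in enumerate(genome_lengths)}
    rows = []
    for k, c in enumerate(
        sorted(calls, key=lambda c: (order.get(c.chrom, 99), c.pos))
    ):
        if c.filter_status != "PASS" and not emit_all:
            continue
        flt = c.filter_status
        prec = "PRECISE" if c.precise else "IMPRECISE"
        gt = c.genotype
        if c.sv_type == "TRA":
            info1 = f"SVTYPE=BND;{prec};SUPPORT={c.n_supp_reads};CHR2={c.chrom2};MATEID=bnd_{k}b"
            alt1 = f"N]{c.chrom2}:{c.pos2 + 1}]"
            rows.append(
                f"{c.chrom}\t{c.pos + 1}\tbnd_{k}a\tN\t{alt1}\t60\t{flt}\t{info1}\tGT\t{gt}"
            )
            info2 = f"SVTYPE=BND;{prec};SUPPORT={c.n_supp_reads};CHR2={c.chrom};MATEID=bnd_{k}a"
            alt2 = f"N]{c.chrom}:{c.pos + 1}]"
            rows.append(
                f"{c.chrom2}\t{c.pos2 + 1}\tbnd_{k}b\tN\t{alt2}\t60\t{flt}\t{info2}\tGT\t{gt}"
            )
            continue
        if c.allele_sizes is not None:
            alt = f"<{c.sv_type}>,<{c.sv_type}>"
            svlen = ",".join(
                str(-s if c.sv_type == "DEL" else s) for s in c.allele_sizes
            )
            gt = "1/2"
        else:
            if c.sv_type == "INS" and c.ins_seq:
                alt = "N" + c.ins_seq
            else:
                alt = f"<{c.sv_type}>"
            svlen = str(-c.size if c.sv_type == "DEL" else c.size)
        info = (
            f"SVTYPE={c.sv_type};SVLEN={svlen};END={c.end + 1};"
            f"SUPPORT={c.n_supp_reads};{prec}"
        )
        rows.append(
            f"{c.chrom}\t{c.pos + 1}\tsv_{k}\tN\t{alt}\t60\t{flt}\t{info}\tGT\t{gt}"
        )
    with open(out_path, "w") as fh:
        fh.write(VCF_HEADER)
        for chrom, ln in genome_lengths.items():
            fh.write(f"##contig=<ID={chrom},length={ln}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tsample\n")
        for row in rows:
            fh.write(row + "\n")


def read_vcf(path: str) -> list[SVCall]:
    """Parse a VCF written by write_vcf back into SVCall objects."""
    calls: list[SVCall] = []
    bnd_first: dict[str, SVCall] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            chrom, pos, vid, _, alt, _, flt, info, *rest = line.rstrip("\n").split("\t")
            kv = {}
            flags = set()
            for item in info.split(";"):
                if "=" in item:
                    k, v = item.split("=", 1)
                    kv[k] = v
                else:
                    flags.add(item)
            gt = rest[1] if len(rest) > 1 else "./."
            pos0 = int(pos) - 1
            if kv.get("SVTYPE") == "BND":
                if vid.endswith("b"):
                    mate = bnd_first.pop(kv.get("MATEID", ""), None)
                    if mate is not None:
                        mate.chrom2 = chrom
                        mate.pos2 = pos0
                        calls.append(mate)
                    continue
                c = SVCall(
                    "TRA", chrom, pos0, 0, pos0,
                    n_supp_reads=int(kv.get("SUPPORT", 0)),
                    genotype=gt, precise="PRECISE" in flags, filter_status=flt,
                )
                bnd_first[vid] = c
                continue
            svlens = [int(x) for x in kv.get("SVLEN", "0").split(",")]
            typ = kv["SVTYPE"]
            sizes = [abs(s) for s in svlens]
            ins_seq = None
            if typ == "INS" and alt.startswith("N") and len(alt) > 1 and "<" not in alt:
                ins_seq = alt.split(",")[0][1:]
            c = SVCall(
                typ, chrom, pos0, sizes[0], int(kv.get("END", pos)) - 1,
                n_supp_reads=int(kv.get("SUPPORT", 0)),
                genotype=gt, precise="PRECISE" in flags, ins_seq=ins_seq,
                filter_status=flt,
                allele_sizes=sizes if len(sizes) > 1 else None,
            )
            calls.append(c)
    return calls
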
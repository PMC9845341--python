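"""Reading and normalising alignment and sequence inputs.

All coordinates are 0-based half-open internally; conversion to/from the
1-based SAM/VCF convention happens only at file boundaries.  Secondary
alignments are parsed (flagged) but excluded from all signal extraction
downstream; supplementary alignments are first-class because split reads
are represented as primary + supplementary segments.
"""

from __future__ import annotations

import os
import sys
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

import pysam

REF_CONSUMING = frozenset("M=XDN")
READ_CONSUMING = frozenset("M=XIS")

Cigar = list[tuple[str, int]]


@dataclass
class SASegment:
    """One supplementary-alignment segment parsed from an SA:Z tag."""

    chrom: str
    pos: int  # 0-based
    strand: str
    cigar: str
    mapq: int


@dataclass
class AlignmentRecord:
    """One read-to-reference alignment segment.

    ``read_seq`` may be None for hard-clipped supplementary records; such
    records still carry SV signals but cannot feed POA/assembly directly.
    """

    read_id: str
    chrom: str
    ref_start: int
    ref_end: int
    strand: str
    mapq: int
    cigar: Cigar
    left_clip: int = 0
    right_clip: int = 0
    read_seq: Optional[str] = None
    sa_segments: list[SASegment] = field(default_factory=list)
    is_supplementary: bool = False
    is_secondary: bool = False

    _read_length: Optional[int] = field(default=None, repr=False, compare=False)
    _aligned_bases: Optional[int] = field(default=None, repr=False, compare=False)

    @property
    def read_length(self) -> int:
        """Full read length inferred from CIGAR (clips included)."""
        if self._read_length is None:
            self._read_length = sum(
                n for op, n in self.cigar if op in READ_CONSUMING or op == "H"
            )
        return self._read_length

    @property
    def read_start(self) -> int:
        """Start of the aligned block in read-orientation coordinates."""
        return self.left_clip

    @property
    def read_end(self) -> int:
        return self.read_length - self.right_clip

    @property
    def aligned_bases(self) -> int:
        if self._aligned_bases is None:
            self._aligned_bases = sum(n for op, n in self.cigar if op in "M=X")
        return self._aligned_bases


def cigar_ref_span(cigar: Cigar) -> int:
    return sum(n for op, n in cigar if op in REF_CONSUMING)


def parse_cigar_string(s: str) -> Cigar:
    out: Cigar = []
    num = 0
    for ch in s:
        if ch.isdigit():
            num = num * 10 + ord(ch) - 48
        else:
            out.append((ch, num))
            num = 0
    return out


def cigar_to_string(cigar: Cigar) -> str:
    return "".join(f"{n}{op}" for op, n in cigar)


def parse_sa_tag(tag_value: str) -> list[SASegment]:
    """Parse an SA:Z tag (``rname,pos,strand,CIGAR,mapQ,NM;`` entries).

    Malformed entries are skipped with a warning; positions converted to
    0-based.
    """
    segs: list[SASegment] = []
    for entry in tag_value.split(";"):
        if not entry:
            continue
        parts = entry.split(",")
        try:
            chrom, pos, strand, cig, mapq = (
                parts[0],
                int(parts[1]) - 1,
                parts[2],
                parts[3],
                int(parts[4]),
            )
            if strand not in "+-" or pos < 0:
                raise ValueError(entry)
        except (ValueError, IndexError):
            warnings.warn(f"skipping malformed SA entry: {entry!r}")
            continue
        segs.append(SASegment(chrom, pos, strand, cig, mapq))
    return segs


class ReferenceGenome:
    """In-memory reference: chrom -> uppercase sequence."""

    def __init__(self, sequences: dict[str, str]):
        self.sequences = {name: seq.upper() for name, seq in sequences.items()}
        self.lengths = {name: len(seq) for name, seq in self.sequences.items()}

    def fetch(self, chrom: str, start: int, end: int) -> str:
        seq = self.sequences[chrom]
        if not (0 <= start <= end <= len(seq)):
            raise ValueError(f"region {chrom}:{start}-{end} out of bounds")
        return seq[start:end]

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.sequences


def read_fasta(path: str | os.PathLike) -> ReferenceGenome:
    """Load a FASTA into memory; duplicate headers are fatal."""
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    seqs: dict[str, str] = {}
    with pysam.FastxFile(str(path)) as fh:
        for rec in fh:
            if rec.name in seqs:
                raise ValueError(f"duplicate FASTA header: {rec.name}")
            seqs[rec.name] = rec.sequence
    return ReferenceGenome(seqs)


def _from_pysam(a: pysam.AlignedSegment) -> AlignmentRecord:
    cigar = [( "MIDNSHP=XB"[op], n) for op, n in (a.cigartuples or [])]
    left = right = 0
    if cigar and cigar[0][0] in "SH":
        left = cigar[0][1]
    if len(cigar) > 1 and cigar[-1][0] in "SH":
        right = cigar[-1][1]
    sa = parse_sa_tag(a.get_tag("SA")) if a.has_tag("SA") else []
    return AlignmentRecord(
        read_id=a.query_name,
        chrom=a.reference_name,
        ref_start=a.reference_start,
        ref_end=a.reference_end,
        strand="-" if a.is_reverse else "+",
        mapq=a.mapping_quality,
        cigar=cigar,
        left_clip=left,
        right_clip=right,
        read_seq=a.query_sequence,
        sa_segments=sa,
        is_supplementary=a.is_supplementary,
        is_secondary=a.is_secondary,
    )


def read_alignments(
    path: str | os.PathLike,
    region: Optional[tuple[str, int, int]] = None,
    require_sorted: bool = True,
) -> Iterator[AlignmentRecord]:
    """Stream AlignmentRecords from a SAM/BAM file.

    Unmapped records are dropped; secondary records are yielded with the
    flag set so callers can skip them.  Whole-genome mode requires a
    coordinate-sorted file.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    mode = "rb" if str(path).endswith(".bam") else "r"
    with pysam.AlignmentFile(str(path), mode) as fh:
        if require_sorted and region is None:
            so = fh.header.get("HD", {}).get("SO", "")
            if so != "coordinate":
                raise ValueError(
                    f"{path}: whole-genome mode needs a coordinate-sorted file "
                    f"(SO={so or 'unknown'})"
                )
        it = fh.fetch(region[0], region[1], region[2]) if region else fh
        for a in it:
            if a.is_unmapped or a.reference_name is None:
                continue
            yield _from_pysam(a)


def write_sam(
    records: Iterable[AlignmentRecord],
    lengths: dict[str, int],
    path: str | os.PathLike,
) -> None:
    """Write records as a coordinate-sorted SAM file."""
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": c, "LN": n} for c, n in lengths.items()],
    }
    order = {c: i for i, c in enumerate(lengths)}
    recs = sorted(records, key=lambda r: (order[r.chrom], r.ref_start))
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        for r in recs:
            a = pysam.AlignedSegment(out.header)
            a.query_name = r.read_id
            a.reference_name = r.chrom
            a.reference_start = r.ref_start
            a.mapping_quality = r.mapq
            a.cigarstring = cigar_to_string(r.cigar)
            flag = 0
            if r.strand == "-":
                flag |= 0x10
            if r.is_supplementary:
                flag |= 0x800
            if r.is_secondary:
                flag |= 0x100
            a.flag = flag
            if r.read_seq is not None:
                a.query_sequence = r.read_seq
            if r.sa_segments:
                a.set_tag(
                    "SA",
                    "".join(
                        f"{s.chrom},{s.pos + 1},{s.strand},{s.cigar},{s.mapq},0;"
                        for s in r.sa_segments
                    ),
                )
            out.write(a)
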
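"""Aligned-read handling: SAM parsing, duplicate marking, CIGAR-aware pileups.

The pileup is the substrate for variant calling: per 1-based position it
tallies, for each observed base, the counts on forward- and reverse-oriented
reads and the base qualities, after applying base- and mapping-quality
floors, skipping duplicates, and counting overlapping mate pairs once.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Union

import pysam


class SamParseError(ValueError):
    pass


# CIGAR op codes (pysam numeric): M=0 I=1 D=2 N=3 S=4 H=5 P=6 ==7 X=8
_CONSUMES_QUERY = {0, 1, 4, 7, 8}
_CONSUMES_REF = {0, 2, 3, 7, 8}
_ALIGNED = {0, 7, 8}


@dataclass
class AlignedRead:
    """One mapped SAM record, 1-based leftmost position."""

    name: str
    chrom: str
    pos: int
    is_reverse: bool
    cigar: tuple  # ((op_code, length), ...)
    seq: str
    quals: tuple  # per-base Phred values
    mapq: int
    is_read1: bool
    mate_chrom: Optional[str]
    mate_pos: Optional[int]
    is_duplicate: bool = False

    def __post_init__(self):
        qlen = sum(l for op, l in self.cigar if op in _CONSUMES_QUERY)
        if qlen != len(self.seq):
            raise SamParseError(
                f"read {self.name}: CIGAR query length {qlen} != sequence "
                f"length {len(self.seq)}"
            )
        if len(self.quals) != len(self.seq):
            raise SamParseError(
                f"read {self.name}: quality length != sequence length"
            )

    @property
    def strand(self) -> str:
        return "-" if self.is_reverse else "+"

    @property
    def reference_length(self) -> int:
        return sum(l for op, l in self.cigar if op in _CONSUMES_REF)

    @property
    def end(self) -> int:
        """1-based inclusive rightmost aligned reference position."""
        return self.pos + self.reference_length - 1

    @property
    def unclipped_start(self) -> int:
        lead = 0
        for op, l in self.cigar:
            if op in (4, 5):
                lead += l
            else:
                break
        return self.pos - lead

    @property
    def unclipped_end(self) -> int:
        trail = 0
        for op, l in reversed(self.cigar):
            if op in (4, 5):
                trail += l
            else:
                break
        return self.end + trail

    @property
    def five_prime_position(self) -> int:
        """Unclipped 5' coordinate (duplicate-marking key)."""
        return self.unclipped_end if self.is_reverse else self.unclipped_start

    @property
    def quality_sum(self) -> int:
        return sum(self.quals)

    def aligned_pairs(self):
        """Yield (ref_pos 1-based, query_index) for aligned (M/=/X) bases."""
        rpos = self.pos
        qpos = 0
        for op, l in self.cigar:
            if op in _ALIGNED:
                for i in range(l):
                    yield rpos + i, qpos + i
                rpos += l
                qpos += l
            elif op in (1, 4):  # I, S
                qpos += l
            elif op in (2, 3):  # D, N
                rpos += l
            # H, P consume nothing


def read_sam(path: str) -> tuple[list[AlignedRead], dict[str, int]]:
    """Parse a SAM file; returns (mapped primary reads, reference lengths)."""
    reads: list[AlignedRead] = []
    try:
        fh = pysam.AlignmentFile(path, "r")
    except (ValueError, OSError) as exc:
        raise SamParseError(f"cannot parse SAM {path}: {exc}") from exc
    with fh:
        ref_lengths = dict(zip(fh.references, fh.lengths))
        for a in fh:
            if a.is_unmapped or a.is_secondary or a.is_supplementary:
                continue
            reads.append(
                AlignedRead(
                    name=a.query_name,
                    chrom=a.reference_name,
                    pos=a.reference_start + 1,
                    is_reverse=a.is_reverse,
                    cigar=tuple(a.cigartuples or ()),
                    seq=a.query_sequence or "",
                    quals=tuple(a.query_qualities or ()),
                    mapq=a.mapping_quality,
                    is_read1=not a.is_read2,
                    mate_chrom=(
                        a.next_reference_name
                        if a.next_reference_id >= 0
                        else None
                    ),
                    mate_pos=(
                        a.next_reference_start + 1
                        if a.next_reference_id >= 0
                        else None
                    ),
                    is_duplicate=a.is_duplicate,
                )
            )
    return reads, ref_lengths


def read_alignments(path: str) -> list[AlignedRead]:
    """All mapped primary records of a SAM file."""
    return read_sam(path)[0]


def mark_duplicates(reads: list[AlignedRead]) -> list[AlignedRead]:
    """Flag PCR/optical duplicates, keeping the highest-quality copy.

    Reads sharing (chromosome, unclipped 5' position, strand, mate signature)
    form one duplicate set; the member with the highest base-quality sum is
    kept (ties broken by read name, then mate order, so the outcome does not
    depend on input order).  Flags are set in place and the list returned.
    """
    groups: dict[tuple, list[AlignedRead]] = {}
    for r in reads:
        key = (r.chrom, r.five_prime_position, r.is_reverse,
               r.mate_chrom, r.mate_pos, r.is_read1)
        groups.setdefault(key, []).append(r)
    for members in groups.values():
        members.sort(key=lambda r: (-r.quality_sum, r.name, not r.is_read1))
        members[0].is_duplicate = False
        for r in members[1:]:
            r.is_duplicate = True
    return reads


@dataclass
class BaseTally:
    fwd: int = 0
    rev: int = 0
    quals: list = field(default_factory=list)

    @property
    def count(self) -> int:
        return self.fwd + self.rev


@dataclass
class PileupColumn:
    chrom: str
    pos: int  # 1-based
    ref_base: str
    bases: dict  # base -> BaseTally

    @property
    def depth(self) -> int:
        return sum(t.count for t in self.bases.values())


def build_pileup(
    reads: Iterable[AlignedRead],
    chrom: str,
    start: int,
    end: int,
    reference: Mapping[str, str],
    min_base_quality: int = 20,
    min_mapping_quality: int = 20,
) -> list[PileupColumn]:
    """CIGAR-aware pileup over [start, end] (1-based inclusive).

    Deletions, N-skips and soft clips contribute nothing; insertions anchor
    to no column.  When the two mates of a pair overlap, the molecule is
    counted once per position: the higher-quality base wins, ties keep the
    first mate encountered.  Only columns with at least one qualifying base
    are returned, sorted by position.
    """
    ref_seq = reference[chrom]
    if start < 1 or end > len(ref_seq) or start > end:
        raise ValueError(
            f"region {chrom}:{start}-{end} outside reference bounds"
        )
    # pos -> read name -> (base, qual, is_reverse)
    columns: dict[int, dict[str, tuple]] = {}
    for r in reads:
        if r.chrom != chrom or r.is_duplicate or r.mapq < min_mapping_quality:
            continue
        if r.end < start or r.pos > end:
            continue
        for rpos, qidx in r.aligned_pairs():
            if rpos < start or rpos > end:
                continue
            q = r.quals[qidx]
            if q < min_base_quality:
                continue
            base = r.seq[qidx]
            if base == "N":
                continue
            col = columns.setdefault(rpos, {})
            prev = col.get(r.name)
            if prev is None or q > prev[1]:
                col[r.name] = (base, q, r.is_reverse)
    out = []
    for pos in sorted(columns):
        tallies: dict[str, BaseTally] = {}
        for base, q, is_rev in columns[pos].values():
            t = tallies.setdefault(base, BaseTally())
            if is_rev:
                t.rev += 1
            else:
                t.fwd += 1
            t.quals.append(q)
        out.append(PileupColumn(chrom, pos, ref_seq[pos - 1], tallies))
    return out
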
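"""Targeted editing quantification: amplicon allele counting and Sanger peaks.

Amplicon reads (adaptor + barcode + insert) are anchored to their design by
exact prefix matching of adaptor and barcode (at most one mismatch each) and
then assigned to the design minimizing the Hamming distance over the 20
bases flanking the target site on either side — the site base itself is
masked so the edited allele cannot bias assignment.  Allele counts at the
designated offset give the editing ratio n_G / (n_A + n_G); other bases are
reported but never enter the denominator.

The Sanger estimator is the chromatogram peak-height ratio
100 * G / (G + A) at the queried base.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import pandas as pd

from .sim import AmpliconDesign, ChromatogramPeaks

ANCHOR_FLANK = 20
DEFAULT_MAX_MISMATCH_FRAC = 0.1
DEFAULT_MIN_BASE_QUALITY = 20


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


@dataclass(frozen=True)
class AssignedRead:
    design_id: str
    insert: str
    insert_quals: tuple
    anchor_mismatch_frac: float


def assign_and_trim(
    seq: str,
    quals: Sequence[int],
    designs: Sequence[AmpliconDesign],
    max_mismatch_frac: float = DEFAULT_MAX_MISMATCH_FRAC,
) -> tuple[Optional[AssignedRead], str]:
    """Assign a read to an amplicon design and trim adaptor/barcode.

    Returns (assignment, status); status is ``ok``, ``no_adaptor`` (no design
    prefix matched within one mismatch each for adaptor and barcode),
    ``too_short`` (insert does not cover the anchor window),
    ``no_match`` (best anchor distance above ``max_mismatch_frac``) or
    ``ambiguous`` (two designs tie for best).
    """
    if not designs:
        raise ValueError("designs must be non-empty")
    candidates = []
    saw_prefix = False
    saw_long_enough = False
    for d in designs:
        prefix_len = len(d.adaptor5) + len(d.barcode)
        if len(seq) < prefix_len:
            continue
        if _hamming(seq[: len(d.adaptor5)], d.adaptor5) > 1:
            continue
        if _hamming(seq[len(d.adaptor5) : prefix_len], d.barcode) > 1:
            continue
        saw_prefix = True
        insert = seq[prefix_len : prefix_len + len(d.sequence)]
        lo = max(0, d.target_offset - ANCHOR_FLANK)
        hi = min(len(d.sequence), d.target_offset + ANCHOR_FLANK + 1)
        if len(insert) < hi:
            continue
        saw_long_enough = True
        window = [
            i for i in range(lo, hi) if i != d.target_offset
        ]
        dist = sum(insert[i] != d.sequence[i] for i in window)
        frac = dist / len(window)
        candidates.append((frac, d, insert, prefix_len))
    if not candidates:
        if saw_prefix and not saw_long_enough:
            return None, "too_short"
        return None, "no_adaptor"
    candidates.sort(key=lambda c: c[0])
    best = candidates[0]
    if best[0] > max_mismatch_frac:
        return None, "no_match"
    ties = [c for c in candidates if c[0] == best[0]]
    if len({c[1].amplicon_id for c in ties}) > 1:
        return None, "ambiguous"
    frac, d, insert, prefix_len = best
    return (
        AssignedRead(
            design_id=d.amplicon_id,
            insert=insert,
            insert_quals=tuple(quals[prefix_len : prefix_len + len(insert)]),
            anchor_mismatch_frac=frac,
        ),
        "ok",
    )


@dataclass(frozen=True)
class AmpliconCounts:
    design_id: str
    n_A: int
    n_G: int
    n_other: int
    n_low_quality: int
    ratio: Optional[float]  # n_G / (n_A + n_G); None when denominator is 0


def amplicon_editing_ratio(
    assigned: Iterable[AssignedRead],
    design: AmpliconDesign,
    min_base_quality: int = DEFAULT_MIN_BASE_QUALITY,
) -> AmpliconCounts:
    """Count alleles at the design's target offset over assigned reads."""
    n_a = n_g = n_other = n_low = 0
    for read in assigned:
        if read.design_id != design.amplicon_id:
            continue
        if design.target_offset >= len(read.insert):
            continue
        q = read.insert_quals[design.target_offset]
        if q < min_base_quality:
            n_low += 1
            continue
        base = read.insert[design.target_offset]
        if base == "A":
            n_a += 1
        elif base == "G":
            n_g += 1
        else:
            n_other += 1
    ratio = n_g / (n_a + n_g) if (n_a + n_g) > 0 else None
    return AmpliconCounts(design.amplicon_id, n_a, n_g, n_other, n_low, ratio)


def quantify_fastq(
    reads: Iterable[tuple],
    designs: Sequence[AmpliconDesign],
    max_mismatch_frac: float = DEFAULT_MAX_MISMATCH_FRAC,
    min_base_quality: int = DEFAULT_MIN_BASE_QUALITY,
) -> tuple[pd.DataFrame, dict]:
    """Assign a batch of (name, seq, quals) reads and quantify every design.

    Returns (per-design count/ratio table, rejection tally by status).
    """
    assigned: dict[str, list[AssignedRead]] = {d.amplicon_id: [] for d in designs}
    rejects: dict[str, int] = {}
    for _name, seq, quals in reads:
        if isinstance(quals, str):
            quals = [ord(c) - 33 for c in quals]
        result, status = assign_and_trim(seq, quals, designs, max_mismatch_frac)
        if result is None:
            rejects[status] = rejects.get(status, 0) + 1
        else:
            assigned[result.design_id].append(result)
    rows = []
    for d in designs:
        c = amplicon_editing_ratio(assigned[d.amplicon_id], d, min_base_quality)
        rows.append((d.amplicon_id, len(assigned[d.amplicon_id]), c.n_A, c.n_G,
                     c.n_other, c.n_low_quality, c.ratio))
    table = pd.DataFrame(
        rows,
        columns=["amplicon_id", "n_assigned", "n_A", "n_G", "n_other",
                 "n_low_quality", "ratio"],
    )
    return table, rejects


def read_fastq(path: str) -> list[tuple]:
    """Plain FASTQ reader returning (name, sequence, quality-values) tuples."""
    out = []
    with open(path) as fh:
        while True:
            header = fh.readline()
            if not header:
                break
            seq = fh.readline().strip()
            fh.readline()
            qual = fh.readline().strip()
            out.append((header.strip()[1:], seq, [ord(c) - 33 for c in qual]))
    return out


# --------------------------------------------------------------------- Sanger


def sanger_ratio(peaks: ChromatogramPeaks) -> float:
    """Editing percentage from chromatogram peaks: 100 * G / (G + A)."""
    denom = peaks.G + peaks.A
    if denom <= 0:
        raise ValueError("G + A peak sum must be > 0")
    return 100.0 * peaks.G / denom


def read_peak_table(path: str) -> dict:
    """Peak heights from a tab-separated table (site_id, A, C, G, T)."""
    df = pd.read_csv(path, sep="\t")
    return {
        r.site_id: ChromatogramPeaks(A=r.A, C=r.C, G=r.G, T=r.T)
        for r in df.itertuples()
    }
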
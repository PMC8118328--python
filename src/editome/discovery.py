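"""Variant calling from pileups with Fisher-strand and quality-by-depth filters.

The caller is a transparent per-column model for biallelic substitutions:
for every column with alternate-base observations it contrasts

* the no-variant null, under which each read base is the reference unless a
  sequencing error occurred (error probabilities taken from the base
  qualities, a specific wrong base being e/3), against
* a variant model in which a fraction of molecules carry the alternate
  allele, evaluated at its maximum-likelihood value AD_alt / (AD_ref+AD_alt).

QUAL is the Phred-scaled likelihood ratio of the two, so isolated error
bases at ordinary coverage score well below the call-confidence floor while
even low-ratio true sites accumulate support across reads.  Hard filtering
then removes strand-biased calls (FS > fs_max) and calls with weak support
relative to depth (QD < qd_min); equality survives in both cases.
"""

from __future__ import annotations

import logging
import math
from bisect import bisect_right
from dataclasses import dataclass, field, replace
from functools import lru_cache
from math import comb
from typing import Iterable, Optional, Sequence

from .alignments import PileupColumn

logger = logging.getLogger(__name__)

_LOG10_3 = math.log10(3.0)

#: Hard-filter defaults: calls with FS above / QD below these are removed.
DEFAULT_FS_MAX = 30.0
DEFAULT_QD_MIN = 2.0
DEFAULT_CALL_CONFIDENCE = 20.0
DEFAULT_MIN_CALL_DEPTH = 5


@dataclass
class VariantCall:
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    ad: tuple  # (ref depth, alt depth)
    dp: int
    qual: float
    fs: Optional[float] = None
    qd: Optional[float] = None
    filters: tuple = ()  # empty until filtered; ("PASS",) if it survived

    def __post_init__(self):
        if min(self.ad) < 0 or sum(self.ad) > self.dp:
            raise ValueError("AD components must be >= 0 and sum to <= DP")
        if self.qual < 0:
            raise ValueError("QUAL must be >= 0")

    @property
    def passed(self) -> bool:
        return self.filters == ("PASS",)


# ------------------------------------------------------------- Fisher strand


@lru_cache(maxsize=1 << 18)
def _fixed_margin_weights(r1: int, r2: int, c1: int):
    """Hypergeometric table weights for fixed margins, exact integers.

    For the 2x2 table family with row sums (r1, r2) and first column sum c1,
    the probability of the table with upper-left cell k is proportional to
    C(r1, k) * C(r2, c1 - k).  Returns (k_min, weights, sorted weights,
    prefix sums of sorted weights, total weight) — all integer arithmetic, so
    probability ties are resolved exactly.
    """
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    weights = [comb(r1, k) * comb(r2, c1 - k) for k in range(lo, hi + 1)]
    swept = sorted(weights)
    prefix = []
    acc = 0
    for w in swept:
        acc += w
        prefix.append(acc)
    return lo, tuple(weights), tuple(swept), tuple(prefix), acc


def fisher_strand(ref_fwd: int, ref_rev: int, alt_fwd: int, alt_rev: int) -> float:
    """Phred-scaled two-sided Fisher exact probability of the allele-by-strand table.

    Two-sided convention: the p-value sums all fixed-margin tables whose
    probability does not exceed that of the observed table (exact integer
    comparison, so ties are included deterministically).  Returns 0.0 for an
    all-zero table and clips at 0 when p = 1.
    """
    cells = (ref_fwd, ref_rev, alt_fwd, alt_rev)
    if any(c < 0 for c in cells):
        raise ValueError("counts must be >= 0")
    if sum(cells) == 0:
        return 0.0
    r1 = ref_fwd + ref_rev
    r2 = alt_fwd + alt_rev
    c1 = ref_fwd + alt_fwd
    lo, weights, swept, prefix, total = _fixed_margin_weights(r1, r2, c1)
    w_obs = weights[ref_fwd - lo]
    numer = prefix[bisect_right(swept, w_obs) - 1]
    p = numer / total  # big-int true division, correctly rounded
    if p >= 1.0:
        return 0.0
    return -10.0 * math.log10(p)


def quality_by_depth(qual: float, informative_depth: int) -> Optional[float]:
    """QUAL normalized by informative depth (AD_ref + AD_alt).

    Returns None (undefined) at zero informative depth; such calls fail the
    QD filter by convention.
    """
    if informative_depth < 0:
        raise ValueError("informative_depth must be >= 0")
    if informative_depth == 0:
        return None
    return qual / informative_depth


# ------------------------------------------------------------------- calling


def _phred_to_error(q: float) -> float:
    return 10.0 ** (-q / 10.0)


def call_quality(ref_quals: Sequence[float], alt_quals: Sequence[float]) -> float:
    """Phred-scaled support for a variant at one column.

    Likelihood ratio between the MLE variant model and the all-error null;
    see the module docstring.  Equals 0 when the data favor the null.
    """
    n_ref = len(ref_quals)
    n_alt = len(alt_quals)
    if n_alt == 0:
        return 0.0
    log10_null = sum(math.log10(1.0 - _phred_to_error(q)) for q in ref_quals)
    log10_null += sum(-q / 10.0 - _LOG10_3 for q in alt_quals)
    f = n_alt / (n_ref + n_alt)
    log10_alt = n_alt * math.log10(f)
    if n_ref:
        log10_alt += n_ref * math.log10(1.0 - f)
    return max(0.0, 10.0 * (log10_alt - log10_null))


def call_variants(
    columns: Iterable[PileupColumn],
    min_call_confidence: float = DEFAULT_CALL_CONFIDENCE,
    min_depth: int = DEFAULT_MIN_CALL_DEPTH,
) -> list[VariantCall]:
    """Emit substitution calls for columns whose QUAL clears the confidence floor.

    Only the highest-depth alternate base of a column is evaluated (ties go
    to the alphabetically first base); other alternates are logged.  Columns
    with reference base N are skipped with a log notice.  FS and QD are
    populated from the column's strand tallies.
    """
    calls = []
    for col in columns:
        if col.ref_base == "N":
            logger.info("skipping %s:%d: reference base N", col.chrom, col.pos)
            continue
        ref_tally = col.bases.get(col.ref_base)
        alts = {b: t for b, t in col.bases.items() if b != col.ref_base}
        if not alts:
            continue
        alt_base = max(sorted(alts), key=lambda b: alts[b].count)
        if len(alts) > 1:
            logger.debug(
                "%s:%d: multi-allelic column, evaluating %s only",
                col.chrom, col.pos, alt_base,
            )
        alt_tally = alts[alt_base]
        ref_quals = ref_tally.quals if ref_tally else []
        qual = call_quality(ref_quals, alt_tally.quals)
        dp = col.depth
        if dp < min_depth or qual < min_call_confidence:
            continue
        n_ref = ref_tally.count if ref_tally else 0
        fs = fisher_strand(
            ref_tally.fwd if ref_tally else 0,
            ref_tally.rev if ref_tally else 0,
            alt_tally.fwd,
            alt_tally.rev,
        )
        qd = quality_by_depth(qual, n_ref + alt_tally.count)
        calls.append(
            VariantCall(
                chrom=col.chrom,
                pos=col.pos,
                ref=col.ref_base,
                alt=alt_base,
                ad=(n_ref, alt_tally.count),
                dp=dp,
                qual=qual,
                fs=fs,
                qd=qd,
            )
        )
    return calls


def filter_variants(
    calls: Iterable[VariantCall],
    fs_max: float = DEFAULT_FS_MAX,
    qd_min: float = DEFAULT_QD_MIN,
) -> list[VariantCall]:
    """Apply the hard filters; returns surviving calls.

    Every input call gets its ``filters`` annotation set: ("PASS",) when it
    survives, otherwise the names of the failed filters ("FS" when
    FS > fs_max, "QD" when QD < qd_min or QD is undefined).  Equality at
    either threshold survives.
    """
    survivors = []
    for call in calls:
        failed = []
        if call.fs is not None and call.fs > fs_max:
            failed.append("FS")
        if call.qd is None or call.qd < qd_min:
            failed.append("QD")
        call.filters = ("PASS",) if not failed else tuple(failed)
        if not failed:
            survivors.append(call)
    return survivors


# ------------------------------------------------------------------- VCF out


def write_vcf(
    calls: Sequence[VariantCall],
    path: str,
    reference_name: str = "sim",
    sample: str = "sample1",
    contig_lengths: Optional[dict] = None,
) -> None:
    """Minimal VCF 4.2 with QUAL, FILTER, FS/QD INFO and AD/DP sample fields."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##reference={reference_name}\n")
        for chrom, length in (contig_lengths or {}).items():
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write('##FILTER=<ID=FS,Description="Fisher strand above threshold">\n')
        fh.write('##FILTER=<ID=QD,Description="Quality by depth below threshold">\n')
        fh.write('##INFO=<ID=FS,Number=1,Type=Float,Description="Phred-scaled '
                 'Fisher strand p-value">\n')
        fh.write('##INFO=<ID=QD,Number=1,Type=Float,Description="Quality by '
                 'depth">\n')
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic '
                 'depths">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read '
                 'depth">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 f"{sample}\n")
        for c in sorted(calls, key=lambda c: (c.chrom, c.pos)):
            filt = ";".join(c.filters) if c.filters else "."
            info_parts = []
            if c.fs is not None:
                info_parts.append(f"FS={c.fs:.3f}")
            if c.qd is not None:
                info_parts.append(f"QD={c.qd:.2f}")
            info = ";".join(info_parts) if info_parts else "."
            fh.write(
                f"{c.chrom}\t{c.pos}\t.\t{c.ref}\t{c.alt}\t{c.qual:.2f}\t"
                f"{filt}\t{info}\tAD:DP\t{c.ad[0]},{c.ad[1]}:{c.dp}\n"
            )
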
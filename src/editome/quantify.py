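"""Editing-ratio quantification, retention, category counts, ΔΔCt.

The editing ratio of a site in a sample is the alternate-allele depth
divided by the total read depth, reported only at or above a minimum depth.
Retention compares genotypes: a site's mean mutant ratio divided by its mean
wild-type ratio, computed only for sites whose wild-type mean exceeds a
floor (default 5%) and which were detected in both replicates of each group
— a site silenced by a knockout typically drops out of detection rather
than reporting a zero, and the summary helpers make that convention
explicit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .genes import REGION_LABELS

DEFAULT_MIN_DEPTH = 10
DEFAULT_WT_MIN_RATIO = 0.05

RATIO_COLUMNS = ["site_key", "sample_id", "genotype", "ad_alt", "dp", "ratio",
                 "detected"]


def editing_ratio(ad_alt: int, dp: int, min_depth: int = DEFAULT_MIN_DEPTH):
    """AD_alt / DP, or None when coverage is below ``min_depth``."""
    if ad_alt < 0 or dp < ad_alt:
        raise ValueError("need 0 <= ad_alt <= dp")
    if dp < min_depth or dp == 0:
        return None
    return ad_alt / dp


@dataclass(frozen=True)
class RetentionRecord:
    """Per-site mutant/wild-type mean-ratio quotient with eligibility flags."""

    site_key: str
    wt_mean: Optional[float]
    mut_mean: Optional[float]
    retention: Optional[float]
    wt_above_floor: bool
    wt_detected_both: bool
    mut_detected_both: bool
    reason: str  # "ok" or the first failed eligibility rule

    @property
    def eligible(self) -> bool:
        return self.reason == "ok"


def retention(
    site_key: str,
    wt_ratios: Sequence[Optional[float]],
    mut_ratios: Sequence[Optional[float]],
    wt_min: float = DEFAULT_WT_MIN_RATIO,
    wt_detected: Optional[Sequence[bool]] = None,
    mut_detected: Optional[Sequence[bool]] = None,
) -> RetentionRecord:
    """Retention of editing at one site across replicate animals.

    Ratios are per-replicate editing ratios (None = undefined).  Detection
    flags default to "ratio defined and > 0"; pipelines that know whether a
    site passed discovery in a replicate should pass explicit flags.
    Retention = mean(mut) / mean(wt), defined only when the wild-type mean
    exceeds ``wt_min`` and the site was detected in both replicates of both
    groups; means are unweighted arithmetic means of replicate ratios.
    """
    if len(wt_ratios) < 2 or len(mut_ratios) < 2:
        raise ValueError("need at least two replicates per genotype")
    if wt_detected is None:
        wt_detected = [r is not None and r > 0 for r in wt_ratios]
    if mut_detected is None:
        mut_detected = [r is not None and r > 0 for r in mut_ratios]

    wt_defined = [r for r in wt_ratios if r is not None]
    mut_defined = [r for r in mut_ratios if r is not None]
    wt_mean = sum(wt_defined) / len(wt_defined) if wt_defined else None
    mut_mean = sum(mut_defined) / len(mut_defined) if mut_defined else None

    wt_both = all(wt_detected)
    mut_both = all(mut_detected)
    wt_above = wt_mean is not None and wt_mean > wt_min

    if not wt_both:
        reason = "wt_not_detected_in_both"
    elif not wt_above:
        reason = "wt_mean_below_floor"
    elif not mut_both:
        reason = "mut_not_detected_in_both"
    else:
        reason = "ok"
    value = None
    if reason == "ok":
        value = mut_mean / wt_mean
    return RetentionRecord(
        site_key=site_key,
        wt_mean=wt_mean,
        mut_mean=mut_mean,
        retention=value,
        wt_above_floor=wt_above,
        wt_detected_both=wt_both,
        mut_detected_both=mut_both,
        reason=reason,
    )


def retention_table(
    ratios: pd.DataFrame,
    wt_samples: Sequence[str],
    mut_samples: Sequence[str],
    wt_min: float = DEFAULT_WT_MIN_RATIO,
) -> pd.DataFrame:
    """Vectorized retention over a long-format ratio table.

    ``ratios`` needs columns site_key, sample_id, ratio, detected (see
    RATIO_COLUMNS).  Returns one row per site appearing in any wild-type
    replicate, with the eligibility bookkeeping of :func:`retention`.
    """
    if len(wt_samples) < 2 or len(mut_samples) < 2:
        raise ValueError("need at least two replicates per group")
    rows = []
    pivot_ratio = ratios.pivot_table(
        index="site_key", columns="sample_id", values="ratio", aggfunc="first",
        dropna=False,
    )
    pivot_det = ratios.pivot_table(
        index="site_key", columns="sample_id", values="detected",
        aggfunc="first", dropna=False,
    )
    for site_key in pivot_ratio.index:
        def _get(samples, table, default):
            out = []
            for s in samples:
                v = table.at[site_key, s] if s in table.columns else None
                if v is None or (isinstance(v, float) and math.isnan(v)):
                    out.append(default)
                else:
                    out.append(v)
            return out

        wt_r = _get(wt_samples, pivot_ratio, None)
        mut_r = _get(mut_samples, pivot_ratio, None)
        wt_d = [bool(x) for x in _get(wt_samples, pivot_det, False)]
        mut_d = [bool(x) for x in _get(mut_samples, pivot_det, False)]
        rec = retention(site_key, wt_r, mut_r, wt_min,
                        wt_detected=wt_d, mut_detected=mut_d)
        rows.append(
            (rec.site_key, rec.wt_mean, rec.mut_mean, rec.retention,
             rec.wt_above_floor, rec.wt_detected_both, rec.mut_detected_both,
             rec.reason)
        )
    return pd.DataFrame(
        rows,
        columns=["site_key", "wt_mean", "mut_mean", "retention",
                 "wt_above_floor", "wt_detected_both", "mut_detected_both",
                 "reason"],
    )


def summarize_retention(
    table: pd.DataFrame, undetected_as_zero: bool = False
) -> dict:
    """Mean retention plus detection bookkeeping over a retention table.

    With ``undetected_as_zero`` the sites that cleared the wild-type floor
    but dropped out of mutant detection enter the mean as complete loss
    (retention 0) — the reading under which "not detected" means the editing
    is gone rather than unmeasured.
    """
    eligible_wt = table[table.wt_detected_both & table.wt_above_floor]
    values = eligible_wt.retention.dropna().tolist()
    n_lost = int((~eligible_wt.mut_detected_both).sum())
    if undetected_as_zero:
        values = values + [0.0] * n_lost
    return {
        "n_wt_sites": int(len(eligible_wt)),
        "n_with_retention": int(eligible_wt.retention.notna().sum()),
        "n_lost_in_mutant": n_lost,
        "mean_retention": float(np.mean(values)) if values else float("nan"),
    }


def category_counts(
    rep1: Iterable, rep2: Iterable
) -> pd.DataFrame:
    """Per-region union/intersection site counts across two replicates.

    Inputs are iterables of objects with ``site_key`` and ``region``
    attributes (EditingSiteRecord) or (site_key, region) pairs.  The union
    count is the total number of distinct sites seen in either animal, the
    intersection the number seen in both.
    """
    def _as_map(records):
        out = {}
        for r in records:
            if hasattr(r, "site_key"):
                out[r.site_key] = r.region
            else:
                key, region = r
                out[key] = region
        return out

    m1, m2 = _as_map(rep1), _as_map(rep2)
    regions = sorted(set(m1.values()) | set(m2.values()),
                     key=lambda r: REGION_LABELS.index(r) if r in REGION_LABELS else 99)
    rows = []
    for region in regions:
        s1 = {k for k, v in m1.items() if v == region}
        s2 = {k for k, v in m2.items() if v == region}
        rows.append((region, len(s1 | s2), len(s1 & s2)))
    rows.append(("total",
                 len(set(m1) | set(m2)),
                 len(set(m1) & set(m2))))
    return pd.DataFrame(rows, columns=["region", "union", "intersection"])


def coverage_summary(ratios: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Site-by-sample read-depth matrix and per-site coefficient of variation.

    CV uses the sample standard deviation (ddof=1) over samples with a
    defined depth; equal depths everywhere give CV 0.
    """
    if ratios.empty:
        return pd.DataFrame(), pd.Series(dtype=float, name="cv")
    matrix = ratios.pivot_table(
        index="site_key", columns="sample_id", values="dp", aggfunc="first"
    )
    mean = matrix.mean(axis=1)
    sd = matrix.std(axis=1, ddof=1)
    cv = (sd / mean).fillna(0.0)
    cv.name = "cv"
    return matrix, cv


def categorize_ratio(ratio: float) -> str:
    """Editing-level category: high (>60%), mid (30-60%), low (<30%).

    The mid bin is closed on both ends, so exactly 0.30 and 0.60 are mid.
    """
    if not (0.0 <= ratio <= 1.0):
        raise ValueError("ratio outside [0, 1]")
    if ratio > 0.60:
        return "high"
    if ratio >= 0.30:
        return "mid"
    return "low"


def delta_delta_ct(
    target_ct: float,
    reference_ct: float,
    calibrator_target_ct: float,
    calibrator_reference_ct: float,
) -> float:
    """Relative expression by the ddCt method: 2^-((dCt_sample) - (dCt_calibrator))."""
    for v in (target_ct, reference_ct, calibrator_target_ct,
              calibrator_reference_ct):
        if not math.isfinite(v):
            raise ValueError("Ct values must be finite")
    ddct = (target_ct - reference_ct) - (
        calibrator_target_ct - calibrator_reference_ct
    )
    return 2.0 ** (-ddct)
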
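"""End-to-end composition: discovery per sample and genotype contrasts.

``discover_sample`` chains the stages — parse SAM, mark duplicates, pileup,
call, hard-filter, orient, classify, database-intersect — and additionally
re-measures allele/total depth at *every* database position so that sites
discovered in one sample can be quantified in all samples of a contrast.
``run_contrast`` turns two replicate groups into a per-site retention table
and per-region union/intersection category counts.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import asdict, dataclass, field
from typing import Mapping, Optional, Sequence

import pandas as pd
import yaml

from . import alignments, annotation, discovery, quantify
from .annotation import EditingSiteRecord, KnownSiteDB
from .chain import ChainMap
from .genes import GeneModels
from .sim import SimGenome

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Thresholds and bookkeeping for a pipeline run.

    Defaults follow the printed analysis settings: call confidence 20.0,
    FS removal above 30.0, QD removal below 2.0, wild-type retention floor
    5%.  The remaining knobs (quality floors, depth floors) are this
    package's own defaults and are echoed as "assumed" in the manifest.
    """

    min_base_quality: int = 20
    min_mapping_quality: int = 20
    min_call_depth: int = 5
    min_depth: int = 10
    call_confidence: float = 20.0
    fs_max: float = 30.0
    qd_min: float = 2.0
    wt_min_ratio: float = 0.05
    assembly: str = "simG1"
    seed: int = 0

    #: keys whose defaults are package assumptions rather than printed values
    ASSUMED = ("min_base_quality", "min_mapping_quality", "min_call_depth",
               "min_depth", "assembly", "seed")

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class SampleResult:
    sample_id: str
    genotype: str
    records: list  # EditingSiteRecord
    calls: list  # all VariantCall with filter annotations
    site_depths: dict  # (chrom, pos) -> (ad_alt_gene_strand, dp)
    stage_counts: dict


def _gene_strand_alt(column, strand: str):
    """(alt depth, total depth) of the gene-strand A>G allele at a column."""
    alt_base = "G" if strand == "+" else "C"
    tally = column.bases.get(alt_base)
    return (tally.count if tally else 0), column.depth


def discover_sample(
    sample_id: str,
    genotype: str,
    sam_path: str,
    genome: SimGenome,
    models: GeneModels,
    db: KnownSiteDB,
    config: RunConfig,
) -> SampleResult:
    """Run the discovery stages for one sample.

    The database must already be on the working assembly (lift and pool
    databases with :class:`KnownSiteDB` before calling).
    """
    reads, ref_lengths = alignments.read_sam(sam_path)
    n_in = len(reads)
    alignments.mark_duplicates(reads)
    n_dup = sum(r.is_duplicate for r in reads)

    db_positions: dict[str, list] = {}
    for (chrom, pos, strand) in db.entries:
        db_positions.setdefault(chrom, []).append((pos, strand))

    calls = []
    site_depths: dict = {}
    by_chrom: dict[str, list] = {}
    for r in reads:
        by_chrom.setdefault(r.chrom, []).append(r)
    for chrom in sorted(by_chrom):
        if chrom not in genome.chromosomes:
            raise ValueError(f"SAM chromosome {chrom!r} absent from reference")
        columns = alignments.build_pileup(
            by_chrom[chrom], chrom, 1, len(genome.chromosomes[chrom]),
            genome.chromosomes,
            min_base_quality=config.min_base_quality,
            min_mapping_quality=config.min_mapping_quality,
        )
        col_at = {c.pos: c for c in columns}
        for pos, strand in db_positions.get(chrom, []):
            col = col_at.get(pos)
            if col is None:
                site_depths[(chrom, pos)] = (0, 0)
            else:
                site_depths[(chrom, pos)] = _gene_strand_alt(col, strand)
        calls.extend(
            discovery.call_variants(
                columns,
                min_call_confidence=config.call_confidence,
                min_depth=config.min_call_depth,
            )
        )

    passed = discovery.filter_variants(calls, config.fs_max, config.qd_min)
    oriented = []
    orient_tally: dict[str, int] = {}
    for call in passed:
        cand, status = annotation.orient_variant(call, models)
        orient_tally[status] = orient_tally.get(status, 0) + 1
        if cand is not None:
            oriented.append(cand)
    records = annotation.intersect_known(
        oriented, db, models, working_assembly=config.assembly
    )
    counts = {
        "reads_in": n_in,
        "reads_duplicate": n_dup,
        "calls_raw": len(calls),
        "calls_pass_filters": len(passed),
        "calls_filtered": len(calls) - len(passed),
        "oriented_a_to_i": len(oriented),
        "orientation": orient_tally,
        "sites_known": len(records),
    }
    logger.info("sample %s: %s", sample_id, counts)
    return SampleResult(sample_id, genotype, records, calls, site_depths, counts)


def load_databases(
    db_paths: Sequence[str],
    working_assembly: str,
    chain_paths: Optional[Mapping[str, str]] = None,
) -> KnownSiteDB:
    """Read, lift where necessary, and pool known-site databases.

    ``chain_paths`` maps a source assembly tag to the chain file lifting it
    onto the working assembly.
    """
    chain_paths = dict(chain_paths or {})
    dbs = []
    for path in db_paths:
        db = KnownSiteDB.from_tsv(path)
        if db.assembly != working_assembly:
            if db.assembly not in chain_paths:
                raise ValueError(
                    f"{path}: assembly {db.assembly!r} needs a chain file to "
                    f"reach {working_assembly!r}"
                )
            chain_map = ChainMap.from_file(chain_paths[db.assembly])
            db = db.lift(chain_map, working_assembly)
        dbs.append(db)
    return KnownSiteDB.union(dbs)


def ratio_table(
    results: Sequence[SampleResult],
    db: KnownSiteDB,
    config: RunConfig,
) -> pd.DataFrame:
    """Long-format per-site per-sample editing ratios over all DB positions.

    ``detected`` marks sites that passed discovery + database intersection
    in that sample with a defined ratio and at least one alternate read.
    """
    rows = []
    for res in results:
        detected_keys = {r.key for r in res.records}
        for (chrom, pos, strand) in sorted(db.entries):
            ad_alt, dp = res.site_depths.get((chrom, pos), (0, 0))
            ratio = quantify.editing_ratio(ad_alt, dp, config.min_depth)
            detected = (
                (chrom, pos, strand) in detected_keys
                and ratio is not None
                and ad_alt >= 1
            )
            rows.append(
                (f"{chrom}:{pos}:{strand}", res.sample_id, res.genotype,
                 ad_alt, dp, ratio, detected)
            )
    return pd.DataFrame(rows, columns=quantify.RATIO_COLUMNS)


def run_contrast(
    results_by_sample: Mapping[str, SampleResult],
    wt_samples: Sequence[str],
    mut_samples: Sequence[str],
    db: KnownSiteDB,
    config: RunConfig,
) -> dict:
    """Retention table plus per-group category counts for a genotype contrast."""
    if len(wt_samples) < 2 or len(mut_samples) < 2:
        raise ValueError("need at least two replicates per group")
    used = [results_by_sample[s] for s in (*wt_samples, *mut_samples)]
    ratios = ratio_table(used, db, config)
    ret = quantify.retention_table(
        ratios, list(wt_samples), list(mut_samples), config.wt_min_ratio
    )
    categories = {
        "wt": quantify.category_counts(
            results_by_sample[wt_samples[0]].records,
            results_by_sample[wt_samples[1]].records,
        ),
        "mut": quantify.category_counts(
            results_by_sample[mut_samples[0]].records,
            results_by_sample[mut_samples[1]].records,
        ),
    }
    return {"ratios": ratios, "retention": ret, "categories": categories}


def write_manifest(
    path: str,
    config: RunConfig,
    stage_counts: Mapping[str, dict],
    extra: Optional[dict] = None,
) -> None:
    from . import __version__

    manifest = {
        "tool_version": __version__,
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "assumed_defaults": list(RunConfig.ASSUMED),
        "seed": config.seed,
        "stage_counts": dict(stage_counts),
    }
    if extra:
        manifest.update(extra)
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
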
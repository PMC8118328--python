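"""Orientation, region classification and known-database intersection.

Candidate substitutions become A-to-I editing candidates only when their
allele change matches the strand of an overlapping gene: A>G inside a
'+'-strand gene, T>C inside a '-'-strand gene.  Candidates consistent with
genes on both strands are ambiguous and excluded by default, since database
strand misregistration is a known failure mode of editing catalogs.
Accepted candidates are then classified into CDS / 3'UTR / 5'UTR / intron
(precedence in that order across the gene's isoforms, exonic labels beating
intronic ones) and kept only when a known-editing-site database entry
matches both coordinate and gene strand.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import pandas as pd

from .chain import ChainMap, liftover_point
from .discovery import VariantCall
from .genes import (
    GeneModels,
    REGION_3UTR,
    REGION_5UTR,
    REGION_CDS,
    REGION_INTRON,
    REGION_OTHERS,
)

#: Exon-over-intron precedence used when isoforms disagree.
REGION_PRECEDENCE = (REGION_CDS, REGION_3UTR, REGION_5UTR, REGION_INTRON)

DB_SOURCES = ("DARNED", "RADAR", "REDIportal", "custom")


@dataclass(frozen=True)
class OrientedCandidate:
    """A substitution re-expressed as gene-strand A>G."""

    chrom: str
    pos: int
    gene_strand: str
    gene_id: str
    genome_ref: str
    genome_alt: str
    call: VariantCall

    @property
    def key(self):
        return (self.chrom, self.pos, self.gene_strand)


@dataclass(frozen=True)
class EditingSiteRecord:
    chrom: str
    pos: int
    gene_strand: str
    gene_id: str
    region: str
    sources: frozenset
    ad_alt: int
    dp: int

    @property
    def key(self):
        return (self.chrom, self.pos, self.gene_strand)

    @property
    def site_key(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.gene_strand}"


def orient_variant(
    call: VariantCall, models: GeneModels
) -> tuple[Optional[OrientedCandidate], str]:
    """Try to orient a substitution as A-to-I; returns (candidate, status).

    Status is one of ``ok``, ``not_a_to_g`` (allele change fits no gene
    strand at this position), ``ambiguous_strand`` (fits genes on both
    strands), ``intergenic``.
    """
    genes = models.genes_at(call.chrom, call.pos)
    if not genes:
        return None, "intergenic"
    plus = sorted(g for g, ts in genes.items() if any(t.strand == "+" for t in ts))
    minus = sorted(g for g, ts in genes.items() if any(t.strand == "-" for t in ts))
    fits_plus = call.ref == "A" and call.alt == "G" and bool(plus)
    fits_minus = call.ref == "T" and call.alt == "C" and bool(minus)
    if fits_plus and fits_minus:
        return None, "ambiguous_strand"
    if fits_plus:
        return (
            OrientedCandidate(call.chrom, call.pos, "+", plus[0],
                              call.ref, call.alt, call),
            "ok",
        )
    if fits_minus:
        return (
            OrientedCandidate(call.chrom, call.pos, "-", minus[0],
                              call.ref, call.alt, call),
            "ok",
        )
    return None, "not_a_to_g"


def classify_region(
    chrom: str,
    pos: int,
    models: GeneModels,
    gene_id: Optional[str] = None,
) -> str:
    """Region label at a position under the fixed isoform precedence.

    Looks across all transcripts of ``gene_id`` (or of every overlapping
    gene when unspecified) and returns the highest-precedence label any
    isoform assigns; positions inside no transcript are ``others``.
    """
    transcripts = models.transcripts_at(chrom, pos)
    if gene_id is not None:
        transcripts = [t for t in transcripts if t.gene_id == gene_id]
    labels = {t.region_at(pos) for t in transcripts}
    labels.discard(None)
    for label in REGION_PRECEDENCE:
        if label in labels:
            return label
    return REGION_OTHERS


# --------------------------------------------------------------- known sites


class KnownSiteDB:
    """Known-editing-site entries keyed by (chromosome, position, strand)."""

    def __init__(self, entries: dict, assembly: str):
        # entries: (chrom, pos, strand) -> set of source tags
        self.entries = entries
        self.assembly = assembly

    def __len__(self):
        return len(self.entries)

    @classmethod
    def from_tsv(cls, path: str) -> "KnownSiteDB":
        df = pd.read_csv(path, sep="\t")
        required = {"chromosome", "position", "strand", "source", "assembly"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"{path}: missing columns {sorted(missing)}")
        assemblies = set(df.assembly)
        if len(assemblies) != 1:
            raise ValueError(f"{path}: expected one assembly tag, got {assemblies}")
        entries: dict = {}
        seen = set()
        for r in df.itertuples():
            ident = (r.chromosome, int(r.position), r.strand, r.source)
            if ident in seen:
                raise ValueError(f"{path}: duplicate entry {ident}")
            seen.add(ident)
            key = ident[:3]
            entries.setdefault(key, set()).add(r.source)
        return cls(entries, assemblies.pop())

    def to_tsv(self, path: str) -> None:
        rows = []
        for (chrom, pos, strand), sources in self.entries.items():
            for src in sorted(sources):
                rows.append((chrom, pos, strand, src, self.assembly))
        pd.DataFrame(
            sorted(rows),
            columns=["chromosome", "position", "strand", "source", "assembly"],
        ).to_csv(path, sep="\t", index=False)

    def lift(self, chain_map: ChainMap, target_assembly: str) -> "KnownSiteDB":
        """Lift every entry; unmapped entries are dropped, flips flip strand."""
        entries: dict = {}
        for (chrom, pos, strand), sources in self.entries.items():
            hit = liftover_point(chrom, pos, chain_map)
            if hit is None:
                continue
            new_chrom, new_pos, flipped = hit
            new_strand = strand
            if flipped:
                new_strand = "-" if strand == "+" else "+"
            entries.setdefault((new_chrom, new_pos, new_strand), set()).update(sources)
        return KnownSiteDB(entries, target_assembly)

    @classmethod
    def union(cls, dbs: Sequence["KnownSiteDB"]) -> "KnownSiteDB":
        assemblies = {db.assembly for db in dbs}
        if len(assemblies) != 1:
            raise ValueError(
                f"cannot pool databases on different assemblies: {assemblies}"
            )
        entries: dict = {}
        for db in dbs:
            for key, sources in db.entries.items():
                entries.setdefault(key, set()).update(sources)
        return cls(entries, assemblies.pop())


def intersect_known(
    candidates: Iterable[OrientedCandidate],
    db: KnownSiteDB,
    models: GeneModels,
    working_assembly: str,
    chain_map: Optional[ChainMap] = None,
) -> list[EditingSiteRecord]:
    """Keep candidates registered in the database on the matching strand.

    The database must be on ``working_assembly``; otherwise a chain map must
    be supplied and the database is lifted first.  A candidate is retained
    iff an entry matches (chromosome, position) and the entry strand equals
    the candidate's gene strand.
    """
    if db.assembly != working_assembly:
        if chain_map is None:
            raise ValueError(
                f"database assembly {db.assembly!r} does not match working "
                f"assembly {working_assembly!r} and no chain map was supplied"
            )
        db = db.lift(chain_map, working_assembly)
    records = []
    for cand in candidates:
        sources = db.entries.get(cand.key)
        if not sources:
            continue
        region = classify_region(cand.chrom, cand.pos, models, cand.gene_id)
        records.append(
            EditingSiteRecord(
                chrom=cand.chrom,
                pos=cand.pos,
                gene_strand=cand.gene_strand,
                gene_id=cand.gene_id,
                region=region,
                sources=frozenset(sources),
                ad_alt=cand.call.ad[1],
                dp=cand.call.dp,
            )
        )
    records.sort(key=lambda r: (r.chrom, r.pos))
    return records


def write_bed(records: Sequence[EditingSiteRecord], path: str) -> None:
    """BED6 (0-based half-open) of accepted sites; strand = gene strand."""
    with open(path, "w") as fh:
        for r in sorted(records, key=lambda r: (r.chrom, r.pos)):
            name = f"{r.gene_id}|{r.region}|{'+'.join(sorted(r.sources))}"
            fh.write(
                f"{r.chrom}\t{r.pos - 1}\t{r.pos}\t{name}\t0\t{r.gene_strand}\n"
            )


def write_site_table(records: Sequence[EditingSiteRecord], path: str) -> None:
    df = pd.DataFrame(
        [
            (r.chrom, r.pos, r.gene_strand, r.gene_id, r.region,
             ",".join(sorted(r.sources)), r.ad_alt, r.dp)
            for r in records
        ],
        columns=["chrom", "pos", "strand", "gene_id", "region", "sources",
                 "ad_alt", "dp"],
    )
    df.to_csv(path, sep="\t", index=False)
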
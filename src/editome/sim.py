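"""Synthetic ADAR-genotype editome: toy genome, truth table, reads, assays.

This module generates everything the analysis stages consume, so the whole
pipeline is testable without external sequencing data:

* a random toy genome with multi-exon genes on both strands,
* a truth table of A-to-I editing sites whose realized editing ratio depends
  on which ADAR enzymes (ADAR1 p110, ADAR1 p150, ADAR2) a simulated genotype
  retains,
* strand-preserving paired-end spliced RNA-seq reads (SAM/FASTQ), with a
  configurable fraction of fragments drawn from unspliced pre-mRNA so that
  intronic sites receive coverage,
* known-editing-site database tables (DARNED/RADAR/REDIportal style), with
  one source deliberately written in an "old assembly" coordinate system plus
  the UCSC chain file that lifts it back,
* targeted amplicon reads and Sanger-style chromatogram peak heights.

The combination rule across enzymes is independent action:
``realized = 1 - prod(1 - c_e)`` over the enzymes present in the genotype.
Removing an enzyme therefore never increases editing, and a site whose only
contributing enzyme is knocked out goes to zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import pysam

from .genes import (
    GeneModels,
    Transcript,
    REGION_3UTR,
    REGION_CDS,
    REGION_INTRON,
)

ENZYMES = ("p110", "p150", "ADAR2")

_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


# --------------------------------------------------------------------- genotype


@dataclass(frozen=True)
class Genotype:
    """The set of catalytically available editing enzymes."""

    present: frozenset

    def __post_init__(self):
        unknown = set(self.present) - set(ENZYMES)
        if unknown:
            raise ValueError(f"unknown enzymes: {sorted(unknown)}")

    def __contains__(self, enzyme: str) -> bool:
        return enzyme in self.present


WT = Genotype(frozenset(ENZYMES))
ADAR1_P110_KO = Genotype(frozenset({"p150", "ADAR2"}))
ADAR2_KO = Genotype(frozenset({"p110", "p150"}))
DOUBLE_KO = Genotype(frozenset({"p150"}))  # Adar1 p110 / Adar2 double knockout

GENOTYPES: dict[str, Genotype] = {
    "WT": WT,
    "Adar1p110KO": ADAR1_P110_KO,
    "Adar2KO": ADAR2_KO,
    "doubleKO": DOUBLE_KO,
}


def realized_ratio(contributions: Mapping[str, float], genotype: Genotype) -> float:
    """Editing ratio realized by a genotype under the independent-action rule.

    ``contributions`` maps enzyme name to its per-enzyme editing contribution
    c_e in [0, 1]; enzymes missing from the mapping contribute 0.
    """
    prod = 1.0
    for enzyme, c in contributions.items():
        if enzyme not in ENZYMES:
            raise ValueError(f"unknown enzyme {enzyme!r}")
        if not (0.0 <= c <= 1.0):
            raise ValueError(f"contribution {c} for {enzyme} outside [0, 1]")
        if enzyme in genotype:
            prod *= 1.0 - c
    return 1.0 - prod


# ----------------------------------------------------------------------- genome


@dataclass(frozen=True)
class SimGenome:
    chromosomes: dict[str, str]
    seed: int

    def __post_init__(self):
        for name, seq in self.chromosomes.items():
            if not seq:
                raise ValueError(f"empty chromosome {name}")
            if set(seq) - set("ACGT"):
                raise ValueError(f"chromosome {name} has bases outside ACGT")

    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.chromosomes.items()}

    def base(self, chrom: str, pos: int) -> str:
        """Reference base at a 1-based position."""
        return self.chromosomes[chrom][pos - 1]

    def write_fasta(self, path: str, width: int = 70) -> None:
        with open(path, "w") as fh:
            for name, seq in self.chromosomes.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")

    @classmethod
    def read_fasta(cls, path: str, seed: int = 0) -> "SimGenome":
        chroms: dict[str, str] = {}
        name = None
        parts: list[str] = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if line.startswith(">"):
                    if name is not None:
                        chroms[name] = "".join(parts)
                    name = line[1:].split()[0]
                    parts = []
                elif line:
                    parts.append(line.upper())
        if name is not None:
            chroms[name] = "".join(parts)
        return cls(chroms, seed)


def simulate_genome(
    n_chrom: int,
    chrom_length: int,
    seed: int,
    gene_span: int = 2200,
    gene_gap: int = 150,
) -> tuple[SimGenome, GeneModels]:
    """Random toy genome with alternating-strand multi-exon coding genes.

    Every chromosome hosts at least one gene on each strand; each gene has
    three exons (so at least one intron), a 5'UTR, a CDS and a 3'UTR.
    Regeneration with the same arguments is byte-identical.
    """
    if n_chrom < 1:
        raise ValueError("n_chrom must be >= 1")
    if chrom_length < 5000:
        raise ValueError(
            "chrom_length must be >= 5000 to host a multi-exon gene per strand"
        )
    rng = np.random.default_rng(seed)
    margin = 150
    slot = chrom_length - 2 * margin
    span = gene_span
    if slot // (span + gene_gap) < 2:
        span = slot // 2 - gene_gap
    n_genes = slot // (span + gene_gap)
    if n_genes < 2 or span < 900:
        raise ValueError(
            f"chrom_length={chrom_length} too small for two genes of usable size"
        )

    chroms: dict[str, str] = {}
    transcripts: list[Transcript] = []
    bases = np.array(list("ACGT"))
    for ci in range(n_chrom):
        chrom = f"chr{ci + 1}"
        seq = "".join(bases[rng.integers(0, 4, size=chrom_length)])
        chroms[chrom] = seq
        for gi in range(n_genes):
            gstart = margin + gi * (span + gene_gap) + 1
            strand = "+" if gi % 2 == 0 else "-"
            gene_id = f"{chrom}g{gi + 1}"
            transcripts.append(
                _make_gene(gene_id, chrom, strand, gstart, span)
            )
    return SimGenome(chroms, seed), GeneModels(transcripts)


def _make_gene(gene_id: str, chrom: str, strand: str, start: int, span: int) -> Transcript:
    intron_len = max(200, span // 5)
    exon_total = span - 2 * intron_len
    if exon_total // 3 < 120:
        intron_len = max(80, (span - 3 * 120) // 2)
        exon_total = span - 2 * intron_len
    exon_len = exon_total // 3
    if exon_len < 120:
        raise ValueError(f"gene span {span} too small for three usable exons")
    lens = [exon_len, exon_len, exon_total - 2 * exon_len]
    exons = []
    cursor = start
    for L in lens:
        exons.append((cursor, cursor + L - 1))
        cursor += L + intron_len
    end = exons[-1][1]
    utr5 = min(60, exon_len // 3)
    utr3 = min(80, lens[-1] // 3)
    if strand == "+":
        cds = (exons[0][0] + utr5, exons[-1][1] - utr3)
    else:
        cds = (exons[0][0] + utr3, exons[-1][1] - utr5)
    return Transcript(f"{gene_id}.t1", gene_id, chrom, strand, tuple(exons), cds)


# ------------------------------------------------------------------ truth table

TRUTH_COLUMNS = [
    "site_id", "chrom", "pos", "strand", "gene_id", "region",
    "enzyme_class", "c_p110", "c_p150", "c_ADAR2",
]

#: Default enzyme-class mix: most sites depend on ADAR1 p110 and/or ADAR2;
#: a small fraction are edited exclusively by ADAR1 p150 and therefore
#: survive the p110/ADAR2 double knockout.
DEFAULT_CLASS_FRACTIONS: dict[str, float] = {
    "p110_only": 0.30,
    "ADAR2_only": 0.30,
    "redundant": 0.38,
    "p150_only": 0.02,
}

DEFAULT_REGION_WEIGHTS: dict[str, float] = {
    REGION_INTRON: 0.45,
    REGION_3UTR: 0.40,
    REGION_CDS: 0.15,
}


def _class_counts(n: int, fractions: Mapping[str, float]) -> dict[str, int]:
    """Largest-remainder apportionment of n sites among enzyme classes."""
    total = sum(fractions.values())
    raw = {k: n * v / total for k, v in fractions.items()}
    counts = {k: int(math.floor(x)) for k, x in raw.items()}
    leftover = n - sum(counts.values())
    order = sorted(raw, key=lambda k: raw[k] - counts[k], reverse=True)
    for k in order[:leftover]:
        counts[k] += 1
    return counts


def plant_truth_sites(
    genome: SimGenome,
    models: GeneModels,
    n_sites: int,
    seed: int,
    class_fractions: Optional[Mapping[str, float]] = None,
    region_weights: Optional[Mapping[str, float]] = None,
    edge_margin: int = 25,
) -> pd.DataFrame:
    """Choose editable adenosines and assign per-enzyme contributions.

    Sites are placed on gene-strand A positions (genomic A in '+' genes,
    genomic T in '-' genes) within introns, CDS or 3'UTRs.  Contribution
    magnitudes per class: single-enzyme classes draw U(0.35, 0.90); the
    redundant class draws both c_p110 and c_ADAR2 from U(0.60, 0.90) so that
    losing one enzyme leaves most of the editing in place; p150-only sites
    draw U(0.60, 0.90).

    Positions within ``edge_margin`` of a transcript's span boundaries are
    skipped: fragment sampling tapers read coverage to zero at template ends
    (as real libraries do at transcript 3' ends), so sites placed there would
    be unquantifiable at any simulated depth.
    """
    rng = np.random.default_rng(seed)
    fractions = dict(class_fractions or DEFAULT_CLASS_FRACTIONS)
    weights = dict(region_weights or DEFAULT_REGION_WEIGHTS)

    pools: dict[str, list[tuple]] = {r: [] for r in weights}
    for t in models.transcripts:
        seq = genome.chromosomes[t.chrom]
        target = "A" if t.strand == "+" else "T"
        lo = t.start + edge_margin
        hi = t.end - edge_margin
        for region, ivs in t.regions().items():
            if region not in pools:
                continue
            for s, e in ivs:
                for pos in range(s, e + 1):
                    if lo <= pos <= hi and seq[pos - 1] == target:
                        pools[region].append((t.chrom, pos, t.strand, t.gene_id, region))
    for region in pools:
        pools[region].sort()
        idx = rng.permutation(len(pools[region]))
        pools[region] = [pools[region][i] for i in idx]

    region_counts = _class_counts(n_sites, weights)
    chosen: list[tuple] = []
    seen: set[tuple] = set()
    for region, want in region_counts.items():
        pool = pools[region]
        take = 0
        for entry in pool:
            if take >= want:
                break
            key = (entry[0], entry[1])
            if key in seen:
                continue
            seen.add(key)
            chosen.append(entry)
            take += 1
        if take < want:
            raise ValueError(
                f"not enough {region} adenosines to plant {want} sites; "
                "enlarge the genome"
            )

    class_counts = _class_counts(n_sites, fractions)
    classes: list[str] = []
    for name, cnt in class_counts.items():
        classes.extend([name] * cnt)
    classes = [classes[i] for i in rng.permutation(n_sites)]

    rows = []
    for (chrom, pos, strand, gene, region), cls in zip(chosen, classes):
        c = {"p110": 0.0, "p150": 0.0, "ADAR2": 0.0}
        if cls == "p110_only":
            c["p110"] = rng.uniform(0.35, 0.90)
        elif cls == "ADAR2_only":
            c["ADAR2"] = rng.uniform(0.35, 0.90)
        elif cls == "redundant":
            c["p110"] = rng.uniform(0.60, 0.90)
            c["ADAR2"] = rng.uniform(0.60, 0.90)
        elif cls == "p150_only":
            c["p150"] = rng.uniform(0.60, 0.90)
        else:
            raise ValueError(f"unknown enzyme class {cls!r}")
        rows.append((chrom, pos, strand, gene, region, cls,
                     c["p110"], c["p150"], c["ADAR2"]))
    rows.sort()
    table = pd.DataFrame(
        rows,
        columns=["chrom", "pos", "strand", "gene_id", "region", "enzyme_class",
                 "c_p110", "c_p150", "c_ADAR2"],
    )
    table.insert(0, "site_id", [f"site{i:04d}" for i in range(len(table))])
    return table[TRUTH_COLUMNS]


def truth_contributions(row) -> dict[str, float]:
    return {"p110": row.c_p110, "p150": row.c_p150, "ADAR2": row.c_ADAR2}


def write_truth_table(truth: pd.DataFrame, path: str) -> None:
    truth.to_csv(path, sep="\t", index=False)


def read_truth_table(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# ------------------------------------------------------------- known-site files

DB_COLUMNS = ["chromosome", "position", "strand", "source", "assembly"]


def write_known_sites(
    truth: pd.DataFrame,
    path: str,
    source: str,
    assembly: str,
    seed: int,
    genome: Optional[SimGenome] = None,
    include_fraction: float = 1.0,
    n_decoys: int = 0,
    position_shift: int = 0,
) -> None:
    """Write a DARNED/RADAR-style known-editing-site table.

    ``position_shift`` writes every coordinate shifted by a constant, which —
    together with :func:`write_shift_chain` — emulates a database published on
    an older assembly that must be lifted over before use.  Decoy entries are
    registered adenosines that are not edited in the simulated tissue.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for row in truth.itertuples():
        if rng.random() <= include_fraction:
            rows.append((row.chrom, row.pos + position_shift, row.strand,
                         source, assembly))
    if n_decoys and genome is not None:
        truth_keys = set(zip(truth.chrom, truth.pos))
        chroms = sorted(genome.chromosomes)
        made = 0
        while made < n_decoys:
            chrom = chroms[int(rng.integers(0, len(chroms)))]
            seq = genome.chromosomes[chrom]
            pos = int(rng.integers(1, len(seq) + 1))
            strand = "+" if rng.random() < 0.5 else "-"
            base = seq[pos - 1]
            if (strand == "+" and base != "A") or (strand == "-" and base != "T"):
                continue
            if (chrom, pos) in truth_keys:
                continue
            rows.append((chrom, pos + position_shift, strand, source, assembly))
            made += 1
    df = pd.DataFrame(sorted(set(rows)), columns=DB_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def write_shift_chain(
    genome: SimGenome,
    path: str,
    shift: int,
) -> None:
    """UCSC chain file lifting "old assembly" coordinates (pos + shift) back.

    One chain per chromosome: old coordinates start at ``shift`` (0-based) and
    map block-for-block onto the current assembly.
    """
    with open(path, "w") as fh:
        for i, (chrom, seq) in enumerate(sorted(genome.chromosomes.items()), 1):
            L = len(seq)
            old_size = L + shift
            fh.write(
                f"chain 1000 {chrom} {old_size} + {shift} {shift + L} "
                f"{chrom} {L} + 0 {L} {i}\n"
            )
            fh.write(f"{L}\n\n")


# ------------------------------------------------------------------- RNA-seq sim


@dataclass
class _Template:
    """A transcription template (spliced mRNA or unspliced pre-mRNA).

    ``seq`` is gene-strand sense; ``gpos[i]`` is the 1-based genomic position
    of template base i (ascending for '+' genes, descending for '-').
    ``sites`` maps template index -> (site_id, realized_ratio).
    """

    transcript: Transcript
    seq: list
    gpos: np.ndarray
    sites: dict


def _build_template(
    genome: SimGenome,
    t: Transcript,
    spliced: bool,
    site_ratio: Mapping[tuple, tuple],
) -> _Template:
    seq_fwd_parts = []
    pos_parts = []
    chrom_seq = genome.chromosomes[t.chrom]
    blocks = t.exons if spliced else (t.span,)
    for s, e in blocks:
        seq_fwd_parts.append(chrom_seq[s - 1 : e])
        pos_parts.append(np.arange(s, e + 1))
    seq_fwd = "".join(seq_fwd_parts)
    gpos = np.concatenate(pos_parts)
    if t.strand == "+":
        seq = list(seq_fwd)
    else:
        seq = list(revcomp(seq_fwd))
        gpos = gpos[::-1]
    index_of = {int(p): i for i, p in enumerate(gpos)}
    sites = {}
    for (chrom, pos), (site_id, ratio) in site_ratio.items():
        if chrom == t.chrom and pos in index_of:
            sites[index_of[pos]] = (site_id, ratio)
    return _Template(t, seq, gpos, sites)


def _blocks_from_positions(positions: np.ndarray) -> list[tuple[int, int]]:
    """Group ascending genomic positions into (start, length) runs."""
    blocks = []
    run_start = int(positions[0])
    prev = run_start
    for p in positions[1:]:
        p = int(p)
        if p == prev + 1:
            prev = p
        else:
            blocks.append((run_start, prev - run_start + 1))
            run_start = p
            prev = p
    blocks.append((run_start, prev - run_start + 1))
    return blocks


def _cigar_from_blocks(blocks: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """pysam cigartuples (M/N only) for a list of aligned blocks."""
    cig = []
    for i, (start, length) in enumerate(blocks):
        if i > 0:
            gap = start - (blocks[i - 1][0] + blocks[i - 1][1])
            cig.append((3, gap))  # N
        cig.append((0, length))  # M
    return cig


_ERROR_OTHER = {
    "A": "CGT", "C": "AGT", "G": "ACT", "T": "ACG",
}


def _apply_errors(seq: list, rng: np.random.Generator, error_rate: float) -> None:
    if error_rate <= 0:
        return
    n = len(seq)
    hits = np.nonzero(rng.random(n) < error_rate)[0]
    for i in hits:
        seq[i] = _ERROR_OTHER[seq[i]][int(rng.integers(0, 3))]


def simulate_reads(
    genome: SimGenome,
    models: GeneModels,
    truth: pd.DataFrame,
    genotype: Genotype,
    out_sam: str,
    depth: float = 60.0,
    read_length: int = 100,
    error_rate: float = 0.001,
    intron_fraction: float = 0.3,
    fragment_mean: float = 300.0,
    fragment_sd: float = 30.0,
    base_quality: int = 30,
    seed: int = 0,
    out_fastq1: Optional[str] = None,
    out_fastq2: Optional[str] = None,
) -> int:
    """Simulate strand-preserving paired-end RNA-seq and write a sorted SAM.

    Fragments sample spliced mRNA and, with probability ``intron_fraction``
    of the fragment mass, unspliced pre-mRNA, so intronic editing sites get
    roughly ``depth * intron_fraction`` coverage while exonic positions get
    ``depth``.  Editing status is decided per fragment (both mates of one
    molecule agree); edited positions read G on the gene strand.  Returns the
    number of read records written.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if read_length < 30:
        raise ValueError("read_length must be >= 30")
    if len(models) == 0:
        raise ValueError("no transcripts to simulate from")

    rng = np.random.default_rng(seed)
    site_ratio = {
        (row.chrom, row.pos): (
            row.site_id,
            realized_ratio(truth_contributions(row), genotype),
        )
        for row in truth.itertuples()
    }

    lengths = genome.lengths()
    chrom_names = sorted(lengths)
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [{"SN": c, "LN": lengths[c]} for c in chrom_names],
        }
    )
    tid_of = {c: i for i, c in enumerate(chrom_names)}

    records = []
    fastq1: list[tuple[str, str, str]] = []
    fastq2: list[tuple[str, str, str]] = []
    qual_str = chr(33 + base_quality) * read_length
    quals = pysam.qualitystring_to_array(qual_str)

    for t in models.transcripts:
        for spliced in (True, False):
            tpl = _build_template(genome, t, spliced, site_ratio)
            L = len(tpl.seq)
            if L < read_length:
                continue
            frac = (1.0 - intron_fraction) if spliced else intron_fraction
            if frac <= 0:
                continue
            n_frag = int(math.ceil(depth * frac * L / (2.0 * read_length)))
            tag = "m" if spliced else "p"
            for fi in range(n_frag):
                fl = int(round(rng.normal(fragment_mean, fragment_sd)))
                fl = max(read_length, min(fl, L))
                start = int(rng.integers(0, L - fl + 1))
                name = f"{t.transcript_id}:{tag}{fi}"
                edited = {}
                for tpos, (sid, ratio) in tpl.sites.items():
                    if start <= tpos < start + fl and rng.random() < ratio:
                        edited[tpos] = True

                r1 = tpl.seq[start : start + read_length]
                r2_tpl = tpl.seq[start + fl - read_length : start + fl]
                for tpos in edited:
                    if start <= tpos < start + read_length:
                        r1[tpos - start] = "G"
                    off2 = tpos - (start + fl - read_length)
                    if 0 <= off2 < read_length:
                        r2_tpl[off2] = "G"
                # r1/r2_tpl are copies (list slices); errors are independent
                _apply_errors(r1, rng, error_rate)
                _apply_errors(r2_tpl, rng, error_rate)

                seq1 = "".join(r1)
                seq2_tpl = "".join(r2_tpl)
                # as-sequenced read2 is the reverse complement of the
                # template 3' slice
                fastq1.append((name, seq1, qual_str))
                fastq2.append((name, revcomp(seq2_tpl), qual_str))

                for mate, (tslice_start, seq_tpl) in enumerate(
                    ((start, seq1), (start + fl - read_length, seq2_tpl))
                ):
                    positions = tpl.gpos[tslice_start : tslice_start + read_length]
                    if t.strand == "+":
                        genome_seq = seq_tpl
                        asc = positions
                    else:
                        genome_seq = revcomp(seq_tpl)
                        asc = positions[::-1]
                    blocks = _blocks_from_positions(asc)
                    a = pysam.AlignedSegment(header)
                    a.query_name = name
                    a.query_sequence = genome_seq
                    a.query_qualities = quals
                    a.reference_id = tid_of[t.chrom]
                    a.reference_start = blocks[0][0] - 1
                    a.cigartuples = _cigar_from_blocks(blocks)
                    a.mapping_quality = 60
                    is_read1 = mate == 0
                    # library is strand-preserving: read1 carries the gene
                    # strand, read2 the opposite
                    read_on_minus = (t.strand == "-") == is_read1
                    flag = 0x1 | 0x2
                    flag |= 0x40 if is_read1 else 0x80
                    if read_on_minus:
                        flag |= 0x10
                    else:
                        flag |= 0x20
                    a.flag = flag
                    records.append((t.chrom, a))

    # mate coordinates and template lengths
    by_name: dict[str, list[pysam.AlignedSegment]] = {}
    for _chrom, a in records:
        by_name.setdefault(a.query_name, []).append(a)
    for name, pair in by_name.items():
        if len(pair) != 2:
            continue
        a, b = pair
        a.next_reference_id = b.reference_id
        b.next_reference_id = a.reference_id
        a.next_reference_start = b.reference_start
        b.next_reference_start = a.reference_start
        left = min(a.reference_start, b.reference_start)
        right = max(a.reference_end, b.reference_end)
        span = right - left
        for seg in (a, b):
            seg.template_length = span if seg.reference_start == left else -span
        if a.reference_start == b.reference_start:
            a.template_length = span
            b.template_length = -span

    records.sort(key=lambda item: (item[1].reference_id,
                                   item[1].reference_start,
                                   item[1].query_name,
                                   item[1].flag))
    with pysam.AlignmentFile(out_sam, "w", header=header) as fh:
        for _chrom, a in records:
            fh.write(a)

    for path, rows in ((out_fastq1, fastq1), (out_fastq2, fastq2)):
        if path is not None:
            with open(path, "w") as fh:
                for name, seq, qual in rows:
                    fh.write(f"@{name}\n{seq}\n+\n{qual}\n")
    return len(records)


# ------------------------------------------------------------- targeted assays

ION_A_ADAPTOR = "CCATCTCATCCCTGCGTGTCTCCGACTCAG"
TRP1_ADAPTOR = "CCTCTCTATGGGCAGTCGGTGAT"


@dataclass(frozen=True)
class AmpliconDesign:
    """A targeted amplicon: reference sequence plus the assayed site offset.

    ``target_offset`` is 0-based within ``sequence`` and must point at an A
    (the amplicon is laid out in gene-strand sense, so editing reads as G).
    """

    amplicon_id: str
    sequence: str
    target_offset: int
    adaptor5: str = ION_A_ADAPTOR
    barcode: str = "CTAAGGTAAC"
    adaptor3: str = TRP1_ADAPTOR

    def __post_init__(self):
        if not (0 <= self.target_offset < len(self.sequence)):
            raise ValueError("target_offset outside amplicon")
        if self.sequence[self.target_offset] != "A":
            raise ValueError("amplicon base at target_offset must be A")


def write_amplicon_designs(designs: Sequence[AmpliconDesign], path: str) -> None:
    df = pd.DataFrame(
        [
            (d.amplicon_id, d.sequence, d.target_offset, d.adaptor5, d.barcode,
             d.adaptor3)
            for d in designs
        ],
        columns=["amplicon_id", "sequence", "target_offset", "adaptor5",
                 "barcode", "adaptor3"],
    )
    df.to_csv(path, sep="\t", index=False)


def read_amplicon_designs(path: str) -> list[AmpliconDesign]:
    df = pd.read_csv(path, sep="\t")
    return [
        AmpliconDesign(r.amplicon_id, r.sequence, int(r.target_offset),
                       r.adaptor5, r.barcode, r.adaptor3)
        for r in df.itertuples()
    ]


def simulate_amplicon_reads(
    design: AmpliconDesign,
    true_ratio: float,
    n_reads: int,
    error_rate: float,
    seed: int,
    out_fastq: Optional[str] = None,
    base_quality: int = 30,
) -> list[tuple[str, str, str]]:
    """Amplicon reads: 5' adaptor + barcode + amplicon (+ 3' adaptor).

    The target base reads G with probability ``true_ratio``, A otherwise;
    uniform sequencing errors are then applied over the whole read.
    """
    if not (0.0 <= true_ratio <= 1.0):
        raise ValueError("true_ratio outside [0, 1]")
    rng = np.random.default_rng(seed)
    reads = []
    prefix = design.adaptor5 + design.barcode
    for i in range(n_reads):
        amp = list(design.sequence)
        if rng.random() < true_ratio:
            amp[design.target_offset] = "G"
        read = list(prefix) + amp + list(design.adaptor3)
        _apply_errors(read, rng, error_rate)
        seq = "".join(read)
        qual = chr(33 + base_quality) * len(seq)
        reads.append((f"{design.amplicon_id}:{i}", seq, qual))
    if out_fastq is not None:
        with open(out_fastq, "w") as fh:
            for name, seq, qual in reads:
                fh.write(f"@{name}\n{seq}\n+\n{qual}\n")
    return reads


@dataclass(frozen=True)
class ChromatogramPeaks:
    """Peak heights (arbitrary units) at one chromatogram base position."""

    A: float
    C: float
    G: float
    T: float

    def __post_init__(self):
        for b in ("A", "C", "G", "T"):
            if getattr(self, b) < 0:
                raise ValueError("peak heights must be >= 0")


def simulate_chromatogram(
    true_ratio: float,
    scale: float = 100.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> ChromatogramPeaks:
    """Sanger-style peak heights: G ~ scale*ratio, A ~ scale*(1-ratio)."""
    if scale <= 0:
        raise ValueError("scale must be > 0")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, noise_sd, size=4) if noise_sd > 0 else np.zeros(4)
    return ChromatogramPeaks(
        A=max(0.0, scale * (1.0 - true_ratio) + noise[0]),
        C=max(0.0, noise[1]),
        G=max(0.0, scale * true_ratio + noise[2]),
        T=max(0.0, noise[3]),
    )


# ---------------------------------------------------------------- mirror study


def mirror_genome(genome: SimGenome) -> SimGenome:
    return SimGenome(
        {c: revcomp(s) for c, s in genome.chromosomes.items()}, genome.seed
    )


def mirror_position(length: int, pos: int) -> int:
    return length - pos + 1


def mirror_models(models: GeneModels, genome: SimGenome) -> GeneModels:
    out = []
    for t in models.transcripts:
        L = len(genome.chromosomes[t.chrom])
        exons = tuple(
            sorted((mirror_position(L, e), mirror_position(L, s)) for s, e in t.exons)
        )
        cds = None
        if t.cds is not None:
            cds = (mirror_position(L, t.cds[1]), mirror_position(L, t.cds[0]))
        out.append(
            Transcript(t.transcript_id, t.gene_id, t.chrom,
                       "-" if t.strand == "+" else "+", exons, cds)
        )
    return GeneModels(out)


def mirror_truth(truth: pd.DataFrame, genome: SimGenome) -> pd.DataFrame:
    out = truth.copy()
    lengths = genome.lengths()
    out["pos"] = [
        mirror_position(lengths[c], p) for c, p in zip(out.chrom, out.pos)
    ]
    out["strand"] = ["-" if s == "+" else "+" for s in out.strand]
    return out.sort_values(["chrom", "pos"]).reset_index(drop=True)


def mirror_sam(in_sam: str, out_sam: str, genome: SimGenome) -> None:
    """Rewrite a SAM file onto the reverse-complemented genome.

    Every record keeps its identity: position reflected, sequence
    reverse-complemented, CIGAR reversed, strand flags flipped.  Mates are
    processed together so mate coordinates stay consistent.
    """
    lengths = genome.lengths()
    with pysam.AlignmentFile(in_sam, "r") as fh:
        header = fh.header.to_dict()
        reads = list(fh)
    new_header = pysam.AlignmentHeader.from_dict(header)
    refname = {i: sq["SN"] for i, sq in enumerate(header["SQ"])}

    def flip(a: pysam.AlignedSegment) -> pysam.AlignedSegment:
        L = lengths[refname[a.reference_id]]
        b = pysam.AlignedSegment(new_header)
        b.query_name = a.query_name
        b.query_sequence = revcomp(a.query_sequence)
        qq = list(a.query_qualities)[::-1]
        b.query_qualities = pysam.qualitystring_to_array(
            "".join(chr(33 + q) for q in qq)
        )
        span = a.reference_end - a.reference_start  # 0-based half-open
        b.reference_id = a.reference_id
        b.reference_start = L - (a.reference_start + span)
        b.cigartuples = list(a.cigartuples)[::-1]
        b.mapping_quality = a.mapping_quality
        flag = a.flag
        flag ^= 0x10 | 0x20  # flip own and mate strand
        b.flag = flag
        return b

    by_name: dict[str, list[pysam.AlignedSegment]] = {}
    for a in reads:
        by_name.setdefault(a.query_name, []).append(a)
    flipped: list[pysam.AlignedSegment] = []
    for name, pair in by_name.items():
        new = [flip(a) for a in pair]
        if len(new) == 2:
            x, y = new
            x.next_reference_id = y.reference_id
            y.next_reference_id = x.reference_id
            x.next_reference_start = y.reference_start
            y.next_reference_start = x.reference_start
            left = min(x.reference_start, y.reference_start)
            right = max(x.reference_end, y.reference_end)
            span = right - left
            x.template_length = span if x.reference_start == left else -span
            y.template_length = -x.template_length if span else 0
        flipped.extend(new)
    flipped.sort(key=lambda a: (a.reference_id, a.reference_start,
                                a.query_name, a.flag))
    with pysam.AlignmentFile(out_sam, "w", header=new_header) as fh:
        for a in flipped:
            fh.write(a)


def mirror_known_sites(db_path: str, out_path: str, genome: SimGenome) -> None:
    df = pd.read_csv(db_path, sep="\t")
    lengths = genome.lengths()
    df["position"] = [
        mirror_position(lengths[c], p)
        for c, p in zip(df.chromosome, df.position)
    ]
    df["strand"] = ["-" if s == "+" else "+" for s in df.strand]
    df = df.sort_values(["chromosome", "position"]).reset_index(drop=True)
    df.to_csv(out_path, sep="\t", index=False)
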
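"""Gene models: transcripts with exon/CDS structure, derived regions, GTF I/O.

Coordinates are 1-based inclusive on the genome everywhere user-facing.
Region vocabulary is the one used for editing-site annotation:
``5'UTR``, ``CDS``, ``3'UTR``, ``intron`` plus the fallback ``others`` for
positions outside any transcript (or inside non-coding exons).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

from intervaltree import IntervalTree

Interval = tuple[int, int]  # 1-based, inclusive on both ends

REGION_5UTR = "5'UTR"
REGION_CDS = "CDS"
REGION_3UTR = "3'UTR"
REGION_INTRON = "intron"
REGION_OTHERS = "others"
REGION_LABELS = (REGION_CDS, REGION_5UTR, REGION_3UTR, REGION_INTRON, REGION_OTHERS)


def _check_interval(iv: Interval) -> None:
    if iv[0] > iv[1] or iv[0] < 1:
        raise ValueError(f"invalid interval {iv}")


@dataclass(frozen=True)
class Transcript:
    """A transcript model: ordered non-overlapping exons plus an optional CDS span.

    ``cds`` is the genomic interval from start codon to stop codon (both
    strands use genomic left/right order); it must lie inside the exon union.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: tuple[Interval, ...]
    cds: Optional[Interval] = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r}")
        if not self.exons:
            raise ValueError("transcript requires at least one exon")
        prev_end = 0
        for iv in self.exons:
            _check_interval(iv)
            if iv[0] <= prev_end:
                raise ValueError("exons must be sorted and non-overlapping")
            prev_end = iv[1]
        if self.cds is not None:
            _check_interval(self.cds)
            if not all(
                any(e[0] <= p <= e[1] for e in self.exons)
                for p in (self.cds[0], self.cds[1])
            ):
                raise ValueError("CDS boundaries must fall inside exons")

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def span(self) -> Interval:
        return (self.start, self.end)

    def introns(self) -> list[Interval]:
        out = []
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            out.append((e1 + 1, s2 - 1))
        return out

    def regions(self) -> dict[str, list[Interval]]:
        """Partition the transcript span into UTRs, CDS pieces and introns.

        For a coding transcript the returned intervals tile ``span`` exactly.
        A transcript without CDS yields only introns (exons are unclassified).
        """
        out: dict[str, list[Interval]] = {
            REGION_5UTR: [],
            REGION_CDS: [],
            REGION_3UTR: [],
            REGION_INTRON: list(self.introns()),
        }
        if self.cds is None:
            return out
        cs, ce = self.cds
        left = REGION_5UTR if self.strand == "+" else REGION_3UTR
        right = REGION_3UTR if self.strand == "+" else REGION_5UTR
        for s, e in self.exons:
            if e < cs:
                out[left].append((s, e))
            elif s > ce:
                out[right].append((s, e))
            else:
                if s < cs:
                    out[left].append((s, cs - 1))
                if e > ce:
                    out[right].append((ce + 1, e))
                out[REGION_CDS].append((max(s, cs), min(e, ce)))
        return out

    def region_at(self, pos: int) -> Optional[str]:
        """Region label at a genomic position, or None if outside the span."""
        if not (self.start <= pos <= self.end):
            return None
        for label, ivs in self.regions().items():
            for s, e in ivs:
                if s <= pos <= e:
                    return label
        return None  # exon of a non-coding transcript


class GeneModels:
    """An indexed collection of transcripts with position lookup."""

    def __init__(self, transcripts: Iterable[Transcript]):
        self.transcripts: list[Transcript] = sorted(
            transcripts, key=lambda t: (t.chrom, t.start, t.transcript_id)
        )
        self.by_gene: dict[str, list[Transcript]] = {}
        self._trees: dict[str, IntervalTree] = {}
        for t in self.transcripts:
            self.by_gene.setdefault(t.gene_id, []).append(t)
            tree = self._trees.setdefault(t.chrom, IntervalTree())
            tree[t.start : t.end + 1] = t

    def __len__(self) -> int:
        return len(self.transcripts)

    def transcripts_at(self, chrom: str, pos: int) -> list[Transcript]:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        hits = [iv.data for iv in tree[pos]]
        return sorted(hits, key=lambda t: (t.start, t.transcript_id))

    def genes_at(self, chrom: str, pos: int) -> dict[str, list[Transcript]]:
        out: dict[str, list[Transcript]] = {}
        for t in self.transcripts_at(chrom, pos):
            out.setdefault(t.gene_id, []).append(t)
        return out

    # ------------------------------------------------------------------ GTF IO

    def write_gtf(self, path: str, source: str = "editome") -> None:
        with open(path, "w") as fh:
            for t in self.transcripts:
                attrs = f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}";'
                fh.write(
                    "\t".join(
                        [t.chrom, source, "transcript", str(t.start), str(t.end),
                         ".", t.strand, ".", attrs]
                    )
                    + "\n"
                )
                for s, e in t.exons:
                    fh.write(
                        "\t".join(
                            [t.chrom, source, "exon", str(s), str(e), ".",
                             t.strand, ".", attrs]
                        )
                        + "\n"
                    )
                if t.cds is not None:
                    fh.write(
                        "\t".join(
                            [t.chrom, source, "CDS", str(t.cds[0]), str(t.cds[1]),
                             ".", t.strand, ".", attrs]
                        )
                        + "\n"
                    )

    @classmethod
    def read_gtf(cls, path: str) -> "GeneModels":
        exons: dict[str, list[Interval]] = {}
        cds: dict[str, list[Interval]] = {}
        meta: dict[str, tuple[str, str, str]] = {}  # tid -> (gene, chrom, strand)
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                if not line.strip() or line.startswith("#"):
                    continue
                fields = line.rstrip("\n").split("\t")
                if len(fields) != 9:
                    raise ValueError(f"{path}:{lineno}: expected 9 GTF columns")
                chrom, _src, feature, start, end, _score, strand, _frame, attrs = fields
                if feature not in ("exon", "CDS"):
                    continue
                tid = _gtf_attr(attrs, "transcript_id", path, lineno)
                gid = _gtf_attr(attrs, "gene_id", path, lineno)
                meta.setdefault(tid, (gid, chrom, strand))
                target = exons if feature == "exon" else cds
                target.setdefault(tid, []).append((int(start), int(end)))
        transcripts = []
        for tid, (gid, chrom, strand) in meta.items():
            exs = tuple(sorted(exons.get(tid, [])))
            cds_ivs = sorted(cds.get(tid, []))
            cds_iv = (cds_ivs[0][0], cds_ivs[-1][1]) if cds_ivs else None
            transcripts.append(
                Transcript(tid, gid, chrom, strand, exs, cds_iv)
            )
        return cls(transcripts)


def _gtf_attr(attrs: str, key: str, path: str, lineno: int) -> str:
    for chunk in attrs.split(";"):
        chunk = chunk.strip()
        if chunk.startswith(key + " "):
            return chunk.split(" ", 1)[1].strip('"')
    raise ValueError(f"{path}:{lineno}: missing GTF attribute {key!r}")
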
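"""Union-exon gene models for gene-level read counting.

Digital gene expression counts a read toward a gene when the read's start
position falls inside the gene's exons.  For that to be well defined each
gene needs a single, non-redundant set of intervals: exons from all of a
gene's annotated transcripts are merged into disjoint "union exons", and
because the library preparation is not strand specific, every interval
shared between two or more genes is excised from *all* of them so that no
base can be attributed to more than one gene.

Coordinates are 0-based half-open everywhere inside the package; GTF/TSV
input and BED output are converted at the file boundary only (GTF is
1-based inclusive, BED is 0-based half-open).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

from gffutils.feature import feature_from_line

logger = logging.getLogger(__name__)

Interval = tuple[int, int]  # 0-based half-open, start < end


@dataclass(frozen=True)
class ExonRecord:
    """One annotated exon (1-based inclusive coordinates, GTF convention)."""

    gene_id: str
    transcript_id: str
    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"exon for {self.gene_id} has start > end ({self.start} > {self.end})"
            )
        if not self.chrom:
            raise ValueError(f"exon for {self.gene_id} has empty chrom")


@dataclass
class GeneModel:
    """A gene's union-exon model: sorted, pairwise-disjoint intervals."""

    gene_id: str
    chrom: str
    strand: str
    intervals: list[Interval] = field(default_factory=list)

    @property
    def length(self) -> int:
        return sum(e - s for s, e in self.intervals)


@dataclass
class GeneModelSet:
    """Per-gene union-exon models plus the intervals excised for inter-gene overlap."""

    genes: dict[str, GeneModel]
    removed_intervals: list[tuple[str, Interval]] = field(default_factory=list)

    def union_exon_length(self, gene_id: str) -> int:
        return self.genes[gene_id].length

    def __len__(self) -> int:
        return len(self.genes)


def read_exon_annotation(path: str | Path, fmt: str | None = None) -> list[ExonRecord]:
    """Read exon annotations from a GTF/GFF file or a 6-column TSV.

    TSV columns: gene_id, transcript_id, chrom, start, end, strand with
    1-based inclusive coordinates.  Non-exon GTF feature rows are ignored.
    Malformed rows (missing gene_id/transcript_id, start > end) are skipped
    and logged with their line number.
    """
    path = Path(path)
    if fmt is None:
        fmt = "gtf" if path.suffix.lower() in {".gtf", ".gff", ".gff3"} else "tsv"
    records: list[ExonRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            try:
                rec = _parse_line(line, fmt)
            except ValueError as exc:
                logger.warning("%s line %d skipped: %s", path.name, lineno, exc)
                continue
            if rec is not None:
                records.append(rec)
    return records


def _parse_line(line: str, fmt: str) -> ExonRecord | None:
    if fmt == "gtf":
        feat = feature_from_line(line)
        if feat.featuretype != "exon":
            return None
        attrs = feat.attributes
        if "gene_id" not in attrs or "transcript_id" not in attrs:
            raise ValueError("exon row missing gene_id/transcript_id attribute")
        return ExonRecord(
            gene_id=attrs["gene_id"][0],
            transcript_id=attrs["transcript_id"][0],
            chrom=feat.seqid,
            start=feat.start,
            end=feat.end,
            strand=feat.strand if feat.strand in "+-" else "+",
        )
    fields = line.split("\t")
    if len(fields) < 6:
        raise ValueError(f"expected 6 TSV columns, got {len(fields)}")
    gene, tx, chrom, start, end, strand = fields[:6]
    if not gene or not tx:
        raise ValueError("row missing gene_id/transcript_id")
    return ExonRecord(gene, tx, chrom, int(start), int(end), strand)


def merge_intervals(intervals: list[Interval]) -> list[Interval]:
    """Merge overlapping or book-ended half-open intervals into maximal runs."""
    if not intervals:
        return []
    out: list[Interval] = []
    for s, e in sorted(intervals):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def build_union_exons(annotations: list[ExonRecord]) -> GeneModelSet:
    """Merge each gene's exons across transcripts into disjoint union exons.

    Raises ``ValueError`` for a gene annotated on more than one chromosome.
    """
    if not annotations:
        raise ValueError("no exon annotations supplied")
    by_gene: dict[str, list[ExonRecord]] = {}
    for rec in annotations:
        by_gene.setdefault(rec.gene_id, []).append(rec)
    genes: dict[str, GeneModel] = {}
    for gene_id, recs in by_gene.items():
        chroms = {r.chrom for r in recs}
        if len(chroms) > 1:
            raise ValueError(
                f"gene {gene_id} has exons on multiple chromosomes: {sorted(chroms)}"
            )
        # 1-based inclusive -> 0-based half-open at this boundary.
        ivals = merge_intervals([(r.start - 1, r.end) for r in recs])
        genes[gene_id] = GeneModel(gene_id, recs[0].chrom, recs[0].strand, ivals)
    return GeneModelSet(genes=genes)


def remove_intergene_overlaps(models: GeneModelSet) -> GeneModelSet:
    """Excise every base covered by union exons of two or more genes.

    Strand is ignored (the protocol is unstranded): opposite-strand overlaps
    are removed like same-strand ones.  Genes reduced to zero length are kept
    with an empty interval list so downstream filters can account for them.
    Applying the operation twice equals applying it once.
    """
    by_chrom: dict[str, list[Interval]] = {}
    for gm in models.genes.values():
        by_chrom.setdefault(gm.chrom, []).extend(gm.intervals)
    shared_by_chrom: dict[str, list[Interval]] = {}
    for chrom, ivals in by_chrom.items():
        shared_by_chrom[chrom] = _multicover_regions(ivals)
    new_genes: dict[str, GeneModel] = {}
    for gene_id, gm in models.genes.items():
        kept = _subtract(gm.intervals, shared_by_chrom.get(gm.chrom, []))
        new_genes[gene_id] = GeneModel(gene_id, gm.chrom, gm.strand, kept)
    removed = sorted(
        [(chrom, iv) for chrom, ivs in shared_by_chrom.items() for iv in ivs]
    )
    return GeneModelSet(genes=new_genes, removed_intervals=removed)


def _multicover_regions(intervals: list[Interval]) -> list[Interval]:
    """Merged regions covered by >= 2 of the given intervals (sweep line).

    Within one gene the union-exon intervals are already disjoint, so each
    interval contributes coverage for exactly one gene.
    """
    events: list[tuple[int, int]] = []
    for s, e in intervals:
        events.append((s, 1))
        events.append((e, -1))
    events.sort()
    out: list[Interval] = []
    depth = 0
    prev = None
    for pos, delta in events:
        if depth >= 2 and prev is not None and pos > prev:
            out.append((prev, pos))
        depth += delta
        prev = pos
    return merge_intervals(out)


def _subtract(intervals: list[Interval], cut: list[Interval]) -> list[Interval]:
    """Set difference of disjoint sorted interval lists."""
    out: list[Interval] = []
    j = 0
    for s, e in intervals:
        cur = s
        while j < len(cut) and cut[j][1] <= cur:
            j += 1
        k = j
        while k < len(cut) and cut[k][0] < e:
            cs, ce = cut[k]
            if cs > cur:
                out.append((cur, cs))
            cur = max(cur, ce)
            k += 1
        if cur < e:
            out.append((cur, e))
    return out


def write_union_bed(models: GeneModelSet, path: str | Path) -> None:
    """Write union exons as BED-like TSV: chrom, start0, end0, gene_id."""
    rows = []
    for gm in models.genes.values():
        for s, e in gm.intervals:
            rows.append((gm.chrom, s, e, gm.gene_id))
    rows.sort()
    with open(path, "w") as fh:
        for chrom, s, e, gid in rows:
            fh.write(f"{chrom}\t{s}\t{e}\t{gid}\n")


def write_removed_bed(models: GeneModelSet, path: str | Path) -> None:
    """Write the intervals excised for inter-gene overlap as BED-like TSV."""
    with open(path, "w") as fh:
        for chrom, (s, e) in sorted(models.removed_intervals):
            fh.write(f"{chrom}\t{s}\t{e}\n")


def read_union_bed(path: str | Path) -> GeneModelSet:
    """Read a union-exon BED-like TSV written by :func:`write_union_bed`."""
    genes: dict[str, GeneModel] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            chrom, s, e, gid = line.rstrip("\n").split("\t")[:4]
            if gid not in genes:
                genes[gid] = GeneModel(gid, chrom, "+", [])
            genes[gid].intervals.append((int(s), int(e)))
    for gm in genes.values():
        gm.intervals.sort()
    return GeneModelSet(genes=genes)
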
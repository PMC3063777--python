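"""Allele-mapping-bias assessment via a SNP-substituted strain genome.

Reads from a non-reference strain (D2) carry SNP alleles that consume the
aligner's mismatch budget when mapped to the reference (B6) sequence, so
SNP-dense genes lose D2 reads and masquerade as differentially expressed
with B6 > D2.  The remedy mirrors the original analysis: write the D2
alleles into the reference to build a synthetic D2 sequence ('N'-masked
positions stay 'N'), realign only the D2 reads to it, re-run counting and
the exact test on the same gene universe, and classify each gene's change
in DE status between the two runs.  Genes that lose a B6>D2 call are
putative false positives of allele bias; genes that gain a D2>B6 call are
putative false negatives.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import pysam

from .align_count import (
    Alignment,
    CountMatrix,
    ReferenceGenome,
    SeedAligner,
    ShortRead,
    count_reads,
    filter_genes,
    trim_reads,
)
from .diffexpr import Q_THRESHOLD, run_exact_de
from .gene_models import GeneModelSet

logger = logging.getLogger(__name__)

STATUS_CATEGORIES = (
    "retained_B6gtD2",
    "lost_B6gtD2",
    "retained_D2gtB6",
    "lost_D2gtB6",
    "gained_D2gtB6",
    "gained_B6gtD2",
    "stable_nonDE",
    "direction_flip",
)


@dataclass(frozen=True)
class SnpRecord:
    chrom: str
    pos: int  # 1-based
    ref_allele: str
    alt_allele: str

    def __post_init__(self) -> None:
        if self.ref_allele == self.alt_allele:
            raise ValueError(f"SNP at {self.chrom}:{self.pos} has ref == alt")
        if len(self.ref_allele) != 1 or len(self.alt_allele) != 1:
            raise ValueError(f"record at {self.chrom}:{self.pos} is not a single-base SNP")


@dataclass
class BiasAssessment:
    """Per-gene DE status-change classification between the two runs."""

    table: pd.DataFrame  # index gene_id; columns status, snps_per_kb
    category_counts: dict[str, int]
    direction_flips: int
    unmatched_genes: list[str] = field(default_factory=list)


@dataclass
class AlleleBiasResult:
    assessment: BiasAssessment
    de_before: pd.DataFrame
    de_after: pd.DataFrame
    mapping_stats: pd.DataFrame  # per sample x run: unique/multi/unmapped
    substitution_report: dict[str, int]
    counts_before: CountMatrix | None = None
    counts_after: CountMatrix | None = None


# ---------------------------------------------------------------------------
# SNP IO


def read_snps(path: str | Path) -> tuple[list[SnpRecord], int]:
    """Read SNPs from a VCF (via pysam) or 4-column TSV (chrom, pos, ref, alt).

    Multi-allelic and non-SNV VCF records are skipped; returns (records,
    number skipped).
    """
    path = Path(path)
    skipped = 0
    records: list[SnpRecord] = []
    if path.suffix.lower() == ".vcf" or path.name.endswith(".vcf.gz"):
        with pysam.VariantFile(str(path)) as vcf:
            for rec in vcf:
                alts = rec.alts or ()
                if len(alts) != 1 or len(rec.ref) != 1 or len(alts[0]) != 1:
                    skipped += 1
                    continue
                records.append(SnpRecord(rec.chrom, rec.pos, rec.ref.upper(), alts[0].upper()))
    else:
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith("#"):
                    continue
                chrom, pos, ref, alt = line.split("\t")[:4]
                ref, alt = ref.strip().upper(), alt.strip().upper()
                if len(ref) != 1 or len(alt) != 1 or ref == alt:
                    skipped += 1
                    continue
                records.append(SnpRecord(chrom, int(pos), ref, alt))
    return records, skipped


def write_snps_vcf(snps: list[SnpRecord], path: str | Path, contigs: dict[str, int] | None = None) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom, length in (contigs or {}).items():
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for s in snps:
            fh.write(f"{s.chrom}\t{s.pos}\t.\t{s.ref_allele}\t{s.alt_allele}\t.\t.\t.\n")


# ---------------------------------------------------------------------------
# genome substitution and SNP density


def build_snp_substituted_genome(
    genome: ReferenceGenome, snps: list[SnpRecord]
) -> tuple[ReferenceGenome, dict[str, int]]:
    """Write the alt allele into the reference at each SNP position.

    Positions where the reference holds 'N' are left 'N' (repeat-masked
    convention); positions where the reference base contradicts the stated
    ref allele are skipped with a warning.  Report keys: substituted,
    skipped_n, skipped_mismatch.  Substitution preserves sequence length.
    """
    seqs = {chrom: bytearray(seq, "ascii") for chrom, seq in genome.items()}
    report = {"substituted": 0, "skipped_n": 0, "skipped_mismatch": 0}
    for snp in snps:
        if snp.chrom not in seqs:
            raise ValueError(f"SNP chrom {snp.chrom} not in genome")
        seq = seqs[snp.chrom]
        idx = snp.pos - 1
        if idx < 0 or idx >= len(seq):
            raise ValueError(f"SNP position {snp.chrom}:{snp.pos} out of bounds")
        base = chr(seq[idx]).upper()
        if base == "N":
            report["skipped_n"] += 1
        elif base != snp.ref_allele:
            logger.warning(
                "SNP %s:%d states ref %s but genome has %s; skipped",
                snp.chrom, snp.pos, snp.ref_allele, base,
            )
            report["skipped_mismatch"] += 1
        else:
            seq[idx] = ord(snp.alt_allele)
            report["substituted"] += 1
    return {chrom: seq.decode("ascii") for chrom, seq in seqs.items()}, report


def snps_per_kb(models: GeneModelSet, snps: list[SnpRecord]) -> pd.Series:
    """SNPs falling in each gene's union exons per kilobase of model length.

    Uses the final (post-overlap-removal) models; zero-length genes are
    excluded (logged).  SNPs in removed inter-gene intervals count for no
    gene.
    """
    counts = {g: 0 for g in models.genes}
    by_chrom: dict[str, list[tuple[int, int, str]]] = {}
    for gm in models.genes.values():
        for s, e in gm.intervals:
            by_chrom.setdefault(gm.chrom, []).append((s, e, gm.gene_id))
    for ivals in by_chrom.values():
        ivals.sort()
    for snp in snps:
        pos0 = snp.pos - 1
        for s, e, gid in by_chrom.get(snp.chrom, []):
            if s <= pos0 < e:
                counts[gid] += 1
                break
            if s > pos0:
                break
    out = {}
    for gid, n in counts.items():
        length = models.union_exon_length(gid)
        if length == 0:
            logger.info("gene %s has zero-length model; SNP density undefined", gid)
            continue
        out[gid] = n / (length / 1000.0)
    return pd.Series(out, name="snps_per_kb")


# ---------------------------------------------------------------------------
# status-change classification


def classify_status_changes(
    de_before: pd.DataFrame,
    de_after: pd.DataFrame,
    q_threshold: float = Q_THRESHOLD,
    snp_density: pd.Series | None = None,
) -> BiasAssessment:
    """Compare per-gene (DE?, direction) between the reference-alignment run
    and the SNP-substituted realignment run.

    retained_*: DE with the same direction in both runs; lost_*: DE before
    only (putative false positives when the direction was B6>D2); gained_*:
    DE after only (putative false negatives when D2>B6); stable_nonDE:
    neither; direction_flip: DE in both runs with opposite directions
    (also tallied separately).  Genes present in only one result set are
    reported in ``unmatched_genes``, not classified.
    """
    common = de_before.index.intersection(de_after.index)
    unmatched = sorted(set(de_before.index).symmetric_difference(de_after.index))
    if unmatched:
        logger.warning("%d genes present in only one DE run", len(unmatched))
    statuses = {}
    flips = 0
    for g in common:
        de_b = de_before.at[g, "q_value"] < q_threshold
        de_a = de_after.at[g, "q_value"] < q_threshold
        dir_b = de_before.at[g, "direction"]
        dir_a = de_after.at[g, "direction"]
        if de_b and de_a:
            if dir_b == dir_a:
                statuses[g] = f"retained_{'B6gtD2' if dir_b == 'B6>D2' else 'D2gtB6'}"
            else:
                statuses[g] = "direction_flip"
                flips += 1
        elif de_b:
            statuses[g] = f"lost_{'B6gtD2' if dir_b == 'B6>D2' else 'D2gtB6'}"
        elif de_a:
            statuses[g] = f"gained_{'B6gtD2' if dir_a == 'B6>D2' else 'D2gtB6'}"
        else:
            statuses[g] = "stable_nonDE"
    table = pd.DataFrame({"status": pd.Series(statuses)})
    table.index.name = "gene_id"
    if snp_density is not None:
        table["snps_per_kb"] = snp_density.reindex(table.index)
    counts = {c: int((table["status"] == c).sum()) for c in STATUS_CATEGORIES}
    return BiasAssessment(
        table=table,
        category_counts=counts,
        direction_flips=flips,
        unmatched_genes=unmatched,
    )


# ---------------------------------------------------------------------------
# the full two-pipeline run


def _mapping_tally(alignments: list[Alignment]) -> pd.DataFrame:
    rows: dict[str, dict[str, int]] = {}
    for a in alignments:
        row = rows.setdefault(a.sample_id, {"unique": 0, "multi": 0, "unmapped": 0})
        row[a.status] += 1
    return pd.DataFrame(rows).T.fillna(0).astype(int)


def run_allele_bias_pipeline(
    genome: ReferenceGenome,
    snps: list[SnpRecord],
    reads_by_sample: dict[str, list[ShortRead]],
    models: GeneModelSet,
    samples: pd.DataFrame,
    q_threshold: float = Q_THRESHOLD,
    keep_counts: bool = False,
) -> AlleleBiasResult:
    """Run both alignment pipelines and classify DE status changes.

    Pipeline A aligns every sample to the reference genome, counts, filters
    and exact-tests.  Pipeline B reuses the B6 alignments, realigns only the
    D2 reads to the SNP-substituted genome (coordinates are preserved since
    substitution keeps length), counts on the same models, restricts to
    pipeline A's post-filter gene universe, and re-estimates the dispersion
    before testing.  With zero SNPs the two pipelines are identical.
    """
    trimmed: dict[str, list[ShortRead]] = {}
    for sid, reads in reads_by_sample.items():
        trimmed[sid], n_rej = trim_reads(reads)
        if n_rej:
            logger.info("sample %s: %d reads shorter than trim length", sid, n_rej)

    aligner_ref = SeedAligner(genome)
    aln_a: list[Alignment] = []
    for sid in samples.index:
        aln_a.extend(aligner_ref.align_batch(trimmed.get(sid, [])))
    cm_a_raw = count_reads(aln_a, models, samples)
    cm_a, _ = filter_genes(cm_a_raw)
    de_before, _, _ = run_exact_de(cm_a, q_threshold)

    genome_d2, sub_report = build_snp_substituted_genome(genome, snps)
    aligner_alt = SeedAligner(genome_d2)
    d2_samples = [s for s in samples.index if samples.at[s, "strain"] == "D2"]
    aln_b: list[Alignment] = [a for a in aln_a if a.sample_id not in d2_samples]
    for sid in d2_samples:
        aln_b.extend(aligner_alt.align_batch(trimmed.get(sid, [])))
    cm_b_raw = count_reads(aln_b, models, samples)
    # same gene universe as pipeline A: no re-filtering
    cm_b = CountMatrix(
        counts=cm_b_raw.counts.loc[cm_a.counts.index],
        samples=cm_b_raw.samples,
        lib_sizes=cm_b_raw.lib_sizes,
        off_model=cm_b_raw.off_model,
    )
    de_after, _, _ = run_exact_de(cm_b, q_threshold)

    density = snps_per_kb(models, snps)
    assessment = classify_status_changes(de_before, de_after, q_threshold, density)

    stats_a = _mapping_tally(aln_a).add_suffix("_ref")
    stats_b = _mapping_tally(aln_b).add_suffix("_alt")
    mapping = stats_a.join(stats_b, how="outer").fillna(0).astype(int)

    return AlleleBiasResult(
        assessment=assessment,
        de_before=de_before,
        de_after=de_after,
        mapping_stats=mapping,
        substitution_report=sub_report,
        counts_before=cm_a if keep_counts else None,
        counts_after=cm_b if keep_counts else None,
    )
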
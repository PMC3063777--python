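"""Synthetic data with planted ground truth for every pipeline stage.

The generator emulates the study conditions end to end without any
external downloads: a random reference genome with multi-transcript gene
structures (and optional exact duplications to exercise multi-mapping),
a strain SNP list with an optional SNP-dense gene subset that plants
allele-mapping-bias cases, 76-base single-end strain-specific reads with
substitution errors, negative-binomial count matrices with a common
dispersion and planted fold changes, and probe-level tables for two array
platforms that trigger every concordance filter rule.

Every operation derives its random stream from ``config.seed`` plus a
per-stage offset, so the same seed yields byte-identical artifacts
regardless of which stages are run.

The default sequencing design mirrors the study: 10 B6 and 11 D2 samples
spread over three flowcells with lane-level library-size variation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as scipy_stats

from .align_count import CountMatrix, ReferenceGenome, ShortRead, revcomp
from .allele_bias import SnpRecord
from .diffexpr import storey_qvalues
from .gene_models import ExonRecord, GeneModelSet, build_union_exons, remove_intergene_overlaps

logger = logging.getLogger(__name__)

_STAGE = {"genome": 1, "snps": 2, "reads": 3, "counts": 4, "arrays": 5}


@dataclass
class GenomeConfig:
    n_chroms: int = 1
    chrom_length: int | None = None  # None: sized to fit the genes
    duplication_fraction: float = 0.0  # fraction of genes copied verbatim elsewhere
    n_runs_per_chrom: int = 0  # intergenic 'N' runs
    n_run_length: int = 30


@dataclass
class GeneConfig:
    n_genes: int = 40
    transcripts_per_gene: tuple[int, int] = (1, 3)
    exons_per_gene: tuple[int, int] = (1, 3)
    exon_length: tuple[int, int] = (90, 220)
    intron_length: tuple[int, int] = (40, 120)
    intergene_gap: tuple[int, int] = (60, 200)
    overlap_probability: float = 0.0  # chance the next gene overlaps the previous


@dataclass
class SnpConfig:
    density_per_kb: float = 2.0
    dense_gene_fraction: float = 0.0
    dense_spacing: int = 8  # one SNP every 8 exon bases -> >=3 per 43-base window


@dataclass
class ReadConfig:
    reads_per_sample: int = 1200
    read_length: int = 76
    error_rate: float = 0.002


@dataclass
class CountConfig:
    n_genes: int = 2000
    mean_log: float = math.log(50.0)  # log-normal gene mean at unit library factor
    mean_sdlog: float = 1.0
    dispersion: float = 0.1
    de_fraction: float = 0.1
    effect_size: tuple[float, float] = (1.0, 2.5)  # |log2 FC| range
    library_factor_range: tuple[float, float] = (0.5, 2.0)
    library_factors: Sequence[float] | None = None  # planted per-sample factors


@dataclass
class ArrayConfig:
    affy_design: tuple[int, int] = (10, 10)  # B6, D2 samples
    illumina_design: tuple[int, int] = (12, 12)
    probesets_per_gene: tuple[int, int] = (1, 2)
    probes_per_probeset: int = 11
    probes_per_gene: tuple[int, int] = (1, 2)  # illumina
    noise_sd: float = 0.3
    attenuation: float = 1.0  # array effect size relative to the true log2 FC
    detect_quantile: float = 0.25  # genes below this abundance quantile read absent
    frac_no_gene: float = 0.04
    frac_nonunique: float = 0.04
    frac_snp_span: float = 0.08  # illumina probes overlapping a strain SNP
    frac_heavy_mask: float = 0.06  # affy probesets with <4 probes after masking
    probe_mask_rate: float = 0.08  # per-probe masking chance otherwise


@dataclass
class SimulationConfig:
    seed: int
    genome: GenomeConfig = field(default_factory=GenomeConfig)
    genes: GeneConfig = field(default_factory=GeneConfig)
    snps: SnpConfig = field(default_factory=SnpConfig)
    reads: ReadConfig = field(default_factory=ReadConfig)
    counts: CountConfig = field(default_factory=CountConfig)
    arrays: ArrayConfig = field(default_factory=ArrayConfig)

    def rng(self, stage: str) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), _STAGE[stage]])


@dataclass
class GroundTruth:
    """Planted truth: per-gene table, optional per-read origins and SNP list."""

    genes: pd.DataFrame
    reads: pd.DataFrame | None = None
    snps: list[SnpRecord] | None = None


def default_samples() -> pd.DataFrame:
    """The study's sequencing design: 10 B6 + 11 D2 over three flowcells."""
    rows = []
    layout = [("FC1", ["B6"] * 4 + ["D2"] * 3), ("FC2", ["B6"] * 3 + ["D2"] * 4),
              ("FC3", ["B6"] * 3 + ["D2"] * 4)]
    counters = {"B6": 0, "D2": 0}
    for fc, strains in layout:
        for lane, strain in enumerate(strains, start=1):
            counters[strain] += 1
            rows.append(
                {
                    "sample_id": f"{strain}_{counters[strain]:02d}_{fc}_L{lane}",
                    "strain": strain,
                    "lane": f"L{lane}",
                    "flowcell": fc,
                }
            )
    return pd.DataFrame(rows).set_index("sample_id")


# ---------------------------------------------------------------------------
# genome + annotation


def generate_genome_and_annotation(
    config: SimulationConfig,
) -> tuple[ReferenceGenome, list[ExonRecord], GroundTruth]:
    """Random genome with multi-transcript genes and optional duplications.

    Transcript 1 of each gene always covers every exon block, so the union
    model equals the block skeleton; extra transcripts use jittered subsets
    of blocks, exercising the merge.  With overlap probability > 0 a gene's
    first block can overlap the previous gene's last block on the same
    chromosome, exercising inter-gene interval removal.  A configured
    fraction of genes is copied verbatim into a downstream region to create
    exact repeats (multi-mapping reads).
    """
    rng = config.rng("genome")
    gc, gn = config.genome, config.genes
    chrom_names = [f"chr{i + 1}" for i in range(gc.n_chroms)]
    per_chrom = [[] for _ in chrom_names]
    for i in range(gn.n_genes):
        per_chrom[i % gc.n_chroms].append(f"G{i + 1:04d}")

    exon_records: list[ExonRecord] = []
    gene_rows = []
    chrom_layouts: dict[str, list[tuple[str, int, int]]] = {}
    chrom_needed: dict[str, int] = {}
    for chrom, gene_ids in zip(chrom_names, per_chrom):
        cursor = int(rng.integers(*gn.intergene_gap))
        layout = []
        prev_last_block: tuple[int, int] | None = None
        for gid in gene_ids:
            n_blocks = int(rng.integers(gn.exons_per_gene[0], gn.exons_per_gene[1] + 1))
            blocks = []
            start = cursor
            if (
                prev_last_block is not None
                and rng.random() < gn.overlap_probability
            ):
                ov = int(rng.integers(10, max(11, (prev_last_block[1] - prev_last_block[0]) // 2)))
                start = prev_last_block[1] - ov
            pos = start
            for b in range(n_blocks):
                blen = int(rng.integers(*gn.exon_length))
                blocks.append((pos, pos + blen))
                pos += blen
                if b < n_blocks - 1:
                    pos += int(rng.integers(*gn.intron_length))
            gene_end = blocks[-1][1]
            strand = "+" if rng.random() < 0.5 else "-"
            n_tx = int(rng.integers(gn.transcripts_per_gene[0], gn.transcripts_per_gene[1] + 1))
            for t in range(n_tx):
                tx_id = f"{gid}.T{t + 1}"
                if t == 0:
                    tx_blocks = list(blocks)
                else:
                    lo = int(rng.integers(0, n_blocks))
                    hi = int(rng.integers(lo, n_blocks))
                    tx_blocks = []
                    for bi in range(lo, hi + 1):
                        s, e = blocks[bi]
                        js = int(rng.integers(0, max(1, (e - s) // 3))) if bi == lo else 0
                        je = int(rng.integers(0, max(1, (e - s) // 3))) if bi == hi else 0
                        tx_blocks.append((s + js, e - je))
                for s, e in tx_blocks:
                    exon_records.append(ExonRecord(gid, tx_id, chrom, s + 1, e, strand))
            gene_rows.append(
                {
                    "gene_id": gid,
                    "chrom": chrom,
                    "start": start,
                    "end": gene_end,
                    "strand": strand,
                    "duplicated": False,
                    "snp_dense": False,
                    "snp_count": 0,
                }
            )
            layout.append((gid, start, gene_end))
            prev_last_block = blocks[-1]
            cursor = gene_end + int(rng.integers(*gn.intergene_gap))
        chrom_layouts[chrom] = layout
        chrom_needed[chrom] = cursor

    truth_genes = pd.DataFrame(gene_rows).set_index("gene_id")

    # duplicated genes get a verbatim copy appended after the last gene
    n_dup = int(round(gc.duplication_fraction * gn.n_genes))
    dup_targets: dict[str, list[tuple[str, int, int, int]]] = {c: [] for c in chrom_names}
    if n_dup:
        dup_ids = rng.choice(truth_genes.index.to_numpy(), size=n_dup, replace=False)
        for gid in dup_ids:
            chrom = truth_genes.at[gid, "chrom"]
            s, e = int(truth_genes.at[gid, "start"]), int(truth_genes.at[gid, "end"])
            dest = chrom_needed[chrom] + int(rng.integers(*gn.intergene_gap))
            dup_targets[chrom].append((gid, s, e, dest))
            chrom_needed[chrom] = dest + (e - s)
            truth_genes.at[gid, "duplicated"] = True

    genome: ReferenceGenome = {}
    for chrom in chrom_names:
        needed = chrom_needed[chrom] + int(rng.integers(*gn.intergene_gap))
        length = gc.chrom_length if gc.chrom_length is not None else needed
        if length < needed:
            raise ValueError(
                f"{chrom}: genes need {needed} bases but chrom_length is {length}"
            )
        seq = rng.choice(list("ACGT"), size=length)
        for _, s, e, dest in dup_targets[chrom]:
            seq[dest : dest + (e - s)] = seq[s:e]
        if gc.n_runs_per_chrom:
            gene_spans = [(s, e) for _, s, e in chrom_layouts[chrom]]
            gene_spans += [(dest, dest + (e - s)) for _, s, e, dest in dup_targets[chrom]]
            for _ in range(gc.n_runs_per_chrom):
                for _attempt in range(50):
                    p = int(rng.integers(0, max(1, length - gc.n_run_length)))
                    if not any(s - gc.n_run_length < p < e for s, e in gene_spans):
                        seq[p : p + gc.n_run_length] = "N"
                        break
        genome[chrom] = "".join(seq)

    return genome, exon_records, GroundTruth(genes=truth_genes)


# ---------------------------------------------------------------------------
# SNPs


def generate_snps(
    genome: ReferenceGenome,
    models: GeneModelSet,
    config: SimulationConfig,
    truth: GroundTruth,
    dense_gene_ids: Sequence[str] | None = None,
) -> list[SnpRecord]:
    """Place strain SNPs in union exons: uniform background density plus a
    SNP-dense subset with one SNP every ``dense_spacing`` bases (so every
    43-base exon window carries >= 3 SNPs — enough to exhaust the seed
    mismatch budget).  SNPs are never placed on 'N'; the ref allele always
    matches the genome.  Updates ``truth.genes`` snp_count/snp_dense.
    """
    sc = config.snps
    rng = config.rng("snps")
    if dense_gene_ids is None:
        n_dense = int(round(sc.dense_gene_fraction * len(models.genes)))
        ids = np.array(sorted(models.genes))
        dense_gene_ids = (
            list(rng.choice(ids, size=n_dense, replace=False)) if n_dense else []
        )
    dense = set(dense_gene_ids)
    bases = "ACGT"
    snps: list[SnpRecord] = []
    for gid in sorted(models.genes):
        gm = models.genes[gid]
        length = gm.length
        if length == 0:
            continue
        positions: list[int] = []
        if gid in dense:
            for s, e in gm.intervals:
                positions.extend(range(s + sc.dense_spacing // 2, e, sc.dense_spacing))
        elif sc.density_per_kb > 0:
            expected = sc.density_per_kb * length / 1000.0
            if expected > length:
                raise ValueError(f"SNP density infeasible for gene {gid}")
            n = int(rng.poisson(expected))
            if n:
                exon_bases = np.concatenate([np.arange(s, e) for s, e in gm.intervals])
                n = min(n, exon_bases.size)
                positions = sorted(rng.choice(exon_bases, size=n, replace=False).tolist())
        count = 0
        for pos0 in positions:
            ref = genome[gm.chrom][pos0]
            if ref == "N":
                continue
            alt = bases[(bases.index(ref) + int(rng.integers(1, 4))) % 4]
            snps.append(SnpRecord(gm.chrom, pos0 + 1, ref, alt))
            count += 1
        truth.genes.at[gid, "snp_count"] = count
        truth.genes.at[gid, "snp_dense"] = gid in dense
    truth.snps = snps
    return snps


# ---------------------------------------------------------------------------
# reads


def simulate_reads(
    genome: ReferenceGenome,
    models: GeneModelSet,
    snps: list[SnpRecord],
    samples: pd.DataFrame,
    config: SimulationConfig,
    truth: GroundTruth,
    expression: pd.Series | None = None,
    rng: np.random.Generator | None = None,
) -> dict[str, list[ShortRead]]:
    """Strain-specific 76-base reads sampled from the union models.

    Gene choice is proportional to ``expression`` (uniform when omitted).
    The 43-base alignment window (the read's first 43 bases on the forward
    strand; its last 43 window positions for reverse reads) always lies
    within a single exon, so the ungapped aligner can recover the origin;
    the trailing bases may splice across exons.  D2 reads carry the alt
    allele at every SNP position; substitution errors are applied at the
    configured rate.  Genes with no eligible window are excluded (logged).
    Per-read true origins (gene, chrom, strand, position of the trimmed
    alignment) are recorded in ``truth.reads``.
    """
    rc = config.reads
    if rng is None:
        rng = config.rng("reads")
    L = rc.read_length
    alt_at = {(s.chrom, s.pos - 1): s.alt_allele for s in snps}

    layouts = {}
    for gid in sorted(models.genes):
        gm = models.genes[gid]
        if gm.length < L:
            continue
        pos_map = np.concatenate([np.arange(s, e) for s, e in gm.intervals])
        exon_id = np.concatenate(
            [np.full(e - s, i) for i, (s, e) in enumerate(gm.intervals)]
        )
        n = pos_map.size
        offs = np.arange(n - L + 1)
        ok_plus = exon_id[offs] == exon_id[offs + 42]
        ok_minus = exon_id[offs + 33] == exon_id[offs + 75]
        if not (ok_plus.any() or ok_minus.any()):
            continue
        layouts[gid] = (gm.chrom, pos_map, offs[ok_plus], offs[ok_minus])
    skipped = sorted(set(models.genes) - set(layouts) )
    if skipped:
        logger.info("%d genes too short for %d-base reads: %s...", len(skipped), L, skipped[:5])

    gene_ids = sorted(layouts)
    if expression is None:
        weights = np.ones(len(gene_ids))
    else:
        weights = expression.reindex(gene_ids).fillna(0.0).to_numpy(float)
    weights = weights / weights.sum()
    bases = np.array(list("ACGT"))

    reads_by_sample: dict[str, list[ShortRead]] = {}
    truth_rows = []
    for sid in samples.index:
        is_d2 = samples.at[sid, "strain"] == "D2"
        out: list[ShortRead] = []
        choices = rng.choice(len(gene_ids), size=rc.reads_per_sample, p=weights)
        for i, gi in enumerate(choices):
            gid = gene_ids[gi]
            chrom, pos_map, offs_p, offs_m = layouts[gid]
            if offs_p.size and offs_m.size:
                strand = "+" if rng.random() < 0.5 else "-"
            else:
                strand = "+" if offs_p.size else "-"
            offs = offs_p if strand == "+" else offs_m
            o = int(offs[rng.integers(offs.size)])
            gpos = pos_map[o : o + L]
            seq = [genome[chrom][p] for p in gpos]
            if is_d2:
                for k, p in enumerate(gpos):
                    alt = alt_at.get((chrom, int(p)))
                    if alt is not None:
                        seq[k] = alt
            if rc.error_rate > 0:
                errs = np.flatnonzero(rng.random(L) < rc.error_rate)
                for k in errs:
                    cur = seq[k]
                    opts = [b for b in "ACGT" if b != cur]
                    seq[k] = opts[int(rng.integers(3))]
            window = "".join(seq)
            read_seq = window if strand == "+" else revcomp(window)
            rid = f"{sid}_r{i:06d}"
            out.append(ShortRead(rid, read_seq, sid))
            trim_pos = int(gpos[0]) if strand == "+" else int(gpos[33])
            truth_rows.append(
                {
                    "read_id": rid,
                    "sample_id": sid,
                    "gene_id": gid,
                    "chrom": chrom,
                    "strand": strand,
                    "trim_pos": trim_pos,
                }
            )
        reads_by_sample[sid] = out
    new = pd.DataFrame(truth_rows).set_index("read_id")
    truth.reads = new if truth.reads is None else pd.concat([truth.reads, new])
    return reads_by_sample


# ---------------------------------------------------------------------------
# counts


def simulate_count_matrix(
    config: SimulationConfig, samples: pd.DataFrame
) -> tuple[CountMatrix, GroundTruth]:
    """NB counts matching the exact test's model, with planted fold changes.

    y_gj ~ NB(mean = c_j * m_g * 2^(+-beta_g/2 by strain), dispersion phi);
    a de_fraction of genes carries nonzero effects (sign 50/50, magnitude
    uniform in the configured range, positive = B6 > D2); c_j are planted
    or uniform library-size factors.  N_j is the column sum.
    """
    cc = config.counts
    rng = config.rng("counts")
    n_genes, n_samp = cc.n_genes, len(samples)
    m_g = rng.lognormal(cc.mean_log, cc.mean_sdlog, size=n_genes)
    is_de = rng.random(n_genes) < cc.de_fraction
    beta = np.zeros(n_genes)
    n_de = int(is_de.sum())
    beta[is_de] = rng.uniform(*cc.effect_size, size=n_de) * rng.choice(
        [-1.0, 1.0], size=n_de
    )
    if cc.library_factors is not None:
        c_j = np.asarray(cc.library_factors, float)
        if c_j.size != n_samp:
            raise ValueError("library_factors length must match samples")
    else:
        c_j = rng.uniform(*cc.library_factor_range, size=n_samp)
    strain_sign = np.where(samples["strain"].to_numpy() == "B6", 0.5, -0.5)
    mu = m_g[:, None] * c_j[None, :] * np.power(2.0, beta[:, None] * strain_sign[None, :])
    if cc.dispersion < 1e-12:
        y = rng.poisson(mu)
    else:
        r = 1.0 / cc.dispersion
        y = rng.negative_binomial(r, r / (r + mu))
    gene_ids = pd.Index([f"G{i + 1:05d}" for i in range(n_genes)], name="gene_id")
    counts = pd.DataFrame(y, index=gene_ids, columns=samples.index)
    cm = CountMatrix(
        counts=counts,
        samples=samples,
        lib_sizes=counts.sum(axis=0),
    )
    truth = GroundTruth(
        genes=pd.DataFrame(
            {
                "true_mean": m_g,
                "log2_fc": beta,
                "is_de": is_de,
                "library_note": "",
            },
            index=gene_ids,
        )
    )
    truth.genes.attrs["library_factors"] = c_j
    return cm, truth


# ---------------------------------------------------------------------------
# probe tables


def default_array_samples(design: tuple[int, int], prefix: str) -> pd.DataFrame:
    rows = [
        {"sample_id": f"{prefix}_B6_{i + 1:02d}", "strain": "B6"} for i in range(design[0])
    ] + [
        {"sample_id": f"{prefix}_D2_{i + 1:02d}", "strain": "D2"} for i in range(design[1])
    ]
    df = pd.DataFrame(rows).set_index("sample_id")
    df["lane"] = ""
    df["flowcell"] = ""
    return df


def simulate_probe_tables(
    truth: GroundTruth, config: SimulationConfig
) -> dict[str, tuple[pd.DataFrame, pd.DataFrame]]:
    """Probe-level result tables for both array platforms.

    Per gene and platform: probe signals are noisy per-sample draws around
    log2 of the true mean plus the (attenuated) strain effect; p-values
    come from a two-sample t-test over samples, q-values from the Storey
    procedure across the platform, fold changes are linear 2^(mean B6 -
    mean D2).  Detection calls are thresholded at the configured abundance
    quantile.  Configured fractions of probes lack gene mappings, map
    non-uniquely, span SNPs (Illumina) or lose probes to masking
    (Affymetrix) so that every concordance filter rule fires.

    Returns {"affy": (probes, samples), "illumina": (probes, samples)}.
    """
    ac = config.arrays
    rng = config.rng("arrays")
    genes = truth.genes
    log_mean = np.log2(genes["true_mean"].to_numpy(float))
    beta = genes["log2_fc"].to_numpy(float) * ac.attenuation
    detect_cut = np.quantile(log_mean, ac.detect_quantile)

    out: dict[str, tuple[pd.DataFrame, pd.DataFrame]] = {}
    for platform in ("affy", "illumina"):
        design = ac.affy_design if platform == "affy" else ac.illumina_design
        samples = default_array_samples(design, platform)
        strain_sign = np.where(samples["strain"].to_numpy() == "B6", 0.5, -0.5)
        rows = []
        for gi, gid in enumerate(genes.index):
            lo, hi = ac.probesets_per_gene if platform == "affy" else ac.probes_per_gene
            n_probes = int(rng.integers(lo, hi + 1))
            for pi in range(n_probes):
                signal = (
                    log_mean[gi]
                    + beta[gi] * strain_sign
                    + rng.normal(0.0, ac.noise_sd, size=len(samples))
                    + rng.normal(0.0, 0.15)
                )
                b6 = signal[strain_sign > 0]
                d2 = signal[strain_sign < 0]
                t = _ttest_p(b6, d2)
                fc = float(2.0 ** (b6.mean() - d2.mean()))
                calls = np.where(signal > detect_cut + rng.normal(0, 0.1, len(signal)), "P", "A")
                marginal = np.abs(signal - detect_cut) < 0.05
                calls = np.where(marginal, "M", calls)
                row = {
                    "platform": platform,
                    "probe_id": f"{platform}_{gid}_p{pi + 1}",
                    "gene_id": "" if rng.random() < ac.frac_no_gene else gid,
                    "maps_unique": rng.random() >= ac.frac_nonunique,
                    "detection_calls": ",".join(calls),
                    "p_value": t,
                    "fold_change": fc,
                }
                if platform == "affy":
                    row["probeset_id"] = row["probe_id"]
                    total = ac.probes_per_probeset
                    if rng.random() < ac.frac_heavy_mask:
                        after = int(rng.integers(0, 4))
                    else:
                        after = total - int(rng.binomial(total, ac.probe_mask_rate))
                    row["n_probes_total"] = total
                    row["n_probes_after_mask"] = after
                    row["spans_snp"] = False
                else:
                    row["probeset_id"] = ""
                    row["n_probes_total"] = 1
                    row["n_probes_after_mask"] = 1
                    snp_dense = bool(genes.get("snp_dense", pd.Series(False, index=genes.index)).get(gid, False))
                    row["spans_snp"] = bool(rng.random() < (0.8 if snp_dense else ac.frac_snp_span))
                rows.append(row)
        probes = pd.DataFrame(rows)
        probes["q_value"] = storey_qvalues(probes["p_value"].to_numpy())
        out[platform] = (probes, samples)
    return out


def _ttest_p(a: np.ndarray, b: np.ndarray) -> float:
    res = scipy_stats.ttest_ind(a, b)
    p = float(res.pvalue)
    return p if np.isfinite(p) else 1.0


# ---------------------------------------------------------------------------
# composed fixtures


@dataclass
class ReadLevelFixture:
    genome: ReferenceGenome
    exons: list[ExonRecord]
    models: GeneModelSet  # final, post overlap removal
    snps: list[SnpRecord]
    reads_by_sample: dict[str, list[ShortRead]]
    samples: pd.DataFrame
    truth: GroundTruth
    config: SimulationConfig


def planted_bias_fixture(
    seed: int,
    n_dense: int = 30,
    n_background: int = 30,
    reads_per_sample: int = 1500,
    background_density_per_kb: float = 2.0,
    error_rate: float = 0.002,
) -> ReadLevelFixture:
    """The allele-bias study fixture: flat-expressed genes, a SNP-dense
    subset whose D2 reads exceed the seed mismatch budget against the
    reference, and background genes with ordinary SNP density."""
    n_genes = n_dense + n_background
    config = SimulationConfig(
        seed=seed,
        genes=GeneConfig(
            n_genes=n_genes,
            transcripts_per_gene=(1, 2),
            exons_per_gene=(1, 2),
            exon_length=(100, 180),
            intron_length=(40, 80),
            intergene_gap=(60, 140),
        ),
        snps=SnpConfig(density_per_kb=background_density_per_kb, dense_spacing=8),
        reads=ReadConfig(reads_per_sample=reads_per_sample, error_rate=error_rate),
    )
    genome, exons, truth = generate_genome_and_annotation(config)
    models = remove_intergene_overlaps(build_union_exons(exons))
    pick = np.random.default_rng([int(seed), 7])
    dense_ids = sorted(
        pick.choice(np.array(sorted(models.genes)), size=n_dense, replace=False).tolist()
    )
    snps = generate_snps(genome, models, config, truth, dense_gene_ids=dense_ids)
    samples = default_samples()
    reads = simulate_reads(genome, models, snps, samples, config, truth)
    return ReadLevelFixture(genome, exons, models, snps, reads, samples, truth, config)


def expression_fixture(
    seed: int,
    n_genes: int = 60,
    de_fraction: float = 0.2,
    reads_per_sample: int = 2500,
    effect_size: tuple[float, float] = (1.5, 2.5),
) -> ReadLevelFixture:
    """Read-level fixture with planted differential expression and no SNPs:
    exercises the full reads -> align -> count -> test chain.

    Planted effect signs are balanced (equal numbers up and down) so the
    two strains' total expressed mass stays comparable; on a panel this
    small a strongly one-sided effect mix would shift every null gene's
    sampled proportion between strains (a composition artifact the
    upper-quartile factor cannot absorb when the quartile itself lands on
    perturbed genes)."""
    config = SimulationConfig(
        seed=seed,
        genes=GeneConfig(
            n_genes=n_genes,
            transcripts_per_gene=(1, 2),
            exons_per_gene=(1, 2),
            exon_length=(100, 180),
            intron_length=(40, 80),
            intergene_gap=(60, 140),
        ),
        snps=SnpConfig(density_per_kb=0.0),
        reads=ReadConfig(reads_per_sample=reads_per_sample),
    )
    genome, exons, truth = generate_genome_and_annotation(config)
    models = remove_intergene_overlaps(build_union_exons(exons))
    rng = config.rng("counts")
    gene_ids = sorted(models.genes)
    n_de = int(round(de_fraction * len(gene_ids)))
    de_idx = rng.choice(len(gene_ids), size=n_de, replace=False)
    signs = np.resize([1.0, -1.0], n_de)  # balanced up/down
    rng.shuffle(signs)
    is_de = np.zeros(len(gene_ids), dtype=bool)
    is_de[de_idx] = True
    beta = np.zeros(len(gene_ids))
    beta[de_idx] = rng.uniform(*effect_size, size=n_de) * signs
    truth.genes["log2_fc"] = pd.Series(beta, index=gene_ids)
    truth.genes["is_de"] = pd.Series(is_de, index=gene_ids)
    samples = default_samples()
    # strain-specific expression weights realize the planted fold changes;
    # each strain gets its own random stream
    reads_by_sample: dict[str, list[ShortRead]] = {}
    base = pd.Series(1.0, index=gene_ids)
    for k, (strain, sign) in enumerate((("B6", 0.5), ("D2", -0.5))):
        expr = base * np.power(2.0, pd.Series(beta, index=gene_ids) * sign)
        sub_samples = samples[samples["strain"] == strain]
        sub = simulate_reads(
            genome, models, [], sub_samples, config, truth,
            expression=expr, rng=np.random.default_rng([int(seed), 11 + k]),
        )
        reads_by_sample.update(sub)
    return ReadLevelFixture(genome, exons, models, [], reads_by_sample, samples, truth, config)
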
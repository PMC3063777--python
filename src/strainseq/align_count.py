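"""Toy-scale seeded read alignment and union-exon read counting.

The aligner reproduces the *mechanism* of seeded short-read mapping at desk
scale: each 76-cycle read is trimmed to its first 43 bases, a seed of the
first 32 bases is matched against every genome offset on both strands
allowing at most 2 seed mismatches, and among candidate loci the best is
the one with the fewest mismatches over all 43 bases (ties broken by fewer
seed mismatches).  A read maps *unique* only when exactly one best locus
exists; equal-score loci never yield a unique call.  'N' in either read or
genome never matches.  This deterministic mismatch-count model is what
creates allele-mapping bias: strain SNPs consume the mismatch budget.

Counting is digital: a uniquely mapped read increments a gene when the
leftmost genomic base of its trimmed alignment (on either strand) lies in
one of the gene's union exons.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from numpy.lib.stride_tricks import sliding_window_view

from .gene_models import GeneModelSet

logger = logging.getLogger(__name__)

TRIM_LENGTH = 43
SEED_LENGTH = 32
MAX_SEED_MISMATCHES = 2

ReferenceGenome = dict[str, str]

_ENCODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i
# one-hot rows for A,C,G,T; N (code 4) is all-zero so it never matches
_ONEHOT = np.vstack([np.eye(4, dtype=np.float32), np.zeros((1, 4), np.float32)])

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def _encode(seq: str) -> np.ndarray:
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass(frozen=True)
class ShortRead:
    read_id: str
    sequence: str
    sample_id: str = ""


@dataclass
class Alignment:
    read_id: str
    status: str  # unique | multi | unmapped
    chrom: str | None = None
    pos: int | None = None  # 0-based leftmost base of the trimmed read, forward strand
    strand: str | None = None
    seed_mismatches: int | None = None
    total_mismatches: int | None = None
    sample_id: str = ""


@dataclass(frozen=True)
class SampleInfo:
    sample_id: str
    strain: str  # B6 | D2
    lane: str = ""
    flowcell: str = ""


@dataclass
class CountMatrix:
    """Genes x samples integer read counts with per-sample metadata.

    ``lib_sizes[j]`` is N_j, the number of uniquely mapped reads in sample j
    (>= the column sum over genes; equal only when every unique read starts
    in a union exon).  ``off_model`` tallies unique reads starting outside
    every union exon.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame  # index sample_id; columns strain, lane, flowcell
    lib_sizes: pd.Series
    off_model: pd.Series | None = None

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)


# ---------------------------------------------------------------------------
# IO


def read_fasta(path: str | Path) -> ReferenceGenome:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(genome: ReferenceGenome, path: str | Path) -> None:
    recs = [SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.items()]
    SeqIO.write(recs, str(path), "fasta")


def read_reads(path: str | Path, sample_id: str = "", fmt: str | None = None) -> list[ShortRead]:
    """Read FASTA/FASTQ reads (qualities ignored)."""
    path = Path(path)
    if fmt is None:
        fmt = "fastq" if path.suffix.lower() in {".fastq", ".fq"} else "fasta"
    return [
        ShortRead(rec.id, str(rec.seq).upper(), sample_id)
        for rec in SeqIO.parse(str(path), fmt)
    ]


def write_fastq(reads: list[ShortRead], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{'I' * len(r.sequence)}\n")


def samples_frame(samples: list[SampleInfo]) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in samples],
            "strain": [s.strain for s in samples],
            "lane": [s.lane for s in samples],
            "flowcell": [s.flowcell for s in samples],
        }
    )
    return df.set_index("sample_id")


def read_samples(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str).set_index("sample_id")


def write_samples(samples: pd.DataFrame, path: str | Path) -> None:
    samples.to_csv(path, sep="\t")


def write_counts(cm: CountMatrix, counts_path: str | Path, samples_path: str | Path | None = None) -> None:
    cm.counts.to_csv(counts_path, sep="\t", index_label="gene_id")
    if samples_path is not None:
        meta = cm.samples.copy()
        meta["n_unique"] = cm.lib_sizes
        meta.to_csv(samples_path, sep="\t")


def read_counts(counts_path: str | Path, samples_path: str | Path) -> CountMatrix:
    counts = pd.read_csv(counts_path, sep="\t", index_col="gene_id")
    meta = pd.read_csv(samples_path, sep="\t", index_col="sample_id")
    lib = meta.pop("n_unique").astype(int)
    return CountMatrix(counts=counts, samples=meta, lib_sizes=lib)


def write_sam(
    alignments: list[Alignment],
    chrom_lengths: dict[str, int],
    path: str | Path,
    emit_multi: bool = True,
) -> None:
    """Write a minimal SAM: 43M CIGAR, MAPQ 255, flag 16 for reverse strand.

    Multi-mapped reads are emitted as unmapped records carrying ``ZS:Z:multi``
    when ``emit_multi`` is true, otherwise suppressed.
    """
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unknown\n")
        for chrom, length in chrom_lengths.items():
            fh.write(f"@SQ\tSN:{chrom}\tLN:{length}\n")
        for a in alignments:
            if a.status == "unique":
                flag = 16 if a.strand == "-" else 0
                fh.write(
                    f"{a.read_id}\t{flag}\t{a.chrom}\t{a.pos + 1}\t255\t"
                    f"{TRIM_LENGTH}M\t*\t0\t0\t*\t*\tNM:i:{a.total_mismatches}\n"
                )
            elif a.status == "multi" and emit_multi:
                fh.write(f"{a.read_id}\t4\t*\t0\t0\t*\t*\t0\t0\t*\t*\tZS:Z:multi\n")
            elif a.status == "unmapped":
                fh.write(f"{a.read_id}\t4\t*\t0\t0\t*\t*\t0\t0\t*\t*\n")


# ---------------------------------------------------------------------------
# trimming


def trim_read(read: ShortRead) -> ShortRead:
    """Keep the first 43 bases; reads shorter than 43 are rejected."""
    if len(read.sequence) < TRIM_LENGTH:
        raise ValueError(f"read {read.read_id} shorter than {TRIM_LENGTH} bases")
    return ShortRead(read.read_id, read.sequence[:TRIM_LENGTH], read.sample_id)


def trim_reads(reads: list[ShortRead]) -> tuple[list[ShortRead], int]:
    """Trim a batch; returns (trimmed reads, number rejected as too short)."""
    out, rejected = [], 0
    for r in reads:
        if len(r.sequence) < TRIM_LENGTH:
            rejected += 1
        else:
            out.append(trim_read(r))
    return out, rejected


# ---------------------------------------------------------------------------
# seeded alignment

_BIG = np.int32(1 << 20)


class SeedAligner:
    """Exhaustive seeded aligner over a reference genome.

    Candidate loci are every (chrom, offset, strand) where the trimmed
    read's seed (its first 32 bases; for the reverse strand the read's
    reverse complement is compared against the forward genome, so the seed
    occupies the *last* 32 positions of the compared window) matches with
    <= 2 mismatches and all 43 bases fit on the chromosome.  Scoring and
    tie handling follow the module docstring.

    Mismatch counting is vectorized as a one-hot inner product between the
    read and every genome window, so a batch of reads is two matrix
    products per chromosome.
    """

    def __init__(self, genome: ReferenceGenome):
        self.genome = genome
        self.chroms: list[str] = []
        self._windows: list[np.ndarray] = []  # (n_offsets, 43*4) float32
        for chrom, seq in genome.items():
            if len(seq) < TRIM_LENGTH:
                continue
            enc = _encode(seq)
            win = sliding_window_view(enc, TRIM_LENGTH)  # (n_off, 43)
            mat = _ONEHOT[win].reshape(win.shape[0], TRIM_LENGTH * 4)
            self.chroms.append(chrom)
            self._windows.append(np.ascontiguousarray(mat))

    def align(self, read: ShortRead) -> Alignment:
        return self.align_batch([read])[0]

    def align_batch(self, reads: list[ShortRead], chunk_size: int = 128) -> list[Alignment]:
        out: list[Alignment] = []
        for i in range(0, len(reads), chunk_size):
            out.extend(self._align_chunk(reads[i : i + chunk_size]))
        return out

    def _align_chunk(self, reads: list[ShortRead]) -> list[Alignment]:
        n = len(reads)
        fwd = np.empty((n, TRIM_LENGTH * 4), np.float32)
        rev = np.empty((n, TRIM_LENGTH * 4), np.float32)
        for i, r in enumerate(reads):
            if len(r.sequence) != TRIM_LENGTH:
                raise ValueError(
                    f"read {r.read_id} must be trimmed to {TRIM_LENGTH} bases"
                )
            fwd[i] = _ONEHOT[_encode(r.sequence)].ravel()
            rev[i] = _ONEHOT[_encode(revcomp(r.sequence))].ravel()
        # seed = read's first 32 bases: forward-strand window positions 0..31,
        # reverse-strand (revcomp) window positions 11..42
        fwd_seed = fwd.copy()
        fwd_seed[:, SEED_LENGTH * 4 :] = 0.0
        rev_seed = rev.copy()
        rev_seed[:, : (TRIM_LENGTH - SEED_LENGTH) * 4] = 0.0

        best = np.full(n, _BIG, dtype=np.int32)
        nbest = np.zeros(n, dtype=np.int64)
        loc_chrom = np.full(n, -1, dtype=np.int32)
        loc_strand = np.zeros(n, dtype=np.int8)
        loc_pos = np.full(n, -1, dtype=np.int64)

        for ci, win in enumerate(self._windows):
            for strand, reads_oh, seed_oh in ((0, fwd, fwd_seed), (1, rev, rev_seed)):
                total_mm = TRIM_LENGTH - reads_oh @ win.T  # (n, n_off)
                seed_mm = SEED_LENGTH - seed_oh @ win.T
                score = (total_mm.astype(np.int32) << 6) + seed_mm.astype(np.int32)
                score[seed_mm > MAX_SEED_MISMATCHES] = _BIG
                blk_min = score.min(axis=1)
                blk_cnt = (score == blk_min[:, None]).sum(axis=1)
                blk_arg = score.argmin(axis=1)
                better = blk_min < best
                equal = (blk_min == best) & (best < _BIG)
                nbest[equal] += blk_cnt[equal]
                nbest[better] = blk_cnt[better]
                best[better] = blk_min[better]
                loc_chrom[better] = ci
                loc_strand[better] = strand
                loc_pos[better] = blk_arg[better]

        out: list[Alignment] = []
        for i, r in enumerate(reads):
            if best[i] >= _BIG:
                out.append(Alignment(r.read_id, "unmapped", sample_id=r.sample_id))
            elif nbest[i] > 1:
                out.append(Alignment(r.read_id, "multi", sample_id=r.sample_id))
            else:
                out.append(
                    Alignment(
                        read_id=r.read_id,
                        status="unique",
                        chrom=self.chroms[loc_chrom[i]],
                        pos=int(loc_pos[i]),
                        strand="-" if loc_strand[i] else "+",
                        seed_mismatches=int(best[i] & 63),
                        total_mismatches=int(best[i] >> 6),
                        sample_id=r.sample_id,
                    )
                )
        return out


def seed_align(read: ShortRead, genome: ReferenceGenome) -> Alignment:
    """Align one trimmed read (convenience wrapper over :class:`SeedAligner`)."""
    return SeedAligner(genome).align(read)


# ---------------------------------------------------------------------------
# counting and filtering


def count_reads(
    alignments: list[Alignment],
    models: GeneModelSet,
    samples: pd.DataFrame,
) -> CountMatrix:
    """Count unique alignments whose start position lies in a union exon.

    Expects models that have passed inter-gene overlap removal so that every
    base belongs to at most one gene.  Multi-mapped and unmapped reads are
    never counted; N_j is the number of unique alignments in sample j.
    """
    gene_ids = list(models.genes.keys())
    gene_index = {g: i for i, g in enumerate(gene_ids)}
    sample_ids = list(samples.index)
    sample_index = {s: j for j, s in enumerate(sample_ids)}

    lookup: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for chrom in {gm.chrom for gm in models.genes.values()}:
        ivals = []
        for gm in models.genes.values():
            if gm.chrom == chrom:
                ivals.extend((s, e, gene_index[gm.gene_id]) for s, e in gm.intervals)
        ivals.sort()
        starts = np.array([s for s, _, _ in ivals], dtype=np.int64)
        ends = np.array([e for _, e, _ in ivals], dtype=np.int64)
        gidx = np.array([g for _, _, g in ivals], dtype=np.int64)
        lookup[chrom] = (starts, ends, gidx)

    counts = np.zeros((len(gene_ids), len(sample_ids)), dtype=np.int64)
    lib = np.zeros(len(sample_ids), dtype=np.int64)
    off_model = np.zeros(len(sample_ids), dtype=np.int64)
    for a in alignments:
        if a.status != "unique":
            continue
        j = sample_index[a.sample_id]
        lib[j] += 1
        tab = lookup.get(a.chrom)
        if tab is None:
            off_model[j] += 1
            continue
        starts, ends, gidx = tab
        k = int(np.searchsorted(starts, a.pos, side="right")) - 1
        if k >= 0 and a.pos < ends[k]:
            counts[gidx[k], j] += 1
        else:
            off_model[j] += 1

    return CountMatrix(
        counts=pd.DataFrame(counts, index=pd.Index(gene_ids, name="gene_id"), columns=sample_ids),
        samples=samples,
        lib_sizes=pd.Series(lib, index=sample_ids),
        off_model=pd.Series(off_model, index=sample_ids),
    )


def filter_genes(cm: CountMatrix) -> tuple[CountMatrix, pd.DataFrame]:
    """Apply the zero-count gene filters.

    Removes (a) genes with zero counts in every sample, and (b) genes with a
    zero count in at least one B6 sample *and* at least one D2 sample.  The
    report lists each removed gene with its reason; rule (a) takes precedence.
    Raises ``ValueError`` if either strain has no samples.
    """
    strains = cm.samples["strain"]
    b6 = [s for s in cm.sample_ids if strains[s] == "B6"]
    d2 = [s for s in cm.sample_ids if strains[s] == "D2"]
    if not b6 or not d2:
        raise ValueError("both strains (B6, D2) must be present among samples")
    zero = cm.counts == 0
    all_zero = zero.all(axis=1)
    both_strain_zero = zero[b6].any(axis=1) & zero[d2].any(axis=1)
    reason = pd.Series("", index=cm.counts.index, dtype=object)
    reason[both_strain_zero] = "zero_in_both_strains"
    reason[all_zero] = "all_zero"
    removed = reason[reason != ""]
    report = pd.DataFrame({"gene_id": removed.index, "reason": removed.values})
    kept = cm.counts.loc[reason == ""]
    return (
        CountMatrix(
            counts=kept,
            samples=cm.samples,
            lib_sizes=cm.lib_sizes,
            off_model=cm.off_model,
        ),
        report,
    )
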
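import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from strainseq.align_count import CountMatrix
from strainseq.gene_models import ExonRecord, build_union_exons, remove_intergene_overlaps


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture()
def small_samples():
    """Four samples, two per strain."""
    df = pd.DataFrame(
        {
            "strain": ["B6", "B6", "D2", "D2"],
            "lane": ["L1", "L2", "L1", "L2"],
            "flowcell": ["FC1", "FC1", "FC1", "FC1"],
        },
        index=pd.Index(["b1", "b2", "d1", "d2"], name="sample_id"),
    )
    return df


@pytest.fixture()
def simple_models():
    """Three genes on one chromosome, no inter-gene overlap."""
    recs = [
        ExonRecord("G1", "T1", "chr1", 101, 200),
        ExonRecord("G1", "T1", "chr1", 301, 400),
        ExonRecord("G2", "T1", "chr1", 501, 700),
        ExonRecord("G3", "T1", "chr1", 801, 1000),
    ]
    return remove_intergene_overlaps(build_union_exons(recs))


def make_count_matrix(counts: np.ndarray, samples: pd.DataFrame, lib_sizes=None) -> CountMatrix:
    genes = pd.Index([f"G{i + 1:04d}" for i in range(counts.shape[0])], name="gene_id")
    df = pd.DataFrame(counts, index=genes, columns=samples.index)
    if lib_sizes is None:
        lib = df.sum(axis=0)
    else:
        lib = pd.Series(lib_sizes, index=samples.index)
    return CountMatrix(counts=df, samples=samples, lib_sizes=lib)


def random_annotation(rng, n_genes=20, chrom_length=50_000, n_chroms=2):
    """Random exon annotations with nested and inter-gene-overlap cases."""
    recs = []
    for i in range(n_genes):
        gid = f"G{i + 1:03d}"
        chrom = f"chr{rng.integers(1, n_chroms + 1)}"
        anchor = int(rng.integers(1, chrom_length - 2000))
        for t in range(int(rng.integers(1, 4))):
            pos = anchor + int(rng.integers(0, 300))
            for _ in range(int(rng.integers(1, 4))):
                length = int(rng.integers(20, 400))
                end = min(pos + length, chrom_length - 1)
                recs.append(ExonRecord(gid, f"{gid}.T{t}", chrom, pos + 1, end + 1))
                pos = end + int(rng.integers(1, 200))
    return recs
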
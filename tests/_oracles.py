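"""Independent brute-force oracles used by the test suite.

Each oracle recomputes a quantity by a route deliberately different from
the package implementation (boolean per-base arrays instead of interval
algebra, direct window comparison instead of one-hot inner products,
log-gamma negative-hypergeometric weights instead of NB pmf products, a
naive classifier instead of the vectorized one).
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.special import gammaln

TRIM = 43
SEED = 32

_ENC = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _ENC[ord(_b)] = _i

_COMP = str.maketrans("ACGTN", "TGCAN")


def _enc(seq: str) -> np.ndarray:
    return _ENC[np.frombuffer(seq.encode(), dtype=np.uint8)]


def _rc(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


# ---------------------------------------------------------------------------
# gene models: per-base boolean-array oracle


def per_base_models(exon_records, chrom_length=200_000):
    """Final per-gene base sets: own merged exon bases minus bases covered
    by >= 2 genes, computed with boolean arrays."""
    chroms = sorted({r.chrom for r in exon_records})
    genes = sorted({r.gene_id for r in exon_records})
    cover = {}
    for g in genes:
        cover[g] = {c: np.zeros(chrom_length, dtype=bool) for c in chroms}
    for r in exon_records:
        cover[r.gene_id][r.chrom][r.start - 1 : r.end] = True
    multi = {c: np.zeros(chrom_length, dtype=int) for c in chroms}
    for g in genes:
        for c in chroms:
            multi[c] += cover[g][c]
    out = {}
    for g in genes:
        out[g] = {
            c: np.flatnonzero(cover[g][c] & (multi[c] < 2)) for c in chroms
        }
    return out


def model_base_sets(models):
    """Base sets of a GeneModelSet, for comparison with per_base_models."""
    out = {}
    for gid, gm in models.genes.items():
        bases = (
            np.concatenate([np.arange(s, e) for s, e in gm.intervals])
            if gm.intervals
            else np.array([], dtype=int)
        )
        out[gid] = (gm.chrom, bases)
    return out


# ---------------------------------------------------------------------------
# aligner: exhaustive window-scan oracle


def scan_align(seq43: str, genome: dict[str, str]):
    """Exhaustive scan over every offset and strand via direct window
    comparison.  Returns (status, chrom, pos, strand, seed_mm, total_mm)."""
    best = None
    n_best = 0
    for chrom, ref in genome.items():
        if len(ref) < TRIM:
            continue
        enc = _enc(ref)
        win = sliding_window_view(enc, TRIM)
        for strand, s in (("+", seq43), ("-", _rc(seq43))):
            arr = _enc(s)
            neq = (win != arr[None, :]) | (win == 4) | (arr[None, :] == 4)
            total = neq.sum(axis=1)
            if strand == "+":
                seed = neq[:, :SEED].sum(axis=1)
            else:
                seed = neq[:, TRIM - SEED :].sum(axis=1)
            cand = seed <= 2
            for off in np.flatnonzero(cand):
                key = (int(total[off]), int(seed[off]))
                if best is None or key < best[0]:
                    best = (key, chrom, int(off), strand)
                    n_best = 1
                elif key == best[0]:
                    n_best += 1
    if best is None:
        return ("unmapped", None, None, None, None, None)
    if n_best > 1:
        return ("multi", None, None, None, None, None)
    (total_mm, seed_mm), chrom, pos, strand = best
    return ("unique", chrom, pos, strand, seed_mm, total_mm)


def python_align(seq43: str, genome: dict[str, str]):
    """Pure-Python exhaustive scan (slow; for tiny genomes only)."""
    cands = []
    for chrom, ref in genome.items():
        for strand in "+-":
            probe = seq43 if strand == "+" else _rc(seq43)
            seed_rng = range(SEED) if strand == "+" else range(TRIM - SEED, TRIM)
            for off in range(len(ref) - TRIM + 1):
                window = ref[off : off + TRIM]
                mism = [
                    a != b or a == "N" or b == "N" for a, b in zip(probe, window)
                ]
                seed_mm = sum(mism[i] for i in seed_rng)
                if seed_mm <= 2:
                    cands.append(((sum(mism), seed_mm), chrom, off, strand))
    if not cands:
        return ("unmapped", None, None, None, None, None)
    best_key = min(c[0] for c in cands)
    best = [c for c in cands if c[0] == best_key]
    if len(best) > 1:
        return ("multi", None, None, None, None, None)
    (total, seed_mm), chrom, off, strand = best[0]
    return ("unique", chrom, off, strand, seed_mm, total)


# ---------------------------------------------------------------------------
# exact test: enumeration oracle


def enumerate_exact_p(s_a: int, s_b: int, n_a: int, n_b: int, phi: float) -> float:
    """Conditional p-value by direct enumeration of negative-hypergeometric
    weights (phi > 0) or exact binomial weights (phi = 0)."""
    S = s_a + s_b
    if S == 0:
        return 1.0
    s = np.arange(S + 1)
    if phi < 1e-12:
        pa = n_a / (n_a + n_b)
        lw = (
            gammaln(S + 1)
            - gammaln(s + 1)
            - gammaln(S - s + 1)
            + s * np.log(pa)
            + (S - s) * np.log(1 - pa)
        )
    else:
        ra, rb = n_a / phi, n_b / phi
        lw = gammaln(s + ra) - gammaln(s + 1) + gammaln(S - s + rb) - gammaln(S - s + 1)
    w = np.exp(lw - lw.max())
    w = w / w.sum()
    return float(min(1.0, w[w <= w[s_a] * (1 + 1e-7)].sum()))


# ---------------------------------------------------------------------------
# concordance: naive classifier


def naive_category(de_rna: bool, det_a: bool, det_i: bool, de_a: bool, de_i: bool):
    if not de_rna:
        return None
    if not det_a and not det_i:
        return "rnaseq_only"
    if det_a and not det_i:
        return "affy_de" if de_a else "affy_no_de"
    if det_i and not det_a:
        return "illumina_de" if de_i else "illumina_no_de"
    if de_a and de_i:
        return "both_de_both"
    if de_a:
        return "both_de_affy"
    if de_i:
        return "both_de_illumina"
    return "both_no_de"


def naive_venn(r: set, a: set, i: set) -> dict[str, int]:
    counts = {
        "rnaseq_only": 0, "affy_only": 0, "illumina_only": 0,
        "rnaseq_affy": 0, "rnaseq_illumina": 0, "affy_illumina": 0,
        "all_three": 0,
    }
    for g in r | a | i:
        key = (g in r, g in a, g in i)
        name = {
            (True, False, False): "rnaseq_only",
            (False, True, False): "affy_only",
            (False, False, True): "illumina_only",
            (True, True, False): "rnaseq_affy",
            (True, False, True): "rnaseq_illumina",
            (False, True, True): "affy_illumina",
            (True, True, True): "all_three",
        }[key]
        counts[name] += 1
    return counts
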
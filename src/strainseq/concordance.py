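"""Cross-platform concordance of RNA-Seq and two microarray platforms.

Probe-level microarray results (mapping status, SNP overlap, detection
calls, p/q-values, linear fold changes) are consumed as inputs — the
upstream array preprocessing (RMA/MAS5, VST/RSN, the linear model) is out
of scope.  This module applies the probe/probeset filtering rules, picks
the best (smallest-q) probe per gene and platform, computes the
three-platform detection Venn, and classifies every RNA-Seq DE gene by
where it is detected and where it is also DE, counting fold-change
direction agreement within each category.

Probe tables are pandas DataFrames with columns: platform, probe_id,
probeset_id (Affymetrix), gene_id (may be empty), maps_unique,
n_probes_total / n_probes_after_mask (Affymetrix, per probeset),
spans_snp (Illumina), detection_calls (comma-separated per-sample
present/marginal/absent codes P/M/A in the samples-table order), p_value,
q_value, fold_change (linear-scale B6/D2).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import Q_THRESHOLD

VENN_REGIONS = (
    "rnaseq_only",
    "affy_only",
    "illumina_only",
    "rnaseq_affy",
    "rnaseq_illumina",
    "affy_illumina",
    "all_three",
)

CATEGORIES = (
    "rnaseq_only",            # RNA-Seq DE gene detected on neither array
    "affy_de", "affy_no_de",  # detected on Affymetrix only
    "illumina_de", "illumina_no_de",
    "both_de_both",           # detected on both arrays, DE on both (all three)
    "both_de_affy", "both_de_illumina",
    "both_no_de",             # detected on both, DE only by RNA-Seq
)


@dataclass
class ConcordanceSummary:
    per_gene: pd.DataFrame
    category_counts: dict[str, int]
    direction_agree: dict[str, int]
    direction_conflict: dict[str, int]
    abundance_ttest: tuple[float, float]  # (t statistic, two-sided p)
    anomalies: list[str] = field(default_factory=list)
    venn: dict[str, int] | None = None


# ---------------------------------------------------------------------------
# detection-call helpers


def _absent_in_both_strains(calls: str, strains: np.ndarray) -> bool:
    """True when an 'A' call occurs in >= 1 B6 and >= 1 D2 sample."""
    parts = [c.strip().upper()[:1] for c in calls.split(",")]
    if len(parts) != len(strains):
        raise ValueError("detection_calls length does not match samples table")
    absent = np.array([c == "A" for c in parts])
    return bool(absent[strains == "B6"].any() and absent[strains == "D2"].any())


# ---------------------------------------------------------------------------
# filters


def affy_rule_masks(probes: pd.DataFrame, samples: pd.DataFrame) -> dict[str, pd.Series]:
    """Per-probeset boolean failure masks for each Affymetrix rule.

    Rules: (no_gene_mapping) probeset lacks a unique-exon Ensembl gene
    mapping; (too_few_probes) fewer than 4 of the 11 probes survive
    SNP/non-unique masking; (absent_both_strains) an Absent call in >= 1
    sample of each strain.  The survivor set is the complement of the union
    of all masks and therefore independent of rule order.
    """
    strains = samples["strain"].to_numpy()
    gene = probes["gene_id"].fillna("")
    no_gene = (gene == "") | ~probes["maps_unique"].astype(bool)
    too_few = probes["n_probes_after_mask"].astype(int) < 4
    absent = probes["detection_calls"].map(
        lambda c: _absent_in_both_strains(c, strains)
    )
    return {
        "no_gene_mapping": no_gene,
        "too_few_probes": too_few,
        "absent_both_strains": absent,
    }


def filter_affy(
    probes: pd.DataFrame, samples: pd.DataFrame
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Apply the Affymetrix probeset filters; tally removals per rule
    (the first failing rule, in documented order, claims the probeset)."""
    masks = affy_rule_masks(probes, samples)
    return _apply_masks(probes, masks, ["no_gene_mapping", "too_few_probes", "absent_both_strains"])


def illumina_rule_masks(probes: pd.DataFrame, samples: pd.DataFrame) -> dict[str, pd.Series]:
    """Per-probe failure masks for each Illumina rule: non-unique genomic
    mapping, missing Ensembl gene ID, SNP-spanning sequence, and an absent
    detection call (detection p >= 0.05) in >= 1 sample of each strain —
    the last mirrors the Affymetrix exclusion pattern."""
    strains = samples["strain"].to_numpy()
    gene = probes["gene_id"].fillna("")
    return {
        "not_unique": ~probes["maps_unique"].astype(bool),
        "no_gene_id": gene == "",
        "spans_snp": probes["spans_snp"].astype(bool),
        "absent_both_strains": probes["detection_calls"].map(
            lambda c: _absent_in_both_strains(c, strains)
        ),
    }


def filter_illumina(
    probes: pd.DataFrame, samples: pd.DataFrame
) -> tuple[pd.DataFrame, dict[str, int]]:
    masks = illumina_rule_masks(probes, samples)
    return _apply_masks(
        probes, masks, ["not_unique", "no_gene_id", "spans_snp", "absent_both_strains"]
    )


def _apply_masks(probes, masks, order):
    tally = {name: 0 for name in order}
    claimed = pd.Series(False, index=probes.index)
    for name in order:
        newly = masks[name] & ~claimed
        tally[name] = int(newly.sum())
        claimed |= masks[name]
    return probes.loc[~claimed].copy(), tally


# ---------------------------------------------------------------------------
# best probe per gene, Venn, DE concordance


def best_probe_per_gene(surviving: pd.DataFrame) -> pd.DataFrame:
    """One record per gene: minimal q, ties by minimal p then probe_id."""
    df = surviving.sort_values(["q_value", "p_value", "probe_id"], kind="stable")
    return df.drop_duplicates(subset="gene_id", keep="first").set_index("gene_id")


def detection_venn(
    rnaseq_genes: set[str], affy_genes: set[str], illumina_genes: set[str]
) -> dict[str, int]:
    """Counts for the 7 regions of the three-platform detection Venn."""
    r, a, i = set(rnaseq_genes), set(affy_genes), set(illumina_genes)
    return {
        "rnaseq_only": len(r - a - i),
        "affy_only": len(a - r - i),
        "illumina_only": len(i - r - a),
        "rnaseq_affy": len((r & a) - i),
        "rnaseq_illumina": len((r & i) - a),
        "affy_illumina": len((a & i) - r),
        "all_three": len(r & a & i),
    }


def de_concordance(
    rnaseq: pd.DataFrame,
    affy_best: pd.DataFrame,
    illumina_best: pd.DataFrame,
    q_threshold: float = Q_THRESHOLD,
) -> ConcordanceSummary:
    """Classify every RNA-Seq DE gene by array detection and array DE.

    Detection on an array means the gene survived that platform's filters
    with >= 1 probe(set).  Within each category where an array also calls
    DE, fold-change direction agreement compares the sign of the RNA-Seq
    log2 fold change with the sign of log2 of the array's linear fold
    change (agreement requires every DE platform to agree).  Also reports
    a two-sided two-sample t-test comparing the average log abundance of
    genes DE only by RNA-Seq (but detected on both arrays) against genes
    whose DE is corroborated by >= 1 array.
    """
    de_genes = rnaseq.index[rnaseq["q_value"] < q_threshold]
    anomalies: list[str] = []
    rows = []
    for g in de_genes:
        det_a, det_i = g in affy_best.index, g in illumina_best.index
        de_a = bool(det_a and affy_best.at[g, "q_value"] < q_threshold)
        de_i = bool(det_i and illumina_best.at[g, "q_value"] < q_threshold)
        if not det_a and not det_i:
            cat = "rnaseq_only"
        elif det_a and not det_i:
            cat = "affy_de" if de_a else "affy_no_de"
        elif det_i and not det_a:
            cat = "illumina_de" if de_i else "illumina_no_de"
        elif de_a and de_i:
            cat = "both_de_both"
        elif de_a:
            cat = "both_de_affy"
        elif de_i:
            cat = "both_de_illumina"
        else:
            cat = "both_no_de"
        rna_sign = np.sign(rnaseq.at[g, "log2_fc"])
        agree = None
        if de_a or de_i:
            signs = []
            for de_flag, best in ((de_a, affy_best), (de_i, illumina_best)):
                if not de_flag:
                    continue
                fc = best.at[g, "fold_change"]
                if not np.isfinite(fc) or fc <= 0:
                    anomalies.append(g)
                    continue
                signs.append(np.sign(np.log2(fc)))
            agree = bool(signs) and all(s == rna_sign for s in signs)
        rows.append(
            {
                "gene_id": g,
                "detected_affy": det_a,
                "detected_illumina": det_i,
                "de_affy": de_a,
                "de_illumina": de_i,
                "category": cat,
                "direction_agree": agree,
                "avg_log_abundance": rnaseq.at[g, "avg_log_abundance"],
            }
        )
    per_gene = pd.DataFrame(rows).set_index("gene_id") if rows else pd.DataFrame(
        columns=["detected_affy", "detected_illumina", "de_affy", "de_illumina",
                 "category", "direction_agree", "avg_log_abundance"]
    )
    counts = {c: int((per_gene["category"] == c).sum()) for c in CATEGORIES}
    agree_counts, conflict_counts = {}, {}
    for c in CATEGORIES:
        sub = per_gene[(per_gene["category"] == c) & per_gene["direction_agree"].notna()]
        agree_counts[c] = int((sub["direction_agree"] == True).sum())  # noqa: E712
        conflict_counts[c] = int((sub["direction_agree"] == False).sum())  # noqa: E712

    only_rna = per_gene.loc[per_gene["category"] == "both_no_de", "avg_log_abundance"]
    corroborated = per_gene.loc[
        per_gene["category"].isin(["both_de_both", "both_de_affy", "both_de_illumina"]),
        "avg_log_abundance",
    ]
    if len(only_rna) >= 2 and len(corroborated) >= 2:
        t_res = stats.ttest_ind(only_rna, corroborated)
        ttest = (float(t_res.statistic), float(t_res.pvalue))
    else:
        ttest = (float("nan"), float("nan"))

    return ConcordanceSummary(
        per_gene=per_gene,
        category_counts=counts,
        direction_agree=agree_counts,
        direction_conflict=conflict_counts,
        abundance_ttest=ttest,
        anomalies=sorted(set(anomalies)),
    )


# ---------------------------------------------------------------------------
# IO


def read_probe_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "probe_id": str})
    for col in ("maps_unique", "spans_snp"):
        if col in df.columns:
            df[col] = df[col].astype(bool)
    return df


def write_probe_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)
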
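"""Allele-mapping bias: SNP-dense genes masquerade as differentially expressed.

A fixture plants 10 SNP-dense, flat-expressed genes (a SNP every 8 exon
bases, so every 43-base window of a D2 read carries more mismatches than
the 2-mismatch seed budget) among 10 ordinary genes.  Aligning everything
to the B6 reference loses most D2 reads from the dense genes, so they are
called DE with B6 > D2.  Realigning the D2 reads to the SNP-substituted
genome recovers them: the calls are reclassified as lost (putative false
positives of allele bias).
"""

from strainseq import run_allele_bias_pipeline
from strainseq.synthetic import planted_bias_fixture

fx = planted_bias_fixture(seed=11, n_dense=10, n_background=10, reads_per_sample=800)
print(f"genome: {sum(len(s) for s in fx.genome.values())} bases, "
      f"{len(fx.models.genes)} genes, {len(fx.snps)} SNPs "
      f"({int(fx.truth.genes['snp_dense'].sum())} SNP-dense genes)")

result = run_allele_bias_pipeline(
    fx.genome, fx.snps, fx.reads_by_sample, fx.models, fx.samples
)

print(f"\nsubstitution report: {result.substitution_report}")
print("\nDE status changes between reference and SNP-substituted runs:")
for cat, n in result.assessment.category_counts.items():
    if n:
        print(f"  {cat}: {n}")

d2 = [s for s in fx.samples.index if fx.samples.at[s, "strain"] == "D2"]
gain = (result.mapping_stats.loc[d2, "unique_alt"]
        - result.mapping_stats.loc[d2, "unique_ref"])
print(f"\nD2 uniquely mapped reads gained after substitution: "
      f"min {gain.min()}, mean {gain.mean():.0f} per sample")

tab = result.assessment.table
lost = tab[tab["status"] == "lost_B6gtD2"]["snps_per_kb"]
stable = tab[tab["status"] == "stable_nonDE"]["snps_per_kb"]
print(f"\nSNPs/kb: lost_B6gtD2 genes median {lost.median():.1f} "
      f"vs stable genes median {stable.median():.1f}")
print(
    "\nthe lost calls are exactly the SNP-dense genes: their apparent"
    "\nB6>D2 expression was an artifact of D2 reads exhausting the"
    "\nmismatch budget, not of biology."
)
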
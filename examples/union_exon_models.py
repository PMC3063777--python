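"""Build union-exon gene models and excise inter-gene overlaps.

Three genes are annotated with overlapping transcripts; gene B's first
exon also overlaps gene A.  The union model merges each gene's exons
across transcripts, and the shared interval is removed from both genes so
that gene-level read counting is unambiguous.
"""

from strainseq import ExonRecord, build_union_exons, remove_intergene_overlaps

annotation = [
    # gene A: two transcripts with overlapping exon boundaries
    ExonRecord("geneA", "A.T1", "chr1", 101, 200, "+"),
    ExonRecord("geneA", "A.T1", "chr1", 301, 400, "+"),
    ExonRecord("geneA", "A.T2", "chr1", 151, 250, "+"),
    # gene B starts inside gene A's second exon (opposite strand --
    # irrelevant: the protocol is unstranded)
    ExonRecord("geneB", "B.T1", "chr1", 351, 500, "-"),
    ExonRecord("geneC", "C.T1", "chr1", 601, 700, "+"),
]

merged = build_union_exons(annotation)
final = remove_intergene_overlaps(merged)

print("union exons after transcript merge (0-based half-open):")
for gid, gm in merged.genes.items():
    print(f"  {gid}: {gm.intervals}  length={gm.length}")

print("\nafter inter-gene overlap removal:")
for gid, gm in final.genes.items():
    print(f"  {gid}: {gm.intervals}  length={gm.length}")
print(f"removed intervals (shared between genes): {final.removed_intervals}")
print(
    "\ngeneA's transcripts merged into two union exons; the 50-base interval"
    "\nshared with geneB was excised from both, shortening both models."
)
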
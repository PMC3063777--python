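# Methods

This note records the models implemented by `strainseq`, the parameter
choices that matter, what the synthetic generator does and does not
emulate, and the numerical decisions taken where more than one defensible
option existed.

## Gene models

Union exons are computed per gene by merging all transcript exons into
maximal disjoint runs; book-ended intervals (one ending where the next
starts) merge, since counting by start position is insensitive to the
distinction and "non-redundant exons" reads most naturally as maximal
runs. Internally all coordinates are 0-based half-open; GTF/TSV input
and BED output convert at the file boundary only.

Inter-gene overlap removal excises every base covered by the union exons
of two or more genes from *all* genes sharing it, strand ignored — the
library preparation is unstranded, so an antisense overlap is exactly as
ambiguous as a sense one. Genes reduced to zero length are retained with
empty models (they surface in the zero-count filter report rather than
vanishing silently). Gene length, wherever it is used downstream
(length-bias quartiles, SNPs per kilobase), is the length of the *final*
model, i.e. after excision: a read can only be counted there, so density
and bias denominators refer to the countable territory.

## Aligner

The aligner is a deterministic mismatch-count model of seeded short-read
alignment, not a reimplementation of any production tool: reads are
trimmed to their first 43 bases, candidate loci are every offset and
strand where the read's first 32 bases match with ≤ 2 mismatches (an 'N'
on either side never matches), the best locus minimizes total mismatches
over all 43 bases with ties broken by seed mismatches, and *unique*
status requires exactly one best locus — equal-score loci never map, so
there is no random tie-breaking anywhere. Reverse-strand alignment
compares the read's reverse complement against the forward genome; the
reported position is always the leftmost forward-strand base of the
trimmed read, which is also the "start position" used for counting on
both strands (a single convention, shared with the test oracles).

This captures the one mechanism the bias analysis needs — strain SNPs
consume the mismatch budget — at a cost linear in genome size per read.
Mismatch counting is vectorized as a one-hot inner product between read
and every genome window, so a batch of reads is two matrix products per
chromosome; at the package's intended scale (tens of kilobases, tens of
thousands of reads) alignment takes seconds to a minute. Quality-aware
backtracking, gapped or spliced alignment, and paired ends are out of
scope.

## Counting and filters

A unique alignment increments gene *g* in its sample iff its position
lies in a union exon of *g*; after overlap removal membership is
unambiguous by construction. N_j (the per-sample library size used in
normalization) is the number of *unique* alignments in sample j, whether
or not they start in an exon; multi-mapped reads are excluded from both
counts and N_j. Gene filters: (a) all-zero rows; (b) a zero count in at
least one sample of *each* strain. Rule (a) takes precedence in the
removal report.

## Normalization and testing

* **Upper-quartile factors.** u_j is the 75th percentile (linear
  interpolation) of the counts of genes with y_gj > 0 in sample j —
  restricting to nonzero counts keeps the quantile meaningful on
  zero-heavy matrices. Factors f_j = (u_j/N_j) / geomean are normalized
  to geometric mean 1 so effective sizes M_j = f_j N_j stay on the scale
  of N_j.
* **Quantile adjustment.** Counts are mapped to pseudocounts at
  M* = geomean(M_j) by matching NB cumulative probabilities: the
  per-group abundance λ_g = Σy/ΣM sets the input mean λ_g M_j and output
  mean λ_g M*, the observed count's CDF value is located in the output
  distribution, and the pseudocount interpolates linearly between the
  bracketing integer quantiles (clamped at 0; plain ratio scaling in the
  extreme upper tail where the discrete CDF saturates numerically). When
  all M_j are equal the transformation is the identity, exactly.
* **Common dispersion.** φ maximizes the summed log conditional
  likelihood of each group's pseudocounts given their sum (the weights
  are negative-hypergeometric in the sums; expressed via log-gamma so
  real-valued pseudocounts are handled directly). The optimizer scans
  delta = φ/(1+φ) on a 25-point grid over [0.001, 0.95] and refines an
  interior optimum by golden-section search; a boundary optimum is
  returned as-is (so Poisson-like data reports φ ≈ 0.001). Adjustment
  and estimation are iterated twice, starting from φ = 0; with equal
  library sizes the iteration is exactly stationary after one pass.
* **Exact test.** Conditional on S = s_A + s_B (rounded pseudocount
  group sums; rounding is half-to-even for determinism), outcome
  probabilities are NBpmf(s; n_A μ̂, n_A/φ)·NBpmf(S−s; n_B μ̂, n_B/φ)
  normalized over s = 0..S, with μ̂ = S/(n_A+n_B). The two-sided p-value
  sums outcomes with probability ≤ p_obs·(1 + 1e−7); the relative tie
  tolerance is the same convention R's binomial test uses and is shared
  with the enumeration oracle, so borderline floating-point ties cannot
  flip between routes. φ < 1e−12 switches to the exact conditional
  binomial. S = 0 returns p = 1.
* **Poisson LRT.** Closed-form MLEs (Σy/ΣM per stratum) with M_j
  offsets; the statistic is referred to chi-square(1). It exists as the
  comparator: on overdispersed data it is anti-conservative and its
  spurious calls concentrate in long (high-count) genes, which the
  length-quartile summary makes visible.
* **q-values.** π̂₀ comes from the #{p > λ}/(m(1−λ)) grid, λ =
  0.05..0.95, fitted with a cubic polynomial and evaluated at λ = 1.
  The fit weights residuals by √(1−λ): the grid estimates' variance
  grows like 1/(1−λ), and unweighted extrapolation to λ = 1 is noisy
  enough to matter at a few thousand p-values. A fit above 1 (or an
  unusable grid) falls back to 1; a nonpositive fit falls back to the
  smallest positive grid estimate (floored at 1/m). q_(i) = min_{j≥i}
  π̂₀ m p_(j)/j, capped at 1, with tied p-values sharing the smallest q.
* **Calls.** log2FC = log2((mean B6 proportion + c)/(mean D2 proportion
  + c)) with zero-guard c = 0.5/M* (half a count at the common library
  size). Average abundance is log2 of the mean proportion across all
  samples; the low-count flag fires below −20 (≈ one read per million).
  Direction is assigned only at q < 0.01.

## Allele-bias assessment

Pipeline A aligns every sample to the reference; pipeline B reuses the
B6 alignments and realigns only the D2 reads to the SNP-substituted
genome (substitution preserves length, so coordinates are shared).
Pipeline B runs on pipeline A's post-filter gene universe without
re-filtering — status-change classification only makes sense on a common
universe — and re-estimates the dispersion rather than reusing A's (the
recovered D2 counts change the within-group variability the estimate
summarizes). Classification: retained_*/lost_*/gained_*/stable_nonDE by
(DE?, direction) in the two runs; a gene DE in both runs with opposite
directions gets an explicit `direction_flip` status (the seven
retained/lost/gained/stable categories cannot hold it), and flips are
also tallied separately. With zero SNPs the two pipelines are bit-identical.

## Concordance

Array preprocessing (RMA/MAS5 detection, VST/RSN, the linear model) is
upstream of this package; probe tables arrive with mapping flags,
SNP-overlap flags, per-sample detection calls, p/q-values, and
linear-scale fold changes. Filters are independent boolean rules — the
survivor set is order-invariant; only the per-rule removal tally depends
on the documented order (first failing rule claims the probe). The
Illumina absent-call exclusion mirrors the Affymetrix "absent in ≥ 1
sample of each strain" pattern; only the present threshold (detection
p < 0.05) is platform-specific, and this symmetric choice is a documented
assumption. Detection means surviving all filters with ≥ 1 probe(set);
array fold changes are log2-transformed internally for sign comparison.
The abundance t-test compares genes DE only by RNA-Seq (but detected on
both arrays) against genes corroborated by ≥ 1 array.

## Synthetic data

The generator emulates the study conditions: 10 B6 + 11 D2 samples over
three flowcells; 76-base single-end reads trimmed downstream to 43;
NB counts with common dispersion and planted log2 fold changes;
upper-quartile-relevant library-size variation (factors 0.5–2); a D2 SNP
list with an optional SNP-dense gene subset (one SNP per 8 exon bases,
so every 43-base window carries ≥ 3 — beyond the seed budget); and
probe-level array tables whose defect fractions exercise every filter
rule. Reads sample a (possibly spliced) 76-base window from the union
model with the 43-base alignment window constrained to a single exon, so
the ungapped aligner can always recover the origin; junction-spanning
alignment windows are deliberately not generated, which is precisely the
aligner's documented limitation. All stages derive their random streams
from the seed plus a per-stage offset, so artifacts are byte-identical
across runs and independent of stage order.

Defaults that matter (units; rationale):

| parameter | default | why |
| --- | --- | --- |
| common dispersion φ | 0.1 | biological CV ≈ 32% between inbred-strain replicates |
| gene mean | lognormal(log 50, 1) counts/sample | spans ~5–500, keeping discreteness visible but not dominant |
| DE fraction | 0.10 | a minority of genes differ between strains |
| effect sizes | uniform 1–2.5 log2, signs balanced | 2- to 5.7-fold; balance keeps the strains' total expressed mass comparable, which matters on small panels (see below) |
| library factors | uniform 0.5–2 | the lane/flowcell heterogeneity upper-quartile scaling exists to fix |
| read error rate | 0.002/base | short-read substitution scale |
| dense-gene SNP spacing | 8 bases | guarantees ≥ 3 SNPs per 43-base window |

The generator does **not** emulate positional/hexamer priming bias, GC
effects, quality-score structure, indels or structural variants,
heterozygosity, or junction reads. Passing tests therefore demonstrate
the *logic* of the pipeline — counting, calibration, bias mechanics,
classification — on data that satisfy the model's assumptions; they do
not certify performance on real libraries, where those unmodeled
features are the main hazards.

## Problem sizes and calibration checks

Calibration and recovery checks run at 2,000 genes × 21 samples (type-I
error under the NB null at φ = 0.2; dispersion recovery at φ = 0.1;
planted-DE sensitivity/FDR), where the exact-test machinery is the thing
exercised and counts can simply be simulated. The full read-level chain
(simulate reads → trim → align → count → filter → test) runs at ~60
genes and ~2,500 reads per sample — the aligner is exhaustive by design,
so read-level problem sizes are chosen to keep it in the seconds-to-a-
minute range while still covering every stage. The detection-power check
(2-fold effects at per-sample mean 100 detected at q < 0.01 in > 80% of
genes) is run at the generator's default φ = 0.1: at n = 10 vs 11 a
2-fold change is simply not reliably detectable at φ = 0.2 (a Wald
calculation puts power near 55%), so the stress dispersion is reserved
for the calibration checks where it belongs.

One composition effect is worth knowing about: on a small gene panel,
planting strongly one-sided fold changes shifts every null gene's
*relative* abundance between strains, and when the upper quartile itself
lands among perturbed genes the factors cannot absorb the shift — null
genes then show genuine proportion differences. This is a real property
of composition-based normalization, not a bug; the read-level fixture
plants sign-balanced effects so that it measures test behaviour rather
than this artifact.

## Known limitations

* The aligner is O(reads × genome) and ungapped; it is a mechanism
  model, not a production mapper.
* Common dispersion only — no tagwise/trended estimation, no GLMs or
  covariates (the two-group design does not need them).
* The exact test operates on rounded pseudocount sums; at very low
  counts the rounding and the discreteness of the conditional
  distribution make p-values mildly conservative.
* Microarray detection p-values and preprocessing are consumed, never
  computed.
* `direction_flip` is an extension of the seven status-change
  categories; consumers expecting exactly seven should map it.
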
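"""Negative-binomial exact testing on counts with planted fold changes.

Counts for 2,000 genes across the study design (10 B6 vs 11 D2 lanes,
variable library sizes) are simulated with common dispersion 0.1 and 10%
of genes carrying 2- to 5.7-fold planted changes.  The pipeline
upper-quartile normalizes, estimates the common dispersion by conditional
maximum likelihood, runs the exact test, and converts p-values to Storey
q-values; the Poisson likelihood-ratio comparator is run on the same
matrix to show its anti-conservativeness under overdispersion.
"""

import numpy as np

from strainseq import filter_genes, run_exact_de, run_poisson_de
from strainseq.synthetic import (
    CountConfig,
    SimulationConfig,
    default_samples,
    simulate_count_matrix,
)

samples = default_samples()
config = SimulationConfig(
    seed=7,
    counts=CountConfig(n_genes=2000, dispersion=0.1, de_fraction=0.1,
                       effect_size=(1.0, 2.5)),
)
cm, truth = simulate_count_matrix(config, samples)
kept, report = filter_genes(cm)
print(f"{len(cm.counts)} simulated genes; {len(report)} removed by zero-count filters")

results, factors, dispersion = run_exact_de(kept)
print(f"\nupper-quartile factors span {factors.factors.min():.2f}-{factors.factors.max():.2f}"
      f" (geometric mean 1)")
print(f"estimated common dispersion phi = {dispersion.phi:.4f} (true 0.1)")

de_called = results[results["q_value"] < 0.01]
n_up = (de_called["direction"] == "B6>D2").sum()
n_down = (de_called["direction"] == "D2>B6").sum()
print(f"\nexact test: {len(de_called)} DE genes at q < 0.01 "
      f"({n_up} B6>D2, {n_down} D2>B6)")

t = truth.genes.loc[results.index]
detected = results["q_value"] < 0.01
sens = (detected & t["is_de"]).sum() / t["is_de"].sum()
fdr = (detected & ~t["is_de"]).sum() / max(int(detected.sum()), 1)
print(f"against planted truth: sensitivity {100 * sens:.1f}%, FDR {100 * fdr:.1f}%")

poisson, _ = run_poisson_de(kept)
print(f"\nPoisson LRT on the same matrix rejects {100 * (poisson['p_value'] < 0.05).mean():.1f}%"
      f" of genes at p < 0.05 vs {100 * (results['p_value'] < 0.05).mean():.1f}% for the"
      f" exact test --\nwith only 10% of genes truly DE the Poisson model is"
      f" strongly anti-conservative\nbecause it ignores biological overdispersion.")
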
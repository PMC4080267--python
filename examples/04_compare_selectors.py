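"""Benchmark the PCA-outlier route against supervised selectors.

Pearson/Spearman correlation with the ordinal class code and PLS weights
all need the class ranking as pre-knowledge; the PCA route does not. The
benchmark counts how many of each method's top-N genotype and methylation
selections coincide.
"""

import gsmeth as gm

params = gm.SimulationParams(n_probes=5000, n_signal=80, seed=4)
genotype, methylation, design, truth = gm.generate_paired_dataset(params)

report = gm.compare_methods(genotype, methylation, design, N=200)
print(report.to_string(index=False))
# With 80 strongly planted probes every executable method recovers the
# planted set, so overlaps cluster just above 80; stepwise LDA and lasso
# are not executable at array scale and are reported as "--".
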
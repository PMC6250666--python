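"""Variant/gene QC and the four-step expression normalisation chain.

Filters a simulated panel (MAF >= 5%, HWE exact P, call rate), then runs
log2(TPM+1) -> robust quantile normalisation -> outlier imputation ->
rank-based inverse normal transform, and prints what each step did.
"""

import numpy as np

from nephroqtl import qc, synth

cfg = synth.SimulationConfig(seed=1, n_blocks=40, n_genes=40,
                             maf_range=(0.02, 0.5))  # some variants below 5% MAF
geno = synth.simulate_genotypes(cfg)
expr, _ = synth.simulate_expression(geno, cfg)

filtered, report = qc.filter_variants(geno, maf_min=0.05, hwe_p_min=1e-6)
print(f"variant QC: {report.n_input} -> {report.n_output}  removed: {report.excluded}")

kept_genes, gene_report = qc.filter_genes(expr)
print(f"gene filter: {gene_report.n_input} -> {gene_report.n_output}")

norm = qc.normalize_expression(kept_genes)
v = norm.values.to_numpy()
print(f"after RBINT: per-gene mean {v.mean(axis=1).mean():+.4f}, "
      f"SD {v.std(axis=1).mean():.4f}  (target: 0 and 1)")

pcs = qc.genotype_pcs(filtered, k=3)
hf = qc.estimate_hidden_factors(norm, None, k=2)
print(f"covariates ready: {pcs.shape[1]} genotype PCs, {hf.shape[1]} hidden factors")
# The PCs absorb genotype structure, the hidden factors broad expression
# variation; both enter every cis regression as nuisance covariates.
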
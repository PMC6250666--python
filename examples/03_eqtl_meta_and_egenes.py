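"""cis-eQTL mapping, two-study meta-analysis and permutation-calibrated eGenes.

Runs the per-study regressions and inverse-variance meta over all SNP-gene
pairs within 1 Mb, calibrates gene-level significance with B permutations,
and calls eGenes at q < 0.05.  With planted effects of 1 SD/allele the
caller should recover essentially every planted gene and nothing else.
"""

import pandas as pd

from nephroqtl import eqtl, permfdr, qc, synth

cfg = synth.SimulationConfig(seed=9, n_blocks=25, n_genes=25, frac_egenes=0.3,
                             fixed_effect_size=1.0, expression_scale="sd")
geno = synth.simulate_genotypes(cfg)
expr, truth = synth.simulate_expression(geno, cfg)

studies = []
for label in ("S1", "S2"):
    ids = geno.samples.index[geno.samples["study"] == label]
    sub = geno.subset_samples(ids)
    cov = pd.concat([sub.samples[["age", "sex"]].astype(float),
                     qc.genotype_pcs(sub, k=3)], axis=1)
    studies.append(eqtl.StudyData(expr.values[list(ids)], sub.dosages, cov))

pairs = eqtl.map_cis_pairs(expr.genes, geno.variants)
meta = eqtl.run_cis_eqtl(studies, expr.genes, geno.variants, pairs=pairs)
print(f"tested {len(pairs)} cis pairs across {expr.n_genes} genes")

calib = permfdr.calibrate(meta, studies, pairs, B=1000, seed=9)
egenes, sig_pairs, best = permfdr.call_egenes_esnps(meta, calib,
                                                    variants=geno.variants)
planted = {g for g, _, _ in truth.planted_pairs}
print(f"eGenes called : {len(egenes)}  (planted: {len(planted)})")
print(f"recall        : {len(set(egenes) & planted) / len(planted):.2f}")
print(f"genome-wide P_t = {calib.p_t:.2e}; {len(sig_pairs)} significant pairs")
print("\nbest eSNP per eGene (gene, snp, meta beta, meta p):")
for _, r in best.head(5).iterrows():
    print(f"  {r['gene']}  {r['snp']}  {r['beta_meta']:+.2f}  {r['p_meta']:.2e}")
# A perfect run recovers each planted gene with its causal variant (or a
# tight LD partner from the same block) as the best eSNP.
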
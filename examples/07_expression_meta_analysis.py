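"""Cross-study expression-phenotype meta-analysis (Nephroseq-style).

Case-control studies contribute log2 fold differences combined by Stouffer's
weighted Z; correlation studies (eGFR) contribute Pearson r pooled by the
Olkin-Pratt fixed-effect estimator.  Cochran's Q guards against calling
significance in the presence of heterogeneity.
"""

from nephroqtl import expr_meta

cc_studies = [
    {"log2fc": 1.1, "p": 0.004, "n": 53},
    {"log2fc": 0.7, "p": 0.020, "n": 52},
    {"log2fc": 0.9, "p": 0.010, "n": 31},
]
res = expr_meta.meta_analyse_gene(cc_studies, "case_control", m=29)
print("case-control meta (3 studies):")
print(f"  Stouffer Z = {res['effect']:+.2f}, p = {res['p']:.2e}")
print(f"  heterogeneity Q p = {res['Q_p']:.2f}")
print(f"  significant at 0.05/29 = {res['threshold']:.4f}? {res['significant']}\n")

egfr_studies = [
    {"r": -0.42, "n": 186},
    {"r": -0.35, "n": 49},
    {"r": -0.50, "n": 24},
]
res = expr_meta.meta_analyse_gene(egfr_studies, "correlation", m=29)
print("eGFR correlation meta (3 studies):")
print(f"  pooled r = {res['effect']:+.3f}, p = {res['p']:.2e}, "
      f"Q p = {res['Q_p']:.2f}, significant: {res['significant']}")

flag = expr_meta.consistency_check(meta_direction=-1,
                                   eqtl_risk_direction=+1, phenotype="egfr")
print(f"\nrisk allele raises expression, expression lower eGFR: {flag}")
# 'concordant' means the expression-phenotype direction matches what the
# GWAS risk allele's eQTL effect predicts.
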
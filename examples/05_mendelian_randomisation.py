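"""Two-sample MR of gene expression on a trait with the three robust estimators.

Simulates 30 instruments with a true causal effect of 0.3 trait units per
1-SD expression, contaminates them with directional pleiotropy, and shows
how the Egger intercept picks the pleiotropy up while the slope estimates
stay close to the truth.
"""

from nephroqtl import mr, synth

print("clean instruments (theta = 0.3):")
inst = synth.simulate_mr_summary(30, theta=0.3, seed=8)
res = mr.run_mr(inst, m=7, n_boot=500, seed=8)
for e in res["estimates"]:
    print(f"  {e.method:26s} theta={e.theta:+.3f}  se={e.se:.3f}  p={e.p:.2e}")
print(f"  Cochran Q p = {res['sensitivity']['Q_p']:.3f}  "
      f"verdict: causal={res['verdict']['causal']} "
      f"(threshold {res['verdict']['threshold']:.4f})")

print("\ndirectional pleiotropy 0.05 on every instrument "
      "(60 precise instruments, se_y = 0.01):")
inst = synth.simulate_mr_summary(60, theta=0.3, pleiotropy_mean=0.05,
                                 pleiotropy_sd=0.01, se_y=0.01, seed=8)
egger = mr.egger_robust(inst)
print(f"  egger slope     = {egger.theta:+.3f} (true 0.3)")
print(f"  egger intercept = {egger.intercept:+.3f} (true pleiotropy 0.05), "
      f"p = {egger.intercept_p:.3g}")
# IVW absorbs uniform pleiotropy into its slope; the Egger intercept
# estimates it directly and its test flags the violated assumption.  The
# slope/intercept split is only well identified when exposure effects vary
# and outcome noise is small; on a noisier single dataset the intercept is
# unbiased only on average.
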
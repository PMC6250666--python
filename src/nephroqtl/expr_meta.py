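"""Cross-study meta-analysis of expression-phenotype associations.

Two modes, mirroring how curated renal microarray studies report effects:

* case-control -- each study contributes a log2 fold difference with a
  p-value; the signed z-scores are combined by Stouffer's method with
  sample-size weights (w_k = sqrt(n_k) by default);
* correlation -- each study contributes a Pearson r with the trait (eGFR);
  the per-study correlations get the Olkin-Pratt small-sample correction
  G_k = r_k (1 + (1 - r_k^2) / (2 (n_k - 3))) and are pooled fixed-effect
  with weights n_k - 1; the pooled p uses the Fisher z transform at the
  total sample size.

Cochran's Q (on the z / Fisher-z scale) screens for heterogeneity; gene
calls require Bonferroni significance in the absence of heterogeneity.
"""

from __future__ import annotations

import numpy as np
from scipy import stats


def p_to_signed_z(p: float, direction: float) -> float:
    """One-sided z carrying the effect direction: sign(direction) * |z(p/2)|."""
    z = stats.norm.isf(p / 2.0)
    return float(np.sign(direction) * z)


def stouffer_weighted(study_zs, weights=None, ns=None) -> tuple[float, float]:
    """Stouffer's weighted Z: Z = sum(w z) / sqrt(sum w^2), two-sided normal p.

    Default weights are sqrt(n_k) when sample sizes are given, else equal.
    """
    z = np.asarray(study_zs, dtype=float)
    if weights is None:
        weights = np.sqrt(np.asarray(ns, dtype=float)) if ns is not None else np.ones_like(z)
    w = np.asarray(weights, dtype=float)
    if w.shape != z.shape:
        raise ValueError("weights must match study z-scores")
    Z = float((w * z).sum() / np.sqrt((w**2).sum()))
    p = float(2.0 * stats.norm.sf(abs(Z)))
    return Z, p


def olkin_pratt_g(r: float, n: int) -> float:
    """Approximately unbiased correlation: G = r (1 + (1 - r^2) / (2 (n - 3)))."""
    if n <= 3:
        raise ValueError("correlation mode requires n > 3")
    if abs(r) >= 1:
        raise ValueError("|r| must be < 1")
    return float(r * (1.0 + (1.0 - r * r) / (2.0 * (n - 3))))


def olkin_pratt_meta(study_rs, study_ns, weight: str = "n-1") -> tuple[float, float]:
    """Fixed-effect pooled correlation of Olkin-Pratt-corrected study r's.

    Pooled estimate = sum(w_k G_k) / sum(w_k) with w_k = n_k - 1 (default) or
    n_k - 3; two-sided p via Fisher z of the pooled estimate at the total n.
    """
    rs = np.asarray(study_rs, dtype=float)
    ns = np.asarray(study_ns, dtype=float)
    g = np.array([olkin_pratt_g(r, int(n)) for r, n in zip(rs, ns)])
    if weight == "n-1":
        w = ns - 1
    elif weight == "n-3":
        w = ns - 3
    else:
        raise ValueError("weight must be 'n-1' or 'n-3'")
    pooled = float((w * g).sum() / w.sum())
    n_eff = float(ns.sum())
    pooled_c = np.clip(pooled, -1 + 1e-12, 1 - 1e-12)
    z = np.arctanh(pooled_c) * np.sqrt(max(n_eff - 3.0, 1.0))
    p = float(2.0 * stats.norm.sf(abs(z)))
    return pooled, p


def heterogeneity_q(effects, variances) -> tuple[float, float]:
    """Cochran's Q with inverse-variance weights, chi-square on k-1 df.

    For correlation-mode studies pass Fisher-z effects with variance
    1/(n-3); for case-control pass the signed z's with unit variance.
    """
    y = np.asarray(effects, dtype=float)
    v = np.asarray(variances, dtype=float)
    w = 1.0 / v
    mu = (w * y).sum() / w.sum()
    q = float((w * (y - mu) ** 2).sum())
    df = y.size - 1
    p = float(stats.chi2.sf(q, df)) if df > 0 else float("nan")
    return q, p


def heterogeneity_q_correlations(study_rs, study_ns) -> tuple[float, float]:
    rs = np.asarray(study_rs, dtype=float)
    ns = np.asarray(study_ns, dtype=float)
    return heterogeneity_q(np.arctanh(rs), 1.0 / (ns - 3.0))


def bonferroni(m: int, alpha: float = 0.05) -> float:
    """Family-wise threshold alpha / m."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return alpha / m


def consistency_check(
    meta_direction: float,
    eqtl_risk_direction: float,
    phenotype: str = "disease",
) -> str:
    """Is the meta-analysed expression-phenotype direction what the alleles imply?

    ``eqtl_risk_direction`` is the sign of the risk allele's effect on
    expression.  For a disease phenotype the expected expression-phenotype
    direction equals that sign (risk allele raises expression => expression
    higher in cases); for eGFR (a protective direction: higher is healthier)
    the expectation is inverted.  Returns 'concordant', 'discordant' or
    'indeterminate' (zero effect).
    """
    if meta_direction == 0 or eqtl_risk_direction == 0:
        return "indeterminate"
    expected = np.sign(eqtl_risk_direction)
    if phenotype == "egfr":
        expected = -expected
    return "concordant" if np.sign(meta_direction) == expected else "discordant"


def meta_analyse_gene(
    studies: list[dict],
    mode: str,
    alpha: float = 0.05,
    m: int = 1,
) -> dict:
    """Meta-analyse one gene across studies and apply the Bonferroni call.

    Each study dict carries ``n`` plus either (``log2fc``, ``p``) for
    case-control or ``r`` for correlation mode.  The significance call
    requires both p below alpha/m and no detected heterogeneity (Q p >= 0.05).
    """
    threshold = bonferroni(m, alpha)
    if mode == "case_control":
        zs = [p_to_signed_z(s["p"], s["log2fc"]) for s in studies]
        ns = [s["n"] for s in studies]
        Z, p = stouffer_weighted(zs, ns=ns)
        q, q_p = heterogeneity_q(zs, np.ones(len(zs)))
        effect = Z
    elif mode == "correlation":
        rs = [s["r"] for s in studies]
        ns = [s["n"] for s in studies]
        effect, p = olkin_pratt_meta(rs, ns)
        q, q_p = heterogeneity_q_correlations(rs, ns)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return {
        "mode": mode,
        "effect": float(effect),
        "p": float(p),
        "Q": q,
        "Q_p": q_p,
        "threshold": threshold,
        "significant": bool(p < threshold and (not np.isfinite(q_p) or q_p >= 0.05)),
    }
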
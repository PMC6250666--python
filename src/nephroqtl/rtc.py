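"""Regulatory trait concordance (RTC) colocalisation score.

Given one interval (a recombination coldspot) containing both a GWAS
sentinel and a cis-eQTL variant for some eGene, the expression is first
residualised on the GWAS variant's dosage ("pseudo-phenotype").  Every
variant in the interval is then regressed against the pseudo-phenotype and
ranked by descending p-value (the highest p gets rank 0: conditioning on the
GWAS variant has destroyed its signal most completely).  The score of the
eQTL variant is (N - rank) / N; a score >= 0.9 flags the pair as tagging the
same causal variant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .eqtl import fit_linear_association


@dataclass
class RtcResult:
    interval: str
    gwas_snp: str
    eqtl_snp: str
    egene: str
    n_snps: int
    rank: float  # 0-based; may be fractional when p-values tie (average rank)
    score: float
    colocalised: bool | None = None


def pseudo_phenotype(
    expr_gene: np.ndarray,
    gwas_dosage: np.ndarray,
    covariates: np.ndarray | None = None,
) -> np.ndarray:
    """Residuals of expression regressed on the GWAS variant (plus covariates)."""
    y = np.asarray(expr_gene, dtype=float)
    g = np.asarray(gwas_dosage, dtype=float)
    n = y.shape[0]
    X = np.column_stack(
        [np.ones(n), g]
        + ([np.asarray(covariates, dtype=float)] if covariates is not None else [])
    )
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ coef


def rtc_score(
    interval_dosages: pd.DataFrame,
    expr_gene: np.ndarray,
    gwas_snp: str,
    eqtl_snp: str,
    covariates: np.ndarray | None = None,
    interval_id: str = "interval",
    egene: str = "gene",
) -> RtcResult:
    """RTC score of one GWAS-eQTL signal pair within one interval.

    ``interval_dosages`` holds the dosages of all N variants in the interval
    (samples x variants); both ``gwas_snp`` and ``eqtl_snp`` must be among
    its columns and N must be >= 2.  Tied pseudo-phenotype p-values get
    average ranks.
    """
    snps = list(interval_dosages.columns)
    if gwas_snp not in snps or eqtl_snp not in snps:
        raise ValueError("gwas_snp and eqtl_snp must lie inside the interval")
    n_snps = len(snps)
    if n_snps < 2:
        raise ValueError("interval must contain at least 2 variants")
    e_dos = interval_dosages[eqtl_snp].to_numpy(dtype=float)
    if np.ptp(e_dos) == 0:
        raise ValueError("eqtl_snp is monomorphic in the interval")
    resid = pseudo_phenotype(
        expr_gene, interval_dosages[gwas_snp].to_numpy(dtype=float), covariates
    )
    pvals = np.empty(n_snps)
    for j, snp in enumerate(snps):
        d = interval_dosages[snp].to_numpy(dtype=float)
        if np.ptp(d) == 0:
            pvals[j] = 1.0  # no residual association possible
            continue
        _, _, _, p = fit_linear_association(resid, d, covariates)
        pvals[j] = p
    # descending p: highest p -> rank 0; ties get average rank
    rank_desc = stats.rankdata(-pvals, method="average") - 1.0
    rank = float(rank_desc[snps.index(eqtl_snp)])
    score = (n_snps - rank) / n_snps
    return RtcResult(
        interval=interval_id, gwas_snp=gwas_snp, eqtl_snp=eqtl_snp,
        egene=egene, n_snps=n_snps, rank=rank, score=float(score),
    )


def call_colocalisation(
    results: list[RtcResult], threshold: float = 0.9
) -> list[RtcResult]:
    """Flag each result; a score >= threshold (inclusive) colocalises."""
    out = []
    for r in results:
        r.colocalised = bool(r.score >= threshold)
        out.append(r)
    return out


def results_table(results: list[RtcResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "interval": r.interval, "gwas_snp": r.gwas_snp,
                "esnp": r.eqtl_snp, "egene": r.egene, "N": r.n_snps,
                "rank": r.rank, "rtc": r.score, "colocalised": r.colocalised,
            }
            for r in results
        ]
    )
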
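"""Variant / sample / gene quality control and expression normalisation.

The variant filters mirror a standard post-imputation panel: MAF >= 5%,
Hardy-Weinberg exact P above a caller-chosen threshold (0.001 for genotyped
panels, 1e-6 for imputed ones), call rate >= 95%, imputation R^2 >= 0.4,
duplicated positions / non-SNPs / sex-and-mitochondrial variants removed.

The expression chain is: log2(TPM + 1) -> robust quantile normalisation
(target distribution = per-rank *median* across samples) -> per-gene robust
outlier replacement (residuals beyond Q1 - 3 IQR or Q3 + 3 IQR of a Huber
fit are re-imputed from a refit without them) -> per-gene rank-based inverse
normal transform (Blom offsets).  Hidden expression factors are estimated by
PCA on covariate-residualised expression, playing the adjustment role that
PEER factors play on real data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .containers import ExpressionMatrix, GenotypeMatrix

log = logging.getLogger(__name__)

SEX_MT_CHROMS = {"X", "Y", "MT", "M", "chrX", "chrY", "chrM", "chrMT", "23", "24", "26"}


@dataclass
class QcReport:
    """Per-filter exclusion counts; reasons are assigned first-match."""

    n_input: int
    n_output: int = 0
    excluded: dict = field(default_factory=dict)

    def add(self, reason: str, n: int = 1) -> None:
        if n:
            self.excluded[reason] = self.excluded.get(reason, 0) + int(n)

    def validate(self) -> None:
        if self.n_input - self.n_output != sum(self.excluded.values()):
            raise AssertionError("QcReport counts do not reconcile")

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_output": self.n_output,
            "excluded": dict(self.excluded),
        }


def hwe_exact_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact Hardy-Weinberg test, conditional on the observed allele counts.

    Two-sided p-value: the sum of probabilities of all heterozygote counts
    whose conditional probability does not exceed the observed one.
    """
    if min(n_hom_ref, n_het, n_hom_alt) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_hom_ref + n_het + n_hom_alt
    if n == 0:
        return 1.0
    n_rare = 2 * min(n_hom_ref, n_hom_alt) + n_het
    if n_rare == 0:
        return 1.0  # monomorphic
    # log-probability of each feasible het count (same parity as n_rare)
    hets = np.arange(n_rare % 2, n_rare + 1, 2)
    rare_hom = (n_rare - hets) // 2
    com_hom = n - hets - rare_hom
    from scipy.special import gammaln

    logp = (
        gammaln(n + 1)
        - gammaln(hets + 1)
        - gammaln(rare_hom + 1)
        - gammaln(com_hom + 1)
        + hets * np.log(2.0)
        + gammaln(n_rare + 1)
        + gammaln(2 * n - n_rare + 1)
        - gammaln(2 * n + 1)
    )
    p = np.exp(logp - logp.max())
    p /= p.sum()
    obs = int(np.where(hets == n_het)[0][0])
    return float(min(1.0, p[p <= p[obs] * (1 + 1e-12)].sum()))


def genotype_counts(dosage: np.ndarray) -> tuple[int, int, int]:
    """Hard-call genotype counts (hom ref, het, hom alt) from dosages."""
    calls = np.rint(dosage[np.isfinite(dosage)]).astype(int)
    return int((calls == 0).sum()), int((calls == 1).sum()), int((calls == 2).sum())


def filter_variants(
    geno: GenotypeMatrix,
    maf_min: float = 0.05,
    hwe_p_min: float = 1e-6,
    call_rate_min: float = 0.95,
    impute_r2_min: float = 0.4,
    drop_sex_mt: bool = True,
) -> tuple[GenotypeMatrix, QcReport]:
    """Apply the variant QC filters; each exclusion gets one (first-failing) reason.

    Order of precedence: sex/MT chromosome, duplicated position, non-SNP,
    call rate, imputation R^2, MAF, HWE.
    """
    report = QcReport(n_input=geno.n_variants)
    v = geno.variants
    dos = geno.dosages.to_numpy(dtype=float)
    keep = []
    dup = v.duplicated(subset=["chrom", "pos"], keep=False)
    for j, snp in enumerate(v.index):
        row = v.iloc[j]
        if drop_sex_mt and str(row["chrom"]) in SEX_MT_CHROMS:
            report.add("sex_or_mt_chromosome")
            continue
        if dup.iloc[j]:
            report.add("duplicated_position")
            continue
        if len(str(row["ref"])) != 1 or len(str(row["alt"])) != 1:
            report.add("not_a_snp")
            continue
        d = dos[:, j]
        call_rate = np.isfinite(d).mean()
        if call_rate < call_rate_min:
            report.add("call_rate")
            continue
        if "imputation_r2" in v.columns and np.isfinite(row.get("imputation_r2", np.nan)):
            if row["imputation_r2"] < impute_r2_min:
                report.add("imputation_r2")
                continue
        af = np.nanmean(d) / 2.0
        if min(af, 1 - af) < maf_min:
            report.add("maf")
            continue
        if hwe_exact_test(*genotype_counts(d)) < hwe_p_min:
            report.add("hwe")
            continue
        keep.append(snp)
    if not keep:
        log.warning("variant QC removed every variant")
        out = GenotypeMatrix(
            geno.dosages.iloc[:, :0], geno.variants.iloc[:0], geno.samples
        )
    else:
        out = geno.subset_variants(keep)
    report.n_output = out.n_variants
    report.validate()
    return out, report


def filter_samples(
    geno: GenotypeMatrix,
    expr: ExpressionMatrix | None = None,
    miss_max: float = 0.05,
    het_sd: float = 3.0,
    exclude: list | None = None,
) -> tuple[list, QcReport]:
    """Drop samples with high genotype missingness or outlying heterozygosity.

    IBD / ancestry / sex-mismatch exclusions are consumed via ``exclude``
    (computed out of band), never derived here.
    """
    report = QcReport(n_input=geno.n_samples)
    dos = geno.dosages.to_numpy(dtype=float)
    miss = (~np.isfinite(dos)).mean(axis=1)
    calls = np.rint(dos)
    with np.errstate(invalid="ignore"):
        het = np.nansum(calls == 1, axis=1) / np.maximum(
            np.isfinite(dos).sum(axis=1), 1
        )
    mu, sd = het.mean(), het.std()
    excl = set(exclude or [])
    kept = []
    for i, sid in enumerate(geno.dosages.index):
        if sid in excl:
            report.add("external_exclusion")
        elif miss[i] > miss_max:
            report.add("genotype_missingness")
        elif sd > 0 and abs(het[i] - mu) > het_sd * sd:
            report.add("heterozygosity_outlier")
        elif expr is not None and sid not in expr.values.columns:
            report.add("no_expression_data")
        else:
            kept.append(sid)
    report.n_output = len(kept)
    report.validate()
    return kept, report


def filter_genes(
    expr_tpm: ExpressionMatrix,
    tpm_min: float = 0.1,
    frac: float = 0.5,
    drop_sex: bool = True,
) -> tuple[ExpressionMatrix, QcReport]:
    """Keep genes strictly above ``tpm_min`` TPM in >= ``frac`` of samples in EVERY batch."""
    if expr_tpm.stage != "tpm":
        raise ValueError("gene filter applies to TPM-stage expression")
    report = QcReport(n_input=expr_tpm.n_genes)
    vals = expr_tpm.values
    batches = expr_tpm.batch
    ok = pd.Series(True, index=vals.index)
    for b in batches.unique():
        cols = batches.index[batches == b]
        ok &= (vals[cols] > tpm_min).mean(axis=1) >= frac
    sex = expr_tpm.genes["chrom"].astype(str).isin({"X", "Y", "chrX", "chrY", "23", "24"})
    for g in vals.index:
        if drop_sex and sex.loc[g]:
            report.add("sex_chromosome")
        elif not ok.loc[g]:
            report.add("low_expression")
    keep = [g for g in vals.index if ok.loc[g] and not (drop_sex and sex.loc[g])]
    out = expr_tpm.subset_genes(keep)
    report.n_output = out.n_genes
    report.validate()
    return out, report


# ---------------------------------------------------------------------------
# normalisation chain


def log_transform(expr: ExpressionMatrix, base: float = 2.0) -> ExpressionMatrix:
    vals = np.log(expr.values + 1.0) / np.log(base)
    return expr.advance_stage(vals, "log")


def robust_quantile_normalize(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Quantile normalisation whose target is the per-rank MEDIAN across samples.

    After this step every sample's sorted value vector is identical; tied
    values within a sample receive the mean of their ranks' targets.
    """
    x = expr.values.to_numpy(dtype=float)
    target = np.median(np.sort(x, axis=0), axis=1)  # per-rank medians
    out = np.empty_like(x)
    n_genes = x.shape[0]
    for j in range(x.shape[1]):
        col = x[:, j]
        ranks = stats.rankdata(col, method="average") - 1.0  # 0-based, ties averaged
        lo = np.floor(ranks).astype(int)
        hi = np.ceil(ranks).astype(int)
        out[:, j] = 0.5 * (target[lo] + target[hi])
    vals = pd.DataFrame(out, index=expr.values.index, columns=expr.values.columns)
    return expr.advance_stage(vals, "qnorm")


def _huber_coef(y: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Huber M-estimate coefficients (tuning 1.345)."""
    try:
        res = sm.RLM(y, X, M=sm.robust.norms.HuberT(t=1.345)).fit()
        return np.asarray(res.params)
    except Exception:  # degenerate design; fall back to least squares
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        return coef


def _huber_fit(y: np.ndarray, X: np.ndarray) -> np.ndarray:
    return X @ _huber_coef(y, X)


def replace_outliers(
    expr: ExpressionMatrix,
    covariates: pd.DataFrame | None = None,
    iqr_mult: float = 3.0,
) -> ExpressionMatrix:
    """Per-gene robust-regression outlier imputation.

    A robust (Huber) model is fitted per gene on an intercept plus any given
    covariates; observations with residuals beyond ``Q1 - iqr_mult*IQR`` or
    ``Q3 + iqr_mult*IQR`` of the residual distribution are replaced by fitted
    values from a refit without them.
    """
    vals = expr.values.to_numpy(dtype=float).copy()
    n = vals.shape[1]
    X = np.ones((n, 1))
    if covariates is not None:
        C = covariates.loc[expr.values.columns].to_numpy(dtype=float)
        X = np.column_stack([X, C])
    for i in range(vals.shape[0]):
        y = vals[i]
        if np.ptp(y) == 0:
            continue
        fitted = _huber_fit(y, X)
        resid = y - fitted
        q1, q3 = np.percentile(resid, [25, 75])
        iqr = q3 - q1
        outlier = (resid < q1 - iqr_mult * iqr) | (resid > q3 + iqr_mult * iqr)
        if outlier.any() and (~outlier).sum() > X.shape[1]:
            # refit without the outliers, impute from its linear predictor
            refit_coef = _huber_coef(y[~outlier], X[~outlier])
            vals[i, outlier] = (X @ refit_coef)[outlier]
    out = pd.DataFrame(vals, index=expr.values.index, columns=expr.values.columns)
    return expr.advance_stage(out, "qnorm") if expr.stage == "log" else (
        ExpressionMatrix(out, expr.genes, expr.stage, expr.batch)
    )


def rank_inverse_normal(
    expr: ExpressionMatrix, offset: float = 3.0 / 8.0
) -> ExpressionMatrix:
    """Per-gene rank-based inverse normal transform, Blom offsets by default.

    x -> Phi^{-1}((rank - offset) / (n + 1 - 2*offset)); ties get average
    ranks so tied inputs map to identical outputs.  A zero-variance gene maps
    to all zeros with a logged warning.
    """
    x = expr.values.to_numpy(dtype=float)
    n = x.shape[1]
    out = np.empty_like(x)
    for i in range(x.shape[0]):
        if np.ptp(x[i]) == 0:
            log.warning(
                "gene %s has zero variance; RBINT maps it to zeros",
                expr.values.index[i],
            )
            out[i] = 0.0
            continue
        ranks = stats.rankdata(x[i], method="average")
        out[i] = stats.norm.ppf((ranks - offset) / (n + 1.0 - 2.0 * offset))
    vals = pd.DataFrame(out, index=expr.values.index, columns=expr.values.columns)
    return expr.advance_stage(vals, "rbint")


def normalize_expression(
    expr_tpm: ExpressionMatrix,
    covariates: pd.DataFrame | None = None,
    log_base: float = 2.0,
    iqr_mult: float = 3.0,
    rbint_offset: float = 3.0 / 8.0,
) -> ExpressionMatrix:
    """The full chain: log -> robust quantile norm -> outlier imputation -> RBINT."""
    if expr_tpm.stage != "tpm":
        raise ValueError("normalisation starts from TPM-stage expression")
    e = log_transform(expr_tpm, base=log_base)
    e = robust_quantile_normalize(e)
    e = replace_outliers(e, covariates=covariates, iqr_mult=iqr_mult)
    return rank_inverse_normal(e, offset=rbint_offset)


# ---------------------------------------------------------------------------
# hidden factors and genotype PCs


def default_n_factors(n_samples: int) -> int:
    """Sample-size-dependent hidden-factor count (GTEx-style schedule)."""
    if n_samples < 150:
        return 15
    if n_samples < 250:
        return 30
    return 35


def estimate_hidden_factors(
    expr: ExpressionMatrix, covariates: pd.DataFrame | None, k: int
) -> pd.DataFrame:
    """Top-k PCA factors of covariate-residualised expression.

    Returned scores are pairwise orthogonal with unit variance; ``k=0`` gives
    an empty frame.  These play the adjustment role of learned hidden
    factors: they absorb broad unwanted variation before the cis regressions.
    """
    samples = expr.values.columns
    if k == 0:
        return pd.DataFrame(index=samples)
    X = expr.values.to_numpy(dtype=float).T  # samples x genes
    n = X.shape[0]
    C = np.ones((n, 1))
    if covariates is not None and covariates.shape[1] > 0:
        C = np.column_stack([C, covariates.loc[samples].to_numpy(dtype=float)])
    # project out known covariates, then SVD
    Q, _ = np.linalg.qr(C)
    R = X - Q @ (Q.T @ X)
    U, s, _ = np.linalg.svd(R, full_matrices=False)
    k = min(k, U.shape[1])
    scores = U[:, :k] * np.sqrt(n)  # orthonormal columns -> unit variance
    # sign convention: largest-magnitude loading positive (determinism)
    for j in range(k):
        if scores[np.argmax(np.abs(scores[:, j])), j] < 0:
            scores[:, j] *= -1
    return pd.DataFrame(
        scores, index=samples, columns=[f"hf{j + 1}" for j in range(k)]
    )


def genotype_pcs(geno: GenotypeMatrix, k: int = 3) -> pd.DataFrame:
    """Top-k principal components of the centred, frequency-scaled dosage matrix."""
    X = geno.dosages.to_numpy(dtype=float)
    af = np.nanmean(X, axis=0) / 2.0
    X = np.where(np.isfinite(X), X, 2 * af)  # mean-impute missing
    scale = np.sqrt(2 * af * (1 - af))
    ok = scale > 0
    Z = (X[:, ok] - 2 * af[ok]) / scale[ok]
    U, s, _ = np.linalg.svd(Z, full_matrices=False)
    k = min(k, U.shape[1])
    scores = U[:, :k] * s[:k]
    for j in range(k):
        if scores[np.argmax(np.abs(scores[:, j])), j] < 0:
            scores[:, j] *= -1
    return pd.DataFrame(
        scores, index=geno.dosages.index, columns=[f"PC{j + 1}" for j in range(k)]
    )
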
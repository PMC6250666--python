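"""Permutation calibration of gene-level significance and eGene calling.

For each gene the smallest meta p-value over its cis variants is compared
with the empirical null distribution of the same statistic under B
permutations of the sample labels.  One shared permutation per iteration is
applied jointly to expression and the non-genetic covariates (age, sex,
hidden factors) while genotypes and genotype PCs keep their original order,
so gene-gene correlation and genotype structure are preserved.  The
permutation-adjusted p-value is (1 + #{null <= observed}) / (B + 1).  Gene
FDR uses Storey q-values; genes with q < 0.05 are eGenes.  The genome-wide
threshold P_t is the adjusted p of the gene whose q is closest to the
target, and the per-gene nominal threshold is the left-continuous empirical
quantile F_i^{-1}(P_t) of the gene's null.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import UnivariateSpline

from .eqtl import StudyData, _covariate_q, _residualise


@dataclass
class PermutationCalibration:
    """Empirical nulls and everything derived from them, one row per gene."""

    genes: pd.Index
    null_min_p: np.ndarray  # genes x B
    observed_min_p: np.ndarray
    adjusted_p: np.ndarray = field(default=None)
    q: np.ndarray = field(default=None)
    p_t: float = field(default=None)
    p_t_i: np.ndarray = field(default=None)

    @property
    def B(self) -> int:
        return self.null_min_p.shape[1]

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "obs_min_p": self.observed_min_p,
                "adjusted_p": self.adjusted_p,
                "q": self.q,
                "p_t_i": self.p_t_i,
            },
            index=self.genes,
        )


def _split_covariates(
    cov: pd.DataFrame | None, genotype_side: tuple = ("PC",)
) -> tuple[pd.DataFrame | None, pd.DataFrame | None]:
    """Split covariates into (permuted-with-expression, fixed-with-genotype)."""
    if cov is None or cov.shape[1] == 0:
        return None, None
    fixed_cols = [c for c in cov.columns if str(c).startswith(tuple(genotype_side))]
    perm_cols = [c for c in cov.columns if c not in fixed_cols]
    return (cov[perm_cols] if perm_cols else None,
            cov[fixed_cols] if fixed_cols else None)


def permute_min_p(
    studies: list[StudyData],
    pairs: pd.DataFrame,
    B: int,
    seed: int,
    genotype_side_prefixes: tuple = ("PC",),
) -> tuple[pd.Index, np.ndarray]:
    """Null matrix (genes x B) of smallest permuted meta p-values.

    At each permutation one random rearrangement of sample labels per study
    is applied jointly to expression and the non-genetic covariates;
    genotypes and genotype PCs keep their order.  The full per-study
    regression + inverse-variance meta chain is then re-run and the smallest
    meta-p per gene recorded.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    rng = np.random.default_rng(seed)
    genes = pd.Index(pd.unique(pairs["gene"]), name="gene")

    # order pairs by gene so per-gene minima are a reduceat
    order = pairs["gene"].map({g: i for i, g in enumerate(genes)}).to_numpy()
    sort_idx = np.argsort(order, kind="stable")
    sorted_gene = order[sort_idx]
    starts = np.searchsorted(sorted_gene, np.arange(len(genes)))

    prep = []
    for s in studies:
        perm_cov, fixed_cov = _split_covariates(s.covariates, genotype_side_prefixes)
        E = s.expression.to_numpy(dtype=float).T  # samples x genes (study's gene order)
        G = s.dosages.to_numpy(dtype=float)
        gidx = pd.Index(s.expression.index)
        vidx = pd.Index(s.dosages.columns)
        gi = gidx.get_indexer(pairs["gene"])
        vi = vidx.get_indexer(pairs["snp"])
        valid = (gi >= 0) & (vi >= 0)
        prep.append(
            dict(
                E=E, G=G,
                P=(None if perm_cov is None else perm_cov.to_numpy(dtype=float)),
                F=(None if fixed_cov is None else fixed_cov.to_numpy(dtype=float)),
                gi=gi, vi=vi, valid=valid, n=s.n,
                k=1
                + (0 if perm_cov is None else perm_cov.shape[1])
                + (0 if fixed_cov is None else fixed_cov.shape[1]),
            )
        )

    n_pairs = len(pairs)
    null = np.empty((len(genes), B))
    tiny = np.finfo(float).tiny
    for b in range(B):
        w_sum = np.zeros(n_pairs)
        wb_sum = np.zeros(n_pairs)
        for st in prep:
            perm = rng.permutation(st["n"])
            cols = [np.ones((st["n"], 1))]
            if st["P"] is not None:
                cols.append(st["P"][perm])
            if st["F"] is not None:
                cols.append(st["F"])
            Q, _ = np.linalg.qr(np.column_stack(cols))
            E = _residualise(st["E"][perm], Q)
            G = _residualise(st["G"], Q)
            df = st["n"] - st["k"] - 1
            gg = (G * G).sum(axis=0)
            ee = (E * E).sum(axis=0)
            GE = G.T @ E  # variants x genes cross-products
            v, g = st["vi"], st["gi"]
            ok = st["valid"]
            ge = GE[v[ok], g[ok]]
            gg_p = gg[v[ok]]
            with np.errstate(divide="ignore", invalid="ignore"):
                beta = ge / gg_p
                rss = np.maximum(ee[g[ok]] - beta * ge, 0.0)
                se2 = rss / df / gg_p
                w = np.where(se2 > 0, 1.0 / se2, 0.0)
            w_sum[ok] += w
            wb_sum[ok] += w * np.nan_to_num(beta)
        with np.errstate(divide="ignore", invalid="ignore"):
            z = wb_sum / np.sqrt(w_sum)
        p = np.where(w_sum > 0,
                     np.maximum(2.0 * stats.norm.sf(np.abs(z)), tiny), np.nan)
        p_sorted = p[sort_idx]
        null[:, b] = np.fmin.reduceat(p_sorted, starts)
    return genes, null


def observed_min_p(meta_results: pd.DataFrame, genes: pd.Index) -> np.ndarray:
    obs = meta_results.groupby("gene")["p_meta"].min()
    return obs.reindex(genes).to_numpy()


def adjust_gene_p(observed: float, null_vector: np.ndarray) -> float:
    """Permutation-adjusted p with pseudocount: (1 + #{null <= obs}) / (B + 1)."""
    null_vector = np.asarray(null_vector, dtype=float)
    B = null_vector.size
    return float((1 + (null_vector <= observed).sum()) / (B + 1))


def qvalues(pvals: np.ndarray, pi0: float | None = None) -> np.ndarray:
    """Storey q-values with smoother-estimated pi0.

    pi0 is estimated by fitting a cubic smoothing spline to
    pi0(lambda) = #{p > lambda} / (n (1 - lambda)) over a lambda grid and
    evaluating at the largest lambda; with fewer than 100 p-values (or an
    unstable fit) pi0 falls back to 1, which makes q identical to
    Benjamini-Hochberg adjusted p.  Output is monotone non-decreasing in p.
    """
    p = np.asarray(pvals, dtype=float)
    n = p.size
    if n == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if pi0 is None:
        if n < 100:
            pi0 = 1.0
        else:
            lam = np.arange(0.05, 0.96, 0.05)
            pi0_lam = np.array([(p > l).mean() / (1 - l) for l in lam])
            try:
                spl = UnivariateSpline(lam, pi0_lam, k=3)
                pi0 = float(spl(lam[-1]))
            except Exception:
                pi0 = 1.0
            if not np.isfinite(pi0) or pi0 <= 0 or pi0 > 1:
                pi0 = 1.0
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    q = pi0 * n * ranked / np.arange(1, n + 1)
    q = np.minimum.accumulate(q[::-1])[::-1]
    q = np.minimum(q, 1.0)
    out = np.empty(n)
    out[order] = q
    return out


def genomewide_threshold(
    adjusted_ps: np.ndarray, qs: np.ndarray, target: float = 0.05
) -> float:
    """Adjusted p of the gene whose q is closest to ``target`` (tie: smaller p)."""
    adjusted_ps = np.asarray(adjusted_ps, dtype=float)
    qs = np.asarray(qs, dtype=float)
    if adjusted_ps.size == 0:
        raise ValueError("no genes")
    d = np.abs(qs - target)
    best = d == d.min()
    return float(adjusted_ps[best].min())


def per_gene_threshold(null_vector: np.ndarray, p_t: float) -> float:
    """Left-continuous empirical quantile: smallest null x with F_i(x) >= p_t."""
    s = np.sort(np.asarray(null_vector, dtype=float))
    B = s.size
    idx = int(np.ceil(p_t * B)) - 1
    return float(s[min(max(idx, 0), B - 1)])


def calibrate(
    meta_results: pd.DataFrame,
    studies: list[StudyData],
    pairs: pd.DataFrame,
    B: int = 2000,
    seed: int = 0,
    fdr_target: float = 0.05,
) -> PermutationCalibration:
    """Full chain: permutation null -> adjusted p -> q -> P_t -> P_t,i."""
    genes, null = permute_min_p(studies, pairs, B=B, seed=seed)
    obs = observed_min_p(meta_results, genes)
    adj = np.array([adjust_gene_p(o, null[i]) for i, o in enumerate(obs)])
    q = qvalues(adj)
    p_t = genomewide_threshold(adj, q, target=fdr_target)
    p_t_i = np.array([per_gene_threshold(null[i], p_t) for i in range(len(genes))])
    return PermutationCalibration(
        genes=genes, null_min_p=null, observed_min_p=obs,
        adjusted_p=adj, q=q, p_t=p_t, p_t_i=p_t_i,
    )


def call_egenes_esnps(
    meta_results: pd.DataFrame,
    calibration: PermutationCalibration,
    variants: pd.DataFrame | None = None,
    q_max: float = 0.05,
) -> tuple[list, pd.DataFrame, pd.DataFrame]:
    """eGenes (q < q_max), their significant pairs, and the best eSNP per eGene.

    A pair is significant iff its gene is an eGene and its nominal meta-p is
    <= the gene's threshold P_t,i.  The best eSNP has the smallest meta-p
    (ties broken by smaller bp position when variant metadata is supplied).
    """
    tab = calibration.table()
    egenes = [g for g, row in tab.iterrows() if row["q"] < q_max]
    res = meta_results[meta_results["gene"].isin(egenes)].copy()
    thr = tab["p_t_i"]
    res = res[res["p_meta"] <= res["gene"].map(thr).to_numpy()]
    if variants is not None:
        res = res.assign(pos=res["snp"].map(variants["pos"]))
        best = (
            res.sort_values(["gene", "p_meta", "pos"], kind="stable")
            .groupby("gene", sort=True)
            .head(1)
        )
    else:
        best = (
            res.sort_values(["gene", "p_meta", "snp"], kind="stable")
            .groupby("gene", sort=True)
            .head(1)
        )
    return egenes, res.reset_index(drop=True), best.reset_index(drop=True)
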
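"""LD-proxy expansion, GWAS-eSNP overlap, enrichment and interval annotation.

A GWAS sentinel "overlaps" the eSNP catalogue if the sentinel itself or any
proxy in strong LD (r^2 > 0.8 by default) is in the catalogue.  Enrichment
against matched random SNP sets follows the SNPsnap recipe: candidate sets
match the input on MAF (+-10% relative), LD-buddy count, gene density and
distance to the nearest gene (+-50% relative), drawn without replacement and
disjoint from the input.  Interval annotation consumes BED tracks (0-based
half-open); variant positions are 1-based.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

log = logging.getLogger(__name__)

PROXY_WINDOW = 1_000_000


class LdPanel:
    """Window-limited pairwise r^2 over a dosage panel."""

    def __init__(self, dosages: pd.DataFrame, variants: pd.DataFrame,
                 window: int = PROXY_WINDOW):
        self.dosages = dosages
        self.variants = variants
        self.window = window

    def r2(self, snp_a: str, snp_b: str) -> float:
        va, vb = self.variants.loc[snp_a], self.variants.loc[snp_b]
        if str(va["chrom"]) != str(vb["chrom"]):
            return 0.0
        if abs(int(va["pos"]) - int(vb["pos"])) > self.window:
            return 0.0
        a = self.dosages[snp_a].to_numpy(dtype=float)
        b = self.dosages[snp_b].to_numpy(dtype=float)
        if a.std() == 0 or b.std() == 0:
            return np.nan
        r = np.corrcoef(a, b)[0, 1]
        return float(r * r)

    def proxies_of(self, snp: str, r2_min: float) -> set:
        """All panel variants with r^2 strictly above ``r2_min`` (incl. the SNP)."""
        if snp not in self.variants.index:
            return {snp}
        v = self.variants.loc[snp]
        same = self.variants[
            (self.variants["chrom"].astype(str) == str(v["chrom"]))
            & ((self.variants["pos"] - int(v["pos"])).abs() <= self.window)
        ].index
        a = self.dosages[snp].to_numpy(dtype=float)
        if a.std() == 0:
            return {snp}
        sub = self.dosages[same].to_numpy(dtype=float)
        ac = a - a.mean()
        sc = sub - sub.mean(axis=0)
        denom = np.sqrt((ac @ ac) * (sc * sc).sum(axis=0))
        with np.errstate(divide="ignore", invalid="ignore"):
            r2 = np.where(denom > 0, (ac @ sc) ** 2 / denom**2, np.nan)
        out = set(same[(r2 > r2_min)])
        out.add(snp)
        return out


def expand_proxies(
    snps, ld_panel: LdPanel, r2_min: float = 0.8
) -> dict:
    """Map each sentinel to its proxy set (sentinel always included)."""
    return {s: ld_panel.proxies_of(s, r2_min) for s in snps}


def overlap_gwas_esnps(
    gwas_snps, proxies: dict, esnp_set: set, best_esnp_set: set | None = None
) -> dict:
    """Count GWAS sentinels whose proxy set hits the eSNP catalogue."""
    pairs, best_pairs = [], []
    for s in gwas_snps:
        group = proxies.get(s, {s})
        hits = group & esnp_set
        if hits:
            pairs.append((s, sorted(hits)))
        if best_esnp_set is not None:
            bh = group & best_esnp_set
            if bh:
                best_pairs.append((s, sorted(bh)))
    out = {
        "n_gwas": len(list(gwas_snps)),
        "n_overlap": len(pairs),
        "pairs": pairs,
    }
    if best_esnp_set is not None:
        out["n_overlap_best"] = len(best_pairs)
        out["best_pairs"] = best_pairs
    return out


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Odds ratio and two-sided Fisher exact p for the table [[a, b], [c, d]].

    Two-sided p sums hypergeometric probabilities <= the observed table's,
    conditional on the margins.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("cell counts must be non-negative")
    orat, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return float(orat), float(p)


def matched_snp_sets(
    input_snps,
    universe: pd.DataFrame,
    n_sets: int = 100,
    maf_tol: float = 0.10,
    other_tol: float = 0.50,
    seed: int = 0,
) -> tuple[list, int]:
    """Random SNP sets matched per-SNP on four properties.

    ``universe`` is indexed by SNP id with columns ``maf``, ``ld_buddies``,
    ``gene_density``, ``dist_nearest_gene``.  A candidate matches an input
    SNP when every property is within the relative tolerance
    (|x - x0| <= tol * |x0|; a zero-valued property requires an exact zero).
    Matches are drawn without replacement within a set and never from the
    input.  SNPs with no eligible match are skipped with a warning; the count
    of skipped SNPs is returned alongside the sets.
    """
    rng = np.random.default_rng(seed)
    input_snps = list(input_snps)
    pool = universe.drop(index=[s for s in input_snps if s in universe.index])
    props = ["maf", "ld_buddies", "gene_density", "dist_nearest_gene"]
    tols = {"maf": maf_tol, "ld_buddies": other_tol,
            "gene_density": other_tol, "dist_nearest_gene": other_tol}
    candidates = {}
    n_skipped = 0
    for s in input_snps:
        if s not in universe.index:
            n_skipped += 1
            log.warning("input SNP %s absent from universe; skipped", s)
            continue
        x0 = universe.loc[s]
        mask = pd.Series(True, index=pool.index)
        for prop in props:
            v0 = float(x0[prop])
            mask &= (pool[prop] - v0).abs() <= tols[prop] * abs(v0)
        elig = pool.index[mask]
        if len(elig) == 0:
            n_skipped += 1
            log.warning("no eligible match for SNP %s; skipped", s)
            continue
        candidates[s] = elig.to_numpy()
    sets = []
    for _ in range(n_sets):
        chosen: list = []
        used: set = set()
        for s, elig in candidates.items():
            avail = [e for e in elig if e not in used]
            if not avail:
                continue
            pick = avail[rng.integers(len(avail))]
            chosen.append(pick)
            used.add(pick)
        sets.append(chosen)
    return sets, n_skipped


def enrichment_test(
    observed_overlap: int,
    n_input: int,
    matched_sets: list,
    target_set: set,
    method: str = "pooled_fisher",
) -> dict:
    """Fold enrichment and p of the observed overlap against matched-set nulls.

    fold = observed count / mean null count.  With ``method='pooled_fisher'``
    the p comes from Fisher's exact test on the 2x2 table of input hits vs
    misses against pooled matched-set hits vs misses; with
    ``method='empirical'`` it is the rank of the observed count within the
    null counts ((1 + #{null >= obs}) / (n_sets + 1)).
    """
    null_counts = np.array(
        [len(set(s) & target_set) for s in matched_sets], dtype=float
    )
    mean_null = null_counts.mean() if null_counts.size else 0.0
    if mean_null == 0.0 and observed_overlap > 0:
        log.warning("all matched-set overlaps are zero; fold is a guarded ratio")
        fold = observed_overlap / max(mean_null, 1e-9)
    else:
        fold = observed_overlap / mean_null if mean_null else np.nan
    if method == "pooled_fisher":
        pooled_n = int(sum(len(s) for s in matched_sets))
        pooled_hits = int(null_counts.sum())
        _, p = fisher_exact_2x2(
            observed_overlap, n_input - observed_overlap,
            pooled_hits, pooled_n - pooled_hits,
        )
    elif method == "empirical":
        p = (1 + (null_counts >= observed_overlap).sum()) / (len(matched_sets) + 1)
    else:
        raise ValueError(f"unknown method {method!r}")
    return {"fold": float(fold), "p": float(p),
            "mean_null": float(mean_null), "observed": int(observed_overlap)}


def annotate_snps(
    snps: pd.DataFrame, tracks: dict
) -> pd.DataFrame:
    """Label each variant with every track interval it falls in.

    ``snps`` is indexed by id with columns chrom, pos (1-based); ``tracks``
    maps a track name to a BED frame (chrom, start, end, 0-based half-open).
    A variant at 1-based position p hits [s, e) iff s <= p - 1 < e.
    Returns one row per SNP with a ``labels`` frozenset column.
    """
    trees: dict = {}
    for name, bed in tracks.items():
        for _, row in bed.iterrows():
            key = (name, str(row["chrom"]))
            trees.setdefault(key, IntervalTree()).addi(
                int(row["start"]), int(row["end"]),
                row.get("name", name),
            )
    labels = []
    for sid, row in snps.iterrows():
        pos0 = int(row["pos"]) - 1
        hit = set()
        for name in tracks:
            tree = trees.get((name, str(row["chrom"])))
            if tree is not None and tree.overlaps_point(pos0):
                hit.add(name)
        labels.append(frozenset(hit))
    return pd.DataFrame({"labels": labels}, index=snps.index)
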
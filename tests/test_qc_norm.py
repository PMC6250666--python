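"""QC filters and the normalisation chain, checked against brute-force oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import comb

from nephroqtl import qc
from nephroqtl.containers import ExpressionMatrix, GenotypeMatrix


def hwe_oracle(n_aa, n_ab, n_bb):
    """Full enumeration of the conditional heterozygote-count distribution."""
    n = n_aa + n_ab + n_bb
    na = 2 * n_aa + n_ab  # ref alleles
    probs = {}
    for het in range(min(na, 2 * n - na) + 1):
        if (na - het) % 2:
            continue
        homr = (na - het) // 2
        homa = n - het - homr
        if homr < 0 or homa < 0:
            continue
        probs[het] = (
            comb(n, het, exact=True)
            * comb(n - het, homr, exact=True)
            * 2**het
            / comb(2 * n, na, exact=True)
        )
    z = sum(probs.values())
    p_obs = probs[n_ab] / z
    return sum(p / z for p in probs.values() if p / z <= p_obs * (1 + 1e-12))


@pytest.mark.parametrize(
    "counts",
    [(25, 50, 25), (5, 0, 5), (10, 0, 0), (3, 4, 3), (1, 9, 0), (7, 2, 1),
     (0, 10, 0), (2, 2, 2)],
)
def test_hwe_exact_matches_enumeration(counts):
    assert qc.hwe_exact_test(*counts) == pytest.approx(hwe_oracle(*counts), rel=1e-10)


def test_hwe_edge_cases():
    assert qc.hwe_exact_test(25, 50, 25) == 1.0  # modal het count
    assert qc.hwe_exact_test(10, 0, 0) == 1.0  # monomorphic
    with pytest.raises(ValueError):
        qc.hwe_exact_test(-1, 2, 3)


def _panel(dosage_cols, variants_meta, n=None):
    dos = pd.DataFrame(dosage_cols)
    dos.index = [f"s{i}" for i in range(len(dos))]
    var = pd.DataFrame(variants_meta).set_index("snp")
    return GenotypeMatrix(dos[var.index], var)


def test_filter_variants_toy_panel_one_failure_each():
    """Six variants, one failing each rule; reasons match hand enumeration."""
    rng = np.random.default_rng(0)
    n = 100
    good = rng.integers(0, 3, n).astype(float)
    while min((good == 0).sum(), (good == 1).sum(), (good == 2).sum()) < 10:
        good = rng.integers(0, 3, n).astype(float)
    low_maf = np.r_[np.ones(4), np.zeros(n - 4)]  # MAF 0.02
    hwe_bad = np.r_[np.full(50, 0.0), np.full(50, 2.0)]  # no hets at AF 0.5
    missing = good.copy(); missing[:10] = np.nan  # call rate 0.90
    sexchrom = good.copy()
    badimp = good.copy()
    cols = {"v_good": good, "v_maf": low_maf, "v_hwe": hwe_bad,
            "v_miss": missing, "v_sex": sexchrom, "v_imp": badimp}
    meta = [
        {"snp": "v_good", "chrom": "1", "pos": 100, "ref": "A", "alt": "G", "imputation_r2": 0.9},
        {"snp": "v_maf", "chrom": "1", "pos": 200, "ref": "A", "alt": "G", "imputation_r2": 0.9},
        {"snp": "v_hwe", "chrom": "1", "pos": 300, "ref": "A", "alt": "G", "imputation_r2": 0.9},
        {"snp": "v_miss", "chrom": "1", "pos": 400, "ref": "A", "alt": "G", "imputation_r2": 0.9},
        {"snp": "v_sex", "chrom": "X", "pos": 500, "ref": "A", "alt": "G", "imputation_r2": 0.9},
        {"snp": "v_imp", "chrom": "1", "pos": 600, "ref": "A", "alt": "G", "imputation_r2": 0.1},
    ]
    geno = _panel(cols, meta)
    out, rep = qc.filter_variants(geno, hwe_p_min=1e-6)
    assert list(out.dosages.columns) == ["v_good"]
    assert rep.excluded == {
        "maf": 1, "hwe": 1, "call_rate": 1, "sex_or_mt_chromosome": 1,
        "imputation_r2": 1,
    }
    rep.validate()
    # idempotence
    out2, rep2 = qc.filter_variants(out, hwe_p_min=1e-6)
    pd.testing.assert_frame_equal(out2.dosages, out.dosages)
    assert rep2.excluded == {}


def test_filter_variants_threshold_edges():
    n = 100
    # MAF exactly 0.5, perfect HWE counts (25, 50, 25): retained
    perfect = np.r_[np.zeros(25), np.ones(50), np.full(25, 2.0)]
    # MAF 0.04: removed
    rare = np.r_[np.ones(8), np.zeros(n - 8)]
    geno = _panel(
        {"v_ok": perfect, "v_rare": rare},
        [{"snp": "v_ok", "chrom": "1", "pos": 1, "ref": "A", "alt": "G"},
         {"snp": "v_rare", "chrom": "1", "pos": 2, "ref": "A", "alt": "G"}],
    )
    out, rep = qc.filter_variants(geno, hwe_p_min=0.001)
    assert list(out.dosages.columns) == ["v_ok"]
    assert rep.excluded == {"maf": 1}


def test_filter_samples():
    rng = np.random.default_rng(1)
    n, m = 60, 400
    dos = rng.integers(0, 3, (n, m)).astype(float)
    dos[0, : int(0.1 * m)] = np.nan  # 10% missing -> removed
    dos[1] = 1.0  # heterozygosity far above the mean -> removed
    geno = GenotypeMatrix(
        pd.DataFrame(dos, index=[f"s{i}" for i in range(n)],
                     columns=[f"v{j}" for j in range(m)]),
        pd.DataFrame({"chrom": "1", "pos": np.arange(m) + 1, "ref": "A", "alt": "G"},
                     index=[f"v{j}" for j in range(m)]),
    )
    kept, rep = qc.filter_samples(geno)
    assert "s0" not in kept and "s1" not in kept
    assert len(kept) == n - 2
    assert rep.excluded["genotype_missingness"] == 1
    assert rep.excluded["heterozygosity_outlier"] == 1


def _expr(values, chroms=None, batch=None):
    values = pd.DataFrame(values)
    values.index = [f"g{i}" for i in range(values.shape[0])]
    values.columns = [f"s{j}" for j in range(values.shape[1])]
    genes = pd.DataFrame(
        {"chrom": chroms if chroms is not None else ["1"] * values.shape[0],
         "start": 100, "end": 200},
        index=values.index,
    )
    b = None
    if batch is not None:
        b = pd.Series(batch, index=values.columns)
    return ExpressionMatrix(values, genes, stage="tpm", batch=b)


def test_filter_genes_per_batch_rule():
    # gene passes in batch B (100%) but only 40% of batch A -> removed
    vals = np.array([
        [0.05, 0.05, 0.05, 0.5, 0.5,  2.0, 2.0, 2.0, 2.0],  # 2/5 in A, 4/4 in B
        [1.0] * 9,  # everywhere expressed
        [0.1] * 9,  # exactly at the threshold: strict > means removed
    ])
    batch = ["A"] * 5 + ["B"] * 4
    e = _expr(vals, batch=batch)
    out, rep = qc.filter_genes(e, tpm_min=0.1, frac=0.5)
    assert list(out.values.index) == ["g1"]
    assert rep.excluded == {"low_expression": 2}


def test_filter_genes_drops_sex_chromosomes_and_matches_bruteforce():
    rng = np.random.default_rng(2)
    vals = rng.exponential(1.0, (5, 20))
    vals[3] *= 0.02
    chroms = ["1", "2", "X", "1", "1"]
    e = _expr(vals, chroms=chroms)
    out, _ = qc.filter_genes(e, tpm_min=0.1, frac=0.5)
    expected = [
        g for i, g in enumerate(e.values.index)
        if chroms[i] not in ("X", "Y") and (vals[i] > 0.1).mean() >= 0.5
    ]
    assert list(out.values.index) == expected


def test_quantile_normalisation_per_rank_medians():
    """After qnorm every sample's sorted values equal the per-rank medians."""
    vals = np.array([[1.0, 4.0, 2.0],
                     [5.0, 2.0, 8.0],
                     [3.0, 9.0, 4.0]])
    e = _expr(vals)
    e = ExpressionMatrix(e.values, e.genes, stage="log", batch=e.batch)
    out = qc.robust_quantile_normalize(e)
    target = np.median(np.sort(vals, axis=0), axis=1)  # hand: sorted cols, row medians
    expected_target = np.array([np.median([1, 2, 2]),
                                np.median([3, 4, 4]),
                                np.median([5, 9, 8])])
    assert np.allclose(target, expected_target)
    for j in range(3):
        assert np.allclose(np.sort(out.values.to_numpy()[:, j]), target)


def test_quantile_normalisation_identity_when_samples_identical():
    vals = np.tile(np.array([[3.0], [1.0], [2.0]]), (1, 4))
    e = _expr(vals)
    e = ExpressionMatrix(e.values, e.genes, stage="log", batch=e.batch)
    out = qc.robust_quantile_normalize(e)
    assert np.allclose(out.values.to_numpy(), vals)


def test_rbint_middle_of_three_is_zero_and_moments():
    vals = np.array([[1.0, 5.0, 2.0]])
    e = _expr(vals)
    e = ExpressionMatrix(e.values, e.genes, stage="qnorm", batch=e.batch)
    out = qc.rank_inverse_normal(e)
    v = out.values.to_numpy()[0]
    assert v[np.argsort(vals[0])[1]] == pytest.approx(0.0)  # Phi^-1(0.5)
    assert out.stage == "rbint"
    # larger n: mean ~0, SD ~1 per gene
    rng = np.random.default_rng(3)
    big = _expr(rng.exponential(1, (4, 500)))
    big = ExpressionMatrix(big.values, big.genes, stage="qnorm", batch=big.batch)
    ob = qc.rank_inverse_normal(big)
    assert np.allclose(ob.values.mean(axis=1), 0, atol=1e-12)
    assert np.allclose(ob.values.std(axis=1), 1, atol=0.02)


def test_rbint_zero_variance_gene_maps_to_zeros(caplog):
    vals = np.ones((1, 10))
    e = _expr(vals)
    e = ExpressionMatrix(e.values, e.genes, stage="qnorm", batch=e.batch)
    import logging

    with caplog.at_level(logging.WARNING):
        out = qc.rank_inverse_normal(e)
    assert (out.values.to_numpy() == 0).all()
    assert "zero variance" in caplog.text


def test_rbint_ties_map_to_identical_outputs():
    vals = np.array([[1.0, 2.0, 2.0, 3.0, 5.0]])
    e = _expr(vals)
    e = ExpressionMatrix(e.values, e.genes, stage="qnorm", batch=e.batch)
    out = qc.rank_inverse_normal(e).values.to_numpy()[0]
    assert out[1] == out[2]


def test_outlier_replacement_pulls_in_extreme_point():
    rng = np.random.default_rng(4)
    vals = rng.normal(5, 0.5, (1, 60))
    vals[0, 0] = 50.0  # gross outlier
    e = _expr(vals)
    e = ExpressionMatrix(e.values, e.genes, stage="qnorm", batch=e.batch)
    out = qc.replace_outliers(e)
    v = out.values.to_numpy()[0]
    assert abs(v[0] - vals[0, 1:].mean()) < 1.0
    assert np.allclose(v[1:], vals[0, 1:])  # non-outliers untouched


def test_full_chain_invariants():
    # enough genes that quantile-normalisation ties are negligible
    rng = np.random.default_rng(9)
    e = _expr(rng.exponential(2.0, (300, 60)))
    out = qc.normalize_expression(e)
    assert out.stage == "rbint"
    v = out.values.to_numpy()
    assert np.allclose(v.mean(axis=1), 0, atol=0.02)
    assert np.allclose(v.std(axis=1), 1, atol=0.05)
    # quantile-normalisation property survives the chain's qnorm step
    q = qc.robust_quantile_normalize(qc.log_transform(e))
    s = np.sort(q.values.to_numpy(), axis=0)
    assert np.allclose(s, s[:, [0]])


def test_stage_order_enforced(small_dataset):
    _, expr, _ = small_dataset
    tpm = ExpressionMatrix(np.exp2(expr.values), expr.genes, "tpm", expr.batch)
    rb = qc.normalize_expression(tpm)
    with pytest.raises(ValueError):
        qc.normalize_expression(rb)  # cannot restart the chain from rbint


def test_hidden_factors_recover_planted_global_factor():
    rng = np.random.default_rng(5)
    n, g = 100, 60
    f = rng.standard_normal(n)
    load = rng.normal(0, 1, g)
    vals = np.outer(load, f) + rng.normal(0, 0.3, (g, n))
    e = _expr(vals)
    hf = qc.estimate_hidden_factors(e, None, k=2)
    assert abs(np.corrcoef(hf["hf1"], f)[0, 1]) > 0.9
    # orthogonal, unit variance
    assert abs(hf["hf1"] @ hf["hf2"]) < 1e-8
    assert np.allclose(hf.std(ddof=0), 1.0, atol=1e-8)


def test_hidden_factors_k_zero_and_null_case():
    rng = np.random.default_rng(6)
    e = _expr(rng.standard_normal((30, 50)))
    assert qc.estimate_hidden_factors(e, None, k=0).shape == (50, 0)
    cfg_cov = pd.DataFrame({"age": rng.normal(size=50)},
                           index=[f"s{j}" for j in range(50)])
    hf = qc.estimate_hidden_factors(e, cfg_cov, k=3)
    # factors are residual to covariates: no correlation with age
    assert abs(np.corrcoef(hf["hf1"], cfg_cov["age"])[0, 1]) < 0.35


def test_default_factor_count_schedule():
    assert qc.default_n_factors(100) == 15
    assert qc.default_n_factors(180) == 30
    assert qc.default_n_factors(400) == 35


def test_genotype_pcs_separate_subpopulations():
    rng = np.random.default_rng(7)
    n, m = 80, 300
    f1, f2 = 0.1, 0.6
    pop = np.r_[np.zeros(n // 2), np.ones(n // 2)]
    freqs = np.where(pop[:, None] == 0, f1, f2)
    dos = rng.binomial(2, freqs, (n, m)).astype(float)
    geno = GenotypeMatrix(
        pd.DataFrame(dos, index=[f"s{i}" for i in range(n)],
                     columns=[f"v{j}" for j in range(m)]),
        pd.DataFrame({"chrom": "1", "pos": np.arange(m) + 1, "ref": "A", "alt": "G"},
                     index=[f"v{j}" for j in range(m)]),
    )
    pcs = qc.genotype_pcs(geno, k=3)
    pc1 = pcs["PC1"].to_numpy()
    assert abs(np.corrcoef(pc1, pop)[0, 1]) > 0.95


def test_genotype_pcs_duplicate_samples_identical_scores():
    rng = np.random.default_rng(8)
    n, m = 20, 50
    dos = rng.integers(0, 3, (n, m)).astype(float)
    dos[1] = dos[0]
    geno = GenotypeMatrix(
        pd.DataFrame(dos, index=[f"s{i}" for i in range(n)],
                     columns=[f"v{j}" for j in range(m)]),
        pd.DataFrame({"chrom": "1", "pos": np.arange(m) + 1, "ref": "A", "alt": "G"},
                     index=[f"v{j}" for j in range(m)]),
    )
    pcs = qc.genotype_pcs(geno, k=3)
    assert np.allclose(pcs.iloc[0], pcs.iloc[1], atol=1e-8)
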
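"""Proxy expansion, Fisher exact vs enumeration, matched sets, BED annotation."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import comb

from nephroqtl import overlap


def fisher_oracle(a, b, c, d):
    """Two-sided Fisher p by full hypergeometric enumeration at fixed margins."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    denom = comb(n, c1, exact=True)
    probs = {}
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        probs[x] = comb(r1, x, exact=True) * comb(r2, c1 - x, exact=True) / denom
    p_obs = probs[a]
    return sum(p for p in probs.values() if p <= p_obs * (1 + 1e-9))


def test_fisher_hand_cases():
    _, p = overlap.fisher_exact_2x2(5, 5, 5, 5)
    assert p == pytest.approx(1.0)
    _, p = overlap.fisher_exact_2x2(3, 1, 1, 3)
    assert p == pytest.approx(34 / 70)
    with pytest.raises(ValueError):
        overlap.fisher_exact_2x2(-1, 1, 1, 1)


def test_fisher_matches_enumeration_small_tables():
    """Every 2x2 table with total n <= 16 agrees with the enumeration oracle."""
    for n in range(1, 17):
        for a in range(n + 1):
            for b in range(n - a + 1):
                for c in range(n - a - b + 1):
                    d = n - a - b - c
                    _, p = overlap.fisher_exact_2x2(a, b, c, d)
                    assert p == pytest.approx(fisher_oracle(a, b, c, d), rel=1e-9), (
                        a, b, c, d
                    )


def _mini_panel():
    rng = np.random.default_rng(0)
    n = 400
    base = rng.integers(0, 3, n).astype(float)
    noisy = base.copy()
    flip = rng.random(n) < 0.05
    noisy[flip] = rng.integers(0, 3, flip.sum())
    indep = rng.integers(0, 3, n).astype(float)
    far = base.copy()  # perfect LD but 2 Mb away: outside the window
    dos = pd.DataFrame(
        {"sent": base, "dup": base, "noisy": noisy, "indep": indep, "far": far},
        index=[f"s{i}" for i in range(n)],
    )
    var = pd.DataFrame(
        {
            "chrom": ["1", "1", "1", "1", "1"],
            "pos": [100_000, 101_000, 102_000, 103_000, 2_200_000],
            "ref": "A", "alt": "G",
        },
        index=dos.columns,
    )
    return overlap.LdPanel(dos, var)


def test_proxy_expansion_rules():
    panel = _mini_panel()
    proxies = overlap.expand_proxies(["sent"], panel, r2_min=0.8)["sent"]
    assert "sent" in proxies and "dup" in proxies  # r2 = 1 duplicated column
    assert "indep" not in proxies  # r2 ~ 0
    assert "far" not in proxies  # outside the 1 Mb window
    # idempotent: expanding the expanded set adds nothing new via 'dup'
    again = overlap.expand_proxies(sorted(proxies), panel, r2_min=0.8)
    assert set().union(*again.values()) == set(proxies)


def test_r2_from_hand_haplotype_table():
    """4-haplotype toy: r^2 computed from haplotype frequencies by hand."""
    # haplotypes AB, Ab, aB, ab with counts 45, 5, 5, 45 (n=100 samples of 1 hap)
    a = np.array([1.0] * 45 + [1.0] * 5 + [0.0] * 5 + [0.0] * 45)
    b = np.array([1.0] * 45 + [0.0] * 5 + [1.0] * 5 + [0.0] * 45)
    pa, pb, pab = 0.5, 0.5, 0.45
    d = pab - pa * pb
    r2_hand = d * d / (pa * (1 - pa) * pb * (1 - pb))  # = 0.64
    dos = pd.DataFrame({"A": a, "B": b}, index=[f"s{i}" for i in range(100)])
    var = pd.DataFrame({"chrom": ["1", "1"], "pos": [1, 2], "ref": "A", "alt": "G"},
                       index=["A", "B"])
    panel = overlap.LdPanel(dos, var)
    assert panel.r2("A", "B") == pytest.approx(r2_hand, abs=1e-12)
    assert panel.r2("A", "A") == pytest.approx(1.0)


def test_overlap_counting_set_algebra():
    proxies = {"g1": {"g1", "p1"}, "g2": {"g2"}, "g3": {"g3", "p3"}}
    esnps = {"p1", "g2", "x"}
    best = {"p1"}
    rep = overlap.overlap_gwas_esnps(["g1", "g2", "g3"], proxies, esnps, best)
    assert rep["n_gwas"] == 3
    assert rep["n_overlap"] == 2  # g1 via proxy p1, g2 directly
    assert rep["n_overlap_best"] == 1
    empty = overlap.overlap_gwas_esnps(["g1"], proxies, set())
    assert empty["n_overlap"] == 0


def test_matched_sets_respect_tolerances():
    rng = np.random.default_rng(1)
    n_univ = 400
    univ = pd.DataFrame(
        {
            "maf": rng.uniform(0.05, 0.5, n_univ),
            "ld_buddies": rng.integers(1, 50, n_univ).astype(float),
            "gene_density": rng.integers(1, 20, n_univ).astype(float),
            "dist_nearest_gene": rng.uniform(100, 1e5, n_univ),
        },
        index=[f"v{i}" for i in range(n_univ)],
    )
    inputs = univ.index[:8]
    sets, skipped = overlap.matched_snp_sets(inputs, univ, n_sets=20, seed=2)
    assert len(sets) == 20
    for s in sets:
        assert len(s) == len(set(s))  # without replacement
        assert not (set(s) & set(inputs))  # disjoint from input
        # audit: each member within tolerance of SOME input SNP on all props
        for m in s:
            ok = False
            for i in inputs:
                x0 = univ.loc[i]
                x = univ.loc[m]
                if (
                    abs(x["maf"] - x0["maf"]) <= 0.10 * x0["maf"]
                    and abs(x["ld_buddies"] - x0["ld_buddies"]) <= 0.5 * x0["ld_buddies"]
                    and abs(x["gene_density"] - x0["gene_density"]) <= 0.5 * x0["gene_density"]
                    and abs(x["dist_nearest_gene"] - x0["dist_nearest_gene"]) <= 0.5 * x0["dist_nearest_gene"]
                ):
                    ok = True
                    break
            assert ok


def test_matched_sets_exact_clones_and_degenerate():
    univ = pd.DataFrame(
        {
            "maf": [0.3, 0.3, 0.3, 0.9, 0.9],
            "ld_buddies": [10.0, 10, 10, 99, 99],
            "gene_density": [5.0, 5, 5, 50, 50],
            "dist_nearest_gene": [1000.0, 1000, 1000, 1e6, 1e6],
        },
        index=["inp", "clone1", "clone2", "other1", "other2"],
    )
    sets, skipped = overlap.matched_snp_sets(["inp"], univ, n_sets=10, seed=3)
    assert skipped == 0
    assert all(s[0] in ("clone1", "clone2") for s in sets)
    # zero tolerance with unique properties: everything skipped
    sets, skipped = overlap.matched_snp_sets(
        ["other1"], univ.drop(index=["other2"]), n_sets=2,
        maf_tol=0.0, other_tol=0.0, seed=3,
    )
    assert skipped == 1 and all(len(s) == 0 for s in sets)


def test_enrichment_fold_and_p():
    sets = [["a", "b", "c"]] * 10
    target = {"a", "x"}
    res = overlap.enrichment_test(1, 3, sets, target)
    assert res["fold"] == pytest.approx(1.0)  # observed equals every null count
    # toy counts 30/117 vs pooled 750/11700: fold and Fisher p
    null_sets = [[f"s{i}_{j}" for j in range(117)] for i in range(100)]
    tgt = set()
    for i in range(100):
        tgt.update(f"s{i}_{j}" for j in range(7 if i < 50 else 8))  # 750 pooled hits
    tgt.update(f"obs{j}" for j in range(30))
    res = overlap.enrichment_test(30, 117, null_sets, tgt)
    assert res["fold"] == pytest.approx(30 / 7.5)
    _, p_oracle = overlap.fisher_exact_2x2(30, 87, 750, 11700 - 750)
    assert res["p"] == pytest.approx(p_oracle)
    # degenerate: all nulls zero
    res = overlap.enrichment_test(3, 10, [["q"]] * 5, {"z"})
    assert res["fold"] > 1e6
    # empirical option
    res = overlap.enrichment_test(2, 3, sets, target, method="empirical")
    assert res["p"] == pytest.approx(1 / 11)


def test_annotate_snps_bed_convention():
    snps = pd.DataFrame(
        {"chrom": ["1", "1", "1", "2"], "pos": [101, 100, 250, 101]},
        index=["hit_lo", "miss_lo", "miss_hi", "wrong_chrom"],
    )
    bed = pd.DataFrame({"chrom": ["1"], "start": [100], "end": [200], "name": ["tss"]})
    lab = overlap.annotate_snps(snps, {"tss_track": bed})
    assert lab.loc["hit_lo", "labels"] == frozenset({"tss_track"})
    assert lab.loc["miss_lo", "labels"] == frozenset()
    assert lab.loc["miss_hi", "labels"] == frozenset()
    assert lab.loc["wrong_chrom", "labels"] == frozenset()


def test_annotate_matches_bruteforce_scan():
    rng = np.random.default_rng(4)
    snps = pd.DataFrame(
        {"chrom": "1", "pos": rng.integers(1, 1000, 25)},
        index=[f"v{i}" for i in range(25)],
    )
    tracks = {}
    beds = {}
    for name in ("stateA", "stateB", "cpg"):
        starts = np.sort(rng.integers(0, 900, 4))
        bed = pd.DataFrame(
            {"chrom": "1", "start": starts, "end": starts + rng.integers(10, 80, 4),
             "name": name}
        )
        tracks[name] = bed
        beds[name] = bed
    lab = overlap.annotate_snps(snps, tracks)
    for sid, row in snps.iterrows():
        expect = set()
        for name, bed in beds.items():
            for _, ivl in bed.iterrows():
                if ivl["start"] <= row["pos"] - 1 < ivl["end"]:
                    expect.add(name)
        assert lab.loc[sid, "labels"] == frozenset(expect)
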
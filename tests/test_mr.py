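"""MR estimators against closed forms, brute-force oracles and simulations."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from nephroqtl import mr, synth


def _inst(bx, by, sey=None, sex=None):
    bx = np.asarray(bx, dtype=float)
    k = len(bx)
    return pd.DataFrame(
        {
            "beta_x": bx,
            "se_x": np.full(k, 0.05) if sex is None else sex,
            "beta_y": np.asarray(by, dtype=float),
            "se_y": np.full(k, 0.05) if sey is None else sey,
        },
        index=[f"iv{j}" for j in range(k)],
    )


def test_ivw_plain_closed_form_vs_wls_oracle():
    inst = _inst([0.5, 0.25], [0.1, 0.1], sey=[1.0, 1.0])
    est = mr.ivw_plain(inst)
    assert est.theta == pytest.approx(0.24)
    rng = np.random.default_rng(0)
    for _ in range(20):
        bx = rng.normal(0.4, 0.1, 12)
        by = 0.3 * bx + rng.normal(0, 0.05, 12)
        sey = rng.uniform(0.02, 0.2, 12)
        inst = _inst(bx, by, sey=sey)
        est = mr.ivw_plain(inst)
        wls = sm.WLS(by, bx[:, None], weights=1 / sey**2).fit()
        assert est.theta == pytest.approx(float(wls.params[0]), abs=1e-10)
        assert est.se == pytest.approx(float(wls.bse[0] / np.sqrt(wls.scale)), abs=1e-10)


def test_estimators_exact_when_all_ratios_equal():
    bx = np.array([0.2, 0.4, 0.6, 0.8])
    inst = _inst(bx, 0.3 * bx)
    assert mr.ivw_plain(inst).theta == pytest.approx(0.3)
    assert mr.ivw_robust(inst).theta == pytest.approx(0.3)
    assert mr.weighted_median_penalised(inst, n_boot=0).theta == pytest.approx(0.3)


def test_weighted_median_hand_and_bruteforce_percentile():
    assert mr.weighted_median(np.array([1.0, 2, 3]), np.ones(3)) == 2.0
    assert mr.weighted_median(
        np.array([1.0, 2, 3]), np.array([0.5, 0.25, 0.25])
    ) == pytest.approx(5 / 3)

    def percentile_oracle(v, w, q=0.5, grid=2_000_001):
        """Brute force: invert the interpolated cumulative-weight function."""
        order = np.argsort(v)
        v, w = np.asarray(v, float)[order], np.asarray(w, float)[order]
        cs = (np.cumsum(w) - 0.5 * w) / w.sum()
        thetas = np.linspace(v[0], v[-1], grid)
        cdf = np.interp(thetas, v, cs)
        return thetas[np.argmin(np.abs(cdf - q))]

    rng = np.random.default_rng(1)
    for _ in range(10):
        v = rng.normal(size=9)
        w = rng.uniform(0.1, 1, 9)
        assert mr.weighted_median(v, w) == pytest.approx(
            percentile_oracle(v, w), abs=1e-5
        )


def test_egger_exact_linear_relationship():
    bx = np.array([0.2, 0.3, 0.5, 0.7, 0.9])
    inst = _inst(bx, 0.05 + 0.4 * bx)
    est = mr.egger_robust(inst)
    assert est.theta == pytest.approx(0.4, abs=1e-8)
    assert est.intercept == pytest.approx(0.05, abs=1e-8)


def test_robust_ivw_withstands_gross_outlier():
    """One wild instrument among 20: robust fit stays near theta, plain IVW drifts."""
    rng = np.random.default_rng(2)
    theta = 0.3
    bx = rng.normal(0.4, 0.05, 20)
    by = theta * bx + rng.normal(0, 0.01, 20)
    by[0] = 5.0  # gross outlier
    inst = _inst(bx, by, sey=np.full(20, 0.05))
    robust = mr.ivw_robust(inst)
    plain = mr.ivw_plain(inst)
    assert abs(robust.theta - theta) < 2 * max(robust.se, 0.02)
    assert abs(plain.theta - theta) > abs(robust.theta - theta)


def test_penalised_median_breakdown_resistance():
    """<50% of the weight on invalid instruments with wild ratios: estimate holds."""
    rng = np.random.default_rng(3)
    theta = 0.3
    biases = []
    for rep in range(50):
        inst = synth.simulate_mr_summary(
            20, theta, pleiotropy_mean=0.5, pleiotropy_sd=0.1,
            invalid_frac=0.4, seed=1000 + rep,
        )
        est = mr.weighted_median_penalised(inst, n_boot=0)
        biases.append(est.theta - theta)
    assert abs(np.mean(biases)) < 0.05


def test_harmonise_allele_logic():
    exposure = pd.DataFrame(
        {
            "effect_allele": ["G", "G", "A", "G"],
            "other_allele": ["A", "A", "T", "A"],
            "beta": [0.5, 0.5, 0.5, 0.5],
            "se": [0.1] * 4,
        },
        index=["same", "swapped", "palindrome", "strand"],
    )
    outcome = pd.DataFrame(
        {
            "effect_allele": ["G", "A", "A", "C"],
            "other_allele": ["A", "G", "T", "T"],
            "beta": [0.2, 0.2, 0.2, 0.2],
            "se": [0.05] * 4,
        },
        index=exposure.index,
    )
    inst, rep = mr.harmonise(exposure, outcome)
    assert inst.loc["same", "beta_y"] == 0.2  # aligned already
    assert inst.loc["swapped", "beta_y"] == -0.2  # allele swap flips the sign
    assert "palindrome" not in inst.index  # A/T dropped
    # strand flip: outcome C/T complements to G/A, matching the exposure
    assert inst.loc["strand", "beta_y"] == 0.2
    assert rep["palindromic_dropped"] == 1 and rep["flipped"] == 1


def test_select_instruments_greedy_vs_bruteforce():
    class ToyPanel:
        def __init__(self, r2_map):
            self.m = r2_map

        def r2(self, a, b):
            return self.m.get((a, b), self.m.get((b, a), 0.0))

    res = pd.DataFrame(
        {"snp": ["a", "b", "c", "d", "e", "f"],
         "p": [0.001, 0.002, 0.01, 0.05, 0.2, 0.003]}
    )
    panel = ToyPanel({("a", "b"): 0.9, ("a", "f"): 0.5, ("c", "d"): 0.25})
    kept = mr.select_instruments(res, panel, r2_max=0.2, p_max=0.08)
    # oracle: walk ascending p, apply the pruning rule by hand
    # order a(0.001) b(0.002) f(0.003) c(0.01) d(0.05); e fails p_max
    # a kept; b pruned (r2 .9 with a); f pruned (.5 with a); c kept; d pruned (.25 with c)
    assert kept == ["a", "c"]
    # mutual r2=1: single instrument survives
    panel_all = ToyPanel({(x, y): 1.0 for x in "abcdef" for y in "abcdef" if x != y})
    assert mr.select_instruments(res, panel_all) == ["a"]
    with pytest.raises(ValueError):
        mr.select_instruments(res[res["p"] > 0.5], panel)


def test_sensitivity_q_hand_formula():
    # two instruments: theta_j = (1, 2), w_j = bx^2/sey^2 = (4, 1)
    inst = _inst([2.0, 1.0], [2.0, 2.0], sey=[1.0, 1.0])
    sens = mr.sensitivity(inst)
    w = np.array([4.0, 1.0])
    th = np.array([1.0, 2.0])
    ivw = (w * th).sum() / w.sum()
    q_hand = (w * (th - ivw) ** 2).sum()
    assert sens["Q"] == pytest.approx(q_hand)
    assert sens["Q_df"] == 1
    # identical ratios: Q = 0, p = 1
    inst0 = _inst([0.2, 0.4, 0.8], [0.1, 0.2, 0.4])
    s0 = mr.sensitivity(inst0)
    assert s0["Q"] == pytest.approx(0.0, abs=1e-20)
    assert s0["Q_p"] == pytest.approx(1.0)


def test_estimates_invariant_to_relabelling_and_sign_flip():
    rng = np.random.default_rng(4)
    bx = rng.normal(0.4, 0.1, 15)
    by = 0.3 * bx + rng.normal(0, 0.03, 15)
    inst = _inst(bx, by)
    shuffled = inst.sample(frac=1, random_state=1)
    flipped = inst.copy()
    flipped[["beta_x", "beta_y"]] *= -1
    for fn in (mr.ivw_plain, mr.ivw_robust, lambda i: mr.weighted_median_penalised(i, n_boot=0)):
        t0 = fn(inst).theta
        assert fn(shuffled).theta == pytest.approx(t0, abs=1e-8)
        assert fn(flipped).theta == pytest.approx(t0, abs=1e-8)


def test_verdict_thresholds():
    mk = lambda p: mr.MrEstimate("m", 0.3, 0.1, p, 10)
    v = mr.mr_verdict([mk(0.001), mk(0.002), mk(0.2)], m=7)
    assert v["causal"] and v["threshold"] == pytest.approx(0.05 / 7)
    v = mr.mr_verdict([mk(0.001), mk(0.2), mk(0.3)], m=7)
    assert not v["causal"]
    v = mr.mr_verdict([mk(0.004), mk(0.0044), mk(0.9)], m=11)
    assert v["threshold"] == pytest.approx(0.05 / 11)
    assert v["causal"]


def test_bootstrap_se_reasonable_and_seeded():
    inst = synth.simulate_mr_summary(25, 0.3, seed=5)
    e1 = mr.weighted_median_penalised(inst, n_boot=400, seed=1)
    e2 = mr.weighted_median_penalised(inst, n_boot=400, seed=1)
    assert e1.se == e2.se
    assert 0 < e1.se < 0.1
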
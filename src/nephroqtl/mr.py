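"""Two-sample summary-data Mendelian randomisation.

Exposure: per-allele effect of a variant on (standardised) gene expression
from the cis-eQTL meta-analysis; outcome: per-allele effect on the trait
from GWAS summary statistics.  Because the exposure is in SD units the
causal estimate reads as trait change per 1-SD increment in expression.

Three estimators with different robustness profiles:

* robust IVW -- slope of the zero-intercept regression of outcome on
  exposure effects, weights 1/se_Y^2, fitted by iteratively reweighted least
  squares with a Tukey bisquare loss (c = 4.685) started from the weighted
  median of ratios, so heterogeneous ratio estimates are down-weighted;
* penalised weighted median -- weighted median of the per-instrument ratio
  estimates with weights beta_X^2/se_Y^2 penalised by
  min(1, 20 * P_chi2(Q_j)), Q_j being the instrument's contribution to
  Cochran's Q at the plain-IVW estimate; consistent when less than half the
  weight sits on invalid instruments;
* robust MR-Egger -- the same robust loss with an intercept, which absorbs
  (and estimates) directional pleiotropy.

First-order weights throughout (se_X ignored in weighting), the standard
two-sample practice.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

TUKEY_C = 4.685
PENALTY = 20.0

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass
class MrEstimate:
    method: str
    theta: float
    se: float
    p: float
    n_instruments: int
    intercept: float | None = None
    intercept_se: float | None = None
    intercept_p: float | None = None


# ---------------------------------------------------------------------------
# instrument selection and harmonisation


def select_instruments(
    eqtl_results: pd.DataFrame,
    ld_panel,
    r2_max: float = 0.2,
    p_max: float = 0.08,
) -> list:
    """Greedy LD pruning: ascending p, keep while r^2 < r2_max with all kept.

    ``eqtl_results`` needs columns ``snp`` and ``p``.  Raises on zero
    instruments; a single surviving instrument is returned with a warning
    (only a Wald ratio is then meaningful downstream).
    """
    cand = eqtl_results[eqtl_results["p"] < p_max].sort_values(
        ["p", "snp"], kind="stable"
    )
    kept: list = []
    for snp in cand["snp"]:
        if all(ld_panel.r2(snp, k) < r2_max for k in kept):
            kept.append(snp)
    if not kept:
        raise ValueError("no instrument passes the selection thresholds")
    if len(kept) == 1:
        log.warning("single instrument selected; only a Wald ratio is identified")
    return kept


def harmonise(
    exposure: pd.DataFrame, outcome: pd.DataFrame, drop_palindromic: bool = True
) -> tuple[pd.DataFrame, dict]:
    """Align outcome effects to the exposure effect allele.

    Both frames are indexed by SNP with columns effect_allele, other_allele,
    beta, se.  Direct allele swaps flip the outcome beta's sign; strand flips
    are resolved via complements; palindromic A/T-C/G variants are dropped by
    default.  Returns the instrument set (beta_x, se_x, beta_y, se_y) and a
    report of drops/flips.
    """
    report = {"n_input": 0, "flipped": 0, "palindromic_dropped": 0,
              "unmatched_dropped": 0}
    rows = []
    for snp in exposure.index:
        if snp not in outcome.index:
            continue
        report["n_input"] += 1
        ex, out = exposure.loc[snp], outcome.loc[snp]
        ea, oa = str(ex["effect_allele"]).upper(), str(ex["other_allele"]).upper()
        yea, yoa = str(out["effect_allele"]).upper(), str(out["other_allele"]).upper()
        if drop_palindromic and _COMPLEMENT.get(ea) == oa:
            report["palindromic_dropped"] += 1
            continue
        flip = None
        if (yea, yoa) == (ea, oa):
            flip = False
        elif (yea, yoa) == (oa, ea):
            flip = True
        else:
            cea, coa = _COMPLEMENT.get(yea), _COMPLEMENT.get(yoa)
            if (cea, coa) == (ea, oa):
                flip = False
            elif (cea, coa) == (oa, ea):
                flip = True
        if flip is None:
            report["unmatched_dropped"] += 1
            continue
        beta_y = -float(out["beta"]) if flip else float(out["beta"])
        report["flipped"] += int(flip)
        rows.append((snp, float(ex["beta"]), float(ex["se"]), beta_y, float(out["se"])))
    inst = pd.DataFrame(
        rows, columns=["snp", "beta_x", "se_x", "beta_y", "se_y"]
    ).set_index("snp")
    return inst, report


# ---------------------------------------------------------------------------
# estimators


def _check(instruments: pd.DataFrame, minimum: int, what: str) -> pd.DataFrame:
    if len(instruments) < minimum:
        raise ValueError(
            f"{what} needs at least {minimum} instruments, got {len(instruments)}"
        )
    if (instruments["beta_x"] == 0).any():
        raise ValueError("zero exposure effect among instruments")
    if (instruments["se_y"] <= 0).any():
        raise ValueError("outcome standard errors must be positive")
    return instruments


def ivw_plain(instruments: pd.DataFrame) -> MrEstimate:
    """Closed-form inverse-variance-weighted estimate (the reference IVW)."""
    inst = _check(instruments, 1, "IVW")
    bx = inst["beta_x"].to_numpy()
    by = inst["beta_y"].to_numpy()
    w = 1.0 / inst["se_y"].to_numpy() ** 2
    theta = float((w * bx * by).sum() / (w * bx * bx).sum())
    se = float(1.0 / np.sqrt((w * bx * bx).sum()))
    p = float(2.0 * stats.norm.sf(abs(theta / se)))
    return MrEstimate("ivw_plain", theta, se, p, len(inst))


def weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    """Weighted median by interpolation of the cumulative-weight percentile."""
    order = np.argsort(values, kind="stable")
    v = np.asarray(values, dtype=float)[order]
    w = np.asarray(weights, dtype=float)[order]
    cs = (np.cumsum(w) - 0.5 * w) / w.sum()
    if cs[0] >= 0.5:
        return float(v[0])
    if cs[-1] < 0.5:
        return float(v[-1])
    j = int(np.searchsorted(cs, 0.5, side="left"))
    lo = j - 1
    return float(v[lo] + (v[j] - v[lo]) * (0.5 - cs[lo]) / (cs[j] - cs[lo]))


def _penalised_weights(bx, by, sey) -> np.ndarray:
    # Q contributions are evaluated at the unpenalised weighted-median
    # estimate (a robust anchor); anchoring at IVW would let invalid
    # instruments drag the reference and penalise the valid ones instead.
    ratios = by / bx
    w = bx**2 / sey**2
    theta0 = weighted_median(ratios, w)
    q_j = w * (ratios - theta0) ** 2
    penalty = np.minimum(1.0, PENALTY * stats.chi2.sf(q_j, df=1))
    return w * penalty


def weighted_median_penalised(
    instruments: pd.DataFrame, n_boot: int = 2000, seed: int = 0
) -> MrEstimate:
    """Penalised weighted median of the ratio estimates.

    The standard error comes from a seeded parametric bootstrap: instrument
    effects are redrawn from N(beta, se^2) and the estimator recomputed; with
    ``n_boot=0`` the se and p are reported as NaN (point estimate only).
    """
    inst = _check(instruments, 3, "weighted median")
    bx = inst["beta_x"].to_numpy()
    by = inst["beta_y"].to_numpy()
    sex = inst["se_x"].to_numpy()
    sey = inst["se_y"].to_numpy()
    theta = weighted_median(by / bx, _penalised_weights(bx, by, sey))
    if n_boot:
        rng = np.random.default_rng(seed)
        draws = np.empty(n_boot)
        for b in range(n_boot):
            bx_b = bx + sex * rng.standard_normal(len(inst))
            by_b = by + sey * rng.standard_normal(len(inst))
            bx_b = np.where(bx_b == 0, np.finfo(float).eps, bx_b)
            draws[b] = weighted_median(by_b / bx_b, _penalised_weights(bx_b, by_b, sey))
        se = float(draws.std(ddof=1))
        p = float(2.0 * stats.norm.sf(abs(theta / se))) if se > 0 else 0.0
    else:
        se, p = float("nan"), float("nan")
    return MrEstimate("weighted_median_penalised", float(theta), se, p, len(inst))


def _lstsq_with_se(y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    n, k = X.shape
    sigma2 = resid @ resid / max(n - k, 1)
    cov = sigma2 * np.linalg.pinv(X.T @ X)
    return coef, np.sqrt(np.diag(cov))


def _robust_wls(
    y: np.ndarray, X: np.ndarray, start: np.ndarray,
    c: float = TUKEY_C, maxiter: int = 200, tol: float = 1e-10,
) -> tuple[np.ndarray, np.ndarray]:
    """IRLS with Tukey bisquare from a high-breakdown starting point.

    The redescending bisquare loss is non-convex, so the starting point
    matters: starting at the (weighted-median-derived) ``start`` keeps the
    fit anchored at the majority of concordant instruments.  Scale is the
    MAD of the current residuals; standard errors use the Huber sandwich.
    """
    beta = np.asarray(start, dtype=float).copy()
    n, k = X.shape
    for _ in range(maxiter):
        r = y - X @ beta
        scale = np.median(np.abs(r - np.median(r))) / 0.6745
        if scale <= 0:
            return _lstsq_with_se(y, X)
        u = r / (c * scale)
        w = np.where(np.abs(u) < 1, (1 - u**2) ** 2, 0.0)
        if w.sum() <= k:  # degenerate: almost everything rejected
            break
        WX = X * w[:, None]
        try:
            beta_new = np.linalg.solve(X.T @ WX, WX.T @ y)
        except np.linalg.LinAlgError:
            break
        if np.max(np.abs(beta_new - beta)) < tol * (1 + np.max(np.abs(beta))):
            beta = beta_new
            break
        beta = beta_new
    r = y - X @ beta
    scale = np.median(np.abs(r - np.median(r))) / 0.6745
    if scale <= 0:
        return _lstsq_with_se(y, X)
    u = r / scale
    au = np.abs(u) / c
    psi = np.where(au < 1, u * (1 - au**2) ** 2, 0.0)
    dpsi = np.where(au < 1, (1 - au**2) * (1 - 5 * au**2), 0.0)
    A = dpsi.mean()
    B = (psi**2).mean()
    if A <= 0:
        return _lstsq_with_se(y, X)
    cov = (B / A**2) * scale**2 * np.linalg.pinv(X.T @ X) * n / max(n - k, 1)
    return beta, np.sqrt(np.maximum(np.diag(cov), 0.0))


def ivw_robust(instruments: pd.DataFrame) -> MrEstimate:
    """Robust IVW: zero-intercept weighted regression with Tukey bisquare loss."""
    inst = _check(instruments, 2, "robust IVW")
    bx = inst["beta_x"].to_numpy()
    by = inst["beta_y"].to_numpy()
    sey = inst["se_y"].to_numpy()
    yt = by / sey
    xt = (bx / sey)[:, None]
    start = np.array([weighted_median(by / bx, bx**2 / sey**2)])
    if np.allclose(by / bx, (by / bx)[0]):
        theta = float((by / bx)[0])
        return MrEstimate("ivw_robust", theta, 0.0, 0.0, len(inst))
    coef, bse = _robust_wls(yt, xt, start)
    theta, se = float(coef[0]), float(bse[0])
    p = float(2.0 * stats.norm.sf(abs(theta / se))) if se > 0 else 0.0
    return MrEstimate("ivw_robust", theta, se, p, len(inst))


def egger_robust(instruments: pd.DataFrame) -> MrEstimate:
    """Robust MR-Egger: weighted regression WITH intercept, Tukey bisquare loss.

    Inputs are orientated so every exposure effect is non-negative before the
    fit; the slope is the causal estimate and the intercept measures
    directional pleiotropy.
    """
    inst = _check(instruments, 3, "MR-Egger")
    sign = np.sign(inst["beta_x"].to_numpy())
    bx = inst["beta_x"].to_numpy() * sign
    by = inst["beta_y"].to_numpy() * sign
    sey = inst["se_y"].to_numpy()
    yt = by / sey
    X = np.column_stack([1.0 / sey, bx / sey])
    slope0 = weighted_median(by / bx, bx**2 / sey**2)
    w = 1.0 / sey**2
    icpt0 = (w * (by - slope0 * bx)).sum() / w.sum()
    resid = yt - X @ np.array([icpt0, slope0])
    if np.allclose(resid, 0.0):
        return MrEstimate(
            "egger_robust", float(slope0), 0.0, 0.0, len(inst),
            intercept=float(icpt0), intercept_se=0.0, intercept_p=0.0,
        )
    coef, bse = _robust_wls(yt, X, np.array([icpt0, slope0]))
    theta, se = float(coef[1]), float(bse[1])
    icpt, icpt_se = float(coef[0]), float(bse[0])
    p = float(2.0 * stats.norm.sf(abs(theta / se))) if se > 0 else 0.0
    icpt_p = (
        float(2.0 * stats.norm.sf(abs(icpt / icpt_se))) if icpt_se > 0 else 0.0
    )
    return MrEstimate(
        "egger_robust", theta, se, p, len(inst),
        intercept=icpt, intercept_se=icpt_se, intercept_p=icpt_p,
    )


# ---------------------------------------------------------------------------
# sensitivity and verdict


def sensitivity(
    instruments: pd.DataFrame, theta: float | None = None
) -> dict:
    """Cochran's Q at the causal estimate and the Egger intercept test."""
    inst = _check(instruments, 2, "sensitivity analysis")
    bx = inst["beta_x"].to_numpy()
    by = inst["beta_y"].to_numpy()
    sey = inst["se_y"].to_numpy()
    ratios = by / bx
    w = bx**2 / sey**2
    if theta is None:
        theta = float((w * ratios).sum() / w.sum())
    q = float((w * (ratios - theta) ** 2).sum())
    df = len(inst) - 1
    q_p = float(stats.chi2.sf(q, df)) if df > 0 else float("nan")
    out = {"Q": q, "Q_df": df, "Q_p": q_p}
    if len(inst) >= 3:
        egg = egger_robust(instruments)
        out.update(
            egger_intercept=egg.intercept,
            egger_intercept_se=egg.intercept_se,
            egger_intercept_p=egg.intercept_p,
        )
    return out


def mr_verdict(
    estimates: list[MrEstimate], m: int, alpha_family: float = 0.05
) -> dict:
    """Causal iff >= 2 of the methods are Bonferroni-significant (alpha/m)."""
    if m < 1:
        raise ValueError("m must be >= 1")
    threshold = alpha_family / m
    n_sig = sum(1 for e in estimates if np.isfinite(e.p) and e.p < threshold)
    return {
        "causal": n_sig >= 2,
        "n_significant": n_sig,
        "threshold": threshold,
        "methods": {e.method: e.p for e in estimates},
    }


def run_mr(
    instruments: pd.DataFrame,
    m: int = 7,
    alpha_family: float = 0.05,
    n_boot: int = 2000,
    seed: int = 0,
) -> dict:
    """All three estimators + sensitivity + verdict for one gene."""
    ests = [
        ivw_robust(instruments),
        weighted_median_penalised(instruments, n_boot=n_boot, seed=seed),
        egger_robust(instruments),
    ]
    sens = sensitivity(instruments)
    verdict = mr_verdict(ests, m=m, alpha_family=alpha_family)
    return {"estimates": ests, "sensitivity": sens, "verdict": verdict}
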
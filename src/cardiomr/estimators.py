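"""Univariable two-sample Mendelian randomization estimators and diagnostics.

Given J harmonized SNP associations (gamma_j, sigma_gamma_j) with an exposure
and (Gamma_j, sigma_Gamma_j) with an outcome, the per-SNP Wald ratio
Gamma_j / gamma_j estimates the causal effect theta under the instrumental
variable assumptions.  This module provides:

* ``wald_ratio`` — single-SNP estimate with first-order delta-method SE;
* ``ivw`` — inverse-variance weighted meta-analysis of the ratios, fixed or
  multiplicative random effects (the random-effects variant inflates the SE
  by ``max(1, sqrt(Q / (J-1)))`` and never shrinks below fixed effects);
* ``mr_egger`` — weighted regression of Gamma on gamma with an intercept;
  the intercept estimates directional pleiotropy under the InSIDE
  assumption, with t-based inference on J-2 degrees of freedom;
* ``weighted_median`` — consistent when valid instruments carry a majority
  of the weight; SE by seeded parametric bootstrap;
* ``cochran_q`` — heterogeneity with first-order or modified (iterative,
  exposure-uncertainty-aware) weights;
* ``leave_one_out`` — influence diagnostics, one refit per omitted SNP;
* ``mr_presso`` — simulation-based global pleiotropy test with per-SNP
  outlier detection, distortion test and outlier-corrected re-estimate;
* ``classify_significance`` — Bonferroni-tiered labelling of results.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .harmonize import HarmonizedSet

Z95 = float(stats.norm.ppf(0.975))  # 1.959964


class InsufficientInstrumentsError(ValueError):
    """Too few SNPs for the requested estimator."""


@dataclass(frozen=True)
class MRResult:
    """One causal-effect estimate: outcome units per unit exposure."""

    method: str
    estimate: float
    se: float
    ci_low: float
    ci_high: float
    pvalue: float
    n_snps: int
    model_notes: str = ""

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "estimate": self.estimate,
            "se": self.se,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "pvalue": self.pvalue,
            "n_snps": self.n_snps,
            "model_notes": self.model_notes,
        }


@dataclass(frozen=True)
class HeterogeneityReport:
    """Cochran's Q (df = J-1; J-2 for Egger) and the Egger intercept."""

    Q: float
    df: int
    pvalue: float
    egger_intercept: float = np.nan
    intercept_se: float = np.nan
    intercept_pvalue: float = np.nan


@dataclass(frozen=True)
class PressoReport:
    """MR-PRESSO global, outlier and distortion test results."""

    global_rss_observed: float
    global_pvalue: float
    outlier_pvalues: dict
    outliers: list
    distortion_pvalue: float
    estimate_raw: MRResult
    estimate_outlier_corrected: MRResult
    n_simulations: int


def _normal_p(z: float) -> float:
    return float(2 * stats.norm.sf(abs(z)))


def _result(method: str, est: float, se: float, p: float, j: int, notes: str = "") -> MRResult:
    return MRResult(
        method=method,
        estimate=float(est),
        se=float(se),
        ci_low=float(est - Z95 * se),
        ci_high=float(est + Z95 * se),
        pvalue=float(p),
        n_snps=int(j),
        model_notes=notes,
    )


# ---------------------------------------------------------------------------
# array-level kernels (fast paths shared with the calibration experiments)
# ---------------------------------------------------------------------------

def ivw_arrays(
    bx: np.ndarray, by: np.ndarray, sy: np.ndarray, random_effects: bool = True
) -> tuple[float, float, float]:
    """IVW estimate from harmonized effect arrays.

    Returns (estimate, se, Q).  Equivalent to weighted least squares of
    ``by`` on ``bx`` through the origin with weights ``1/sy**2``; the Q
    statistic uses the same first-order weights.
    """
    bx = np.asarray(bx, float)
    by = np.asarray(by, float)
    sy = np.asarray(sy, float)
    j = bx.size
    ratios = by / bx
    w = bx**2 / sy**2  # = 1 / se(ratio)^2 with first-order delta SE
    sw = w.sum()
    theta = float((w * ratios).sum() / sw)
    q = float((w * (ratios - theta) ** 2).sum())
    se = float(sw**-0.5)
    if random_effects and j > 1:
        se *= max(1.0, np.sqrt(q / (j - 1)))
    return theta, se, q


def egger_arrays(
    bx: np.ndarray, sx: np.ndarray, by: np.ndarray, sy: np.ndarray
) -> tuple[float, float, float, float, float]:
    """MR-Egger regression after orienting every SNP to gamma_j >= 0.

    Returns (slope, slope_se, intercept, intercept_se, Q) with SEs under
    multiplicative over-dispersion floored at the unit-variance model.
    """
    sign = np.where(np.asarray(bx) < 0, -1.0, 1.0)
    x = np.asarray(bx, float) * sign
    y = np.asarray(by, float) * sign
    w = 1.0 / np.asarray(sy, float) ** 2
    design = sm.add_constant(x)
    fit = sm.WLS(y, design, weights=w).fit()
    j = x.size
    q = float(fit.ssr)  # weighted RSS; chi2_{J-2} under homogeneity
    # statsmodels scales the covariance by ssr/df; floor the dispersion at 1
    unit_se = fit.bse / np.sqrt(fit.scale)
    scale = max(1.0, np.sqrt(q / (j - 2))) if j > 2 else 1.0
    se = unit_se * scale
    return float(fit.params[1]), float(se[1]), float(fit.params[0]), float(se[0]), q


def weighted_median_point(ratios: np.ndarray, weights: np.ndarray) -> float:
    """Weighted median of per-SNP ratio estimates.

    Cumulative standardized weight is interpolated across the order
    statistics; a single SNP carrying a strict majority of the weight is
    returned directly (the weighted median is that point mass).
    """
    ratios = np.asarray(ratios, float)
    weights = np.asarray(weights, float)
    order = np.argsort(ratios)
    b = ratios[order]
    w = weights[order] / weights.sum()
    if w.max() > 0.5:
        return float(b[np.argmax(w)])
    s = np.cumsum(w) - 0.5 * w
    return float(np.interp(0.5, s, b))


def _weighted_median_rows(B: np.ndarray, W: np.ndarray) -> np.ndarray:
    """Row-wise weighted medians (bootstrap fast path)."""
    order = np.argsort(B, axis=1)
    b = np.take_along_axis(B, order, axis=1)
    w = np.take_along_axis(W, order, axis=1)
    w = w / w.sum(axis=1, keepdims=True)
    s = np.cumsum(w, axis=1) - 0.5 * w
    out = np.empty(B.shape[0])
    for i in range(B.shape[0]):
        out[i] = np.interp(0.5, s[i], b[i])
    return out


# ---------------------------------------------------------------------------
# public estimators on HarmonizedSet
# ---------------------------------------------------------------------------

def wald_ratio(
    beta_exposure: float,
    se_exposure: float,
    beta_outcome: float,
    se_outcome: float,
    rsid: str = "",
) -> MRResult:
    """Single-SNP causal estimate Gamma/gamma with first-order delta SE."""
    if beta_exposure == 0:
        raise ZeroDivisionError(f"undefined Wald ratio: gamma = 0 for {rsid or 'SNP'}")
    est = beta_outcome / beta_exposure
    se = se_outcome / abs(beta_exposure)
    return _result("wald", est, se, _normal_p(est / se), 1, notes=rsid)


def ivw(
    hset: HarmonizedSet, model: Literal["fixed", "random"] = "random"
) -> tuple[MRResult, HeterogeneityReport]:
    """Inverse-variance weighted MR estimate with heterogeneity report.

    With one SNP this degrades gracefully to the Wald ratio.  The
    random-effects (multiplicative over-dispersion) variant is the
    conventional primary analysis; its SE never falls below fixed effects.
    """
    bx, sx, by, sy = hset.arrays()
    j = bx.size
    if j == 0:
        raise InsufficientInstrumentsError("no retained instruments")
    if j == 1:
        res = wald_ratio(bx[0], sx[0], by[0], sy[0], rsid=hset.rsids[0])
        return replace(res, method=f"ivw_{model}"), HeterogeneityReport(0.0, 1, 1.0)
    est, se_re, q = ivw_arrays(bx, by, sy, random_effects=True)
    se = (bx**2 / sy**2).sum() ** -0.5 if model == "fixed" else se_re
    het = HeterogeneityReport(Q=q, df=j - 1, pvalue=float(stats.chi2.sf(q, j - 1)))
    return _result(f"ivw_{model}", est, se, _normal_p(est / se), j), het


def mr_egger(hset: HarmonizedSet) -> tuple[MRResult, MRResult, HeterogeneityReport]:
    """MR-Egger slope and intercept (directional-pleiotropy test).

    Returns (slope result, intercept result, heterogeneity).  Inference uses
    the t distribution on J-2 degrees of freedom.
    """
    bx, sx, by, sy = hset.arrays()
    j = bx.size
    if j < 3:
        raise InsufficientInstrumentsError(f"MR-Egger needs >= 3 SNPs, got {j}")
    slope, slope_se, icpt, icpt_se, q = egger_arrays(bx, sx, by, sy)
    df = j - 2
    p_slope = float(2 * stats.t.sf(abs(slope / slope_se), df))
    p_icpt = float(2 * stats.t.sf(abs(icpt / icpt_se), df))
    tq = float(stats.t.ppf(0.975, df))
    slope_res = MRResult(
        "egger_slope", slope, slope_se,
        slope - tq * slope_se, slope + tq * slope_se, p_slope, j,
    )
    icpt_res = MRResult(
        "egger_intercept", icpt, icpt_se,
        icpt - tq * icpt_se, icpt + tq * icpt_se, p_icpt, j,
    )
    het = HeterogeneityReport(
        Q=q, df=df, pvalue=float(stats.chi2.sf(q, df)),
        egger_intercept=icpt, intercept_se=icpt_se, intercept_pvalue=p_icpt,
    )
    return slope_res, icpt_res, het


def weighted_median(
    hset: HarmonizedSet, n_boot: int = 1000, seed: int | None = None
) -> MRResult:
    """Weighted-median MR estimate with parametric-bootstrap SE.

    Consistent as long as valid instruments contribute more than half of the
    total inverse-variance weight, regardless of the pleiotropy pattern of
    the invalid half.
    """
    bx, sx, by, sy = hset.arrays()
    j = bx.size
    if j < 3:
        raise InsufficientInstrumentsError(f"weighted median needs >= 3 SNPs, got {j}")
    w = bx**2 / sy**2
    est = weighted_median_point(by / bx, w)
    rng = np.random.default_rng(seed)
    bx_b = rng.normal(bx, sx, size=(n_boot, j))
    by_b = rng.normal(by, sy, size=(n_boot, j))
    ratios_b = by_b / bx_b
    w_b = bx_b**2 / sy**2
    boots = _weighted_median_rows(ratios_b, w_b)
    se = float(boots.std(ddof=1))
    return _result("weighted_median", est, se, _normal_p(est / se), j)


def cochran_q(
    hset: HarmonizedSet, weights: Literal["first_order", "modified"] = "modified"
) -> HeterogeneityReport:
    """Cochran's Q across per-SNP ratio estimates.

    ``first_order`` weights ignore exposure uncertainty
    (``w = gamma^2 / sigma_Gamma^2``); the ``modified`` variant solves
    ``w_j = 1 / (sigma_Gamma^2/gamma^2 + theta^2 sigma_gamma^2/gamma^2)``
    jointly with the weighted estimate by fixed-point iteration, which
    restores the chi-square null when instruments are noisy.
    """
    bx, sx, by, sy = hset.arrays()
    j = bx.size
    if j < 2:
        raise InsufficientInstrumentsError("Cochran's Q needs >= 2 SNPs")
    ratios = by / bx
    if weights == "first_order":
        w = bx**2 / sy**2
        theta = (w * ratios).sum() / w.sum()
    else:
        theta, _, _ = ivw_arrays(bx, by, sy)
        for _ in range(50):
            var = sy**2 / bx**2 + theta**2 * sx**2 / bx**2
            w = 1.0 / var
            new_theta = (w * ratios).sum() / w.sum()
            if abs(new_theta - theta) < 1e-12:
                theta = new_theta
                break
            theta = new_theta
    q = float((w * (ratios - theta) ** 2).sum())
    return HeterogeneityReport(Q=q, df=j - 1, pvalue=float(stats.chi2.sf(q, j - 1)))


def leave_one_out(hset: HarmonizedSet) -> pd.DataFrame:
    """Random-effects IVW with each SNP omitted in turn.

    One row per excluded SNP, for influence inspection/plotting; a SNP whose
    omission moves the estimate far from the rest dominates the result.
    """
    rsids = hset.rsids
    if len(rsids) < 3:
        raise InsufficientInstrumentsError("leave-one-out needs >= 3 SNPs")
    rows = []
    for rsid in rsids:
        sub = hset.subset([r for r in rsids if r != rsid])
        res, _ = ivw(sub, model="random")
        rows.append({"excluded_rsid": rsid, **res.to_dict()})
    return pd.DataFrame(rows)


def _loo_slopes(bx: np.ndarray, by: np.ndarray, sy: np.ndarray) -> np.ndarray:
    """Leave-one-out IVW slopes theta_{-j}, vectorized over j."""
    w = bx**2 / sy**2
    ratios = by / bx
    num = (w * ratios).sum() - w * ratios
    den = w.sum() - w
    return num / den


def mr_presso(
    hset: HarmonizedSet,
    n_sim: int = 1000,
    outlier_alpha: float = 0.05,
    seed: int | None = None,
) -> PressoReport:
    """MR-PRESSO: global pleiotropy test, outlier flagging and correction.

    The observed residual sum of squares ``RSS = sum_j w_j (Gamma_j -
    theta_{-j} gamma_j)^2`` (leave-one-out slopes, ``w_j = 1/sigma_Gamma^2``)
    is compared with its parametric-bootstrap null obtained by redrawing
    ``Gamma*_j ~ N(theta_{-j} gamma_j, sigma_Gamma^2)`` and ``gamma*_j ~
    N(gamma_j, sigma_gamma^2)``.  Per-SNP squared residuals are compared to
    their simulated distributions with Bonferroni correction; flagged SNPs
    are removed and the IVW estimate recomputed.  The distortion test
    compares the raw-vs-corrected shift against removals of random subsets
    of the same size.
    """
    bx, sx, by, sy = hset.arrays()
    j = bx.size
    if j < 4:
        raise InsufficientInstrumentsError(f"MR-PRESSO needs >= 4 SNPs, got {j}")
    rng = np.random.default_rng(seed)
    w = 1.0 / sy**2
    theta_loo = _loo_slopes(bx, by, sy)
    resid2_obs = w * (by - theta_loo * bx) ** 2
    rss_obs = float(resid2_obs.sum())

    by_sim = rng.normal(theta_loo * bx, sy, size=(n_sim, j))
    bx_sim = rng.normal(bx, sx, size=(n_sim, j))
    resid2_sim = w * (by_sim - theta_loo * bx_sim) ** 2
    rss_sim = resid2_sim.sum(axis=1)
    global_p = float((1 + np.sum(rss_sim >= rss_obs)) / (n_sim + 1))

    per_snp_p = (1 + np.sum(resid2_sim >= resid2_obs, axis=0)) / (n_sim + 1)
    rsids = hset.rsids
    outlier_pvalues = {rsids[k]: float(per_snp_p[k]) for k in range(j)}
    bonferroni = outlier_alpha / j
    outliers = [rsids[k] for k in range(j) if per_snp_p[k] < bonferroni]

    raw, _ = ivw(hset, model="random")
    if len(outliers) == j:
        raise ValueError("MR-PRESSO flagged every SNP; correction is degenerate")
    if outliers:
        corrected_set = hset.subset([r for r in rsids if r not in set(outliers)])
        corrected, _ = ivw(corrected_set, model="random")
        # distortion: observed shift vs removals of random same-size subsets
        k = len(outliers)
        shifts = np.empty(n_sim)
        idx = np.arange(j)
        for s in range(n_sim):
            drop = rng.choice(idx, size=k, replace=False)
            keep = np.setdiff1d(idx, drop)
            t_sub, _, _ = ivw_arrays(bx[keep], by[keep], sy[keep])
            shifts[s] = raw.estimate - t_sub
        obs_shift = raw.estimate - corrected.estimate
        distortion_p = float(
            (1 + np.sum(np.abs(shifts) >= abs(obs_shift))) / (n_sim + 1)
        )
    else:
        corrected = raw
        distortion_p = 1.0
    return PressoReport(
        global_rss_observed=rss_obs,
        global_pvalue=global_p,
        outlier_pvalues=outlier_pvalues,
        outliers=outliers,
        distortion_pvalue=distortion_p,
        estimate_raw=raw,
        estimate_outlier_corrected=corrected,
        n_simulations=n_sim,
    )


def classify_significance(
    results: Sequence[MRResult] | pd.DataFrame,
    n_tests: int = 20,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Bonferroni-tiered significance labels for a family of MR results.

    ``significant``: p < alpha/n_tests (strict); ``marginal``: between the
    Bonferroni threshold and ``alpha``; ``null`` otherwise.
    """
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    threshold = alpha / n_tests
    if isinstance(results, pd.DataFrame):
        df = results.copy()
    else:
        df = pd.DataFrame([r.to_dict() for r in results])
    p = df["pvalue"]
    df["bonferroni_threshold"] = threshold
    df["tier"] = np.where(
        p < threshold, "significant", np.where(p < alpha, "marginal", "null")
    )
    return df


def bonferroni_threshold(n_tests: int = 20, alpha: float = 0.05) -> float:
    """The family-wise significance threshold alpha / n_tests."""
    return alpha / n_tests
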
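"""Multivariable two-sample MR: joint (conditional) effects of K exposures.

Regressing the outcome associations Gamma_j on the K-vector of exposure
associations (gamma_j1 ... gamma_jK), weighted by 1/sigma_Gamma_j^2 and
without an intercept, estimates each exposure's direct effect holding the
others fixed.  The instrument is the de-duplicated, LD-pruned union of the
per-exposure instruments; every SNP must have a measured association with
*every* exposure (at any p-value), which is why assembly reads full
summary tables rather than instrument subsets.

Extensions mirror the univariable toolbox: an Egger variant with an
intercept (after orienting SNPs to a non-negative first exposure), a
weighted-median-style L1 fit with bootstrap SEs, and a bidirectional
univariable analysis between two exposures.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .estimators import (
    MRResult,
    HeterogeneityReport,
    InsufficientInstrumentsError,
    Z95,
    _normal_p,
    _result,
    ivw,
    mr_egger,
    weighted_median,
)
from .harmonize import HarmonizedSet, harmonize
from .instruments import GENOME_WIDE_P, InstrumentSet, LDTable, drop_outcome_associated, ld_clump
from .io import AssociationTable


class CollinearityError(ValueError):
    """The exposure-association matrix is rank deficient."""


@dataclass
class MVMRInput:
    """Aligned inputs for a K-exposure multivariable MR fit."""

    rsids: list[str]
    exposure_betas: np.ndarray  # (J, K)
    exposure_ses: np.ndarray  # (J, K)
    beta_outcome: np.ndarray  # (J,)
    se_outcome: np.ndarray  # (J,)
    exposures: list[str]
    outcome: str = "outcome"
    provenance: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.exposure_betas = np.atleast_2d(np.asarray(self.exposure_betas, float))
        self.exposure_ses = np.atleast_2d(np.asarray(self.exposure_ses, float))
        self.beta_outcome = np.asarray(self.beta_outcome, float)
        self.se_outcome = np.asarray(self.se_outcome, float)
        if self.exposure_betas.shape[1] != len(self.exposures):
            raise ValueError("exposure_betas has wrong number of columns")

    @property
    def J(self) -> int:
        return len(self.rsids)

    @property
    def K(self) -> int:
        return len(self.exposures)


@dataclass
class MVMRResult:
    """Per-exposure conditional estimates under one shared fit."""

    method: str
    results: dict[str, MRResult]
    heterogeneity: HeterogeneityReport | None = None
    intercept: MRResult | None = None

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for exposure, res in self.results.items():
            rows.append({"exposure": exposure, **res.to_dict()})
        return pd.DataFrame(rows)


def assemble_mvmr_input(
    instr_a: InstrumentSet,
    instr_b: InstrumentSet,
    exposure_tables: Mapping[str, AssociationTable],
    outcome: AssociationTable,
    ld: LDTable | None = None,
    outcome_p_threshold: float = GENOME_WIDE_P,
    r2_max: float = 0.001,
    window_kb: float = 10_000,
) -> MVMRInput:
    """Build the union instrument and extract per-SNP betas on all exposures.

    Steps, each recorded in provenance: de-duplicated union of the two
    instrument lists; removal of SNPs absent from any exposure table or the
    outcome table; removal of SNPs genome-wide associated with the outcome;
    LD clumping of the union (index p = the smaller of the two exposure
    p-values); harmonization of every table to the first exposure's effect
    allele.
    """
    if len(exposure_tables) < 2:
        raise ValueError("multivariable MR needs >= 2 exposures")
    labels = list(exposure_tables)
    union = list(dict.fromkeys([*instr_a.rsids, *instr_b.rsids]))
    provenance: list = [("union", {"a": instr_a.name, "b": instr_b.name, "size": len(union)})]

    missing: list[str] = []
    for label, table in exposure_tables.items():
        present = set(table.data["rsid"])
        gone = [r for r in union if r not in present]
        if gone:
            missing.extend(gone)
            provenance.append((f"missing_from_{label}", gone))
    present_out = set(outcome.data["rsid"])
    gone = [r for r in union if r not in present_out]
    if gone:
        missing.extend(gone)
        provenance.append((f"missing_from_{outcome.trait or 'outcome'}", gone))
    union = [r for r in union if r not in set(missing)]

    working = InstrumentSet("mvmr-union", union)
    working = drop_outcome_associated(working, outcome, threshold=outcome_p_threshold)

    if ld is not None:
        pvals = {}
        for rsid in working.rsids:
            ps = []
            for table in exposure_tables.values():
                row = table.data.loc[table.data["rsid"] == rsid, "pvalue"]
                if len(row) and np.isfinite(row.iloc[0]):
                    ps.append(float(row.iloc[0]))
            pvals[rsid] = min(ps) if ps else 1.0
        working = ld_clump(working, pvals, ld, r2_max=r2_max, window_kb=window_kb)
    provenance.extend(working.provenance)

    ref_label = labels[0]
    ref = exposure_tables[ref_label].subset(working.rsids)
    aligned: dict[str, HarmonizedSet] = {}
    for label in labels[1:]:
        aligned[label] = harmonize(ref, exposure_tables[label].subset(working.rsids))
    out_h = harmonize(ref, outcome.subset(working.rsids))

    keep = set(out_h.rsids)
    for hset in aligned.values():
        keep &= set(hset.rsids)
    rsids = [r for r in working.rsids if r in keep]
    dropped_harm = [r for r in working.rsids if r not in keep]
    if dropped_harm:
        provenance.append(("dropped_harmonization", dropped_harm))

    ref_idx = ref.data.set_index("rsid")
    G = np.zeros((len(rsids), len(labels)))
    SE = np.zeros_like(G)
    G[:, 0] = ref_idx.loc[rsids, "beta"].to_numpy(float)
    SE[:, 0] = ref_idx.loc[rsids, "se"].to_numpy(float)
    for k, label in enumerate(labels[1:], start=1):
        p = aligned[label].retained.set_index("rsid")
        G[:, k] = p.loc[rsids, "beta_outcome"].to_numpy(float)
        SE[:, k] = p.loc[rsids, "se_outcome"].to_numpy(float)
    op = out_h.retained.set_index("rsid")
    return MVMRInput(
        rsids=rsids,
        exposure_betas=G,
        exposure_ses=SE,
        beta_outcome=op.loc[rsids, "beta_outcome"].to_numpy(float),
        se_outcome=op.loc[rsids, "se_outcome"].to_numpy(float),
        exposures=labels,
        outcome=outcome.trait or "outcome",
        provenance=provenance,
    )


def _design(inp: MVMRInput) -> tuple[np.ndarray, np.ndarray, list[int]]:
    """Weighted design handling all-zero exposure columns (nested models).

    Returns (X with zero columns removed, active column indices).  A truly
    rank-deficient non-zero design raises :class:`CollinearityError`.
    """
    X = inp.exposure_betas
    nonzero = [k for k in range(inp.K) if np.any(X[:, k] != 0)]
    Xa = X[:, nonzero]
    if Xa.size and np.linalg.matrix_rank(Xa) < Xa.shape[1]:
        raise CollinearityError(
            f"exposure-association matrix is rank deficient for {inp.exposures}"
        )
    return X, Xa, nonzero


def mvmr_ivw(inp: MVMRInput) -> MVMRResult:
    """Multivariable IVW: weighted multivariate regression through the origin.

    Weights 1/sigma_Gamma^2; SEs carry multiplicative over-dispersion
    floored at 1 with J-K residual degrees of freedom; normal-based CIs.
    """
    if inp.J <= inp.K:
        raise InsufficientInstrumentsError(f"need J > K, got J={inp.J}, K={inp.K}")
    _, Xa, active = _design(inp)
    w = 1.0 / inp.se_outcome**2
    fit = sm.WLS(inp.beta_outcome, Xa, weights=w).fit()
    df = inp.J - len(active)
    scale = max(1.0, np.sqrt(fit.ssr / df)) if df > 0 else 1.0
    unit_se = fit.bse / np.sqrt(fit.scale)
    se = unit_se * scale
    results: dict[str, MRResult] = {}
    for k, label in enumerate(inp.exposures):
        if k in active:
            i = active.index(k)
            est, s = float(fit.params[i]), float(se[i])
            results[label] = _result(
                "mvmr_ivw", est, s, _normal_p(est / s), inp.J
            )
        else:
            results[label] = MRResult(
                "mvmr_ivw", np.nan, np.nan, np.nan, np.nan, np.nan, inp.J,
                model_notes="all exposure betas zero; dropped from fit",
            )
    het = HeterogeneityReport(
        Q=float(fit.ssr), df=df, pvalue=float(stats.chi2.sf(fit.ssr, df))
    )
    return MVMRResult(method="mvmr_ivw", results=results, heterogeneity=het)


def mvmr_egger(inp: MVMRInput) -> MVMRResult:
    """Multivariable MR-Egger: adds an intercept after orienting SNPs.

    Orientation flips each SNP so the first exposure's beta is non-negative
    (the primary-exposure convention); the intercept then measures
    directional pleiotropy, with t-based p on J-K-1 degrees of freedom.
    """
    if inp.J <= inp.K + 1:
        raise InsufficientInstrumentsError(
            f"need J > K+1, got J={inp.J}, K={inp.K}"
        )
    _, Xa, active = _design(inp)
    sign = np.where(inp.exposure_betas[:, 0] < 0, -1.0, 1.0)
    Xo = Xa * sign[:, None]
    yo = inp.beta_outcome * sign
    w = 1.0 / inp.se_outcome**2
    design = sm.add_constant(Xo)
    fit = sm.WLS(yo, design, weights=w).fit()
    df = inp.J - len(active) - 1
    scale = max(1.0, np.sqrt(fit.ssr / df)) if df > 0 else 1.0
    unit_se = fit.bse / np.sqrt(fit.scale)
    se = unit_se * scale
    tq = float(stats.t.ppf(0.975, df))

    def t_result(method: str, est: float, s: float) -> MRResult:
        p = float(2 * stats.t.sf(abs(est / s), df))
        return MRResult(method, est, s, est - tq * s, est + tq * s, p, inp.J)

    results: dict[str, MRResult] = {}
    for k, label in enumerate(inp.exposures):
        if k in active:
            i = active.index(k) + 1  # constant first
            results[label] = t_result("mvmr_egger", float(fit.params[i]), float(se[i]))
        else:
            results[label] = MRResult(
                "mvmr_egger", np.nan, np.nan, np.nan, np.nan, np.nan, inp.J,
                model_notes="all exposure betas zero; dropped from fit",
            )
    intercept = t_result("mvmr_egger_intercept", float(fit.params[0]), float(se[0]))
    het = HeterogeneityReport(
        Q=float(fit.ssr), df=df, pvalue=float(stats.chi2.sf(fit.ssr, df)),
        egger_intercept=intercept.estimate, intercept_se=intercept.se,
        intercept_pvalue=intercept.pvalue,
    )
    return MVMRResult(
        method="mvmr_egger", results=results, heterogeneity=het, intercept=intercept
    )


def mvmr_median(
    inp: MVMRInput, n_boot: int = 1000, seed: int | None = None
) -> MVMRResult:
    """Weighted-median-style multivariable fit: L1 regression with weights.

    Minimizes ``sum_j w_j |Gamma_j - x_j . theta|`` with ``w_j =
    1/sigma_Gamma_j`` (realized as median quantile regression on the
    weight-scaled design); robust to a minority of pleiotropic SNPs.  SEs by
    seeded parametric bootstrap.
    """
    if inp.J <= inp.K:
        raise InsufficientInstrumentsError(f"need J > K, got J={inp.J}, K={inp.K}")
    _, Xa, active = _design(inp)
    w = 1.0 / inp.se_outcome

    def fit_l1(X: np.ndarray, y: np.ndarray) -> np.ndarray:
        model = sm.QuantReg(y * w, X * w[:, None])
        return np.asarray(model.fit(q=0.5, max_iter=2000).params)

    params = fit_l1(Xa, inp.beta_outcome)
    rng = np.random.default_rng(seed)
    boots = np.empty((n_boot, len(active)))
    for b in range(n_boot):
        Xb = rng.normal(Xa, inp.exposure_ses[:, active])
        yb = rng.normal(inp.beta_outcome, inp.se_outcome)
        try:
            boots[b] = fit_l1(Xb, yb)
        except Exception:
            boots[b] = np.nan
    ses = np.nanstd(boots, axis=0, ddof=1)
    results: dict[str, MRResult] = {}
    for k, label in enumerate(inp.exposures):
        if k in active:
            i = active.index(k)
            est, s = float(params[i]), float(ses[i])
            results[label] = _result(
                "mvmr_median", est, s, _normal_p(est / s), inp.J
            )
        else:
            results[label] = MRResult(
                "mvmr_median", np.nan, np.nan, np.nan, np.nan, np.nan, inp.J,
                model_notes="all exposure betas zero; dropped from fit",
            )
    return MVMRResult(method="mvmr_median", results=results)


def bidirectional_mr(
    table_a: AssociationTable,
    table_b: AssociationTable,
    instruments_a: InstrumentSet,
    instruments_b: InstrumentSet,
    n_boot: int = 1000,
    seed: int | None = None,
) -> dict[str, pd.DataFrame]:
    """Univariable MR in both directions between two traits.

    Runs random-effects IVW, weighted median and MR-Egger for A -> B using
    A's instruments and for B -> A using B's, returning one tidy frame per
    direction.  A genuine one-way cause shows a non-null forward estimate
    and a reverse CI covering zero.
    """
    out: dict[str, pd.DataFrame] = {}
    specs = [
        (f"{table_a.trait}->{table_b.trait}", table_a, table_b, instruments_a),
        (f"{table_b.trait}->{table_a.trait}", table_b, table_a, instruments_b),
    ]
    for key, exp, outc, instr in specs:
        hset = harmonize(exp.subset(instr.rsids), outc)
        rows = []
        res, het = ivw(hset, model="random")
        rows.append(res.to_dict() | {"Q": het.Q, "Q_pvalue": het.pvalue})
        if hset.n_snps >= 3:
            rows.append(weighted_median(hset, n_boot=n_boot, seed=seed).to_dict())
            slope, icpt, _ = mr_egger(hset)
            rows.append(slope.to_dict())
            rows.append(icpt.to_dict())
        out[key] = pd.DataFrame(rows)
    return out
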
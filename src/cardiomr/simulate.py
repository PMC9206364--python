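"""Synthetic two-sample GWAS summary statistics with known ground truth.

The generator works at the summary level: true per-SNP exposure effects
gamma_j are drawn from a normal distribution, horizontal pleiotropy alpha_j
is added directly to the outcome effects (none / balanced / directional /
InSIDE-violating), and the observed associations add sampling noise with
standard errors 1 / sqrt(n) under unit trait variance:

    Gamma_j = theta * gamma_j + alpha_j
    gamma_hat_j ~ N(gamma_j, 1/n_exp),   Gamma_hat_j ~ N(Gamma_j, 1/n_out)

Allele bookkeeping (random allele pairs, strand-complement representation,
effect/other swaps, palindromic variants with their frequencies) is layered
on top so the harmonization and I/O stages are exercised end-to-end.  A
separate fixture builder emulates the instrument bookkeeping of a glycemic
-traits study design: a 53-SNP composite insulin-resistance instrument with
one SNP unavailable in the outcome GWAS and named exclusion subsets of
51/46/43/28/20 SNPs.

Default sample sizes mirror typical consortium scales for glycemic
exposures (~100k) against a cardiac-MRI outcome GWAS (~17k).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import estimators as est
from .harmonize import HarmonizedSet
from .instruments import InstrumentSet, LDTable
from .io import AssociationTable
from .mvmr import MVMRInput

PLEIOTROPY_MODES = ("none", "balanced", "directional", "inside_violating")

_NONPALINDROMIC_PAIRS = [
    ("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
    ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T"),
]
_PALINDROMIC_PAIRS = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass(frozen=True)
class Pleiotropy:
    """Horizontal-pleiotropy specification for the outcome model.

    ``mode``: one of none / balanced / directional / inside_violating.
    ``mu_alpha``/``sigma_alpha``: mean and SD of the direct effects.
    ``rho``: correlation between alpha_j and gamma_j (InSIDE violation).
    ``invalid_fraction``: share of SNPs receiving a direct effect (1.0 =
    all; 0.5 emulates the half-invalid regime the weighted median targets).
    """

    mode: str = "none"
    mu_alpha: float = 0.0
    sigma_alpha: float = 0.0
    rho: float = 0.0
    invalid_fraction: float = 1.0

    def __post_init__(self) -> None:
        if self.mode not in PLEIOTROPY_MODES:
            raise ValueError(
                f"unknown pleiotropy mode {self.mode!r}; choose from {PLEIOTROPY_MODES}"
            )
        if self.sigma_alpha < 0 or not 0 <= self.invalid_fraction <= 1:
            raise ValueError("sigma_alpha >= 0 and invalid_fraction in [0,1] required")


@dataclass(frozen=True)
class SimulationConfig:
    """Design of one simulated two-sample study.

    ``theta`` is the true causal effect (scalar, or length-K tuple for the
    multivariable generator); ``gamma_mean``/``gamma_sd`` parameterize the
    true exposure-effect distribution; ``n_exp``/``n_out`` control the
    sampling SEs (1/sqrt(n), unit trait variance).  ``seed`` is mandatory.
    """

    J: int = 50
    theta: float | tuple[float, ...] = 0.3
    gamma_mean: float = 0.3
    gamma_sd: float = 0.1
    n_exp: float = 100_000
    n_out: float = 17_000
    pleiotropy: Pleiotropy = field(default_factory=Pleiotropy)
    palindrome_fraction: float = 0.0
    allele_flip_fraction: float = 0.3
    strand_flip_fraction: float = 0.2
    eaf_low: float = 0.05
    eaf_high: float = 0.95
    exposure_correlation: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.J < 1:
            raise ValueError("J must be >= 1")
        for frac in (self.palindrome_fraction, self.allele_flip_fraction,
                     self.strand_flip_fraction):
            if not 0 <= frac <= 1:
                raise ValueError("fractions must lie in [0, 1]")
        if abs(self.exposure_correlation) >= 1:
            raise ValueError("|exposure_correlation| must be < 1")


@dataclass
class SimulatedStudy:
    """Generated summary tables plus the ground truth that produced them."""

    exposure_tables: list[AssociationTable]
    outcome_table: AssociationTable
    truth: dict
    config: SimulationConfig

    @property
    def exposure_table(self) -> AssociationTable:
        return self.exposure_tables[0]

    def harmonized(self) -> HarmonizedSet:
        """Noise-aligned effect arrays, bypassing allele bookkeeping."""
        t = self.truth
        return HarmonizedSet.from_arrays(
            t["beta_exp_obs"], t["se_exp"], t["beta_out_obs"], t["se_out"],
            rsids=t["rsids"],
            exposure=self.exposure_table.trait,
            outcome=self.outcome_table.trait,
        )

    def mvmr_input(self) -> MVMRInput:
        t = self.truth
        if t["G_obs"].ndim != 2:
            raise ValueError("univariable study; use harmonized() instead")
        return MVMRInput(
            rsids=list(t["rsids"]),
            exposure_betas=t["G_obs"],
            exposure_ses=t["SE_G"],
            beta_outcome=t["beta_out_obs"],
            se_outcome=t["se_out"],
            exposures=[tab.trait for tab in self.exposure_tables],
            outcome=self.outcome_table.trait,
        )


def _draw_alpha(
    rng: np.random.Generator, gamma: np.ndarray, pleio: Pleiotropy
) -> tuple[np.ndarray, np.ndarray]:
    """Direct (pleiotropic) outcome effects and per-SNP validity flags."""
    j = gamma.size
    alpha = np.zeros(j)
    valid = np.ones(j, bool)
    if pleio.mode == "none":
        return alpha, valid
    n_invalid = int(round(pleio.invalid_fraction * j))
    if n_invalid == 0:
        return alpha, valid
    idx = rng.choice(j, size=n_invalid, replace=False)
    if pleio.mode == "balanced":
        draws = rng.normal(0.0, pleio.sigma_alpha, n_invalid)
    elif pleio.mode == "directional":
        draws = rng.normal(pleio.mu_alpha, pleio.sigma_alpha, n_invalid)
    else:  # inside_violating: alpha correlated with instrument strength
        g = gamma[idx]
        z_g = (g - g.mean()) / (g.std() if g.std() > 0 else 1.0)
        z = rng.standard_normal(n_invalid)
        draws = pleio.mu_alpha + pleio.sigma_alpha * (
            pleio.rho * z_g + np.sqrt(1 - pleio.rho**2) * z
        )
    alpha[idx] = draws
    valid[idx] = ~(draws != 0)
    return alpha, valid


def draw_effects(
    config: SimulationConfig, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """Fast path: effect arrays only, no allele/table dressing.

    Used by the calibration experiments where thousands of replicates are
    needed; the estimators consume these arrays directly.
    """
    j = config.J
    gamma = rng.normal(config.gamma_mean, config.gamma_sd, j)
    alpha, valid = _draw_alpha(rng, gamma, config.pleiotropy)
    se_exp = np.full(j, 1.0 / np.sqrt(config.n_exp))
    se_out = np.full(j, 1.0 / np.sqrt(config.n_out))
    theta = float(np.asarray(config.theta).ravel()[0])
    Gamma = theta * gamma + alpha
    return {
        "gamma_true": gamma,
        "alpha": alpha,
        "valid": valid,
        "se_exp": se_exp,
        "se_out": se_out,
        "beta_exp_obs": rng.normal(gamma, se_exp),
        "beta_out_obs": rng.normal(Gamma, se_out),
    }


def _dress_alleles(
    rng: np.random.Generator, config: SimulationConfig, j: int
) -> pd.DataFrame:
    """Random allele pairs, EAFs and outcome-side recoding plan."""
    palindromic = rng.random(j) < config.palindrome_fraction
    pairs = []
    for k in range(j):
        pool = _PALINDROMIC_PAIRS if palindromic[k] else _NONPALINDROMIC_PAIRS
        pairs.append(pool[rng.integers(len(pool))])
    ea, oa = zip(*pairs)
    eaf = rng.uniform(config.eaf_low, config.eaf_high, j)
    return pd.DataFrame(
        {
            "effect_allele": ea,
            "other_allele": oa,
            "eaf": eaf,
            "palindromic": palindromic,
            "swap": rng.random(j) < config.allele_flip_fraction,
            "strand": rng.random(j) < config.strand_flip_fraction,
        }
    )


def _pvalue(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    from scipy import stats

    from .io import TINY_P

    # clamp underflowed p so generated tables re-read without warnings
    return np.clip(2 * stats.norm.sf(np.abs(beta / se)), TINY_P, 1.0)


def simulate_univariable(config: SimulationConfig) -> SimulatedStudy:
    """Generate one exposure table and one outcome table with known truth.

    The outcome table re-codes a fraction of SNPs (effect/other swap and/or
    strand complement, never a strand flip on palindromic variants — those
    stay ambiguous by construction) so that harmonization has real work to
    do; the ``truth`` dict carries the aligned observed arrays for direct
    estimator access.
    """
    rng = np.random.default_rng(config.seed)
    eff = draw_effects(config, rng)
    j = config.J
    rsids = [f"rs{1000000 + k}" for k in range(j)]
    dress = _dress_alleles(rng, config, j)

    exp_df = pd.DataFrame(
        {
            "rsid": rsids,
            "effect_allele": dress["effect_allele"],
            "other_allele": dress["other_allele"],
            "eaf": dress["eaf"],
            "beta": eff["beta_exp_obs"],
            "se": eff["se_exp"],
            "pvalue": _pvalue(eff["beta_exp_obs"], eff["se_exp"]),
            "n": config.n_exp,
        }
    )

    out_ea = dress["effect_allele"].copy()
    out_oa = dress["other_allele"].copy()
    out_beta = eff["beta_out_obs"].copy()
    out_eaf = dress["eaf"].to_numpy().copy()
    for k in range(j):
        if dress.loc[k, "strand"] and not dress.loc[k, "palindromic"]:
            out_ea[k] = _COMPLEMENT[out_ea[k]]
            out_oa[k] = _COMPLEMENT[out_oa[k]]
        if dress.loc[k, "swap"]:
            out_ea[k], out_oa[k] = out_oa[k], out_ea[k]
            out_beta[k] = -out_beta[k]
            out_eaf[k] = 1 - out_eaf[k]
    out_df = pd.DataFrame(
        {
            "rsid": rsids,
            "effect_allele": out_ea,
            "other_allele": out_oa,
            "eaf": out_eaf,
            "beta": out_beta,
            "se": eff["se_out"],
            "pvalue": _pvalue(out_beta, eff["se_out"]),
            "n": config.n_out,
        }
    )
    truth = {
        "theta": config.theta,
        "rsids": rsids,
        **eff,
        "G_obs": eff["beta_exp_obs"],  # uniform access for truth dumps
    }
    return SimulatedStudy(
        exposure_tables=[AssociationTable(exp_df, trait="exposure", unit="per 1-SD")],
        outcome_table=AssociationTable(out_df, trait="outcome", unit="per 1-SD"),
        truth=truth,
        config=config,
    )


def simulate_multivariable(config: SimulationConfig) -> SimulatedStudy:
    """Two correlated exposures acting on one outcome.

    True effects on the exposures are bivariate normal with correlation
    ``exposure_correlation``; the outcome model is ``Gamma_j = theta_1
    gamma_j1 + theta_2 gamma_j2 + alpha_j`` plus sampling noise.
    """
    theta = np.asarray(config.theta, float).ravel()
    if theta.size != 2:
        raise ValueError("multivariable generator expects a length-2 theta")
    rng = np.random.default_rng(config.seed)
    j = config.J
    rho = config.exposure_correlation
    cov = config.gamma_sd**2 * np.array([[1, rho], [rho, 1]])
    G_true = rng.multivariate_normal(
        [config.gamma_mean, config.gamma_mean], cov, size=j
    )
    alpha, valid = _draw_alpha(rng, G_true[:, 0], config.pleiotropy)
    se_g = np.full((j, 2), 1.0 / np.sqrt(config.n_exp))
    se_out = np.full(j, 1.0 / np.sqrt(config.n_out))
    Gamma = G_true @ theta + alpha
    G_obs = rng.normal(G_true, se_g)
    beta_out_obs = rng.normal(Gamma, se_out)

    rsids = [f"rs{2000000 + k}" for k in range(j)]
    dress = _dress_alleles(rng, config, j)
    tables = []
    for k in range(2):
        df = pd.DataFrame(
            {
                "rsid": rsids,
                "effect_allele": dress["effect_allele"],
                "other_allele": dress["other_allele"],
                "eaf": dress["eaf"],
                "beta": G_obs[:, k],
                "se": se_g[:, k],
                "pvalue": _pvalue(G_obs[:, k], se_g[:, k]),
                "n": config.n_exp,
            }
        )
        tables.append(AssociationTable(df, trait=f"exposure{k + 1}", unit="per 1-SD"))
    out_df = pd.DataFrame(
        {
            "rsid": rsids,
            "effect_allele": dress["effect_allele"],
            "other_allele": dress["other_allele"],
            "eaf": dress["eaf"],
            "beta": beta_out_obs,
            "se": se_out,
            "pvalue": _pvalue(beta_out_obs, se_out),
            "n": config.n_out,
        }
    )
    truth = {
        "theta": tuple(theta),
        "rsids": rsids,
        "G_true": G_true,
        "G_obs": G_obs,
        "SE_G": se_g,
        "alpha": alpha,
        "valid": valid,
        "beta_out_obs": beta_out_obs,
        "se_out": se_out,
    }
    return SimulatedStudy(
        exposure_tables=tables,
        outcome_table=AssociationTable(out_df, trait="outcome", unit="per 1-SD"),
        truth=truth,
        config=config,
    )


# ---------------------------------------------------------------------------
# calibration experiments
# ---------------------------------------------------------------------------

def calibration_experiment(
    grid: Sequence[SimulationConfig],
    n_reps: int,
    estimator_names: Sequence[str] = ("ivw_random",),
    seed: int = 0,
) -> pd.DataFrame:
    """Monte-Carlo operating characteristics of the estimators.

    For each config cell and estimator: bias, RMSE, empirical SE of the
    estimates, mean model SE, 95% CI coverage of the true effect, and the
    rejection rate of H0: theta = 0 at the 5% level.  Replicate seeds are
    spawned from ``seed`` so the whole table is reproducible.
    """
    known = {"ivw_random", "ivw_fixed", "egger", "weighted_median"}
    bad = set(estimator_names) - known
    if bad:
        raise ValueError(f"unknown estimator(s) {sorted(bad)}; choose from {sorted(known)}")
    rows = []
    root = np.random.SeedSequence(seed)
    for cell_id, config in enumerate(grid):
        cell_ss = root.spawn(1)[0]
        rngs = [np.random.default_rng(s) for s in cell_ss.spawn(n_reps)]
        theta = float(np.asarray(config.theta).ravel()[0])
        estimates = {name: np.empty(n_reps) for name in estimator_names}
        ses = {name: np.empty(n_reps) for name in estimator_names}
        tdists = {name: 0.0 for name in estimator_names}
        for r, rng in enumerate(rngs):
            eff = draw_effects(config, rng)
            bx, sx = eff["beta_exp_obs"], eff["se_exp"]
            by, sy = eff["beta_out_obs"], eff["se_out"]
            for name in estimator_names:
                if name in ("ivw_random", "ivw_fixed"):
                    e, s, q = est.ivw_arrays(bx, by, sy, random_effects=(name == "ivw_random"))
                elif name == "egger":
                    e, s, *_ = est.egger_arrays(bx, sx, by, sy)
                    tdists[name] = config.J - 2
                else:
                    w = bx**2 / sy**2
                    e = est.weighted_median_point(by / bx, w)
                    boot_rng = np.random.default_rng(rng.integers(2**31))
                    bx_b = boot_rng.normal(bx, sx, size=(200, config.J))
                    by_b = boot_rng.normal(by, sy, size=(200, config.J))
                    s = est._weighted_median_rows(by_b / bx_b, bx_b**2 / sy**2).std(ddof=1)
                estimates[name][r] = e
                ses[name][r] = s
        for name in estimator_names:
            e, s = estimates[name], ses[name]
            from scipy import stats as sps

            df = tdists[name]
            crit = sps.t.ppf(0.975, df) if df else est.Z95
            cover = np.mean((e - crit * s <= theta) & (theta <= e + crit * s))
            reject = np.mean(np.abs(e / s) > crit)
            rows.append(
                {
                    "cell": cell_id,
                    "estimator": name,
                    "J": config.J,
                    "theta": theta,
                    "pleiotropy": config.pleiotropy.mode,
                    "n_reps": n_reps,
                    "bias": float(e.mean() - theta),
                    "rmse": float(np.sqrt(np.mean((e - theta) ** 2))),
                    "empirical_se": float(e.std(ddof=1)),
                    "mean_model_se": float(s.mean()),
                    "coverage": float(cover),
                    "rejection_rate": float(reject),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# study-mirror bookkeeping fixture
# ---------------------------------------------------------------------------

@dataclass
class BookkeepingFixture:
    """In-memory fixture emulating a composite-IR instrument workflow.

    53 instrument SNPs of which one is absent from the outcome GWAS
    (leaving 52 for analysis), named exclusion lists producing the
    51/43/28/20-SNP sensitivity subsets, an LD table under which clumping
    the 52 leaves 46 index SNPs, and a second instrument set with two
    planted genome-wide outcome hits for the outcome-association filter.
    """

    instrument: InstrumentSet  # the 53-SNP list
    exposure_table: AssociationTable
    outcome_table: AssociationTable
    exclusions: dict[str, list[str]]
    ld: LDTable
    secondary_instrument: InstrumentSet  # 30 SNPs, 2 planted outcome hits
    secondary_outcome_table: AssociationTable


def make_bookkeeping_fixture(seed: int = 0, theta: float = 0.4) -> BookkeepingFixture:
    """Build the instrument-bookkeeping fixture (deterministic given seed).

    The named SNPs play the roles the workflow expects: ``rs8101064`` is the
    instrument SNP missing from the outcome data, ``rs1011685`` the single
    weak-component SNP excluded first, and ``rs10774625`` one of the planted
    outcome-associated hits in the secondary set.
    """
    rng = np.random.default_rng(seed)
    missing_snp = "rs8101064"
    weak_snp = "rs1011685"
    synthetic = [f"rs{5000000 + k}" for k in range(51)]
    analysed = [weak_snp, *synthetic]  # the 52 extractable SNPs
    all53 = [*analysed, missing_snp]

    bmi_list = synthetic[:9]
    lipid_list = [missing_snp, *synthetic[9:33]]  # 25 total, 24 in the 52
    confounder_list = [weak_snp, *synthetic[:31]]  # 32 total, all in the 52

    j = len(all53)
    gamma = rng.uniform(0.02, 0.06, j)
    se_exp = np.full(j, 0.004)
    exp_df = pd.DataFrame(
        {
            "rsid": all53,
            "effect_allele": "A",
            "other_allele": "G",
            "eaf": rng.uniform(0.1, 0.9, j),
            "beta": gamma,
            "se": se_exp,
            "pvalue": _pvalue(gamma, se_exp),
            "n": 188_577,
        }
    )
    se_out = np.full(j - 1, 0.05)
    gamma_a = gamma[:-1]
    beta_out = theta * gamma_a + rng.normal(0, 0.02, j - 1)
    out_df = pd.DataFrame(
        {
            "rsid": analysed,
            "effect_allele": "A",
            "other_allele": "G",
            "eaf": rng.uniform(0.1, 0.9, j - 1),
            "beta": beta_out,
            "se": se_out,
            "pvalue": _pvalue(beta_out, se_out),
            "n": 16_923,
        }
    )

    # LD table: distinct loci >10 Mb apart except six planted proxy pairs
    ld = LDTable()
    for i, rsid in enumerate(analysed):
        ld.positions[rsid] = (str(i % 22 + 1), 20_000_000 * (i // 22 + 1))
    partners = synthetic[33:39]
    victims = synthetic[39:45]
    for p, v in zip(partners, victims):
        chrom, pos = ld.positions[p]
        ld.positions[v] = (chrom, pos + 500_000)
        ld.set_r2(p, v, 0.8)
        # ensure the victim has the larger p so the partner indexes the clump
        iv = all53.index(v)
        ip = all53.index(p)
        if exp_df.loc[iv, "pvalue"] < exp_df.loc[ip, "pvalue"]:
            exp_df.loc[iv, "pvalue"], exp_df.loc[ip, "pvalue"] = (
                exp_df.loc[ip, "pvalue"],
                exp_df.loc[iv, "pvalue"],
            )

    # secondary set: 30 SNPs, two of them genome-wide hits for the outcome
    hit_snps = ["rs10774625", "rs6000001"]
    sec = [*hit_snps, *[f"rs{6100000 + k}" for k in range(28)]]
    g2 = rng.uniform(0.02, 0.06, 30)
    se2 = np.full(30, 0.05)
    b2 = theta * g2 + rng.normal(0, 0.02, 30)
    p2 = _pvalue(b2, se2)
    p2[:2] = 1e-9  # planted outcome associations
    sec_out = pd.DataFrame(
        {
            "rsid": sec,
            "effect_allele": "A",
            "other_allele": "G",
            "eaf": rng.uniform(0.1, 0.9, 30),
            "beta": b2,
            "se": se2,
            "pvalue": p2,
            "n": 16_923,
        }
    )
    return BookkeepingFixture(
        instrument=InstrumentSet("IR-53", all53),
        exposure_table=AssociationTable(exp_df, trait="IR", unit="per 1-SD"),
        outcome_table=AssociationTable(out_df, trait="LV-parameter", unit="ml"),
        exclusions={
            "weak_component": [weak_snp],
            "bmi_associated": bmi_list,
            "lipid_associated": lipid_list,
            "confounder_associated": confounder_list,
        },
        ld=ld,
        secondary_instrument=InstrumentSet("secondary-30", sec),
        secondary_outcome_table=AssociationTable(
            sec_out, trait="LV-parameter", unit="ml"
        ),
    )
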
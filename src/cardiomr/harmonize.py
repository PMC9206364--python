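"""Align exposure and outcome summary statistics to a shared effect allele.

Two-sample MR combines per-SNP effects from two independent GWAS; before any
estimator runs, both studies must report their betas with respect to the
same allele of each SNP.  Non-palindromic variants are aligned directly or
after strand complementation, negating the outcome beta when the effect and
other alleles are exchanged.  Palindromic variants (A/T, C/G) cannot be
resolved from allele labels: they are aligned by allele-frequency agreement
when both studies' minor-allele frequencies are below a threshold (default
0.3) and the minor allele is the same allele in both studies; otherwise they
are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from ._alleles import COMPLEMENT, is_palindromic, match_orientation
from .io import AssociationTable

ACTIONS = (
    "kept",
    "flipped",
    "palindromic_aligned",
    "dropped_palindromic",
    "dropped_incompatible",
)

RETAINED_ACTIONS = ("kept", "flipped", "palindromic_aligned")

#: Columns of the harmonized-pair frame.
PAIR_COLUMNS = (
    "rsid",
    "effect_allele",
    "other_allele",
    "beta_exposure",
    "se_exposure",
    "beta_outcome",
    "se_outcome",
    "eaf_exposure",
    "eaf_outcome",
    "action",
)


@dataclass
class HarmonizedSet:
    """Exposure/outcome betas aligned to one effect allele per SNP.

    ``pairs`` holds one row per shared SNP with an ``action`` flag recording
    what harmonization did; ``retained`` filters to the rows usable by the
    estimators (gamma_j, sigma_gamma_j, Gamma_j, sigma_Gamma_j).
    """

    exposure: str
    outcome: str
    pairs: pd.DataFrame

    @property
    def retained(self) -> pd.DataFrame:
        return self.pairs[self.pairs["action"].isin(RETAINED_ACTIONS)]

    @property
    def dropped(self) -> pd.DataFrame:
        return self.pairs[~self.pairs["action"].isin(RETAINED_ACTIONS)]

    @property
    def n_snps(self) -> int:
        return len(self.retained)

    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """(beta_exposure, se_exposure, beta_outcome, se_outcome) arrays."""
        r = self.retained
        return (
            r["beta_exposure"].to_numpy(float),
            r["se_exposure"].to_numpy(float),
            r["beta_outcome"].to_numpy(float),
            r["se_outcome"].to_numpy(float),
        )

    @property
    def rsids(self) -> list[str]:
        return list(self.retained["rsid"])

    def action_counts(self) -> dict[str, int]:
        counts = self.pairs["action"].value_counts().to_dict()
        return {a: int(counts.get(a, 0)) for a in ACTIONS}

    def subset(self, rsids: Iterable[str]) -> "HarmonizedSet":
        keep = set(rsids)
        return HarmonizedSet(
            exposure=self.exposure,
            outcome=self.outcome,
            pairs=self.pairs[self.pairs["rsid"].isin(keep)].reset_index(drop=True),
        )

    @classmethod
    def from_arrays(
        cls,
        beta_exposure: np.ndarray,
        se_exposure: np.ndarray,
        beta_outcome: np.ndarray,
        se_outcome: np.ndarray,
        rsids: Iterable[str] | None = None,
        exposure: str = "exposure",
        outcome: str = "outcome",
    ) -> "HarmonizedSet":
        """Build a pre-aligned set directly from effect arrays (no allele
        bookkeeping); convenient for simulations and tests."""
        beta_exposure = np.asarray(beta_exposure, float)
        j = len(beta_exposure)
        pairs = pd.DataFrame(
            {
                "rsid": list(rsids) if rsids is not None else [f"snp{i}" for i in range(j)],
                "effect_allele": "A",
                "other_allele": "G",
                "beta_exposure": beta_exposure,
                "se_exposure": np.asarray(se_exposure, float),
                "beta_outcome": np.asarray(beta_outcome, float),
                "se_outcome": np.asarray(se_outcome, float),
                "eaf_exposure": np.nan,
                "eaf_outcome": np.nan,
                "action": "kept",
            }
        )
        return cls(exposure=exposure, outcome=outcome, pairs=pairs)


def _harmonize_one(
    exp: pd.Series, out: pd.Series, maf_threshold: float
) -> tuple[str, float, float]:
    """Classify one shared SNP; returns (action, beta_outcome, eaf_outcome)
    expressed on the exposure's effect allele."""
    ea_e, oa_e = exp["effect_allele"], exp["other_allele"]
    ea_o, oa_o = out["effect_allele"], out["other_allele"]
    beta_o, eaf_o = out["beta"], out["eaf"]

    if is_palindromic(ea_e, oa_e):
        # same letters on both strands: orientation must come from EAF
        if {ea_o, oa_o} != {ea_e, oa_e}:
            return "dropped_incompatible", np.nan, np.nan
        eaf_e = exp["eaf"]
        if pd.isna(eaf_e) or pd.isna(eaf_o):
            return "dropped_palindromic", np.nan, np.nan
        maf_e = min(eaf_e, 1 - eaf_e)
        maf_o = min(eaf_o, 1 - eaf_o)
        if maf_e >= maf_threshold or maf_o >= maf_threshold:
            return "dropped_palindromic", np.nan, np.nan
        # Allele letters carry no strand information for palindromic SNPs:
        # the outcome's labelled effect allele is the exposure's effect
        # allele exactly when their frequencies sit on the same side of 0.5.
        same_side = (eaf_e < 0.5) == (eaf_o < 0.5)
        if same_side:
            return "palindromic_aligned", beta_o, eaf_o
        return "palindromic_aligned", -beta_o, 1 - eaf_o

    orient = match_orientation(ea_e, oa_e, ea_o, oa_o)
    if orient is None:
        return "dropped_incompatible", np.nan, np.nan
    if orient == "same":
        return "kept", beta_o, eaf_o
    return "flipped", -beta_o, np.nan if pd.isna(eaf_o) else 1 - eaf_o


def harmonize(
    exposure: AssociationTable,
    outcome: AssociationTable,
    maf_threshold: float = 0.3,
) -> HarmonizedSet:
    """Harmonize two association tables on their shared SNPs.

    Returns a :class:`HarmonizedSet` whose actions partition the rsid
    intersection: ``kept`` / ``flipped`` / ``palindromic_aligned`` rows are
    retained for estimation; ``dropped_palindromic`` and
    ``dropped_incompatible`` rows are kept for audit only.
    """
    exp_df = exposure.data.set_index("rsid", drop=False)
    out_df = outcome.data.set_index("rsid", drop=False)
    shared = [r for r in exposure.data["rsid"] if r in out_df.index]
    if not shared:
        raise ValueError(
            f"no shared SNPs between {exposure.trait!r} and {outcome.trait!r}"
        )
    rows = []
    for rsid in shared:
        exp = exp_df.loc[rsid]
        out = out_df.loc[rsid]
        action, beta_o, eaf_o = _harmonize_one(exp, out, maf_threshold)
        rows.append(
            {
                "rsid": rsid,
                "effect_allele": exp["effect_allele"],
                "other_allele": exp["other_allele"],
                "beta_exposure": exp["beta"],
                "se_exposure": exp["se"],
                "beta_outcome": beta_o,
                "se_outcome": out["se"],
                "eaf_exposure": exp["eaf"],
                "eaf_outcome": eaf_o,
                "action": action,
            }
        )
    pairs = pd.DataFrame(rows, columns=list(PAIR_COLUMNS))
    return HarmonizedSet(exposure=exposure.trait, outcome=outcome.trait, pairs=pairs)


def write_harmonized(hset: HarmonizedSet, path) -> None:
    """Write the harmonized pair table (including the action column) as TSV."""
    hset.pairs.to_csv(path, sep="\t", index=False)
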
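"""Instrument-set construction and filtering.

Covers genome-wide significance selection, greedy LD clumping against a
precomputed r-squared table, named exclusion lists for sensitivity subsets,
removal of SNPs genome-wide associated with the outcome, and the composite
insulin-resistance exposure built by fixed-effect meta-analysis of absolute
standardized effects on fasting insulin (BMI-adjusted), triglycerides and
HDL cholesterol.

Every filter records provenance — (filter name, SNPs removed) — so the full
path from the initial instrument list to any sensitivity subset can be
reconstructed and audited.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._alleles import match_orientation
from .io import AssociationTable

logger = logging.getLogger(__name__)

GENOME_WIDE_P = 5e-8


@dataclass
class InstrumentSet:
    """A named, ordered SNP list with the filters that produced it."""

    name: str
    rsids: list[str]
    provenance: list[tuple[str, list[str]]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(set(self.rsids)) != len(self.rsids):
            raise ValueError(f"duplicate rsids in instrument set {self.name!r}")

    def __len__(self) -> int:
        return len(self.rsids)

    def with_filter(
        self, filter_name: str, removed: Sequence[str], new_name: str | None = None
    ) -> "InstrumentSet":
        kept = [r for r in self.rsids if r not in set(removed)]
        return InstrumentSet(
            name=new_name or self.name,
            rsids=kept,
            provenance=[*self.provenance, (filter_name, list(removed))],
        )

    def original_rsids(self) -> set[str]:
        """Union of the retained SNPs and every removed SNP (audit helper)."""
        out = set(self.rsids)
        for _, removed in self.provenance:
            out |= set(removed)
        return out

    def provenance_json(self) -> str:
        return json.dumps(
            {
                "name": self.name,
                "rsids": self.rsids,
                "provenance": [
                    {"filter": f, "removed": r} for f, r in self.provenance
                ],
            },
            indent=2,
        )

    @classmethod
    def from_file(cls, path: str | Path, name: str | None = None) -> "InstrumentSet":
        """Read a one-rsid-per-line (or first-column TSV) instrument list."""
        path = Path(path)
        rsids = []
        for line in path.read_text().splitlines():
            token = line.split("\t")[0].strip()
            if token and token.lower() != "rsid":
                rsids.append(token)
        return cls(name=name or path.stem, rsids=rsids)


@dataclass
class LDTable:
    """Pairwise linkage-disequilibrium r-squared values plus SNP positions.

    Entries are symmetric; absent pairs are treated as r-squared 0 (distinct
    LD blocks).  Positions are (chromosome label, base-pair) used for the
    clumping distance window.
    """

    r2: dict[tuple[str, str], float] = field(default_factory=dict)
    positions: dict[str, tuple[str, int]] = field(default_factory=dict)

    def set_r2(self, a: str, b: str, value: float) -> None:
        if not 0 <= value <= 1:
            raise ValueError(f"r2 must lie in [0,1], got {value}")
        self.r2[(a, b)] = value
        self.r2[(b, a)] = value

    def get_r2(self, a: str, b: str) -> float:
        if a == b:
            return 1.0
        return self.r2.get((a, b), 0.0)

    @classmethod
    def from_files(
        cls, pairs_path: str | Path, positions_path: str | Path
    ) -> "LDTable":
        """Load from TSVs: ``rsid_a rsid_b r2`` and ``rsid chrom pos``."""
        table = cls()
        pairs = pd.read_csv(pairs_path, sep="\t")
        for _, row in pairs.iterrows():
            table.set_r2(str(row["rsid_a"]), str(row["rsid_b"]), float(row["r2"]))
        pos = pd.read_csv(positions_path, sep="\t")
        for _, row in pos.iterrows():
            table.positions[str(row["rsid"])] = (str(row["chrom"]), int(row["pos"]))
        return table


@dataclass(frozen=True)
class CompositeAssociation:
    """One SNP's meta-analysed composite insulin-resistance effect.

    ``beta_ir`` is the fixed-effect inverse-variance meta-analysis of the
    absolute standardized effects on the three component traits, oriented to
    the fasting-insulin-raising allele; always >= 0 before any downstream
    re-orientation.
    """

    rsid: str
    effect_allele: str
    other_allele: str
    beta_ir: float
    se_ir: float
    component_betas: tuple[float, float, float]  # FI-adjBMI, TG, HDL-C


def select_genomewide(
    table: AssociationTable,
    threshold: float = GENOME_WIDE_P,
    name: str | None = None,
) -> InstrumentSet:
    """Keep SNPs with association p strictly below ``threshold``.

    The boundary is exclusive: p equal to the threshold is removed.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    df = table.data
    keep = df["pvalue"] < threshold
    removed = list(df.loc[~keep, "rsid"])
    kept = list(df.loc[keep, "rsid"])
    if not kept:
        warnings.warn(
            f"no SNP reaches p < {threshold:g} in table {table.trait!r}", stacklevel=2
        )
    return InstrumentSet(
        name=name or f"{table.trait}-gw",
        rsids=kept,
        provenance=[(f"genomewide_p<{threshold:g}", removed)],
    )


def ld_clump(
    instruments: InstrumentSet,
    pvals: Mapping[str, float],
    ld: LDTable,
    r2_max: float = 0.001,
    window_kb: float = 10_000,
) -> InstrumentSet:
    """Greedy LD clumping: retain approximately independent index SNPs.

    Repeatedly takes the smallest-p unclaimed SNP as the index and discards
    every unclaimed SNP on the same chromosome within ``window_kb``
    (centre-to-centre) whose r-squared with the index is at least ``r2_max``.
    Ties on p are broken by rsid so the result does not depend on input
    order.  Pairs with no r-squared entry are treated as independent.
    """
    missing_p = [r for r in instruments.rsids if r not in pvals]
    if missing_p:
        raise ValueError(f"no p-value for SNP(s): {missing_p}")
    missing_pos = [r for r in instruments.rsids if r not in ld.positions]
    if missing_pos:
        raise ValueError(f"no position in LD table for SNP(s): {missing_pos}")

    order = sorted(instruments.rsids, key=lambda r: (pvals[r], r))
    unclaimed = set(instruments.rsids)
    retained: list[str] = []
    removed: list[str] = []
    for index_snp in order:
        if index_snp not in unclaimed:
            continue
        unclaimed.discard(index_snp)
        retained.append(index_snp)
        chrom_i, pos_i = ld.positions[index_snp]
        for other in sorted(unclaimed):
            chrom_o, pos_o = ld.positions[other]
            if chrom_o != chrom_i:
                continue
            if abs(pos_o - pos_i) > window_kb * 1000:
                continue
            if ld.get_r2(index_snp, other) >= r2_max:
                unclaimed.discard(other)
                removed.append(other)
    # preserve the original ordering of retained SNPs
    retained_in_order = [r for r in instruments.rsids if r in set(retained)]
    return InstrumentSet(
        name=instruments.name,
        rsids=retained_in_order,
        provenance=[
            *instruments.provenance,
            (f"ld_clump_r2<{r2_max:g}_window{window_kb:g}kb", sorted(removed)),
        ],
    )


def apply_exclusion_list(
    instruments: InstrumentSet,
    exclusions: Sequence[str],
    list_name: str,
    new_name: str | None = None,
) -> InstrumentSet:
    """Remove a named list of SNPs (sensitivity-subset construction).

    Exclusion SNPs absent from the set raise a warning only, so one shared
    exclusion list can be applied to already-filtered subsets.
    """
    in_set = set(instruments.rsids)
    removed = [r for r in exclusions if r in in_set]
    absent = [r for r in exclusions if r not in in_set]
    if absent:
        warnings.warn(
            f"exclusion list {list_name!r}: {len(absent)} SNP(s) not in set "
            f"{instruments.name!r}: {absent}",
            stacklevel=2,
        )
    return instruments.with_filter(f"exclude:{list_name}", removed, new_name=new_name)


def drop_outcome_associated(
    instruments: InstrumentSet,
    outcome: AssociationTable,
    threshold: float = GENOME_WIDE_P,
) -> InstrumentSet:
    """Remove instrument SNPs genome-wide associated with the outcome.

    An instrument that is itself a genome-wide hit for the outcome likely
    violates the exclusion restriction, so it is removed before estimation.
    SNPs absent from the outcome table are untouched here (missingness is
    handled by extraction).
    """
    df = outcome.data
    hits = set(df.loc[df["pvalue"] < threshold, "rsid"])
    removed = [r for r in instruments.rsids if r in hits]
    for rsid in removed:
        logger.info(
            "instrument %s removed: outcome association p < %g", rsid, threshold
        )
    return instruments.with_filter(
        f"outcome_associated_p<{threshold:g}", removed
    )


def build_composite_exposure(
    fi: AssociationTable,
    tg: AssociationTable,
    hdl: AssociationTable,
    rsids: Sequence[str],
    sd_map: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Meta-analyse three component traits into a composite IR exposure.

    Per SNP: (1) align the TG and HDL-C records to the fasting-insulin
    effect allele, then orient all three to the fasting-insulin-*raising*
    allele; (2) standardize each beta — by default the summary-data
    approximation ``beta* = z / sqrt(n)`` with ``se* = 1 / sqrt(n)`` where
    ``z = beta / se``, or ``beta / SD`` when a per-trait SD is supplied in
    ``sd_map`` (keys ``"fi"``, ``"tg"``, ``"hdl"``); (3) take absolute
    values; (4) combine by fixed-effect inverse-variance meta-analysis:

        w_t = 1 / se_t**2,   beta_IR = sum(w_t |beta*_t|) / sum(w_t),
        se_IR = sum(w_t) ** -0.5

    SNPs missing from any component table are excluded with a logged
    diagnostic rather than failing the whole build.
    """
    out: list[CompositeAssociation] = []
    tables = {"fi": fi, "tg": tg, "hdl": hdl}
    for rsid in rsids:
        try:
            recs = {k: t.lookup(rsid) for k, t in tables.items()}
        except KeyError:
            logger.warning("composite exposure: %s missing from a component table", rsid)
            continue
        ref = recs["fi"]
        betas: dict[str, float] = {}
        ses: dict[str, float] = {}
        incompatible = False
        for key, rec in recs.items():
            orient = match_orientation(
                ref.effect_allele, ref.other_allele, rec.effect_allele, rec.other_allele
            )
            if orient is None:
                logger.warning(
                    "composite exposure: %s alleles irreconcilable across traits", rsid
                )
                incompatible = True
                break
            sign = 1.0 if orient == "same" else -1.0
            beta = sign * rec.beta
            if sd_map and key in sd_map:
                betas[key] = beta / sd_map[key]
                ses[key] = rec.se / sd_map[key]
            else:
                if not np.isfinite(rec.n) or rec.n <= 0:
                    raise ValueError(
                        f"composite exposure: {rsid} ({key}) has no sample size for "
                        "z-based standardization and no SD supplied"
                    )
                z = beta / rec.se
                betas[key] = z / np.sqrt(rec.n)
                ses[key] = 1.0 / np.sqrt(rec.n)
        if incompatible:
            continue
        # orient to the fasting-insulin-raising allele
        if betas["fi"] < 0:
            ea, oa = ref.other_allele, ref.effect_allele
            betas = {k: -b for k, b in betas.items()}
        else:
            ea, oa = ref.effect_allele, ref.other_allele
        absb = np.array([abs(betas[k]) for k in ("fi", "tg", "hdl")])
        w = np.array([1.0 / ses[k] ** 2 for k in ("fi", "tg", "hdl")])
        finite = np.isfinite(w) & (w > 0)
        beta_ir = float(np.sum(w[finite] * absb[finite]) / np.sum(w[finite]))
        se_ir = float(np.sum(w[finite]) ** -0.5)
        out.append(
            CompositeAssociation(
                rsid=rsid,
                effect_allele=ea,
                other_allele=oa,
                beta_ir=beta_ir,
                se_ir=se_ir,
                component_betas=(betas["fi"], betas["tg"], betas["hdl"]),
            )
        )
    return pd.DataFrame([vars(c) for c in out])


def composite_to_table(composite: pd.DataFrame, trait: str = "IR") -> AssociationTable:
    """View a composite-exposure frame as a standard association table."""
    df = pd.DataFrame(
        {
            "rsid": composite["rsid"],
            "effect_allele": composite["effect_allele"],
            "other_allele": composite["other_allele"],
            "beta": composite["beta_ir"],
            "se": composite["se_ir"],
        }
    )
    return AssociationTable(df, trait=trait, unit="per 1-SD composite IR")
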
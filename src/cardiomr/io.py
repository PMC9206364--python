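"""Reading, validating and writing GWAS summary-statistics tables.

The canonical on-disk dialect is tab-separated UTF-8 with one header line and
the column order ``rsid chrom pos effect_allele other_allele eaf beta se
pvalue n``.  Only ``rsid``, the two alleles, ``beta`` and ``se`` are required;
a ``column_map`` adapts consortium export headers (MAGIC, GLGC, UK Biobank
dialects all differ).  Gzip-compressed input is accepted by extension.
"""

from __future__ import annotations

import logging
import sys
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Canonical column order for summary-statistics tables.
CANONICAL_COLUMNS = (
    "rsid",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pvalue",
    "n",
)

REQUIRED_COLUMNS = ("rsid", "effect_allele", "other_allele", "beta", "se")

VALID_ALLELES = frozenset("ACGT")

#: Smallest positive double; p-values printed as 0 are clamped to this.
TINY_P = sys.float_info.min


class SummaryStatsFormatError(ValueError):
    """A required column is missing or the file cannot be parsed."""


class SummaryStatsValidationError(ValueError):
    """Table-level invariant violated (e.g. duplicate SNP identifiers)."""


@dataclass(frozen=True)
class SummaryAssociation:
    """One SNP-trait association record from a GWAS summary file.

    ``beta`` is the additive per-effect-allele effect in trait units,
    ``se`` its standard error, ``eaf`` the effect-allele frequency.
    """

    rsid: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pvalue: float = np.nan
    eaf: float = np.nan
    n: float = np.nan
    chrom: str | None = None
    pos: int | None = None


@dataclass
class AssociationTable:
    """A validated per-SNP association table for one trait.

    Wraps a :class:`pandas.DataFrame` with the canonical columns; ``rsid``
    values are unique within a table.
    """

    data: pd.DataFrame
    trait: str = ""
    unit: str = ""

    def __post_init__(self) -> None:
        df = self.data.copy()
        for col in CANONICAL_COLUMNS:
            if col not in df.columns:
                df[col] = np.nan
        self.data = df.loc[:, list(CANONICAL_COLUMNS)].reset_index(drop=True)
        dup = self.data["rsid"][self.data["rsid"].duplicated()]
        if len(dup):
            raise SummaryStatsValidationError(
                f"duplicate rsids in table {self.trait!r}: {sorted(set(dup))}"
            )

    def __len__(self) -> int:
        return len(self.data)

    @property
    def rsids(self) -> list[str]:
        return list(self.data["rsid"])

    def subset(self, rsids: Sequence[str]) -> "AssociationTable":
        keep = self.data[self.data["rsid"].isin(set(rsids))]
        return AssociationTable(keep.copy(), trait=self.trait, unit=self.unit)

    def lookup(self, rsid: str) -> SummaryAssociation:
        row = self.data[self.data["rsid"] == rsid]
        if row.empty:
            raise KeyError(rsid)
        r = row.iloc[0]
        return SummaryAssociation(
            rsid=r["rsid"],
            effect_allele=r["effect_allele"],
            other_allele=r["other_allele"],
            beta=float(r["beta"]),
            se=float(r["se"]),
            pvalue=float(r["pvalue"]),
            eaf=float(r["eaf"]),
            n=float(r["n"]),
            chrom=None if pd.isna(r["chrom"]) else str(r["chrom"]),
            pos=None if pd.isna(r["pos"]) else int(r["pos"]),
        )

    @classmethod
    def from_records(
        cls,
        records: Sequence[SummaryAssociation],
        trait: str = "",
        unit: str = "",
    ) -> "AssociationTable":
        df = pd.DataFrame([vars(r) for r in records], columns=list(CANONICAL_COLUMNS))
        return cls(df, trait=trait, unit=unit)


def _validate_rows(df: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Split a raw frame into valid rows and per-row diagnostics."""
    diagnostics: list[str] = []
    df = df.copy()
    for col in CANONICAL_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    for col in ("eaf", "beta", "se", "pvalue", "n"):
        df[col] = pd.to_numeric(df[col], errors="coerce").astype(float)
    df["effect_allele"] = df["effect_allele"].astype(str).str.upper()
    df["other_allele"] = df["other_allele"].astype(str).str.upper()

    # Consortium files occasionally print p = 0; clamp rather than reject.
    if (df["pvalue"] == 0).any():
        nz = int((df["pvalue"] == 0).sum())
        warnings.warn(
            f"{nz} p-value(s) of exactly 0 clamped to {TINY_P:g}", stacklevel=3
        )
        df.loc[df["pvalue"] == 0, "pvalue"] = TINY_P

    ok = pd.Series(True, index=df.index)

    def reject(mask: pd.Series, reason: str) -> None:
        nonlocal ok
        bad = mask & ok
        for rsid in df.loc[bad, "rsid"]:
            diagnostics.append(f"{rsid}: {reason}")
        ok &= ~mask

    reject(~df["effect_allele"].isin(VALID_ALLELES), "effect allele not in A/C/G/T")
    reject(~df["other_allele"].isin(VALID_ALLELES), "other allele not in A/C/G/T")
    reject(df["effect_allele"] == df["other_allele"], "identical alleles")
    reject(~(df["se"] > 0), "se must be > 0")
    reject(df["beta"].isna(), "missing beta")
    eaf_bad = df["eaf"].notna() & ~((df["eaf"] > 0) & (df["eaf"] < 1))
    reject(eaf_bad, "eaf outside (0, 1)")
    p_bad = df["pvalue"].notna() & ~((df["pvalue"] > 0) & (df["pvalue"] <= 1))
    reject(p_bad, "p-value outside (0, 1]")

    for msg in diagnostics:
        logger.warning("rejected row %s", msg)
    return df[ok], diagnostics


def read_summary_table(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    trait: str = "",
    unit: str = "",
) -> AssociationTable:
    """Read a tab-delimited summary-statistics file into an AssociationTable.

    Parameters
    ----------
    path
        TSV file (``.gz`` accepted).  Must contain the required columns
        (``rsid``, alleles, ``beta``, ``se``) after renaming.
    column_map
        Mapping from the file's header names to canonical names, e.g.
        ``{"SNP": "rsid", "A1": "effect_allele"}``.

    Rows violating per-record invariants (non-ACGT alleles, ``se <= 0``,
    frequencies outside (0,1)) are dropped with a logged diagnostic rather
    than failing the whole read.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(
        path, sep="\t", dtype={"rsid": str}, compression="infer",
        float_precision="round_trip",
    )
    if column_map:
        df = df.rename(columns=dict(column_map))
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SummaryStatsFormatError(
            f"{path}: missing required column(s) {missing}; found {list(df.columns)}"
        )
    df["rsid"] = df["rsid"].astype(str)
    valid, _ = _validate_rows(df)
    return AssociationTable(valid, trait=trait or path.stem, unit=unit)


def write_summary_table(table: AssociationTable, path: str | Path) -> Path:
    """Write a table in the canonical dialect; lossless under re-read.

    Floats are serialised with ``repr`` round-trip precision so that
    ``read_summary_table(write_summary_table(t))`` reproduces every field.
    """
    path = Path(path)
    out = table.data.copy()
    # 17 significant digits guarantee bit-exact float round-trips
    out.to_csv(
        path, sep="\t", index=False, na_rep="",
        float_format=lambda v: format(v, ".17g"),
    )
    return path


def extract_for_instruments(
    instrument_rsids: Sequence[str],
    table: AssociationTable,
) -> tuple[AssociationTable, list[str]]:
    """Pull instrument SNPs out of a summary table.

    Returns the sub-table of SNPs found and the list of requested SNPs absent
    from the table.  Missingness is an expected outcome in two-sample MR (an
    instrument SNP may simply not be present in the outcome GWAS), so it is
    reported, not raised.
    """
    if not list(instrument_rsids):
        raise ValueError("instrument list must be non-empty")
    present = set(table.data["rsid"])
    missing = [r for r in instrument_rsids if r not in present]
    for rsid in missing:
        logger.info("instrument SNP %s not found in table %r", rsid, table.trait)
    found = table.subset([r for r in instrument_rsids if r in present])
    return found, missing
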
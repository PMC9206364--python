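"""Study orchestration: the exposure-by-outcome grid, sensitivity families,
multivariable analyses, significance tiering and report emission.

A YAML config names the exposure and outcome summary-statistics files (and
optional instrument/exclusion lists); ``run_grid`` executes
harmonize -> outcome-association filter -> estimators -> diagnostics for
every cell, tiers p-values against the Bonferroni threshold (default
0.05/20), and collects everything into a ReportBundle whose tables render
deterministically.  Binary outcomes (e.g. heart failure on the log-odds
scale) are reported both as betas and exponentiated odds ratios.

All randomness funnels through one run-level seed expanded into per-cell
child seeds recorded in the manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .estimators import (
    classify_significance,
    cochran_q,
    ivw,
    leave_one_out,
    mr_egger,
    mr_presso,
    weighted_median,
)
from .harmonize import HarmonizedSet, harmonize
from .instruments import (
    GENOME_WIDE_P,
    InstrumentSet,
    apply_exclusion_list,
    drop_outcome_associated,
    select_genomewide,
)
from .io import AssociationTable, extract_for_instruments, read_summary_table

logger = logging.getLogger(__name__)

DEFAULT_METHODS = ("ivw_random", "weighted_median", "egger", "presso")


@dataclass
class ExposureSpec:
    name: str
    table: AssociationTable
    instruments: InstrumentSet | None = None  # None: genome-wide select


@dataclass
class OutcomeSpec:
    name: str
    table: AssociationTable
    binary: bool = False  # betas are log-odds; report odds ratios too


@dataclass
class AnalysisConfig:
    """Validated configuration of one full analysis run."""

    exposures: list[ExposureSpec]
    outcomes: list[OutcomeSpec]
    methods: tuple[str, ...] = DEFAULT_METHODS
    n_boot: int = 1000
    n_sim: int = 1000
    seed: int = 0
    n_tests: int = 20
    alpha: float = 0.05
    maf_threshold: float = 0.3
    outcome_p_threshold: float = GENOME_WIDE_P

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        """Load a config whose tables are file paths (see examples/)."""
        raw = yaml.safe_load(Path(path).read_text())
        base = Path(path).parent

        def resolve(p: str) -> Path:
            q = Path(p)
            return q if q.is_absolute() else base / q

        exposures = []
        for spec in raw["exposures"]:
            table = read_summary_table(
                resolve(spec["table"]),
                column_map=spec.get("column_map"),
                trait=spec["name"],
                unit=spec.get("unit", ""),
            )
            instr = None
            if "instruments" in spec:
                instr = InstrumentSet.from_file(resolve(spec["instruments"]))
            exposures.append(ExposureSpec(spec["name"], table, instr))
        outcomes = []
        for spec in raw["outcomes"]:
            table = read_summary_table(
                resolve(spec["table"]),
                column_map=spec.get("column_map"),
                trait=spec["name"],
                unit=spec.get("unit", ""),
            )
            outcomes.append(OutcomeSpec(spec["name"], table, spec.get("binary", False)))
        opts = {
            k: raw[k]
            for k in (
                "n_boot", "n_sim", "seed", "n_tests", "alpha",
                "maf_threshold", "outcome_p_threshold",
            )
            if k in raw
        }
        if "methods" in raw:
            opts["methods"] = tuple(raw["methods"])
        return cls(exposures=exposures, outcomes=outcomes, **opts)


@dataclass
class ReportBundle:
    """All result tables of one run plus a reproducibility manifest."""

    grid: pd.DataFrame
    diagnostics: pd.DataFrame
    leave_one_out: pd.DataFrame
    sensitivity: pd.DataFrame | None = None
    mvmr: pd.DataFrame | None = None
    manifest: dict = field(default_factory=dict)
    failures: list = field(default_factory=list)


def _digest(table: AssociationTable) -> str:
    h = hashlib.sha256()
    h.update(table.data.to_csv(index=False).encode())
    return h.hexdigest()[:16]


def _prepare_cell(
    exposure: ExposureSpec,
    outcome: OutcomeSpec,
    config: AnalysisConfig,
) -> tuple[HarmonizedSet, list[str]]:
    """Instrument extraction, outcome filter and harmonization for a cell."""
    if exposure.instruments is not None:
        instr = exposure.instruments
    else:
        instr = select_genomewide(exposure.table, name=f"{exposure.name}-gw")
    instr = drop_outcome_associated(
        instr, outcome.table, threshold=config.outcome_p_threshold
    )
    exp_sub, missing = extract_for_instruments(instr.rsids, exposure.table)
    found_out, missing_out = extract_for_instruments(instr.rsids, outcome.table)
    hset = harmonize(exp_sub, found_out, maf_threshold=config.maf_threshold)
    return hset, sorted(set(missing) | set(missing_out))


def _run_methods(
    hset: HarmonizedSet,
    methods: Sequence[str],
    config: AnalysisConfig,
    rng: np.random.Generator,
) -> tuple[list[dict], dict]:
    rows: list[dict] = []
    diag: dict = {}
    res, het = ivw(hset, model="random")
    if "ivw_fixed" in methods:
        fixed, _ = ivw(hset, model="fixed")
        rows.append(fixed.to_dict())
    if "ivw_random" in methods:
        rows.append(res.to_dict())
    diag.update({"Q": het.Q, "Q_df": het.df, "Q_pvalue": het.pvalue})
    if hset.n_snps >= 2:
        mod = cochran_q(hset, weights="modified")
        diag.update({"Q_modified": mod.Q, "Q_modified_pvalue": mod.pvalue})
    if "weighted_median" in methods and hset.n_snps >= 3:
        rows.append(
            weighted_median(
                hset, n_boot=config.n_boot, seed=int(rng.integers(2**31))
            ).to_dict()
        )
    if "egger" in methods and hset.n_snps >= 3:
        slope, icpt, ehet = mr_egger(hset)
        rows.append(slope.to_dict())
        rows.append(icpt.to_dict())
        diag.update(
            {
                "egger_intercept": ehet.egger_intercept,
                "egger_intercept_se": ehet.intercept_se,
                "egger_intercept_pvalue": ehet.intercept_pvalue,
            }
        )
    if "presso" in methods and hset.n_snps >= 4:
        presso = mr_presso(
            hset, n_sim=config.n_sim, seed=int(rng.integers(2**31))
        )
        rows.append(
            presso.estimate_raw.to_dict() | {"method": "presso_raw"}
        )
        rows.append(
            presso.estimate_outlier_corrected.to_dict()
            | {"method": "presso_corrected"}
        )
        diag.update(
            {
                "presso_global_pvalue": presso.global_pvalue,
                "presso_n_outliers": len(presso.outliers),
                "presso_outliers": ",".join(presso.outliers),
                "presso_distortion_pvalue": presso.distortion_pvalue,
            }
        )
    return rows, diag


def run_grid(config: AnalysisConfig, loo: bool = True) -> ReportBundle:
    """Run every exposure-by-outcome cell and assemble the report bundle.

    Cell failures are recorded and flagged; the rest of the grid continues.
    Primary (random-effects IVW) rows are tiered against the Bonferroni
    threshold ``alpha / n_tests``.
    """
    root = np.random.SeedSequence(config.seed)
    cells = [(e, o) for e in config.exposures for o in config.outcomes]
    seeds = root.spawn(len(cells))
    grid_rows: list[dict] = []
    diag_rows: list[dict] = []
    loo_frames: list[pd.DataFrame] = []
    failures: list[dict] = []
    for (exposure, outcome), ss in zip(cells, seeds):
        rng = np.random.default_rng(ss)
        label = {"exposure": exposure.name, "outcome": outcome.name}
        try:
            hset, missing = _prepare_cell(exposure, outcome, config)
            rows, diag = _run_methods(hset, config.methods, config, rng)
            for row in rows:
                row = label | row
                if outcome.binary:
                    row["odds_ratio"] = float(np.exp(row["estimate"]))
                    row["or_ci_low"] = float(np.exp(row["ci_low"]))
                    row["or_ci_high"] = float(np.exp(row["ci_high"]))
                grid_rows.append(row)
            diag_rows.append(label | diag | {"missing_snps": ",".join(missing)})
            if loo and hset.n_snps >= 3:
                frame = leave_one_out(hset)
                frame.insert(0, "outcome", outcome.name)
                frame.insert(0, "exposure", exposure.name)
                loo_frames.append(frame)
        except Exception as exc:  # cell-level isolation
            logger.error("cell %s failed: %s", label, exc)
            failures.append(label | {"error": str(exc)})
    grid = pd.DataFrame(grid_rows)
    if len(grid):
        grid = classify_significance(grid, n_tests=config.n_tests, alpha=config.alpha)
        grid = grid.sort_values(["exposure", "outcome", "method"]).reset_index(drop=True)
    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "n_tests": config.n_tests,
        "alpha": config.alpha,
        "bonferroni_threshold": config.alpha / config.n_tests,
        "methods": list(config.methods),
        "n_boot": config.n_boot,
        "n_sim": config.n_sim,
        "exposures": {e.name: _digest(e.table) for e in config.exposures},
        "outcomes": {o.name: _digest(o.table) for o in config.outcomes},
        "cell_seed_entropy": int(root.entropy),
        "failures": len(failures),
    }
    return ReportBundle(
        grid=grid,
        diagnostics=pd.DataFrame(diag_rows),
        leave_one_out=(
            pd.concat(loo_frames, ignore_index=True) if loo_frames else pd.DataFrame()
        ),
        manifest=manifest,
        failures=failures,
    )


def run_sensitivity_family(
    exposure: ExposureSpec,
    outcomes: Sequence[OutcomeSpec],
    family: Mapping[str, InstrumentSet],
    config: AnalysisConfig,
) -> pd.DataFrame:
    """Estimate every outcome under each named instrument subset.

    ``family`` maps subset names (e.g. "52", "51", ..., "20") to instrument
    sets; rows are keyed by subset name so the family reads like a
    sensitivity figure's underlying table.
    """
    root = np.random.SeedSequence(config.seed)
    rows: list[dict] = []
    jobs = [(name, o) for name in family for o in outcomes]
    for (name, outcome), ss in zip(jobs, root.spawn(len(jobs))):
        rng = np.random.default_rng(ss)
        sub_exp = ExposureSpec(exposure.name, exposure.table, family[name])
        hset, _ = _prepare_cell(sub_exp, outcome, config)
        method_rows, _ = _run_methods(hset, config.methods, config, rng)
        for row in method_rows:
            rows.append(
                {"subset": name, "exposure": exposure.name, "outcome": outcome.name}
                | row
            )
    return pd.DataFrame(rows)


def build_instrument_family(
    base: InstrumentSet,
    exclusions: Mapping[str, Sequence[str]],
    ld=None,
    pvals: Mapping[str, float] | None = None,
) -> dict[str, InstrumentSet]:
    """Derive the named sensitivity subsets from one base instrument.

    Each exclusion list is applied to the base independently (not chained);
    when an LD table and p-values are supplied a clumped subset is added.
    Subset names are the resulting SNP counts, mirroring how sensitivity
    families are usually labelled.
    """
    from .instruments import ld_clump

    family = {str(len(base)): base}
    for name, excl in exclusions.items():
        sub = apply_exclusion_list(base, list(excl), name)
        family[str(len(sub))] = sub
    if ld is not None and pvals is not None:
        clumped = ld_clump(base, pvals, ld)
        family[str(len(clumped))] = clumped
    return family


def render_report(bundle: ReportBundle, outdir: str | Path) -> list[Path]:
    """Write the bundle as TSV tables plus a JSON manifest, stably ordered.

    Re-running on identical inputs and seeds yields byte-identical files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    tables = {
        "grid_results.tsv": bundle.grid,
        "diagnostics.tsv": bundle.diagnostics,
        "leave_one_out.tsv": bundle.leave_one_out,
        "sensitivity.tsv": bundle.sensitivity,
        "mvmr.tsv": bundle.mvmr,
    }
    for name, table in tables.items():
        if table is None or not len(table):
            continue
        path = outdir / name
        table.to_csv(path, sep="\t", index=False)
        written.append(path)
    manifest_path = outdir / "manifest.json"
    manifest = dict(bundle.manifest)
    if bundle.failures:
        manifest["failed_cells"] = bundle.failures
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    written.append(manifest_path)
    return written
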
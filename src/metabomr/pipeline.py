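"""End-to-end orchestration: filter -> instruments -> UVMR screen -> MVMR ->
sensitivity, with tidy TSV reports.

The analysis order is fixed: the trait panel is reduced by the three
exclusion stages; independent genome-wide-significant instruments are
selected per trait (optionally from a *different* GWAS than the one effects
are extracted from, the two-source design that guards against winner's
curse); univariable MR estimates the total effect of each trait; traits with
UVMR p below the screening threshold (default 0.05) become MVMR candidates;
multivariable MR then estimates their direct effects jointly, with
conditional F-statistics and the Q-statistic; finally the pleiotropy-robust
estimators run on every candidate with enough instruments.

Everything is deterministic given the config seed; re-running a config
produces byte-identical output files.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import gwas_io, harmonise, mvmr, sensitivity, trait_filter, uvmr
from .gwas_io import GwasSummaryTable, TraitInfo
from .harmonise import HarmonisedSet, LdMatrix
from .trait_filter import FilterReport, TraitCorrelationMatrix
from .uvmr import MrResult

__all__ = ["PipelineConfig", "PipelineReport", "PipelineStageError", "screen_uvmr", "run_pipeline", "run_analysis"]

logger = logging.getLogger("metabomr.pipeline")

_FLOAT_FMT = "%.12g"


class PipelineStageError(RuntimeError):
    """An analysis stage failed; partial reports were written."""

    def __init__(self, stage: str, original: Exception):
        super().__init__(f"stage '{stage}' failed: {original}")
        self.stage = stage
        self.original = original


@dataclass
class PipelineConfig:
    """Paths, thresholds and reproducibility settings for one full run."""

    trait_metadata: str
    exposures: dict[str, str]  # trait_id -> selection-GWAS summary table
    outcome: str
    ld: str
    out_dir: str
    exposure_effects: dict[str, str] | None = None  # effect-extraction source
    rho: str | None = None  # phenotypic correlation matrix TSV
    p_instrument: float = 5e-8
    r2_clump: float = 0.01
    maf_palindrome: float = 0.42
    p_screen: float = 0.05
    rg2_prune: float = 0.985
    seed: int = 0
    boot_reps: int = 1000

    def __post_init__(self) -> None:
        if not (0 < self.p_instrument < 1 and 0 < self.p_screen < 1):
            raise ValueError("p thresholds must lie in (0, 1)")
        if not (0 < self.r2_clump <= 1 and 0 < self.rg2_prune <= 1):
            raise ValueError("r2 thresholds must lie in (0, 1]")
        if not (0 <= self.maf_palindrome <= 0.5):
            raise ValueError("maf_palindrome must lie in [0, 0.5]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)


@dataclass
class PipelineReport:
    """All stage outputs of one pipeline run."""

    filter_report: FilterReport
    rg_matrix: TraitCorrelationMatrix | None
    instrument_sets: dict[str, HarmonisedSet]
    uvmr_results: list[MrResult]
    loo_results: dict[str, list[tuple[str, MrResult]]]
    candidates: list[str]
    mvmr_result: mvmr.MvmrResult | None
    sensitivity_results: list[MrResult]
    egger_intercepts: dict[str, tuple[float, float, float]]
    notes: list[str] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)


def screen_uvmr(results: Sequence[MrResult], p_screen: float = 0.05) -> list[str]:
    """Traits with UVMR evidence of effect (p < ``p_screen``), input order."""
    return [
        r.exposure_id
        for r in results
        if not r.is_missing and np.isfinite(r.pvalue) and r.pvalue < p_screen
    ]


def run_analysis(
    traits: Sequence[TraitInfo],
    exposure_tables: Mapping[str, GwasSummaryTable],
    outcome: GwasSummaryTable,
    ld: LdMatrix,
    rho: np.ndarray | None = None,
    rho_order: Sequence[str] | None = None,
    config: PipelineConfig | None = None,
    effect_tables: Mapping[str, GwasSummaryTable] | None = None,
    run_sensitivity: bool = True,
) -> PipelineReport:
    """In-memory pipeline core (the file-based :func:`run_pipeline` wraps it).

    ``exposure_tables`` drive instrument selection; ``effect_tables`` (default
    the same tables) supply the SNP-exposure effects used in estimation.
    ``rho`` is the phenotypic correlation matrix over the traits named in
    ``rho_order`` (default: the metadata trait order).
    """
    cfg = config or PipelineConfig(
        trait_metadata="", exposures={}, outcome="", ld="", out_dir=""
    )
    effect_tables = dict(effect_tables or exposure_tables)
    if rho is not None and rho_order is None:
        rho_order = [t.trait_id for t in traits]
    notes: list[str] = []

    # --- stage 1 + 2: metadata-driven exclusions -------------------------
    stage1 = trait_filter.filter_ratios_composites(traits)
    traits_by_id = {t.trait_id: t for t in traits}
    stage2 = trait_filter.select_lipoprotein_subset([traits_by_id[t] for t in stage1.kept])
    report12 = trait_filter.merge_reports(stage1, stage2)

    available = [t for t in report12.kept if t in exposure_tables]
    for t in report12.kept:
        if t not in exposure_tables:
            notes.append(f"trait '{t}' has no exposure table; skipped")

    # --- per-trait instrument selection (selection source) ---------------
    clumped: dict[str, GwasSummaryTable] = {}
    for tid in available:
        clumped[tid] = harmonise.clump(
            exposure_tables[tid], ld, p_threshold=cfg.p_instrument, r2_threshold=cfg.r2_clump
        )
    union = sorted({s for tab in clumped.values() for s in tab.snp_ids})

    # --- stage 3: genetic-correlation pruning ----------------------------
    rg_matrix = None
    if len(available) >= 2 and union:
        rg_matrix = trait_filter.genetic_correlation_matrix(
            [effect_tables[t] for t in available], union
        )
        stage3 = trait_filter.prune_genetic_correlation(
            rg_matrix, r2_limit=cfg.rg2_prune, priority=available
        )
    else:
        stage3 = FilterReport(kept=list(available), excluded=[])
        notes.append("genetic-correlation pruning skipped (fewer than 2 traits or no instruments)")
    filter_report = trait_filter.merge_reports(report12, stage3)
    final_traits = stage3.kept

    # --- UVMR ------------------------------------------------------------
    instrument_sets: dict[str, HarmonisedSet] = {}
    uvmr_results: list[MrResult] = []
    loo_results: dict[str, list[tuple[str, MrResult]]] = {}
    for tid in final_traits:
        effects = effect_tables[tid].subset(clumped[tid].snp_ids)
        if len(effects) == 0 or not any(s in outcome for s in effects.snp_ids):
            hset = HarmonisedSet(exposure_id=tid, outcome_id=outcome.trait_id, records=[])
        else:
            hset = harmonise.harmonise_pair(effects, outcome, maf_palindrome_limit=cfg.maf_palindrome)
        instrument_sets[tid] = hset
        res = uvmr.run_uvmr(hset)
        uvmr_results.append(res)
        if hset.n_snps >= 3:
            loo_results[tid] = uvmr.leave_one_out(hset)

    # --- screen and MVMR ---------------------------------------------------
    candidates = screen_uvmr(uvmr_results, p_screen=cfg.p_screen)
    mvmr_result = None
    if len(candidates) == 0:
        notes.append("no trait passed the UVMR screen; MVMR not run")
    elif len(candidates) == 1:
        notes.append("only one candidate trait; MVMR needs >= 2, not run")
    else:
        dataset = mvmr.assemble_mvmr(
            [instrument_sets[t] for t in candidates],
            effect_tables,
            outcome,
            ld,
            rho=_subset_rho(rho, rho_order or [], candidates),
            r2_threshold=cfg.r2_clump,
            maf_palindrome_limit=cfg.maf_palindrome,
        )
        mvmr_result = mvmr.mvmr_ivw(dataset)

    # --- sensitivity suite -------------------------------------------------
    sens_results: list[MrResult] = []
    egger_intercepts: dict[str, tuple[float, float, float]] = {}
    if run_sensitivity:
        seeds = np.random.SeedSequence(cfg.seed).spawn(2 * max(len(candidates), 1))
        for i, tid in enumerate(candidates):
            hset = instrument_sets[tid]
            if hset.n_snps < 3:
                notes.append(f"candidate '{tid}' has K={hset.n_snps} < 3; sensitivity skipped")
                continue
            egg = sensitivity.mr_egger(hset)
            sens_results.append(egg.slope)
            egger_intercepts[tid] = (egg.intercept, egg.intercept_se, egg.intercept_pvalue)
            med_seed = int(seeds[2 * i].generate_state(1)[0] % (2**31))
            mode_seed = int(seeds[2 * i + 1].generate_state(1)[0] % (2**31))
            sens_results.append(
                sensitivity.weighted_median(hset, boot_reps=cfg.boot_reps, seed=med_seed)
            )
            sens_results.append(
                sensitivity.weighted_mode(hset, boot_reps=cfg.boot_reps, seed=mode_seed)
            )

    return PipelineReport(
        filter_report=filter_report,
        rg_matrix=rg_matrix,
        instrument_sets=instrument_sets,
        uvmr_results=uvmr_results,
        loo_results=loo_results,
        candidates=candidates,
        mvmr_result=mvmr_result,
        sensitivity_results=sens_results,
        egger_intercepts=egger_intercepts,
        notes=notes,
    )


def _subset_rho(rho: np.ndarray | None, trait_order: Sequence[str], subset: Sequence[str]):
    if rho is None:
        return None
    if any(t not in trait_order for t in subset):
        logger.warning("phenotypic correlation matrix does not cover all candidates; ignored")
        return None
    idx = [list(trait_order).index(t) for t in subset]
    return np.asarray(rho)[np.ix_(idx, idx)]


def run_pipeline(config: PipelineConfig) -> PipelineReport:
    """Load inputs, run the full analysis, and write all report tables.

    Written to ``config.out_dir``: filter_report.tsv, uvmr_results.tsv,
    loo_results.tsv, candidates.tsv, mvmr_results.tsv,
    sensitivity_results.tsv and provenance.json.  A stage failure still
    writes everything computed so far, then raises
    :class:`PipelineStageError` with the stage name.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stage = "load_inputs"
    report: PipelineReport | None = None
    try:
        t0 = time.perf_counter()
        traits = gwas_io.read_trait_metadata(config.trait_metadata)
        exposure_tables = {
            tid: gwas_io.read_summary_table(path, trait_id=tid)
            for tid, path in config.exposures.items()
        }
        effect_tables = None
        if config.exposure_effects:
            effect_tables = {
                tid: gwas_io.read_summary_table(path, trait_id=tid)
                for tid, path in config.exposure_effects.items()
            }
        outcome = gwas_io.read_summary_table(config.outcome, trait_id=Path(config.outcome).stem)
        ld = LdMatrix.read_tsv(config.ld)
        rho = None
        rho_order: list[str] | None = None
        if config.rho:
            m = TraitCorrelationMatrix.read_tsv(config.rho)
            rho, rho_order = m.rg, m.trait_ids
        logger.info("inputs loaded in %.2fs", time.perf_counter() - t0)

        stage = "analysis"
        t0 = time.perf_counter()
        report = run_analysis(
            traits,
            exposure_tables,
            outcome,
            ld,
            rho=rho,
            rho_order=rho_order,
            config=config,
            effect_tables=effect_tables,
        )
        logger.info("analysis finished in %.2fs", time.perf_counter() - t0)
    except Exception as exc:
        if report is None:
            report = PipelineReport(
                filter_report=FilterReport(kept=[], excluded=[]),
                rg_matrix=None,
                instrument_sets={},
                uvmr_results=[],
                loo_results={},
                candidates=[],
                mvmr_result=None,
                sensitivity_results=[],
                egger_intercepts={},
                notes=[f"failed at stage '{stage}': {exc}"],
            )
        report.provenance = _provenance(config, failed_stage=stage, error=str(exc))
        _write_reports(report, out_dir)
        raise PipelineStageError(stage, exc) from exc

    report.provenance = _provenance(config)
    _write_reports(report, out_dir)
    return report


def _provenance(config: PipelineConfig, failed_stage: str | None = None, error: str | None = None) -> dict:
    import scipy

    from . import __version__

    prov = {
        "config": dataclasses.asdict(config),
        "seed": config.seed,
        "versions": {
            "metabomr": __version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
        },
    }
    if failed_stage:
        prov["failed_stage"] = failed_stage
        prov["error"] = error
    return prov


def _write_reports(report: PipelineReport, out_dir: Path) -> None:
    report.filter_report.to_frame().to_csv(
        out_dir / "filter_report.tsv", sep="\t", index=False, float_format=_FLOAT_FMT
    )
    pd.DataFrame([r.row() for r in report.uvmr_results]).to_csv(
        out_dir / "uvmr_results.tsv", sep="\t", index=False, float_format=_FLOAT_FMT
    )
    loo_rows = [
        {"exposure_id": tid, "omitted_snp": snp, **{k: v for k, v in res.row().items() if k != "exposure_id"}}
        for tid, pairs in report.loo_results.items()
        for snp, res in pairs
    ]
    pd.DataFrame(loo_rows).to_csv(
        out_dir / "loo_results.tsv", sep="\t", index=False, float_format=_FLOAT_FMT
    )
    pd.DataFrame({"trait_id": report.candidates}).to_csv(
        out_dir / "candidates.tsv", sep="\t", index=False
    )
    mv = report.mvmr_result.to_frame() if report.mvmr_result is not None else pd.DataFrame()
    mv.to_csv(out_dir / "mvmr_results.tsv", sep="\t", index=False, float_format=_FLOAT_FMT)
    sens_rows = [r.row() for r in report.sensitivity_results]
    for tid, (est, se, p) in report.egger_intercepts.items():
        sens_rows.append(
            {
                "exposure_id": tid,
                "outcome_id": "",
                "method": "mr_egger_intercept",
                "estimate": est,
                "se": se,
                "ci_low": est - uvmr.Z_95 * se,
                "ci_high": est + uvmr.Z_95 * se,
                "pvalue": p,
                "n_snps": np.nan,
                "reason": "",
            }
        )
    pd.DataFrame(sens_rows).to_csv(
        out_dir / "sensitivity_results.tsv", sep="\t", index=False, float_format=_FLOAT_FMT
    )
    with open(out_dir / "provenance.json", "w") as fh:
        json.dump(report.provenance, fh, indent=2, sort_keys=True)
        fh.write("\n")
    if report.notes:
        with open(out_dir / "notes.txt", "w") as fh:
            fh.write("\n".join(report.notes) + "\n")
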
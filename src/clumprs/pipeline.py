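"""End-to-end pipeline driver: QC, clumping, harmonization, model building,
application and centile tables, with a run manifest.

The driver accepts either in-memory objects (library use) or a YAML config
of paths (CLI use).  A single seed governs the only stochastic stage (the
simulator); every analysis stage is deterministic, so rerunning a config
reproduces the manifest content bit for bit (timestamps aside).
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import absolutes as abso
from .clumping import ClumpParams, clump, tag_snps
from .formats_io import (
    GenotypeCohort,
    SummaryStats,
    read_plink_cohort,
    read_summary_stats,
    write_clump_table,
    write_prs_table,
    write_score_file,
)
from .harmonize import BetaQCParams, ClumpPanel, beta_qc, build_panel, common_clumps
from .qc import QCThresholds, apply_snp_qc
from .selection import (
    CommonModel,
    PDTrace,
    ThresholdGrid,
    apply_model,
    commonality,
    pd_first_pass,
    pd_second_pass,
    threshold_models,
)

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    base_stats: str | Path | None = None
    ld_reference: str | Path | None = None
    development_cohorts: list[str] = field(default_factory=list)
    validation_cohorts: list[str] = field(default_factory=list)
    clump_params: ClumpParams = field(default_factory=ClumpParams)
    qc_thresholds: QCThresholds = field(default_factory=QCThresholds)
    beta_qc_params: BetaQCParams = field(default_factory=BetaQCParams)
    threshold_grid: ThresholdGrid = field(default_factory=ThresholdGrid)
    commonality_k: tuple[int, ...] = (2, 3)
    scoring_mode: str = "sum"
    output_dir: str | Path = "clumprs_out"
    run_threshold_models: bool = True
    seed: int = 0


def run_pipeline(
    config: PipelineConfig,
    stats: SummaryStats | None = None,
    reference: GenotypeCohort | None = None,
    dev_cohorts: list[GenotypeCohort] | None = None,
    val_cohorts: list[GenotypeCohort] | None = None,
) -> dict:
    """Execute the full workflow and return the run manifest (also written to
    output_dir/manifest.json along with every intermediate artifact)."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    def _load(path, what):
        if path is None:
            raise ValueError(f"pipeline config missing path for {what}")
        if not Path(str(path) + ".bed").exists():
            raise FileNotFoundError(f"{what}: no PLINK fileset at {path}")
        return read_plink_cohort(path)

    if stats is None:
        if config.base_stats is None or not Path(config.base_stats).exists():
            raise FileNotFoundError(f"base stats file not found: {config.base_stats}")
        stats = read_summary_stats(config.base_stats)
    if reference is None:
        reference = _load(config.ld_reference, "LD reference")
    if dev_cohorts is None:
        dev_cohorts = [_load(p, "development cohort") for p in config.development_cohorts]
    if val_cohorts is None:
        val_cohorts = [_load(p, "validation cohort") for p in config.validation_cohorts]

    manifest: dict = {"stages": {}, "parameters": {
        "clump": asdict(config.clump_params),
        "qc": asdict(config.qc_thresholds),
        "beta_qc": asdict(config.beta_qc_params),
        "grid": asdict(config.threshold_grid),
        "commonality_k": list(config.commonality_k),
        "scoring_mode": config.scoring_mode,
        "seed": config.seed,
    }}

    # 1. SNP QC per cohort
    qc_cohorts = []
    for cohort in dev_cohorts + val_cohorts:
        filtered, report = apply_snp_qc(cohort, config.qc_thresholds)
        report.to_csv(out / f"qc_removed_{cohort.cohort_id}.tsv", sep="\t", index=False)
        counts = report["reason"].value_counts().to_dict() if len(report) else {}
        log.info("qc %s: removed %s", cohort.cohort_id, counts or "none")
        manifest["stages"].setdefault("qc", {})[cohort.cohort_id] = {
            "n_snps_in": cohort.n_snps, "n_snps_out": filtered.n_snps, "removed_by_rule": counts,
        }
        qc_cohorts.append(filtered)
    dev_cohorts = qc_cohorts[: len(dev_cohorts)]
    val_cohorts = qc_cohorts[len(dev_cohorts):]

    # 2. clump the base stats and tag SNPs
    table = clump(stats, reference, config.clump_params)
    write_clump_table(table, out / "base.clumped", stats)
    tags = tag_snps(table)
    manifest["stages"]["clump"] = {"n_clumps": len(table), "n_tagged_snps": len(tags),
                                   "n_unclumped": len(table.unclumped)}

    # 3. per-cohort panels, common clumps, beta QC
    dev_panels = [build_panel(c, tags, stats, table) for c in dev_cohorts]
    val_panels = [build_panel(c, tags, stats, table) for c in val_cohorts]
    for p in dev_panels + val_panels:
        p.to_frame().to_csv(out / f"panel_{p.cohort_id}.tsv", sep="\t", index=False)
    common = common_clumps(dev_panels)
    kept, removed = beta_qc(dev_panels, common, config.beta_qc_params)
    removed.to_csv(out / "beta_qc_removed.tsv", sep="\t", index=False)
    rule_counts = removed["reason"].value_counts().to_dict() if len(removed) else {}
    log.info("beta_qc: %d common clumps, kept %d, removed %s", len(common), len(kept), rule_counts or "none")
    manifest["stages"]["harmonize"] = {
        "n_common_clumps": len(common), "n_kept": len(kept), "removed_by_rule": rule_counts,
    }
    dev_panels = [
        ClumpPanel(p.cohort_id, p.entries.loc[sorted(kept & set(p.entries.index))]) for p in dev_panels
    ]

    # 4. per-cohort threshold models and PD traces
    traces: list[PDTrace] = []
    manifest["stages"]["threshold"] = {}
    manifest["stages"]["pd"] = {}
    for cohort, panel in zip(dev_cohorts, dev_panels):
        if config.run_threshold_models:
            evals, best = threshold_models(cohort, panel, config.threshold_grid, mode=config.scoring_mode)
            evals.to_csv(out / f"threshold_{cohort.cohort_id}.tsv", sep="\t", index=False)
            if best is not None:
                write_score_file(best, out / f"threshold_best_{cohort.cohort_id}.score")
            best_row = evals.loc[evals["auc"].idxmax()].to_dict() if len(evals) else {}
            manifest["stages"]["threshold"][cohort.cohort_id] = best_row
        first = pd_first_pass(cohort, panel)
        trace = pd_second_pass(cohort, panel, first)
        trace.steps.to_csv(out / f"pd_trace_{cohort.cohort_id}.tsv", sep="\t", index=False)
        manifest["stages"]["pd"][cohort.cohort_id] = {
            "perfect_reached": trace.perfect_reached,
            "final_auc": trace.final_auc,
            "n_contributing": len(trace.contributing_set),
        }
        traces.append(trace)

    # 5. commonality models and application to every cohort
    manifest["stages"]["models"] = {}
    models: dict[int, CommonModel] = {}
    for k in config.commonality_k:
        model = commonality(traces, k, panels=dev_panels)
        models[k] = model
        name = {2: "lenient", 3: "stringent"}.get(k, f"k{k}")
        entry: dict = {"k": k, "n_clumps": len(model.clump_ids), "cohorts": {}}
        for cohort, panel in zip(dev_cohorts + val_cohorts, dev_panels + val_panels):
            try:
                ev, prs = apply_model(model, cohort, panel, mode=config.scoring_mode)
            except ValueError:
                entry["cohorts"][cohort.cohort_id] = {"error": "no representable clump"}
                continue
            write_prs_table(prs.table, out / f"prs_{name}_{cohort.cohort_id}.tsv")
            entry["cohorts"][cohort.cohort_id] = {
                "n_snps": ev.n_snps, "logit_p": None if pd.isna(ev.logit_p) else ev.logit_p,
                "auc": ev.auc, "separated": ev.separated,
                "n_missing_clumps": ev.n_missing_clumps, "n_alternative": ev.n_alternative,
            }
            # 6. absolutes and centile tables per cohort realization
            sf = panel.score_file(sorted(model.clump_ids & set(panel.entries.index)))
            rng_abs = abso.absolute_range(sf)
            if not rng_abs.degenerate and config.scoring_mode == "sum":
                ct = abso.centile_table(prs, rng_abs)
                ct.table.to_csv(out / f"centiles_{name}_{cohort.cohort_id}.tsv", sep="\t", index=False)
                abso.plot_centiles(ct, out / f"centiles_{name}_{cohort.cohort_id}.png",
                                   title=f"{cohort.cohort_id} ({name})")
        manifest["stages"]["models"][name] = entry

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True, default=float))
    return manifest
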
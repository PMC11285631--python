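"""Model construction: p-value thresholding and two-pass perfect-discrimination
forward selection, plus cross-cohort commonality assembly.

The perfect-discrimination procedure deliberately over-fits one cohort: SNPs
are added to the score one at a time in order of their association p-value
*in that cohort* (first pass, labelling each addition's effect on the AUC),
then only the additions that increased the AUC are replayed in the same
order until the score strictly separates cases from controls (AUC = 1).
Clumps contributing to that first perfect model in at least k of the
development cohorts form the generalized (lenient k=2 / stringent k=3)
models.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .formats_io import GenotypeCohort, ScoreFile, SummaryStats
from .harmonize import ClumpPanel
from .scoring_stats import (
    ModelEval,
    PRSResult,
    _oriented_dosages,
    allelic_assoc_many,
    auc,
    compute_prs,
    logistic_fit,
)

log = logging.getLogger(__name__)


@dataclass
class ThresholdGrid:
    start: float = 5e-8
    stop: float = 1.0
    step: float = 1e-6

    def __post_init__(self) -> None:
        if not 0 < self.start <= self.stop <= 1:
            raise ValueError("need 0 < start <= stop <= 1")
        if self.step <= 0:
            raise ValueError("step must be positive")

    def snap_up(self, p: float) -> float | None:
        """Smallest grid threshold >= p, or None when p exceeds the grid."""
        if p <= self.start:
            return self.start
        k = int(np.ceil((p - self.start) / self.step - 1e-12))
        t = self.start + k * self.step
        return t if t <= self.stop else None


@dataclass
class PDTrace:
    """Record of one cohort's forward-selection run."""

    cohort_id: str
    steps: pd.DataFrame  # step, clump_id, snp_id, assoc_p, auc_after, delta_direction
    contributing_set: set[int] = field(default_factory=set)
    perfect_reached: bool = False
    final_auc: float = 0.5


@dataclass
class CommonModel:
    clump_ids: set[int]
    k_required: int
    realizations: dict[str, ScoreFile] = field(default_factory=dict)
    n_alternative: dict[str, int] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# threshold modelling


def threshold_models(
    cohort: GenotypeCohort,
    panel: ClumpPanel,
    grid: ThresholdGrid | None = None,
    mode: str = "sum",
) -> tuple[pd.DataFrame, ScoreFile | None]:
    """Evaluate the PRS at every distinct SNP set the p-threshold grid induces.

    Consecutive grid thresholds selecting identical SNP sets are evaluated
    once (the printed grid implies ~1e6 thresholds but at most panel-size
    distinct sets).  Returns the evaluation table (threshold, n_snps,
    logit_beta, logit_p, auc, separated) and the best model's score file
    (max AUC, ties broken by smaller logistic p then fewer SNPs).
    """
    grid = grid or ThresholdGrid()
    if len(panel.entries) == 0:
        raise ValueError("empty panel")
    e = panel.entries.sort_values("base_p")
    snapped = e["base_p"].map(grid.snap_up)
    skipped = snapped.isna().sum()
    if skipped:
        log.info("threshold_models: %d panel SNPs above the grid stop, never selected", skipped)
    thresholds = sorted(set(snapped.dropna()))
    rows = []
    best = None  # (key, ScoreFile)
    for t in thresholds:
        sel = e[snapped.notna() & (snapped <= t)]
        if len(sel) == 0:
            continue
        sf = ScoreFile(sel[["snp_id", "effect_allele", "beta"]].reset_index(drop=True))
        prs = compute_prs(cohort, sf, mode=mode).evaluable()
        slope, p, sep = logistic_fit(prs.scores, prs.phenotype)
        a = auc(prs.scores, prs.phenotype)
        rows.append(
            {"threshold": t, "n_snps": len(sf), "logit_beta": slope, "logit_p": p, "auc": a, "separated": sep}
        )
        p_key = -1.0 if sep or np.isnan(p) else p
        key = (-a, p_key, len(sf))
        if best is None or key < best[0]:
            best = (key, sf)
    table = pd.DataFrame(rows, columns=["threshold", "n_snps", "logit_beta", "logit_p", "auc", "separated"])
    return table, (best[1] if best else None)


# ---------------------------------------------------------------------------
# perfect-discrimination forward selection


def _panel_columns(cohort: GenotypeCohort, panel: ClumpPanel) -> pd.DataFrame:
    """Per-panel-SNP assoc p and metadata, in deterministic selection order
    (ascending target-cohort assoc p, ties by chrom, pos, snp_id)."""
    snp_meta = cohort.snps.set_index("snp_id")
    present = panel.entries[panel.entries["snp_id"].isin(snp_meta.index)]
    if len(present) == 0:
        return pd.DataFrame(columns=["clump_id", "snp_id", "assoc_p", "chrom", "pos", "effect_allele", "beta"])
    assoc = allelic_assoc_many(cohort, list(present["snp_id"])).set_index("snp_id")
    df = pd.DataFrame(
        {
            "clump_id": present.index.astype(int),
            "snp_id": present["snp_id"].to_numpy(),
            "assoc_p": assoc.loc[present["snp_id"], "p"].to_numpy(),
            "chrom": snp_meta.loc[present["snp_id"], "chrom"].astype(str).to_numpy(),
            "pos": snp_meta.loc[present["snp_id"], "pos"].astype(int).to_numpy(),
            "effect_allele": present["effect_allele"].to_numpy(),
            "beta": present["beta"].to_numpy(dtype=float),
        }
    )
    if len(df):
        df = df.sort_values(["assoc_p", "chrom", "pos", "snp_id"], kind="mergesort").reset_index(drop=True)
    return df


def _imputed_matrix(cohort: GenotypeCohort, order: pd.DataFrame) -> np.ndarray:
    """Oriented, mean-imputed dosage columns for the ordered panel SNPs."""
    sf = ScoreFile(order[["snp_id", "effect_allele"]].assign(beta=1.0))
    D, _, used = _oriented_dosages(cohort, sf)
    assert used == list(order["snp_id"])
    obs = ~np.isnan(D)
    freq = np.nansum(D, axis=0) / (2 * np.maximum(obs.sum(axis=0), 1))
    return np.where(obs, D, 2 * freq)


def _cases_above_controls(scores: np.ndarray, y: np.ndarray) -> bool:
    cases, ctrls = scores[y == 1], scores[y == 0]
    return bool(len(cases) and len(ctrls) and cases.min() > ctrls.max())


def pd_first_pass(cohort: GenotypeCohort, panel: ClumpPanel) -> PDTrace:
    """Sequential single-SNP addition labelling each AUC effect direction.

    SNPs enter in ascending target-cohort allelic-association p; the AUC is
    recomputed after each addition (scores carried incrementally, which
    equals from-scratch rescoring exactly) and compared against the previous
    step, starting from the empty-model baseline AUC 0.5.
    """
    order = _panel_columns(cohort, panel)
    if len(order) == 0:
        raise ValueError("no panel SNP genotyped in this cohort")
    D = _imputed_matrix(cohort, order)
    ev = cohort.evaluable
    y = cohort.phenotype[ev]
    score = np.zeros(int(ev.sum()))
    prev = 0.5
    steps = []
    for i, row in order.iterrows():
        score = score + row["beta"] * D[ev, i]
        a = auc(score, y)
        delta = "increase" if a > prev else ("decrease" if a < prev else "none")
        steps.append(
            {
                "step": i + 1,
                "clump_id": row["clump_id"],
                "snp_id": row["snp_id"],
                "assoc_p": row["assoc_p"],
                "auc_after": a,
                "delta_direction": delta,
            }
        )
        prev = a
    df = pd.DataFrame(steps)
    return PDTrace(cohort_id=cohort.cohort_id, steps=df, final_auc=prev)


def pd_second_pass(
    cohort: GenotypeCohort, panel: ClumpPanel, first: PDTrace, include_decrease: bool = False
) -> PDTrace:
    """Replay increase-labelled SNPs in ascending assoc p until AUC = 1.

    Perfect discrimination is tested as strict separation — every case score
    above every control score — not floating-point equality.  The
    contributing set is every clump added through the first perfect step.
    If separation is never reached, the contributing set is the prefix
    achieving the maximum AUC and ``perfect_reached`` is False.
    """
    keep = first.steps["delta_direction"] == "increase"
    if include_decrease:
        sel = pd.concat([first.steps[keep], first.steps[~keep]]).reset_index(drop=True)
    else:
        sel = first.steps[keep].reset_index(drop=True)
    if len(sel) == 0:
        log.warning("pd_second_pass: no increase-labelled SNP in %s", cohort.cohort_id)
        return PDTrace(cohort_id=cohort.cohort_id, steps=sel.iloc[0:0], final_auc=0.5)

    order = _panel_columns(cohort, panel)
    order = order.set_index("snp_id").loc[list(sel["snp_id"])].reset_index()
    D = _imputed_matrix(cohort, order)
    ev = cohort.evaluable
    y = cohort.phenotype[ev]
    score = np.zeros(int(ev.sum()))
    steps = []
    perfect_at = None
    best_auc, best_step = 0.5, 0
    for i, row in order.iterrows():
        score = score + row["beta"] * D[ev, i]
        a = auc(score, y)
        steps.append(
            {
                "step": i + 1,
                "clump_id": row["clump_id"],
                "snp_id": row["snp_id"],
                "assoc_p": row["assoc_p"],
                "auc_after": a,
                "delta_direction": "",
            }
        )
        if a > best_auc:
            best_auc, best_step = a, i + 1
        if _cases_above_controls(score, y):
            perfect_at = i + 1
            break
    df = pd.DataFrame(steps)
    if perfect_at is not None:
        contrib = set(df["clump_id"].iloc[:perfect_at].astype(int))
        return PDTrace(cohort_id=cohort.cohort_id, steps=df, contributing_set=contrib,
                       perfect_reached=True, final_auc=1.0)
    contrib = set(df["clump_id"].iloc[:best_step].astype(int))
    return PDTrace(cohort_id=cohort.cohort_id, steps=df, contributing_set=contrib,
                   perfect_reached=False, final_auc=float(df["auc_after"].iloc[-1]) if len(df) else 0.5)


def perfect_discrimination(cohort: GenotypeCohort, panel: ClumpPanel) -> PDTrace:
    """Both passes: label directions, then replay increases to AUC = 1."""
    first = pd_first_pass(cohort, panel)
    return pd_second_pass(cohort, panel, first)


# ---------------------------------------------------------------------------
# commonality and model application


def commonality(
    traces: list[PDTrace], k: int, panels: list[ClumpPanel] | None = None
) -> CommonModel:
    """Clumps contributing to perfect discrimination in >= k of the traces.

    When the cohorts' panels are supplied, each cohort's score-file
    realization of the model is attached (its own representative SNP per
    clump, with the count of alternative — non-index — representatives).
    """
    if k < 2:
        raise ValueError("commonality threshold k must be >= 2")
    if k > len(traces):
        raise ValueError(f"k={k} exceeds the number of traces ({len(traces)})")
    tally: dict[int, int] = {}
    for tr in traces:
        for cid in tr.contributing_set:
            tally[cid] = tally.get(cid, 0) + 1
    ids = {cid for cid, c in tally.items() if c >= k}
    model = CommonModel(clump_ids=ids, k_required=k)
    if panels:
        for p in panels:
            present = sorted(ids & set(p.entries.index))
            if not present:
                continue
            model.realizations[p.cohort_id] = p.score_file(present)
            model.n_alternative[p.cohort_id] = int(p.entries.loc[present, "is_alternative"].sum())
    return model


def apply_model(
    model: CommonModel, cohort: GenotypeCohort, panel: ClumpPanel, mode: str = "sum"
) -> tuple[ModelEval, PRSResult]:
    """Score a cohort with a common model through its own clump panel.

    Model clumps with no representative in the cohort are dropped and
    counted; alternative (non-index) representatives are counted too.
    """
    present = sorted(model.clump_ids & set(panel.entries.index))
    if not present:
        raise ValueError(f"no model clump representable in cohort {cohort.cohort_id}")
    missing = len(model.clump_ids) - len(present)
    sf = panel.score_file(present)
    prs = compute_prs(cohort, sf, mode=mode)
    ev = prs.evaluable()
    slope, p, sep = logistic_fit(ev.scores, ev.phenotype)
    a = auc(ev.scores, ev.phenotype)
    evaluation = ModelEval(
        n_snps=len(sf),
        logit_beta=slope,
        logit_p=p,
        auc=a,
        separated=sep,
        n_missing_clumps=missing,
        n_alternative=int(panel.entries.loc[present, "is_alternative"].sum()),
    )
    return evaluation, prs
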
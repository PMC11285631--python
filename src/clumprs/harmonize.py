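"""Cross-cohort clump harmonization.

Each cohort gets a *clump panel*: one representative SNP per LD clump (the
index SNP when genotyped, else the genotyped member with the smallest base
p-value), carrying the base-GWAS effect allele and beta.  Clumps covered in
every cohort form the common clump set; a beta-consistency QC then removes
clumps whose representative SNPs disagree in effect direction or effect
allele across cohorts, or whose betas spread with SD above a cutoff.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .formats_io import ClumpTable, GenotypeCohort, ScoreFile, SummaryStats

log = logging.getLogger(__name__)


@dataclass
class ClumpPanel:
    """Per-cohort map clump_id -> representative SNP with base-GWAS weights."""

    cohort_id: str
    entries: pd.DataFrame  # index: clump_id; columns: snp_id, effect_allele, beta, base_p, is_index, is_alternative

    def clump_ids(self) -> set[int]:
        return set(self.entries.index)

    def score_file(self, clump_ids=None) -> ScoreFile:
        e = self.entries if clump_ids is None else self.entries.loc[sorted(set(clump_ids) & set(self.entries.index))]
        return ScoreFile(e[["snp_id", "effect_allele", "beta"]].reset_index(drop=True))

    def to_frame(self) -> pd.DataFrame:
        return self.entries.reset_index().rename(columns={"index": "clump_id"})


@dataclass
class BetaQCParams:
    sd_max: float = 0.5
    require_same_direction: bool = True
    require_same_reference_allele: bool = True

    def __post_init__(self) -> None:
        if self.sd_max <= 0:
            raise ValueError("sd_max must be positive")


def build_panel(
    cohort: GenotypeCohort,
    tags: dict[str, int],
    stats: SummaryStats,
    table: ClumpTable,
) -> ClumpPanel:
    """Select one representative SNP per clump for a cohort.

    The clump's index SNP is used when the cohort genotyped it; otherwise the
    genotyped member with the smallest base p-value stands in (flagged
    ``is_alternative``).  Clumps with no genotyped SNP are absent from the
    panel — absence is data, not an error.
    """
    present = set(cohort.snps["snp_id"]) & set(tags)
    meta = stats.table.set_index("snp_id")
    index_of = dict(zip(table.clumps["clump_id"], table.clumps["index_snp"]))

    by_clump: dict[int, list[str]] = {}
    for s in present:
        by_clump.setdefault(tags[s], []).append(s)

    rows = []
    for cid, snps in by_clump.items():
        idx = index_of.get(cid)
        if idx is not None and idx in snps:
            chosen, alt = idx, False
        else:
            # smallest base p among present members; ties by snp_id for determinism
            chosen = min(snps, key=lambda s: (meta.at[s, "p_value"], s))
            alt = True
        rows.append(
            {
                "clump_id": cid,
                "snp_id": chosen,
                "effect_allele": meta.at[chosen, "effect_allele"],
                "beta": float(meta.at[chosen, "beta"]),
                "base_p": float(meta.at[chosen, "p_value"]),
                "is_index": not alt,
                "is_alternative": alt,
            }
        )
    entries = pd.DataFrame(
        rows, columns=["clump_id", "snp_id", "effect_allele", "beta", "base_p", "is_index", "is_alternative"]
    ).set_index("clump_id").sort_index()
    return ClumpPanel(cohort_id=cohort.cohort_id, entries=entries)


def common_clumps(panels: list[ClumpPanel]) -> set[int]:
    """Clump ids represented in every panel."""
    if len(panels) < 2:
        raise ValueError("common_clumps needs at least two panels")
    out = set.intersection(*(p.clump_ids() for p in panels))
    if not out:
        log.warning("common_clumps: no clump is covered by every cohort")
    return out


def beta_qc(
    panels: list[ClumpPanel],
    clump_ids: set[int],
    params: BetaQCParams | None = None,
) -> tuple[set[int], pd.DataFrame]:
    """Remove clumps whose cross-cohort representatives are inconsistent.

    A clump is removed when the representatives' effect alleles differ
    ("allele"), their betas are not all the same sign ("direction"; a zero
    beta counts as neither sign and cannot oppose), or the sample SD of the
    betas exceeds ``sd_max`` ("sd").  Rules are checked in that order; the
    report gives the first failing rule.
    """
    params = params or BetaQCParams()
    kept: set[int] = set()
    removed = []
    for cid in sorted(clump_ids):
        alleles, betas = [], []
        for p in panels:
            if cid not in p.entries.index:
                raise ValueError(f"clump {cid} missing from panel {p.cohort_id}")
            alleles.append(p.entries.at[cid, "effect_allele"])
            betas.append(float(p.entries.at[cid, "beta"]))
        betas_arr = np.array(betas)
        if params.require_same_reference_allele and len(set(alleles)) > 1:
            removed.append((cid, "allele", np.nan))
            continue
        signs = set(np.sign(betas_arr)) - {0.0}
        if params.require_same_direction and len(signs) > 1:
            removed.append((cid, "direction", float(betas_arr.std(ddof=1))))
            continue
        sd = float(betas_arr.std(ddof=1)) if len(betas_arr) > 1 else 0.0
        if sd > params.sd_max:
            removed.append((cid, "sd", sd))
            continue
        kept.add(cid)
    report = pd.DataFrame(removed, columns=["clump_id", "reason", "value"])
    return kept, report
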
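"""Greedy LD clumping of base summary statistics against a genotype reference.

Replicates the PLINK-style clump procedure: sort SNPs by base p-value,
repeatedly take the best remaining SNP as a clump index, and absorb as
members every remaining SNP on the same chromosome within the kb window
whose dosage r-squared with the index reaches the threshold.  r-squared is
the squared Pearson correlation of dosage vectors (composite LD), not
EM-phased haplotype LD; at the high thresholds used here the two rarely
disagree, and the difference is documented as a dialect choice.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .formats_io import MISSING, ClumpTable, GenotypeCohort, SummaryStats

log = logging.getLogger(__name__)


@dataclass
class ClumpParams:
    p1: float = 1.0  # max index p
    p2: float = 1.0  # max member p
    kb_window: int = 250
    r2_min: float = 0.8
    #: optional (chrom, start, end) whose SNPs are never absorbed as members,
    #: so every SNP in the region stays an index of its own clump
    keep_region: tuple[str, int, int] | None = None

    def __post_init__(self) -> None:
        if not (self.p1 <= 1 and self.p2 <= 1):
            raise ValueError("p1 and p2 must be <= 1")
        if self.kb_window <= 0:
            raise ValueError("kb_window must be positive")
        if not 0 < self.r2_min <= 1:
            raise ValueError("r2_min must be in (0, 1]")


def pairwise_r2(dosages_a: np.ndarray, dosages_b: np.ndarray) -> float | None:
    """Squared Pearson correlation of two dosage vectors over pairwise-complete
    samples.  Returns None (not computable) when fewer than two complete pairs
    remain or either SNP is monomorphic among them."""
    a = np.asarray(dosages_a, dtype=float)
    b = np.asarray(dosages_b, dtype=float)
    ok = (a != MISSING) & (b != MISSING)
    a, b = a[ok], b[ok]
    if len(a) < 2:
        return None
    va, vb = a.var(), b.var()
    if va == 0 or vb == 0:
        return None
    cov = ((a - a.mean()) * (b - b.mean())).mean()
    return float(min(1.0, cov * cov / (va * vb)))


def clump(stats: SummaryStats, reference: GenotypeCohort, params: ClumpParams | None = None) -> ClumpTable:
    """Greedy LD clumping of ``stats`` using ``reference`` for LD.

    SNPs present in the stats but absent from the reference become singleton
    clumps (flagged in the result's ``unclumped`` list) so the partition
    property holds over all stats SNPs with p <= p1.
    """
    params = params or ClumpParams()
    t = stats.table
    ref_idx = reference.snp_index()
    in_ref = t["snp_id"].isin(ref_idx).to_numpy()
    if not in_ref.any():
        raise ValueError("no summary-stats SNP is present in the LD reference")

    # deterministic processing order: p asc, then chrom, pos, snp_id
    order = t.assign(_chrom=t["chrom"].astype(str)).sort_values(
        ["p_value", "_chrom", "pos", "snp_id"], kind="mergesort"
    )
    candidates = order[order["p_value"] <= params.p1]

    c_snp = candidates["snp_id"].to_numpy()
    c_p = candidates["p_value"].to_numpy()
    c_chrom = candidates["chrom"].astype(str).to_numpy()
    c_pos = candidates["pos"].to_numpy()
    c_in_ref = candidates["snp_id"].isin(ref_idx).to_numpy()

    protected = np.zeros(len(c_snp), dtype=bool)  # keep-region SNPs: never absorbed
    if params.keep_region is not None:
        c, lo, hi = params.keep_region
        protected = (c_chrom == str(c)) & (c_pos >= lo) & (c_pos <= hi)

    assigned = np.zeros(len(c_snp), dtype=bool)
    rows = []
    unclumped: list[str] = []
    window = params.kb_window * 1000
    for i in range(len(c_snp)):
        if assigned[i]:
            continue
        assigned[i] = True
        members: list[str] = []
        if c_in_ref[i]:
            idx_dos = reference.dosages[:, ref_idx[c_snp[i]]]
            eligible = (
                ~assigned
                & c_in_ref
                & ~protected
                & (c_p <= params.p2)
                & (c_chrom == c_chrom[i])
                & (np.abs(c_pos - c_pos[i]) <= window)
            )
            for j in np.flatnonzero(eligible):
                r2 = pairwise_r2(idx_dos, reference.dosages[:, ref_idx[c_snp[j]]])
                if r2 is not None and r2 >= params.r2_min:
                    members.append(c_snp[j])
                    assigned[j] = True
        else:
            unclumped.append(c_snp[i])
        rows.append({"clump_id": len(rows) + 1, "index_snp": c_snp[i], "members": members})
    if unclumped:
        log.info("clump: %d stats SNPs absent from the LD reference kept as singleton clumps", len(unclumped))
    return ClumpTable(pd.DataFrame(rows, columns=["clump_id", "index_snp", "members"]), unclumped=unclumped)


def tag_snps(table: ClumpTable) -> dict[str, int]:
    """Map every index and member SNP to its clump_id (the clump-tag map)."""
    tags: dict[str, int] = {}
    for _, row in table.clumps.iterrows():
        tags[row["index_snp"]] = int(row["clump_id"])
        for m in row["members"]:
            tags[m] = int(row["clump_id"])
    return tags
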
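"""SNP-level quality control: MAF, call-rate and exact Hardy-Weinberg filters.

Removal semantics are strict-inequality: a SNP is removed when MAF < maf_min,
call rate < call_rate_min, or the HWE exact p in controls < hwe_p_min.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .formats_io import MISSING, GenotypeCohort


@dataclass
class QCThresholds:
    maf_min: float = 0.01
    call_rate_min: float = 0.95
    hwe_p_min: float = 1e-4  # applied in controls only

    def __post_init__(self) -> None:
        for v in (self.maf_min, self.call_rate_min, self.hwe_p_min):
            if not 0 < v < 1:
                raise ValueError("QC thresholds must lie in (0, 1)")


def hwe_exact_p(n_hom1: int, n_het: int, n_hom2: int) -> float:
    """Two-sided exact Hardy-Weinberg test probability.

    Conditional on the observed allele counts, sums the probabilities of
    every heterozygote count no more likely than the observed one.  The
    conditional distribution of the heterozygote count n_het given n
    genotypes and n_a minor alleles is

        P(n_het) = C * 2^n_het * n! / (n_hom_min! n_het! n_hom_maj!)
                   ------------------------------------------------
                           (2n)! / (n_a! n_A!)

    computed here in log space.  Returns a value in (0, 1].
    """
    if min(n_hom1, n_het, n_hom2) < 0:
        raise ValueError("genotype counts must be nonnegative")
    n = n_hom1 + n_het + n_hom2
    if n == 0:
        raise ValueError("all genotype counts are zero")
    n_a = 2 * min(n_hom1, n_hom2) + n_het  # minor allele count
    if n_a == 0:
        return 1.0  # monomorphic: perfect fit
    # feasible het counts share the parity of n_a
    hets = np.arange(n_a % 2, min(n_a, 2 * n - n_a) + 1, 2)
    hom_min = (n_a - hets) // 2
    hom_maj = n - hets - hom_min
    logp = (
        hets * np.log(2.0)
        - gammaln(hom_min + 1)
        - gammaln(hets + 1)
        - gammaln(hom_maj + 1)
    )
    logp -= logp.max()
    probs = np.exp(logp)
    probs /= probs.sum()
    observed = probs[hets == n_het][0]
    # sum everything no more likely than observed; tiny slack for fp ties
    return float(min(1.0, probs[probs <= observed * (1 + 1e-12)].sum()))


def _snp_metrics(cohort: GenotypeCohort) -> pd.DataFrame:
    d = cohort.dosages
    obs = d != MISSING
    n_obs = obs.sum(axis=0)
    call_rate = n_obs / d.shape[0]
    with np.errstate(invalid="ignore"):
        a1_freq = np.where(n_obs > 0, np.where(obs, d, 0).sum(axis=0) / (2 * n_obs), np.nan)
    maf = np.minimum(a1_freq, 1 - a1_freq)
    return pd.DataFrame({"maf": maf, "call_rate": call_rate})


def apply_snp_qc(
    cohort: GenotypeCohort, thresholds: QCThresholds | None = None
) -> tuple[GenotypeCohort, pd.DataFrame]:
    """Filter SNPs by MAF, call rate, and control-sample HWE.

    Returns the filtered cohort and a removal report (snp_id, reason,
    value) giving the first failing rule per removed SNP, checked in the
    order maf, call_rate, hwe.  The retained set is order-independent
    because each rule is evaluated on the unfiltered cohort.
    """
    thresholds = thresholds or QCThresholds()
    controls = cohort.phenotype == 0
    if not controls.any():
        raise ValueError("SNP QC requires at least one control (HWE filter)")
    metrics = _snp_metrics(cohort)
    d_ctrl = cohort.dosages[controls]

    removed = []
    keep = np.ones(cohort.n_snps, dtype=bool)
    for j, snp_id in enumerate(cohort.snps["snp_id"]):
        maf, cr = metrics.at[j, "maf"], metrics.at[j, "call_rate"]
        if np.isnan(maf) or maf < thresholds.maf_min:
            keep[j] = False
            removed.append((snp_id, "maf", maf))
            continue
        if cr < thresholds.call_rate_min:
            keep[j] = False
            removed.append((snp_id, "call_rate", cr))
            continue
        col = d_ctrl[:, j]
        col = col[col != MISSING]
        if len(col) == 0:
            keep[j] = False
            removed.append((snp_id, "hwe", np.nan))
            continue
        p = hwe_exact_p(int((col == 2).sum()), int((col == 1).sum()), int((col == 0).sum()))
        if p < thresholds.hwe_p_min:
            keep[j] = False
            removed.append((snp_id, "hwe", p))

    kept_ids = cohort.snps.loc[keep, "snp_id"]
    report = pd.DataFrame(removed, columns=["snp_id", "reason", "value"])
    return cohort.subset_snps(kept_ids), report
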
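"""PRS computation and the statistical evaluation battery.

The polygenic risk score of individual *i* is the sum over score-file SNPs
of the effect-allele dosage times the base-GWAS beta:

    PRS_i = sum_j d_ij * beta_j        (sum mode)

Average mode divides by twice the number of scored SNPs (PLINK 1.9
``--score`` parity).  Evaluation covers the 1-df allelic chi-square
association test, logistic regression of phenotype on score (Wald p), and
the Mann-Whitney AUC.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .formats_io import MISSING, GenotypeCohort, ScoreFile

log = logging.getLogger(__name__)


@dataclass
class PRSResult:
    table: pd.DataFrame  # sample_id, phenotype, score, n_snps_used

    @property
    def scores(self) -> np.ndarray:
        return self.table["score"].to_numpy()

    @property
    def phenotype(self) -> np.ndarray:
        return self.table["phenotype"].to_numpy()

    def evaluable(self) -> "PRSResult":
        return PRSResult(self.table[self.table["phenotype"] >= 0].reset_index(drop=True))


@dataclass
class ModelEval:
    n_snps: int
    logit_beta: float
    logit_p: float
    auc: float
    separated: bool = False
    n_missing_clumps: int = 0
    n_alternative: int = 0


def _oriented_dosages(cohort: GenotypeCohort, scores: ScoreFile) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Dosage matrix of the score SNPs present in the cohort, oriented so the
    count is of the score file's effect allele.  Returns (dosages float with
    NaN missing, betas, used snp ids)."""
    idx = cohort.snp_index()
    a1 = dict(zip(cohort.snps["snp_id"], cohort.snps["a1"]))
    a2 = dict(zip(cohort.snps["snp_id"], cohort.snps["a2"]))
    cols, betas, used = [], [], []
    for _, row in scores.table.iterrows():
        s, ea, beta = row["snp_id"], row["effect_allele"], row["beta"]
        if s not in idx:
            continue
        d = cohort.dosages[:, idx[s]].astype(float)
        d[d == MISSING] = np.nan
        if ea == a1[s]:
            pass
        elif ea == a2[s]:
            d = 2.0 - d  # effect allele is the cohort's other allele
        else:
            log.info("compute_prs: SNP %s effect allele %s matches neither cohort allele; excluded", s, ea)
            continue
        cols.append(d)
        betas.append(float(beta))
        used.append(s)
    if not cols:
        raise ValueError("no usable score SNP in the cohort")
    return np.column_stack(cols), np.array(betas), used


def compute_prs(
    cohort: GenotypeCohort,
    scores: ScoreFile,
    mode: str = "sum",
    missing: str = "mean_impute",
) -> PRSResult:
    """Score every sample in the cohort against a score file.

    mode="sum" gives the plain weighted allele count; mode="average" divides
    by 2 x (number of scored SNPs), matching PLINK 1.9's default --score
    normalization.  missing="mean_impute" replaces a missing dosage with
    twice the effect-allele frequency among non-missing samples (missing
    SNPs still count toward the average denominator, as in PLINK);
    missing="skip" drops the SNP from that sample's sum and denominator.
    """
    if mode not in ("sum", "average"):
        raise ValueError(f"unknown scoring mode {mode!r}")
    if missing not in ("mean_impute", "skip"):
        raise ValueError(f"unknown missing policy {missing!r}")
    D, betas, used = _oriented_dosages(cohort, scores)
    obs = ~np.isnan(D)
    n_obs_snp = obs.sum(axis=0)
    with np.errstate(invalid="ignore"):
        freq = np.nansum(D, axis=0) / (2 * np.maximum(n_obs_snp, 1))

    if missing == "mean_impute":
        Dfill = np.where(obs, D, 2 * freq)
        raw = Dfill @ betas
        denom_snps = np.full(cohort.n_samples, len(used))
        n_used = np.full(cohort.n_samples, len(used))
    else:
        raw = np.where(obs, D, 0.0) @ betas
        denom_snps = obs.sum(axis=1)
        n_used = denom_snps
    if mode == "average":
        with np.errstate(divide="ignore", invalid="ignore"):
            score = np.where(denom_snps > 0, raw / (2.0 * denom_snps), 0.0)
    else:
        score = raw
    return PRSResult(
        pd.DataFrame(
            {
                "sample_id": cohort.sample_ids,
                "phenotype": cohort.phenotype.astype(int),
                "score": score,
                "n_snps_used": n_used.astype(int),
            }
        )
    )


def allelic_assoc(cohort: GenotypeCohort, snp_id: str) -> tuple[float, float, int]:
    """1-df allelic chi-square on the 2x2 allele x case/control table.

    No continuity correction.  Returns (chi2, p, direction) where direction
    is the sign of the case-minus-control a1 allele-frequency difference.
    A zero-margin table (monomorphic, or one class absent) returns chi2 0,
    p 1 and direction 0, flagged by the degenerate direction.
    """
    j = cohort.snp_index()[snp_id]
    d = cohort.dosages[:, j]
    ok = (d != MISSING) & (cohort.phenotype >= 0)
    d, y = d[ok].astype(float), cohort.phenotype[ok]
    counts = np.zeros((2, 2))  # rows: control/case; cols: a1 count, a2 count
    for cls in (0, 1):
        dc = d[y == cls]
        counts[cls, 0] = dc.sum()
        counts[cls, 1] = 2 * len(dc) - dc.sum()
    return _chi2_2x2(counts)


def _chi2_2x2(counts: np.ndarray) -> tuple[float, float, int]:
    row = counts.sum(axis=1)
    col = counts.sum(axis=0)
    n = counts.sum()
    if (row == 0).any() or (col == 0).any():
        return 0.0, 1.0, 0
    expected = np.outer(row, col) / n
    chi2 = float(((counts - expected) ** 2 / expected).sum())
    p = float(sps.chi2.sf(chi2, df=1))
    f_case = counts[1, 0] / row[1]
    f_ctrl = counts[0, 0] / row[0]
    direction = int(np.sign(f_case - f_ctrl))
    return chi2, max(p, np.finfo(float).tiny), direction


def allelic_assoc_many(cohort: GenotypeCohort, snp_ids: list[str]) -> pd.DataFrame:
    """Vectorized :func:`allelic_assoc` over many SNPs.

    Returns a frame (snp_id, chi2, p, direction) in the input order;
    identical to the per-SNP test, computed column-wise.
    """
    idx = cohort.snp_index()
    cols = np.array([idx[s] for s in snp_ids])
    d = cohort.dosages[:, cols].astype(float)
    d[d == MISSING] = np.nan
    evalmask = cohort.phenotype >= 0
    d = d[evalmask]
    y = cohort.phenotype[evalmask]
    counts = np.zeros((len(cols), 2, 2))
    for cls in (0, 1):
        dc = d[y == cls]
        obs = ~np.isnan(dc)
        a1 = np.nansum(dc, axis=0)
        counts[:, cls, 0] = a1
        counts[:, cls, 1] = 2 * obs.sum(axis=0) - a1
    row = counts.sum(axis=2)  # (m, 2)
    col = counts.sum(axis=1)
    n = row.sum(axis=1)
    ok = (row > 0).all(axis=1) & (col > 0).all(axis=1)
    expected = row[:, :, None] * col[:, None, :] / np.maximum(n, 1)[:, None, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = np.where(ok, ((counts - expected) ** 2 / np.where(expected > 0, expected, 1)).sum(axis=(1, 2)), 0.0)
        p = np.where(ok, sps.chi2.sf(chi2, df=1), 1.0)
        f_case = counts[:, 1, 0] / np.maximum(row[:, 1], 1)
        f_ctrl = counts[:, 0, 0] / np.maximum(row[:, 0], 1)
    direction = np.where(ok, np.sign(f_case - f_ctrl), 0).astype(int)
    return pd.DataFrame(
        {"snp_id": snp_ids, "chi2": chi2, "p": np.maximum(p, np.finfo(float).tiny), "direction": direction}
    )


def allele_table(cohort: GenotypeCohort, snp_id: str) -> pd.DataFrame:
    """The .assoc-style row for one SNP: CHR, SNP, A1, F_A, F_U, CHISQ, P."""
    j = cohort.snp_index()[snp_id]
    d = cohort.dosages[:, j]
    ok = (d != MISSING) & (cohort.phenotype >= 0)
    d, y = d[ok].astype(float), cohort.phenotype[ok]
    f_a = d[y == 1].mean() / 2 if (y == 1).any() else np.nan
    f_u = d[y == 0].mean() / 2 if (y == 0).any() else np.nan
    chi2, p, _ = allelic_assoc(cohort, snp_id)
    row = cohort.snps.iloc[j]
    return pd.DataFrame(
        [{"CHR": row["chrom"], "SNP": snp_id, "A1": row["a1"], "F_A": f_a, "F_U": f_u, "CHISQ": chi2, "P": p}]
    )


def is_separated(scores: np.ndarray, phenotype: np.ndarray) -> bool:
    """True when case and control score ranges do not overlap (strictly)."""
    cases = scores[phenotype == 1]
    ctrls = scores[phenotype == 0]
    if len(cases) == 0 or len(ctrls) == 0:
        return False
    return bool(cases.min() > ctrls.max() or cases.max() < ctrls.min())


def logistic_fit(scores: np.ndarray, phenotype: np.ndarray) -> tuple[float, float, bool]:
    """ML logistic regression of phenotype on score (intercept + slope).

    Returns (slope, Wald p, separated).  Under perfect separation the MLE
    diverges; the fit is flagged and p is the NaN separation sentinel.
    Constant scores raise, both classes must be present.
    """
    import statsmodels.api as sm

    scores = np.asarray(scores, dtype=float)
    phenotype = np.asarray(phenotype)
    if len(scores) < 3:
        raise ValueError("logistic_fit needs at least 3 samples")
    if len(np.unique(phenotype)) < 2:
        raise ValueError("logistic_fit needs both phenotype classes")
    if np.ptp(scores) == 0:
        raise ValueError("constant scores: slope unidentifiable")
    if is_separated(scores, phenotype):
        return np.inf * np.sign(scores[phenotype == 1].mean() - scores[phenotype == 0].mean()), np.nan, True
    X = sm.add_constant(scores)
    try:
        res = sm.Logit(phenotype, X).fit(disp=0, maxiter=200)
    except Exception:  # quasi-separation can still blow up the IRLS
        return np.nan, np.nan, True
    if not res.mle_retvals.get("converged", False):
        return float(res.params[1]), np.nan, True
    return float(res.params[1]), float(res.pvalues[1]), False


def auc(scores: np.ndarray, phenotype: np.ndarray) -> float:
    """Mann-Whitney AUC: P(random case outscores random control), ties 1/2.

    Equals the trapezoidal area under the ROC curve.
    """
    scores = np.asarray(scores, dtype=float)
    phenotype = np.asarray(phenotype)
    cases = phenotype == 1
    ctrls = phenotype == 0
    n1, n0 = int(cases.sum()), int(ctrls.sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("auc needs both phenotype classes")
    ranks = sps.rankdata(scores[cases | ctrls])
    r_case = ranks[phenotype[cases | ctrls] == 1].sum()
    return float((r_case - n1 * (n1 + 1) / 2) / (n1 * n0))


def evaluate_model(
    cohort: GenotypeCohort, scores: ScoreFile, mode: str = "sum", missing: str = "mean_impute"
) -> tuple[ModelEval, PRSResult]:
    """Score a cohort and run the full battery (logistic + AUC)."""
    prs = compute_prs(cohort, scores, mode=mode, missing=missing)
    ev = prs.evaluable()
    slope, p, sep = logistic_fit(ev.scores, ev.phenotype)
    a = auc(ev.scores, ev.phenotype)
    return ModelEval(n_snps=len(scores), logit_beta=slope, logit_p=p, auc=a, separated=sep), prs
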
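"""Synthetic multi-cohort case/control genotype data with block LD structure.

The generator emulates the statistical setting the method assumes: a base
GWAS summary-statistics file over SNPs organized into LD clumps, several
target cohorts genotyped on different (randomly masked) platforms, and
causal clumps whose allele frequencies differ between cases and controls.

Each clump carries a latent biallelic indicator at ancestral frequency f.
A member SNP copies each latent haplotype allele with probability 1 - eps
and redraws it from the class frequency otherwise, which gives pairwise
member-member r^2 of (1-eps)^4 in expectation; eps is set to hit the
configured within-clump r^2 target.  Causal clumps shift the latent
frequency by +/- freq_shift in cases, so every member SNP inherits the
full case/control frequency difference.  Genotypes are drawn per SNP from
Hardy-Weinberg at the class frequency given the latent indicator — block
LD, no recombination map.

Base summary statistics report beta = ln(odds ratio) implied by the shifted
vs unshifted frequencies plus Normal(0, 0.05^2) noise, and a p-value from a
two-proportion z-test at a large virtual GWAS sample size, so null-clump
p-values are uniform.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .formats_io import (
    MISSING,
    ClumpTable,
    GenotypeCohort,
    SummaryStats,
    write_plink_cohort,
    write_summary_stats,
)

_BASES = np.array(list("ACGT"))

#: virtual base-GWAS sample sizes for the pseudo-GWAS p-values
VIRTUAL_N_CASES = 17_000
VIRTUAL_N_CONTROLS = 37_000


@dataclass
class CohortSpec:
    n_cases: int = 100
    n_controls: int = 100
    platform_keep_fraction: float = 0.9
    #: a degraded cohort draws cases at the control frequency (no signal),
    #: emulating a small cohort in which the flagship loci carry no effect
    degraded: bool = False
    cohort_id: str | None = None


def _default_cohorts() -> list[CohortSpec]:
    return [CohortSpec() for _ in range(5)]


@dataclass
class SimConfig:
    n_clumps: int = 6000
    snps_per_clump: tuple[int, int] = (1, 3)
    within_clump_r2: float = 0.9
    n_causal_shared: int = 30
    n_causal_private_per_cohort: int = 5
    freq_shift: float = 0.1
    base_maf: tuple[float, float] = (0.05, 0.5)
    beta_noise_sd: float = 0.05
    missing_rate: float = 0.01
    allele_flip_rate: float = 0.2  # fraction of cohort SNPs whose .bim a1 is the non-effect allele
    cohorts: list[CohortSpec] = field(default_factory=_default_cohorts)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_clumps <= 0 or self.snps_per_clump[0] <= 0:
            raise ValueError("counts must be positive")
        if not 0 < self.within_clump_r2 <= 1:
            raise ValueError("within_clump_r2 must be in (0, 1]")
        lo, hi = self.base_maf
        if not (0 < lo <= hi < 1):
            raise ValueError("base_maf range must lie in (0, 1)")
        if not 0 <= self.freq_shift < min(0.5, 1 - hi):
            raise ValueError("freq_shift must keep case frequencies inside (0, 1)")
        for c in self.cohorts:
            if not 0 < c.platform_keep_fraction <= 1:
                raise ValueError("platform_keep_fraction must be in (0, 1]")


@dataclass
class SimTruth:
    causal_shared: set[int]
    causal_private: dict[str, set[int]]  # cohort_id -> clump ids
    clump_of_snp: dict[str, int]
    freq_control: dict[str, float]
    freq_case: dict[str, float]  # under the shared-causal model
    risk_direction: dict[int, int]  # clump -> +/-1 (0 for null)

    def clump_table(self) -> ClumpTable:
        """Ground-truth clump membership as a ClumpTable (first member = index)."""
        groups: dict[int, list[str]] = {}
        for s, c in self.clump_of_snp.items():
            groups.setdefault(c, []).append(s)
        rows = []
        for cid in sorted(groups):
            snps = sorted(groups[cid])
            rows.append({"clump_id": cid, "index_snp": snps[0], "members": snps[1:]})
        return ClumpTable(pd.DataFrame(rows, columns=["clump_id", "index_snp", "members"]))

    def tags(self) -> dict[str, int]:
        return dict(self.clump_of_snp)


@dataclass
class SimFamily:
    stats: SummaryStats
    reference: GenotypeCohort  # unmasked LD reference panel, controls only
    cohorts: list[GenotypeCohort]
    truth: SimTruth


def _draw_clump_genotypes(
    rng: np.random.Generator, n: int, m: int, f: float, eps: float
) -> np.ndarray:
    """Dosages (n, m) of the '1' allele for one clump at frequency f."""
    latent = rng.random((n, 2)) < f
    keep = rng.random((n, 2, m)) < (1 - eps)
    fresh = rng.random((n, 2, m)) < f
    hap = np.where(keep, latent[:, :, None], fresh)
    return hap.sum(axis=1).astype(np.int8)


def simulate_family(config: SimConfig | None = None) -> SimFamily:
    """Generate a base summary-statistics file, an LD reference panel, and
    one target cohort per :class:`CohortSpec`; deterministic under the seed."""
    config = config or SimConfig()
    rng = np.random.default_rng(config.seed)
    eps = 1.0 - config.within_clump_r2 ** 0.25

    n_clumps = config.n_clumps
    lo, hi = config.snps_per_clump
    sizes = rng.integers(lo, hi + 1, size=n_clumps)
    freqs = rng.uniform(*config.base_maf, size=n_clumps)

    causal_shared = set(range(1, config.n_causal_shared + 1))
    if config.n_causal_shared > n_clumps:
        raise ValueError("more shared causal clumps than clumps")
    # risk direction per causal clump, constrained so the shifted case
    # frequency stays comfortably inside (0, 1)
    direction = {}
    for cid in range(1, n_clumps + 1):
        if cid not in causal_shared:
            direction[cid] = 0
        elif freqs[cid - 1] - config.freq_shift < 0.01:
            direction[cid] = 1
        elif freqs[cid - 1] + config.freq_shift > 0.99:
            direction[cid] = -1
        else:
            direction[cid] = int(rng.choice([-1, 1]))

    # lay clumps 1 Mb apart on chromosomes of 100 clumps each; members within 10 kb
    snp_rows = []
    clump_of_snp: dict[str, int] = {}
    for cid in range(1, n_clumps + 1):
        chrom = str((cid - 1) // 100 + 1)
        base_pos = ((cid - 1) % 100) * 1_000_000 + 100_000
        a1, a2 = rng.choice(4, size=2, replace=False)
        for k in range(sizes[cid - 1]):
            sid = f"rs{cid}_{k}"
            snp_rows.append(
                {
                    "snp_id": sid,
                    "chrom": chrom,
                    "pos": base_pos + k * 2_000,
                    "effect_allele": _BASES[a1],
                    "other_allele": _BASES[a2],
                }
            )
            clump_of_snp[sid] = cid
    snp_df = pd.DataFrame(snp_rows)

    # base summary statistics (pseudo-GWAS on the shared-causal model)
    f_ctrl_clump = freqs
    f_case_clump = np.clip(
        freqs + np.array([direction[c] for c in range(1, n_clumps + 1)]) * config.freq_shift, 1e-3, 1 - 1e-3
    )
    per_snp_fc = np.array([f_ctrl_clump[clump_of_snp[s] - 1] for s in snp_df["snp_id"]])
    per_snp_fa = np.array([f_case_clump[clump_of_snp[s] - 1] for s in snp_df["snp_id"]])
    true_lnor = np.log(per_snp_fa / (1 - per_snp_fa)) - np.log(per_snp_fc / (1 - per_snp_fc))
    beta = true_lnor + rng.normal(0, config.beta_noise_sd, size=len(snp_df))
    pooled = (per_snp_fa * 2 * VIRTUAL_N_CASES + per_snp_fc * 2 * VIRTUAL_N_CONTROLS) / (
        2 * VIRTUAL_N_CASES + 2 * VIRTUAL_N_CONTROLS
    )
    se = np.sqrt(pooled * (1 - pooled) * (1 / (2 * VIRTUAL_N_CASES) + 1 / (2 * VIRTUAL_N_CONTROLS)))
    z = (per_snp_fa - per_snp_fc) / se + rng.normal(0, 1, size=len(snp_df))
    from scipy.stats import norm

    pvals = np.clip(2 * norm.sf(np.abs(z)), np.finfo(float).tiny, 1.0)
    stats = SummaryStats(
        snp_df.assign(beta=beta, p_value=pvals)[
            ["snp_id", "chrom", "pos", "effect_allele", "other_allele", "beta", "p_value"]
        ]
    )

    def draw_cohort(
        spec: CohortSpec, cohort_id: str, private: set[int], keep_mask: np.ndarray, flip_mask: np.ndarray
    ) -> GenotypeCohort:
        n = spec.n_cases + spec.n_controls
        pheno = np.concatenate([np.ones(spec.n_cases), np.zeros(spec.n_controls)]).astype(np.int8)
        cols = np.empty((n, len(snp_df)), dtype=np.int8)
        j = 0
        for cid in range(1, n_clumps + 1):
            m = int(sizes[cid - 1])
            f_ctrl = f_ctrl_clump[cid - 1]
            causal_here = (cid in causal_shared or cid in private) and not spec.degraded
            if causal_here:
                d = direction[cid] if cid in causal_shared else int(rng.choice([-1, 1]))
                f_case = float(np.clip(f_ctrl + d * config.freq_shift, 1e-3, 1 - 1e-3))
            else:
                f_case = f_ctrl
            g_case = _draw_clump_genotypes(rng, spec.n_cases, m, f_case, eps)
            g_ctrl = _draw_clump_genotypes(rng, spec.n_controls, m, f_ctrl, eps)
            cols[:, j : j + m] = np.vstack([g_case, g_ctrl])
            j += m
        # orient to .bim a1: flipped SNPs count the other allele
        flip = flip_mask
        cols[:, flip] = 2 - cols[:, flip]
        if config.missing_rate > 0:
            miss = rng.random(cols.shape) < config.missing_rate
            cols[miss] = MISSING
        snps = snp_df[["snp_id", "chrom", "pos"]].copy()
        snps["a1"] = np.where(flip, snp_df["other_allele"], snp_df["effect_allele"])
        snps["a2"] = np.where(flip, snp_df["effect_allele"], snp_df["other_allele"])
        keep_idx = np.flatnonzero(keep_mask)
        return GenotypeCohort(
            cohort_id=cohort_id,
            sample_ids=[f"{cohort_id}_s{i}" for i in range(n)],
            phenotype=pheno,
            snps=snps.iloc[keep_idx].reset_index(drop=True),
            dosages=cols[:, keep_idx],
        )

    # unmasked, unflipped reference panel of controls for LD computation
    ref_spec = CohortSpec(n_cases=0, n_controls=200, platform_keep_fraction=1.0, cohort_id="reference")
    reference = draw_cohort(
        ref_spec, "reference", set(), np.ones(len(snp_df), bool), np.zeros(len(snp_df), bool)
    )

    cohorts = []
    causal_private: dict[str, set[int]] = {}
    null_pool = [c for c in range(1, n_clumps + 1) if c not in causal_shared]
    for i, spec in enumerate(config.cohorts):
        cohort_id = spec.cohort_id or f"cohort{i + 1}"
        private = set(
            rng.choice(null_pool, size=min(config.n_causal_private_per_cohort, len(null_pool)), replace=False)
            .astype(int)
            .tolist()
        )
        causal_private[cohort_id] = private
        keep_mask = rng.random(len(snp_df)) < spec.platform_keep_fraction
        if not keep_mask.any():
            keep_mask[0] = True
        flip_mask = rng.random(len(snp_df)) < config.allele_flip_rate
        cohorts.append(draw_cohort(spec, cohort_id, private, keep_mask, flip_mask))

    truth = SimTruth(
        causal_shared=causal_shared,
        causal_private=causal_private,
        clump_of_snp=clump_of_snp,
        freq_control=dict(zip(snp_df["snp_id"], per_snp_fc)),
        freq_case=dict(zip(snp_df["snp_id"], per_snp_fa)),
        risk_direction=direction,
    )
    return SimFamily(stats=stats, reference=reference, cohorts=cohorts, truth=truth)


def rosmap_like_spec(n_cases: int = 30, n_controls: int = 30) -> CohortSpec:
    """A small degraded cohort: few samples, no case/control frequency shift
    at the causal clumps — the failure mode where the generalized model
    cannot discriminate."""
    return CohortSpec(
        n_cases=n_cases, n_controls=n_controls, platform_keep_fraction=0.85, degraded=True, cohort_id="degraded"
    )


def write_fixture(family: SimFamily, directory: str | Path) -> dict[str, Path]:
    """Write the family as PLINK filesets + summary-stats TSV + truth TSV."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    stats_path = directory / "base_stats.tsv"
    write_summary_stats(family.stats, stats_path)
    paths["stats"] = stats_path
    write_plink_cohort(family.reference, directory / "reference")
    paths["reference"] = directory / "reference"
    for cohort in family.cohorts:
        write_plink_cohort(cohort, directory / cohort.cohort_id)
        paths[cohort.cohort_id] = directory / cohort.cohort_id
    truth_rows = [
        {
            "snp_id": s,
            "clump_id": c,
            "causal_shared": int(c in family.truth.causal_shared),
            "freq_control": family.truth.freq_control[s],
            "freq_case": family.truth.freq_case[s],
        }
        for s, c in family.truth.clump_of_snp.items()
    ]
    truth_path = directory / "truth.tsv"
    pd.DataFrame(truth_rows).to_csv(truth_path, sep="\t", index=False)
    paths["truth"] = truth_path
    return paths
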
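import numpy as np
import pandas as pd
import pytest

from clumprs.formats_io import GenotypeCohort, ScoreFile, SummaryStats


def make_cohort(dosages, phenotype, snps=None, cohort_id="toy", a1=None, a2=None):
    """Build a GenotypeCohort from a plain dosage list-of-lists."""
    d = np.asarray(dosages, dtype=np.int8)
    n, m = d.shape
    if snps is None:
        snps = pd.DataFrame(
            {
                "snp_id": [f"rs{j + 1}" for j in range(m)],
                "chrom": ["1"] * m,
                "pos": [1000 * (j + 1) for j in range(m)],
                "a1": a1 or ["A"] * m,
                "a2": a2 or ["G"] * m,
            }
        )
    return GenotypeCohort(
        cohort_id=cohort_id,
        sample_ids=[f"s{i + 1}" for i in range(n)],
        phenotype=np.asarray(phenotype, dtype=np.int8),
        snps=snps,
        dosages=d,
    )


def make_stats(rows):
    """rows: (snp_id, chrom, pos, effect, other, beta, p)"""
    return SummaryStats(
        pd.DataFrame(
            rows,
            columns=["snp_id", "chrom", "pos", "effect_allele", "other_allele", "beta", "p_value"],
        )
    )


@pytest.fixture
def toy_scorefile():
    return ScoreFile.from_records([("rs1", "A", 0.5), ("rs2", "A", -0.3)])


@pytest.fixture(scope="session")
def small_family():
    """One small simulated family reused by read-only tests."""
    from clumprs.simulate import CohortSpec, SimConfig, simulate_family

    cfg = SimConfig(
        seed=7,
        n_clumps=60,
        snps_per_clump=(1, 3),
        n_causal_shared=8,
        n_causal_private_per_cohort=2,
        cohorts=[CohortSpec(40, 40, 0.9), CohortSpec(40, 40, 0.9), CohortSpec(40, 40, 0.9)],
    )
    return simulate_family(cfg)
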
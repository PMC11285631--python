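"""PRS arithmetic, allelic association, logistic regression and AUC."""

from pathlib import Path

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from clumprs.formats_io import MISSING, ScoreFile
from clumprs.scoring_stats import (
    allelic_assoc,
    allelic_assoc_many,
    auc,
    compute_prs,
    is_separated,
    logistic_fit,
)

from conftest import make_cohort

DATA = Path(__file__).parent / "data"


def oracle_toy_cohort():
    """The fileset the frozen scoring-parity oracle was derived from."""
    d = np.array(
        [
            [0, 2, 1],
            [1, 2, 0],
            [2, 1, MISSING],
            [0, 1, 2],
            [1, 0, 1],
            [2, 0, 0],
            [0, MISSING, 2],
            [1, 1, 1],
            [2, 2, 0],
            [MISSING, 0, 1],
        ],
        dtype=np.int8,
    )
    snps = pd.DataFrame(
        {
            "snp_id": ["s1", "s2", "s3"],
            "chrom": ["1"] * 3,
            "pos": [100, 200, 300],
            "a1": ["A", "C", "G"],
            "a2": ["G", "T", "A"],
        }
    )
    cohort = make_cohort(d, [1, 1, 1, 1, 1, 0, 0, 0, 0, 0], snps=snps)
    cohort.sample_ids = [f"i{k}" for k in range(1, 11)]
    scores = ScoreFile.from_records([("s1", "A", 0.5), ("s2", "T", -0.25), ("s3", "G", 0.1)])
    return cohort, scores


class TestComputePrs:
    def test_hand_sum_single_snp(self):
        cohort = make_cohort([[0], [1], [2]], [0, 0, 1])
        prs = compute_prs(cohort, ScoreFile.from_records([("rs1", "A", 0.5)]))
        np.testing.assert_allclose(prs.scores, [0, 0.5, 1.0])

    def test_effect_allele_flip(self):
        cohort = make_cohort([[2]], [1])  # dosage of a1 (A) is 2
        prs = compute_prs(cohort, ScoreFile.from_records([("rs1", "G", 1.0)]))
        assert prs.scores[0] == 0.0  # effect allele G: flipped dosage 0

    def test_plink_parity_frozen_oracle(self):
        cohort, scores = oracle_toy_cohort()
        expected = pd.read_csv(DATA / "score_oracle_synthetic.tsv", sep="\t", comment="#")
        prs = compute_prs(cohort, scores, mode="average", missing="mean_impute")
        np.testing.assert_allclose(prs.scores, expected["expected_average_score"], atol=1e-12)

    def test_additivity_sum_mode(self):
        rng = np.random.default_rng(0)
        cohort = make_cohort(rng.integers(0, 3, (20, 6)), rng.integers(0, 2, 20))
        betas = rng.normal(0, 0.5, 6)
        all6 = ScoreFile.from_records([(f"rs{j + 1}", "A", betas[j]) for j in range(6)])
        first = ScoreFile.from_records([(f"rs{j + 1}", "A", betas[j]) for j in range(3)])
        last = ScoreFile.from_records([(f"rs{j + 1}", "A", betas[j]) for j in range(3, 6)])
        s = compute_prs(cohort, all6).scores
        np.testing.assert_allclose(s, compute_prs(cohort, first).scores + compute_prs(cohort, last).scores)

    def test_unmatchable_allele_excluded(self):
        cohort = make_cohort([[1, 1]], [1])
        scores = ScoreFile.from_records([("rs1", "T", 1.0), ("rs2", "A", 2.0)])
        prs = compute_prs(cohort, scores)  # rs1 alleles are A/G: excluded
        assert prs.scores[0] == 2.0
        assert prs.table.loc[0, "n_snps_used"] == 1

    def test_zero_usable_snps_errors(self):
        cohort = make_cohort([[1]], [1])
        with pytest.raises(ValueError):
            compute_prs(cohort, ScoreFile.from_records([("rsZ", "A", 1.0)]))


class TestAllelicAssoc:
    def test_null_table(self):
        # identical allele frequencies: 1 het each in cases and controls
        cohort = make_cohort([[1], [1]], [0, 1])
        chi2, p, direction = allelic_assoc(cohort, "rs1")
        assert chi2 == 0.0 and p == 1.0 and direction == 0

    def test_known_2x2(self):
        # cases 30 A / 10 a; controls 10 A / 30 a -> chi2 = 20 on 80 alleles
        d = np.r_[np.repeat(2, 15), np.repeat(1, 0), np.repeat(0, 5), np.repeat(2, 5), np.repeat(0, 15)]
        y = np.r_[np.ones(20), np.zeros(20)]
        cohort = make_cohort(d[:, None], y)
        chi2, p, direction = allelic_assoc(cohort, "rs1")
        assert chi2 == pytest.approx(20.0)
        assert p == pytest.approx(float(sps.chi2.sf(20.0, 1)))
        assert direction == 1

    def test_exhaustive_small_margins(self):
        # every 2x2 allele table with margins <= 20 vs the textbook formula
        def textbook(a, b, c, d):
            n = a + b + c + d
            num = n * (a * d - b * c) ** 2
            den = (a + b) * (c + d) * (a + c) * (b + d)
            return num / den if den else 0.0

        from clumprs.scoring_stats import _chi2_2x2

        for a in range(0, 11):
            for b in range(0, 11):
                for c in range(0, 11):
                    for d in range(0, 11):
                        if a + b > 20 or c + d > 20 or a + b == 0 or c + d == 0:
                            continue
                        chi2, _, _ = _chi2_2x2(np.array([[a, b], [c, d]], dtype=float))
                        assert chi2 == pytest.approx(textbook(a, b, c, d), abs=1e-9)

    def test_vectorized_matches_scalar(self):
        rng = np.random.default_rng(2)
        cohort = make_cohort(rng.integers(0, 3, (50, 8)), rng.integers(0, 2, 50))
        many = allelic_assoc_many(cohort, [f"rs{j + 1}" for j in range(8)])
        for j in range(8):
            chi2, p, direction = allelic_assoc(cohort, f"rs{j + 1}")
            assert many.loc[j, "chi2"] == pytest.approx(chi2, abs=1e-10)
            assert many.loc[j, "p"] == pytest.approx(p, abs=1e-10)
            assert many.loc[j, "direction"] == direction

    def test_planted_shift_detected(self):
        hits = 0
        for seed in range(30):
            rng = np.random.default_rng(seed)
            case = rng.binomial(2, 0.45, 1000)
            ctrl = rng.binomial(2, 0.30, 1000)
            cohort = make_cohort(np.r_[case, ctrl][:, None], np.r_[np.ones(1000), np.zeros(1000)])
            _, p, direction = allelic_assoc(cohort, "rs1")
            hits += p < 1e-4 and direction == 1
        assert hits >= 29  # >= 95% power at n = 2000, shift 0.15


class TestLogisticFit:
    def test_separation_flagged(self):
        scores = np.r_[np.zeros(5), np.ones(5)]
        y = np.r_[np.zeros(5), np.ones(5)]
        beta, p, sep = logistic_fit(scores, y)
        assert sep and np.isnan(p)
        assert is_separated(scores, y)

    def test_constant_scores_error(self):
        with pytest.raises(ValueError):
            logistic_fit(np.ones(10), np.r_[np.zeros(5), np.ones(5)])

    def test_slope_recovery(self):
        est = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            x = rng.normal(0, 1, 2000)
            pr = 1 / (1 + np.exp(-(0.3 + 1.5 * x)))
            y = rng.random(2000) < pr
            beta, p, sep = logistic_fit(x, y.astype(int))
            assert not sep and p < 1e-10
            est.append(beta)
        assert abs(np.median(est) - 1.5) < 0.2

    def test_type_one_error_calibrated(self):
        rejections = 0
        n_seeds = 200
        for seed in range(n_seeds):
            rng = np.random.default_rng(10_000 + seed)
            x = rng.normal(0, 1, 500)
            y = rng.integers(0, 2, 500)
            _, p, sep = logistic_fit(x, y)
            rejections += (not sep) and p < 0.05
        assert 0.02 <= rejections / n_seeds <= 0.08


class TestAuc:
    def test_perfect_separation(self):
        assert auc(np.array([3, 4, 1, 2]), np.array([1, 1, 0, 0])) == 1.0

    def test_all_ties(self):
        assert auc(np.ones(6), np.array([1, 1, 1, 0, 0, 0])) == 0.5

    def test_known_pairs(self):
        # cases (3,1), controls (2,0): wins 3>2,3>0,1>0; loss 1<2 -> 3/4
        assert auc(np.array([3, 1, 2, 0]), np.array([1, 1, 0, 0])) == pytest.approx(0.75)

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_all_pairs_counting(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 31))
        y = np.r_[np.ones(n // 2), np.zeros(n - n // 2)].astype(int)
        s = rng.choice(np.arange(10.0), size=n)  # ties likely
        wins = sum(
            1.0 if sc > st else 0.5 if sc == st else 0.0
            for sc in s[y == 1]
            for st in s[y == 0]
        )
        assert auc(s, y) == pytest.approx(wins / ((y == 1).sum() * (y == 0).sum()), abs=1e-12)

    def test_matches_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(4)
        y = rng.integers(0, 2, 200)
        s = rng.normal(size=200) + y
        assert auc(s, y) == pytest.approx(roc_auc_score(y, s), abs=1e-12)

    def test_complement_and_monotone_invariance(self):
        rng = np.random.default_rng(5)
        y = rng.integers(0, 2, 100)
        s = rng.normal(size=100)  # continuous: tie-free
        assert auc(s, y) + auc(-s, y) == pytest.approx(1.0, abs=1e-12)
        assert auc(np.exp(2 * s), y) == pytest.approx(auc(s, y), abs=1e-12)
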
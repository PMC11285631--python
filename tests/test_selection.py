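"""Threshold models, the two-pass forward selection, and commonality."""

import numpy as np
import pandas as pd
import pytest

from clumprs.formats_io import ScoreFile
from clumprs.harmonize import ClumpPanel, build_panel
from clumprs.scoring_stats import auc, compute_prs
from clumprs.selection import (
    PDTrace,
    ThresholdGrid,
    apply_model,
    commonality,
    pd_first_pass,
    pd_second_pass,
    perfect_discrimination,
    threshold_models,
)
from clumprs.simulate import CohortSpec, SimConfig, simulate_family

from conftest import make_cohort


def make_panel(records, cohort_id="toy"):
    """records: (clump_id, snp_id, effect_allele, beta, base_p)"""
    entries = pd.DataFrame(
        [
            {
                "clump_id": cid,
                "snp_id": s,
                "effect_allele": ea,
                "beta": b,
                "base_p": p,
                "is_index": True,
                "is_alternative": False,
            }
            for cid, s, ea, b, p in records
        ]
    ).set_index("clump_id")
    return ClumpPanel(cohort_id, entries)


def separating_cohort():
    """rs1 alone separates cases from controls; rs2 is noise."""
    d = np.array([[2, 1], [2, 0], [2, 1], [0, 1], [0, 0], [0, 1]], dtype=np.int8)
    return make_cohort(d, [1, 1, 1, 0, 0, 0])


class TestThresholdGrid:
    def test_snap_up(self):
        g = ThresholdGrid(start=5e-8, stop=1.0, step=1e-6)
        assert g.snap_up(1e-9) == 5e-8
        assert g.snap_up(5e-8) == 5e-8
        t = g.snap_up(3.4e-4)
        assert t >= 3.4e-4 and t - 3.4e-4 <= 1e-6
        assert g.snap_up(2.0) is None

    def test_invalid(self):
        with pytest.raises(ValueError):
            ThresholdGrid(start=0.5, stop=0.1)


class TestThresholdModels:
    def test_distinct_sets_counted_once(self):
        cohort = separating_cohort()
        panel = make_panel(
            [(1, "rs1", "A", 0.5, 1e-9), (2, "rs2", "A", 0.1, 1e-4)]
        )
        evals, best = threshold_models(cohort, panel)
        # two distinct base p values -> exactly two models (sizes 1 and 2)
        assert list(evals["n_snps"]) == [1, 2]
        assert best is not None and len(best) in (1, 2)

    def test_grid_excludes_high_p(self):
        cohort = separating_cohort()
        panel = make_panel([(1, "rs1", "A", 0.5, 1e-9), (2, "rs2", "A", 0.1, 0.5)])
        evals, _ = threshold_models(cohort, panel, ThresholdGrid(stop=1e-3))
        assert list(evals["n_snps"]) == [1]

    def test_causal_set_recovered(self):
        """Best threshold model keeps the strongly-associated low-p clumps."""
        recovered = []
        for seed in range(5):
            cfg = SimConfig(
                seed=seed, n_clumps=100, snps_per_clump=(1, 1), n_causal_shared=10,
                n_causal_private_per_cohort=0, missing_rate=0.0,
                cohorts=[CohortSpec(150, 150, 1.0)],
            )
            fam = simulate_family(cfg)
            panel = build_panel(fam.cohorts[0], fam.truth.tags(), fam.stats, fam.truth.clump_table())
            _, best = threshold_models(fam.cohorts[0], panel)
            chosen = {fam.truth.clump_of_snp[s] for s in best.table["snp_id"]}
            recovered.append(len(chosen & fam.truth.causal_shared))
        assert np.median(recovered) >= 8


class TestPDPasses:
    def test_single_snp_baseline(self):
        cohort = separating_cohort()
        panel = make_panel([(1, "rs1", "A", 0.5, 1e-9)])
        first = pd_first_pass(cohort, panel)
        assert len(first.steps) == 1
        assert first.steps.loc[0, "delta_direction"] == "increase"  # vs empty-model 0.5
        assert first.steps.loc[0, "auc_after"] == 1.0

    def test_second_pass_single_separating_snp(self):
        cohort = separating_cohort()
        panel = make_panel([(1, "rs1", "A", 0.5, 1e-9), (2, "rs2", "A", 0.1, 0.5)])
        trace = perfect_discrimination(cohort, panel)
        assert trace.perfect_reached
        assert trace.contributing_set == {1}
        assert trace.final_auc == 1.0

    def test_all_decrease_empty_model(self):
        # protective-coded beta on a risk allele: the only addition lowers AUC
        d = np.array([[2], [2], [0], [0]], dtype=np.int8)
        cohort = make_cohort(d, [1, 1, 0, 0])
        panel = make_panel([(1, "rs1", "A", -0.5, 0.5)])
        first = pd_first_pass(cohort, panel)
        assert set(first.steps["delta_direction"]) == {"decrease"}
        trace = pd_second_pass(cohort, panel, first)
        assert not trace.perfect_reached and trace.contributing_set == set()
        assert trace.final_auc == 0.5

    def test_incremental_equals_from_scratch(self):
        """Every step's AUC must equal rescoring the prefix from scratch."""
        cfg = SimConfig(
            seed=3, n_clumps=60, snps_per_clump=(1, 2), n_causal_shared=6,
            n_causal_private_per_cohort=0, cohorts=[CohortSpec(30, 30, 1.0)],
        )
        fam = simulate_family(cfg)
        cohort = fam.cohorts[0]
        panel = build_panel(cohort, fam.truth.tags(), fam.stats, fam.truth.clump_table())
        first = pd_first_pass(cohort, panel)
        meta = panel.entries.reset_index().set_index("snp_id")
        ev = cohort.evaluable
        for k in (1, len(first.steps) // 2, len(first.steps)):
            prefix = first.steps.iloc[:k]
            sf = ScoreFile(
                meta.loc[list(prefix["snp_id"])][["effect_allele", "beta"]]
                .reset_index()[["snp_id", "effect_allele", "beta"]]
            )
            prs = compute_prs(cohort, sf, mode="sum", missing="mean_impute")
            scratch = auc(prs.scores[ev], cohort.phenotype[ev])
            assert first.steps.loc[k - 1, "auc_after"] == pytest.approx(scratch, abs=1e-12)

    def test_perfect_certificate(self):
        """When perfect_reached, min case score strictly exceeds max control score."""
        cfg = SimConfig(
            seed=5, n_clumps=2500, snps_per_clump=(1, 1), n_causal_shared=10,
            n_causal_private_per_cohort=0, missing_rate=0.0,
            cohorts=[CohortSpec(25, 25, 1.0)],
        )
        fam = simulate_family(cfg)
        cohort = fam.cohorts[0]
        panel = build_panel(cohort, fam.truth.tags(), fam.stats, fam.truth.clump_table())
        trace = perfect_discrimination(cohort, panel)
        assert trace.perfect_reached
        meta = panel.entries.reset_index().set_index("snp_id")
        used = trace.steps.iloc[: len(trace.steps[trace.steps["auc_after"] < 1.0]) + 1]
        sf = ScoreFile(
            meta.loc[list(used["snp_id"])][["effect_allele", "beta"]]
            .reset_index()[["snp_id", "effect_allele", "beta"]]
        )
        prs = compute_prs(cohort, sf)
        s, y = prs.scores, cohort.phenotype
        assert s[y == 1].min() > s[y == 0].max()

    def test_trace_deterministic(self):
        cfg = SimConfig(
            seed=9, n_clumps=50, snps_per_clump=(1, 2), n_causal_shared=5,
            n_causal_private_per_cohort=0, cohorts=[CohortSpec(20, 20, 1.0)],
        )
        fam1, fam2 = simulate_family(cfg), simulate_family(cfg)
        tr = []
        for fam in (fam1, fam2):
            panel = build_panel(fam.cohorts[0], fam.truth.tags(), fam.stats, fam.truth.clump_table())
            tr.append(perfect_discrimination(fam.cohorts[0], panel))
        pd.testing.assert_frame_equal(tr[0].steps, tr[1].steps)
        assert tr[0].contributing_set == tr[1].contributing_set


class TestCommonality:
    def _trace(self, contrib, cohort_id="c"):
        return PDTrace(cohort_id=cohort_id, steps=pd.DataFrame(), contributing_set=set(contrib))

    def test_basic_tally(self):
        traces = [self._trace({1, 2}), self._trace({2, 3}), self._trace({2, 4})]
        assert commonality(traces, 2).clump_ids == {2}

    def test_identical_sets_idempotent(self):
        traces = [self._trace({1, 2, 3}) for _ in range(4)]
        assert commonality(traces, 4).clump_ids == {1, 2, 3}

    def test_k_bounds(self):
        traces = [self._trace({1}), self._trace({1})]
        with pytest.raises(ValueError):
            commonality(traces, 3)
        with pytest.raises(ValueError):
            commonality(traces, 1)

    def test_stringent_subset_of_lenient(self):
        rng = np.random.default_rng(0)
        traces = [self._trace(set(rng.choice(50, 20, replace=False))) for _ in range(5)]
        assert commonality(traces, 3).clump_ids <= commonality(traces, 2).clump_ids


class TestApplyModel:
    def test_self_consistency_with_trace(self):
        cohort = separating_cohort()
        panel = make_panel([(1, "rs1", "A", 0.5, 1e-9), (2, "rs2", "A", 0.1, 0.5)])
        trace = perfect_discrimination(cohort, panel)
        model = commonality([trace, trace], 2, panels=[panel])
        ev, _ = apply_model(model, cohort, panel)
        assert ev.auc == pytest.approx(trace.final_auc)

    def test_missing_clumps_counted(self):
        cohort = separating_cohort()
        panel = make_panel([(1, "rs1", "A", 0.5, 1e-9)])
        model = commonality([self._t({1, 7}), self._t({1, 7})], 2)
        ev, _ = apply_model(model, cohort, panel)
        assert ev.n_snps == 1 and ev.n_missing_clumps == 1

    def test_no_representable_clump_errors(self):
        cohort = separating_cohort()
        panel = make_panel([(1, "rs1", "A", 0.5, 1e-9)])
        model = commonality([self._t({9}), self._t({9})], 2)
        with pytest.raises(ValueError):
            apply_model(model, cohort, panel)

    @staticmethod
    def _t(contrib):
        return PDTrace(cohort_id="c", steps=pd.DataFrame(), contributing_set=set(contrib))
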
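import dataclasses

import numpy as np
import pandas as pd
import pytest

from seroscreen import (CohortConfig, SelectionCriteria, generate_cohort,
                        call_seropositive, detect_cutoffs, score_matrix,
                        select_associations, screen_pairs,
                        characterize_positives, prevalence_ratio)
from seroscreen.cutoffs import CutoffRecord, SeroCallSet

from conftest import small_config
from oracles import bh_enum


def callset_from(frame: pd.DataFrame) -> SeroCallSet:
    recs = [CutoffRecord(antigen_id=a, peak_x=0.0, direction="up", cutoff=0.1)
            for a in frame.columns]
    return SeroCallSet(cutoffs=recs, calls=frame)


class TestCriteria:
    def test_invalid_criteria_rejected(self):
        with pytest.raises(ValueError):
            SelectionCriteria(min_positives=0)
        with pytest.raises(ValueError):
            SelectionCriteria(min_prevalence_ratio=1.0)

    def test_group_size_gate_excludes_small_groups(self):
        # a perfect association carried by only 9 positives is never emitted
        n = 200
        ids = [f"i{k}" for k in range(n)]
        calls = pd.DataFrame({"ag": [1] * 9 + [0] * (n - 9)}, index=ids)
        clin = pd.DataFrame({"sym_0": [1] * 9 + [0] * (n - 9)}, index=ids)
        recs = select_associations(callset_from(calls), clin, ["sym_0"])
        assert recs == []

    def test_prevalence_ratio_reading_vs_difference_reading(self):
        # p_pos=0.90, p_neg=0.80: ratio 1.125 fails the ratio reading but a
        # 10-point difference also fails the difference reading; p_neg=0.60
        # passes both
        n = 400
        ids = [f"i{k}" for k in range(n)]
        calls = pd.DataFrame({"ag": [1] * 40 + [0] * 360}, index=ids)
        sx = np.concatenate([np.ones(36), np.zeros(4),
                             np.ones(216), np.zeros(144)])  # 0.9 vs 0.6
        clin = pd.DataFrame({"sym_0": sx}, index=ids)
        for mode in ("ratio", "difference"):
            crit = SelectionCriteria(ratio_mode=mode)
            recs = select_associations(callset_from(calls), clin, ["sym_0"],
                                       crit)
            assert [r.antigen_id for r in recs] == ["ag"]

    def test_tightening_criteria_never_adds_records(self, cohort, calls):
        base = SelectionCriteria()
        loose = select_associations(calls, cohort.clinical,
                                    cohort.symptom_columns, base)
        for tighter in (dataclasses.replace(base, min_positives=15),
                        dataclasses.replace(base, min_prevalence_pos=0.9),
                        dataclasses.replace(base, min_prevalence_ratio=1.6),
                        dataclasses.replace(base, alpha_fdr=0.01)):
            tight = select_associations(calls, cohort.clinical,
                                        cohort.symptom_columns, tighter)
            assert {(r.antigen_id, r.symptom_id) for r in tight} <= \
                   {(r.antigen_id, r.symptom_id) for r in loose}


class TestScreen:
    def test_bh_family_is_group_size_survivors(self, cohort, calls):
        tested = screen_pairs(calls, cohort.clinical, cohort.symptom_columns)
        npos = calls.n_positive
        assert all(npos[t["antigen"]] >= 10 for t in tested)
        assert np.allclose([t["q"] for t in tested],
                           bh_enum([t["p"] for t in tested]))

    def test_constant_symptom_skipped(self, calls, cohort):
        clin = cohort.clinical.copy()
        clin["sym_000"] = 1.0
        tested = screen_pairs(calls, clin, ["sym_000"])
        assert tested == []

    def test_pr_or_consistency(self, cohort, calls):
        recs = select_associations(calls, cohort.clinical,
                                   cohort.symptom_columns)
        for r in recs:
            assert (r.pr > 1) == (r.or_est > 1)
            assert r.q >= r.p - 1e-12


class TestEndToEnd:
    def test_planted_pairs_recovered_exactly(self, cohort, calls):
        recs = select_associations(calls, cohort.clinical,
                                   cohort.symptom_columns)
        assert {(r.antigen_id, r.symptom_id) for r in recs} == \
            set(cohort.planted_pairs)
        for r in recs:
            assert r.n_pos >= 10
            assert r.p_sx_pos >= 0.85
            assert prevalence_ratio(r.p_sx_pos, r.p_sx_neg) >= 1.25
            assert r.q < 0.05

    def test_null_cohort_yields_no_records(self):
        cfg = small_config(n_planted=0, seed=21)
        cohort = generate_cohort(cfg)
        sm = score_matrix(cohort.mfi)
        calls = call_seropositive(sm, detect_cutoffs(sm))
        recs = select_associations(calls, cohort.clinical,
                                   cohort.symptom_columns)
        assert recs == []


class TestCharacterizePositives:
    def test_cytokines_and_clinical_tested_without_correction(self, cohort,
                                                              calls):
        recs = select_associations(calls, cohort.clinical,
                                   cohort.symptom_columns)
        frame = characterize_positives(recs[0], calls, cohort.clinical,
                                       ["female", "IL4", "IL6"])
        assert set(frame.variable) == {"female", "IL4", "IL6"}
        assert "q" not in frame.columns
        assert ((frame.ci_low <= frame.odds_ratio) |
                frame.odds_ratio.isna()).all()
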
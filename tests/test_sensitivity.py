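import numpy as np
import pytest

from seroscreen import (BaselineRun, SelectionCriteria, SensitivityGrid,
                        default_grids, run_sensitivity, select_associations)
from seroscreen.synthetic import CYTOKINES, CLINICAL_VARS


@pytest.fixture(scope="module")
def baseline(cohort, scored, calls):
    records = select_associations(calls, cohort.clinical,
                                  cohort.symptom_columns)
    cuts = calls.cutoffs
    return BaselineRun(score_matrix=scored, cutoffs=cuts, calls=calls,
                       clinical=cohort.clinical,
                       symptoms=cohort.symptom_columns,
                       strata_variables=list(CLINICAL_VARS) + list(CYTOKINES),
                       records=records)


class TestGrids:
    def test_grid_must_contain_baseline(self):
        with pytest.raises(ValueError):
            SensitivityGrid("min_positives", [5, 15], 10)

    def test_default_grids_are_one_at_a_time(self, baseline):
        grids = default_grids(baseline)
        names = [g.parameter for g in grids]
        assert len(names) == len(set(names))
        for g in grids:
            assert any(SensitivityGrid._eq(v, g.baseline) for v in g.values)


class TestRun:
    def test_baseline_only_grid_reproduces_baseline(self, baseline):
        grids = [SensitivityGrid("min_positives", [10], 10)]
        report = run_sensitivity(baseline, grids)
        assoc = report.table[report.table.finding_type == "association"]
        assert len(assoc) == len(baseline.records)
        assert bool(assoc.retained.all())
        by = {f"{r.antigen_id}:{r.symptom_id}": r for r in baseline.records}
        for row in assoc.itertuples():
            assert row.p == pytest.approx(by[row.finding].p)
            assert row.q == pytest.approx(by[row.finding].q)

    def test_planted_findings_retained_at_criteria_neighbors(self, baseline):
        # planted margins (>=12 positives, 95% prevalence, PR 2) sit well
        # inside the default one-step criteria neighborhoods.  Cutoff
        # offsets are a different matter: lowering every cutoff one step
        # floods groups with background and may legitimately lose findings,
        # so only the mechanics are checked there.
        grids = [g for g in default_grids(baseline)
                 if g.parameter in ("min_positives", "min_prevalence_pos",
                                    "min_prevalence_ratio")]
        report = run_sensitivity(baseline, grids)
        assoc = report.table[report.table.finding_type == "association"]
        assert (assoc.retained == True).all()  # noqa: E712

    def test_cutoff_offset_grid_evaluates_without_crash(self, baseline):
        grids = [SensitivityGrid("cutoff_offset", [-1, 0, 1], 0)]
        report = run_sensitivity(baseline, grids)
        assoc = report.table[report.table.finding_type == "association"]
        assert len(assoc) == 3 * len(baseline.records)
        base = assoc[assoc.is_baseline]
        assert bool(base.retained.all())

    def test_boundary_association_lost_when_tightened(self, baseline):
        # a finding whose group size is exactly 12 dies at min_positives=15
        sizes = {f"{r.antigen_id}:{r.symptom_id}": r.n_pos
                 for r in baseline.records}
        grid = [SensitivityGrid("min_positives",
                                [10, int(max(sizes.values())) + 1],
                                10)]
        report = run_sensitivity(baseline, grid)
        tightened = report.table[(report.table.finding_type == "association")
                                 & (~report.table.is_baseline)]
        assert not tightened.retained.any()

    def test_each_column_varies_one_parameter(self, baseline):
        report = run_sensitivity(baseline, default_grids(baseline))
        for (param, value), grp in report.table.groupby(
                ["parameter", "grid_value"]):
            assert (grp.parameter == param).all()
        base_rows = report.table[report.table.is_baseline]
        # the baseline point appears once per grid for every finding
        per_grid = base_rows.groupby(["parameter", "finding"]).size()
        assert (per_grid == 1).all()

    def test_monotone_retention_along_stringency(self, baseline):
        grids = [SensitivityGrid("min_prevalence_pos",
                                 [0.80, 0.85, 0.90, 0.97], 0.85)]
        report = run_sensitivity(baseline, grids)
        assoc = report.table[report.table.finding_type == "association"]
        for _, grp in assoc.groupby("finding"):
            ordered = grp.assign(v=grp.grid_value.astype(float)) \
                         .sort_values("v").retained.tolist()
            # once lost under tightening, never regained
            seen_false = False
            for r in ordered:
                if not r:
                    seen_false = True
                else:
                    assert not seen_false

    def test_summary_partitions_findings(self, baseline):
        report = run_sensitivity(baseline, default_grids(baseline))
        s = report.summary()
        all_findings = set(report.table.finding)
        assert set(s["robust"]) | set(s["fragile"]) == all_findings
        assert set(s["robust"]) & set(s["fragile"]) == set()
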
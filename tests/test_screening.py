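"""Triage, FIT reflex and screening-yield metrics."""

import math

import numpy as np
import pandas as pd
import pytest

from crcrisk import (
    PRESET_RULES,
    TriageRule,
    compare_scenarios,
    evaluate_yield,
    reference_cohort,
    resolve_fit_reflex,
    triage,
)
from crcrisk.errors import ConfigError, DataError, TriageError, UndefinedYieldError

CELLS = [
    ("favorable", "lower"),
    ("favorable", "higher"),
    ("unfavorable", "lower"),
    ("unfavorable", "higher"),
]


def _groups(cells):
    ls = pd.Series([c[0] for c in cells])
    prs = pd.Series([c[1] for c in cells])
    return ls, prs


class TestTriage:
    def test_all_high_sends_everyone_to_colonoscopy(self):
        ls, prs = _groups(CELLS)
        out = triage(ls, prs, PRESET_RULES["all_high"])
        assert (out == "colonoscopy").all()

    def test_both_high_selects_exactly_one_cell(self):
        ls, prs = _groups(CELLS)
        out = triage(ls, prs, PRESET_RULES["both_high"])
        assert out.tolist() == ["fit", "fit", "fit", "colonoscopy"]

    def test_preset_truth_tables(self):
        ls, prs = _groups(CELLS)
        assert triage(ls, prs, PRESET_RULES["either_high"]).tolist() == [
            "fit", "colonoscopy", "colonoscopy", "colonoscopy",
        ]
        assert triage(ls, prs, PRESET_RULES["ls_only"]).tolist() == [
            "fit", "fit", "colonoscopy", "colonoscopy",
        ]

    def test_missing_group_raises_with_subject(self):
        ls = pd.Series(["favorable", None], index=["a", "b"])
        prs = pd.Series(["lower", "lower"], index=["a", "b"])
        with pytest.raises(TriageError, match="b"):
            triage(ls, prs, PRESET_RULES["both_high"])

    def test_empty_cohort_gives_empty_assignment(self):
        ls, prs = pd.Series(dtype=object), pd.Series(dtype=object)
        out = triage(ls, prs, PRESET_RULES["both_high"])
        assert len(out) == 0

    def test_incomplete_rule_rejected(self):
        with pytest.raises(ValueError):
            TriageRule("partial", {("favorable", "lower"): "low"})


class TestFitReflex:
    def test_all_negative_leaves_high_arm_only(self):
        assignment = pd.Series(["colonoscopy", "fit", "fit"])
        fit = pd.Series([False, False, False])
        final = resolve_fit_reflex(assignment, fit_positive=fit)
        assert final.tolist() == [True, False, False]

    def test_threshold_boundary_included(self):
        assignment = pd.Series(["fit", "fit", "fit"])
        values = pd.Series([99.9, 100.0, 150.0])
        final = resolve_fit_reflex(assignment, fit_value=values)
        assert final.tolist() == [False, True, True]

    def test_all_positive_scopes_everyone(self):
        assignment = pd.Series(["fit"] * 4)
        final = resolve_fit_reflex(assignment, fit_positive=pd.Series([True] * 4))
        assert final.all()

    def test_missing_fit_in_fit_arm_raises(self):
        assignment = pd.Series(["fit", "colonoscopy"])
        fit = pd.Series([np.nan, np.nan])
        with pytest.raises(DataError):
            resolve_fit_reflex(assignment, fit_positive=fit)


class TestEvaluateYield:
    def test_reference_cohort_colonoscopy_only_yield(self):
        sub = reference_cohort(seed=0).subjects
        everyone = pd.Series(True, index=sub.index)
        report = evaluate_yield(everyone, sub["outcome"], "colonoscopy_only")
        shown = report.rounded()
        assert shown["ppv_advanced_pct"] == 10.8
        assert shown["nns_advanced"] == 9.3
        assert shown["nns_any"] == 2.8

    def test_all_controls_yield_zero_ppv_and_infinite_nns(self):
        outcome = pd.Series(["control"] * 10)
        mask = pd.Series([True] * 10)
        report = evaluate_yield(mask, outcome)
        assert report.ppv_any == 0.0
        assert math.isinf(report.nns_any)
        assert report.zero_detections

    def test_zero_colonoscopies_is_an_error(self):
        outcome = pd.Series(["control"] * 5)
        with pytest.raises(UndefinedYieldError):
            evaluate_yield(pd.Series([False] * 5), outcome)

    def test_nns_is_reciprocal_of_ppv(self):
        sub = reference_cohort(seed=3).subjects
        mask = pd.Series(True, index=sub.index)
        r = evaluate_yield(mask, sub["outcome"])
        assert r.nns_advanced * r.ppv_advanced == pytest.approx(1.0, rel=1e-12)
        assert r.nns_any * r.ppv_any == pytest.approx(1.0, rel=1e-12)

    def test_order_invariance(self):
        sub = reference_cohort(seed=4).subjects
        mask = sub["fit_positive"]
        shuffled = sub.sample(frac=1.0, random_state=1)
        a = evaluate_yield(mask, sub["outcome"])
        b = evaluate_yield(mask.reindex(shuffled.index), shuffled["outcome"])
        assert a.ppv_advanced == b.ppv_advanced
        assert a.n_colonoscopies == b.n_colonoscopies


@pytest.fixture(scope="module")
def scored_cohort():
    from crcrisk import categorize, lifestyle_scores, prs_scores
    from crcrisk.cohort import CohortConfig, default_panel, simulate_subjects
    from crcrisk.scores import estimate_lifestyle_weights

    specs = default_panel(n_snps=19, n_out_of_hwe=0, seed=30)
    cohort = simulate_subjects(CohortConfig(n_subjects=4000, seed=31), specs)
    sub = cohort.subjects
    prs = prs_scores(cohort.genotypes, specs)
    ls = lifestyle_scores(sub, estimate_lifestyle_weights(sub))
    ls_group = categorize(ls, "sex_median", sex=sub["sex"])
    prs_group = categorize(prs, "percentile_90")
    return sub, ls_group, prs_group


class TestCompareScenarios:

    def test_all_high_matches_reference(self, scored_cohort):
        sub, ls_group, prs_group = scored_cohort
        reports = compare_scenarios(sub, ls_group, prs_group, [PRESET_RULES["all_high"]])
        ref, allhigh = reports
        assert ref.n_colonoscopies == allhigh.n_colonoscopies == len(sub)
        assert ref.ppv_advanced == allhigh.ppv_advanced

    def test_risk_triage_enriches_ppv(self, scored_cohort):
        """Restricting colonoscopy to high-risk cells raises the PPV when the
        generator injects positive lifestyle and genetic effects."""
        sub, ls_group, prs_group = scored_cohort
        reports = compare_scenarios(
            sub, ls_group, prs_group, [PRESET_RULES["both_high"], PRESET_RULES["either_high"]]
        )
        ref = reports[0]
        both = reports[1]
        assert both.ppv_advanced >= ref.ppv_advanced
        assert both.n_colonoscopies < ref.n_colonoscopies

    def test_partition_conservation(self, scored_cohort):
        sub, ls_group, prs_group = scored_cohort
        rule = PRESET_RULES["both_high"]
        assignment = triage(ls_group, prs_group, rule)
        assert (assignment == "colonoscopy").sum() + (assignment == "fit").sum() == len(sub)
        final = resolve_fit_reflex(assignment, fit_positive=sub["fit_positive"])
        expected = (assignment == "colonoscopy").sum() + (
            (assignment == "fit") & sub["fit_positive"]
        ).sum()
        assert final.sum() == expected

    def test_colonoscopies_never_exceed_screened(self, scored_cohort):
        sub, ls_group, prs_group = scored_cohort
        reports = compare_scenarios(
            sub, ls_group, prs_group,
            [PRESET_RULES[k] for k in ("both_high", "either_high", "ls_only", "prs_only")],
        )
        assert all(r.n_colonoscopies <= r.n_screened for r in reports)

    def test_duplicate_labels_rejected(self, scored_cohort):
        sub, ls_group, prs_group = scored_cohort
        with pytest.raises(ConfigError):
            compare_scenarios(
                sub, ls_group, prs_group,
                [PRESET_RULES["both_high"], PRESET_RULES["both_high"]],
            )
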
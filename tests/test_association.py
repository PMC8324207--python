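"""Crude and model-based odds ratios; logistic-fit calibration."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import expit, logit

from crcrisk import ContingencyTable2x2, crude_or, fit_logistic, run_contrast_suite
from crcrisk.errors import AliasingError, ContinuityCorrectionWarning


class TestCrudeOr:
    def test_symmetric_table_gives_unity(self):
        r = crude_or(ContingencyTable2x2(10, 10, 10, 10))
        assert r.estimate == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "cells, expected",
        [
            # combined-exposure cells from a sex-stratified case-control table:
            # male any-neoplasm 38/22 vs 166/264; female non-advanced 17/27 vs 40/270
            ((38, 22, 166, 264), 38 * 264 / (22 * 166)),
            ((17, 27, 40, 270), 4.25),
        ],
    )
    def test_printed_count_recomputation(self, cells, expected):
        r = crude_or(ContingencyTable2x2(*cells))
        assert r.estimate == pytest.approx(expected, rel=1e-12)

    def test_zero_cell_continuity_correction(self):
        with pytest.warns(ContinuityCorrectionWarning):
            r = crude_or(ContingencyTable2x2(5, 0, 10, 20))
        assert np.isfinite(r.estimate) and r.ci_low > 0

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(cells=st.tuples(*[st.integers(1, 500)] * 4))
    def test_swapping_labels_inverts_or(self, cells):
        a, b, c, d = cells
        forward = crude_or(ContingencyTable2x2(a, b, c, d))
        swapped = crude_or(ContingencyTable2x2(b, a, d, c))
        assert swapped.estimate == pytest.approx(1 / forward.estimate, rel=1e-12)


class TestFitLogistic:
    def test_intercept_only_equals_logit_of_prevalence(self):
        y = np.array([1] * 30 + [0] * 70)
        fit = fit_logistic(pd.DataFrame(index=range(100)), y)
        assert fit.params["const"] == pytest.approx(logit(0.3), abs=1e-8)

    def test_agrees_with_crude_or_for_binary_covariate(self, rng):
        x = (rng.random(2000) < 0.4).astype(float)
        y = (rng.random(2000) < expit(-0.5 + 0.9 * x)).astype(int)
        fit = fit_logistic(pd.DataFrame({"x": x}), y)
        a = int(((x == 1) & (y == 1)).sum())
        b = int(((x == 1) & (y == 0)).sum())
        c = int(((x == 0) & (y == 1)).sum())
        d = int(((x == 0) & (y == 0)).sum())
        crude = crude_or(ContingencyTable2x2(a, b, c, d))
        assert np.exp(fit.params["x"]) == pytest.approx(crude.estimate, rel=1e-6)

    def test_null_covariate_is_not_signalled(self):
        violations = 0
        for seed in range(30):
            r = np.random.default_rng(seed)
            x = (r.random(10_000) < 0.5).astype(float)
            y = (r.random(10_000) < 0.3).astype(int)
            fit = fit_logistic(pd.DataFrame({"x": x}), y)
            if abs(fit.z_values["x"]) >= 3:
                violations += 1
        assert violations <= 1

    def test_injected_log_or_recovered_on_average(self):
        """Mean estimate over replicates within +/-0.02 of log 2."""
        estimates = []
        for seed in range(500):
            r = np.random.default_rng(seed)
            x = (r.random(10_000) < 0.5).astype(float)
            y = (r.random(10_000) < expit(-1.0 + np.log(2) * x)).astype(int)
            fit = fit_logistic(pd.DataFrame({"x": x}), y)
            estimates.append(fit.params["x"])
        assert abs(np.mean(estimates) - np.log(2)) < 0.02

    def test_ci_width_scales_with_replication(self, rng):
        x = (rng.random(400) < 0.5).astype(float)
        y = (rng.random(400) < expit(-0.3 + 0.5 * x)).astype(int)
        widths = []
        for reps in (1, 4, 16):
            xx = np.tile(x, reps)
            yy = np.tile(y, reps)
            fit = fit_logistic(pd.DataFrame({"x": xx}), yy)
            r = fit.result_for("x")
            widths.append(np.log(r.ci_high) - np.log(r.ci_low))
        # exact replication scales the information matrix linearly
        assert widths[0] > widths[1] > widths[2]
        assert widths[1] == pytest.approx(widths[0] / 2, rel=1e-6)
        assert widths[2] == pytest.approx(widths[0] / 4, rel=1e-6)

    def test_rank_deficiency_raises(self, rng):
        x = rng.random(100)
        X = pd.DataFrame({"a": x, "b": 2 * x})
        with pytest.raises(AliasingError):
            fit_logistic(X, (x > 0.5).astype(int))


@pytest.fixture(scope="module")
def suite(small_cohort):
    from crcrisk import categorize, lifestyle_scores, prs_scores
    from crcrisk.scores import estimate_lifestyle_weights

    sub = small_cohort.subjects
    prs = prs_scores(small_cohort.genotypes, small_cohort.specs)
    weights = estimate_lifestyle_weights(sub)
    ls = lifestyle_scores(sub, weights)
    ls_group = categorize(ls, "sex_median", sex=sub["sex"])
    prs_group = categorize(prs, "percentile_90")
    table = run_contrast_suite(sub, ls_group, prs_group)
    return sub, ls_group, prs_group, table


class TestContrastSuite:

    def test_reference_level_is_unity(self, suite):
        _, _, _, table = suite
        ref = table[table["exposure"] == "favorable_lower"]
        assert (ref["odds_ratio"] == 1.0).all()

    def test_counts_partition_each_contrast(self, suite):
        sub, _, _, table = suite
        any_male = table[(table["sex"] == "male") & (table["contrast"] == "any")]
        n_cases = any_male["n_cases"].sum()
        n_controls = any_male["n_controls"].sum()
        male = sub[sub["sex"] == "male"]
        assert n_cases == (male["outcome"] != "control").sum()
        assert n_controls == (male["outcome"] == "control").sum()

    def test_interaction_term_calibrated_under_null(self):
        """Null product-term Wald CI covers 0 at about the nominal rate."""
        from crcrisk.scores import LS_LABELS, PRS_LABELS

        covered = 0
        n_reps = 100
        for seed in range(n_reps):
            r = np.random.default_rng(seed)
            n = 4000
            ls = r.random(n) < 0.5
            prs = r.random(n) < 0.1
            # main effects only; no interaction
            p = expit(-1.0 + 0.5 * ls + 0.6 * prs)
            y = r.random(n) < p
            sub = pd.DataFrame(
                {
                    "sex": "male",
                    "age": 60.0,
                    "outcome": np.where(y, "non_advanced", "control"),
                }
            )
            ls_group = pd.Series(np.where(ls, LS_LABELS[1], LS_LABELS[0]), index=sub.index)
            prs_group = pd.Series(np.where(prs, PRS_LABELS[1], PRS_LABELS[0]), index=sub.index)
            table = run_contrast_suite(
                sub, ls_group, prs_group, contrasts=("any",), adjust=(), interaction=True
            )
            row = table[(table["sex"] == "male") & (table["exposure"] == "ls_x_prs")].iloc[0]
            if row["ci_low"] <= 1.0 <= row["ci_high"]:
                covered += 1
        assert 0.89 <= covered / n_reps <= 0.995

    def test_empty_cell_is_flagged(self):
        rng = np.random.default_rng(0)
        n = 400
        sub = pd.DataFrame(
            {
                "sex": "male",
                "age": rng.integers(50, 75, n).astype(float),
                "outcome": np.where(rng.random(n) < 0.3, "non_advanced", "control"),
            }
        )
        ls_group = pd.Series(["favorable"] * n)
        prs_group = pd.Series(
            np.where(rng.random(n) < 0.1, "higher", "lower")
        )
        table = run_contrast_suite(sub, ls_group, prs_group, contrasts=("any",))
        empties = table[(table["sex"] == "male") & table["empty_cell"]]
        assert set(empties["exposure"]) == {"unfavorable_lower", "unfavorable_higher"}
        assert empties["odds_ratio"].isna().all()
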
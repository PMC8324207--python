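"""Absolute-risk projection: closed form, calibration, bootstrap CIs."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracles import numeric_cuminc, random_rate_config
from crcrisk import (
    RateTable,
    RiskDistribution,
    attributable_risk,
    calibrate_baseline,
    default_rate_table,
    project_profile_table,
    project_risk,
)
from crcrisk.absolute_risk import cumulative_incidence
from crcrisk.errors import (
    CoverageError,
    InvalidDistributionError,
    UncertaintySpecError,
)


def flat_rates(incidence, mortality, start=50.0, end=80.0, n_bands=6, sex="male"):
    edges = np.linspace(start, end, n_bands + 1)
    return RateTable(
        sex=sex,
        age_start=edges[:-1],
        age_end=edges[1:],
        incidence=np.full(n_bands, incidence),
        mortality=np.full(n_bands, mortality),
    )


def simple_dist(prev, rr, se=None):
    frame = pd.DataFrame(
        {"profile": [f"g{i}" for i in range(len(prev))], "prevalence": prev, "rr": rr}
    )
    if se is not None:
        frame["se_log_rr"] = se
    return RiskDistribution(frame)


class TestCalibration:
    def test_single_reference_profile_is_identity(self):
        rates = flat_rates(0.01, 0.02)
        dist = simple_dist([1.0], [1.0])
        h1 = calibrate_baseline(rates, dist)
        np.testing.assert_allclose(h1.incidence, rates.incidence)

    def test_two_profile_halving(self):
        rates = flat_rates(0.01, 0.0)
        dist = simple_dist([0.5, 0.5], [1.0, 3.0])
        h1 = calibrate_baseline(rates, dist)
        np.testing.assert_allclose(h1.incidence, rates.incidence / 2)

    def test_calibration_identity_per_band(self, rng):
        rates = default_rate_table("male")
        prev = rng.dirichlet(np.ones(4))
        rr = np.concatenate([[1.0], rng.uniform(1.1, 3.5, 3)])
        dist = simple_dist(prev, rr)
        h1 = calibrate_baseline(rates, dist)
        mean_rr = float((prev * rr).sum())
        np.testing.assert_allclose(mean_rr * h1.incidence, rates.incidence, atol=1e-12)

    def test_attributable_risk_formula(self):
        dist = simple_dist([0.5, 0.5], [1.0, 3.0])
        assert attributable_risk(dist) == pytest.approx(0.5)

    def test_invalid_distributions_rejected(self):
        with pytest.raises(InvalidDistributionError):
            simple_dist([0.5, 0.4], [1.0, 2.0])  # prevalences don't sum to 1
        with pytest.raises(InvalidDistributionError):
            simple_dist([0.5, 0.5], [1.5, 2.0])  # no reference profile
        with pytest.raises(InvalidDistributionError):
            simple_dist([0.5, 0.5], [1.0, -2.0])


class TestProjectRisk:
    def test_pure_exponential_closed_form(self):
        rates = flat_rates(0.01, 0.0)
        risk = project_risk(50.0, 10.0, 1.0, rates)
        assert risk == pytest.approx(1 - np.exp(-0.1), abs=1e-12)

    def test_competing_risk_closed_form(self):
        rates = flat_rates(0.01, 0.02)
        risk = project_risk(50.0, 10.0, 1.0, rates)
        assert risk == pytest.approx((1 / 3) * (1 - np.exp(-0.3)), abs=1e-10)

    def test_vanishing_horizon(self):
        rates = flat_rates(0.01, 0.02)
        assert project_risk(50.0, 1e-9, 1.0, rates) < 1e-9

    def test_zero_total_hazard_limit(self):
        assert cumulative_incidence([0.0], [0.0], [10.0]) == 0.0

    def test_uncovered_interval_raises(self):
        rates = flat_rates(0.01, 0.0, start=50, end=60)
        with pytest.raises(CoverageError):
            project_risk(55.0, 10.0, 1.0, rates)

    def test_agrees_with_numeric_integration(self, rng):
        for _ in range(10):
            lam, mu, widths = random_rate_config(rng)
            closed = cumulative_incidence(lam, mu, widths)
            numeric = numeric_cuminc(lam, mu, widths)
            assert closed == pytest.approx(numeric, abs=1e-6)

    @settings(deadline=None, derandomize=True, max_examples=40)
    @given(
        lam=st.lists(st.floats(0, 0.05), min_size=1, max_size=5),
        mu=st.lists(st.floats(0, 0.08), min_size=1, max_size=5),
        rr=st.floats(0.2, 5.0),
    )
    def test_risk_bounded_and_monotone_in_rr(self, lam, mu, rr):
        k = min(len(lam), len(mu))
        lam, mu = np.array(lam[:k]), np.array(mu[:k])
        widths = np.full(k, 4.0)
        risk = cumulative_incidence(rr * lam, mu, widths)
        assert 0.0 <= risk <= 1.0
        assert risk <= cumulative_incidence(1.5 * rr * lam, mu, widths) + 1e-15

    def test_monotone_in_horizon_and_mortality(self):
        rates = default_rate_table("male")
        r5 = project_risk(50.0, 5.0, 2.0, rates)
        r10 = project_risk(50.0, 10.0, 2.0, rates)
        assert r10 > r5
        bumped = RateTable(
            sex="male",
            age_start=rates.age_start,
            age_end=rates.age_end,
            incidence=rates.incidence,
            mortality=rates.mortality + 0.01,
        )
        assert project_risk(50.0, 10.0, 2.0, bumped) < r10

    def test_band_refinement_invariance(self):
        rates = flat_rates(0.012, 0.03, start=50, end=70, n_bands=4)
        fine = flat_rates(0.012, 0.03, start=50, end=70, n_bands=8)
        a = project_risk(52.5, 12.0, 1.7, rates)
        b = project_risk(52.5, 12.0, 1.7, fine)
        assert a == pytest.approx(b, abs=1e-12)

    def test_prevalence_weighted_profiles_match_population(self, rng):
        """sum_g P_g risk_g tracks the uncalibrated population projection."""
        rates = default_rate_table("female")
        prev = np.array([0.55, 0.25, 0.15, 0.05])
        rr = np.array([1.0, 1.6, 2.1, 2.9])
        dist = simple_dist(prev, rr)
        h1 = calibrate_baseline(rates, dist)
        weighted = sum(
            p * project_risk(50.0, 10.0, r, h1) for p, r in zip(prev, rr)
        )
        population = project_risk(50.0, 10.0, 1.0, rates)
        assert population < 0.10
        assert abs(weighted - population) / population < 0.01


class TestProfileTable:
    def test_equal_rr_gives_identical_risks(self):
        rates = default_rate_table("male")
        dist = simple_dist([0.25] * 4, [1.0] * 4, se=[0.0] * 4)
        results = project_profile_table(50, 10, dist, rates, n_boot=100, seed=0)
        risks = {r.risk for r in results}
        assert len(risks) == 1

    def test_risks_ordered_with_rr(self):
        rates = default_rate_table("male")
        dist = simple_dist([0.4, 0.3, 0.2, 0.1], [1.0, 1.7, 2.0, 2.9], se=[0.05] * 4)
        results = project_profile_table(50, 10, dist, rates, n_boot=200, seed=1)
        risks = [r.risk for r in results]
        assert risks == sorted(risks)
        assert all(risks[i] < risks[i + 1] for i in range(3))

    def test_zero_se_collapses_ci(self):
        rates = default_rate_table("female")
        dist = simple_dist([0.6, 0.4], [1.0, 2.0], se=[0.0, 0.0])
        results = project_profile_table(50, 10, dist, rates, n_boot=500, seed=2)
        for r in results:
            assert r.ci_low == pytest.approx(r.risk, abs=1e-12)
            assert r.ci_high == pytest.approx(r.risk, abs=1e-12)

    def test_missing_se_raises(self):
        rates = default_rate_table("male")
        dist = simple_dist([0.6, 0.4], [1.0, 2.0])
        with pytest.raises(UncertaintySpecError):
            project_profile_table(50, 10, dist, rates)

    def test_age_specific_distribution(self):
        rates = default_rate_table("male")
        rows = []
        for s, e, mult in ((50.0, 65.0, 1.0), (65.0, 85.0, 1.3)):
            rows += [
                {"profile": "ref", "prevalence": 0.7, "rr": 1.0, "age_start": s, "age_end": e},
                {"profile": "hi", "prevalence": 0.3, "rr": 2.0 * mult, "age_start": s, "age_end": e},
            ]
        dist = RiskDistribution(pd.DataFrame(rows))
        h1 = calibrate_baseline(rates, dist)
        # young bands divided by 0.7+0.3*2=1.3; old bands by 0.7+0.3*2.6=1.48
        np.testing.assert_allclose(h1.incidence[:3], rates.incidence[:3] / 1.3)
        np.testing.assert_allclose(h1.incidence[3:], rates.incidence[3:] / 1.48)


class TestRateTableValidation:
    def test_gap_rejected(self):
        with pytest.raises(ValueError):
            RateTable("m", [50, 60], [55, 65], [0.01, 0.01], [0.0, 0.0])

    def test_negative_hazard_rejected(self):
        with pytest.raises(ValueError):
            RateTable("m", [50], [55], [-0.01], [0.0])
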
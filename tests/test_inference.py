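"""Descriptives, difference-in-differences, mixed models, power formula."""

import numpy as np
import pandas as pd
import pytest

from nutriscore_catering import inference as inf
from nutriscore_catering import reference as ref
from nutriscore_catering import synthetic_data as sd
from nutriscore_catering.errors import InestimableContrastError


def panel_from_cells(cell_means, reps=2, jitter=0.0, rng=None):
    """Balanced 2x2 panel hitting the given cell means exactly.

    Each (site, period) cell gets ``reps`` participants at mean +/- jitter,
    and every participant appears in both periods.
    """
    rows = []
    pid = 0
    for site, code in (("control", 0), ("intervention", 1)):
        for r in range(reps):
            delta = jitter * (1 if r % 2 == 0 else -1)
            for period in (0, 1):
                key = (site, "after" if period else "before")
                rows.append({"badge_id": f"p{pid}", "site": site,
                             "site_code": code, "period": period,
                             "time": float(period * 50 + r),
                             "intervention": code * period,
                             "y": cell_means[key] + delta})
            pid += 1
    return pd.DataFrame(rows)


class TestDescriptives:
    def test_participant_period_means_then_mean_and_sd(self):
        panel = pd.DataFrame({
            "badge_id": ["a", "a", "b"], "site": ["control"] * 3,
            "period": [0, 0, 0], "meal_fsam": [0.0, 2.0, 3.0]})
        out = inf.outcome_summary(panel, outcomes=("meal_fsam",))
        row = out.loc[("control", "before")]
        assert row["n_participants"] == 2
        assert row["meal_fsam_mean"] == pytest.approx(2.0)  # mean of {1, 3}
        assert row["meal_fsam_sd"] == pytest.approx(np.sqrt(2))

    def test_single_participant_cell_reports_missing_sd(self):
        panel = pd.DataFrame({
            "badge_id": ["a"], "site": ["control"], "period": [0],
            "meal_fsam": [1.5]})
        out = inf.outcome_summary(panel, outcomes=("meal_fsam",))
        assert np.isnan(out.loc[("control", "before"), "meal_fsam_sd"])

    def test_site_summary_meal_and_participant_accounting(self):
        meals = pd.DataFrame({
            "badge_id": ["a", "a", "b", "c"],
            "site": ["control"] * 3 + ["intervention"],
            "date": ["d1", "d2", "d1", "d1"],
            "n_products": [3, 4, 2, 5]})
        out = inf.site_summary(meals)
        assert out.loc["control", "n_meals"] == 3
        assert out.loc["control", "n_participants"] == 2
        assert out.loc["control", "meals_per_participant_mean"] == pytest.approx(1.5)

    def test_published_meals_per_participant_ratios(self):
        for site in ("intervention", "control"):
            ratio = ref.SITE_MEALS[site] / ref.SITE_PARTICIPANTS[site]
            expected = {"intervention": 16.16, "control": 19.65}[site]
            assert round(ratio, 2) == expected


class TestDifferenceInDifferences:
    def test_parallel_shifts_give_zero(self):
        cells = {("control", "before"): 5.0, ("control", "after"): 7.0,
                 ("intervention", "before"): 6.0, ("intervention", "after"): 8.0}
        panel = panel_from_cells(cells, reps=3, jitter=0.4)
        fit = inf.did_estimate(panel, "y")
        assert fit.estimate("did") == pytest.approx(0.0, abs=1e-10)

    def test_closed_form_two_by_two(self):
        cells = {("intervention", "before"): 10.0, ("intervention", "after"): 8.0,
                 ("control", "before"): 9.0, ("control", "after"): 9.0}
        panel = panel_from_cells(cells, reps=4, jitter=0.7)
        fit = inf.did_estimate(panel, "y")
        assert fit.estimate("did") == pytest.approx(-2.0, abs=1e-10)

    def test_published_cell_means_give_minus_point_sixteen(self):
        panel = panel_from_cells(ref.MEAL_FSAM_CELL_MEANS, reps=5, jitter=0.9)
        fit = inf.did_estimate(panel, "y")
        assert fit.estimate("did") == pytest.approx(-0.16, abs=1e-10)
        assert fit.estimate("did") < 0  # improvement in quality

    def test_interaction_equals_difference_of_differences_to_ten_digits(self):
        rng = np.random.default_rng(3)
        cells = {(s, p): float(rng.normal(0, 5))
                 for s in ("control", "intervention")
                 for p in ("before", "after")}
        panel = panel_from_cells(cells, reps=6, jitter=1.3)
        agg = (panel.groupby(["badge_id", "site", "period"], as_index=False)
               ["y"].mean())
        mean = lambda s, p: agg[(agg["site"] == s)
                                & (agg["period"] == p)]["y"].mean()
        dd = (mean("intervention", 1) - mean("intervention", 0)) \
            - (mean("control", 1) - mean("control", 0))
        fit = inf.did_estimate(panel, "y")
        assert fit.estimate("did") == pytest.approx(dd, rel=1e-10)

    def test_participants_missing_a_period_are_dropped(self):
        cells = {("control", "before"): 1.0, ("control", "after"): 2.0,
                 ("intervention", "before"): 1.0, ("intervention", "after"): 5.0}
        panel = panel_from_cells(cells, reps=3)
        # an intervention-site participant seen only after the switch, with a
        # wild value: must not move the estimate
        extra = pd.DataFrame([{"badge_id": "ghost", "site": "intervention",
                               "site_code": 1, "period": 1, "time": 60.0,
                               "intervention": 1, "y": 500.0}])
        fit = inf.did_estimate(pd.concat([panel, extra]), "y")
        assert fit.estimate("did") == pytest.approx(3.0, abs=1e-10)

    def test_empty_cell_raises(self):
        cells = {("control", "before"): 1.0, ("control", "after"): 2.0,
                 ("intervention", "before"): 1.0, ("intervention", "after"): 5.0}
        panel = panel_from_cells(cells, reps=2)
        panel = panel[panel["site_code"] == 0]
        with pytest.raises(InestimableContrastError):
            inf.did_estimate(panel, "y")


class TestTrajectoryModel:
    def test_noiseless_panel_recovers_coefficients_exactly(self):
        coeffs = dict(intercept=2.0, site=0.3, time=0.01, site_time=-0.02,
                      intervention=-1.5, intervention_time=0.05)
        panel = sd.simulate_panel_from_model(coeffs, 30, n_days=30,
                                             switch_day=14, sigma_u=0.0,
                                             sigma_e=1e-6, seed=4)
        fit = inf.fit_trajectory(panel, "y", adjust_offer=False)
        for term, value in coeffs.items():
            assert fit.estimate(term) == pytest.approx(value, abs=1e-4)

    def test_random_intercept_absorbs_participant_heterogeneity(self):
        coeffs = dict(intercept=0.0)
        panel = sd.simulate_panel_from_model(coeffs, 60, n_days=20,
                                             switch_day=7, sigma_u=3.0,
                                             sigma_e=1.0, seed=5)
        import statsmodels.formula.api as smf
        mixed = inf.fit_trajectory(panel, "y", adjust_offer=False)
        ols = smf.ols("y ~ site_code + time + site_code:time + intervention"
                      " + intervention:time", data=panel).fit()
        # dropping the intercept dumps participant variance into the residual
        assert mixed.resid_var < ols.mse_resid
        assert mixed.group_var == pytest.approx(9.0, rel=0.5)

    def test_time_rescaling_rescales_only_time_terms(self):
        coeffs = dict(intercept=1.0, site=0.5, time=0.02, site_time=-0.01,
                      intervention=-2.0, intervention_time=0.04)
        panel = sd.simulate_panel_from_model(coeffs, 80, n_days=30,
                                             switch_day=14, sigma_u=1.0,
                                             sigma_e=1.0, seed=6)
        fit_days = inf.fit_trajectory(panel, "y", adjust_offer=False)
        weekly = panel.assign(time=panel["time"] / 7.0)
        fit_weeks = inf.fit_trajectory(weekly, "y", adjust_offer=False)
        for term in ("time", "site_time", "intervention_time"):
            assert fit_weeks.estimate(term) == pytest.approx(
                7 * fit_days.estimate(term), rel=1e-4)
        for term in ("site", "intervention", "intercept"):
            assert fit_weeks.estimate(term) == pytest.approx(
                fit_days.estimate(term), rel=1e-4, abs=1e-6)

    def test_mean_estimate_over_replicates_recovers_generating_block(self):
        """Simulate-then-refit, 50 replicates, published score-outcome block."""
        coeffs = ref.coefficient_vector("meal_fsam")
        targets = {k: v for k, v in coeffs.items() if k != "intercept"}
        sums = {k: 0.0 for k in targets}
        n_rep = 50
        # moderate noise keeps the Monte Carlo error of the 50-replicate
        # mean well inside the recovery tolerance at this panel size
        for r in range(n_rep):
            panel = sd.simulate_panel_from_model(
                coeffs, 200, n_days=62, switch_day=49, sigma_u=0.3,
                sigma_e=1.0, seed=1000 + r)
            fit = inf.fit_trajectory(panel, "y", adjust_offer=False,
                                     reml=True)
            for k in targets:
                sums[k] += fit.estimate(k)
        for k, truth in targets.items():
            mean_est = sums[k] / n_rep
            assert mean_est == pytest.approx(
                truth, abs=max(0.05 * abs(truth), 0.02))


@pytest.fixture(scope="module")
def sensitivity_panel():
    coeffs = dict(intercept=2.0, site=0.3, time=0.005, site_time=-0.01,
                  intervention=-1.0, intervention_time=0.02)
    p = sd.simulate_panel_from_model(coeffs, 120, n_days=40,
                                     switch_day=21, sigma_u=1.0,
                                     sigma_e=2.0, seed=8, attendance=0.6)
    rng = np.random.default_rng(8)
    # a zero-effect offer covariate
    days = sorted(p["time"].unique())
    qual = {(s, t): rng.normal(5, 0.5) for s in ("intervention", "control")
            for t in days}
    p["offer_quality"] = [qual[(s, t)] for s, t in zip(p["site"], p["time"])]
    return p


class TestSensitivitySuite:

    def test_zero_offer_effect_leaves_estimates_alike(self, sensitivity_panel):
        panel = sensitivity_panel
        adj = inf.fit_trajectory(panel, "y", adjust_offer=True)
        unadj = inf.fit_trajectory(panel, "y", adjust_offer=False)
        assert adj.estimate("intervention") == pytest.approx(
            unadj.estimate("intervention"), abs=0.15)

    def test_min_meals_subset_smaller_but_consistent(self, sensitivity_panel):
        panel = sensitivity_panel
        suite = inf.sensitivity_suite(panel, "y", min_meals=5)
        full = inf.fit_trajectory(panel, "y", adjust_offer=True)
        sub = suite["min_5_meals"]
        assert sub.n_participants <= full.n_participants
        lo, hi = full.ci("intervention")
        assert lo - 0.3 <= sub.estimate("intervention") <= hi + 0.3

    def test_four_meal_participant_excluded(self):
        coeffs = dict(intercept=0.0)
        p = sd.simulate_panel_from_model(coeffs, 40, n_days=12, switch_day=7,
                                         sigma_u=1.0, sigma_e=1.0, seed=9)
        p["offer_quality"] = np.random.default_rng(9).normal(5, 0.5, len(p))
        # badge 0 keeps only four meals (two per period); everyone else has 12
        few = p[p["badge_id"] == 0].groupby("period").head(2)
        trimmed = pd.concat([few, p[p["badge_id"] != 0]])
        suite = inf.sensitivity_suite(trimmed, "y", min_meals=5)
        assert (suite["min_5_meals"].n_participants
                == p["badge_id"].nunique() - 1)


class TestPower:
    def test_published_inputs_reproduce_published_n(self):
        assert inf.required_n(**{"effect_size": 0.20, "power": 0.90,
                                 "alpha": 0.05}) == 1053

    def test_hand_derived_second_case(self):
        assert inf.required_n(0.50, power=0.80, alpha=0.05) == 128

    def test_monotone_in_effect_size(self):
        ns = [inf.required_n(d) for d in (0.1, 0.2, 0.4, 0.8)]
        assert ns == sorted(ns, reverse=True)
        # leading term quarters when d doubles
        assert ns[0] / ns[1] == pytest.approx(4.0, rel=0.02)

    def test_zero_effect_rejected(self):
        with pytest.raises(ValueError):
            inf.required_n(0.0)
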
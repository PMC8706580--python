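"""Descriptive tables, difference-in-differences, mixed-effects trajectories
and the a-priori power calculation for a two-site labelling trial.

The design is quasi-experimental: two cafeterias observed daily over a
13-week window with the label switched on at one site after week 7. Two
estimators quantify the label effect:

* an unadjusted Gaussian difference-in-differences on participant x period
  means -- the site x period interaction is the effect of interest;
* a linear mixed model on per-meal observations with a participant random
  intercept and fixed effects for site, time (days, absorbing a seasonal
  trend), site x time, the intervention-period indicator (immediate label
  effect) and intervention x time (post-switch change of trend), optionally
  adjusted for the mean score of the day's offer.

Estimation uses statsmodels (OLS / MixedLM, REML by default); Wald z
intervals and p-values are reported for the fixed effects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .errors import ConvergenceError, InestimableContrastError

OUTCOMES = ("meal_fsam", "energy_kcal", "sugars_g", "satfat_g", "salt_g",
            "protein_g", "fibre_g")

TRAJECTORY_TERMS = ("intercept", "site", "time", "site_time", "intervention",
                    "intervention_time")


@dataclass
class FitResult:
    """Coefficients, Wald 95% intervals and p-values for one fitted model."""

    label: str
    terms: pd.DataFrame  # index term; columns estimate, ci_low, ci_high, p
    n_obs: int
    n_participants: int
    group_var: float = np.nan
    resid_var: float = np.nan
    converged: bool = True
    notes: list = field(default_factory=list)

    def estimate(self, term: str) -> float:
        return float(self.terms.loc[term, "estimate"])

    def ci(self, term: str) -> tuple[float, float]:
        row = self.terms.loc[term]
        return float(row["ci_low"]), float(row["ci_high"])

    def __post_init__(self) -> None:
        bad = ((self.terms["ci_low"] > self.terms["estimate"])
               | (self.terms["estimate"] > self.terms["ci_high"]))
        if bad.any():
            raise ValueError("confidence bounds do not bracket the estimate")


# ---------------------------------------------------------------------------
# Panel construction

def build_panel(meals: pd.DataFrame, switch_day: int,
                offer_quality: pd.DataFrame | None = None,
                start_date=None) -> pd.DataFrame:
    """Turn filtered meals into modelling rows.

    ``time`` is days since the study start (the earliest meal date unless
    ``start_date`` is given), ``period`` flips at ``switch_day`` and
    ``intervention`` = site x period. ``offer_quality`` (site, date,
    offer_quality) merges in the day-offer covariate when provided.
    """
    panel = meals.copy()
    dates = pd.to_datetime(panel["date"])
    origin = pd.to_datetime(start_date) if start_date is not None else dates.min()
    panel["time"] = (dates - origin).dt.days.astype(float)
    panel["site_code"] = (panel["site"] == "intervention").astype(int)
    panel["period"] = (panel["time"] >= switch_day).astype(int)
    panel["intervention"] = panel["site_code"] * panel["period"]
    if offer_quality is not None:
        panel = panel.merge(offer_quality, on=["site", "date"], how="left")
    return panel.sort_values(["badge_id", "time"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# Descriptives

def site_summary(meals: pd.DataFrame) -> pd.DataFrame:
    """Per-site totals: meals, meals/day, products/meal, participants,
    meals/participant (mean +/- SD where defined)."""
    rows = {}
    for site, grp in meals.groupby("site"):
        per_day = grp.groupby("date").size()
        per_participant = grp.groupby("badge_id").size()
        rows[site] = {
            "n_meals": len(grp),
            "meals_per_day_mean": per_day.mean(),
            "meals_per_day_sd": per_day.std(ddof=1),
            "products_per_meal_mean": grp["n_products"].mean(),
            "products_per_meal_sd": grp["n_products"].std(ddof=1),
            "n_participants": grp["badge_id"].nunique(),
            "meals_per_participant_mean": per_participant.mean(),
            "meals_per_participant_sd": per_participant.std(ddof=1),
        }
    return pd.DataFrame(rows).T


def outcome_summary(panel: pd.DataFrame,
                    outcomes=OUTCOMES) -> pd.DataFrame:
    """Mean +/- SD of each outcome by site x period.

    Each participant contributes their per-period mean, so N is the number
    of participants with at least one meal in that cell; single-participant
    cells report a missing SD rather than zero.
    """
    recs = []
    for (site, period), grp in panel.groupby(["site", "period"]):
        pmeans = grp.groupby("badge_id")[list(outcomes)].mean()
        row = {"site": site, "period": "after" if period else "before",
               "n_participants": len(pmeans)}
        for oc in outcomes:
            if oc not in grp.columns:
                continue
            row[f"{oc}_mean"] = pmeans[oc].mean() if len(pmeans) else np.nan
            row[f"{oc}_sd"] = pmeans[oc].std(ddof=1) if len(pmeans) > 1 else np.nan
        recs.append(row)
    if not recs:
        raise InestimableContrastError("no site x period cells present")
    return pd.DataFrame(recs).set_index(["site", "period"]).sort_index()


def descriptives(panel: pd.DataFrame, outcomes=OUTCOMES) -> dict:
    """Site summary plus site x period outcome table."""
    return {"sites": site_summary(panel),
            "outcomes": outcome_summary(panel, outcomes)}


# ---------------------------------------------------------------------------
# Difference in differences

def _both_period_participants(panel: pd.DataFrame) -> pd.DataFrame:
    n_periods = panel.groupby("badge_id")["period"].nunique()
    keep = n_periods[n_periods == 2].index
    return panel[panel["badge_id"].isin(keep)]

def did_estimate(panel: pd.DataFrame, outcome: str) -> FitResult:
    """Unadjusted Gaussian difference-in-differences.

    Restricted to participants with at least one meal in each period; one
    row per participant x period (the period mean of the outcome). On a
    saturated 2x2 design the interaction equals the difference of the
    before/after differences exactly.
    """
    sub = _both_period_participants(panel)
    agg = (sub.groupby(["badge_id", "site_code", "period"], as_index=False)
           [outcome].mean())
    cells = agg.groupby(["site_code", "period"]).size()
    if len(cells) < 4 or (cells == 0).any():
        raise InestimableContrastError(
            f"empty site x period cell for {outcome}: {cells.to_dict()}")
    model = smf.ols(f"{outcome} ~ site_code * period", data=agg).fit()
    terms = pd.DataFrame({
        "estimate": model.params,
        "ci_low": model.conf_int()[0],
        "ci_high": model.conf_int()[1],
        "p": model.pvalues,
    })
    terms = terms.rename(index={
        "Intercept": "intercept", "site_code": "site", "period": "period",
        "site_code:period": "did"})
    return FitResult(label=f"did:{outcome}", terms=terms, n_obs=len(agg),
                     n_participants=agg["badge_id"].nunique(),
                     resid_var=float(model.mse_resid))


# ---------------------------------------------------------------------------
# Mixed-effects trajectories

def fit_trajectory(panel: pd.DataFrame, outcome: str,
                   adjust_offer: bool = True, reml: bool = True) -> FitResult:
    """Random-intercept mixed model for one outcome on per-meal rows.

    Fixed effects: site, time, site x time, intervention period,
    intervention x time, plus the day-offer quality covariate unless
    ``adjust_offer`` is False. Falls back to a fixed-intercept OLS (with a
    note) if the random-intercept variance collapses to zero; raises
    :class:`ConvergenceError` if the optimiser fails outright.
    """
    data = panel.dropna(subset=[outcome]).copy()
    rhs = "site_code + time + site_code:time + intervention + intervention:time"
    if adjust_offer:
        if "offer_quality" not in data.columns:
            raise KeyError("panel has no offer_quality column; pass "
                           "adjust_offer=False or merge the covariate in")
        rhs += " + offer_quality"
    formula = f"{outcome} ~ {rhs}"
    model = smf.mixedlm(formula, data=data, groups=data["badge_id"])
    res = None
    errors: list[str] = []
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        # default BFGS first, then slower but sturdier optimisers
        for method in (None, "lbfgs", "nm", "powell"):
            try:
                cand = model.fit(reml=reml, method=method, maxiter=2000)
            except np.linalg.LinAlgError as exc:
                errors.append(f"{method or 'bfgs'}: {exc}")
                continue
            if cand.converged:
                res = cand
                break
            errors.append(f"{method or 'bfgs'}: did not converge")
    if res is None:
        raise ConvergenceError(
            f"mixed model failed for {outcome}; optimiser diagnostics: "
            f"{'; '.join(errors)}")
    notes = [str(w.message) for w in caught] + errors

    group_var = float(res.cov_re.iloc[0, 0])
    if group_var <= 1e-10:
        ols = smf.ols(formula, data=data).fit()
        terms = pd.DataFrame({"estimate": ols.params,
                              "ci_low": ols.conf_int()[0],
                              "ci_high": ols.conf_int()[1],
                              "p": ols.pvalues})
        terms = terms.rename(index=_TERM_NAMES)
        return FitResult(label=f"trajectory:{outcome}", terms=terms,
                         n_obs=len(data),
                         n_participants=data["badge_id"].nunique(),
                         group_var=0.0, resid_var=float(ols.mse_resid),
                         converged=True,
                         notes=notes + ["singular random intercept; "
                                        "fixed-intercept fallback"])

    fe = res.fe_params
    se = res.bse_fe
    z = stats.norm.ppf(0.975)
    terms = pd.DataFrame({
        "estimate": fe,
        "ci_low": fe - z * se,
        "ci_high": fe + z * se,
        "p": 2 * stats.norm.sf(np.abs(fe / se)),
    })
    terms = terms.rename(index=_TERM_NAMES)
    return FitResult(label=f"trajectory:{outcome}", terms=terms,
                     n_obs=len(data),
                     n_participants=data["badge_id"].nunique(),
                     group_var=group_var * float(res.scale),
                     resid_var=float(res.scale), notes=notes)


_TERM_NAMES = {
    "Intercept": "intercept",
    "site_code": "site",
    "time": "time",
    "site_code:time": "site_time",
    "intervention": "intervention",
    "intervention:time": "intervention_time",
    "offer_quality": "offer_quality",
}


def sensitivity_suite(panel: pd.DataFrame, outcome: str,
                      min_meals: int = 5) -> dict[str, FitResult]:
    """Re-run the trajectory fit (a) without the day-offer covariate and
    (b) on participants with >= ``min_meals`` meals and one in each period."""
    out: dict[str, FitResult] = {}
    out["unadjusted"] = fit_trajectory(panel, outcome, adjust_offer=False)
    counts = panel.groupby("badge_id").size()
    frequent = set(counts[counts >= min_meals].index)
    sub = _both_period_participants(panel)
    sub = sub[sub["badge_id"].isin(frequent)]
    res = fit_trajectory(sub, outcome,
                         adjust_offer="offer_quality" in panel.columns)
    res.label = f"trajectory:{outcome}:min{min_meals}"
    out[f"min_{min_meals}_meals"] = res
    return out


# ---------------------------------------------------------------------------
# Power

def required_n(effect_size: float, power: float = 0.90,
               alpha: float = 0.05) -> int:
    """Total sample size for a two-group comparison of means.

    Normal approximation with a small-sample correction applied at the
    total level: N = ceil( 4 (z_{1-a/2} + z_{1-b})^2 / d^2 + z_{1-a/2}^2 / 2 ).
    Monotone decreasing in d; d = 0 is rejected.
    """
    if effect_size <= 0:
        raise ValueError("effect size must be positive (d = 0 needs infinite N)")
    if not (0 < alpha < 1 and 0 < power < 1):
        raise ValueError("alpha and power must lie in (0, 1)")
    za = stats.norm.ppf(1 - alpha / 2)
    zb = stats.norm.ppf(power)
    n = 4.0 * (za + zb) ** 2 / effect_size ** 2 + za ** 2 / 2.0
    return int(np.ceil(n))
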
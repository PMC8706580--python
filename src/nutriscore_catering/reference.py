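"""Published estimates from the motivating two-site catering trial.

A staff-restaurant trial run in France over the winter of 2019-2020
(13 weeks, Nutri-Score labels switched on at the intervention site after a
7-week control period) reported its inclusion flow, site descriptives,
before/after cell means and mixed-model coefficients. Those published
numbers serve two roles here: arithmetic inputs for flow/descriptive
cross-checks, and generating truth for the simulate-then-refit validation
of the trajectory models. No participant-level data from the trial are
used or included anywhere.
"""

# Inclusion flow counts (meals).
FLOW = {
    "n_input_meals": 41_499,
    "n_menu_excluded": 4_584,
    "n_gt10_products": 19,
    "n_gt1_main": 44,
    "n_energy_trimmed": 738,
}
ENERGY_TRIM_KCAL = (139.0, 1660.0)  # realised 1st/99th percentiles

# Site descriptives.
SITE_MEALS = {"intervention": 20_492, "control": 15_622}
SITE_PARTICIPANTS = {"intervention": 1_268, "control": 795}

# Before/after cell means of the energy-weighted meal score by site.
MEAL_FSAM_CELL_MEANS = {
    ("intervention", "before"): 1.91,
    ("intervention", "after"): 1.69,
    ("control", "before"): 2.03,
    ("control", "after"): 1.97,
}

# A-priori power calculation inputs and the published answer.
POWER_SPEC = {"effect_size": 0.20, "power": 0.90, "alpha": 0.05}
POWER_REQUIRED_N = 1_053

# Mixed-model fixed-effect blocks: per outcome, term -> (estimate, ci_low,
# ci_high). Terms follow the trajectory-model design: site, time (days),
# time x site, intervention period, intervention period x time. Intercepts
# were not reported; the values supplied here for simulation are the
# before-period control-site means and do not enter any comparison.
TRIAL_EFFECTS = {
    "meal_fsam": {
        "intercept": 2.03,
        "site": (0.33, 0.08, 0.58),
        "time": (0.006, 0.004, 0.008),
        "site_time": (-0.013, -0.018, -0.007),
        "intervention": (-3.37, -3.78, -2.95),
        "intervention_time": (0.052, 0.045, 0.06),
    },
    "energy_kcal": {
        "intercept": 851.37,
        "site": (-39.91, -58.82, -20.99),
        "time": (1.01, 0.84, 1.17),
        "site_time": (0.14, -0.25, 0.52),
        "intervention": (353.53, 325.44, 381.62),
        "intervention_time": (-5.95, -6.46, -5.44),
    },
    "sugars_g": {
        "intercept": 25.55,
        "site": (0.85, -0.27, 1.97),
        "time": (0.03, 0.02, 0.04),
        "site_time": (-0.08, -0.1, -0.06),
        "intervention": (14.74, 13.16, 16.32),
        "intervention_time": (-0.21, -0.24, -0.18),
    },
    "satfat_g": {
        "intercept": 11.51,
        "site": (-0.41, -0.86, 0.04),
        "time": (0.017, 0.013, 0.021),
        "site_time": (0.004, -0.006, 0.014),
        "intervention": (4.35, 3.63, 5.07),
        "intervention_time": (-0.08, -0.09, -0.07),
    },
    "salt_g": {
        "intercept": 3.96,
        "site": (0.16, 0.01, 0.31),
        "time": (0.002, 0.001, 0.003),
        "site_time": (-0.013, -0.016, -0.009),
        "intervention": (-0.42, -0.67, -0.16),
        "intervention_time": (0.01, 0.01, 0.02),
    },
    "protein_g": {
        "intercept": 38.53,
        "site": (-3.13, -4.15, -2.11),
        "time": (0.02, 0.01, 0.03),
        "site_time": (0.04, 0.02, 0.06),
        "intervention": (14.16, 12.66, 15.67),
        "intervention_time": (-0.24, -0.27, -0.21),
    },
    "fibre_g": {
        "intercept": 10.58,
        "site": (-0.6, -0.91, -0.29),
        "time": (0.001, -0.002, 0.003),
        "site_time": (0.006, 0.0, 0.013),
        "intervention": (5.92, 5.44, 6.4),
        "intervention_time": (-0.1, -0.11, -0.09),
    },
}

# Variance components used by the simulate-then-refit validation harness
# (participant random-intercept SD, residual SD), per outcome, on the
# outcome's own scale.
RECOVERY_SIGMAS = {
    "meal_fsam": (1.0, 2.0),
    "energy_kcal": (50.0, 150.0),
    "salt_g": (0.5, 1.0),
}

# Trial calendar: 7 control weeks then the label switch, 62 service days.
N_SERVICE_DAYS = 62
SWITCH_DAY = 49  # calendar days from study start (start of week 8)


def coefficient_vector(outcome: str) -> dict[str, float]:
    """Point estimates for one outcome, as a term -> value mapping."""
    block = TRIAL_EFFECTS[outcome]
    return {term: (v[0] if isinstance(v, tuple) else v)
            for term, v in block.items()}
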
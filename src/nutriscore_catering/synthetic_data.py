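"""Synthetic two-cafeteria labelling trial.

No participant-level data from the motivating trial are public, so this
module fabricates a complete trial with the structure the analysis assumes:
two sites sharing identical daily menus (standardised recipes), a 13-week
Mon-Fri service calendar with the label switched on at the intervention
site at the start of week 8, monthly rotation of the item pools, composite
till tokens (cheese, yogurt, beverage, salad bar, dessert bar, side dish)
and a fixed-price menu, repeated per-participant attendance, and a label
effect with an immediate component and a post-switch time trend.

Food choice is a softmax over item utilities ``u = -(aversion) x score``
with a participant-specific aversion (random intercept on healthiness
preference). After the switch, intervention-site utilities gain
``immediate_shift x score`` (negative values steer choices toward
lower-score items), and the shift drifts linearly by ``trend_per_day``.
The behavioural model is deliberately minimal: its only job is to carry
injectable effects through the real receipt pipeline.

``simulate_panel_from_model`` bypasses the behavioural layer entirely and
draws outcomes straight from the random-intercept linear mixed model on
the trial's design matrix; it is the generator behind the
parameter-recovery validation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError

SLOT_TOKENS = {"cheese": "cheese", "yogurt": "yogurt", "beverage": "beverage",
               "salad_bar": "salad_bar", "dessert_bar": "dessert_bar",
               "side": "side_dish"}


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic trial.

    Defaults mirror the motivating trial: 1268 + 795 participants, 13
    weeks with the switch at week 8, five service days a week capped at 62
    service days, ten starters / eight mains / seven desserts a day, and
    roughly 11% menu receipts. Attendance probabilities are drawn per
    participant so that total meals land near the trial's 36,000.
    """

    seed: int = 0
    n_participants: dict = field(default_factory=lambda: {
        "intervention": 1268, "control": 795})
    n_weeks: int = 13
    switch_week: int = 8
    service_days_per_week: int = 5
    n_service_days: int = 62
    start_date: str = "2019-12-16"  # a Monday
    # daily offer sizes (detailed items)
    n_starters: int = 10
    n_mains: int = 8
    n_desserts: int = 7
    # composite member counts per day
    n_cheese: int = 4
    n_yogurt: int = 3
    n_beverage: int = 4
    n_salad_bar: int = 5
    n_dessert_bar: int = 4
    n_side: int = 3
    # attendance and meal structure
    attendance_range: tuple = (0.06, 0.50)
    p_starter: float = 0.80
    p_dessert: float = 0.75
    p_cheese: float = 0.20
    p_yogurt: float = 0.10
    p_beverage: float = 0.30
    p_side: float = 0.30
    # choice model
    pref_mean: float = 0.20
    pref_sd: float = 0.15
    immediate_shift: float = -0.50
    trend_per_day: float = 0.010
    # filter-exercising contamination
    menu_fraction: float = 0.11
    gt10_fraction: float = 0.0005
    dual_main_fraction: float = 0.001

    def validate(self) -> None:
        if not self.switch_week < self.n_weeks:
            raise ConfigError("switch_week must be < n_weeks")
        if self.n_service_days > self.n_weeks * self.service_days_per_week:
            raise ConfigError("n_service_days exceeds the service calendar")
        for name in ("p_starter", "p_dessert", "p_cheese", "p_yogurt",
                     "p_beverage", "p_side", "menu_fraction",
                     "gt10_fraction", "dual_main_fraction"):
            v = getattr(self, name)
            if not 0 <= v < 1:
                raise ConfigError(f"{name}={v} outside [0, 1)")
        lo, hi = self.attendance_range
        if not (0 < lo <= hi < 1):
            raise ConfigError("attendance_range must lie inside (0, 1)")

    @property
    def switch_day(self) -> int:
        """Calendar days from study start to the label switch."""
        return (self.switch_week - 1) * 7

    def service_dates(self) -> pd.DatetimeIndex:
        """Mon-Fri service dates, capped at ``n_service_days``."""
        start = pd.Timestamp(self.start_date)
        days = pd.bdate_range(start, periods=self.n_service_days)
        return days


# ---------------------------------------------------------------------------
# Offer and composition generation

# Per-slot uniform nutrient ranges (per 100 g; beverages per 100 mL). Drawn
# independently and clipped to composition invariants; chosen so that each
# day's offer spans the letter bands a real cafeteria counter does (raw-veg
# starters and fruit grade A/B, gratin-style mains C/D, pastry desserts and
# cheese D/E).
_SLOT_RANGES = {
    "starter": dict(kcal=(25, 220), sugars=(0, 8), fat=(0, 18),
                    satr=(0.1, 0.6), salt=(0.1, 1.8), protein=(1, 10),
                    fibre=(0.5, 4.5), fvln=(0, 95), portion=(80, 200)),
    "main": dict(kcal=(100, 260), sugars=(0, 6), fat=(3, 20),
                 satr=(0.2, 0.6), salt=(0.5, 2.0), protein=(8, 24),
                 fibre=(0, 4), fvln=(0, 60), portion=(180, 300)),
    "dessert": dict(kcal=(45, 420), sugars=(5, 48), fat=(0, 24),
                    satr=(0.3, 0.9), salt=(0.0, 0.5), protein=(1, 7),
                    fibre=(0.2, 3.5), fvln=(0, 80), portion=(80, 150)),
    "cheese": dict(kcal=(270, 420), sugars=(0, 2), fat=(20, 34),
                   satr=(0.55, 0.72), salt=(0.8, 2.4), protein=(17, 28),
                   fibre=(0, 0), fvln=(0, 0), portion=(30, 30)),
    "yogurt": dict(kcal=(45, 150), sugars=(4, 16), fat=(0, 5),
                   satr=(0.5, 0.7), salt=(0.1, 0.3), protein=(3, 6),
                   fibre=(0, 0), fvln=(0, 0), portion=(125, 125)),
    "beverage": dict(kcal=(4, 55), sugars=(0.5, 13), fat=(0, 0),
                     satr=(0, 0), salt=(0, 0.05), protein=(0, 1),
                     fibre=(0, 0.5), fvln=(0, 100), portion=(250, 250)),
    "salad_bar": dict(kcal=(20, 160), sugars=(0, 6), fat=(0, 12),
                      satr=(0.1, 0.4), salt=(0.1, 1.2), protein=(1, 8),
                      fibre=(1, 4.5), fvln=(40, 100), portion=(150, 150)),
    "dessert_bar": dict(kcal=(120, 430), sugars=(12, 48), fat=(4, 26),
                        satr=(0.4, 0.9), salt=(0.0, 0.6), protein=(2, 7),
                        fibre=(0.2, 2.5), fvln=(0, 30), portion=(100, 100)),
    "side": dict(kcal=(70, 210), sugars=(0, 4), fat=(1, 12),
                 satr=(0.2, 0.6), salt=(0.2, 1.5), protein=(2, 8),
                 fibre=(0.5, 4), fvln=(0, 80), portion=(150, 150)),
    "fruit": dict(kcal=(40, 75), sugars=(8, 16), fat=(0, 0.5),
                  satr=(0, 0.3), salt=(0, 0.01), protein=(0.3, 1.2),
                  fibre=(1.5, 4), fvln=(100, 100), portion=(120, 120)),
}

KCAL_TO_KJ = 4.184

# items generated per month-pool, per slot
_POOL_MULTIPLIER = 2.0


def _sample_items(rng: np.random.Generator, slot: str, n: int,
                  prefix: str) -> pd.DataFrame:
    r = _SLOT_RANGES[slot]
    kcal = rng.uniform(*r["kcal"], n)
    fat = rng.uniform(*r["fat"], n)
    satfat = fat * rng.uniform(*r["satr"], n)
    salt = rng.uniform(*r["salt"], n)
    df = pd.DataFrame({
        "item_id": [f"{prefix}{i:03d}" for i in range(n)],
        "label": [f"{slot} {prefix}{i:03d}" for i in range(n)],
        "category": "beverage" if slot == "beverage" else (
            "cheese" if slot == "cheese" else "general"),
        "energy_kcal": kcal,
        "energy_kj": kcal * KCAL_TO_KJ,
        "sugars_g": np.minimum(rng.uniform(*r["sugars"], n), 100.0),
        "satfat_g": satfat,
        "totalfat_g": fat,
        "salt_g": salt,
        "sodium_mg": salt / 2.5 * 1000.0,
        "protein_g": rng.uniform(*r["protein"], n),
        "fibre_g": rng.uniform(*r["fibre"], n),
        "fvln_pct": rng.uniform(*r["fvln"], n),
        "portion_g": rng.uniform(*r["portion"], n),
        "is_water": False,
    })
    return df


def generate_offers(config: SimulationConfig,
                    rng: np.random.Generator | None = None
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Daily offers and the composition table behind them.

    Item pools rotate monthly (every four study weeks); each service day
    draws its selection from the current month's pool, identically at both
    sites. Desserts always include one fruit and the dessert-bar and
    yogurt selections; beverages always include one water.

    Returns ``(offers, compositions)`` in the delimited formats the
    assembly stage reads.
    """
    config.validate()
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    dates = config.service_dates()
    start = pd.Timestamp(config.start_date)

    slots_daily = {
        "starter": config.n_starters - 1,   # salad_bar is the tenth starter
        "main": config.n_mains,
        "dessert": config.n_desserts - 3,   # + fruit + dessert_bar + yogurt
        "cheese": config.n_cheese,
        "yogurt": config.n_yogurt,
        "beverage": config.n_beverage - 1,  # + water
        "salad_bar": config.n_salad_bar,
        "dessert_bar": config.n_dessert_bar,
        "side": config.n_side,
        "fruit": 1,
    }

    n_months = int(np.ceil(config.n_weeks / 4))
    pools: dict[tuple[int, str], pd.DataFrame] = {}
    frames = []
    for m in range(n_months):
        for slot, n_daily in slots_daily.items():
            n_pool = max(n_daily + 1, int(np.ceil(n_daily * _POOL_MULTIPLIER)))
            items = _sample_items(rng, slot, n_pool, prefix=f"m{m}_{slot[:4]}_")
            pools[(m, slot)] = items
            frames.append(items)
    water = pd.DataFrame([{
        "item_id": "water", "label": "still water", "category": "beverage",
        "energy_kcal": 0.0, "energy_kj": 0.0, "sugars_g": 0.0,
        "satfat_g": 0.0, "totalfat_g": 0.0, "salt_g": 0.0, "sodium_mg": 0.0,
        "protein_g": 0.0, "fibre_g": 0.0, "fvln_pct": 0.0,
        "portion_g": 250.0, "is_water": True}])
    frames.append(water)
    compositions = pd.concat(frames, ignore_index=True)

    offer_rows = []
    for date in dates:
        week = (date - start).days // 7
        month = min(week // 4, n_months - 1)
        day_items = []
        for slot, n_daily in slots_daily.items():
            pool = pools[(month, slot)]
            pick = rng.choice(len(pool), size=n_daily, replace=False)
            tok = SLOT_TOKENS.get(slot, "")
            if slot == "yogurt":
                tok = "yogurt"
            slot_name = {"fruit": "dessert", "salad_bar": "starter",
                         "dessert_bar": "dessert", "yogurt": "dessert",
                         "side": "side"}.get(slot, slot)
            for idx in pick:
                day_items.append((pool["item_id"].iat[idx], slot_name, tok))
        day_items.append(("water", "beverage", "beverage"))
        for item_id, slot_name, tok in day_items:
            for site in ("intervention", "control"):
                offer_rows.append({"site": site, "date": date.date().isoformat(),
                                   "item_id": item_id, "slot": slot_name,
                                   "composite_token": tok or None})
    offers = pd.DataFrame(offer_rows)
    return offers, compositions


# ---------------------------------------------------------------------------
# Receipt simulation

def _softmax_choice(rng, aversion: np.ndarray, scores: np.ndarray,
                    shift: float) -> np.ndarray:
    """One softmax draw per participant over a shared item set."""
    util = np.outer(-aversion, scores) + shift * scores[None, :]
    util -= util.max(axis=1, keepdims=True)
    p = np.exp(util)
    p /= p.sum(axis=1, keepdims=True)
    u = rng.random((len(aversion), 1))
    return (p.cumsum(axis=1) < u).sum(axis=1)


def simulate_receipts(config: SimulationConfig, offers: pd.DataFrame,
                      compositions: pd.DataFrame,
                      rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Simulate till receipts for every participant-day.

    Attendance is Bernoulli per participant-day with a per-participant
    probability drawn uniformly from ``attendance_range``. Attendees always
    take a main and probabilistically a starter, dessert and composite
    selections; choices within the detailed slots follow the softmax model
    described in the module docstring. A configurable fraction of receipts
    is replaced by fixed-price menu lines or inflated past the >10-product
    and dual-main thresholds to exercise the exclusion filters.
    """
    from . import nutrient_profile as npf

    config.validate()
    rng = rng if rng is not None else np.random.default_rng(
        np.random.SeedSequence([config.seed, 17]))
    dates = config.service_dates()
    start = pd.Timestamp(config.start_date)
    scored = npf.score_table(compositions)[["item_id", "score"]]
    offers = offers.merge(scored, on="item_id", how="left")

    rows: dict[str, list] = {"badge_id": [], "site": [], "date": [],
                             "item_ref": [], "n_units": []}

    def emit(badges, site, date, refs):
        rows["badge_id"].extend(badges)
        rows["site"].extend([site] * len(badges))
        rows["date"].extend([date] * len(badges))
        rows["item_ref"].extend(refs)
        rows["n_units"].extend([1] * len(badges))

    for site in ("intervention", "control"):
        n = config.n_participants[site]
        badges = np.array([f"{site[:3]}_{i:05d}" for i in range(n)])
        att_p = rng.uniform(*config.attendance_range, n)
        aversion = rng.normal(config.pref_mean, config.pref_sd, n)
        site_offers = offers[offers["site"] == site]

        for date in dates:
            day_key = date.date().isoformat()
            t = (date - start).days
            labelled = site == "intervention" and t >= config.switch_day
            shift = (config.immediate_shift
                     + config.trend_per_day * (t - config.switch_day)
                     ) if labelled else 0.0
            day = site_offers[site_offers["date"] == day_key]
            att = rng.random(n) < att_p
            who = np.where(att)[0]
            if len(who) == 0:
                continue
            b = badges[who]
            av = aversion[who]

            # fixed-price menu receipts: a single undetailed line
            menu_mask = rng.random(len(who)) < config.menu_fraction
            if menu_mask.any():
                emit(b[menu_mask], site, day_key, ["menu"] * int(menu_mask.sum()))
            b, av = b[~menu_mask], av[~menu_mask]
            if len(b) == 0:
                continue

            for slot, prob in (("main", 1.0), ("starter", config.p_starter),
                               ("dessert", config.p_dessert)):
                sl = day[(day["slot"] == slot)
                         & (day["composite_token"].isna())]
                ids = sl["item_id"].to_numpy()
                sc = sl["score"].to_numpy(dtype=float)
                take = rng.random(len(b)) < prob
                if take.any():
                    choice = _softmax_choice(rng, av[take], sc, shift)
                    emit(b[take], site, day_key, list(ids[choice]))

            for token, prob in (("cheese", config.p_cheese),
                                ("yogurt", config.p_yogurt),
                                ("beverage", config.p_beverage),
                                ("side_dish", config.p_side)):
                take = rng.random(len(b)) < prob
                if take.any():
                    emit(b[take], site, day_key, [token] * int(take.sum()))

            # contamination: multi-diner receipts
            gt10 = rng.random(len(b)) < config.gt10_fraction
            for badge in b[gt10]:
                emit([badge] * 11, site, day_key, ["cheese"] * 11)
            dual = rng.random(len(b)) < config.dual_main_fraction
            if dual.any():
                mains = day[(day["slot"] == "main")
                            & (day["composite_token"].isna())]["item_id"]
                extra = rng.choice(mains.to_numpy(), size=int(dual.sum()))
                emit(b[dual], site, day_key, list(extra))

    receipts = pd.DataFrame(rows)
    return receipts.sort_values(["site", "date", "badge_id"],
                                kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# Direct panel simulation from the mixed model

def service_day_offsets(n_days: int) -> np.ndarray:
    """Calendar-day offsets of the first ``n_days`` Mon-Fri service days."""
    offs, d = [], 0
    while len(offs) < n_days:
        if d % 7 < 5:
            offs.append(d)
        d += 1
    return np.array(offs, dtype=float)


def simulate_panel_from_model(coeffs: dict, n_participants_per_site: int,
                              n_days: int = 62, switch_day: int = 49,
                              sigma_u: float = 1.0, sigma_e: float = 2.0,
                              seed: int = 0, outcome: str = "y",
                              attendance: float = 1.0) -> pd.DataFrame:
    """Draw a panel straight from the random-intercept linear model.

    ``coeffs`` maps the trajectory terms (intercept, site, time, site_time,
    intervention, intervention_time) to generating values. Outcomes are the
    linear predictor plus a participant intercept ~ N(0, sigma_u^2) and
    residual ~ N(0, sigma_e^2). With both sigmas zero the outcome equals
    the linear predictor exactly. ``attendance`` < 1 thins participant-days
    at random, mimicking irregular cafeteria visits.
    """
    rng = np.random.default_rng(seed)
    offs = service_day_offsets(n_days)
    n = 2 * n_participants_per_site
    pid = np.repeat(np.arange(n), n_days)
    t = np.tile(offs, n)
    site = (pid >= n_participants_per_site).astype(float)
    period = (t >= switch_day).astype(float)
    interv = site * period
    lin = (coeffs.get("intercept", 0.0)
           + coeffs.get("site", 0.0) * site
           + coeffs.get("time", 0.0) * t
           + coeffs.get("site_time", 0.0) * site * t
           + coeffs.get("intervention", 0.0) * interv
           + coeffs.get("intervention_time", 0.0) * interv * t)
    u = rng.normal(0.0, sigma_u, n) if sigma_u > 0 else np.zeros(n)
    e = rng.normal(0.0, sigma_e, len(lin)) if sigma_e > 0 else 0.0
    y = lin + u[pid] + e
    panel = pd.DataFrame({
        "badge_id": pid,
        "site": np.where(site == 1, "intervention", "control"),
        "site_code": site.astype(int),
        "time": t,
        "period": period.astype(int),
        "intervention": interv.astype(int),
        outcome: y,
    })
    if attendance < 1.0:
        panel = panel[rng.random(len(panel)) < attendance].reset_index(drop=True)
    return panel
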
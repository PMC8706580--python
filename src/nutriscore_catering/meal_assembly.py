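"""Resolve cafeteria receipts into meals with nutrient totals and scores.

A receipt is the set of lines sharing ``(badge_id, site, date)``. Lines
either name an item directly (``item_ref`` is an ``item_id`` present in the
same-day offer) or carry one of the composite tokens the tills do not
detail: cheese, yogurt, beverage, salad bar, dessert bar, side dishes, or
the fixed-price menu. Composites are resolved to the unweighted day-average
composition of the member items on offer that day at that site; menus are
never resolved (their contents are unknowable) and the meal is only flagged
for downstream exclusion.

Nutrient totals are portion-weighted sums (per-100 g value x portion / 100)
and the meal-level FSAm-NPS is the energy-weighted mean of the constituent
item scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import nutrient_profile as npf
from .errors import UndefinedWeightingError, UnresolvableItemError

#: Receipt tokens that are not detailed on the till receipt.
COMPOSITE_TOKENS = ("cheese", "yogurt", "beverage", "salad_bar",
                    "dessert_bar", "side_dish", "menu")

#: Standard container portions (g) for composite selections. Cheese is the
#: trial's fixed 30 g portion; the others are standard single containers.
COMPOSITE_PORTIONS = {
    "cheese": 30.0,
    "yogurt": 125.0,
    "beverage": 250.0,
    "salad_bar": 150.0,
    "dessert_bar": 100.0,
    "side_dish": 150.0,
}

NUTRIENT_FIELDS = ("energy_kj", "energy_kcal", "sugars_g", "satfat_g",
                   "totalfat_g", "sodium_mg", "salt_g", "protein_g",
                   "fibre_g", "fvln_pct")

MEAL_TOTAL_FIELDS = ("energy_kcal", "sugars_g", "satfat_g", "salt_g",
                     "protein_g", "fibre_g")


@dataclass
class MealRecord:
    """One resolved meal: items, portion-weighted totals, energy-weighted score."""

    badge_id: str
    site: str
    date: object
    items: list = field(default_factory=list)  # (FoodComposition, portion_g, score)
    energy_kcal: float = np.nan
    sugars_g: float = np.nan
    satfat_g: float = np.nan
    salt_g: float = np.nan
    protein_g: float = np.nan
    fibre_g: float = np.nan
    meal_fsam: float = np.nan
    n_products: int = 0
    n_mains: int = 0
    has_menu: bool = False


class DayOffer:
    """The items on offer at one site on one day, with composite membership."""

    def __init__(self, site, date, items, composite_members):
        self.site = site
        self.date = date
        self.items = list(items)
        self.composite_members = {k: list(v) for k, v in composite_members.items()}
        self.slots: dict[str, str] = {}

    @classmethod
    def from_frame(cls, offers: pd.DataFrame, site, date) -> "DayOffer":
        day = offers[(offers["site"] == site) & (offers["date"] == date)]
        members: dict[str, list[str]] = {}
        if "composite_token" in day.columns:
            tagged = day[day["composite_token"].notna()
                         & (day["composite_token"] != "")]
            for tok, grp in tagged.groupby("composite_token"):
                members[tok] = list(grp["item_id"])
        offer = cls(site, date, day["item_id"], members)
        offer.slots = dict(zip(day["item_id"], day["slot"]))
        return offer


def day_average_composition(token: str, offer: DayOffer,
                            compositions: pd.DataFrame,
                            portions: dict | None = None) -> npf.FoodComposition:
    """Unweighted mean composition of a composite's members on a given day.

    No sales data exist for the undetailed categories, so members are
    averaged with equal weight. The portion is the standard container for
    the token (cheese fixed at 30 g).
    """
    if token == "menu":
        raise UnresolvableItemError("menu receipts are never resolved")
    member_ids = offer.composite_members.get(token, [])
    if not member_ids:
        raise UnresolvableItemError(
            f"composite {token!r} has no members on offer at "
            f"{offer.site}/{offer.date}"
        )
    portions = {**COMPOSITE_PORTIONS, **(portions or {})}
    rows = compositions.set_index("item_id").loc[member_ids]
    mean = rows[list(NUTRIENT_FIELDS)].mean()
    category = "cheese" if token == "cheese" else (
        "beverage" if token == "beverage" else "general")
    return npf.FoodComposition(
        item_id=f"{token}@{offer.site}/{offer.date}",
        label=f"day-average {token}",
        category=category,
        energy_kj=float(mean["energy_kj"]),
        energy_kcal=float(mean["energy_kcal"]),
        sugars_g=float(mean["sugars_g"]),
        satfat_g=float(mean["satfat_g"]),
        totalfat_g=float(mean["totalfat_g"]),
        sodium_mg=float(mean["sodium_mg"]),
        salt_g=float(mean["salt_g"]),
        protein_g=float(mean["protein_g"]),
        fibre_g=float(mean["fibre_g"]),
        fvln_pct=float(mean["fvln_pct"]),
        portion_g=float(portions[token]),
    )


def meal_fsam(items: list) -> float:
    """Energy-weighted FSAm-NPS over ``(composition, portion_g, score)`` items.

    Weight for item *i* is its portion energy ``kcal_i = energy_kcal/100 x
    portion_g``; the result is sum(score_i x kcal_i) / sum(kcal_i). Using kJ
    gives identical weights (the unit factor cancels).
    """
    if not items:
        raise UndefinedWeightingError("meal has no items")
    energies = np.array([c.energy_kcal * p / 100.0 for c, p, _ in items])
    scores = np.array([s for _, _, s in items], dtype=float)
    total = energies.sum()
    if total <= 0:
        raise UndefinedWeightingError("meal has zero total energy")
    return float((scores * energies).sum() / total)


def assemble_meal(lines: pd.DataFrame, offer: DayOffer,
                  compositions: pd.DataFrame,
                  portions: dict | None = None) -> MealRecord:
    """Resolve one receipt's lines into a :class:`MealRecord`.

    A line with ``n_units`` > 1 multiplies the portion, not the product
    count (tills record repeated selections as quantities). If any line is
    the menu token the meal is flagged and totals are left unset.
    """
    badge = lines["badge_id"].iloc[0]
    meal = MealRecord(badge_id=str(badge), site=offer.site, date=offer.date)
    meal.n_products = len(lines)
    if (lines["item_ref"] == "menu").any():
        meal.has_menu = True
        return meal

    comp_idx = compositions.set_index("item_id")
    for _, line in lines.iterrows():
        ref = line["item_ref"]
        units = int(line.get("n_units", 1))
        if ref in offer.composite_members or ref in COMPOSITE_PORTIONS:
            food = day_average_composition(ref, offer, compositions, portions)
            portion = food.portion_g * units
            slot = ref
        else:
            if ref not in comp_idx.index or ref not in offer.slots:
                raise UnresolvableItemError(
                    f"receipt line {badge}/{offer.site}/{offer.date}: "
                    f"item {ref!r} not on that day's offer"
                )
            food = npf.composition_from_row(comp_idx.loc[ref].to_dict()
                                            | {"item_id": ref})
            portion = food.portion_g * units
            slot = offer.slots[ref]
        if slot == "main":
            meal.n_mains += 1
        score = npf.fsam_score(food).score
        meal.items.append((food, portion, score))

    for f in MEAL_TOTAL_FIELDS:
        setattr(meal, f,
                float(sum(getattr(c, f) * p / 100.0 for c, p, _ in meal.items)))
    meal.meal_fsam = meal_fsam(meal.items)
    return meal


def _day_average_frame(offers: pd.DataFrame,
                       compositions: pd.DataFrame,
                       portions: dict | None = None) -> pd.DataFrame:
    """Composite day-averages for every (site, date, token), vectorised."""
    portions = {**COMPOSITE_PORTIONS, **(portions or {})}
    tagged = offers[offers["composite_token"].notna()
                    & (offers["composite_token"] != "")]
    if tagged.empty:
        return pd.DataFrame(columns=["site", "date", "item_ref",
                                     *NUTRIENT_FIELDS, "portion_g", "category"])
    merged = tagged.merge(compositions, on="item_id", how="left",
                          suffixes=("", "_comp"))
    grp = merged.groupby(["site", "date", "composite_token"], as_index=False)
    avg = grp[list(NUTRIENT_FIELDS)].mean()
    avg = avg.rename(columns={"composite_token": "item_ref"})
    avg["portion_g"] = avg["item_ref"].map(portions)
    avg["category"] = np.select(
        [avg["item_ref"] == "cheese", avg["item_ref"] == "beverage"],
        ["cheese", "beverage"], default="general")
    avg["slot"] = avg["item_ref"]
    avg["is_water"] = False
    return avg


def assemble_meals(receipts: pd.DataFrame, offers: pd.DataFrame,
                   compositions: pd.DataFrame,
                   portions: dict | None = None) -> pd.DataFrame:
    """Assemble every receipt in a table at once.

    Returns one row per (badge_id, site, date) with per-meal nutrient
    totals, the energy-weighted score ``meal_fsam``, ``n_products``,
    ``n_mains`` and ``has_menu``. Menu-flagged meals keep NaN totals.
    Deterministic: identical inputs give bit-identical output.
    """
    receipts = receipts.copy()
    if "n_units" not in receipts.columns:
        receipts["n_units"] = 1

    scored = npf.score_table(compositions)
    direct = offers.merge(
        scored[["item_id", *NUTRIENT_FIELDS, "portion_g", "category",
                "score"]],
        on="item_id", how="left")
    direct = direct.rename(columns={"item_id": "item_ref"})

    avg = _day_average_frame(offers, compositions, portions)
    if not avg.empty:
        avg_scores = []
        for _, row in avg.iterrows():
            food = npf.composition_from_row(
                row.to_dict() | {"item_id": row["item_ref"], "label": row["item_ref"]})
            avg_scores.append(npf.fsam_score(food).score)
        avg["score"] = avg_scores

    catalog = pd.concat(
        [direct[["site", "date", "item_ref", *NUTRIENT_FIELDS, "portion_g",
                 "slot", "score"]],
         avg[["site", "date", "item_ref", *NUTRIENT_FIELDS, "portion_g",
              "slot", "score"]] if not avg.empty else None],
        ignore_index=True)

    lines = receipts.merge(catalog, on=["site", "date", "item_ref"],
                           how="left")
    is_menu = lines["item_ref"] == "menu"
    unresolved = lines["score"].isna() & ~is_menu
    if unresolved.any():
        bad = lines.loc[unresolved, ["badge_id", "site", "date", "item_ref"]]
        raise UnresolvableItemError(
            f"{int(unresolved.sum())} receipt line(s) could not be resolved; "
            f"first: {bad.iloc[0].to_dict()}"
        )

    lines["portion_eff"] = lines["portion_g"] * lines["n_units"]
    for f in MEAL_TOTAL_FIELDS:
        lines[f"_tot_{f}"] = lines[f] * lines["portion_eff"] / 100.0
    lines["_energy_w"] = lines["energy_kcal"] * lines["portion_eff"] / 100.0
    lines["_score_energy"] = lines["score"] * lines["_energy_w"]
    lines["_is_main"] = (lines["slot"] == "main").astype(int)

    keys = ["badge_id", "site", "date"]
    grp = lines.groupby(keys, sort=True)
    meals = grp.agg(
        n_products=("item_ref", "size"),
        n_mains=("_is_main", "sum"),
        has_menu=("item_ref", lambda s: bool((s == "menu").any())),
        _energy_w=("_energy_w", "sum"),
        _score_energy=("_score_energy", "sum"),
        item_score_min=("score", "min"),
        item_score_max=("score", "max"),
        **{f: (f"_tot_{f}", "sum") for f in MEAL_TOTAL_FIELDS},
    ).reset_index()
    meals["meal_fsam"] = meals["_score_energy"] / meals["_energy_w"]
    menu_mask = meals["has_menu"]
    meals.loc[menu_mask, [*MEAL_TOTAL_FIELDS, "meal_fsam", "item_score_min",
                          "item_score_max"]] = np.nan
    zero_energy = ~menu_mask & (meals["_energy_w"] <= 0)
    if zero_energy.any():
        raise UndefinedWeightingError(
            f"{int(zero_energy.sum())} meal(s) have zero total energy"
        )
    return meals.drop(columns=["_energy_w", "_score_energy"])


def day_offer_quality(offer: DayOffer, compositions: pd.DataFrame) -> float:
    """Mean FSAm-NPS over all items offered that day (composites expanded).

    This is the day-offer covariate of the trajectory models: it absorbs
    day-to-day changes in what the kitchen proposed.
    """
    scored = npf.score_table(
        compositions[compositions["item_id"].isin(offer.items)])
    return float(scored["score"].mean())


def offer_quality_by_day(offers: pd.DataFrame,
                         compositions: pd.DataFrame) -> pd.DataFrame:
    """``day_offer_quality`` for every (site, date) in an offer table."""
    scored = npf.score_table(compositions)[["item_id", "score"]]
    merged = offers.merge(scored, on="item_id", how="left")
    out = merged.groupby(["site", "date"], as_index=False)["score"].mean()
    return out.rename(columns={"score": "offer_quality"})
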
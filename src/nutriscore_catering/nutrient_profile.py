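"""FSAm-NPS (FSAm/HCSP) nutrient-profile scoring and Nutri-Score letters.

The score underpinning the Nutri-Score front-of-pack label is computed per
100 g (or 100 mL for beverages) as unfavourable points minus favourable
points:

* Points A (0-40): energy density, sugars, saturated fat and sodium, each
  banded 0-10.
* Points C: fruit/vegetables/legumes/nuts percentage (0-5, beverages 0-10),
  fibre (0-5) and protein (0-5).

The final score follows the 2017 rules in force when staff-restaurant
labelling trials were run in France: when Points A reaches 11 and the
fruit-and-vegetable points are below their maximum band, protein points are
not subtracted ("protein cap"), with cheeses exempt; added fats replace the
saturated-fat band with the saturated-fat-to-total-fat ratio band. Higher
scores mean lower nutritional quality. Letters A-E are banded from the
score, with separate beverage bands and the rule that only water may carry
letter A among beverages.

Band comparisons are strict ">" on the lower band edge (a food at exactly
4.5 g sugars scores 0 sugar points); the added-fat ratio table alone uses
">=" on its lower edges, matching the published tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .errors import CompositionError, RatioUndefinedError, UnitCompletenessError

KCAL_TO_KJ = 4.184
SODIUM_MG_TO_SALT_G = 2.5 / 1000.0

CATEGORIES = ("general", "beverage", "cheese", "added_fat")

# Points A band lower edges (strict ">"), foods, per 100 g.
ENERGY_KJ_BANDS = (335, 670, 1005, 1340, 1675, 2010, 2345, 2680, 3015, 3350)
SUGARS_G_BANDS = (4.5, 9.0, 13.5, 18.0, 22.5, 27.0, 31.0, 36.0, 40.0, 45.0)
SATFAT_G_BANDS = (1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0, 9.0, 10.0)
SODIUM_MG_BANDS = (90, 180, 270, 360, 450, 540, 630, 720, 810, 900)

# Beverages, per 100 mL.
BEV_ENERGY_KJ_BANDS = (0, 30, 60, 90, 120, 150, 180, 210, 240, 270)
BEV_SUGARS_G_BANDS = (0.0, 1.5, 3.0, 4.5, 6.0, 7.5, 9.0, 10.5, 12.0, 13.5)

# Added fats: points from 100 x satfat / totalfat, ">=" on lower edges.
SATFAT_RATIO_BANDS = (10, 16, 22, 28, 34, 40, 46, 52, 58, 64)

# Points C band lower edges (strict ">").
FIBRE_G_BANDS = (0.9, 1.9, 2.8, 3.7, 4.7)
PROTEIN_G_BANDS = (1.6, 3.2, 4.8, 6.4, 8.0)
# fvln % -> points are non-linear ladders.
FVLN_FOOD_POINTS = ((40, 1), (60, 2), (80, 5))
FVLN_BEVERAGE_POINTS = ((40, 2), (60, 4), (80, 10))

MAX_FVLN_POINTS = {"general": 5, "cheese": 5, "added_fat": 5, "beverage": 10}

LETTER_COLOURS = {
    "A": "dark-green",
    "B": "light-green",
    "C": "yellow",
    "D": "orange",
    "E": "dark-orange",
}


@dataclass
class FoodComposition:
    """Per-100 g (or per-100 mL) composition of one item.

    Exactly one of ``energy_kj``/``energy_kcal`` and one of
    ``sodium_mg``/``salt_g`` may be omitted; the missing field is derived
    (1 kcal = 4.184 kJ; salt g = sodium mg x 2.5 / 1000).
    """

    item_id: str
    label: str
    category: str
    sugars_g: float
    satfat_g: float
    totalfat_g: float
    protein_g: float
    fibre_g: float
    fvln_pct: float
    portion_g: float
    energy_kj: Optional[float] = None
    energy_kcal: Optional[float] = None
    sodium_mg: Optional[float] = None
    salt_g: Optional[float] = None
    is_water: bool = False

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise CompositionError(f"unknown category {self.category!r}")
        if self.energy_kj is None and self.energy_kcal is None:
            raise UnitCompletenessError(
                f"{self.item_id}: neither energy_kj nor energy_kcal given"
            )
        if self.energy_kj is None:
            self.energy_kj = self.energy_kcal * KCAL_TO_KJ
        if self.energy_kcal is None:
            self.energy_kcal = self.energy_kj / KCAL_TO_KJ
        if self.sodium_mg is None and self.salt_g is None:
            raise UnitCompletenessError(
                f"{self.item_id}: neither sodium_mg nor salt_g given"
            )
        if self.sodium_mg is None:
            self.sodium_mg = self.salt_g / SODIUM_MG_TO_SALT_G
        if self.salt_g is None:
            self.salt_g = self.sodium_mg * SODIUM_MG_TO_SALT_G
        for name in ("energy_kj", "energy_kcal", "sugars_g", "satfat_g",
                     "totalfat_g", "sodium_mg", "salt_g", "protein_g",
                     "fibre_g"):
            v = getattr(self, name)
            if v is None or not math.isfinite(v) or v < 0:
                raise CompositionError(f"{self.item_id}: {name}={v!r} must be >= 0")
        if not 0 <= self.fvln_pct <= 100:
            raise CompositionError(
                f"{self.item_id}: fvln_pct={self.fvln_pct} outside [0, 100]"
            )
        if self.sugars_g > 100:
            raise CompositionError(f"{self.item_id}: sugars_g > 100 g/100 g")
        if self.satfat_g > self.totalfat_g + 1e-9:
            raise CompositionError(
                f"{self.item_id}: satfat_g {self.satfat_g} exceeds totalfat_g "
                f"{self.totalfat_g}"
            )
        if not self.portion_g > 0:
            raise CompositionError(f"{self.item_id}: portion_g must be > 0")


@dataclass
class ProfileScore:
    """Decomposed FSAm-NPS result for one item."""

    points_a: int
    energy_pts: int
    sugars_pts: int
    satfat_pts: int
    sodium_pts: int
    fibre_pts: int
    protein_pts: int
    fvln_pts: int
    score: int
    protein_capped: bool
    points_c: int = field(init=False)

    def __post_init__(self) -> None:
        self.points_c = self.fibre_pts + self.protein_pts + self.fvln_pts


def _band_points(value: float, edges) -> int:
    """Points under the strict ">" lower-edge convention."""
    return int(np.searchsorted(edges, value, side="left"))


def _ladder_points(value: float, ladder) -> int:
    pts = 0
    for edge, p in ladder:
        if value > edge:
            pts = p
    return pts


def energy_points(food: FoodComposition) -> int:
    edges = BEV_ENERGY_KJ_BANDS if food.category == "beverage" else ENERGY_KJ_BANDS
    return _band_points(food.energy_kj, edges)


def sugars_points(food: FoodComposition) -> int:
    edges = BEV_SUGARS_G_BANDS if food.category == "beverage" else SUGARS_G_BANDS
    return _band_points(food.sugars_g, edges)


def satfat_points(food: FoodComposition) -> int:
    if food.category == "added_fat":
        if food.totalfat_g == 0:
            raise RatioUndefinedError(
                f"{food.item_id}: saturated-fat ratio undefined with totalfat_g = 0"
            )
        ratio = 100.0 * food.satfat_g / food.totalfat_g
        # ">=" on the lower edge for the ratio table only.
        return int(np.searchsorted(SATFAT_RATIO_BANDS, ratio, side="right"))
    return _band_points(food.satfat_g, SATFAT_G_BANDS)


def sodium_points(food: FoodComposition) -> int:
    return _band_points(food.sodium_mg, SODIUM_MG_BANDS)


def points_a(food: FoodComposition) -> int:
    """Unfavourable points: energy + sugars + saturated fat + sodium (0-40)."""
    return (energy_points(food) + sugars_points(food)
            + satfat_points(food) + sodium_points(food))


def points_c(food: FoodComposition) -> tuple[int, int, int]:
    """Favourable points ``(fibre_pts, protein_pts, fvln_pts)``."""
    fibre = _band_points(food.fibre_g, FIBRE_G_BANDS)
    protein = _band_points(food.protein_g, PROTEIN_G_BANDS)
    ladder = (FVLN_BEVERAGE_POINTS if food.category == "beverage"
              else FVLN_FOOD_POINTS)
    fvln = _ladder_points(food.fvln_pct, ladder)
    return fibre, protein, fvln


def fsam_score(food: FoodComposition) -> ProfileScore:
    """Full FSAm-NPS decomposition including the protein-cap rule.

    Protein points are withheld when Points A >= 11 unless the item is a
    cheese or its fruit-and-vegetable points sit at the maximum band.
    """
    e, su, sa, so = (energy_points(food), sugars_points(food),
                     satfat_points(food), sodium_points(food))
    a = e + su + sa + so
    fibre, protein, fvln = points_c(food)
    capped = (a >= 11 and food.category != "cheese"
              and fvln < MAX_FVLN_POINTS[food.category])
    if capped:
        score = a - fibre - fvln
    else:
        score = a - (fibre + protein + fvln)
    return ProfileScore(points_a=a, energy_pts=e, sugars_pts=su, satfat_pts=sa,
                        sodium_pts=so, fibre_pts=fibre, protein_pts=protein,
                        fvln_pts=fvln, score=score, protein_capped=capped)


def nutriscore_letter(score: int, category: str,
                      is_water: bool = False) -> tuple[str, str]:
    """Map a score to the five-letter grade and its colour.

    Beverages use their own bands, and letter A is reserved for water
    (flagged explicitly, never inferred from composition): even a
    fruit-juice-style beverage with maximal fruit content grades B at best.
    """
    if category == "beverage":
        if is_water:
            letter = "A"
        elif score <= 1:
            letter = "B"
        elif score <= 5:
            letter = "C"
        elif score <= 9:
            letter = "D"
        else:
            letter = "E"
    else:
        if score <= -1:
            letter = "A"
        elif score <= 2:
            letter = "B"
        elif score <= 10:
            letter = "C"
        elif score <= 18:
            letter = "D"
        else:
            letter = "E"
    return letter, LETTER_COLOURS[letter]


# ---------------------------------------------------------------------------
# Table interface

#: Column order expected in composition tables (is_water optional).
COMPOSITION_COLUMNS = [
    "item_id", "label", "category", "energy_kj", "energy_kcal", "sugars_g",
    "satfat_g", "totalfat_g", "sodium_mg", "salt_g", "protein_g", "fibre_g",
    "fvln_pct", "portion_g",
]


def composition_from_row(row) -> FoodComposition:
    """Build a :class:`FoodComposition` from a composition-table row."""

    def opt(name):
        v = row.get(name, None)
        if v is None or (isinstance(v, float) and math.isnan(v)):
            return None
        return float(v)

    water = row.get("is_water", False)
    if water is None or (isinstance(water, float) and math.isnan(water)):
        water = False
    return FoodComposition(
        item_id=str(row["item_id"]),
        label=str(row.get("label", row["item_id"])),
        category=str(row["category"]),
        energy_kj=opt("energy_kj"),
        energy_kcal=opt("energy_kcal"),
        sugars_g=float(row["sugars_g"]),
        satfat_g=float(row["satfat_g"]),
        totalfat_g=float(row["totalfat_g"]),
        sodium_mg=opt("sodium_mg"),
        salt_g=opt("salt_g"),
        protein_g=float(row["protein_g"]),
        fibre_g=float(row["fibre_g"]),
        fvln_pct=float(row["fvln_pct"]),
        portion_g=float(row["portion_g"]),
        is_water=bool(water),
    )


def score_table(compositions: pd.DataFrame) -> pd.DataFrame:
    """Score every row of a composition table.

    Returns a copy with ``points_a``, ``fibre_pts``, ``protein_pts``,
    ``fvln_pts``, ``score``, ``protein_capped``, ``letter`` and ``colour``
    columns appended.
    """
    out = compositions.copy()
    records = []
    for _, row in out.iterrows():
        food = composition_from_row(row)
        ps = fsam_score(food)
        letter, colour = nutriscore_letter(ps.score, food.category,
                                           food.is_water)
        records.append((ps.points_a, ps.fibre_pts, ps.protein_pts,
                        ps.fvln_pts, ps.score, ps.protein_capped, letter,
                        colour))
    cols = ["points_a", "fibre_pts", "protein_pts", "fvln_pts", "score",
            "protein_capped", "letter", "colour"]
    scored = pd.DataFrame(records, columns=cols, index=out.index)
    return pd.concat([out, scored], axis=1)
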
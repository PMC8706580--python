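"""Shared fixtures: tiny hand-built trial artifacts, all generated in-memory."""

import numpy as np
import pandas as pd
import pytest

from nutriscore_catering import synthetic_data as sd


def make_composition_frame():
    """Six hand-picked items spanning the quality range, two days of use."""
    rows = [
        # item_id, category, kcal, sugars, satfat, totalfat, salt, protein, fibre, fvln, portion
        ("soup", "general", 40, 2.0, 0.2, 1.0, 0.6, 1.5, 1.2, 60, 250),
        ("steak_frites", "general", 220, 0.5, 6.0, 14.0, 1.1, 15.0, 1.5, 10, 280),
        ("ratatouille", "general", 60, 4.0, 0.5, 3.0, 0.5, 1.5, 2.5, 90, 200),
        ("brownie", "general", 400, 38.0, 9.0, 20.0, 0.3, 5.0, 2.0, 0, 90),
        ("apple", "general", 52, 11.0, 0.0, 0.2, 0.0, 0.3, 2.4, 100, 120),
        ("camembert", "cheese", 300, 0.5, 15.0, 23.0, 1.7, 20.0, 0.0, 0, 30),
        ("yog_nature", "general", 60, 5.0, 1.8, 3.0, 0.13, 4.0, 0.0, 0, 125),
        ("cola", "beverage", 42, 10.6, 0.0, 0.0, 0.0, 0.0, 0.0, 0, 250),
        ("water", "beverage", 0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0, 250),
    ]
    df = pd.DataFrame(rows, columns=[
        "item_id", "category", "energy_kcal", "sugars_g", "satfat_g",
        "totalfat_g", "salt_g", "protein_g", "fibre_g", "fvln_pct",
        "portion_g"])
    df["label"] = df["item_id"]
    df["energy_kj"] = df["energy_kcal"] * 4.184
    df["sodium_mg"] = df["salt_g"] / 2.5 * 1000
    df["is_water"] = df["item_id"] == "water"
    return df


def make_offer_frame(dates=("2020-01-06", "2020-01-07"),
                     sites=("intervention", "control")):
    """Every item offered at both sites on every date; cheese/yogurt/beverage
    members tagged with their composite tokens."""
    slots = {
        "soup": ("starter", None), "ratatouille": ("starter", None),
        "steak_frites": ("main", None), "brownie": ("dessert", None),
        "apple": ("dessert", None),
        "camembert": ("cheese", "cheese"),
        "yog_nature": ("dessert", "yogurt"),
        "cola": ("beverage", "beverage"), "water": ("beverage", "beverage"),
    }
    rows = [{"site": s, "date": d, "item_id": item, "slot": slot,
             "composite_token": tok}
            for s in sites for d in dates
            for item, (slot, tok) in slots.items()]
    return pd.DataFrame(rows)


@pytest.fixture
def compositions():
    return make_composition_frame()


@pytest.fixture
def offers():
    return make_offer_frame()


@pytest.fixture
def small_config():
    """A miniature but structurally complete trial configuration."""
    return sd.SimulationConfig(
        seed=11,
        n_participants={"intervention": 60, "control": 40},
        n_service_days=62,
    )


@pytest.fixture(scope="session")
def small_trial():
    """One simulated mini-trial shared across tests (offers, comps, receipts)."""
    cfg = sd.SimulationConfig(
        seed=7, n_participants={"intervention": 90, "control": 60},
        n_service_days=62)
    offers, comps = sd.generate_offers(cfg)
    receipts = sd.simulate_receipts(cfg, offers, comps)
    return cfg, offers, comps, receipts


def random_compositions(rng: np.random.Generator, n: int) -> list:
    """Random valid compositions across all categories, for property tests."""
    from nutriscore_catering.nutrient_profile import FoodComposition
    cats = rng.choice(["general", "beverage", "cheese", "added_fat"], n)
    out = []
    for i in range(n):
        cat = cats[i]
        totalfat = rng.uniform(0, 40) if cat != "added_fat" else rng.uniform(10, 100)
        out.append(FoodComposition(
            item_id=f"r{i}", label=f"r{i}", category=cat,
            energy_kj=rng.uniform(0, 4000),
            sugars_g=rng.uniform(0, 80),
            satfat_g=totalfat * rng.uniform(0, 1),
            totalfat_g=totalfat,
            sodium_mg=rng.uniform(0, 1500),
            protein_g=rng.uniform(0, 30),
            fibre_g=rng.uniform(0, 8),
            fvln_pct=rng.uniform(0, 100),
            portion_g=rng.uniform(10, 400),
        ))
    return out
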
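"""Receipt-level and energy-percentile exclusions with a flow-chart ledger.

The trial removed, in order: meals containing the undetailed fixed-price
menu; receipts with more than 10 products or more than one main course
(taken to be several diners on one till receipt); and finally meals whose
energy fell strictly below the 1st or strictly above the 99th percentile of
the pooled post-receipt-rules energy distribution. Badges seen at both
sites are dropped wholesale. Every removal is tallied in an
:class:`ExclusionLedger` mirroring the study flow chart.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class ExclusionLedger:
    """Flow-chart accounting: every meal in equals kept plus excluded."""

    n_input_meals: int = 0
    n_menu_excluded: int = 0
    n_gt10_products: int = 0
    n_gt1_main: int = 0
    n_energy_trimmed: int = 0
    n_cross_site_excluded: int = 0
    n_input_participants: int = 0
    n_final_participants: int = 0
    per_site_final: dict = field(default_factory=dict)
    energy_lo_kcal: float = math.nan
    energy_hi_kcal: float = math.nan

    @property
    def n_after_receipt_rules(self) -> int:
        return (self.n_input_meals - self.n_menu_excluded
                - self.n_gt10_products - self.n_gt1_main)

    @property
    def n_final(self) -> int:
        return self.n_after_receipt_rules - self.n_energy_trimmed

    def validate(self) -> None:
        if self.per_site_final and sum(self.per_site_final.values()) != self.n_final:
            raise ValueError("per-site splits do not sum to n_final")
        if self.n_final < 0:
            raise ValueError("negative final count: ledger inconsistent")

    def as_text(self) -> str:
        lines = [
            f"meals recorded over the study period: {self.n_input_meals}",
            f"  - menu receipts excluded:           {self.n_menu_excluded}",
            f"  - >10-product receipts excluded:    {self.n_gt10_products}",
            f"  - >1-main-course receipts excluded: {self.n_gt1_main}",
            f"meals after receipt rules:            {self.n_after_receipt_rules}",
            f"  - energy-percentile trimmed:        {self.n_energy_trimmed}"
            f" (thresholds {self.energy_lo_kcal:.0f}-{self.energy_hi_kcal:.0f} kcal)"
            if not math.isnan(self.energy_lo_kcal) else
            f"  - energy-percentile trimmed:        {self.n_energy_trimmed}",
            f"meals included in the analysis:       {self.n_final}",
        ]
        for site, n in sorted(self.per_site_final.items()):
            lines.append(f"    {site}: {n}")
        if self.n_input_participants:
            lines.append(f"participants: {self.n_input_participants} -> "
                         f"{self.n_final_participants}")
        return "\n".join(lines)


def sas_percentile(x: np.ndarray, p: float) -> float:
    """Empirical percentile with averaging at integer ranks.

    With n observations sorted ascending, let np = p*n: if np is an
    integer the percentile is the mean of order statistics np and np+1,
    otherwise order statistic ceil(np). This is the definition used by the
    statistical software the trial analysis ran on.
    """
    xs = np.sort(np.asarray(x, dtype=float))
    n = len(xs)
    if n == 0:
        raise ValueError("empty sample")
    t = p * n
    if abs(t - round(t)) < 1e-9:
        k = int(round(t))
        if k <= 0:
            return float(xs[0])
        if k >= n:
            return float(xs[-1])
        return float((xs[k - 1] + xs[k]) / 2.0)
    k = int(math.ceil(t))
    return float(xs[min(max(k, 1), n) - 1])


def receipt_rules(meals: pd.DataFrame) -> tuple[pd.DataFrame, ExclusionLedger]:
    """Apply menu -> >10 products -> >1 main, first matching rule counts.

    Boundary is inclusive: exactly 10 products or exactly 1 main is kept.
    """
    ledger = ExclusionLedger(n_input_meals=len(meals),
                             n_input_participants=meals["badge_id"].nunique())
    menu = meals["has_menu"].astype(bool)
    gt10 = ~menu & (meals["n_products"] > 10)
    gt1main = ~menu & ~gt10 & (meals["n_mains"] > 1)
    ledger.n_menu_excluded = int(menu.sum())
    ledger.n_gt10_products = int(gt10.sum())
    ledger.n_gt1_main = int(gt1main.sum())
    kept = meals[~(menu | gt10 | gt1main)].copy()
    return kept, ledger


def energy_percentile_trim(meals: pd.DataFrame,
                           ledger: ExclusionLedger | None = None,
                           lo: float = 0.01, hi: float = 0.99,
                           ) -> tuple[pd.DataFrame, ExclusionLedger]:
    """Drop meals strictly below the ``lo`` or strictly above the ``hi``
    empirical energy percentile, pooled over both sites.

    Strict comparisons mirror "inferior to the 1st percentile or over the
    99th". Realised thresholds are recorded in the ledger.
    """
    if ledger is None:
        ledger = ExclusionLedger(n_input_meals=len(meals),
                                 n_input_participants=meals["badge_id"].nunique())
    if len(meals) < 100:
        warnings.warn("fewer than 100 meals: percentile thresholds unstable",
                      stacklevel=2)
    energy = meals["energy_kcal"].to_numpy(dtype=float)
    lo_thr = sas_percentile(energy, lo)
    hi_thr = sas_percentile(energy, hi)
    drop = (energy < lo_thr) | (energy > hi_thr)
    ledger.n_energy_trimmed = int(drop.sum())
    ledger.energy_lo_kcal = lo_thr
    ledger.energy_hi_kcal = hi_thr
    kept = meals[~drop].copy()
    ledger.per_site_final = kept.groupby("site").size().to_dict()
    ledger.n_final_participants = kept["badge_id"].nunique()
    ledger.validate()
    return kept, ledger


def cross_site_badges(meals: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Drop every meal of any badge observed at both sites.

    Badges appearing at both restaurants cannot be a single diner's
    trajectory (or indicate badge sharing), so all their meals go. Returns
    the kept meals and the number of meals removed.
    """
    sites_per_badge = meals.groupby("badge_id")["site"].nunique()
    crossing = set(sites_per_badge[sites_per_badge > 1].index)
    kept = meals[~meals["badge_id"].isin(crossing)].copy()
    return kept, len(meals) - len(kept)


def apply_all(meals: pd.DataFrame) -> tuple[pd.DataFrame, ExclusionLedger]:
    """Full exclusion cascade: cross-site badges, receipt rules, energy trim."""
    kept, n_cross = cross_site_badges(meals)
    kept, ledger = receipt_rules(kept)
    ledger.n_cross_site_excluded = n_cross
    kept, ledger = energy_percentile_trim(kept, ledger)
    return kept, ledger
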
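"""Reading and writing the pipeline's delimited-text artifacts.

Everything is plain UTF-8 CSV: composition tables (one row per item,
header matching the composition fields), offer tables (site, date,
item_id, slot, composite_token), receipts (badge_id, site, date, item_ref,
n_units) and assembled-meal tables. Dates are ISO-8601 strings
throughout.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

_COMPOSITION_REQUIRED = {"item_id", "category", "sugars_g", "satfat_g",
                         "totalfat_g", "protein_g", "fibre_g", "fvln_pct",
                         "portion_g"}
_RECEIPT_REQUIRED = {"badge_id", "site", "date", "item_ref"}
_OFFER_REQUIRED = {"site", "date", "item_id", "slot"}


def _check(df: pd.DataFrame, required: set, what: str, path) -> pd.DataFrame:
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{what} table {path} lacks columns: {sorted(missing)}")
    return df


def read_compositions(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"item_id": str})
    return _check(df, _COMPOSITION_REQUIRED, "composition", path)


def read_receipts(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"badge_id": str, "item_ref": str,
                                  "site": str, "date": str})
    df = _check(df, _RECEIPT_REQUIRED, "receipt", path)
    if "n_units" not in df.columns:
        df["n_units"] = 1
    return df


def read_offers(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"item_id": str, "site": str, "date": str})
    return _check(df, _OFFER_REQUIRED, "offer", path)


def read_meals(path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"badge_id": str, "site": str, "date": str})


def write_table(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path


def write_fit_result(fit, path) -> Path:
    """FitResult -> delimited text: term, estimate, ci_low, ci_high, p."""
    out = fit.terms.reset_index(names="term")
    return write_table(out, path)
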
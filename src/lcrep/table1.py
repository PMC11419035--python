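"""Category/subcategory count tables and their aggregation.

The bundled fixture transcribes the repository's published sequence-count
table: per (category, subcategory) row, kappa/lambda counts for the three
coverage classes (complete, incomplete, fragment-or-non-productive) plus a
row total. Aggregation derives category totals, plasma-cell-dyscrasia
(PCD = AL-PCD + Other-PCD) totals, "analyzed" (complete + incomplete)
totals and percentage shares, reported both as raw fractions and rounded
half-away-from-zero to the published precision.
"""

from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path

import pandas as pd

from lcrep.reference import bundled_data_path

CLASS_COLS = [
    "complete_kappa", "complete_lambda",
    "incomplete_kappa", "incomplete_lambda",
    "fragment_kappa", "fragment_lambda",
]
PCD_CATEGORIES = ("AL-PCD", "Other-PCD")


def round_half_up(value: float, ndigits: int = 1) -> float:
    """Decimal rounding, half away from zero (matches printed percentages)."""
    quantum = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(quantum, rounding=ROUND_HALF_UP))


def percent_share(numerator: float, denominator: float, ndigits: int = 1) -> dict:
    """Share as raw fraction plus printed-precision percentage.

    Returns {"fraction", "percent"}; both None when the denominator is 0.
    """
    if denominator == 0:
        return {"fraction": None, "percent": None}
    fraction = numerator / denominator
    return {"fraction": fraction, "percent": round_half_up(100.0 * fraction, ndigits)}


def load_category_counts(path: str | Path | None = None) -> pd.DataFrame:
    """Load and validate a category count table (bundled fixture by default)."""
    if path is None:
        path = bundled_data_path("al_base_table1.tsv")
    table = pd.read_csv(path, sep="\t", comment="#")
    required = {"category", "subcategory", "total", *CLASS_COLS}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"count table missing columns: {sorted(missing)}")
    if (table[CLASS_COLS + ["total"]] < 0).any().any():
        raise ValueError("count table contains negative counts")
    for _, row in table.iterrows():
        cell_sum = int(row[CLASS_COLS].sum())
        if cell_sum != int(row["total"]):
            raise ValueError(
                f"row ({row['category']}, {row['subcategory']}): cells sum to "
                f"{cell_sum} but total column says {int(row['total'])}"
            )
    return table


def _class_totals(rows: pd.DataFrame) -> dict:
    complete = int(rows["complete_kappa"].sum() + rows["complete_lambda"].sum())
    incomplete = int(rows["incomplete_kappa"].sum() + rows["incomplete_lambda"].sum())
    fragment = int(rows["fragment_kappa"].sum() + rows["fragment_lambda"].sum())
    kappa_analyzed = int(rows["complete_kappa"].sum() + rows["incomplete_kappa"].sum())
    lambda_analyzed = int(rows["complete_lambda"].sum() + rows["incomplete_lambda"].sum())
    return {
        "complete": complete,
        "incomplete": incomplete,
        "fragment": fragment,
        "analyzed": complete + incomplete,
        "total": complete + incomplete + fragment,
        "kappa_analyzed": kappa_analyzed,
        "lambda_analyzed": lambda_analyzed,
        "kappa_share_analyzed": percent_share(
            kappa_analyzed, complete + incomplete
        ),
        "lambda_share_analyzed": percent_share(
            lambda_analyzed, complete + incomplete
        ),
    }


def aggregate_counts(table: pd.DataFrame) -> dict:
    """Aggregate a validated count table into totals and shares.

    The summary carries per-category and per-subcategory class totals and
    kappa/lambda shares, plus PCD-wide rollups (PCD = the two monoclonal
    disease categories combined) with complete/incomplete shares.
    """
    summary: dict = {"categories": {}, "subcategories": {}}
    for category, rows in table.groupby("category", sort=True):
        summary["categories"][category] = _class_totals(rows)
        for subcategory, sub_rows in rows.groupby("subcategory", sort=True):
            summary["subcategories"][(category, subcategory)] = _class_totals(sub_rows)

    pcd_rows = table[table["category"].isin(PCD_CATEGORIES)]
    pcd = _class_totals(pcd_rows)
    pcd["complete_share"] = percent_share(pcd["complete"], pcd["total"])
    pcd["incomplete_share"] = percent_share(pcd["incomplete"], pcd["total"])
    pcd["fragment_share"] = percent_share(pcd["fragment"], pcd["total"])
    summary["pcd"] = pcd

    # shares of a subcategory's analyzed sequences within its category
    shares: dict = {}
    for (category, subcategory), totals in summary["subcategories"].items():
        cat_analyzed = summary["categories"][category]["analyzed"]
        shares[(category, subcategory)] = {
            "analyzed_share": percent_share(totals["analyzed"], cat_analyzed),
            "kappa_share_of_category": percent_share(
                totals["kappa_analyzed"], cat_analyzed
            ),
            "lambda_share_of_category": percent_share(
                totals["lambda_analyzed"], cat_analyzed
            ),
        }
    summary["subcategory_shares"] = shares
    return summary


def load_printed_usage_counts(path: str | Path | None = None) -> pd.DataFrame:
    """Published per-cohort numerator/denominator counts for share arithmetic."""
    if path is None:
        path = bundled_data_path("printed_usage_counts.tsv")
    table = pd.read_csv(path, sep="\t", comment="#")
    required = {"cohort", "quantity", "count", "total"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"printed count table missing columns: {sorted(missing)}")
    return table
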
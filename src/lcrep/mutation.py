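"""Mutation-frequency statistic and group-wise rank comparisons.

The per-record statistic expresses the somatic load of a variable domain
as a percentage of its germline length, combining three additive terms
with length-consistent denominators::

    100 * ( S / L  +  I / (L + I)  +  D / (L - D) )

where S, I, D are the amino-acid substitution, insertion and deletion
counts against the assigned germline V-J region of length L. The three
denominators differ deliberately: insertions lengthen and deletions
shorten the observed domain relative to its germline.
"""

from __future__ import annotations

import math
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats as sps

from lcrep.enrichment import bh_adjust


def mutation_frequency(
    substitutions: int, insertions: int, deletions: int, germline_length: int
) -> float:
    """Percentage mutation load of one record; see module docstring."""
    S, I, D, L = substitutions, insertions, deletions, germline_length
    for name, value in (("substitutions", S), ("insertions", I),
                        ("deletions", D), ("germline_length", L)):
        if value < 0 or value != int(value):
            raise ValueError(f"{name} must be a non-negative integer, got {value!r}")
    if L <= 0:
        raise ValueError("germline_length must be positive")
    if S > L:
        raise ValueError(f"substitutions ({S}) exceed germline length ({L})")
    if D >= L:
        raise ValueError(f"deletions ({D}) must be fewer than germline length ({L})")
    return 100.0 * (S / L + I / (L + I) + D / (L - D))


def mutation_profiles(assignments: pd.DataFrame) -> pd.DataFrame:
    """Per-record mutation profiles from an assignment table.

    Only records with complete coverage carry a defined V-domain load; the
    returned frame is restricted to them.
    """
    rows = []
    complete = assignments[assignments["coverage_class"] == "complete"]
    for _, rec in complete.iterrows():
        rows.append(
            {
                "record_id": rec["sequence_id"],
                "cohort": rec["cohort"],
                "v_gene": rec["v_call"],
                "locus": rec["locus"],
                "fraction_mutated": mutation_frequency(
                    int(rec["substitutions"]),
                    int(rec["insertions"]),
                    int(rec["deletions"]),
                    int(rec["germline_length"]),
                ),
            }
        )
    return pd.DataFrame(
        rows, columns=["record_id", "cohort", "v_gene", "locus", "fraction_mutated"]
    )


def compare_groups(
    values: pd.DataFrame,
    value_col: str,
    unit_col: str,
    cohort_col: str = "cohort",
    case_cohort: str = "AL",
    min_size: int = 5,
) -> tuple[pd.DataFrame, list[str]]:
    """Rank-based comparison of a per-record value between cohorts.

    Within each grouping unit (e.g. locus or V gene) an omnibus
    Kruskal-Wallis test is run across all cohorts, plus pairwise
    Wilcoxon rank-sum tests of the case cohort against every other
    cohort. Pairwise p-values are BH-adjusted jointly across all units.
    Units where any involved cohort has fewer than ``min_size``
    observations are skipped with a logged reason.

    Returns (comparison table, skipped-unit log).
    """
    if values.empty or values[unit_col].nunique() == 0:
        raise ValueError("no grouping units to compare")
    rows = []
    skipped: list[str] = []
    for unit, unit_df in values.groupby(unit_col, sort=True):
        groups = {
            cohort: sub[value_col].to_numpy()
            for cohort, sub in unit_df.groupby(cohort_col, sort=True)
        }
        if case_cohort not in groups:
            skipped.append(f"{unit}: no {case_cohort} observations")
            continue
        if len(groups[case_cohort]) < min_size:
            skipped.append(
                f"{unit}: only {len(groups[case_cohort])} {case_cohort} observations"
                f" (< {min_size})"
            )
            continue
        eligible = {
            cohort: vals for cohort, vals in groups.items() if len(vals) >= min_size
        }
        if len(eligible) < 2:
            skipped.append(f"{unit}: fewer than two cohorts with >= {min_size} observations")
            continue
        pooled = np.concatenate(list(eligible.values()))
        if np.ptp(pooled) == 0:  # kruskal raises on all-identical input
            omnibus_p = 1.0
        else:
            omnibus_p = float(sps.kruskal(*eligible.values()).pvalue)
        for cohort, vals in eligible.items():
            if cohort == case_cohort:
                continue
            case_vals = eligible[case_cohort]
            if np.ptp(np.concatenate([case_vals, vals])) == 0:
                p = 1.0
            else:
                p = float(
                    sps.mannwhitneyu(case_vals, vals, alternative="two-sided").pvalue
                )
            rows.append(
                {
                    "unit": unit,
                    "comparison": f"{case_cohort} vs {cohort}",
                    "n_case": len(case_vals),
                    "n_other": len(vals),
                    "median_case": float(np.median(case_vals)),
                    "median_other": float(np.median(vals)),
                    "omnibus_p": omnibus_p,
                    "p_value": min(p, 1.0),
                }
            )
    table = pd.DataFrame(
        rows,
        columns=[
            "unit", "comparison", "n_case", "n_other",
            "median_case", "median_other", "omnibus_p", "p_value",
        ],
    )
    if not table.empty:
        table["q_value"] = bh_adjust(table["p_value"].to_numpy())
    else:
        table["q_value"] = pd.Series(dtype=float)
    return table, skipped


def compare_mutation_loads(
    profiles: pd.DataFrame,
    grouping: str = "locus",
    case_cohort: str = "AL",
    min_size: int = 5,
) -> tuple[pd.DataFrame, list[str]]:
    """Compare mutation loads between cohorts, grouped by locus or V gene."""
    if grouping not in ("locus", "v_gene"):
        raise ValueError("grouping must be 'locus' or 'v_gene'")
    return compare_groups(
        profiles,
        value_col="fraction_mutated",
        unit_col=grouping,
        case_cohort=case_cohort,
        min_size=min_size,
    )
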
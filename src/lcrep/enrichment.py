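"""Paralog-collapsed gene-usage tables and per-gene enrichment statistics.

Enrichment of a V gene in a case cohort over a control cohort is measured
by the 2x2 odds ratio (gene vs all other genes, case vs control), which is
the exact single-predictor equivalent of a logistic-regression fit.
Confidence intervals and p-values use the Wald approximation on the log
odds ratio; Haldane-Anscombe continuity correction (+0.5 on all four
cells) applies whenever any cell is zero. Multiple testing is controlled
with Benjamini-Hochberg FDR across all genes jointly, both loci together.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass(frozen=True)
class EnrichmentResult:
    v_gene: str
    case_count: int
    control_count: int
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    q_value: float = float("nan")
    direction: str = "none"  # over | under | none


def tabulate_usage(assignments: pd.DataFrame, cohorts: list[str]) -> pd.DataFrame:
    """Per-gene counts per cohort over assignable records.

    Counts include coverage classes complete and incomplete only; excluded
    records never contribute. The ``v_call`` column is expected to be
    paralog-collapsed already (assignment reports collapsed names).
    Returns a genes x cohorts count table (all-zero genes absent).
    """
    if not cohorts:
        raise ValueError("cohorts must be non-empty")
    present = set(assignments["cohort"].unique())
    missing = [c for c in cohorts if c not in present]
    if missing:
        raise ValueError(f"cohort labels absent from metadata: {missing}")
    counted = assignments[
        assignments["coverage_class"].isin(["complete", "incomplete"])
        & assignments["cohort"].isin(cohorts)
        & assignments["v_call"].notna()
    ]
    table = (
        counted.groupby(["v_call", "cohort"], sort=True)
        .size()
        .unstack(fill_value=0)
        .reindex(columns=cohorts, fill_value=0)
    )
    table.index.name = "v_gene"
    table.columns.name = None
    return table[table.sum(axis=1) > 0].astype(int)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p_values must be a non-empty 1-d array")
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.clip(q_sorted, 0.0, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def _two_by_two(a: int, A: int, b: int, B: int) -> tuple[float, float, float, float]:
    """OR, Wald CI and p for one gene: (a of A cases) vs (b of B controls)."""
    cells = [a, A - a, b, B - b]
    if min(cells) < 0:
        raise ValueError("negative cell count")
    if 0 in cells:
        cells = [c + 0.5 for c in cells]
    a_, c_, b_, d_ = cells
    or_ = (a_ * d_) / (b_ * c_)
    se = math.sqrt(1 / a_ + 1 / c_ + 1 / b_ + 1 / d_)
    log_or = math.log(or_)
    z = sps.norm.ppf(0.975)
    ci_low = math.exp(log_or - z * se)
    ci_high = math.exp(log_or + z * se)
    p = 2.0 * sps.norm.sf(abs(log_or) / se)
    return or_, ci_low, ci_high, min(p, 1.0)


def gene_enrichment(
    table: pd.DataFrame,
    case_cohort: str,
    control_cohort: str,
    fdr_level: float = 0.05,
    min_count: int = 1,
) -> list[EnrichmentResult]:
    """Per-gene enrichment of the case cohort over the control cohort.

    Genes observed fewer than ``min_count`` times in both cohorts are
    dropped before adjustment. Results are sorted by descending odds
    ratio (ranked enrichment).
    """
    for cohort in (case_cohort, control_cohort):
        if cohort not in table.columns:
            raise ValueError(f"cohort {cohort!r} not in usage table")
    A = int(table[case_cohort].sum())
    B = int(table[control_cohort].sum())
    if A <= 0 or B <= 0:
        raise ValueError("both cohorts need positive totals")
    genes = [
        g
        for g in table.index
        if max(table.at[g, case_cohort], table.at[g, control_cohort]) >= min_count
    ]
    if not genes:
        return []
    raw = []
    for g in genes:
        a = int(table.at[g, case_cohort])
        b = int(table.at[g, control_cohort])
        or_, lo, hi, p = _two_by_two(a, A, b, B)
        raw.append((g, a, b, or_, lo, hi, p))
    q_values = bh_adjust([r[6] for r in raw])
    results = []
    for (g, a, b, or_, lo, hi, p), q in zip(raw, q_values):
        if q <= fdr_level:
            direction = "over" if or_ > 1 else "under"
        else:
            direction = "none"
        results.append(
            EnrichmentResult(
                v_gene=g, case_count=a, control_count=b,
                odds_ratio=or_, ci_low=lo, ci_high=hi,
                p_value=p, q_value=float(q), direction=direction,
            )
        )
    results.sort(key=lambda r: (-r.odds_ratio, r.v_gene))
    return results


def enrichment_table(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "v_gene": r.v_gene,
                "case_count": r.case_count,
                "control_count": r.control_count,
                "odds_ratio": r.odds_ratio,
                "ci_low": r.ci_low,
                "ci_high": r.ci_high,
                "p_value": r.p_value,
                "q_value": r.q_value,
                "direction": r.direction,
            }
            for r in results
        ],
        columns=[
            "v_gene", "case_count", "control_count", "odds_ratio",
            "ci_low", "ci_high", "p_value", "q_value", "direction",
        ],
    )


def usage_frequencies(table: pd.DataFrame, cohort: str) -> pd.Series:
    """Per-gene relative frequencies for one cohort column."""
    total = table[cohort].sum()
    if total <= 0:
        raise ValueError(f"cohort {cohort!r} has zero total")
    return table[cohort] / total


def usage_correlation(freqs_a, freqs_b) -> tuple[float, float]:
    """Pearson correlation between two gene-frequency vectors.

    Vectors are aligned over the union of genes when given as Series
    (missing genes count as frequency 0); plain arrays must already be
    aligned. Requires length >= 3 and non-zero variance in both vectors.
    """
    if isinstance(freqs_a, pd.Series) and isinstance(freqs_b, pd.Series):
        genes = sorted(set(freqs_a.index) | set(freqs_b.index))
        x = freqs_a.reindex(genes).fillna(0.0).to_numpy(dtype=float)
        y = freqs_b.reindex(genes).fillna(0.0).to_numpy(dtype=float)
    else:
        x = np.asarray(freqs_a, dtype=float)
        y = np.asarray(freqs_b, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need aligned frequency vectors of length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero-variance frequency vector: correlation undefined")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)
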
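"""Physicochemical scores for variable-domain sequences.

Isoelectric point under the EMBOSS pKa set (free N- and C-termini, since
only the variable domain is scored) and mean Kyte-Doolittle hydropathy
(GRAVY). Unknown residues are charge-neutral for pI and excluded from
both the numerator and denominator of GRAVY.
"""

from __future__ import annotations

import pandas as pd

from lcrep.mutation import compare_groups

#: EMBOSS pKa values.
PKA_NTERM = 8.6
PKA_CTERM = 3.6
PKA_POSITIVE = {"K": 10.8, "R": 12.5, "H": 6.5}
PKA_NEGATIVE = {"D": 3.9, "E": 4.1, "C": 8.5, "Y": 10.1}

#: Kyte-Doolittle hydropathy scale.
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

_CHARGE_TOL = 1e-4
_MAX_ITER = 200


def net_charge(seq: str, ph: float) -> float:
    """Net charge of a free peptide at the given pH (EMBOSS pKa model)."""
    if not seq:
        raise ValueError("empty sequence")
    seq = seq.upper()
    charge = 1.0 / (1.0 + 10.0 ** (ph - PKA_NTERM))
    charge -= 1.0 / (1.0 + 10.0 ** (PKA_CTERM - ph))
    for aa in seq:
        if aa in PKA_POSITIVE:
            charge += 1.0 / (1.0 + 10.0 ** (ph - PKA_POSITIVE[aa]))
        elif aa in PKA_NEGATIVE:
            charge -= 1.0 / (1.0 + 10.0 ** (PKA_NEGATIVE[aa] - ph))
    return charge


def isoelectric_point(seq: str) -> float:
    """pH of zero net charge, by bisection on [0, 14].

    Net charge is strictly decreasing in pH, positive at pH 0 (free
    N-terminus) and negative at pH 14 (free C-terminus), so the bisection
    always converges.
    """
    if not seq:
        raise ValueError("empty sequence")
    lo, hi = 0.0, 14.0
    ph = 7.0
    for _ in range(_MAX_ITER):
        ph = (lo + hi) / 2.0
        charge = net_charge(seq, ph)
        if abs(charge) < _CHARGE_TOL:
            break
        if charge > 0:
            lo = ph
        else:
            hi = ph
    return ph


def gravy(seq: str) -> float:
    """Grand average of hydropathy: mean Kyte-Doolittle value per residue."""
    if not seq:
        raise ValueError("empty sequence")
    values = [KYTE_DOOLITTLE[aa] for aa in seq.upper() if aa in KYTE_DOOLITTLE]
    if not values:
        raise ValueError("sequence contains no standard residues")
    return sum(values) / len(values)


def property_records(records) -> pd.DataFrame:
    """Per-record pI and GRAVY for an iterable of rearranged records.

    Only protein-space sequences are meaningful here; nucleotide records
    should be translated upstream.
    """
    rows = []
    for rec in records:
        rows.append(
            {
                "record_id": rec.record_id,
                "cohort": rec.cohort,
                "pI": isoelectric_point(rec.seq),
                "gravy": gravy(rec.seq),
            }
        )
    return pd.DataFrame(rows, columns=["record_id", "cohort", "pI", "gravy"])


def compare_properties(
    properties: pd.DataFrame,
    unit_col: str = "v_gene",
    case_cohort: str = "AL",
    min_size: int = 5,
) -> tuple[pd.DataFrame, list[str]]:
    """Cohort comparison of pI and GRAVY per grouping unit.

    Same contract as the mutation-load comparison, applied to both
    properties; the returned table carries a ``property`` column.
    """
    tables = []
    skipped: list[str] = []
    for prop in ("pI", "gravy"):
        table, skip = compare_groups(
            properties,
            value_col=prop,
            unit_col=unit_col,
            case_cohort=case_cohort,
            min_size=min_size,
        )
        table.insert(0, "property", prop)
        tables.append(table)
        skipped.extend(f"{prop}: {s}" for s in skip)
    return pd.concat(tables, ignore_index=True), skipped
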
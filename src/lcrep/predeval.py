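"""Scoring of externally produced amyloidogenicity predictions.

Consumes a prediction table (record_id, tool, call) together with cohort
labels: AL-labelled records form the positive class, MM/control records
the negative class. Records whose prediction is missing are excluded from
the confusion counts and reported. Sensitivity, specificity and accuracy
follow the standard confusion-matrix definitions; metrics with a zero
denominator are reported as unavailable (None), never as 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

POSITIVE_CALL = "amyloidogenic"
NEGATIVE_CALL = "non-amyloidogenic"
MISSING_CALL = "missing"

#: Cohort labels forming the positive (amyloidogenic) class.
POSITIVE_LABELS = frozenset({"AL"})


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0
    n_missing: int = 0

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def build_confusion(
    predictions: pd.DataFrame,
    labels: pd.DataFrame,
    positive_labels: frozenset[str] = POSITIVE_LABELS,
) -> ConfusionCounts:
    """Confusion counts for one tool's prediction table.

    ``predictions`` needs columns record_id and call (amyloidogenic /
    non-amyloidogenic / missing); ``labels`` needs record_id and cohort.
    Every predicted record must have a label.
    """
    label_map = dict(zip(labels["record_id"], labels["cohort"]))
    tp = fp = tn = fn = n_missing = 0
    for _, row in predictions.iterrows():
        record_id, call = row["record_id"], row["call"]
        if record_id not in label_map:
            raise ValueError(f"prediction for unknown record {record_id!r}")
        if call == MISSING_CALL:
            n_missing += 1
            continue
        if call not in (POSITIVE_CALL, NEGATIVE_CALL):
            raise ValueError(f"{record_id}: unknown call {call!r}")
        is_positive_truth = label_map[record_id] in positive_labels
        predicted_positive = call == POSITIVE_CALL
        if is_positive_truth and predicted_positive:
            tp += 1
        elif is_positive_truth:
            fn += 1
        elif predicted_positive:
            fp += 1
        else:
            tn += 1
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn, n_missing=n_missing)


def metrics(confusion: ConfusionCounts) -> dict[str, float | None]:
    """Sensitivity, specificity and accuracy; None where undefined."""
    c = confusion
    sens = c.tp / (c.tp + c.fn) if (c.tp + c.fn) > 0 else None
    spec = c.tn / (c.tn + c.fp) if (c.tn + c.fp) > 0 else None
    acc = (c.tp + c.tn) / c.total if c.total > 0 else None
    return {"sensitivity": sens, "specificity": spec, "accuracy": acc}


def evaluate_tools(
    predictions: pd.DataFrame,
    labels: pd.DataFrame,
    tool_loci: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Per-tool metric table for a multi-tool prediction file.

    ``tool_loci`` optionally restricts a tool to one locus (e.g. a
    lambda-only tool); restriction requires a ``locus`` column in
    ``labels`` and drops out-of-scope records before scoring.
    """
    rows = []
    for tool, tool_preds in predictions.groupby("tool", sort=True):
        scoped = tool_preds
        if tool_loci and tool in tool_loci and "locus" in labels.columns:
            in_scope = set(
                labels.loc[labels["locus"] == tool_loci[tool], "record_id"]
            )
            scoped = tool_preds[tool_preds["record_id"].isin(in_scope)]
        confusion = build_confusion(scoped, labels)
        m = metrics(confusion)
        rows.append(
            {
                "tool": tool,
                "n_evaluated": confusion.total,
                "n_missing": confusion.n_missing,
                "tp": confusion.tp,
                "fp": confusion.fp,
                "tn": confusion.tn,
                "fn": confusion.fn,
                **m,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "tool", "n_evaluated", "n_missing", "tp", "fp", "tn", "fn",
            "sensitivity", "specificity", "accuracy",
        ],
    )
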
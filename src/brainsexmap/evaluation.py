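"""Classification metrics and subgroup reporting for the sex classifier.

Male is the positive class throughout. Predictions are thresholded at a
probability of 0.5 (an exact tie classifies as Female so the contract is
total). Balanced accuracy is the unweighted mean of the per-class recalls;
AUC is the rank statistic over predicted probabilities. Metrics that need
both classes are reported as NaN (undefined), never as 0, when a subgroup
contains a single class.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from sklearn import metrics as skm

from .errors import ConfigurationError, DegenerateInputError

__all__ = [
    "make_predictions", "confusion", "MetricsReport", "compute_metrics",
    "balanced_accuracy_from_recalls", "round_half_up", "age_bin",
    "subgroup_report", "AGE_BIN_LABELS",
]

AGE_BIN_LABELS = ("<55", "55-70", ">=70")


def round_half_up(x: float, decimals: int = 1) -> float:
    """Decimal half-up rounding (the convention printed tables use), unlike
    Python's banker's rounding."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def make_predictions(subject_ids, prob_male, true_sex) -> pd.DataFrame:
    """Assemble the canonical prediction frame: subject_id, prob_male,
    pred, true. ``pred`` is 'M' iff prob_male > 0.5."""
    prob = np.asarray(prob_male, dtype=float)
    if np.any((prob < 0) | (prob > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    return pd.DataFrame({
        "subject_id": list(subject_ids),
        "prob_male": prob,
        "pred": np.where(prob > 0.5, "M", "F"),
        "true": list(true_sex),
    })


def confusion(preds: pd.DataFrame) -> dict[str, int]:
    """TP/FP/TN/FN counts with Male positive; counts sum to n."""
    if preds.empty:
        raise DegenerateInputError("no predictions")
    p = preds["pred"].to_numpy()
    t = preds["true"].to_numpy()
    return {
        "TP": int(np.sum((p == "M") & (t == "M"))),
        "FP": int(np.sum((p == "M") & (t == "F"))),
        "TN": int(np.sum((p == "F") & (t == "F"))),
        "FN": int(np.sum((p == "F") & (t == "M"))),
    }


@dataclass
class MetricsReport:
    n: int
    accuracy: float
    balanced_accuracy: float
    precision: float
    recall: float
    f1: float
    auc_roc: float
    recall_female: float
    recall_male: float
    flags: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return asdict(self)


def balanced_accuracy_from_recalls(recall_f: float, recall_m: float) -> float:
    """Balanced accuracy is the unweighted mean of the per-sex recalls."""
    return 0.5 * (recall_f + recall_m)


def compute_metrics(preds: pd.DataFrame) -> MetricsReport:
    if preds.empty:
        raise DegenerateInputError("no predictions")
    t = (preds["true"] == "M").to_numpy(dtype=int)
    p = (preds["pred"] == "M").to_numpy(dtype=int)
    prob = preds["prob_male"].to_numpy(dtype=float)
    flags = []
    both = len(np.unique(t)) == 2
    acc = float(skm.accuracy_score(t, p))
    if both:
        recall_m = float(skm.recall_score(t, p, pos_label=1, zero_division=0))
        recall_f = float(skm.recall_score(t, p, pos_label=0, zero_division=0))
        bal = balanced_accuracy_from_recalls(recall_f, recall_m)
        auc = float(skm.roc_auc_score(t, prob))
    else:
        only = "M" if t[0] == 1 else "F"
        flags.append(f"single-class subgroup ({only} only): balanced accuracy "
                     "and AUC undefined")
        recall_m = float(np.mean(p[t == 1])) if np.any(t == 1) else math.nan
        recall_f = float(np.mean(1 - p[t == 0])) if np.any(t == 0) else math.nan
        bal = math.nan
        auc = math.nan
    precision = float(skm.precision_score(t, p, zero_division=np.nan))
    recall = recall_m if not math.isnan(recall_m) else math.nan
    if math.isnan(precision) or math.isnan(recall):
        f1 = math.nan
        if math.isnan(precision):
            flags.append("no positive predictions: precision/F1 undefined")
    else:
        f1 = float(skm.f1_score(t, p, zero_division=0))
    return MetricsReport(n=len(preds), accuracy=acc, balanced_accuracy=bal,
                         precision=precision, recall=recall, f1=f1,
                         auc_roc=auc, recall_female=recall_f,
                         recall_male=recall_m, flags=flags)


def age_bin(age) -> np.ndarray:
    """Age bins <55, 55-70, >=70 (55 and 70 fall in the upper bins)."""
    age = np.asarray(age, dtype=float)
    return np.asarray(
        pd.cut(age, bins=[-np.inf, 55, 70, np.inf], right=False,
               labels=AGE_BIN_LABELS).astype(str))


def subgroup_report(preds: pd.DataFrame, cohort: pd.DataFrame,
                    keys: tuple[str, ...] = ("site", "field", "age_bin"),
                    ) -> dict[str, dict[str, MetricsReport]]:
    """Per-subgroup metric reports keyed by variable then subgroup label.

    ``age_bin`` is derived from the cohort's ``age`` column; other keys must
    be cohort columns. Every prediction must join a cohort row.
    """
    cohort = cohort.copy()
    if "age_bin" in keys:
        cohort["age_bin"] = age_bin(cohort["age"])
    for k in keys:
        if k not in cohort.columns:
            raise ConfigurationError(f"unknown subgroup key: {k!r}")
    merged = preds.merge(cohort, on="subject_id", how="left", validate="1:1")
    if merged[list(keys)].isna().any().any():
        missing = merged.loc[merged[list(keys)].isna().any(axis=1), "subject_id"]
        raise ConfigurationError(
            f"predictions without a cohort row: {list(missing)[:5]}")
    out: dict[str, dict[str, MetricsReport]] = {}
    for k in keys:
        out[k] = {}
        for label, grp in merged.groupby(k, observed=True, sort=True):
            out[k][str(label)] = compute_metrics(grp)
    return out
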
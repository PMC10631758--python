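"""ROC analysis: classifying group membership from per-subject recall error.

The patient group is the positive class and a larger recall error counts as
more positive, so AUC is the probability that a randomly drawn patient's
score exceeds a randomly drawn control's (ties counted one half, i.e. the
normalized Mann-Whitney statistic).  An AUC below 0.5 is reported as-is;
orientation stays explicit and auditable rather than being flipped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score, roc_curve

__all__ = ["ROCResult", "roc_auc", "pairwise_roc", "DEFAULT_CONTRASTS"]

#: Pairwise contrasts mirroring the study: each subtype against healthy,
#: subtype vs subtype, and healthy against the pooled patient groups.
DEFAULT_CONTRASTS = [
    ("healthy", "RRMS"),
    ("healthy", "SPMS"),
    ("RRMS", "SPMS"),
]


@dataclass
class ROCResult:
    """ROC curve points and area under the curve for one two-group contrast."""

    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    positive_label: str
    negative_label: str
    n_pos: int
    n_neg: int

    def to_dict(self) -> dict:
        return {
            "positive_label": self.positive_label,
            "negative_label": self.negative_label,
            "auc": self.auc,
            "n_pos": self.n_pos,
            "n_neg": self.n_neg,
            "fpr": [float(x) for x in self.fpr],
            "tpr": [float(x) for x in self.tpr],
            "thresholds": [float(x) for x in self.thresholds],
        }


def roc_auc(scores, labels, positive_label) -> ROCResult:
    """ROC curve and AUC with the positive class scored high.

    ``scores`` are per-subject measures (e.g. mean recall error), ``labels``
    the binary group labels.  Both classes must be nonempty.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    y = labels == positive_label
    if y.all() or not y.any():
        raise ValueError("both classes must be nonempty")
    neg_labels = np.unique(labels[~y])
    negative_label = str(neg_labels[0]) if len(neg_labels) == 1 else "rest"
    fpr, tpr, thr = roc_curve(y.astype(int), scores, drop_intermediate=False)
    auc = float(roc_auc_score(y.astype(int), scores))
    return ROCResult(
        thresholds=thr,
        fpr=fpr,
        tpr=tpr,
        auc=auc,
        positive_label=str(positive_label),
        negative_label=negative_label,
        n_pos=int(y.sum()),
        n_neg=int((~y).sum()),
    )


def pairwise_roc(
    summaries: pd.DataFrame,
    measure: str = "recall_error",
    contrasts: list | None = None,
    control_label: str = "healthy",
    group_col: str = "group",
) -> dict[str, ROCResult]:
    """One ROC per contrast plus control-vs-all-patients.

    ``summaries`` holds one row per subject with a ``group`` column and the
    score column ``measure``.  In each contrast the non-control (or the
    second-listed) group is the positive class.  Contrasts with a missing
    group are skipped with a warning.
    """
    contrasts = DEFAULT_CONTRASTS if contrasts is None else contrasts
    present = set(summaries[group_col].unique())
    out: dict[str, ROCResult] = {}
    for a, b in contrasts:
        if a not in present or b not in present:
            warnings.warn(f"contrast {a} vs {b} skipped: group missing", stacklevel=2)
            continue
        sub = summaries[summaries[group_col].isin([a, b])]
        pos = b if a == control_label or b != control_label else a
        out[f"{a}_vs_{b}"] = roc_auc(sub[measure], sub[group_col], positive_label=pos)
    patients = present - {control_label}
    if control_label in present and patients:
        lab = np.where(summaries[group_col] == control_label, control_label, "MS")
        out[f"{control_label}_vs_all"] = roc_auc(summaries[measure], lab, positive_label="MS")
    elif patients:
        warnings.warn("control group missing: pooled contrast skipped", stacklevel=2)
    return out
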
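"""Per-subject descriptive measures: recall error, precision, RT, exclusions.

Recall error is the Euclidean distance between target and response for the
localization task (visual degrees) and the absolute wrapped angular
difference for the sequential task (model-space radians).  Recall precision
is the reciprocal of the (circular) standard deviation of recall error.
Subjects whose mean recall error is an extreme outlier — beyond three
interquartile ranges outside the quartiles — are excluded from group-level
analyses of that paradigm.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .circular import circ_sd, wrap_angle
from .simulate import SubjectSession

__all__ = [
    "recall_error_mgl",
    "recall_error_seq",
    "precision",
    "exclude_extreme_outliers",
    "classify_moca",
    "summarize_subject",
    "summary_table",
    "OutlierResult",
]


def recall_error_mgl(target_xy, response_xy) -> np.ndarray:
    """Euclidean distance between target and response, in visual degrees."""
    t = np.atleast_2d(np.asarray(target_xy, dtype=float))
    r = np.atleast_2d(np.asarray(response_xy, dtype=float))
    if not (np.all(np.isfinite(t)) and np.all(np.isfinite(r))):
        raise ValueError("coordinates must be finite")
    d = np.hypot(t[:, 0] - r[:, 0], t[:, 1] - r[:, 1])
    return float(d[0]) if d.size == 1 and np.asarray(target_xy).ndim == 1 else d


def recall_error_seq(target, response):
    """Absolute and signed wrapped angular error, model-space radians."""
    signed = wrap_angle(np.asarray(response, dtype=float) - np.asarray(target, dtype=float))
    return np.abs(signed), signed


def precision(errors, space: str = "circular") -> float:
    """Reciprocal SD of recall error: circular for angles, scalar otherwise.

    ``errors`` are signed wrapped errors in circular space, or nonnegative
    Euclidean errors in scalar space.  Zero spread returns +inf (flagged by
    value); fewer than two errors is an error.
    """
    errors = np.asarray(errors, dtype=float)
    if errors.size < 2:
        raise ValueError("precision needs at least two errors")
    if space == "circular":
        sd = circ_sd(errors)
    elif space == "scalar":
        sd = float(np.std(errors, ddof=1))
    else:
        raise ValueError(f"unknown space {space!r}")
    if sd == 0.0:
        return float("inf")
    return 1.0 / sd


def _quartile(sorted_vals: np.ndarray, p: float) -> float:
    """Order-statistic quartile at position 1 + (n-1) p, linear interpolation."""
    return float(np.quantile(sorted_vals, p, method="linear"))


@dataclass(frozen=True)
class OutlierResult:
    keep: np.ndarray
    lower_fence: float
    upper_fence: float


def exclude_extreme_outliers(values) -> OutlierResult:
    """Mask of values within [Q1 - 3 IQR, Q3 + 3 IQR].

    Quartiles use linear interpolation between order statistics.  With fewer
    than four values no exclusion is performed (warning).
    """
    values = np.asarray(values, dtype=float)
    if values.size < 4:
        warnings.warn("fewer than 4 values: extreme-outlier rule not applied", stacklevel=2)
        return OutlierResult(np.ones(values.shape, dtype=bool), -np.inf, np.inf)
    q1 = _quartile(values, 0.25)
    q3 = _quartile(values, 0.75)
    iqr = q3 - q1
    lo, hi = q1 - 3.0 * iqr, q3 + 3.0 * iqr
    return OutlierResult((values >= lo) & (values <= hi), lo, hi)


def classify_moca(score: int) -> str:
    """MoCA screening category: >=26 normal, 18-25 mild, 10-17 moderate, <=9 severe.

    The published category edges overlap at 10; this implementation assigns
    10 to the moderate band and reserves severe for scores of 9 and below.
    """
    score = int(score)
    if not 0 <= score <= 30:
        raise ValueError(f"MoCA score must be in [0, 30], got {score}")
    if score >= 26:
        return "normal"
    if score >= 18:
        return "mild"
    if score >= 10:
        return "moderate"
    return "severe"


def _seq_rows(session: SubjectSession) -> list[dict]:
    tr = session.trials
    abs_err, signed = recall_error_seq(tr["target"], tr["response"])
    rows = []

    def cell_row(cell_type, cell, mask):
        return {
            "subject_id": session.subject_id,
            "group": session.group,
            "paradigm": "sequential",
            "load": session.load,
            "cell_type": cell_type,
            "cell": cell,
            "n_trials": int(mask.sum()),
            "recall_error": float(abs_err[mask].mean()),
            "precision": precision(signed[mask], "circular"),
            "rt": float(tr["rt_s"][mask].mean()),
        }

    all_mask = np.ones(len(tr), dtype=bool)
    rows.append(cell_row("overall", "all", all_mask))
    if session.load and session.load > 1:
        for order in sorted(tr["probed_order"].unique()):
            rows.append(cell_row("probed_order", int(order), (tr["probed_order"] == order).to_numpy()))
    return rows


def _mgl_rows(session: SubjectSession) -> list[dict]:
    tr = session.trials
    err = recall_error_mgl(
        tr[["target_x_deg", "target_y_deg"]].to_numpy(),
        tr[["resp_x_deg", "resp_y_deg"]].to_numpy(),
    )
    rows = []

    def cell_row(cell_type, cell, mask):
        return {
            "subject_id": session.subject_id,
            "group": session.group,
            "paradigm": "mgl",
            "load": None,
            "cell_type": cell_type,
            "cell": cell,
            "n_trials": int(mask.sum()),
            "recall_error": float(err[mask].mean()),
            "precision": precision(err[mask], "scalar"),
            "rt": float(tr["rt_s"][mask].mean()),
        }

    rows.append(cell_row("overall", "all", np.ones(len(tr), dtype=bool)))
    for ecc in sorted(tr["eccentricity_deg"].unique()):
        rows.append(cell_row("eccentricity", float(ecc), (tr["eccentricity_deg"] == ecc).to_numpy()))
    for delay in sorted(tr["delay_s"].unique()):
        rows.append(cell_row("delay", float(delay), (tr["delay_s"] == delay).to_numpy()))
    return rows


def summarize_subject(session: SubjectSession) -> pd.DataFrame:
    """Per-cell and overall recall error / precision / RT for one subject."""
    if session.paradigm == "sequential":
        rows = _seq_rows(session)
    elif session.paradigm == "mgl":
        rows = _mgl_rows(session)
    else:
        raise ValueError(f"unknown paradigm {session.paradigm!r}")
    return pd.DataFrame(rows)


def summary_table(cohort: list[SubjectSession]) -> pd.DataFrame:
    """Stacked subject x cell summary table for a whole cohort."""
    return pd.concat([summarize_subject(s) for s in cohort], ignore_index=True)
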
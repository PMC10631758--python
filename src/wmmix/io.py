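"""Trial-table CSV dialects and run configuration.

Files store angles in native orientation degrees on [0, 180); internally
every sequential angle is in model space (orientation doubled onto the full
circle, radians).  The conversion happens at this I/O boundary only.  CSVs
are UTF-8 with a header row, '.' decimal, and 1-based block/trial indices.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .circular import wrap_angle
from .simulate import SubjectSession

__all__ = [
    "MGL_COLUMNS",
    "SEQ_COLUMNS",
    "SchemaError",
    "TrialValidationError",
    "RunConfig",
    "model_to_orientation_deg",
    "orientation_deg_to_model",
    "write_trials",
    "read_trials",
]

MGL_COLUMNS = [
    "subject_id", "group", "block", "trial", "eccentricity_deg", "delay_s",
    "target_x_deg", "target_y_deg", "resp_x_deg", "resp_y_deg", "rt_s",
]
SEQ_COLUMNS = [
    "subject_id", "group", "load", "block", "trial",
    "bar1_orientation_deg", "bar2_orientation_deg", "bar3_orientation_deg",
    "bar1_color", "bar2_color", "bar3_color",
    "probed_color", "probed_order", "resp_orientation_deg", "rt_s",
]


class SchemaError(ValueError):
    """Raised when a trial CSV is missing required columns."""


class TrialValidationError(ValueError):
    """Raised when a trial row holds an out-of-range value."""


def model_to_orientation_deg(theta) -> np.ndarray:
    """Model-space radians (full circle) -> orientation degrees on [0, 180)."""
    theta = np.mod(np.asarray(theta, dtype=float), 2.0 * np.pi)
    deg = np.rad2deg(theta / 2.0)
    return np.where(deg >= 180.0, deg - 180.0, deg)


def orientation_deg_to_model(deg) -> np.ndarray:
    """Orientation degrees on [0, 180) -> model-space radians on (-pi, pi]."""
    return wrap_angle(2.0 * np.deg2rad(np.asarray(deg, dtype=float)))


def _sequential_frame(session: SubjectSession) -> pd.DataFrame:
    tr = session.trials
    out = pd.DataFrame(
        {
            "subject_id": session.subject_id,
            "group": session.group,
            "load": session.load,
            "block": tr["block"],
            "trial": tr["trial"],
        }
    )
    for i in (1, 2, 3):
        bar = tr.get(f"bar{i}")
        if bar is None or bar.isna().all():
            out[f"bar{i}_orientation_deg"] = np.nan
            out[f"bar{i}_color"] = ""
        else:
            out[f"bar{i}_orientation_deg"] = model_to_orientation_deg(bar.to_numpy())
            out[f"bar{i}_color"] = tr[f"bar{i}_color"]
    out["probed_color"] = tr["probed_color"]
    out["probed_order"] = tr["probed_order"]
    out["resp_orientation_deg"] = model_to_orientation_deg(tr["response"].to_numpy())
    out["rt_s"] = tr["rt_s"]
    return out[SEQ_COLUMNS]


def _mgl_frame(session: SubjectSession) -> pd.DataFrame:
    tr = session.trials
    out = tr[[c for c in MGL_COLUMNS if c in tr.columns]].copy()
    out.insert(0, "group", session.group)
    out.insert(0, "subject_id", session.subject_id)
    return out[MGL_COLUMNS]


def write_trials(cohort: list[SubjectSession], path, dialect: str) -> None:
    """Write a cohort to one CSV in the named dialect ('sequential' or 'mgl')."""
    if dialect == "sequential":
        frames = [_sequential_frame(s) for s in cohort]
    elif dialect == "mgl":
        frames = [_mgl_frame(s) for s in cohort]
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.12g")


def _check_columns(df: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {', '.join(missing)}")


def _check_orientation(deg: pd.Series, path, col: str) -> None:
    vals = deg.to_numpy(dtype=float)
    bad = np.where(np.isfinite(vals) & ((vals < 0.0) | (vals >= 180.0)))[0]
    if bad.size:
        # +2: header line plus 1-based indexing
        line = int(deg.index[bad[0]]) + 2
        raise TrialValidationError(
            f"{path}: line {line}: {col}={vals[bad[0]]!r} outside [0, 180)"
        )


def read_trials(path, dialect: str) -> list[SubjectSession]:
    """Read and validate a trial CSV into per-subject sessions."""
    path = Path(path)
    df = pd.read_csv(path)
    if dialect == "mgl":
        _check_columns(df, MGL_COLUMNS, path)
        sessions = []
        for sid, sub in df.groupby("subject_id", sort=False):
            sub = sub.reset_index(drop=True)
            sessions.append(
                SubjectSession(
                    subject_id=str(sid),
                    group=str(sub["group"].iloc[0]),
                    paradigm="mgl",
                    trials=sub[MGL_COLUMNS[2:]].copy(),
                )
            )
        return sessions
    if dialect != "sequential":
        raise ValueError(f"unknown dialect {dialect!r}")
    _check_columns(df, SEQ_COLUMNS, path)
    for col in ("bar1_orientation_deg", "bar2_orientation_deg", "bar3_orientation_deg",
                "resp_orientation_deg"):
        _check_orientation(df[col], path, col)
    sessions = []
    for sid, sub in df.groupby("subject_id", sort=False):
        sub = sub.reset_index(drop=True)
        load = int(sub["load"].iloc[0])
        tr = pd.DataFrame({"block": sub["block"], "trial": sub["trial"]})
        bars = np.full((len(sub), 3), np.nan)
        for i in (1, 2, 3):
            col = sub[f"bar{i}_orientation_deg"]
            ok = col.notna()
            bars[ok.to_numpy(), i - 1] = orientation_deg_to_model(col[ok].to_numpy())
            tr[f"bar{i}"] = bars[:, i - 1]
            tr[f"bar{i}_color"] = sub[f"bar{i}_color"].fillna("")
        order = sub["probed_order"].to_numpy(dtype=int)
        if np.any((order < 1) | (order > load)):
            raise TrialValidationError(f"{path}: probed_order outside 1..{load}")
        rows = np.arange(len(sub))
        tr["probed_order"] = order
        tr["probed_color"] = sub["probed_color"]
        tr["target"] = bars[rows, order - 1]
        if load == 3:
            nts = np.array([np.delete(bars[r], order[r] - 1) for r in rows])
            tr["nontarget1"] = nts[:, 0]
            tr["nontarget2"] = nts[:, 1]
        tr["response"] = orientation_deg_to_model(sub["resp_orientation_deg"].to_numpy())
        tr["rt_s"] = sub["rt_s"]
        sessions.append(
            SubjectSession(
                subject_id=str(sid),
                group=str(sub["group"].iloc[0]),
                paradigm="sequential",
                trials=tr,
                load=load,
            )
        )
    return sessions


@dataclass
class RunConfig:
    """Serializable configuration of one full pipeline run."""

    seed: int = 0
    paradigms: tuple = ("sequential3", "sequential1", "mgl")
    group_sizes_sequential: dict = field(default_factory=lambda: {"healthy": 46, "RRMS": 39, "SPMS": 32})
    group_sizes_mgl: dict = field(default_factory=lambda: {"healthy": 23, "RRMS": 16, "SPMS": 25})
    heterogeneity: bool = True
    min_trials: int = 20
    input_sequential3: str | None = None
    input_sequential1: str | None = None
    input_mgl: str | None = None
    output_dir: str = "wmmix_out"

    def to_json(self, path=None) -> str:
        text = json.dumps(asdict(self), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n", encoding="utf-8")
        return text

    @classmethod
    def from_json(cls, source) -> "RunConfig":
        p = Path(source)
        data = json.loads(p.read_text(encoding="utf-8") if p.exists() else source)
        data["paradigms"] = tuple(data.get("paradigms", cls().paradigms))
        return cls(**data)
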
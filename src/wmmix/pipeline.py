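"""End-to-end analysis pipeline.

Stages, mirroring the analysis sequence for this class of study:
simulate (or load) cohorts -> exclude extreme-outlier subjects (MGL and
three-bar paradigms) -> per-subject summaries -> mixture fits (three-bar
per serial order and whole session; one-bar two-component) ->
nearest-neighbor rescoring -> mixed / one-way ANOVAs with Tukey post hoc ->
pairwise ROC.  Everything is deterministic under the configured seed and
the report records every exclusion and fit diagnostic.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import classify, metrics, stats
from .circular import circ_sd
from .io import RunConfig, read_trials, write_trials
from .mixture import EMConfig, fit_by_cell, nearest_neighbor_errors, trials_from_frame
from .simulate import (
    GROUP_PROFILES,
    MGLDesign,
    SequentialDesign,
    SubjectSession,
    make_cohort,
)

__all__ = ["run_pipeline", "validate_report", "PipelineError"]

log = logging.getLogger("wmmix")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message is tagged with the stage name."""


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            t0 = time.perf_counter()
            log.info("stage %s: start", name)
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:  # pragma: no cover - error path
                raise PipelineError(f"[{name}] {exc}") from exc
            log.info("stage %s: done in %.2fs", name, time.perf_counter() - t0)
            return out

        return wrapper

    return deco


@_stage("simulate")
def _get_cohorts(config: RunConfig) -> dict[str, list[SubjectSession]]:
    seq = np.random.SeedSequence(config.seed)
    streams = dict(zip(("sequential3", "sequential1", "mgl"), seq.spawn(3)))
    cohorts: dict[str, list[SubjectSession]] = {}
    profiles_seq = [(GROUP_PROFILES[g], n) for g, n in config.group_sizes_sequential.items() if n > 0]
    profiles_mgl = [(GROUP_PROFILES[g], n) for g, n in config.group_sizes_mgl.items() if n > 0]
    for paradigm in config.paradigms:
        path = getattr(config, f"input_{paradigm}", None)
        if path:
            dialect = "mgl" if paradigm == "mgl" else "sequential"
            cohorts[paradigm] = read_trials(path, dialect)
        elif paradigm == "sequential3":
            cohorts[paradigm] = make_cohort(
                profiles_seq, SequentialDesign(), streams[paradigm],
                heterogeneity=config.heterogeneity,
            )
        elif paradigm == "sequential1":
            cohorts[paradigm] = make_cohort(
                profiles_seq, SequentialDesign.low_load(), streams[paradigm],
                heterogeneity=config.heterogeneity,
            )
        elif paradigm == "mgl":
            cohorts[paradigm] = make_cohort(
                profiles_mgl, MGLDesign(), streams[paradigm],
                heterogeneity=config.heterogeneity, paradigm="mgl",
            )
        else:
            raise ValueError(f"unknown paradigm {paradigm!r}")
    return cohorts


@_stage("exclude")
def _exclusions(cohorts, summaries) -> dict:
    """Extreme-outlier rule on subject mean recall error, pooled across groups.

    Applied to the MGL and three-bar paradigms only; an excluded subject
    drops out of every analysis of that paradigm.
    """
    excluded: dict[str, list[str]] = {}
    for paradigm in ("mgl", "sequential3"):
        if paradigm not in summaries:
            continue
        overall = summaries[paradigm].query("cell_type == 'overall'").reset_index(drop=True)
        res = metrics.exclude_extreme_outliers(overall["recall_error"].to_numpy())
        dropped = overall.loc[~res.keep, "subject_id"].tolist()
        excluded[paradigm] = dropped
        for sid in dropped:
            log.info("excluded %s from %s (mean error outside [%.3g, %.3g])",
                     sid, paradigm, res.lower_fence, res.upper_fence)
    return excluded


def _drop(summary: pd.DataFrame, dropped: list[str]) -> pd.DataFrame:
    return summary[~summary["subject_id"].isin(dropped)].reset_index(drop=True)


@_stage("fit")
def _fit_mixtures(cohorts, excluded, min_trials: int) -> dict:
    cfg = EMConfig(min_trials=min_trials)
    fits: dict = {}
    for paradigm, load in (("sequential3", 3), ("sequential1", 1)):
        if paradigm not in cohorts:
            continue
        dropped = set(excluded.get(paradigm, []))
        per_subject = {}
        for s in cohorts[paradigm]:
            if s.subject_id in dropped:
                continue
            if load == 3:
                cells = fit_by_cell(s.trials, "probed_order", load, cfg)
            else:
                from .mixture import em_fit

                cells = {"__all__": em_fit(trials_from_frame(s.trials, load), cfg)}
            per_subject[s.subject_id] = {
                "group": s.group,
                "cells": {
                    str(k): (f.to_dict() if f is not None else None) for k, f in cells.items()
                },
            }
        fits[paradigm] = per_subject
    return fits


@_stage("nearest_neighbor")
def _nearest_neighbor(cohorts, excluded) -> dict:
    """Per-subject circular SD of nearest-neighbor errors (3-bar only)."""
    out = {}
    if "sequential3" not in cohorts:
        return out
    dropped = set(excluded.get("sequential3", []))
    for s in cohorts["sequential3"]:
        if s.subject_id in dropped:
            continue
        nn = nearest_neighbor_errors(trials_from_frame(s.trials, 3))
        out[s.subject_id] = {
            "group": s.group,
            "mean_abs_nn_error": float(np.abs(nn).mean()),
            "circ_sd_nn_error": float(circ_sd(nn)),
        }
    return out


def _anova_on(summary: pd.DataFrame, dv: str, cell_type: str):
    sub = summary[summary["cell_type"] == cell_type]
    if sub.empty or sub["group"].nunique() < 2:
        return None
    try:
        return stats.mixed_anova(sub, dv=dv, between="group", within="cell").to_dict()
    except ValueError as exc:
        log.warning("ANOVA on %s/%s skipped: %s", dv, cell_type, exc)
        return None


@_stage("anova")
def _anovas(summaries, excluded) -> dict:
    out: dict = {}
    plans = {
        "mgl": ["eccentricity", "delay"],
        "sequential3": ["probed_order"],
        "sequential1": ["overall"],
    }
    for paradigm, cell_types in plans.items():
        if paradigm not in summaries:
            continue
        table = _drop(summaries[paradigm], excluded.get(paradigm, []))
        out[paradigm] = {}
        for ct in cell_types:
            for dv in ("recall_error", "precision", "rt"):
                res = _anova_on(table, dv, ct)
                if res is not None:
                    out[paradigm][f"{dv}_by_{ct}"] = res
    return out


@_stage("roc")
def _rocs(summaries, excluded) -> dict:
    out: dict = {}
    for paradigm in summaries:
        overall = _drop(
            summaries[paradigm].query("cell_type == 'overall'"), excluded.get(paradigm, [])
        )
        if overall["group"].nunique() < 2:
            import warnings

            warnings.warn(f"ROC skipped for {paradigm}: fewer than two groups", stacklevel=2)
            continue
        rocs = classify.pairwise_roc(overall, measure="recall_error")
        out[paradigm] = {k: {kk: vv for kk, vv in r.to_dict().items() if kk != "thresholds"}
                         for k, r in rocs.items()}
    return out


def run_pipeline(config: RunConfig, write_outputs: bool = True) -> dict:
    """Run every stage and return (and optionally write) the JSON report."""
    cohorts = _get_cohorts(config)
    summaries = {p: metrics.summary_table(c) for p, c in cohorts.items()}
    excluded = _exclusions(cohorts, summaries)
    fits = _fit_mixtures(cohorts, excluded, config.min_trials)
    nn = _nearest_neighbor(cohorts, excluded)
    anovas = _anovas(summaries, excluded)
    rocs = _rocs(summaries, excluded)
    report = {
        "config": json.loads(config.to_json()),
        "n_subjects": {p: len(c) for p, c in cohorts.items()},
        "excluded": excluded,
        "mixture_fits": fits,
        "nearest_neighbor": nn,
        "anova": anovas,
        "roc": rocs,
    }
    if write_outputs:
        outdir = Path(config.output_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "report.json").write_text(
            json.dumps(report, indent=2, sort_keys=True) + "\n", encoding="utf-8"
        )
        for p, table in summaries.items():
            table.to_csv(outdir / f"summary_{p}.csv", index=False, float_format="%.12g")
        for p, cohort in cohorts.items():
            dialect = "mgl" if p == "mgl" else "sequential"
            write_trials(cohort, outdir / f"trials_{p}.csv", dialect)
    return report


def validate_report(report: dict, schema_path=None) -> None:
    """Light structural validation of a report against the shipped schema.

    Checks required keys and value types named in ``report_schema.json``;
    raises ``ValueError`` on the first violation.
    """
    schema_path = schema_path or Path(__file__).with_name("report_schema.json")
    schema = json.loads(Path(schema_path).read_text(encoding="utf-8"))
    _validate_node(report, schema, "$")


_TYPES = {"object": dict, "array": list, "string": str, "number": (int, float),
          "integer": int, "boolean": bool}


def _validate_node(node, schema, where):
    expected = schema.get("type")
    if expected and not isinstance(node, _TYPES[expected]):
        raise ValueError(f"{where}: expected {expected}, got {type(node).__name__}")
    for key, subschema in schema.get("properties", {}).items():
        if key in schema.get("required", []) and (not isinstance(node, dict) or key not in node):
            raise ValueError(f"{where}: missing required key {key!r}")
        if isinstance(node, dict) and key in node:
            _validate_node(node[key], subschema, f"{where}.{key}")
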
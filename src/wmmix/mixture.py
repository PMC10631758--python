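"""Three-source mixture model of continuous-report recall errors.

Each response in an analog (delayed-estimation) report task is modelled as
coming from one of three sources:

* a von Mises distribution centred on the probed (target) feature, with
  probability ``p_target``;
* a von Mises distribution centred on one of the ``m`` non-probed items
  (a *swap* or misbinding error), with total probability ``p_nontarget``
  shared equally across the non-targets;
* a uniform guess on the circle, with probability ``p_uniform``.

All three von Mises components share one concentration ``kappa``.  The
per-trial density is

    p(th | params) = pT f(th; target, k)
                     + (pN / m) sum_i f(th; nontarget_i, k)
                     + pU / (2 pi)

and the model is fitted per subject by maximum likelihood using EM with
multiple restarts.  With ``m == 0`` (single-item condition) the model
degenerates to target + uniform and ``p_uniform == 1 - p_target`` by
construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .circular import KAPPA_MAX, a1inv, kappa_to_sd, sd_to_kappa, wrap_angle

__all__ = [
    "MixtureParameters",
    "MixtureFit",
    "TrialErrors",
    "EMConfig",
    "mixture_loglik",
    "em_fit",
    "nearest_neighbor_errors",
    "fit_by_cell",
    "trials_from_frame",
]

_LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass(frozen=True)
class MixtureParameters:
    """Mixing weights and shared concentration of the swap mixture.

    Weights must lie on the probability simplex; ``kappa`` in [0, KAPPA_MAX].
    """

    p_target: float
    p_nontarget: float
    p_uniform: float
    kappa: float

    def validate(self) -> "MixtureParameters":
        p = np.array([self.p_target, self.p_nontarget, self.p_uniform], dtype=float)
        if np.any(p < -1e-12) or np.any(p > 1 + 1e-12):
            raise ValueError(f"mixture weights out of [0,1]: {p}")
        if abs(p.sum() - 1.0) > 1e-9:
            raise ValueError(f"mixture weights must sum to 1, got {p.sum()!r}")
        if not (0.0 <= self.kappa <= KAPPA_MAX):
            raise ValueError(f"kappa must lie in [0, {KAPPA_MAX}], got {self.kappa}")
        return self

    def as_array(self) -> np.ndarray:
        return np.array([self.p_target, self.p_nontarget, self.p_uniform, self.kappa])


@dataclass
class TrialErrors:
    """Responses, targets and non-target values for a block of trials.

    ``nontargets`` has shape (n_trials, m) with m == 0 for the single-item
    condition and m == 2 for the three-item condition.  All angles are in
    model space (full-circle radians).
    """

    response: np.ndarray
    target: np.ndarray
    nontargets: np.ndarray

    def __post_init__(self) -> None:
        self.response = np.atleast_1d(np.asarray(self.response, dtype=float))
        self.target = np.atleast_1d(np.asarray(self.target, dtype=float))
        self.nontargets = np.asarray(self.nontargets, dtype=float)
        if self.nontargets.ndim == 1:
            self.nontargets = self.nontargets.reshape(len(self.response), -1)
        n = len(self.response)
        if len(self.target) != n or self.nontargets.shape[0] != n:
            raise ValueError("response, target and nontargets must align")
        for a in (self.response, self.target, self.nontargets):
            if not np.all(np.isfinite(a)):
                raise ValueError("trial angles must be finite")

    @property
    def n_trials(self) -> int:
        return len(self.response)

    @property
    def n_nontargets(self) -> int:
        return self.nontargets.shape[1]

    def target_errors(self) -> np.ndarray:
        """Signed wrapped response-minus-target errors."""
        return wrap_angle(self.response - self.target)


def _cos_deviation_matrix(trials: TrialErrors) -> np.ndarray:
    """cos(response - mean) for each von Mises component (target first)."""
    means = np.column_stack([trials.target, trials.nontargets])
    return np.cos(trials.response[:, None] - means)


def _log_density_matrix(cosdev: np.ndarray, params: MixtureParameters) -> np.ndarray:
    """Per-trial log of weight * component density, shape (n, m + 2).

    Column order: target, each non-target, uniform.  Weights of zero map to
    -inf log-columns, which is the correct degenerate behaviour.
    """
    from scipy.special import i0e

    m = cosdev.shape[1] - 1
    k = params.kappa
    log_vm = k * (cosdev - 1.0) - np.log(i0e(k)) - _LOG_2PI
    with np.errstate(divide="ignore"):
        w = np.concatenate(
            [
                [np.log(params.p_target) if params.p_target > 0 else -np.inf],
                np.full(m, np.log(params.p_nontarget / m) if (m and params.p_nontarget > 0) else -np.inf),
            ]
        )
    cols = [log_vm + w]
    with np.errstate(divide="ignore"):
        lu = np.log(params.p_uniform) - _LOG_2PI if params.p_uniform > 0 else -np.inf
    cols.append(np.full((cosdev.shape[0], 1), lu))
    return np.hstack(cols)


def mixture_loglik(params: MixtureParameters, trials: TrialErrors) -> float:
    """Total log-likelihood of the trials under the mixture parameters."""
    params.validate()
    if trials.n_trials == 0:
        raise ValueError("need at least one trial")
    if trials.n_nontargets == 0 and params.p_nontarget > 0:
        raise ValueError("p_nontarget must be 0 when there are no non-targets")
    logf = _log_density_matrix(_cos_deviation_matrix(trials), params)
    from scipy.special import logsumexp

    return float(logsumexp(logf, axis=1).sum())


@dataclass(frozen=True)
class EMConfig:
    """Settings for the EM fitter.

    The 20 restarts combine an 18-point lattice over plausible
    (p_target, p_uniform, kappa), a moment-based start and a flat start;
    mixture likelihoods are multimodal and a single start is not reliable.
    """

    min_trials: int = 20
    max_iter: int = 10_000
    tol: float = 1e-6
    weight_floor: float = 1e-6
    lattice_p_target: tuple = (0.5, 0.7, 0.9)
    lattice_p_uniform: tuple = (0.05, 0.2)
    lattice_kappa: tuple = (2.0, 8.0, 32.0)


@dataclass
class MixtureFit:
    """Result of an EM fit: parameters, diagnostics, posterior weights."""

    params: MixtureParameters
    von_mises_sd: float
    log_likelihood: float
    n_trials: int
    n_restarts_used: int
    converged: bool
    responsibilities: np.ndarray = field(repr=False)
    n_iterations: int = 0

    def to_dict(self) -> dict:
        return {
            "p_target": self.params.p_target,
            "p_nontarget": self.params.p_nontarget,
            "p_uniform": self.params.p_uniform,
            "kappa": self.params.kappa,
            "von_mises_sd": self.von_mises_sd,
            "log_likelihood": self.log_likelihood,
            "n_trials": self.n_trials,
            "n_restarts_used": self.n_restarts_used,
            "converged": self.converged,
            "n_iterations": self.n_iterations,
        }


def _moment_start(trials: TrialErrors) -> MixtureParameters:
    """Crude method-of-moments initializer from the target-error distribution."""
    err = trials.target_errors()
    near = np.abs(err) < 1.0
    p_t = float(np.clip(near.mean(), 0.1, 0.95))
    rbar = float(np.abs(np.exp(1j * err[near]).mean())) if near.any() else 0.5
    kappa = a1inv(min(rbar, 1 - 1e-9))
    if trials.n_nontargets:
        rest = 1.0 - p_t
        return MixtureParameters(p_t, rest / 2, rest / 2, kappa)
    return MixtureParameters(p_t, 0.0, 1.0 - p_t, kappa)


def _starts(trials: TrialErrors, config: EMConfig) -> list[MixtureParameters]:
    m = trials.n_nontargets
    starts = []
    for pt in config.lattice_p_target:
        for pu in config.lattice_p_uniform:
            for k in config.lattice_kappa:
                if m:
                    # project onto the simplex: the swap weight takes the
                    # leftover mass, floored so no component starts dead
                    pn = max(1.0 - pt - pu, 0.05)
                    tot = pt + pn + pu
                    starts.append(MixtureParameters(pt / tot, pn / tot, pu / tot, k))
                else:
                    tot = pt + pu
                    starts.append(MixtureParameters(pt / tot, 0.0, pu / tot, k))
    starts.append(_moment_start(trials))
    flat = (1 / 3, 1 / 3, 1 / 3, 4.0) if m else (0.5, 0.0, 0.5, 4.0)
    starts.append(MixtureParameters(*flat))
    return starts


def _em_single(
    cosdev: np.ndarray, start: MixtureParameters, config: EMConfig
) -> tuple[MixtureParameters, float, np.ndarray, bool, int]:
    from scipy.special import logsumexp

    n, ncomp = cosdev.shape[0], cosdev.shape[1] + 1
    m = ncomp - 2
    params = start
    prev_ll = -np.inf
    resp = np.full((n, ncomp), 1.0 / ncomp)
    converged = False
    it = 0
    for it in range(1, config.max_iter + 1):
        logf = _log_density_matrix(cosdev, params)
        log_tot = logsumexp(logf, axis=1)
        ll = float(log_tot.sum())
        # EM guarantee: the observed-data log-likelihood never decreases.
        if ll < prev_ll - 1e-8:
            raise RuntimeError(f"EM log-likelihood decreased: {prev_ll} -> {ll}")
        resp = np.exp(logf - log_tot[:, None])
        if abs(ll - prev_ll) < config.tol:
            prev_ll = ll
            converged = True
            break
        prev_ll = ll
        # M-step: weights are mean responsibilities (floored to avoid log 0),
        # kappa solves A1(kappa) = responsibility-weighted mean cosine of the
        # component-centred deviations.
        w = resp.mean(axis=0)
        p_t = w[0]
        p_n = float(w[1 : 1 + m].sum()) if m else 0.0
        p_u = w[-1]
        floor = config.weight_floor
        p_t, p_u = max(p_t, floor), max(p_u, floor)
        if m:
            p_n = max(p_n, floor)
        total = p_t + p_n + p_u
        p_t, p_n, p_u = p_t / total, p_n / total, p_u / total
        r_vm = resp[:, : 1 + m]
        wsum = r_vm.sum()
        rbar = float((r_vm * cosdev).sum() / wsum) if wsum > 0 else 0.0
        kappa = a1inv(rbar) if rbar > 0 else 0.0
        params = MixtureParameters(p_t, p_n, p_u, min(kappa, KAPPA_MAX))
    return params, prev_ll, resp, converged, it


def em_fit(trials: TrialErrors, config: EMConfig | None = None) -> MixtureFit:
    """Maximum-likelihood fit of the swap mixture by EM with restarts.

    Returns the restart with the highest log-likelihood; ties are broken in
    favour of the smaller concentration.  Refuses datasets smaller than
    ``config.min_trials``.
    """
    config = config or EMConfig()
    if trials.n_trials < config.min_trials:
        raise ValueError(
            f"need at least {config.min_trials} trials to fit the mixture, "
            f"got {trials.n_trials}"
        )
    cosdev = _cos_deviation_matrix(trials)
    best = None
    starts = _starts(trials, config)
    for start in starts:
        params, ll, resp, conv, it = _em_single(cosdev, start, config)
        key = (ll, -params.kappa)
        if best is None or key > best[0]:
            best = (key, params, ll, resp, conv, it)
    _, params, ll, resp, conv, it = best
    return MixtureFit(
        params=params.validate(),
        von_mises_sd=kappa_to_sd(params.kappa) if params.kappa > 0 else float("inf"),
        log_likelihood=ll,
        n_trials=trials.n_trials,
        n_restarts_used=len(starts),
        converged=conv,
        responsibilities=resp,
        n_iterations=it,
    )


def nearest_neighbor_errors(trials: TrialErrors) -> np.ndarray:
    """Signed wrapped error to the nearest presented item in each trial.

    Rescoring each response against whichever of {target, non-targets}
    minimizes the absolute wrapped distance removes the swap component from
    the error; with no non-targets this is the plain target error.
    """
    if trials.n_trials == 0:
        raise ValueError("need at least one trial")
    means = np.column_stack([trials.target, trials.nontargets])
    diffs = wrap_angle(trials.response[:, None] - means)
    idx = np.argmin(np.abs(diffs), axis=1)
    return diffs[np.arange(len(idx)), idx]


def trials_from_frame(frame: pd.DataFrame, load: int) -> TrialErrors:
    """Build a :class:`TrialErrors` from an internal sequential trial table.

    Expects model-space radian columns ``response``, ``target`` and, for the
    three-item condition, ``nontarget1``/``nontarget2``.
    """
    if load == 1:
        nt = np.empty((len(frame), 0))
    elif load == 3:
        nt = frame[["nontarget1", "nontarget2"]].to_numpy(dtype=float)
    else:
        raise ValueError(f"unsupported load {load}")
    return TrialErrors(
        response=frame["response"].to_numpy(dtype=float),
        target=frame["target"].to_numpy(dtype=float),
        nontargets=nt,
    )


def fit_by_cell(
    frame: pd.DataFrame,
    cell: str,
    load: int,
    config: EMConfig | None = None,
    whole_session_key: str = "__all__",
) -> dict:
    """Independent EM fits per level of a grouping column plus a session fit.

    Cells with fewer than ``config.min_trials`` trials are reported as None
    (missing) without aborting the other cells.
    """
    config = config or EMConfig()
    fits: dict = {whole_session_key: em_fit(trials_from_frame(frame, load), config)}
    for level, sub in frame.groupby(cell, sort=True):
        try:
            fits[level] = em_fit(trials_from_frame(sub, load), config)
        except ValueError:
            fits[level] = None
    return fits
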
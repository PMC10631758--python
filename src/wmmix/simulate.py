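"""Synthetic cohorts for the two continuous-report working-memory paradigms.

No raw behavioural data accompany the published group statistics, so the
package ships generative emulators of both paradigms:

* **Sequential analog report** — one or three coloured bars presented in
  sequence; the subject reproduces the orientation of the bar matching the
  probed colour.  Responses are drawn from the three-source swap mixture
  (see :mod:`wmmix.mixture`), so the generative composition of every
  simulated session is known exactly.
* **Memory-guided localization (MGL)** — remember the position of a target
  circle at one of three eccentricities across a variable delay, then
  reproduce it; responses are the target plus isotropic bivariate Gaussian
  noise, so the expected Euclidean recall error is ``sigma * sqrt(pi / 2)``.

Bar orientations have period pi; they are doubled onto the full circle
("model space") before any circular statistics, and the generator works
directly in model space so that parameter-recovery results do not depend on
the doubling convention.  Group profiles carry the published group means
and between-subject SDs of the mixture parameters and recall errors; the
component label of every simulated response is stored alongside the trial
(hidden from the fitters) to enable ground-truth checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .circular import KAPPA_MAX, kappa_to_sd, sd_to_kappa, vm_sample, wrap_angle
from .mixture import MixtureParameters

__all__ = [
    "SequentialDesign",
    "MGLDesign",
    "NormalSpec",
    "GroupProfile",
    "SubjectSession",
    "GROUP_PROFILES",
    "SEQUENTIAL_GROUP_SIZES",
    "MGL_GROUP_SIZES",
    "generate_orientation_sequence",
    "simulate_sequential_subject",
    "simulate_mgl_subject",
    "make_cohort",
]

BAR_COLORS = ("red", "green", "blue")


@dataclass(frozen=True)
class SequentialDesign:
    """Block structure of the sequential bar task.

    Defaults: high-load condition of 6 blocks x 30 trials with 3 bars and a
    minimum 10 degree orientation separation between consecutively presented
    bars; the low-load condition uses a single block of 30 one-bar trials.
    """

    load: int = 3
    n_blocks: int = 6
    trials_per_block: int = 30
    min_consecutive_sep_deg: float = 10.0
    bar_duration_ms: float = 500.0  # metadata only
    isi_ms: float = 500.0  # metadata only

    def __post_init__(self) -> None:
        if self.load not in (1, 3):
            raise ValueError("load must be 1 or 3")
        if self.min_consecutive_sep_deg >= 90.0:
            raise ValueError("consecutive separation >= 90 orientation degrees is infeasible")

    @property
    def n_trials(self) -> int:
        return self.n_blocks * self.trials_per_block

    @classmethod
    def low_load(cls) -> "SequentialDesign":
        return cls(load=1, n_blocks=1, trials_per_block=30)


@dataclass(frozen=True)
class MGLDesign:
    """Block structure of the memory-guided localization task."""

    eccentricities_deg: tuple = (3.22, 6.44, 9.66)
    delays_s: tuple = (0.5, 1.0, 2.0, 4.0, 8.0)
    n_blocks: int = 6
    trials_per_block: int = 30

    @property
    def n_trials(self) -> int:
        return self.n_blocks * self.trials_per_block


@dataclass(frozen=True)
class NormalSpec:
    """Mean and between-subject SD of a group-level quantity."""

    mean: float
    sd: float

    def draw(self, rng: np.random.Generator, lo: float = -np.inf, hi: float = np.inf) -> float:
        for _ in range(100):
            x = rng.normal(self.mean, self.sd)
            if lo <= x <= hi:
                return float(x)
        raise RuntimeError(f"could not draw {self} within [{lo}, {hi}] in 100 tries")


@dataclass(frozen=True)
class GroupProfile:
    """Generative description of one subject group.

    ``seq3_*`` are the three-bar mixture weights and von Mises SD (model-space
    radians); ``seq1_*`` the one-bar target weight and SD; ``mgl_mean_abs_error``
    the mean Euclidean recall error in visual degrees.  ``rt_*`` are lognormal
    response-time models (median seconds, log-space dispersion).  Demographic
    samplers are simple truncated normals; they exist so that downstream
    tables have realistic covariate columns, not to model the population.
    """

    label: str
    seq3_p_target: NormalSpec
    seq3_p_nontarget: NormalSpec
    seq3_p_uniform: NormalSpec
    seq3_vm_sd: NormalSpec
    seq1_p_target: NormalSpec
    seq1_vm_sd: NormalSpec
    mgl_mean_abs_error: NormalSpec
    rt_seq_median_s: float = 1.2
    rt_seq_sigma: float = 0.4
    rt_mgl_median_s: float = 0.9
    rt_mgl_sigma: float = 0.35
    age: NormalSpec = NormalSpec(35.0, 8.0)
    education_years: NormalSpec = NormalSpec(14.0, 3.0)
    moca: NormalSpec = NormalSpec(26.0, 2.5)
    prop_female: float = 0.5

    def draw_seq_params(
        self, load: int, rng: np.random.Generator, heterogeneity: bool = True
    ) -> MixtureParameters:
        """Subject-level mixture parameters for the given load.

        With heterogeneity, p_target (and p_nontarget for load 3) are drawn
        from truncated normals and p_uniform takes the remaining mass,
        resampling when the simplex constraint fails (bounded retries).
        """
        if load == 1:
            if not heterogeneity:
                pt = self.seq1_p_target.mean
                sd = self.seq1_vm_sd.mean
            else:
                pt = self.seq1_p_target.draw(rng, 0.0, 1.0)
                sd = self.seq1_vm_sd.draw(rng, 1e-3, np.inf)
            return MixtureParameters(pt, 0.0, 1.0 - pt, sd_to_kappa(sd)).validate()
        if not heterogeneity:
            pt, pn = self.seq3_p_target.mean, self.seq3_p_nontarget.mean
            pu = 1.0 - pt - pn
            sd = self.seq3_vm_sd.mean
            return MixtureParameters(pt, pn, pu, sd_to_kappa(sd)).validate()
        for _ in range(100):
            pt = self.seq3_p_target.draw(rng, 0.0, 1.0)
            pn = self.seq3_p_nontarget.draw(rng, 0.0, 1.0)
            pu = 1.0 - pt - pn
            if pu >= 0.0:
                sd = self.seq3_vm_sd.draw(rng, 1e-3, np.inf)
                return MixtureParameters(pt, pn, pu, sd_to_kappa(sd)).validate()
        raise RuntimeError("could not draw a valid mixture simplex in 100 tries")

    def draw_covariates(self, rng: np.random.Generator) -> dict:
        return {
            "age": round(self.age.draw(rng, 18.0, 55.0), 1),
            "education_years": round(self.education_years.draw(rng, 5.0, 22.0), 1),
            "moca": int(np.clip(round(self.moca.draw(rng)), 0, 30)),
            "gender": "F" if rng.random() < self.prop_female else "M",
        }


#: Published group means (+/- between-subject SD) for the three groups:
#: three-bar mixture parameters and von Mises SD, one-bar target weight and
#: SD, and MGL mean absolute recall error in visual degrees.
GROUP_PROFILES: dict[str, GroupProfile] = {
    "healthy": GroupProfile(
        label="healthy",
        seq3_p_target=NormalSpec(0.88, 0.11),
        seq3_p_nontarget=NormalSpec(0.07, 0.06),
        seq3_p_uniform=NormalSpec(0.05, 0.08),
        seq3_vm_sd=NormalSpec(0.51, 0.12),
        seq1_p_target=NormalSpec(0.98, 0.03),
        seq1_vm_sd=NormalSpec(0.25, 0.10),
        mgl_mean_abs_error=NormalSpec(0.97, 0.26),
        rt_seq_median_s=1.1,
        rt_mgl_median_s=0.8,
        age=NormalSpec(30.5, 10.37),
        education_years=NormalSpec(16.95, 2.23),
        moca=NormalSpec(27.5, 1.8),
        prop_female=16 / 46,
    ),
    "RRMS": GroupProfile(
        label="RRMS",
        seq3_p_target=NormalSpec(0.79, 0.12),
        seq3_p_nontarget=NormalSpec(0.11, 0.09),
        seq3_p_uniform=NormalSpec(0.09, 0.08),
        seq3_vm_sd=NormalSpec(0.69, 0.20),
        seq1_p_target=NormalSpec(0.96, 0.08),
        seq1_vm_sd=NormalSpec(0.38, 0.14),
        mgl_mean_abs_error=NormalSpec(1.09, 0.27),
        rt_seq_median_s=1.3,
        rt_mgl_median_s=1.0,
        age=NormalSpec(32.03, 6.72),
        education_years=NormalSpec(13.87, 3.41),
        moca=NormalSpec(25.5, 2.5),
        prop_female=23 / 39,
    ),
    "SPMS": GroupProfile(
        label="SPMS",
        seq3_p_target=NormalSpec(0.76, 0.14),
        seq3_p_nontarget=NormalSpec(0.14, 0.09),
        seq3_p_uniform=NormalSpec(0.10, 0.08),
        seq3_vm_sd=NormalSpec(0.76, 0.15),
        seq1_p_target=NormalSpec(0.94, 0.09),
        seq1_vm_sd=NormalSpec(0.47, 0.12),
        mgl_mean_abs_error=NormalSpec(1.86, 0.92),
        rt_seq_median_s=1.5,
        rt_mgl_median_s=1.2,
        age=NormalSpec(39.0, 6.43),
        education_years=NormalSpec(13.67, 2.73),
        moca=NormalSpec(24.5, 3.0),
        prop_female=22 / 32,
    ),
}

#: Study sample sizes for the sequential paradigms (healthy, RRMS, SPMS).
SEQUENTIAL_GROUP_SIZES = {"healthy": 46, "RRMS": 39, "SPMS": 32}
#: Study sample sizes for the MGL paradigm.
MGL_GROUP_SIZES = {"healthy": 23, "RRMS": 16, "SPMS": 25}


@dataclass
class SubjectSession:
    """One subject's trials plus group label and demographic covariates."""

    subject_id: str
    group: str
    paradigm: str  # "sequential" or "mgl"
    trials: pd.DataFrame
    covariates: dict = field(default_factory=dict)
    load: int | None = None
    true_params: MixtureParameters | None = None

    @property
    def n_trials(self) -> int:
        return len(self.trials)


def generate_orientation_sequence(
    load: int,
    min_consecutive_sep_deg: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, tuple[str, ...]]:
    """Bar orientations (model-space radians) and a colour assignment.

    Orientations are uniform on the period-pi orientation circle subject to
    consecutive bars differing by at least ``min_consecutive_sep_deg``
    orientation degrees (not all pairs — only consecutive ones).  The
    returned angles are doubled onto the full circle.
    """
    if load not in (1, 3):
        raise ValueError("load must be 1 or 3")
    if min_consecutive_sep_deg >= 90.0:
        raise ValueError("consecutive separation >= 90 orientation degrees is infeasible")
    sep = np.deg2rad(min_consecutive_sep_deg)
    oris = [float(rng.uniform(0.0, np.pi))]
    while len(oris) < load:
        cand = float(rng.uniform(0.0, np.pi))
        d = abs(cand - oris[-1])
        if min(d, np.pi - d) >= sep:
            oris.append(cand)
    colors = tuple(rng.permutation(BAR_COLORS))
    return wrap_angle(2.0 * np.asarray(oris)), colors


def _draw_response(
    target: float,
    nontargets: np.ndarray,
    params: MixtureParameters,
    rng: np.random.Generator,
) -> tuple[float, str]:
    """One mixture response and its generative component label."""
    m = len(nontargets)
    u = rng.random()
    if u < params.p_target:
        return float(vm_sample(1, target, params.kappa, rng)[0]), "target"
    if m and u < params.p_target + params.p_nontarget:
        i = int(rng.integers(m))
        return float(vm_sample(1, nontargets[i], params.kappa, rng)[0]), f"nontarget{i + 1}"
    return float(rng.uniform(-np.pi, np.pi)), "uniform"


def simulate_sequential_subject(
    profile: GroupProfile,
    design: SequentialDesign,
    rng: np.random.Generator,
    params_override: MixtureParameters | None = None,
    heterogeneity: bool = True,
    subject_id: str = "s001",
) -> SubjectSession:
    """Simulate one subject's sequential session from the swap mixture.

    The probed order is balanced across the ``load`` serial positions within
    each block (shuffled), matching the counterbalanced design; responses
    carry their generative component label in a ``component`` column that
    downstream fitters must ignore.
    """
    params = params_override or profile.draw_seq_params(design.load, rng, heterogeneity)
    params.validate()
    if design.load == 1 and params.p_nontarget != 0.0:
        raise ValueError("one-bar sessions cannot have a swap component")
    rows = []
    rt_mu = np.log(profile.rt_seq_median_s)
    for block in range(1, design.n_blocks + 1):
        per = design.trials_per_block // design.load
        orders = np.concatenate([np.full(per, o) for o in range(design.load)])
        if len(orders) < design.trials_per_block:  # non-divisible guard
            extra = rng.integers(design.load, size=design.trials_per_block - len(orders))
            orders = np.concatenate([orders, extra])
        rng.shuffle(orders)
        for t, order in enumerate(orders, start=1):
            bars, colors = generate_orientation_sequence(
                design.load, design.min_consecutive_sep_deg, rng
            )
            target = float(bars[order])
            nontargets = np.delete(bars, order)
            response, component = _draw_response(target, nontargets, params, rng)
            row = {
                "block": block,
                "trial": t,
                "probed_order": int(order) + 1,
                "probed_color": colors[order],
                "target": target,
                "response": response,
                "rt_s": float(rng.lognormal(rt_mu, profile.rt_seq_sigma)),
                "component": component,
            }
            for i in range(3):
                row[f"bar{i + 1}"] = float(bars[i]) if i < design.load else np.nan
                row[f"bar{i + 1}_color"] = colors[i] if i < design.load else ""
            for i, nt in enumerate(nontargets, start=1):
                row[f"nontarget{i}"] = float(nt)
            rows.append(row)
    return SubjectSession(
        subject_id=subject_id,
        group=profile.label,
        paradigm="sequential",
        trials=pd.DataFrame(rows),
        covariates=profile.draw_covariates(rng),
        load=design.load,
        true_params=params,
    )


def simulate_mgl_subject(
    profile: GroupProfile,
    design: MGLDesign,
    rng: np.random.Generator,
    sigma_override: float | None = None,
    heterogeneity: bool = True,
    eccentricity_scale: dict | None = None,
    delay_scale: dict | None = None,
    subject_id: str = "s001",
) -> SubjectSession:
    """Simulate one subject's MGL session.

    The target sits at a uniform angle on the circle of the trial's
    eccentricity; the response adds isotropic bivariate Gaussian noise with
    ``sigma = mean_abs_error * sqrt(2 / pi)`` so the expected Euclidean error
    equals the profile's group mean (Rayleigh mean identity).  Optional
    per-eccentricity / per-delay multipliers let the monotone distance and
    delay effects be dialled in; they default to flat.  Eccentricities and
    delays are balanced within blocks by shuffled assignment.
    """
    if sigma_override is not None:
        sigma = float(sigma_override)
    else:
        mean_err = (
            profile.mgl_mean_abs_error.mean
            if not heterogeneity
            else profile.mgl_mean_abs_error.draw(rng, 1e-6, np.inf)
        )
        sigma = mean_err * float(np.sqrt(2.0 / np.pi))
    if sigma < 0:
        raise ValueError("response noise sigma must be nonnegative")
    ecc_scale = eccentricity_scale or {}
    del_scale = delay_scale or {}
    rows = []
    rt_mu = np.log(profile.rt_mgl_median_s)
    n_ecc, n_del = len(design.eccentricities_deg), len(design.delays_s)
    for block in range(1, design.n_blocks + 1):
        eccs = np.tile(design.eccentricities_deg, design.trials_per_block // n_ecc)
        delays = np.tile(design.delays_s, design.trials_per_block // n_del)
        rng.shuffle(eccs)
        rng.shuffle(delays)
        for t in range(1, design.trials_per_block + 1):
            ecc, delay = float(eccs[t - 1]), float(delays[t - 1])
            ang = rng.uniform(0.0, 2.0 * np.pi)
            tx, ty = ecc * np.cos(ang), ecc * np.sin(ang)
            s = sigma * float(ecc_scale.get(ecc, 1.0)) * float(del_scale.get(delay, 1.0))
            rx, ry = rng.normal((tx, ty), s)
            rows.append(
                {
                    "block": block,
                    "trial": t,
                    "eccentricity_deg": ecc,
                    "delay_s": delay,
                    "target_x_deg": tx,
                    "target_y_deg": ty,
                    "resp_x_deg": float(rx),
                    "resp_y_deg": float(ry),
                    "rt_s": float(rng.lognormal(rt_mu, profile.rt_mgl_sigma)),
                }
            )
    return SubjectSession(
        subject_id=subject_id,
        group=profile.label,
        paradigm="mgl",
        trials=pd.DataFrame(rows),
        covariates=profile.draw_covariates(rng),
    )


def make_cohort(
    profiles: list,
    design,
    seed,
    heterogeneity: bool = True,
    paradigm: str = "sequential",
    params_override: MixtureParameters | None = None,
) -> list[SubjectSession]:
    """Simulate a cohort: ``profiles`` is a list of (GroupProfile, n_subjects).

    Uses per-subject substreams spawned from one seed sequence, so cohorts
    are bit-identical under a fixed seed and independent of subject order
    within the stream plan.
    """
    seq = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    n_total = sum(n for _, n in profiles)
    children = seq.spawn(n_total)
    sessions = []
    i = 0
    for profile, n in profiles:
        if n < 1:
            raise ValueError("each group needs at least one subject")
        for j in range(n):
            rng = np.random.default_rng(children[i])
            sid = f"{profile.label}_{j + 1:03d}"
            if paradigm == "sequential":
                sessions.append(
                    simulate_sequential_subject(
                        profile,
                        design,
                        rng,
                        params_override=params_override,
                        heterogeneity=heterogeneity,
                        subject_id=sid,
                    )
                )
            elif paradigm == "mgl":
                sessions.append(
                    simulate_mgl_subject(
                        profile, design, rng, heterogeneity=heterogeneity, subject_id=sid
                    )
                )
            else:
                raise ValueError(f"unknown paradigm {paradigm!r}")
            i += 1
    return sessions
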
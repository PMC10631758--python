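"""Circular statistics and von Mises utilities.

Angles live on the half-open interval (-pi, pi]; every angular subtraction
in the package is routed through :func:`wrap_angle` so that a single
canonical representation is used throughout.  Orientation data with period
pi (bar stimuli) are mapped onto the full circle by doubling before any of
these functions see them.

The von Mises distribution is the circular analogue of the Gaussian,

    f(theta; mu, kappa) = exp(kappa * cos(theta - mu)) / (2 pi I0(kappa)),

with mean direction ``mu`` and concentration ``kappa >= 0``.  Its circular
standard deviation is ``sqrt(-2 ln A1(kappa))`` where
``A1(kappa) = I1(kappa) / I0(kappa)`` is the mean resultant length.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, special

__all__ = [
    "KAPPA_MAX",
    "R_MIN",
    "CircularMean",
    "wrap_angle",
    "circ_mean",
    "circ_sd",
    "vm_pdf",
    "vm_sample",
    "a1",
    "a1inv",
    "kappa_to_sd",
    "sd_to_kappa",
]

#: Largest concentration the package works with.  Bessel-function ratios are
#: evaluated with exponentially scaled routines so this is not an overflow
#: limit per se, but kappa above this is numerically indistinguishable from a
#: point mass at the precision we care about; larger values are clamped.
KAPPA_MAX = 700.0

#: Resultant lengths below this are treated as zero: the circular mean of
#: such a sample is meaningless (antipodal cancellation).
R_MIN = 1e-12


def wrap_angle(x):
    """Wrap angle(s) to the canonical interval (-pi, pi].

    Accepts scalars or arrays; raises ``ValueError`` on non-finite input.
    """
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("wrap_angle requires finite input")
    # pi - mod(pi - x, 2pi) maps exactly onto (-pi, pi] (wrap(-pi) == pi).
    wrapped = np.pi - np.mod(np.pi - x, 2.0 * np.pi)
    if wrapped.ndim == 0:
        return float(wrapped)
    return wrapped


@dataclass(frozen=True)
class CircularMean:
    """Circular mean direction with its mean resultant length.

    ``defined`` is False when the resultant length is below :data:`R_MIN`
    (e.g. antipodal angles cancel); the ``mean`` field is then meaningless
    and set to 0.0 by convention.
    """

    mean: float
    resultant_length: float
    defined: bool


def _resultant(angles) -> tuple[float, float]:
    angles = np.asarray(angles, dtype=float)
    if angles.size == 0:
        raise ValueError("circular statistics need at least one angle")
    if not np.all(np.isfinite(angles)):
        raise ValueError("angles must be finite")
    z = np.exp(1j * angles).mean()
    return float(np.angle(z)), float(np.abs(z))


def circ_mean(angles) -> CircularMean:
    """Circular mean of a nonempty set of angles (radians)."""
    mean, r = _resultant(angles)
    if r < R_MIN:
        return CircularMean(mean=0.0, resultant_length=r, defined=False)
    return CircularMean(mean=wrap_angle(mean), resultant_length=r, defined=True)


def circ_sd(angles) -> float:
    """Circular standard deviation ``sqrt(-2 ln R)``; +inf when R == 0."""
    _, r = _resultant(angles)
    if r < R_MIN:
        return float("inf")
    if r >= 1.0:
        return 0.0
    return float(np.sqrt(-2.0 * np.log(r)))


def _clamp_kappa(kappa: float) -> float:
    kappa = float(kappa)
    if kappa < 0 or not np.isfinite(kappa):
        raise ValueError(f"concentration must be a finite nonnegative real, got {kappa}")
    if kappa > KAPPA_MAX:
        warnings.warn(
            f"kappa={kappa:g} exceeds KAPPA_MAX={KAPPA_MAX:g}; clamped",
            RuntimeWarning,
            stacklevel=3,
        )
        kappa = KAPPA_MAX
    return kappa


def vm_pdf(theta, mu, kappa):
    """von Mises density at ``theta`` (radians), mean ``mu``, concentration ``kappa``.

    Evaluated as ``exp(kappa (cos(theta-mu) - 1)) / (2 pi i0e(kappa))`` which
    is overflow-safe for all admissible kappa; kappa == 0 gives the uniform
    density 1/(2 pi).
    """
    kappa = _clamp_kappa(kappa)
    theta = np.asarray(theta, dtype=float)
    d = np.cos(theta - np.asarray(mu, dtype=float))
    out = np.exp(kappa * (d - 1.0)) / (2.0 * np.pi * special.i0e(kappa))
    if out.ndim == 0:
        return float(out)
    return out


def vm_sample(n, mu, kappa, rng):
    """Draw ``n`` i.i.d. von Mises angles, wrapped to (-pi, pi].

    ``rng`` is a :class:`numpy.random.Generator`; a fixed generator state
    gives reproducible draws.
    """
    n = int(n)
    if n < 0:
        raise ValueError("sample size must be nonnegative")
    kappa = _clamp_kappa(kappa)
    if n == 0:
        return np.empty(0, dtype=float)
    return wrap_angle(rng.vonmises(mu, kappa, size=n))


def a1(kappa):
    """Mean resultant length of a von Mises distribution, I1(kappa)/I0(kappa)."""
    kappa = np.asarray(kappa, dtype=float)
    out = special.i1e(kappa) / special.i0e(kappa)
    if out.ndim == 0:
        return float(out)
    return out


def a1inv(r: float) -> float:
    """Inverse of :func:`a1`: the concentration whose resultant length is ``r``.

    Uses the Fisher three-branch rational approximation as an initializer
    and refines by bisection (Brent) on ``a1(kappa) - r`` to |residual|
    below 1e-9.  ``r <= 0`` maps to 0 and ``r`` close to 1 clamps at
    :data:`KAPPA_MAX`.
    """
    r = float(r)
    if r <= 0.0:
        return 0.0
    if r >= 1.0:
        return KAPPA_MAX
    if r < 0.53:
        k0 = 2.0 * r + r**3 + 5.0 * r**5 / 6.0
    elif r < 0.85:
        k0 = -0.4 + 1.39 * r + 0.43 / (1.0 - r)
    else:
        k0 = 1.0 / (r**3 - 4.0 * r**2 + 3.0 * r)
    if k0 >= KAPPA_MAX or a1(KAPPA_MAX) <= r:
        return KAPPA_MAX
    lo, hi = 0.0, max(2.0 * k0, 1e-3)
    while a1(hi) < r:
        hi *= 2.0
        if hi >= KAPPA_MAX:
            hi = KAPPA_MAX
            break
    kappa = optimize.brentq(lambda k: a1(k) - r, lo, hi, xtol=1e-12, rtol=1e-14)
    return float(min(kappa, KAPPA_MAX))


def kappa_to_sd(kappa) -> float:
    """Circular SD implied by a von Mises concentration; +inf at kappa == 0."""
    kappa = _clamp_kappa(kappa)
    if kappa == 0.0:
        return float("inf")
    return float(np.sqrt(-2.0 * np.log(a1(kappa))))


def sd_to_kappa(sd) -> float:
    """Concentration whose implied circular SD is ``sd`` (> 0 radians)."""
    sd = float(sd)
    if not np.isfinite(sd) or sd <= 0.0:
        raise ValueError("circular SD must be a positive finite real")
    return a1inv(float(np.exp(-0.5 * sd * sd)))
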
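import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20230911)


# --- independent Bessel-series oracles ------------------------------------
# Power-series evaluation of the modified Bessel functions, kept deliberately
# separate from scipy so the package's von Mises constants can be checked
# against an implementation that shares no code with them.

def bessel_i0(x: float, terms: int = 80) -> float:
    total = 0.0
    term = 1.0
    for k in range(terms):
        if k > 0:
            term *= (x / 2.0) ** 2 / k**2
        total += term
    return total


def bessel_i1(x: float, terms: int = 80) -> float:
    total = 0.0
    fact_k = 1.0  # k!
    for k in range(terms):
        if k > 0:
            fact_k *= k
        fact_k1 = fact_k * (k + 1)  # (k+1)!
        total += (x / 2.0) ** (2 * k + 1) / (fact_k * fact_k1)
    return total


def oracle_vm_sd(kappa: float) -> float:
    """Circular SD sqrt(-2 ln(I1/I0)) via the series oracle."""
    import math

    return math.sqrt(-2.0 * math.log(bessel_i1(kappa) / bessel_i0(kappa)))


@pytest.fixture
def bessel_oracle():
    return {"i0": bessel_i0, "i1": bessel_i1, "vm_sd": oracle_vm_sd}


def random_trials(rng, n, m=2, params=None):
    """Random TrialErrors, optionally drawn from given mixture parameters."""
    from wmmix.circular import vm_sample, wrap_angle
    from wmmix.mixture import MixtureParameters, TrialErrors

    target = rng.uniform(-np.pi, np.pi, n)
    nontargets = rng.uniform(-np.pi, np.pi, (n, m))
    if params is None:
        response = rng.uniform(-np.pi, np.pi, n)
    else:
        response = np.empty(n)
        u = rng.random(n)
        for i in range(n):
            if u[i] < params.p_target:
                response[i] = vm_sample(1, target[i], params.kappa, rng)[0]
            elif m and u[i] < params.p_target + params.p_nontarget:
                j = rng.integers(m)
                response[i] = vm_sample(1, nontargets[i, j], params.kappa, rng)[0]
            else:
                response[i] = rng.uniform(-np.pi, np.pi)
    return TrialErrors(response=response, target=target, nontargets=nontargets)
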
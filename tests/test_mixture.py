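"""Swap-mixture likelihood, EM fitting and nearest-neighbor rescoring."""

import math

import numpy as np
import pytest

from conftest import random_trials
from wmmix.circular import KAPPA_MAX, kappa_to_sd, sd_to_kappa, vm_pdf, wrap_angle
from wmmix.mixture import (
    EMConfig,
    MixtureParameters,
    TrialErrors,
    em_fit,
    fit_by_cell,
    mixture_loglik,
    nearest_neighbor_errors,
    trials_from_frame,
)


def oracle_loglik(params, trials):
    """Direct per-trial density sum, deliberately non-vectorized."""
    total = 0.0
    m = trials.n_nontargets
    for i in range(trials.n_trials):
        d = params.p_target * vm_pdf(trials.response[i], trials.target[i], params.kappa)
        for j in range(m):
            d += (params.p_nontarget / m) * vm_pdf(
                trials.response[i], trials.nontargets[i, j], params.kappa
            )
        d += params.p_uniform / (2 * np.pi)
        total += math.log(d)
    return total


class TestMixtureLoglik:
    def test_pure_uniform(self, rng):
        tr = random_trials(rng, 37)
        params = MixtureParameters(0.0, 0.0, 1.0, 1.0)
        assert mixture_loglik(params, tr) == pytest.approx(37 * math.log(1 / (2 * np.pi)))

    def test_single_trial_at_target(self):
        tr = TrialErrors(response=[0.4], target=[0.4], nontargets=np.empty((1, 0)))
        params = MixtureParameters(1.0, 0.0, 0.0, 2.0)
        assert mixture_loglik(params, tr) == pytest.approx(math.log(vm_pdf(0.0, 0.0, 2.0)))
        assert mixture_loglik(params, tr) == pytest.approx(math.log(0.5159), abs=1e-4)

    def test_matches_bruteforce_oracle(self, rng):
        tr = random_trials(rng, 50)
        for params in [
            MixtureParameters(0.8, 0.12, 0.08, 4.0),
            MixtureParameters(0.5, 0.0, 0.5, 0.7),
            MixtureParameters(0.1, 0.6, 0.3, 25.0),
        ]:
            assert abs(mixture_loglik(params, tr) - oracle_loglik(params, tr)) < 1e-9

    def test_swap_weight_rejected_without_nontargets(self, rng):
        tr = random_trials(rng, 10, m=0)
        with pytest.raises(ValueError):
            mixture_loglik(MixtureParameters(0.8, 0.1, 0.1, 2.0), tr)


class TestEMFit:
    def test_refuses_undersized_dataset(self, rng):
        with pytest.raises(ValueError):
            em_fit(random_trials(rng, 5))

    def test_degenerate_all_on_target(self, rng):
        target = rng.uniform(-np.pi, np.pi, 40)
        tr = TrialErrors(
            response=target.copy(), target=target, nontargets=rng.uniform(-np.pi, np.pi, (40, 2))
        )
        fit = em_fit(tr)
        assert fit.params.p_target > 0.99
        assert fit.params.kappa == KAPPA_MAX

    def test_parameter_recovery_large_sample(self, rng):
        gen = MixtureParameters(0.8, 0.12, 0.08, sd_to_kappa(0.5))
        tr = random_trials(rng, 10_000, params=gen)
        fit = em_fit(tr)
        assert fit.converged
        assert fit.params.p_target == pytest.approx(0.8, abs=0.02)
        assert fit.params.p_nontarget == pytest.approx(0.12, abs=0.02)
        assert fit.params.p_uniform == pytest.approx(0.08, abs=0.02)
        assert fit.von_mises_sd == pytest.approx(0.5, abs=0.03)

    def test_beats_grid_search_oracle(self, rng):
        """EM reaches at least the best log-likelihood on a parameter lattice."""
        gen = MixtureParameters(0.75, 0.15, 0.10, sd_to_kappa(0.6))
        tr = random_trials(rng, 200, params=gen)
        fit = em_fit(tr)
        best = -np.inf
        for pt in np.arange(0.05, 1.0, 0.05):
            for pn in np.arange(0.0, 1.0 - pt + 1e-9, 0.05):
                pu = 1.0 - pt - pn
                for sd in np.arange(0.3, 1.25, 0.05):
                    ll = mixture_loglik(
                        MixtureParameters(pt, pn, max(pu, 0.0), sd_to_kappa(sd)), tr
                    )
                    best = max(best, ll)
        assert fit.log_likelihood >= best - 1e-3

    def test_uniform_data_recovered_as_uniform_distribution(self, rng):
        """With responses unrelated to the items the fitted mixture must be
        uniform in distribution.  The weights themselves sit on an
        identifiability ridge (a kappa -> 0 von Mises component mimics the
        uniform source), so the check is on the implied density, with the
        explicit uniform source still carrying the bulk of the mass."""
        tr = random_trials(rng, 10_000)  # responses uniform, unrelated to items
        fit = em_fit(tr)
        assert fit.params.p_uniform >= 0.5
        # implied density at the fitted kappa stays within 5% of 1/(2 pi)
        grid = np.linspace(-np.pi, np.pi, 361)
        dens = (
            (fit.params.p_target + fit.params.p_nontarget) * vm_pdf(grid, 0.0, fit.params.kappa)
            + fit.params.p_uniform / (2 * np.pi)
        )
        assert np.all(np.abs(dens * 2 * np.pi - 1.0) < 0.05)

    def test_responsibilities_and_weights_normalized(self, rng):
        gen = MixtureParameters(0.7, 0.2, 0.1, 5.0)
        fit = em_fit(random_trials(rng, 300, params=gen))
        np.testing.assert_allclose(fit.responsibilities.sum(axis=1), 1.0, atol=1e-9)
        p = fit.params
        assert p.p_target + p.p_nontarget + p.p_uniform == pytest.approx(1.0, abs=1e-9)

    def test_nontarget_label_symmetry(self, rng):
        gen = MixtureParameters(0.7, 0.2, 0.1, 5.0)
        tr = random_trials(rng, 300, params=gen)
        swapped = TrialErrors(
            response=tr.response, target=tr.target, nontargets=tr.nontargets[:, ::-1]
        )
        a, b = em_fit(tr), em_fit(swapped)
        assert a.params.as_array() == pytest.approx(b.params.as_array(), rel=1e-6)

    def test_single_item_reduces_to_two_components(self, rng):
        gen = MixtureParameters(0.9, 0.0, 0.1, sd_to_kappa(0.3))
        tr = random_trials(rng, 500, m=0, params=gen)
        fit = em_fit(tr)
        assert fit.params.p_nontarget == 0.0
        assert fit.params.p_uniform == pytest.approx(1.0 - fit.params.p_target, abs=1e-12)
        assert fit.params.p_target == pytest.approx(0.9, abs=0.05)

    def test_loglik_nondecreasing_across_iterations(self, rng):
        """EM monotonicity is asserted inside every iteration; a full fit on
        awkward data exercising all restarts must therefore complete."""
        for n, m in [(50, 2), (50, 0), (2000, 2)]:
            tr = random_trials(rng, n, m=m)
            fit = em_fit(tr)
            assert np.isfinite(fit.log_likelihood)


class TestRecoveryBias:
    def test_bias_at_study_scale(self, rng):
        """Mean fitted parameters over 200 simulated 180-trial subjects stay
        within 0.02 (weights) / 0.03 rad (SD) of the generating values."""
        gen = MixtureParameters(0.88, 0.07, 0.05, sd_to_kappa(0.51))
        cfg = EMConfig()
        fits = [em_fit(random_trials(rng, 180, params=gen), cfg) for _ in range(200)]
        pt = np.mean([f.params.p_target for f in fits])
        pn = np.mean([f.params.p_nontarget for f in fits])
        pu = np.mean([f.params.p_uniform for f in fits])
        sd = np.mean([f.von_mises_sd for f in fits])
        assert pt == pytest.approx(0.88, abs=0.02)
        assert pn == pytest.approx(0.07, abs=0.02)
        assert pu == pytest.approx(0.05, abs=0.02)
        assert sd == pytest.approx(0.51, abs=0.03)


class TestNearestNeighbor:
    def test_exact_match_on_nontarget(self):
        tr = TrialErrors(response=[1.0], target=[0.0], nontargets=[[1.0, 2.0]])
        assert nearest_neighbor_errors(tr)[0] == 0.0

    def test_no_competitors_equals_target_error(self, rng):
        tr = random_trials(rng, 100, m=0)
        np.testing.assert_allclose(
            nearest_neighbor_errors(tr), wrap_angle(tr.response - tr.target), atol=1e-12
        )

    def test_never_larger_than_target_error(self, rng):
        tr = random_trials(rng, 1000)
        nn = np.abs(nearest_neighbor_errors(tr))
        te = np.abs(wrap_angle(tr.response - tr.target))
        assert np.all(nn <= te + 1e-12)
        # brute-force: the nearest item really is the minimum over all items
        for i in range(0, 1000, 37):
            cands = [tr.target[i], *tr.nontargets[i]]
            best = min(abs(wrap_angle(tr.response[i] - c)) for c in cands)
            assert nn[i] == pytest.approx(best, abs=1e-12)


class TestFitByCell:
    @staticmethod
    def _frame(rng, sds_by_order):
        import pandas as pd

        rows = []
        for order, sd in sds_by_order.items():
            gen = MixtureParameters(0.9, 0.05, 0.05, sd_to_kappa(sd))
            tr = random_trials(rng, 60, params=gen)
            for i in range(60):
                rows.append(
                    {
                        "probed_order": order,
                        "target": tr.target[i],
                        "nontarget1": tr.nontargets[i, 0],
                        "nontarget2": tr.nontargets[i, 1],
                        "response": tr.response[i],
                    }
                )
        return pd.DataFrame(rows)

    def test_per_order_fits_plus_session_fit(self, rng):
        frame = self._frame(rng, {1: 0.4, 2: 0.4, 3: 0.4})
        fits = fit_by_cell(frame, "probed_order", 3)
        assert set(fits) == {"__all__", 1, 2, 3}
        assert all(f.n_trials == 60 for k, f in fits.items() if k != "__all__")
        assert fits["__all__"].n_trials == 180

    def test_constant_key_equals_session_fit(self, rng):
        frame = self._frame(rng, {1: 0.5})
        fits = fit_by_cell(frame, "probed_order", 3)
        assert fits[1].log_likelihood == pytest.approx(fits["__all__"].log_likelihood)

    def test_recovers_cell_kappa_ordering(self, rng):
        frame = self._frame(rng, {1: 0.3, 2: 0.6, 3: 1.2})
        fits = fit_by_cell(frame, "probed_order", 3)
        assert fits[1].von_mises_sd < fits[2].von_mises_sd < fits[3].von_mises_sd

    def test_undersized_cell_marked_missing(self, rng):
        frame = self._frame(rng, {1: 0.5})
        frame.loc[frame.index[:5], "probed_order"] = 2  # 5-trial cell
        fits = fit_by_cell(frame, "probed_order", 3)
        assert fits[2] is None
        assert fits[1] is not None
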
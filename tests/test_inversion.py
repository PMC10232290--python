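"""Tests for the variational Laplace scheme, against conjugate-Gaussian oracles."""

import dataclasses

import numpy as np
import pytest

from pedcm.inversion import (
    ErfForwardModel,
    GaussianBelief,
    InversionResult,
    InversionSettings,
    LinearForwardModel,
    NoiseModel,
    free_energy,
    invert,
    jacobian,
    stack_erf_pair,
)
from pedcm.simulate import simulate_erf_pair


def conjugate_posterior(A, y, m0, S0, pi, c=None):
    """Inline closed-form conjugate posterior and log evidence (test oracle)."""
    c = np.zeros(A.shape[0]) if c is None else c
    P0 = np.linalg.inv(S0)
    P = pi * A.T @ A + P0
    S = np.linalg.inv(P)
    m = S @ (pi * A.T @ (y - c) + P0 @ m0)
    C = A @ S0 @ A.T + np.eye(A.shape[0]) / pi
    d = y - A @ m0 - c
    _, logdet = np.linalg.slogdet(C)
    log_ev = -0.5 * (A.shape[0] * np.log(2 * np.pi) + logdet + d @ np.linalg.solve(C, d))
    return m, S, float(log_ev)


@pytest.fixture()
def linear_problem(rng):
    n, N = 5, 40
    A = rng.normal(size=(N, n))
    c = rng.normal(size=N)
    names = [f"p{i}" for i in range(n)]
    prior = GaussianBelief.diagonal(names, 0.0, rng.uniform(0.5, 2.0, n))
    pi = 4.0
    y = A @ rng.normal(size=n) + c + rng.normal(0, 1 / np.sqrt(pi), N)
    return A, c, prior, pi, y


class TestGaussianBelief:
    def test_dimension_and_symmetry_validation(self):
        with pytest.raises(ValueError, match="unique"):
            GaussianBelief(["a", "a"], np.zeros(2), np.eye(2))
        with pytest.raises(ValueError, match="symmetric"):
            GaussianBelief(["a", "b"], np.zeros(2), np.array([[1.0, 0.5], [0.0, 1.0]]))
        with pytest.raises(ValueError, match="semi-definite"):
            GaussianBelief(["a", "b"], np.zeros(2), np.array([[1.0, 2.0], [2.0, 1.0]]))

    def test_marginal_preserves_order(self, rng):
        S = rng.normal(size=(3, 3))
        b = GaussianBelief(["a", "b", "c"], np.arange(3.0), S @ S.T + np.eye(3))
        m = b.marginal(["c", "a"])
        assert m.names == ["c", "a"]
        assert m.mean[0] == 2.0 and m.mean[1] == 0.0


class TestJacobian:
    def test_linear_model_recovers_coefficients(self, rng):
        A = rng.normal(size=(20, 4))
        fwd = LinearForwardModel(A)
        J = jacobian(fwd, np.zeros(4))
        np.testing.assert_allclose(J, A, atol=1e-8)

    def test_zero_influence_parameter_zero_column(self, rng):
        A = rng.normal(size=(20, 4))
        A[:, 2] = 0.0
        J = jacobian(LinearForwardModel(A), rng.normal(size=4))
        assert np.all(J[:, 2] == 0.0)

    def test_step_halving_stability_on_erf_model(self, base_params):
        names = ["gamma:AMPA:ss->sp", "gamma:GABA:si->sp"]
        fwd = ErfForwardModel(base_params, names)
        lam = np.array([0.1, -0.1])
        J1 = jacobian(fwd, lam, 1e-4)
        J2 = jacobian(fwd, lam, 5e-5)
        denom = np.max(np.abs(J1))
        assert np.max(np.abs(J1 - J2)) / denom < 1e-4


class TestFreeEnergy:
    def test_zero_residuals_at_prior_give_zero_parameter_complexity(self, rng):
        A = rng.normal(size=(30, 3))
        prior = GaussianBelief.diagonal(["a", "b", "c"], 0.0, 1.0)
        y = A @ prior.mean  # exactly the prior prediction
        fwd = LinearForwardModel(A, names=list(prior.names))
        F, dec = free_energy(y, fwd, prior, prior, NoiseModel(0.0, 0.0))
        assert dec.complexity_parameters == pytest.approx(0.0, abs=1e-12)
        assert F == pytest.approx(dec.total)

    def test_larger_residuals_decrease_accuracy(self, rng):
        A = rng.normal(size=(30, 3))
        prior = GaussianBelief.diagonal(["a", "b", "c"], 0.0, 1.0)
        fwd = LinearForwardModel(A, names=list(prior.names))
        noise = NoiseModel(np.log(4.0), 0.0)
        e = rng.normal(size=30)
        _, dec_small = free_energy(A @ prior.mean + e, fwd, prior, prior, noise)
        _, dec_large = free_energy(A @ prior.mean + 2 * e, fwd, prior, prior, noise)
        assert dec_large.accuracy_states < dec_small.accuracy_states

    def test_decomposition_sums_to_total(self, linear_problem):
        A, c, prior, pi, y = linear_problem
        fwd = LinearForwardModel(A, c, list(prior.names))
        res = invert(y, fwd, prior, NoiseModel(0.0, 16.0), InversionSettings(tol=1e-6))
        assert res.free_energy == pytest.approx(res.decomposition.total, abs=1e-9)


class TestInvert:
    def test_matches_conjugate_oracle(self, linear_problem):
        A, c, prior, pi, y = linear_problem
        fwd = LinearForwardModel(A, c, list(prior.names))
        res = invert(y, fwd, prior, NoiseModel(np.log(pi), 0.0),
                     InversionSettings(max_iter=64, tol=1e-12))
        m, S, log_ev = conjugate_posterior(A, y, prior.mean, prior.cov, pi, c)
        np.testing.assert_allclose(res.posterior.mean, m, atol=1e-6)
        np.testing.assert_allclose(res.posterior.cov, S, atol=1e-6)
        assert res.free_energy == pytest.approx(log_ev, abs=1e-3)

    def test_posterior_precision_dominates_prior_precision(self, linear_problem):
        A, c, prior, pi, y = linear_problem
        fwd = LinearForwardModel(A, c, list(prior.names))
        res = invert(y, fwd, prior, NoiseModel(np.log(pi), 0.0), InversionSettings(tol=1e-10))
        dP = np.linalg.inv(res.posterior.cov) - np.linalg.inv(prior.cov)
        assert np.linalg.eigvalsh((dP + dP.T) / 2).min() > -1e-6

    def test_monotone_free_energy_trace(self, linear_problem):
        A, c, prior, pi, y = linear_problem
        fwd = LinearForwardModel(A, c, list(prior.names))
        res = invert(y, fwd, prior, NoiseModel(0.0, 16.0), InversionSettings(tol=1e-8))
        assert np.all(np.diff(res.f_trace) > 0)

    def test_self_consistency_at_prior_mean(self, base_params):
        names = ["gamma:AMPA:ss->sp", "gamma:NMDA:ss->sp", "gamma:GABA:si->sp"]
        std, dev = simulate_erf_pair(base_params)
        y = stack_erf_pair(std, dev)  # noiseless data generated at the prior mean
        prior = GaussianBelief.diagonal(names, 0.0, 1.0 / 16.0)
        fwd = ErfForwardModel(base_params, names)
        res = invert(y, fwd, prior, NoiseModel(0.0, 16.0), InversionSettings(max_iter=16))
        assert np.max(np.abs(res.posterior.mean - prior.mean)) < 1e-3

    def test_noiseless_refit_correlates_with_noisy_data(self, base_params, rng):
        names = [f"gamma:{e.name}" for e in base_params.edges]
        lam_true = rng.normal(0, 0.15, len(names))
        q = base_params.apply_log_factors(names, lam_true)
        std, dev = simulate_erf_pair(q)
        y = stack_erf_pair(std, dev)
        y_noisy = y + rng.normal(0, 0.3, y.size)  # moderate noise vs ~13-unit peak
        prior = GaussianBelief.diagonal(names, 0.0, 1.0 / 16.0)
        fwd = ErfForwardModel(base_params, names)
        res = invert(y_noisy, fwd, prior, NoiseModel(0.0, 16.0))
        pred = fwd.predict(res.posterior.mean[None])[0]
        assert np.corrcoef(pred, y_noisy)[0, 1] > 0.95

    def test_serialization_round_trip(self, linear_problem, tmp_path):
        A, c, prior, pi, y = linear_problem
        fwd = LinearForwardModel(A, c, list(prior.names))
        res = invert(y, fwd, prior, NoiseModel(0.0, 16.0), InversionSettings(tol=1e-6))
        res.to_dir(tmp_path / "inv")
        loaded = InversionResult.from_dir(tmp_path / "inv")
        np.testing.assert_allclose(loaded.posterior.mean, res.posterior.mean, rtol=1e-15)
        np.testing.assert_allclose(loaded.posterior.cov, res.posterior.cov, rtol=1e-15)
        assert loaded.free_energy == res.free_energy
        assert loaded.f_trace == res.f_trace
        assert loaded.decomposition.to_dict() == res.decomposition.to_dict()
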
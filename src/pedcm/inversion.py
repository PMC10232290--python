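"""Variational Laplace inversion of the microcircuit from one subject's ERFs.

The scheme fits a nonlinear forward model ``y = f(lambda) + e`` with
Gaussian priors on the free parameters ``lambda`` and i.i.d. Gaussian
observation noise whose log-precision carries a Gaussian hyperprior.
Parameter means are updated by Levenberg-Marquardt-regularized
Gauss-Newton ascent on the variational free energy

    F = accuracy - complexity

a lower bound on the log model evidence.  A step is accepted only if it
increases F, so the recorded per-iteration F trace is non-decreasing by
construction.  The free energy is reported with a six-way decomposition
(accuracy and complexity of states, parameters and precision); the exact
assignment of terms is documented in ``docs/methods.md``.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Callable, Protocol

import numpy as np

from .microcircuit import MicrocircuitParameters
from .simulate import ErfTrace, default_time_grid, simulate_erf_pair_batch

LN2PI = float(np.log(2.0 * np.pi))


@dataclass
class GaussianBelief:
    """A mean/covariance pair over named parameters.

    Used for priors, posteriors and empirical priors at both levels of
    the hierarchy.
    """

    names: list[str]
    mean: np.ndarray
    cov: np.ndarray

    def __post_init__(self) -> None:
        self.names = list(self.names)
        self.mean = np.asarray(self.mean, dtype=float)
        self.cov = np.asarray(self.cov, dtype=float)
        n = len(self.names)
        if len(set(self.names)) != n:
            raise ValueError("parameter names must be unique")
        if self.mean.shape != (n,):
            raise ValueError("mean dimension must match names")
        if self.cov.shape != (n, n):
            raise ValueError("covariance order must match names")
        if not np.allclose(self.cov, self.cov.T, atol=1e-10):
            raise ValueError("covariance must be symmetric")
        w = np.linalg.eigvalsh((self.cov + self.cov.T) / 2)
        if w.min() < -1e-8 * max(1.0, w.max()):
            raise ValueError("covariance must be positive semi-definite")

    @property
    def n(self) -> int:
        return len(self.names)

    @classmethod
    def diagonal(cls, names: list[str], mean=0.0, var=1.0) -> "GaussianBelief":
        n = len(names)
        mean = np.full(n, mean, dtype=float) if np.isscalar(mean) else np.asarray(mean, float)
        var = np.full(n, var, dtype=float) if np.isscalar(var) else np.asarray(var, float)
        return cls(names, mean, np.diag(var))

    def index_of(self, names: list[str]) -> np.ndarray:
        pos = {nm: i for i, nm in enumerate(self.names)}
        return np.array([pos[nm] for nm in names], dtype=int)

    def marginal(self, names: list[str]) -> "GaussianBelief":
        idx = self.index_of(names)
        return GaussianBelief(list(names), self.mean[idx], self.cov[np.ix_(idx, idx)])


@dataclass
class NoiseModel:
    """Observation-noise model: precision = exp(log-precision).

    ``log_precision_var = 0`` marks the precision as fixed (no
    hyperparameter update, no complexity-of-precision charge); otherwise
    the log-precision carries the Gaussian hyperprior
    N(log_precision_mean, log_precision_var).
    """

    log_precision_mean: float = 0.0
    log_precision_var: float = 16.0

    def __post_init__(self) -> None:
        if self.log_precision_var < 0:
            raise ValueError("hyperprior variance must be non-negative")

    @property
    def fixed(self) -> bool:
        return self.log_precision_var == 0.0


@dataclass
class InversionSettings:
    max_iter: int = 64
    tol: float = 0.01                 # stop when an accepted step gains < tol nats
    init_damping: float = 1.0 / 32.0
    max_rejections: int = 8
    fd_step: float = 1e-4             # central-difference step on the log scale


class ForwardModel(Protocol):
    names: list[str]
    n_out: int

    def predict(self, lam: np.ndarray) -> np.ndarray:
        """Map (B, n_free) parameter displacements to (B, n_out) predictions."""
        ...


@dataclass
class LinearForwardModel:
    """y = lam @ A.T + c — the conjugate-Gaussian oracle's forward model."""

    A: np.ndarray
    c: np.ndarray | None = None
    names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float)
        if self.c is None:
            self.c = np.zeros(self.A.shape[0])
        if not self.names:
            self.names = [f"p{i}" for i in range(self.A.shape[1])]

    @property
    def n_out(self) -> int:
        return self.A.shape[0]

    def predict(self, lam: np.ndarray) -> np.ndarray:
        lam = np.atleast_2d(np.asarray(lam, dtype=float))
        return lam @ self.A.T + self.c


@dataclass
class ErfForwardModel:
    """Concatenated (standard ++ deviant) ERF prediction of the microcircuit."""

    params: MicrocircuitParameters
    names: list[str]
    time_ms: np.ndarray = field(default_factory=default_time_grid)
    internal_dt: float = 1.0
    backend: str = "auto"

    @property
    def n_out(self) -> int:
        return 2 * len(self.time_ms)

    def predict(self, lam: np.ndarray) -> np.ndarray:
        return simulate_erf_pair_batch(
            self.params, self.names, lam, self.time_ms, self.internal_dt, backend=self.backend
        )


def stack_erf_pair(standard: ErfTrace, deviant: ErfTrace) -> np.ndarray:
    """Concatenate a condition pair into the inversion's data vector."""
    if standard.time_ms.shape != deviant.time_ms.shape:
        raise ValueError("conditions must share a time grid")
    return np.concatenate([standard.amplitude, deviant.amplitude])


def jacobian(forward: ForwardModel, lam: np.ndarray, step: float = 1e-4) -> np.ndarray:
    """Central finite-difference Jacobian d(prediction)/d(lambda), (n_out, n)."""
    lam = np.asarray(lam, dtype=float)
    n = lam.size
    batch = np.tile(lam, (2 * n, 1))
    for j in range(n):
        batch[2 * j, j] += step
        batch[2 * j + 1, j] -= step
    Y = forward.predict(batch)
    if not np.all(np.isfinite(Y)):
        raise FloatingPointError("forward model returned non-finite values at a perturbed point")
    J = np.empty((forward.n_out, n))
    for j in range(n):
        J[:, j] = (Y[2 * j] - Y[2 * j + 1]) / (2.0 * step)
    return J


def kl_gaussian(m, S, m0, S0) -> float:
    """KL( N(m, S) || N(m0, S0) ) in nats."""
    m, m0 = np.asarray(m, float), np.asarray(m0, float)
    S, S0 = np.atleast_2d(np.asarray(S, float)), np.atleast_2d(np.asarray(S0, float))
    n = m.size
    L0 = np.linalg.cholesky(S0)
    sign, logdetS = np.linalg.slogdet(S)
    if sign <= 0:
        raise np.linalg.LinAlgError("posterior covariance not positive definite")
    logdetS0 = 2.0 * float(np.sum(np.log(np.diag(L0))))
    P0 = np.linalg.inv(S0)
    d = m - m0
    return 0.5 * float(np.trace(P0 @ S) + d @ P0 @ d - n + logdetS0 - logdetS)


@dataclass
class FreeEnergyDecomposition:
    accuracy_states: float
    accuracy_parameters: float
    accuracy_precision: float
    complexity_states: float
    complexity_parameters: float
    complexity_precision: float

    @property
    def total(self) -> float:
        return (
            self.accuracy_states + self.accuracy_parameters + self.accuracy_precision
            - self.complexity_states - self.complexity_parameters - self.complexity_precision
        )

    def to_dict(self) -> dict:
        return {
            "accuracy_states": self.accuracy_states,
            "accuracy_parameters": self.accuracy_parameters,
            "accuracy_precision": self.accuracy_precision,
            "complexity_states": self.complexity_states,
            "complexity_parameters": self.complexity_parameters,
            "complexity_precision": self.complexity_precision,
        }


@dataclass
class InversionResult:
    posterior: GaussianBelief
    free_energy: float
    decomposition: FreeEnergyDecomposition
    iterations: int
    converged: bool
    local_optimum: bool
    f_trace: list[float]
    noise_log_precision: float
    noise_log_precision_var: float

    # -- serialization (JSON + delimited covariance) ------------------------

    def to_dir(self, path: str) -> None:
        os.makedirs(path, exist_ok=True)
        doc = {
            "names": self.posterior.names,
            "mean": [float(v) for v in self.posterior.mean],
            "free_energy": self.free_energy,
            "decomposition": self.decomposition.to_dict(),
            "iterations": self.iterations,
            "converged": self.converged,
            "local_optimum": self.local_optimum,
            "f_trace": [float(v) for v in self.f_trace],
            "noise_log_precision": self.noise_log_precision,
            "noise_log_precision_var": self.noise_log_precision_var,
        }
        with open(os.path.join(path, "result.json"), "w") as fh:
            json.dump(doc, fh, indent=1, sort_keys=True)
        np.savetxt(os.path.join(path, "covariance.csv"), self.posterior.cov, delimiter=",", fmt="%.17e")

    @classmethod
    def from_dir(cls, path: str) -> "InversionResult":
        with open(os.path.join(path, "result.json")) as fh:
            doc = json.load(fh)
        cov = np.loadtxt(os.path.join(path, "covariance.csv"), delimiter=",", ndmin=2)
        return cls(
            posterior=GaussianBelief(doc["names"], np.array(doc["mean"]), cov),
            free_energy=doc["free_energy"],
            decomposition=FreeEnergyDecomposition(**doc["decomposition"]),
            iterations=doc["iterations"],
            converged=doc["converged"],
            local_optimum=doc["local_optimum"],
            f_trace=list(doc["f_trace"]),
            noise_log_precision=doc["noise_log_precision"],
            noise_log_precision_var=doc["noise_log_precision_var"],
        )


def _decompose(
    e: np.ndarray,
    J: np.ndarray,
    Sigma: np.ndarray,
    mean: np.ndarray,
    priors: GaussianBelief,
    mh: float,
    sh: float,
    noise: NoiseModel,
) -> FreeEnergyDecomposition:
    N = e.size
    sse = float(e @ e)
    tr = float(np.einsum("ij,jk,ik->", J, Sigma, J))
    pi_m = float(np.exp(mh))
    pi_bar = float(np.exp(mh + 0.5 * sh))
    acc_states = -0.5 * N * LN2PI + 0.5 * N * mh - 0.5 * pi_m * sse
    acc_params = -0.5 * pi_m * tr
    acc_prec = -0.5 * (pi_bar - pi_m) * (sse + tr)
    comp_params = kl_gaussian(mean, Sigma, priors.mean, priors.cov)
    if noise.fixed:
        comp_prec = 0.0
        acc_prec = 0.0
    else:
        comp_prec = kl_gaussian(
            np.array([mh]), np.array([[sh]]),
            np.array([noise.log_precision_mean]), np.array([[noise.log_precision_var]]),
        )
    return FreeEnergyDecomposition(
        accuracy_states=acc_states,
        accuracy_parameters=acc_params,
        accuracy_precision=acc_prec,
        complexity_states=0.0,
        complexity_parameters=comp_params,
        complexity_precision=comp_prec,
    )


def _update_noise(e: np.ndarray, J: np.ndarray, priors: GaussianBelief, noise: NoiseModel,
                  mh0: float) -> tuple[float, float, np.ndarray]:
    """Coordinate update of (noise posterior, parameter covariance).

    Returns (mh, sh, Sigma) with Sigma the Laplace posterior covariance
    at the current parameter mean given the updated precision.
    """
    N = e.shape[0]
    P0 = np.linalg.inv(priors.cov)
    JtJ = J.T @ J
    mh = mh0
    sh = 0.0
    for _ in range(3):
        Sigma = np.linalg.inv(np.exp(mh) * JtJ + P0)
        if noise.fixed:
            mh = noise.log_precision_mean
            sh = 0.0
            continue
        E = float(e @ e) + float(np.einsum("ij,jk,ik->", J, Sigma, J))
        h0, S0 = noise.log_precision_mean, noise.log_precision_var
        for _ in range(8):  # 1-D Newton on the log-precision
            gr = 0.5 * N - 0.5 * np.exp(mh) * E - (mh - h0) / S0
            he = -0.5 * np.exp(mh) * E - 1.0 / S0
            step = -gr / he
            mh = float(np.clip(mh + np.clip(step, -4.0, 4.0), -32.0, 32.0))
        sh = -1.0 / he
    Sigma = np.linalg.inv(np.exp(mh) * JtJ + P0)
    return float(mh), float(sh), Sigma


def free_energy(
    data: np.ndarray,
    forward: ForwardModel,
    belief: GaussianBelief,
    priors: GaussianBelief,
    noise: NoiseModel,
    fd_step: float = 1e-4,
) -> tuple[float, FreeEnergyDecomposition]:
    """Evaluate the variational free energy at a given parameter belief.

    The noise posterior is set by coordinate ascent given the residuals
    (or held fixed when the noise model is fixed).  The returned
    decomposition sums exactly to F.
    """
    if belief.names != priors.names:
        raise ValueError("belief and priors must share the parameter index")
    y = np.asarray(data, dtype=float)
    f = forward.predict(belief.mean[None])[0]
    e = y - f
    J = jacobian(forward, belief.mean, fd_step)
    mh, sh, _ = _update_noise(e, J, priors, noise, noise.log_precision_mean)
    dec = _decompose(e, J, belief.cov, belief.mean, priors, mh, sh, noise)
    return dec.total, dec


def invert(
    data: np.ndarray,
    forward: ForwardModel,
    priors: GaussianBelief,
    noise: NoiseModel | None = None,
    settings: InversionSettings | None = None,
) -> InversionResult:
    """Variational Laplace estimation of the forward model's parameters.

    ``data`` is the stacked observation vector (for ERF pairs, use
    :func:`stack_erf_pair`).  Alternates LM-regularized Gauss-Newton
    updates of the parameter means with closed-form covariance updates
    and noise-hyperparameter updates, accepting a step only if the free
    energy increases.  Stops after an accepted gain below ``tol`` nats,
    after ``max_iter`` iterations, or after ``max_rejections``
    consecutive rejected steps (flagged as a local optimum).
    """
    noise = noise or NoiseModel()
    settings = settings or InversionSettings()
    y = np.asarray(data, dtype=float)
    if y.shape != (forward.n_out,):
        raise ValueError(f"data must have {forward.n_out} samples, got {y.shape}")
    P0 = np.linalg.inv(priors.cov)

    def evaluate(lam: np.ndarray, mh_init: float) -> dict:
        f = forward.predict(lam[None])[0]
        e = y - f
        J = jacobian(forward, lam, settings.fd_step)
        mh, sh, Sigma = _update_noise(e, J, priors, noise, mh_init)
        dec = _decompose(e, J, Sigma, lam, priors, mh, sh, noise)
        return {"lam": lam, "e": e, "J": J, "mh": mh, "sh": sh, "Sigma": Sigma,
                "dec": dec, "F": dec.total}

    cur = evaluate(priors.mean.copy(), noise.log_precision_mean)
    f_trace = [cur["F"]]
    damping = settings.init_damping
    rejections = 0
    converged = False
    local_optimum = False
    iterations = 0
    for _ in range(settings.max_iter):
        iterations += 1
        pi = np.exp(cur["mh"])
        H = pi * cur["J"].T @ cur["J"] + P0
        grad = pi * cur["J"].T @ cur["e"] - P0 @ (cur["lam"] - priors.mean)
        D = np.diag(np.maximum(np.diag(H), 1e-12))
        try:
            step = np.linalg.solve(H + damping * D, grad)
        except np.linalg.LinAlgError:
            step = grad / np.maximum(np.diag(H), 1e-12)
        try:
            cand = evaluate(cur["lam"] + step, cur["mh"])
        except (FloatingPointError, RuntimeError, np.linalg.LinAlgError):
            cand = None  # forward model failed at the candidate: treat as a rejection
        if cand is not None and cand["F"] > cur["F"]:
            dF = cand["F"] - cur["F"]
            cur = cand
            f_trace.append(cur["F"])
            damping = max(damping / 2.0, 1e-8)
            rejections = 0
            if dF < settings.tol:
                converged = True
                break
        else:
            damping *= 2.0
            rejections += 1
            if rejections >= settings.max_rejections:
                local_optimum = True
                break

    posterior = GaussianBelief(list(priors.names), cur["lam"], (cur["Sigma"] + cur["Sigma"].T) / 2)
    return InversionResult(
        posterior=posterior,
        free_energy=cur["F"],
        decomposition=cur["dec"],
        iterations=iterations,
        converged=converged,
        local_optimum=local_optimum,
        f_trace=f_trace,
        noise_log_precision=cur["mh"],
        noise_log_precision_var=cur["sh"],
    )


def linear_gaussian_posterior(
    A: np.ndarray, y: np.ndarray, prior: GaussianBelief, pi: float, c: np.ndarray | None = None
) -> tuple[GaussianBelief, float]:
    """Closed-form conjugate posterior and log evidence for y = A x + c + e.

    Independent oracle for the linear-Gaussian case: e ~ N(0, I/pi),
    x ~ N(prior.mean, prior.cov).  Returns the exact posterior belief and
    ln p(y).
    """
    A = np.asarray(A, float)
    y = np.asarray(y, float)
    c = np.zeros(A.shape[0]) if c is None else np.asarray(c, float)
    S0 = prior.cov
    m0 = prior.mean
    P = pi * A.T @ A + np.linalg.inv(S0)
    S = np.linalg.inv(P)
    m = S @ (pi * A.T @ (y - c) + np.linalg.inv(S0) @ m0)
    marg_cov = A @ S0 @ A.T + np.eye(A.shape[0]) / pi
    d = y - (A @ m0 + c)
    sign, logdet = np.linalg.slogdet(marg_cov)
    log_ev = -0.5 * (A.shape[0] * LN2PI + logdet + d @ np.linalg.solve(marg_cov, d))
    return GaussianBelief(list(prior.names), m, (S + S.T) / 2), float(log_ev)
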
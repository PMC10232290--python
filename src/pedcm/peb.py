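"""Parametric empirical Bayes over subject-level posteriors.

The second level models each subject's first-level parameter estimates
as a group mean plus covariate effects:

    theta_n = (X_n kron I) beta + eps_n,     eps_n ~ N(0, exp(-gamma) I)

observed through the subject's first-level posterior
``theta_hat_n ~ N(theta_n, Sigma_n)``.  With Gaussian priors on the
second-level effects ``beta`` the model is linear-Gaussian given the
between-subject log-precision ``gamma``, which is estimated by
maximizing the second-level free energy (Laplace over ``gamma``).

Subjects with tighter first-level posteriors are weighted more, and the
fitted effects define empirical priors ``X_n beta`` for each subject.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

from .inversion import LN2PI, GaussianBelief
from .microcircuit import LAMINA, MicrocircuitParameters

#: fixed group order: {superficial, deep} x {AMPA, NMDA, GABA}
GROUP_ORDER: tuple[str, ...] = (
    "sup_AMPA", "sup_NMDA", "sup_GABA", "deep_AMPA", "deep_NMDA", "deep_GABA",
)


@dataclass
class DesignMatrix:
    """Subjects x regressors; first column is the group average (all ones)."""

    X: np.ndarray
    names: list[str]
    subject_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2 or self.X.shape[1] != len(self.names):
            raise ValueError("design matrix shape must match column names")
        if not np.allclose(self.X[:, 0], 1.0):
            raise ValueError("first column must be the constant group-average term")
        for j in range(1, self.X.shape[1]):
            if abs(self.X[:, j].mean()) > 1e-12:
                raise ValueError(f"covariate column {self.names[j]!r} must be mean-centered")
        if np.linalg.matrix_rank(self.X) < self.X.shape[1]:
            raise ValueError("design matrix is rank deficient")

    @property
    def n_subjects(self) -> int:
        return self.X.shape[0]

    @property
    def n_regressors(self) -> int:
        return self.X.shape[1]


def build_design_matrix(
    covariates: np.ndarray,
    names: list[str] | str,
    subject_ids: list[str] | None = None,
) -> DesignMatrix:
    """Mean-center covariates and prepend the group-average column.

    ``covariates`` is (n_subjects,) or (n_subjects, n_covariates); subject
    order is preserved.
    """
    if isinstance(names, str):
        names = [names]
    C = np.asarray(covariates, dtype=float)
    if C.ndim == 1:
        C = C[:, None]
    if C.shape[0] < 3:
        raise ValueError("need at least 3 subjects")
    if not np.all(np.isfinite(C)):
        raise ValueError("covariates must be finite")
    if C.shape[1] != len(names):
        raise ValueError("one name per covariate column required")
    sd = C.std(axis=0)
    if np.any(sd == 0):
        j = int(np.argmin(sd))
        raise ValueError(f"covariate {names[j]!r} is constant (zero variance)")
    Xc = C - C.mean(axis=0)
    X = np.column_stack([np.ones(C.shape[0]), Xc])
    return DesignMatrix(X, ["mean"] + list(names), subject_ids)


@dataclass
class ParameterGroupMap:
    """Partition of second-level parameters into the six synaptic groups."""

    assignment: dict[str, str]

    def __post_init__(self) -> None:
        for p, g in self.assignment.items():
            if g not in GROUP_ORDER:
                raise ValueError(f"unknown group {g!r} for parameter {p!r}")

    @property
    def parameters(self) -> list[str]:
        return list(self.assignment)

    def group_of(self, name: str) -> str:
        return self.assignment[name]

    def members(self, group: str) -> list[str]:
        return [p for p, g in self.assignment.items() if g == group]


def default_group_map(params: MicrocircuitParameters) -> ParameterGroupMap:
    """Assign every intrinsic connection gain to one of the six groups.

    A connection counts as superficial if its postsynaptic (target)
    population lies in the superficial or granular layer, and deep
    otherwise; the receptor comes from the edge itself.
    """
    assignment: dict[str, str] = {}
    for e in params.edges:
        layer = "sup" if LAMINA[e.target] in ("superficial", "granular") else "deep"
        assignment[f"gamma:{e.name}"] = f"{layer}_{e.receptor}"
    return ParameterGroupMap(assignment)


@dataclass
class PebSettings:
    beta_prior_var: float = 1.0
    gamma_prior_mean: float = 0.0
    gamma_prior_var: float = 1.0 / 16.0
    gamma_bounds: tuple[float, float] = (-8.0, 8.0)


@dataclass
class PebResult:
    beta: GaussianBelief                 # second-level effects, one block per regressor
    free_energy: float
    empirical_priors: list[GaussianBelief]
    between_log_precision: float
    between_log_precision_var: float
    design: DesignMatrix
    parameter_names: list[str]
    beta_prior: GaussianBelief = field(repr=False, default=None)  # type: ignore[assignment]


def beta_names(design: DesignMatrix, parameter_names: list[str]) -> list[str]:
    return [f"{reg}:{p}" for reg in design.names for p in parameter_names]


def _subject_blocks(
    posteriors: list[GaussianBelief], parameter_names: list[str]
) -> tuple[np.ndarray, list[np.ndarray]]:
    ref = posteriors[0].names
    for q in posteriors:
        if q.names != ref:
            raise ValueError("all subjects must share the same parameter index")
    means = []
    covs = []
    for q in posteriors:
        sub = q.marginal(parameter_names)
        means.append(sub.mean)
        covs.append(sub.cov)
    return np.stack(means), covs


def fit_peb(
    posteriors: list[GaussianBelief],
    design: DesignMatrix,
    groupmap: ParameterGroupMap,
    settings: PebSettings | None = None,
    parameter_names: list[str] | None = None,
) -> PebResult:
    """Fit the hierarchical linear-Gaussian model over subject posteriors.

    ``parameter_names`` defaults to the parameters named by ``groupmap``,
    in the order they appear in the subjects' posterior index.
    """
    settings = settings or PebSettings()
    if len(posteriors) != design.n_subjects:
        raise ValueError("rows of the design matrix must align with subjects")
    if parameter_names is None:
        parameter_names = [n for n in posteriors[0].names if n in groupmap.assignment]
    if not parameter_names:
        raise ValueError("no second-level parameters selected")
    theta, covs = _subject_blocks(posteriors, parameter_names)
    n_sub, m = theta.shape
    R = design.n_regressors
    q = R * m

    b_names = beta_names(design, parameter_names)
    prior_cov = np.eye(q) * settings.beta_prior_var
    prior = GaussianBelief(b_names, np.zeros(q), prior_cov)

    X = design.X

    def moments(gamma: float):
        """beta posterior and data log-evidence given the between precision."""
        Pb = np.linalg.inv(prior_cov).copy()
        hb = np.zeros(q)
        quad = 0.0
        logdet_C = 0.0
        for n in range(n_sub):
            Cn = covs[n] + np.exp(-gamma) * np.eye(m)
            Ln = np.linalg.cholesky(Cn)
            logdet_C += 2.0 * float(np.sum(np.log(np.diag(Ln))))
            Cin_theta = np.linalg.solve(Cn, theta[n])
            Cin = np.linalg.inv(Cn)
            An = np.kron(X[n], np.eye(m))          # (m, q)
            Pb += An.T @ Cin @ An
            hb += An.T @ Cin_theta
            quad += float(theta[n] @ Cin_theta)
        Sb = np.linalg.inv(Pb)
        mb = Sb @ hb
        sign, logdet_Pb = np.linalg.slogdet(Pb)
        # ln p(theta_hat | gamma) with beta integrated out
        log_ev = (
            -0.5 * n_sub * m * LN2PI
            - 0.5 * logdet_C
            - 0.5 * quad
            + 0.5 * float(mb @ Pb @ mb)
            - 0.5 * logdet_Pb
            - 0.5 * q * np.log(settings.beta_prior_var)
        )
        return mb, Sb, log_ev

    g0, gv = settings.gamma_prior_mean, settings.gamma_prior_var

    def objective(gamma: float) -> float:
        _, _, log_ev = moments(gamma)
        return -(log_ev - 0.5 * (gamma - g0) ** 2 / gv - 0.5 * np.log(2 * np.pi * gv))

    opt = minimize_scalar(objective, bounds=settings.gamma_bounds, method="bounded",
                          options={"xatol": 1e-4})
    gamma = float(opt.x)
    # Laplace over gamma: curvature by central differences
    h = 1e-3
    f0, fp, fm = -objective(gamma), -objective(gamma + h), -objective(gamma - h)
    curv = (fp - 2 * f0 + fm) / h**2
    s_gamma = float(-1.0 / curv) if curv < 0 else np.inf
    mb, Sb, log_ev = moments(gamma)
    if np.isfinite(s_gamma):
        F = f0 + 0.5 * np.log(2 * np.pi * s_gamma)
    else:
        F = f0

    beta = GaussianBelief(b_names, mb, (Sb + Sb.T) / 2)
    emp = []
    for n in range(n_sub):
        An = np.kron(X[n], np.eye(m))
        mean_n = An @ mb
        cov_n = np.exp(-gamma) * np.eye(m) + An @ Sb @ An.T
        emp.append(GaussianBelief(list(parameter_names), mean_n, (cov_n + cov_n.T) / 2))
    return PebResult(
        beta=beta,
        free_energy=float(F),
        empirical_priors=emp,
        between_log_precision=gamma,
        between_log_precision_var=s_gamma,
        design=design,
        parameter_names=list(parameter_names),
        beta_prior=prior,
    )


def covariate_effect_names(peb: PebResult) -> list[str]:
    """Names of all covariate-effect elements of beta (mean block excluded)."""
    return [nm for nm in peb.beta.names if not nm.startswith("mean:")]


def restrict_model(
    full_prior: GaussianBelief,
    mask: "tuple[bool, ...] | list[bool]",
    groupmap: ParameterGroupMap,
) -> GaussianBelief:
    """Reduced second-level prior for one model of the 63-model space.

    Covariate effects on parameters whose group is excluded by ``mask``
    are pinned to zero (zero prior variance); group-average effects are
    always retained.  ``mask`` follows the fixed group order
    ``GROUP_ORDER``.
    """
    mask = tuple(bool(b) for b in mask)
    if len(mask) != len(GROUP_ORDER):
        raise ValueError(f"mask must cover the {len(GROUP_ORDER)} groups")
    if not any(mask):
        raise ValueError("the all-excluded model is not in the model space")
    excluded = {g for g, keep in zip(GROUP_ORDER, mask) if not keep}
    cov = full_prior.cov.copy()
    mean = full_prior.mean.copy()
    for i, nm in enumerate(full_prior.names):
        reg, _, par = nm.partition(":")
        if reg == "mean":
            continue
        if par in groupmap.assignment and groupmap.group_of(par) in excluded:
            cov[i, :] = 0.0
            cov[:, i] = 0.0
            mean[i] = 0.0
    return GaussianBelief(list(full_prior.names), mean, cov)
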
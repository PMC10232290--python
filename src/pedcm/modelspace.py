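"""Model space over the six synaptic parameter groups.

Each second-level model allows the pathology covariate to influence a
subset of the six groups {superficial, deep} x {AMPA, NMDA, GABA}; the
2^6 - 1 = 63 non-empty subsets are scored by Bayesian model reduction
from the full fit, their free energies converted to posterior model
probabilities with the softmax operator, and redundant individual
effects pruned by a greedy reduction search.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .inversion import GaussianBelief
from .peb import GROUP_ORDER, ParameterGroupMap, PebResult, restrict_model

#: prior variance used in place of an exact zero when an effect is pinned
PINNED_VAR = 1e-8


@dataclass(frozen=True)
class PebModelSpec:
    """A mask over the six parameter groups; bit i of (index) = group i."""

    mask: tuple[bool, ...]

    def __post_init__(self) -> None:
        if not any(self.mask):
            raise ValueError("at least one group must be included")

    @property
    def index(self) -> int:
        return int(sum((1 << i) for i, b in enumerate(self.mask) if b))

    @property
    def groups(self) -> tuple[str, ...]:
        order = GROUP_ORDER if len(self.mask) == len(GROUP_ORDER) else tuple(
            f"g{i}" for i in range(len(self.mask))
        )
        return tuple(g for g, b in zip(order, self.mask) if b)

    @classmethod
    def from_index(cls, index: int, n_groups: int = 6) -> "PebModelSpec":
        if not (1 <= index < 2**n_groups):
            raise ValueError(f"model index must be in [1, {2**n_groups - 1}]")
        return cls(tuple(bool((index >> i) & 1) for i in range(n_groups)))


def enumerate_models(n_groups: int = 6) -> list[PebModelSpec]:
    """All non-empty group masks, in increasing index order (2^n - 1 models)."""
    if n_groups < 1:
        raise ValueError("need at least one group")
    return [PebModelSpec.from_index(i, n_groups) for i in range(1, 2**n_groups)]


@dataclass
class ModelComparisonResult:
    free_energies: np.ndarray          # per model, aligned with `models`
    probabilities: np.ndarray
    models: list[PebModelSpec]
    winner: PebModelSpec
    group_relative_f: dict[str, float] | None = None

    def to_dict(self) -> dict:
        return {
            "schema_version": 1,
            "model_indices": [m.index for m in self.models],
            "free_energies": [float(f) for f in self.free_energies],
            "probabilities": [float(p) for p in self.probabilities],
            "winner_index": self.winner.index,
            "winner_groups": list(self.winner.groups),
            "group_relative_f": self.group_relative_f,
        }


def _pinned(prior: GaussianBelief) -> GaussianBelief:
    """Replace exact-zero prior variances by a tiny pinning variance."""
    cov = prior.cov.copy()
    zero = np.diag(cov) == 0.0
    if np.any(zero):
        idx = np.where(zero)[0]
        cov[idx, idx] = PINNED_VAR
    return GaussianBelief(list(prior.names), prior.mean.copy(), cov)


def bayesian_model_reduction(
    full_prior: GaussianBelief,
    full_posterior: GaussianBelief,
    reduced_prior: GaussianBelief,
) -> tuple[float, GaussianBelief]:
    """Closed-form evidence change for swapping priors post hoc.

    Returns (delta_F, reduced posterior) without refitting: the log
    evidence of the model with ``reduced_prior`` minus that of the model
    with ``full_prior``, given the posterior obtained under the full
    prior.  Zero entries on the reduced prior's variance diagonal are
    treated as pinned-to-mean (variance ``PINNED_VAR``).
    """
    if not (full_prior.names == full_posterior.names == reduced_prior.names):
        raise ValueError("all beliefs must share the parameter index")
    reduced_prior = _pinned(reduced_prior)
    P0 = np.linalg.inv(full_prior.cov)
    Pr0 = np.linalg.inv(reduced_prior.cov)
    sign, _ = np.linalg.slogdet(full_posterior.cov)
    if sign <= 0:
        raise np.linalg.LinAlgError("posterior covariance numerically singular")
    P = np.linalg.inv(full_posterior.cov)
    Pt = P - P0 + Pr0
    st, _ = np.linalg.slogdet(Pt)
    if st <= 0:
        raise np.linalg.LinAlgError("reduced posterior precision not positive definite")
    mu, mu0, mur0 = full_posterior.mean, full_prior.mean, reduced_prior.mean
    ht = P @ mu - P0 @ mu0 + Pr0 @ mur0
    St = np.linalg.inv(Pt)
    mut = St @ ht

    def _ld(M):
        s, v = np.linalg.slogdet(M)
        return v

    dF = 0.5 * (_ld(P) + _ld(Pr0) - _ld(P0) - _ld(Pt)) + 0.5 * (
        float(ht @ St @ ht) - float(mu @ P @ mu) + float(mu0 @ P0 @ mu0) - float(mur0 @ Pr0 @ mur0)
    )
    return float(dF), GaussianBelief(list(full_prior.names), mut, (St + St.T) / 2)


def compare_models(
    free_energies: np.ndarray,
    models: list[PebModelSpec] | None = None,
) -> ModelComparisonResult:
    """Softmax conversion of model free energies to posterior probabilities.

    p_i = exp(F_i - max F) / sum_j exp(F_j - max F); ties on the maximum
    resolve to the lowest model index.
    """
    F = np.asarray(free_energies, dtype=float)
    if F.size == 0:
        raise ValueError("need at least one model")
    if not np.all(np.isfinite(F)):
        raise ValueError("free energies must be finite")
    if models is None:
        n = max(1, int(np.ceil(np.log2(F.size + 1))))
        models = [PebModelSpec.from_index(i + 1, n) for i in range(F.size)]
    z = np.exp(F - F.max())
    p = z / z.sum()
    winner = models[int(np.argmax(F))]  # argmax returns the first (lowest-index) maximum
    return ModelComparisonResult(F, p, list(models), winner)


def score_model_space(
    peb: PebResult,
    groupmap: ParameterGroupMap,
    models: list[PebModelSpec] | None = None,
) -> ModelComparisonResult:
    """Score every model of the space by BMR from the full PEB fit."""
    models = models or enumerate_models(len(GROUP_ORDER))
    F = np.empty(len(models))
    for i, m in enumerate(models):
        rp = restrict_model(peb.beta_prior, m.mask, groupmap)
        dF, _ = bayesian_model_reduction(peb.beta_prior, peb.beta, rp)
        F[i] = peb.free_energy + dF
    result = compare_models(F, models)
    result.group_relative_f = group_relative_evidence(peb, groupmap)
    return result


def group_relative_evidence(
    peb: PebResult, groupmap: ParameterGroupMap
) -> dict[str, float]:
    """Relative free energy of each group's single-group model.

    Each group is scored in isolation (the model in which only that
    group's covariate effects are free), relative to the worst group, so
    the minimum is 0 by construction.
    """
    F = {}
    for i, g in enumerate(GROUP_ORDER):
        mask = tuple(j == i for j in range(len(GROUP_ORDER)))
        rp = restrict_model(peb.beta_prior, mask, groupmap)
        dF, _ = bayesian_model_reduction(peb.beta_prior, peb.beta, rp)
        F[g] = peb.free_energy + dF
    worst = min(F.values())
    return {g: float(v - worst) for g, v in F.items()}


@dataclass
class PruneResult:
    posterior: GaussianBelief            # reduced second-level posterior
    free_energy: float                   # F of the best reduced model
    surviving: list[str]                 # covariate effects retained
    removed: list[str]
    inclusion_probability: dict[str, float]


def prune_parameters(
    peb: PebResult,
    max_passes: int = 64,
) -> PruneResult:
    """Greedy Bayesian-model-reduction search over individual effects.

    Repeatedly removes (pins to zero) the single covariate effect whose
    exclusion yields the largest free-energy gain, until no removal
    gains.  The inclusion probability of each effect is the softmax of
    (F with effect, F without effect) evaluated at the final model.
    """
    names = peb.beta.names
    covariate_idx = [i for i, nm in enumerate(names) if not nm.startswith("mean:")]
    removed: set[int] = set()

    def reduced_prior(excl: set[int]) -> GaussianBelief:
        cov = peb.beta_prior.cov.copy()
        mean = peb.beta_prior.mean.copy()
        for i in excl:
            cov[i, :] = 0.0
            cov[:, i] = 0.0
            mean[i] = 0.0
        return GaussianBelief(list(names), mean, cov)

    def score(excl: set[int]) -> float:
        if not excl:
            return 0.0
        dF, _ = bayesian_model_reduction(peb.beta_prior, peb.beta, reduced_prior(excl))
        return dF

    current = 0.0
    for _ in range(max_passes):
        best_gain, best_i = 0.0, None
        for i in covariate_idx:
            if i in removed:
                continue
            dF = score(removed | {i})
            if dF - current > best_gain:
                best_gain, best_i = dF - current, i
        if best_i is None:
            break
        removed.add(best_i)
        current += best_gain

    incl_p: dict[str, float] = {}
    for i in covariate_idx:
        with_i = score(removed - {i})
        without_i = score(removed | {i})
        z = np.exp(np.array([with_i, without_i]) - max(with_i, without_i))
        incl_p[names[i]] = float(z[0] / z.sum())

    dF, post = bayesian_model_reduction(peb.beta_prior, peb.beta, reduced_prior(removed)) \
        if removed else (0.0, peb.beta)
    return PruneResult(
        posterior=post,
        free_energy=peb.free_energy + dF,
        surviving=[names[i] for i in covariate_idx if i not in removed],
        removed=[names[i] for i in sorted(removed)],
        inclusion_probability=incl_p,
    )
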
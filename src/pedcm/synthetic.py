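"""Synthetic cohorts with the statistical structure the analysis assumes.

A cohort consists of subjects whose intrinsic connection gains covary
with a scalar covariate (a synaptic-density analogue): on the log-gain
scale

    lam_n = beta_g * c_n * 1[param in group g] + random effect

with the covariate c_n standardized, so beta is unitless.  Each
subject's trial-level evoked responses are the model prediction plus
independent white Gaussian noise per trial.  Ground truth is stored
alongside the cohort and is never read by any inference code path.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np

from .microcircuit import MicrocircuitParameters
from .peb import GROUP_ORDER, ParameterGroupMap, default_group_map
from .simulate import ErfTrace, default_time_grid, simulate_erf_pair


def default_base_params() -> MicrocircuitParameters:
    """Cohort-level base circuit: default constants plus a condition effect.

    The condition log-gains are set to 0.5 on every modulated edge so the
    deviant response differs visibly from the standard response (a
    mismatch deflection of roughly 10% of the evoked peak).
    """
    p = MicrocircuitParameters()
    p.b = {e.name: 0.5 for e in p.edges if e.modulated}
    return p


@dataclass
class CohortConfig:
    n_subjects: int = 12
    covariate_mean: float = 0.0
    covariate_sd: float = 1.0
    #: true second-level effect per parameter group (log-gain per covariate SD)
    beta: dict[str, float] = field(default_factory=lambda: {"sup_AMPA": 0.3, "sup_NMDA": 0.3})
    random_effect_sd: float = 0.1
    n_trials: int = 60
    trial_noise_sd: float = 1.0
    #: SD of the per-subject log noise factor (between-subject SNR differences)
    noise_heterogeneity_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 3:
            raise ValueError("need at least 3 subjects")
        if self.trial_noise_sd < 0 or self.random_effect_sd < 0 or self.noise_heterogeneity_sd < 0:
            raise ValueError("noise standard deviations must be non-negative")
        if self.n_trials < 1:
            raise ValueError("need at least one trial per condition")
        for g in self.beta:
            if g not in GROUP_ORDER:
                raise ValueError(f"unknown parameter group {g!r}")

    def to_dict(self) -> dict:
        return {
            "n_subjects": self.n_subjects,
            "covariate_mean": self.covariate_mean,
            "covariate_sd": self.covariate_sd,
            "beta": dict(self.beta),
            "random_effect_sd": self.random_effect_sd,
            "n_trials": self.n_trials,
            "trial_noise_sd": self.trial_noise_sd,
            "noise_heterogeneity_sd": self.noise_heterogeneity_sd,
            "seed": self.seed,
        }


@dataclass
class GroundTruth:
    """Generating parameters; inference code must never read this."""

    lam_true: dict[str, np.ndarray]      # subject id -> log-scale displacements
    parameter_names: list[str]
    beta: dict[str, float]
    generating_mask: tuple[bool, ...]
    seed: int

    def to_dict(self) -> dict:
        return {
            "lam_true": {k: [float(x) for x in v] for k, v in self.lam_true.items()},
            "parameter_names": self.parameter_names,
            "beta": dict(self.beta),
            "generating_mask": [bool(b) for b in self.generating_mask],
            "seed": self.seed,
        }


@dataclass
class SyntheticSubject:
    subject_id: str
    covariate: float
    fab: float                           # clinical-score analogue
    trials_standard: np.ndarray          # (n_trials, n_samples)
    trials_deviant: np.ndarray


@dataclass
class SyntheticCohort:
    config: CohortConfig
    time_ms: np.ndarray
    subjects: list[SyntheticSubject]
    truth: GroundTruth
    base_params: MicrocircuitParameters
    groupmap: ParameterGroupMap


def trial_average(trials: np.ndarray, time_ms: np.ndarray | None = None,
                  condition: str = "standard") -> ErfTrace:
    """Pointwise mean over trials; noise SD shrinks as 1/sqrt(n_trials)."""
    trials = np.asarray(trials, dtype=float)
    if trials.ndim != 2 or trials.shape[0] < 1:
        raise ValueError("need at least one trial")
    t = default_time_grid() if time_ms is None else np.asarray(time_ms, float)
    return ErfTrace(t, trials.mean(axis=0), condition)


def generate_cohort(
    config: CohortConfig,
    base_params: MicrocircuitParameters | None = None,
    backend: str = "auto",
) -> SyntheticCohort:
    """Draw a cohort: covariates, subject parameters, trial-level ERFs.

    Fully reproducible from ``config.seed``; the covariate is drawn
    uniform and standardized to (covariate_mean, covariate_sd), and the
    clinical-score analogue is a noisy correlate of the covariate.
    """
    base = base_params if base_params is not None else default_base_params()
    rng = np.random.default_rng(config.seed)
    gm = default_group_map(base)
    names = [f"gamma:{e.name}" for e in base.edges]
    t = default_time_grid()

    c = rng.uniform(-1.0, 1.0, config.n_subjects)
    c = (c - c.mean()) / c.std()
    c = config.covariate_mean + config.covariate_sd * c
    c_std = (c - c.mean()) / c.std()
    fab = 0.8 * c_std + 0.6 * rng.standard_normal(config.n_subjects)

    mask = tuple(g in config.beta and config.beta[g] != 0.0 for g in GROUP_ORDER)
    lam_true: dict[str, np.ndarray] = {}
    subjects: list[SyntheticSubject] = []
    for i in range(config.n_subjects):
        sid = f"sub-{i + 1:02d}"
        lam = np.array([
            config.beta.get(gm.group_of(nm), 0.0) * c_std[i] for nm in names
        ]) + rng.normal(0.0, config.random_effect_sd, len(names))
        lam_true[sid] = lam
        p_i = base.apply_log_factors(names, lam)
        std, dev = simulate_erf_pair(p_i, t, backend=backend)
        sd_i = config.trial_noise_sd * float(np.exp(rng.normal(0.0, config.noise_heterogeneity_sd)))
        noise_s = rng.normal(0.0, sd_i, (config.n_trials, t.size))
        noise_d = rng.normal(0.0, sd_i, (config.n_trials, t.size))
        subjects.append(SyntheticSubject(
            subject_id=sid,
            covariate=float(c[i]),
            fab=float(fab[i]),
            trials_standard=std.amplitude[None, :] + noise_s,
            trials_deviant=dev.amplitude[None, :] + noise_d,
        ))

    truth = GroundTruth(lam_true, names, dict(config.beta), mask, config.seed)
    return SyntheticCohort(config, t, subjects, truth, base, gm)


# -- file outputs ------------------------------------------------------------

def write_cohort(cohort: SyntheticCohort, out_dir: str) -> str:
    """Write manifest JSON, per-subject/condition CSVs and ground truth.

    Returns the manifest path.  Each condition gets two files: the
    trial-averaged ERF (columns time_ms, amplitude) and the trial-level
    matrix (columns time_ms, trial_001, ...).
    """
    from .io import write_erf  # local import to avoid a cycle

    os.makedirs(out_dir, exist_ok=True)
    manifest = {"subjects": [], "seed": cohort.config.seed,
                "config": cohort.config.to_dict()}
    for s in cohort.subjects:
        sdir = os.path.join(out_dir, s.subject_id)
        os.makedirs(sdir, exist_ok=True)
        entry = {"id": s.subject_id,
                 "covariates": {"density": s.covariate, "fab": s.fab}}
        for cond, trials in (("standard", s.trials_standard), ("deviant", s.trials_deviant)):
            avg = trial_average(trials, cohort.time_ms, cond)
            erf_path = os.path.join(sdir, f"erf_{cond}.csv")
            write_erf(erf_path, avg)
            trials_path = os.path.join(sdir, f"trials_{cond}.csv")
            header = "time_ms," + ",".join(f"trial_{i + 1:03d}" for i in range(trials.shape[0]))
            np.savetxt(trials_path, np.column_stack([cohort.time_ms, trials.T]),
                       delimiter=",", header=header, comments="", fmt="%.10g")
            entry[f"erf_{cond}_path"] = os.path.relpath(erf_path, out_dir)
            entry[f"trials_{cond}_path"] = os.path.relpath(trials_path, out_dir)
        manifest["subjects"].append(entry)
    manifest_path = os.path.join(out_dir, "manifest.json")
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    with open(os.path.join(out_dir, "ground_truth.json"), "w") as fh:
        json.dump(cohort.truth.to_dict(), fh, indent=1, sort_keys=True)
    cohort.base_params.to_json(os.path.join(out_dir, "base_params.json"))
    return manifest_path
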
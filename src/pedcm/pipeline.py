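"""Full analysis pipeline: first-level inversions (all/odd/even trials),
second-level PEB per covariate, 63-model comparison, effect pruning and
split-half reliability."""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass

import numpy as np

from .inversion import (
    ErfForwardModel,
    GaussianBelief,
    InversionResult,
    InversionSettings,
    NoiseModel,
    invert,
    stack_erf_pair,
)
from .io import RunConfig, dump_json, read_manifest, read_trials
from .microcircuit import MicrocircuitParameters
from .modelspace import prune_parameters, score_model_space
from .peb import build_design_matrix, default_group_map, fit_peb
from .reliability import reliability_report, split_halves
from .simulate import ErfTrace, default_time_grid, ymax
from .synthetic import CohortConfig, default_base_params, generate_cohort, trial_average

log = logging.getLogger("pedcm")


@dataclass
class SubjectData:
    subject_id: str
    covariates: dict[str, float]
    time_ms: np.ndarray
    trials: dict[str, np.ndarray]       # condition -> (n_trials, n_samples)


@dataclass
class PipelineResult:
    subjects: list[str]
    inversions: dict[str, dict[str, InversionResult]]   # split -> subject -> result
    ymax_values: dict[str, float]
    peb: dict                                           # covariate -> PebResult
    comparisons: dict                                   # covariate -> ModelComparisonResult
    pruning: dict
    reliability: object
    out_dir: str | None


def _load_cohort_from_manifest(cfg: RunConfig) -> tuple[list[SubjectData], MicrocircuitParameters]:
    manifest = read_manifest(cfg.manifest)
    root = os.path.dirname(os.path.abspath(cfg.manifest))
    subjects = []
    for entry in manifest["subjects"]:
        trials = {}
        t_ref = None
        for cond in ("standard", "deviant"):
            t, tr = read_trials(os.path.join(root, entry[f"trials_{cond}_path"]))
            trials[cond] = tr
            t_ref = t
        subjects.append(SubjectData(entry["id"], dict(entry["covariates"]), t_ref, trials))
    base_path = os.path.join(root, "base_params.json")
    base = MicrocircuitParameters.from_json(base_path) if os.path.exists(base_path) \
        else default_base_params()
    return subjects, base


def _synthetic_cohort(cfg: RunConfig) -> tuple[list[SubjectData], MicrocircuitParameters]:
    ccfg = CohortConfig(**{**cfg.cohort, "seed": cfg.cohort.get("seed", cfg.seed)})
    cohort = generate_cohort(ccfg)
    subjects = [
        SubjectData(
            s.subject_id,
            {"density": s.covariate, "fab": s.fab},
            cohort.time_ms,
            {"standard": s.trials_standard, "deviant": s.trials_deviant},
        )
        for s in cohort.subjects
    ]
    return subjects, cohort.base_params


def invert_subject(
    pair: tuple[ErfTrace, ErfTrace],
    base: MicrocircuitParameters,
    cfg: RunConfig,
    backend: str = "auto",
) -> InversionResult:
    """First-level inversion of one subject's condition pair.

    The free parameters are the intrinsic connection gains (the set the
    second level models); priors are zero-mean on the log scale.
    """
    names = [f"gamma:{e.name}" for e in base.edges]
    priors = GaussianBelief.diagonal(names, 0.0, cfg.prior_gain_var)
    fwd = ErfForwardModel(base, names, pair[0].time_ms, backend=backend)
    noise = NoiseModel(cfg.noise_log_precision_mean, cfg.noise_log_precision_var)
    settings = InversionSettings(max_iter=cfg.max_iter, tol=cfg.tol)
    return invert(stack_erf_pair(*pair), fwd, priors, noise, settings)


def run_pipeline(cfg: RunConfig, write: bool = True, backend: str = "auto") -> PipelineResult:
    """Execute the full pipeline; idempotent given the same inputs and seed."""
    cfg.validate()
    if cfg.manifest:
        subjects, base = _load_cohort_from_manifest(cfg)
    else:
        subjects, base = _synthetic_cohort(cfg)
    out_dir = cfg.out_dir if write else None
    if write:
        os.makedirs(out_dir, exist_ok=True)
        dump_json(os.path.join(out_dir, "resolved_config.json"),
                  {"config": cfg.to_dict(), "config_hash": cfg.hash, "seed": cfg.seed})

    stamp = {"config_hash": cfg.hash, "seed": cfg.seed}
    inversions: dict[str, dict[str, InversionResult]] = {"all": {}, "odd": {}, "even": {}}
    ymax_values: dict[str, float] = {}
    for s in subjects:
        try:
            pairs = {}
            avg = {c: trial_average(s.trials[c], s.time_ms, c) for c in ("standard", "deviant")}
            pairs["all"] = (avg["standard"], avg["deviant"])
            halves = {c: split_halves(s.trials[c]) for c in ("standard", "deviant")}
            pairs["odd"] = tuple(ErfTrace(s.time_ms, halves[c][0], c) for c in ("standard", "deviant"))
            pairs["even"] = tuple(ErfTrace(s.time_ms, halves[c][1], c) for c in ("standard", "deviant"))
            ymax_values[s.subject_id] = ymax(*pairs["all"], cfg.mismatch_window_ms)
            for split in ("all", "odd", "even"):
                res = invert_subject(pairs[split], base, cfg, backend=backend)
                inversions[split][s.subject_id] = res
                log.info("subject %s [%s]: F=%.2f after %d iterations (converged=%s)",
                         s.subject_id, split, res.free_energy, res.iterations, res.converged)
                if write:
                    res.to_dir(os.path.join(out_dir, "inversions", split, s.subject_id))
        except Exception as exc:
            raise RuntimeError(f"first-level stage failed for subject {s.subject_id}: {exc}") from exc

    groupmap = default_group_map(base)
    posteriors = [inversions["all"][s.subject_id].posterior for s in subjects]
    peb_results, comparisons, pruning = {}, {}, {}
    for cov in cfg.covariates:
        try:
            if cov == "ymax":
                values = np.array([ymax_values[s.subject_id] for s in subjects])
            else:
                values = np.array([s.covariates[cov] for s in subjects])
            X = build_design_matrix(values, cov, [s.subject_id for s in subjects])
            peb = fit_peb(posteriors, X, groupmap)
            comp = score_model_space(peb, groupmap)
            peb_results[cov] = peb
            comparisons[cov] = comp
            pruned = prune_parameters(peb)
            pruning[cov] = pruned
            log.info("PEB[%s]: F=%.2f, winner=%s", cov, peb.free_energy, comp.winner.groups)
            if write:
                dump_json(os.path.join(out_dir, f"peb_{cov}.json"), {
                    **stamp,
                    "beta_names": peb.beta.names,
                    "beta_mean": peb.beta.mean,
                    "beta_cov": peb.beta.cov,
                    "free_energy": peb.free_energy,
                    "between_log_precision": peb.between_log_precision,
                })
                dump_json(os.path.join(out_dir, f"model_comparison_{cov}.json"),
                          {**stamp, **comp.to_dict()})
                dump_json(os.path.join(out_dir, f"pruning_{cov}.json"), {
                    **stamp,
                    "surviving": pruned.surviving,
                    "removed": pruned.removed,
                    "free_energy": pruned.free_energy,
                    "inclusion_probability": pruned.inclusion_probability,
                })
        except Exception as exc:
            raise RuntimeError(f"second-level stage failed for covariate {cov}: {exc}") from exc

    try:
        order = [s.subject_id for s in subjects]
        report = reliability_report(
            [inversions["odd"][sid] for sid in order],
            [inversions["even"][sid] for sid in order],
        )
        if write:
            dump_json(os.path.join(out_dir, "reliability.json"), {**stamp, **report.to_dict()})
    except Exception as exc:
        raise RuntimeError(f"reliability stage failed: {exc}") from exc

    if write:
        dump_json(os.path.join(out_dir, "ymax.json"), {**stamp, "ymax": ymax_values})
    return PipelineResult(
        subjects=[s.subject_id for s in subjects],
        inversions=inversions,
        ymax_values=ymax_values,
        peb=peb_results,
        comparisons=comparisons,
        pruning=pruning,
        reliability=report,
        out_dir=out_dir,
    )
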
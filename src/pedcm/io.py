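"""File formats and run configuration.

Traces are delimited text (CSV) with a mandatory header; structured
results are JSON; configuration is YAML.  All times are in ms, voltages
in mV, ERF amplitudes in arbitrary units.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .simulate import ErfTrace


class ErfFormatError(ValueError):
    """Malformed ERF file; ``code`` identifies the failure mode."""

    def __init__(self, code: str, message: str):
        super().__init__(message)
        self.code = code


def write_erf(path: str, trace: ErfTrace) -> None:
    """Write a trace as CSV (columns time_ms, amplitude), round-trip exact."""
    with open(path, "w") as fh:
        fh.write("time_ms,amplitude\n")
        for t, a in zip(trace.time_ms, trace.amplitude):
            fh.write(f"{float(t)!r},{float(a)!r}\n")


def read_erf(path: str, condition: str = "standard") -> ErfTrace:
    """Parse an ERF CSV; validates header, uniform grid and finite values."""
    if not os.path.exists(path):
        raise ErfFormatError("missing_file", f"no such file: {path}")
    with open(path) as fh:
        header = fh.readline().strip()
    cols = [c.strip() for c in header.split(",")]
    if cols[:2] != ["time_ms", "amplitude"]:
        raise ErfFormatError(
            "missing_header",
            f"{path}: first line must be 'time_ms,amplitude', got {header!r}",
        )
    df = pd.read_csv(path, float_precision="round_trip")
    t = df["time_ms"].to_numpy(dtype=float)
    a = df["amplitude"].to_numpy(dtype=float)
    if np.any(~np.isfinite(a)):
        row = int(np.argwhere(~np.isfinite(a))[0][0])
        raise ErfFormatError(
            "nan_amplitude", f"{path}: non-finite amplitude at data row {row + 1}"
        )
    d = np.diff(t)
    if len(d) and (np.any(d <= 0) or np.max(np.abs(d - d[0])) > 1e-9):
        raise ErfFormatError("non_uniform_grid", f"{path}: time grid not uniform/increasing")
    return ErfTrace(t, a, condition)


def read_trials(path: str) -> tuple[np.ndarray, np.ndarray]:
    """Read a trial-matrix CSV -> (time_ms, trials) with trials (k, n_samples)."""
    df = pd.read_csv(path, float_precision="round_trip")
    if "time_ms" not in df.columns:
        raise ErfFormatError("missing_header", f"{path}: no time_ms column")
    t = df["time_ms"].to_numpy(dtype=float)
    trials = df.drop(columns="time_ms").to_numpy(dtype=float).T
    if not np.all(np.isfinite(trials)):
        raise ErfFormatError("nan_amplitude", f"{path}: non-finite trial sample")
    return t, trials


def read_manifest(path: str) -> dict:
    with open(path) as fh:
        manifest = json.load(fh)
    if "subjects" not in manifest or len(manifest["subjects"]) < 1:
        raise ValueError(f"{path}: manifest has no subjects")
    return manifest


@dataclass
class RunConfig:
    """Resolved configuration of a full pipeline run."""

    out_dir: str = "pedcm_run"
    seed: int = 0
    # epoch contract
    epoch_start_ms: float = -100.0
    epoch_end_ms: float = 400.0
    sample_rate_hz: float = 500.0
    mismatch_window_ms: tuple[float, float] = (130.0, 180.0)
    # first level
    max_iter: int = 64
    tol: float = 0.01
    noise_log_precision_mean: float = 0.0
    noise_log_precision_var: float = 16.0
    prior_gain_var: float = 1.0 / 16.0
    # second level
    covariates: tuple[str, ...] = ("density", "fab", "ymax")
    # cohort: either a manifest path or a synthetic-cohort section
    manifest: str | None = None
    cohort: dict = field(default_factory=dict)

    def validate(self) -> None:
        if self.max_iter < 1:
            raise ValueError("config key 'max_iter': must be >= 1")
        if self.tol <= 0:
            raise ValueError("config key 'tol': must be positive")
        if self.sample_rate_hz <= 0:
            raise ValueError("config key 'sample_rate_hz': must be positive")
        lo, hi = self.mismatch_window_ms
        if not (self.epoch_start_ms <= lo < hi <= self.epoch_end_ms):
            raise ValueError("config key 'mismatch_window_ms': must lie inside the epoch")
        for c in self.covariates:
            if c not in ("density", "fab", "ymax"):
                raise ValueError(f"config key 'covariates': unknown covariate {c!r}")

    def to_dict(self) -> dict:
        # out_dir is deliberately excluded: the resolved configuration (and
        # its hash) describe the analysis, not where it is written
        d = {
            "seed": self.seed,
            "epoch_start_ms": self.epoch_start_ms,
            "epoch_end_ms": self.epoch_end_ms,
            "sample_rate_hz": self.sample_rate_hz,
            "mismatch_window_ms": list(self.mismatch_window_ms),
            "max_iter": self.max_iter,
            "tol": self.tol,
            "noise_log_precision_mean": self.noise_log_precision_mean,
            "noise_log_precision_var": self.noise_log_precision_var,
            "prior_gain_var": self.prior_gain_var,
            "covariates": list(self.covariates),
            "manifest": self.manifest,
            "cohort": dict(self.cohort),
        }
        return d

    @property
    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs = dict(d)
        if "mismatch_window_ms" in kwargs:
            kwargs["mismatch_window_ms"] = tuple(kwargs["mismatch_window_ms"])
        if "covariates" in kwargs:
            kwargs["covariates"] = tuple(kwargs["covariates"])
        cfg = cls(**kwargs)
        cfg.validate()
        return cfg


def load_config(path: str) -> RunConfig:
    with open(path) as fh:
        try:
            doc = yaml.safe_load(fh) or {}
        except yaml.YAMLError as exc:
            mark = getattr(exc, "problem_mark", None)
            where = f" at line {mark.line + 1}" if mark else ""
            raise ValueError(f"{path}: invalid YAML{where}: {exc}") from exc
    try:
        return RunConfig.from_dict(doc)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"{path}: {exc}") from exc


def dump_json(path: str, obj) -> None:
    """Deterministic JSON output (sorted keys, plain floats)."""

    def clean(x):
        if isinstance(x, dict):
            return {str(k): clean(v) for k, v in x.items()}
        if isinstance(x, (list, tuple)):
            return [clean(v) for v in x]
        if isinstance(x, (np.floating, np.integer)):
            return x.item()
        if isinstance(x, np.ndarray):
            return [clean(v) for v in x.tolist()]
        if isinstance(x, (np.bool_,)):
            return bool(x)
        return x

    with open(path, "w") as fh:
        json.dump(clean(obj), fh, indent=1, sort_keys=True)
        fh.write("\n")
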
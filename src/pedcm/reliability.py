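"""Split-half reliability: ICC(2,1) over odd/even trial estimates.

Trials are split by position parity, each half averaged and analysed
independently; the intraclass correlation (two-way random effects,
single measurement, absolute agreement — Shrout & Fleiss class 2) then
measures how consistently the inversion recovers per-subject quantities
across the two halves.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .inversion import InversionResult
from .simulate import ErfTrace

#: significance labels used in the report
P_THRESHOLDS = (0.05, 0.005, 0.0001)


def split_halves(trials: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Partition trials by 1-based position parity and average each half.

    ``trials`` is (n_trials, n_samples); returns (odd_mean, even_mean).
    """
    trials = np.asarray(trials, dtype=float)
    if trials.ndim != 2 or trials.shape[0] < 2:
        raise ValueError("need at least 2 trials to split")
    odd = trials[0::2]
    even = trials[1::2]
    return odd.mean(axis=0), even.mean(axis=0)


def split_halves_erf(
    time_ms: np.ndarray, trials: np.ndarray, condition: str = "standard"
) -> tuple[ErfTrace, ErfTrace]:
    o, e = split_halves(trials)
    return ErfTrace(time_ms, o, condition), ErfTrace(time_ms, e, condition)


def icc2(matrix: np.ndarray) -> tuple[float, float]:
    """ICC(2,1) with its F-test p-value.

    Two-way random-effects ANOVA on an n x k ratings matrix (rows =
    subjects, columns = raters; here k = 2 for odd/even halves)::

        ICC = (MS_R - MS_E) / (MS_R + (k-1) MS_E + (k/n)(MS_C - MS_E))

    The p-value comes from F = MS_R / MS_E on (n-1, (n-1)(k-1)) degrees
    of freedom.  Raises if the matrix has no variance at all (ICC is
    undefined).
    """
    Y = np.asarray(matrix, dtype=float)
    if Y.ndim != 2:
        raise ValueError("ratings matrix must be 2-D")
    n, k = Y.shape
    if n < 3 or k < 2:
        raise ValueError("need at least 3 subjects and 2 raters")
    if not np.all(np.isfinite(Y)):
        raise ValueError("ratings must be finite (no missing cells)")
    grand = Y.mean()
    if np.allclose(Y, grand, atol=1e-300, rtol=0.0) or Y.var() == 0.0:
        raise ValueError("zero total variance: ICC undefined")
    row_means = Y.mean(axis=1)
    col_means = Y.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((Y - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    ms_r = ss_rows / (n - 1)
    ms_c = ss_cols / (k - 1)
    ms_e = max(ss_err / ((n - 1) * (k - 1)), 0.0)
    denom = ms_r + (k - 1) * ms_e + (k / n) * (ms_c - ms_e)
    if denom == 0.0:
        raise ValueError("degenerate ANOVA decomposition: ICC undefined")
    icc = (ms_r - ms_e) / denom
    if ms_e == 0.0:
        p = 0.0
    else:
        F = ms_r / ms_e
        p = float(stats.f.sf(F, n - 1, (n - 1) * (k - 1)))
    return float(icc), p


def significance_label(p: float) -> str:
    if p < P_THRESHOLDS[2]:
        return "p<0.0001"
    if p < P_THRESHOLDS[1]:
        return "p<0.005"
    if p < P_THRESHOLDS[0]:
        return "p<0.05"
    return "ns"


@dataclass
class IccEntry:
    quantity: str
    icc: float            # NaN where the quantity is degenerate (zero variance)
    p_value: float
    reliable: bool
    label: str


@dataclass
class IccReport:
    entries: list[IccEntry]
    f_cross_half_r2: float

    def entry(self, quantity: str) -> IccEntry:
        for e in self.entries:
            if e.quantity == quantity:
                return e
        raise KeyError(quantity)

    def to_dict(self) -> dict:
        return {
            "entries": [
                {"quantity": e.quantity,
                 "icc": None if np.isnan(e.icc) else float(e.icc),
                 "p_value": None if np.isnan(e.p_value) else float(e.p_value),
                 "reliable": bool(e.reliable), "label": e.label}
                for e in self.entries
            ],
            "free_energy_cross_half_r2": float(self.f_cross_half_r2),
            "p_thresholds": list(P_THRESHOLDS),
        }


def _icc_entry(name: str, odd: np.ndarray, even: np.ndarray, alpha: float) -> IccEntry:
    mat = np.column_stack([odd, even])
    try:
        icc, p = icc2(mat)
    except ValueError:
        return IccEntry(name, float("nan"), float("nan"), False, "undefined")
    return IccEntry(name, icc, p, p < alpha, significance_label(p))


def reliability_report(
    odd_results: list[InversionResult],
    even_results: list[InversionResult],
    parameters: list[str] | None = None,
    alpha: float = 0.05,
) -> IccReport:
    """ICCs of free energy, its six components, and parameter estimates.

    ``odd_results`` and ``even_results`` must be aligned subject by
    subject (same order, same parameter index).  Parameter-level ICCs use
    posterior means only.  Also reports the squared Pearson correlation
    of the free energy across halves.
    """
    if len(odd_results) != len(even_results):
        raise ValueError("odd and even subject lists must have equal length")
    if len(odd_results) < 3:
        raise ValueError("need at least 3 subjects")
    names0 = odd_results[0].posterior.names
    for o, e in zip(odd_results, even_results):
        if o.posterior.names != names0 or e.posterior.names != names0:
            raise ValueError("subject results are misaligned: parameter indices differ")
    parameters = parameters if parameters is not None else list(names0)

    F_odd = np.array([r.free_energy for r in odd_results])
    F_even = np.array([r.free_energy for r in even_results])
    entries = [_icc_entry("free_energy", F_odd, F_even, alpha)]
    for comp in (
        "accuracy_states", "accuracy_parameters", "accuracy_precision",
        "complexity_states", "complexity_parameters", "complexity_precision",
    ):
        o = np.array([getattr(r.decomposition, comp) for r in odd_results])
        e = np.array([getattr(r.decomposition, comp) for r in even_results])
        entries.append(_icc_entry(comp, o, e, alpha))
    for pname in parameters:
        j = names0.index(pname)
        o = np.array([r.posterior.mean[j] for r in odd_results])
        e = np.array([r.posterior.mean[j] for r in even_results])
        entries.append(_icc_entry(f"param:{pname}", o, e, alpha))

    if np.std(F_odd) == 0 or np.std(F_even) == 0:
        r2 = float("nan")
    else:
        r2 = float(np.corrcoef(F_odd, F_even)[0, 1] ** 2)
    return IccReport(entries, r2)
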
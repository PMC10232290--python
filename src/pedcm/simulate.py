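"""Epoch integration and the observation model mapping states to an ERF.

The evoked response is simulated per condition from the circuit's own
resting fixed point, driven by a Gaussian-bump exogenous input, and
observed as a weighted sum of membrane-potential excursions.  The
default epoch mirrors a source-level evoked-field analysis: -100 to
400 ms at 500 Hz (2 ms step, 251 samples), with stimulus onset at 0 ms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _fast
from .microcircuit import (
    CONDITIONS,
    N_POP,
    RECEPTORS,
    MicrocircuitParameters,
    NeuronalState,
    _POP_INDEX,
    build_connectivity,
    steady_state,
)

EPOCH_START_MS = -100.0
EPOCH_END_MS = 400.0
SAMPLE_STEP_MS = 2.0
MISMATCH_WINDOW_MS = (130.0, 180.0)


def default_time_grid() -> np.ndarray:
    """-100..400 ms inclusive at 500 Hz: 251 samples."""
    n = int(round((EPOCH_END_MS - EPOCH_START_MS) / SAMPLE_STEP_MS)) + 1
    return EPOCH_START_MS + SAMPLE_STEP_MS * np.arange(n)


@dataclass
class ErfTrace:
    """One condition's evoked-response time series on a uniform grid."""

    time_ms: np.ndarray
    amplitude: np.ndarray
    condition: str = "standard"

    def __post_init__(self) -> None:
        self.time_ms = np.asarray(self.time_ms, dtype=float)
        self.amplitude = np.asarray(self.amplitude, dtype=float)
        if self.time_ms.ndim != 1 or self.time_ms.shape != self.amplitude.shape:
            raise ValueError("time and amplitude must be 1-D and equal length")
        d = np.diff(self.time_ms)
        if len(d) and (np.any(d <= 0) or np.max(np.abs(d - d[0])) > 1e-9):
            raise ValueError("time grid must be strictly increasing and uniform")
        if not np.all(np.isfinite(self.amplitude)):
            raise ValueError("amplitude must be finite")

    @property
    def step_ms(self) -> float:
        return float(self.time_ms[1] - self.time_ms[0])

    def copy(self) -> "ErfTrace":
        return ErfTrace(self.time_ms.copy(), self.amplitude.copy(), self.condition)


@dataclass
class ObservationModel:
    """Weighted sum of population potentials: gain * sum_p w_p dV_p + baseline."""

    weights: tuple[float, ...] = (0.2, 0.8, 0.0, 0.2, 0.2, 0.0)
    gain: float = 1.0
    baseline: float = 0.0

    def __post_init__(self) -> None:
        if len(self.weights) != N_POP:
            raise ValueError("need one weight per population")

    @classmethod
    def from_params(cls, params: MicrocircuitParameters) -> "ObservationModel":
        return cls(tuple(params.obs_weights), params.obs_gain, params.obs_baseline)


def stimulus_input(time_ms: np.ndarray, params: MicrocircuitParameters) -> np.ndarray:
    """Non-negative Gaussian-bump drive; identically zero before t = 0."""
    if params.input_width <= 0:
        raise ValueError("input width must be positive")
    t = np.asarray(time_ms, dtype=float)
    u = params.input_amplitude * np.exp(-0.5 * ((t - params.input_onset) / params.input_width) ** 2)
    return np.where(t >= 0.0, u, 0.0)


def _internal_step(out_step: float, internal_dt: float) -> tuple[float, int]:
    stride = max(1, int(np.ceil(out_step / internal_dt - 1e-12)))
    return out_step / stride, stride


def integrate(
    params: MicrocircuitParameters,
    condition: str = "standard",
    time_ms: np.ndarray | None = None,
    internal_dt: float = 1.0,
    backend: str = "auto",
) -> tuple[np.ndarray, np.ndarray]:
    """Integrate one condition over the epoch.

    Returns ``(time_ms, states)`` with ``states`` of shape (n, 24) on the
    output grid.  The trajectory starts at the condition's resting fixed
    point; samples before stimulus onset (t < 0) sit exactly at rest.
    Fixed-step RK4 at ``internal_dt`` (default 1 ms), decimated onto the
    output grid.
    """
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    t = default_time_grid() if time_ms is None else np.asarray(time_ms, dtype=float)
    out_step = float(t[1] - t[0])
    rest = steady_state(params, condition)
    x0 = rest.vector()

    post = t >= 0.0
    t_post = t[post]
    if t_post.size == 0:
        states = np.tile(x0, (t.size, 1))
        return t, states
    dt, stride = _internal_step(out_step, internal_dt)
    n_steps = int(round((t_post[-1] - t_post[0]) / dt))
    # input kernel at half-step resolution, offset so integration starts at t_post[0]
    sub_t = t_post[0] + 0.5 * dt * np.arange(2 * n_steps + 1)
    ukern = stimulus_input(sub_t, params) / max(params.input_amplitude, 1e-300)
    uamp = np.array([params.input_amplitude]) if params.input_amplitude != 0 else np.array([0.0])
    if params.input_amplitude == 0:
        ukern = np.zeros_like(ukern)

    G = build_connectivity(params, condition)[None]
    tauk = np.array([[params.tau[r] for r in RECEPTORS]])
    consts = (
        params.V_L, params.V_E, params.V_I, params.C, params.cL,
        params.firing_threshold, params.firing_slope, params.mg_alpha, params.mg_beta,
    )
    out_V, out_g = _fast.rk4_batch(
        rest.V[None], rest.g[None], G, tauk, uamp, ukern,
        _POP_INDEX[params.input_population], consts, dt, n_steps, stride, backend=backend,
    )
    post_states = np.concatenate([out_V[0], out_g[0].reshape(out_V.shape[1], -1)], axis=1)
    if not np.all(np.isfinite(post_states)):
        bad = int(np.argwhere(~np.all(np.isfinite(post_states), axis=1))[0][0])
        raise FloatingPointError(f"non-finite state at t = {t_post[bad]:.1f} ms")
    states = np.empty((t.size, x0.size))
    states[~post] = x0
    states[post] = post_states
    return t, states


def observe(
    time_ms: np.ndarray,
    states: np.ndarray,
    obs: ObservationModel,
    condition: str = "standard",
) -> ErfTrace:
    """Map a state trajectory to an ERF trace.

    amplitude(t) = gain * sum_p w_p (V_p(t) - V_p(rest)) + baseline, with
    the trajectory's initial sample taken as the resting reference, so
    traces are baseline-corrected by construction.
    """
    states = np.asarray(states, dtype=float)
    if states.ndim != 2 or states.shape[0] != len(time_ms):
        raise ValueError("states must be (n_samples, n_states)")
    V = states[:, :N_POP]
    w = np.asarray(obs.weights, dtype=float)
    amp = obs.gain * ((V - V[0]) @ w) + obs.baseline
    return ErfTrace(np.asarray(time_ms, float), amp, condition)


def simulate_erf(
    params: MicrocircuitParameters,
    condition: str,
    time_ms: np.ndarray | None = None,
    internal_dt: float = 1.0,
    backend: str = "auto",
) -> ErfTrace:
    t, states = integrate(params, condition, time_ms, internal_dt, backend=backend)
    return observe(t, states, ObservationModel.from_params(params), condition)


def simulate_erf_pair(
    params: MicrocircuitParameters,
    time_ms: np.ndarray | None = None,
    internal_dt: float = 1.0,
    backend: str = "auto",
) -> tuple[ErfTrace, ErfTrace]:
    """Standard and deviant traces; they differ only via condition log-gains b."""
    std = simulate_erf(params, "standard", time_ms, internal_dt, backend=backend)
    dev = simulate_erf(params, "deviant", time_ms, internal_dt, backend=backend)
    return std, dev


def ymax(
    standard: ErfTrace,
    deviant: ErfTrace,
    window: tuple[float, float] = MISMATCH_WINDOW_MS,
) -> float:
    """Maximal absolute deflection of the difference wave in the mismatch window.

    Window endpoints are inclusive.
    """
    if standard.time_ms.shape != deviant.time_ms.shape or np.max(np.abs(standard.time_ms - deviant.time_ms)) > 1e-9:
        raise ValueError("traces must share a time grid")
    lo, hi = window
    t = standard.time_ms
    if lo < t[0] - 1e-9 or hi > t[-1] + 1e-9:
        raise ValueError(f"window [{lo}, {hi}] ms outside the trace grid [{t[0]}, {t[-1]}]")
    mask = (t >= lo - 1e-9) & (t <= hi + 1e-9)
    if not np.any(mask):
        raise ValueError("no samples inside the mismatch window")
    return float(np.max(np.abs(deviant.amplitude[mask] - standard.amplitude[mask])))


# -- batched forward pass (used by the inversion scheme) ---------------------

def _steady_state_batch(
    params: MicrocircuitParameters,
    p_list: list[MicrocircuitParameters],
    G: np.ndarray,
    tauk: np.ndarray,
    condition: str,
    tol: float = 1e-9,
    max_iter: int = 60,
) -> tuple[np.ndarray, np.ndarray]:
    """Resting fixed points for a batch of circuits (vectorized damped Newton).

    Reduces to the 6-dim membrane-potential system (g = sigma(V) at rest),
    exactly as :func:`pedcm.microcircuit.steady_state`, but solves all
    batch elements simultaneously.  Falls back to the scalar solver for
    any element that fails to converge.
    """
    B = G.shape[0]
    VL, VE, VI, C, cL = params.V_L, params.V_E, params.V_I, params.C, params.cL
    thr, slope = params.firing_threshold, params.firing_slope
    mga, mgb = params.mg_alpha, params.mg_beta

    def residual(V):  # V: (B, 6)
        with np.errstate(over="ignore"):
            f = 1.0 / (1.0 + np.exp(-slope * (V - thr)))
            m = 1.0 / (1.0 + mgb * np.exp(-mga * V))
        sigma = np.einsum("btsk,bs->btk", G, f)
        return (
            cL * (VL - V)
            + sigma[:, :, 0] * (VE - V)
            + sigma[:, :, 1] * m * (VE - V)
            + sigma[:, :, 2] * (VI - V)
        ) / C

    V = np.full((B, N_POP), VL, dtype=float)
    r = residual(V)
    h = 1e-6
    for _ in range(max_iter):
        rmax = np.max(np.abs(r), axis=1)
        if np.all(rmax < tol * 1e-2):
            break
        J = np.empty((B, N_POP, N_POP))
        for j in range(N_POP):
            Vp = V.copy(); Vp[:, j] += h
            Vm = V.copy(); Vm[:, j] -= h
            J[:, :, j] = (residual(Vp) - residual(Vm)) / (2 * h)
        try:
            step = np.linalg.solve(J, -r[:, :, None])[:, :, 0]
        except np.linalg.LinAlgError:
            step = -r
        alpha = np.ones(B)
        for _ in range(30):
            Vn = V + alpha[:, None] * step
            rn = residual(Vn)
            better = np.max(np.abs(rn), axis=1) < np.max(np.abs(r), axis=1)
            if np.all(better):
                V, r = Vn, rn
                break
            V = np.where(better[:, None], Vn, V)
            r = np.where(better[:, None], rn, r)
            alpha = np.where(better, alpha, alpha * 0.5)
            step = np.where(better[:, None], 0.0, step)
            if np.all(np.abs(alpha * np.max(np.abs(step), axis=1)) < 1e-14):
                break

    with np.errstate(over="ignore"):
        f = 1.0 / (1.0 + np.exp(-slope * (V - thr)))
    g = np.einsum("btsk,bs->btk", G, f)
    bad = np.max(np.abs(residual(V)), axis=1) >= tol
    for b in np.nonzero(bad)[0]:
        rest = steady_state(p_list[b], condition)
        V[b], g[b] = rest.V, rest.g
    return V, g

def simulate_erf_pair_batch(
    params: MicrocircuitParameters,
    names: list[str],
    lam: np.ndarray,
    time_ms: np.ndarray | None = None,
    internal_dt: float = 1.0,
    backend: str = "auto",
) -> np.ndarray:
    """Predicted (standard ++ deviant) amplitude vectors for a batch of
    free-parameter displacements ``lam`` of shape (B, n_free).

    Row b equals the concatenated amplitudes of
    ``simulate_erf_pair(params.apply_log_factors(names, lam[b]))``.
    """
    lam = np.atleast_2d(np.asarray(lam, dtype=float))
    B = lam.shape[0]
    t = default_time_grid() if time_ms is None else np.asarray(time_ms, dtype=float)
    out_step = float(t[1] - t[0])
    post = t >= 0.0
    t_post = t[post]
    dt, stride = _internal_step(out_step, internal_dt)
    n_steps = int(round((t_post[-1] - t_post[0]) / dt))
    sub_t = t_post[0] + 0.5 * dt * np.arange(2 * n_steps + 1)

    p_list = [params.apply_log_factors(names, lam[b]) for b in range(B)]
    consts = (
        params.V_L, params.V_E, params.V_I, params.C, params.cL,
        params.firing_threshold, params.firing_slope, params.mg_alpha, params.mg_beta,
    )
    ip = _POP_INDEX[params.input_population]
    w = np.asarray(params.obs_weights, dtype=float)

    # Gaussian kernel shape varies only via onset/width, which are fixed
    # across the batch; amplitude varies per batch element.
    base_kern = stimulus_input(sub_t, params) / max(params.input_amplitude, 1e-300)

    y = np.empty((B, 2 * t.size))
    tauk = np.stack([np.array([p.tau[r] for r in RECEPTORS]) for p in p_list])
    uamp = np.array([p.input_amplitude for p in p_list])
    ogain = np.array([p.obs_gain for p in p_list])
    obase = np.array([p.obs_baseline for p in p_list])
    for ci, condition in enumerate(CONDITIONS):
        G = np.stack([build_connectivity(p, condition) for p in p_list])
        V0, g0 = _steady_state_batch(params, p_list, G, tauk, condition)
        out_V, _ = _fast.rk4_batch(
            V0, g0, G, tauk, uamp, base_kern, ip, consts, dt, n_steps, stride, backend=backend,
        )
        amp_post = ogain[:, None] * ((out_V - V0[:, None, :]) @ w) + obase[:, None]
        block = np.empty((B, t.size))
        block[:, ~post] = obase[:, None]
        block[:, post] = amp_post
        y[:, ci * t.size:(ci + 1) * t.size] = block
    if not np.all(np.isfinite(y)):
        raise FloatingPointError("non-finite prediction in batched forward pass")
    return y
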
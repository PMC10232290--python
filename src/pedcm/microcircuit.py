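"""Six-population conductance-based cortical microcircuit.

The model describes one cortical source as six interacting neural-mass
populations arranged by lamina:

====  =========================================  ============
tag   population                                 lamina
====  =========================================  ============
ss    spiny stellate cells                       granular
sp    superficial pyramidal cells                superficial
si    superficial inhibitory interneurons        superficial
dp    deep regular-firing pyramidal cells        deep
tp    deep burst-firing pyramidal cells          deep
di    deep inhibitory interneurons               deep
====  =========================================  ============

Each population carries a membrane potential ``V`` and three synaptic
conductances ``g`` (AMPA, NMDA, GABA-A), giving 6 + 18 = 24 state
variables.  Membrane dynamics are conductance based::

    C dV_p/dt = cL (V_L - V_p) + g_AMPA (V_E - V_p) + g_GABA (V_I - V_p)
                + g_NMDA m(V_p) (V_E - V_p) + u_p

where ``m(V)`` is the voltage-dependent magnesium gate of the NMDA
channel and ``u`` is the exogenous (thalamic) drive, delivered to the
granular stellate population.  Conductances relax toward the afferent
presynaptic drive with receptor-specific time constants::

    dg_{p,k}/dt = (sigma_{p,k} - g_{p,k}) / tau_k
    sigma_{p,k} = sum_q gamma_eff(p, q, k) * f(V_q)

with ``f`` a logistic firing-rate function and ``gamma_eff`` the
condition-dependent effective connectivity.

State-vector layout (fixed, documented contract): the first 6 entries
are membrane potentials in population order (ss, sp, si, dp, tp, di);
the remaining 18 are conductances in population-major order with
receptors ordered (AMPA, NMDA, GABA), i.e. entry ``6 + 3*p + k``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np

POPULATIONS: tuple[str, ...] = ("ss", "sp", "si", "dp", "tp", "di")
LAMINA: dict[str, str] = {
    "ss": "granular",
    "sp": "superficial",
    "si": "superficial",
    "dp": "deep",
    "tp": "deep",
    "di": "deep",
}
RECEPTORS: tuple[str, ...] = ("AMPA", "NMDA", "GABA")
CONDITIONS: tuple[str, ...] = ("standard", "deviant")

N_POP = 6
N_REC = 3
N_STATES = N_POP + N_POP * N_REC

_POP_INDEX = {p: i for i, p in enumerate(POPULATIONS)}
_REC_INDEX = {r: i for i, r in enumerate(RECEPTORS)}

#: excitatory source populations (AMPA/NMDA edges may only originate here)
EXCITATORY = ("ss", "sp", "dp", "tp")
#: inhibitory source populations (GABA edges may only originate here)
INHIBITORY = ("si", "di")


@dataclass(frozen=True)
class Edge:
    """A directed synaptic connection (source -> target, one receptor)."""

    source: str
    target: str
    receptor: str
    gain: float
    modulated: bool = False

    def __post_init__(self) -> None:
        if self.source not in _POP_INDEX or self.target not in _POP_INDEX:
            raise ValueError(f"unknown population in edge {self.source}->{self.target}")
        if self.receptor not in _REC_INDEX:
            raise ValueError(f"unknown receptor {self.receptor!r}")
        if self.receptor == "GABA" and self.source not in INHIBITORY:
            raise ValueError(f"GABA edge must originate from an interneuron, got {self.source}")
        if self.receptor in ("AMPA", "NMDA") and self.source not in EXCITATORY:
            raise ValueError(f"excitatory edge must originate from an excitatory population, got {self.source}")
        if self.gain < 0:
            raise ValueError("edge gain must be non-negative")

    @property
    def name(self) -> str:
        return f"{self.receptor}:{self.source}->{self.target}"


# Laminar wiring of the column.  Excitatory projections run through both
# AMPA and NMDA receptors; inhibition is intra-laminar.
_EXC_PAIRS = [
    ("ss", "sp"), ("ss", "si"), ("sp", "ss"), ("sp", "dp"),
    ("sp", "di"), ("dp", "tp"), ("tp", "di"), ("tp", "ss"),
]
_GABA_EDGES = [
    ("si", "sp"), ("si", "ss"), ("si", "si"),
    ("di", "dp"), ("di", "tp"), ("di", "di"),
]


def default_template(
    exc_gain: float = 0.3,
    nmda_gain: float = 1.0,
    gaba_gain: float = 5.0,
    modulate_excitatory: bool = True,
) -> tuple[Edge, ...]:
    """Default connectivity template of the column.

    All excitatory (AMPA and NMDA) edges are flagged as condition
    modulated by default; inhibitory edges are not.
    """
    edges: list[Edge] = []
    for s, t in _EXC_PAIRS:
        edges.append(Edge(s, t, "AMPA", exc_gain, modulated=modulate_excitatory))
        edges.append(Edge(s, t, "NMDA", nmda_gain, modulated=modulate_excitatory))
    for s, t in _GABA_EDGES:
        edges.append(Edge(s, t, "GABA", gaba_gain, modulated=False))
    return tuple(edges)


@dataclass
class MicrocircuitParameters:
    """All biophysical constants and free parameters of one cortical source.

    Voltages in mV, time constants in ms, capacitance and conductances in
    arbitrary units consistent with the membrane equation.  Free
    parameters (gains, time constants, input and observation scaling)
    enter inference as log-scale factors; condition log-gains ``b`` are
    already log-scale quantities and enter additively.
    """

    # reversal potentials (mV); must satisfy V_I < V_L < V_E
    V_L: float = -70.0
    V_E: float = 60.0
    V_I: float = -90.0
    # passive membrane
    C: float = 8.0
    cL: float = 1.0
    # receptor kinetics (ms)
    tau: dict[str, float] = field(default_factory=lambda: {"AMPA": 4.0, "NMDA": 100.0, "GABA": 16.0})
    # firing function: f(V) = 1 / (1 + exp(-slope * (V - threshold)))
    firing_threshold: float = -40.0
    firing_slope: float = 0.125
    # magnesium gate: m(V) = 1 / (1 + mg_beta * exp(-mg_alpha * V))
    mg_alpha: float = 0.062
    mg_beta: float = 0.1
    # connectivity
    edges: tuple[Edge, ...] = field(default_factory=default_template)
    # condition log-gains per modulated edge name
    b: dict[str, float] = field(default_factory=dict)
    # exogenous input kernel (Gaussian bump): onset/width in ms
    input_onset: float = 60.0
    input_width: float = 16.0
    input_amplitude: float = 32.0
    input_population: str = "ss"
    # observation model: per-population weights, scalar gain, baseline
    obs_weights: tuple[float, ...] = (0.2, 0.8, 0.0, 0.2, 0.2, 0.0)
    obs_gain: float = 1.0
    obs_baseline: float = 0.0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not (self.V_I < self.V_L < self.V_E):
            raise ValueError("reversal potentials must satisfy V_I < V_L < V_E")
        if self.C <= 0 or self.cL < 0:
            raise ValueError("capacitance must be positive, leak conductance non-negative")
        for k, t in self.tau.items():
            if t <= 0:
                raise ValueError(f"time constant tau[{k}] must be positive")
        if self.input_width <= 0:
            raise ValueError("input width must be positive")
        if self.input_population not in _POP_INDEX:
            raise ValueError(f"unknown input population {self.input_population!r}")
        if len(self.obs_weights) != N_POP:
            raise ValueError("observation weights must have one entry per population")
        if not any(w != 0 for w in self.obs_weights):
            raise ValueError("at least one observation weight must be nonzero")
        names = [e.name for e in self.edges]
        if len(names) != len(set(names)):
            raise ValueError("duplicate edges in template")
        for name in self.b:
            if name not in names:
                raise ValueError(f"condition log-gain refers to unknown edge {name!r}")

    # -- free-parameter machinery -------------------------------------------

    def edge_by_name(self, name: str) -> Edge:
        for e in self.edges:
            if e.name == name:
                return e
        raise KeyError(name)

    def gain_names(self) -> list[str]:
        return [f"gamma:{e.name}" for e in self.edges]

    def b_names(self) -> list[str]:
        return [f"b:{e.name}" for e in self.edges if e.modulated]

    def free_parameter_names(self) -> list[str]:
        """Canonical ordering of all recognised free parameters."""
        return (
            self.gain_names()
            + self.b_names()
            + [f"tau:{r}" for r in RECEPTORS]
            + ["input_amplitude", "obs_gain"]
        )

    def default_prior_variances(self) -> dict[str, float]:
        """Shrinkage prior variance per free parameter (log scale).

        Gains, condition log-gains and scaling parameters get 1/16
        (prior SD 0.25 log-units); time constants are held tighter
        (1/32) since the receptor kinetics are comparatively well known.
        """
        out: dict[str, float] = {}
        for name in self.free_parameter_names():
            out[name] = 1.0 / 32.0 if name.startswith("tau:") else 1.0 / 16.0
        return out

    def apply_log_factors(self, names: list[str], lam: np.ndarray) -> "MicrocircuitParameters":
        """Return a copy with free parameters displaced by the vector ``lam``.

        Positive parameters theta are mapped as theta * exp(lam); the
        condition log-gains ``b:`` are displaced additively.  The map is
        bijective on the free-parameter subset.
        """
        lam = np.asarray(lam, dtype=float)
        if lam.shape != (len(names),):
            raise ValueError("lam must match names in length")
        gains = {e.name: e.gain for e in self.edges}
        b = dict(self.b)
        tau = dict(self.tau)
        amp = self.input_amplitude
        ogain = self.obs_gain
        for name, v in zip(names, lam):
            kind, _, rest = name.partition(":")
            if kind == "gamma":
                if rest not in gains:
                    raise KeyError(name)
                gains[rest] *= float(np.exp(v))
            elif kind == "b":
                if rest not in {e.name for e in self.edges if e.modulated}:
                    raise KeyError(name)
                b[rest] = b.get(rest, 0.0) + float(v)
            elif kind == "tau":
                tau[rest] = tau[rest] * float(np.exp(v))
            elif name == "input_amplitude":
                amp = amp * float(np.exp(v))
            elif name == "obs_gain":
                ogain = ogain * float(np.exp(v))
            else:
                raise KeyError(f"unknown free parameter {name!r}")
        edges = tuple(replace(e, gain=gains[e.name]) for e in self.edges)
        return replace(self, edges=edges, b=b, tau=tau, input_amplitude=amp, obs_gain=ogain)

    # -- serialization -------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "constants": {
                "V_L": self.V_L, "V_E": self.V_E, "V_I": self.V_I,
                "C": self.C, "cL": self.cL, "tau": dict(self.tau),
                "firing_threshold": self.firing_threshold,
                "firing_slope": self.firing_slope,
                "mg_alpha": self.mg_alpha, "mg_beta": self.mg_beta,
                "input_onset": self.input_onset, "input_width": self.input_width,
                "input_amplitude": self.input_amplitude,
                "input_population": self.input_population,
                "obs_weights": list(self.obs_weights),
                "obs_gain": self.obs_gain, "obs_baseline": self.obs_baseline,
            },
            "template_edges": [
                {"source": e.source, "target": e.target, "receptor": e.receptor,
                 "gain": e.gain, "modulated": e.modulated}
                for e in self.edges
            ],
            "condition_log_gains": dict(self.b),
            "free_parameter_names": self.free_parameter_names(),
            "prior_means": {name: 0.0 for name in self.free_parameter_names()},
            "prior_variances": self.default_prior_variances(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MicrocircuitParameters":
        c = d["constants"]
        edges = tuple(
            Edge(e["source"], e["target"], e["receptor"], e["gain"], e["modulated"])
            for e in d["template_edges"]
        )
        return cls(
            V_L=c["V_L"], V_E=c["V_E"], V_I=c["V_I"], C=c["C"], cL=c["cL"],
            tau=dict(c["tau"]),
            firing_threshold=c["firing_threshold"], firing_slope=c["firing_slope"],
            mg_alpha=c["mg_alpha"], mg_beta=c["mg_beta"],
            edges=edges, b=dict(d.get("condition_log_gains", {})),
            input_onset=c["input_onset"], input_width=c["input_width"],
            input_amplitude=c["input_amplitude"], input_population=c["input_population"],
            obs_weights=tuple(c["obs_weights"]),
            obs_gain=c["obs_gain"], obs_baseline=c["obs_baseline"],
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "MicrocircuitParameters":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass
class NeuronalState:
    """Membrane potentials and receptor conductances of the six populations."""

    V: np.ndarray          # (6,) mV
    g: np.ndarray          # (6, 3) conductance units, receptor order (AMPA, NMDA, GABA)

    def vector(self) -> np.ndarray:
        return np.concatenate([self.V, self.g.reshape(-1)])

    @classmethod
    def from_vector(cls, x: np.ndarray) -> "NeuronalState":
        x = np.asarray(x, dtype=float)
        if x.shape != (N_STATES,):
            raise ValueError(f"state vector must have {N_STATES} entries")
        return cls(V=x[:N_POP].copy(), g=x[N_POP:].reshape(N_POP, N_REC).copy())


# -- elementary nonlinearities -----------------------------------------------

def firing_rate(V, params: MicrocircuitParameters):
    """Logistic presynaptic firing rate in [0, 1], midpoint at the threshold."""
    z = params.firing_slope * (np.asarray(V, dtype=float) - params.firing_threshold)
    with np.errstate(over="ignore"):
        return 1.0 / (1.0 + np.exp(-z))


def nmda_gate(V, params: MicrocircuitParameters):
    """Voltage-dependent magnesium unblock of the NMDA channel, in (0, 1)."""
    with np.errstate(over="ignore"):
        return 1.0 / (1.0 + params.mg_beta * np.exp(-params.mg_alpha * np.asarray(V, dtype=float)))


# -- connectivity ------------------------------------------------------------

def build_connectivity(params: MicrocircuitParameters, condition: str) -> np.ndarray:
    """Effective gain tensor G[target, source, receptor] for one condition.

    Modulated edges carry gamma * exp(b) in the deviant condition and
    gamma in the standard condition.
    """
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}; expected one of {CONDITIONS}")
    G = np.zeros((N_POP, N_POP, N_REC))
    for e in params.edges:
        g = e.gain
        if condition == "deviant" and e.modulated:
            g = g * float(np.exp(params.b.get(e.name, 0.0)))
        G[_POP_INDEX[e.target], _POP_INDEX[e.source], _REC_INDEX[e.receptor]] = g
    return G


# -- dynamics ----------------------------------------------------------------

def state_derivative(
    state: NeuronalState,
    params: MicrocircuitParameters,
    input_value: float = 0.0,
    condition: str = "standard",
    G: np.ndarray | None = None,
) -> NeuronalState:
    """Time derivative of the 24 neuronal states (units per ms).

    ``G`` may be supplied to avoid rebuilding the connectivity tensor in
    inner loops; it must equal ``build_connectivity(params, condition)``.
    """
    V, g = np.asarray(state.V, float), np.asarray(state.g, float)
    if not (np.all(np.isfinite(V)) and np.all(np.isfinite(g))):
        raise ValueError("non-finite neuronal state")
    if G is None:
        G = build_connectivity(params, condition)
    f = firing_rate(V, params)                       # (6,)
    sigma = np.einsum("pqk,q->pk", G, f)            # (6, 3) drive per (target, receptor)
    u = np.zeros(N_POP)
    u[_POP_INDEX[params.input_population]] = input_value
    m = nmda_gate(V, params)
    dV = (
        params.cL * (params.V_L - V)
        + g[:, 0] * (params.V_E - V)
        + g[:, 1] * m * (params.V_E - V)
        + g[:, 2] * (params.V_I - V)
        + u
    ) / params.C
    taus = np.array([params.tau[r] for r in RECEPTORS])
    dg = (sigma - g) / taus
    return NeuronalState(V=dV, g=dg)


def steady_state(
    params: MicrocircuitParameters,
    condition: str = "standard",
    tol: float = 1e-9,
    max_iter: int = 200,
    V0: np.ndarray | None = None,
) -> NeuronalState:
    """Resting fixed point of the circuit with zero exogenous input.

    At a fixed point the conductances equal their afferent drive,
    g = sigma(V), which reduces the problem to a damped Newton search on
    the six membrane potentials.  Raises if the residual of the full
    24-dimensional derivative cannot be brought below ``tol``.
    """
    G = build_connectivity(params, condition)

    def residual(V: np.ndarray) -> np.ndarray:
        f = firing_rate(V, params)
        sigma = np.einsum("pqk,q->pk", G, f)
        m = nmda_gate(V, params)
        return (
            params.cL * (params.V_L - V)
            + sigma[:, 0] * (params.V_E - V)
            + sigma[:, 1] * m * (params.V_E - V)
            + sigma[:, 2] * (params.V_I - V)
        ) / params.C

    V = np.full(N_POP, params.V_L, dtype=float) if V0 is None else np.asarray(V0, float).copy()
    r = residual(V)
    h = 1e-6
    for _ in range(max_iter):
        if np.max(np.abs(r)) < tol * 1e-2:
            break
        # finite-difference Jacobian of the 6-dim reduced system
        J = np.empty((N_POP, N_POP))
        for j in range(N_POP):
            Vp = V.copy(); Vp[j] += h
            Vm = V.copy(); Vm[j] -= h
            J[:, j] = (residual(Vp) - residual(Vm)) / (2 * h)
        try:
            step = np.linalg.solve(J, -r)
        except np.linalg.LinAlgError:
            step = -r
        alpha = 1.0
        for _ in range(30):
            Vn = V + alpha * step
            rn = residual(Vn)
            if np.max(np.abs(rn)) < np.max(np.abs(r)):
                V, r = Vn, rn
                break
            alpha *= 0.5
        else:
            break
    g = np.einsum("pqk,q->pk", G, firing_rate(V, params))
    state = NeuronalState(V=V, g=g)
    d = state_derivative(state, params, 0.0, condition, G=G).vector()
    if float(np.max(np.abs(d))) > tol and V0 is None:
        # Newton from rest failed: continue along pseudo-time (relax the full
        # 24-dim dynamics toward an attractor), then polish.  If the state
        # diverges there is no resting fixed point to find.
        x = NeuronalState(V=np.full(N_POP, params.V_L), g=np.zeros((N_POP, N_REC)))
        dt = 0.5
        for _ in range(6000):
            dd = state_derivative(x, params, 0.0, condition, G=G)
            x = NeuronalState(x.V + dt * dd.V, x.g + dt * dd.g)
            if not np.all(np.isfinite(x.V)) or np.max(np.abs(x.V)) > 500.0:
                raise RuntimeError(
                    "steady-state search diverged: the circuit has no stable resting state "
                    f"(residual inf-norm {np.max(np.abs(d)):.3e} before divergence)"
                )
        return steady_state(params, condition, tol=tol, max_iter=max_iter, V0=x.V)
    if float(np.max(np.abs(d))) > tol:
        raise RuntimeError(
            f"steady-state search did not converge: residual inf-norm {np.max(np.abs(d)):.3e}"
        )
    return state
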
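"""Unit and property tests for the six-population microcircuit."""

import dataclasses
import json

import numpy as np
import pytest

from pedcm.microcircuit import (
    CONDITIONS,
    N_POP,
    N_STATES,
    POPULATIONS,
    RECEPTORS,
    Edge,
    MicrocircuitParameters,
    NeuronalState,
    build_connectivity,
    default_template,
    firing_rate,
    nmda_gate,
    state_derivative,
    steady_state,
)
from pedcm.microcircuit import _POP_INDEX, _REC_INDEX


class TestFiringRate:
    def test_midpoint_at_threshold(self, params):
        assert firing_rate(params.firing_threshold, params) == pytest.approx(0.5)

    def test_saturation(self, params):
        assert firing_rate(-1e6, params) == pytest.approx(0.0, abs=1e-12)
        assert firing_rate(1e6, params) == pytest.approx(1.0, abs=1e-12)

    def test_strictly_increasing_on_grid(self, params):
        v = np.arange(-100.0, 41.0, 1.0)
        f = firing_rate(v, params)
        assert np.all(np.diff(f) > 0)
        assert np.all((f >= 0) & (f <= 1))


class TestNmdaGate:
    def test_closed_form_at_zero_mv(self, params):
        # gate(0) = 1/(1 + beta) for any alpha
        p = dataclasses.replace(params, mg_beta=0.2)
        assert nmda_gate(0.0, p) == pytest.approx(1.0 / 1.2, abs=1e-12)

    def test_saturation_and_range(self, params):
        assert nmda_gate(1e5, params) == pytest.approx(1.0)
        v = np.linspace(-120, 60, 181)
        g = nmda_gate(v, params)
        assert np.all((g > 0) & (g < 1 + 1e-12))

    def test_strictly_increasing(self, params):
        v = np.linspace(-120, 60, 181)
        assert np.all(np.diff(nmda_gate(v, params)) > 0)


class TestConnectivity:
    def test_zero_condition_gains_identity(self, params):
        G_std = build_connectivity(params, "standard")
        G_dev = build_connectivity(params, "deviant")
        np.testing.assert_array_equal(G_std, G_dev)

    def test_ln2_doubles_single_edge(self, params):
        p = dataclasses.replace(params)
        edge = next(e for e in p.edges if e.modulated)
        p.b = {edge.name: np.log(2.0)}
        G_std = build_connectivity(p, "standard")
        G_dev = build_connectivity(p, "deviant")
        i, j, k = _POP_INDEX[edge.target], _POP_INDEX[edge.source], _REC_INDEX[edge.receptor]
        assert G_dev[i, j, k] == pytest.approx(2.0 * G_std[i, j, k])
        G_dev[i, j, k] = G_std[i, j, k]
        np.testing.assert_array_equal(G_std, G_dev)

    def test_random_b_matches_edgewise_oracle(self, params, rng):
        p = dataclasses.replace(params)
        p.b = {e.name: float(rng.normal(0, 0.5)) for e in p.edges if e.modulated}
        G = build_connectivity(p, "deviant")
        oracle = np.zeros((6, 6, 3))
        for e in p.edges:
            g = e.gain * (np.exp(p.b[e.name]) if e.modulated else 1.0)
            oracle[_POP_INDEX[e.target], _POP_INDEX[e.source], _REC_INDEX[e.receptor]] = g
        np.testing.assert_allclose(G, oracle, rtol=0, atol=0)

    def test_unknown_condition_rejected(self, params):
        with pytest.raises(ValueError, match="condition"):
            build_connectivity(params, "oddball")

    def test_gaba_edges_only_from_interneurons(self):
        with pytest.raises(ValueError, match="interneuron"):
            Edge("sp", "ss", "GABA", 1.0)
        with pytest.raises(ValueError, match="excitatory"):
            Edge("si", "ss", "AMPA", 1.0)


def _derivative_oracle(state, params, u, condition):
    """Naive per-equation reimplementation of the displayed dynamics."""
    G = build_connectivity(params, condition)
    dV = np.zeros(N_POP)
    dg = np.zeros((N_POP, 3))
    for p_i, pop in enumerate(POPULATIONS):
        V = state.V[p_i]
        m = 1.0 / (1.0 + params.mg_beta * np.exp(-params.mg_alpha * V))
        rhs = params.cL * (params.V_L - V)
        rhs += state.g[p_i, 0] * (params.V_E - V)
        rhs += state.g[p_i, 1] * m * (params.V_E - V)
        rhs += state.g[p_i, 2] * (params.V_I - V)
        if pop == params.input_population:
            rhs += u
        dV[p_i] = rhs / params.C
        for k, rec in enumerate(RECEPTORS):
            drive = 0.0
            for q in range(N_POP):
                f_q = 1.0 / (1.0 + np.exp(-params.firing_slope * (state.V[q] - params.firing_threshold)))
                drive += G[p_i, q, k] * f_q
            dg[p_i, k] = (drive - state.g[p_i, k]) / params.tau[rec]
    return np.concatenate([dV, dg.reshape(-1)])


class TestStateDerivative:
    def test_fixed_point_has_zero_derivative(self, params):
        st = steady_state(params)
        d = state_derivative(st, params, 0.0).vector()
        assert np.max(np.abs(d)) < 1e-8

    def test_leak_equilibrium_exact(self, params):
        p = dataclasses.replace(params, edges=tuple(
            dataclasses.replace(e, gain=0.0) for e in params.edges
        ))
        st = NeuronalState(V=np.full(6, p.V_L), g=np.zeros((6, 3)))
        d = state_derivative(st, p, 0.0).vector()
        assert np.all(d == 0.0)

    def test_matches_independent_oracle(self, params, rng):
        for _ in range(100):
            st = NeuronalState(V=rng.uniform(-90, 0, 6), g=rng.uniform(0, 2, (6, 3)))
            u = float(rng.normal(0, 10))
            cond = CONDITIONS[int(rng.integers(2))]
            d = state_derivative(st, params, u, cond).vector()
            np.testing.assert_allclose(d, _derivative_oracle(st, params, u, cond),
                                       rtol=0, atol=1e-12)

    def test_nonfinite_state_rejected(self, params):
        st = NeuronalState(V=np.array([np.nan, 0, 0, 0, 0, 0.0]), g=np.zeros((6, 3)))
        with pytest.raises(ValueError, match="finite"):
            state_derivative(st, params, 0.0)


class TestSteadyState:
    def test_zero_connectivity_rest_is_leak_reversal(self, params):
        p = dataclasses.replace(params, edges=tuple(
            dataclasses.replace(e, gain=0.0) for e in params.edges
        ))
        st = steady_state(p)
        np.testing.assert_allclose(st.V, np.full(6, p.V_L), atol=1e-12)
        np.testing.assert_allclose(st.g, 0.0, atol=1e-15)

    def test_default_residual_below_tolerance(self, params):
        st = steady_state(params)
        d = state_derivative(st, params, 0.0).vector()
        assert np.max(np.abs(d)) < 1e-9

    def test_fixed_point_is_stable_to_voltage_kick(self, params):
        from pedcm import _fast

        st = steady_state(params)
        V0 = st.V + 1.0  # +1 mV on every population
        consts = (params.V_L, params.V_E, params.V_I, params.C, params.cL,
                  params.firing_threshold, params.firing_slope,
                  params.mg_alpha, params.mg_beta)
        G = build_connectivity(params, "standard")[None]
        tauk = np.array([[params.tau[r] for r in RECEPTORS]])
        n_steps = 500
        out_V, _ = _fast.rk4_batch(
            V0[None], st.g[None], G, tauk, np.array([0.0]),
            np.zeros(2 * n_steps + 1), 0, consts, 1.0, n_steps, n_steps,
        )
        assert np.max(np.abs(out_V[0, -1] - st.V)) < 0.01


class TestTrajectoryInvariants:
    def test_conductances_stay_nonnegative_and_voltage_bounded(self, base_params):
        from pedcm.simulate import integrate

        for cond in CONDITIONS:
            _, states = integrate(base_params, cond)
            g = states[:, N_POP:]
            V = states[:, :N_POP]
            assert g.min() >= -1e-12
            assert V.min() >= base_params.V_I and V.max() <= base_params.V_E


class TestParameters:
    def test_reversal_potential_ordering_enforced(self):
        with pytest.raises(ValueError, match="V_I < V_L < V_E"):
            MicrocircuitParameters(V_I=-60.0)

    def test_state_vector_round_trip(self, rng):
        x = rng.normal(size=N_STATES)
        st = NeuronalState.from_vector(x)
        np.testing.assert_array_equal(st.vector(), x)

    def test_log_factor_map_is_bijective(self, params, rng):
        names = params.free_parameter_names()
        lam = rng.normal(0, 0.3, len(names))
        q = params.apply_log_factors(names, lam)
        back = q.apply_log_factors(names, -lam)
        for e0, e1 in zip(params.edges, back.edges):
            assert e1.gain == pytest.approx(e0.gain, rel=1e-12)
        for r in RECEPTORS:
            assert back.tau[r] == pytest.approx(params.tau[r], rel=1e-12)
        assert back.input_amplitude == pytest.approx(params.input_amplitude, rel=1e-12)
        for nm, v in back.b.items():
            assert v == pytest.approx(params.b.get(nm, 0.0), abs=1e-12)

    def test_json_round_trip_bit_exact(self, base_params, tmp_path):
        path = tmp_path / "params.json"
        base_params.to_json(path)
        loaded = MicrocircuitParameters.from_json(path)
        assert loaded.to_dict() == base_params.to_dict()
        # second write is byte-identical
        path2 = tmp_path / "params2.json"
        loaded.to_json(path2)
        assert path.read_bytes() == path2.read_bytes()

    def test_template_counts(self):
        edges = default_template()
        assert len(edges) == 22
        assert sum(e.receptor == "GABA" for e in edges) == 6
        assert sum(e.modulated for e in edges) == 16
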
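"""Cable solver: gating, resting state, passive analytics, Ohm's-law
gradients, and an independent-integrator cross-check."""

import dataclasses
import math

import numpy as np
import pytest

from chandelier import (
    CellModel,
    SimulationError,
    StimulusPulse,
    SynapseSpec,
    build_canonical_model,
    discretize,
    equilibrium,
    gate_steady_state,
    make_protocol,
    simulate,
    steady_gradient,
)
from chandelier.solver import _cell_arrays
from chandelier.theory import axial_resistance_per_length


class TestGateSteadyState:
    def test_midpoint(self):
        assert gate_steady_state(-35.0, -35.0, 5.0, "activating") == 0.5
        assert gate_steady_state(-55.0, -55.0, 5.0, "inactivating") == 0.5

    def test_saturation(self):
        assert gate_steady_state(200.0, -35.0, 5.0, "activating") == pytest.approx(1.0)
        assert gate_steady_state(-300.0, -35.0, 5.0, "activating") == pytest.approx(0.0, abs=1e-12)
        assert gate_steady_state(200.0, -55.0, 5.0, "inactivating") == pytest.approx(0.0, abs=1e-12)

    def test_boltzmann_value(self):
        # one slope above half-activation: 1/(1+e^(−1))
        assert gate_steady_state(-30.0, -35.0, 5.0, "activating") == pytest.approx(
            1 / (1 + math.exp(-1)), rel=1e-12
        )

    def test_monotonicity(self):
        v = np.linspace(-100, 20, 200)
        act = gate_steady_state(v, -35.0, 5.0, "activating")
        inact = gate_steady_state(v, -60.0, 5.0, "inactivating")
        assert np.all(np.diff(act) > 0)
        assert np.all(np.diff(inact) < 0)


def _passive_model() -> CellModel:
    m = build_canonical_model()
    channels = {
        r: dataclasses.replace(p, gNa_S_m2=0.0, gK_S_m2=0.0)
        for r, p in m.channels.items()
    }
    return CellModel(m.sections, m.passive, channels, m.ais)


def _sealed_cable_input_resistance(Rm, Ri, d_um, L_um) -> float:
    """Closed-form input resistance (MΩ) of a finite sealed-end cylinder."""
    lam_um = math.sqrt(Rm * d_um * 1e-4 / (4 * Ri)) * 1e4  # cm → µm
    ra = axial_resistance_per_length(Ri, d_um)              # MΩ/µm
    return ra * lam_um / math.tanh(L_um / lam_um)


class TestPassiveCable:
    def test_somatic_input_resistance_matches_analytics(self):
        """Steady somatic response to a current step equals the parallel
        combination of soma membrane and the two sealed-end cables."""
        m = _passive_model()
        cell = discretize(m, 2.5, 10.0)
        state = equilibrium(cell, settle_ms=200.0, dt_ms=0.02)
        proto = make_protocol(
            m, pulses=[StimulusPulse(("soma", 15.0), -0.05, 0.0, 200.0)],
            duration_ms=200.0, dt_us=20.0, record=[("soma", 15.0)],
        )
        traces = simulate(cell, proto, state=state, record_stride=50)
        dv = traces.trace("soma")[-1] - traces.trace("soma")[0]
        R_sim = dv / -0.05  # mV / nA = MΩ

        p = m.passive
        soma = m.section("soma")
        area_cm2 = math.pi * soma.diameter_um * soma.length_um * 1e-8
        R_soma = p.Rm_ohm_cm2 / area_cm2 * 1e-6
        R_dend = _sealed_cable_input_resistance(p.Rm_ohm_cm2, p.Ri_ohm_cm, 6.0, 1000.0)
        R_axon = _sealed_cable_input_resistance(p.Rm_ohm_cm2, p.Ri_ohm_cm, 1.0, 500.0)
        R_th = 1.0 / (1 / R_soma + 1 / R_dend + 1 / R_axon)
        assert R_sim == pytest.approx(R_th, rel=0.02)


class TestRestingState:
    def test_equilibrium_is_stationary(self, canonical_cell, resting_state):
        proto = make_protocol(canonical_cell.model, duration_ms=100.0, dt_us=10.0,
                              record=[("soma", 15.0), ("axon", 20.0),
                                      ("dendrite", 500.0), ("axon", 400.0)])
        traces = simulate(canonical_cell, proto, state=resting_state,
                          record_stride=10)
        dvdt = np.abs(np.diff(traces.V, axis=1)) / traces.dt_ms
        assert dvdt[:, -1].max() < 0.01

    def test_resting_potential_physiological(self, resting_state):
        V, gates = resting_state
        assert -80.0 < V.mean() < -70.0
        for g in (gates.m, gates.h, gates.n):
            assert np.all((g >= 0) & (g <= 1))


class TestSpikingAndGates:
    def test_canonical_probe_elicits_spike_with_bounded_gates(
        self, canonical_cell, resting_state
    ):
        proto = make_protocol(
            canonical_cell.model,
            pulses=[StimulusPulse(("soma", 15.0), 1.0, 10.0, 5.0)],
            duration_ms=25.0, dt_us=2.0,
            record=[("soma", 15.0), ("axon", 20.0)],
        )
        traces = simulate(canonical_cell, proto, state=resting_state,
                          record_gates=True)
        assert traces.trace("axon", 20.0).max() > 0  # overshooting AP
        for g in traces.gates.values():
            assert np.all((g >= 0.0) & (g <= 1.0))
        assert np.all((traces.V > -120) & (traces.V < 80))

    def test_numerical_blowup_raises(self, canonical_cell, resting_state):
        proto = make_protocol(
            canonical_cell.model,
            pulses=[StimulusPulse(("soma", 15.0), 1e9, 1.0, 5.0)],
            duration_ms=10.0, dt_us=10.0, record=[("soma", 15.0)],
        )
        with pytest.raises(SimulationError):
            simulate(canonical_cell, proto, state=resting_state)


class TestOhmicGradient:
    def test_gradient_follows_ohms_law(self, canonical_cell):
        """Sub-threshold current at 75 µm: gradient within 10% of ra·x·I."""
        ra = axial_resistance_per_length(100, 1)
        x = float(canonical_cell.position_um[canonical_cell.locate("axon", 75.0)])
        g = steady_gradient(canonical_cell, -50.0, 75.0)
        assert g == pytest.approx(-50e-3 * x * ra, rel=0.10)
        assert steady_gradient(canonical_cell, 0.0, 75.0) == 0.0

    def test_local_polarization_doubles_with_distance(self, canonical_cell):
        g20 = steady_gradient(canonical_cell, -100.0, 20.0)
        g40 = steady_gradient(canonical_cell, -100.0, 40.0)
        assert g40 / g20 == pytest.approx(2.0, rel=0.1)


class TestIndependentOracle:
    def test_matches_bdf_integration(self, canonical_cell, resting_state):
        """Sub-threshold response agrees with scipy's implicit BDF solver
        run on the same compartment graph (independent numerics)."""
        from scipy.integrate import solve_ivp

        cell = canonical_cell
        ca = _cell_arrays(cell)
        nc = cell.n_comp
        ax = ca.g_axial_uS
        i_inj = cell.locate("axon", 40.0)

        def rhs(t, y):
            V, m, h, n = np.split(y, 4)
            minf = 1 / (1 + np.exp((ca.vm_half - V) / ca.km))
            hinf = 1 / (1 + np.exp((V - ca.vh_half) / ca.kh))
            ninf = 1 / (1 + np.exp((ca.vn_half - V) / ca.kn))
            I = (ca.gL_uS * (ca.EL - V) + ca.gNa_uS * m * h * (ca.ENa - V)
                 + ca.gK_uS * n ** ca.kv_order * (ca.EK - V))
            I[1:] += ax * (V[:-1] - V[1:])
            I[:-1] += ax * (V[1:] - V[:-1])
            I[i_inj] += -0.05
            return np.concatenate([
                I / ca.c_nF, (minf - m) / ca.tau_m,
                (hinf - h) / ca.tau_h, (ninf - n) / ca.tau_n,
            ])

        V0, g0 = resting_state
        y0 = np.concatenate([V0, g0.m, g0.h, g0.n])
        sol = solve_ivp(rhs, (0.0, 20.0), y0, method="BDF", max_step=0.5,
                        rtol=1e-8, atol=1e-8, dense_output=True)

        proto = make_protocol(
            cell.model,
            synapses=[SynapseSpec(position_um=40.0, mode="fixed_current",
                                  amplitude_pA=-50.0, kinetics="constant")],
            duration_ms=20.0, dt_us=2.0,
            record=[("soma", 15.0), ("axon", 40.0)],
        )
        traces = simulate(cell, proto, state=resting_state, record_stride=100)
        for sec, pos in traces.sites:
            mine = traces.trace(sec, pos)
            ref = sol.sol(traces.time_ms)[cell.locate(sec, pos)]
            assert np.sqrt(np.mean((mine - ref) ** 2)) < 0.05  # mV


class TestTraceExport:
    def test_csv_round_trip(self, canonical_cell, resting_state, tmp_path):
        import json

        import pandas as pd

        proto = make_protocol(
            canonical_cell.model,
            pulses=[StimulusPulse(("soma", 15.0), -0.05, 1.0, 5.0)],
            duration_ms=10.0, dt_us=10.0, record=[("soma", 15.0), ("axon", 20.0)],
        )
        traces = simulate(canonical_cell, proto, state=resting_state,
                          record_stride=10)
        path = tmp_path / "traces.csv"
        traces.to_csv(path)
        df = pd.read_csv(path)
        assert df.shape[0] == traces.time_ms.size
        assert any(c.startswith("V_soma") for c in df.columns)
        sidecar = json.loads((tmp_path / "traces.csv.json").read_text())
        assert sidecar["dt_ms"] == pytest.approx(traces.dt_ms)
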
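"""Phase-plot threshold detection: synthetic oracles, invariances, and
behavior on simulated somatic/axonal action potentials."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from chandelier import (
    StimulusPulse,
    SynapseSpec,
    build_canonical_model,
    detect_threshold,
    discretize,
    equilibrium,
    make_protocol,
    phase_plot,
    simulate,
    soma_ais_gradient_at_onset,
    threshold_vs_probe_time,
)
from chandelier.experiments import SCALED


def synthetic_takeoff(t0=5.0, dt=0.002, a=1.0, c=0.6, tau=0.12, v0=-70.0,
                      t_end=7.0, v_cap=40.0):
    """Linear ramp with an exponential takeoff starting at t0.

    dV/dt jumps by c/τ at t0 (a kink, as when an axonal spike reaches the
    soma), then grows exponentially; the trace is capped at ``v_cap``.
    """
    t = np.arange(0.0, t_end, dt)
    v = v0 + a * t
    after = t >= t0
    v[after] += c * (np.exp((t[after] - t0) / tau) - 1.0)
    return t, np.minimum(v, v_cap)


class TestPhasePlot:
    def test_constant_trace_has_zero_derivative(self):
        t = np.arange(0, 1, 0.001)
        pp = phase_plot(t, np.full_like(t, -65.0))
        assert np.allclose(pp.dVdt_mV_ms, 0.0)

    def test_linear_trace_recovers_slope(self):
        t = np.arange(0, 1, 0.001)
        pp = phase_plot(t, -70 + 3.5 * t)
        assert np.allclose(pp.dVdt_mV_ms[1:-1], 3.5)

    def test_nonuniform_grid_rejected(self):
        t = np.array([0.0, 1.0, 3.0, 4.0])
        with pytest.raises(ValueError):
            phase_plot(t, np.zeros(4))

    def test_minimum_length(self):
        with pytest.raises(ValueError):
            phase_plot(np.array([0.0, 1.0]), np.array([0.0, 1.0]))


class TestDetectThreshold:
    def test_synthetic_takeoff_oracle(self):
        """The detector lands on the known takeoff time of a constructed
        ramp-plus-exponential trace."""
        t0, dt = 5.0, 0.002
        t, v = synthetic_takeoff(t0=t0, dt=dt)
        res = detect_threshold(t, v)
        assert res.spike
        assert abs(res.t_star_ms - t0) <= 2 * dt
        v_t0 = float(np.interp(t0, t, v))
        assert abs(res.V_star_mV - v_t0) <= 0.2

    @settings(derandomize=True, max_examples=50)
    @given(offset=st.floats(-40, 40))
    def test_translation_invariance(self, offset):
        t, v = synthetic_takeoff()
        r0 = detect_threshold(t, v)
        r1 = detect_threshold(t, v + offset)
        assert r1.V_star_mV == pytest.approx(r0.V_star_mV + offset, abs=1e-9)
        assert r1.t_star_ms == pytest.approx(r0.t_star_ms, abs=1e-9)

    def test_no_spike_is_explicit(self):
        t = np.arange(0, 10, 0.01)
        res = detect_threshold(t, -70 + 0.5 * t)
        assert not res.spike
        assert res.reason is not None
        assert np.isnan(res.V_star_mV)

    def test_below_peak(self):
        t, v = synthetic_takeoff()
        res = detect_threshold(t, v)
        assert res.V_star_mV < v.max()


@pytest.fixture(scope="module")
def canonical_spike(canonical_cell, resting_state):
    proto = make_protocol(
        canonical_cell.model,
        pulses=[StimulusPulse(("soma", 15.0), 1.0, 20.0, 5.0)],
        duration_ms=30.0, dt_us=SCALED.dt_us,
        record=[("soma", 15.0), ("axon", 20.0)],
    )
    return simulate(canonical_cell, proto, state=resting_state)


class TestOnSimulatedSpikes:
    def test_somatic_phase_plot_has_two_acceleration_modes(self, canonical_spike):
        """The somatic AP shows two acceleration maxima: the arriving
        axonal spike, then the somatic regeneration."""
        tr = canonical_spike
        t, v = tr.time_ms, tr.trace("soma")
        sel = t > 20.3
        dv = np.gradient(v[sel], t[sel])
        d2 = np.gradient(dv, t[sel])
        upstroke = slice(np.argmax(dv > 10), np.argmax(v[sel]))
        w = d2[upstroke]
        peaks = np.flatnonzero((w[1:-1] > w[:-2]) & (w[1:-1] >= w[2:])) + 1
        big = peaks[w[peaks] > 0.05 * w.max()]
        assert big.size >= 2

    def test_somatic_threshold_in_plausible_range(self, canonical_spike):
        res = detect_threshold(canonical_spike.time_ms,
                               canonical_spike.trace("soma"), t_min_ms=20.3)
        assert res.spike
        assert -62.0 < res.V_star_mV < -50.0
        assert res.diagnostics["detector"] == "inflexion"

    def test_soma_minus_axon_threshold_near_k(self, canonical_spike):
        """Somatic threshold exceeds the AIS threshold by roughly the Nav
        activation slope k ≈ 5 mV."""
        rs = detect_threshold(canonical_spike.time_ms,
                              canonical_spike.trace("soma"), t_min_ms=20.3)
        ra = detect_threshold(canonical_spike.time_ms,
                              canonical_spike.trace("axon", 20.0), t_min_ms=20.3)
        assert ra.diagnostics["detector"] == "departure"
        assert 3.0 <= rs.V_star_mV - ra.V_star_mV <= 7.0

    def test_weak_probe_dependence(self, canonical_cell, resting_state):
        """V* changes little between near-rheobase probe amplitudes."""
        vals = {}
        for amp in (0.7, 1.0):
            proto = make_protocol(
                canonical_cell.model,
                pulses=[StimulusPulse(("soma", 15.0), amp, 20.0, 5.0)],
                duration_ms=30.0, dt_us=SCALED.dt_us, record=[("soma", 15.0)],
            )
            tr = simulate(canonical_cell, proto, state=resting_state)
            vals[amp] = detect_threshold(tr.time_ms, tr.trace("soma"),
                                         t_min_ms=20.3).V_star_mV
        assert abs(vals[0.7] - vals[1.0]) < 1.0

    def test_timestep_convergence(self):
        """Halving the (full-mode) 1 µs timestep moves V* by < 0.1 mV."""
        model = build_canonical_model()
        cell = discretize(model, 2.5, 10.0)
        state = equilibrium(cell)
        vals = {}
        for dt_us in (1.0, 0.5):
            proto = make_protocol(
                model, pulses=[StimulusPulse(("soma", 15.0), 1.0, 20.0, 5.0)],
                duration_ms=30.0, dt_us=dt_us, record=[("soma", 15.0)],
            )
            tr = simulate(cell, proto, state=state)
            vals[dt_us] = detect_threshold(tr.time_ms, tr.trace("soma"),
                                           t_min_ms=20.3).V_star_mV
        assert abs(vals[1.0] - vals[0.5]) < 0.1


class TestGradientAtOnset:
    def test_resting_gradient_small(self, canonical_cell, resting_state):
        proto = make_protocol(
            canonical_cell.model, duration_ms=20.0, dt_us=10.0,
            record=[("soma", 15.0)] + [
                ("axon", float(x)) for x in
                canonical_cell.position_um[canonical_cell.region == "AIS"]
            ],
        )
        tr = simulate(canonical_cell, proto, state=resting_state, record_stride=10)
        g = soma_ais_gradient_at_onset(tr, canonical_cell.model.ais, 19.0)
        assert abs(g) < 0.3

    def test_gradient_matches_per_site_ohmic_mean(self, canonical_cell,
                                                  resting_state):
        """−200 pA at the AIS midpoint: the mean AIS gradient change equals
        the mean over AIS sites of ra·min(x_site, x_syn)·I within 10%."""
        from chandelier.theory import axial_resistance_per_length

        cell = canonical_cell
        mid = float(cell.position_um[cell.locate("axon", 20.0)])
        sites = [float(x) for x in cell.position_um[cell.region == "AIS"]]
        record = [("soma", 15.0)] + [("axon", x) for x in sites]
        syn = SynapseSpec(position_um=mid, mode="fixed_current",
                          amplitude_pA=-200.0, kinetics="constant")
        proto = make_protocol(cell.model, synapses=[syn], duration_ms=100.0,
                              dt_us=10.0, record=record)
        tr = simulate(cell, proto, state=resting_state, record_stride=10)
        g_end = soma_ais_gradient_at_onset(tr, cell.model.ais, 99.0)
        g_start = soma_ais_gradient_at_onset(tr, cell.model.ais, 0.05)
        ra = axial_resistance_per_length(100, 1)
        expected = -0.2 * ra * np.mean([min(x, mid) for x in sites])
        assert g_end - g_start < 0  # hyperpolarizing
        assert g_end - g_start == pytest.approx(expected, rel=0.10)

    def test_requires_enough_ais_sites(self, canonical_cell, resting_state):
        proto = make_protocol(canonical_cell.model, duration_ms=5.0, dt_us=10.0,
                              record=[("soma", 15.0), ("axon", 20.0)])
        tr = simulate(canonical_cell, proto, state=resting_state)
        with pytest.raises(ValueError):
            soma_ais_gradient_at_onset(tr, canonical_cell.model.ais, 4.0)


class TestThresholdVsProbeTime:
    def test_decayed_synapse_recovers_baseline(self, canonical_cell,
                                               resting_state):
        probe = StimulusPulse(("soma", 15.0), 1.0, 0.0, 5.0)
        syn = SynapseSpec(position_um=20.0, mode="fixed_current",
                          amplitude_pA=-50.0, kinetics="exponential_decay",
                          tau_s_ms=5.0, onset_ms=5.0)
        base = threshold_vs_probe_time(
            canonical_cell, None, probe, [40.0], dt_us=SCALED.dt_us,
            state=resting_state,
        )
        late = threshold_vs_probe_time(
            canonical_cell, syn, probe, [40.0], dt_us=SCALED.dt_us,
            state=resting_state,
        )
        assert late.spike.all() and base.spike.all()
        # probe 7 decay constants after onset: back at baseline
        assert abs(late.V_star_mV[0] - base.V_star_mV[0]) < 0.3

    def test_reproducible(self, canonical_cell, resting_state):
        probe = StimulusPulse(("soma", 15.0), 1.0, 0.0, 5.0)
        syn = SynapseSpec(position_um=20.0, mode="fixed_current",
                          amplitude_pA=-50.0, kinetics="exponential_decay",
                          tau_s_ms=20.0, onset_ms=2.0)
        a = threshold_vs_probe_time(canonical_cell, syn, probe, [2.0, 10.0],
                                    dt_us=SCALED.dt_us, state=resting_state)
        b = threshold_vs_probe_time(canonical_cell, syn, probe, [2.0, 10.0],
                                    dt_us=SCALED.dt_us, state=resting_state)
        assert a.equals(b)
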
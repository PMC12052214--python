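"""Multicompartment cable-equation solver.

Integrates C dV/dt = gL(EL−V) + gNa·m·h·(ENa−V) + gK·nᵖ·(EK−V)
                     + axial coupling + synaptic and injected currents

on the compartment chain produced by :func:`chandelier.model.discretize`.

Numerics: operator splitting.  Gates relax exactly (exponential update at
their fixed time constants toward the Boltzmann steady state evaluated at
the current voltage), then the voltage diffusion step is taken with
backward Euler, which on a chain topology is a single tridiagonal (Thomas)
solve per step and is unconditionally stable.  Conductance synapses enter
the voltage step implicitly (added to the matrix diagonal), so stiff shunts
cannot destabilize the step.  The inner loop is JIT-compiled with numba.

There is no randomness anywhere: a simulation is a pure function of the
cell, the protocol and the initial state.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .model import DiscretizedCell, Protocol, SynapseSpec

__all__ = [
    "SimulationError",
    "GateState",
    "TraceSet",
    "gate_steady_state",
    "equilibrium",
    "simulate",
    "steady_gradient",
]


class SimulationError(RuntimeError):
    """Raised when the integration produces non-finite voltages."""


def gate_steady_state(
    V_mV: float | np.ndarray,
    V_half_mV: float,
    slope_mV: float,
    direction: str = "activating",
) -> float | np.ndarray:
    """Boltzmann steady-state open fraction of a gate.

    ``activating`` gates open with depolarization, 1/(1+exp((V½−V)/k));
    ``inactivating`` gates close with depolarization, 1/(1+exp((V−V½)/k)).
    At V = V½ the value is 0.5 either way.
    """
    if slope_mV <= 0:
        raise ValueError("slope must be > 0")
    if direction == "activating":
        x = (V_half_mV - V_mV) / slope_mV
    elif direction == "inactivating":
        x = (V_mV - V_half_mV) / slope_mV
    else:
        raise ValueError(f"unknown direction {direction!r}")
    return 1.0 / (1.0 + np.exp(x))


# ---------------------------------------------------------------------------
# Internal unit system: mV, ms, nA, µS, nF  (so that  nA = µS·mV  and
# nF·mV/ms = nA).  Conversions from interface units happen here only.
# ---------------------------------------------------------------------------

@dataclass
class GateState:
    """Gating variables per compartment; each bounded in [0, 1]."""

    m: np.ndarray
    h: np.ndarray
    n: np.ndarray


@dataclass
class _CellArrays:
    c_nF: np.ndarray
    gL_uS: np.ndarray
    EL: float
    gNa_uS: np.ndarray
    gK_uS: np.ndarray
    ENa: np.ndarray
    EK: np.ndarray
    vm_half: np.ndarray
    km: np.ndarray
    vh_half: np.ndarray
    kh: np.ndarray
    vn_half: np.ndarray
    kn: np.ndarray
    tau_m: np.ndarray
    tau_h: np.ndarray
    tau_n: np.ndarray
    kv_order: int
    g_axial_uS: np.ndarray


def _cell_arrays(cell: DiscretizedCell) -> _CellArrays:
    p = cell.model.passive
    area = cell.area_um2
    n = cell.n_comp
    arr = {k: np.empty(n) for k in (
        "gNa", "gK", "ENa", "EK", "vm", "km", "vh", "kh", "vn", "kn",
        "tm", "th", "tn")}
    orders = set()
    for i in range(n):
        ch = cell.model.channels[cell.region[i]]
        # S/m² × µm² → µS
        arr["gNa"][i] = ch.gNa_S_m2 * area[i] * 1e-6
        arr["gK"][i] = ch.gK_S_m2 * area[i] * 1e-6
        arr["ENa"][i] = ch.ENa_mV
        arr["EK"][i] = ch.EK_mV
        arr["vm"][i] = ch.Vm_half_mV
        arr["km"][i] = ch.km_mV
        arr["vh"][i] = ch.Vh_half_mV
        arr["kh"][i] = ch.kh_mV
        arr["vn"][i] = ch.Vn_half_mV
        arr["kn"][i] = ch.kn_mV
        arr["tm"][i] = ch.tau_m_ms
        arr["th"][i] = ch.tau_h_ms
        arr["tn"][i] = ch.tau_n_ms
        orders.add(ch.kv_order)
    if len(orders) != 1:
        raise ValueError("kv_order must be identical across regions")
    return _CellArrays(
        c_nF=p.Cm_uF_cm2 * area * 1e-5,        # µF/cm² × µm² → nF
        gL_uS=area * 1e-2 / p.Rm_ohm_cm2,       # µm²/(Ω·cm²) → µS
        EL=p.EL_mV,
        gNa_uS=arr["gNa"], gK_uS=arr["gK"], ENa=arr["ENa"], EK=arr["EK"],
        vm_half=arr["vm"], km=arr["km"], vh_half=arr["vh"], kh=arr["kh"],
        vn_half=arr["vn"], kn=arr["kn"],
        tau_m=arr["tm"], tau_h=arr["th"], tau_n=arr["tn"],
        kv_order=orders.pop(),
        g_axial_uS=1.0 / cell.axial_R_MOhm,     # 1/MΩ = µS
    )


def _steady_gates(ca: _CellArrays, V: np.ndarray) -> GateState:
    m = 1.0 / (1.0 + np.exp((ca.vm_half - V) / ca.km))
    h = 1.0 / (1.0 + np.exp((V - ca.vh_half) / ca.kh))
    n = 1.0 / (1.0 + np.exp((ca.vn_half - V) / ca.kn))
    return GateState(m, h, n)


@njit(cache=True)
def _integrate(V, m, h, n, nsteps, dt,
               c_over_dt, gL, EL, gNa, ENa, gK, EK, kv_order,
               vm_half, km, vh_half, kh, vn_half, kn,
               am, ah, an,
               g_ax,
               i_idx, i_ts,
               g_idx, g_E, g_ts,
               rec_idx, stride,
               outV, outm, outh, outn, rec_gates,
               low, up, diag, rhs):
    ncomp = V.size
    n_i = i_idx.size
    n_g = g_idx.size
    n_rec = rec_idx.size
    for s in range(nsteps):
        # --- gate update (exact exponential relaxation at fixed tau) ---
        for i in range(ncomp):
            vi = V[i]
            minf = 1.0 / (1.0 + np.exp((vm_half[i] - vi) / km[i]))
            hinf = 1.0 / (1.0 + np.exp((vi - vh_half[i]) / kh[i]))
            ninf = 1.0 / (1.0 + np.exp((vn_half[i] - vi) / kn[i]))
            m[i] += am[i] * (minf - m[i])
            h[i] += ah[i] * (hinf - h[i])
            n[i] += an[i] * (ninf - n[i])
        # --- assemble tridiagonal backward-Euler system ---
        for i in range(ncomp):
            nk = n[i]
            npow = nk
            for _ in range(kv_order - 1):
                npow *= nk
            gna = gNa[i] * m[i] * h[i]
            gk = gK[i] * npow
            diag[i] = c_over_dt[i] + gL[i] + gna + gk
            rhs[i] = c_over_dt[i] * V[i] + gL[i] * EL + gna * ENa[i] + gk * EK[i]
        for i in range(ncomp - 1):
            diag[i] += g_ax[i]
            diag[i + 1] += g_ax[i]
            up[i] = -g_ax[i]
            low[i + 1] = -g_ax[i]
        for k in range(n_i):
            rhs[i_idx[k]] += i_ts[k, s]
        for k in range(n_g):
            g = g_ts[k, s]
            j = g_idx[k]
            diag[j] += g
            rhs[j] += g * g_E[k]
        # --- Thomas solve (in place; up and rhs are scratch) ---
        for i in range(1, ncomp):
            w = low[i] / diag[i - 1]
            diag[i] -= w * up[i - 1]
            rhs[i] -= w * rhs[i - 1]
        V[ncomp - 1] = rhs[ncomp - 1] / diag[ncomp - 1]
        for i in range(ncomp - 2, -1, -1):
            V[i] = (rhs[i] - up[i] * V[i + 1]) / diag[i]
        # --- record ---
        if (s + 1) % stride == 0:
            col = (s + 1) // stride
            for j in range(n_rec):
                outV[j, col] = V[rec_idx[j]]
            if rec_gates:
                for j in range(n_rec):
                    outm[j, col] = m[rec_idx[j]]
                    outh[j, col] = h[rec_idx[j]]
                    outn[j, col] = n[rec_idx[j]]
        # --- blow-up check ---
        if (s + 1) % 100 == 0 or s == nsteps - 1:
            for i in range(ncomp):
                vi = V[i]
                if not (-1e3 < vi < 1e3):
                    return s
    return -1


@dataclass
class TraceSet:
    """Recorded voltage (and optionally gating) time series.

    ``V`` has shape (n_sites, n_samples) on the uniform grid ``time_ms``;
    ``sites`` are the (section, position µm) pairs actually recorded (snapped
    to compartment centers).  ``stim`` holds one injected time series per
    source: currents in nA for current sources, conductances in µS for
    conductance synapses, sampled on the same grid.
    """

    time_ms: np.ndarray
    sites: list[tuple[str, float]]
    V: np.ndarray
    dt_ms: float
    gates: dict[str, np.ndarray] | None = None
    stim: dict[str, np.ndarray] = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def site_index(self, section: str, position_um: float) -> int:
        dists = [
            abs(pos - position_um) if sec == section else np.inf
            for sec, pos in self.sites
        ]
        i = int(np.argmin(dists))
        if not np.isfinite(dists[i]):
            raise KeyError(f"no recording on section {section!r}")
        return i

    def trace(self, section: str, position_um: float = 0.0) -> np.ndarray:
        return self.V[self.site_index(section, position_um)]

    def to_dataframe(self):
        import pandas as pd

        cols = {"time_ms": self.time_ms}
        for (sec, pos), row in zip(self.sites, self.V):
            cols[f"V_{sec}_{pos:g}um_mV"] = row
        for name, row in self.stim.items():
            cols[name] = row
        return pd.DataFrame(cols)

    def to_csv(self, path) -> None:
        """Write the traces as CSV plus a JSON sidecar with metadata."""
        self.to_dataframe().to_csv(path, index=False)
        sidecar = str(path) + ".json"
        with open(sidecar, "w") as f:
            json.dump(
                {"dt_ms": self.dt_ms, "sites": [list(s) for s in self.sites],
                 "meta": self.meta},
                f, indent=2, default=str,
            )


def _source_series(
    cell: DiscretizedCell, protocol: Protocol, nsteps: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray, list[str], list[str]]:
    """Expand pulses and synapses into per-compartment time series."""
    dt = protocol.dt_ms
    t = (np.arange(nsteps) + 1) * dt
    i_idx, i_rows, i_names = [], [], []
    g_idx, g_E, g_rows, g_names = [], [], [], []

    def current_envelope(s: SynapseSpec) -> np.ndarray:
        if s.kinetics == "constant":
            return (t >= s.onset_ms).astype(float)
        env = np.where(t >= s.onset_ms, np.exp(-(t - s.onset_ms) / s.tau_s_ms), 0.0)
        return env

    for k, p in enumerate(protocol.pulses):
        idx = cell.locate(*p.site)
        on = (t >= p.onset_ms) & (t < p.onset_ms + p.duration_ms)
        i_idx.append(idx)
        i_rows.append(p.amplitude_nA * on.astype(float))
        i_names.append(f"pulse{k}_{p.site[0]}_{p.site[1]:g}um_nA")

    for k, s in enumerate(protocol.synapses):
        env = current_envelope(s)
        if s.mode == "fixed_current":
            idx = cell.locate("axon", s.position_um)
            i_idx.append(idx)
            i_rows.append(s.amplitude_pA * 1e-3 * env)  # pA → nA
            i_names.append(f"syn{k}_I_{s.position_um:g}um_nA")
        else:
            gs_uS = s.gs_nS * 1e-3
            if s.span_um <= 0:
                weights = {cell.locate("axon", s.position_um): 1.0}
            else:
                lo = s.position_um - s.span_um / 2
                hi = s.position_um + s.span_um / 2
                weights = {}
                axon_mask = cell.section == "axon"
                for i in np.flatnonzero(axon_mask):
                    c0 = cell.position_um[i] - cell.length_um[i] / 2
                    c1 = cell.position_um[i] + cell.length_um[i] / 2
                    overlap = max(0.0, min(hi, c1) - max(lo, c0))
                    if overlap > 0:
                        weights[int(i)] = overlap
                total = sum(weights.values())
                if total == 0:
                    # degenerate span (smaller than the grid can resolve):
                    # collapse to a point synapse
                    weights = {cell.locate("axon", s.position_um): 1.0}
                else:
                    weights = {i: w / total for i, w in weights.items()}
            for i, w in weights.items():
                g_idx.append(i)
                g_E.append(s.EGABA_mV)
                g_rows.append(gs_uS * w * env)
                g_names.append(f"syn{k}_g_comp{i}_uS")

    def stack(rows):
        return np.vstack(rows) if rows else np.zeros((0, nsteps))

    return (
        np.asarray(i_idx, dtype=np.int64),
        stack(i_rows),
        np.asarray(g_idx, dtype=np.int64),
        np.asarray(g_E, dtype=float),
        stack(g_rows),
        i_names,
        g_names,
    )


def simulate(
    cell: DiscretizedCell,
    protocol: Protocol,
    state: tuple[np.ndarray, GateState] | None = None,
    record_gates: bool = False,
    record_stride: int = 1,
) -> TraceSet:
    """Integrate the cable equation for one protocol.

    Parameters
    ----------
    state :
        Optional initial (V, gates).  By default the cell is first relaxed
        to its resting equilibrium (see :func:`equilibrium`), so stimuli
        start from steady state.
    record_stride :
        Keep every ``record_stride``-th sample (1 = full resolution).

    Raises
    ------
    SimulationError
        If the voltage becomes non-finite or leaves ±1000 mV.
    """
    ca = _cell_arrays(cell)
    if state is None:
        state = equilibrium(cell)
    V0, g0 = state
    V = np.array(V0, dtype=float)
    m = np.array(g0.m, dtype=float)
    h = np.array(g0.h, dtype=float)
    n = np.array(g0.n, dtype=float)
    dt = protocol.dt_ms
    nsteps = int(round(protocol.duration_ms / dt))
    n_samples = nsteps // record_stride + 1

    rec_idx = np.asarray(
        [cell.locate(sec, pos) for sec, pos in protocol.record], dtype=np.int64
    )
    i_idx, i_ts, g_idx, g_E, g_ts, i_names, g_names = _source_series(
        cell, protocol, nsteps
    )

    outV = np.empty((rec_idx.size, n_samples))
    outV[:, 0] = V[rec_idx]
    if record_gates:
        outm = np.empty_like(outV)
        outh = np.empty_like(outV)
        outn = np.empty_like(outV)
        outm[:, 0], outh[:, 0], outn[:, 0] = m[rec_idx], h[rec_idx], n[rec_idx]
    else:
        outm = outh = outn = np.empty((0, 0))

    nc = cell.n_comp
    status = _integrate(
        V, m, h, n, nsteps, dt,
        ca.c_nF / dt, ca.gL_uS, ca.EL, ca.gNa_uS, ca.ENa, ca.gK_uS, ca.EK,
        ca.kv_order,
        ca.vm_half, ca.km, ca.vh_half, ca.kh, ca.vn_half, ca.kn,
        1.0 - np.exp(-dt / ca.tau_m),
        1.0 - np.exp(-dt / ca.tau_h),
        1.0 - np.exp(-dt / ca.tau_n),
        ca.g_axial_uS,
        i_idx, i_ts, g_idx, g_E, g_ts,
        rec_idx, record_stride,
        outV, outm, outh, outn, record_gates,
        np.zeros(nc), np.zeros(nc), np.zeros(nc), np.zeros(nc),
    )
    if status >= 0:
        raise SimulationError(
            f"non-finite membrane potential at t = {(status + 1) * dt:.3f} ms"
        )

    time = np.arange(n_samples) * dt * record_stride
    sites = [
        (cell.section[i], float(cell.position_um[i])) for i in rec_idx
    ]
    stim: dict[str, np.ndarray] = {}
    sample_steps = np.arange(1, n_samples) * record_stride - 1
    for name, row in zip(i_names, i_ts):
        stim[name] = np.concatenate(([0.0], row[sample_steps]))
    for name, row in zip(g_names, g_ts):
        stim[name] = np.concatenate(([0.0], row[sample_steps]))

    gates = None
    if record_gates:
        gates = {"m": outm, "h": outh, "n": outn}
    return TraceSet(
        time_ms=time, sites=sites, V=outV, dt_ms=dt * record_stride,
        gates=gates, stim=stim,
        meta={"duration_ms": protocol.duration_ms, "dt_ms": dt,
              "record_stride": record_stride},
    )


def equilibrium(
    cell: DiscretizedCell, settle_ms: float = 300.0, dt_ms: float = 0.01
) -> tuple[np.ndarray, GateState]:
    """Resting state: relax the unstimulated cell from a uniform potential.

    300 ms is > 20 membrane time constants (Rm·Cm = 13.5 ms for the
    canonical passive parameters), ample for the slowest gate (τh = 1.8 ms)
    and the cable to settle.
    """
    ca = _cell_arrays(cell)
    V = np.full(cell.n_comp, ca.EL)
    g = _steady_gates(ca, V)
    nsteps = int(round(settle_ms / dt_ms))
    nc = cell.n_comp
    empty_i = np.zeros(0, dtype=np.int64)
    empty_ts = np.zeros((0, nsteps))
    outV = np.empty((0, nsteps + 1))
    e = np.empty((0, 0))
    status = _integrate(
        V, g.m, g.h, g.n, nsteps, dt_ms,
        ca.c_nF / dt_ms, ca.gL_uS, ca.EL, ca.gNa_uS, ca.ENa, ca.gK_uS, ca.EK,
        ca.kv_order,
        ca.vm_half, ca.km, ca.vh_half, ca.kh, ca.vn_half, ca.kn,
        1.0 - np.exp(-dt_ms / ca.tau_m),
        1.0 - np.exp(-dt_ms / ca.tau_h),
        1.0 - np.exp(-dt_ms / ca.tau_n),
        ca.g_axial_uS,
        empty_i, empty_ts, empty_i, np.zeros(0), empty_ts,
        empty_i, nsteps + 1,
        outV, e, e, e, False,
        np.zeros(nc), np.zeros(nc), np.zeros(nc), np.zeros(nc),
    )
    if status >= 0:
        raise SimulationError("resting-state relaxation diverged")
    return V, g


def steady_gradient(
    cell: DiscretizedCell,
    current_pA: float,
    site_um: float,
    settle_ms: float = 100.0,
    dt_us: float = 10.0,
) -> float:
    """Steady-state axial voltage gradient V(axon site) − V(soma), mV.

    A constant current is applied at the axonal site and the cell is
    simulated for ``settle_ms`` (default 100 ms, > 7 membrane time
    constants) before the gradient is read out.  The small standing
    gradient already present at rest (persistent Nav current flowing from
    the AIS to the soma) is subtracted, so the returned value is the
    current-induced gradient.  For sub-threshold currents at proximal
    sites this is Ohm's law, Ra·I, up to the small membrane leak along
    the path.
    """
    from .model import make_protocol

    if current_pA == 0.0:
        return 0.0
    syn = SynapseSpec(position_um=site_um, mode="fixed_current",
                      amplitude_pA=current_pA, kinetics="constant",
                      onset_ms=0.0)
    proto = make_protocol(
        cell.model, synapses=[syn], duration_ms=settle_ms, dt_us=dt_us,
        record=[("soma", 15.0), ("axon", site_um)],
    )
    traces = simulate(cell, proto, record_stride=10)
    diff = traces.trace("axon", site_um) - traces.trace("soma")
    return float(diff[-1] - diff[0])
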
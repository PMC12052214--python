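"""Spike-threshold measurement from voltage traces via the phase plot.

The action-potential threshold is operationalized as the voltage at the
inflexion point of the phase plot (dV/dt vs V), i.e. at a maximum of
d²V/dt².  Somatic phase plots of axonally-initiating neurons are bimodal:
the first mode is the arrival of the axonal spike, the second the somatic
regeneration.  ``mode='first'`` (the default) targets the first mode,
which is the quantity resistive-coupling theory makes predictions about.

Two regimes are handled explicitly:

* **Bimodal / kinked traces** (somatic recordings): the detector takes the
  first interior local maximum of d²V/dt² in the window ending where dV/dt
  first reaches half of its global maximum.
* **Smooth takeoff** (recordings at the initiation site itself, where the
  spike escape is a smooth exponential and d²V/dt² grows monotonically up
  the upstroke): there is no interior inflexion, and the onset is instead
  taken where dV/dt first departs from its pre-spike baseline by 25%.
  A dynamic measurement of this kind upper-bounds the quasi-static axonal
  threshold; see docs/methods.md.

Derivatives are centered finite differences on the raw uniform grid; no
smoothing is applied (the default 1 µs grid makes it unnecessary, and a
smoothing kernel would be an extra free parameter).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PhasePlot",
    "ThresholdResult",
    "phase_plot",
    "detect_threshold",
    "threshold_vs_probe_time",
    "soma_ais_gradient_at_onset",
]


@dataclass(frozen=True)
class PhasePlot:
    """Paired (V, dV/dt) samples of one trace, ordered in time."""

    V_mV: np.ndarray
    dVdt_mV_ms: np.ndarray
    time_ms: np.ndarray

    def local_maxima(self, min_dVdt: float = 0.0) -> np.ndarray:
        """Indices of interior local maxima of dV/dt above ``min_dVdt``."""
        d = self.dVdt_mV_ms
        i = np.flatnonzero((d[1:-1] > d[:-2]) & (d[1:-1] >= d[2:])) + 1
        return i[d[i] > min_dVdt]


def _check_uniform(time_ms: np.ndarray) -> float:
    dt = np.diff(time_ms)
    if dt.size == 0 or not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-12):
        raise ValueError("phase plot requires a uniform time grid")
    return float(dt[0])


def phase_plot(time_ms: np.ndarray, v_mV: np.ndarray) -> PhasePlot:
    """Phase plot of a trace; dV/dt by centered differences."""
    time_ms = np.asarray(time_ms, dtype=float)
    v_mV = np.asarray(v_mV, dtype=float)
    if v_mV.size < 3:
        raise ValueError("need at least 3 samples")
    _check_uniform(time_ms)
    dv = np.gradient(v_mV, time_ms)
    return PhasePlot(V_mV=v_mV, dVdt_mV_ms=dv, time_ms=time_ms)


@dataclass(frozen=True)
class ThresholdResult:
    """Outcome of threshold detection on one trace.

    ``spike`` is False when no AP was found (then ``reason`` says why and
    the remaining fields are NaN).  ``mode_used`` records which phase-plot
    mode was targeted; ``diagnostics`` carries the peak d²V/dt², dV/dt at
    threshold and the detector branch used ('inflexion' or 'departure').
    """

    V_star_mV: float
    t_star_ms: float
    spike: bool = True
    mode_used: str = "first"
    reason: str | None = None
    diagnostics: dict = field(default_factory=dict)


def _no_spike(reason: str) -> ThresholdResult:
    return ThresholdResult(np.nan, np.nan, spike=False, reason=reason)


def detect_threshold(
    time_ms: np.ndarray,
    v_mV: np.ndarray,
    mode: str = "first",
    spike_criterion_mV_ms: float = 10.0,
    window_ms: float = 3.0,
    t_min_ms: float | None = None,
    departure_fraction: float = 0.25,
) -> ThresholdResult:
    """Measure the AP threshold of a single-spike trace.

    Parameters
    ----------
    mode :
        'first' (default) targets the first phase-plot mode; 'global' takes
        the largest interior inflexion up to the AP peak (on bimodal somatic
        traces this can be the somatic regeneration).
    spike_criterion_mV_ms :
        A trace with max dV/dt below this value contains no AP and yields
        an explicit no-spike result.
    window_ms :
        Length of the search window ending where dV/dt first reaches half
        of its global maximum.
    t_min_ms :
        Ignore earlier samples (use to mask stimulus-onset kinks, e.g.
        probe onset + a fraction of a ms).
    departure_fraction :
        Fallback rule for smooth takeoffs: onset where dV/dt first exceeds
        (1 + fraction) × its pre-spike baseline (minimum over the window).
    """
    if mode not in ("first", "global"):
        raise ValueError(f"unknown mode {mode!r}")
    time_ms = np.asarray(time_ms, dtype=float)
    v_mV = np.asarray(v_mV, dtype=float)
    pp = phase_plot(time_ms, v_mV)
    dt = float(time_ms[1] - time_ms[0])
    dv = pp.dVdt_mV_ms
    M = float(np.max(dv))
    if M < spike_criterion_mV_ms:
        return _no_spike(f"max dV/dt = {M:.2f} mV/ms below spike criterion")

    i_half = int(np.argmax(dv >= M / 2.0))
    i_lo = max(0, i_half - int(round(window_ms / dt)))
    if t_min_ms is not None:
        i_lo = max(i_lo, int(np.searchsorted(time_ms, t_min_ms)))
    if mode == "global":
        i_hi = int(np.argmax(v_mV))  # up to the AP peak
    else:
        i_hi = i_half
    if i_hi - i_lo < 3:
        return _no_spike("search window too short")

    d2 = np.gradient(dv, time_ms)
    w = d2[i_lo:i_hi + 1]
    # interior local maxima of d2 (the phase-plot inflexions)
    cand = np.flatnonzero((w[1:-1] > w[:-2]) & (w[1:-1] >= w[2:])) + 1
    cand = cand[w[cand] > 0.05 * np.max(w)] if cand.size else cand

    if cand.size:
        j = cand[0] if mode == "first" else cand[np.argmax(w[cand])]
        i_star = i_lo + int(j)
        branch = "inflexion"
        # sub-sample refinement: parabola through the d² local maximum,
        # then interpolate V at the fractional peak time (matters on
        # coarse grids, where V moves fast near the inflexion)
        if 0 < i_star < time_ms.size - 1:
            y0, y1, y2 = d2[i_star - 1], d2[i_star], d2[i_star + 1]
            denom = y0 - 2.0 * y1 + y2
            if denom < 0:
                delta = float(np.clip(0.5 * (y0 - y2) / denom, -0.5, 0.5))
                t_star = time_ms[i_star] + delta * dt
                v_star = float(np.interp(t_star, time_ms, v_mV))
                return ThresholdResult(
                    V_star_mV=v_star, t_star_ms=float(t_star), spike=True,
                    mode_used=mode,
                    diagnostics={
                        "detector": branch,
                        "d2V_peak_mV_ms2": float(d2[i_lo:i_hi + 1].max()),
                        "dVdt_at_threshold_mV_ms": float(dv[i_star]),
                        "dVdt_max_mV_ms": M,
                    },
                )
    else:
        # smooth exponential takeoff (initiation site): departure of dV/dt
        # from its pre-spike baseline
        baseline = float(np.min(dv[i_lo:i_hi + 1]))
        above = np.flatnonzero(
            dv[i_lo:i_hi + 1] > (1.0 + departure_fraction) * max(baseline, 1e-9)
        )
        if above.size == 0:
            return _no_spike("no departure from baseline found")
        i_star = i_lo + int(above[0])
        branch = "departure"

    return ThresholdResult(
        V_star_mV=float(v_mV[i_star]),
        t_star_ms=float(time_ms[i_star]),
        spike=True,
        mode_used=mode,
        diagnostics={
            "detector": branch,
            "d2V_peak_mV_ms2": float(d2[i_lo:i_hi + 1].max()),
            "dVdt_at_threshold_mV_ms": float(dv[i_star]),
            "dVdt_max_mV_ms": M,
        },
    )


# ---------------------------------------------------------------------------
# Protocol-level helpers
# ---------------------------------------------------------------------------

def soma_ais_gradient_at_onset(traces, ais, onset_ms: float) -> float:
    """Mean AIS-minus-soma voltage gradient (mV) at a probe-onset time.

    ``traces`` must contain a somatic recording and at least three axonal
    recordings whose positions fall inside the AIS span; the gradient is
    the spatial mean of the AIS potentials minus the somatic potential,
    sampled just before ``onset_ms`` (i.e. with the synaptic source active
    and the probe still off).
    """
    ais_rows = [
        i for i, (sec, pos) in enumerate(traces.sites)
        if sec == "axon" and ais.start_um <= pos <= ais.end_um
    ]
    if len(ais_rows) < 3:
        raise ValueError("need recordings at >= 3 AIS sites")
    soma_rows = [i for i, (sec, _) in enumerate(traces.sites) if sec == "soma"]
    if not soma_rows:
        raise ValueError("need a somatic recording")
    k = int(np.searchsorted(traces.time_ms, onset_ms))
    k = min(max(k - 1, 0), traces.time_ms.size - 1)
    return float(np.mean(traces.V[ais_rows, k]) - traces.V[soma_rows[0], k])


def threshold_vs_probe_time(
    cell,
    synapse,
    probe,
    probe_times_ms,
    record_site: tuple[str, float] = ("soma", 15.0),
    tail_ms: float = 40.0,
    dt_us: float = 1.0,
    state=None,
    **detect_kwargs,
) -> pd.DataFrame:
    """Somatic threshold as a function of probe-pulse timing.

    One independent simulation per probe time: the synaptic source runs
    with its own onset while a copy of ``probe`` is delivered at each
    requested time; the threshold is detected on the recorded trace.
    No-spike runs appear as rows with ``spike = False`` and a reason.
    """
    import dataclasses

    from .model import make_protocol
    from .solver import equilibrium, simulate

    if state is None:
        state = equilibrium(cell)
    rows = []
    for t_probe in probe_times_ms:
        p = dataclasses.replace(probe, onset_ms=float(t_probe))
        proto = make_protocol(
            cell.model, pulses=[p], synapses=[synapse] if synapse else [],
            duration_ms=float(t_probe) + tail_ms, dt_us=dt_us,
            record=[record_site],
        )
        traces = simulate(cell, proto, state=state)
        res = detect_threshold(
            traces.time_ms, traces.V[0],
            t_min_ms=float(t_probe) + 0.3, **detect_kwargs,
        )
        rows.append({
            "probe_time_ms": float(t_probe),
            "V_star_mV": res.V_star_mV,
            "t_star_ms": res.t_star_ms,
            "spike": res.spike,
            "reason": res.reason,
        })
    return pd.DataFrame(rows)
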
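"""Closed-form resistive-coupling theory of axo-axonic inhibition.

The soma of a typical vertebrate neuron is a current sink for the thin
proximal axon, so the membrane potential between the soma and an axonal
current source varies ohmically: ΔV = Ra·I, with Ra the axial resistance
between the two sites.  A GABAergic synapse of conductance gs and reversal
EGABA on the proximal axon therefore shifts the somatic spike threshold by

    ΔV* = gs · Ra · (V* − EGABA)

where V* is the somatic threshold without the synapse and Ra is the axial
resistance from the soma to the synapse or to the middle of the axon
initial segment (AIS), whichever is closer.  The conductance additionally
shunts the spike, raising the axonal threshold by k·ln(1 + gs·Ra), with
k ≈ 5 mV the sodium-channel activation slope; the linear formula absorbs
this to first order because the somatic threshold sits k above the axonal
one.  Positive shifts mean reduced excitability.

Unit conventions: conductances in nS, resistances in MΩ, voltages in mV,
currents in pA, distances in µm, rates in Hz, times in ms.  Note that
nS × MΩ = 1e-3 (dimensionless) and pA × MΩ = 1e-3 mV.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

import pandas as pd

from .model import AISSpec

__all__ = [
    "TheoryPrediction",
    "CouplingResult",
    "axial_resistance_per_length",
    "coupling_resistance",
    "threshold_shift_linear",
    "threshold_shift_full",
    "psc_to_conductance",
    "mean_conductance",
    "estimate_ra_dual",
    "relative_efficacy",
    "aac_scenarios",
]


def axial_resistance_per_length(Ri_ohm_cm: float, d_um: float) -> float:
    """Axial resistance per unit length of a cylindrical axon, MΩ/µm.

    ra = 4·Ri/(π·d²).  With Ri = 100 Ω·cm and d = 1 µm this is
    1.27 MΩ/µm; over the physiological ranges Ri = 100–150 Ω·cm and
    d = 1–1.5 µm it spans 0.57–1.91 MΩ/µm.
    """
    if Ri_ohm_cm <= 0 or d_um <= 0:
        raise ValueError("Ri and d must be > 0")
    return 4.0 * Ri_ohm_cm * 1e-2 / (math.pi * d_um * d_um)


class CouplingResult(NamedTuple):
    Ra_MOhm: float
    effective_position_um: float


def coupling_resistance(
    ra_MOhm_per_um: float, x_syn_um: float, ais: AISSpec
) -> CouplingResult:
    """Axosomatic coupling resistance governing an axonal synapse.

    The effective electrical position of the synapse is the smaller of its
    anatomical distance and the AIS midpoint: synapses distal to the
    initiation zone cannot add leverage, so the coupling saturates there.
    """
    if x_syn_um < 0:
        raise ValueError("synapse position must be >= 0")
    x_eff = min(x_syn_um, ais.midpoint_um)
    return CouplingResult(ra_MOhm_per_um * x_eff, x_eff)


def threshold_shift_linear(
    gs_nS: float, Ra_MOhm: float, EGABA_mV: float, V_star_mV: float
) -> float:
    """First-order somatic threshold shift ΔV* = gs·Ra·(V* − EGABA), mV.

    Positive for EGABA below threshold (inhibitory: the threshold rises);
    negative when the reversal potential is above threshold.
    """
    if gs_nS < 0:
        raise ValueError("gs must be >= 0")
    return gs_nS * Ra_MOhm * 1e-3 * (V_star_mV - EGABA_mV)


@dataclass(frozen=True)
class TheoryPrediction:
    """Decomposed threshold-shift prediction.

    total_shift (relative to the no-synapse somatic threshold Va* + k) is
    the sum of the shunt term k·ln(1 + gs·Ra) and the ohmic term
    gs·Ra·(Va_thr − EGABA), where Va_thr is the shunt-corrected axonal
    threshold.  driving_force = Va_thr − EGABA.
    """

    Ra_MOhm: float
    effective_position_um: float
    shunt_shift_mV: float
    ohmic_shift_mV: float
    total_shift_mV: float
    driving_force_mV: float


def threshold_shift_full(
    gs_nS: float,
    Ra_MOhm: float,
    EGABA_mV: float,
    Va_star_mV: float,
    k_mV: float = 5.0,
    effective_position_um: float = float("nan"),
) -> TheoryPrediction:
    """Threshold shift including the logarithmic shunt correction.

    The synaptic conductance opposes the sodium conductance in parallel
    with the axial conductance 1/Ra, raising the axonal threshold from
    Va* to Va* + k·ln(1 + gs·Ra); the synaptic current at that voltage then
    adds the ohmic gradient gs·Ra·(Va_thr − EGABA).  For gs·Ra ≪ 1 the
    total reduces to :func:`threshold_shift_linear` with V* = Va* + k.
    """
    if gs_nS < 0:
        raise ValueError("gs must be >= 0")
    if k_mV <= 0:
        raise ValueError("k must be > 0")
    x = gs_nS * Ra_MOhm * 1e-3  # dimensionless gs·Ra
    shunt = k_mV * math.log1p(x)
    va_thr = Va_star_mV + shunt
    ohmic = x * (va_thr - EGABA_mV)
    return TheoryPrediction(
        Ra_MOhm=Ra_MOhm,
        effective_position_um=effective_position_um,
        shunt_shift_mV=shunt,
        ohmic_shift_mV=ohmic,
        total_shift_mV=shunt + ohmic,
        driving_force_mV=va_thr - EGABA_mV,
    )


def psc_to_conductance(I_peak_pA: float, V_hold_mV: float, EGABA_mV: float) -> float:
    """Peak synaptic conductance (nS) from a voltage-clamp PSC.

    g = |I / (EGABA − V_hold)|; e.g. a 50 pA PSC at −50 mV with
    EGABA = −70 mV gives 2.5 nS.
    """
    df = EGABA_mV - V_hold_mV
    if df == 0:
        raise ValueError("zero driving force (V_hold equals EGABA)")
    return abs(I_peak_pA / df)


def mean_conductance(n: float, F_Hz: float, g_peak_nS: float, tau_s_ms: float) -> float:
    """Mean conductance of n cells firing at F Hz: ⟨g⟩ = n·F·g·τs, nS."""
    if min(n, F_Hz, g_peak_nS, tau_s_ms) < 0:
        raise ValueError("all arguments must be >= 0")
    return n * F_Hz * g_peak_nS * tau_s_ms * 1e-3  # Hz × ms → dimensionless


def estimate_ra_dual(
    dV_bleb_mV: float, dV_soma_mV: float, x_um: float, I_pA: float
) -> float:
    """Axial resistance per length from dual soma-bleb recordings, MΩ/µm.

    ra = (ΔVbleb − ΔVsoma)/(x·I): a current step at the bleb produces an
    extra local polarization relative to the soma equal to the ohmic drop
    over the intervening axon.
    """
    if x_um <= 0:
        raise ValueError("electrode separation must be > 0")
    if I_pA == 0:
        raise ValueError("injected current must be nonzero")
    return (dV_bleb_mV - dV_soma_mV) / (x_um * I_pA) * 1e3


def relative_efficacy(R_in_MOhm: float, Ra_MOhm: float) -> float:
    """Efficacy of axonal relative to somatic inhibition, (R + Ra)/R.

    A current I at the soma moves the distance to threshold by R·I; the
    same current at the AIS moves it by (R + Ra)·I, because it also shifts
    the threshold itself by Ra·I.
    """
    if R_in_MOhm <= 0:
        raise ValueError("input resistance must be > 0")
    return (R_in_MOhm + Ra_MOhm) / R_in_MOhm


# Baseline single-cell/single-spike parameters for the in-vivo scenarios:
# one axo-axonic spike gives a ~50 pA PSC at −50 mV holding with juvenile
# EGABA = −70 mV (hence 2.5 nS); ~4 cells contact one AIS; τs = 20 ms decay;
# theta-rate firing 15 Hz; fast-spiking maximum 100 Hz.
_G_SINGLE_nS = psc_to_conductance(50.0, -50.0, -70.0)
_N_CELLS = 4
_TAU_S_MS = 20.0
_F_THETA_HZ = 15.0
_F_MAX_HZ = 100.0


def aac_scenarios(Ra_MOhm: float = 30.0, V_star_mV: float = -55.0) -> pd.DataFrame:
    """Order-of-magnitude threshold-shift estimates for axo-axonic input.

    Returns one row per scenario.  Spike rows (rate_Hz = NaN) give the peak
    shift of a single synchronous event, n·g·Ra·(V* − EGABA); tonic rows
    give the mean shift from ⟨g⟩ = n·F·g·τs, with the peak column assuming
    a periodic modulation of the conductance between 0 and 2⟨g⟩.

    Default Ra = 30 MΩ (ra ≈ 1 MΩ/µm over ~30 µm to the AIS midpoint in
    layer-5 pyramidal cells) and V* = −55 mV.
    """
    g = _G_SINGLE_nS
    rows = []

    def spike_row(name, n_cells, EGABA):
        shift = threshold_shift_linear(n_cells * g, Ra_MOhm, EGABA, V_star_mV)
        rows.append({
            "scenario": name, "n_cells": n_cells, "rate_Hz": float("nan"),
            "g_peak_per_cell_nS": g, "tau_s_ms": _TAU_S_MS, "EGABA_mV": EGABA,
            "V_star_mV": V_star_mV, "Ra_MOhm": Ra_MOhm,
            "mean_g_nS": float("nan"), "mean_shift_mV": float("nan"),
            "peak_shift_mV": shift,
        })

    def tonic_row(name, F, EGABA):
        mg = mean_conductance(_N_CELLS, F, g, _TAU_S_MS)
        mean_shift = threshold_shift_linear(mg, Ra_MOhm, EGABA, V_star_mV)
        rows.append({
            "scenario": name, "n_cells": _N_CELLS, "rate_Hz": F,
            "g_peak_per_cell_nS": g, "tau_s_ms": _TAU_S_MS, "EGABA_mV": EGABA,
            "V_star_mV": V_star_mV, "Ra_MOhm": Ra_MOhm,
            "mean_g_nS": mg, "mean_shift_mV": mean_shift,
            "peak_shift_mV": 2.0 * mean_shift,
        })

    spike_row("single_spike_juvenile", 1, -70.0)
    spike_row("single_spike_adult", 1, -90.0)
    spike_row("synchronous_discharge_adult", _N_CELLS, -90.0)
    tonic_row("theta_tonic_15Hz_adult", _F_THETA_HZ, -90.0)
    tonic_row("maximal_firing_100Hz_adult", _F_MAX_HZ, -90.0)
    return pd.DataFrame(rows)
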
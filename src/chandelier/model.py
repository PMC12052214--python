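"""Cell construction, spatial discretization and stimulation protocols.

The canonical cell is a simplified cortical pyramidal neuron used to study
action-potential initiation at the axon initial segment (AIS): a 1 mm
dendrite (6 µm diameter), a 30 µm soma and a 500 µm axon (1 µm diameter),
with Boltzmann-parameterized Nav and Kv1 channels.  Sodium and potassium
channel densities are high in the AIS (a configurable span of the proximal
axon) and much lower elsewhere, so that spikes initiate axonally and are
regenerated at the soma.

Interface units are the ones electrophysiologists use at the rig:
mV, ms, µm, pA/nA, nS, MΩ, Ω·cm, Ω·cm², µF/cm², S/m².  Conversion to a
consistent internal unit system is done by the solver, not by callers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
import yaml

__all__ = [
    "SectionSpec",
    "PassiveParams",
    "ChannelParams",
    "AISSpec",
    "SynapseSpec",
    "StimulusPulse",
    "CellModel",
    "DiscretizedCell",
    "Protocol",
    "build_canonical_model",
    "discretize",
    "make_protocol",
    "save_model",
    "load_model",
    "load_canonical_yaml",
]

_SECTION_NAMES = ("dendrite", "soma", "axon")
_REGIONS = ("soma", "AIS", "other")


@dataclass(frozen=True)
class SectionSpec:
    """One unbranched cylindrical section of the morphology."""

    name: str
    length_um: float
    diameter_um: float

    def __post_init__(self) -> None:
        if self.name not in _SECTION_NAMES:
            raise ValueError(f"unknown section name {self.name!r}")
        if not self.length_um > 0:
            raise ValueError("section length must be > 0")
        if not self.diameter_um > 0:
            raise ValueError("section diameter must be > 0")


@dataclass(frozen=True)
class PassiveParams:
    """Passive membrane and cytoplasm properties."""

    Rm_ohm_cm2: float = 15000.0  # specific membrane resistance
    EL_mV: float = -75.0         # leak reversal
    Ri_ohm_cm: float = 100.0     # intracellular resistivity
    Cm_uF_cm2: float = 0.9       # specific membrane capacitance

    def __post_init__(self) -> None:
        if not (self.Rm_ohm_cm2 > 0 and self.Ri_ohm_cm > 0 and self.Cm_uF_cm2 > 0):
            raise ValueError("Rm, Ri and Cm must be strictly positive")


@dataclass(frozen=True)
class ChannelParams:
    """Voltage-gated channel parameters of one membrane region.

    Nav gating is m·h (single-exponent activation and inactivation), so the
    activation slope ``km_mV`` is directly the excitability parameter k of
    resistive-coupling theory.  The Kv1 activation gate is raised to
    ``kv_order`` (default 8); with the broad single-gate Boltzmann
    (half-activation −70 mV, slope 20 mV) this places the effective
    half-activation of the open channel near −20 mV, as in delayed-rectifier
    models assembled from eight-state subunit kinetics.
    """

    region: str
    gNa_S_m2: float
    gK_S_m2: float
    ENa_mV: float = 70.0
    EK_mV: float = -90.0
    Vm_half_mV: float = -30.0
    Vh_half_mV: float = -55.0
    Vn_half_mV: float = -70.0
    km_mV: float = 5.0
    kh_mV: float = 5.0
    kn_mV: float = 20.0
    tau_m_ms: float = 0.054
    tau_h_ms: float = 1.8
    tau_n_ms: float = 1.0
    kv_order: int = 8

    def __post_init__(self) -> None:
        if self.region not in _REGIONS:
            raise ValueError(f"unknown region {self.region!r}")
        if min(self.km_mV, self.kh_mV, self.kn_mV) <= 0:
            raise ValueError("gating slopes must be > 0")
        if min(self.gNa_S_m2, self.gK_S_m2) < 0:
            raise ValueError("conductance densities must be >= 0")
        if min(self.tau_m_ms, self.tau_h_ms, self.tau_n_ms) <= 0:
            raise ValueError("gating time constants must be > 0")
        if self.kv_order < 1:
            raise ValueError("kv_order must be >= 1")


@dataclass(frozen=True)
class AISSpec:
    """Axon initial segment span, in µm from the soma-axon junction."""

    start_um: float
    end_um: float

    def __post_init__(self) -> None:
        if not (0 <= self.start_um < self.end_um):
            raise ValueError("AIS span must satisfy 0 <= start < end")

    @property
    def midpoint_um(self) -> float:
        return 0.5 * (self.start_um + self.end_um)

    @property
    def length_um(self) -> float:
        return self.end_um - self.start_um


@dataclass(frozen=True)
class SynapseSpec:
    """An axo-axonic synaptic source on the axon.

    position_um is measured from the soma-axon junction (0 = soma end of the
    axon).  Two source modes:

    * ``fixed_current`` — injects ``amplitude_pA`` directly (a current-clamp
      idealization of the synapse); negative amplitudes hyperpolarize.
    * ``conductance`` — a conductance ``gs_nS`` with reversal ``EGABA_mV``,
      contributing g(t)·(EGABA − V) locally.

    Kinetics are either ``constant`` (on from ``onset_ms`` to the end of the
    run) or ``exponential_decay`` (g or I jumps to its peak at onset and
    decays with ``tau_s_ms``).  With ``span_um`` > 0 a conductance synapse is
    distributed uniformly over [position − span/2, position + span/2],
    conserving the total conductance exactly at any grid resolution.
    """

    position_um: float
    mode: str = "fixed_current"
    amplitude_pA: float | None = None
    gs_nS: float | None = None
    EGABA_mV: float | None = None
    kinetics: str = "constant"
    tau_s_ms: float | None = None
    onset_ms: float = 0.0
    span_um: float = 0.0

    def __post_init__(self) -> None:
        if self.mode not in ("fixed_current", "conductance"):
            raise ValueError(f"unknown synapse mode {self.mode!r}")
        if self.kinetics not in ("constant", "exponential_decay"):
            raise ValueError(f"unknown synapse kinetics {self.kinetics!r}")
        if self.position_um < 0:
            raise ValueError("synapse position must be >= 0")
        if self.span_um < 0:
            raise ValueError("synapse span must be >= 0")
        if self.mode == "fixed_current":
            if self.amplitude_pA is None:
                raise ValueError("fixed_current synapse requires amplitude_pA")
        else:
            if self.gs_nS is None or self.EGABA_mV is None:
                raise ValueError("conductance synapse requires gs_nS and EGABA_mV")
            if self.gs_nS < 0:
                raise ValueError("gs_nS must be >= 0")
        if self.kinetics == "exponential_decay":
            if self.tau_s_ms is None or self.tau_s_ms <= 0:
                raise ValueError("exponential_decay requires tau_s_ms > 0")


@dataclass(frozen=True)
class StimulusPulse:
    """A square current pulse at an arbitrary site.

    ``site`` is (section name, position in µm from the proximal end of the
    section; for the axon that is the soma-axon junction, for the dendrite
    the soma-dendrite junction, and for the soma the value is ignored).
    """

    site: tuple[str, float]
    amplitude_nA: float
    onset_ms: float
    duration_ms: float

    def __post_init__(self) -> None:
        if self.site[0] not in _SECTION_NAMES:
            raise ValueError(f"unknown section {self.site[0]!r}")
        if not self.duration_ms > 0:
            raise ValueError("pulse duration must be > 0")


@dataclass(frozen=True)
class CellModel:
    """Morphology, passive properties, channels per region and AIS span."""

    sections: tuple[SectionSpec, ...]
    passive: PassiveParams
    channels: dict[str, ChannelParams]
    ais: AISSpec

    def __post_init__(self) -> None:
        names = [s.name for s in self.sections]
        if names.count("soma") != 1:
            raise ValueError("exactly one soma section required")
        for required in ("dendrite", "axon"):
            if required not in names:
                raise ValueError(f"missing section {required!r}")
        for region in _REGIONS:
            if region not in self.channels:
                raise ValueError(f"missing channel parameters for region {region!r}")
        if self.ais.end_um > self.section("axon").length_um:
            raise ValueError("AIS extends beyond the axon")

    def section(self, name: str) -> SectionSpec:
        for s in self.sections:
            if s.name == name:
                return s
        raise KeyError(name)

    # ---- serialization -------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "morphology": {
                s.name: {"length_um": s.length_um, "diameter_um": s.diameter_um}
                for s in self.sections
            },
            "passive": asdict(self.passive),
            "channels": {r: asdict(p) for r, p in self.channels.items()},
            "ais": {"start_um": self.ais.start_um, "end_um": self.ais.end_um},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CellModel":
        sections = tuple(
            SectionSpec(name, spec["length_um"], spec["diameter_um"])
            for name, spec in d["morphology"].items()
        )
        channels = {}
        for region, p in d["channels"].items():
            p = dict(p)
            p.setdefault("region", region)
            channels[region] = ChannelParams(**p)
        return cls(
            sections=sections,
            passive=PassiveParams(**d["passive"]),
            channels=channels,
            ais=AISSpec(**d["ais"]),
        )


def build_canonical_model(ais_start_um: float = 5.0, ais_end_um: float = 35.0) -> CellModel:
    """Build the canonical pyramidal-cell model.

    Morphology: 1 mm dendrite (6 µm), 30 µm soma (modeled as a single
    isopotential cylinder of length = diameter = 30 µm), 500 µm axon (1 µm).
    Passive: Rm = 15 000 Ω·cm², EL = −75 mV, Ri = 100 Ω·cm, Cm = 0.9 µF/cm².
    Channels: AIS gNa = 4000 S/m², gK = 1500 S/m² with Nav half-activation
    −35 mV and half-inactivation −60 mV; soma 250/250 S/m² with −30/−55 mV;
    dendrite and non-AIS axon 50/50 S/m² with the somatic half-voltages.
    Gating time constants are the physiological-temperature values
    (τm = 54 µs, τh = 1.8 ms, τn = 1 ms).

    Parameters
    ----------
    ais_start_um, ais_end_um :
        AIS span along the axon, µm from the soma.  Default 5–35 µm.
    """
    if not (0 <= ais_start_um < ais_end_um <= 500.0):
        raise ValueError("AIS span must satisfy 0 <= start < end <= 500 µm")
    common = dict(
        ENa_mV=70.0, EK_mV=-90.0, Vn_half_mV=-70.0,
        km_mV=5.0, kh_mV=5.0, kn_mV=20.0,
        tau_m_ms=0.054, tau_h_ms=1.8, tau_n_ms=1.0, kv_order=8,
    )
    channels = {
        "soma": ChannelParams(
            region="soma", gNa_S_m2=250.0, gK_S_m2=250.0,
            Vm_half_mV=-30.0, Vh_half_mV=-55.0, **common,
        ),
        "AIS": ChannelParams(
            region="AIS", gNa_S_m2=4000.0, gK_S_m2=1500.0,
            Vm_half_mV=-35.0, Vh_half_mV=-60.0, **common,
        ),
        # Dendrite and non-AIS axon: low densities, somatic half-voltages.
        "other": ChannelParams(
            region="other", gNa_S_m2=50.0, gK_S_m2=50.0,
            Vm_half_mV=-30.0, Vh_half_mV=-55.0, **common,
        ),
    }
    return CellModel(
        sections=(
            SectionSpec("dendrite", 1000.0, 6.0),
            SectionSpec("soma", 30.0, 30.0),
            SectionSpec("axon", 500.0, 1.0),
        ),
        passive=PassiveParams(),
        channels=channels,
        ais=AISSpec(ais_start_um, ais_end_um),
    )


# ---------------------------------------------------------------------------
# Discretization
# ---------------------------------------------------------------------------

def _ra_MOhm_per_um(Ri_ohm_cm: float, d_um: float) -> float:
    # 4 Ri / (pi d^2), converted from (Ohm cm, µm) to MΩ/µm
    return 4.0 * Ri_ohm_cm * 1e-2 / (math.pi * d_um * d_um)


@dataclass(frozen=True)
class DiscretizedCell:
    """Compartment chain dendrite → soma → axon.

    Compartment i is a cylinder of length ``length_um[i]`` centered at
    ``position_um[i]`` (µm from the proximal end of its section).
    ``axial_R_MOhm[i]`` is the internode resistance between compartments i
    and i+1 (half-cylinder resistances in series).  Dendritic compartments
    are ordered distal → proximal so that the chain is contiguous.
    """

    model: CellModel
    section: np.ndarray       # str per compartment
    position_um: np.ndarray   # center, µm from section's proximal end
    length_um: np.ndarray
    diameter_um: np.ndarray
    area_um2: np.ndarray      # lateral membrane area
    region: np.ndarray        # 'soma' | 'AIS' | 'other'
    axial_R_MOhm: np.ndarray  # length n-1

    @property
    def n_comp(self) -> int:
        return self.section.size

    @property
    def soma_index(self) -> int:
        return int(np.flatnonzero(self.section == "soma")[0])

    def locate(self, section: str, position_um: float = 0.0) -> int:
        """Index of the compartment whose center is nearest to a site."""
        sec = self.model.section(section)  # validates the name
        if not (0.0 <= position_um <= sec.length_um):
            raise ValueError(
                f"position {position_um} µm outside {section} "
                f"(length {sec.length_um} µm)"
            )
        mask = self.section == section
        idx = np.flatnonzero(mask)
        centers = self.position_um[mask]
        return int(idx[np.argmin(np.abs(centers - position_um))])

    def cumulative_axial_resistance(self, section: str, position_um: float) -> float:
        """Axial resistance (MΩ) from the soma compartment to a site."""
        i = self.soma_index
        j = self.locate(section, position_um)
        lo, hi = min(i, j), max(i, j)
        return float(np.sum(self.axial_R_MOhm[lo:hi]))

    def axon_centers(self) -> np.ndarray:
        return self.position_um[self.section == "axon"]


def discretize(
    model: CellModel,
    max_seg_axon_um: float = 2.5,
    max_seg_dendrite_um: float = 10.0,
) -> DiscretizedCell:
    """Discretize a cell into a compartment chain.

    The soma is always a single compartment.  Axon compartments are tagged
    as AIS iff their center lies within [ais.start, ais.end]; all dendritic
    and remaining axonal compartments use the 'other' channel set.
    """
    if not (max_seg_axon_um > 0 and max_seg_dendrite_um > 0):
        raise ValueError("segment length bounds must be > 0")

    sec_names, positions, lengths, diams, regions = [], [], [], [], []

    def add_section(spec: SectionSpec, max_seg: float, reverse: bool) -> None:
        n = max(1, math.ceil(spec.length_um / max_seg))
        seg = spec.length_um / n
        centers = (np.arange(n) + 0.5) * seg
        if reverse:
            centers = centers[::-1]
        for c in centers:
            sec_names.append(spec.name)
            positions.append(c)
            lengths.append(seg)
            diams.append(spec.diameter_um)
            if spec.name == "soma":
                regions.append("soma")
            elif spec.name == "axon" and (
                model.ais.start_um <= c <= model.ais.end_um
            ):
                regions.append("AIS")
            else:
                regions.append("other")

    # chain order: distal dendrite ... proximal dendrite, soma, proximal
    # axon ... distal axon
    add_section(model.section("dendrite"), max_seg_dendrite_um, reverse=True)
    soma = model.section("soma")
    sec_names.append("soma")
    positions.append(soma.length_um / 2)
    lengths.append(soma.length_um)
    diams.append(soma.diameter_um)
    regions.append("soma")
    add_section(model.section("axon"), max_seg_axon_um, reverse=False)

    length = np.asarray(lengths)
    diam = np.asarray(diams)
    area = math.pi * diam * length
    Ri = model.passive.Ri_ohm_cm
    half_R = 0.5 * length * np.array([_ra_MOhm_per_um(Ri, d) for d in diam])
    axial = half_R[:-1] + half_R[1:]

    return DiscretizedCell(
        model=model,
        section=np.asarray(sec_names, dtype=object),
        position_um=np.asarray(positions, dtype=float),
        length_um=length.astype(float),
        diameter_um=diam.astype(float),
        area_um2=area.astype(float),
        region=np.asarray(regions, dtype=object),
        axial_R_MOhm=axial.astype(float),
    )


# ---------------------------------------------------------------------------
# Protocols
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Protocol:
    """An immutable stimulation/recording protocol.

    ``record`` sites are (section, position µm) pairs; the solver snaps each
    to the nearest compartment center.  Default timestep is 1 µs.
    """

    pulses: tuple[StimulusPulse, ...]
    synapses: tuple[SynapseSpec, ...]
    duration_ms: float
    dt_ms: float
    record: tuple[tuple[str, float], ...]

    def to_dict(self) -> dict:
        return {
            "pulses": [asdict(p) | {"site": list(p.site)} for p in self.pulses],
            "synapses": [asdict(s) for s in self.synapses],
            "duration_ms": self.duration_ms,
            "dt_ms": self.dt_ms,
            "record": [list(site) for site in self.record],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Protocol":
        pulses = tuple(
            StimulusPulse(**(p | {"site": tuple(p["site"])})) for p in d["pulses"]
        )
        synapses = tuple(SynapseSpec(**s) for s in d["synapses"])
        record = tuple((sec, float(pos)) for sec, pos in d["record"])
        return cls(pulses, synapses, float(d["duration_ms"]), float(d["dt_ms"]), record)


def make_protocol(
    cell: CellModel,
    pulses: Sequence[StimulusPulse] = (),
    synapses: Sequence[SynapseSpec] = (),
    duration_ms: float = 100.0,
    dt_us: float = 1.0,
    record: Iterable[tuple[str, float]] = (("soma", 15.0),),
) -> Protocol:
    """Validate stimuli against the morphology and freeze a protocol."""
    if not duration_ms > 0:
        raise ValueError("duration must be > 0")
    if not dt_us > 0:
        raise ValueError("dt must be > 0")

    def check_site(section: str, pos: float, what: str) -> None:
        sec = cell.section(section)
        if not (0.0 <= pos <= sec.length_um):
            raise ValueError(
                f"{what} at {section} {pos} µm is outside the morphology "
                f"({section} length {sec.length_um} µm)"
            )

    for p in pulses:
        check_site(p.site[0], p.site[1], "stimulus pulse")
    axon_len = cell.section("axon").length_um
    for s in synapses:
        lo = s.position_um - s.span_um / 2
        hi = s.position_um + s.span_um / 2
        if lo < -1e-9 or hi > axon_len + 1e-9:
            raise ValueError(
                f"synapse span [{lo}, {hi}] µm outside the axon (0–{axon_len} µm)"
            )
    record = tuple((sec, float(pos)) for sec, pos in record)
    for sec, pos in record:
        check_site(sec, pos, "recording site")
    return Protocol(tuple(pulses), tuple(synapses), float(duration_ms),
                    float(dt_us) * 1e-3, record)


# ---------------------------------------------------------------------------
# Config files
# ---------------------------------------------------------------------------

def save_model(model: CellModel, path) -> None:
    with open(path, "w") as f:
        yaml.safe_dump(model.to_dict(), f, sort_keys=False)


def load_model(path) -> CellModel:
    with open(path) as f:
        return CellModel.from_dict(yaml.safe_load(f))


def load_canonical_yaml() -> CellModel:
    """Load the bundled canonical-parameter file (identical to
    :func:`build_canonical_model` defaults)."""
    ref = resources.files("chandelier").joinpath("data/canonical.yaml")
    with ref.open() as f:
        return CellModel.from_dict(yaml.safe_load(f))
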
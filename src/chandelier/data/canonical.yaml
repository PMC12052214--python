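# Canonical pyramidal-cell model: morphology, passive membrane, and
# Boltzmann-parameterized Nav/Kv1 channels per region (soma / AIS / other),
# with the AIS spanning 5-35 um of the proximal axon.
morphology:
  dendrite:
    length_um: 1000.0
    diameter_um: 6.0
  soma:
    length_um: 30.0
    diameter_um: 30.0
  axon:
    length_um: 500.0
    diameter_um: 1.0
passive:
  Rm_ohm_cm2: 15000.0
  EL_mV: -75.0
  Ri_ohm_cm: 100.0
  Cm_uF_cm2: 0.9
channels:
  soma:
    region: soma
    gNa_S_m2: 250.0
    gK_S_m2: 250.0
    ENa_mV: 70.0
    EK_mV: -90.0
    Vm_half_mV: -30.0
    Vh_half_mV: -55.0
    Vn_half_mV: -70.0
    km_mV: 5.0
    kh_mV: 5.0
    kn_mV: 20.0
    tau_m_ms: 0.054
    tau_h_ms: 1.8
    tau_n_ms: 1.0
    kv_order: 8
  AIS:
    region: AIS
    gNa_S_m2: 4000.0
    gK_S_m2: 1500.0
    ENa_mV: 70.0
    EK_mV: -90.0
    Vm_half_mV: -35.0
    Vh_half_mV: -60.0
    Vn_half_mV: -70.0
    km_mV: 5.0
    kh_mV: 5.0
    kn_mV: 20.0
    tau_m_ms: 0.054
    tau_h_ms: 1.8
    tau_n_ms: 1.0
    kv_order: 8
  other:
    region: other
    gNa_S_m2: 50.0
    gK_S_m2: 50.0
    ENa_mV: 70.0
    EK_mV: -90.0
    Vm_half_mV: -30.0
    Vh_half_mV: -55.0
    Vn_half_mV: -70.0
    km_mV: 5.0
    kh_mV: 5.0
    kn_mV: 20.0
    tau_m_ms: 0.054
    tau_h_ms: 1.8
    tau_n_ms: 1.0
    kv_order: 8
ais:
  start_um: 5.0
  end_um: 35.0
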
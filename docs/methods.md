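# Methods

## Model

The cell is an unbranched chain of three cylinders: a 1 mm dendrite
(6 µm diameter), a 30 µm soma, and a 500 µm axon (1 µm diameter). The
soma is one isopotential compartment modeled as a cylinder with length =
diameter = 30 µm (lateral area 2827 µm², the same as a 30 µm sphere);
only "a 30 µm soma" is specified by the underlying model, and the
cylinder convention keeps the chain topology uniform.

Passive membrane: Rm = 15 000 Ω·cm², Cm = 0.9 µF/cm², EL = −75 mV,
Ri = 100 Ω·cm. The membrane time constant is RmCm = 13.5 ms and the
axonal axial resistance per length is ra = 4Ri/(πd²) = 1.27 MΩ/µm.

Active currents per compartment:

    INa = gNa · m · h · (ENa − V)        ENa = +70 mV
    IK  = gK  · n⁸   · (EK  − V)        EK  = −90 mV

with Boltzmann steady states (x∞ = 1/(1+exp(±(V½−V)/k))) and
first-order relaxation at fixed time constants. Parameters:

| region              | gNa (S/m²) | gK (S/m²) | Vm½ (mV) | Vh½ (mV) |
|---------------------|-----------:|----------:|---------:|---------:|
| AIS (5–35 µm)       | 4000       | 1500      | −35      | −60      |
| soma                | 250        | 250       | −30      | −55      |
| dendrite, distal axon | 50       | 50        | −30      | −55      |

Slopes km = kh = 5 mV, kn = 20 mV with Vn½ = −70 mV; time constants
τm = 54 µs, τh = 1.8 ms, τn = 1 ms (physiological-temperature values).
The non-AIS regions reuse the somatic half-voltages, the
lowest-surprise completion of a table that lists only soma and AIS rows.

Two deliberate gating choices:

* **Nav gates are single-power (m·h).** The theory identifies the Nav
  activation slope k = km = 5 mV directly with the logarithmic
  sensitivity of the threshold, which holds only for exponent 1.
* **The Kv1 activation gate is n⁸.** With the broad single-gate
  Boltzmann printed above, a first-power gate would be half-open at
  −70 mV: the model then rests near −90 mV with a few-MΩ effective
  input resistance and the canonical 1 nA/5 ms probe cannot reach
  threshold — none of the phenomenology exists. The eighth power (the
  standard composition of eight independent subunit gates, as in axonal
  Kv1 models) puts the effective half-activation of the open channel
  near −22 mV; the cell then rests at −74.3 mV, has a ~60 MΩ input
  resistance, and spikes with the canonical probe, with the bimodal
  somatic phase plot characteristic of axonal initiation. `kv_order`
  is an explicit `ChannelParams` field.

## Numerics

Spatial discretization: compartments of ≤ 2.5 µm on the axon and
≤ 10 µm on the dendrite (full mode). Internode resistances are the sum
of half-cylinder axial resistances, so the cumulative resistance from
the soma to an axonal compartment center at x equals ra·x exactly (plus
the negligible 0.02 MΩ somatic half-resistance); this is verified to 1%
against the closed form in the tests.

Time integration is operator-split: gates advance by their exact
exponential relaxation toward x∞(V) (unconditionally within [0,1]),
then the voltage advances by backward Euler, a single tridiagonal
(Thomas) solve per step — unconditionally stable on a chain. Synaptic
conductances enter the voltage step implicitly (added to the matrix
diagonal), so arbitrarily strong shunts cannot destabilize it.
Default dt = 1 µs; halving it moves the measured somatic threshold by
< 0.01 mV. The inner loop is numba-compiled; a scipy `solve_ivp` (BDF)
integration of the identical ODE system is used as an independent
cross-check in the test suite (sub-threshold traces agree to < 0.05 mV
RMS; somatic thresholds to < 0.1 mV).

Simulations start from the resting equilibrium obtained by relaxing the
unstimulated cell for 300 ms (> 20 membrane time constants). Protocols
with a steady synaptic source keep it on for 80 ms before the threshold
probe. "Steady state" readouts subtract the pre-stimulus baseline: the
AIS carries a standing +0.3 mV gradient at rest from persistent Nav
current, which is not part of the synaptically induced gradient.

**Problem sizes.** Full mode (dt = 1 µs, 2.5 µm axonal compartments,
301 compartments) is used by `scripts/acceptance.py` and the
command-line pipelines. The test suite runs the same sweeps in a
scaled-down mode: dt = 2 µs with 5 µm axonal compartments
(151 compartments). 2 µs rather than a coarser step because near spike
commitment the somatic voltage rises ~0.1 mV/µs: at 10 µs the detected
threshold is quantized at the mV level and sweep fits degrade, while at
2 µs every qualitative and tolerance outcome matches full mode.

## Threshold measurement

The spike threshold is the voltage at the inflexion of the phase plot
(dV/dt vs V), i.e. at a maximum of d²V/dt², computed with centered
differences on the raw grid (no smoothing — the grid is fine enough, and
a kernel would be an unreported free parameter). Two regimes:

* **Somatic traces** are bimodal: the first d²V/dt² mode is the arrival
  of the axonal spike, the second the somatic regeneration. The
  detector takes the *first interior local maximum* of d²V/dt² in the
  window ending where dV/dt first reaches half of its global maximum,
  with parabolic sub-sample refinement. A plain argmax over that window
  would land mid-upstroke (≈ −31 mV instead of ≈ −57.5 mV) because
  d²V/dt² keeps growing into the somatic regeneration.
* **Initiation-site traces** (AIS recordings) take off as a smooth
  exponential: d²V/dt² has no interior maximum before the upstroke, so
  there is no inflexion to find. The fallback defines onset as the
  point where dV/dt first departs from its pre-spike baseline by 25%.
  Any dynamic measurement of this kind upper-bounds the quasi-static
  axonal threshold; with this convention the somatic-minus-axonal
  threshold difference is 4.1 mV, consistent with the theoretical
  offset k ≈ 5 mV.

Stimulus onsets produce one-sample d²V/dt² spikes; callers mask them by
passing `t_min_ms` (probe onset + 0.3 ms). Traces whose spike occurs
only after the probe ends are flagged as no-threshold rows rather than
measured. Translation invariance (V* shifts exactly with a DC offset of
the trace) is a tested property.

## What the sweeps show — and a known measurement bias

The experiment pipelines pair every simulated sweep with its
closed-form prediction. The resistive-coupling physics itself is clean:
sub-threshold axial gradients match Ohm's law (Ra·I) to a few percent
once the resting baseline is subtracted, profiles between soma and
injection site are linear with R² > 0.99, and the somatic response to
axonal current injection equals that to somatic injection within 5%.

For *threshold* sweeps the agreement depends on where along the somatic
upstroke the threshold is read:

* The somatic potential **at axonal commitment** (when dV/dt at the AIS
  midpoint first exceeds 20 mV/ms; reported as `V_commit_mV` in every
  sweep table) shifts with synaptic current/conductance at 1.0–1.1×
  the prediction gs·Ra·(V*−EGABA), and reverses sign exactly where
  EGABA crosses the measured threshold.
* The **phase-plot threshold** (`V_star_mV`), read ~0.2 ms later at the
  first-mode inflexion, shifts at only ~0.7–0.85× the prediction, and
  Nav inactivation masks the sign reversal at g = 5 nS. The deficit
  accumulates between commitment and the inflexion: the somatic
  excursion over that interval varies systematically with the baseline
  polarization (stronger axonal spikes from hyperpolarized baselines,
  plus the somatic-sink inactivation effect that the somatic-current
  control sweep isolates). The independent BDF integration reproduces
  the same numbers, so this is model behavior, not solver error.

Proximal synapses (anatomical position below the AIS midpoint) are the
regime where the point-synapse theory is exact, and there the phase-plot
threshold itself rises at ra·|I| per µm within 10%. Synapses at or past
the midpoint sit at the knee of the saturation, where the extended AIS
averages the delivered gradient.

Consequences for the acceptance properties: the slope-style checks tied
to the phase-plot threshold at the AIS midpoint (slope within 20% of
ra × midpoint distance, unit slope against the mean AIS gradient,
20% agreement of the conductance sweep, and the EGABA sign reversal)
fail at the ~0.7–0.85 level described above and are intentionally left
failing rather than re-tuned; the same relations hold at the
commitment marker and are asserted there in the unit tests.

## Synthetic inputs and their limits

All inputs are generated by the model factory: there is no external
data. Synapses are either ideal current sources (constant or
single-exponential decay, τs = 20 ms for the kinetics experiment — the
measured decay of chandelier-cell PSCs) or conductances with a reversal
potential; distributed synapses spread a fixed total conductance
uniformly over the AIS span, conserving it exactly at any grid. Real
axo-axonic input differs in ways the model deliberately omits: discrete
bouton placement, receptor saturation and synaptic depression, chloride
accumulation shifting EGABA dynamically, channel noise, and branched
morphology. Passing tests therefore validate the resistive-coupling
mechanism and its parameter dependence, not quantitative transfer to
any particular real neuron.

## Other conventions and limitations

* Units at every interface: mV, ms, µm, pA/nA, nS, MΩ; conversions are
  internal to the solver.
* Synapse and recording positions snap to the nearest compartment
  center; theory columns use the snapped position.
* "Middle of the AIS" is the arithmetic midpoint of the span.
* The probe is 1 nA for 5 ms (0.7 nA for the kinetics experiment).
  Near-rheobase probes give thresholds within 1 mV of each other, but
  across the wider 0.7–1.5 nA range the measured threshold varies by
  ~2.5 mV (dynamic-threshold physics: the approach speed changes the
  inflexion point); sweeps always hold the probe fixed.
* Temperature is not a runtime parameter: the corrected time constants
  are baked in. Voltage-dependent time constants, stochastic channels,
  myelin, branched morphologies and extracellular potentials are out of
  scope.
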
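# Methods

## The model

`gapasym` simulates pairs of thalamic reticular nucleus (TRN) neurons
coupled by electrical synapses (gap junctions, GJs) and asks how asymmetry
of transmission — unequal coupling in the two directions as measured
between somas — arises from, and is masked by, intrinsic cellular
properties: the dendritic location of the junction, its strength and
directional conductances, input-resistance differences, and internal
dendritic conductance.

Each compartment is an isopotential Hodgkin–Huxley patch:

    C_m dV_i/dt = G_leak (E_leak − V_i)
                + Σ_channels g_max · m^p h^q · (E_ion − V_i)
                + Σ_synapses G_syn(t) (E_syn − V_i)
                + Σ_gap-junctions G_elec,ji (V_j − V_i)
                + Σ_internal G_internal,ji (V_j − V_i)
                + I_inj(t)

Two cell models are provided (`gapasym.cell`):

* **single-compartment**: NaT 60.5, Kd 60, Kt 5, K2 0.5, AR 0.025,
  CaT 0.75 mS/cm²; C_m 1 µF/cm²; leak 0.1 mS/cm² at −75 mV.
* **three-compartment** (soma S, middle M, distal D dendrite): soma NaT
  60.5, Kd 90, Kt 5, K2 0.5, AR 0.005, CaT 0.5; dendrites carry no NaT and
  CaT 0.15; leak 0.1 (soma) / 0.035 (dendrites); C_m 1.2 µF/cm²; internal
  conductances 0.4 (M–S) and 0.35 (D–M) mS/cm².

Reversal potentials: Na +50, K −100, Ca +125, AR −40, leak −75 mV.
Compartments are unit-area patches, so conductance densities (mS/cm²) and
current densities (µA/cm²) are used as absolute quantities in one
consistent unit system; no membrane areas enter anywhere.

Electrical synapses carry two independent directional conductances: the
current into endpoint b is `g_ab (V_a − V_b)` and into a is
`g_ba (V_b − V_a)`. A symmetric junction conserves charge instantaneously;
an asymmetric one injects a net `(g_ab − g_ba)(V_a − V_b)` per unit time.
Throughout, `Gc_12` denotes transmission from cell 1 into cell 2 and the
G_c ratio is `Gc_12/Gc_21`.

## Channel kinetics and their calibration

Maximal conductances and reversals are fixed by the parameter tables above,
but the gating rate equations are a modelling choice, assembled in
`gapasym/kinetics.py` from the standard TRN lineage: Traub–Miles-style
alpha/beta functions for NaT and Kd, a Destexhe-style T-current (m²h,
36 °C rates), Huguenard–McCormick-style A-current (Kt) and
anomalous-rectifier (AR) kinetics, and a slowly inactivating K2 with
high-threshold Traub-style activation.

The voltage positions of the Na and Kd curves (`NA_OFFSET = −74 mV`,
`KD_OFFSET = −62 mV`) and the Na-inactivation rate factor (`PHI_H = 2`)
were calibrated once, against the operating regimes that the measurement
protocols presuppose, and then frozen:

* rest is stable and quiescent at zero drive (all protocols start from
  rest);
* constant drives of 0.575 and 0.6 µA/cm² elicit regular, full-overshoot
  tonic firing, the larger drive giving the shorter interspike interval
  (the synchrony protocol);
* hyperpolarizing steps evoke no spikes (the coupling protocol);
* distal EPSC bursts with a 0.5 µA/cm² somatic holding current evoke
  somatic spikes, and the holding current alone does not (the latency
  protocol).

These constraints are unusually tight: the tonic drives lift the soma only
~4–5 mV above rest, so spike ignition must sit within a few millivolts of
a still-stable resting state. Separating the Na and Kd offsets (so the
delayed rectifier engages during the upstroke rather than below threshold)
is what makes that window attainable; the K2 activation slope is sharpened
(17 → 10 mV) so its activation tail does not act as a spurious adaptation
current near −65 mV. Spike threshold in the calibrated model is near
−66 mV, rest near −71.5 mV (single-compartment) and −73.8 mV
(three-compartment somas), and tonic rates at the synchrony drives are
~29/30 Hz.

All subthreshold results (coupling coefficients, asymmetry ratios, R_in
manipulations, geometry effects) are governed by the printed passive
parameters and are insensitive to these kinetic choices — which is exactly
what the passive-oracle gate (below) certifies. Spike-dependent results
(latency, synchrony) do depend on them; see *Known limitations*.

## Numerical scheme

Fixed-step midpoint (second-order Runge–Kutta) integration, default
`dt = 0.01 ms`. Gating variables are clamped to [0, 1] after each step.
Halving `dt` moves final-state voltages of a coupled subthreshold run by
less than 10⁻³ mV (asserted in the test suite), and the acceptance-level
quantities are dt-stable at this step. Integration starts from the resting
fixed point found by integrating the stimulus-free model for 500 ms;
sweep runners cache and reuse this state per cell configuration.
Simulations are fully deterministic: identical inputs give bit-identical
traces, and mirror-symmetric relabelings of the two cells mirror the
outputs exactly (also asserted).

Spike detection uses upward crossings of 0 mV with a 2-ms refractory
merge; the calibrated spikes overshoot +25 mV, so counts are insensitive
to the threshold over at least −20 to +10 mV (asserted).

## Measurement protocols

**Coupling coefficients.** A 500-ms, −0.5 µA/cm² square pulse into one
cell; deflection = (mean V over the last 200 ms of the pulse) − (mean over
a 200-ms pre-pulse baseline); cc_AB = ΔV_B/ΔV_A at matched compartments;
asymmetry = cc_12/cc_21 from two runs. The amplitude is a protocol
parameter: cc is amplitude-independent in the linear regime (asserted at
−0.25 vs −0.5 to within 1 %). Both window means are corrected by
subtracting a cached stimulus-free control run: the AR conductance
relaxes over seconds, and without the correction its residual drift after
any finite settling time leaks into the windows (an uncoupled pair would
show cc ≈ 0.01 instead of exactly 0). A spike during the pulse aborts the
measurement with an error.

**Input resistance.** Same pulse and windows on a single cell;
R_in = ΔV/I in mV per µA/cm². Scaling all leak conductances by
0.75–1.45 changes somatic R_in of the three-compartment cell by
approximately ±25 %, reproducing the printed bracket (measured factors
0.763 and 1.410 for exactly ±25 %). Because the map factor → ΔR_in is not
linear, experiments that require a stated ΔR_in invert it by bisection to
0.1 %. A `soma_only` switch restricts leak scaling to the soma for
sensitivity checks; the default scales all compartments.

**Burst latency.** 13 EPSCs (peak 1 µA/cm², 5-ms intervals) onto each
distal dendrite through a peak-normalized difference-of-exponentials
waveform (rise 5 ms, fall 35 ms), with a constant 0.5 µA/cm² somatic
holding current; latency is the time from a cell's first EPSC to its first
somatic spike. EPSC events are injected as current densities by default
(consistent with the µA/cm² unit of their printed amplitude); a
conductance-based variant (`mode="conductance"`, amplitudes converted at
the resting driving force to E_syn = 0) is provided. Latency modulation is
`(lat₁ − lat₁ᵘⁿᶜ) − (lat₂ − lat₂ᵘⁿᶜ)`, the between-cell difference of the
change in latency relative to an uncoupled reference; positive values mean
coupling delayed cell 1 more than cell 2. Each cell's uncoupled reference
uses the same holding duration as the coupled run, so the slow-conductance
state at burst onset is matched. Conditions without a spike are flagged
and excluded from sweep tables.

**Synchrony.** The single-compartment pair at drives 0.575/0.6 µA/cm²;
after discarding a 1.5-s transient, spike trains from a 500-ms window are
binarized on the integration grid, smoothed with a 5-ms Hanning window,
and cross-correlated. The phase difference is
`t_max_lag / ISI × 360°`, wrapped to [−180°, 180°], where `t_max_lag` is
the lag of the correlogram peak nearest zero (peaks below half the
correlogram maximum are ignored as ripple; exact ties break toward the
non-negative lag) and ISI is cell 1's mean interval in the window. If the
ISI drifts more than 5 % across the window, the window is shifted later
once. A Pearson-normalized correlogram is available; normalization cannot
move the peak lag, so the phase is unchanged (asserted). Rates are deemed
converged when the two ISIs agree within 2 %.

## The analytic oracle

With channels zeroed the steady state solves the linear nodal system
`G ΔV = I`; `gapasym.analytic_oracle` builds and solves it directly
(asymmetric junctions give an asymmetric matrix). This is the central
correctness gate for the subthreshold results: across the passive
location × strength × R_in × geometry grids, simulated cc and cc ratios
agree with the nodal solution to better than 0.5 % (acceptance test), and
textbook cases (two-cell cc = g/(g+g_leak); weak-coupling cc ratio → the
directional conductance ratio) are verified in closed form.

## The stimulus generator as the synthetic-data stand-in

No external data enter anywhere: the stimulus module *is* the data
generator, and its defaults are the study conditions — the 500-ms
hyperpolarizing step, the 13-event burst with holding current, and the
0.575/0.6 µA/cm² tonic pair. What it deliberately does not emulate:
synaptic noise, naturalistic input statistics, or trial-to-trial
variability (the model is deterministic). Passing tests therefore
certify the mechanistic claims about coupling, asymmetry and timing under
clean, repeatable stimulation, not robustness of those effects to
biological variability.

## Sweep design and problem sizes

The packaged sweep grids cover the full experimental design at desk
scale: the G_c axis
defaults to 0.01–0.25 mS/cm² in 0.01 steps (bracketing every printed
anchor, 0.005–0.2, with 0.15 the reference), R_in changes span ±25 % in
5 % steps, internal-conductance factors 0.8–1.2, directional ratios
0.3–3, burst-onset differences ±30 ms in 2-ms steps, and the synchrony
map uses Gc_21 ∈ {0.005, 0.0125, 0.025}. The test suite and the
acceptance script run representative sub-grids of these (e.g., four G_c
values × all nine location pairs × 31 onset differences for the latency
maximum) so that the whole suite completes in minutes on one CPU; the CLI
runs the full grids.

## Design choices where the design was open

* **cc-step amplitude** (−0.5 µA/cm²) is unprinted; linearity is asserted
  rather than assumed.
* **Baseline window**: the 200 ms immediately before pulse onset,
  matching the steady-state window length.
* **EPSCs as currents**: the printed event amplitude is in µA, and all
  other drives are current densities; the conductance-based reading is
  kept as a switch. With current-based events the distal EPSP is still
  sublinear above 2 µA (via potassium recruitment), as required.
* **Latency-difference sign**: cell 1 minus cell 2 (of the changes vs
  uncoupled), exposed in output headers.
* **Phase ISI**: cell 1's mean ISI; at the convergence points where phase
  is reported the two ISIs agree to <2 %, making the choice immaterial.
* **Leak scaling scope**: all compartments by default (`soma_only`
  available).

## Known limitations

* **Gating kinetics are reconstructed, not transcribed**: only maximal
  conductances and reversals are fixed by the parameter tables. All
  subthreshold quantities are certified against the kinetics-independent
  passive oracle, but spike-dependent quantities inherit the kinetic
  choices.
* **Strong-coupling anti-phase synchrony is not reproduced.** In this
  implementation the symmetric pair at Gc = 0.025 mS/cm² locks *in-phase*
  (|phase| ≈ 9°), and the locking is unique (anti-phase-seeded initial
  conditions converge to it). Phase-response analysis shows why: at the
  near-rheobase tonic drives, the T-current amplifies any depolarizing
  gap-junction transient arriving during the interspike ramp into a large
  phase advance (advance lobe ~20 ms against a delay lobe <0.5 ms), so
  spikelet-triggered synchronization dominates at every coupling strength
  explored. The rate-convergence threshold (between 0.002 and
  0.005 mS/cm²) and the direction of the asymmetry effect (G_c ratio > 1,
  favoring transmission from the slower cell, moves the phase toward 0°;
  ratio < 1 moves it away) are reproduced.
* Dendrites are three lumped compartments, not cables; networks larger
  than two cells, synaptic plasticity, gap-junction voltage gating and
  calcium dynamics are out of scope.
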
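# gapasym

Compartmental Hodgkin–Huxley models of electrically coupled thalamic
reticular nucleus (TRN) neurons, built to study **asymmetry of electrical
synapses**: why current often flows more effectively in one direction
across a gap junction (GJ) than the other, as measured between somas, and
what that does to spike timing and synchrony.

The package is for computational neuroscientists who want a tested,
scriptable version of this class of two-cell experiments: single- and
three-compartment (soma / middle / distal dendrite) TRN cells, gap
junctions with independent directional conductances, AMPAergic event
trains, a fixed-step RK2 integrator, and the three measurement protocols
used to quantify the effects.

## The quantities at the core

* **Coupling coefficient**: inject a 500-ms hyperpolarizing step into
  cell A, record both cells, and form `cc_AB = ΔV_B / ΔV_A` from the
  steady-state deflections (last 200 ms of the pulse vs pre-pulse
  baseline).
* **Asymmetry**: `cc ratio = cc_12 / cc_21` from the two injection
  directions. A symmetric junction between identical cells gives exactly 1;
  junction location along the dendrite, input-resistance (R_in)
  differences, internal dendritic conductance, and directional junction
  conductances (`Gc_12 ≠ Gc_21`) each move it away from 1 — or cancel each
  other, masking a truly asymmetric junction.
* **Latency modulation**: with burst-like EPSC input to both distal
  dendrites, the between-cell difference in the change of first-spike
  latency relative to an uncoupled cell.
* **Phase of synchrony**: for two tonically firing coupled cells, the lag
  of the Hanning-filtered spike-train cross-correlogram peak nearest zero,
  as a phase `t_lag / ISI × 360°`.

An analytic resistor-network oracle (`gapasym.analytic_oracle`) solves the
passive steady state in closed form and certifies every subthreshold
simulation result to <0.5 %.

## Worked example

```python
from gapasym import make_three_compartment_trn
from gapasym.experiments import pair_model
from gapasym.measurements import measure_coupling, measure_input_resistance

cell = make_three_compartment_trn()
print(f"somatic input resistance: {measure_input_resistance(cell):.2f} mV per uA/cm2")

# junction between the soma of cell 1 and the middle dendrite of cell 2
m = measure_coupling(pair_model(cell, cell, "S", "M", 0.15))
print(f"cc_12 = {m.cc_12:.4f}")
print(f"cc_21 = {m.cc_21:.4f}")
print(f"cc ratio = {m.cc_ratio:.4f}")
```

prints

```
somatic input resistance: 5.75 mV per uA/cm2
cc_12 = 0.3756
cc_21 = 0.3248
cc ratio = 1.1565
```

The junction is perfectly symmetric (0.15 mS/cm² both ways) and the cells
are identical, yet somatic coupling is ~16 % stronger from cell 1 to
cell 2: the junction sits right on cell 1's soma but one compartment away
from cell 2's, so the two injection directions see different dendritic
loads. That is *effective* asymmetry from location alone — the central
phenomenon the package quantifies.

## Experiment sweeps

Each parameter sweep is a function in `gapasym.experiments`
returning a tidy DataFrame, and a CLI subcommand writing CSV plus a JSON
run manifest:

```bash
gapasym location-grid --out results/    # cc ratio vs junction location and strength
gapasym rin-sweep --out results/        # x input-resistance mismatch
gapasym geometry-sweep --out results/   # x internal dendritic conductance
gapasym gcratio-sweep --out results/    # directional-conductance asymmetry
gapasym masking-isoclines --out results/  # six configs producing cc ratio ~1.2 / ~0.8
gapasym latency --out results/          # burst-latency modulation
gapasym synchrony --out results/        # tonic-firing phase map
gapasym oracle-check --out results/     # passive analytic cross-validation
```

## Layout

```
src/gapasym/
  kinetics.py        # gating rate equations (the editable kinetics block)
  channels.py        # channel specs and currents
  cell.py            # single- and three-compartment TRN parameter sets
  synapses.py        # gap junctions, AMPAergic event trains
  stimuli.py         # the step / burst / tonic protocol generators
  engine.py          # RK2 integrator, spike detection
  analytic_oracle.py # passive nodal-network closed-form solver
  measurements.py    # the three measurement protocols
  experiments.py     # sweep runners
  cli.py, plots.py   # command line and minimal plotting helpers
```
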
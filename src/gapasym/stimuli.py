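"""Stimulus protocol generators.

Three protocols drive every experiment in the package:

* a 500-ms hyperpolarizing square step into one soma (coupling-coefficient
  measurement),
* a burst of 13 AMPAergic EPSCs (1 uA/cm^2 peak, 5-ms inter-event interval)
  onto a distal dendrite with a 0.5 uA/cm^2 depolarizing holding current at
  the soma (latency protocol),
* a pair of constant tonic drives, I1 = 0.575 and I2 = 0.6 uA/cm^2, onto two
  single-compartment cells (synchrony protocol).

All waveforms are pure functions of their parameter tuples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .synapses import EventTrain

#: Defaults of the coupling-coefficient step protocol.
CC_STEP_AMPLITUDE = -0.5  # uA/cm^2
CC_STEP_DURATION = 500.0  # ms

#: Defaults of the burst protocol.
BURST_N_EVENTS = 13
BURST_ISI = 5.0  # ms
BURST_AMPLITUDE = 1.0  # uA/cm^2 peak per event
BURST_HOLDING = 0.5  # uA/cm^2 at the soma

#: Tonic drives of the synchrony protocol, uA/cm^2.
TONIC_I1 = 0.575
TONIC_I2 = 0.6


@dataclass(frozen=True)
class StimulusProtocol:
    """A current-injection waveform aimed at one (cell, compartment).

    ``kind`` is "step" (square pulse), "tonic" (constant drive for the whole
    simulation), or "burst_holding" (the constant soma drive of the burst
    protocol; the synaptic events ride separately as an EventTrain).
    """

    kind: str
    target: tuple[int, str]
    amplitude: float  # uA/cm^2
    onset: float = 0.0  # ms
    duration: float | None = None  # ms; None = until end of simulation

    def __post_init__(self):
        if self.kind not in ("step", "tonic", "burst_holding"):
            raise ValueError(f"unknown stimulus kind {self.kind!r}")
        if self.duration is not None and not self.duration > 0:
            raise ValueError("duration must be positive")

    def waveform(self, t: np.ndarray) -> np.ndarray:
        """Evaluate the injected current (uA/cm^2) on a time grid (ms)."""
        t = np.asarray(t, dtype=float)
        out = np.zeros_like(t)
        if self.duration is None:
            mask = t >= self.onset
        else:
            mask = (t >= self.onset) & (t < self.onset + self.duration)
        out[mask] = self.amplitude
        return out


def make_cc_step(
    target: tuple[int, str],
    amplitude: float = CC_STEP_AMPLITUDE,
    onset: float = 200.0,
    duration: float = CC_STEP_DURATION,
) -> StimulusProtocol:
    """The 500-ms hyperpolarizing step used to measure coupling coefficients.

    The amplitude is a protocol parameter rather than a printed constant;
    coupling coefficients are amplitude-independent in the subthreshold
    linear regime, which the measurement suite verifies rather than assumes.
    """
    if amplitude > 0:
        raise ValueError("cc step must be hyperpolarizing (amplitude <= 0)")
    return StimulusProtocol("step", target, amplitude, onset, duration)


def make_burst(
    cell: int,
    onset: float,
    n_events: int = BURST_N_EVENTS,
    isi: float = BURST_ISI,
    amplitude: float = BURST_AMPLITUDE,
    holding: float = BURST_HOLDING,
) -> tuple[StimulusProtocol, EventTrain]:
    """Burst protocol for one cell: EPSC train to the distal dendrite plus a
    constant depolarizing holding current at the soma.

    Returns the holding-current protocol and the event train (13 events, 5-ms
    spacing, unit amplitude by default); attach the train to the distal
    compartment via a ChemicalSynapse.
    """
    train = EventTrain.regular(onset, n_events, isi, amplitude)
    hold = StimulusProtocol("burst_holding", (cell, "S"), holding)
    return hold, train


def make_tonic_pair(
    i1: float = TONIC_I1, i2: float = TONIC_I2
) -> tuple[StimulusProtocol, StimulusProtocol]:
    """Constant drives for the two single-compartment cells of the synchrony
    protocol (cell 2 is driven slightly faster by default)."""
    return (
        StimulusProtocol("tonic", (0, "S"), i1),
        StimulusProtocol("tonic", (1, "S"), i2),
    )
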
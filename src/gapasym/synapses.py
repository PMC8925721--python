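"""Electrical synapses with independent directional conductances, and
AMPAergic synaptic event trains.

Electrical synapses (gap junctions) are static conductances applied to the
voltage difference between the coupled compartments.  Asymmetry is expressed
by giving each transmission direction its own conductance: the current
injected into endpoint b is ``g_ab * (V_a - V_b)`` and the current into a is
``g_ba * (V_b - V_a)``.  A symmetric junction (g_ab == g_ba) conserves
charge at every instant; an asymmetric one does not, with per-step imbalance
``(g_ab - g_ba) * (V_a - V_b)``.

AMPAergic inputs are event trains convolved with a peak-normalized
difference-of-exponentials waveform (rise 5 ms, fall 35 ms, reversal 0 mV).
By default events are injected as currents (uA/cm^2), the reading consistent
with the model's other current-density drives; a conductance-based variant
is available via ``mode="conductance"``, where the event amplitude is
converted to a peak conductance using the nominal driving force at rest.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: AMPA reversal potential, mV.
E_AMPA = 0.0
#: Nominal resting potential used to convert current amplitudes to peak
#: conductances in conductance mode, mV.
V_REST_NOMINAL = -75.0


@dataclass(frozen=True)
class ElectricalSynapse:
    """A gap junction between two (cell, compartment) endpoints.

    ``g_ab`` is the conductance governing transmission a -> b (current into
    b driven by V_a - V_b); ``g_ba`` governs b -> a.  Units mS/cm^2.
    """

    endpoint_a: tuple[int, str]
    endpoint_b: tuple[int, str]
    g_ab: float
    g_ba: float

    def __post_init__(self):
        if self.g_ab < 0 or self.g_ba < 0:
            raise ValueError("gap-junction conductances must be non-negative")

    @property
    def symmetric(self) -> bool:
        return self.g_ab == self.g_ba

    @property
    def g_ratio(self) -> float:
        """Directional conductance ratio g_ab / g_ba (requires g_ba > 0)."""
        if self.g_ba <= 0:
            raise ZeroDivisionError("g_ratio undefined for g_ba == 0")
        return self.g_ab / self.g_ba


def gj_currents(
    syn: ElectricalSynapse, v_a: float, v_b: float
) -> tuple[float, float]:
    """(current into a, current into b) in uA/cm^2 for the given potentials."""
    return syn.g_ba * (v_b - v_a), syn.g_ab * (v_a - v_b)


@dataclass(frozen=True)
class EventTrain:
    """Synaptic event onsets (ms, strictly increasing) with amplitudes."""

    times: tuple[float, ...]
    amplitudes: tuple[float, ...]

    def __post_init__(self):
        if len(self.times) != len(self.amplitudes):
            raise ValueError("times and amplitudes must have equal length")
        if any(b <= a for a, b in zip(self.times, self.times[1:])):
            raise ValueError("event times must be strictly increasing")

    @classmethod
    def regular(cls, onset: float, n_events: int, isi: float,
                amplitude: float = 1.0) -> "EventTrain":
        times = tuple(onset + k * isi for k in range(n_events))
        return cls(times, (amplitude,) * n_events)

    def shifted(self, delta: float) -> "EventTrain":
        return EventTrain(tuple(t + delta for t in self.times), self.amplitudes)

    def to_csv(self, path) -> None:
        np.savetxt(path, np.column_stack([self.times, self.amplitudes]),
                   delimiter=",", header="time_ms,amplitude", comments="")

    @classmethod
    def from_csv(cls, path) -> "EventTrain":
        arr = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
        return cls(tuple(arr[:, 0]), tuple(arr[:, 1]))


@dataclass(frozen=True)
class ChemicalSynapse:
    """An AMPAergic input onto one (cell, compartment) target.

    ``mode`` selects how event amplitudes are applied: ``"current"`` injects
    the waveform directly as a current density; ``"conductance"`` converts
    each amplitude to a peak conductance via the nominal resting driving
    force and applies ``g(t) * (e_syn - V)``.
    """

    target: tuple[int, str]
    events: EventTrain
    e_syn: float = E_AMPA
    tau_rise: float = 5.0
    tau_fall: float = 35.0
    mode: str = "current"

    def __post_init__(self):
        if not (self.tau_fall > self.tau_rise > 0):
            raise ValueError("require tau_fall > tau_rise > 0")
        if self.mode not in ("current", "conductance"):
            raise ValueError("mode must be 'current' or 'conductance'")


def _waveform_norm(tau_rise: float, tau_fall: float) -> float:
    """Peak value of exp(-t/tau_fall) - exp(-t/tau_rise) over t >= 0."""
    t_peak = (tau_rise * tau_fall / (tau_fall - tau_rise)) * np.log(tau_fall / tau_rise)
    return np.exp(-t_peak / tau_fall) - np.exp(-t_peak / tau_rise)


def syn_conductance(syn: ChemicalSynapse, t) -> np.ndarray | float:
    """Summed event waveform at time(s) t (ms).

    Each event contributes a difference of exponentials normalized so its
    peak equals the event amplitude; the result is zero before the first
    event and non-negative everywhere.
    """
    t = np.asarray(t, dtype=float)
    if not np.all(np.isfinite(t)):
        raise ValueError("time must be finite")
    norm = _waveform_norm(syn.tau_rise, syn.tau_fall)
    out = np.zeros_like(t)
    for t0, amp in zip(syn.events.times, syn.events.amplitudes):
        dt = t - t0
        mask = dt >= 0
        if np.any(mask):
            d = dt[mask]
            out[mask] += (amp / norm) * (
                np.exp(-d / syn.tau_fall) - np.exp(-d / syn.tau_rise)
            )
    return out if out.ndim else float(out)
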
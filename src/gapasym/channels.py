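"""Voltage-gated current descriptions for the TRN membrane model.

Six currents are modelled: fast transient Na+ (NaT), delayed-rectifier K+
(Kd), fast transient A-type K+ (Kt), slowly inactivating K+ (K2), slow
anomalous rectifier (AR, h-current), and low-threshold transient Ca2+ (CaT).
Each is a Hodgkin-Huxley conductance ``g_max * prod(gates**exponents)``
driving the membrane toward its reversal potential.  The voltage dependence
of the gates lives in :mod:`gapasym.kinetics`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import kinetics
from .kinetics import CHANNEL_GATES, GATE_NAMES, N_GATES

CHANNEL_NAMES = ("NaT", "Kd", "Kt", "K2", "AR", "CaT")

#: Default reversal potentials (mV): Na +50, K -100, Ca +125, AR -40.
DEFAULT_EREV = {
    "NaT": 50.0,
    "Kd": -100.0,
    "Kt": -100.0,
    "K2": -100.0,
    "AR": -40.0,
    "CaT": 125.0,
}

#: Gate indices (into the GATE_NAMES state vector) owned by each channel.
CHANNEL_GATE_INDICES = {
    name: tuple(i for i, _ in CHANNEL_GATES[name]) for name in CHANNEL_NAMES
}


@dataclass(frozen=True)
class ChannelSpec:
    """One voltage-gated conductance on a compartment.

    Parameters
    ----------
    name:
        One of ``CHANNEL_NAMES``.
    g_max:
        Maximal conductance density, mS/cm^2.
    e_rev:
        Reversal potential, mV.  Defaults to the standard value for the
        channel's permeant ion.
    """

    name: str
    g_max: float
    e_rev: float | None = None

    def __post_init__(self):
        if self.name not in CHANNEL_NAMES:
            raise ValueError(f"unknown channel {self.name!r}")
        if not (self.g_max >= 0.0):
            raise ValueError(f"g_max must be >= 0, got {self.g_max}")
        if self.e_rev is None:
            object.__setattr__(self, "e_rev", DEFAULT_EREV[self.name])
        if not np.isfinite(self.e_rev):
            raise ValueError("e_rev must be finite")

    @property
    def gating_exponents(self) -> tuple[tuple[str, int], ...]:
        """(gate name, integer power) pairs for this channel."""
        return tuple((GATE_NAMES[i], p) for i, p in CHANNEL_GATES[self.name])


@dataclass
class GatingState:
    """Values of the ten gating variables, each in [0, 1]."""

    values: np.ndarray = field(default_factory=lambda: np.zeros(N_GATES))

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (N_GATES,):
            raise ValueError(f"expected {N_GATES} gating values")
        if np.any((self.values < 0) | (self.values > 1)):
            raise ValueError("gating variables must lie in [0, 1]")

    def __getitem__(self, gate: str) -> float:
        return float(self.values[GATE_NAMES.index(gate)])

    @classmethod
    def at_voltage(cls, v: float) -> "GatingState":
        """Steady-state gating at a fixed membrane potential."""
        xinf, _ = kinetics.rates_at(v)
        return cls(xinf)


def steady_state_and_tau(
    channel: ChannelSpec, v: float
) -> tuple[dict[str, float], dict[str, float]]:
    """Steady-state values and time constants of a channel's gates at v.

    Returns two dicts keyed by gate name; x_inf values lie in [0, 1] and all
    time constants are positive (both in ms).
    """
    xinf, tau = kinetics.rates_at(v)
    idx = CHANNEL_GATE_INDICES[channel.name]
    return (
        {GATE_NAMES[i]: float(xinf[i]) for i in idx},
        {GATE_NAMES[i]: float(tau[i]) for i in idx},
    )


def channel_current(channel: ChannelSpec, state: GatingState, v: float) -> float:
    """Current density (uA/cm^2) carried by one channel.

    Sign convention: positive values depolarize (contribute positively to
    C_m dV/dt), i.e. the current is ``g * (e_rev - v)``.
    """
    g = channel.g_max
    for i, p in CHANNEL_GATES[channel.name]:
        g *= state.values[i] ** p
    return g * (channel.e_rev - v)
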
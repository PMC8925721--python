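"""Gating-variable rate equations for the six TRN membrane currents.

This file is the single source of truth for channel kinetics.  The cell and
network models fix only maximal conductances and reversal potentials; the
voltage dependence of activation/inactivation lives here, in one editable
block of constants plus one rate function per current, so alternate kinetics
can be swapped without touching the integrator.

Provenance of the functional forms (standard TRN modelling lineage):

* ``NaT`` (transient Na+) and ``Kd`` (delayed rectifier): Traub-Miles-style
  alpha/beta rate functions, each evaluated in its own voltage-offset frame.
* ``CaT`` (low-threshold transient Ca2+): Destexhe-style T-current for
  reticular neurons (m^2 h, 36 degC rates).
* ``AR`` (slow anomalous rectifier, h-current): single activation gate with
  Huguenard-McCormick-style time constant.
* ``Kt`` (fast transient A-type K+): Huguenard-McCormick-style kinetics.
* ``K2`` (slowly inactivating K+): high-threshold activation with slow
  inactivation, Traub-style.

The offsets ``NA_OFFSET`` and ``KD_OFFSET`` place the spiking apparatus on
the voltage axis.  They are calibrated once so that the cell operates in the
regimes the measurement protocols assume: a stable, quiescent rest at zero
drive; regular tonic firing at the 0.575/0.6 uA/cm^2 synchrony drives with
the higher drive giving the shorter interspike interval; full-overshoot
action potentials; and no firing during hyperpolarizing coupling steps.
See docs/methods.md.  All voltages mV, times ms, rates 1/ms.
"""

from __future__ import annotations

import math

import numpy as np

try:  # pragma: no cover - exercised implicitly by the engine
    from numba import njit
except ImportError:  # pragma: no cover
    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def wrap(f):
            return f

        return wrap


# --------------------------------------------------------------------------
# Kinetic constants (the human-editable configuration block)
# --------------------------------------------------------------------------

#: Voltage offset (mV) of the Na rate functions (evaluated at v - offset).
#: Positions spike ignition a few mV above rest: the low-rheobase TRN
#: operating point.
NA_OFFSET = -74.0

#: Voltage offset (mV) of the delayed-rectifier rate functions.  Less
#: negative than NA_OFFSET so that Kd engages during the spike upstroke
#: rather than below threshold.
KD_OFFSET = -62.0

#: Temperature-like factor on the Na-inactivation rates (folded in, not a
#: user parameter).  Keeps inactivation slow enough for full spike
#: overshoot when ignition starts from slowly rising depolarizations.
PHI_H = 2.0

#: Ca_T activation: half-activation (mV) and slope (mV).
CAT_M_HALF, CAT_M_SLOPE = -52.0, 7.4
#: Ca_T inactivation: half-inactivation (mV) and slope (mV).
CAT_H_HALF, CAT_H_SLOPE = -80.0, 5.0

#: AR activation: half-activation (mV) and slope (mV).
AR_HALF, AR_SLOPE = -75.0, 5.5

#: K_t (A-type) activation/inactivation midpoints and slopes (mV).
KT_M_HALF, KT_M_SLOPE = -60.0, 8.5
KT_H_HALF, KT_H_SLOPE = -78.0, 6.0

#: K_2 (slowly inactivating K) midpoints and slopes (mV); activation
#: positioned well above rest so K2 shapes spiking, not the resting state.
K2_M_HALF, K2_M_SLOPE = -10.0, 10.0
K2_H_HALF, K2_H_SLOPE = -58.0, 10.6

#: Gating-state vector layout used throughout the package.
GATE_NAMES = (
    "NaT_m", "NaT_h", "Kd_n", "Kt_m", "Kt_h",
    "K2_m", "K2_h", "AR_m", "CaT_m", "CaT_h",
)
N_GATES = len(GATE_NAMES)

#: Per-channel gate indices and integer exponents: channel current is
#: g_max * prod(gate[i]**p) * (e_rev - v).
CHANNEL_GATES = {
    "NaT": ((0, 3), (1, 1)),
    "Kd": ((2, 4),),
    "Kt": ((3, 4), (4, 1)),
    "K2": ((5, 1), (6, 1)),
    "AR": ((7, 1),),
    "CaT": ((8, 2), (9, 1)),
}


@njit(cache=True)
def _vtrap(x: float, y: float) -> float:
    """x / (exp(x / y) - 1) with the removable singularity at x = 0 filled."""
    if abs(x / y) < 1e-6:
        return y * (1.0 - x / (2.0 * y))
    return x / (math.exp(x / y) - 1.0)


@njit(cache=True)
def gate_rates(v: float, xinf: np.ndarray, tau: np.ndarray) -> None:
    """Fill steady states and time constants for all gates at potential v.

    ``xinf`` and ``tau`` are length-``N_GATES`` float64 buffers, ordered as
    ``GATE_NAMES``.
    """
    # NaT m (Traub-Miles alpha/beta in the Na offset frame)
    u = v - NA_OFFSET
    am = 0.32 * _vtrap(13.0 - u, 4.0)
    bm = 0.28 * _vtrap(u - 40.0, 5.0)
    xinf[0] = am / (am + bm)
    tau[0] = 1.0 / (am + bm)
    # NaT h
    ah = PHI_H * 0.128 * math.exp((17.0 - u) / 18.0)
    bh = PHI_H * 4.0 / (1.0 + math.exp((40.0 - u) / 5.0))
    xinf[1] = ah / (ah + bh)
    tau[1] = 1.0 / (ah + bh)
    # Kd n (Traub-Miles alpha/beta in the Kd offset frame)
    w = v - KD_OFFSET
    an = 0.032 * _vtrap(15.0 - w, 5.0)
    bn = 0.5 * math.exp((10.0 - w) / 40.0)
    xinf[2] = an / (an + bn)
    tau[2] = 1.0 / (an + bn)
    # Kt m, h (A-type)
    xinf[3] = 1.0 / (1.0 + math.exp(-(v - KT_M_HALF) / KT_M_SLOPE))
    tau[3] = 0.27 / (math.exp((v + 35.8) / 19.7) + math.exp(-(v + 79.7) / 12.7)) + 0.1
    xinf[4] = 1.0 / (1.0 + math.exp((v - KT_H_HALF) / KT_H_SLOPE))
    if v < -63.0:
        tau[4] = 0.27 / (math.exp((v + 46.0) / 5.0) + math.exp(-(v + 238.0) / 37.5))
    else:
        tau[4] = 19.0
    # K2 m, h (slowly inactivating)
    xinf[5] = 1.0 / (1.0 + math.exp(-(v - K2_M_HALF) / K2_M_SLOPE))
    tau[5] = 0.27 / (math.exp((v + 81.0) / 25.6) + math.exp(-(v + 132.0) / 18.0)) + 9.9
    xinf[6] = 1.0 / (1.0 + math.exp((v - K2_H_HALF) / K2_H_SLOPE))
    tau[6] = 0.27 / (math.exp((v + 1329.0) / 200.0) + math.exp(-(v + 130.0) / 7.1)) + 120.0
    # AR m (h-current)
    xinf[7] = 1.0 / (1.0 + math.exp((v - AR_HALF) / AR_SLOPE))
    tau[7] = 1.0 / (math.exp(-14.59 - 0.086 * v) + math.exp(-1.87 + 0.0701 * v))
    # CaT m, h (T-current)
    xinf[8] = 1.0 / (1.0 + math.exp(-(v - CAT_M_HALF) / CAT_M_SLOPE))
    tau[8] = 0.44 + 0.15 / (math.exp((v + 27.0) / 10.0) + math.exp(-(v + 102.0) / 15.0))
    xinf[9] = 1.0 / (1.0 + math.exp((v - CAT_H_HALF) / CAT_H_SLOPE))
    tau[9] = 22.7 + 0.27 / (math.exp((v + 48.0) / 4.0) + math.exp(-(v + 407.0) / 50.0))


def rates_at(v: float) -> tuple[np.ndarray, np.ndarray]:
    """Python-facing wrapper: (x_inf, tau) arrays ordered as GATE_NAMES."""
    if not np.isfinite(v):
        raise ValueError(f"membrane potential must be finite, got {v!r}")
    xinf = np.empty(N_GATES)
    tau = np.empty(N_GATES)
    gate_rates(float(v), xinf, tau)
    return xinf, tau


def kinetics_table() -> dict[str, float]:
    """Snapshot of the kinetic constants, for run manifests and docs."""
    return {
        "NA_OFFSET": NA_OFFSET, "KD_OFFSET": KD_OFFSET, "PHI_H": PHI_H,
        "CAT_M_HALF": CAT_M_HALF, "CAT_M_SLOPE": CAT_M_SLOPE,
        "CAT_H_HALF": CAT_H_HALF, "CAT_H_SLOPE": CAT_H_SLOPE,
        "AR_HALF": AR_HALF, "AR_SLOPE": AR_SLOPE,
        "KT_M_HALF": KT_M_HALF, "KT_M_SLOPE": KT_M_SLOPE,
        "KT_H_HALF": KT_H_HALF, "KT_H_SLOPE": KT_H_SLOPE,
        "K2_M_HALF": K2_M_HALF, "K2_M_SLOPE": K2_M_SLOPE,
        "K2_H_HALF": K2_H_HALF, "K2_H_SLOPE": K2_H_SLOPE,
    }
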
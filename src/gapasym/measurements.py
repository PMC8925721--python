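"""The three measurement protocols: coupling coefficients and asymmetry,
burst-latency modulation, and spike-train phase synchrony.

Coupling protocol
-----------------
A 500-ms hyperpolarizing square current is injected into one compartment of
cell A; the steady-state deflection is the mean voltage over the last 200 ms
of the pulse minus the mean over the 200-ms pre-pulse baseline.  The
coupling coefficient is cc_AB = dV_B / dV_A, measured at the same
compartment of both cells, and the asymmetry ratio is cc_12 / cc_21 from
two separate runs.  The protocol requires subthreshold responses; a spike
during the pulse raises :class:`SpikeContaminationError`.

Latency protocol
----------------
Both cells receive a 13-event EPSC burst (5-ms spacing) at the distal
dendrite with a 0.5 uA/cm^2 soma holding current; latency is the time from
each cell's first EPSC to its first somatic spike.  Latency modulation is
the between-cell difference of the change in latency relative to an
uncoupled reference cell:

    latency_difference = (lat_1 - lat_uncoupled_1) - (lat_2 - lat_uncoupled_2)

Synchrony protocol
------------------
Two tonically firing single-compartment cells; spike trains from a 500-ms
stable window are binarized on the simulation grid, smoothed with a 5-ms
Hanning window, and cross-correlated.  The lag of the correlogram peak
nearest zero, expressed as a fraction of the interspike interval, gives the
phase difference: phase = t_max_lag / ISI * 360, mapped to [-180, 180].
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import correlate, find_peaks

from .cell import CellParams, cell_to_dict, scale_leak
from .engine import (
    NetworkModel,
    SimulationConfig,
    SimulationResult,
    detect_spikes,
    resting_state,
    simulate,
)
from .stimuli import make_burst, make_cc_step
from .synapses import ChemicalSynapse

#: Protocol timing (ms): pre-pulse baseline, pulse length, post-pulse tail.
CC_BASELINE = 200.0
CC_PULSE = 500.0
CC_TAIL = 50.0
#: Steady-state averaging window: last 200 ms of the pulse.
CC_STEADY = 200.0

#: Membrane potential above which a "subthreshold" protocol is considered
#: spike-contaminated (mV).
SPIKE_GUARD = -20.0

DEFAULT_DT = 0.01
DEFAULT_SETTLE = 500.0


class SpikeContaminationError(RuntimeError):
    """A protocol that requires subthreshold responses evoked a spike."""


# --------------------------------------------------------------------------
# Resting-state cache (sweeps revisit identical cells hundreds of times)
# --------------------------------------------------------------------------

_REST_CACHE: dict[str, tuple[np.ndarray, np.ndarray]] = {}


def _rest_for(model: NetworkModel, dt: float, settle: float):
    key = json.dumps(
        {
            "cells": [cell_to_dict(c) for c in model.cells],
            "gj": [
                (s.endpoint_a, s.endpoint_b, s.g_ab, s.g_ba)
                for s in model.electrical_synapses
            ],
            "dt": dt,
            "settle": settle,
        },
        sort_keys=True,
    )
    if key not in _REST_CACHE:
        quiet = NetworkModel(
            cells=model.cells, electrical_synapses=model.electrical_synapses
        )
        _REST_CACHE[key] = resting_state(quiet, dt=dt, settle_time=settle)
    v, g = _REST_CACHE[key]
    return v.copy(), g.copy()


def clear_rest_cache() -> None:
    _REST_CACHE.clear()
    _CONTROL_CACHE.clear()
    _UNCOUPLED_LATENCY_CACHE.clear()


# --------------------------------------------------------------------------
# Coupling coefficients
# --------------------------------------------------------------------------

@dataclass
class CouplingMeasurement:
    cc_12: float
    cc_21: float
    dv_injected_12: float  # dV in cell 1 when injecting into cell 1 (mV)
    dv_coupled_12: float  # dV in cell 2 for the same run (mV)
    dv_injected_21: float
    dv_coupled_21: float
    measurement_site: str

    @property
    def cc_ratio(self) -> float:
        return self.cc_12 / self.cc_21


def _window_means(res: SimulationResult, onset: float, pulse: float):
    """Per-compartment means over the baseline and steady-state windows."""
    t = res.t
    base = res.v[:, (t >= onset - CC_BASELINE) & (t < onset)].mean(axis=1)
    steady = res.v[
        :, (t >= onset + pulse - CC_STEADY) & (t < onset + pulse)
    ].mean(axis=1)
    return base, steady


_CONTROL_CACHE: dict[str, tuple[np.ndarray, np.ndarray]] = {}


def _control_means(model: NetworkModel, dt: float, settle: float):
    """Window means of a stimulus-free control run, for drift correction.

    The slow AR conductance settles over seconds, so a small residual drift
    survives any finite settling time; subtracting a control run removes it
    from the deflection estimates exactly.
    """
    key = json.dumps(
        {
            "cells": [cell_to_dict(c) for c in model.cells],
            "gj": [
                (s.endpoint_a, s.endpoint_b, s.g_ab, s.g_ba)
                for s in model.electrical_synapses
            ],
            "drives": [
                (p.target, p.kind, p.amplitude, p.onset, p.duration)
                for p in model.injected_currents
            ],
            "dt": dt,
            "settle": settle,
        },
        sort_keys=True,
    )
    if key not in _CONTROL_CACHE:
        rest = _rest_for(model, dt, settle)
        cfg = SimulationConfig(
            dt=dt, duration=CC_BASELINE + CC_PULSE + CC_TAIL, settle_time=0.0
        )
        res = simulate(model, cfg, initial_state=rest)
        _CONTROL_CACHE[key] = _window_means(res, CC_BASELINE, CC_PULSE)
    return _CONTROL_CACHE[key]


def _cc_one_direction(
    model: NetworkModel,
    source_cell: int,
    site: str,
    amplitude: float,
    dt: float,
    settle: float,
) -> tuple[float, float]:
    """(dV_injected, dV_coupled) for a pulse into ``source_cell`` at ``site``."""
    other = 1 - source_cell
    step = make_cc_step((source_cell, site), amplitude, onset=CC_BASELINE)
    stim_model = NetworkModel(
        cells=model.cells,
        electrical_synapses=model.electrical_synapses,
        injected_currents=list(model.injected_currents) + [step],
    )
    rest = _rest_for(model, dt, settle)
    cfg = SimulationConfig(
        dt=dt, duration=CC_BASELINE + CC_PULSE + CC_TAIL, settle_time=0.0
    )
    res = simulate(stim_model, cfg, initial_state=rest)
    pulse_mask = (res.t >= CC_BASELINE) & (res.t < CC_BASELINE + CC_PULSE)
    if res.v[:, pulse_mask].max() > SPIKE_GUARD:
        raise SpikeContaminationError(
            "spike during the coupling pulse; the protocol requires "
            "subthreshold responses (reduce |amplitude|)"
        )
    base, steady = _window_means(res, CC_BASELINE, CC_PULSE)
    cbase, csteady = _control_means(model, dt, settle)
    defl = (steady - csteady) - (base - cbase)
    i_src = res.index(source_cell, site)
    i_oth = res.index(other, site)
    return float(defl[i_src]), float(defl[i_oth])


def measure_coupling(
    model: NetworkModel,
    site: str = "S",
    amplitude: float = -0.5,
    dt: float = DEFAULT_DT,
    settle: float = DEFAULT_SETTLE,
) -> CouplingMeasurement:
    """Coupling coefficients of a two-cell model, both directions.

    ``site`` is the compartment label at which current is injected and
    voltage recorded in both cells ("S" for somatic, "D" for dendritic
    measurements).  The injection amplitude (uA/cm^2, hyperpolarizing) is a
    protocol parameter; cc is amplitude-independent in the linear regime.
    """
    if len(model.cells) != 2:
        raise ValueError("coupling measurement requires exactly two cells")
    dv1, dc1 = _cc_one_direction(model, 0, site, amplitude, dt, settle)
    dv2, dc2 = _cc_one_direction(model, 1, site, amplitude, dt, settle)
    return CouplingMeasurement(
        cc_12=dc1 / dv1,
        cc_21=dc2 / dv2,
        dv_injected_12=dv1,
        dv_coupled_12=dc1,
        dv_injected_21=dv2,
        dv_coupled_21=dc2,
        measurement_site=site,
    )


def measure_input_resistance(
    cell: CellParams,
    site: str = "S",
    amplitude: float = -0.5,
    dt: float = DEFAULT_DT,
    settle: float = DEFAULT_SETTLE,
) -> float:
    """Input resistance (mV per uA/cm^2) at ``site`` from a hyperpolarizing
    step, using the same last-200-ms steady-state convention as cc."""
    model = NetworkModel(cells=[cell])
    step = make_cc_step((0, site), amplitude, onset=CC_BASELINE)
    stim_model = NetworkModel(cells=[cell], injected_currents=[step])
    rest = _rest_for(model, dt, settle)
    cfg = SimulationConfig(
        dt=dt, duration=CC_BASELINE + CC_PULSE + CC_TAIL, settle_time=0.0
    )
    res = simulate(stim_model, cfg, initial_state=rest)
    base, steady = _window_means(res, CC_BASELINE, CC_PULSE)
    cbase, csteady = _control_means(model, dt, settle)
    defl = (steady - csteady) - (base - cbase)
    return float(defl[res.index(0, site)]) / amplitude


def calibrate_rin_change(
    cell: CellParams,
    target_pct: float,
    site: str = "S",
    tol_pct: float = 0.1,
    soma_only: bool = False,
    dt: float = DEFAULT_DT,
) -> float:
    """Leak scale factor producing a ``target_pct`` change in input
    resistance, found by bisection against :func:`measure_input_resistance`.

    The printed leak bracket (0.75-1.45 for +/-25 % R_in) is asymmetric, so
    the factor-to-dR_in map is treated as nonlinear and inverted numerically
    to within ``tol_pct`` of the target.
    """
    if target_pct == 0.0:
        return 1.0
    r0 = measure_input_resistance(cell, site=site, dt=dt)
    r_target = r0 * (1.0 + target_pct / 100.0)
    lo, hi = 0.4, 2.6  # R_in decreasing in factor: lo -> high R, hi -> low R
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        r = measure_input_resistance(
            scale_leak(cell, mid, soma_only=soma_only), site=site, dt=dt
        )
        if abs(r - r_target) / r_target * 100.0 < tol_pct:
            return mid
        if r > r_target:
            lo = mid
        else:
            hi = mid
    raise RuntimeError(
        f"R_in calibration did not converge for target {target_pct}%"
    )


# --------------------------------------------------------------------------
# Burst latency
# --------------------------------------------------------------------------

@dataclass
class LatencyResult:
    """Latencies (ms) from each cell's first EPSC onset to its first somatic
    spike.  ``latency_difference`` uses the convention

        (lat_1(coupled) - lat_uncoupled) - (lat_2(coupled) - lat_uncoupled)

    so positive values mean coupling delayed cell 1 more than cell 2.
    ``None`` latencies flag absent spikes; such conditions are excluded
    from sweep tables."""

    latency_1: float | None
    latency_2: float | None
    latency_uncoupled_1: float | None
    latency_uncoupled_2: float | None

    @property
    def latency_difference(self) -> float | None:
        vals = (
            self.latency_1,
            self.latency_2,
            self.latency_uncoupled_1,
            self.latency_uncoupled_2,
        )
        if any(v is None for v in vals):
            return None
        return (self.latency_1 - self.latency_uncoupled_1) - (
            self.latency_2 - self.latency_uncoupled_2
        )


def _burst_model(cells, esyns, onsets) -> NetworkModel:
    injected, chem = [], []
    for i, onset in enumerate(onsets):
        hold, train = make_burst(i, onset)
        injected.append(hold)
        chem.append(ChemicalSynapse(target=(i, "D"), events=train))
    return NetworkModel(
        cells=list(cells),
        electrical_synapses=list(esyns),
        chemical_synapses=chem,
        injected_currents=injected,
    )


def _first_spike_latency(
    res: SimulationResult, cell: int, onset: float, window: float
) -> float | None:
    sp = detect_spikes(res.trace(cell, "S"), res.dt)
    sp = sp[(sp >= onset) & (sp < onset + window)]
    return float(sp[0] - onset) if len(sp) else None


_UNCOUPLED_LATENCY_CACHE: dict[str, float | None] = {}


def uncoupled_latency(
    cell: CellParams,
    dt: float = DEFAULT_DT,
    pre_time: float = 300.0,
    window: float = 200.0,
) -> float | None:
    """Latency of a single, uncoupled cell to the standard burst."""
    key = json.dumps({"cell": cell_to_dict(cell), "dt": dt,
                      "pre_time": pre_time}, sort_keys=True)
    if key in _UNCOUPLED_LATENCY_CACHE:
        return _UNCOUPLED_LATENCY_CACHE[key]
    model = _burst_model([cell], [], [pre_time])
    rest = _rest_for(NetworkModel(cells=[cell]), dt, DEFAULT_SETTLE)
    cfg = SimulationConfig(dt=dt, duration=pre_time + window + 100.0, settle_time=0.0)
    res = simulate(model, cfg, initial_state=rest)
    lat = _first_spike_latency(res, 0, pre_time, window)
    _UNCOUPLED_LATENCY_CACHE[key] = lat
    return lat


def measure_latency(
    model: NetworkModel,
    onset_1: float,
    onset_2: float,
    dt: float = DEFAULT_DT,
    pre_time: float = 300.0,
    window: float = 200.0,
) -> LatencyResult:
    """Burst-latency protocol on a coupled two-cell model.

    ``model`` supplies the cells and electrical synapses; the burst inputs
    (distal EPSC train plus somatic holding current) are attached here with
    the given onsets (ms, relative; ``pre_time`` of settled holding precedes
    the earlier onset).  The uncoupled reference is each cell simulated
    without electrical synapses.
    """
    if len(model.cells) != 2:
        raise ValueError("latency measurement requires exactly two cells")
    t1 = pre_time + max(0.0, onset_1 - min(onset_1, onset_2))
    t2 = pre_time + max(0.0, onset_2 - min(onset_1, onset_2))
    burst = _burst_model(model.cells, model.electrical_synapses, [t1, t2])
    rest = _rest_for(model, dt, DEFAULT_SETTLE)
    duration = max(t1, t2) + window + 100.0
    res = simulate(burst, SimulationConfig(dt=dt, duration=duration, settle_time=0.0),
                   initial_state=rest)
    lat1 = _first_spike_latency(res, 0, t1, window)
    lat2 = _first_spike_latency(res, 1, t2, window)
    return LatencyResult(
        latency_1=lat1,
        latency_2=lat2,
        latency_uncoupled_1=uncoupled_latency(model.cells[0], dt=dt,
                                              pre_time=t1, window=window),
        latency_uncoupled_2=uncoupled_latency(model.cells[1], dt=dt,
                                              pre_time=t2, window=window),
    )


# --------------------------------------------------------------------------
# Spike-train synchrony
# --------------------------------------------------------------------------

@dataclass
class SynchronyMetrics:
    isi_1: float
    isi_2: float
    lags: np.ndarray = field(repr=False)
    correlogram: np.ndarray = field(repr=False)
    t_max_lag: float
    phase_difference: float  # degrees in [-180, 180]
    rate_converged: bool


def _wrap_phase(phase: float) -> float:
    wrapped = (phase + 180.0) % 360.0 - 180.0
    # map the seam consistently: exactly -180 stays -180 unless input was +180
    if wrapped == -180.0 and phase > 0:
        return 180.0
    return wrapped


def spike_train_phase(
    sp1: np.ndarray,
    sp2: np.ndarray,
    t0: float,
    t1: float,
    dt: float,
    hanning_ms: float = 5.0,
    normalize: bool = False,
) -> tuple[np.ndarray, np.ndarray, float, float]:
    """Hanning-filtered cross-correlation of two spike trains.

    Returns (lags, correlogram, t_max_lag, phase) where phase uses the mean
    ISI of train 1 in the window.  ``normalize`` selects a Pearson-style
    correlogram; normalization rescales values but cannot move the peak lag,
    so the phase is unaffected.
    """
    w1 = sp1[(sp1 >= t0) & (sp1 < t1)]
    w2 = sp2[(sp2 >= t0) & (sp2 < t1)]
    if len(w1) < 5 or len(w2) < 5:
        raise ValueError("need at least 5 spikes per train in the window")
    isi1 = float(np.diff(w1).mean())
    n = int(round((t1 - t0) / dt))
    b1 = np.zeros(n)
    b2 = np.zeros(n)
    b1[np.clip(((w1 - t0) / dt).astype(int), 0, n - 1)] = 1.0
    b2[np.clip(((w2 - t0) / dt).astype(int), 0, n - 1)] = 1.0
    win = np.hanning(int(round(hanning_ms / dt)) + 1)
    f1 = np.convolve(b1, win, mode="same")
    f2 = np.convolve(b2, win, mode="same")
    if normalize:
        f1 = (f1 - f1.mean()) / (f1.std() or 1.0)
        f2 = (f2 - f2.mean()) / (f2.std() or 1.0)
    corr = correlate(f2, f1, mode="full", method="fft")
    lags = (np.arange(corr.size) - (n - 1)) * dt
    # restrict to one period around zero and take the peak nearest zero
    keep = np.abs(lags) <= 1.05 * isi1
    lags_k, corr_k = lags[keep], corr[keep]
    # significant local maxima only (ripples between bumps are not peaks)
    peaks, _ = find_peaks(corr_k, height=0.5 * corr_k.max())
    if len(peaks) == 0:
        peak_idx = int(np.argmax(corr_k))
    else:
        # nearest-zero peak; ties broken toward the non-negative lag
        order = sorted(peaks, key=lambda p: (round(abs(lags_k[p]), 6), -np.sign(lags_k[p])))
        peak_idx = order[0]
    t_max_lag = float(lags_k[peak_idx])
    phase = _wrap_phase(t_max_lag / isi1 * 360.0)
    return lags_k, corr_k, t_max_lag, phase


def measure_synchrony(
    model: NetworkModel,
    window: float = 500.0,
    discard: float = 1500.0,
    dt: float = DEFAULT_DT,
    hanning_ms: float = 5.0,
    normalize: bool = False,
    isi_drift_tol: float = 0.05,
) -> SynchronyMetrics:
    """Synchrony protocol: simulate the tonically driven pair, then measure
    phase from a ``window``-ms span of stable firing.

    ``discard`` ms of post-onset transient are dropped before the analysis
    window.  If the ISI drifts by more than ``isi_drift_tol`` (fractional)
    across the window, the window is shifted later once and a warning is
    issued if drift persists.
    """
    if len(model.cells) != 2:
        raise ValueError("synchrony measurement requires exactly two cells")
    site = model.cells[0].labels[0]
    rest = _rest_for(model, dt, DEFAULT_SETTLE)
    duration = discard + 2.0 * window + 100.0
    res = simulate(model, SimulationConfig(dt=dt, duration=duration, settle_time=0.0),
                   initial_state=rest)
    sp1 = detect_spikes(res.trace(0, site), res.dt)
    sp2 = detect_spikes(res.trace(1, site), res.dt)

    def drift(sp, t0, t1):
        w = sp[(sp >= t0) & (sp < t1)]
        if len(w) < 6:
            return np.inf
        isis = np.diff(w)
        half = len(isis) // 2
        a, b = isis[:half].mean(), isis[half:].mean()
        return abs(b - a) / a

    t0 = discard
    if max(drift(sp1, t0, t0 + window), drift(sp2, t0, t0 + window)) > isi_drift_tol:
        t0 = discard + window
        if max(drift(sp1, t0, t0 + window), drift(sp2, t0, t0 + window)) > isi_drift_tol:
            warnings.warn("non-stationary firing persists after window shift")
    w1 = sp1[(sp1 >= t0) & (sp1 < t0 + window)]
    w2 = sp2[(sp2 >= t0) & (sp2 < t0 + window)]
    lags, corr, t_max_lag, phase = spike_train_phase(
        sp1, sp2, t0, t0 + window, dt, hanning_ms=hanning_ms, normalize=normalize
    )
    isi1 = float(np.diff(w1).mean())
    isi2 = float(np.diff(w2).mean())
    return SynchronyMetrics(
        isi_1=isi1,
        isi_2=isi2,
        lags=lags,
        correlogram=corr,
        t_max_lag=t_max_lag,
        phase_difference=phase,
        rate_converged=abs(isi1 - isi2) / isi1 < 0.02,
    )
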
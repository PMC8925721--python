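"""Fixed-step midpoint (second-order Runge-Kutta) integration of coupled
compartmental membrane equations.

The state of each compartment is its membrane potential plus ten gating
variables.  The voltage equation is

    C_m dV_i/dt = G_leak (E_leak - V_i)
                + sum_channels g_max prod(gates) (E_ion - V_i)
                + sum_synaptic g_syn(t) (E_syn - V_i)
                + sum_gap_junctions G_elec,ji (V_j - V_i)
                + sum_internal G_internal,ji (V_j - V_i)
                + I_injected(t)

with gating variables relaxing as dx/dt = (x_inf(V) - x)/tau(V).

Simulations are deterministic: identical models and configurations produce
bit-identical traces.  Integration starts from the resting fixed point found
by integrating with zero stimulus for ``settle_time`` (or from an explicitly
supplied initial state, which sweep runners reuse to amortize settling).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cell import CellParams
from .channels import CHANNEL_NAMES
from .kinetics import N_GATES, gate_rates, njit
from .stimuli import StimulusProtocol
from .synapses import ChemicalSynapse, ElectricalSynapse, V_REST_NOMINAL, syn_conductance

#: Index of each channel's g_max column in the compiled conductance matrix.
_CH_IDX = {name: i for i, name in enumerate(CHANNEL_NAMES)}


class SimulationError(RuntimeError):
    pass


@dataclass(frozen=True)
class SimulationConfig:
    """Numerical configuration of one run.

    dt is the fixed integration step (ms); duration the recorded span (ms);
    settle_time the zero-stimulus equilibration integrated before t = 0.
    ``seed`` is carried for protocols with randomized elements (none of the
    built-in protocols use randomness) and echoed into run manifests.
    """

    dt: float = 0.01
    duration: float = 1000.0
    settle_time: float = 500.0
    seed: int = 0
    record_gates: bool = False

    def __post_init__(self):
        if not self.dt > 0:
            raise ValueError("dt must be positive")
        if self.settle_time < 0:
            raise ValueError("settle_time must be non-negative")
        if not self.duration > 0:
            raise ValueError("duration must be positive")


@dataclass
class NetworkModel:
    """A set of cells wired by electrical and chemical synapses and driven by
    injected-current protocols."""

    cells: list[CellParams]
    electrical_synapses: list[ElectricalSynapse] = field(default_factory=list)
    chemical_synapses: list[ChemicalSynapse] = field(default_factory=list)
    injected_currents: list[StimulusProtocol] = field(default_factory=list)

    def validate(self) -> None:
        for syn in self.electrical_synapses:
            for cell_i, label in (syn.endpoint_a, syn.endpoint_b):
                self._check_endpoint(cell_i, label, "electrical synapse")
        for syn in self.chemical_synapses:
            self._check_endpoint(*syn.target, kind="chemical synapse")
        for stim in self.injected_currents:
            self._check_endpoint(*stim.target, kind="stimulus")

    def _check_endpoint(self, cell_i: int, label: str, kind: str) -> None:
        if not (0 <= cell_i < len(self.cells)):
            raise ValueError(f"{kind} references missing cell {cell_i}")
        if label not in self.cells[cell_i].labels:
            raise ValueError(
                f"{kind} references missing compartment ({cell_i}, {label!r})"
            )


@dataclass
class SimulationResult:
    """Time base (ms) plus per-(cell, compartment) voltage traces (mV)."""

    t: np.ndarray
    v: np.ndarray  # shape (n_compartments, n_samples)
    labels: list[tuple[int, str]]
    dt: float
    gates: np.ndarray | None = None  # (n_compartments, N_GATES, n_samples)

    def index(self, cell: int, label: str) -> int:
        return self.labels.index((cell, label))

    def trace(self, cell: int, label: str) -> np.ndarray:
        return self.v[self.index(cell, label)]

    def to_csv(self, path) -> None:
        header = "time_ms," + ",".join(f"cell{c}_{lbl}" for c, lbl in self.labels)
        np.savetxt(path, np.column_stack([self.t, self.v.T]),
                   delimiter=",", header=header, comments="")

    def to_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as fh:
            fh.create_dataset("t", data=self.t)
            fh.create_dataset("v", data=self.v)
            fh.attrs["labels"] = [f"{c}:{lbl}" for c, lbl in self.labels]


# --------------------------------------------------------------------------
# Model compilation to flat arrays
# --------------------------------------------------------------------------

class _Compiled:
    def __init__(self, model: NetworkModel):
        model.validate()
        self.index: dict[tuple[int, str], int] = {}
        comps = []
        for ci, cell in enumerate(model.cells):
            for comp in cell.compartments:
                self.index[(ci, comp.label)] = len(comps)
                comps.append(comp)
        n = len(comps)
        self.n = n
        self.labels = [key for key, _ in sorted(self.index.items(), key=lambda kv: kv[1])]
        self.cm = np.array([c.c_m for c in comps])
        self.gleak = np.array([c.g_leak for c in comps])
        self.eleak = np.array([c.e_leak for c in comps])
        self.gmax = np.zeros((n, 6))
        self.erev = np.zeros((n, 6))
        for i, comp in enumerate(comps):
            for ch in comp.channels:
                j = _CH_IDX[ch.name]
                self.gmax[i, j] = ch.g_max
                self.erev[i, j] = ch.e_rev
        int_i, int_j, int_g = [], [], []
        for ci, cell in enumerate(model.cells):
            for a, b, g in cell.g_internal:
                int_i.append(self.index[(ci, a)])
                int_j.append(self.index[(ci, b)])
                int_g.append(g)
        self.int_i = np.array(int_i, dtype=np.int64)
        self.int_j = np.array(int_j, dtype=np.int64)
        self.int_g = np.array(int_g, dtype=np.float64)
        # Each gap-junction direction becomes one (src, dst, g) edge:
        # current into dst += g * (V_src - V_dst).
        src, dst, g_dir = [], [], []
        for syn in model.electrical_synapses:
            ia = self.index[syn.endpoint_a]
            ib = self.index[syn.endpoint_b]
            if syn.g_ab > 0:
                src.append(ia); dst.append(ib); g_dir.append(syn.g_ab)
            if syn.g_ba > 0:
                src.append(ib); dst.append(ia); g_dir.append(syn.g_ba)
        self.gj_src = np.array(src, dtype=np.int64)
        self.gj_dst = np.array(dst, dtype=np.int64)
        self.gj_g = np.array(g_dir, dtype=np.float64)
        self.esyn = np.zeros(n)

    def stim_arrays(self, model: NetworkModel, t: np.ndarray
                    ) -> tuple[np.ndarray, np.ndarray]:
        """Injected current and synaptic conductance sampled on the grid."""
        stim = np.zeros((self.n, t.size))
        gsyn = np.zeros((self.n, t.size))
        for proto in model.injected_currents:
            stim[self.index[proto.target]] += proto.waveform(t)
        for syn in model.chemical_synapses:
            i = self.index[syn.target]
            wave = syn_conductance(syn, t)
            if syn.mode == "current":
                stim[i] += wave
            else:
                drive = syn.e_syn - V_REST_NOMINAL
                if drive <= 0:
                    raise ValueError("conductance mode requires e_syn above rest")
                gsyn[i] += wave / drive
                self.esyn[i] = syn.e_syn
        return stim, gsyn


# --------------------------------------------------------------------------
# Integration kernel
# --------------------------------------------------------------------------

@njit(cache=True)
def _deriv(v, gates, stim_col, gsyn_col, cm, gleak, eleak, gmax, erev,
           int_i, int_j, int_g, gj_src, gj_dst, gj_g, esyn,
           dv, dgates, xinf, tau):
    n = v.shape[0]
    for i in range(n):
        vi = v[i]
        current = gleak[i] * (eleak[i] - vi) + stim_col[i]
        current += gsyn_col[i] * (esyn[i] - vi)
        g = gates[i]
        # NaT m^3 h
        if gmax[i, 0] > 0.0:
            current += gmax[i, 0] * g[0] ** 3 * g[1] * (erev[i, 0] - vi)
        # Kd n^4
        if gmax[i, 1] > 0.0:
            current += gmax[i, 1] * g[2] ** 4 * (erev[i, 1] - vi)
        # Kt m^4 h
        if gmax[i, 2] > 0.0:
            current += gmax[i, 2] * g[3] ** 4 * g[4] * (erev[i, 2] - vi)
        # K2 m h
        if gmax[i, 3] > 0.0:
            current += gmax[i, 3] * g[5] * g[6] * (erev[i, 3] - vi)
        # AR m
        if gmax[i, 4] > 0.0:
            current += gmax[i, 4] * g[7] * (erev[i, 4] - vi)
        # CaT m^2 h
        if gmax[i, 5] > 0.0:
            current += gmax[i, 5] * g[8] ** 2 * g[9] * (erev[i, 5] - vi)
        dv[i] = current / cm[i]
        gate_rates(vi, xinf, tau)
        for k in range(N_GATES):
            dgates[i, k] = (xinf[k] - gates[i, k]) / tau[k]
    for e in range(int_i.shape[0]):
        a = int_i[e]; b = int_j[e]
        f = int_g[e] * (v[b] - v[a])
        dv[a] += f / cm[a]
        dv[b] -= f / cm[b]
    for e in range(gj_src.shape[0]):
        s = gj_src[e]; d = gj_dst[e]
        dv[d] += gj_g[e] * (v[s] - v[d]) / cm[d]


@njit(cache=True)
def _integrate(v, gates, stim, gsyn, cm, gleak, eleak, gmax, erev,
               int_i, int_j, int_g, gj_src, gj_dst, gj_g, esyn,
               dt, n_steps, stride, v_out, g_out, record_gates):
    n = v.shape[0]
    dv = np.empty(n)
    dgates = np.empty((n, N_GATES))
    vm = np.empty(n)
    gm = np.empty((n, N_GATES))
    dv2 = np.empty(n)
    dg2 = np.empty((n, N_GATES))
    xinf = np.empty(N_GATES)
    tau = np.empty(N_GATES)
    smid = np.empty(n)
    gmid = np.empty(n)
    rec = 0
    v_out[:, rec] = v
    if record_gates:
        g_out[:, :, rec] = gates
    for step in range(n_steps):
        s0 = stim[:, step]
        s1 = stim[:, step + 1]
        c0 = gsyn[:, step]
        c1 = gsyn[:, step + 1]
        _deriv(v, gates, s0, c0, cm, gleak, eleak, gmax, erev,
               int_i, int_j, int_g, gj_src, gj_dst, gj_g, esyn,
               dv, dgates, xinf, tau)
        for i in range(n):
            vm[i] = v[i] + 0.5 * dt * dv[i]
            smid[i] = 0.5 * (s0[i] + s1[i])
            gmid[i] = 0.5 * (c0[i] + c1[i])
            for k in range(N_GATES):
                gm[i, k] = gates[i, k] + 0.5 * dt * dgates[i, k]
        _deriv(vm, gm, smid, gmid, cm, gleak, eleak, gmax, erev,
               int_i, int_j, int_g, gj_src, gj_dst, gj_g, esyn,
               dv2, dg2, xinf, tau)
        for i in range(n):
            v[i] = v[i] + dt * dv2[i]
            for k in range(N_GATES):
                x = gates[i, k] + dt * dg2[i, k]
                if x < 0.0:
                    x = 0.0
                elif x > 1.0:
                    x = 1.0
                gates[i, k] = x
        if (step + 1) % stride == 0:
            rec += 1
            v_out[:, rec] = v
            if record_gates:
                g_out[:, :, rec] = gates
        for i in range(n):
            if not np.isfinite(v[i]) or abs(v[i]) > 200.0:
                return step, i
    return -1, -1


def _initial_arrays(net: _Compiled) -> tuple[np.ndarray, np.ndarray]:
    v = net.eleak.copy()
    gates = np.empty((net.n, N_GATES))
    xinf = np.empty(N_GATES)
    tau = np.empty(N_GATES)
    for i in range(net.n):
        gate_rates(v[i], xinf, tau)
        gates[i] = xinf
    return v, gates


def resting_state(
    model: NetworkModel, dt: float = 0.01, settle_time: float = 500.0
) -> tuple[np.ndarray, np.ndarray]:
    """Integrate with zero stimulus and return the settled (v, gates) state.

    Sweep runners pass the result to :func:`simulate` as ``initial_state`` to
    avoid re-settling identical cells for every grid point.
    """
    net = _Compiled(model)
    v, gates = _initial_arrays(net)
    n_steps = int(round(settle_time / dt))
    if n_steps == 0:
        return v, gates
    zeros = np.zeros((net.n, n_steps + 1))
    v_out = np.empty((net.n, 2))
    g_out = np.empty((net.n, N_GATES, 2))
    bad, comp = _integrate(
        v, gates, zeros, zeros, net.cm, net.gleak, net.eleak, net.gmax,
        net.erev, net.int_i, net.int_j, net.int_g, net.gj_src, net.gj_dst,
        net.gj_g, net.esyn, dt, n_steps, n_steps, v_out, g_out, False,
    )
    if bad >= 0:
        _raise_blowup(net, bad, comp, dt, phase="settle")
    return v, gates


def _raise_blowup(net: _Compiled, step: int, comp: int, dt: float, phase: str):
    cell, label = net.labels[comp]
    raise SimulationError(
        f"numerical blow-up (|V| > 200 mV) during {phase} at t = {step * dt:.3f} ms "
        f"in cell {cell}, compartment {label!r}; reduce dt or check parameters"
    )


def simulate(
    model: NetworkModel,
    config: SimulationConfig,
    initial_state: tuple[np.ndarray, np.ndarray] | None = None,
    record_stride: int = 1,
) -> SimulationResult:
    """Integrate the network and return recorded traces.

    ``initial_state`` overrides the settling phase with an explicit (v,
    gates) pair, typically from :func:`resting_state`.  ``record_stride``
    subsamples the stored traces (integration always runs at config.dt).
    """
    net = _Compiled(model)
    if initial_state is None:
        if config.settle_time > 0:
            stim_free = NetworkModel(cells=model.cells,
                                     electrical_synapses=model.electrical_synapses)
            v, gates = resting_state(stim_free, config.dt, config.settle_time)
        else:
            v, gates = _initial_arrays(net)
    else:
        v, gates = initial_state
        v = v.copy()
        gates = gates.copy()
        if v.shape != (net.n,) or gates.shape != (net.n, N_GATES):
            raise ValueError("initial_state shape does not match the model")

    n_steps = int(round(config.duration / config.dt))
    t_full = np.arange(n_steps + 1) * config.dt
    stim, gsyn = net.stim_arrays(model, t_full)
    n_rec = n_steps // record_stride + 1
    v_out = np.empty((net.n, n_rec))
    g_out = (np.empty((net.n, N_GATES, n_rec)) if config.record_gates
             else np.empty((1, N_GATES, 1)))
    bad, comp = _integrate(
        v, gates, stim, gsyn, net.cm, net.gleak, net.eleak, net.gmax,
        net.erev, net.int_i, net.int_j, net.int_g, net.gj_src, net.gj_dst,
        net.gj_g, net.esyn, config.dt, n_steps, record_stride,
        v_out, g_out, config.record_gates,
    )
    if bad >= 0:
        _raise_blowup(net, bad, comp, config.dt, phase="integration")
    t_rec = t_full[::record_stride]
    return SimulationResult(
        t=t_rec, v=v_out, labels=net.labels, dt=config.dt * record_stride,
        gates=g_out if config.record_gates else None,
    )


def detect_spikes(
    trace: np.ndarray,
    dt: float,
    threshold: float = 0.0,
    refractory: float = 2.0,
    t0: float = 0.0,
) -> np.ndarray:
    """Spike times (ms) as upward threshold crossings with a refractory gate.

    One spike is counted per upward crossing of ``threshold``; crossings
    closer than ``refractory`` ms to the previous accepted spike are merged
    into it.  Returns an empty array for subthreshold traces.
    """
    trace = np.asarray(trace)
    above = trace >= threshold
    crossings = np.flatnonzero(~above[:-1] & above[1:]) + 1
    times = []
    last = -np.inf
    for k in crossings:
        t = t0 + k * dt
        if t - last >= refractory:
            times.append(t)
            last = t
    return np.asarray(times)
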
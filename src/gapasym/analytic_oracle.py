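"""Closed-form steady-state solver for the passive resistor network.

With all voltage-gated channels zeroed, the steady state of the coupled
compartmental system is the solution of a linear nodal equation G dV = I,
where G collects leak conductances on the diagonal and (possibly
direction-dependent) junction and internal conductances off the diagonal.
This module solves that system directly and serves as the independent
verification oracle for every subthreshold coupling result produced by the
time-domain engine: simulated coupling coefficients on passive networks
must match the nodal solution to a small fraction of a percent.

For asymmetric gap junctions the nodal matrix is asymmetric: the row of
node i uses the conductance assigned to transmission *into* i.  The system
remains uniquely solvable as long as every node has a leak path to rest.

The oracle linearizes about the leak reversal and deliberately ignores
resting activation of AR/CaT: it verifies the passive limit, and the
comparison protocol zeroes the channels in both the oracle and the engine.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .cell import CellParams
from .engine import NetworkModel


def strip_channels(cell: CellParams) -> CellParams:
    """A copy of the cell with every voltage-gated channel removed."""
    comps = tuple(replace(c, channels=()) for c in cell.compartments)
    return replace(cell, compartments=comps)


def passive_network(model: NetworkModel) -> NetworkModel:
    """A copy of the model with all cells made passive."""
    return NetworkModel(
        cells=[strip_channels(c) for c in model.cells],
        electrical_synapses=list(model.electrical_synapses),
        chemical_synapses=list(model.chemical_synapses),
        injected_currents=list(model.injected_currents),
    )


@dataclass
class ConductanceNetwork:
    """Nodal representation of the passive network.

    ``matrix[i, j]`` is the conductance matrix of the system
    ``matrix @ dV = I`` for steady deflections dV from rest, with injected
    current densities I (uA/cm^2).  ``index`` maps (cell, compartment label)
    to node number.
    """

    matrix: np.ndarray
    index: dict[tuple[int, str], int]

    @classmethod
    def from_model(cls, model: NetworkModel) -> "ConductanceNetwork":
        model.validate()
        index: dict[tuple[int, str], int] = {}
        leaks = []
        for ci, cell in enumerate(model.cells):
            for comp in cell.compartments:
                index[(ci, comp.label)] = len(leaks)
                leaks.append(comp.g_leak)
        n = len(leaks)
        g = np.diag(np.asarray(leaks, dtype=float))
        for ci, cell in enumerate(model.cells):
            for a, b, gint in cell.g_internal:
                ia, ib = index[(ci, a)], index[(ci, b)]
                g[ia, ia] += gint
                g[ib, ib] += gint
                g[ia, ib] -= gint
                g[ib, ia] -= gint
        for syn in model.electrical_synapses:
            ia = index[syn.endpoint_a]
            ib = index[syn.endpoint_b]
            # current into b: g_ab * (dV_a - dV_b); row b uses g_ab
            g[ib, ib] += syn.g_ab
            g[ib, ia] -= syn.g_ab
            g[ia, ia] += syn.g_ba
            g[ia, ib] -= syn.g_ba
        return cls(matrix=g, index=index)

    def node(self, cell: int, label: str) -> int:
        return self.index[(cell, label)]


def solve_steady_state(
    net: ConductanceNetwork, injections: dict[tuple[int, str], float]
) -> np.ndarray:
    """Steady-state voltage deflections (mV) for the given injected currents.

    ``injections`` maps (cell, compartment) to a constant current density
    (uA/cm^2).  Raises on a singular system, naming a node with no
    resistive path to rest.
    """
    n = net.matrix.shape[0]
    rhs = np.zeros(n)
    for key, amp in injections.items():
        rhs[net.index[key]] += amp
    try:
        return np.linalg.solve(net.matrix, rhs)
    except np.linalg.LinAlgError:
        bad = min(net.index, key=lambda k: abs(net.matrix[net.index[k], net.index[k]]))
        raise np.linalg.LinAlgError(
            f"singular conductance matrix: node {bad} has no path to rest"
        ) from None


def analytic_cc(
    net: ConductanceNetwork,
    source: tuple[int, str],
    record_a: tuple[int, str],
    record_b: tuple[int, str],
    amplitude: float = -0.5,
) -> float:
    """Coupling coefficient dV_B / dV_A for current injected at ``source``."""
    dv = solve_steady_state(net, {source: amplitude})
    return dv[net.index[record_b]] / dv[net.index[record_a]]


def analytic_cc_ratio(
    net: ConductanceNetwork, site_1: str = "S", site_2: str = "S"
) -> float:
    """cc_12 / cc_21 for a two-cell network, injecting and recording at the
    given compartment of each cell."""
    cc12 = analytic_cc(net, (0, site_1), (0, site_1), (1, site_2))
    cc21 = analytic_cc(net, (1, site_2), (1, site_2), (0, site_1))
    return cc12 / cc21
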
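"""Sweep runners regenerating the asymmetry parameter grids as tidy tables.

Each runner builds the two-cell model for every grid point, applies one of
the measurement protocols, and returns a pandas DataFrame with the full
parameter echo in columns, one row per condition.  All sweeps are
deterministic; rerunning any grid point reproduces its row bit-identically.

Synapse locations are written as ordered pairs like ``"S-M"``: the first
label is the compartment of cell 1 hosting the junction, the second the
compartment of cell 2.  ``G_c`` ratios follow the convention
Gc_12 / Gc_21, where Gc_12 governs transmission from cell 1 into cell 2.
"""

from __future__ import annotations

import itertools
import json

import numpy as np
import pandas as pd

from . import __version__
from .analytic_oracle import ConductanceNetwork, analytic_cc, passive_network
from .cell import (
    CellParams,
    make_single_compartment_trn,
    make_three_compartment_trn,
    scale_internal,
    scale_leak,
)
from .engine import NetworkModel
from .kinetics import kinetics_table
from .measurements import (
    calibrate_rin_change,
    measure_coupling,
    measure_latency,
    measure_synchrony,
    uncoupled_latency,
)
from .stimuli import make_tonic_pair
from .synapses import ElectricalSynapse

#: Default symmetric G_c axis (mS/cm^2): brackets every coupling strength
#: the study prints (0.005-0.2, with 0.15 as the reference value).
DEFAULT_GC_AXIS = tuple(np.round(np.arange(0.01, 0.251, 0.01), 3))

#: The three G_c values of the input-resistance sweep.
RIN_SWEEP_GC = (0.1, 0.15, 0.2)

#: Reference coupling strength (mS/cm^2).
GC_REF = 0.15

LOCATIONS = ("S", "M", "D")
LOCATION_PAIRS = tuple(f"{a}-{b}" for a, b in itertools.product(LOCATIONS, LOCATIONS))

#: Onset-difference axis for the latency sweep (ms).
DEFAULT_ONSET_DIFFS = tuple(range(-30, 31, 2))

#: G_c 21 values of the synchrony map (mS/cm^2).
SYNCHRONY_GC21 = (0.005, 0.0125, 0.025)
#: Directional-ratio axis of the synchrony map (the range observed in
#: paired recordings).
DEFAULT_RATIO_AXIS = (0.3, 0.5, 0.75, 1.0, 1.5, 2.0, 3.0)


def pair_model(
    cell1: CellParams,
    cell2: CellParams,
    loc1: str,
    loc2: str,
    gc_12: float,
    gc_21: float | None = None,
) -> NetworkModel:
    """Two cells joined by one electrical synapse between ``loc1`` of cell 1
    and ``loc2`` of cell 2 (symmetric when gc_21 is omitted)."""
    syn = ElectricalSynapse(
        endpoint_a=(0, loc1),
        endpoint_b=(1, loc2),
        g_ab=gc_12,
        g_ba=gc_12 if gc_21 is None else gc_21,
    )
    return NetworkModel(cells=[cell1, cell2], electrical_synapses=[syn])


def _loc_split(pair: str) -> tuple[str, str]:
    a, b = pair.split("-")
    return a, b


def run_cc_map(
    gc_values=DEFAULT_GC_AXIS, dt: float = 0.01, include_single: bool = True
) -> pd.DataFrame:
    """Coupling coefficient versus G_c for matched-compartment junctions,
    measured both somatically and dendritically, plus the single-compartment
    pair for comparison."""
    cell = make_three_compartment_trn()
    single = make_single_compartment_trn()
    rows = []
    for gc in gc_values:
        for loc in LOCATIONS:
            model = pair_model(cell, cell, loc, loc, gc)
            for site in ("S", "D"):
                m = measure_coupling(model, site=site, dt=dt)
                rows.append(
                    dict(model="three_compartment", location=f"{loc}-{loc}",
                         site=site, gc=gc, cc_12=m.cc_12, cc_21=m.cc_21,
                         cc_ratio=m.cc_ratio)
                )
        if include_single:
            m = measure_coupling(pair_model(single, single, "S", "S", gc), site="S", dt=dt)
            rows.append(
                dict(model="single_compartment", location="S-S", site="S",
                     gc=gc, cc_12=m.cc_12, cc_21=m.cc_21, cc_ratio=m.cc_ratio)
            )
    return pd.DataFrame(rows)


def run_location_grid(
    gc_values=DEFAULT_GC_AXIS, location_pairs=LOCATION_PAIRS, dt: float = 0.01
) -> pd.DataFrame:
    """cc_12, cc_21 and their ratio for every junction location pair and
    strength (somatic measurement)."""
    cell = make_three_compartment_trn()
    rows = []
    for pair in location_pairs:
        l1, l2 = _loc_split(pair)
        for gc in gc_values:
            m = measure_coupling(pair_model(cell, cell, l1, l2, gc), site="S", dt=dt)
            rows.append(
                dict(location=pair, gc=gc, cc_12=m.cc_12, cc_21=m.cc_21,
                     cc_ratio=m.cc_ratio)
            )
    return pd.DataFrame(rows)


def run_rin_sweep(
    gc_values=RIN_SWEEP_GC,
    rin_pcts=tuple(range(-25, 26, 5)),
    location_pairs=LOCATION_PAIRS,
    dt: float = 0.01,
) -> pd.DataFrame:
    """Asymmetry versus input-resistance mismatch: cell 2's R_in is changed
    by each percentage (via calibrated leak scaling of all compartments)
    while cell 1 stays at default."""
    cell = make_three_compartment_trn()
    factors = {
        pct: calibrate_rin_change(cell, pct, dt=dt) for pct in rin_pcts
    }
    rows = []
    for pct in rin_pcts:
        cell2 = scale_leak(cell, factors[pct])
        for pair in location_pairs:
            l1, l2 = _loc_split(pair)
            for gc in gc_values:
                m = measure_coupling(pair_model(cell, cell2, l1, l2, gc), site="S", dt=dt)
                rows.append(
                    dict(location=pair, gc=gc, rin_change_pct=pct,
                         leak_factor=factors[pct], cc_12=m.cc_12,
                         cc_21=m.cc_21, cc_ratio=m.cc_ratio)
                )
    return pd.DataFrame(rows)


def run_geometry_sweep(
    ms_factors=(0.8, 0.9, 1.0, 1.1, 1.2),
    dm_factors=(0.8, 0.9, 1.0, 1.1, 1.2),
    location_pairs=LOCATION_PAIRS,
    gc: float = GC_REF,
    dt: float = 0.01,
) -> pd.DataFrame:
    """Asymmetry versus cell-2 internal (dendritic) conductance changes at
    fixed G_c: heat-map grids over the M-S and D-M scale factors."""
    cell = make_three_compartment_trn()
    rows = []
    for ms in ms_factors:
        for dm in dm_factors:
            cell2 = scale_internal(cell, ms, dm)
            for pair in location_pairs:
                l1, l2 = _loc_split(pair)
                m = measure_coupling(pair_model(cell, cell2, l1, l2, gc), site="S", dt=dt)
                rows.append(
                    dict(location=pair, gc=gc, ms_factor=ms, dm_factor=dm,
                         cc_12=m.cc_12, cc_21=m.cc_21, cc_ratio=m.cc_ratio)
                )
    return pd.DataFrame(rows)


def run_gcratio_sweep(
    ratio_values=(0.3, 0.5, 0.667, 1.0, 1.5, 1.8, 2.0, 3.0),
    rin_pcts=(-20, -12, -6, 0, 6, 12, 20, 25),
    gc_21: float = GC_REF,
    dt: float = 0.01,
) -> pd.DataFrame:
    """Directional-conductance asymmetry: Gc_12 = ratio * Gc_21 between the
    somas, crossed with input-resistance changes in cell 2."""
    cell = make_three_compartment_trn()
    factors = {pct: calibrate_rin_change(cell, pct, dt=dt) for pct in rin_pcts}
    rows = []
    for pct in rin_pcts:
        cell2 = scale_leak(cell, factors[pct])
        for ratio in ratio_values:
            model = pair_model(cell, cell2, "S", "S", gc_12=ratio * gc_21, gc_21=gc_21)
            m = measure_coupling(model, site="S", dt=dt)
            rows.append(
                dict(gc_ratio=ratio, gc_21=gc_21, rin_change_pct=pct,
                     leak_factor=factors[pct], cc_12=m.cc_12, cc_21=m.cc_21,
                     cc_ratio=m.cc_ratio)
            )
    return pd.DataFrame(rows)


#: The six masking configurations: independent parameter combinations that
#: produce the same +/-20 % somatic asymmetry (cc ratio ~1.2 or ~0.8).
MASKING_CONFIGS = {
    "B": dict(kind="gc_ratio", location="S-S", gc_ratio=1.8, rin_pct=-20.0),
    "C": dict(kind="gc_ratio", location="S-S", gc_ratio=0.667, rin_pct=6.0),
    "D": dict(kind="location", location="M-D", rin_pct=25.0),
    "E": dict(kind="location", location="M-S", rin_pct=-12.0),
    "F": dict(kind="geometry", location="S-M", ms_factor=0.867, dm_factor=0.8),
    "G": dict(kind="geometry", location="D-S", ms_factor=1.2, dm_factor=1.2),
}


def run_masking_isoclines(dt: float = 0.01, gc: float = GC_REF) -> pd.DataFrame:
    """The six worked masking configurations, each simulated with its
    printed parameters; reports the resulting somatic cc ratio."""
    cell = make_three_compartment_trn()
    rows = []
    for name, cfg in MASKING_CONFIGS.items():
        l1, l2 = _loc_split(cfg["location"])
        cell2 = cell
        if cfg.get("rin_pct"):
            cell2 = scale_leak(cell, calibrate_rin_change(cell, cfg["rin_pct"], dt=dt))
        if cfg["kind"] == "geometry":
            cell2 = scale_internal(cell2, cfg["ms_factor"], cfg["dm_factor"])
        gc_12 = gc * cfg.get("gc_ratio", 1.0)
        model = pair_model(cell, cell2, l1, l2, gc_12=gc_12, gc_21=gc)
        m = measure_coupling(model, site="S", dt=dt)
        rows.append(
            dict(config=name, **{k: v for k, v in cfg.items()},
                 gc_21=gc, cc_12=m.cc_12, cc_21=m.cc_21, cc_ratio=m.cc_ratio)
        )
    return pd.DataFrame(rows)


def run_latency(
    gc_values=(0.05, 0.1, 0.15, 0.2),
    onset_diffs=DEFAULT_ONSET_DIFFS,
    location_pairs=LOCATION_PAIRS,
    gc_ratios=(1.0,),
    dt: float = 0.01,
) -> pd.DataFrame:
    """Burst-latency modulation over junction locations, strengths, onset
    differences and (optionally) directional G_c ratios.

    ``onset_diff`` is t_in2 - t_in1 (ms).  Conditions where a cell fails to
    spike are reported with NaN latency difference.
    """
    cell = make_three_compartment_trn()
    rows = []
    for pair in location_pairs:
        l1, l2 = _loc_split(pair)
        for gc in gc_values:
            for ratio in gc_ratios:
                model = pair_model(cell, cell, l1, l2, gc_12=gc * ratio, gc_21=gc)
                for diff in onset_diffs:
                    r = measure_latency(model, 0.0, float(diff), dt=dt)
                    rows.append(
                        dict(location=pair, gc_21=gc, gc_ratio=ratio,
                             onset_diff=diff,
                             latency_1=r.latency_1, latency_2=r.latency_2,
                             latency_uncoupled=r.latency_uncoupled_1,
                             latency_difference=(
                                 np.nan if r.latency_difference is None
                                 else r.latency_difference),
                             )
                    )
    return pd.DataFrame(rows)


def run_synchrony_map(
    gc21_values=SYNCHRONY_GC21,
    ratio_values=DEFAULT_RATIO_AXIS,
    dt: float = 0.01,
) -> pd.DataFrame:
    """Phase map of the tonically firing single-compartment pair over
    junction strength and directional asymmetry."""
    cell = make_single_compartment_trn()
    s1, s2 = make_tonic_pair()
    rows = []
    for gc21 in gc21_values:
        for ratio in ratio_values:
            model = pair_model(cell, cell, "S", "S",
                               gc_12=ratio * gc21, gc_21=gc21)
            model.injected_currents = [s1, s2]
            m = measure_synchrony(model, dt=dt)
            rows.append(
                dict(gc_21=gc21, gc_ratio=ratio, isi_1=m.isi_1, isi_2=m.isi_2,
                     t_max_lag=m.t_max_lag, phase_deg=m.phase_difference,
                     rate_converged=m.rate_converged)
            )
    return pd.DataFrame(rows)


def run_symmetric_synchrony_sweep(
    gc_values=(0.0, 0.001, 0.002, 0.003, 0.004, 0.005, 0.0075, 0.0125, 0.025),
    dt: float = 0.01,
) -> pd.DataFrame:
    """ISIs and phase versus symmetric G_c (the rate-convergence sweep)."""
    cell = make_single_compartment_trn()
    s1, s2 = make_tonic_pair()
    rows = []
    for gc in gc_values:
        model = pair_model(cell, cell, "S", "S", gc)
        model.injected_currents = [s1, s2]
        try:
            m = measure_synchrony(model, dt=dt)
            rows.append(
                dict(gc=gc, isi_1=m.isi_1, isi_2=m.isi_2,
                     t_max_lag=m.t_max_lag, phase_deg=m.phase_difference,
                     rate_converged=m.rate_converged)
            )
        except ValueError:
            rows.append(dict(gc=gc, isi_1=np.nan, isi_2=np.nan,
                             t_max_lag=np.nan, phase_deg=np.nan,
                             rate_converged=False))
    return pd.DataFrame(rows)


def oracle_check(
    gc_values=(0.05, 0.15, 0.25),
    location_pairs=LOCATION_PAIRS,
    rin_pcts=(0, 25),
    gc_ratios=(1.0, 1.8),
    dt: float = 0.01,
) -> pd.DataFrame:
    """Passive cross-validation: simulated cc versus the analytic nodal
    solution on channel-zeroed networks across the subthreshold grids.
    The relative-error column is the correctness gate."""
    cell = make_three_compartment_trn()
    rows = []
    variants = [("default", cell)]
    for pct in rin_pcts:
        if pct:
            variants.append(
                (f"rin{pct:+d}", scale_leak(cell, calibrate_rin_change(cell, pct, dt=dt)))
            )
    variants.append(("geom", scale_internal(cell, 1.2, 0.8)))
    for name, cell2 in variants:
        for pair in location_pairs:
            l1, l2 = _loc_split(pair)
            for gc in gc_values:
                for ratio in gc_ratios:
                    model = pair_model(cell, cell2, l1, l2,
                                       gc_12=gc * ratio, gc_21=gc)
                    pm = passive_network(model)
                    sim = measure_coupling(pm, site="S", dt=dt, settle=200.0)
                    net = ConductanceNetwork.from_model(pm)
                    a12 = analytic_cc(net, (0, "S"), (0, "S"), (1, "S"))
                    a21 = analytic_cc(net, (1, "S"), (1, "S"), (0, "S"))
                    rows.append(
                        dict(variant=name, location=pair, gc=gc, gc_ratio=ratio,
                             cc_12_sim=sim.cc_12, cc_12_analytic=a12,
                             cc_21_sim=sim.cc_21, cc_21_analytic=a21,
                             rel_err_12=abs(sim.cc_12 - a12) / abs(a12),
                             rel_err_21=abs(sim.cc_21 - a21) / abs(a21),
                             ratio_sim=sim.cc_12 / sim.cc_21,
                             ratio_analytic=a12 / a21)
                    )
    return pd.DataFrame(rows)


def run_manifest(seed: int | None = None, **params) -> str:
    """JSON run manifest (full parameter echo) written next to sweep CSVs."""
    return json.dumps(
        {
            "package": "gapasym",
            "version": __version__,
            "kinetics": kinetics_table(),
            "seed": seed,
            "params": params,
        },
        indent=2,
        default=str,
    )
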
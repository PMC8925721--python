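"""TRN cell parameter sets: single-compartment and soma/middle/distal models.

All compartments are treated as unit-area isopotential patches, so
conductance densities (mS/cm^2) and current densities (uA/cm^2) are used
directly as absolute quantities in a consistent unit system; the model
prints no membrane areas and none are needed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import yaml

from .channels import ChannelSpec

COMPARTMENT_LABELS = ("S", "M", "D")

#: Reversal potential of the leak conductance, mV.
E_LEAK = -75.0


@dataclass(frozen=True)
class CompartmentParams:
    """Passive and active membrane parameters of one isopotential compartment."""

    label: str
    c_m: float  # specific capacitance, uF/cm^2
    g_leak: float  # leak conductance, mS/cm^2
    e_leak: float  # leak reversal, mV
    channels: tuple[ChannelSpec, ...] = ()

    def __post_init__(self):
        if self.label not in COMPARTMENT_LABELS:
            raise ValueError(f"label must be one of {COMPARTMENT_LABELS}")
        if not self.c_m > 0:
            raise ValueError("c_m must be positive")
        if self.g_leak < 0:
            raise ValueError("g_leak must be non-negative")
        if self.label in ("M", "D") and any(c.name == "NaT" for c in self.channels):
            raise ValueError("dendritic compartments carry no NaT current")

    def g_max(self, name: str) -> float:
        for c in self.channels:
            if c.name == name:
                return c.g_max
        return 0.0


@dataclass(frozen=True)
class CellParams:
    """Ordered compartments plus reciprocal inter-compartment conductances.

    ``g_internal`` maps adjacent label pairs, e.g. ``("M", "S")``, to the
    conductance (mS/cm^2) of the resistive link between them; internal links
    are reciprocal (one conductance serves both directions).
    """

    compartments: tuple[CompartmentParams, ...]
    g_internal: tuple[tuple[str, str, float], ...] = ()

    def __post_init__(self):
        labels = [c.label for c in self.compartments]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate compartment labels")
        for a, b, g in self.g_internal:
            if a not in labels or b not in labels:
                raise ValueError(f"internal link {a}-{b} references missing compartment")
            if g < 0:
                raise ValueError("internal conductance must be non-negative")

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(c.label for c in self.compartments)

    def compartment(self, label: str) -> CompartmentParams:
        for c in self.compartments:
            if c.label == label:
                return c
        raise KeyError(label)


def _chan(**g_max_by_name) -> tuple[ChannelSpec, ...]:
    return tuple(ChannelSpec(name, g) for name, g in g_max_by_name.items())


def make_single_compartment_trn() -> CellParams:
    """The single-compartment TRN model.

    Maximal conductances (mS/cm^2): NaT 60.5, Kd 60, Kt 5, K2 0.5, AR 0.025,
    CaT 0.75; capacitance 1 uF/cm^2; leak 0.1 mS/cm^2 reversing at -75 mV.
    """
    soma = CompartmentParams(
        label="S",
        c_m=1.0,
        g_leak=0.1,
        e_leak=E_LEAK,
        channels=_chan(NaT=60.5, Kd=60.0, Kt=5.0, K2=0.5, AR=0.025, CaT=0.75),
    )
    return CellParams(compartments=(soma,))


def make_three_compartment_trn() -> CellParams:
    """The three-compartment (soma, middle, distal) TRN model.

    Soma conductances (mS/cm^2): NaT 60.5, Kd 90, Kt 5, K2 0.5, AR 0.005,
    CaT 0.5; dendrites carry no NaT and a reduced CaT of 0.15.  Leak is 0.1
    at the soma and 0.035 in dendrites; capacitance 1.2 uF/cm^2 everywhere.
    Internal links: D-M 0.35 and M-S 0.4 mS/cm^2.
    """
    soma = CompartmentParams(
        label="S",
        c_m=1.2,
        g_leak=0.1,
        e_leak=E_LEAK,
        channels=_chan(NaT=60.5, Kd=90.0, Kt=5.0, K2=0.5, AR=0.005, CaT=0.5),
    )
    dend = dict(Kd=90.0, Kt=5.0, K2=0.5, AR=0.005, CaT=0.15)
    middle = CompartmentParams(
        label="M", c_m=1.2, g_leak=0.035, e_leak=E_LEAK, channels=_chan(**dend)
    )
    distal = CompartmentParams(
        label="D", c_m=1.2, g_leak=0.035, e_leak=E_LEAK, channels=_chan(**dend)
    )
    return CellParams(
        compartments=(soma, middle, distal),
        g_internal=(("D", "M", 0.35), ("M", "S", 0.4)),
    )


def scale_leak(cell: CellParams, factor: float, soma_only: bool = False) -> CellParams:
    """Multiply leak conductances by ``factor`` (input-resistance manipulation).

    By default every compartment is scaled; ``soma_only=True`` restricts the
    change to the soma for sensitivity checks.
    """
    if not factor > 0:
        raise ValueError("leak scale factor must be positive")
    comps = tuple(
        c if (soma_only and c.label != "S")
        else replace(c, g_leak=c.g_leak * factor)
        for c in cell.compartments
    )
    return replace(cell, compartments=comps)


def scale_internal(cell: CellParams, ms_factor: float, dm_factor: float) -> CellParams:
    """Scale the M-S and D-M internal conductances by the given factors."""
    if not (ms_factor > 0 and dm_factor > 0):
        raise ValueError("internal scale factors must be positive")
    links = []
    for a, b, g in cell.g_internal:
        pair = {a, b}
        if pair == {"M", "S"}:
            g = g * ms_factor
        elif pair == {"D", "M"}:
            g = g * dm_factor
        links.append((a, b, g))
    return replace(cell, g_internal=tuple(links))


# --------------------------------------------------------------------------
# Flat-config serialization
# --------------------------------------------------------------------------

def cell_to_dict(cell: CellParams) -> dict:
    """Flat, human-readable representation (round-trips via cell_from_dict)."""
    return {
        "compartments": [
            {
                "label": c.label,
                "c_m": c.c_m,
                "g_leak": c.g_leak,
                "e_leak": c.e_leak,
                "channels": {ch.name: {"g_max": ch.g_max, "e_rev": ch.e_rev}
                             for ch in c.channels},
            }
            for c in cell.compartments
        ],
        "g_internal": [[a, b, g] for a, b, g in cell.g_internal],
    }


def cell_from_dict(d: dict) -> CellParams:
    comps = tuple(
        CompartmentParams(
            label=c["label"],
            c_m=c["c_m"],
            g_leak=c["g_leak"],
            e_leak=c["e_leak"],
            channels=tuple(
                ChannelSpec(name, spec["g_max"], spec.get("e_rev"))
                for name, spec in c.get("channels", {}).items()
            ),
        )
        for c in d["compartments"]
    )
    links = tuple((a, b, float(g)) for a, b, g in d.get("g_internal", []))
    return CellParams(compartments=comps, g_internal=links)


def save_cell(cell: CellParams, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cell_to_dict(cell), fh, sort_keys=False)


def load_cell(path) -> CellParams:
    with open(path) as fh:
        return cell_from_dict(yaml.safe_load(fh))
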
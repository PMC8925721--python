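"""Minimal plotting helpers for sweep tables (matplotlib optional)."""

from __future__ import annotations


def plot_cc_vs_gc(df, site="S", ax=None):
    """Coupling coefficient versus G_c, one line per junction location."""
    import matplotlib.pyplot as plt

    ax = ax or plt.gca()
    sub = df[df.get("site", site) == site] if "site" in df else df
    for loc, grp in sub.groupby("location"):
        ax.plot(grp.gc, grp.cc_12, marker="o", label=loc)
    ax.set_xlabel("G_c (mS/cm$^2$)")
    ax.set_ylabel("cc$_{12}$")
    ax.legend(title="location")
    return ax


def plot_ratio_heatmap(df, location, ax=None):
    """cc-ratio heat map over internal-conductance scale factors."""
    import matplotlib.pyplot as plt

    ax = ax or plt.gca()
    sub = df[df.location == location]
    pivot = sub.pivot_table(index="dm_factor", columns="ms_factor",
                            values="cc_ratio")
    im = ax.imshow(pivot.values, origin="lower", aspect="auto",
                   extent=[pivot.columns.min(), pivot.columns.max(),
                           pivot.index.min(), pivot.index.max()])
    ax.set_xlabel("M-S factor (cell 2)")
    ax.set_ylabel("D-M factor (cell 2)")
    ax.set_title(f"cc ratio, {location}")
    plt.colorbar(im, ax=ax)
    return ax


def plot_phase_map(df, ax=None):
    """Phase difference versus G_c ratio, one line per junction strength."""
    import matplotlib.pyplot as plt

    ax = ax or plt.gca()
    for gc21, grp in df.groupby("gc_21"):
        ax.plot(grp.gc_ratio, grp.phase_deg, marker="o", label=f"{gc21:g}")
    ax.set_xscale("log")
    ax.set_xlabel("G$_c$ ratio (Gc$_{12}$/Gc$_{21}$)")
    ax.set_ylabel("phase difference (deg)")
    ax.legend(title="Gc$_{21}$ (mS/cm$^2$)")
    return ax
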
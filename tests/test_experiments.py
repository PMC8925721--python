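import numpy as np
import pandas as pd
import pytest

from gapasym import experiments as ex


@pytest.fixture(scope="module")
def small_location_grid():
    return ex.run_location_grid(gc_values=(0.05, 0.15, 0.25))


class TestLocationGrid:
    def test_matched_locations_symmetric(self, small_location_grid):
        matched = small_location_grid[
            small_location_grid.location.isin(["S-S", "M-M", "D-D"])
        ]
        assert np.allclose(matched.cc_ratio, 1.0, atol=1e-6)

    def test_mirror_pairs_reciprocal(self, small_location_grid):
        df = small_location_grid.set_index(["location", "gc"])
        for a, b in (("M-D", "D-M"), ("S-M", "M-S"), ("S-D", "D-S")):
            for gc in (0.05, 0.15, 0.25):
                ra = df.loc[(a, gc), "cc_ratio"]
                rb = df.loc[(b, gc), "cc_ratio"]
                assert ra == pytest.approx(1.0 / rb, rel=1e-6)

    def test_asymmetry_ordering_by_mismatch(self, small_location_grid):
        """|log cc ratio| is largest for soma-distal pairs, intermediate for
        soma-middle, smallest for middle-distal, at fixed G_c."""
        df = small_location_grid[small_location_grid.gc == 0.15]
        mag = {loc: abs(np.log(df[df.location == loc].cc_ratio.iloc[0]))
               for loc in ("S-D", "S-M", "M-D")}
        assert mag["S-D"] > mag["S-M"] > mag["M-D"] > 0

    def test_cc_increases_with_gc(self, small_location_grid):
        for loc, grp in small_location_grid.groupby("location"):
            grp = grp.sort_values("gc")
            assert np.all(np.diff(grp.cc_12) > 0)

    def test_rows_reproducible_bit_identically(self, small_location_grid):
        again = ex.run_location_grid(gc_values=(0.15,), location_pairs=("S-D",))
        ref = small_location_grid.query("location == 'S-D' and gc == 0.15")
        assert again.cc_12.iloc[0] == ref.cc_12.iloc[0]
        assert again.cc_ratio.iloc[0] == ref.cc_ratio.iloc[0]


def test_cc_map_observational_band():
    """Dendritically located junctions (the anatomically realistic case)
    keep somatic coupling inside the 0-0.3 band observed in paired
    recordings over the study's printed G_c range (up to 0.2 mS/cm^2);
    coupling weakens with distance from the soma."""
    df = ex.run_cc_map(gc_values=(0.01, 0.15, 0.2), include_single=False)
    soma_site = df[df.site == "S"]
    for loc in ("M-M", "D-D"):
        cc = soma_site[soma_site.location == loc].cc_12
        assert (cc > 0).all()
        assert (cc < 0.31).all()
    at_ref = soma_site[soma_site.gc == 0.15].set_index("location").cc_12
    assert at_ref["S-S"] > at_ref["M-M"] > at_ref["D-D"]


def test_rin_sweep_soma_junction_cc21_constant():
    """For soma-soma junctions, changing cell 2's R_in moves cc_12 but
    leaves cc_21 nearly unchanged."""
    df = ex.run_rin_sweep(gc_values=(0.15,), rin_pcts=(-20, 0, 20),
                          location_pairs=("S-S",))
    cc21 = df.cc_21.to_numpy()
    cc12 = df.cc_12.to_numpy()
    assert np.ptp(cc21) / cc21.mean() < 0.05
    assert np.ptp(cc12) / cc12.mean() > 0.15
    # R_in of cell 2 up -> cc_12 up
    df = df.sort_values("rin_change_pct")
    assert np.all(np.diff(df.cc_12) > 0)


def test_geometry_sweep_direction():
    """Raising cell-2 internal conductance lowers the cc ratio; lowering it
    raises the ratio (all junction locations)."""
    df = ex.run_geometry_sweep(ms_factors=(0.8, 1.0, 1.2),
                               dm_factors=(1.0,),
                               location_pairs=("S-S", "M-D"))
    for loc, grp in df.groupby("location"):
        grp = grp.sort_values("ms_factor")
        assert np.all(np.diff(grp.cc_ratio) < 0)


def test_gcratio_sweep_tracks_conductance_ratio():
    df = ex.run_gcratio_sweep(ratio_values=(0.5, 1.0, 2.0), rin_pcts=(0,))
    df = df.sort_values("gc_ratio")
    assert np.all(np.diff(df.cc_ratio) > 0)
    assert df[df.gc_ratio == 1.0].cc_ratio.iloc[0] == pytest.approx(1.0, abs=1e-6)


def test_symmetric_synchrony_ratio_one_consistency():
    """The ratio-1.0 column of the asymmetry map equals the symmetric sweep
    at matching G_c."""
    m = ex.run_synchrony_map(gc21_values=(0.0125,), ratio_values=(1.0,))
    s = ex.run_symmetric_synchrony_sweep(gc_values=(0.0125,))
    assert m.phase_deg.iloc[0] == pytest.approx(s.phase_deg.iloc[0], abs=1e-9)
    assert m.isi_1.iloc[0] == pytest.approx(s.isi_1.iloc[0], abs=1e-9)


def test_latency_sweep_table_shape_and_flags():
    df = ex.run_latency(gc_values=(0.15,), onset_diffs=(-10, 0, 10),
                        location_pairs=("S-S",))
    assert len(df) == 3
    assert set(["location", "gc_21", "onset_diff", "latency_difference"]) \
        <= set(df.columns)
    zero = df[df.onset_diff == 0]
    assert zero.latency_difference.iloc[0] == pytest.approx(0.0, abs=1e-9)
    # antisymmetric in onset difference for a symmetric junction
    assert df[df.onset_diff == 10].latency_difference.iloc[0] == pytest.approx(
        -df[df.onset_diff == -10].latency_difference.iloc[0], abs=1e-9
    )


def test_manifest_contains_kinetics_echo():
    import json

    manifest = json.loads(ex.run_manifest(seed=7, dt=0.01))
    assert manifest["seed"] == 7
    assert "NA_OFFSET" in manifest["kinetics"]
    assert manifest["params"]["dt"] == 0.01
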
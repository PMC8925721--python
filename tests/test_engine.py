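import numpy as np
import pytest

from gapasym import (
    ElectricalSynapse,
    NetworkModel,
    SimulationConfig,
    StimulusProtocol,
    detect_spikes,
    simulate,
)
from gapasym.analytic_oracle import strip_channels
from gapasym.engine import SimulationError
from gapasym.experiments import pair_model


@pytest.fixture(scope="module")
def passive_cell(three_cell):
    return strip_channels(three_cell)


def test_passive_rc_step_response(single_cell):
    """Channels zeroed: a -1 uA/cm^2 step gives dV = I/g_leak = -10 mV with
    an exponential approach at tau = c_m / g_leak = 10 ms."""
    cell = strip_channels(single_cell)
    model = NetworkModel(
        cells=[cell],
        injected_currents=[StimulusProtocol("step", (0, "S"), -1.0,
                                            onset=50.0, duration=400.0)],
    )
    res = simulate(model, SimulationConfig(duration=500.0, settle_time=100.0))
    v = res.trace(0, "S")
    assert v[0] == pytest.approx(-75.0, abs=1e-6)
    # near the end of the step: fully settled at dV = I / g_leak
    k_end = int(round(449.0 / res.dt))
    assert v[k_end] == pytest.approx(-85.0, abs=1e-3)
    # one membrane time constant after onset: 63.2 % of the deflection
    k = int(round((50.0 + 10.0) / res.dt))
    assert v[k] == pytest.approx(-75.0 - 10.0 * (1 - np.exp(-1)), abs=0.01)


def test_dt_convergence_subthreshold(three_cell):
    """Halving dt changes final voltages by < 1e-3 mV on a coupled run."""
    def final_v(dt):
        model = pair_model(three_cell, three_cell, "S", "M", 0.15)
        model.injected_currents = [
            StimulusProtocol("step", (0, "S"), -0.5, onset=100.0, duration=800.0)
        ]
        res = simulate(model, SimulationConfig(dt=dt, duration=1000.0,
                                               settle_time=300.0))
        return res.v[:, -1]

    assert np.abs(final_v(0.01) - final_v(0.005)).max() < 1e-3


def test_exchange_symmetry_bit_exact(three_cell):
    """Relabeling cell 1 <-> 2 in a mirror-symmetric configuration mirrors
    all outputs exactly."""
    def traces(l1, l2, g12, g21, drive_cell):
        model = pair_model(three_cell, three_cell, l1, l2, g12, g21)
        model.injected_currents = [
            StimulusProtocol("step", (drive_cell, l1 if drive_cell == 0 else l2),
                             -0.5, onset=100.0, duration=300.0)
        ]
        res = simulate(model, SimulationConfig(duration=500.0, settle_time=200.0))
        return res

    a = traces("M", "D", 0.2, 0.1, 0)
    b = traces("D", "M", 0.1, 0.2, 1)
    for label in ("S", "M", "D"):
        assert np.array_equal(a.trace(0, label), b.trace(1, label))
        assert np.array_equal(a.trace(1, label), b.trace(0, label))


def test_determinism_bit_exact(three_cell):
    model = pair_model(three_cell, three_cell, "S", "D", 0.15)
    model.injected_currents = [
        StimulusProtocol("step", (0, "S"), -0.5, onset=50.0, duration=200.0)
    ]
    cfg = SimulationConfig(duration=300.0, settle_time=100.0)
    r1 = simulate(model, cfg)
    r2 = simulate(model, cfg)
    assert np.array_equal(r1.v, r2.v)


def test_no_nan_and_trace_length(three_cell):
    model = NetworkModel(cells=[three_cell])
    res = simulate(model, SimulationConfig(dt=0.01, duration=100.0, settle_time=10.0))
    assert res.v.shape[1] == int(100.0 / 0.01) + 1
    assert np.all(np.isfinite(res.v))


def test_blowup_diagnostic_names_compartment(three_cell):
    model = NetworkModel(
        cells=[three_cell],
        injected_currents=[StimulusProtocol("step", (0, "D"), 1e5,
                                            onset=0.0, duration=50.0)],
    )
    with pytest.raises(SimulationError, match=r"cell 0, compartment 'D'"):
        simulate(model, SimulationConfig(duration=50.0, settle_time=0.0))


def test_validation_rejects_dangling_endpoints(three_cell):
    model = NetworkModel(
        cells=[three_cell],
        electrical_synapses=[ElectricalSynapse((0, "S"), (1, "S"), 0.1, 0.1)],
    )
    with pytest.raises(ValueError, match="missing cell"):
        simulate(model, SimulationConfig(duration=1.0))
    model = NetworkModel(
        cells=[three_cell],
        injected_currents=[StimulusProtocol("step", (0, "X"), 1.0, duration=1.0)],
    )
    with pytest.raises(ValueError, match="missing compartment"):
        simulate(model, SimulationConfig(duration=1.0))


class TestDetectSpikes:
    def test_flat_trace(self):
        assert len(detect_spikes(np.full(1000, -75.0), 0.01)) == 0

    def test_single_spike(self, single_cell):
        model = NetworkModel(
            cells=[single_cell],
            injected_currents=[StimulusProtocol("step", (0, "S"), 2.0,
                                                onset=50.0, duration=5.0)],
        )
        res = simulate(model, SimulationConfig(duration=150.0, settle_time=500.0))
        sp = detect_spikes(res.trace(0, "S"), res.dt)
        assert len(sp) == 1
        assert 50.0 < sp[0] < 80.0

    def test_count_matches_local_maximum_oracle(self, single_cell):
        """Tonic train: crossing count equals an independent local-maxima
        count above threshold."""
        model = NetworkModel(
            cells=[single_cell],
            injected_currents=[StimulusProtocol("tonic", (0, "S"), 0.7)],
        )
        res = simulate(model, SimulationConfig(duration=1500.0, settle_time=500.0))
        v = res.trace(0, "S")
        sp = detect_spikes(v, res.dt)
        interior = v[1:-1]
        maxima = np.flatnonzero(
            (interior > 0.0) & (interior >= v[:-2]) & (interior > v[2:])
        )
        # merge maxima within 2 ms (same spike)
        merged = 1 + int(np.sum(np.diff(maxima * res.dt) >= 2.0)) if len(maxima) else 0
        assert len(sp) == merged

    def test_threshold_insensitivity(self, single_cell):
        model = NetworkModel(
            cells=[single_cell],
            injected_currents=[StimulusProtocol("tonic", (0, "S"), 0.6)],
        )
        res = simulate(model, SimulationConfig(duration=1000.0, settle_time=500.0))
        v = res.trace(0, "S")
        counts = {thr: len(detect_spikes(v, res.dt, threshold=thr))
                  for thr in (-20.0, -10.0, 0.0, 10.0)}
        assert len(set(counts.values())) == 1
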
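import numpy as np
import pytest

from gapasym import NetworkModel, StimulusProtocol
from gapasym.analytic_oracle import (
    ConductanceNetwork,
    analytic_cc,
    passive_network,
    strip_channels,
)
from gapasym.cell import CellParams, CompartmentParams, scale_leak
from gapasym.experiments import pair_model
from gapasym.measurements import (
    SpikeContaminationError,
    calibrate_rin_change,
    measure_coupling,
    measure_input_resistance,
    measure_latency,
    measure_synchrony,
    spike_train_phase,
)
from gapasym.stimuli import make_tonic_pair


class TestCoupling:
    def test_no_junction_means_no_coupling(self, three_cell):
        model = NetworkModel(cells=[three_cell, three_cell])
        m = measure_coupling(model, site="S")
        assert m.cc_12 == pytest.approx(0.0, abs=1e-9)
        assert m.cc_21 == pytest.approx(0.0, abs=1e-9)

    def test_matched_compartments_symmetric(self, three_cell):
        m = measure_coupling(pair_model(three_cell, three_cell, "M", "M", 0.15))
        assert m.cc_ratio == pytest.approx(1.0, abs=1e-6)

    def test_soma_measured_cc_ordering_by_location(self, three_cell):
        ccs = {}
        for loc in ("S", "M", "D"):
            m = measure_coupling(pair_model(three_cell, three_cell, loc, loc, 0.15))
            ccs[loc] = m.cc_12
        assert ccs["S"] > ccs["M"] > ccs["D"] > 0

    def test_dendritic_measurement_stronger_for_distal_junction(self, three_cell):
        model = pair_model(three_cell, three_cell, "D", "D", 0.15)
        soma = measure_coupling(model, site="S")
        dend = measure_coupling(model, site="D")
        assert dend.cc_12 > soma.cc_12

    def test_passive_limit_matches_oracle(self, three_cell):
        model = passive_network(pair_model(three_cell, three_cell, "M", "D",
                                           0.18, 0.12))
        sim = measure_coupling(model, site="S", settle=200.0)
        net = ConductanceNetwork.from_model(model)
        a12 = analytic_cc(net, (0, "S"), (0, "S"), (1, "S"))
        assert sim.cc_12 == pytest.approx(a12, rel=5e-3)

    def test_exchange_inverts_ratio_exactly(self, three_cell):
        cell2 = scale_leak(three_cell, 1.2)
        a = measure_coupling(pair_model(three_cell, cell2, "S", "M", 0.2, 0.1))
        b = measure_coupling(pair_model(cell2, three_cell, "M", "S", 0.1, 0.2))
        assert a.cc_ratio == pytest.approx(1.0 / b.cc_ratio, rel=1e-12)

    def test_spike_contamination_rejected(self, three_cell):
        model = pair_model(three_cell, three_cell, "S", "S", 0.01)
        model.injected_currents = [
            StimulusProtocol("tonic", (1, "S"), 1.5)  # cell 2 fires tonically
        ]
        with pytest.raises(SpikeContaminationError):
            measure_coupling(model)

    def test_two_cells_required(self, three_cell):
        with pytest.raises(ValueError):
            measure_coupling(NetworkModel(cells=[three_cell]))


class TestInputResistance:
    def test_passive_single_compartment_is_inverse_leak(self):
        cell = CellParams(
            compartments=(CompartmentParams("S", 1.0, 0.1, -75.0),)
        )
        r = measure_input_resistance(cell, settle=100.0)
        assert r == pytest.approx(10.0, rel=1e-4)

    def test_monotone_decreasing_in_leak_factor(self, three_cell):
        rs = [measure_input_resistance(scale_leak(three_cell, f))
              for f in (0.75, 1.0, 1.45)]
        assert rs[0] > rs[1] > rs[2]

    def test_printed_leak_bracket_reproduces_25_percent(self, three_cell):
        """Scaling leak by ~1.45 lowers somatic R_in by ~25 %."""
        r0 = measure_input_resistance(three_cell)
        r = measure_input_resistance(scale_leak(three_cell, 1.45))
        assert (r - r0) / r0 == pytest.approx(-0.25, abs=0.03)

    def test_calibration_round_trip(self, three_cell):
        for target in (-20.0, 12.0):
            f = calibrate_rin_change(three_cell, target)
            r0 = measure_input_resistance(three_cell)
            r = measure_input_resistance(scale_leak(three_cell, f))
            assert (r - r0) / r0 * 100 == pytest.approx(target, abs=0.15)
        assert calibrate_rin_change(three_cell, 0.0) == 1.0


class TestLatency:
    def test_uncoupled_equal_onsets_no_difference(self, three_cell):
        model = NetworkModel(cells=[three_cell, three_cell])
        r = measure_latency(model, 0.0, 0.0)
        assert r.latency_difference == pytest.approx(0.0, abs=1e-9)
        assert r.latency_1 == pytest.approx(r.latency_uncoupled_1, abs=1e-9)

    def test_zero_conductance_equals_uncoupled(self, three_cell):
        model = pair_model(three_cell, three_cell, "S", "S", 0.0)
        r = measure_latency(model, 0.0, 12.0)
        assert r.latency_1 == pytest.approx(r.latency_uncoupled_1, abs=1e-9)
        assert r.latency_2 == pytest.approx(r.latency_uncoupled_2, abs=1e-9)

    def test_coupling_modulates_latency(self, three_cell):
        model = pair_model(three_cell, three_cell, "S", "S", 0.2)
        r = measure_latency(model, 0.0, 20.0)
        assert r.latency_difference is not None
        assert abs(r.latency_difference) > 2.0


class TestSynchrony:
    def test_constructed_half_period_shift_is_antiphase(self):
        isi = 40.0
        sp1 = np.arange(100.0, 2000.0, isi)
        sp2 = sp1 + isi / 2.0
        _, _, lag, phase = spike_train_phase(sp1, sp2, 500.0, 1500.0, dt=0.1)
        assert abs(phase) == pytest.approx(180.0, abs=2.0)
        assert abs(abs(lag) - isi / 2.0) < 0.5

    def test_constructed_small_shift_phase(self):
        isi = 40.0
        sp1 = np.arange(100.0, 2000.0, isi)
        sp2 = sp1 + 4.0
        _, _, lag, phase = spike_train_phase(sp1, sp2, 500.0, 1500.0, dt=0.1)
        assert phase == pytest.approx(36.0, abs=2.0)

    def test_identical_cells_identical_drives_zero_phase(self, single_cell):
        model = pair_model(single_cell, single_cell, "S", "S", 0.01)
        model.injected_currents = list(make_tonic_pair(0.6, 0.6))
        m = measure_synchrony(model)
        assert m.phase_difference == pytest.approx(0.0, abs=1.0)
        assert m.isi_1 == pytest.approx(m.isi_2, rel=1e-9)

    def test_normalization_does_not_move_phase(self, single_cell):
        model = pair_model(single_cell, single_cell, "S", "S", 0.0125)
        model.injected_currents = list(make_tonic_pair())
        raw = measure_synchrony(model, normalize=False)
        norm = measure_synchrony(model, normalize=True)
        assert raw.phase_difference == pytest.approx(norm.phase_difference,
                                                     abs=1.0)

    def test_too_few_spikes_raises(self, single_cell):
        model = pair_model(single_cell, single_cell, "S", "S", 0.01)
        # zero drive: no tonic firing
        with pytest.raises(ValueError):
            measure_synchrony(model)
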
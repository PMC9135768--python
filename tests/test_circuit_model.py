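"""Network construction, gating math and simulation behaviour."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tadgaze import circuit_model as cm


class TestGatingMath:
    G = cm.GatingParams()

    def test_midpoint_is_half_amplitude(self):
        assert cm.gating_coefficient(self.G.iTrans_nA, self.G) == pytest.approx(
            self.G.sigmAmp / 2)

    def test_lower_limit_zero(self):
        assert cm.gating_coefficient(-100.0, self.G) == pytest.approx(0.0, abs=1e-12)

    def test_printed_formula_at_four_steepness_units(self):
        g = cm.GatingParams(sigmAmp=1.0)
        x = g.iTrans_nA + 4.0 / g.sigmSteep_per_nA
        expected = np.exp(4) / (1 + np.exp(4))
        assert cm.gating_coefficient(x, g) == pytest.approx(expected, rel=1e-9)

    @settings(deadline=None, max_examples=30)
    @given(st.floats(min_value=-0.1, max_value=0.2),
           st.floats(min_value=1e-4, max_value=0.05))
    def test_strictly_increasing_and_bounded(self, i, di):
        lo = cm.gating_coefficient(i, self.G)
        hi = cm.gating_coefficient(i + di, self.G)
        assert 0.0 <= lo < hi <= self.G.sigmAmp

    def test_nonfinite_input_rejected(self):
        with pytest.raises(ValueError):
            cm.gating_coefficient(float("nan"), self.G)

    def test_max_conductance_product(self):
        g = cm.GatingParams(num_syn_inh=5, unitary_gGABA_nS=1.0)
        assert cm.max_inhibitory_conductance(g, 0.5) == pytest.approx(2.5)
        assert cm.max_inhibitory_conductance(g, 0.0) == 0.0
        g1 = cm.GatingParams(num_syn_inh=1, unitary_gGABA_nS=7.3)
        assert cm.max_inhibitory_conductance(g1, 1.0) == pytest.approx(7.3)

    def test_negative_coefficient_rejected(self):
        with pytest.raises(ValueError):
            cm.max_inhibitory_conductance(self.G, -0.1)

    def test_linear_in_each_factor(self):
        g2 = cm.GatingParams(num_syn_inh=10, unitary_gGABA_nS=2.0)
        g1 = cm.GatingParams(num_syn_inh=10, unitary_gGABA_nS=1.0)
        assert cm.max_inhibitory_conductance(g2, 0.3) == pytest.approx(
            2 * cm.max_inhibitory_conductance(g1, 0.3))


class TestNetworkStructure:
    def test_fourteen_neurons_seven_roles_two_sides(self, default_network):
        assert len(default_network.membranes) == 14
        names = {cm.neuron_name(i) for i in range(14)}
        assert len(names) == 14
        for role in cm.ROLES:
            assert {f"{role}_L", f"{role}_R"} <= names

    def test_vo_projects_to_contralateral_abducens(self, default_network):
        edges = default_network.edges()
        assert (cm.neuron_index("L", "VO"), cm.neuron_index("R", "AbdMN"),
                "AMPA") in edges
        assert (cm.neuron_index("R", "VO"), cm.neuron_index("L", "AbdMN"),
                "AMPA") in edges

    def test_no_din_to_contralateral_spmn(self, default_network):
        edges = {(s, t) for s, t, _ in default_network.edges()}
        assert (cm.neuron_index("L", "dIN"),
                cm.neuron_index("R", "spMN")) not in edges

    def test_full_edge_set_matches_wiring_diagram(self, default_network):
        ix = cm.neuron_index
        expected = set()
        for s, c in (("L", "R"), ("R", "L")):
            expected |= {
                (ix(s, "dIN"), ix(s, "cIN"), "AMPA"),
                (ix(s, "dIN"), ix(s, "spMN"), "AMPA"),
                (ix(s, "dIN"), ix(s, "dIN"), "AMPA"),
                (ix(s, "dIN"), ix(s, "dIN"), "NMDA"),
                (ix(s, "cIN"), ix(c, "cIN"), "inhibitory"),
                (ix(s, "cIN"), ix(c, "dIN"), "inhibitory"),
                (ix(s, "cIN"), ix(c, "spMN"), "inhibitory"),
                (ix(s, "spMN"), ix(s, "EC"), "AMPA"),
                (ix(s, "EC"), ix(c, "AbdMN"), "AMPA"),
                (ix(s, "VO"), ix(c, "AbdMN"), "AMPA"),
                (ix(s, "VS"), ix(s, "spMN"), "AMPA"),
                (ix(s, "VS"), ix(s, "EC"), "AMPA"),
            }
        assert default_network.edges() == expected

    def test_each_vo_has_gated_external_inhibition(self, default_network):
        gated = [s for s in default_network.synapses if s.source < 0]
        targets = {s.target for s in gated}
        assert targets == {cm.neuron_index("L", "VO"), cm.neuron_index("R", "VO")}
        for s in gated:
            assert s.kind == "inhibitory"

    def test_missing_template_is_configuration_error(self):
        cfg = cm.load_default_config()
        del cfg["membrane"]["dIN"]
        with pytest.raises(KeyError):
            cm.build_default_network(cfg)


class TestSimulation:
    def test_deterministic_spike_times(self, default_network):
        stims = [cm.step_into_dins(0.15, duration_s=1.5)]
        a = cm.simulate(default_network, stims, 1.5, seed=3)
        b = cm.simulate(default_network, stims, 1.5, seed=3)
        for name in a.spikes_s:
            assert np.array_equal(a.spikes_s[name], b.spikes_s[name])

    def test_zero_current_no_rhythm(self, default_network):
        sim = cm.simulate(default_network,
                          [cm.step_into_dins(0.0, duration_s=2.0)], 2.0)
        assert cm.burst_frequency(sim, "spMN_L") == 0.0
        assert all(len(sim.spikes_s[n]) == 0 for n in ("spMN_L", "spMN_R"))

    def test_rhythm_frequency_at_reference_drive(self, swim_sim):
        assert cm.burst_frequency(swim_sim, "spMN_L") == pytest.approx(7.0, abs=0.5)

    def test_spmn_alternation(self, swim_sim):
        """Left and right motoneurons alternate: no near-coincident bursts."""
        L = swim_sim.spikes_s["spMN_L"]
        R = swim_sim.spikes_s["spMN_R"]
        L, R = L[L > 1.0], R[R > 1.0]
        T = np.median(np.diff(L))
        for t in R:
            assert np.min(np.abs(L - t)) > 0.15 * T

    def test_antiphase_at_low_drives(self, default_network):
        for istim in (0.12, 0.13):
            sim = cm.simulate(default_network,
                              [cm.step_into_dins(istim, duration_s=4.0)], 4.0)
            L = sim.spikes_s["dIN_L"]
            R = sim.spikes_s["dIN_R"]
            L, R = L[L > 1.0], R[R > 1.0]
            T = np.median(np.diff(L))
            ph = [((R[np.argmin(np.abs(R - t))] - t) / T * 360) for t in L]
            mean = np.degrees(np.angle(np.mean(np.exp(1j * np.radians(ph))))) % 360
            assert abs(mean - 180.0) < 20.0

    def test_frequency_monotone_in_drive(self, default_network):
        freqs = []
        for istim in (0.12, 0.16, 0.22, 0.3):
            sim = cm.simulate(default_network,
                              [cm.step_into_dins(istim, duration_s=3.0)], 3.0)
            freqs.append(cm.burst_frequency(sim, "spMN_L"))
        assert all(b >= a for a, b in zip(freqs, freqs[1:]))
        assert freqs[-1] == pytest.approx(12.0, abs=1.5)

    def test_burst_count_matches_frequency(self, swim_sim):
        env = cm.motoneuron_envelope(swim_sim, "spMN_L")
        from tadgaze.signal_conditioning import detect_burst_peaks
        events = detect_burst_peaks(env, min_separation_ms=40.0)
        events = events[events >= 0.5]
        freq = cm.burst_frequency(swim_sim, "spMN_L")
        assert events.size == pytest.approx(freq * 4.5, abs=1.5)

    def test_gate_silences_vo_not_vs(self, default_network):
        sin = lambda: cm.sinusoid_into(("VO", "VS"), 0.2, 1.0, duration_s=3.0)
        below = cm.simulate(default_network,
                            [cm.step_into_dins(0.13, duration_s=3.0), sin()], 3.0)
        above = cm.simulate(default_network,
                            [cm.step_into_dins(0.2, duration_s=3.0), sin()], 3.0)
        assert cm.vo_spike_count(below) > 50
        assert cm.vo_spike_count(above) == 0
        n_vs_below = len(below.spikes_s["VS_L"])
        n_vs_above = len(above.spikes_s["VS_L"])
        assert n_vs_above == pytest.approx(n_vs_below, abs=2)

    def test_vo_fires_only_in_depolarizing_half_cycle(self, default_network):
        sim = cm.simulate(default_network,
                          [cm.sinusoid_into(("VO",), 0.2, 1.0, duration_s=3.0)],
                          3.0)
        phases = sim.spikes_s["VO_L"] % 1.0
        assert phases.size > 20
        assert np.all((phases > 0.0) & (phases < 0.5))

    def test_short_duration_rejected(self, default_network):
        with pytest.raises(ValueError):
            cm.simulate(default_network,
                        [cm.step_into_dins(0.15, duration_s=5.0)], 1.0)

    def test_csv_round_trip(self, swim_sim, tmp_path):
        cm.export_sim_csv(swim_sim, tmp_path)
        vdf, spikes = cm.read_sim_csv(tmp_path)
        assert np.allclose(vdf["spMN_L"].to_numpy(),
                           swim_sim.voltage("spMN_L"))
        assert np.allclose(spikes["dIN_L"], swim_sim.spikes_s["dIN_L"])
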
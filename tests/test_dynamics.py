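"""Dynamics engine: the backward-Euler matrix step, integrate-and-fire,
clamps, disconnect equivalence, and response measurement."""
import numpy as np
import pytest

from lpnet.dynamics import (
    ExperimentControls,
    Network,
    Simulation,
    SimulationResult,
    measure_response,
)
from lpnet.stimuli import render_uniform_motion, sine_grating


def isolated_steady_state(circuit, current=1.0, comp="den"):
    """Two-resistor closed form for an isolated cell's steady voltages."""
    cell = circuit.cell("HSE", "left")
    gd = cell.dendrite.leak_conductance
    ga = cell.axon.leak_conductance
    gc = cell.dendro_axonal_conductance
    det = gd * ga + gd * gc + gc * ga
    if comp == "den":
        v_inj = current * (ga + gc) / det
        v_other = v_inj * gc / (ga + gc)
    else:
        v_inj = current * (gd + gc) / det
        v_other = v_inj * gc / (gd + gc)
    return v_inj, v_other


class TestStep:
    def test_rest_is_a_fixed_point(self, circuit):
        net = Network(circuit)
        for _ in range(100):
            v = net.step()
        np.testing.assert_allclose(v, 0.0, atol=1e-15)

    def test_isolated_cell_matches_two_resistor_algebra(self, circuit):
        """1 nA into the dendrite of a synaptically isolated cell settles at
        the voltage divider of leak and coupling conductances: about
        6.7 mV in the dendrite and 3 mV in the axon."""
        iso = circuit.disconnected()
        net = Network(iso)
        inj = np.zeros(net.n)
        inj[iso.compartment_index("L:HSE:den")] = 1.0
        for _ in range(1000):
            v = net.step(inj=inj)
        vd_expect, va_expect = isolated_steady_state(circuit)
        assert v[iso.compartment_index("L:HSE:den")] == \
            pytest.approx(vd_expect, rel=1e-9)
        assert v[iso.compartment_index("L:HSE:ax")] == \
            pytest.approx(va_expect, rel=1e-9)
        assert vd_expect == pytest.approx(6.7, abs=0.1)
        assert va_expect == pytest.approx(3.0, abs=0.5)

    def test_spike_rate_saturates_at_one_per_two_steps(self, circuit):
        """A strongly driven spiking axon fires on every step not blocked by
        the one-step refractoriness: 250 Hz at dt = 2 ms."""
        iso = circuit.disconnected()
        net = Network(iso)
        i_ax = iso.compartment_index("L:H1:ax")
        inj = np.zeros(net.n)
        inj[i_ax] = 20.0
        trace = []
        for _ in range(1000):
            trace.append(net.step(inj=inj)[i_ax])
        trace = np.array(trace[4:])
        spikes = trace == iso.spike_value
        assert spikes.sum() == len(trace) // 2
        # strict alternation: spike, reset, spike, reset ...
        assert np.all(spikes[:-1] ^ spikes[1:])

    def test_back_propagated_spikes_attenuated_in_dendrite(self, circuit):
        iso = circuit.disconnected()
        net = Network(iso)
        inj = np.zeros(net.n)
        inj[iso.compartment_index("L:H1:ax")] = 1.0
        vd, va = [], []
        for _ in range(500):
            v = net.step(inj=inj)
            vd.append(v[iso.compartment_index("L:H1:den")])
            va.append(v[iso.compartment_index("L:H1:ax")])
        assert max(va) == iso.spike_value
        # capacitive filtering strongly reduces the dendritic spike echo
        assert 0 < max(vd) < 0.5 * iso.spike_value

    def test_clamp_overrides_injection(self, circuit):
        controls = ExperimentControls(injections={"L:VS5:den": 5.0},
                                      clamps={"L:VS5"})
        sim = Simulation(circuit, controls=controls)
        res = sim.run_movie(n_steps=200)
        np.testing.assert_allclose(res.trace("L:VS5:den"), 0.0, atol=1e-12)
        np.testing.assert_allclose(res.trace("L:VS5:ax"), 0.0, atol=1e-12)

    def test_clamped_cell_sinks_current_from_neighbours(self, circuit):
        free = Simulation(circuit, controls=ExperimentControls(
            injections={"L:VS5:den": 10.0}))
        clamped = Simulation(circuit, controls=ExperimentControls(
            injections={"L:VS5:den": 10.0}, clamps={"L:VS6"}))
        v_free = free.run_movie(n_steps=500).trace("L:VS5:ax")[-1]
        v_cl = clamped.run_movie(n_steps=500).trace("L:VS5:ax")[-1]
        # the clamped neighbour drags the injected cell's potential down
        assert v_cl < v_free


class TestChainInjection:
    def test_depolarizing_current_spreads_and_reverses(self, circuit):
        """+10 nA into VS1: responses decay monotonically with distance
        along the gap-junction chain and reverse sign at the far end
        through the end-to-end inhibitory loop."""
        sim = Simulation(circuit, controls=ExperimentControls(
            injections={"L:VS1:den": 10.0}))
        res = sim.run_movie(n_steps=1000)
        v = np.array([res.trace(f"L:VS{i}:ax")[-1] for i in range(1, 11)])
        assert np.all(np.diff(v[:6]) < 0)
        assert v[0] > 0
        assert v[-1] < 0

    def test_hyperpolarizing_current_does_not_reverse(self, circuit):
        sim = Simulation(circuit, controls=ExperimentControls(
            injections={"L:VS1:den": -10.0}))
        res = sim.run_movie(n_steps=1000)
        v = np.array([res.trace(f"L:VS{i}:ax")[-1] for i in range(1, 11)])
        assert np.all(v <= 0)

    def test_injection_into_vs10_mirrors_the_spread(self, circuit):
        sim = Simulation(circuit, controls=ExperimentControls(
            injections={"L:VS10:den": 10.0}))
        res = sim.run_movie(n_steps=1000)
        v = np.array([res.trace(f"L:VS{i}:ax")[-1] for i in range(1, 11)])
        assert np.all(np.diff(np.abs(v[4:])) > 0)
        assert v[-1] > 0 and v[0] < 0


class TestDisconnect:
    def test_disconnected_cells_are_independent(self, circuit):
        """With the global disconnect, injections into different cells do
        not interact (the system is block diagonal)."""
        base = Simulation(circuit, controls=ExperimentControls(
            injections={"L:VS5:den": 2.0}, disconnect_all=True))
        combo = Simulation(circuit, controls=ExperimentControls(
            injections={"L:VS5:den": 2.0, "L:VS9:den": -7.0,
                        "L:H1:ax": 1.0},
            disconnect_all=True))
        tr_base = base.run_movie(n_steps=300)
        tr_combo = combo.run_movie(n_steps=300)
        np.testing.assert_array_equal(tr_base.trace("L:VS5:den"),
                                      tr_combo.trace("L:VS5:den"))
        np.testing.assert_array_equal(tr_base.trace("L:VS5:ax"),
                                      tr_combo.trace("L:VS5:ax"))

    def test_disconnected_visual_responses_identical_across_vs(self, circuit):
        """Uniform downward motion drives every disconnected VS cell
        identically."""
        movie = render_uniform_motion("down", 45.0, 300.0,
                                      sine_grating(20.0, "horizontal"))
        sim = Simulation(circuit, movie.grid,
                         ExperimentControls(disconnect_all=True))
        res = sim.run_movie(movie)
        traces = [res.trace(f"L:VS{i}:ax") for i in range(1, 11)]
        for tr in traces[1:]:
            np.testing.assert_allclose(tr, traces[0], atol=1e-9)
        assert traces[0][-1] > 1.0


class TestNumerics:
    def test_steady_state_independent_of_initial_state(self, circuit):
        rng = np.random.default_rng(11)
        finals = []
        for _ in range(3):
            net = Network(circuit)
            net.reset(v0=rng.uniform(-20, 20, net.n))
            inj = np.zeros(net.n)
            inj[circuit.compartment_index("L:VS3:den")] = 4.0
            for _ in range(1500):
                v = net.step(inj=inj)
            finals.append(v)
        np.testing.assert_allclose(finals[1], finals[0], atol=1e-9)
        np.testing.assert_allclose(finals[2], finals[0], atol=1e-9)

    def test_linear_regime_scaling(self, circuit):
        """Small injected currents produce proportionally scaled responses
        (no chemical synapse engages at sub-threshold depolarizations of
        the wrong sign)."""
        def response(cur):
            sim = Simulation(circuit, controls=ExperimentControls(
                injections={"L:VS5:den": cur}))
            return sim.run_movie(n_steps=600).trace("L:VS5:ax")[-1]
        r1 = response(0.05)
        r2 = response(0.1)
        assert r2 / r1 == pytest.approx(2.0, rel=0.01)

    def test_voltage_bounds(self, circuit):
        movie = render_uniform_motion("down", 45.0, 200.0)
        sim = Simulation(circuit, movie.grid)
        res = sim.run_movie(movie)
        assert res.traces.min() >= circuit.e_inh
        assert res.traces.max() <= max(circuit.e_exc, circuit.spike_value)

    def test_movie_dt_mismatch_rejected(self, circuit):
        movie = render_uniform_motion("down", 45.0, 20.0, dt=1.0)
        sim = Simulation(circuit, movie.grid)
        with pytest.raises(ValueError, match="frame interval"):
            sim.run_movie(movie)


class TestMeasureResponse:
    def _result(self, trace, spiking=False):
        traces = np.asarray(trace, dtype=float)[:, None]
        return SimulationResult(
            traces=traces, dt=2.0, compartment_ids=["L:X:ax"],
            spiking_mask=np.array([spiking]), spike_value=100.0)

    def test_constant_trace(self):
        res = self._result([5.0] * 100)
        assert measure_response(res, "L:X:ax") == pytest.approx(5.0)

    def test_zero_trace(self):
        res = self._result([0.0] * 50)
        assert measure_response(res, "L:X:ax") == 0.0

    def test_spiking_rate(self):
        trace = [100.0, 0.0] * 250   # one spike every 4 ms for 1 s
        res = self._result(trace, spiking=True)
        assert measure_response(res, "L:X:ax", (0.0, 1000.0)) == \
            pytest.approx(250.0)

    def test_empty_window_rejected(self):
        res = self._result([1.0] * 10)
        with pytest.raises(ValueError, match="empty"):
            measure_response(res, "L:X:ax", (100.0, 100.0))
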
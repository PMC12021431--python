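import numpy as np
import pytest

import spikecode as sc
from spikecode.errors import ConfigurationError, ValidationError
from spikecode.network import NeuronParams, NeuronState, encode_input_current


def make_encoder(offsets, gain=1.0):
    n = len(offsets)
    return sc.InputEncoder(n_in=n, offsets=np.asarray(offsets, float), gain=gain)


class TestInputEncoding:
    def test_quadrant_one_point(self):
        # s = (3, 4): quadrant-1 neurons with zero offset receive the
        # magnitude 5, everyone else nothing
        enc = make_encoder([0.0] * 8)
        stim = sc.StimulusTrace(values=np.array([[3.0, 4.0]]), ds=2)
        cur = encode_input_current(stim, enc)
        assert np.allclose(cur[0, :2], 5.0)  # first quarter is quadrant 1
        assert np.all(cur[0, 2:] == 0)

    def test_origin_silences_everyone(self):
        enc = make_encoder([0.0] * 8)
        stim = sc.StimulusTrace(values=np.zeros((3, 2)), ds=2)
        assert np.all(encode_input_current(stim, enc) == 0)

    def test_offset_shifts_tuning(self):
        # s = (0.05, 0.05): a quadrant-1 neuron with offset 0.1 sees the
        # shifted point in quadrant 3 and stays silent; a zero-offset
        # quadrant-1 neuron is driven
        enc = make_encoder([0.1, 0.0] + [0.0] * 6)  # both in quadrant 1
        stim = sc.StimulusTrace(values=np.array([[0.05, 0.05]]), ds=2)
        cur = encode_input_current(stim, enc)
        assert cur[0, 0] == 0.0
        assert cur[0, 1] == pytest.approx(np.hypot(0.05, 0.05))

    def test_on_axis_points_drive_no_zero_offset_neuron(self):
        enc = make_encoder([0.0] * 4)
        stim = sc.StimulusTrace(values=np.array([[1.0, 0.0], [0.0, -2.0]]), ds=2)
        assert np.all(encode_input_current(stim, enc) == 0)

    def test_gain_scales_current(self):
        enc = make_encoder([0.0] * 4, gain=2.5)
        stim = sc.StimulusTrace(values=np.array([[1.0, 1.0]]), ds=2)
        cur = encode_input_current(stim, enc)
        assert cur[0, 0] == pytest.approx(2.5 * np.sqrt(2.0))

    def test_n_in_not_divisible_by_4(self):
        with pytest.raises(ConfigurationError):
            sc.InputEncoder(n_in=6, offsets=np.zeros(6))


class TestSynapticCurrent:
    def test_no_spikes_no_current(self):
        w = np.ones((3, 5))
        assert np.all(sc.synaptic_current(np.zeros(5), w) == 0)

    def test_one_hot_picks_column(self, rng):
        w = rng.standard_normal((4, 6))
        x = np.zeros(6)
        x[2] = 1
        np.testing.assert_allclose(sc.synaptic_current(x, w), w[:, 2])

    def test_matches_naive_double_loop(self, rng):
        w = rng.standard_normal((5, 7))
        x = (rng.random(7) < 0.5).astype(float)
        expected = np.array([sum(w[i, j] * x[j] for j in range(7)) for i in range(5)])
        np.testing.assert_allclose(sc.synaptic_current(x, w), expected)

    def test_shape_mismatch(self):
        with pytest.raises(ValidationError):
            sc.synaptic_current(np.zeros(4), np.ones((3, 5)))


class TestAlphaDynamics:
    def params(self, n=1, alpha=0.8, beta=0.7, thr=10.0):
        return NeuronParams(model="alpha", alpha=np.full(n, alpha),
                            beta=np.full(n, beta), u_thr=np.full(n, thr))

    def test_zero_input_fixed_point(self):
        p = self.params()
        state = NeuronState.zeros(1, "alpha")
        for _ in range(20):
            state, spikes = sc.step_alpha_layer(state, p, np.zeros(1))
            assert spikes[0] == 0
            assert state.u[0] == 0

    def test_pulse_follows_geometric_decays(self):
        # unit pulse at step 0, threshold unreachable: the current traces are
        # exactly alpha**n and -beta**n and U = tau * (alpha**n - beta**n)
        alpha, beta = 0.8, 0.7
        p = self.params(alpha=alpha, beta=beta)
        tau = float(sc.tau_alpha(np.array([alpha]), np.array([beta]))[0])
        state = NeuronState.zeros(1, "alpha")
        for n in range(5):
            cur = np.ones(1) if n == 0 else np.zeros(1)
            state, _ = sc.step_alpha_layer(state, p, cur)
            assert state.i_exc[0] == pytest.approx(alpha**n)
            assert state.i_inh[0] == pytest.approx(-(beta**n))
            assert state.u[0] == pytest.approx(tau * (alpha**n - beta**n))

    def test_constant_subthreshold_input_converges(self):
        alpha, beta, c = 0.85, 0.75, 0.01
        p = self.params(alpha=alpha, beta=beta, thr=10.0)
        tau = float(sc.tau_alpha(np.array([alpha]), np.array([beta]))[0])
        u_ss = tau * c * (1 / (1 - alpha) - 1 / (1 - beta))
        state = NeuronState.zeros(1, "alpha")
        for _ in range(300):
            state, spikes = sc.step_alpha_layer(state, p, np.full(1, c))
            assert spikes[0] == 0
        assert state.u[0] == pytest.approx(u_ss, rel=1e-6)

    def test_alpha_must_exceed_beta(self):
        with pytest.raises(ConfigurationError):
            NeuronParams(model="alpha", alpha=np.array([0.7]),
                         beta=np.array([0.8]), u_thr=np.array([0.5]))

    def test_positive_input_keeps_potential_nonnegative(self, rng):
        p = self.params(n=3, alpha=0.85, beta=0.7, thr=0.3)
        state = NeuronState.zeros(3, "alpha")
        for _ in range(200):
            state, _ = sc.step_alpha_layer(state, p, rng.random(3))
            assert np.all(state.u >= -1e-12)


class TestLifDynamics:
    def params(self, n=1, beta=0.8, thr=10.0):
        return NeuronParams(model="lif", alpha=None, beta=np.full(n, beta),
                            u_thr=np.full(n, thr))

    def test_zero_input_stays_zero(self):
        state = NeuronState.zeros(1, "lif")
        state, spikes = sc.step_lif_layer(state, self.params(), np.zeros(1))
        assert state.u[0] == 0 and spikes[0] == 0

    def test_constant_input_geometric_limit(self):
        beta, c = 0.8, 0.05
        p = self.params(beta=beta)
        state = NeuronState.zeros(1, "lif")
        for _ in range(200):
            state, _ = sc.step_lif_layer(state, p, np.full(1, c))
        assert state.u[0] == pytest.approx(c / (1 - beta), rel=1e-6)

    def test_threshold_crossing_resets(self):
        p = self.params(thr=0.5)
        state = NeuronState.zeros(1, "lif")
        state, spikes = sc.step_lif_layer(state, p, np.ones(1))
        assert spikes[0] == 1
        state, spikes = sc.step_lif_layer(state, p, np.zeros(1))
        assert state.u[0] == 0.0  # reset to U_reset on the following step

    def test_beta_bounds(self):
        with pytest.raises(ConfigurationError):
            self.params(beta=1.2)


class TestBuildNetwork:
    def test_weight_statistics(self):
        net = sc.build_network([100, 100], p=0.7, seed=0)
        w = net.weights[0]
        present = w != 0
        frac = present.mean()
        # binomial 3-sigma band around p over 10^4 entries
        assert abs(frac - 0.7) < 3 * np.sqrt(0.7 * 0.3 / w.size)
        var = w[present].var()
        assert abs(var - 1 / 70) / (1 / 70) < 0.1
        # signs balanced among present entries
        pos = (w[present] > 0).mean()
        assert abs(pos - 0.5) < 0.05

    def test_dense_when_p_is_one(self):
        net = sc.build_network([20, 20], p=1.0, seed=1)
        assert np.all(net.weights[0] != 0)

    def test_seed_contract(self):
        a = sc.build_network([16, 8, 4], seed=7)
        b = sc.build_network([16, 8, 4], seed=7)
        for wa, wb in zip(a.weights, b.weights):
            assert np.array_equal(wa, wb)
        assert np.array_equal(a.encoder.offsets, b.encoder.offsets)

    def test_parameter_tables(self):
        net = sc.build_network([400, 4], model="alpha", seed=0)
        p = net.neuron_params[0]
        assert np.all((p.alpha > 0.7) & (p.alpha < 0.9))
        np.testing.assert_allclose(p.alpha - p.beta, 0.1)
        assert np.all((p.u_thr >= 0) & (p.u_thr <= 0.5))
        lif = sc.build_network([400, 4], model="lif", seed=0).neuron_params[0]
        assert np.all((lif.beta > 0.7) & (lif.beta < 0.9))
        assert np.all((lif.u_thr >= 0) & (lif.u_thr <= 1.1))

    @pytest.mark.parametrize("sizes,p", [([8], 0.7), ([8, 0], 0.7), ([8, 8], 0.0),
                                         ([8, 8], 1.5)])
    def test_invalid_configs(self, sizes, p):
        with pytest.raises(ConfigurationError):
            sc.build_network(sizes, p=p)


class TestSimulate:
    def test_silence_propagates(self):
        net = sc.build_network([8, 6, 4], seed=0)
        stim = sc.StimulusTrace(values=np.zeros((50, 2)), ds=2)
        rasters = sc.simulate(net, stim)
        assert all(np.all(r.spikes == 0) for r in rasters)

    def test_unreachable_thresholds_give_empty_rasters(self, sos_stimulus):
        net = sc.build_network([8, 6, 4], seed=0)
        for p in net.neuron_params:
            p.u_thr = np.full(p.n, 1e9)
        rasters = sc.simulate(net, sos_stimulus)
        assert all(np.all(r.spikes == 0) for r in rasters)

    def test_shapes_binary_and_determinism(self, small_net, sos_stimulus):
        rasters = sc.simulate(small_net, sos_stimulus)
        assert [r.spikes.shape for r in rasters] == [(2000, 8), (2000, 6), (2000, 4)]
        assert all(set(np.unique(r.spikes)) <= {0, 1} for r in rasters)
        again = sc.simulate(small_net, sos_stimulus)
        for a, b in zip(rasters, again):
            assert np.array_equal(a.spikes, b.spikes)

    def test_input_layer_spikes_only_when_driven(self, sos_stimulus):
        # a spiking input neuron must be receiving a positive quadrant current
        # at that step (the quadrant code gates who can fire)
        net = sc.build_network([16, 4], seed=2)
        currents = encode_input_current(sos_stimulus, net.encoder)
        raster = sc.simulate(net, sos_stimulus)[0]
        fired = raster.spikes.astype(bool)
        # membrane needs at least one driven step in the recent past; check
        # the weaker but exact invariant: silent-input neurons never fire
        never_driven = np.all(currents == 0, axis=0)
        assert not np.any(fired[:, never_driven])

    def test_five_layer_names(self):
        net = sc.build_network([8, 8, 4, 8, 4], seed=0)
        stim = sc.StimulusTrace(values=np.zeros((10, 2)), ds=2)
        names = [r.layer for r in sc.simulate(net, stim)]
        assert names == ["input", "E1", "B", "E2", "output"]


def test_raster_event_export(tmp_path):
    spikes = np.zeros((10, 3), dtype=np.uint8)
    spikes[2, 1] = 1
    spikes[7, 0] = 1
    raster = sc.SpikeRaster(spikes=spikes, layer="hidden")
    events = raster.to_events()
    np.testing.assert_array_equal(events, [[2, 1], [7, 0]])
    path = tmp_path / "events.csv"
    raster.to_csv(path)
    assert path.read_text().splitlines()[0] == "time_ms,neuron_index"
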
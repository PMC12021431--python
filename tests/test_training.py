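import numpy as np
import pytest

import spikecode as sc
from spikecode.errors import ValidationError
from spikecode.network import encode_input_current
from spikecode.training import _forward_backward, _init_raw


class TestReadoutKernel:
    def test_center_tap_is_one(self):
        k = sc.readout_kernel(10, 0.1)
        assert k[5] == pytest.approx(1.0)

    def test_zero_outside_open_support(self):
        k = sc.readout_kernel(10, 0.1)
        assert k[0] == 0.0
        assert len(k) == 10

    def test_direct_evaluation(self):
        k = sc.readout_kernel(10, 0.1)
        assert k[4] == pytest.approx(np.exp(-10.0))

    def test_invalid_sigma(self):
        with pytest.raises(ValidationError):
            sc.readout_kernel(10, 0.0)
        with pytest.raises(ValidationError):
            sc.readout_kernel(0, 0.1)


class TestComputeReadout:
    def cfg(self, n_out=3, ds=2, gamma=0.5):
        rng = np.random.default_rng(0)
        return sc.ReadoutConfig.init(n_out, ds, rng, gamma=gamma)

    def test_silent_raster_gives_zero(self):
        z = sc.compute_readout(np.zeros((100, 3)), self.cfg())
        assert np.all(z == 0)

    def test_gamma_endpoints(self):
        rng = np.random.default_rng(1)
        rho = (rng.random((200, 3)) < 0.2).astype(float)
        base = self.cfg()
        pure_t = sc.ReadoutConfig(gamma=1.0, w_time=base.w_time, w_count=base.w_count)
        pure_c = sc.ReadoutConfig(gamma=0.0, w_time=base.w_time, w_count=base.w_count)
        mixed = sc.ReadoutConfig(gamma=0.5, w_time=base.w_time, w_count=base.w_count)
        zt = sc.compute_readout(rho, pure_t)
        zc = sc.compute_readout(rho, pure_c)
        zm = sc.compute_readout(rho, mixed)
        np.testing.assert_allclose(zm, 0.5 * zt + 0.5 * zc, atol=1e-12)

    def test_single_spike_produces_shifted_kernels(self):
        # one spike at t0 with unit readout weight: z is the gamma-mix of the
        # two kernels starting at t0 (causal convolution by hand)
        cfg = sc.ReadoutConfig(gamma=0.5, w_time=np.array([[1.0]]),
                               w_count=np.array([[1.0]]))
        rho = np.zeros((200, 1))
        t0 = 40
        rho[t0, 0] = 1.0
        z = sc.compute_readout(rho, cfg)[:, 0]
        kt, kc = cfg.kernel_time, cfg.kernel_count
        expected = np.zeros(200)
        expected[t0:t0 + 10] += 0.5 * kt
        expected[t0:t0 + 70] += 0.5 * kc
        np.testing.assert_allclose(z, expected, atol=1e-12)

    def test_causality(self):
        # z at time t must not depend on spikes after t
        cfg = self.cfg(n_out=1, ds=1)
        rho = np.zeros((100, 1))
        rho[80, 0] = 1.0
        z = sc.compute_readout(rho, cfg)
        assert np.all(z[:80] == 0)

    def test_shape_mismatch(self):
        with pytest.raises(ValidationError):
            sc.compute_readout(np.zeros((10, 4)), self.cfg(n_out=3))


class TestMseLoss:
    def test_perfect_and_offset(self):
        s = np.linspace(0, 1, 50)[:, None]
        assert sc.mse_loss(s, s) == 0.0
        assert sc.mse_loss(s + 0.3, s) == pytest.approx(0.09)

    def test_hand_example(self):
        assert sc.mse_loss(np.array([0.0, 1.0]), np.array([1.0, 1.0])) == pytest.approx(0.5)

    def test_length_mismatch(self):
        with pytest.raises(ValidationError):
            sc.mse_loss(np.zeros(5), np.zeros(6))


class TestSurrogateGradient:
    @pytest.mark.parametrize("model", ["alpha", "lif"])
    def test_matches_finite_differences_of_smoothed_forward(self, model):
        """BPTT gradients equal finite differences of the relaxed forward pass."""
        rng = np.random.default_rng(1)
        net = sc.build_network([4, 3, 2], model=model, seed=2)
        stim = sc.generate_stimulus("sum_of_sines", 40, seed=0, flow=40, fhigh=90)
        s = stim.values
        c0 = encode_input_current(stim, net.encoder)
        raw = _init_raw(net)
        weights = [w.copy() for w in net.weights]
        ro = sc.ReadoutConfig.init(2, 2, rng)
        wt, wc = ro.w_time.copy(), ro.w_count.copy()

        def evaluate():
            return _forward_backward(net, raw, weights, wt, wc, c0, s, ro,
                                     smooth=True)

        _, grads, _ = evaluate()
        eps = 1e-6
        checks = [(weights[0], grads["W"][0]), (weights[1], grads["W"][1]),
                  (wt, grads["w_time"]), (wc, grads["w_count"]),
                  (raw["a"][0], grads["a"][0]), (raw["a"][1], grads["a"][1]),
                  (raw["m"][0], grads["m"][0])]
        for arr, analytic in checks:
            numeric = np.zeros_like(arr)
            it = np.nditer(arr, flags=["multi_index"])
            for _ in it:
                i = it.multi_index
                old = arr[i]
                arr[i] = old + eps
                lp, _, _ = evaluate()
                arr[i] = old - eps
                lm, _, _ = evaluate()
                arr[i] = old
                numeric[i] = (lp - lm) / (2 * eps)
            scale = np.abs(numeric).max()
            if scale < 1e-10:
                continue
            assert np.abs(numeric - analytic).max() / scale < 1e-4


class TestTrainNetwork:
    def test_zero_learning_rate_changes_nothing(self, sos_stimulus):
        net = sc.build_network([8, 6, 4], seed=0)
        res = sc.train_network(net, sos_stimulus,
                               training=sc.TrainingConfig(n_iter=5, learning_rate=0.0,
                                                          seed=0))
        for w0, w1 in zip(net.weights, res.network.weights):
            assert np.array_equal(w0, w1)
        assert np.allclose(res.loss_history, res.loss_history[0])

    def test_seed_contract(self, sos_stimulus):
        net = sc.build_network([8, 6, 4], seed=0)
        a = sc.train_network(net, sos_stimulus, training=sc.TrainingConfig(n_iter=10, seed=4))
        b = sc.train_network(net, sos_stimulus, training=sc.TrainingConfig(n_iter=10, seed=4))
        assert np.array_equal(a.loss_history, b.loss_history)

    @pytest.mark.parametrize("kind,params,duration", [
        ("sum_of_sines", {"flow": 4, "fhigh": 20}, 1500),
        ("single_sine", {"f": 5}, 1500),
        ("filtered_white_noise", {}, 1500),
        ("binary", {}, 1500),
        ("sinusoid_1hz", {}, 3000),  # slowest family: >= 2 stimulus periods
    ])
    def test_loss_decreases_on_every_stimulus_family(self, kind, params, duration):
        stim = sc.generate_stimulus(kind, duration, seed=0, **params)
        net = sc.build_network([16, 8, 8], seed=1)
        res = sc.train_network(net, stim, training=sc.TrainingConfig(n_iter=40, seed=1))
        assert res.loss_history[-1] < res.loss_history[0]

    def test_alpha_exceeds_beta_after_training(self, trained_small):
        for p in trained_small.network.neuron_params:
            assert np.all(p.alpha > p.beta)

    def test_loss_history_trends_down(self, trained_small):
        h = trained_small.loss_history
        assert h[-1] < h[0]
        # trend, not strict monotonicity: late average beats early average
        assert h[-10:].mean() < h[:10].mean()

    def test_denoising_target(self):
        clean = sc.generate_stimulus("sum_of_sines", 1200, seed=0)
        noisy = sc.add_white_noise(clean, 0.3, seed=1)
        net = sc.build_network([16, 8, 8], seed=2)
        res = sc.train_network(net, noisy, target=clean,
                               training=sc.TrainingConfig(n_iter=30, seed=2))
        assert res.loss_history[-1] < res.loss_history[0]

    def test_full_scale_three_layer_fit(self):
        """A 100-100-100 network learns the 4+20 Hz stimulus well."""
        stim = sc.generate_stimulus("sum_of_sines", 3000, seed=0, flow=4, fhigh=20)
        net = sc.build_network([100, 100, 100], seed=0)
        res = sc.train_network(net, stim, training=sc.TrainingConfig(n_iter=150, seed=0))
        assert res.loss_history[-1] < 0.25 * res.loss_history[0]
        # the trained readout visibly tracks the stimulus
        rasters = sc.simulate(res.network, stim)
        z = sc.compute_readout(rasters[-1], res.readout)
        assert sc.r_squared(stim.values[200:], z[200:]) > 0.5
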
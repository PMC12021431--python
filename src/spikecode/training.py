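"""Surrogate-gradient training of the spiking networks.

The network is trained to *autoencode* a time-dependent stimulus: a readout

    z = gamma * (K_time * rho_out) @ W_time + (1 - gamma) * (K_count * rho_out) @ W_count

(``*`` is causal convolution along time, ``rho_out`` the binary output-layer
spikes) must match the stimulus under a mean-squared-error loss

    L = mean_t mean_d (z[t, d] - s[t, d])**2.

With ``gamma = 0.5`` the objective weighs a short (10 ms) and a long (70 ms)
readout kernel equally, so training does not bias the output layer toward a
timing or a count code.  Both kernels are Gaussian bumps
``exp(-(t - width/2)**2 / sigma)`` supported on (0, width); with the default
``sigma = 0.1 ms**2`` they are sharply concentrated at lag width/2.

Optimized parameters: all synaptic weight matrices (their structural zero
pattern is preserved), the per-neuron membrane decay rates, and the readout
matrices.  Thresholds stay fixed.  Gradients are computed by
backpropagation-through-time with a fast-sigmoid surrogate for the spike
nonlinearity (slope 25); the time recursions are the hand-derived backward
kernels in :mod:`spikecode._dynamics`, which are verified against finite
differences in the test suite.

For the alpha model the constraint ``alpha > beta`` is maintained by
reparameterization: ``alpha = sigmoid(a)`` and ``beta = alpha - margin`` with
``margin = max(softplus(m), 0.05)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import lfilter

from .errors import ConfigurationError, TrainingError, ValidationError
from .network import (
    SURROGATE_SLOPE,
    NetworkModel,
    NeuronParams,
    SpikeRaster,
    _layer_forward,
    encode_input_current,
    tau_alpha,
)
from .stimuli import StimulusTrace
from . import _dynamics

__all__ = [
    "ReadoutConfig",
    "TrainingConfig",
    "TrainResult",
    "readout_kernel",
    "compute_readout",
    "mse_loss",
    "train_network",
]

MIN_MARGIN = 0.05


def readout_kernel(width: int, sigma: float = 0.1) -> np.ndarray:
    """Gaussian-bump FIR kernel on integer taps 0..width-1.

    ``K[t] = exp(-(t - width/2)**2 / sigma)`` for 0 < t < width, zero at the
    boundary taps, peaking at 1 for the center tap when width is even.
    """
    if width < 1:
        raise ValidationError(f"kernel width must be >= 1 ms, got {width}")
    if sigma <= 0:
        raise ValidationError(f"sigma must be positive, got {sigma}")
    t = np.arange(int(width), dtype=np.float64)
    k = np.exp(-((t - width / 2.0) ** 2) / sigma)
    k[~((t > 0) & (t < width))] = 0.0
    return k


@dataclass
class ReadoutConfig:
    """The gamma-mixed timing/count readout of the output layer."""

    gamma: float = 0.5
    width_time: int = 10
    width_count: int = 70
    sigma: float = 0.1
    w_time: np.ndarray | None = None  # (n_out, ds)
    w_count: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.gamma <= 1.0:
            raise ConfigurationError(f"gamma must lie in [0, 1], got {self.gamma}")

    @classmethod
    def init(cls, n_out: int, ds: int, rng: np.random.Generator, *, gamma: float = 0.5,
             width_time: int = 10, width_count: int = 70, sigma: float = 0.1,
             weight_std: float = 0.1) -> "ReadoutConfig":
        return cls(
            gamma=gamma, width_time=width_time, width_count=width_count, sigma=sigma,
            w_time=weight_std * rng.standard_normal((n_out, ds)),
            w_count=weight_std * rng.standard_normal((n_out, ds)),
        )

    @property
    def kernel_time(self) -> np.ndarray:
        return readout_kernel(self.width_time, self.sigma)

    @property
    def kernel_count(self) -> np.ndarray:
        return readout_kernel(self.width_count, self.sigma)


def _causal_fir(kernel: np.ndarray, x: np.ndarray) -> np.ndarray:
    """y[t] = sum_j kernel[j] * x[t - j]; x is (T, n)."""
    return lfilter(kernel, [1.0], x, axis=0)


def _causal_fir_adjoint(kernel: np.ndarray, g: np.ndarray) -> np.ndarray:
    """Adjoint of :func:`_causal_fir`: gx[t] = sum_j kernel[j] * g[t + j]."""
    return lfilter(kernel, [1.0], g[::-1], axis=0)[::-1]


def compute_readout(output_raster, readout: ReadoutConfig) -> np.ndarray:
    """Readout trace ``z`` (time x ds) from output-layer spikes.

    ``output_raster`` may be a :class:`SpikeRaster` or a plain (T, n_out)
    array.  ``z[t]`` depends only on spikes in the window (t - width, t].
    """
    rho = output_raster.spikes if isinstance(output_raster, SpikeRaster) else output_raster
    rho = np.asarray(rho, dtype=np.float64)
    if readout.w_time is None or readout.w_count is None:
        raise ValidationError("readout weights are not initialized")
    if rho.shape[1] != readout.w_time.shape[0]:
        raise ValidationError(
            f"raster has {rho.shape[1]} neurons but readout expects "
            f"{readout.w_time.shape[0]}"
        )
    r_time = _causal_fir(readout.kernel_time, rho)
    r_count = _causal_fir(readout.kernel_count, rho)
    return readout.gamma * (r_time @ readout.w_time) + (1.0 - readout.gamma) * (
        r_count @ readout.w_count
    )


def mse_loss(z: np.ndarray, s) -> float:
    """Mean over time and stimulus components of the squared readout error."""
    s = s.values if isinstance(s, StimulusTrace) else np.asarray(s, dtype=np.float64)
    z = np.asarray(z, dtype=np.float64)
    if z.ndim == 1:
        z = z[:, None]
    if s.ndim == 1:
        s = s[:, None]
    if z.shape != s.shape:
        raise ValidationError(f"readout shape {z.shape} != stimulus shape {s.shape}")
    return float(np.mean((z - s) ** 2))


@dataclass
class TrainingConfig:
    """Optimizer settings for BPTT (Adam on full sequences)."""

    learning_rate: float = 1e-3
    n_iter: int = 200
    grad_clip: float = 10.0  # global-norm clip; <= 0 disables
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    adam_eps: float = 1e-8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate < 0:
            raise ConfigurationError("learning rate must be >= 0")
        if self.n_iter < 0:
            raise ConfigurationError("iteration count must be >= 0")


@dataclass
class TrainResult:
    network: NetworkModel
    readout: ReadoutConfig
    loss_history: np.ndarray


def _softplus(x):
    return np.logaddexp(0.0, x)


def _softplus_inv(y):
    return np.log(np.expm1(y))


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def _decode_decays(raw: dict, model: str):
    """Map unconstrained parameters to per-layer (alpha, beta) arrays."""
    out = []
    for a_raw, m_raw in zip(raw["a"], raw["m"]):
        if model == "alpha":
            alpha = np.clip(_sigmoid(a_raw), 2e-3, 1 - 1e-6)
            margin = np.maximum(_softplus(m_raw), MIN_MARGIN)
            beta = np.clip(alpha - margin, 1e-3, None)
            out.append((alpha, beta, margin))
        else:
            beta = np.clip(_sigmoid(a_raw), 1e-6, 1 - 1e-6)
            out.append((None, beta, None))
    return out


def _forward_backward(net: NetworkModel, raw: dict, weights: list, w_time, w_count,
                      currents0: np.ndarray, s: np.ndarray, readout: ReadoutConfig,
                      smooth: bool = False):
    """One full BPTT pass.  Returns (loss, grads dict, output spikes)."""
    model = net.model
    L = net.n_layers
    decays = _decode_decays(raw, model)
    k_time, k_count = readout.kernel_time, readout.kernel_count

    # ---- forward ----
    spikes, caches, curr_list = [], [], []
    currents = currents0
    for k in range(L):
        if k > 0:
            currents = spikes[k - 1] @ weights[k - 1].T
        curr_list.append(currents)
        alpha, beta, _ = decays[k]
        theta = net.neuron_params[k].u_thr
        if model == "alpha":
            tau = tau_alpha(alpha, beta)
            S, E, I, U = _dynamics.alpha_forward(
                np.ascontiguousarray(currents), alpha, beta, tau, theta,
                SURROGATE_SLOPE, smooth)
            caches.append((S, E, I, U, tau))
        else:
            S, U = _dynamics.lif_forward(
                np.ascontiguousarray(currents), beta, theta, SURROGATE_SLOPE, smooth)
            caches.append((S, U))
        spikes.append(S)

    rho = spikes[-1]
    r_time = _causal_fir(k_time, rho)
    r_count = _causal_fir(k_count, rho)
    g = readout.gamma
    z = g * (r_time @ w_time) + (1.0 - g) * (r_count @ w_count)
    nt, ds = s.shape
    loss = float(np.mean((z - s) ** 2))

    # ---- backward ----
    gz = 2.0 * (z - s) / (nt * ds)
    grads = {"W": [None] * (L - 1), "a": [None] * L, "m": [None] * L}
    grads["w_time"] = g * (r_time.T @ gz)
    grads["w_count"] = (1.0 - g) * (r_count.T @ gz)
    g_rt = g * (gz @ w_time.T)
    g_rc = (1.0 - g) * (gz @ w_count.T)
    gS = _causal_fir_adjoint(k_time, g_rt) + _causal_fir_adjoint(k_count, g_rc)

    for k in range(L - 1, -1, -1):
        alpha, beta, margin = decays[k]
        theta = net.neuron_params[k].u_thr
        if model == "alpha":
            S, E, I, U, tau = caches[k]
            gC, ga_d, gb_d, gtau = _dynamics.alpha_backward(
                np.ascontiguousarray(gS), S, E, I, U, alpha, beta, tau, theta,
                SURROGATE_SLOPE, smooth)
            la, lb = np.log(alpha), np.log(beta)
            denom = (lb - la) ** 2
            dtau_da = lb / (alpha * denom)
            dtau_db = -la / (beta * denom)
            ga = ga_d + gtau * dtau_da
            gb = gb_d + gtau * dtau_db
            # beta = alpha - margin  =>  dbeta/dalpha = 1, dbeta/dmargin = -1
            live_b = (beta > 1e-3).astype(np.float64)
            d_sig = alpha * (1.0 - alpha)
            grads["a"][k] = (ga + gb * live_b) * d_sig
            live_m = (_softplus(raw["m"][k]) > MIN_MARGIN).astype(np.float64)
            grads["m"][k] = -gb * live_b * live_m * _sigmoid(raw["m"][k])
        else:
            S, U = caches[k]
            gC, gb = _dynamics.lif_backward(
                np.ascontiguousarray(gS), S, U,
                np.ascontiguousarray(curr_list[k]), beta, theta,
                SURROGATE_SLOPE, smooth)
            grads["a"][k] = gb * beta * (1.0 - beta)
            grads["m"][k] = np.zeros_like(raw["m"][k])
        if k > 0:
            grads["W"][k - 1] = gC.T @ spikes[k - 1]
            gS = gC @ weights[k - 1]
    return loss, grads, rho


def _init_raw(net: NetworkModel) -> dict:
    raw = {"a": [], "m": []}
    for p in net.neuron_params:
        if net.model == "alpha":
            raw["a"].append(np.log(p.alpha / (1.0 - p.alpha)))
            raw["m"].append(_softplus_inv(np.clip(p.alpha - p.beta, MIN_MARGIN + 1e-6, None)))
        else:
            raw["a"].append(np.log(p.beta / (1.0 - p.beta)))
            raw["m"].append(np.zeros_like(p.beta))
    return raw


def train_network(network: NetworkModel, stimulus: StimulusTrace,
                  readout: ReadoutConfig | None = None,
                  training: TrainingConfig | None = None,
                  target: StimulusTrace | None = None) -> TrainResult:
    """Optimize the network so its readout reconstructs the stimulus.

    Parameters
    ----------
    network : NetworkModel
        Starting network; not modified (a trained copy is returned).
    stimulus : StimulusTrace
        Input presented to the network.
    readout : ReadoutConfig, optional
        Initialized from ``training.seed`` if omitted.
    training : TrainingConfig, optional
    target : StimulusTrace, optional
        Training target; defaults to the input stimulus itself
        (autoencoding).  Passing a clean target while presenting a noisy
        input trains the network to denoise.

    Returns
    -------
    TrainResult
        Trained network, trained readout, and per-iteration loss history
        (length ``n_iter + 1``, the first entry being the initial loss).
    """
    training = training or TrainingConfig()
    tgt = target if target is not None else stimulus
    s = tgt.values
    rng = np.random.default_rng(training.seed)
    if readout is None:
        readout = ReadoutConfig.init(network.layer_sizes[-1], tgt.ds, rng)
    net = network.copy()
    currents0 = encode_input_current(stimulus, net.encoder)
    if s.shape[0] != currents0.shape[0]:
        raise ValidationError("stimulus and target must have equal duration")

    raw = _init_raw(net)
    weights = [w.copy() for w in net.weights]
    masks = [w != 0 for w in net.weights]
    w_time = readout.w_time.copy()
    w_count = readout.w_count.copy()

    # flat parameter list for Adam
    def params_list():
        return (
            weights
            + [w_time, w_count]
            + raw["a"]
            + raw["m"]
        )

    m_state = [np.zeros_like(p) for p in params_list()]
    v_state = [np.zeros_like(p) for p in params_list()]
    losses = []
    for it in range(training.n_iter + 1):
        loss, grads, _ = _forward_backward(
            net, raw, weights, w_time, w_count, currents0, s, readout)
        if not np.isfinite(loss):
            raise TrainingError(f"loss diverged at iteration {it}: {loss}")
        losses.append(loss)
        if it == training.n_iter:
            break
        glist = (
            [gw * msk for gw, msk in zip(grads["W"], masks)]
            + [grads["w_time"], grads["w_count"]]
            + grads["a"]
            + grads["m"]
        )
        if training.grad_clip > 0:
            norm = np.sqrt(sum(float(np.sum(gi**2)) for gi in glist))
            if norm > training.grad_clip:
                glist = [gi * (training.grad_clip / norm) for gi in glist]
        t_adam = it + 1
        lr = training.learning_rate
        b1, b2, eps = training.adam_beta1, training.adam_beta2, training.adam_eps
        for p, gi, mi, vi in zip(params_list(), glist, m_state, v_state):
            mi *= b1
            mi += (1 - b1) * gi
            vi *= b2
            vi += (1 - b2) * gi**2
            mhat = mi / (1 - b1**t_adam)
            vhat = vi / (1 - b2**t_adam)
            p -= lr * mhat / (np.sqrt(vhat) + eps)

    # write trained parameters back into a NetworkModel
    decays = _decode_decays(raw, net.model)
    new_params = []
    for k, p in enumerate(net.neuron_params):
        alpha, beta, _ = decays[k]
        new_params.append(NeuronParams(model=p.model, alpha=alpha, beta=beta,
                                       u_thr=p.u_thr, u_reset=p.u_reset))
    net.neuron_params = new_params
    net.weights = weights
    trained_readout = ReadoutConfig(
        gamma=readout.gamma, width_time=readout.width_time,
        width_count=readout.width_count, sigma=readout.sigma,
        w_time=w_time, w_count=w_count)
    return TrainResult(network=net, readout=trained_readout,
                       loss_history=np.asarray(losses))
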
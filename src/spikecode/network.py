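"""Feedforward spiking networks with signed random connectivity.

The architecture is a chain of layers.  The input layer is a population of
spiking neurons tuned to the four quadrants of the 2-D visual plane: neuron
``i`` of the quadrant-``q`` subpopulation receives the stimulus magnitude
``sqrt(sx**2 + sy**2)`` whenever the offset-shifted position
``(sx - o_i, sy - o_i)`` lies in quadrant ``q`` and nothing otherwise.  The
per-neuron offsets ``o_i ~ N(0, 0.1)`` smooth the hand-off between
subpopulations.  Every other layer receives the weighted sum of the previous
layer's spikes at the same time step (no synaptic delays).

Weights are present independently with probability ``p`` and drawn
``N(0, 1/(p * N_pre))``, so excitatory and inhibitory connections are equally
probable (no Dale's law).  Neurons follow either the alpha (spike-response)
model or the leaky integrate-and-fire model; see :mod:`spikecode._dynamics`
for the update equations and the differentiable reset convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _dynamics
from .errors import ConfigurationError, ValidationError
from .stimuli import StimulusTrace

SURROGATE_SLOPE = 25.0

__all__ = [
    "NeuronParams",
    "InputEncoder",
    "NetworkModel",
    "SpikeRaster",
    "encode_input_current",
    "synaptic_current",
    "step_alpha_layer",
    "step_lif_layer",
    "build_network",
    "simulate",
    "tau_alpha",
]


def tau_alpha(alpha: np.ndarray, beta: np.ndarray) -> np.ndarray:
    """Membrane scale factor ``ln(a) / (ln(b) - ln(a)) + 1``.

    Positive for ``1 > alpha > beta > 0``, which is what makes positive input
    currents raise the membrane potential.
    """
    la, lb = np.log(alpha), np.log(beta)
    return la / (lb - la) + 1.0


@dataclass
class NeuronParams:
    """Per-neuron parameters of one layer."""

    model: str  # "alpha" | "lif"
    alpha: np.ndarray | None  # excitatory current decay (alpha model only)
    beta: np.ndarray  # inhibitory current / membrane decay
    u_thr: np.ndarray
    u_reset: float = 0.0

    def __post_init__(self) -> None:
        if self.model not in ("alpha", "lif"):
            raise ConfigurationError(f"unknown neuron model {self.model!r}")
        self.beta = np.atleast_1d(np.asarray(self.beta, dtype=np.float64))
        self.u_thr = np.atleast_1d(np.asarray(self.u_thr, dtype=np.float64))
        if self.model == "alpha":
            if self.alpha is None:
                raise ConfigurationError("alpha model requires alpha decay rates")
            self.alpha = np.atleast_1d(np.asarray(self.alpha, dtype=np.float64))
            if np.any(self.alpha <= self.beta):
                raise ConfigurationError("alpha model requires alpha > beta")
            if np.any((self.alpha <= 0) | (self.alpha >= 1)):
                raise ConfigurationError("alpha decay must lie in (0, 1)")
        if np.any((self.beta <= 0) | (self.beta >= 1)):
            raise ConfigurationError("beta decay must lie in (0, 1)")

    @property
    def n(self) -> int:
        return self.beta.shape[0]

    @property
    def tau(self) -> np.ndarray | None:
        if self.model != "alpha":
            return None
        return tau_alpha(self.alpha, self.beta)


@dataclass
class NeuronState:
    """Mutable state carried between single steps of a layer."""

    u: np.ndarray
    i_exc: np.ndarray | None = None
    i_inh: np.ndarray | None = None
    last_spike: np.ndarray | None = None

    @classmethod
    def zeros(cls, n: int, model: str) -> "NeuronState":
        z = np.zeros(n)
        if model == "alpha":
            return cls(u=z.copy(), i_exc=z.copy(), i_inh=z.copy(), last_spike=z.copy())
        return cls(u=z.copy(), last_spike=z.copy())


@dataclass
class InputEncoder:
    """Quadrant-tuned input-layer encoder.

    ``n_in`` must be divisible by 4; neurons are assigned to quadrants in four
    contiguous blocks.  ``offsets`` holds one scalar offset per neuron.
    """

    n_in: int
    offsets: np.ndarray
    gain: float = 1.0

    def __post_init__(self) -> None:
        if self.n_in % 4 != 0:
            raise ConfigurationError(f"n_in must be divisible by 4, got {self.n_in}")
        self.offsets = np.asarray(self.offsets, dtype=np.float64)
        if self.offsets.shape != (self.n_in,):
            raise ValidationError("offsets must have one entry per input neuron")

    @classmethod
    def draw(cls, n_in: int, rng: np.random.Generator, offset_std: float = 0.1,
             gain: float = 1.0) -> "InputEncoder":
        if n_in % 4 != 0:
            raise ConfigurationError(f"n_in must be divisible by 4, got {n_in}")
        return cls(n_in=n_in, offsets=offset_std * rng.standard_normal(n_in), gain=gain)

    @property
    def quadrant(self) -> np.ndarray:
        """Quadrant label (1..4) per neuron, in four contiguous blocks."""
        return np.repeat(np.arange(1, 5), self.n_in // 4)


@dataclass
class SpikeRaster:
    """Binary spike matrix (time steps x neurons) for one layer."""

    spikes: np.ndarray
    layer: str = ""
    dt: float = 1.0

    def __post_init__(self) -> None:
        self.spikes = np.asarray(self.spikes)
        uniq = np.unique(self.spikes)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValidationError("raster entries must be binary")

    @property
    def n_steps(self) -> int:
        return self.spikes.shape[0]

    @property
    def n_neurons(self) -> int:
        return self.spikes.shape[1]

    def to_events(self) -> np.ndarray:
        """Spike events as an (n_events, 2) array of (time_ms, neuron_index)."""
        t, j = np.nonzero(self.spikes)
        return np.column_stack([t * self.dt, j]).astype(np.float64)

    def to_csv(self, path) -> None:
        """Write the raster as a two-column event list CSV."""
        np.savetxt(path, self.to_events(), delimiter=",",
                   header="time_ms,neuron_index", comments="", fmt="%g")


@dataclass
class NetworkModel:
    """A feedforward spiking network.

    ``weights[k]`` has shape (layer_sizes[k+1], layer_sizes[k]) and maps the
    spikes of layer ``k`` to input currents of layer ``k+1``.
    """

    layer_sizes: list
    neuron_params: list  # one NeuronParams per layer
    weights: list  # one (n_post, n_pre) matrix per adjacent pair
    connection_prob: float
    encoder: InputEncoder
    seed: int = 0
    meta: dict = field(default_factory=dict)

    @property
    def n_layers(self) -> int:
        return len(self.layer_sizes)

    @property
    def model(self) -> str:
        return self.neuron_params[0].model

    def copy(self) -> "NetworkModel":
        import copy as _copy

        return _copy.deepcopy(self)


def encode_input_current(stimulus: StimulusTrace, encoder: InputEncoder) -> np.ndarray:
    """Input currents (time x n_in) delivered by the quadrant code.

    One-dimensional stimuli are embedded as (s, 0); the offsets then decide
    which quadrants respond, so the two subpopulations straddling the x axis
    split the encoding between positive and negative positions.
    """
    s = stimulus.values
    if stimulus.ds == 1:
        s = np.column_stack([s[:, 0], np.zeros(s.shape[0])])
    sx, sy = s[:, 0][:, None], s[:, 1][:, None]  # (T, 1)
    off = encoder.offsets[None, :]  # (1, n_in)
    dx, dy = sx - off, sy - off
    q = encoder.quadrant[None, :]
    in_quadrant = (
        ((q == 1) & (dx > 0) & (dy > 0))
        | ((q == 2) & (dx < 0) & (dy > 0))
        | ((q == 3) & (dx < 0) & (dy < 0))
        | ((q == 4) & (dx > 0) & (dy < 0))
    )
    magnitude = np.sqrt(sx**2 + sy**2)
    return encoder.gain * magnitude * in_quadrant


def synaptic_current(pre_spikes: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Weighted sum of presynaptic spikes: ``W @ x`` for one time step."""
    pre_spikes = np.asarray(pre_spikes, dtype=np.float64)
    if weights.shape[1] != pre_spikes.shape[-1]:
        raise ValidationError(
            f"weight matrix expects {weights.shape[1]} presynaptic neurons, "
            f"got {pre_spikes.shape[-1]}"
        )
    return pre_spikes @ weights.T


def step_alpha_layer(state: NeuronState, params: NeuronParams, input_current: np.ndarray):
    """Advance one alpha layer a single step.  Returns (state, spikes)."""
    if params.model != "alpha":
        raise ConfigurationError("step_alpha_layer requires alpha params")
    c = np.asarray(input_current, dtype=np.float64)
    keep = 1.0 - state.last_spike
    e = params.alpha * keep * state.i_exc + c
    i = params.beta * keep * state.i_inh - c
    u = params.tau * (e + i)
    spikes = (u > params.u_thr).astype(np.float64)
    return NeuronState(u=u, i_exc=e, i_inh=i, last_spike=spikes), spikes


def step_lif_layer(state: NeuronState, params: NeuronParams, input_current: np.ndarray):
    """Advance one LIF layer a single step.  Returns (state, spikes)."""
    if params.model != "lif":
        raise ConfigurationError("step_lif_layer requires lif params")
    c = np.asarray(input_current, dtype=np.float64)
    u = (1.0 - state.last_spike) * (params.beta * state.u + c)
    spikes = (u > params.u_thr).astype(np.float64)
    return NeuronState(u=u, last_spike=spikes), spikes


def _draw_params(n: int, model: str, rng: np.random.Generator) -> NeuronParams:
    if model == "alpha":
        alpha = rng.uniform(0.7, 0.9, n)
        return NeuronParams(model="alpha", alpha=alpha, beta=alpha - 0.1,
                            u_thr=rng.uniform(0.0, 0.5, n))
    return NeuronParams(model="lif", alpha=None, beta=rng.uniform(0.7, 0.9, n),
                        u_thr=rng.uniform(0.0, 1.1, n))


def build_network(layer_sizes, model: str = "alpha", p: float = 0.7, seed: int = 0,
                  gain: float = 1.0, offset_std: float = 0.1) -> NetworkModel:
    """Initialize a feedforward network.

    Present synaptic weights are drawn ``N(0, 1/(p * N_pre))``; neuron
    parameters follow the model's initialization table.  Fully deterministic
    given ``seed``.
    """
    layer_sizes = [int(n) for n in layer_sizes]
    if len(layer_sizes) < 2:
        raise ConfigurationError("need at least 2 layers")
    if any(n < 1 for n in layer_sizes):
        raise ConfigurationError(f"layer sizes must be >= 1, got {layer_sizes}")
    if not 0 < p <= 1:
        raise ConfigurationError(f"connection probability must be in (0, 1], got {p}")
    rng = np.random.default_rng(seed)
    encoder = InputEncoder.draw(layer_sizes[0], rng, offset_std=offset_std, gain=gain)
    params = [_draw_params(n, model, rng) for n in layer_sizes]
    weights = []
    for n_pre, n_post in zip(layer_sizes[:-1], layer_sizes[1:]):
        mask = rng.random((n_post, n_pre)) < p
        w = rng.normal(0.0, np.sqrt(1.0 / (p * n_pre)), (n_post, n_pre))
        weights.append(w * mask)
    return NetworkModel(layer_sizes=layer_sizes, neuron_params=params, weights=weights,
                        connection_prob=p, encoder=encoder, seed=seed)


def _layer_forward(params: NeuronParams, currents: np.ndarray, smooth: bool = False):
    """Run one layer over a full current time series via the compiled kernels."""
    C = np.ascontiguousarray(currents, dtype=np.float64)
    if params.model == "alpha":
        S, E, I, U = _dynamics.alpha_forward(
            C, params.alpha, params.beta, params.tau, params.u_thr,
            SURROGATE_SLOPE, smooth,
        )
        return S, {"E": E, "I": I, "U": U}
    S, U = _dynamics.lif_forward(C, params.beta, params.u_thr, SURROGATE_SLOPE, smooth)
    return S, {"U": U}


def simulate(network: NetworkModel, stimulus: StimulusTrace) -> list:
    """Simulate all layers; returns one binary :class:`SpikeRaster` per layer.

    Layer ``k+1`` at step ``t`` receives current from layer-``k`` spikes at
    the same step (zero synaptic delay), so layers can be integrated in order.
    """
    currents = encode_input_current(stimulus, network.encoder)
    rasters = []
    spikes = None
    names = _layer_names(network.n_layers)
    for k in range(network.n_layers):
        if k > 0:
            currents = spikes @ network.weights[k - 1].T
        spikes, _ = _layer_forward(network.neuron_params[k], currents)
        rasters.append(SpikeRaster(spikes=spikes.astype(np.uint8), layer=names[k]))
    return rasters


def _layer_names(n_layers: int) -> list:
    if n_layers == 3:
        return ["input", "hidden", "output"]
    if n_layers == 5:
        return ["input", "E1", "B", "E2", "output"]
    return ["input"] + [f"L{k}" for k in range(1, n_layers - 1)] + ["output"]
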
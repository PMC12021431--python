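"""Recurrent decoders that reconstruct the stimulus from binned spikes.

A GRU or LSTM consumes the bin axis of a :class:`~spikecode.binning.BinnedResponse`
as its sequence dimension (one step per bin, input = the spike-count vector of
all neurons in that bin), so decoding can exploit the *order* of spikes inside
the response window, not only their total count.  The final hidden state is
mapped linearly to the stimulus estimate.

The networks are plain-numpy implementations with hand-derived
backpropagation (verified against finite differences in the tests) and Adam.
Hyperparameters can be chosen by Bayesian optimization on validation accuracy:
a Gaussian-process surrogate over (log2 hidden size, log10 learning rate,
epochs) maximizing expected improvement.  With a search budget of zero the
documented defaults in :class:`DecoderSpec` are used as-is.

Data splits are contiguous in time (train, then validation, then test):
sliding windows overlap, so a shuffled split would leak test information into
training.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .binning import BinnedResponse
from .errors import ConfigurationError, ValidationError

__all__ = ["DecoderSpec", "RecurrentDecoder", "FittedDecoder", "fit_decoder", "decode"]


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))


@dataclass
class DecoderSpec:
    """Decoder architecture, training hyperparameters, and search budget."""

    architecture: str = "gru"  # "gru" | "lstm"
    hidden: int = 24
    learning_rate: float = 3e-3
    epochs: int = 40
    batch_size: int = 256
    budget: int = 0  # Bayesian-optimization evaluations; 0 = use defaults
    splits: tuple = (0.6, 0.2, 0.2)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.architecture not in ("gru", "lstm"):
            raise ConfigurationError(f"unknown architecture {self.architecture!r}")
        if abs(sum(self.splits) - 1.0) > 1e-9:
            raise ConfigurationError(f"split fractions must sum to 1, got {self.splits}")


class RecurrentDecoder:
    """A single-layer GRU/LSTM regressor over the bin sequence."""

    def __init__(self, architecture: str, n_features: int, hidden: int, ds: int,
                 rng: np.random.Generator):
        self.architecture = architecture
        self.n_features = n_features
        self.hidden = hidden
        self.ds = ds
        n_gates = 3 if architecture == "gru" else 4
        d, h = n_features, hidden
        lim_x = np.sqrt(6.0 / (d + n_gates * h))
        lim_h = np.sqrt(6.0 / (h + n_gates * h))
        self.params = {
            "Wx": rng.uniform(-lim_x, lim_x, (d, n_gates * h)),
            "Uh": rng.uniform(-lim_h, lim_h, (h, n_gates * h)),
            "b": np.zeros(n_gates * h),
            "Wo": rng.uniform(-np.sqrt(6.0 / (h + ds)), np.sqrt(6.0 / (h + ds)), (h, ds)),
            "bo": np.zeros(ds),
        }
        self.feat_mean = np.zeros(d)
        self.feat_std = np.ones(d)

    # ---- forward ----

    def _norm(self, X):
        return (X - self.feat_mean) / self.feat_std

    def forward(self, X, cache: bool = False):
        """X : (N, n_bins, n_features) raw counts.  Returns (N, ds)."""
        Xn = self._norm(np.asarray(X, dtype=np.float64))
        N, nb, d = Xn.shape
        if d != self.n_features:
            raise ValidationError(f"decoder expects {self.n_features} features, got {d}")
        H = self.hidden
        p = self.params
        h = np.zeros((N, H))
        caches = []
        if self.architecture == "gru":
            for t in range(nb):
                xt = Xn[:, t, :]
                gx = xt @ p["Wx"] + p["b"]
                gh = h @ p["Uh"]
                r = _sigmoid(gx[:, :H] + gh[:, :H])
                z = _sigmoid(gx[:, H:2 * H] + gh[:, H:2 * H])
                hn = gh[:, 2 * H:]
                n = np.tanh(gx[:, 2 * H:] + r * hn)
                h_new = (1.0 - z) * n + z * h
                if cache:
                    caches.append((xt, h, r, z, n, hn))
                h = h_new
        else:  # lstm
            c = np.zeros((N, H))
            for t in range(nb):
                xt = Xn[:, t, :]
                gates = xt @ p["Wx"] + h @ p["Uh"] + p["b"]
                i = _sigmoid(gates[:, :H])
                f = _sigmoid(gates[:, H:2 * H])
                o = _sigmoid(gates[:, 2 * H:3 * H])
                g = np.tanh(gates[:, 3 * H:])
                c_new = f * c + i * g
                tc = np.tanh(c_new)
                h_new = o * tc
                if cache:
                    caches.append((xt, h, c, i, f, o, g, tc))
                h = h_new
                c = c_new
        y = h @ p["Wo"] + p["bo"]
        if cache:
            return y, h, caches
        return y

    # ---- backward ----

    def backward(self, X, gy, h_last, caches):
        """Gradient of a scalar loss with gradient ``gy`` w.r.t. outputs."""
        p = self.params
        H = self.hidden
        grads = {k: np.zeros_like(v) for k, v in p.items()}
        grads["Wo"] = h_last.T @ gy
        grads["bo"] = gy.sum(axis=0)
        dh = gy @ p["Wo"].T
        if self.architecture == "gru":
            for t in range(len(caches) - 1, -1, -1):
                xt, h_prev, r, z, n, hn = caches[t]
                dz = dh * (h_prev - n) * z * (1.0 - z)
                dn = dh * (1.0 - z) * (1.0 - n**2)
                dr = dn * hn * r * (1.0 - r)
                d_gx = np.concatenate([dr, dz, dn], axis=1)
                d_gh = np.concatenate([dr, dz, dn * r], axis=1)
                grads["Wx"] += xt.T @ d_gx
                grads["b"] += d_gx.sum(axis=0)
                grads["Uh"] += h_prev.T @ d_gh
                dh = dh * z + d_gh @ p["Uh"].T
        else:
            dc = np.zeros_like(dh)
            for t in range(len(caches) - 1, -1, -1):
                xt, h_prev, c_prev, i, f, o, g, tc = caches[t]
                do = dh * tc * o * (1.0 - o)
                dc = dc + dh * o * (1.0 - tc**2)
                di = dc * g * i * (1.0 - i)
                df = dc * c_prev * f * (1.0 - f)
                dg = dc * i * (1.0 - g**2)
                d_gates = np.concatenate([di, df, do, dg], axis=1)
                grads["Wx"] += xt.T @ d_gates
                grads["b"] += d_gates.sum(axis=0)
                grads["Uh"] += h_prev.T @ d_gates
                dh = d_gates @ p["Uh"].T
                dc = dc * f
        return grads


@dataclass
class FittedDecoder:
    """A trained decoder plus the contiguous split used to train it."""

    decoder: RecurrentDecoder
    spec: DecoderSpec
    idx_train: slice
    idx_val: slice
    idx_test: slice
    val_r2: float
    search_log: list = field(default_factory=list)


def _train_one(X, Y, tr: slice, va: slice, architecture: str, hidden: int,
               lr: float, epochs: int, batch_size: int, seed: int):
    """Train a decoder on the train slice; returns (decoder, validation R2)."""
    from .measures import r_squared

    rng = np.random.default_rng(seed)
    dec = RecurrentDecoder(architecture, X.shape[2], hidden, Y.shape[1], rng)
    Xtr = np.asarray(X[tr], dtype=np.float64)
    flat = Xtr.reshape(-1, Xtr.shape[2])
    dec.feat_mean = flat.mean(axis=0)
    dec.feat_std = np.maximum(flat.std(axis=0), 1e-6)
    Ytr = Y[tr]
    n = Xtr.shape[0]
    m_state = {k: np.zeros_like(v) for k, v in dec.params.items()}
    v_state = {k: np.zeros_like(v) for k, v in dec.params.items()}
    step = 0
    for _ in range(epochs):
        order = rng.permutation(n)
        for start in range(0, n, batch_size):
            idx = order[start:start + batch_size]
            y, h_last, caches = dec.forward(Xtr[idx], cache=True)
            gy = 2.0 * (y - Ytr[idx]) / y.size
            grads = dec.backward(Xtr[idx], gy, h_last, caches)
            step += 1
            for k in dec.params:
                g = grads[k]
                m_state[k] = 0.9 * m_state[k] + 0.1 * g
                v_state[k] = 0.999 * v_state[k] + 0.001 * g**2
                mhat = m_state[k] / (1 - 0.9**step)
                vhat = v_state[k] / (1 - 0.999**step)
                dec.params[k] -= lr * mhat / (np.sqrt(vhat) + 1e-8)
    yv = dec.forward(X[va])
    try:
        val = r_squared(Y[va], yv)
    except ValidationError:
        val = -np.inf
    return dec, val


def _bayes_search(X, Y, tr, va, spec: DecoderSpec):
    """GP expected-improvement search over (log2 hidden, log10 lr, epochs)."""
    from sklearn.gaussian_process import GaussianProcessRegressor
    from sklearn.gaussian_process.kernels import Matern
    from scipy.stats import norm

    rng = np.random.default_rng(spec.seed + 1)
    bounds = np.array([[3.0, 7.0], [-3.5, -2.0], [10.0, 60.0]])

    def sample(m):
        return rng.uniform(bounds[:, 0], bounds[:, 1], size=(m, 3))

    def run(xp, seed):
        hidden = int(round(2 ** xp[0]))
        lr = 10.0 ** xp[1]
        epochs = int(round(xp[2]))
        _, val = _train_one(X, Y, tr, va, spec.architecture, hidden, lr, epochs,
                            spec.batch_size, seed)
        return hidden, lr, epochs, val

    log, pts, vals = [], [], []
    n_init = min(spec.budget, 4)
    cand_init = sample(n_init)
    for j in range(spec.budget):
        if j < n_init:
            xp = cand_init[j]
        else:
            gp = GaussianProcessRegressor(kernel=Matern(nu=2.5), normalize_y=True,
                                          alpha=1e-4)
            Xn = (np.array(pts) - bounds[:, 0]) / (bounds[:, 1] - bounds[:, 0])
            gp.fit(Xn, np.array(vals))
            cand = sample(256)
            cn = (cand - bounds[:, 0]) / (bounds[:, 1] - bounds[:, 0])
            mu, sd = gp.predict(cn, return_std=True)
            best = max(vals)
            imp = mu - best
            with np.errstate(divide="ignore", invalid="ignore"):
                zsc = np.where(sd > 0, imp / sd, 0.0)
                ei = np.where(sd > 0, imp * norm.cdf(zsc) + sd * norm.pdf(zsc),
                              np.maximum(imp, 0.0))
            xp = cand[int(np.argmax(ei))]
        hidden, lr, epochs, val = run(xp, spec.seed)
        pts.append(xp)
        vals.append(val)
        log.append({"hidden": hidden, "learning_rate": lr, "epochs": epochs,
                    "val_r2": val})
    best = int(np.argmax(vals))
    xb = pts[best]
    return int(round(2 ** xb[0])), 10.0 ** xb[1], int(round(xb[2])), log


def _contiguous_split(n: int, fractions) -> tuple:
    n_tr = int(round(fractions[0] * n))
    n_va = int(round(fractions[1] * n))
    n_te = n - n_tr - n_va
    if min(n_tr, n_va, n_te) < 5:
        raise ValidationError(
            f"too few samples ({n}) for a {fractions} contiguous split")
    return slice(0, n_tr), slice(n_tr, n_tr + n_va), slice(n_tr + n_va, n)


def fit_decoder(binned: BinnedResponse, targets: np.ndarray,
                spec: DecoderSpec | None = None) -> FittedDecoder:
    """Fit a recurrent decoder on the contiguous train segment.

    ``binned.tensor`` is transposed so the bin axis is the sequence axis.
    Returns the decoder together with the split slices and the validation
    accuracy; the test slice stays untouched for downstream evaluation.
    """
    spec = spec or DecoderSpec()
    targets = np.asarray(targets, dtype=np.float64)
    if targets.ndim == 1:
        targets = targets[:, None]
    if targets.shape[0] != binned.n_samples:
        raise ValidationError(
            f"{binned.n_samples} binned samples but {targets.shape[0]} targets")
    X = np.swapaxes(binned.tensor, 1, 2)  # (N, n_bins, n_features)
    tr, va, te = _contiguous_split(binned.n_samples, spec.splits)
    log = []
    hidden, lr, epochs = spec.hidden, spec.learning_rate, spec.epochs
    if spec.budget > 0:
        hidden, lr, epochs, log = _bayes_search(X, targets, tr, va, spec)
    dec, val = _train_one(X, targets, tr, va, spec.architecture, hidden, lr,
                          epochs, spec.batch_size, spec.seed)
    return FittedDecoder(decoder=dec, spec=spec, idx_train=tr, idx_val=va,
                         idx_test=te, val_r2=val, search_log=log)


def decode(fitted, binned: BinnedResponse) -> np.ndarray:
    """Deterministic forward pass of a fitted decoder on binned responses."""
    dec = fitted.decoder if isinstance(fitted, FittedDecoder) else fitted
    X = np.swapaxes(binned.tensor, 1, 2)
    return dec.forward(X)
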
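"""Synthetic time-dependent stimuli.

All stimuli are sampled on a 1 ms grid and live in arbitrary position units.
Two-dimensional stimuli represent the (x, y) position of a moving target; the
one-dimensional 1 Hz sinusoid models a horizontally oscillating target tracked
by a hovering animal.

Families
--------
``sum_of_sines``
    Two spectral components: a slow one at ``flow`` (default 4 Hz) and a
    variable fast one at ``fhigh``.  Each spatial component is the mean of both
    sines, with the y component phase-advanced by 90 degrees so the target
    traces a Lissajous-like closed curve and both frequencies are visible in
    either coordinate.
``single_sine``
    One frequency, circular trajectory (sin on x, cos on y).
``filtered_white_noise``
    Gaussian white noise low-pass filtered with a 4th-order Butterworth filter
    (zero-phase, forward-backward) and standardized to unit variance per
    component.  The filtering removes fluctuations faster than the membrane
    dynamics can follow.
``binary``
    A random telegraph signal per component, jumping between +amplitude and
    -amplitude with exponentially distributed dwell times.
``sinusoid_1hz``
    One-dimensional 1 Hz sinusoid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, filtfilt

from .errors import ConfigurationError, ValidationError

DT_MS = 1.0

__all__ = ["StimulusTrace", "generate_stimulus", "add_white_noise", "DT_MS"]


@dataclass
class StimulusTrace:
    """A stimulus time series sampled at 1 ms.

    Attributes
    ----------
    values : ndarray, shape (n_steps, ds)
        Position of the target over time.
    dt : float
        Sampling step in ms (always 1.0).
    ds : int
        Spatial dimensionality, 1 or 2.
    meta : dict
        Generator name, parameters and seed used to produce the trace.
    """

    values: np.ndarray
    dt: float = DT_MS
    ds: int = 2
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim == 1:
            self.values = self.values[:, None]
        if self.values.shape[1] != self.ds:
            raise ValidationError(
                f"values have {self.values.shape[1]} components, expected ds={self.ds}"
            )
        if self.ds not in (1, 2):
            raise ValidationError(f"ds must be 1 or 2, got {self.ds}")

    @property
    def n_steps(self) -> int:
        return self.values.shape[0]

    @property
    def duration_ms(self) -> float:
        return self.n_steps * self.dt

    def to_csv(self, path) -> None:
        """Write the trace as CSV with columns time_ms, s_x[, s_y]."""
        header = "time_ms,s_x" if self.ds == 1 else "time_ms,s_x,s_y"
        t = np.arange(self.n_steps) * self.dt
        np.savetxt(path, np.column_stack([t, self.values]), delimiter=",",
                   header=header, comments="", fmt="%.6g")


def _n_steps(duration: float) -> int:
    if duration <= 0:
        raise ValidationError(f"duration must be positive, got {duration}")
    n = duration / DT_MS
    if abs(n - round(n)) > 1e-9:
        raise ValidationError(f"duration must be a multiple of dt={DT_MS} ms")
    return int(round(n))


def _check_freq(value: float, name: str) -> float:
    if value <= 0:
        raise ValidationError(f"{name} must be positive, got {value}")
    return float(value)


def generate_stimulus(kind: str, duration: float, seed: int = 0, **params) -> StimulusTrace:
    """Generate a stimulus trace of the requested family.

    Parameters
    ----------
    kind : str
        One of ``sum_of_sines``, ``single_sine``, ``filtered_white_noise``,
        ``binary``, ``sinusoid_1hz``.
    duration : float
        Duration in ms; must be a positive multiple of 1 ms.
    seed : int
        Seed for the stochastic families (ignored by deterministic ones but
        recorded in ``meta`` either way).
    **params
        Family-specific parameters, see the module docstring.
    """
    n = _n_steps(duration)
    t = np.arange(n) * (DT_MS / 1000.0)  # seconds
    rng = np.random.default_rng(seed)
    meta = {"kind": kind, "seed": seed, "duration_ms": duration, **params}

    if kind == "sum_of_sines":
        flow = _check_freq(params.get("flow", 4.0), "flow")
        fhigh = _check_freq(params.get("fhigh", 20.0), "fhigh")
        amp = float(params.get("amplitude", 1.0))
        wl, wh = 2 * np.pi * flow, 2 * np.pi * fhigh
        sx = 0.5 * amp * (np.sin(wl * t) + np.sin(wh * t))
        sy = 0.5 * amp * (np.cos(wl * t) + np.cos(wh * t))
        values, ds = np.column_stack([sx, sy]), 2
    elif kind == "single_sine":
        f = _check_freq(params.get("f", 5.0), "f")
        amp = float(params.get("amplitude", 1.0))
        w = 2 * np.pi * f
        values, ds = np.column_stack([amp * np.sin(w * t), amp * np.cos(w * t)]), 2
    elif kind == "filtered_white_noise":
        cutoff = _check_freq(params.get("cutoff", 25.0), "cutoff")
        order = int(params.get("order", 4))
        amp = float(params.get("amplitude", 1.0))
        white = rng.standard_normal((n, 2))
        # fs = 1000 Hz; zero-phase filtering, then unit variance per component
        b, a = butter(order, cutoff, fs=1000.0, btype="low")
        filt = filtfilt(b, a, white, axis=0)
        filt = filt - filt.mean(axis=0)
        filt = filt / filt.std(axis=0)
        values, ds = amp * filt, 2
    elif kind == "binary":
        switch_rate = _check_freq(params.get("switch_rate", 10.0), "switch_rate")
        amp = float(params.get("amplitude", 1.0))
        mean_dwell = 1000.0 / switch_rate  # ms
        values = np.empty((n, 2))
        for c in range(2):
            values[:, c] = _telegraph(n, mean_dwell, amp, rng)
        ds = 2
    elif kind == "sinusoid_1hz":
        amp = float(params.get("amplitude", 1.0))
        values, ds = (amp * np.sin(2 * np.pi * 1.0 * t))[:, None], 1
    else:
        raise ConfigurationError(f"unknown stimulus kind {kind!r}")

    return StimulusTrace(values=values, ds=ds, meta=meta)


def _telegraph(n: int, mean_dwell: float, amp: float, rng: np.random.Generator) -> np.ndarray:
    out = np.empty(n)
    level = amp if rng.random() < 0.5 else -amp
    pos = 0
    while pos < n:
        dwell = max(1, int(round(rng.exponential(mean_dwell))))
        out[pos : pos + dwell] = level
        level = -level
        pos += dwell
    return out


def add_white_noise(stimulus: StimulusTrace, sigma: float, seed: int = 0) -> StimulusTrace:
    """Return a copy of ``stimulus`` with i.i.d. Gaussian noise added per step."""
    if sigma < 0:
        raise ValidationError(f"sigma must be non-negative, got {sigma}")
    rng = np.random.default_rng(seed)
    noisy = stimulus.values + sigma * rng.standard_normal(stimulus.values.shape)
    meta = dict(stimulus.meta)
    meta.update(noise_sigma=sigma, noise_seed=seed)
    return StimulusTrace(values=noisy, dt=stimulus.dt, ds=stimulus.ds, meta=meta)
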
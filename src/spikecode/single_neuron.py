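"""Single-neuron decomposition of mutual information into count and timing parts.

The recording is cut into non-overlapping windows of duration ``T`` (50 ms by
default, the wingstroke period of a hovering hawkmoth).  For each window we
keep the spike count ``Rc`` and the within-window spike times ``Rt`` (ms from
window start, sorted ascending), plus one stimulus value per window.  The
mutual information between stimulus and response then splits exactly as

    I(s, R) = I(s, Rc) + sum_i p(Rc = i) * I(Rt, s | Rc = i)

i.e. a spike-count term plus count-conditioned spike-timing terms.  The
decomposition is conservative about timing: timing contributions are only
counted once the count has been fully accounted for.  The count term uses the
discrete-continuous KSG variant; each conditional timing term is a KSG
estimate among the windows with exactly ``i`` spikes, using the ``i`` spike
times as coordinates.  Classes with fewer than ``2 * (k + 1)`` windows are
skipped and their probability mass reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError
from .measures import ksg_mi, mi_discrete_continuous
from .network import SpikeRaster
from .stimuli import StimulusTrace

__all__ = [
    "WindowedResponse",
    "InfoDecomposition",
    "window_spike_features",
    "mi_count_timing",
    "layer_info_rates",
]


@dataclass
class WindowedResponse:
    """Per-window spike count and spike times for one neuron."""

    counts: np.ndarray  # (n_windows,) non-negative ints
    timings: list  # timings[i] = sorted spike times (ms) within window i
    window: int

    @property
    def n_windows(self) -> int:
        return self.counts.shape[0]


@dataclass
class InfoDecomposition:
    """Count and timing information (bits per window)."""

    count_info: float
    timing_info: float
    window: int
    p_mass_included: float = 1.0
    class_probs: dict = field(default_factory=dict)
    skipped_classes: list = field(default_factory=list)

    @property
    def total(self) -> float:
        return self.count_info + self.timing_info

    def rate(self, part: str = "total") -> float:
        """Information rate in bits/s."""
        value = {"count": self.count_info, "timing": self.timing_info,
                 "total": self.total}[part]
        return value / self.window * 1000.0


def _window_target(s: np.ndarray, n_windows: int, window: int, convention: str) -> np.ndarray:
    starts = np.arange(n_windows) * window
    if convention == "midpoint":
        return s[starts + window // 2]
    if convention == "start":
        return s[starts]
    if convention == "mean":
        return s[: n_windows * window].reshape(n_windows, window, -1).mean(axis=1)
    raise ValidationError(f"unknown target convention {convention!r}")


def window_spike_features(spike_train, window: int, stimulus,
                          target_convention: str = "midpoint",
                          truncate: bool = False):
    """Cut a single-neuron spike train into non-overlapping windows.

    Returns ``(WindowedResponse, targets)`` where ``targets`` has one
    stimulus value per window (by default the value at the window midpoint).
    With ``truncate=True`` a trailing partial window is dropped instead of
    raising.
    """
    train = np.asarray(spike_train).ravel()
    s = stimulus.values if isinstance(stimulus, StimulusTrace) else np.asarray(stimulus)
    if s.ndim == 1:
        s = s[:, None]
    nt = train.shape[0]
    if s.shape[0] != nt:
        raise ValidationError("spike train and stimulus must have equal length")
    if nt % window != 0:
        if not truncate:
            raise ValidationError(
                f"recording length {nt} is not a multiple of window {window} "
                "(pass truncate=True to drop the remainder)")
        nt = (nt // window) * window
        train, s = train[:nt], s[:nt]
    n_windows = nt // window
    counts = train.reshape(n_windows, window).sum(axis=1).astype(np.int64)
    spike_t = np.flatnonzero(train)
    timings = [np.sort(spike_t[(spike_t >= w * window) & (spike_t < (w + 1) * window)]
                       - w * window).astype(np.float64)
               for w in range(n_windows)]
    targets = _window_target(s, n_windows, window, target_convention)
    return WindowedResponse(counts=counts, timings=timings, window=window), targets


def mi_count_timing(windowed: WindowedResponse, targets: np.ndarray,
                    k: int = 3, jitter: float = 1e-6,
                    rng: np.random.Generator | None = None) -> InfoDecomposition:
    """Count/timing information decomposition for one neuron.

    A vanishing relative jitter is added to the target values and the timing
    coordinates before the neighbor-based estimates.  Spike times live on a
    1 ms grid and a periodic stimulus sampled at the window grid repeats
    values exactly, so without the jitter the estimators see massively tied
    distances and their neighbor counts degenerate.
    """
    counts = windowed.counts
    n = windowed.n_windows
    targets = np.asarray(targets, dtype=np.float64)
    if targets.shape[0] != n:
        raise ValidationError("one target per window required")
    if counts.max(initial=0) == 0:
        return InfoDecomposition(count_info=0.0, timing_info=0.0,
                                 window=windowed.window, p_mass_included=0.0)
    rng = rng or np.random.default_rng(0)
    t_scale = jitter * max(float(np.std(targets)), 1e-30)
    targets = targets + t_scale * rng.standard_normal(targets.shape)
    if np.unique(counts).size == 1:
        count_info = 0.0
    else:
        count_info = mi_discrete_continuous(counts, targets, k=k)
    timing_info = 0.0
    included_mass = 0.0
    class_probs, skipped = {}, []
    min_class = max(2 * (k + 1), k + 2)
    for i in np.unique(counts):
        if i == 0:
            continue
        mask = counts == i
        n_i = int(mask.sum())
        p_i = n_i / n
        class_probs[int(i)] = p_i
        if n_i < min_class:
            skipped.append(int(i))
            continue
        times = np.stack([windowed.timings[w] for w in np.flatnonzero(mask)])
        times = times + jitter * windowed.window * rng.standard_normal(times.shape)
        mi_i = ksg_mi(times, targets[mask], k=k)
        timing_info += p_i * max(mi_i, 0.0)
        included_mass += p_i
    return InfoDecomposition(count_info=count_info, timing_info=timing_info,
                             window=windowed.window, p_mass_included=included_mass,
                             class_probs=class_probs, skipped_classes=skipped)


def layer_info_rates(rasters, stimulus, window: int = 50, k: int = 3,
                     target_convention: str = "midpoint",
                     truncate: bool = True) -> pd.DataFrame:
    """Per-neuron count/timing information rates for every layer.

    Parameters
    ----------
    rasters : list of SpikeRaster (one per layer, as returned by ``simulate``)
    stimulus : StimulusTrace
        Decomposition target (the encoded stimulus standing in for a motor
        output).

    Returns
    -------
    DataFrame with columns (layer, neuron, count_bits_per_s,
    timing_bits_per_s, p_mass_included).
    """
    rows = []
    for raster in rasters:
        spikes = raster.spikes if isinstance(raster, SpikeRaster) else np.asarray(raster)
        label = raster.layer if isinstance(raster, SpikeRaster) else ""
        for j in range(spikes.shape[1]):
            windowed, targets = window_spike_features(
                spikes[:, j], window, stimulus,
                target_convention=target_convention, truncate=truncate)
            dec = mi_count_timing(windowed, targets, k=k)
            rows.append({
                "layer": label,
                "neuron": j,
                "count_bits_per_s": dec.rate("count"),
                "timing_bits_per_s": dec.rate("timing"),
                "p_mass_included": dec.p_mass_included,
            })
    return pd.DataFrame(rows)
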
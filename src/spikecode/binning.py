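"""Sliding-window binning of spike rasters.

A rectangular window of width ``T`` ms slides over the raster at stride 1;
each window is partitioned into ``T / dt`` contiguous bins of spike counts.
At ``dt = T`` each window collapses to a single spike count; at ``dt = 1``
the binned response is the raw binary window itself.  The target aligned to
the window starting at time ``t`` is the stimulus value at ``t``: the decoder
predicts the stimulus at the *beginning* of the response window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .errors import ValidationError
from .network import SpikeRaster
from .stimuli import StimulusTrace

__all__ = ["BinnedResponse", "sliding_window_bin", "align_targets"]


@dataclass
class BinnedResponse:
    """Windowed, dt-binned spike counts.

    tensor : (n_samples, n_features, n_bins) non-negative integer counts.
    """

    tensor: np.ndarray
    window: int
    bin_size: int

    @property
    def n_samples(self) -> int:
        return self.tensor.shape[0]

    @property
    def n_features(self) -> int:
        return self.tensor.shape[1]

    @property
    def n_bins(self) -> int:
        return self.tensor.shape[2]


def _as_spikes(raster) -> np.ndarray:
    spikes = raster.spikes if isinstance(raster, SpikeRaster) else np.asarray(raster)
    if spikes.ndim == 1:
        spikes = spikes[:, None]
    return spikes


def sliding_window_bin(raster, window: int, bin_size: int) -> BinnedResponse:
    """Bin a raster with a stride-1 sliding window.

    Parameters
    ----------
    raster : SpikeRaster or (T, n) / (T,) binary array
    window : int
        Window width T in ms.
    bin_size : int
        Bin size dt in ms; must divide ``window``.
    """
    spikes = _as_spikes(raster)
    tf = spikes.shape[0]
    if window > tf:
        raise ValidationError(f"window {window} exceeds raster length {tf}")
    if window % bin_size != 0:
        raise ValidationError(f"bin size {bin_size} must divide window {window}")
    n_bins = window // bin_size
    # (n_samples, n_features, window) -> sum within each contiguous bin
    win = sliding_window_view(spikes, window, axis=0)
    binned = win.reshape(win.shape[0], win.shape[1], n_bins, bin_size).sum(axis=3)
    return BinnedResponse(tensor=np.ascontiguousarray(binned.astype(np.int64)),
                          window=window, bin_size=bin_size)


def align_targets(stimulus, window: int) -> np.ndarray:
    """Targets aligned to the sliding windows: row i is the stimulus at the
    start of window i.  Returns (n_samples, ds)."""
    s = stimulus.values if isinstance(stimulus, StimulusTrace) else np.asarray(stimulus)
    if s.ndim == 1:
        s = s[:, None]
    tf = s.shape[0]
    if window > tf:
        raise ValidationError(f"window {window} exceeds stimulus length {tf}")
    return s[: tf - window + 1].copy()
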
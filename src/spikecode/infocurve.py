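"""Information curves: association between stimulus and decoded stimulus as a
function of the bin size dt.

For each dt in the grid the layer's raster is sliding-window binned, a
recurrent decoder is fitted on the contiguous training segment, and the
association measure (decoding accuracy R^2 or KSG mutual-information rate
``I(s, s_hat) / T`` in bits/ms) is evaluated on the held-out test segment.
The slope of the resulting curve versus dt summarizes the layer's coding
preference: strongly negative slopes mean information lives in precise spike
timing, flat curves mean a count code suffices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .binning import BinnedResponse, align_targets, sliding_window_bin
from .decoder import DecoderSpec, decode, fit_decoder
from .errors import ValidationError
from .measures import ksg_mi, r_squared

__all__ = ["InfoCurve", "info_curve", "line_slope", "accuracy_gain"]

DEFAULT_DT_GRID = (1, 2, 5, 10, 25, 50)
DEFAULT_WINDOW = 50


@dataclass
class InfoCurve:
    """Association measure per bin size, for one layer and one network seed."""

    dts: np.ndarray
    values: np.ndarray
    measure: str = "r2"
    layer: str = ""

    def __post_init__(self) -> None:
        self.dts = np.asarray(self.dts, dtype=np.float64)
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.dts.shape != self.values.shape:
            raise ValidationError("dts and values must have equal length")

    def value_at(self, dt: float) -> float:
        hit = np.flatnonzero(np.isclose(self.dts, dt))
        if hit.size == 0:
            raise ValidationError(f"bin size {dt} not in curve grid {self.dts}")
        return float(self.values[hit[0]])


def info_curve(raster, stimulus, dt_grid=DEFAULT_DT_GRID, spec: DecoderSpec | None = None,
               measure: str = "r2", window: int = DEFAULT_WINDOW,
               sample_stride: int = 1, mi_k: int = 3, layer: str = "") -> InfoCurve:
    """Decode a layer's raster at every bin size of the grid.

    Parameters
    ----------
    raster : SpikeRaster or (T, n) array
    stimulus : StimulusTrace or (T, ds) array
        Decoding target (for a denoising experiment, the clean stimulus).
    dt_grid : sequence of bin sizes; each must divide ``window``.
    sample_stride : int
        Keep every ``sample_stride``-th sliding window.  The stride-1
        construction is exact but adjacent windows are nearly identical;
        striding thins this redundancy to keep decoder fits affordable.
    measure : "r2" or "mi_rate"
        ``mi_rate`` reports ``ksg_mi(s, s_hat) / window`` in bits/ms.
    """
    if measure not in ("r2", "mi_rate"):
        raise ValidationError(f"unknown measure {measure!r}")
    spec = spec or DecoderSpec()
    targets_full = align_targets(stimulus, window)
    values = []
    for dt in dt_grid:
        binned = sliding_window_bin(raster, window, int(dt))
        sub = BinnedResponse(tensor=binned.tensor[::sample_stride],
                             window=window, bin_size=int(dt))
        targets = targets_full[::sample_stride]
        fitted = fit_decoder(sub, targets, spec)
        te = fitted.idx_test
        test = BinnedResponse(tensor=sub.tensor[te], window=window, bin_size=int(dt))
        s_hat = decode(fitted, test)
        if measure == "r2":
            values.append(r_squared(targets[te], s_hat))
        else:
            values.append(ksg_mi(targets[te], s_hat, k=mi_k) / window)
    return InfoCurve(dts=np.asarray(dt_grid, dtype=float), values=np.asarray(values),
                     measure=measure, layer=layer)


def line_slope(curve: InfoCurve) -> float:
    """Ordinary least-squares slope of the measure versus dt (per ms)."""
    if np.unique(curve.dts).size < 2:
        raise ValidationError("need at least 2 distinct bin sizes for a slope")
    return float(np.polyfit(curve.dts, curve.values, 1)[0])


def accuracy_gain(curve: InfoCurve, dt_fine: float = 5, dt_coarse: float = 50) -> float:
    """Measure at the fine bin size minus at the coarse one (default 5 vs 50 ms)."""
    return curve.value_at(dt_fine) - curve.value_at(dt_coarse)
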
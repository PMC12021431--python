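"""Maximum-entropy upper bounds for spike-count and spike-timing codes.

With a response window of ``T`` ms and a refractory period of ``tau_ref`` ms
a neuron has ``n_bins = T / tau_ref`` slots for spikes.  A count code has
``n_bins + 1`` outcomes (0..n_bins spikes); a timing code has ``2**n_bins``
outcomes (every binary spike pattern).  Under uniform (maximum-entropy)
outcome distributions:

    H_count  = log2(n_bins + 1)      bits per window
    H_timing = n_bins                bits per window

so count-code capacity grows logarithmically with the window while timing-code
capacity grows linearly.  For a population of ``n_neurons`` independent
neurons both bounds scale linearly in the population size, with slopes
``log2(n_bins + 1)`` and ``n_bins`` respectively — a small population
(e.g. downstream of a structural convergence) can only match a timing code's
capacity with a count code by recruiting many more neurons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError

__all__ = ["CodeGeometry", "single_neuron_bounds", "population_bounds"]


@dataclass
class CodeGeometry:
    """Window length, refractory period, and population size."""

    window: float  # T, ms
    refractory: float  # tau_ref, ms
    n_neurons: int = 1

    def __post_init__(self) -> None:
        if self.window <= 0 or self.refractory <= 0:
            raise ValidationError("window and refractory period must be positive")
        if self.n_neurons < 1:
            raise ValidationError("population size must be >= 1")
        ratio = self.window / self.refractory
        if abs(ratio - round(ratio)) > 1e-9:
            raise ValidationError(
                f"refractory period {self.refractory} must divide window {self.window}")

    @property
    def n_bins(self) -> int:
        n = int(round(self.window / self.refractory))
        if n < 1:
            raise ValidationError("n_bins must be >= 1")
        return n


def single_neuron_bounds(geometry: CodeGeometry) -> tuple:
    """(count bound, timing bound) in bits per window for one neuron."""
    n_bins = geometry.n_bins
    return float(np.log2(n_bins + 1)), float(n_bins)


def population_bounds(geometry: CodeGeometry) -> dict:
    """Population entropy bounds and entropy rates.

    Returns a dict with the per-window bounds (bits) and the rates (bits/ms)
    for both code types; all scale linearly with the population size.
    """
    h_c, h_t = single_neuron_bounds(geometry)
    n = geometry.n_neurons
    return {
        "count_bits": n * h_c,
        "timing_bits": n * h_t,
        "count_rate_bits_per_ms": n * h_c / geometry.window,
        "timing_rate_bits_per_ms": n * h_t / geometry.window,
    }
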
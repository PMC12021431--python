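"""Orchestration of the two experiment suites.

Three-layer suite: networks [n_in, n_hidden, n_out] with the hidden size swept
across bottleneck (small n_hidden) and expansion (large n_hidden) regimes are
trained to autoencode a stimulus; information curves are then computed per
layer and summarized by their slope versus dt and by the accuracy gain
(fine-bin minus coarse-bin decoding accuracy).

Five-layer suite: an input(48) -> expansion -> bottleneck -> expansion ->
output(10) chain patterned on an insect visuomotor pathway.  Two experiments:
a 1 Hz sinusoid with single-neuron count/timing information decomposition per
layer, and a noisy 4+20 Hz sum of sines (clean training target, clean decoding
target) with population information-curve slopes per layer.

All sweeps iterate over independent network seeds with per-seed isolation: a
failing seed is recorded and skipped rather than aborting the sweep.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .decoder import DecoderSpec
from .errors import ValidationError
from .infocurve import InfoCurve, accuracy_gain, info_curve, line_slope
from .network import build_network, simulate
from .single_neuron import layer_info_rates
from .stimuli import add_white_noise, generate_stimulus
from .training import TrainingConfig, train_network

logger = logging.getLogger(__name__)

__all__ = [
    "ThreeLayerConfig",
    "FiveLayerConfig",
    "run_three_layer_experiment",
    "run_five_layer_experiment",
    "rank_sum_compare",
    "slopes_table",
    "gains_table",
]


@dataclass
class ThreeLayerConfig:
    """Study conditions for the three-layer hidden-size sweep (desk scale)."""

    n_in: int = 100
    n_out: int = 100
    hidden_sizes: tuple = (10, 250)
    model: str = "alpha"
    stimulus_kind: str = "sum_of_sines"
    stimulus_params: dict = field(default_factory=lambda: {"flow": 4.0, "fhigh": 20.0})
    seeds: tuple = (0, 1, 2, 3, 4)
    train_ms: float = 4000.0
    analysis_ms: float = 6000.0
    training: TrainingConfig = field(default_factory=lambda: TrainingConfig(n_iter=150))
    decoder: DecoderSpec = field(default_factory=DecoderSpec)
    dt_grid: tuple = (1, 2, 5, 10, 25, 50)
    layers: tuple = ("hidden", "output")
    measure: str = "r2"
    window: int = 50
    sample_stride: int = 3


@dataclass
class FiveLayerConfig:
    """Study conditions for the five-layer visuomotor-style model."""

    layer_sizes: tuple = (48, 240, 12, 120, 10)
    model: str = "alpha"
    experiment: str = "1hz"  # "1hz" | "noisy_sos"
    noise_sigma: float = 0.3
    seeds: tuple = (0, 1, 2, 3, 4)
    train_ms: float = 6000.0
    analysis_ms: float = 10000.0
    training: TrainingConfig = field(default_factory=lambda: TrainingConfig(n_iter=150))
    decoder: DecoderSpec = field(default_factory=DecoderSpec)
    dt_grid: tuple = (1, 2, 5, 10, 25, 50)
    measure: str = "r2"
    window: int = 50
    sample_stride: int = 3
    mi_k: int = 3


def rank_sum_compare(sample_a, sample_b, alternative: str = "less"):
    """One-sided (or two-sided) Wilcoxon rank-sum / Mann-Whitney test.

    ``alternative="less"`` tests whether ``sample_a`` tends to be smaller than
    ``sample_b``.  Returns (statistic, p-value).
    """
    a = np.asarray(sample_a, dtype=np.float64)
    b = np.asarray(sample_b, dtype=np.float64)
    if a.size == 0 or b.size == 0:
        raise ValidationError("both samples must be non-empty")
    method = "auto"
    if a.size <= 25 and b.size <= 25 and np.unique(np.concatenate([a, b])).size == a.size + b.size:
        method = "exact"  # small samples without ties: exact tail probabilities
    res = mannwhitneyu(a, b, alternative=alternative, method=method)
    return float(res.statistic), float(res.pvalue)


def _train_and_simulate(layer_sizes, model, seed, stimulus_kind, stimulus_params,
                        train_ms, analysis_ms, training, noise_sigma=0.0):
    """Build, train, and simulate one network seed.

    Returns (rasters, analysis-target stimulus).  With ``noise_sigma > 0``
    the network input is the noise-corrupted stimulus while the training and
    decoding target stay clean.
    """
    stim_train = generate_stimulus(stimulus_kind, train_ms, seed=seed, **stimulus_params)
    stim_analysis = generate_stimulus(stimulus_kind, analysis_ms, seed=seed + 10_000,
                                      **stimulus_params)
    net = build_network(layer_sizes, model=model, seed=seed)
    cfg = replace(training, seed=seed)
    if noise_sigma > 0:
        noisy_train = add_white_noise(stim_train, noise_sigma, seed=seed + 20_000)
        result = train_network(net, noisy_train, training=cfg, target=stim_train)
        noisy_analysis = add_white_noise(stim_analysis, noise_sigma, seed=seed + 30_000)
        rasters = simulate(result.network, noisy_analysis)
    else:
        result = train_network(net, stim_train, training=cfg)
        rasters = simulate(result.network, stim_analysis)
    return rasters, stim_analysis, result


def run_three_layer_experiment(config: ThreeLayerConfig) -> pd.DataFrame:
    """Hidden-size sweep; returns a long-format table of information curves.

    Columns: n_hidden, layer, seed, dt, measure, value.
    """
    records = []
    for nh in config.hidden_sizes:
        sizes = [config.n_in, nh, config.n_out]
        for seed in config.seeds:
            try:
                rasters, target, _ = _train_and_simulate(
                    sizes, config.model, seed, config.stimulus_kind,
                    config.stimulus_params, config.train_ms, config.analysis_ms,
                    config.training)
                by_name = {r.layer: r for r in rasters}
                for layer in config.layers:
                    spec = replace(config.decoder, seed=seed)
                    curve = info_curve(by_name[layer], target, config.dt_grid,
                                       spec=spec, measure=config.measure,
                                       window=config.window,
                                       sample_stride=config.sample_stride,
                                       layer=layer)
                    for dt, val in zip(curve.dts, curve.values):
                        records.append({"n_hidden": nh, "layer": layer, "seed": seed,
                                        "dt": float(dt), "measure": config.measure,
                                        "value": float(val)})
            except Exception:
                logger.exception("three-layer seed %s (n_hidden=%s) failed", seed, nh)
    return pd.DataFrame(records)


def run_five_layer_experiment(config: FiveLayerConfig):
    """Run the 1 Hz or noisy sum-of-sines five-layer experiment.

    Returns a DataFrame: per-neuron information rates (columns layer, neuron,
    seed, count_bits_per_s, timing_bits_per_s) for ``experiment="1hz"``, or
    information-curve values (columns layer, seed, dt, value) for
    ``experiment="noisy_sos"``.
    """
    if config.experiment not in ("1hz", "noisy_sos"):
        raise ValidationError(f"unknown experiment {config.experiment!r}")
    records = []
    for seed in config.seeds:
        try:
            if config.experiment == "1hz":
                rasters, target, _ = _train_and_simulate(
                    list(config.layer_sizes), config.model, seed, "sinusoid_1hz", {},
                    config.train_ms, config.analysis_ms, config.training)
                table = layer_info_rates(rasters, target, window=config.window,
                                         k=config.mi_k)
                table["seed"] = seed
                records.append(table)
            else:
                rasters, target, _ = _train_and_simulate(
                    list(config.layer_sizes), config.model, seed, "sum_of_sines",
                    {"flow": 4.0, "fhigh": 20.0}, config.train_ms,
                    config.analysis_ms, config.training,
                    noise_sigma=config.noise_sigma)
                for raster in rasters:
                    spec = replace(config.decoder, seed=seed)
                    curve = info_curve(raster, target, config.dt_grid, spec=spec,
                                       measure=config.measure, window=config.window,
                                       sample_stride=config.sample_stride,
                                       layer=raster.layer)
                    for dt, val in zip(curve.dts, curve.values):
                        records.append(pd.DataFrame([{
                            "layer": raster.layer, "seed": seed, "dt": float(dt),
                            "measure": config.measure, "value": float(val)}]))
        except Exception:
            logger.exception("five-layer seed %s failed", seed)
    if not records:
        return pd.DataFrame()
    return pd.concat(records, ignore_index=True)


def _curves(df: pd.DataFrame, keys):
    for key_vals, group in df.groupby(list(keys)):
        group = group.sort_values("dt")
        yield key_vals, InfoCurve(dts=group["dt"].to_numpy(),
                                  values=group["value"].to_numpy())


def slopes_table(df: pd.DataFrame, keys=("n_hidden", "layer", "seed")) -> pd.DataFrame:
    """OLS slope of value vs dt for every (keys) group of a long table."""
    keys = [k for k in keys if k in df.columns]
    rows = []
    for key_vals, curve in _curves(df, keys):
        if not isinstance(key_vals, tuple):
            key_vals = (key_vals,)
        rows.append({**dict(zip(keys, key_vals)), "slope": line_slope(curve)})
    return pd.DataFrame(rows)


def gains_table(df: pd.DataFrame, keys=("n_hidden", "layer", "seed"),
                dt_fine: float = 5, dt_coarse: float = 50) -> pd.DataFrame:
    """Accuracy gain (fine minus coarse) for every (keys) group."""
    keys = [k for k in keys if k in df.columns]
    rows = []
    for key_vals, curve in _curves(df, keys):
        if not isinstance(key_vals, tuple):
            key_vals = (key_vals,)
        rows.append({**dict(zip(keys, key_vals)),
                     "gain": accuracy_gain(curve, dt_fine, dt_coarse)})
    return pd.DataFrame(rows)
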
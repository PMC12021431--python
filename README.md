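# spikecode

Temporal resolution of spike coding in feedforward spiking networks with
signal convergence and divergence.

Sensorimotor pathways repeatedly expand small populations onto large ones
and converge large populations onto small ones (e.g. an insect visuomotor
pathway: ~48 motion-sensitive inputs → brain → neck connective → thoracic
circuits → 10 wing muscles).  `spikecode` is a research package for asking
how that structure shapes *when spike timing matters*: it trains small
feedforward spiking neural networks (alpha / LIF neurons, surrogate-gradient
BPTT) to autoencode time-dependent stimuli, decodes each layer's population
spike trains binned at temporal resolution Δt with recurrent (GRU/LSTM)
decoders, decomposes single-neuron information into spike-count and
spike-timing parts, and provides the closed-form maximum-entropy bounds

    H̃_count  = log2(n_bins + 1)   bits per window,
    H̃_timing = n_bins             bits per window,   n_bins = T / τ_ref,

which show that count-code capacity grows only logarithmically with the
response window while timing-code capacity grows linearly — so populations
downstream of a structural convergence have the most to gain from precisely
timed spikes.

The decoding analysis slides a window of T = 50 ms over each raster,
subdivides it into bins of Δt ∈ {1, 2, 5, 10, 25, 50} ms, reconstructs the
stimulus from the binned tensor, and summarizes the resulting *information
curve* (R² or KSG mutual-information rate vs Δt) by its slope and by the
accuracy gain ΔR² = R²(5 ms) − R²(50 ms).

Everything runs on plain numpy/scipy: the spiking-network BPTT and the
recurrent decoders use hand-derived gradients (finite-difference-verified in
the test suite), the time recursions are numba-compiled, and the KSG
mutual-information estimators are built on `scipy.spatial.cKDTree`.

## Worked example

Train a bottleneck network on a 4 Hz + 20 Hz sum of sines and measure how
much decoding accuracy its hidden layer loses when spikes are binned
coarsely:

```python
import spikecode as sc

stim = sc.generate_stimulus("sum_of_sines", 4000, seed=0, flow=4, fhigh=20)
net = sc.build_network([100, 10, 100], seed=0)          # 10-neuron bottleneck
result = sc.train_network(net, stim, training=sc.TrainingConfig(n_iter=150, seed=0))
print(f"loss {result.loss_history[0]:.3f} -> {result.loss_history[-1]:.3f}")

probe = sc.generate_stimulus("sum_of_sines", 6000, seed=1, flow=4, fhigh=20)
hidden = sc.simulate(result.network, probe)[1]
curve = sc.info_curve(hidden, probe, dt_grid=(5, 50),
                      spec=sc.DecoderSpec(seed=0), sample_stride=3)
print(f"R2(5 ms) = {curve.value_at(5):.3f}, R2(50 ms) = {curve.value_at(50):.3f}, "
      f"accuracy gain = {sc.accuracy_gain(curve):.3f}")
```

Output:

```
loss 0.251 -> 0.092
R2(5 ms) = 0.989, R2(50 ms) = 0.843, accuracy gain = 0.147
```

The 10-neuron hidden layer reconstructs the stimulus almost perfectly from
1–5 ms bins but loses the 20 Hz component at 50 ms bins (gain ≈ 0.15);
running the same code with `[100, 250, 100]` gives a gain of ≈ 0.00 — an
expansion layer has enough neurons to carry the fast component in counts
alone.

## Analysis scripts

The numbered scripts under `analysis/` run the packaged studies and write
tables to `results/`:

| script | what it does |
| --- | --- |
| `01_entropy_bounds.py` | count/timing capacity bounds vs bins and population size |
| `02_binning_worked_example.py` | the sliding-window binning construction on a 10-step train |
| `03_three_layer_sweep.py` | bottleneck vs expansion hidden layers: accuracy gains and slopes |
| `04_five_layer_single_neuron.py` | 5-layer model, 1 Hz stimulus: count/timing decomposition |
| `05_five_layer_noisy_decoding.py` | 5-layer model, noisy 4+20 Hz: per-layer information curves |

Each accepts `--out`; the network sweeps (03–05) also take `--seed` and
`--n-seeds`.  See `docs/methods.md` for
the model equations, estimator details, the desk-scale study conditions,
and an honest account of which previously reported orderings this implementation does
and does not reproduce.

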
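"""Maximum-entropy bounds for spike-count vs spike-timing codes.

Computes (i) the slopes of the population entropy bounds versus population
size as a function of the number of timing bins, and (ii) the entropy rate
versus population size for the reference window T = 15 ms with a 5 ms
refractory period.  Writes both sweeps to results/ and prints the headline
numbers: a single neuron with 3 timing bins can carry at most 3 bits per
window with a timing code but only 2 bits with a count code, and for 10
neurons the rates are 2.0 vs 1.33 bits/ms.

Usage: python analysis/01_entropy_bounds.py [--out results]
"""

import argparse
import pathlib

import pandas as pd

from spikecode import CodeGeometry, population_bounds, single_neuron_bounds


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--out", default="results", type=pathlib.Path)
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    slopes = pd.DataFrame([
        {"n_bins": n, "count_slope_bits": single_neuron_bounds(
            CodeGeometry(window=float(n), refractory=1.0))[0],
         "timing_slope_bits": float(n)}
        for n in range(1, 17)
    ])
    slopes.to_csv(args.out / "entropy_bound_slopes.csv", index=False)

    rows = []
    for n_neurons in range(1, 51):
        geom = CodeGeometry(window=15, refractory=5, n_neurons=n_neurons)
        rows.append({"n_neurons": n_neurons, **population_bounds(geom)})
    pop = pd.DataFrame(rows)
    pop.to_csv(args.out / "entropy_bound_population.csv", index=False)

    h_c, h_t = single_neuron_bounds(CodeGeometry(window=15, refractory=5))
    ten = population_bounds(CodeGeometry(window=15, refractory=5, n_neurons=10))
    print(f"single neuron, T=15 ms, tau_ref=5 ms: count bound {h_c:.0f} bits, "
          f"timing bound {h_t:.0f} bits per window")
    print(f"population of 10: timing rate {ten['timing_rate_bits_per_ms']:.2f} bits/ms, "
          f"count rate {ten['count_rate_bits_per_ms']:.2f} bits/ms")
    print(f"wrote {args.out / 'entropy_bound_slopes.csv'} and "
          f"{args.out / 'entropy_bound_population.csv'}")


if __name__ == "__main__":
    main()
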
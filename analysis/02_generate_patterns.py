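"""Generate correlated MF activity patterns and check their statistics.

Draws dichotomized-Gaussian ensembles at f_MF = 0.3 for independent
(sigma = 0) and spatially correlated (sigma = 20 um) inputs, and tabulates
the two diagnostics of input statistics: the per-pattern active-fraction
histogram and the pairwise correlation versus inter-rosette distance,
against the specified Gaussian kernel. Writes
results/mf_activity_histogram.csv and results/mf_correlation_vs_distance.csv.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist

from gclayer import anatomy, mf_patterns


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results"))
    ap.add_argument("--f-mf", type=float, default=0.3)
    ap.add_argument("--n-patterns", type=int, default=2000)
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    geom = anatomy.place_cells(seed=args.seed)
    dist = pdist(geom.mf_positions)
    rows_hist, rows_corr = [], []
    for sigma in (0.0, 20.0):
        ens = mf_patterns.make_correlated_patterns(
            geom.mf_positions, args.f_mf, sigma, args.n_patterns, seed=args.seed + 7
        )
        frac = ens.X.mean(axis=1)
        hist, edges = np.histogram(frac, bins=np.linspace(0, 1, 41))
        rows_hist += [{"sigma": sigma, "frac_lo": lo, "frac_hi": hi, "n_patterns": n}
                      for lo, hi, n in zip(edges[:-1], edges[1:], hist)]

        emp = np.corrcoef(ens.X.astype(float), rowvar=False)
        iu = np.triu_indices(geom.n_mf, 1)
        df = pd.DataFrame({"distance_um": dist, "empirical_r": emp[iu],
                           "specified_r": np.exp(-dist**2 / (2 * sigma**2)) if sigma else 0.0})
        binned = (df.groupby(pd.cut(df.distance_um, np.arange(0, 85, 5)), observed=True)
                    .mean(numeric_only=True).reset_index(drop=True))
        binned["sigma"] = sigma
        rows_corr.append(binned)
        print(f"sigma={sigma:4.0f}: mean activity {frac.mean():.3f} "
              f"(specified {args.f_mf}), active-fraction sd {frac.std():.3f}")

    pd.DataFrame(rows_hist).to_csv(args.out / "mf_activity_histogram.csv", index=False)
    corr = pd.concat(rows_corr, ignore_index=True)
    corr.to_csv(args.out / "mf_correlation_vs_distance.csv", index=False)
    near = corr[(corr.sigma == 20.0) & (corr.distance_um < 20)]
    print("\nsigma=20 um: near-pair empirical correlations "
          f"{near.empirical_r.mean():.2f} track the specified kernel "
          f"{near.specified_r.mean():.2f} (attenuated where the latent fit "
          "requires a positive-semidefinite repair; see docs/methods.md).")


if __name__ == "__main__":
    main()
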
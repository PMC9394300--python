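#!/usr/bin/env python
"""Subgroup recovery vs data transformation, and the site-null check.

Runs the five-replicate recovery study: planted cohorts through the full
grid, measuring (i) how well each method x transform cell recovers the
planted subgroups, (ii) whether the expression-independent site labels
ever drive clustering (they must not). Writes results/recovery_study.json.
"""

import argparse
import json
import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parent.parent
sys.path.insert(0, str(ROOT / "src"))

from vizclust.experiments import run_recovery_study


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--n-seeds", type=int, default=5)
    args = ap.parse_args()

    study = run_recovery_study(args.seed, n_seeds=args.n_seeds)
    results = ROOT / "results"
    results.mkdir(exist_ok=True)
    (results / "recovery_study.json").write_text(
        json.dumps(study, indent=2, sort_keys=True) + "\n"
    )

    print(f"{args.n_seeds} replicate cohorts, full grid each")
    print(f"t-SNE  log10+1  + k-means(3): mean ARI "
          f"{study['mean_tsne_log10p1_kmeans3']:.3f}")
    print(f"UMAP   log10+1  + k-means(3): mean ARI "
          f"{study['mean_umap_log10p1_kmeans3']:.3f}")
    print(f"UMAP   raw FPKM + k-means(3): mean ARI "
          f"{study['mean_umap_unprocessed_kmeans3']:.3f}")
    print(f"UMAP   log10+1  + Leiden(15, res 1): mean ARI "
          f"{study['mean_umap_log10p1_leiden']:.3f}  "
          f"(resolution 1 oversplits ~100-sample clusters)")
    print(f"raw < log10+1 recovery in "
          f"{study['n_seeds_unprocessed_below_log10p1']}/{args.n_seeds} seeds")
    print(f"median ARI(site, clusters) over "
          f"{study['n_site_ari']} grid cells: "
          f"{study['median_site_ari']:+.4f}  (site labels are null)")


if __name__ == "__main__":
    main()
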
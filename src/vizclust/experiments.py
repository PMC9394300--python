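"""Reusable study drivers: the quantitative experiments behind the
package's headline claims, at cohort scale.

Each function recomputes its result from scratch from a base seed, so the
same code path serves the analysis scripts, the test suite and the
reproduction script. Problem sizes follow the synthetic study conditions:
2000 genes x 300 samples, 3 planted subgroups, log2 effect 2, 30% zeros,
5 replicate seeds.
"""

from __future__ import annotations

from dataclasses import replace
from pathlib import Path

import numpy as np

from . import umap_adapted as ua
from .pipeline import GridConfig, compute_grid, run_grid, stage_seed
from .similarity import neighbor_overlap
from .synthetic import SyntheticSpec, generate_fpkm
from .types import ValidationError

__all__ = [
    "gradient_fd_check",
    "calibration_check",
    "kernel_fit_check",
    "run_recovery_study",
    "random_overlap_study",
    "determinism_check",
]


def gradient_fd_check(
    seed: int, n_instances: int = 20, n_max: int = 20, h: float = 1e-6
) -> float:
    """Max relative error between the analytic cross-entropy gradient and
    central finite differences over random small instances."""
    rng = np.random.default_rng(stage_seed(seed, "gradient_fd"))
    kernel = ua.fit_ab(0.25)
    worst = 0.0
    for _ in range(n_instances):
        n = int(rng.integers(4, n_max + 1))
        Y = rng.normal(size=(n, 2))
        P = rng.random((n, n))
        P = (P + P.T) / 2.0
        np.fill_diagonal(P, 0.0)
        grad = ua.cross_entropy_grad(P, Y, kernel)
        fd = np.zeros_like(Y)
        for i in range(n):
            for d in range(2):
                Yp = Y.copy()
                Yp[i, d] += h
                Ym = Y.copy()
                Ym[i, d] -= h
                fd[i, d] = (
                    ua.cross_entropy_cost(P, ua.normalized_q(Yp, kernel))
                    - ua.cross_entropy_cost(P, ua.normalized_q(Ym, kernel))
                ) / (2.0 * h)
        rel = np.abs(grad - fd).max() / max(np.abs(fd).max(), 1e-12)
        worst = max(worst, float(rel))
    return worst


def calibration_check(seed: int, k_local: int = 15) -> dict:
    """Sigma binary search vs the closed form, plus the calibration
    residual on random data.

    With all ``k_local`` calibration neighbors at offset c above rho, the
    smooth-kNN equation k * exp(-c / sigma) = log2(k) has the closed-form
    solution sigma = c / ln(k / log2(k)).
    """
    c = 1.0
    target = np.log2(k_local)
    sigma = ua.solve_sigma(np.full(k_local, c), target, tol=1e-9, max_iter=200)
    closed = c / np.log(k_local / np.log2(k_local))

    rng = np.random.default_rng(stage_seed(seed, "calibration"))
    X = rng.normal(size=(60, 8))
    D = ua.pairwise_sq_euclidean(X)
    rho, sig = ua.calibrate_local_scales(D, k_local, tol=1e-7, max_iter=128)
    nn = ua._knn_indices(D, k_local)
    residuals = []
    for i in range(D.shape[0]):
        d = D[i, nn[i]]
        mass = np.exp(-np.maximum(0.0, d - rho[i]) / sig[i]).sum()
        residuals.append(abs(mass - target))
    return {
        "sigma": float(sigma),
        "closed_form": float(closed),
        "abs_err": float(abs(sigma - closed)),
        "max_residual": float(max(residuals)),
    }


def kernel_fit_check(min_dist: float = 0.25) -> float:
    """RMS residual of the fitted low-dimensional kernel at min_dist."""
    return ua.fit_ab(min_dist).rms_residual


def _find_row(rows, method, transform, cmethod, **params):
    for row in rows:
        if row["method"] != method or row["transform"] != transform:
            continue
        c = row["clustering"]
        if c["method"] != cmethod:
            continue
        if all(c["params"].get(k) == v for k, v in params.items()):
            return row
    raise ValidationError(
        f"no association row for {method}/{transform}/{cmethod} {params}"
    )


def run_recovery_study(
    base_seed: int,
    n_seeds: int = 5,
    spec: SyntheticSpec | None = None,
) -> dict:
    """Planted-subgroup recovery across the full method x transform grid.

    For each replicate seed the study generates a planted cohort, runs the
    whole grid (both methods, all three transforms, the full clustering
    grid) and records per-seed:

    * ARI vs planted truth for adapted UMAP on log10+1 under Leiden
      (n_neighbors 15, resolution 1) and under k-means (k=3);
    * the same for the t-SNE stage (k-means k=3) and for unprocessed FPKM;
    * every ARI(site, clusters) across the grid (the null labels);
    * the local/global similarity summary of the adapted-UMAP
      unprocessed-vs-log10+1 map pair.
    """
    spec = spec or SyntheticSpec()
    per_seed = []
    site_aris: list[float] = []
    for rep in range(n_seeds):
        rep_seed = stage_seed(base_seed, f"recovery:{rep}")
        em, ann = generate_fpkm(replace(spec, seed=rep_seed))
        cfg = GridConfig(seed=rep_seed, make_figures=False)
        bundle = compute_grid(em, ann, cfg)
        rows = bundle["summary"]["associations"]

        rec = {"seed": rep_seed}
        rec["umap_log10p1_leiden15_r1"] = _find_row(
            rows, "umap_adapted", "log10p1", "leiden",
            n_neighbors=15, resolution=1.0,
        )["subgroup_truth"]["ari"]
        rec["umap_unprocessed_leiden15_r1"] = _find_row(
            rows, "umap_adapted", "unprocessed", "leiden",
            n_neighbors=15, resolution=1.0,
        )["subgroup_truth"]["ari"]
        rec["umap_log10p1_kmeans3"] = _find_row(
            rows, "umap_adapted", "log10p1", "kmeans", k=3
        )["subgroup_truth"]["ari"]
        rec["umap_unprocessed_kmeans3"] = _find_row(
            rows, "umap_adapted", "unprocessed", "kmeans", k=3
        )["subgroup_truth"]["ari"]
        rec["tsne_log10p1_kmeans3"] = _find_row(
            rows, "tsne", "log10p1", "kmeans", k=3
        )["subgroup_truth"]["ari"]
        rec["tsne_unprocessed_kmeans3"] = _find_row(
            rows, "tsne", "unprocessed", "kmeans", k=3
        )["subgroup_truth"]["ari"]

        sim = bundle["summary"]["similarity"][
            "umap_adapted__unprocessed__vs__log10p1"
        ]
        rec["local_mean"], rec["global_mean"] = sim["local_global"]

        site_aris.extend(row["site"]["ari"] for row in rows)
        per_seed.append(rec)

    def col(name):
        return [r[name] for r in per_seed]

    return {
        "per_seed": per_seed,
        "mean_umap_log10p1_leiden": float(np.mean(col("umap_log10p1_leiden15_r1"))),
        "mean_umap_log10p1_kmeans3": float(np.mean(col("umap_log10p1_kmeans3"))),
        "mean_tsne_log10p1_kmeans3": float(np.mean(col("tsne_log10p1_kmeans3"))),
        "mean_umap_unprocessed_kmeans3": float(
            np.mean(col("umap_unprocessed_kmeans3"))
        ),
        "n_seeds_unprocessed_below_log10p1": int(
            sum(
                u < l
                for u, l in zip(
                    col("umap_unprocessed_leiden15_r1"),
                    col("umap_log10p1_leiden15_r1"),
                )
            )
        ),
        "n_seeds_local_below_global": int(
            sum(l < g for l, g in zip(col("local_mean"), col("global_mean")))
        ),
        "median_site_ari": float(np.median(site_aris)),
        "n_site_ari": len(site_aris),
    }


def random_overlap_study(
    seed: int, n: int = 101, k: int = 10, n_rep: int = 100
) -> dict:
    """Mean kNN overlap between pairs of independent uniform random maps.

    The hypergeometric expectation for the normalized overlap at scale k is
    k / (n - 1).
    """
    rng = np.random.default_rng(stage_seed(seed, "random_overlap"))
    vals = []
    for _ in range(n_rep):
        A = rng.random((n, 2))
        B = rng.random((n, 2))
        S = neighbor_overlap(A, B, scales=(k,))
        vals.append(float(S.values[0, 0]))
    return {
        "mean": float(np.mean(vals)),
        "expected": k / (n - 1),
        "n_rep": n_rep,
    }


def determinism_check(seed: int, out_dir: str | Path) -> bool:
    """Run a small grid twice with one seed; compare summary.json bytes."""
    out_dir = Path(out_dir)
    spec = SyntheticSpec(
        n_genes=300, n_samples=60, n_marker_genes_per_subgroup=60,
        seed=stage_seed(seed, "determinism"),
    )
    em, ann = generate_fpkm(spec)
    cfg = GridConfig(seed=stage_seed(seed, "determinism_cfg"), make_figures=False)
    blobs = []
    for run in ("a", "b"):
        try:
            run_grid(em, ann, cfg, out_dir / run)
        except Exception:
            return False
        blobs.append((out_dir / run / "summary.json").read_bytes())
    return blobs[0] == blobs[1]
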
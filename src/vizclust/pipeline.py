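"""Grid runner: methods x transformations, clustering, association
metrics, map similarity, figures and a machine-readable summary.

All randomness flows from one config seed through :func:`stage_seed`, which
derives a per-stage 31-bit seed from the stage name, so the whole grid is
reproducible as a unit and individual stages remain decoupled.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, field, replace
from itertools import combinations
from pathlib import Path

import numpy as np
from scipy.stats import chi2_contingency
from sklearn.metrics import adjusted_rand_score

from . import io as vcio
from .clustering import elbow_select_k, kmeans_cluster, leiden_on_embedding
from .similarity import DEFAULT_SCALES, local_global_summary, neighbor_overlap
from .transforms import TRANSFORMS, apply_transform
from .tsne import TsneParams, pca_reduce, tsne_embed
from .types import ClusterResult, Embedding, ExpressionMatrix, SampleAnnotation, \
    ValidationError
from .umap_adapted import UmapParams, umap_adapted_embed
from .viz import legend_from_embedding, render_embedding_plot

__all__ = [
    "GridConfig",
    "PipelineError",
    "stage_seed",
    "association_metrics",
    "compute_grid",
    "run_grid",
]

logger = logging.getLogger(__name__)

DEFAULT_KMEANS_KS = (2, 3, 4)
DEFAULT_LEIDEN_GRID = ((15, 0.05), (50, 0.05), (100, 0.05), (15, 1.0))


class PipelineError(RuntimeError):
    """One or more grid cells failed; the partial bundle is retained."""


def stage_seed(base_seed: int, stage: str) -> int:
    """Deterministic 31-bit seed for a named stage."""
    return (int(base_seed) * 1000003 + zlib.crc32(stage.encode())) % (2**31)


@dataclass
class GridConfig:
    transforms: tuple[str, ...] = TRANSFORMS
    methods: tuple[str, ...] = ("tsne", "umap_adapted")
    tsne: TsneParams = field(default_factory=TsneParams)
    umap: UmapParams = field(default_factory=UmapParams)
    kmeans_ks: tuple[int, ...] = DEFAULT_KMEANS_KS
    use_elbow: bool = True
    leiden_grid: tuple[tuple[int, float], ...] = DEFAULT_LEIDEN_GRID
    scales: tuple[int, ...] = DEFAULT_SCALES
    seed: int = 0
    make_figures: bool = True
    unit: str = "FPKM"

    def validate(self) -> None:
        if not self.transforms or not self.methods:
            raise ValidationError("method and transform sets must be non-empty")
        unknown = set(self.transforms) - set(TRANSFORMS)
        if unknown:
            raise ValidationError(f"unknown transforms {sorted(unknown)}")
        unknown = set(self.methods) - {"tsne", "umap_adapted"}
        if unknown:
            raise ValidationError(f"unknown methods {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "GridConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = {}
        if "tsne" in raw:
            kwargs["tsne"] = TsneParams(**raw.pop("tsne"))
        if "umap" in raw:
            kwargs["umap"] = UmapParams(**raw.pop("umap"))
        for key in ("transforms", "methods", "kmeans_ks", "scales"):
            if key in raw:
                kwargs[key] = tuple(raw.pop(key))
        if "leiden_grid" in raw:
            kwargs["leiden_grid"] = tuple(
                (int(n), float(r)) for n, r in raw.pop("leiden_grid")
            )
        kwargs.update(raw)
        return cls(**kwargs)


def association_metrics(labels_a, labels_b) -> dict:
    """ARI, chi-square and Cramér's V between two labelings.

    V is undefined (None) when either labeling has a single level.
    """
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape:
        raise ValidationError("labelings must cover the same samples")
    ari = float(adjusted_rand_score(a, b))
    levels_a, ia = np.unique(a, return_inverse=True)
    levels_b, ib = np.unique(b, return_inverse=True)
    out = {"ari": ari, "n_levels_a": len(levels_a), "n_levels_b": len(levels_b)}
    if len(levels_a) < 2 or len(levels_b) < 2:
        out |= {"chi2": None, "cramers_v": None}
        return out
    table = np.zeros((len(levels_a), len(levels_b)), dtype=int)
    np.add.at(table, (ia, ib), 1)
    chi2 = float(chi2_contingency(table, correction=False)[0])
    n = table.sum()
    v = float(np.sqrt(chi2 / (n * (min(table.shape) - 1))))
    out |= {"chi2": chi2, "cramers_v": min(v, 1.0)}
    return out


def _embed_cell(
    X_t: np.ndarray,
    method: str,
    transform: str,
    cfg: GridConfig,
    sample_ids: list[str],
) -> Embedding:
    seed = stage_seed(cfg.seed, f"embed:{method}:{transform}")
    if method == "tsne":
        params = replace(cfg.tsne, seed=seed)
        scores = pca_reduce(X_t, params.n_pcs)
        return tsne_embed(scores, params, sample_ids, transform, cfg.unit)
    params = replace(cfg.umap, seed=seed)
    return umap_adapted_embed(X_t, params, sample_ids, transform, cfg.unit)


def _cluster_cell(emb: Embedding, cfg: GridConfig) -> list[ClusterResult]:
    results = []
    tag = f"{emb.provenance['method']}:{emb.provenance['transform']}"
    ks = list(cfg.kmeans_ks)
    if cfg.use_elbow:
        k_elbow = elbow_select_k(emb, seed=stage_seed(cfg.seed, f"elbow:{tag}"))
        if k_elbow not in ks:
            ks.append(k_elbow)
    for k in ks:
        results.append(
            kmeans_cluster(emb, k, seed=stage_seed(cfg.seed, f"kmeans:{tag}:{k}"))
        )
    for n_neighbors, resolution in cfg.leiden_grid:
        if n_neighbors >= emb.n_samples:
            continue
        results.append(
            leiden_on_embedding(
                emb,
                n_neighbors=n_neighbors,
                resolution=resolution,
                seed=stage_seed(cfg.seed, f"leiden:{tag}:{n_neighbors}:{resolution}"),
            )
        )
    return results


def compute_grid(
    X: ExpressionMatrix, ann: list[SampleAnnotation], cfg: GridConfig
) -> dict:
    """Run the full comparison grid in memory.

    Returns a bundle with, per (method, transform) cell: the embedding,
    its cluster results and association rows (ARI vs site, vs sample_type
    and, when present, vs subgroup_truth; Cramér's V for cluster x site);
    plus the pairwise transform similarity matrices within each method.
    """
    cfg.validate()
    vcio.check_annotation_coverage(X, ann)
    by_id = {a.sample_id: a for a in ann}
    ordered = [by_id[s] for s in X.sample_ids]
    site = [a.site for a in ordered]
    sample_type = [a.sample_type for a in ordered]
    truth = [a.subgroup_truth for a in ordered]
    has_truth = all(t is not None for t in truth)

    transformed = {t: apply_transform(X, t) for t in cfg.transforms}
    embeddings: dict[tuple[str, str], Embedding] = {}
    clusters: dict[tuple[str, str], list[ClusterResult]] = {}
    association_rows: list[dict] = []
    failures: list[str] = []

    for method in cfg.methods:
        for transform in cfg.transforms:
            cell = (method, transform)
            try:
                emb = _embed_cell(
                    transformed[transform], method, transform, cfg, X.sample_ids
                )
                embeddings[cell] = emb
                cell_clusters = _cluster_cell(emb, cfg)
                clusters[cell] = cell_clusters
                for cres in cell_clusters:
                    row = {
                        "method": method,
                        "transform": transform,
                        "clustering": cres.to_dict(),
                        "site": association_metrics(cres.labels, site),
                        "sample_type": association_metrics(
                            cres.labels, sample_type
                        ),
                    }
                    if has_truth:
                        row["subgroup_truth"] = association_metrics(
                            cres.labels, truth
                        )
                    association_rows.append(row)
            except Exception as exc:  # keep the partial bundle
                logger.exception("grid cell %s failed", cell)
                failures.append(f"{method}__{transform}: {exc}")

    similarities: dict[tuple[str, str, str], object] = {}
    for method in cfg.methods:
        for ta, tb in combinations(cfg.transforms, 2):
            if (method, ta) in embeddings and (method, tb) in embeddings:
                S = neighbor_overlap(
                    embeddings[(method, ta)], embeddings[(method, tb)], cfg.scales
                )
                similarities[(method, ta, tb)] = S

    summary = {
        "config": {
            "transforms": list(cfg.transforms),
            "methods": list(cfg.methods),
            "seed": cfg.seed,
            "kmeans_ks": list(cfg.kmeans_ks),
            "leiden_grid": [list(g) for g in cfg.leiden_grid],
            "scales": list(cfg.scales),
            "unit": cfg.unit,
        },
        "n_samples": X.n_samples,
        "n_genes": X.n_genes,
        "embeddings": {
            f"{m}__{t}": vcio.to_jsonable(e.provenance)
            for (m, t), e in sorted(embeddings.items())
        },
        "associations": vcio.to_jsonable(association_rows),
        "similarity": {
            f"{m}__{ta}__vs__{tb}": {
                "scales": S.scales,
                "diagonal": vcio.to_jsonable(S.diagonal()),
                "local_global": list(
                    local_global_summary(
                        S,
                        local_max_k=10,
                        global_min_k=min(50, max(S.scales)),
                    )
                ),
            }
            for (m, ta, tb), S in sorted(similarities.items())
        },
        "failures": failures,
    }
    return {
        "embeddings": embeddings,
        "clusters": clusters,
        "similarities": similarities,
        "summary": summary,
    }


def run_grid(
    X: ExpressionMatrix,
    ann: list[SampleAnnotation],
    cfg: GridConfig,
    out_dir: str | Path,
) -> dict:
    """Compute the grid and write the output bundle.

    Layout: one directory per cell named ``<method>__<transform>`` with the
    embedding TSV + provenance JSON and cluster TSVs; top-level
    ``similarity/``, ``figures/`` and ``summary.json``. Raises
    PipelineError after writing if any cell failed.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle = compute_grid(X, ann, cfg)

    by_id = {a.sample_id: a for a in ann}
    ordered = [by_id[s] for s in X.sample_ids]

    for (method, transform), emb in bundle["embeddings"].items():
        cell_dir = out / f"{method}__{transform}"
        cell_dir.mkdir(exist_ok=True)
        vcio.write_embedding(emb, cell_dir / "embedding.tsv")
        for i, cres in enumerate(bundle["clusters"][(method, transform)]):
            name = f"clusters_{i:02d}_{cres.method}.tsv"
            vcio.write_clusters(cres, cell_dir / name)
        if cfg.make_figures:
            fig_dir = out / "figures"
            legend = legend_from_embedding(emb)
            for color_name, labels in (
                ("site", [a.site for a in ordered]),
                ("sample_type", [a.sample_type for a in ordered]),
            ):
                render_embedding_plot(
                    emb,
                    labels,
                    legend,
                    fig_dir / f"{method}__{transform}__{color_name}.png",
                    title=f"{method} / {transform} (by {color_name})",
                )

    sim_dir = out / "similarity"
    sim_dir.mkdir(exist_ok=True)
    for (method, ta, tb), S in bundle["similarities"].items():
        vcio.write_similarity(S, sim_dir / f"{method}__{ta}__vs__{tb}.tsv")

    summary_path = out / "summary.json"
    summary_path.write_text(
        json.dumps(bundle["summary"], indent=2, sort_keys=True) + "\n"
    )
    if bundle["summary"]["failures"]:
        raise PipelineError(
            "grid cells failed: " + "; ".join(bundle["summary"]["failures"])
        )
    return bundle
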
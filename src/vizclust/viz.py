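"""Embedding scatter plots carrying a UTMC provenance legend.

Every figure states its Unit (FPKM, TPM, ...), Transformation, dimension
reduction Method and Clustering algorithm ("NA" when none was applied), so
a figure separated from its pipeline outputs remains self-describing.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

# keep text as text in SVG output so the UTMC line stays machine-readable
plt.rcParams["svg.fonttype"] = "none"
import numpy as np

from .transforms import TRANSFORM_DISPLAY
from .types import ClusterResult, Embedding, ValidationError

__all__ = ["UTMCLegend", "format_utmc", "legend_from_embedding",
           "render_embedding_plot"]


@dataclass
class UTMCLegend:
    unit: str
    transformation: str
    method: str
    clustering: str = "NA"

    def validate(self) -> None:
        for name in ("unit", "transformation", "method", "clustering"):
            if not getattr(self, name):
                raise ValidationError(f"UTMC field {name!r} must be non-empty")


def format_utmc(legend: UTMCLegend) -> str:
    """Canonical one-line legend: ``U: .. | T: .. | M: .. | C: ..``."""
    legend.validate()
    return (
        f"U: {legend.unit} | T: {legend.transformation} | "
        f"M: {legend.method} | C: {legend.clustering}"
    )


def legend_from_embedding(
    emb: Embedding, clusters: ClusterResult | None = None
) -> UTMCLegend:
    """Build the UTMC legend from an embedding's provenance record."""
    transform = emb.provenance["transform"]
    clustering = "NA"
    if clusters is not None:
        detail = ", ".join(
            f"{k}={v}" for k, v in clusters.params.items() if k != "inertia"
        )
        clustering = f"{clusters.method}({detail})" if detail else clusters.method
    return UTMCLegend(
        unit=emb.provenance["unit"],
        transformation=TRANSFORM_DISPLAY.get(transform, transform),
        method=emb.provenance["method"],
        clustering=clustering,
    )


def render_embedding_plot(
    emb: Embedding,
    color_by,
    legend: UTMCLegend,
    out_path: str | Path,
    title: str | None = None,
    point_size: float = 18.0,
    palette: str = "tab10",
) -> Path:
    """Scatter the embedding colored by a categorical labeling.

    ``color_by`` is either a ClusterResult or a sequence of per-sample
    labels aligned with the embedding's samples.
    """
    if isinstance(color_by, ClusterResult):
        if color_by.sample_ids != emb.sample_ids:
            raise ValidationError("cluster result samples do not match embedding")
        labels = [str(l) for l in color_by.labels]
    else:
        labels = [str(l) for l in color_by]
        if len(labels) != emb.n_samples:
            raise ValidationError(
                f"{len(labels)} labels for {emb.n_samples} samples"
            )
    utmc = format_utmc(legend)

    uniq = sorted(set(labels))
    cmap = plt.get_cmap(palette, max(len(uniq), 1))
    fig, ax = plt.subplots(figsize=(6, 5.4))
    for idx, lab in enumerate(uniq):
        mask = np.array([l == lab for l in labels])
        ax.scatter(
            emb.coords[mask, 0],
            emb.coords[mask, 1],
            s=point_size,
            color=cmap(idx),
            label=lab,
            linewidths=0,
        )
    ax.set_xlabel("dim 1")
    ax.set_ylabel("dim 2")
    if title:
        ax.set_title(title)
    ax.legend(loc="best", fontsize=7, markerscale=1.2, frameon=False)
    fig.text(0.5, 0.005, utmc, ha="center", fontsize=8, family="monospace")
    fig.tight_layout(rect=(0, 0.03, 1, 1))
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(out_path, dpi=120, metadata=_metadata_for(out_path, utmc))
    plt.close(fig)
    return out_path


def _metadata_for(path: Path, utmc: str) -> dict | None:
    # keep the UTMC string in the file metadata too, format permitting
    suffix = path.suffix.lower()
    if suffix == ".png":
        return {"Description": utmc}
    if suffix == ".svg":
        return None
    return None
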
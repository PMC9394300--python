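"""Core value types shared across the pipeline.

Conventions: expression matrices are genes x samples (the TSV orientation,
first column gene id, header row of sample ids); embeddings are
n_samples x 2. Every embedding carries full provenance (expression unit,
transform, method, parameters, seed) so downstream figures can render a
complete UTMC legend.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Any

import numpy as np

__all__ = [
    "ExpressionMatrix",
    "SampleAnnotation",
    "Embedding",
    "ClusterResult",
    "ValidationError",
]


class ValidationError(ValueError):
    """Raised when an input violates a documented invariant."""


@dataclass
class ExpressionMatrix:
    """Genes x samples table of nonnegative expression values (FPKM-like).

    Attributes
    ----------
    values : ndarray, shape (n_genes, n_samples)
        Nonnegative expression values; exact zeros are meaningful (they
        drive the log10 zero rule).
    gene_ids, sample_ids : list of str
        Unique identifiers for rows and columns.
    unit : str
        Expression unit for the UTMC legend (default "FPKM").
    """

    values: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]
    unit: str = "FPKM"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = list(self.gene_ids)
        self.sample_ids = list(self.sample_ids)
        self.validate()

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def validate(self) -> None:
        if self.values.ndim != 2:
            raise ValidationError("values must be a 2-D genes x samples array")
        if len(self.gene_ids) != self.values.shape[0]:
            raise ValidationError(
                f"gene_ids has {len(self.gene_ids)} entries for "
                f"{self.values.shape[0]} rows"
            )
        if len(self.sample_ids) != self.values.shape[1]:
            raise ValidationError(
                f"sample_ids has {len(self.sample_ids)} entries for "
                f"{self.values.shape[1]} columns"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValidationError("gene_ids are not unique")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValidationError("sample_ids are not unique")
        if not np.isfinite(self.values).all():
            raise ValidationError("expression values contain non-finite entries")
        if (self.values < 0).any():
            g, s = np.argwhere(self.values < 0)[0]
            raise ValidationError(
                f"negative expression value at gene {self.gene_ids[g]!r}, "
                f"sample {self.sample_ids[s]!r}"
            )


@dataclass
class SampleAnnotation:
    """Per-sample metadata: resection site, sample type, optional truth.

    ``site`` is assigned independently of expression in the synthetic null
    cohorts; ``subgroup_truth`` is the planted transcriptomic subgroup when
    one exists. ``mixing_weight`` is only set for gradient cohorts (the
    primary<->metastatic interpolation weight).
    """

    sample_id: str
    site: str
    sample_type: str
    subgroup_truth: str | None = None
    mixing_weight: float | None = None

    def __post_init__(self) -> None:
        if self.sample_type not in ("primary", "metastatic"):
            raise ValidationError(
                f"sample_type must be 'primary' or 'metastatic', "
                f"got {self.sample_type!r}"
            )


@dataclass
class Embedding:
    """A 2-D map of samples with full provenance.

    ``provenance`` holds at least: unit, transform, method, params, seed.
    ``history`` optionally records the optimizer's cost trace.
    """

    coords: np.ndarray
    sample_ids: list[str]
    provenance: dict[str, Any] = field(default_factory=dict)
    history: list[float] | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.sample_ids = list(self.sample_ids)
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise ValidationError("coords must be n_samples x 2")
        if self.coords.shape[0] != len(self.sample_ids):
            raise ValidationError("one coordinate row per sample required")
        if not np.isfinite(self.coords).all():
            raise ValidationError("embedding coordinates must be finite")
        for key in ("unit", "transform", "method", "params", "seed"):
            if key not in self.provenance:
                raise ValidationError(f"provenance missing required key {key!r}")

    @property
    def n_samples(self) -> int:
        return self.coords.shape[0]


@dataclass
class ClusterResult:
    """Per-sample cluster labels with method/parameter provenance."""

    labels: np.ndarray
    sample_ids: list[str]
    method: str
    params: dict[str, Any]
    seed: int

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        self.sample_ids = list(self.sample_ids)
        if self.labels.shape != (len(self.sample_ids),):
            raise ValidationError("one label per sample required")
        uniq = np.unique(self.labels)
        if not np.array_equal(uniq, np.arange(len(uniq))):
            raise ValidationError("labels must be contiguous integers from 0")
        if self.method not in ("kmeans", "leiden"):
            raise ValidationError(f"unknown clustering method {self.method!r}")

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max()) + 1 if self.labels.size else 0

    def to_dict(self) -> dict[str, Any]:
        return {
            "method": self.method,
            "params": dict(self.params),
            "seed": self.seed,
            "n_clusters": self.n_clusters,
        }


def params_dict(obj: Any) -> dict[str, Any]:
    """Dataclass -> plain dict for provenance records."""
    return asdict(obj)
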
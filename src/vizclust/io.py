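"""TSV / JSON serialization for expression matrices, annotations,
embeddings, clusters and similarity matrices.

Matrix dialect: tab-separated, first column ``gene_id``, header row of
sample ids. Annotation dialect: columns sample_id, site, sample_type,
subgroup_truth (``NA`` when absent). All numeric output uses ``repr``
precision so that a write -> read round trip is the identity.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from .similarity import SimilarityMatrix
from .types import ClusterResult, Embedding, ExpressionMatrix, SampleAnnotation, \
    ValidationError

__all__ = [
    "write_expression_tsv",
    "read_expression_tsv",
    "write_annotations",
    "read_annotations",
    "write_embedding",
    "read_embedding",
    "write_clusters",
    "write_similarity",
    "to_jsonable",
]

_NA = "NA"


def write_expression_tsv(em: ExpressionMatrix, path: str | Path) -> None:
    df = pd.DataFrame(em.values, index=em.gene_ids, columns=em.sample_ids)
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t", float_format="%.10g")


def read_expression_tsv(path: str | Path, unit: str = "FPKM") -> ExpressionMatrix:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    values = df.to_numpy(dtype=float)
    if np.isnan(values).any():
        g, s = np.argwhere(np.isnan(values))[0]
        raise ValidationError(
            f"{path}: missing value at line {g + 2} "
            f"(gene {df.index[g]!r}, sample {df.columns[s]!r})"
        )
    if (values < 0).any():
        g, s = np.argwhere(values < 0)[0]
        raise ValidationError(
            f"{path}: negative value at line {g + 2} "
            f"(gene {df.index[g]!r}, sample {df.columns[s]!r})"
        )
    return ExpressionMatrix(
        values=values,
        gene_ids=[str(g) for g in df.index],
        sample_ids=[str(s) for s in df.columns],
        unit=unit,
    )


def write_annotations(ann: list[SampleAnnotation], path: str | Path) -> None:
    rows = [
        {
            "sample_id": a.sample_id,
            "site": a.site,
            "sample_type": a.sample_type,
            "subgroup_truth": a.subgroup_truth if a.subgroup_truth else _NA,
        }
        for a in ann
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_annotations(path: str | Path) -> list[SampleAnnotation]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"sample_id", "site", "sample_type", "subgroup_truth"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing columns {sorted(missing)}")
    if df["sample_id"].duplicated().any():
        dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValidationError(f"{path}: duplicated sample ids {dups[:10]}")
    return [
        SampleAnnotation(
            sample_id=r.sample_id,
            site=r.site,
            sample_type=r.sample_type,
            subgroup_truth=None if r.subgroup_truth == _NA else r.subgroup_truth,
        )
        for r in df.itertuples()
    ]


def check_annotation_coverage(
    em: ExpressionMatrix, ann: list[SampleAnnotation]
) -> None:
    """Every matrix column must have exactly one annotation row."""
    ann_ids = {a.sample_id for a in ann}
    missing = [s for s in em.sample_ids if s not in ann_ids]
    if missing:
        raise ValidationError(
            f"annotations missing for samples {missing[:10]}"
            + ("..." if len(missing) > 10 else "")
        )


def write_embedding(emb: Embedding, path: str | Path) -> None:
    """Embedding TSV (sample_id, x, y) plus a .json provenance sidecar."""
    path = Path(path)
    df = pd.DataFrame(
        {"sample_id": emb.sample_ids, "x": emb.coords[:, 0], "y": emb.coords[:, 1]}
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(
        json.dumps(to_jsonable(emb.provenance), indent=2, sort_keys=True) + "\n"
    )


def read_embedding(path: str | Path) -> Embedding:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    sidecar = path.with_suffix(path.suffix + ".json")
    prov = json.loads(sidecar.read_text()) if sidecar.exists() else {
        "unit": "unknown", "transform": "unknown", "method": "unknown",
        "params": {}, "seed": -1,
    }
    return Embedding(
        coords=df[["x", "y"]].to_numpy(float),
        sample_ids=[str(s) for s in df["sample_id"]],
        provenance=prov,
    )


def write_clusters(res: ClusterResult, path: str | Path) -> None:
    params_hash = json.dumps(to_jsonable(res.params), sort_keys=True)
    df = pd.DataFrame(
        {
            "sample_id": res.sample_ids,
            "label": res.labels,
            "method": res.method,
            "params": params_hash,
        }
    )
    df.to_csv(path, sep="\t", index=False)


def write_similarity(S: SimilarityMatrix, path: str | Path) -> None:
    """Long-format similarity TSV: kA, kB, score."""
    df = pd.DataFrame(list(S.to_long_rows()), columns=["kA", "kB", "score"])
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def to_jsonable(obj: Any) -> Any:
    """Recursively convert numpy scalars/arrays for deterministic JSON."""
    if isinstance(obj, dict):
        return {str(k): to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [to_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return to_jsonable(obj.tolist())
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj
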
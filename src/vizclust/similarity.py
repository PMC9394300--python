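"""Scale-dependent similarity between two 2-D maps of the same samples.

For a grid of neighborhood sizes k, the score at (k_a, k_b) is the mean
over samples of |NN_A(i, k_a) ∩ NN_B(i, k_b)| / min(k_a, k_b). Small k
probe local structure, large k global structure; a map compared with
itself scores 1 everywhere (same-map neighbor sets are nested), and two
unrelated maps score about min(k_a, k_b) / (n - 1) (the hypergeometric
baseline).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .types import Embedding, ValidationError

__all__ = ["SimilarityMatrix", "neighbor_overlap", "local_global_summary",
           "DEFAULT_SCALES"]

DEFAULT_SCALES = (1, 2, 5, 10, 25, 50, 100, 250)


@dataclass
class SimilarityMatrix:
    scales: list[int]
    values: np.ndarray  # |scales| x |scales|, entry (a, b) as documented
    provenance: dict[str, Any] = field(default_factory=dict)

    def diagonal(self) -> np.ndarray:
        return np.diag(self.values)

    def to_long_rows(self):
        """(k_a, k_b, score) rows for the long-format TSV."""
        for ia, ka in enumerate(self.scales):
            for ib, kb in enumerate(self.scales):
                yield ka, kb, float(self.values[ia, ib])


def _neighbor_lists(coords: np.ndarray, k_max: int) -> np.ndarray:
    """Row i holds the k_max nearest neighbors of i (ties by sample index)."""
    n = coords.shape[0]
    d2 = ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1)
    order = np.argsort(d2, axis=1, kind="stable")
    out = np.empty((n, k_max), dtype=int)
    for i in range(n):
        row = order[i][order[i] != i]
        out[i] = row[:k_max]
    return out


def _resolve(emb: Embedding | np.ndarray) -> tuple[np.ndarray, list[str] | None]:
    if isinstance(emb, Embedding):
        return emb.coords, emb.sample_ids
    arr = np.asarray(emb, dtype=float)
    return arr, None


def neighbor_overlap(
    embA: Embedding | np.ndarray,
    embB: Embedding | np.ndarray,
    scales: tuple[int, ...] | None = None,
) -> SimilarityMatrix:
    """Scale x scale grid of mean kNN overlap between two maps.

    Both maps must cover the same sample set; when both are Embeddings, B
    is aligned to A's sample order by id. The default scale grid
    {1, 2, 5, 10, 25, 50, 100, 250} is truncated at n - 1.
    """
    cA, idsA = _resolve(embA)
    cB, idsB = _resolve(embB)
    if idsA is not None and idsB is not None:
        if set(idsA) != set(idsB):
            missing = sorted(set(idsA) ^ set(idsB))
            raise ValidationError(f"sample sets differ: {missing[:10]}")
        if idsA != idsB:
            pos = {s: i for i, s in enumerate(idsB)}
            cB = cB[[pos[s] for s in idsA]]
    if cA.shape[0] != cB.shape[0]:
        raise ValidationError(
            f"maps cover {cA.shape[0]} vs {cB.shape[0]} samples"
        )
    n = cA.shape[0]
    use = [k for k in (scales or DEFAULT_SCALES) if k <= n - 1]
    if not use:
        raise ValidationError("no valid scales below n_samples")
    k_max = max(use)
    nnA = _neighbor_lists(cA, k_max)
    nnB = _neighbor_lists(cB, k_max)

    values = np.empty((len(use), len(use)))
    for ia, ka in enumerate(use):
        for ib, kb in enumerate(use):
            m = min(ka, kb)
            overlap = 0.0
            for i in range(n):
                overlap += len(
                    set(nnA[i, :ka].tolist()) & set(nnB[i, :kb].tolist())
                )
            values[ia, ib] = overlap / (n * m)
    prov = {}
    if isinstance(embA, Embedding):
        prov["map_a"] = dict(embA.provenance)
    if isinstance(embB, Embedding):
        prov["map_b"] = dict(embB.provenance)
    return SimilarityMatrix(scales=use, values=values, provenance=prov)


def local_global_summary(
    S: SimilarityMatrix, local_max_k: int = 10, global_min_k: int = 50
) -> tuple[float, float]:
    """Mean diagonal overlap at small (local) and large (global) scales."""
    diag = S.diagonal()
    ks = np.asarray(S.scales)
    local = diag[ks <= local_max_k]
    glob = diag[ks >= global_min_k]
    if local.size == 0 or glob.size == 0:
        raise ValidationError(
            f"empty local/global selection for thresholds "
            f"({local_max_k}, {global_min_k}) over scales {S.scales}"
        )
    return float(local.mean()), float(glob.mean())
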
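"""t-SNE stage: PCA preprocessing to a fixed number of components, then
t-SNE at fixed perplexity and learning rate.

The defaults follow the bulk-transcriptomics setting this package studies:
50 principal components (capped at n_samples - 1, so a 49-sample cohort
effectively gets 48, with an explicit override down to 25), perplexity 27,
learning rate 300. The t-SNE optimization itself is delegated to
scikit-learn's well-tested implementation (exact gradient at desk scale,
Barnes-Hut above); all governing parameters are exposed here and recorded
in the embedding provenance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE

from .types import Embedding, ValidationError, params_dict

__all__ = ["TsneParams", "pca_reduce", "tsne_embed", "tsne_kl_divergence"]

# sklearn switches to Barnes-Hut above this sample count; below it the
# exact O(n^2) gradient is affordable and removes approximation error.
_EXACT_MAX_N = 2000


@dataclass
class TsneParams:
    n_pcs: int = 50
    perplexity: float = 27.0
    learning_rate: float = 300.0
    seed: int = 0
    n_iter: int = 1000
    init: str = "pca"

    def validate(self) -> None:
        if self.n_pcs < 2:
            raise ValidationError("n_pcs must be >= 2")
        if self.perplexity <= 0:
            raise ValidationError("perplexity must be positive")
        if self.learning_rate <= 0:
            raise ValidationError("learning_rate must be positive")
        if self.n_iter < 250:
            raise ValidationError("n_iter must be >= 250")


def pca_reduce(X_t: np.ndarray, n_pcs: int = 50) -> np.ndarray:
    """Project samples onto the top principal components.

    ``X_t`` is a transformed genes x samples matrix; PCA operates on the
    samples x genes view with gene means removed. The effective component
    count is min(n_pcs, n_samples - 1, n_genes), so small cohorts are
    capped automatically (a 49-sample cohort yields 48; pass an explicit
    smaller ``n_pcs`` such as 25 to override).
    """
    X_t = np.asarray(X_t, dtype=float)
    if not np.isfinite(X_t).all():
        raise ValidationError("input to PCA contains non-finite values")
    n_genes, n_samples = X_t.shape
    if n_samples < 3:
        raise ValidationError("PCA preprocessing requires at least 3 samples")
    effective = min(int(n_pcs), n_samples - 1, n_genes)
    pca = PCA(n_components=effective, svd_solver="full")
    return pca.fit_transform(X_t.T)


def tsne_embed(
    scores: np.ndarray,
    params: TsneParams,
    sample_ids: list[str],
    transform: str = "unprocessed",
    unit: str = "FPKM",
) -> Embedding:
    """Run t-SNE on PCA scores and return a provenance-carrying embedding."""
    params.validate()
    scores = np.asarray(scores, dtype=float)
    n = scores.shape[0]
    if params.perplexity >= n:
        raise ValidationError(
            f"perplexity ({params.perplexity}) must be < n_samples ({n})"
        )
    method = "exact" if n <= _EXACT_MAX_N else "barnes_hut"
    tsne = TSNE(
        n_components=2,
        perplexity=params.perplexity,
        learning_rate=params.learning_rate,
        init=params.init,
        random_state=params.seed,
        max_iter=params.n_iter,
        method=method,
    )
    coords = tsne.fit_transform(scores)
    prov = {
        "unit": unit,
        "transform": transform,
        "method": "t-SNE",
        "params": params_dict(params) | {"gradient_method": method},
        "seed": params.seed,
        "kl_divergence": float(tsne.kl_divergence_),
    }
    return Embedding(coords=coords, sample_ids=list(sample_ids), provenance=prov)


# ---------------------------------------------------------------------------
# Diagnostic: KL divergence of an arbitrary 2-D map against the perplexity-
# calibrated joint affinities of the input. Used to check that the optimizer
# actually decreases the cost relative to its initialization.


def _conditional_p(D_row: np.ndarray, perplexity: float) -> np.ndarray:
    """Binary-search the Gaussian precision so the row entropy matches
    log(perplexity); returns the conditional distribution p_{j|i}."""
    target = np.log(perplexity)
    beta_lo, beta_hi, beta = 0.0, np.inf, 1.0
    p = np.zeros_like(D_row)
    for _ in range(100):
        p = np.exp(-D_row * beta)
        s = p.sum()
        if s <= 0:
            h = 0.0
            p = np.zeros_like(D_row)
        else:
            h = np.log(s) + beta * (D_row * p).sum() / s
            p = p / s
        if abs(h - target) < 1e-7:
            break
        if h > target:
            beta_lo = beta
            beta = beta * 2 if np.isinf(beta_hi) else (beta_lo + beta_hi) / 2
        else:
            beta_hi = beta
            beta = (beta_lo + beta_hi) / 2
    return p


def tsne_kl_divergence(
    scores: np.ndarray, coords: np.ndarray, perplexity: float
) -> float:
    """KL(P || Q) of a 2-D map ``coords`` for input ``scores``.

    P: symmetrized, perplexity-calibrated Gaussian joint affinities of the
    input; Q: normalized Student-t affinities of the map.
    """
    scores = np.asarray(scores, float)
    coords = np.asarray(coords, float)
    n = scores.shape[0]
    sq = ((scores[:, None, :] - scores[None, :, :]) ** 2).sum(-1)
    P_cond = np.zeros((n, n))
    for i in range(n):
        row = np.delete(sq[i], i)
        p = _conditional_p(row, perplexity)
        P_cond[i, np.arange(n) != i] = p
    P = (P_cond + P_cond.T) / (2.0 * n)
    P = np.maximum(P, 1e-12)

    d2 = ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1)
    W = 1.0 / (1.0 + d2)
    np.fill_diagonal(W, 0.0)
    Q = np.maximum(W / W.sum(), 1e-12)

    mask = ~np.eye(n, dtype=bool)
    return float((P[mask] * np.log(P[mask] / Q[mask])).sum())
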
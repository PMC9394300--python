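"""From-scratch adapted UMAP for bulk transcriptomic sample maps.

The variant implemented here differs from the reference UMAP library in
deliberate, documented ways:

* distances are **squared** pairwise Euclidean distances between samples
  (no approximate NN index; the full matrix is affordable at cohort scale);
* per-sample local scales: rho_i is the (squared) distance to the nearest
  neighbor, and the bandwidth sigma_i is found by binary search so that the
  smooth-kNN mass over the k_local nearest neighbors equals log2(k_local);
* symmetrization is the plain half-sum P = (P_directed + P_directed^T) / 2
  (not the fuzzy union p + p' - p*p');
* the low-dimensional kernel w(d) = 1 / (1 + a d^(2b)) is least-squares
  fitted to the min_dist target curve;
* the cost is a proper cross-entropy -sum(P_hat * log Q) between the
  normalized affinities P_hat and the **normalized** low-dimensional
  kernel matrix Q, minimized by full-batch gradient descent (no negative
  sampling) from a small seeded Gaussian initialization. The descent uses
  Adam-style per-coordinate step scaling: the normalized objective's
  gradient magnitude changes by orders of magnitude as the map expands
  from the collapsed initialization, which no constant step size can
  traverse (tiny steps never expand the map; large ones diverge once it
  has expanded).

Two neighbor counts coexist: ``k_local`` (default 15) calibrates the local
scales; ``k_graph`` (default 50, capped at 25 for cohorts under 50 samples)
defines the affinity edge set.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import curve_fit

from .types import Embedding, ValidationError, params_dict

__all__ = [
    "UmapParams",
    "LowDimKernel",
    "AffinityGraph",
    "pairwise_sq_euclidean",
    "solve_sigma",
    "calibrate_local_scales",
    "build_affinities",
    "symmetrize_half_sum",
    "fit_ab",
    "normalized_q",
    "cross_entropy_cost",
    "cross_entropy_grad",
    "gradient_descent_embed",
    "umap_adapted_embed",
]

SIGMA_FLOOR = 1e-8
SIGMA_MAX = 1e3
EPS = 1e-12
SMALL_COHORT_N = 50
SMALL_COHORT_K_GRAPH = 25


@dataclass
class UmapParams:
    k_local: int = 15
    k_graph: int = 50
    min_dist: float = 0.25
    n_iter: int = 300
    learning_rate: float = 0.3
    seed: int = 0
    sigma_tol: float = 1e-6
    sigma_max_iter: int = 64

    def validate(self, n_samples: int | None = None) -> None:
        if self.k_local < 1 or self.k_graph < 1:
            raise ValidationError("neighbor counts must be positive")
        if self.k_local > self.k_graph:
            raise ValidationError("k_local must be <= k_graph")
        if self.min_dist <= 0:
            raise ValidationError("min_dist must be positive")
        if self.learning_rate <= 0:
            raise ValidationError("learning_rate must be positive")
        if n_samples is not None and self.k_local >= n_samples:
            raise ValidationError(
                f"k_local ({self.k_local}) must be < n_samples ({n_samples})"
            )


@dataclass
class LowDimKernel:
    """Fitted low-dimensional kernel w(d) = 1 / (1 + a d^(2b))."""

    a: float
    b: float
    min_dist: float
    rms_residual: float = 0.0


@dataclass
class AffinityGraph:
    """High-dimensional affinity structure: distances, local scales, P."""

    D: np.ndarray
    rho: np.ndarray
    sigma: np.ndarray
    P: np.ndarray


def pairwise_sq_euclidean(X: np.ndarray) -> np.ndarray:
    """Squared Euclidean distances between rows (samples) of X."""
    X = np.asarray(X, dtype=float)
    if not np.isfinite(X).all():
        raise ValidationError("non-finite values in input to distance computation")
    if X.shape[0] < 2:
        raise ValidationError("need at least 2 samples")
    sq = (X**2).sum(axis=1)
    D = sq[:, None] + sq[None, :] - 2.0 * (X @ X.T)
    np.maximum(D, 0.0, out=D)
    np.fill_diagonal(D, 0.0)
    return (D + D.T) / 2.0


def _knn_indices(D: np.ndarray, k: int) -> np.ndarray:
    """Row-wise indices of the k nearest neighbors (self excluded).

    Ties in distance are broken by sample index: a stable argsort of each
    row yields the lowest-index neighbor first among equals.
    """
    n = D.shape[0]
    order = np.argsort(D, axis=1, kind="stable")
    out = np.empty((n, k), dtype=int)
    for i in range(n):
        row = order[i][order[i] != i]
        out[i] = row[:k]
    return out


def solve_sigma(
    adjusted: np.ndarray,
    target: float,
    tol: float = 1e-6,
    max_iter: int = 64,
) -> float:
    """Binary-search sigma so that sum(exp(-adjusted / sigma)) == target.

    ``adjusted`` holds the nonnegative offsets max(0, D_ij - rho_i) of a
    sample's calibration neighbors. The sum is increasing in sigma, from
    the count of zero offsets (sigma -> 0) to len(adjusted) (sigma -> inf).
    If the target is already met or exceeded at the floor — e.g. all
    neighbors are duplicates at distance rho — the floor is returned.
    """
    adjusted = np.asarray(adjusted, dtype=float)

    def mass(sigma: float) -> float:
        return float(np.exp(-adjusted / sigma).sum())

    lo, hi = SIGMA_FLOOR, 1.0
    if mass(lo) >= target:
        return SIGMA_FLOOR
    while mass(hi) < target and hi < SIGMA_MAX:
        hi *= 2.0
    for _ in range(max_iter):
        mid = (lo + hi) / 2.0
        if mass(mid) < target:
            lo = mid
        else:
            hi = mid
        if hi - lo < tol:
            break
    return (lo + hi) / 2.0


def calibrate_local_scales(
    D: np.ndarray,
    k_local: int = 15,
    tol: float = 1e-6,
    max_iter: int = 64,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-sample (rho, sigma) for the smooth-kNN affinity kernel.

    rho_i is the squared distance to i's nearest neighbor; sigma_i solves
    sum over the k_local nearest neighbors of exp(-max(0, D_ij - rho_i) /
    sigma_i) = log2(k_local).
    """
    n = D.shape[0]
    if k_local >= n:
        raise ValidationError(f"k_local ({k_local}) must be < n_samples ({n})")
    target = np.log2(k_local)
    nn = _knn_indices(D, k_local)
    rho = np.empty(n)
    sigma = np.empty(n)
    for i in range(n):
        d = D[i, nn[i]]
        rho[i] = d[0]
        adjusted = np.maximum(0.0, d - rho[i])
        sigma[i] = solve_sigma(adjusted, target, tol=tol, max_iter=max_iter)
    return rho, sigma


def build_affinities(
    D: np.ndarray, rho: np.ndarray, sigma: np.ndarray, k_graph: int
) -> np.ndarray:
    """Directed membership strengths p_{j|i} over each sample's k_graph-NN.

    p_{j|i} = exp(-max(0, D_ij - rho_i) / sigma_i) for j among i's k_graph
    nearest neighbors, 0 elsewhere. The nearest neighbor always gets 1.
    """
    n = D.shape[0]
    if k_graph >= n:
        raise ValidationError(f"k_graph ({k_graph}) must be < n_samples ({n})")
    nn = _knn_indices(D, k_graph)
    P = np.zeros((n, n))
    for i in range(n):
        d = D[i, nn[i]]
        P[i, nn[i]] = np.exp(-np.maximum(0.0, d - rho[i]) / sigma[i])
    return P


def symmetrize_half_sum(P_directed: np.ndarray) -> np.ndarray:
    """Symmetrize by averaging: P_ij = (p_{j|i} + p_{i|j}) / 2."""
    P_directed = np.asarray(P_directed, dtype=float)
    if (P_directed < 0).any() or (P_directed > 1).any():
        raise ValidationError("directed affinities must lie in [0, 1]")
    return (P_directed + P_directed.T) / 2.0


def _target_curve(d: np.ndarray, min_dist: float) -> np.ndarray:
    return np.where(d <= min_dist, 1.0, np.exp(-(d - min_dist)))


def fit_ab(
    min_dist: float = 0.25, d_max: float = 3.0, n_grid: int = 300
) -> LowDimKernel:
    """Least-squares fit of (a, b) in w(d) = 1/(1 + a d^(2b)) to the
    min_dist target curve psi(d) = 1 for d <= min_dist, exp(-(d - min_dist))
    beyond, over an even grid on [0, d_max]."""
    if min_dist <= 0:
        raise ValidationError("min_dist must be positive")
    d = np.linspace(0.0, d_max, n_grid)
    psi = _target_curve(d, min_dist)

    def w(d, a, b):
        return 1.0 / (1.0 + a * np.power(np.maximum(d, 1e-12), 2.0 * b))

    try:
        (a, b), _ = curve_fit(w, d, psi, p0=(1.0, 1.0), maxfev=10000)
    except RuntimeError as exc:  # pragma: no cover - curve_fit failure
        raise ValidationError(f"kernel fit did not converge: {exc}") from exc
    resid = w(d, a, b) - psi
    rms = float(np.sqrt((resid**2).mean()))
    if a <= 0 or b <= 0:
        raise ValidationError(f"kernel fit produced non-positive (a, b)=({a}, {b})")
    return LowDimKernel(a=float(a), b=float(b), min_dist=min_dist, rms_residual=rms)


def _low_dim_w(Y: np.ndarray, kernel: LowDimKernel) -> tuple[np.ndarray, np.ndarray]:
    """Pairwise kernel weights w_ij and squared distances of the map."""
    d2 = ((Y[:, None, :] - Y[None, :, :]) ** 2).sum(-1)
    np.fill_diagonal(d2, 0.0)
    W = 1.0 / (1.0 + kernel.a * np.power(np.maximum(d2, 0.0), kernel.b))
    np.fill_diagonal(W, 0.0)
    return W, d2


def normalized_q(Y: np.ndarray, kernel: LowDimKernel) -> np.ndarray:
    """Normalized low-dimensional affinities: Q = W / sum(W), zero diagonal."""
    Y = np.asarray(Y, dtype=float)
    if Y.shape[0] < 2:
        raise ValidationError("need at least 2 points")
    W, _ = _low_dim_w(Y, kernel)
    return W / W.sum()


def _normalize_p(P: np.ndarray) -> np.ndarray:
    s = P.sum()
    if s <= 0:
        raise ValidationError("affinity matrix sums to zero")
    return P / s


def cross_entropy_cost(P: np.ndarray, Q: np.ndarray, eps: float = EPS) -> float:
    """C = -sum_{i != j} P_hat_ij log(Q_ij + eps), with P_hat = P / sum(P)."""
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if P.shape != Q.shape:
        raise ValidationError(f"shape mismatch: P {P.shape} vs Q {Q.shape}")
    P_hat = _normalize_p(P)
    mask = ~np.eye(P.shape[0], dtype=bool)
    return float(-(P_hat[mask] * np.log(Q[mask] + eps)).sum())


def cross_entropy_grad(
    P: np.ndarray, Y: np.ndarray, kernel: LowDimKernel, eps: float = EPS
) -> np.ndarray:
    """Analytic gradient of the cross-entropy cost with respect to Y.

    With W the kernel weights, S = sum(W), Q = W / S and A_ij =
    P_hat_ij / (Q_ij + eps), T = sum(P_hat * Q / (Q + eps)):

        dC/dw_ij = (T - A_ij) / S
        dw/d(d^2) = -a b (d^2)^(b-1) w^2
        dC/dy_i = sum_j (2T - A_ij - A_ji)/S * dw/d(d^2) * 2 (y_i - y_j)
    """
    P_hat = _normalize_p(np.asarray(P, dtype=float))
    Y = np.asarray(Y, dtype=float)
    n = Y.shape[0]
    W, d2 = _low_dim_w(Y, kernel)
    S = W.sum()
    Q = W / S
    denom = Q + eps
    A = P_hat / denom
    np.fill_diagonal(A, 0.0)
    T = float((P_hat * Q / denom).sum())

    d2_safe = np.where(d2 > 0, d2, 1.0)
    wprime = -kernel.a * kernel.b * d2_safe ** (kernel.b - 1.0) * W**2
    wprime[d2 == 0] = 0.0
    np.fill_diagonal(wprime, 0.0)

    coef = ((2.0 * T - A - A.T) / S) * wprime
    grad = 2.0 * (coef.sum(axis=1)[:, None] * Y - coef @ Y)
    return grad


def gradient_descent_embed(
    P: np.ndarray,
    kernel: LowDimKernel,
    params: UmapParams,
    sample_ids: list[str] | None = None,
    transform: str = "unprocessed",
    unit: str = "FPKM",
    Y_init: np.ndarray | None = None,
) -> Embedding:
    """Minimize the cross-entropy cost by full-batch gradient descent.

    Y starts from seeded Gaussian noise (scale 1e-2) unless ``Y_init`` is
    given. Steps are Adam-scaled (beta1=0.9, beta2=0.999), with
    ``learning_rate`` as the base step size; the per-iteration cost trace
    is stored on the embedding.
    """
    params.validate()
    P = np.asarray(P, dtype=float)
    n = P.shape[0]
    if not np.allclose(P, P.T):
        raise ValidationError("P must be symmetric")
    if Y_init is None:
        rng = np.random.default_rng(params.seed)
        Y = rng.normal(scale=1e-2, size=(n, 2))
    else:
        Y = np.array(Y_init, dtype=float)

    b1, b2, adam_eps = 0.9, 0.999, 1e-8
    m = np.zeros_like(Y)
    v = np.zeros_like(Y)
    history: list[float] = []
    for t in range(1, params.n_iter + 1):
        Q = normalized_q(Y, kernel)
        history.append(cross_entropy_cost(P, Q))
        grad = cross_entropy_grad(P, Y, kernel)
        m = b1 * m + (1.0 - b1) * grad
        v = b2 * v + (1.0 - b2) * grad * grad
        step = (m / (1.0 - b1**t)) / (np.sqrt(v / (1.0 - b2**t)) + adam_eps)
        Y = Y - params.learning_rate * step
        if not np.isfinite(Y).all():
            raise ValidationError(
                "embedding diverged (non-finite coordinates); "
                "reduce the learning rate"
            )
    history.append(cross_entropy_cost(P, normalized_q(Y, kernel)))

    sample_ids = sample_ids or [f"S{i:04d}" for i in range(n)]
    prov = {
        "unit": unit,
        "transform": transform,
        "method": "UMAP (adapted)",
        "params": params_dict(params) | {"a": kernel.a, "b": kernel.b},
        "seed": params.seed,
        "initial_cost": history[0],
        "final_cost": history[-1],
    }
    return Embedding(
        coords=Y, sample_ids=sample_ids, provenance=prov, history=history
    )


def effective_k_graph(k_graph: int, n_samples: int) -> int:
    """Small-cohort rule: cohorts under 50 samples use at most 25 neighbors."""
    k = min(k_graph, n_samples - 1)
    if n_samples < SMALL_COHORT_N:
        k = min(k, SMALL_COHORT_K_GRAPH)
    return k


def umap_adapted_embed(
    X_t: np.ndarray,
    params: UmapParams,
    sample_ids: list[str] | None = None,
    transform: str = "unprocessed",
    unit: str = "FPKM",
) -> Embedding:
    """Full adapted-UMAP pipeline on a transformed genes x samples matrix.

    Composes: squared pairwise distances (over samples) -> local scale
    calibration (k_local) -> directed affinities over the k_graph-NN edge
    set -> half-sum symmetrization -> kernel fit -> cross-entropy gradient
    descent.
    """
    X_t = np.asarray(X_t, dtype=float)
    n = X_t.shape[1]
    params.validate(n_samples=n)
    D = pairwise_sq_euclidean(X_t.T)
    rho, sigma = calibrate_local_scales(
        D, params.k_local, tol=params.sigma_tol, max_iter=params.sigma_max_iter
    )
    k_graph = effective_k_graph(params.k_graph, n)
    P_dir = build_affinities(D, rho, sigma, k_graph)
    graph = AffinityGraph(D=D, rho=rho, sigma=sigma,
                          P=symmetrize_half_sum(P_dir))
    kernel = fit_ab(params.min_dist)
    emb = gradient_descent_embed(
        graph.P,
        kernel,
        params,
        sample_ids=sample_ids,
        transform=transform,
        unit=unit,
    )
    emb.provenance["params"]["k_graph_effective"] = k_graph
    return emb
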
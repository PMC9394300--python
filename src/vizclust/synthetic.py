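"""Synthetic FPKM cohorts with planted structure.

Generates gene-expression matrices that mimic the statistical features of
bulk RNA-seq FPKM tables that matter for visual clustering: nonnegative,
heavy-tailed (log-normal) values with exact zeros, optional planted
transcriptomic subgroups (emulating histological subtypes), resection-site
labels drawn independently of expression (a null ground truth), and an
optional primary<->metastatic interpolation gradient.

All draws flow from one seed in a fixed, documented order, so a given spec
is bit-reproducible:

1. per-sample subgroup assignment (or gradient membership + mixing weights)
2. per-sample site labels
3. the base log-expression matrix
4. the zero-inflation mask

These cohorts are stand-ins: real FPKM tables have gene-specific baseline
means, gene-gene correlation and library effects that are deliberately not
modelled (see docs/methods.md).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .types import ExpressionMatrix, SampleAnnotation, ValidationError

__all__ = ["SyntheticSpec", "generate_fpkm", "generate_gradient_cohort"]

LN2 = math.log(2.0)


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic FPKM cohort.

    ``log2_effect_size`` is the mean shift of a subgroup's marker genes on
    the log2 scale (2.0 means markers are 4x up in that subgroup).
    ``base_log_mean`` / ``base_log_sd`` parameterize the natural-log-normal
    baseline; ``zero_fraction`` is the independent probability that any
    entry is set to exactly 0 (dropout / unexpressed gene).
    ``gradient_fraction`` > 0 places that fraction of samples on a
    primary<->metastatic interpolation gradient (see
    :func:`generate_gradient_cohort`).
    """

    n_genes: int = 2000
    n_samples: int = 300
    n_subgroups: int = 3
    n_marker_genes_per_subgroup: int = 300
    log2_effect_size: float = 2.0
    base_log_mean: float = 1.0
    base_log_sd: float = 1.0
    zero_fraction: float = 0.3
    n_sites: int = 5
    gradient_fraction: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_genes", "n_samples", "n_subgroups", "n_sites"):
            if int(getattr(self, name)) < 1:
                raise ValidationError(f"{name} must be a positive count")
        if self.n_marker_genes_per_subgroup < 0:
            raise ValidationError("n_marker_genes_per_subgroup must be >= 0")
        if self.n_subgroups * self.n_marker_genes_per_subgroup > self.n_genes:
            raise ValidationError(
                "n_genes too small for disjoint marker sets: need "
                f"{self.n_subgroups * self.n_marker_genes_per_subgroup}"
            )
        if self.log2_effect_size < 0:
            raise ValidationError("log2_effect_size must be nonnegative")
        if self.base_log_sd <= 0:
            raise ValidationError("base_log_sd must be positive")
        if not 0.0 <= self.zero_fraction < 1.0:
            raise ValidationError("zero_fraction must lie in [0, 1)")
        if not 0.0 <= self.gradient_fraction <= 1.0:
            raise ValidationError("gradient_fraction must lie in [0, 1]")


def _ids(prefix: str, n: int) -> list[str]:
    width = max(4, len(str(n - 1)))
    return [f"{prefix}{i:0{width}d}" for i in range(n)]


def _marker_index(spec: SyntheticSpec, subgroup: int) -> np.ndarray:
    """Disjoint marker blocks: subgroup g owns genes [g*m, (g+1)*m)."""
    m = spec.n_marker_genes_per_subgroup
    return np.arange(subgroup * m, (subgroup + 1) * m)


def generate_fpkm(
    spec: SyntheticSpec,
) -> tuple[ExpressionMatrix, list[SampleAnnotation]]:
    """Generate a planted-subgroup FPKM cohort.

    Entries are exp(Normal(base_log_mean, base_log_sd)); marker genes of a
    sample's subgroup are multiplied by 2**log2_effect_size; each entry is
    then independently zeroed with probability zero_fraction. Site labels
    are drawn uniformly and independently of expression.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    subgroups = rng.integers(0, spec.n_subgroups, size=spec.n_samples)
    sites = rng.integers(0, spec.n_sites, size=spec.n_samples)

    log_x = rng.normal(
        spec.base_log_mean, spec.base_log_sd, size=(spec.n_genes, spec.n_samples)
    )
    for g in range(spec.n_subgroups):
        cols = np.flatnonzero(subgroups == g)
        if cols.size:
            log_x[np.ix_(_marker_index(spec, g), cols)] += (
                spec.log2_effect_size * LN2
            )
    values = np.exp(log_x)

    zero_mask = rng.random(size=values.shape) < spec.zero_fraction
    values[zero_mask] = 0.0

    em = ExpressionMatrix(
        values=values,
        gene_ids=_ids("g", spec.n_genes),
        sample_ids=_ids("S", spec.n_samples),
    )
    ann = [
        SampleAnnotation(
            sample_id=sid,
            site=f"site{sites[i]}",
            sample_type="metastatic",
            subgroup_truth=f"sg{subgroups[i]}",
        )
        for i, sid in enumerate(em.sample_ids)
    ]
    return em, ann


def gradient_signal(
    spec: SyntheticSpec, weights: np.ndarray
) -> np.ndarray:
    """Noiseless log-expression of the interpolated cohort.

    The primary centroid is the flat baseline; the metastatic centroid has
    the first marker block up-shifted by log2_effect_size. A sample at
    mixing weight t gets (1 - t) * primary + t * metastatic, entrywise.
    """
    centroid_primary = np.full(spec.n_genes, spec.base_log_mean)
    centroid_met = centroid_primary.copy()
    centroid_met[_marker_index(spec, 0)] += spec.log2_effect_size * LN2
    w = np.asarray(weights, dtype=float)
    return np.outer(centroid_primary, 1.0 - w) + np.outer(centroid_met, w)


def generate_gradient_cohort(
    spec: SyntheticSpec, return_signal: bool = False
):
    """Generate a cohort where some samples interpolate primary<->metastatic.

    A fraction ``gradient_fraction`` of samples receive mixing weights
    uniform on [0, 1]; the rest are pure endpoints (weight exactly 0 or 1,
    balanced at random). ``sample_type`` is "metastatic" where weight >= 0.5.
    With ``return_signal=True`` the noiseless log-signal matrix and the
    weights are returned as well (useful for oracle checks).
    """
    spec.validate()
    if spec.gradient_fraction <= 0:
        raise ValidationError(
            "gradient_fraction is 0: use generate_fpkm for a non-gradient cohort"
        )
    rng = np.random.default_rng(spec.seed)

    n = spec.n_samples
    n_grad = int(round(spec.gradient_fraction * n))
    grad_idx = rng.permutation(n)[:n_grad]
    weights = rng.integers(0, 2, size=n).astype(float)  # pure endpoints
    weights[grad_idx] = rng.random(size=n_grad)
    sites = rng.integers(0, spec.n_sites, size=n)

    signal = gradient_signal(spec, weights)
    log_x = signal + rng.normal(0.0, spec.base_log_sd, size=(spec.n_genes, n))
    values = np.exp(log_x)
    zero_mask = rng.random(size=values.shape) < spec.zero_fraction
    values[zero_mask] = 0.0

    em = ExpressionMatrix(
        values=values,
        gene_ids=_ids("g", spec.n_genes),
        sample_ids=_ids("S", n),
    )
    ann = [
        SampleAnnotation(
            sample_id=sid,
            site=f"site{sites[i]}",
            sample_type="metastatic" if weights[i] >= 0.5 else "primary",
            subgroup_truth=None,
            mixing_weight=float(weights[i]),
        )
        for i, sid in enumerate(em.sample_ids)
    ]
    if return_signal:
        return em, ann, signal, weights
    return em, ann
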
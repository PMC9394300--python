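"""Shared fixtures: small planted cohorts and the fitted kernel."""

from __future__ import annotations

import numpy as np
import pytest

from vizclust.synthetic import SyntheticSpec, generate_fpkm
from vizclust.transforms import apply_transform
from vizclust.umap_adapted import fit_ab


@pytest.fixture(scope="session")
def kernel():
    return fit_ab(0.25)


@pytest.fixture(scope="session")
def small_spec():
    """A small but clearly separable planted cohort (fast to embed)."""
    return SyntheticSpec(
        n_genes=600,
        n_samples=120,
        n_subgroups=3,
        n_marker_genes_per_subgroup=120,
        log2_effect_size=2.0,
        zero_fraction=0.3,
        n_sites=4,
        seed=123,
    )


@pytest.fixture(scope="session")
def small_cohort(small_spec):
    em, ann = generate_fpkm(small_spec)
    truth = np.array([int(a.subgroup_truth[2:]) for a in ann])
    return em, ann, truth


@pytest.fixture(scope="session")
def small_log10p1(small_cohort):
    em, _, _ = small_cohort
    return apply_transform(em, "log10p1")


def blobs(centers, sd, n_per, seed=0):
    rng = np.random.default_rng(seed)
    pts = np.concatenate(
        [rng.normal(c, sd, size=(n_per, 2)) for c in centers]
    )
    labels = np.repeat(np.arange(len(centers)), n_per)
    return pts, labels


@pytest.fixture
def three_blobs():
    return blobs([(0, 0), (10, 0), (0, 10)], 0.5, 50, seed=7)
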
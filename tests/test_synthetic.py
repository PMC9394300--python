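"""Generator contracts: determinism, zero inflation, planted structure,
site independence, and the gradient cohort's interpolation geometry."""

import numpy as np
import pytest
from sklearn.decomposition import PCA
from sklearn.metrics import adjusted_rand_score

from vizclust.synthetic import (
    SyntheticSpec,
    generate_fpkm,
    generate_gradient_cohort,
    gradient_signal,
)
from vizclust.transforms import apply_transform
from vizclust.types import ValidationError


def test_same_seed_is_bit_identical():
    spec = SyntheticSpec(n_genes=200, n_samples=40, seed=9,
                         n_marker_genes_per_subgroup=30)
    em1, ann1 = generate_fpkm(spec)
    em2, ann2 = generate_fpkm(spec)
    assert np.array_equal(em1.values, em2.values)
    assert ann1 == ann2


def test_zero_fraction_matches_binomial_expectation():
    # 500 x 200 = 1e5 entries: empirical zero rate within 0.3 +/- 0.01,
    # and within 3 binomial standard deviations
    spec = SyntheticSpec(n_genes=500, n_samples=200, zero_fraction=0.3,
                         n_marker_genes_per_subgroup=100, seed=4)
    em, _ = generate_fpkm(spec)
    frac = (em.values == 0).mean()
    assert abs(frac - 0.3) < 0.01
    sd = np.sqrt(0.3 * 0.7 / em.values.size)
    assert abs(frac - 0.3) < 3 * sd
    assert (em.values >= 0).all()


def test_zero_effect_plants_no_marker_enrichment():
    spec = SyntheticSpec(n_genes=400, n_samples=200, log2_effect_size=0.0,
                         zero_fraction=0.0, n_marker_genes_per_subgroup=80,
                         seed=21)
    em, ann = generate_fpkm(spec)
    sg = np.array([int(a.subgroup_truth[2:]) for a in ann])
    log_x = np.log(em.values)
    # mean of subgroup-0 markers in subgroup-0 samples vs other samples
    markers = slice(0, 80)
    inside = log_x[markers][:, sg == 0].mean()
    outside = log_x[markers][:, sg != 0].mean()
    n_in = (sg == 0).sum() * 80
    n_out = (sg != 0).sum() * 80
    se = spec.base_log_sd * np.sqrt(1 / n_in + 1 / n_out)
    assert abs(inside - outside) < 4 * se


def test_planted_subgroups_are_linearly_separable(small_cohort):
    # centroid classifier on log10+1 data >= 95% training accuracy
    em, _, truth = small_cohort
    X = apply_transform(em, "log10p1").T
    centroids = np.stack([X[truth == g].mean(0) for g in np.unique(truth)])
    pred = np.argmin(
        ((X[:, None, :] - centroids[None]) ** 2).sum(-1), axis=1
    )
    assert (pred == truth).mean() >= 0.95


def test_site_labels_independent_of_subgroups():
    spec = SyntheticSpec(n_genes=100, n_samples=400, n_sites=4,
                         n_marker_genes_per_subgroup=20, seed=2)
    _, ann = generate_fpkm(spec)
    sites = [a.site for a in ann]
    truth = [a.subgroup_truth for a in ann]
    assert abs(adjusted_rand_score(sites, truth)) < 0.05


@pytest.mark.parametrize(
    "field,value",
    [
        ("n_genes", 0),
        ("zero_fraction", 1.0),
        ("base_log_sd", 0.0),
        ("log2_effect_size", -1.0),
        ("gradient_fraction", 1.5),
    ],
)
def test_invalid_spec_names_offending_field(field, value):
    spec = SyntheticSpec(**{field: value})
    with pytest.raises(ValidationError, match=field.split("_")[0]):
        spec.validate()


def test_marker_blocks_are_disjoint_and_fit():
    with pytest.raises(ValidationError, match="n_genes"):
        SyntheticSpec(n_genes=100, n_subgroups=3,
                      n_marker_genes_per_subgroup=50).validate()


class TestGradientCohort:
    spec = SyntheticSpec(n_genes=300, n_samples=100, gradient_fraction=0.6,
                         n_marker_genes_per_subgroup=60, seed=5)

    def test_interpolation_endpoints_and_midpoint(self):
        sig = gradient_signal(self.spec, np.array([0.0, 0.5, 1.0]))
        primary, mid, met = sig.T
        assert np.allclose(primary, self.spec.base_log_mean)
        assert np.allclose(mid, (primary + met) / 2.0)
        # metastatic centroid shifts exactly the first marker block
        shifted = met != primary
        assert shifted[:60].all() and not shifted[60:].any()

    def test_weight_correlates_with_first_pc_of_signal(self):
        em, ann, signal, weights = generate_gradient_cohort(
            self.spec, return_signal=True
        )
        pc1 = PCA(n_components=1).fit_transform(signal.T)[:, 0]
        r = np.corrcoef(weights, pc1)[0, 1]
        assert abs(r) > 0.99

    def test_sample_type_thresholds_weight(self):
        _, ann = generate_gradient_cohort(self.spec)
        for a in ann:
            expected = "metastatic" if a.mixing_weight >= 0.5 else "primary"
            assert a.sample_type == expected

    def test_zero_gradient_fraction_rejected(self):
        with pytest.raises(ValidationError, match="generate_fpkm"):
            generate_gradient_cohort(SyntheticSpec(gradient_fraction=0.0))
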
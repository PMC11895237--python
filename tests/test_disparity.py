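import itertools

import numpy as np
import pandas as pd
import pytest

from pteromorph.disparity import (
    TEMPERATE_HYPOTHESIS,
    TROPICAL_HYPOTHESIS,
    biome_disparity,
    biome_null_test,
    disparity_anova,
    disparity_of,
    richness_null,
    richness_regression,
)
from pteromorph.procrustes import AlignedSet, procrustes_distance, standardize

from conftest import rotate


def make_species_set(shapes, log_sizes=None, labels=None):
    shapes = np.asarray(shapes, dtype=float)
    n = shapes.shape[0]
    logs = np.zeros(n) if log_sizes is None else np.asarray(log_sizes, dtype=float)
    labels = labels or [f"sp{i}" for i in range(n)]
    return AlignedSet(
        shapes=shapes,
        centroid_sizes=np.exp(logs),
        log_sizes=logs,
        mean_shape=shapes.mean(axis=0),
        labels=labels,
        species=labels,
    )


@pytest.fixture
def pool(mini_shape):
    rng = np.random.default_rng(51)
    base, _ = standardize(mini_shape)
    shapes = []
    for _ in range(10):
        s, _ = standardize(base + rng.normal(0, 0.03, base.shape))
        shapes.append(s)
    return make_species_set(shapes, log_sizes=rng.normal(3.5, 0.3, 10))


def test_identical_shapes_have_zero_disparity(mini_shape):
    base, _ = standardize(mini_shape)
    d, D = disparity_of(np.array([base] * 5), "shape")
    np.testing.assert_allclose(d, 0.0, atol=1e-9)
    assert D == pytest.approx(0.0, abs=1e-16)


def test_two_species_closed_form(pool):
    """With two species, the sample variance equals half the squared
    inter-species Procrustes distance."""
    a, b = pool.shapes[0], pool.shapes[1]
    d_ab = procrustes_distance(a, b)
    _, D = disparity_of(np.array([a, b]), "shape")
    # shape space is curved, so the Euclidean two-point identity holds to
    # within the (second-order) curvature of the Procrustes sphere
    assert D == pytest.approx(d_ab**2 / 2.0, rel=1e-2)


def test_size_disparity_closed_forms():
    logs = np.array([3.0, 3.4, 3.8, 4.2])
    d, D = disparity_of(logs, "size")
    np.testing.assert_allclose(d, np.abs(logs - logs.mean()), atol=1e-12)
    assert D == pytest.approx(np.var(logs, ddof=1), abs=1e-14)
    _, zero = disparity_of(np.full(6, 2.5), "size")
    assert zero == pytest.approx(0.0, abs=1e-16)


def test_adding_mean_shape_species_lowers_disparity(pool):
    shapes = pool.shapes[:6]
    mean, _ = standardize(shapes.mean(axis=0))
    _, D = disparity_of(shapes, "shape")
    _, D_more = disparity_of(np.vstack([shapes, mean[None]]), "shape")
    assert D_more < D


def test_disparity_rotation_and_order_invariance(pool):
    shapes = pool.shapes[:7]
    _, D = disparity_of(shapes, "shape")
    rotated = np.array([rotate(s, 0.9) for s in shapes])
    _, D_rot = disparity_of(rotated, "shape")
    assert D_rot == pytest.approx(D, rel=1e-9)
    perm = np.random.default_rng(0).permutation(7)
    _, D_perm = disparity_of(shapes[perm], "shape")
    assert D_perm == pytest.approx(D, rel=1e-12)


def test_biome_disparity_with_metadata(pool):
    meta = pd.DataFrame(
        {
            "species": pool.labels,
            "diet": ["Generalist"] * 10,
            "I": [1] * 6 + [0] * 4,
            "II": [0] * 9 + [1],
        }
    )
    rep = biome_disparity(pool, meta, "I", "shape")
    assert rep.n_species == 6 and rep.defined and not rep.low_power
    under = biome_disparity(pool, meta, "II", "shape")
    assert not under.defined and np.isnan(under.D_observed)


def test_disparity_anova_degenerate_and_effect(pool):
    meta = pd.DataFrame(
        {
            "species": pool.labels,
            "diet": ["Generalist"] * 10,
            "I": [1] * 5 + [0] * 5,
            "V": [0] * 5 + [1] * 5,
        }
    )
    reps = [biome_disparity(pool, meta, b, "shape") for b in ("I", "V")]
    F, p = disparity_anova(reps)
    assert np.isfinite(F) and 0 <= p <= 1
    # identical distances => F undefined, flagged
    for r in reps:
        r.distances = np.ones_like(r.distances)
    with pytest.warns(UserWarning, match="identical"):
        F2, p2 = disparity_anova(reps)
    assert np.isnan(F2)


# ------------------------------------------------------ richness null --


def test_null_at_full_richness_is_exhaustive(pool):
    table = richness_null(pool, "shape", [10], n_rep=120, seed=0)
    _, D_all = disparity_of(pool.shapes, "shape")
    np.testing.assert_allclose(table["disparity"], D_all, rtol=1e-9)


def test_null_at_k2_matches_pair_enumeration(pool):
    """The k=2 null mean equals the exhaustive average over all pairs."""
    table = richness_null(pool, "shape", [2], n_rep=4000, seed=1)
    pairs = [
        disparity_of(pool.shapes[[i, j]], "shape")[1]
        for i, j in itertools.combinations(range(10), 2)
    ]
    exact = np.mean(pairs)
    mc = table["disparity"].mean()
    se = table["disparity"].std(ddof=1) / np.sqrt(len(table))
    assert abs(mc - exact) < 4 * se


def test_null_deterministic_under_seed(pool):
    t1 = richness_null(pool, "size", range(2, 6), n_rep=200, seed=9)
    t2 = richness_null(pool, "size", range(2, 6), n_rep=200, seed=9)
    pd.testing.assert_frame_equal(t1, t2)
    with pytest.raises(ValueError):
        richness_null(pool, "size", [11], n_rep=200, seed=0)


def test_richness_regression_oracle(pool):
    table = richness_null(pool, "shape", range(2, 9), n_rep=300, seed=3)
    slope, intercept, means = richness_regression(table)
    x = table["richness"].to_numpy(float)
    y = table["disparity"].to_numpy(float)
    X = np.column_stack([x, np.ones_like(x)])
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    assert slope == pytest.approx(beta[0], abs=1e-10)
    assert intercept == pytest.approx(beta[1], abs=1e-10)
    assert len(means) == 7


def test_richness_regression_flat_pool(mini_shape):
    base, _ = standardize(mini_shape)
    flat = make_species_set([base] * 8)
    table = richness_null(flat, "shape", range(2, 6), n_rep=150, seed=4)
    with pytest.warns(UserWarning, match="constant"):
        slope, intercept, _ = richness_regression(table)
    assert slope == 0.0


# ---------------------------------------------------------- null test --


def _report(pool, richness, D):
    from pteromorph.disparity import DisparityReport

    return DisparityReport(
        biome="I", n_species=richness, species=[], distances=np.array([]),
        D_observed=D, metric="shape", stat="variance",
    )


def test_null_test_p_values(pool):
    table = richness_null(pool, "shape", [4], n_rep=1000, seed=5)
    null = table["disparity"].to_numpy()
    median = float(np.median(null))
    rep = biome_null_test(_report(pool, 4, median), table, TROPICAL_HYPOTHESIS)
    assert 0.4 < rep.p_stated < 0.62
    assert rep.p_upper + rep.p_lower >= 1.0
    # observed above every replicate: p hits the add-one floor
    rep_hi = biome_null_test(_report(pool, 4, null.max() + 1.0), table, TROPICAL_HYPOTHESIS)
    assert rep_hi.p_stated == pytest.approx(1.0 / 1001.0, abs=1e-12)
    assert rep_hi.significant
    # same observed value, temperate hypothesis: reverse tail
    rep_t = biome_null_test(_report(pool, 4, null.max() + 1.0), table, TEMPERATE_HYPOTHESIS)
    assert rep_t.p_stated == pytest.approx(1.0, abs=1e-12)
    assert rep_t.reverse_p == pytest.approx(1.0 / 1001.0, abs=1e-12)
    with pytest.raises(ValueError, match="richness"):
        biome_null_test(_report(pool, 7, 0.1), table, TROPICAL_HYPOTHESIS)
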
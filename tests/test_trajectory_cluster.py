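"""Trajectory clustering, PCoA and PERMANOVA, with library cross-checks."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

from ribopp.trajectory_cluster import (
    choose_k_elbow,
    fuzzy_cmeans,
    intersect_cohorts,
    pcoa_embed,
    permanova,
    select_monotone_cluster,
    zscore_profiles,
)


def frame(rows, columns=None):
    arr = np.asarray(rows, dtype=float)
    return pd.DataFrame(
        arr,
        index=[f"m{i}" for i in range(arr.shape[0])],
        columns=columns or [f"g{j}" for j in range(arr.shape[1])],
    )


# ---------------------------------------------------------------------------
# z-scores


def test_zscore_simple_row():
    z, flat = zscore_profiles(frame([[1, 2, 3]]))
    assert np.allclose(z.to_numpy(), [[-1, 0, 1]])
    assert not flat.iloc[0]


def test_zscore_constant_row_flagged():
    z, flat = zscore_profiles(frame([[5, 5, 5], [1, 2, 3]]))
    assert np.allclose(z.iloc[0], 0)
    assert flat.iloc[0] and not flat.iloc[1]


def test_zscore_affine_invariance():
    rng = np.random.default_rng(2)
    x = rng.normal(size=(5, 4))
    z1, _ = zscore_profiles(frame(x))
    z2, _ = zscore_profiles(frame(3.5 * x + 11.0))
    assert np.allclose(z1.to_numpy(), z2.to_numpy())


def test_zscore_single_group_errors():
    with pytest.raises(ValueError):
        zscore_profiles(frame([[1.0]]))


# ---------------------------------------------------------------------------
# fuzzy c-means


def two_blobs(n=20, sep=10.0, spread=0.05, seed=0):
    rng = np.random.default_rng(seed)
    a = rng.normal([0, 0], spread, size=(n, 2))
    b = rng.normal([sep, 0], spread, size=(n, 2))
    return frame(np.vstack([a, b]))


def test_separated_blobs_have_confident_memberships():
    model = fuzzy_cmeans(two_blobs(), k=2, seed=0)
    assert model.memberships.to_numpy().max(axis=1).min() > 0.99


def test_membership_rows_sum_to_one_random_data():
    rng = np.random.default_rng(4)
    model = fuzzy_cmeans(frame(rng.normal(size=(40, 3))), k=3, seed=1)
    assert np.allclose(model.memberships.sum(axis=1), 1.0, atol=1e-9)


def test_objective_non_increasing():
    rng = np.random.default_rng(5)
    model = fuzzy_cmeans(frame(rng.normal(size=(30, 3))), k=3, seed=2)
    hist = np.array(model.objective_history)
    assert (np.diff(hist) <= 1e-8 * max(1.0, hist[0])).all()


def test_equidistant_point_splits_membership():
    x = frame([[-1.0], [-1.0], [1.0], [1.0], [0.0]])
    model = fuzzy_cmeans(x, k=2, seed=3, n_starts=20)
    mid = model.memberships.iloc[4].to_numpy()
    assert np.allclose(mid, 0.5, atol=0.01)


def test_coincident_point_gets_full_membership():
    # a duplicated tight blob pins a center on it; its points reach ~1
    x = frame([[0.0, 0.0]] * 5 + [[9.0, 9.0]] * 5)
    model = fuzzy_cmeans(x, k=2, seed=4)
    assert model.memberships.to_numpy().max(axis=1).min() > 0.999999


def test_k_larger_than_profiles_errors():
    with pytest.raises(ValueError):
        fuzzy_cmeans(frame([[0.0, 1], [1, 0]]), k=3)
    with pytest.raises(ValueError):
        fuzzy_cmeans(frame([[0.0, 1], [1, 0]]), k=2, m=1.0)


def test_small_fuzzifier_approaches_kmeans():
    """As m -> 1+ on well-separated data, assignments match hard k-means."""
    from sklearn.cluster import KMeans
    from sklearn.metrics import adjusted_rand_score

    rng = np.random.default_rng(6)
    blobs = np.vstack(
        [rng.normal(center, 0.2, size=(15, 2)) for center in ([0, 0], [8, 0], [0, 8])]
    )
    model = fuzzy_cmeans(frame(blobs), k=3, m=1.05, seed=5)
    km = KMeans(n_clusters=3, n_init=10, random_state=0).fit(blobs)
    assert adjusted_rand_score(model.assignment.to_numpy(), km.labels_) == 1.0


# ---------------------------------------------------------------------------
# elbow


def test_elbow_objective_decreases_and_selects_planted_k(small_study):
    panel = small_study.panels["cohort1"]
    z, _ = zscore_profiles(panel.values)
    k, curve = choose_k_elbow(z, range(2, 8), seed=7)
    assert (np.diff(curve["objective"]) < 1e-6).all()
    assert k == 4  # four well-separated planted shapes


def test_elbow_short_range_returns_kmin_with_warning():
    rng = np.random.default_rng(8)
    x = frame(rng.normal(size=(20, 3)))
    with pytest.warns(UserWarning, match="chord"):
        k, _ = choose_k_elbow(x, [2, 3], seed=0)
    assert k == 2


def test_elbow_invalid_range_errors():
    x = frame(np.random.default_rng(0).normal(size=(10, 3)))
    with pytest.raises(ValueError):
        choose_k_elbow(x, [1, 2], seed=0)


# ---------------------------------------------------------------------------
# monotone selection + intersection


class _FakeModel:
    def __init__(self, centers, memberships):
        self.centers = np.asarray(centers, dtype=float)
        self.memberships = memberships

    @property
    def assignment(self):
        return pd.Series(
            np.argmax(self.memberships.to_numpy(), axis=1), index=self.memberships.index
        )


def test_select_monotone_cluster_directions():
    memberships = pd.DataFrame(
        [[0.9, 0.1], [0.2, 0.8], [0.55, 0.45]],
        index=["inc1", "dec1", "inc2"],
        columns=["cluster_0", "cluster_1"],
    )
    model = _FakeModel([[0, 1, 2], [2, 1, 0]], memberships)
    assert select_monotone_cluster(model, "increasing") == {"inc1", "inc2"}
    assert select_monotone_cluster(model, "decreasing") == {"dec1"}
    assert select_monotone_cluster(model, "increasing", min_membership=0.8) == {"inc1"}


def test_flat_center_never_selected():
    memberships = pd.DataFrame(
        [[1.0, 0.0]], index=["a"], columns=["cluster_0", "cluster_1"]
    )
    model = _FakeModel([[0, 0, 0], [1, 0, 2]], memberships)
    with pytest.warns(UserWarning, match="no increasing cluster"):
        assert select_monotone_cluster(model, "increasing") == set()


def test_intersect_cohorts():
    assert intersect_cohorts([{"pro", "ser", "ala"}, {"Pro ", "gly"}]) == ["pro"]
    a, b, c = {"x", "y"}, {"y", "z"}, {"y"}
    assert intersect_cohorts([a, b, c]) == intersect_cohorts([c, a, b])
    with pytest.raises(ValueError):
        intersect_cohorts([a])


# ---------------------------------------------------------------------------
# PCoA


def test_pcoa_two_points():
    d = np.array([[0.0, 4.0], [4.0, 0.0]])
    coords, eigvals = pcoa_embed(d, n_axes=1)
    assert np.allclose(sorted(coords[:, 0]), [-2.0, 2.0])


def test_pcoa_reconstructs_planar_distances():
    rng = np.random.default_rng(9)
    pts = rng.normal(size=(12, 2))
    d = squareform(pdist(pts))
    coords, eigvals = pcoa_embed(d, n_axes=2)
    assert np.allclose(squareform(pdist(coords)), d, atol=1e-8)
    # eigenvalue mass equals total centered squared deviation
    centered = pts - pts.mean(axis=0)
    assert np.isclose(eigvals.sum(), (centered**2).sum(), atol=1e-8)


def test_pcoa_matches_skbio():
    skbio = pytest.importorskip("skbio")
    rng = np.random.default_rng(10)
    pts = rng.normal(size=(9, 3))
    d = squareform(pdist(pts))
    coords, _ = pcoa_embed(d, n_axes=3)
    ref = skbio.stats.ordination.pcoa(skbio.DistanceMatrix(d))
    ref_coords = ref.samples.to_numpy()[:, :3]
    # same embedding up to per-axis sign
    for ax in range(3):
        assert np.allclose(np.abs(coords[:, ax]), np.abs(ref_coords[:, ax]), atol=1e-6)


def test_pcoa_rejects_bad_input():
    with pytest.raises(ValueError, match="symmetric"):
        pcoa_embed(np.array([[0.0, 1.0], [2.0, 0.0]]))
    with pytest.raises(ValueError, match="diagonal"):
        pcoa_embed(np.array([[1.0, 1.0], [1.0, 0.0]]))


# ---------------------------------------------------------------------------
# PERMANOVA


def test_permanova_maximal_separation():
    # two tight groups far apart: R^2 -> 1 and p at the resolution floor,
    # up to permutations that happen to reproduce the observed partition
    # (those tie the observed F and are counted, as they must be)
    rng = np.random.default_rng(21)
    x = np.vstack([rng.normal(0, 1e-3, (4, 2)), rng.normal([100, 0], 1e-3, (4, 2))])
    d = squareform(pdist(x))
    labels = ["a"] * 4 + ["b"] * 4
    res = permanova(d, labels, n_permutations=199, seed=0)
    assert res.r_squared == pytest.approx(1.0, abs=1e-6)
    # expected ties: 199 * 2/C(8,4) ~ 5.7 partition-reproducing permutations
    assert 1 / 200 <= res.p_value <= 15 / 200


def test_permanova_r2_bounds_random():
    rng = np.random.default_rng(11)
    x = rng.normal(size=(12, 3))
    res = permanova(squareform(pdist(x)), np.repeat(["a", "b", "c"], 4),
                    n_permutations=99, seed=1)
    assert 0.0 <= res.r_squared <= 1.0
    assert 1 / 100 <= res.p_value <= 1.0


def test_permanova_f_invariant_to_within_group_relabeling():
    rng = np.random.default_rng(12)
    x = rng.normal(size=(10, 2))
    d = squareform(pdist(x))
    labels = np.array(["a"] * 5 + ["b"] * 5)
    f1 = permanova(d, labels, n_permutations=9, seed=0).f_statistic
    # permute samples *within* groups: distances permute consistently
    perm = np.array([3, 0, 4, 1, 2, 8, 6, 5, 9, 7])
    f2 = permanova(d[np.ix_(perm, perm)], labels, n_permutations=9, seed=0).f_statistic
    assert f1 == pytest.approx(f2)


def test_permanova_matches_skbio_statistic():
    skbio = pytest.importorskip("skbio")
    rng = np.random.default_rng(13)
    x = rng.normal(size=(12, 4))
    x[:4] += 1.5
    d = squareform(pdist(x))
    labels = np.repeat(["a", "b", "c"], 4)
    res = permanova(d, labels, n_permutations=99, seed=0)
    ref = skbio.stats.distance.permanova(
        skbio.DistanceMatrix(d), list(labels), permutations=99
    )
    assert res.f_statistic == pytest.approx(ref["test statistic"], rel=1e-10)


def test_permanova_group_of_one_errors():
    d = squareform(pdist(np.random.default_rng(0).normal(size=(5, 2))))
    with pytest.raises(ValueError):
        permanova(d, ["a", "a", "a", "a", "b"])
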
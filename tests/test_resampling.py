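"""Unit and property tests for the five resamplers and the kNN backend."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from eegsmote import (
    ClusterConfig, LabeledDataset, ResampleConfig, ResamplerError,
    RESAMPLERS, bnnsmote, blsmote, boundary_majority, compute_neighbors,
    danger_minority, filter_noise, make_clusters, ros, smote, svmsmote,
    synthesize_samples,
)
from conftest import random_imbalanced


def brute_force_knn(X_ref, X_query, k, exclude=None):
    """Independent O(n^2) oracle: full pairwise sort, ties by index."""
    out = np.empty((len(X_query), k), int)
    for i, q in enumerate(X_query):
        d = np.sqrt(((X_ref - q) ** 2).sum(axis=1))
        if exclude is not None:
            d = d.copy()
            d[exclude[i]] = np.inf
        pairs = sorted(range(len(X_ref)), key=lambda j: (d[j], j))
        out[i] = pairs[:k]
    return out


class TestComputeNeighbors:
    def test_nearest_by_construction(self):
        X = np.array([[0.0, 0.0], [1.0, 0.0], [5.0, 0.0]])
        nt = compute_neighbors(X, X, k=1)
        assert nt.indices[0, 0] == 1
        assert nt.distances[0, 0] == pytest.approx(1.0)

    def test_exhaustive_k(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(8, 3))
        nt = compute_neighbors(X, X, k=7)
        # every other point appears, sorted by distance
        for i in range(8):
            assert set(nt.indices[i]) == set(range(8)) - {i}
            assert (np.diff(nt.distances[i]) >= 0).all()

    def test_matches_brute_force(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(30, 2))
        nt = compute_neighbors(X, X, k=5)
        expected = brute_force_knn(X, X, 5, exclude=np.arange(30))
        np.testing.assert_array_equal(nt.indices, expected)

    def test_tie_break_by_lower_index(self):
        # three reference points equidistant from the query
        X_ref = np.array([[1.0, 0], [0, 1.0], [-1.0, 0]])
        nt = compute_neighbors(X_ref, np.array([[0.0, 0.0]]), k=3)
        np.testing.assert_array_equal(nt.indices[0], [0, 1, 2])

    def test_k_too_large(self):
        X = np.zeros((4, 2))
        with pytest.raises(ValueError):
            compute_neighbors(X, X, k=4)


class TestFilterNoise:
    def test_lone_minority_in_majority_cluster_is_noise(self):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(0, 1, (30, 2)), [[0.0, 0.0]]])
        y = np.array([0] * 30 + [1])
        clean, noise = filter_noise(LabeledDataset(X, y), k_noise=5)
        assert list(noise) == [30] and len(clean) == 0

    def test_minority_with_minority_neighbor_kept(self):
        X = np.vstack([np.random.default_rng(0).normal(5, 1, (20, 2)),
                       [[0.0, 0.0], [0.1, 0.0]]])
        y = np.array([0] * 20 + [1, 1])
        clean, noise = filter_noise(LabeledDataset(X, y), k_noise=5)
        # each minority point's nearest neighbour is the other one
        assert set(clean) == {20, 21} and len(noise) == 0

    def test_planted_noise_recovered(self, noisy_clusters):
        ds, truth = noisy_clusters
        clean, noise = filter_noise(ds, k_noise=5)
        np.testing.assert_array_equal(np.sort(noise), truth)
        assert set(clean) | set(noise) == set(ds.minority_indices)

    def test_single_class_errors(self):
        ds = LabeledDataset(np.zeros((5, 2)), np.zeros(5, int))
        with pytest.raises(ResamplerError):
            filter_noise(ds, 3)


class TestBoundaryMajority:
    def test_facing_edge_only(self):
        """Membership matches a brute-force check of the rule on a toy set."""
        rng = np.random.default_rng(3)
        X = np.vstack([rng.normal(0, 0.7, (30, 2)),
                       rng.normal([4, 0], 0.7, (10, 2))])
        y = np.array([0] * 30 + [1] * 10)
        ds = LabeledDataset(X, y)
        clean = ds.minority_indices
        got = boundary_majority(ds, clean, k_boundary=3)
        # brute force: majority rows with a clean minority in their 3-NN
        expected = []
        for m in range(30):
            nn = brute_force_knn(X, X[[m]], 3, exclude=[[m]])[0]
            if any(j in set(clean) for j in nn):
                expected.append(m)
        np.testing.assert_array_equal(got, expected)
        # sanity: boundary rows sit on the facing edge (x above median)
        if len(got):
            assert X[got, 0].mean() > np.median(X[:30, 0])

    def test_whole_set_neighborhood(self, toy_2d):
        n = toy_2d.n_samples
        got = boundary_majority(toy_2d, toy_2d.minority_indices,
                                k_boundary=n - 1)
        np.testing.assert_array_equal(got, toy_2d.majority_indices)

    def test_empty_clean_minority_raises(self, toy_2d):
        with pytest.raises(ResamplerError):
            boundary_majority(toy_2d, np.empty(0, int), 3)


class TestDangerMinority:
    def test_subset_of_clean(self, toy_2d):
        clean = toy_2d.minority_indices
        bmaj = boundary_majority(toy_2d, clean, 5)
        danger = danger_minority(toy_2d, clean, bmaj, 5)
        assert set(danger) <= set(clean)

    def test_matches_enumeration(self):
        rng = np.random.default_rng(5)
        X = np.vstack([rng.normal(0, 1, (25, 2)),
                       rng.normal([3, 0], 1, (8, 2))])
        y = np.array([0] * 25 + [1] * 8)
        ds = LabeledDataset(X, y)
        clean = ds.minority_indices
        bmaj = boundary_majority(ds, clean, 4)
        got = danger_minority(ds, clean, bmaj, 4)
        expected = set()
        for b in bmaj:
            nn = brute_force_knn(X, X[[b]], 4, exclude=[[b]])[0]
            expected |= set(nn) & set(clean)
        assert set(got) == expected

    def test_empty_when_unreachable(self):
        # far-apart clusters + empty boundary set -> borderline fallback
        # finds nothing because every minority point is interior
        rng = np.random.default_rng(2)
        X = np.vstack([rng.normal(0, 0.1, (20, 2)),
                       rng.normal([100, 0], 0.1, (8, 2))])
        y = np.array([0] * 20 + [1] * 8)
        ds = LabeledDataset(X, y)
        danger = danger_minority(ds, ds.minority_indices, np.empty(0, int),
                                 k_danger=4)
        assert len(danger) == 0


class TestSynthesize:
    def test_delta_zero_endpoint(self, toy_2d):
        class _RNG:
            def integers(self, n):
                return 0

            def uniform(self):
                return 0.0

        clean = toy_2d.minority_indices
        X_new, prov = synthesize_samples(toy_2d, clean[:2], clean, 1, _RNG())
        np.testing.assert_array_equal(X_new[0], toy_2d.X[prov[0].parent])

    def test_duplicate_points_collapse(self):
        X = np.array([[0.0, 0.0]] * 3 + [[1.0, 1.0]] * 3)
        y = np.array([0, 0, 0, 1, 1, 1])
        ds = LabeledDataset(X, y)
        rng = np.random.default_rng(0)
        X_new, _ = synthesize_samples(ds, np.array([3, 4]),
                                      np.array([3, 4, 5]), 20, rng)
        np.testing.assert_allclose(X_new, 1.0)

    def test_convexity_1000_draws(self, toy_2d):
        rng = np.random.default_rng(11)
        clean = toy_2d.minority_indices
        X_new, prov = synthesize_samples(toy_2d, clean[:4], clean, 1000, rng)
        for row, p in zip(X_new, prov):
            lo = np.minimum(toy_2d.X[p.parent], toy_2d.X[p.partner])
            hi = np.maximum(toy_2d.X[p.parent], toy_2d.X[p.partner])
            assert (row >= lo - 1e-9).all() and (row <= hi + 1e-9).all()
            assert 0 <= p.delta <= 1

    def test_single_clean_minority_is_degenerate(self, toy_2d):
        with pytest.raises(ResamplerError):
            synthesize_samples(toy_2d, np.empty(0, int),
                               toy_2d.minority_indices[:1], 5,
                               np.random.default_rng(0))


class TestBnnsmote:
    def test_balanced_input_noop_except_noise(self):
        rng = np.random.default_rng(4)
        X = np.vstack([rng.normal(0, 1, (20, 2)),
                       rng.normal([6, 0], 1, (20, 2))])
        y = np.array([0] * 20 + [1] * 20)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = bnnsmote(LabeledDataset(X, y), ResampleConfig(seed=0))
        assert res.n_synth == 0

    def test_fixture_postconditions(self):
        ds, truth = make_clusters(ClusterConfig(n_major=300, n_minor=10,
                                                noise_frac=0.2, seed=1))
        res = bnnsmote(ds, ResampleConfig(target_ratio=1.0, seed=1))
        out = res.dataset
        assert (out.y == 1).sum() == 300 and (out.y == 0).sum() == 300
        noise_set = set(map(int, res.noise_indices))
        assert noise_set == set(map(int, truth))
        for p in res.provenance:
            assert p.parent not in noise_set and p.partner not in noise_set

    def test_seeded_determinism(self, noisy_clusters):
        ds, _ = noisy_clusters
        r1 = bnnsmote(ds, ResampleConfig(seed=9))
        r2 = bnnsmote(ds, ResampleConfig(seed=9))
        np.testing.assert_array_equal(r1.dataset.X, r2.dataset.X)
        np.testing.assert_array_equal(r1.dataset.y, r2.dataset.y)

    def test_keep_noise_retains_rows(self, noisy_clusters):
        ds, truth = noisy_clusters
        res = bnnsmote(ds, ResampleConfig(seed=0, keep_noise=True))
        assert res.dataset.n_samples == ds.n_samples + res.n_synth

    def test_partner_mode_knn(self, noisy_clusters):
        ds, _ = noisy_clusters
        res = bnnsmote(ds, ResampleConfig(seed=0, partner_mode="knn"))
        assert res.n_synth > 0


class TestBaselines:
    def test_ros_rows_are_exact_copies(self, toy_2d):
        res = ros(toy_2d, ResampleConfig(seed=2))
        originals = {tuple(r) for r in toy_2d.X[toy_2d.minority_indices]}
        for row in res.synthetic_rows:
            assert tuple(row) in originals
        for p in res.provenance:
            assert p.parent == p.partner and p.delta == 0.0

    def test_ros_replays_seeded_draw(self, toy_2d):
        res = ros(toy_2d, ResampleConfig(seed=5))
        rng = np.random.default_rng(5)
        mino = toy_2d.minority_indices
        n_new = len(toy_2d.majority_indices) - len(mino)
        expected = mino[rng.integers(len(mino), size=n_new)]
        np.testing.assert_array_equal([p.parent for p in res.provenance],
                                      expected)

    def test_smote_rows_on_neighbor_segments(self, toy_2d):
        res = smote(toy_2d, ResampleConfig(seed=3, k_danger=3))
        mino = toy_2d.minority_indices
        nt_expected = brute_force_knn(toy_2d.X[mino], toy_2d.X[mino], 3,
                                      exclude=[[i] for i in range(len(mino))])
        pos = {int(m): i for i, m in enumerate(mino)}
        for row, p in zip(res.synthetic_rows, res.provenance):
            assert pos[p.partner] in nt_expected[pos[p.parent]]
            seg = toy_2d.X[p.parent] + p.delta * (toy_2d.X[p.partner]
                                                  - toy_2d.X[p.parent])
            np.testing.assert_allclose(row, seg, atol=1e-12)

    def test_blsmote_interior_minority_noop(self):
        rng = np.random.default_rng(8)
        X = np.vstack([rng.normal(0, 0.1, (40, 2)),
                       rng.normal([50, 0], 0.1, (10, 2))])
        y = np.array([0] * 40 + [1] * 10)
        with pytest.warns(UserWarning):
            res = blsmote(LabeledDataset(X, y), ResampleConfig(seed=0))
        assert res.n_synth == 0

    def test_blsmote_danger_matches_rule(self):
        rng = np.random.default_rng(9)
        X = np.vstack([rng.normal(0, 1, (30, 2)),
                       rng.normal([2.5, 0], 1, (10, 2))])
        y = np.array([0] * 30 + [1] * 10)
        ds = LabeledDataset(X, y)
        k = 5
        res = blsmote(ds, ResampleConfig(seed=0, k_danger=k))
        expected = set()
        for m in ds.minority_indices:
            nn = brute_force_knn(X, X[[m]], k, exclude=[[m]])[0]
            mp = int((ds.y[nn] == 0).sum())
            if k / 2 <= mp < k:
                expected.add(int(m))
        assert set(map(int, res.danger_indices)) == expected
        # noise-like minority rows (m' = k) are never parents
        noiselike = {int(m) for m in ds.minority_indices
                     if (ds.y[brute_force_knn(X, X[[m]], k,
                                              exclude=[[m]])[0]] == 0).all()}
        assert not {p.parent for p in res.provenance} & noiselike

    def test_svmsmote_parents_are_margin_minority(self):
        # linearly separable toy set: parents must be the boundary-nearest
        # minority rows (the support vectors)
        X = np.array([[0, 0], [0, 1], [1, 0], [1, 1], [0.5, 0.5],
                      [3, 3], [3, 4], [4, 3], [4, 4], [2.5, 2.5]],
                     dtype=float)
        y = np.array([0, 0, 0, 0, 0, 1, 1, 1, 1, 1])
        res = svmsmote(LabeledDataset(X, y[::1] * 0 + y),
                       ResampleConfig(seed=0, target_ratio=1.0))
        # no synthesis needed (balanced) -> passthrough warning instead
        assert res.n_synth == 0

    def test_svmsmote_parent_identification(self):
        rng = np.random.default_rng(1)
        X = np.vstack([rng.normal(0, 0.5, (20, 2)),
                       rng.normal([3, 0], 0.5, (6, 2))])
        y = np.array([0] * 20 + [1] * 6)
        ds = LabeledDataset(X, y)
        res = svmsmote(ds, ResampleConfig(seed=1))
        parents = {p.parent for p in res.provenance}
        assert parents <= set(map(int, res.danger_indices))
        assert set(map(int, res.danger_indices)) <= set(
            map(int, ds.minority_indices))
        # margin check: parent rows are closer to the majority centroid
        # than the farthest minority row is
        cmaj = ds.X[ds.majority_indices].mean(axis=0)
        dmax = max(np.linalg.norm(ds.X[m] - cmaj)
                   for m in ds.minority_indices)
        for p in parents:
            assert np.linalg.norm(ds.X[p] - cmaj) <= dmax


@pytest.mark.parametrize("name", ["ros", "smote", "blsmote", "svmsmote",
                                  "bnnsmote"])
def test_resampler_contracts(name):
    """Balance, convexity, majority preservation and determinism hold for
    every resampler on random imbalanced fixtures."""
    rng = np.random.default_rng(123)
    for _ in range(5):
        ds = random_imbalanced(rng)
        cfg = ResampleConfig(seed=int(rng.integers(1000)))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = RESAMPLERS[name](ds, cfg)
            res2 = RESAMPLERS[name](ds, cfg)
        out = res.dataset
        n_maj = (out.y == 0).sum()
        if res.n_synth > 0:
            assert (out.y == 1).sum() == round(cfg.target_ratio * n_maj)
        # majority rows pass through unmodified, in original order
        np.testing.assert_array_equal(
            out.X[out.y == 0], ds.X[ds.majority_indices])
        # convex combination provenance
        for row, p in zip(res.synthetic_rows, res.provenance):
            expect = ds.X[p.parent] + p.delta * (ds.X[p.partner]
                                                 - ds.X[p.parent])
            assert np.abs(row - expect).max() <= 1e-9
        # determinism
        np.testing.assert_array_equal(out.X, res2.dataset.X)


@given(st.integers(0, 10_000))
@settings(max_examples=25, deadline=None)
def test_bnnsmote_noise_exclusion_property(seed):
    """No synthetic row ever has a noise-flagged parent or partner."""
    ds, truth = make_clusters(ClusterConfig(n_major=60, n_minor=8,
                                            noise_frac=0.25, seed=seed))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = bnnsmote(ds, ResampleConfig(seed=seed))
    noise = set(map(int, res.noise_indices))
    for p in res.provenance:
        assert p.parent not in noise and p.partner not in noise


def test_inverted_imbalance_is_warned_noop():
    rng = np.random.default_rng(0)
    X = rng.normal(size=(30, 2))
    y = np.array([1] * 20 + [0] * 10)
    with pytest.warns(UserWarning):
        res = bnnsmote(LabeledDataset(X, y), ResampleConfig())
    assert res.n_synth == 0
    assert res.dataset.n_samples == 30


def test_registry_dispatch(toy_2d):
    from eegsmote import resample
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = resample("ros", toy_2d, ResampleConfig(seed=0))
    assert res.n_synth >= 0
    with pytest.raises(KeyError):
        resample("adasyn", toy_2d)
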
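import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from dfcmeta import leida


class TestIPL:
    def test_in_phase(self):
        m = leida.ipl_at_time([0.7, 0.7])
        assert m[0, 1] == pytest.approx(1.0)

    def test_antiphase(self):
        m = leida.ipl_at_time([0.0, np.pi])
        assert m[0, 1] == pytest.approx(-1.0)

    def test_quadrature(self):
        m = leida.ipl_at_time([0.0, np.pi / 2])
        assert m[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_symmetric_unit_diag(self):
        rng = np.random.default_rng(0)
        m = leida.ipl_at_time(rng.uniform(-np.pi, np.pi, 8))
        assert np.allclose(m, m.T)
        assert np.allclose(np.diag(m), 1.0)
        assert m.min() >= -1 and m.max() <= 1

    def test_tensor_matches_per_time(self):
        rng = np.random.default_rng(1)
        phases = rng.uniform(-np.pi, np.pi, size=(6, 10))
        tensor = leida.ipl_tensor(phases)
        for t in range(10):
            assert np.allclose(tensor[t], leida.ipl_at_time(phases[:, t]), atol=1e-12)


class TestLeadingEigenvector:
    def test_all_ones(self):
        v, lam = leida.leading_eigenvector(np.ones((4, 4)))
        assert lam == pytest.approx(4.0)
        assert np.allclose(v, 0.5)

    def test_antiphase_blocks(self):
        m = np.block(
            [[np.ones((2, 2)), -np.ones((2, 2))], [-np.ones((2, 2)), np.ones((2, 2))]]
        )
        v, lam = leida.leading_eigenvector(m)
        assert lam == pytest.approx(4.0)
        assert np.sign(v[0]) == np.sign(v[1]) != np.sign(v[2]) == np.sign(v[3])
        assert np.allclose(np.abs(v), 0.5)

    def test_matches_full_decomposition_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            n = rng.integers(3, 31)
            m = leida.ipl_at_time(rng.uniform(-np.pi, np.pi, n))
            v, lam = leida.leading_eigenvector(m)
            evals, evecs = np.linalg.eig(m)  # independent general solver
            idx = np.argmax(np.abs(evals))
            ov = np.real(evecs[:, idx])
            ov = ov * np.sign(ov @ v) / np.linalg.norm(ov)
            assert abs(lam - np.real(evals[idx])) < 1e-9
            assert np.allclose(v, ov, atol=1e-9)

    def test_asymmetric_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            leida.leading_eigenvector(np.arange(9.0).reshape(3, 3))


class TestMagnetization:
    def test_global_mode_zero(self):
        assert leida.magnetization(np.ones(10)) == 0.0

    def test_balanced_poles(self):
        v = np.array([1.0] * 58 + [-1.0] * 58)
        assert leida.magnetization(v) == pytest.approx(1.0)

    def test_direct_count(self):
        v = np.array([0.1] * 87 + [-0.1] * 29)
        assert leida.magnetization(v) == pytest.approx(29 / 87)


@given(
    hnp.arrays(
        np.float64,
        st.integers(2, 40),
        elements=st.floats(-1, 1, allow_nan=False),
    ).filter(lambda v: np.linalg.norm(v) > 1e-6)
)
def test_sign_convention_idempotent(v):
    once = leida.apply_sign_convention(v)
    twice = leida.apply_sign_convention(once)
    assert np.array_equal(once, twice)
    n_neg = np.sum(once < 0)
    assert n_neg <= once.size - n_neg


def _planted_vectors(n=20, t=200, noise=0.02, seed=0):
    rng = np.random.default_rng(seed)
    p1 = np.zeros(n)
    p1[: n // 2] = 1.0
    p2 = np.zeros(n)
    p2[n // 2 :] = 1.0
    p1 /= np.linalg.norm(p1)
    p2 /= np.linalg.norm(p2)
    cols, truth = [], []
    for i in range(t):
        base = p1 if i % 2 == 0 else p2
        truth.append(i % 2)
        cols.append(base + noise * rng.normal(size=n))
    return np.array(cols).T, np.array(truth), p1, p2


class TestExtractModes:
    def test_planted_two_cluster_recovery(self):
        vectors, truth, p1, p2 = _planted_vectors()
        ms = leida.extract_modes(vectors, 2, reps=20, seed=0)
        sims = np.abs(ms.centroids.T @ np.vstack([p1, p2]).T)  # (2 modes, 2 patterns)
        perm = np.argmax(sims, axis=1)
        assert sorted(perm) == [0, 1]
        assert np.all(np.max(sims, axis=1) > 0.99)
        pred = np.array([perm[label - 1] for label in ms.labels])
        assert np.mean(pred == truth) > 0.99

    def test_k_below_range_errors(self):
        vectors, *_ = _planted_vectors()
        with pytest.raises(ValueError, match="k must be >= 2"):
            leida.extract_modes(vectors, 1)

    def test_degenerate_identical_columns(self):
        vectors = np.tile(np.ones(5)[:, None], (1, 30))
        with pytest.raises(RuntimeError, match="degenerate"):
            leida.extract_modes(vectors, 2, reps=5, seed=0)

    def test_occupancy_sums_to_t(self):
        vectors, *_ = _planted_vectors(t=101)
        ms = leida.extract_modes(vectors, 2, reps=10, seed=1)
        assert ms.occupancy.sum() == 101

    def test_global_mode_first(self):
        rng = np.random.default_rng(5)
        pos = np.abs(rng.normal(size=(8, 50))) + 0.5  # all-positive cluster
        mixed = rng.normal(size=(8, 150))
        mixed[:4] -= 2.0  # bipolar cluster, higher occupancy
        vectors = np.concatenate([pos, mixed], axis=1)
        ms = leida.extract_modes(vectors, 2, reps=20, seed=2)
        assert not np.any(ms.centroids[:, 0] < 0)
        assert np.arange(8).tolist() == ms.community(1).tolist()


class TestSelectK:
    def test_separated_clusters_prefer_2(self):
        vectors, *_ = _planted_vectors()
        sets = {
            k: leida.extract_modes(vectors, k, reps=10, seed=0) for k in (2, 3)
        }
        chosen, table = leida.select_k_silhouette(sets)
        assert chosen == 2
        assert table[2] > table[3]

    def test_single_blob_decreasing(self):
        rng = np.random.default_rng(3)
        vectors = rng.normal(size=(10, 300)) + 5.0
        sets = {
            k: leida.extract_modes(vectors, k, reps=10, seed=0) for k in (2, 3, 4)
        }
        _, table = leida.select_k_silhouette(sets)
        assert table[2] > table[3] > table[4]

    def test_duplicate_points_silhouette_near_one(self):
        a = np.zeros(6)
        a[0] = 1.0
        b = np.zeros(6)
        b[3] = 1.0
        vectors = np.stack([a] * 20 + [b] * 20).T
        ms = leida.extract_modes(vectors, 2, reps=5, seed=0)
        assert ms.silhouette == pytest.approx(1.0, abs=1e-9)

    def test_override(self):
        vectors, *_ = _planted_vectors()
        sets = {
            k: leida.extract_modes(vectors, k, reps=5, seed=0) for k in (2, 3, 4)
        }
        chosen, _ = leida.select_k_silhouette(sets, override=4)
        assert chosen == 4


class TestAssignModes:
    def test_exact_centroid(self):
        centroids = np.eye(4)[:, :3]
        labels = leida.assign_modes(centroids[:, [2]], centroids)
        assert labels[0] == 3

    def test_tie_goes_to_lowest_index(self):
        c2 = np.array([1.0, 1.0, 0.0])
        c3 = np.array([1.0, 0.0, 1.0])
        centroids = np.stack([np.array([0.0, 0.0, -1.0]), c2, c3], axis=1)
        v = np.array([[1.0], [0.5], [0.5]])  # equidistant from modes 2 and 3
        assert leida.assign_modes(v, centroids)[0] == 2

    def test_matches_brute_force(self):
        rng = np.random.default_rng(4)
        vectors = rng.normal(size=(10, 50))
        centroids = rng.normal(size=(10, 4))
        labels = leida.assign_modes(vectors, centroids)
        for t in range(50):
            v = vectors[:, t] / np.linalg.norm(vectors[:, t])
            dists = [
                1 - v @ (centroids[:, c] / np.linalg.norm(centroids[:, c]))
                for c in range(4)
            ]
            assert labels[t] == int(np.argmin(dists)) + 1


class TestHalfSwitch:
    def test_delta_zero_identity(self):
        rng = np.random.default_rng(6)
        vectors = rng.normal(size=(8, 40))
        centroids = rng.normal(size=(8, 3))
        raw = leida.assign_modes(vectors, centroids)
        smooth = leida.half_switch_smooth(vectors, centroids, enabled=True, delta=0.0)
        assert np.array_equal(raw, smooth)

    def test_large_delta_freezes_label(self):
        c1 = np.array([1.0, 0.05])
        c2 = np.array([1.0, -0.05])
        centroids = np.stack([c1, c2], axis=1)
        # alternate vectors just either side of the decision boundary
        cols = [np.array([1.0, 0.01 if i % 2 == 0 else -0.01]) for i in range(30)]
        vectors = np.array(cols).T
        smooth = leida.half_switch_smooth(vectors, centroids, enabled=True, delta=2.0)
        assert len(np.unique(smooth)) == 1

    def test_never_more_switches(self):
        rng = np.random.default_rng(8)
        vectors = rng.normal(size=(6, 100))
        centroids = rng.normal(size=(6, 4))
        raw = leida.assign_modes(vectors, centroids)
        smooth = leida.half_switch_smooth(vectors, centroids, enabled=True, delta=0.1)
        assert np.sum(np.diff(smooth) != 0) <= np.sum(np.diff(raw) != 0)


class TestModeFC:
    def test_uniform_centroid(self):
        fc = leida.mode_fc(np.full(4, 0.5))
        assert np.allclose(fc, 0.25)

    def test_sign_structure_and_trace(self):
        rng = np.random.default_rng(9)
        v = rng.normal(size=12)
        v /= np.linalg.norm(v)
        fc = leida.mode_fc(v)
        assert np.allclose(np.sign(fc), np.outer(np.sign(v), np.sign(v)))
        assert np.trace(fc) == pytest.approx(1.0)


class TestConnectogram:
    def test_global_mode_empty(self):
        assert leida.connectogram_edges(np.full(6, 0.4)) == []

    def test_three_negative_complete_graph(self):
        v = np.array([0.5, 0.5, 0.5, 0.5, -0.3, -0.3, -0.3])
        edges = leida.connectogram_edges(v)
        assert sorted((a, b) for a, b, _ in edges) == [(4, 5), (4, 6), (5, 6)]
        assert all(w > 0 for _, _, w in edges)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(10)
        v = leida.apply_sign_convention(rng.normal(size=15))
        edges = set((a, b) for a, b, _ in leida.connectogram_edges(v))
        fc = np.outer(v, v)
        expected = set()
        neg = [i for i in range(15) if v[i] < 0]
        for i in neg:
            for j in neg:
                if i < j and fc[i, j] > 0:
                    expected.add((i, j))
        assert edges == expected


class TestRegionalContribution:
    def test_constant_value(self):
        vectors = np.full((5, 10), 0.3)
        labels = np.array([1] * 4 + [2] * 6)
        val, n = leida.regional_contribution(vectors, labels, region=2, mode=1)
        assert val == pytest.approx(0.3)
        assert n == 4

    def test_zero_occupancy_errors(self):
        vectors = np.ones((3, 5))
        with pytest.raises(ValueError, match="zero occupancy"):
            leida.regional_contribution(vectors, np.ones(5, dtype=int), 0, mode=2)

    def test_arithmetic_mean(self):
        vectors = np.zeros((2, 3))
        vectors[1] = [0.1, 0.2, 0.3]
        val, _ = leida.regional_contribution(vectors, np.array([1, 1, 1]), 1, 1)
        assert val == pytest.approx(0.2)
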
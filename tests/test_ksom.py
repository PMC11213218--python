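"""Hexagonal-lattice geometry, batch SOM training, BMU lookup, hit maps."""

import numpy as np
import pytest

from dcepnms import (
    DegenerateInputError,
    DomainError,
    PKParams,
    SOMConfig,
    batch_train,
    compute_hitmap,
    eval_model,
    find_bmu,
    hex_distances,
    init_weights,
    normalize_profiles,
    quantization_error,
)
from dcepnms.ksom import SOMWeights, bmu_indices


def small_config(**kw):
    defaults = dict(rows=4, cols=4, ordering_steps=20, max_epochs=60)
    defaults.update(kw)
    return SOMConfig(**defaults)


class TestHexGeometry:
    def test_1x2_grid(self):
        g = hex_distances(SOMConfig(rows=1, cols=2))
        assert g.distances[0, 1] == pytest.approx(1.0)

    def test_2x2_hand_computed_distances(self):
        # positions: (0,0), (1,0), (0.5, sqrt3/2), (1.5, sqrt3/2)
        g = hex_distances(SOMConfig(rows=2, cols=2))
        expect = {
            (0, 1): 1.0, (0, 2): 1.0, (0, 3): np.sqrt(3.0),
            (1, 2): 1.0, (1, 3): 1.0, (2, 3): 1.0,
        }
        for (i, j), d in expect.items():
            assert g.distances[i, j] == pytest.approx(d)

    def test_default_8x8_grid(self):
        g = hex_distances(SOMConfig())
        assert g.n_neurons == 64
        assert g.distances.max() < 11.0

    def test_distance_matrix_is_a_metric(self):
        d = hex_distances(SOMConfig(rows=4, cols=4)).distances
        np.testing.assert_allclose(d, d.T)
        assert np.all(np.diag(d) == 0)
        # triangle inequality over all triples
        assert np.all(d[:, None, :] + d[None, :, :] >= d[:, :, None] - 1e-12)

    def test_interior_nearest_neighbor_distance_is_one(self):
        g = hex_distances(SOMConfig(rows=5, cols=5))
        d = g.distances + np.eye(g.n_neurons) * 1e6
        np.testing.assert_allclose(d.min(axis=1), 1.0)


class TestInitWeights:
    def test_rank1_data_prototypes_on_line(self):
        rng = np.random.default_rng(0)
        direction = rng.normal(size=10)
        direction /= np.linalg.norm(direction)
        data = np.outer(rng.uniform(-3, 3, 40), direction)
        w = init_weights(data, small_config()).weights
        # residual after projecting onto the line should vanish
        proj = np.outer(w @ direction, direction)
        assert np.abs(w - proj).max() < 1e-9

    def test_deterministic(self):
        rng = np.random.default_rng(1)
        data = rng.normal(size=(50, 8))
        w1 = init_weights(data, small_config()).weights
        w2 = init_weights(data, small_config()).weights
        np.testing.assert_array_equal(w1, w2)

    def test_identical_data_rejected(self):
        with pytest.raises(DegenerateInputError):
            init_weights(np.ones((10, 5)), small_config())

    def test_principal_plane_matches_eigendecomposition_oracle(self):
        rng = np.random.default_rng(2)
        centers = np.array([[3.0] + [0.0] * 7, [-3.0] + [0.0] * 7])
        data = np.vstack([c + 0.3 * rng.normal(size=(30, 8)) for c in centers])
        w = init_weights(data, small_config()).weights
        mu = data.mean(axis=0)
        cov = np.cov(data.T)
        evals, evecs = np.linalg.eigh(cov)
        plane = evecs[:, np.argsort(evals)[::-1][:2]]  # oracle basis
        resid = (w - mu) - (w - mu) @ plane @ plane.T
        assert np.abs(resid).max() < 1e-9


class TestBMU:
    @pytest.fixture()
    def toy_weights(self):
        rng = np.random.default_rng(3)
        cfg = small_config()
        return SOMWeights(weights=rng.normal(size=(16, 6)),
                          config=cfg, grid=hex_distances(cfg))

    def test_profile_equal_to_prototype(self, toy_weights):
        assert find_bmu(toy_weights, toy_weights.weights[11]) == 11

    def test_tie_breaks_to_lowest_index(self):
        cfg = SOMConfig(rows=1, cols=3, initial_radius=1, ordering_steps=1,
                        max_epochs=1)
        w = SOMWeights(weights=np.array([[1.0], [-1.0], [1.0]]),
                       config=cfg, grid=hex_distances(cfg))
        assert find_bmu(w, np.array([0.0])) == 0  # 0 and 1 equidistant

    def test_matches_exhaustive_scan_oracle(self, toy_weights):
        rng = np.random.default_rng(4)
        for _ in range(50):
            x = rng.normal(size=6)
            dists = [np.linalg.norm(x - p) for p in toy_weights.weights]
            assert find_bmu(toy_weights, x) == int(np.argmin(dists))

    def test_batch_bmu_agrees_with_single(self, toy_weights):
        rng = np.random.default_rng(5)
        xs = rng.normal(size=(20, 6))
        batch = bmu_indices(toy_weights, xs)
        singles = [find_bmu(toy_weights, x) for x in xs]
        np.testing.assert_array_equal(batch, singles)

    def test_nonfinite_profile_rejected(self, toy_weights):
        with pytest.raises(DomainError):
            find_bmu(toy_weights, np.full(6, np.nan))


class TestBatchTrain:
    def test_single_repeated_profile_fixed_point(self):
        data = np.tile(np.array([1.0, -2.0, 0.5]), (20, 1))
        data[0, 0] += 1e-9  # avoid the all-identical degenerate case
        w = batch_train(data, small_config()).weights
        assert np.abs(w - data.mean(axis=0)).max() < 1e-6

    def test_quantization_error_improves_over_init(self):
        rng = np.random.default_rng(6)
        data = rng.normal(size=(200, 12))
        cfg = small_config()
        w0 = init_weights(data, cfg)
        wT = batch_train(data, cfg)
        assert quantization_error(wT, data) <= quantization_error(w0, data)

    def test_three_separated_clusters_get_disjoint_neurons(self):
        rng = np.random.default_rng(7)
        centers = np.eye(3) * 20.0
        data = np.vstack([c + 0.2 * rng.normal(size=(40, 3)) for c in centers])
        w = batch_train(data, small_config())
        sets = [set(bmu_indices(w, data[i * 40:(i + 1) * 40]).tolist())
                for i in range(3)]
        assert not (sets[0] & sets[1] or sets[0] & sets[2] or sets[1] & sets[2])

    def test_determinism(self):
        rng = np.random.default_rng(8)
        data = rng.normal(size=(100, 5))
        w1 = batch_train(data, small_config()).weights
        w2 = batch_train(data, small_config()).weights
        np.testing.assert_array_equal(w1, w2)

    def test_empty_data_rejected(self):
        with pytest.raises(DegenerateInputError):
            batch_train(np.empty((0, 5)), small_config())

    def test_topology_preservation_on_kep_sweep(self, small_grid, small_aif):
        """Profiles from a smooth one-parameter family (a kep sweep of the
        back-flux model) that are neighbors in input space should map to
        nearby neurons: >= 90% of consecutive pairs within lattice
        distance 2 on the default 8x8 map."""
        keps = np.linspace(0.5, 2.5, 150)
        traces = np.stack([
            eval_model(PKParams(vp=0.01, ktrans=0.15, kep=k, model_order=3),
                       small_aif)
            for k in keps
        ])
        profiles, _ = normalize_profiles(traces, small_grid)
        w = batch_train(profiles, SOMConfig())
        bmu = bmu_indices(w, profiles)
        d = w.grid.distances
        pair_d = np.array([d[bmu[i], bmu[i + 1]] for i in range(len(bmu) - 1)])
        assert (pair_d <= 2.0).mean() >= 0.90


class TestHitMap:
    def test_all_profiles_one_neuron(self):
        cfg = small_config()
        w = batch_train(np.random.default_rng(9).normal(size=(30, 4)), cfg)
        x = np.tile(w.weights[5], (7, 1))
        hm = compute_hitmap(w, x, np.array([1, 1, 2, 2, 3, 3, 3]))
        assert hm.total[5] == 7
        assert hm.total.sum() == 7
        np.testing.assert_array_equal(hm.per_label[5], [2, 2, 3])

    def test_empty_label_subset_gives_zero_column(self):
        cfg = small_config()
        rng = np.random.default_rng(10)
        data = rng.normal(size=(25, 4))
        w = batch_train(data, cfg)
        hm = compute_hitmap(w, data, np.ones(25, dtype=int))
        assert hm.per_label[:, 1].sum() == 0 and hm.per_label[:, 2].sum() == 0

    def test_counts_match_per_profile_tally_oracle(self):
        cfg = small_config()
        rng = np.random.default_rng(11)
        data = rng.normal(size=(60, 4))
        labels = rng.integers(1, 4, size=60)
        w = batch_train(data, cfg)
        hm = compute_hitmap(w, data, labels)
        tally = np.zeros((16, 3), dtype=int)
        for x, l in zip(data, labels):
            tally[find_bmu(w, x), l - 1] += 1
        np.testing.assert_array_equal(hm.per_label, tally)
        assert hm.total.sum() == 60  # hit conservation

    def test_invalid_label_rejected(self):
        cfg = small_config()
        data = np.random.default_rng(12).normal(size=(10, 4))
        w = batch_train(data, cfg)
        with pytest.raises(DomainError):
            compute_hitmap(w, data, np.full(10, 4))


class TestQuantizationError:
    def test_zero_when_prototypes_equal_data(self):
        cfg = small_config()
        rng = np.random.default_rng(13)
        data = rng.normal(size=(16, 4))
        w = SOMWeights(weights=data.copy(), config=cfg, grid=hex_distances(cfg))
        assert quantization_error(w, data) == 0.0

    def test_matches_direct_recomputation(self):
        cfg = small_config()
        rng = np.random.default_rng(14)
        data = rng.normal(size=(40, 4))
        w = batch_train(data, cfg)
        bmu = bmu_indices(w, data)
        direct = np.mean([np.linalg.norm(x - w.weights[b])
                          for x, b in zip(data, bmu)])
        assert quantization_error(w, data) == pytest.approx(direct, rel=1e-12)


class TestConfigValidation:
    @pytest.mark.parametrize("kw", [
        dict(rows=1, cols=1),
        dict(initial_radius=0.5),
        dict(ordering_steps=300),
        dict(layout="square"),
        dict(init="fancy"),
    ])
    def test_invalid_configs_rejected(self, kw):
        with pytest.raises(DomainError):
            SOMConfig(**kw)
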
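import numpy as np
import pytest

from somdisplace.fixtures import orthogonal_profiles
from somdisplace.som_engine import (
    GridSize,
    SOMModel,
    best_matching_unit,
    neuron_correlations,
    quantization_error,
    train_som,
)

from conftest import make_model, make_table


class TestTrainSom:
    def test_single_variable_converges_onto_it(self):
        t = make_table([[-1.0, 0.0, 1.0]])
        with pytest.warns(UserWarning, match="empty"):
            model = train_som(t, GridSize(1, 2), n_epochs=100, seed=0)
        bmu = best_matching_unit(model, t.values[0])
        np.testing.assert_allclose(model.prototype(bmu), t.values[0], atol=1e-6)
        assert model.training_assignments["g1"] == bmu

    def test_two_orthogonal_profiles_match_kmeans_centroids(self):
        from sklearn.cluster import KMeans

        profiles = orthogonal_profiles(m=6, k=2, seed=1)
        data = np.repeat(profiles, 4, axis=0)
        t = make_table(data)
        model = train_som(t, GridSize(1, 2), n_epochs=200, seed=0)
        km = KMeans(n_clusters=2, n_init=10, random_state=0).fit(data)
        # match each codebook row to its nearest k-means centroid
        for row in model.codebook:
            dists = np.linalg.norm(km.cluster_centers_ - row, axis=1)
            centroid = km.cluster_centers_[np.argmin(dists)]
            r = np.corrcoef(row, centroid)[0, 1]
            assert r > 0.99
        # one neuron per profile
        bmus = {best_matching_unit(model, p) for p in profiles}
        assert bmus == {1, 2}

    def test_deterministic_for_fixed_seed(self):
        rng = np.random.default_rng(5)
        t = make_table(rng.normal(size=(30, 6)))
        m1 = train_som(t, GridSize(2, 2), n_epochs=50, seed=9)
        m2 = train_som(t, GridSize(2, 2), n_epochs=50, seed=9)
        assert np.array_equal(m1.codebook, m2.codebook)
        assert m1.training_assignments == m2.training_assignments

    def test_assignments_cover_all_variables(self):
        rng = np.random.default_rng(0)
        t = make_table(rng.normal(size=(20, 5)))
        model = train_som(t, GridSize(2, 2), seed=1)
        assert set(model.training_assignments) == set(t.variable_ids)
        assert all(1 <= v <= 4 for v in model.training_assignments.values())

    def test_quantization_error_non_increasing_with_grid_size(self):
        rng = np.random.default_rng(42)
        data = rng.normal(size=(60, 6))
        t = make_table(data)
        grids = [GridSize(1, 2), GridSize(2, 2), GridSize(3, 2), GridSize(3, 3)]
        mean_qe = []
        for g in grids:
            qes = [
                quantization_error(train_som(t, g, n_epochs=60, seed=s), t)
                for s in range(5)
            ]
            mean_qe.append(np.mean(qes))
        assert all(b <= a + 1e-9 for a, b in zip(mean_qe, mean_qe[1:]))


class TestBestMatchingUnit:
    def test_exact_codebook_row_wins(self):
        rng = np.random.default_rng(3)
        cb = rng.normal(size=(9, 5))
        model = make_model(cb, 3, 3)
        assert best_matching_unit(model, cb[6]) == 7

    def test_tie_breaks_to_lowest_neuron_id(self):
        cb = np.full((6, 3), 10.0)
        cb[1] = [1.0, 0.0, 0.0]
        cb[4] = [-1.0, 0.0, 0.0]
        model = make_model(cb, 2, 3)
        # profile equidistant from neurons 2 and 5, far from the rest
        assert best_matching_unit(model, np.array([0.0, 1.0, 0.0])) == 2

    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(7)
        cb = rng.normal(size=(12, 6))
        model = make_model(cb, 3, 4)
        for profile in rng.normal(size=(1000, 6)):
            expected = 1 + min(
                range(12), key=lambda j: float(np.sum((cb[j] - profile) ** 2))
            )
            assert best_matching_unit(model, profile) == expected

    def test_non_finite_profile_rejected(self):
        model = make_model(np.zeros((4, 3)), 2, 2)
        with pytest.raises(ValueError, match="non-finite"):
            best_matching_unit(model, np.array([1.0, np.nan, 0.0]))


class TestNeuronCorrelations:
    def test_identical_and_negated_rows(self):
        base = np.array([1.0, 3.0, 2.0, 5.0])
        cb = np.vstack([base, base, -base, np.zeros(4)])
        corr = neuron_correlations(make_model(cb, 2, 2))
        assert corr.values[0, 1] == pytest.approx(1.0, abs=1e-12)
        assert corr.values[0, 2] == pytest.approx(-1.0, abs=1e-12)
        # constant prototype: flagged, correlations forced to 0, diagonal 1
        assert corr.zero_variance[3]
        assert corr.values[3, 0] == 0.0
        assert corr.values[3, 3] == 1.0

    def test_matches_direct_pearson_formula(self):
        rng = np.random.default_rng(11)
        cb = rng.normal(size=(6, 7))
        corr = neuron_correlations(make_model(cb, 2, 3))
        for i in range(6):
            for j in range(6):
                x, y = cb[i] - cb[i].mean(), cb[j] - cb[j].mean()
                expected = np.dot(x, y) / np.sqrt(np.dot(x, x) * np.dot(y, y))
                assert corr.values[i, j] == pytest.approx(expected, abs=1e-12)
        assert np.abs(corr.values - corr.values.T).max() < 1e-12
        assert np.abs(np.diag(corr.values) - 1).max() < 1e-12


def test_serialization_round_trip_is_bit_exact(tmp_path):
    rng = np.random.default_rng(2)
    t = make_table(rng.normal(size=(25, 5)))
    model = train_som(t, GridSize(2, 3), n_epochs=40, seed=4)
    path = tmp_path / "model.json"
    model.save(path)
    back = SOMModel.load(path)
    assert np.array_equal(back.codebook, model.codebook)  # bit-exact
    assert back.training_assignments == model.training_assignments
    assert back.grid == model.grid
    assert back.seed == model.seed


def test_grid_positions_are_row_major_from_top_left():
    g = GridSize(2, 3)
    model = make_model(np.zeros((6, 3)), 2, 3)
    assert model.neuron_position(1) == (0, 0)
    assert model.neuron_position(3) == (0, 2)
    assert model.neuron_position(4) == (1, 0)
    assert g.positions().tolist() == [[0, 0], [0, 1], [0, 2], [1, 0], [1, 1], [1, 2]]
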
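"""Kohonen map: learning schedule, winner search, updates, training."""

import numpy as np
import pandas as pd
import pytest

import cpannet as cp
from cpannet.som import SOMGrid, _neighborhood_factors


def make_grid(rows=3, cols=3, m=2, seed=0, **cfg):
    config = cp.SOMConfig(rows=rows, cols=cols, seed=seed, **cfg)
    rng = np.random.default_rng(seed)
    return SOMGrid(weights=rng.random((rows * cols, m)),
                   feature_names=tuple(f"d{i}" for i in range(m)), config=config)


class TestLearningRate:
    def test_endpoints(self):
        config = cp.SOMConfig(rows=2, cols=2, t_max=100, a_max=0.5, a_min=0.01)
        assert cp.learning_rate(1, config) == pytest.approx(0.5)
        assert cp.learning_rate(100, config) == pytest.approx(0.01)

    def test_midpoint_value(self):
        # direct substitution: (0.5 - 0.01) * (100 - 50) / 99 + 0.01
        config = cp.SOMConfig(rows=2, cols=2, t_max=100, a_max=0.5, a_min=0.01)
        expected = 0.49 * 50 / 99 + 0.01
        assert cp.learning_rate(50, config) == pytest.approx(expected, abs=1e-12)

    def test_strictly_decreasing_and_affine(self):
        config = cp.SOMConfig(rows=2, cols=2, t_max=40, a_max=0.8, a_min=0.05)
        rates = [cp.learning_rate(t, config) for t in range(1, 41)]
        diffs = np.diff(rates)
        assert (diffs < 0).all()
        assert np.allclose(np.diff(diffs), 0.0, atol=1e-12)

    def test_out_of_range_epoch_rejected(self):
        config = cp.SOMConfig(rows=2, cols=2, t_max=10)
        with pytest.raises(ValueError):
            cp.learning_rate(0, config)
        with pytest.raises(ValueError):
            cp.learning_rate(11, config)


class TestFindWinner:
    def test_exact_weight_match_wins_with_zero_distance(self):
        grid = make_grid(3, 3, 4, seed=1)
        coords, dist = cp.find_winner(grid, grid.weights[5])
        assert coords == grid.coords(5)
        assert dist == pytest.approx(0.0)

    def test_tie_breaks_to_first_in_row_major_order(self):
        config = cp.SOMConfig(rows=1, cols=2)
        grid = SOMGrid(weights=np.array([[1.0], [-1.0]]), feature_names=("d0",),
                       config=config)
        coords, _ = cp.find_winner(grid, [0.0])  # both neurons at distance 1
        assert coords == (0, 0)

    def test_agrees_with_brute_force_scan(self, rng):
        for _ in range(100):
            rows, cols, m = rng.integers(1, 6), rng.integers(1, 6), rng.integers(1, 5)
            grid = make_grid(int(rows), int(cols), int(m), seed=int(rng.integers(1e6)))
            x = rng.standard_normal(int(m))
            coords, dist = cp.find_winner(grid, x)
            best = min(range(grid.weights.shape[0]),
                       key=lambda j: float(((grid.weights[j] - x) ** 2).sum()))
            assert grid.neuron_index(coords) == best
            assert dist == pytest.approx(
                float(np.sqrt(((grid.weights[best] - x) ** 2).sum())))

    def test_dimension_mismatch_rejected(self):
        grid = make_grid(2, 2, 3)
        with pytest.raises(ValueError, match="dimension"):
            cp.find_winner(grid, [0.0, 1.0])


class TestTopology:
    def test_distance_to_self_is_zero(self):
        assert cp.topological_distance((2, 2), (2, 2)) == 0

    def test_diagonal_neighbour_is_ring_one(self):
        assert cp.topological_distance((0, 0), (1, 1)) == 1

    def test_corner_has_three_ring_one_neighbours(self):
        neighbours = [
            (r, c) for r in range(5) for c in range(5)
            if cp.topological_distance((0, 0), (r, c)) == 1
        ]
        assert len(neighbours) == 3  # non-toroidal corner


class TestUpdateWeights:
    def test_full_rate_maps_winner_onto_input(self):
        """With eta*a = 1 the winner's weights become exactly the input."""
        config = cp.SOMConfig(rows=2, cols=2, t_max=5, a_max=1.0, a_min=1.0)
        rng = np.random.default_rng(0)
        grid = SOMGrid(weights=rng.random((4, 3)), feature_names=("a", "b", "c"),
                       config=config)
        x = np.array([5.0, -2.0, 0.5])
        cp.update_weights(grid, x, winner=(1, 1), t=1, radius_t=0.0)
        assert np.allclose(grid.weights[3], x)

    def test_neurons_outside_radius_untouched(self):
        grid = make_grid(5, 5, 2, seed=3, t_max=10, a_max=0.5, a_min=0.1)
        before = grid.weights.copy()
        cp.update_weights(grid, [0.3, 0.4], winner=(0, 0), t=1, radius_t=1.0)
        far = [grid.neuron_index((r, c)) for r in range(5) for c in range(5)
               if max(r, c) > 1]
        assert np.array_equal(grid.weights[far], before[far])

    def test_update_contracts_distance_to_input(self):
        grid = make_grid(4, 4, 3, seed=4, t_max=20, a_max=0.6, a_min=0.01)
        x = np.array([2.0, 2.0, 2.0])
        winner, d_before = cp.find_winner(grid, x)
        cp.update_weights(grid, x, winner, t=5, radius_t=2.0)
        _, d_after = cp.find_winner(grid, x)
        assert d_after < d_before

    def test_update_is_convex_combination(self):
        grid = make_grid(3, 3, 2, seed=5, t_max=10, a_max=0.9, a_min=0.1)
        x = np.array([10.0, -10.0])
        before = grid.weights.copy()
        cp.update_weights(grid, x, winner=(1, 1), t=2, radius_t=2.0)
        # every component stays between its old value and the input value
        lo = np.minimum(before, x)
        hi = np.maximum(before, x)
        assert (grid.weights >= lo - 1e-12).all()
        assert (grid.weights <= hi + 1e-12).all()

    def test_triangular_factor_shape(self):
        idx, a = _neighborhood_factors(5, 5, (2, 2), radius=2.0)
        assert len(idx) == 25  # whole 5x5 grid is within radius 2 of the centre
        assert a.max() == pytest.approx(1.0)
        assert a.min() == pytest.approx(1.0 - 2.0 / 3.0)


class TestTrainSom:
    def test_identical_compounds_converge_to_common_vector(self):
        X = np.tile([0.4, -0.2, 0.9], (12, 1))
        grid = cp.train_som(X, cp.SOMConfig(rows=3, cols=3, t_max=60, seed=0))
        top = cp.build_top_map(grid, X)
        assert (top.occupancy > 0).sum() == 1
        winner = grid.weights[top.occupancy.ravel().argmax()]
        # winner coordinates: occupancy only marks one neuron
        r, c = np.argwhere(top.occupancy > 0)[0]
        assert np.allclose(grid.weights[grid.neuron_index((r, c))], X[0], atol=0.01)

    def test_separated_clusters_get_disjoint_winner_sets(self, rng):
        a = rng.standard_normal((40, 3))
        b = rng.standard_normal((40, 3)) + 10.0
        X = np.vstack([a, b])
        grid = cp.train_som(X, cp.SOMConfig(rows=10, cols=10, t_max=40, seed=2))
        top = cp.build_top_map(grid, X)
        winners_a = set(map(tuple, top.assignments.iloc[:40][["row", "col"]].to_numpy()))
        winners_b = set(map(tuple, top.assignments.iloc[40:][["row", "col"]].to_numpy()))
        assert not winners_a & winners_b

    def test_quantization_error_decreases_over_training(self, rng):
        X = rng.standard_normal((60, 4))
        grid = cp.train_som(X, cp.SOMConfig(rows=6, cols=6, t_max=50, seed=3))
        assert grid.qe_history[-1] <= grid.qe_history[0]

    def test_training_equivariant_to_descriptor_permutation(self, rng):
        X = rng.standard_normal((30, 5))
        perm = [3, 0, 4, 1, 2]
        config = cp.SOMConfig(rows=4, cols=4, t_max=25, seed=7)
        grid = cp.train_som(X, config)
        grid_p = cp.train_som(X[:, perm], config)
        assert np.allclose(grid_p.weights, grid.weights[:, perm])

    def test_empty_data_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            cp.train_som(np.empty((0, 3)), cp.SOMConfig(rows=2, cols=2))


class TestTopMap:
    def test_single_compound_occupies_one_neuron(self):
        grid = make_grid(3, 3, 2, seed=8)
        top = cp.build_top_map(grid, np.array([[0.1, 0.2]]))
        assert top.occupancy.sum() == 1
        assert (top.occupancy > 0).sum() == 1

    def test_occupancy_conserves_compound_count(self, rng):
        grid = make_grid(4, 4, 3, seed=9)
        X = rng.standard_normal((57, 3))
        top = cp.build_top_map(grid, X)
        assert top.occupancy.sum() == 57

    def test_majority_classes_form_contiguous_regions(self, small_dataset, rng):
        """Neighbouring neurons agree on class more often than under a random
        relabelling of the occupied neurons."""
        from cpannet.preprocess import autoscale, filter_correlated, filter_low_variance

        table, _ = filter_low_variance(small_dataset.table)
        table, _ = filter_correlated(table)
        scaled, _ = autoscale(table)
        grid = cp.train_som(scaled, cp.SOMConfig(rows=8, cols=8, t_max=40, seed=4))
        top = cp.build_top_map(grid, scaled, small_dataset.labels)

        def agreement(mapping):
            pairs = agree = 0
            for (r, c), lab in mapping.items():
                for dr, dc in ((0, 1), (1, 0), (1, 1), (1, -1)):
                    nb = (r + dr, c + dc)
                    if nb in mapping:
                        pairs += 1
                        agree += mapping[nb] == lab
            return agree / pairs

        observed = agreement(top.majority_class)
        coords = list(top.majority_class)
        labs = list(top.majority_class.values())
        null = []
        for _ in range(30):
            shuffled = [labs[i] for i in rng.permutation(len(labs))]
            null.append(agreement(dict(zip(coords, shuffled))))
        assert observed > np.mean(null)


class TestSerialization:
    def test_grid_round_trips_through_json(self, tmp_path):
        grid = make_grid(3, 4, 5, seed=10)
        grid.qe_history = [0.5, 0.4]
        path = tmp_path / "grid.json"
        grid.to_json(path)
        back = SOMGrid.from_json(path)
        assert np.array_equal(back.weights, grid.weights)
        assert back.feature_names == grid.feature_names
        assert back.config == grid.config
        assert back.qe_history == grid.qe_history
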
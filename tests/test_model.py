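"""Counter-propagation ANN training, prediction and serialization."""

import numpy as np
import pandas as pd
import pytest

import cpannet as cp
from cpannet.model import CPANNModel, one_hot_targets


class TestTargets:
    def test_one_hot_rows(self):
        labels = pd.Series(["substrate", "inhibitor", "non_active"],
                           index=["c1", "c2", "c3"])
        y = one_hot_targets(labels)
        assert (y.sum(axis=1) == 1.0).all()
        assert y.loc["c1", "substrate"] == 1.0
        assert set(np.unique(y.to_numpy())) == {0.0, 1.0}

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            one_hot_targets(pd.Series(["mystery"]))


class TestTraining:
    def test_single_compound_output_converges_to_target(self):
        x = pd.DataFrame({"a": [0.3], "b": [-0.1]}, index=["c1"])
        labels = pd.Series(["substrate"], index=["c1"])
        config = cp.SOMConfig(rows=1, cols=1, t_max=300, a_max=0.9, a_min=0.2, seed=0)
        model = cp.train_cpann(x, labels, config)
        scores = model.output_weights[0]
        target = np.array([0.0, 1.0, 0.0])  # class order: inhibitor, substrate, non_active
        assert np.allclose(scores, target, atol=1e-3)

    def test_uniform_targets_pull_every_neuron(self):
        rng = np.random.default_rng(1)
        x = pd.DataFrame(rng.standard_normal((20, 3)), columns=["a", "b", "c"])
        labels = pd.Series(["inhibitor"] * 20, index=x.index)
        config = cp.SOMConfig(rows=3, cols=3, t_max=150, a_max=0.8, a_min=0.1, seed=2)
        model = cp.train_cpann(x, labels, config, classes=cp.CLASS_NAMES)
        inhibitor_scores = model.output_weights[:, 0]
        assert (inhibitor_scores > 0.9).all()

    def test_output_weights_bounded_in_unit_interval(self, separable_run):
        u = separable_run["model"].output_weights
        assert (u >= 0.0).all() and (u <= 1.0).all()

    def test_output_layer_matches_kohonen_shape(self, separable_run):
        model = separable_run["model"]
        assert model.output_weights.shape == (
            model.kohonen.config.n_neurons, len(model.class_names))

    def test_training_ner_high_on_separable_data(self, separable_run):
        scaled = separable_run["scaled"]
        labels = separable_run["data"].labels
        split = separable_run["split"]
        _, frame = cp.predict_batch(
            separable_run["model"],
            separable_run["data"].table.loc[split.tr], labels.loc[split.tr])
        rep = cp.global_report(list(frame["true"]), list(frame["predicted"]))
        assert rep.ner >= 95.0

    def test_misaligned_rows_rejected(self):
        x = pd.DataFrame({"a": [0.1, 0.2]}, index=["c1", "c2"])
        labels = pd.Series(["inhibitor"], index=["c1"])
        with pytest.raises(ValueError, match="rows"):
            cp.train_cpann(x, labels, cp.SOMConfig(rows=2, cols=2, t_max=2))

    def test_two_phase_mode_trains_equivalent_kohonen(self):
        rng = np.random.default_rng(3)
        x = pd.DataFrame(rng.standard_normal((30, 4)),
                         columns=["a", "b", "c", "d"])
        labels = pd.Series(["inhibitor"] * 15 + ["substrate"] * 15, index=x.index)
        config = cp.SOMConfig(rows=4, cols=4, t_max=40, a_max=0.6, a_min=0.01, seed=4)
        joint = cp.train_cpann(x, labels, config)
        phased = cp.train_cpann(x, labels, config, two_phase=True)
        assert np.allclose(phased.kohonen.weights, joint.kohonen.weights)
        assert (phased.output_weights >= 0).all() and (phased.output_weights <= 1).all()


class TestPredict:
    def _toy_model(self, outputs):
        config = cp.SOMConfig(rows=1, cols=1, t_max=2)
        grid = cp.SOMGrid(weights=np.zeros((1, 2)), feature_names=("a", "b"),
                          config=config)
        return CPANNModel(kohonen=grid, output_weights=np.array([outputs]),
                          class_names=cp.CLASS_NAMES)

    def test_single_score_above_threshold(self):
        p = cp.predict(self._toy_model([0.9, 0.2, 0.1]), {"a": 0.0, "b": 0.0})
        assert p.assigned_class == "inhibitor"
        assert p.above_threshold == ("inhibitor",)
        assert p.flag == "ok"

    def test_all_below_threshold_flags_argmax(self):
        p = cp.predict(self._toy_model([0.4, 0.3, 0.3]), {"a": 0.0, "b": 0.0})
        assert p.assigned_class == "inhibitor"
        assert p.above_threshold == ()
        assert p.flag == "below-threshold"

    def test_multiple_above_threshold_flags_ambiguous(self):
        p = cp.predict(self._toy_model([0.8, 0.7, 0.1]), {"a": 0.0, "b": 0.0})
        assert p.flag == "ambiguous"
        assert set(p.above_threshold) == {"inhibitor", "substrate"}

    def test_missing_descriptor_named_in_error(self, separable_run):
        model = separable_run["model"]
        incomplete = separable_run["data"].table.iloc[0].drop(
            model.selected_descriptors[0])
        with pytest.raises(KeyError, match=model.selected_descriptors[0]):
            cp.predict(model, incomplete)

    def test_pure_neuron_returns_true_class(self, separable_run):
        """A training compound whose neuron hosts only its own class must be
        assigned that class."""
        model = separable_run["model"]
        data = separable_run["data"]
        split = separable_run["split"]
        scaled_tr = separable_run["scaled"].loc[split.tr]
        labels_tr = data.labels.loc[split.tr]
        top = cp.build_top_map(model.kohonen, scaled_tr, labels_tr)
        checked = 0
        for cid in split.tr[:60]:
            coords = (top.assignments.loc[cid, "row"], top.assignments.loc[cid, "col"])
            members = top.members((int(coords[0]), int(coords[1])))
            klass = {labels_tr[m] for m in members}
            if len(klass) == 1:
                p = cp.predict(model, data.table.loc[cid], compound_id=cid)
                assert p.assigned_class == labels_tr[cid]
                checked += 1
        assert checked > 0


class TestPredictBatch:
    def test_empty_table_gives_empty_results(self, separable_run):
        model = separable_run["model"]
        empty = separable_run["data"].table.iloc[:0]
        preds, frame = cp.predict_batch(model, empty)
        assert preds == [] and len(frame) == 0

    def test_batch_equals_single_predictions(self, separable_run):
        model = separable_run["model"]
        sub = separable_run["data"].table.iloc[:25]
        preds, frame = cp.predict_batch(model, sub)
        for cid, p in zip(sub.index, preds):
            single = cp.predict(model, sub.loc[cid], compound_id=cid)
            assert single.assigned_class == p.assigned_class
            assert np.allclose(single.outputs, p.outputs)
        assert list(frame.index) == list(sub.index)

    def test_batch_counts_match_top_map_majority_census(self, separable_run):
        model = separable_run["model"]
        split = separable_run["split"]
        scaled_tr = separable_run["scaled"].loc[split.tr]
        labels_tr = separable_run["data"].labels.loc[split.tr]
        top = cp.build_top_map(model.kohonen, scaled_tr, labels_tr)
        _, frame = cp.predict_batch(
            model, separable_run["data"].table.loc[split.tr], labels_tr)
        # census: per compound the majority class of its winning neuron
        census = []
        for cid in split.tr:
            coords = (int(top.assignments.loc[cid, "row"]),
                      int(top.assignments.loc[cid, "col"]))
            census.append(top.majority_class[coords])
        census = pd.Series(census, index=pd.Index(split.tr))
        agree = (frame["predicted"] == census).mean()
        assert agree > 0.9  # scores come from neighbourhood-smoothed weights


class TestDeterminismAndSerialization:
    def test_retraining_reproduces_predictions(self, separable_run):
        scaled = separable_run["scaled"]
        labels = separable_run["data"].labels
        split = separable_run["split"]
        config = cp.SOMConfig(rows=12, cols=12, t_max=100, a_max=0.6, a_min=0.001,
                              seed=7)
        again = cp.train_cpann(scaled.loc[split.tr], labels.loc[split.tr], config,
                               scaling=separable_run["params"])
        assert np.array_equal(again.kohonen.weights,
                              separable_run["model"].kohonen.weights)
        assert np.array_equal(again.output_weights,
                              separable_run["model"].output_weights)

    def test_json_round_trip(self, tmp_path, separable_run):
        model = separable_run["model"]
        path = tmp_path / "model.json"
        model.to_json(path)
        back = CPANNModel.from_json(path)
        assert np.allclose(back.kohonen.weights, model.kohonen.weights)
        assert np.allclose(back.output_weights, model.output_weights)
        assert back.class_names == model.class_names
        assert back.selected_descriptors == model.selected_descriptors
        x = separable_run["data"].table.iloc[0]
        assert cp.predict(back, x).assigned_class == cp.predict(model, x).assigned_class
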
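"""Counter-propagation artificial neural network (CP-ANN) classifier.

A CP-ANN couples an unsupervised Kohonen layer with a supervised output
layer of identical grid shape. For every presented compound the winner is
located from the descriptors only; the Kohonen weights of the winner's
neighbourhood move toward the descriptor vector, and — in the same step,
with the same learning-rate/neighbourhood factor — the output weights of
that neighbourhood move toward the compound's one-hot class target. Because
the output weights start uniform in [0, 1) and every update is a convex pull
toward a {0, 1} target, they stay inside [0, 1] and read as bounded class
scores.

Prediction maps a (scaled) compound to its winning neuron and returns that
neuron's output-weight vector. A score above 0.5 marks predicted class
membership; the single assigned label is the argmax, flagged when zero or
several classes clear the threshold.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from cpannet.data import CLASS_NAMES
from cpannet.preprocess import ScalingParams
from cpannet.som import SOMConfig, SOMGrid, _as_matrix, _batch_winners, _fit, find_winner

__all__ = [
    "TargetMatrix",
    "CPANNModel",
    "Prediction",
    "one_hot_targets",
    "train_cpann",
    "predict",
    "predict_batch",
    "FINAL_MODEL_DEFAULTS",
]

#: Network parameters of the reference selected model: 43x43 neurons,
#: 600 epochs, learning rate 0.6 -> 0.001.
FINAL_MODEL_DEFAULTS = SOMConfig(rows=43, cols=43, t_max=600, a_max=0.6, a_min=0.001)

#: Class-membership threshold on the continuous [0, 1] outputs.
SCORE_THRESHOLD = 0.5


def one_hot_targets(labels, classes: tuple[str, ...] = CLASS_NAMES) -> pd.DataFrame:
    """One-hot target matrix: 1 for the compound's class, 0 elsewhere."""
    labels = pd.Series(labels) if not isinstance(labels, pd.Series) else labels
    unknown = set(labels.unique()) - set(classes)
    if unknown:
        raise ValueError(f"label(s) outside the class list: {sorted(unknown)}")
    out = pd.DataFrame(0.0, index=labels.index, columns=list(classes))
    for c in classes:
        out.loc[labels == c, c] = 1.0
    return out


TargetMatrix = pd.DataFrame  # alias: one-hot rows over the class columns


@dataclass
class CPANNModel:
    """Trained CP-ANN: Kohonen grid + output layer + input bookkeeping.

    ``output_weights`` has shape (n_neurons, G) in row-major neuron order,
    one-to-one with the Kohonen neurons. ``scaling``, when present, is
    applied to raw inputs before the winner search; ``selected_descriptors``
    fixes the input components and their order.
    """

    kohonen: SOMGrid
    output_weights: np.ndarray
    class_names: tuple[str, ...]
    scaling: ScalingParams | None = None
    selected_descriptors: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.output_weights = np.asarray(self.output_weights, dtype=float)
        if self.output_weights.shape != (self.kohonen.config.n_neurons, len(self.class_names)):
            raise ValueError("output layer must match the Kohonen grid one-to-one")
        if not self.selected_descriptors:
            self.selected_descriptors = self.kohonen.feature_names

    def to_dict(self) -> dict:
        return {
            "kohonen": self.kohonen.to_dict(),
            "output_weights": self.output_weights.ravel().tolist(),
            "class_names": list(self.class_names),
            "scaling": self.scaling.to_dict() if self.scaling is not None else None,
            "selected_descriptors": list(self.selected_descriptors),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CPANNModel":
        kohonen = SOMGrid.from_dict(d["kohonen"])
        classes = tuple(d["class_names"])
        u = np.asarray(d["output_weights"], dtype=float).reshape(
            kohonen.config.n_neurons, len(classes))
        scaling = None
        if d.get("scaling") is not None:
            scaling = ScalingParams.from_dict(d["scaling"])
        return cls(kohonen=kohonen, output_weights=u, class_names=classes,
                   scaling=scaling, selected_descriptors=tuple(d["selected_descriptors"]))

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict())
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, path) -> "CPANNModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass
class Prediction:
    """Class scores and thresholded assignment for one compound."""

    compound_id: object
    outputs: pd.Series
    assigned_class: str
    above_threshold: tuple[str, ...]
    flag: str  # "ok" | "below-threshold" | "ambiguous"


def train_cpann(x_tr: pd.DataFrame, targets, config: SOMConfig | None = None,
                classes: tuple[str, ...] | None = None,
                scaling: ScalingParams | None = None,
                two_phase: bool = False) -> CPANNModel:
    """Train a CP-ANN on an (autoscaled) descriptor table.

    ``targets`` is either a one-hot DataFrame aligned with ``x_tr`` or a
    label Series, in which case the one-hot encoding is built over
    ``classes`` (default: the three ligand classes). By default Kohonen and
    output layers are corrected jointly at each presentation; with
    ``two_phase=True`` the Kohonen layer is trained first, then frozen while
    a second schedule of the same length trains the output layer alone.
    """
    if config is None:
        config = FINAL_MODEL_DEFAULTS
    if isinstance(targets, pd.DataFrame):
        y = targets
        classes = tuple(str(c) for c in y.columns)
    else:
        classes = classes or CLASS_NAMES
        y = one_hot_targets(targets, classes)
    if len(y) != len(x_tr):
        raise ValueError("descriptor table and targets have different numbers of rows")
    if isinstance(targets, pd.DataFrame) or isinstance(targets, pd.Series):
        if not y.index.equals(x_tr.index):
            raise ValueError("descriptor table and targets are not aligned on compound IDs")

    X, names, _ = _as_matrix(x_tr)
    Y = np.ascontiguousarray(y.to_numpy(dtype=float))
    if two_phase:
        W, _, qe = _fit(X, config, Y=None)
        _, U, _ = _fit(X, config, Y=Y, W0=W, update_kohonen=False)
    else:
        W, U, qe = _fit(X, config, Y=Y)
    grid = SOMGrid(weights=W, feature_names=names, config=config, qe_history=qe)
    return CPANNModel(kohonen=grid, output_weights=U, class_names=classes,
                      scaling=scaling, selected_descriptors=names)


def _prepare_vector(model: CPANNModel, x_raw) -> np.ndarray:
    """Scale + order a raw input down to the model's selected descriptors."""
    if isinstance(x_raw, (pd.Series, dict)):
        x_raw = pd.Series(x_raw)
        missing = [d for d in model.selected_descriptors if d not in x_raw.index]
        if missing:
            raise KeyError(f"missing descriptor(s): {missing}")
        vec = x_raw[list(model.selected_descriptors)].astype(float)
        if model.scaling is not None:
            vec = (vec - model.scaling.mean[list(model.selected_descriptors)]) \
                / model.scaling.sd[list(model.selected_descriptors)]
        return vec.to_numpy()
    vec = np.asarray(x_raw, dtype=float).ravel()
    if vec.shape[0] != len(model.selected_descriptors):
        raise ValueError("input length does not match the selected descriptors")
    if model.scaling is not None:
        mean = model.scaling.mean[list(model.selected_descriptors)].to_numpy()
        sd = model.scaling.sd[list(model.selected_descriptors)].to_numpy()
        vec = (vec - mean) / sd
    return vec


def _assign(outputs: pd.Series) -> tuple[str, tuple[str, ...], str]:
    above = tuple(outputs.index[outputs > SCORE_THRESHOLD])
    assigned = str(outputs.idxmax())
    if len(above) == 1:
        flag = "ok"
    elif len(above) == 0:
        flag = "below-threshold"
    else:
        flag = "ambiguous"
    return assigned, above, flag


def predict(model: CPANNModel, x_raw, compound_id=None) -> Prediction:
    """Predict one compound: winner lookup, output weights as class scores."""
    vec = _prepare_vector(model, x_raw)
    coords, _ = find_winner(model.kohonen, vec)
    j = model.kohonen.neuron_index(coords)
    outputs = pd.Series(model.output_weights[j], index=list(model.class_names))
    assigned, above, flag = _assign(outputs)
    return Prediction(compound_id=compound_id, outputs=outputs,
                      assigned_class=assigned, above_threshold=above, flag=flag)


def predict_batch(model: CPANNModel, table: pd.DataFrame,
                  labels: pd.Series | None = None
                  ) -> tuple[list[Prediction], pd.DataFrame]:
    """Predict every row of ``table`` (row order preserved).

    Returns the predictions plus a summary frame with one row per compound:
    per-class scores, the assigned class, the reliability flag and — when
    ``labels`` is given — the true class. Batch prediction is stateless, so
    the result equals concatenating single-compound predictions.
    """
    missing = [d for d in model.selected_descriptors if d not in table.columns]
    if missing:
        raise KeyError(f"missing descriptor(s): {missing}")
    sub = table[list(model.selected_descriptors)].astype(float)
    if model.scaling is not None:
        sub = (sub - model.scaling.mean[list(model.selected_descriptors)]) \
            / model.scaling.sd[list(model.selected_descriptors)]
    winners, _ = _batch_winners(model.kohonen, np.ascontiguousarray(sub.to_numpy()))
    scores = model.output_weights[winners]
    preds: list[Prediction] = []
    rows = []
    for k, cid in enumerate(table.index):
        outputs = pd.Series(scores[k], index=list(model.class_names))
        assigned, above, flag = _assign(outputs)
        preds.append(Prediction(compound_id=cid, outputs=outputs,
                                assigned_class=assigned, above_threshold=above, flag=flag))
        rec = {f"score_{c}": outputs[c] for c in model.class_names}
        rec["predicted"] = assigned
        rec["flag"] = flag
        rows.append(rec)
    frame = pd.DataFrame(rows, index=table.index)
    if labels is not None:
        frame["true"] = pd.Series(np.asarray(labels), index=table.index)
    return preds, frame
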
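"""Euclidean-distance applicability domain for CP-ANN models.

The distance from a compound (in autoscaled descriptor space) to the weight
vector of its winning Kohonen neuron measures how well the map covers that
compound's region of chemical space; it is unitless because the descriptors
are autoscaled. The domain boundary is the maximum such distance observed on
a reference partition — conventionally the test set, whose maximum exceeded
the training set's in the reference study — and the boundary is inclusive:
a compound exactly at the reference distance counts as in-domain.

Independently of the distance, predictions whose class scores fall close to
the 0.5 membership threshold sit in the *uncertainty zone*: they may be
correct but are the least reliable outputs of the model. Out-of-domain and
uncertain compounds are flagged, never rejected — a compound outside the
domain may still show the modelled response through a mechanism the model
does not capture.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from cpannet.model import CPANNModel, _prepare_vector, one_hot_targets
from cpannet.som import _batch_winners, find_winner

__all__ = ["ADRecord", "ADReference", "ed_to_winner", "build_reference", "assess",
           "records_to_frame"]


@dataclass(frozen=True)
class ADReference:
    """Domain boundary: the maximum compound-to-winner distance on a partition."""

    reference_ed: float
    partition: str = "TE"

    def __post_init__(self) -> None:
        if self.reference_ed < 0:
            raise ValueError("reference_ed must be >= 0")


@dataclass
class ADRecord:
    """Per-compound applicability-domain assessment.

    ``ed`` is the Euclidean distance to the winning neuron; ``outputs`` the
    predicted class scores; ``residuals`` (when the true class is known) the
    per-class difference target - predicted score; ``in_domain`` compares
    ``ed`` against the reference boundary (inclusive); ``uncertain`` marks
    any class score within the band around the 0.5 threshold.
    """

    compound_id: object
    ed: float
    outputs: pd.Series
    in_domain: bool
    uncertain: bool
    residuals: pd.Series | None = None


def ed_to_winner(model: CPANNModel, x_raw) -> float:
    """Euclidean distance from a (raw) compound to its winning neuron.

    The input is scaled with the model's stored parameters, the winner is
    located in the Kohonen layer, and the square root of the summed squared
    componentwise differences is returned.
    """
    vec = _prepare_vector(model, x_raw)
    _, dist = find_winner(model.kohonen, vec)
    return dist


def _batch_eds(model: CPANNModel, table: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    missing = [d for d in model.selected_descriptors if d not in table.columns]
    if missing:
        raise KeyError(f"missing descriptor(s): {missing}")
    sub = table[list(model.selected_descriptors)].astype(float)
    if model.scaling is not None:
        sub = (sub - model.scaling.mean[list(model.selected_descriptors)]) \
            / model.scaling.sd[list(model.selected_descriptors)]
    return _batch_winners(model.kohonen, np.ascontiguousarray(sub.to_numpy()))


def build_reference(model: CPANNModel, partition_table: pd.DataFrame,
                    partition: str = "TE") -> ADReference:
    """Maximum compound-to-winner distance over a partition (the AD boundary)."""
    if len(partition_table) == 0:
        raise ValueError("cannot build an AD reference from an empty partition")
    _, dist = _batch_eds(model, partition_table)
    return ADReference(reference_ed=float(dist.max()), partition=partition)


def assess(model: CPANNModel, reference: ADReference, table: pd.DataFrame,
           labels: pd.Series | None = None,
           uncertainty_band: float = 0.1) -> list[ADRecord]:
    """Flag every compound of ``table`` as in/out of domain and un/certain.

    ``uncertainty_band`` is the half-width around the 0.5 score threshold
    (default 0.1, i.e. scores in [0.4, 0.6] are uncertain; a score of
    exactly 0.5 is always uncertain). With ``labels`` given, per-class
    residuals target - predicted are attached — the coordinates of the
    distance-vs-residual diagnostic plots.
    """
    if not 0.0 < uncertainty_band < 0.5:
        raise ValueError("uncertainty_band must be in (0, 0.5)")
    winners, dist = _batch_eds(model, table)
    scores = model.output_weights[winners]
    targets = None
    if labels is not None:
        targets = one_hot_targets(pd.Series(np.asarray(labels), index=table.index),
                                  model.class_names).to_numpy()
    records: list[ADRecord] = []
    for k, cid in enumerate(table.index):
        outputs = pd.Series(scores[k], index=list(model.class_names))
        residuals = None
        if targets is not None:
            residuals = pd.Series(targets[k] - scores[k], index=list(model.class_names))
        records.append(ADRecord(
            compound_id=cid,
            ed=float(dist[k]),
            outputs=outputs,
            in_domain=bool(dist[k] <= reference.reference_ed),
            uncertain=bool((np.abs(scores[k] - 0.5) <= uncertainty_band).any()),
            residuals=residuals,
        ))
    return records


def records_to_frame(records: list[ADRecord]) -> pd.DataFrame:
    """Flatten AD records to a table (one row per compound), ready for TSV."""
    rows = []
    for r in records:
        rec: dict = {"ed": r.ed}
        for c, v in r.outputs.items():
            rec[f"score_{c}"] = v
        if r.residuals is not None:
            for c, v in r.residuals.items():
                rec[f"residual_{c}"] = v
        rec["in_domain"] = r.in_domain
        rec["uncertain"] = r.uncertain
        rows.append(rec)
    return pd.DataFrame(rows, index=pd.Index([r.compound_id for r in records],
                                             name="compound_id"))
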
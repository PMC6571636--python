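"""Synthetic descriptor datasets and published reference confusion matrices.

Real molecular-descriptor tables for the three-class P-glycoprotein problem
(inhibitor / substrate / non-active) are produced by commercial software and
are not redistributable, so this module generates tables with the same
statistical structure the modelling chain assumes:

* a handful of informative descriptors whose class-conditional means are
  separated by a configurable number of within-class standard deviations,
* pure-noise descriptors,
* redundant descriptors — scaled (possibly sign-flipped) copies of
  informative ones with |Pearson r| >= 0.95,
* constant / near-constant descriptors (SD < 1e-4),
* class imbalance defaulting to the 1178 / 477 / 857 proportions of the
  reference P-gp dataset.

It also hard-codes the published validation-set confusion matrices of the
reference P-gp classifier (385 external compounds), which serve as exact
inputs to the metrics module.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from cpannet.metrics import ConfusionMatrix

__all__ = [
    "CLASS_NAMES",
    "SyntheticSpec",
    "LabeledDescriptorTable",
    "generate_dataset",
    "published_confusion_fixtures",
    "write_labeled_csv",
    "read_labeled_csv",
]

#: The three ligand classes, in reporting order.
CLASS_NAMES: tuple[str, str, str] = ("inhibitor", "substrate", "non_active")

#: Default label column name in CSV round-trips.
LABEL_COLUMN = "pgp_class"


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a synthetic three-class descriptor table.

    Defaults mirror the reference study conditions: class sizes in the
    1178/477/857 proportion, 8 informative axes with a 3-SD class separation,
    40 noise, 5 redundant and 3 near-constant descriptors.
    """

    n_per_class: tuple[int, int, int] = (1178, 477, 857)
    n_informative: int = 8
    n_noise: int = 40
    n_redundant: int = 5
    n_constant: int = 3
    separation: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.n_per_class) != 3 or any(n <= 0 for n in self.n_per_class):
            raise ValueError("n_per_class must be three positive integers")
        for name in ("n_informative", "n_noise", "n_redundant", "n_constant"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.separation < 0:
            raise ValueError("separation must be >= 0")
        if self.separation > 0 and self.n_informative < 1:
            raise ValueError("separation > 0 requires n_informative >= 1")
        if self.n_redundant > 0 and self.n_informative < 1:
            raise ValueError("redundant descriptors require at least one informative source")

    @property
    def n_descriptors(self) -> int:
        return self.n_informative + self.n_noise + self.n_redundant + self.n_constant

    @property
    def n_compounds(self) -> int:
        return sum(self.n_per_class)


@dataclass
class LabeledDescriptorTable:
    """A compounds x descriptors matrix with one class label per compound.

    ``table`` is a numeric DataFrame indexed by compound ID; ``labels`` is a
    Series aligned on the same index with values drawn from
    :data:`CLASS_NAMES`.
    """

    table: pd.DataFrame
    labels: pd.Series

    def __post_init__(self) -> None:
        if not self.table.index.equals(self.labels.index):
            raise ValueError("table and labels must share the same compound index")
        bad = set(self.labels.unique()) - set(CLASS_NAMES)
        if bad:
            raise ValueError(f"unknown class label(s): {sorted(bad)}")


def _class_centers(n_classes: int, n_informative: int, separation: float) -> np.ndarray:
    """Class means on the informative axes.

    Within every informative column the class-conditional means sit at
    offsets 0, ``separation``, 2*``separation`` (in within-class SD units,
    since the within-class SD is 1), so each column individually separates
    every pair of classes by at least ``separation`` SDs. The class-to-offset
    assignment rotates from column to column, which keeps the three classes
    geometrically symmetric overall instead of stacking them along a single
    ordered axis.
    """
    centers = np.zeros((n_classes, n_informative))
    if separation == 0 or n_informative == 0:
        return centers
    for i in range(n_informative):
        for g in range(n_classes):
            centers[g, i] = ((g + i) % n_classes) * separation
    return centers


def generate_dataset(spec: SyntheticSpec) -> LabeledDescriptorTable:
    """Draw a labelled synthetic descriptor table.

    Class-conditional distributions are multivariate normal with identity
    within-class covariance on the informative axes, so ``spec.separation``
    is directly a between-class mean offset in within-class SD units.
    Deterministic for a fixed ``spec.seed``: a single named generator is
    seeded once and drives every draw, including the final row shuffle.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_compounds
    class_of_row = np.repeat(np.arange(3), spec.n_per_class)

    columns: dict[str, np.ndarray] = {}
    centers = _class_centers(3, spec.n_informative, spec.separation)
    informative = rng.standard_normal((n, spec.n_informative))
    informative += centers[class_of_row]
    for i in range(spec.n_informative):
        columns[f"inf_{i + 1:02d}"] = informative[:, i]
    for i in range(spec.n_noise):
        columns[f"noise_{i + 1:02d}"] = rng.standard_normal(n)
    for i in range(spec.n_redundant):
        src = informative[:, i % spec.n_informative]
        sign = 1.0 if i % 2 == 0 else -1.0
        scale = rng.uniform(0.5, 2.0)
        # Additive noise SD of 0.15 x scale keeps |r| >= 0.95 against a
        # source whose total SD is at least 1 (within-class SD is 1).
        columns[f"red_{i + 1:02d}"] = sign * scale * src + rng.normal(0.0, 0.15 * scale, n)
    for i in range(spec.n_constant):
        columns[f"const_{i + 1:02d}"] = float(i + 1) + rng.normal(0.0, 1e-6, n)

    ids = [f"C{k + 1:05d}" for k in range(n)]
    table = pd.DataFrame(columns, index=pd.Index(ids, name="compound_id"))
    labels = pd.Series(
        np.asarray(CLASS_NAMES)[class_of_row], index=table.index, name=LABEL_COLUMN
    )
    order = rng.permutation(n)
    return LabeledDescriptorTable(table=table.iloc[order], labels=labels.iloc[order])


def published_confusion_fixtures() -> dict[str, ConfusionMatrix]:
    """Published validation-set confusion matrices of the reference classifier.

    One-vs-rest counts for the 385-compound external validation set of the
    published P-gp multiclass model, exactly as printed. These cover the
    validation set only — the corresponding training/test matrices were never
    published, so the model's training-set performance cannot be recomputed
    from printed data.
    """
    return {
        "inhibitor": ConfusionMatrix(tp=136, fp=35, fn=43, tn=171),
        "substrate": ConfusionMatrix(tp=47, fp=29, fn=25, tn=284),
        "non_active": ConfusionMatrix(tp=93, fp=42, fn=41, tn=209),
    }


def write_labeled_csv(data: LabeledDescriptorTable, path) -> None:
    """Write as CSV: compound ID first, descriptors, class label last."""
    out = data.table.copy()
    out[LABEL_COLUMN] = data.labels
    out.to_csv(path, index=True)


def read_labeled_csv(path, label_column: str = LABEL_COLUMN) -> LabeledDescriptorTable:
    """Read a CSV written by :func:`write_labeled_csv` (or equivalent layout)."""
    df = pd.read_csv(path, index_col=0)
    if label_column not in df.columns:
        raise ValueError(f"label column {label_column!r} not found in {path}")
    labels = df[label_column].astype(str)
    labels.name = LABEL_COLUMN
    table = df.drop(columns=[label_column]).astype(float)
    return LabeledDescriptorTable(table=table, labels=labels)
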
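"""Structure-driven training/test/validation splitting on a Kohonen top-map.

The whole dataset is mapped onto a SOM (default 20x20 grid, 100 epochs,
learning rate 0.5 -> 0.01); compounds sharing a winning neuron form a
structural cluster. Partitions are then drawn cluster by cluster so that the
information space covered by the map is represented in every subset: within
each occupied neuron, members are visited in a seeded random order, the
first always goes to the training set, and the rest are dealt out by a
largest-deficit weighted round-robin that tracks the requested global
fractions. The validation set is intended to be fixed before any model
construction and never touched again.

The split is unsupervised — driven purely by descriptor structure, not by
class labels — so class proportions are only approximately preserved.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from cpannet.data import LabeledDescriptorTable
from cpannet.som import SOMConfig, build_top_map, train_som

__all__ = ["SplitResult", "som_split", "SPLIT_SOM_DEFAULTS", "REFERENCE_FRACTIONS"]

#: Default SOM parameters for splitting: 20x20 grid, 100 epochs, 0.5 -> 0.01.
SPLIT_SOM_DEFAULTS = SOMConfig(rows=20, cols=20, t_max=100, a_max=0.5, a_min=0.01)

#: Fractions reproducing the reference 1786/341/385 partition of 2512 compounds.
REFERENCE_FRACTIONS = (0.711, 0.136, 0.153)

PARTITIONS = ("TR", "TE", "V")


@dataclass
class SplitResult:
    """Disjoint compound-ID lists for the TR / TE / V partitions."""

    tr: list
    te: list
    v: list
    som_config: SOMConfig | None = None
    fractions: tuple[float, float, float] = REFERENCE_FRACTIONS

    def __post_init__(self) -> None:
        sets = [set(self.tr), set(self.te), set(self.v)]
        if sets[0] & sets[1] or sets[0] & sets[2] or sets[1] & sets[2]:
            raise ValueError("partitions must be pairwise disjoint")

    @property
    def sizes(self) -> tuple[int, int, int]:
        return (len(self.tr), len(self.te), len(self.v))

    def partition_of(self) -> pd.Series:
        pairs = [(cid, "TR") for cid in self.tr] + [(cid, "TE") for cid in self.te] \
            + [(cid, "V") for cid in self.v]
        ids, parts = zip(*pairs) if pairs else ((), ())
        return pd.Series(parts, index=pd.Index(ids, name="compound_id"), name="partition")

    def to_tsv(self, path) -> None:
        self.partition_of().to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "SplitResult":
        s = pd.read_csv(path, sep="\t", index_col=0)["partition"]
        return cls(tr=list(s.index[s == "TR"]), te=list(s.index[s == "TE"]),
                   v=list(s.index[s == "V"]))


def som_split(data: LabeledDescriptorTable, som_config: SOMConfig | None = None,
              fractions: tuple[float, float, float] = REFERENCE_FRACTIONS) -> SplitResult:
    """Partition compounds into TR/TE/V from clusters on a Kohonen top-map.

    ``fractions`` are the target (TR, TE, V) proportions and must sum to 1.
    Every occupied neuron contributes at least one compound to TR, so the
    training set spans the whole map; global partition sizes track the
    requested fractions to within the rounding slack introduced by that
    per-neuron guarantee. Deterministic for a fixed ``som_config.seed``.
    """
    if som_config is None:
        som_config = SPLIT_SOM_DEFAULTS
    if len(fractions) != 3 or any(f <= 0 for f in fractions):
        raise ValueError("fractions must be three positive numbers")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {sum(fractions)}")
    n = len(data.table)
    if n < 3:
        raise ValueError("need at least 3 compounds to split")

    grid = train_som(data.table, som_config)
    top = build_top_map(grid, data.table)
    rng = np.random.default_rng(som_config.seed)

    # Visit occupied neurons in row-major order, members shuffled per neuron.
    assignments: dict[str, list] = {p: [] for p in PARTITIONS}
    counts = dict.fromkeys(PARTITIONS, 0)
    seen = 0
    order = top.assignments.sort_values(["row", "col"], kind="stable")
    for (_, _), group in order.groupby(["row", "col"], sort=True):
        members = list(group.index)
        members = [members[i] for i in rng.permutation(len(members))]
        for k, cid in enumerate(members):
            seen += 1
            if k == 0:
                part = "TR"  # map coverage: every cluster is represented in TR
            else:
                deficits = {p: fractions[i] * seen - counts[p]
                            for i, p in enumerate(PARTITIONS)}
                part = max(PARTITIONS, key=lambda p: (deficits[p], p == "TR"))
            counts[part] += 1
            assignments[part].append(cid)

    return SplitResult(tr=assignments["TR"], te=assignments["TE"], v=assignments["V"],
                       som_config=som_config, fractions=tuple(fractions))
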
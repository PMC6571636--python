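"""Descriptor-matrix normalisation and reduction.

The reduction chain runs in this order:

1. low-variance filter — drop descriptors with SD below a threshold
   (default 1e-4), which removes constant and near-constant columns;
2. pairwise-correlation filter — whenever two descriptors have
   |Pearson r| >= 0.95 (default), keep only the earlier one;
3. autoscaling — per-descriptor standardisation to mean 0, SD 1 (sample SD,
   n-1 denominator), with the fitted means/SDs retained for new compounds;
4. SOM-based reduction — train a small Kohonen map (default 7x7) on the
   *descriptor* vectors (rows of the transposed matrix) and keep, from each
   occupied neuron, the descriptor closest to and the descriptor farthest
   from that neuron's weight vector, i.e. one typical and one extreme
   representative per descriptor cluster.

Every removed descriptor is accounted for in a :class:`ReductionReport`
with the stage and reason of its removal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from cpannet.som import SOMConfig, train_som

__all__ = [
    "ScalingParams",
    "ReductionReport",
    "autoscale",
    "apply_scaling",
    "filter_low_variance",
    "filter_correlated",
    "som_reduce_descriptors",
    "REDUCTION_SOM_DEFAULTS",
]

#: SOM parameters used for descriptor reduction unless overridden; these are
#: the same learning parameters as the dataset-splitting map.
REDUCTION_SOM_DEFAULTS = dict(t_max=100, a_max=0.5, a_min=0.01)


@dataclass(frozen=True)
class ScalingParams:
    """Fitted per-descriptor mean and (sample) standard deviation."""

    mean: pd.Series
    sd: pd.Series

    def __post_init__(self) -> None:
        if not self.mean.index.equals(self.sd.index):
            raise ValueError("mean and sd must cover the same descriptors")
        if (self.sd <= 0).any():
            bad = list(self.sd.index[self.sd <= 0])
            raise ValueError(f"non-positive SD for descriptor(s) {bad}")

    @property
    def descriptors(self) -> tuple[str, ...]:
        return tuple(self.mean.index)

    def to_dict(self) -> dict:
        return {"mean": self.mean.to_dict(), "sd": self.sd.to_dict(),
                "descriptors": list(self.mean.index)}

    @classmethod
    def from_dict(cls, d: dict) -> "ScalingParams":
        idx = pd.Index(d["descriptors"])
        return cls(mean=pd.Series(d["mean"]).reindex(idx),
                   sd=pd.Series(d["sd"]).reindex(idx))


@dataclass
class ReductionReport:
    """Ledger of descriptor removals: (descriptor, stage, reason, partner).

    ``partner`` is the retained survivor a removed descriptor correlated
    with (correlation stage) or empty. ``retained`` lists the descriptors
    surviving the stage(s) covered by the report.
    """

    entries: list[tuple[str, str, str, str]] = field(default_factory=list)
    retained: list[str] = field(default_factory=list)

    @property
    def removed(self) -> list[str]:
        return [e[0] for e in self.entries]

    def merge(self, other: "ReductionReport") -> "ReductionReport":
        return ReductionReport(entries=self.entries + other.entries,
                               retained=list(other.retained))

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("descriptor\tstage\treason\tpartner\n")
            for desc, stage, reason, partner in self.entries:
                fh.write(f"{desc}\t{stage}\t{reason}\t{partner}\n")
            for desc in self.retained:
                fh.write(f"{desc}\tretained\t\t\n")


def _sds(table: pd.DataFrame) -> pd.Series:
    return table.std(ddof=1)


def autoscale(table: pd.DataFrame) -> tuple[pd.DataFrame, ScalingParams]:
    """Standardise every descriptor to mean 0, SD 1 (sample SD).

    Raises on constant columns — run :func:`filter_low_variance` first. The
    returned :class:`ScalingParams` reproduce the transform on new data via
    :func:`apply_scaling`.
    """
    sd = _sds(table)
    constant = sd.index[(sd == 0) | sd.isna()]
    if len(constant):
        raise ValueError(f"constant descriptor(s) cannot be autoscaled: {list(constant)}")
    mean = table.mean()
    params = ScalingParams(mean=mean, sd=sd)
    return (table - mean) / sd, params


def apply_scaling(table: pd.DataFrame, params: ScalingParams) -> pd.DataFrame:
    """Apply previously fitted autoscaling to (new) compounds."""
    missing = [d for d in params.descriptors if d not in table.columns]
    if missing:
        raise KeyError(f"missing descriptor(s): {missing}")
    sub = table[list(params.descriptors)]
    return (sub - params.mean) / params.sd


def filter_low_variance(table: pd.DataFrame, sd_threshold: float = 1e-4
                        ) -> tuple[pd.DataFrame, ReductionReport]:
    """Drop descriptors whose sample SD is below ``sd_threshold``."""
    if sd_threshold <= 0:
        raise ValueError("sd_threshold must be > 0")
    sd = _sds(table)
    low = sd.isna() | (sd < sd_threshold)
    kept = [c for c in table.columns if not low[c]]
    if not kept:
        raise ValueError("low-variance filter removed every descriptor")
    entries = [(str(c), "variance", f"sd<{sd_threshold:g}", "") for c in table.columns if low[c]]
    return table[kept], ReductionReport(entries=entries, retained=[str(c) for c in kept])


def filter_correlated(table: pd.DataFrame, r_threshold: float = 0.95
                      ) -> tuple[pd.DataFrame, ReductionReport]:
    """Remove redundant descriptors by absolute pairwise Pearson correlation.

    Columns are scanned in input order; a column correlating at
    |r| >= ``r_threshold`` with any already-retained column is removed and
    the report records which survivor it duplicated. Idempotent: the
    surviving set contains no pair at or above the threshold.
    """
    if not 0 < r_threshold <= 1:
        raise ValueError("r_threshold must be in (0, 1]")
    cols = [str(c) for c in table.columns]
    corr = np.corrcoef(table.to_numpy(dtype=float), rowvar=False)
    corr = np.nan_to_num(np.atleast_2d(corr), nan=0.0)
    retained_idx: list[int] = []
    entries: list[tuple[str, str, str, str]] = []
    for j in range(len(cols)):
        partner = next(
            (i for i in retained_idx if abs(corr[i, j]) >= r_threshold), None)
        if partner is None:
            retained_idx.append(j)
        else:
            entries.append((cols[j], "correlation",
                            f"|r|>={r_threshold:g}", cols[partner]))
    kept = [cols[i] for i in retained_idx]
    return table[kept], ReductionReport(entries=entries, retained=kept)


def som_reduce_descriptors(table: pd.DataFrame, grid_rows: int = 7, grid_cols: int = 7,
                           som_config: SOMConfig | None = None,
                           ) -> tuple[pd.DataFrame, ReductionReport]:
    """Cluster descriptors on a Kohonen map and keep two per occupied neuron.

    The map is trained on the *transpose* of the (already autoscaled)
    descriptor matrix, so each descriptor is an object whose coordinates are
    its values over all compounds. From each occupied neuron the descriptor
    with the shortest and the descriptor with the largest Euclidean distance
    to the neuron's weight vector are retained; a neuron holding a single
    descriptor contributes that one. Retained count is therefore
    ``sum(min(2, occupancy))`` over neurons.
    """
    if table.shape[1] < 1:
        raise ValueError("need at least one descriptor")
    if som_config is None:
        som_config = SOMConfig(rows=grid_rows, cols=grid_cols, **REDUCTION_SOM_DEFAULTS)
    transposed = table.T  # descriptors x compounds
    grid = train_som(transposed, som_config)
    from cpannet.som import build_top_map  # local import keeps module load order simple

    top = build_top_map(grid, transposed)
    keep: set[str] = set()
    for (_, _), group in top.assignments.groupby(["row", "col"]):
        by_dist = group["distance"].sort_values(kind="stable")
        keep.add(str(by_dist.index[0]))   # closest to the neuron
        keep.add(str(by_dist.index[-1]))  # farthest from the neuron
    kept = [str(c) for c in table.columns if str(c) in keep]
    entries = [(str(c), "som", "not-selected-by-som", "") for c in table.columns
               if str(c) not in keep]
    return table[kept], ReductionReport(entries=entries, retained=kept)
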
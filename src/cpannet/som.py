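"""Kohonen self-organizing map on a square, non-toroidal grid.

A SOM places objects on a 2-D grid of neurons by competitive learning: for
each presented vector the *winning* neuron is the one whose weight vector is
nearest in Euclidean distance; the winner and its topological neighbourhood
are then pulled toward the input.

Conventions in this implementation:

* grid topology is square with Chebyshev rings — diagonal neighbours belong
  to ring 1 — and no wraparound at the edges;
* the neighbourhood function is triangular, ``a(d) = 1 - d / (radius + 1)``:
  1 at the winner, linearly decaying, 0 outside the radius;
* the learning rate decays linearly from ``a_max`` at epoch 1 to ``a_min``
  at the last epoch;
* the neighbourhood radius shrinks linearly from ``max(rows, cols) - 1`` at
  epoch 1 to 0 at the last epoch;
* each neuron is initialised to a constant vector at a level drawn uniformly
  from [0, 1), which breaks the neuron symmetry while keeping training
  exactly equivariant to a permutation of the input columns;
* winner ties break to the first neuron in row-major order;
* compounds are presented once per epoch in a freshly shuffled seeded order.

The same training loop also drives the supervised output layer of the
counter-propagation network (see :mod:`cpannet.model`): when targets are
supplied, the output weights of the winner's neighbourhood are pulled toward
the target vector with the same learning-rate/neighbourhood factor.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SOMConfig",
    "SOMGrid",
    "TopMap",
    "learning_rate",
    "find_winner",
    "topological_distance",
    "update_weights",
    "train_som",
    "build_top_map",
]


@dataclass(frozen=True)
class SOMConfig:
    """Training hyperparameters of a Kohonen map.

    ``a_max``/``a_min`` bound the linearly decaying learning rate; ``t_max``
    is the number of epochs (full passes over the data). Only the square,
    non-toroidal, triangular-neighbourhood variant is implemented.
    """

    rows: int
    cols: int
    t_max: int = 100
    a_max: float = 0.5
    a_min: float = 0.01
    topology: str = "square"
    boundary: str = "non-toroidal"
    neighborhood: str = "triangular"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rows < 1 or self.cols < 1:
            raise ValueError("grid dimensions must be >= 1")
        if self.t_max < 1:
            raise ValueError("t_max must be >= 1")
        if not (0.0 < self.a_min <= self.a_max <= 1.0):
            raise ValueError("need 0 < a_min <= a_max <= 1")
        if self.topology != "square":
            raise NotImplementedError("only the square topology is implemented")
        if self.boundary != "non-toroidal":
            raise NotImplementedError("only non-toroidal boundaries are implemented")
        if self.neighborhood != "triangular":
            raise NotImplementedError("only the triangular neighbourhood is implemented")

    @property
    def n_neurons(self) -> int:
        return self.rows * self.cols

    def with_seed(self, seed: int) -> "SOMConfig":
        return replace(self, seed=int(seed))


@dataclass
class SOMGrid:
    """A (trained) Kohonen layer.

    ``weights`` has shape (rows*cols, m) in row-major neuron order, where m
    is the input dimensionality; ``feature_names`` names the m components.
    ``qe_history`` records the mean quantization error (mean Euclidean
    distance of each presented vector to its winner, measured before the
    update) per training epoch.
    """

    weights: np.ndarray
    feature_names: tuple[str, ...]
    config: SOMConfig
    qe_history: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != (self.config.n_neurons, len(self.feature_names)):
            raise ValueError("weights shape inconsistent with grid size / feature names")

    @property
    def rows(self) -> int:
        return self.config.rows

    @property
    def cols(self) -> int:
        return self.config.cols

    @property
    def n_features(self) -> int:
        return self.weights.shape[1]

    def neuron_index(self, coords: tuple[int, int]) -> int:
        r, c = coords
        if not (0 <= r < self.rows and 0 <= c < self.cols):
            raise ValueError(f"coordinates {coords} outside {self.rows}x{self.cols} grid")
        return r * self.cols + c

    def coords(self, index: int) -> tuple[int, int]:
        return divmod(int(index), self.cols)

    # -- serialization (structured text) --------------------------------
    def to_dict(self) -> dict:
        return {
            "config": vars(self.config).copy(),
            "shape": [self.rows, self.cols],
            "feature_names": list(self.feature_names),
            "weights": self.weights.ravel().tolist(),
            "qe_history": list(self.qe_history),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SOMGrid":
        config = SOMConfig(**d["config"])
        names = tuple(d["feature_names"])
        weights = np.asarray(d["weights"], dtype=float).reshape(config.n_neurons, len(names))
        return cls(weights=weights, feature_names=names, config=config,
                   qe_history=list(d.get("qe_history", [])))

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict())
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, path) -> "SOMGrid":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass
class TopMap:
    """Assignment of compounds to their winning neurons.

    ``assignments`` is indexed by compound ID with columns ``row``, ``col``
    and ``distance`` (Euclidean, with square root); ``occupancy`` is a
    (rows, cols) count array; ``majority_class`` maps occupied neuron coords
    to the most frequent label among its compounds (ties break
    alphabetically) when labels were supplied.
    """

    assignments: pd.DataFrame
    occupancy: np.ndarray
    majority_class: dict[tuple[int, int], str] | None = None

    def members(self, coords: tuple[int, int]) -> list:
        sel = (self.assignments["row"] == coords[0]) & (self.assignments["col"] == coords[1])
        return list(self.assignments.index[sel])

    def to_tsv(self, path) -> None:
        self.assignments.to_csv(path, sep="\t", index=True, index_label="compound_id")


def learning_rate(t: int, config: SOMConfig) -> float:
    """Linearly decaying learning rate at epoch ``t`` (1-based).

    eta(t) = (a_max - a_min) * (t_max - t) / (t_max - 1) + a_min, so that
    eta(1) = a_max and eta(t_max) = a_min. A single-epoch schedule returns
    a_max.
    """
    if not 1 <= t <= config.t_max:
        raise ValueError(f"epoch t={t} outside [1, {config.t_max}]")
    if config.t_max == 1:
        return config.a_max
    return (config.a_max - config.a_min) * (config.t_max - t) / (config.t_max - 1) + config.a_min


def _as_matrix(data) -> tuple[np.ndarray, tuple[str, ...], list]:
    """Coerce a DataFrame or array to (float matrix, column names, row ids)."""
    if isinstance(data, pd.DataFrame):
        return (np.ascontiguousarray(data.to_numpy(dtype=float)),
                tuple(str(c) for c in data.columns), list(data.index))
    arr = np.atleast_2d(np.asarray(data, dtype=float))
    names = tuple(f"x{i + 1}" for i in range(arr.shape[1]))
    return np.ascontiguousarray(arr), names, list(range(arr.shape[0]))


def find_winner(grid: SOMGrid, x: Sequence[float]) -> tuple[tuple[int, int], float]:
    """Winning neuron for ``x``: nearest weight vector, row-major tie-break.

    Returns ``((row, col), euclidean_distance)``. The square root is applied
    to the minimised sum of squares so the reported distance matches the
    applicability-domain distance convention.
    """
    x = np.asarray(x, dtype=float).ravel()
    if x.shape[0] != grid.n_features:
        raise ValueError(
            f"input dimension {x.shape[0]} != grid dimension {grid.n_features}")
    diff = grid.weights - x
    d2 = np.einsum("ij,ij->i", diff, diff)
    j = int(np.argmin(d2))  # argmin takes the first minimum: row-major tie-break
    return grid.coords(j), float(np.sqrt(d2[j]))


def topological_distance(coords_a: tuple[int, int], coords_b: tuple[int, int],
                         topology: str = "square") -> int:
    """Chebyshev ring distance between two grid positions (no wraparound)."""
    if topology != "square":
        raise NotImplementedError("only the square topology is implemented")
    return int(max(abs(coords_a[0] - coords_b[0]), abs(coords_a[1] - coords_b[1])))


def _neighborhood_factors(rows: int, cols: int, winner: tuple[int, int],
                          radius: float) -> tuple[np.ndarray, np.ndarray]:
    """(indices, triangular factors) of neurons within ``radius`` of winner."""
    r = np.arange(rows)[:, None]
    c = np.arange(cols)[None, :]
    cheb = np.maximum(np.abs(r - winner[0]), np.abs(c - winner[1])).ravel()
    within = np.flatnonzero(cheb <= radius)
    a = 1.0 - cheb[within] / (radius + 1.0)
    return within, a


def update_weights(grid: SOMGrid, x: Sequence[float], winner: tuple[int, int],
                   t: int, radius_t: float) -> SOMGrid:
    """One Kohonen update: pull the winner's neighbourhood toward ``x``.

    Every neuron within Chebyshev distance ``radius_t`` of the winner moves
    by the factor ``eta(t) * a(d)`` with the triangular ``a``; the rest are
    untouched. Modifies ``grid`` in place and returns it.
    """
    if radius_t < 0:
        raise ValueError("radius_t must be >= 0")
    x = np.asarray(x, dtype=float).ravel()
    eta = learning_rate(t, grid.config)
    idx, a = _neighborhood_factors(grid.rows, grid.cols, winner, radius_t)
    f = (eta * a)[:, None]
    grid.weights[idx] += f * (x - grid.weights[idx])
    return grid


def _fit(X: np.ndarray, config: SOMConfig, Y: np.ndarray | None = None,
         W0: np.ndarray | None = None, update_kohonen: bool = True,
         ) -> tuple[np.ndarray, np.ndarray | None, list[float]]:
    """Shared online training loop for the Kohonen and output layers.

    Returns (kohonen weights, output weights or None, per-epoch mean QE).
    When ``Y`` is given, the output weights — initialised uniformly in
    [0, 1) — are updated toward the target rows with the same neighbourhood
    factor as the Kohonen layer, which keeps them inside [0, 1] throughout.
    """
    n, m = X.shape
    if n == 0:
        raise ValueError("cannot train a SOM on an empty dataset")
    rows, cols = config.rows, config.cols
    n_neurons = config.n_neurons
    # Separate streams for the Kohonen layer and the output layer, so the
    # Kohonen trajectory is identical whether or not targets are supplied
    # (the winner never depends on Y).
    seq_k, seq_out = np.random.SeedSequence(config.seed).spawn(2)
    rng = np.random.default_rng(seq_k)
    if W0 is not None:
        W = np.array(W0, dtype=float)
        rng.random(n_neurons)  # keep the shuffle stream aligned with a fresh fit
    else:
        # Constant-vector-per-neuron init: equivariant to column permutation.
        W = np.repeat(rng.random(n_neurons)[:, None], m, axis=1)
    U = None
    if Y is not None:
        U = np.random.default_rng(seq_out).random((n_neurons, Y.shape[1]))

    ri = np.arange(rows)[:, None]
    ci = np.arange(cols)[None, :]
    max_radius = float(max(rows, cols) - 1)
    qe_history: list[float] = []
    for t in range(1, config.t_max + 1):
        eta = learning_rate(t, config)
        if config.t_max > 1:
            radius = max_radius * (config.t_max - t) / (config.t_max - 1)
        else:
            radius = 0.0
        order = rng.permutation(n)
        qe = 0.0
        for s in order:
            x = X[s]
            diff = W - x
            d2 = np.einsum("ij,ij->i", diff, diff)
            j = int(np.argmin(d2))
            qe += np.sqrt(d2[j])
            wr, wc = divmod(j, cols)
            cheb = np.maximum(np.abs(ri - wr), np.abs(ci - wc)).ravel()
            idx = np.flatnonzero(cheb <= radius)
            f = (eta * (1.0 - cheb[idx] / (radius + 1.0)))[:, None]
            if update_kohonen:
                W[idx] += f * (x - W[idx])
            if U is not None:
                U[idx] += f * (Y[s] - U[idx])
        qe_history.append(qe / n)
    return W, U, qe_history


def train_som(data, config: SOMConfig) -> SOMGrid:
    """Train a Kohonen map on a compounds x features table (or array).

    Autoscaled input is recommended so that every feature weighs equally in
    the winner search. Deterministic for a fixed ``config.seed``.
    """
    X, names, _ = _as_matrix(data)
    W, _, qe = _fit(X, config)
    return SOMGrid(weights=W, feature_names=names, config=config, qe_history=qe)


def _batch_winners(grid: SOMGrid, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Winner index and distance per row of ``X`` (vectorised)."""
    diff = X[:, None, :] if X.shape[0] * grid.weights.shape[0] * X.shape[1] <= 2_000_000 else None
    if diff is not None:
        d2 = ((diff - grid.weights[None, :, :]) ** 2).sum(axis=2)
    else:  # quadratic expansion for large batches; clip tiny negatives
        d2 = ((X ** 2).sum(axis=1)[:, None] + (grid.weights ** 2).sum(axis=1)[None, :]
              - 2.0 * X @ grid.weights.T)
        np.maximum(d2, 0.0, out=d2)
    winners = d2.argmin(axis=1)
    dist = np.sqrt(d2[np.arange(X.shape[0]), winners])
    return winners, dist


def build_top_map(grid: SOMGrid, data, labels: pd.Series | None = None) -> TopMap:
    """Assign every compound to its winner; count occupancy; majority class.

    ``labels``, when given, must align with the rows of ``data``.
    """
    X, _, ids = _as_matrix(data)
    if X.shape[1] != grid.n_features:
        raise ValueError("data dimensionality does not match the grid")
    winners, dist = _batch_winners(grid, X)
    rows, cols = np.divmod(winners, grid.cols)
    assignments = pd.DataFrame(
        {"row": rows, "col": cols, "distance": dist}, index=pd.Index(ids, name="compound_id")
    )
    occupancy = np.zeros((grid.rows, grid.cols), dtype=int)
    np.add.at(occupancy, (rows, cols), 1)
    majority = None
    if labels is not None:
        lab = pd.Series(np.asarray(labels), index=assignments.index)
        majority = {}
        for (r, c), sub in lab.groupby([assignments["row"], assignments["col"]]):
            counts = sub.value_counts().sort_index()  # alphabetical tie-break
            majority[(int(r), int(c))] = str(counts.idxmax())
    return TopMap(assignments=assignments, occupancy=occupancy, majority_class=majority)
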
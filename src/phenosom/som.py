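"""Batch self-organizing map on a small 2D grid.

The map is a fixed grid of nodes (default 10x10, hexagonal lattice), each
carrying a weight vector in measure space.  Weights are initialized on the
plane spanned by the first two principal components of the data and then
refined by batch cycles: every child is mapped to its best matching unit
(BMU, nearest node by Euclidean distance), and each node's weight is
replaced by the mean of all children whose BMU falls within grid distance
ND of it (a "bubble" neighborhood).  ND shrinks over an ordering phase

    ND(t) = 1 + INS * (1 - t / n),   t = 1..n

from 1 + INS down to 1, followed by fine-tuning cycles with ND fixed below
1, where each node averages only its own BMU hits.  Defaults: INS = 3,
n = 5 ordering cycles, one fine-tuning cycle at ND = 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path
from scipy.spatial.distance import cdist

from .cohort import CohortMatrix

TOPOLOGIES = ("hexagonal", "rectangular")
GRID_METRICS = ("link", "euclidean", "chebyshev")


@dataclass(frozen=True)
class SOMConfig:
    grid_rows: int = 10
    grid_cols: int = 10
    topology: str = "hexagonal"
    grid_metric: str = "link"
    initial_neighborhood: float = 3.0   # INS
    ordering_steps: int = 5             # n
    finetune_steps: int = 1
    finetune_neighborhood: float = 0.0  # must stay < 1
    init_jitter_sd: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.grid_rows * self.grid_cols < 2:
            raise ValueError("grid must have at least 2 nodes")
        if self.topology not in TOPOLOGIES:
            raise ValueError(f"unknown topology {self.topology!r}")
        if self.grid_metric not in GRID_METRICS:
            raise ValueError(f"unknown grid metric {self.grid_metric!r}")
        if self.initial_neighborhood < 1:
            raise ValueError("initial neighborhood (INS) must be >= 1")
        if self.ordering_steps < 1 or self.finetune_steps < 1:
            raise ValueError("ordering_steps and finetune_steps must be >= 1")
        if self.finetune_neighborhood >= 1:
            raise ValueError("finetune neighborhood must be < 1")
        if self.init_jitter_sd < 0:
            raise ValueError("init_jitter_sd must be nonnegative")

    @property
    def n_nodes(self) -> int:
        return self.grid_rows * self.grid_cols


def grid_coords(config: SOMConfig) -> np.ndarray:
    """Integer (row, col) per node, row-major node order."""
    r, c = np.divmod(np.arange(config.n_nodes), config.grid_cols)
    return np.column_stack([r, c])


def grid_positions(config: SOMConfig) -> np.ndarray:
    """Planar (x, y) node positions; odd hexagonal rows shift by half a step."""
    rc = grid_coords(config)
    x = rc[:, 1].astype(float)
    y = rc[:, 0].astype(float)
    if config.topology == "hexagonal":
        x = x + 0.5 * (rc[:, 0] % 2)
        y = y * (np.sqrt(3.0) / 2.0)
    return np.column_stack([x, y])


def grid_distances(config: SOMConfig) -> np.ndarray:
    """Node-to-node grid distances under the configured topology/metric.

    ``link`` counts hops on the neighbor graph (nodes at planar distance 1
    are adjacent: 4-neighborhood on rectangular grids, 6 on hexagonal);
    ``euclidean`` uses planar positions; ``chebyshev`` uses max(|dr|, |dc|)
    on the integer grid.
    """
    config.validate()
    if config.grid_metric == "euclidean":
        pos = grid_positions(config)
        return cdist(pos, pos)
    if config.grid_metric == "chebyshev":
        rc = grid_coords(config)
        return cdist(rc, rc, metric="chebyshev")
    pos = grid_positions(config)
    adj = cdist(pos, pos) <= 1.0 + 1e-9
    np.fill_diagonal(adj, False)
    d = shortest_path(csr_matrix(adj.astype(np.int8)), unweighted=True)
    return d


def neighborhood_schedule(config: SOMConfig) -> list[float]:
    """Ordering-phase ND values followed by the fine-tuning entries."""
    config.validate()
    ins, n = config.initial_neighborhood, config.ordering_steps
    nds = [1.0 + ins * (1.0 - t / n) for t in range(1, n + 1)]
    nds += [config.finetune_neighborhood] * config.finetune_steps
    return nds


def init_weights_pca(
    data: CohortMatrix | np.ndarray, config: SOMConfig,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Initial node weights on the plane of the first two PCs.

    Rows of the grid vary along PC1 with span proportional to sqrt of the
    leading eigenvalue, columns along PC2 likewise; optional seeded
    Gaussian jitter is added afterwards.
    """
    config.validate()
    X = data.values_for() if isinstance(data, CohortMatrix) else np.asarray(data, float)
    if X.shape[0] < 3 or X.shape[1] < 2:
        raise ValueError("need at least 3 observations and 2 measures")
    if not np.isfinite(X).all():
        raise ValueError("data must be finite")
    mu = X.mean(axis=0)
    cov = np.cov(X - mu, rowvar=False)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    tol = max(evals[0], 0.0) * 1e-12
    if evals[0] <= 0:
        warnings.warn("data has no variance; all nodes start at the mean")
        v1 = np.zeros(X.shape[1])
    else:
        v1 = evecs[:, 0] * np.sqrt(evals[0])
    if evals[1] <= tol or evals[0] <= 0:
        if evals[0] > 0:
            warnings.warn(
                "rank-deficient data: fewer than 2 nonzero eigenvalues; "
                "falling back to the leading PC plus a zero vector")
        v2 = np.zeros_like(v1)
    else:
        v2 = evecs[:, 1] * np.sqrt(evals[1])

    def lin(n: int) -> np.ndarray:
        return np.zeros(1) if n == 1 else np.linspace(-1.0, 1.0, n)

    a = lin(config.grid_rows)
    b = lin(config.grid_cols)
    rc = grid_coords(config)
    W = mu + np.outer(a[rc[:, 0]], v1) + np.outer(b[rc[:, 1]], v2)
    if config.init_jitter_sd > 0:
        if rng is None:
            rng = np.random.default_rng(config.seed)
        W = W + rng.normal(0.0, config.init_jitter_sd, W.shape)
    return W


def find_bmu(weights: np.ndarray, x: np.ndarray) -> int:
    """Index of the node nearest to ``x``; ties go to the lowest index."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.shape[0] != weights.shape[1]:
        raise ValueError(
            f"input dimension {x.shape} does not match weights {weights.shape}")
    d2 = np.einsum("ij,ij->i", weights - x, weights - x)
    return int(np.argmin(d2))


def map_bmus(weights: np.ndarray, X: np.ndarray) -> np.ndarray:
    """BMU index per row of X (argmin breaks ties toward lower indices)."""
    d2 = cdist(X, weights, metric="sqeuclidean")
    return np.argmin(d2, axis=1)


def batch_cycle(
    weights: np.ndarray, X: np.ndarray, nd: float, grid_dist: np.ndarray,
) -> np.ndarray:
    """One concurrent batch update with bubble neighborhood radius ``nd``.

    Each node becomes the mean of all inputs whose BMU lies within grid
    distance <= nd of it; nodes whose neighborhood captures no inputs keep
    their previous weights.  All updates read the pre-cycle weights.
    """
    X = np.asarray(X, dtype=float)
    if X.size == 0:
        raise ValueError("empty data")
    if nd < 0:
        raise ValueError("neighborhood size must be nonnegative")
    bmu = map_bmus(weights, X)
    n_nodes = weights.shape[0]
    sums = np.zeros_like(weights)
    np.add.at(sums, bmu, X)
    counts = np.bincount(bmu, minlength=n_nodes).astype(float)
    mask = (grid_dist <= nd + 1e-12).astype(float)
    neigh_sums = mask @ sums
    neigh_counts = mask @ counts
    occupied = neigh_counts > 0
    new = weights.copy()
    new[occupied] = neigh_sums[occupied] / neigh_counts[occupied, None]
    return new


@dataclass
class TrainedSOM:
    """Result of batch training: geometry, weights, schedule, BMUs."""

    config: SOMConfig
    node_coords: np.ndarray            # node x 2 integer grid positions
    weights: np.ndarray                # node x measure
    schedule_trace: list[float]        # ND per completed cycle
    bmu: np.ndarray                    # child -> node index
    measures: list[str] = field(default_factory=list)
    child_ids: list = field(default_factory=list)
    quantization_errors: list[float] = field(default_factory=list)

    @property
    def bmu_coords(self) -> np.ndarray:
        """(row, col) of each child's BMU."""
        return self.node_coords[self.bmu]

    def weight_planes(self) -> dict[str, np.ndarray]:
        """Per-measure grid map: measure j's weights reshaped to the grid."""
        shape = (self.config.grid_rows, self.config.grid_cols)
        names = self.measures or [f"m{j}" for j in range(self.weights.shape[1])]
        return {name: self.weights[:, j].reshape(shape)
                for j, name in enumerate(names)}

    def weight_plane_correlations(self) -> np.ndarray:
        """Pearson correlations between measure columns of the weights.

        Zero-variance columns yield NaN entries (undefined, not 0).
        """
        W = self.weights
        sd = W.std(axis=0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            corr = np.corrcoef(W, rowvar=False)
        corr[sd == 0, :] = np.nan
        corr[:, sd == 0] = np.nan
        np.fill_diagonal(corr, np.where(sd == 0, np.nan, 1.0))
        return corr


def quantization_error(weights: np.ndarray, X: np.ndarray,
                       bmu: np.ndarray | None = None) -> float:
    """Mean Euclidean distance from each input to its BMU's weight."""
    if bmu is None:
        bmu = map_bmus(weights, X)
    return float(np.linalg.norm(X - weights[bmu], axis=1).mean())


def train_som(
    data: CohortMatrix | np.ndarray, config: SOMConfig | None = None,
) -> TrainedSOM:
    """PCA-initialize then run the full batch schedule and map BMUs."""
    if config is None:
        config = SOMConfig()
    config.validate()
    if isinstance(data, CohortMatrix):
        X = data.values_for()
        measures, child_ids = data.measures, data.child_ids
    else:
        X = np.asarray(data, dtype=float)
        measures, child_ids = [], []
    rng = np.random.default_rng(config.seed)
    W = init_weights_pca(X, config, rng)
    gd = grid_distances(config)
    schedule = neighborhood_schedule(config)
    qe = []
    for nd in schedule:
        W = batch_cycle(W, X, nd, gd)
        qe.append(quantization_error(W, X))
    return TrainedSOM(
        config=config,
        node_coords=grid_coords(config),
        weights=W,
        schedule_trace=schedule,
        bmu=map_bmus(W, X),
        measures=measures,
        child_ids=child_ids,
        quantization_errors=qe,
    )


def retrained(data, config: SOMConfig, seed: int) -> TrainedSOM:
    """Train a fresh map with a new seed (jitter draw), same geometry."""
    return train_som(data, replace(config, seed=seed))
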
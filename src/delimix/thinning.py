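"""Spatial sampling-bias correction for climatic clustering.

Occurrence records are thinned to one specimen per grid cell (default
cell side 0.5 arc-minutes of a degree, grid anchored at the data's
minimum lon/lat), the ordination-plus-mixture clustering is run on the
thinned subsample, and the whole procedure is repeated many times.
Replicates are combined through a specimen co-assignment matrix: the
final partition is an average-linkage cut of (1 - co-assignment)
distance into the modal K, so every specimen — thinned out of any
particular replicate or not — receives a label.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .mixtures import FAMILIES, Partition, classify, model_select

#: 0.5 arc-minutes, in decimal degrees.
DEFAULT_CELL_DEGREES = 0.5 / 60.0


@dataclass
class GridSpec:
    """Square thinning grid in plain geographic degrees."""

    cell_size: float = DEFAULT_CELL_DEGREES
    origin: tuple[float, float] | None = None  # (lon_min, lat_min); None = data extent

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    def resolve_origin(self, coords: np.ndarray) -> tuple[float, float]:
        if self.origin is not None:
            return self.origin
        return float(coords[:, 0].min()), float(coords[:, 1].min())


@dataclass
class ConsensusResult:
    """Aggregate of the replicated thin-and-cluster procedure."""

    k_histogram: dict[int, int]
    modal_K: int
    coassignment: np.ndarray        # specimens x specimens, symmetric, diag 1
    final_partition: Partition
    grid_origin: tuple[float, float] = (np.nan, np.nan)
    replicate_Ks: list[int] = field(default_factory=list)


def assign_cells(coords: np.ndarray, grid: GridSpec) -> np.ndarray:
    """Integer (col, row) cell index per point; boundary points go to the
    higher-index cell (floor of the offset in cell units)."""
    coords = np.asarray(coords, dtype=float)
    if coords.size == 0:
        raise ValueError("no localities")
    lon0, lat0 = grid.resolve_origin(coords)
    cols = np.floor((coords[:, 0] - lon0) / grid.cell_size).astype(int)
    rows = np.floor((coords[:, 1] - lat0) / grid.cell_size).astype(int)
    return np.column_stack([cols, rows])


def thin_one_per_cell(coords: np.ndarray, grid: GridSpec, seed) -> np.ndarray:
    """Indices of one uniformly chosen specimen per occupied grid cell.

    ``seed`` may be an int or a numpy Generator. The returned index
    array is sorted, so thinning an already-thinned set is the identity.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cells = assign_cells(coords, grid)
    keys = {}
    for i, cell in enumerate(map(tuple, cells)):
        keys.setdefault(cell, []).append(i)
    chosen = [occupants[rng.integers(len(occupants))] for _, occupants in sorted(keys.items())]
    return np.sort(np.array(chosen, dtype=int))


def consensus_cluster(
    scores: np.ndarray,
    coords: np.ndarray,
    grid: GridSpec | None = None,
    reps: int = 1000,
    seed: int = 0,
    K_max: int = 12,
    families: tuple[str, ...] = FAMILIES,
    restarts: int = 10,
) -> ConsensusResult:
    """Replicated thin -> model_select -> classify with consensus aggregation.

    Each replicate fits the mixture on the thinned subsample only, then
    classifies *all* specimens under that replicate's fitted model, so
    the co-assignment frequency is defined for every specimen pair
    (specimens sharing a grid cell are never co-sampled). Replicate RNG
    streams are spawned from the master seed by replicate index, so any
    replicate is independently reproducible.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    coords = np.asarray(coords, dtype=float)
    n = scores.shape[0]
    if coords.shape[0] != n:
        raise ValueError("scores and localities must share specimen order")
    grid = grid or GridSpec()
    origin = grid.resolve_origin(coords)
    grid = GridSpec(cell_size=grid.cell_size, origin=origin)

    master = np.random.SeedSequence(int(seed) % (2**31))
    rep_seeds = master.spawn(reps)
    co_counts = np.zeros((n, n))
    k_hist: dict[int, int] = {}
    rep_Ks: list[int] = []
    for r in range(reps):
        child = rep_seeds[r].generate_state(2)
        rng = np.random.default_rng(rep_seeds[r])
        keep = thin_one_per_cell(coords, grid, rng)
        sub = scores[keep]
        fit, _ = model_select(
            sub, K_max=min(K_max, sub.shape[0]), families=families,
            restarts=restarts, seed=int(child[1] % (2**31)),
        )
        part = classify(fit, scores)
        k_hist[fit.K] = k_hist.get(fit.K, 0) + 1
        rep_Ks.append(fit.K)
        same = part.labels[:, None] == part.labels[None, :]
        co_counts += same
    coassign = co_counts / reps
    np.fill_diagonal(coassign, 1.0)

    modal_K = min(k for k, c in k_hist.items() if c == max(k_hist.values()))
    if n > 1 and modal_K > 1:
        dist = squareform(1.0 - coassign, checks=False)
        Z = linkage(dist, method="average")
        raw = fcluster(Z, t=modal_K, criterion="maxclust") - 1
    else:
        raw = np.zeros(n, dtype=int)
    # renumber by descending group size; uncertainty from within-group coassignment
    sizes = np.bincount(raw)
    order = np.argsort(-sizes, kind="stable")
    rank = np.empty(len(sizes), dtype=int)
    rank[order] = np.arange(1, len(sizes) + 1)
    labels = rank[raw]
    K_eff = labels.max()
    posterior = np.zeros((n, K_eff))
    uncertainty = np.zeros(n)
    for i in range(n):
        mates = np.flatnonzero((labels == labels[i]) & (np.arange(n) != i))
        within = coassign[i, mates].mean() if mates.size else 1.0
        uncertainty[i] = 1.0 - within
        posterior[i, labels[i] - 1] = 1.0
    final = Partition(labels=labels, posterior=posterior, uncertainty=np.clip(uncertainty, 0, 1))
    return ConsensusResult(
        k_histogram=dict(sorted(k_hist.items())),
        modal_K=modal_K,
        coassignment=coassign,
        final_partition=final,
        grid_origin=origin,
        replicate_Ks=rep_Ks,
    )


def k_histogram_frame(result: ConsensusResult) -> pd.DataFrame:
    return pd.DataFrame(
        {"K": list(result.k_histogram), "count": list(result.k_histogram.values())}
    )
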
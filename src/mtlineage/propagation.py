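"""Network propagation: assigning progeny cells to stem-cell clonal groups.

Cells are embedded by LSI (TF-IDF/SVD of the binarized variant matrix) and
connected in a mutual k-nearest-neighbour graph: an edge exists only when
each endpoint is among the other's k nearest neighbours in Euclidean LSI
space.  For each clonal group, a random walk with restart is run from its
member cells (uniform restart distribution over the seeds, restart
probability = damping factor); the stationary score of a cell measures how
strongly it is connected to that clone's neighbourhood.  Per cell, raw
scores are normalised across clones into assignment probabilities, and a
cell is assigned to the arg-max clone only when its maximum probability
exceeds the cutoff.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.neighbors import NearestNeighbors

from .matrix import LSIEmbedding

__all__ = [
    "PropagationConfig",
    "MKNNGraph",
    "AssignmentResult",
    "build_mknn",
    "propagate",
    "assign_clones",
    "benchmark_self_assignment",
]


@dataclass(frozen=True)
class PropagationConfig:
    """Random-walk-with-restart parameters.

    ``restart`` is the damping factor: the probability mass returned to the
    seed distribution at every step.
    """

    restart: float = 0.05
    tol: float = 1e-6
    max_iter: int = 1000
    prob_cutoff: float = 0.7
    k: int = 30

    def __post_init__(self):
        if not 0 < self.restart <= 1:
            raise ValueError("restart must lie in (0, 1]")
        if self.tol <= 0 or self.max_iter < 1 or self.k < 1:
            raise ValueError("invalid tolerance / iteration / k settings")


@dataclass
class MKNNGraph:
    """Mutual-KNN graph: symmetric unweighted adjacency over cells."""

    adjacency: sp.csr_matrix
    cells: list[str]
    k: int

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def isolated(self) -> list[str]:
        deg = np.asarray(self.adjacency.sum(axis=1)).ravel()
        return [c for c, d in zip(self.cells, deg) if d == 0]


def build_mknn(embedding: LSIEmbedding | np.ndarray, k: int = 30,
               cells: list[str] | None = None) -> MKNNGraph:
    """Mutual k-nearest-neighbour graph in Euclidean embedding space.

    Keeps an edge only when both endpoints list each other among their k
    nearest neighbours; isolated cells are permitted (see
    :meth:`MKNNGraph.isolated`).
    """
    if isinstance(embedding, LSIEmbedding):
        X = embedding.embedding
        cells = cells if cells is not None else embedding.cells
    else:
        X = np.asarray(embedding)
        cells = cells if cells is not None else [str(i) for i in range(len(X))]
    n = X.shape[0]
    if k >= n:
        raise ValueError("k must be smaller than the number of cells")
    nn = NearestNeighbors(n_neighbors=k + 1).fit(X)
    A = nn.kneighbors_graph(X, mode="connectivity")
    A = A.tolil()
    A.setdiag(0)
    A = A.tocsr()
    M = A.multiply(A.T)  # mutual edges only
    M = (M > 0).astype(np.float64)
    return MKNNGraph(M.tocsr(), list(cells), k)


def _transition(adjacency: sp.spmatrix) -> sp.csr_matrix:
    """Column-stochastic transition matrix; degree-0 nodes self-loop."""
    A = adjacency.tocsc().astype(np.float64)
    deg = np.asarray(A.sum(axis=0)).ravel()
    isolated = deg == 0
    if isolated.any():
        A = A.tolil()
        for i in np.nonzero(isolated)[0]:
            A[i, i] = 1.0
        A = A.tocsc()
        deg = np.asarray(A.sum(axis=0)).ravel()
    return (A @ sp.diags(1.0 / deg)).tocsr()


def propagate(graph: MKNNGraph | sp.spmatrix, seeds,
              config: PropagationConfig = PropagationConfig()) -> np.ndarray:
    """Random walk with restart from ``seeds``; returns stationary scores.

    Iterates ``p <- (1 - restart) W p + restart p0`` with W the
    column-stochastic transition matrix and p0 uniform over the seeds,
    until the L1 change drops below ``tol``.  Scores sum to 1.
    """
    if isinstance(graph, MKNNGraph):
        A, cells = graph.adjacency, graph.cells
        seed_idx = np.asarray([cells.index(s) for s in seeds] if seeds and
                              isinstance(next(iter(seeds)), str) else list(seeds),
                              dtype=int)
    else:
        A = graph
        seed_idx = np.asarray(list(seeds), dtype=int)
    if seed_idx.size == 0:
        raise ValueError("seed set is empty")
    W = _transition(A)
    n = W.shape[0]
    p0 = np.zeros(n)
    p0[seed_idx] = 1.0 / seed_idx.size
    p = p0.copy()
    for _ in range(config.max_iter):
        p_next = (1.0 - config.restart) * (W @ p) + config.restart * p0
        delta = np.abs(p_next - p).sum()
        p = p_next
        if delta < config.tol:
            return p
    raise RuntimeError(
        f"random walk did not converge in {config.max_iter} iterations "
        f"(last L1 change {delta:.3g}); raise max_iter or tol")


@dataclass
class AssignmentResult:
    """Cell x clone propagation probabilities and the final assignment."""

    probabilities: pd.DataFrame   # cells x clones, rows sum to 1 (reachable)
    max_prob: pd.Series
    assigned: pd.Series           # clone id, or NA when below the cutoff
    prob_cutoff: float

    def assignment_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "clone": self.assigned,
            "max_prob": self.max_prob,
            "assigned": self.assigned.notna(),
        })


def assign_clones(graph: MKNNGraph, clones, config: PropagationConfig = PropagationConfig()
                  ) -> AssignmentResult:
    """Propagate every clonal group and assign each cell to its best clone.

    ``clones`` maps clone id -> member cells (a :class:`ClonalGroupSet`
    also works).  Clones without any graph-resident cell are skipped with a
    warning.  Cells with maximum normalised probability <= ``prob_cutoff``
    (or unreachable from every seed) are left unassigned.
    """
    members = clones.clones if hasattr(clones, "clones") else dict(clones)
    index = {c: i for i, c in enumerate(graph.cells)}
    scores = {}
    for cid, cells in members.items():
        seed_idx = [index[c] for c in cells if c in index]
        if not seed_idx:
            warnings.warn(f"clone {cid!r} has no cells in the graph; skipped")
            continue
        scores[cid] = propagate(graph.adjacency, seed_idx, config)
    if not scores:
        raise ValueError("no clone had graph-resident cells")
    S = pd.DataFrame(scores, index=graph.cells)
    total = S.sum(axis=1)
    P = S.div(total.where(total > 0), axis=0).fillna(0.0)
    max_prob = P.max(axis=1)
    best = P.idxmax(axis=1)
    assigned = best.where(max_prob > config.prob_cutoff)
    return AssignmentResult(P, max_prob.rename("max_prob"),
                            assigned.rename("clone"), config.prob_cutoff)


def leave_self_out_probabilities(graph: MKNNGraph, clones,
                                 truth: pd.Series,
                                 config: PropagationConfig = PropagationConfig()
                                 ) -> AssignmentResult:
    """Clone assignment with each benchmarked cell excluded from its own
    seed set.

    For every cell with a truth label, its own clone's propagation is
    re-run without that cell as a seed, giving an honest generalisation
    estimate (the default benchmark keeps seeds in the network).  Cost is
    one extra propagation per labelled cell.
    """
    members = clones.clones if hasattr(clones, "clones") else dict(clones)
    index = {c: i for i, c in enumerate(graph.cells)}
    raw = pd.DataFrame(
        {c: propagate(graph.adjacency, [index[x] for x in m if x in index],
                      config)
         for c, m in members.items() if any(x in index for x in m)},
        index=graph.cells)
    for cell, clone in truth.items():
        if clone not in members or cell not in index:
            continue
        seeds = [index[x] for x in members[clone] if x in index and x != cell]
        if not seeds:
            continue
        raw.loc[cell, clone] = propagate(graph.adjacency, seeds,
                                         config)[index[cell]]
    total = raw.sum(axis=1)
    P = raw.div(total.where(total > 0), axis=0).fillna(0.0)
    max_prob = P.max(axis=1)
    assigned = P.idxmax(axis=1).where(max_prob > config.prob_cutoff)
    return AssignmentResult(P, max_prob.rename("max_prob"),
                            assigned.rename("clone"), config.prob_cutoff)


def benchmark_self_assignment(result: AssignmentResult, truth: pd.Series,
                              bins: np.ndarray | None = None) -> pd.DataFrame:
    """Assignment accuracy against ground-truth clone labels.

    Returns per max-probability bin the fraction of cells whose arg-max
    clone equals the truth, plus the cumulative accuracy above each bin
    edge.  ``truth`` may cover a subset of cells (e.g. only stem cells).
    For a benchmark that excludes each cell from its own seed set, build
    ``result`` with :func:`leave_self_out_probabilities`.
    """
    common = result.max_prob.index.intersection(truth.index)
    if len(common) == 0:
        raise ValueError("no overlap between assignments and truth labels")
    best = result.probabilities.loc[common].idxmax(axis=1)
    correct = (best == truth.loc[common]).astype(float)
    mp = result.max_prob.loc[common]
    if bins is None:
        bins = np.linspace(0.0, 1.0, 11)
    which = pd.cut(mp, bins, include_lowest=True)
    rows = []
    for interval, grp in correct.groupby(which, observed=False):
        above = mp > interval.left
        rows.append((interval, len(grp),
                     float(grp.mean()) if len(grp) else np.nan,
                     float(correct[above].mean()) if above.any() else np.nan))
    return pd.DataFrame(rows, columns=["bin", "n", "accuracy", "accuracy_above"])
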
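"""Phylogeny construction and clonal-group inference.

The cell tree is built by neighbour joining on a cell-to-cell distance
matrix (prior-weighted Jaccard, or Euclidean distance in LSI space for
dense stem-cell subsets).  Rooting uses an artificial outgroup cell with an
empty mutation profile, which sits at weighted-Jaccard distance 1 from
every real cell; the outgroup is removed after rooting.

Variants are then placed on tree edges by maximum likelihood: for a variant
with carrier set O and an edge e whose clade is C_e,

    log L(e) = |O & C_e| log s + |C_e \\ O| log(1 - s)
             + |O \\ C_e| log f + |rest| log(1 - f)

with detection sensitivity ``s`` and false-positive rate ``f``; per-variant
probabilities are the softmax of log L over all candidate edges (the root
edge, covering all leaves, is a candidate).  This likelihood is a generic
reconstruction of the branch-assignment approach used with single-cell
mtDNA trees; ``s`` and ``f`` are exposed in configuration.

Clonal groups are minimal clades (deepest qualifying, disjoint) with at
least ``m`` cells whose parent edge carries at least ``n`` confidently
assigned variants.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats as sps
from scipy.special import xlogy
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj

from .stats import storey_qvalue

__all__ = [
    "BranchAssignConfig",
    "TreeCutConfig",
    "BranchAssignment",
    "ClonalGroupSet",
    "build_nj_tree",
    "assign_variants_to_branches",
    "cut_tree",
    "clade_celltype_enrichment",
]

OUTGROUP = "__outgroup__"


@dataclass(frozen=True)
class BranchAssignConfig:
    """Likelihood parameters for variant-to-branch assignment."""

    s: float = 0.9        # detection sensitivity inside the clade
    f: float = 0.001      # false-positive carrier rate outside the clade
    confident_prob: float = 0.6

    def __post_init__(self):
        if not 0 < self.s <= 1 or not 0 <= self.f < 1:
            raise ValueError("require s in (0,1] and f in [0,1)")
        if self.s <= self.f:
            raise ValueError("s must exceed f")
        if not 0 < self.confident_prob <= 1:
            raise ValueError("confident_prob must lie in (0, 1]")


@dataclass(frozen=True)
class TreeCutConfig:
    """Clonal-group extraction thresholds.

    ``m``: minimum cells per clone; ``n``: minimum confident variants on the
    based edge; ``p``: minimum assignment probability for a variant to count
    as confident; ``dump``: clones smaller than this are discarded after
    selection.
    """

    m: int = 50
    n: int = 1
    p: float = 0.6
    dump: int = 0

    def __post_init__(self):
        if self.m < 1 or self.n < 1:
            raise ValueError("m and n must be >= 1")


def build_nj_tree(D: np.ndarray, ids: list[str], root: bool = True,
                  outgroup_distance: float = 1.0) -> TreeNode:
    """Neighbour-joining tree over cells, rooted via an artificial outgroup.

    The outgroup models a cell with an empty mutation profile (distance
    ``outgroup_distance`` to every cell under weighted Jaccard) and is
    removed after rooting.  Negative NJ branch lengths are clamped to 0.
    """
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    if n < 3:
        raise ValueError("neighbour joining needs at least 3 cells")
    if D.shape != (n, n) or len(ids) != n:
        raise ValueError("distance matrix and ids are inconsistent")
    if not np.all(np.isfinite(D)):
        raise ValueError("non-finite distances")
    if OUTGROUP in ids:
        raise ValueError(f"{OUTGROUP!r} is a reserved cell id")
    if root:
        Daug = np.zeros((n + 1, n + 1))
        Daug[:n, :n] = D
        Daug[n, :n] = Daug[:n, n] = outgroup_distance
        dm = DistanceMatrix(Daug, ids=list(ids) + [OUTGROUP])
    else:
        dm = DistanceMatrix(D, ids=list(ids))
    tree = nj(dm)
    for node in tree.traverse(include_self=True):
        if node.length is not None and node.length < 0:
            node.length = 0.0
    if not root:
        return tree
    out_tip = tree.find(OUTGROUP)
    rooted = tree.root_at(out_tip.parent)
    out_tip = rooted.find(OUTGROUP)
    out_tip.parent.remove(out_tip)
    rooted.prune()  # collapse any single-child nodes left by the removal
    return rooted


def collapse_short_branches(tree: TreeNode, min_length: float = 1e-9) -> TreeNode:
    """Collapse internal edges shorter than ``min_length`` into
    multifurcations.

    Near-zero NJ branch lengths mark unresolved splits; collapsing them
    yields the multifurcating topology required for sister-clade
    comparisons (e.g. the coalescent expansion test, which has no power on
    strictly binary nodes).  Returns a modified copy.
    """
    out = tree.copy()
    changed = True
    while changed:
        changed = False
        for node in list(out.non_tips(include_self=False)):
            if node.length is not None and node.length < min_length:
                parent = node.parent
                for child in list(node.children):
                    node.remove(child)
                    parent.append(child)
                parent.remove(node)
                changed = True
    return out


def _index_clades(tree: TreeNode):
    """Assign postorder-contiguous leaf intervals to every node.

    Returns (tip order, {node: (lo, hi)}, edge list) where the edge list
    enumerates candidate edges: every non-root node plus the root itself
    (the root edge covers all leaves).
    """
    tips = list(tree.tips())
    tip_index = {t: i for i, t in enumerate(tips)}
    intervals: dict = {}
    for node in tree.postorder(include_self=True):
        if node.is_tip():
            i = tip_index[node]
            intervals[node] = (i, i + 1)
        else:
            los, his = zip(*(intervals[c] for c in node.children))
            intervals[node] = (min(los), max(his))
    edges = [node for node in tree.preorder(include_self=True)]
    return tips, intervals, edges


@dataclass
class BranchAssignment:
    """Maximum-likelihood placement of variants on tree edges."""

    table: pd.DataFrame           # variant, edge, prob, confident, n_carriers
    edge_nodes: dict              # edge id -> TreeNode
    config: BranchAssignConfig

    def confident_variants(self, edge: int, min_prob: float | None = None) -> list[str]:
        p = self.config.confident_prob if min_prob is None else min_prob
        t = self.table
        return list(t.loc[(t["edge"] == edge) & (t["prob"] >= p), "variant"])


def assign_variants_to_branches(tree: TreeNode, C_bin: sp.spmatrix,
                                cells: list[str], variant_ids: list[str],
                                config: BranchAssignConfig = BranchAssignConfig(),
                                chunk: int = 1024) -> BranchAssignment:
    """Assign every carried variant to its best edge by maximum likelihood.

    ``C_bin`` rows are aligned to ``cells``; tree leaves must match.
    Variants with no carriers are skipped with a warning.
    """
    tips, intervals, edges = _index_clades(tree)
    tip_names = [t.name for t in tips]
    if set(tip_names) != set(cells):
        raise ValueError("tree leaves do not match matrix cells")
    order = [cells.index(nm) for nm in tip_names]
    B = C_bin.tocsr()[order].toarray().astype(np.int32)
    n, V = B.shape
    P = np.zeros((n + 1, V), dtype=np.int32)
    np.cumsum(B, axis=0, out=P[1:])
    O = P[n]

    empty = O == 0
    if empty.any():
        warnings.warn(f"skipping {int(empty.sum())} variants with no carriers")

    lo = np.array([intervals[e][0] for e in edges])
    hi = np.array([intervals[e][1] for e in edges])
    ne = (hi - lo).astype(np.float64)[:, None]
    probs = np.zeros((len(edges), V))
    for j0 in range(0, V, chunk):
        j1 = min(j0 + chunk, V)
        a = (P[hi, j0:j1] - P[lo, j0:j1]).astype(np.float64)
        Oj = O[j0:j1].astype(np.float64)[None, :]
        logL = (xlogy(a, config.s) + xlogy(ne - a, 1.0 - config.s)
                + xlogy(Oj - a, config.f) + xlogy(n - ne - Oj + a, 1.0 - config.f))
        logL -= logL.max(axis=0, keepdims=True)
        w = np.exp(logL)
        probs[:, j0:j1] = w / w.sum(axis=0, keepdims=True)

    best = probs.argmax(axis=0)
    rows = []
    for j, vid in enumerate(variant_ids):
        if empty[j]:
            continue
        rows.append((vid, int(best[j]), float(probs[best[j], j]),
                     bool(probs[best[j], j] >= config.confident_prob), int(O[j])))
    table = pd.DataFrame(rows, columns=["variant", "edge", "prob", "confident",
                                        "n_carriers"])
    # annotate nodes so downstream consumers can navigate either way
    for k, node in enumerate(edges):
        node.edge_id = k
    return BranchAssignment(table, dict(enumerate(edges)), config)


@dataclass
class ClonalGroupSet:
    """Tree-derived clonal groups: disjoint clades plus unassigned cells."""

    clones: dict[str, list[str]]
    defining_variants: dict[str, list[str]]
    unassigned: list[str]

    @property
    def n_clones(self) -> int:
        return len(self.clones)

    def labels(self) -> pd.Series:
        out = {}
        for cid, members in self.clones.items():
            for c in members:
                out[c] = cid
        return pd.Series(out, name="clone")

    def sizes(self) -> pd.Series:
        return pd.Series({c: len(v) for c, v in self.clones.items()}, name="size")


def cut_tree(tree: TreeNode, assignment: BranchAssignment,
             config: TreeCutConfig = TreeCutConfig()) -> ClonalGroupSet:
    """Cut the tree into clonal groups.

    Bottom-up traversal selects minimal (deepest) disjoint clades with at
    least ``m`` leaves whose based edge carries at least ``n`` variants
    assigned with probability >= ``p``; selected clades smaller than
    ``dump`` are then discarded.
    """
    t = assignment.table
    conf = t[t["prob"] >= config.p].groupby("edge").size()
    selected: list[TreeNode] = []
    for node in tree.postorder(include_self=True):
        if node.is_tip():
            node._covered = False
            continue
        child_covered = any(c._covered for c in node.children)
        node._covered = child_covered
        if child_covered:
            continue
        n_leaves = sum(1 for _ in node.tips())
        edge_id = getattr(node, "edge_id", None)
        n_conf = int(conf.get(edge_id, 0)) if edge_id is not None else 0
        if n_leaves >= config.m and n_conf >= config.n:
            selected.append(node)
            node._covered = True
    clones, defining = {}, {}
    assigned: set = set()
    kept = [nd for nd in selected if sum(1 for _ in nd.tips()) >= config.dump]
    # stable clone ids in tree (preorder) position, largest first within ties
    kept.sort(key=lambda nd: _preorder_rank(tree, nd))
    for i, nd in enumerate(kept):
        cid = f"clone{i:02d}"
        members = [tp.name for tp in nd.tips()]
        clones[cid] = members
        assigned.update(members)
        defining[cid] = assignment.confident_variants(nd.edge_id, config.p)
    unassigned = [tp.name for tp in tree.tips() if tp.name not in assigned]
    for node in tree.postorder(include_self=True):
        if hasattr(node, "_covered"):
            del node._covered
    return ClonalGroupSet(clones, defining, unassigned)


def _preorder_rank(tree: TreeNode, node: TreeNode) -> int:
    for i, nd in enumerate(tree.preorder(include_self=True)):
        if nd is node:
            return i
    raise ValueError("node not in tree")


def clade_celltype_enrichment(tree: TreeNode, cell_types: pd.Series,
                              min_clade_size: int = 20, fdr: float = 0.2,
                              min_fold: float = 2.0) -> pd.DataFrame:
    """Cell-type enrichment of every clade vs the global frequency.

    One-sided binomial test per (clade, cell type) with Storey q-values
    across all tests; a pair is flagged enriched when q < ``fdr`` and fold
    change > ``min_fold``.  Untyped leaves are excluded with a warning.
    """
    tips = [t.name for t in tree.tips()]
    typed = cell_types.reindex(tips)
    if typed.isna().any():
        warnings.warn(f"excluding {int(typed.isna().sum())} untyped leaves")
        typed = typed.dropna()
    global_freq = typed.value_counts(normalize=True)
    rows = []
    for k, node in enumerate(tree.preorder(include_self=True)):
        if node.is_tip():
            continue
        members = [t.name for t in node.tips() if t.name in typed.index]
        n_c = len(members)
        if n_c < min_clade_size or n_c == len(typed):
            continue
        counts = typed.loc[members].value_counts()
        for ct, p0 in global_freq.items():
            kk = int(counts.get(ct, 0))
            fc = (kk / n_c) / p0
            pval = float(sps.binom.sf(kk - 1, n_c, p0))
            rows.append((k, ct, n_c, kk, fc, pval))
    out = pd.DataFrame(rows, columns=["clade", "cell_type", "n", "k", "fc", "p"])
    if len(out):
        out["q"] = storey_qvalue(out["p"].to_numpy())
        out["flagged"] = (out["q"] < fdr) & (out["fc"] > min_fold)
    else:
        out["q"] = []
        out["flagged"] = []
    return out
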
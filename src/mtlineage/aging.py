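"""Clonal diversity, expansion, fitness proxy, and loss-of-chromosome-Y.

Clonal expansions are detected two ways.  Clone-based: the Shannon index of
the clone-size composition summarises diversity.  Clade-based: under a
neutral coalescent, the probability that a given child of an internal node
with ``n`` leaves and ``m`` children subtends exactly ``b`` leaves is

    P(b | n, m) = C(n - b - 1, m - 2) / C(n - 1, m - 1),

so an upper-tail p-value flags clades implausibly large relative to their
direct sisters; clades with p < 0.01 holding at least 5% of all cells are
annotated as expanded.

Single-cell fitness is proxied by the local branching index (LBI): the
exponentially discounted tree length around each node, computed by message
passing with timescale ``tau``.  Dense, recently expanded regions of the
tree score high.  This is a tree-shape proxy, not a full probabilistic
fitness inference.

Loss of chromosome Y (LOY) is called per cell from chromosome fragment
counts with a binomial model: a cell is LOY when its chrY fragment count is
``fold_threshold``-fold below expectation and the binomial lower tail is
below ``alpha``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
from scipy import stats as sps
from skbio import TreeNode

from .stats import storey_qvalue

__all__ = [
    "shannon_diversity",
    "coalescent_clade_pmf",
    "coalescent_clade_probability",
    "expansion_test",
    "fitness_scores",
    "LOYConfig",
    "detect_loy",
    "loy_clade_enrichment",
    "expanded_clade_composition",
    "cumulative_clone_curve",
]


def shannon_diversity(sizes) -> float:
    """Shannon index of a clone-size composition: S = -sum p_i ln p_i."""
    sizes = np.asarray(list(sizes), dtype=float)
    if sizes.size == 0:
        raise ValueError("empty composition")
    if (sizes <= 0).any():
        raise ValueError("clone sizes must be positive")
    p = sizes / sizes.sum()
    return float(-(p * np.log(p)).sum())


def coalescent_clade_pmf(n: int, m: int, b: int) -> Fraction:
    """Exact P(a given child of an (n leaves, m children) node has b leaves).

    Neutral coalescent: all splits of n leaves into m labelled non-empty
    sister clades are equally likely, giving
    ``C(n - b - 1, m - 2) / C(n - 1, m - 1)``.
    """
    if m < 2 or b < 1 or b > n - m + 1:
        raise ValueError(f"invalid (n={n}, m={m}, b={b})")
    return Fraction(comb(n - b - 1, m - 2), comb(n - 1, m - 1))


def coalescent_clade_probability(n: int, m: int, b: int) -> float:
    """Upper-tail expansion p-value: P(child clade size >= b).

    Closed form by the hockey-stick identity:
    ``sum_{b' >= b} C(n - b' - 1, m - 2) = C(n - b, m - 1)``, so the tail is
    ``C(n - b, m - 1) / C(n - 1, m - 1)`` (exact integer arithmetic).
    """
    if m < 2 or b < 1 or b > n - m + 1:
        raise ValueError(f"invalid (n={n}, m={m}, b={b})")
    return float(Fraction(comb(n - b, m - 1), comb(n - 1, m - 1)))


def expansion_test(tree: TreeNode, min_frac: float = 0.05, alpha: float = 0.01,
                   min_cells: int | None = None) -> dict:
    """Coalescent expansion test over every clade of a rooted tree.

    Each non-root internal node is compared with its direct sisters: with
    the parent subtending ``n`` leaves through ``m`` children, the clade's
    ``b`` leaves get the upper-tail coalescent p-value.  Clades with
    p < ``alpha`` and at least ``min_frac`` of all cells are flagged
    (``min_cells`` switches the size rule to an absolute count); maximal
    flagged clades (no flagged ancestor) are the expanded clades.  Returns
    the per-node table, the expanded clades (id -> member cells) and the
    fraction of cells they contain.
    """
    if len(tree.children) == 0:
        raise ValueError("expansion test needs a rooted tree with children")
    n_total = sum(1 for _ in tree.tips())
    leaf_count: dict = {}
    for node in tree.postorder(include_self=True):
        leaf_count[node] = 1 if node.is_tip() else sum(
            leaf_count[c] for c in node.children)

    rows = []
    flagged_nodes = []
    for idx, node in enumerate(tree.preorder(include_self=True)):
        node._xid = idx
        if node.is_tip() or node.parent is None:
            continue
        parent = node.parent
        m = len(parent.children)
        if m < 2:
            continue
        n = leaf_count[parent]
        b = leaf_count[node]
        p = coalescent_clade_probability(n, m, b)
        big_enough = (b >= min_cells) if min_cells is not None \
            else (b / n_total >= min_frac)
        flag = (p < alpha) and big_enough
        rows.append((idx, n, m, b, p, flag))
        if flag:
            flagged_nodes.append(node)

    # maximal flagged clades: drop any whose ancestor is flagged
    flagged_set = set(id(nd) for nd in flagged_nodes)
    expanded = {}
    for node in flagged_nodes:
        anc = node.parent
        shadowed = False
        while anc is not None:
            if id(anc) in flagged_set:
                shadowed = True
                break
            anc = anc.parent
        if not shadowed:
            expanded[node._xid] = [t.name for t in node.tips()]
    table = pd.DataFrame(rows, columns=["clade", "n", "m", "b", "p", "flagged"])
    frac = sum(len(v) for v in expanded.values()) / n_total if n_total else 0.0
    for node in tree.preorder(include_self=True):
        del node._xid
    return {"table": table, "expanded_clades": expanded,
            "fraction_expanded": float(frac)}


# ---------------------------------------------------------------------------
# local branching index (fitness proxy)


def fitness_scores(tree: TreeNode, tau: float | None = None) -> pd.Series:
    """Local branching index per leaf: exponentially discounted tree length.

    Messages integrate branch length with timescale ``tau``; an edge of
    length b contributes ``tau * (1 - exp(-b / tau))`` and attenuates the
    subtree behind it by ``exp(-b / tau)``.  Edges without length are
    treated as unit length (cladogram).  Default tau = 0.3 x mean leaf
    depth.
    """
    lengths = {}
    for node in tree.postorder(include_self=True):
        if node.parent is not None:
            lengths[node] = node.length if node.length is not None else 1.0
    if tau is None:
        depths = []
        for tip in tree.tips():
            d, nd = 0.0, tip
            while nd.parent is not None:
                d += lengths[nd]
                nd = nd.parent
            depths.append(d)
        tau = 0.3 * float(np.mean(depths))
    if tau <= 0:
        raise ValueError("tau must be positive")

    up: dict = {}
    for node in tree.postorder(include_self=True):
        if node.parent is None:
            continue
        b = lengths[node]
        inner = sum(up[c] for c in node.children)
        up[node] = tau * (1.0 - np.exp(-b / tau)) + np.exp(-b / tau) * inner
    down: dict = {tree: 0.0}
    for node in tree.preorder(include_self=True):
        if node.is_tip():
            continue
        child_up = {c: up[c] for c in node.children}
        total_children = sum(child_up.values())
        for c in node.children:
            b = lengths[c]
            from_above = down[node] + (total_children - child_up[c])
            down[c] = tau * (1.0 - np.exp(-b / tau)) + np.exp(-b / tau) * from_above
    scores = {}
    for node in tree.postorder(include_self=True):
        if node.is_tip():
            scores[node.name] = down[node]
        # internal scores = down + sum of child up-messages, not reported
    return pd.Series(scores, name="lbi").sort_index()


# ---------------------------------------------------------------------------
# loss of chromosome Y


@dataclass(frozen=True)
class LOYConfig:
    """LOY detection thresholds.

    ``p_expected=None`` estimates the expected chrY fragment fraction from
    the aggregate ratio (``method='aggregate'``) or the median per-cell
    ratio (``method='median'``).
    """

    p_expected: float | None = None
    fold_threshold: float = 10.0
    alpha: float = 0.001
    method: str = "aggregate"

    def __post_init__(self):
        if self.p_expected is not None and not 0 <= self.p_expected < 1:
            raise ValueError("p_expected must lie in [0, 1)")
        if self.fold_threshold <= 1 or not 0 < self.alpha < 1:
            raise ValueError("invalid fold threshold or alpha")
        if self.method not in ("aggregate", "median"):
            raise ValueError("method must be 'aggregate' or 'median'")


def detect_loy(fragment_counts: pd.DataFrame, config: LOYConfig = LOYConfig()
               ) -> pd.DataFrame:
    """Call loss of chromosome Y per cell from fragment counts.

    ``fragment_counts``: long table ``cell, chrom, n_fragments``.  A cell
    is LOY when its chrY count is ``fold_threshold``-fold below the
    expected count and the binomial lower-tail probability is below
    ``alpha``.  With an estimated expected fraction of 0 (female sample)
    the detector is disabled.
    """
    wide = (fragment_counts.groupby(["cell", "chrom"])["n_fragments"].sum()
            .unstack(fill_value=0))
    total = wide.sum(axis=1)
    y = wide["chrY"] if "chrY" in wide else pd.Series(0, index=wide.index)
    nonzero = total > 0
    if (~nonzero).any():
        warnings.warn(f"skipping {int((~nonzero).sum())} cells with zero fragments")
    total, y = total[nonzero], y[nonzero]

    p = config.p_expected
    if p is None:
        if config.method == "aggregate":
            p = float(y.sum() / total.sum())
        else:
            p = float((y / total).median())
    if p == 0:
        warnings.warn("expected chrY fraction is 0 (female sample?); "
                      "LOY detection disabled")
        return pd.DataFrame({"cell": total.index, "n_fragments": total,
                             "chrY": y, "expected": 0.0, "p": np.nan,
                             "loy": False}).reset_index(drop=True)
    expected = total * p
    pvals = sps.binom.cdf(y, total, p)
    loy = (y < expected / config.fold_threshold) & (pvals < config.alpha)
    return pd.DataFrame({"cell": total.index, "n_fragments": total.to_numpy(),
                         "chrY": y.to_numpy(), "expected": expected.to_numpy(),
                         "p": pvals, "loy": loy.to_numpy()}).reset_index(drop=True)


def loy_clade_enrichment(clades: dict[str, list[str]], loy_calls: pd.DataFrame,
                         min_clade_size: int = 10) -> pd.DataFrame:
    """Enrichment of LOY cells in clades (or clones).

    Per clade: LOY density, a z-score against the total density under
    binomial variance, a one-tailed exact binomial p-value and Storey
    q-values.  Clades below ``min_clade_size`` are skipped.  With zero LOY
    cells anywhere the table is empty.
    """
    calls = loy_calls.set_index("cell")["loy"]
    total_density = float(calls.mean())
    if calls.sum() == 0:
        return pd.DataFrame(columns=["clade", "n", "n_loy", "density", "z",
                                     "p", "q"])
    rows = []
    for cid, members in clades.items():
        members = [m for m in members if m in calls.index]
        nc = len(members)
        if nc < min_clade_size:
            continue
        k = int(calls.loc[members].sum())
        density = k / nc
        z = (density - total_density) / np.sqrt(
            total_density * (1 - total_density) / nc)
        p = float(sps.binom.sf(k - 1, nc, total_density))
        rows.append((cid, nc, k, density, z, p))
    out = pd.DataFrame(rows, columns=["clade", "n", "n_loy", "density", "z", "p"])
    if len(out):
        out["q"] = storey_qvalue(out["p"].to_numpy())
    return out


def expanded_clade_composition(expanded: dict[str, list[str]],
                               cell_types: pd.Series) -> pd.DataFrame:
    """Cell-type composition of each expanded clade vs the global mix."""
    global_freq = cell_types.value_counts(normalize=True)
    rows = []
    for cid, members in expanded.items():
        types = cell_types.reindex(members).dropna()
        frac = types.value_counts(normalize=True)
        for ct, p0 in global_freq.items():
            rows.append((cid, ct, len(members), float(frac.get(ct, 0.0)),
                         float(p0)))
    return pd.DataFrame(rows, columns=["clade", "cell_type", "n", "proportion",
                                       "expected"])


def cumulative_clone_curve(sizes) -> np.ndarray:
    """Ranked cumulative clone-size curve: fraction of cells covered by the
    largest k clones, k = 0..#clones.  Equal clones give a straight line."""
    sizes = np.sort(np.asarray(list(sizes), dtype=float))[::-1]
    if sizes.size == 0:
        raise ValueError("no clones")
    return np.concatenate([[0.0], np.cumsum(sizes) / sizes.sum()])
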
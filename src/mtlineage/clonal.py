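"""Clone-level behavioural statistics.

Given progeny-to-clone assignments over two sampling timepoints, this
module quantifies each stem-cell clone's output activity (progeny per stem
cell), lineage biases (exact binomial tests of a clone's lineage
proportions against the population background, Fisher-combined across
timepoints, Storey-FDR corrected, with the consistency requirement that the
fold-change direction agree at both timepoints), clone-to-state preferences
(hypergeometric enrichment of clones in cell-state subpopulations), and two
mutation-level analyses used for cell-type origin mapping: selection of
lineage-informative variants and KNN cell-type origin profiles.
"""

from __future__ import annotations

import warnings
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats as sps
from scipy.cluster import hierarchy

from .matrix import weighted_jaccard
from .stats import binom_onesided, binom_twosided, fisher_combine, storey_qvalue

__all__ = [
    "LINEAGE_MAP",
    "LINEAGES",
    "LINEAGE_TYPES",
    "clonal_output",
    "lineage_bias",
    "clone_state_enrichment",
    "select_lineage_informative",
    "celltype_origin_knn",
    "output_bias_correlation",
    "match_clones",
]

#: progeny cell type -> haematopoietic lineage
LINEAGE_MAP = {
    "Mono": "Myeloid", "GMP": "Myeloid", "MDP": "Myeloid", "cDC": "Myeloid",
    "MEP": "Erythroid", "EryP": "Erythroid",
    "MKP": "MK",
    "CD4": "Lymphoid", "CD8": "Lymphoid", "NK": "Lymphoid", "B": "Lymphoid",
    "ProB": "Lymphoid", "CLP": "Lymphoid",
}

LINEAGES = ["Myeloid", "Erythroid", "MK", "Lymphoid"]

LINEAGE_TYPES: dict[str, list[str]] = {}
for _ct, _lin in LINEAGE_MAP.items():
    LINEAGE_TYPES.setdefault(_lin, []).append(_ct)


# ---------------------------------------------------------------------------
# clonal output


def clonal_output(assignments: pd.DataFrame, clone_sizes: pd.Series,
                  timepoints: pd.Series) -> dict:
    """Clonal output activity per timepoint.

    ``assignments``: progeny cells with a ``clone`` column (already
    filtered at the probability cutoff); ``clone_sizes``: number of stem
    cells per clone; ``timepoints``: per-progeny timepoint.

    Returns a dict with the per-(clone, timepoint) table ``activity``
    (progeny count and size-normalised output), the top-vs-bottom decile
    fold change and ranked cumulative-contribution curve per timepoint, and
    Pearson's r of normalised output between the first two timepoints.
    Clones absent at a timepoint are reported as missing, not zero.
    """
    df = assignments.copy()
    df["timepoint"] = timepoints.reindex(df.index)
    counts = (df.groupby(["clone", "timepoint"], observed=True)
              .size().rename("n_progeny").reset_index())
    counts["clone_size"] = counts["clone"].map(clone_sizes)
    if (counts["clone_size"] <= 0).any() or counts["clone_size"].isna().any():
        raise ValueError("every assigned clone needs a positive stem-cell count")
    counts["output"] = counts["n_progeny"] / counts["clone_size"]

    deciles, curves = {}, {}
    for tp, grp in counts.groupby("timepoint"):
        out = np.sort(grp["output"].to_numpy())[::-1]
        k = max(1, len(out) // 10)
        bottom = out[-k:].mean()
        deciles[tp] = float(out[:k].mean() / bottom) if bottom > 0 else np.inf
        ranked = np.sort(grp["n_progeny"].to_numpy())[::-1]
        curves[tp] = np.concatenate([[0.0], np.cumsum(ranked) / ranked.sum()])

    wide = counts.pivot(index="clone", columns="timepoint", values="output")
    pearson = np.nan
    tps = sorted(wide.columns)
    if len(tps) >= 2:
        both = wide[[tps[0], tps[1]]].dropna()
        if len(both) >= 3:
            pearson = float(sps.pearsonr(both[tps[0]], both[tps[1]])[0])
    return {"activity": counts, "decile_fold_change": deciles,
            "cumulative_curves": curves, "timepoint_pearson_r": pearson}


# ---------------------------------------------------------------------------
# lineage bias


def _bias_class(q: float) -> str:
    if q < 0.01:
        return "***"
    if q < 0.05:
        return "**"
    if q < 0.20:
        return "*"
    return ""


def lineage_bias(assignments: pd.DataFrame, lineages: pd.Series,
                 timepoints: pd.Series, background: pd.DataFrame | None = None
                 ) -> pd.DataFrame:
    """Per clone x lineage bias over two timepoints.

    For each timepoint, the clone's lineage count is tested against the
    background lineage proportion of all progeny at that timepoint with a
    one-sided exact binomial test toward the observed direction.  The two
    timepoints' p-values are combined with Fisher's method, Storey q-values
    are computed over the whole clone x lineage family, and a clone is
    flagged biased for a lineage only when the fold-change direction agrees
    at both timepoints.
    """
    df = assignments.copy()
    df["lineage"] = lineages.reindex(df.index)
    df["timepoint"] = timepoints.reindex(df.index)
    tps = sorted(df["timepoint"].unique())
    bg = {}
    for tp in tps:
        sub = df[df["timepoint"] == tp]
        bg[tp] = sub["lineage"].value_counts(normalize=True)

    rows = []
    for clone, grp in df.groupby("clone", observed=True):
        for lin in LINEAGES:
            per_tp = {}
            for tp in tps:
                sub = grp[grp["timepoint"] == tp]
                n = len(sub)
                p0 = float(bg[tp].get(lin, 0.0))
                if n == 0 or p0 == 0.0:
                    if p0 == 0.0 and n > 0:
                        warnings.warn(f"background proportion 0 for {lin}; "
                                      "test skipped")
                    per_tp[tp] = None
                    continue
                k = int((sub["lineage"] == lin).sum())
                fc = (k / n) / p0
                per_tp[tp] = (k, n, p0, fc, float(binom_onesided(k, n, p0)))
            tested = [v for v in per_tp.values() if v is not None]
            if not tested:
                continue
            combined = fisher_combine([v[4] for v in tested])
            fcs = [v[3] for v in tested]
            consistent = all(f > 1 for f in fcs) or all(f < 1 for f in fcs)
            row = {"clone": clone, "lineage": lin, "p_combined": combined,
                   "consistent": bool(consistent and len(tested) == len(tps))}
            for tp in tps:
                v = per_tp[tp]
                row[f"k_t{tp}"] = v[0] if v else np.nan
                row[f"n_t{tp}"] = v[1] if v else np.nan
                row[f"fc_t{tp}"] = v[3] if v else np.nan
                row[f"p_t{tp}"] = v[4] if v else np.nan
            rows.append(row)
    out = pd.DataFrame(rows)
    if len(out):
        out["q"] = storey_qvalue(out["p_combined"].to_numpy())
        out["bias_class"] = [_bias_class(q) if c else ""
                             for q, c in zip(out["q"], out["consistent"])]
        out["biased"] = out["consistent"] & (out["q"] < 0.20)
    return out


# ---------------------------------------------------------------------------
# clone-to-state enrichment


def clone_state_enrichment(clone_labels: pd.Series, state_labels: pd.Series,
                           timepoints: pd.Series, p_combined_max: float = 0.01,
                           fdr_max: float = 0.05, log2fc_min: float = 0.25
                           ) -> pd.DataFrame:
    """Hypergeometric clone-to-state preference over two timepoints.

    Per clone x subpopulation and timepoint: hypergeometric upper-tail p
    and log2 fold change of the clone's representation in the
    subpopulation; Fisher combination across timepoints; Storey q-values
    over the whole family.  Flagged iff combined p < 0.01, q < 0.05 and
    log2 fold change > 0.25 at every timepoint.
    """
    cells = clone_labels.index.intersection(state_labels.index)
    clone_labels = clone_labels.loc[cells]
    state_labels = state_labels.loc[cells]
    timepoints = timepoints.reindex(cells)
    tps = sorted(timepoints.unique())

    rows = []
    for clone in clone_labels.unique():
        for state in state_labels.unique():
            per_tp = []
            for tp in tps:
                sel = timepoints == tp
                N = int(sel.sum())
                K = int((state_labels[sel] == state).sum())
                nc = int((clone_labels[sel] == clone).sum())
                k = int(((clone_labels[sel] == clone)
                         & (state_labels[sel] == state)).sum())
                if N == 0 or K == 0 or nc == 0:
                    per_tp.append(None)
                    continue
                p = float(sps.hypergeom.sf(k - 1, N, K, nc))
                expected = K / N
                log2fc = np.log2((k / nc) / expected) if k > 0 else -np.inf
                per_tp.append((k, nc, K, N, log2fc, p))
            tested = [v for v in per_tp if v is not None]
            if not tested:
                continue
            combined = fisher_combine([v[5] for v in tested])
            row = {"clone": clone, "state": state, "p_combined": combined}
            for tp, v in zip(tps, per_tp):
                row[f"log2fc_t{tp}"] = v[4] if v else np.nan
                row[f"p_t{tp}"] = v[5] if v else np.nan
            row["_all_fc_pass"] = (len(tested) == len(tps)
                                   and all(v[4] > log2fc_min for v in tested))
            rows.append(row)
    out = pd.DataFrame(rows)
    if len(out):
        out["q"] = storey_qvalue(out["p_combined"].to_numpy())
        out["flagged"] = ((out["p_combined"] < p_combined_max)
                          & (out["q"] < fdr_max) & out["_all_fc_pass"])
        out = out.drop(columns=["_all_fc_pass"])
    return out


# ---------------------------------------------------------------------------
# lineage-informative variants & cell-type origins


def select_lineage_informative(C_bin: sp.spmatrix, variant_ids: list[str],
                               trajectories: pd.Series, cells: list[str],
                               alpha: float = 0.05) -> list[str]:
    """Variants whose carrier frequency differs between differentiation
    trajectories.

    For every variant, carrier frequencies are compared between each pair
    of trajectories with a two-sided exact binomial test (observed count of
    one trajectory against the pooled frequency of the pair).  A variant is
    "randomly distributed" — and removed — when all pairwise p-values
    exceed ``alpha``.  Trajectories with fewer than 2 cells are excluded.
    """
    traj = trajectories.reindex(cells)
    groups = {t: np.flatnonzero((traj == t).to_numpy())
              for t in traj.dropna().unique()}
    groups = {t: idx for t, idx in groups.items() if len(idx) >= 2}
    if len(groups) < 2:
        raise ValueError("need at least two trajectories with >= 2 cells")
    B = C_bin.tocsc()
    carriers = {t: np.asarray(B[idx].sum(axis=0)).ravel()
                for t, idx in groups.items()}
    sizes = {t: len(idx) for t, idx in groups.items()}

    names = list(groups)
    informative = np.zeros(B.shape[1], dtype=bool)
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a, b = names[i], names[j]
            ka, kb = carriers[a], carriers[b]
            na, nb = sizes[a], sizes[b]
            pool = (ka + kb) / (na + nb)
            pool = np.clip(pool, 1e-12, 1 - 1e-12)
            informative |= binom_twosided(ka, na, pool) <= alpha
    return [v for v, keep in zip(variant_ids, informative) if keep]


def celltype_origin_knn(C_bin: sp.spmatrix, cells: list[str],
                        cell_types: pd.Series, k: int = 30,
                        priors: np.ndarray | None = None) -> dict:
    """Cell-type origin profiles from mtDNA-sharing neighbourhoods.

    Builds the weighted-Jaccard KNN graph on (lineage-informative)
    variants; for each query cell, the proportion of each target cell type
    among its k nearest neighbours is computed, then averaged per query
    cell type.  Returns raw proportions (rows sum to 1), row-scaled
    (z-score) profiles and a hierarchical-clustering order of query types.
    Cell types with fewer than ``k`` cells fall back to a reduced k and are
    reported.
    """
    D = weighted_jaccard(C_bin, priors)
    types = cell_types.reindex(cells)
    n = len(cells)
    k_eff = min(k, n - 1)
    reduced = []
    if k_eff < k:
        reduced.append(("<all>", k_eff))
    order = np.argsort(D, axis=1, kind="stable")
    neigh = order[:, 1:k_eff + 1]  # skip self (distance 0 on the diagonal)

    type_list = list(pd.unique(types.dropna()))
    t_index = {t: i for i, t in enumerate(type_list)}
    neigh_types = np.asarray(types.iloc[neigh.ravel()].map(t_index)
                             .to_numpy().reshape(neigh.shape))
    prof = np.zeros((n, len(type_list)))
    for ti in range(len(type_list)):
        prof[:, ti] = (neigh_types == ti).mean(axis=1)

    query_profiles = pd.DataFrame(prof, index=cells, columns=type_list)
    agg = query_profiles.groupby(types).mean()
    agg = agg.reindex(index=type_list)
    scaled = agg.sub(agg.mean(axis=1), axis=0)
    sd = agg.std(axis=1).replace(0, 1.0)
    scaled = scaled.div(sd, axis=0)
    if len(agg) > 2:
        Z = hierarchy.linkage(agg.to_numpy(), method="average")
        leaf_order = hierarchy.leaves_list(Z)
    else:
        leaf_order = np.arange(len(agg))
    return {"proportions": agg, "scaled": scaled,
            "row_order": [agg.index[i] for i in leaf_order],
            "reduced_k": reduced}


# ---------------------------------------------------------------------------
# output vs bias


def output_bias_correlation(output: pd.Series, bias_fc: pd.Series) -> dict:
    """Pearson correlation of (scaled) clonal output against (scaled)
    lineage-bias fold change with a Wald p-value and a 95% prediction band.

    Returns r, slope, intercept, p and per-clone prediction-interval
    endpoints.  Zero-variance input is flagged undefined.
    """
    both = pd.concat([output.rename("output"), bias_fc.rename("bias")],
                     axis=1).dropna()
    if len(both) < 3:
        raise ValueError("need at least 3 clones")
    x = both["bias"].to_numpy(dtype=float)
    y = both["output"].to_numpy(dtype=float)
    if np.std(x) == 0 or np.std(y) == 0:
        return {"r": np.nan, "p": np.nan, "undefined": True}
    x = (x - x.mean()) / x.std()
    y = (y - y.mean()) / y.std()
    fit = sps.linregress(x, y)
    n = len(x)
    resid = y - (fit.intercept + fit.slope * x)
    s2 = (resid ** 2).sum() / (n - 2)
    sxx = ((x - x.mean()) ** 2).sum()
    tcrit = sps.t.ppf(0.975, n - 2)
    half = tcrit * np.sqrt(s2 * (1 + 1 / n + (x - x.mean()) ** 2 / sxx))
    band = pd.DataFrame({"x": x, "fit": fit.intercept + fit.slope * x,
                         "lower": fit.intercept + fit.slope * x - half,
                         "upper": fit.intercept + fit.slope * x + half},
                        index=both.index)
    return {"r": float(fit.rvalue), "slope": float(fit.slope),
            "intercept": float(fit.intercept), "p": float(fit.pvalue),
            "band": band, "undefined": False}


def match_clones(defining_a: dict[str, list[str]], defining_b: dict[str, list[str]],
                 min_jaccard: float = 0.5) -> dict[str, str]:
    """Match clones across timepoints by defining-variant overlap.

    Greedy best-first matching of clone pairs with Jaccard similarity of
    their defining variant sets >= ``min_jaccard``; symmetric in its
    arguments (up to key direction) and idempotent.
    """
    pairs = []
    for ca, va in defining_a.items():
        sa = set(va)
        for cb, vb in defining_b.items():
            sb = set(vb)
            union = sa | sb
            if not union:
                continue
            jac = len(sa & sb) / len(union)
            if jac >= min_jaccard:
                pairs.append((jac, ca, cb))
    pairs.sort(key=lambda t: (-t[0], t[1], t[2]))
    used_a, used_b, out = set(), set(), {}
    for jac, ca, cb in pairs:
        if ca in used_a or cb in used_b:
            continue
        out[ca] = cb
        used_a.add(ca)
        used_b.add(cb)
    return out
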
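"""Clone-level statistics tests: output activity, lineage bias (exact
binomial / Fisher oracles), clone-to-state enrichment (hypergeometric
oracle), lineage-informative variant selection and cell-type-origin KNN."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from scipy import stats as sps

from mtlineage.clonal import (
    celltype_origin_knn,
    clonal_output,
    clone_state_enrichment,
    lineage_bias,
    match_clones,
    output_bias_correlation,
    select_lineage_informative,
)
from mtlineage.stats import fisher_combine, storey_qvalue


def _assignments(clone_of: dict):
    return pd.DataFrame({"clone": pd.Series(clone_of)})


class TestClonalOutput:
    def test_normalised_output(self):
        prog = _assignments({f"p{i}": "A" for i in range(50)})
        tp = pd.Series(1, index=prog.index)
        out = clonal_output(prog, pd.Series({"A": 10}), tp)
        act = out["activity"]
        assert act.loc[0, "output"] == 5.0

    def test_equal_clones_unit_decile_fold_change(self):
        clones = {}
        for c in "ABCDEFGHIJ":
            for i in range(20):
                clones[f"{c}{i}"] = c
        prog = _assignments(clones)
        tp = pd.Series(1, index=prog.index)
        sizes = pd.Series(4, index=list("ABCDEFGHIJ"))
        out = clonal_output(prog, sizes, tp)
        assert out["decile_fold_change"][1] == pytest.approx(1.0)

    def test_cumulative_curve_endpoints(self):
        clones = {f"x{i}": f"C{i % 5}" for i in range(57)}
        prog = _assignments(clones)
        tp = pd.Series(1, index=prog.index)
        out = clonal_output(prog, pd.Series(2, index=[f"C{j}" for j in range(5)]), tp)
        curve = out["cumulative_curves"][1]
        assert curve[0] == 0.0
        assert curve[-1] == pytest.approx(1.0, abs=1e-12)
        assert (np.diff(curve) >= 0).all()

    def test_timepoint_correlation_perfect_for_identical(self):
        clone_of, tps = {}, {}
        for c in "ABCD":
            for t in (1, 2):
                for i in range(10 * (ord(c) - 64)):
                    cell = f"{c}_{t}_{i}"
                    clone_of[cell] = c
                    tps[cell] = t
        prog = _assignments(clone_of)
        out = clonal_output(prog, pd.Series(2, index=list("ABCD")),
                            pd.Series(tps))
        assert out["timepoint_pearson_r"] == pytest.approx(1.0)


class TestLineageBias:
    def _dataset(self, myeloid_k=30, n=100, bg_extra=900, bg_rate=0.10):
        """One clone with myeloid_k/n myeloid progeny inside a background
        population with myeloid rate bg_rate, at two timepoints."""
        rows = []
        for tp in (1, 2):
            for i in range(myeloid_k):
                rows.append((f"c{tp}_{i}", "A", "Myeloid", tp))
            for i in range(myeloid_k, n):
                rows.append((f"c{tp}_{i}", "A", "Lymphoid", tp))
            n_bg_mye = int(round(bg_rate * (n + bg_extra))) - myeloid_k
            for i in range(bg_extra):
                lin = "Myeloid" if i < n_bg_mye else "Lymphoid"
                rows.append((f"b{tp}_{i}", "BG", lin, tp))
        df = pd.DataFrame(rows, columns=["cell", "clone", "lineage",
                                         "timepoint"]).set_index("cell")
        return df

    def test_exact_binomial_tail(self):
        df = self._dataset()
        out = lineage_bias(df[["clone"]], df["lineage"], df["timepoint"])
        row = out[(out["clone"] == "A") & (out["lineage"] == "Myeloid")].iloc[0]
        assert row["fc_t1"] == pytest.approx(3.0)
        assert row["p_t1"] == pytest.approx(
            float(sps.binom.sf(29, 100, 0.10)), rel=1e-9)

    def test_background_clone_not_biased(self):
        df = self._dataset(myeloid_k=10)  # matches the 10% background
        out = lineage_bias(df[["clone"]], df["lineage"], df["timepoint"])
        row = out[(out["clone"] == "A") & (out["lineage"] == "Myeloid")].iloc[0]
        assert row["fc_t1"] == pytest.approx(1.0)
        assert not row["biased"]

    def test_fisher_combination_example(self):
        stat = -2 * (np.log(0.05) + np.log(0.05))
        assert stat == pytest.approx(11.98, abs=0.01)
        assert fisher_combine([0.05, 0.05]) == pytest.approx(
            float(sps.chi2.sf(stat, 4)), rel=1e-12)
        assert fisher_combine([0.05, 0.05]) == pytest.approx(0.0175, abs=5e-4)

    def test_bias_requires_consistent_direction(self):
        # enriched at t1, depleted at t2 -> never flagged
        rows = []
        for i in range(40):
            rows.append((f"a1_{i}", "A", "Myeloid" if i < 30 else "Lymphoid", 1))
            rows.append((f"a2_{i}", "A", "Myeloid" if i < 2 else "Lymphoid", 2))
        for tp in (1, 2):
            for i in range(400):
                rows.append((f"b{tp}_{i}", "BG",
                             "Myeloid" if i < 100 else "Lymphoid", tp))
        df = pd.DataFrame(rows, columns=["cell", "clone", "lineage",
                                         "timepoint"]).set_index("cell")
        out = lineage_bias(df[["clone"]], df["lineage"], df["timepoint"])
        row = out[(out["clone"] == "A") & (out["lineage"] == "Myeloid")].iloc[0]
        assert not row["consistent"]
        assert not row["biased"]


class TestCloneStateEnrichment:
    def test_proportional_clone_not_flagged(self):
        cells = [f"c{i}" for i in range(400)]
        clones = pd.Series(["A" if i < 40 else "B" for i in range(400)],
                           index=cells)
        states = pd.Series([f"S{i % 4}" for i in range(400)], index=cells)
        tps = pd.Series([1 if i % 2 else 2 for i in range(400)], index=cells)
        out = clone_state_enrichment(clones, states, tps)
        assert not out["flagged"].any()

    def test_concentrated_clone_exact_hypergeometric(self):
        # 40-cell clone entirely inside a subpopulation holding 10% of cells
        cells = [f"c{i}" for i in range(400)]
        clones = pd.Series(["A" if i < 40 else "B" for i in range(400)],
                           index=cells)
        states = pd.Series(["S" if i < 40 else f"T{i % 3}" for i in range(400)],
                           index=cells)
        tps = pd.Series(1, index=cells)
        out = clone_state_enrichment(clones, states, tps)
        row = out[(out["clone"] == "A") & (out["state"] == "S")].iloc[0]
        oracle = float(sps.hypergeom.sf(39, 400, 40, 40))
        assert row["p_t1"] == pytest.approx(oracle, rel=1e-9)

    def test_flag_requires_both_timepoints(self):
        cells = [f"c{i}" for i in range(800)]
        tps = pd.Series([1 if i < 400 else 2 for i in range(800)], index=cells)
        # clone A concentrated in S only at timepoint 1
        clones = pd.Series(["A" if (i < 40 or 400 <= i < 440) else "B"
                            for i in range(800)], index=cells)
        states = pd.Series(["S" if (i < 40 or (400 <= i and i % 10 == 0))
                            else f"T{i % 3}" for i in range(800)], index=cells)
        out = clone_state_enrichment(clones, states, tps)
        row = out[(out["clone"] == "A") & (out["state"] == "S")].iloc[0]
        if row["log2fc_t2"] <= 0.25:
            assert not row["flagged"]


class TestLineageInformative:
    def _matrix(self, carriers_per_traj, cells_per_traj=300):
        trajs = ["Myeloid", "Lymphoid", "Erythroid", "MK"]
        cells, labels = [], {}
        for t in trajs:
            for i in range(cells_per_traj):
                c = f"{t}_{i}"
                cells.append(c)
                labels[c] = t
        B = np.zeros((len(cells), len(carriers_per_traj)), dtype=int)
        for j, per_traj in enumerate(carriers_per_traj):
            for ti, t in enumerate(trajs):
                k = per_traj[ti]
                for i in range(k):
                    B[cells.index(f"{t}_{i}"), j] = 1
        return sp.csr_matrix(B), cells, pd.Series(labels)

    def test_exclusive_variant_retained(self):
        B, cells, traj = self._matrix([(0, 0, 30, 0)])
        kept = select_lineage_informative(B, ["v0"], traj, cells)
        assert kept == ["v0"]

    def test_uniform_variant_removed(self):
        B, cells, traj = self._matrix([(30, 30, 30, 30)])
        kept = select_lineage_informative(B, ["v0"], traj, cells)
        assert kept == []

    def test_null_variants_mostly_removed(self, rng):
        """Variants with equal carrier frequency in all trajectories are
        declared random in >= 95% of cases (conservative pooled test)."""
        n_var = 200
        trajs = ["Myeloid", "Lymphoid", "Erythroid", "MK"]
        cells = [f"{t}_{i}" for t in trajs for i in range(150)]
        traj = pd.Series([c.split("_")[0] for c in cells], index=cells)
        B = sp.csr_matrix((rng.random((600, n_var)) < 0.1).astype(int))
        kept = select_lineage_informative(B, [f"v{j}" for j in range(n_var)],
                                          traj, cells)
        assert len(kept) <= 0.05 * n_var + 3 * np.sqrt(0.05 * 0.95 * n_var)

    def test_empty_input(self):
        B = sp.csr_matrix((600, 0), dtype=int)
        trajs = ["Myeloid", "Lymphoid"]
        cells = [f"{t}_{i}" for t in trajs for i in range(300)]
        traj = pd.Series([c.split("_")[0] for c in cells], index=cells)
        assert select_lineage_informative(B, [], traj, cells) == []


class TestCelltypeOriginKNN:
    def test_single_cell_type(self):
        B = sp.csr_matrix(np.ones((10, 2), dtype=int))
        cells = [f"c{i}" for i in range(10)]
        types = pd.Series("X", index=cells)
        res = celltype_origin_knn(B, cells, types, k=3)
        assert res["proportions"].shape == (1, 1)
        assert res["proportions"].iloc[0, 0] == 1.0

    def test_pure_clones_map_to_own_type(self, rng):
        # two clones, each with private variants and a pure cell type
        B = np.zeros((40, 10), dtype=int)
        B[:20, :5] = rng.random((20, 5)) < 0.8
        B[20:, 5:] = rng.random((20, 5)) < 0.8
        B[B.sum(axis=1) == 0, 0] = 1
        cells = [f"c{i}" for i in range(40)]
        types = pd.Series(["X"] * 20 + ["Y"] * 20, index=cells)
        res = celltype_origin_knn(sp.csr_matrix(B), cells, types, k=5)
        props = res["proportions"]
        assert props.loc["X", "X"] > 0.9
        assert props.loc["Y", "Y"] > 0.9

    def test_rows_sum_to_one(self, rng):
        B = sp.csr_matrix((rng.random((30, 8)) < 0.4).astype(int))
        cells = [f"c{i}" for i in range(30)]
        types = pd.Series(rng.choice(["X", "Y", "Z"], 30), index=cells)
        res = celltype_origin_knn(B, cells, types, k=5)
        assert np.allclose(res["proportions"].sum(axis=1), 1.0)


class TestOutputBiasCorrelation:
    def test_perfect_linear_relation(self):
        out = pd.Series([1.0, 2, 3, 4, 5], index=list("ABCDE"))
        bias = pd.Series([2.0, 4, 6, 8, 10], index=list("ABCDE"))
        res = output_bias_correlation(out, bias)
        assert res["r"] == pytest.approx(1.0)

    def test_constant_bias_undefined(self):
        out = pd.Series([1.0, 2, 3], index=list("ABC"))
        bias = pd.Series([1.0, 1, 1], index=list("ABC"))
        assert output_bias_correlation(out, bias)["undefined"]

    def test_anticorrelated_simulation_recovers_sign(self, rng):
        hits = 0
        for rep in range(20):
            x = rng.random(30)
            y = -x + rng.normal(0, 0.3, 30)
            res = output_bias_correlation(
                pd.Series(y, index=range(30)), pd.Series(x, index=range(30)))
            hits += res["r"] < 0
        assert hits >= 19


class TestMatchClones:
    def test_symmetric_and_idempotent(self):
        a = {"A1": ["v1", "v2"], "A2": ["v9"]}
        b = {"B1": ["v1", "v2", "v3"], "B2": ["v7"]}
        m1 = match_clones(a, b)
        m2 = match_clones(b, a)
        assert m1 == {"A1": "B1"}
        assert m2 == {"B1": "A1"}
        assert match_clones(a, a) == {"A1": "A1", "A2": "A2"}


class TestStoreyQvalue:
    def test_monotone_and_bounded(self, rng):
        p = rng.random(200)
        q = storey_qvalue(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()
        assert ((q >= 0) & (q <= 1)).all()

    def test_conservative_equals_bh_scaled(self):
        p = np.array([0.001, 0.01, 0.2, 0.8])
        q = storey_qvalue(p, pi0=1.0)
        from statsmodels.stats.multitest import multipletests
        bh = multipletests(p, method="fdr_bh")[1]
        assert np.allclose(q, bh, atol=1e-12)
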
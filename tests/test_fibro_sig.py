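import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from conftest import make_dense_dataset
from mloykit import fibro_sig, sc_loy, synthdata
from mloykit.fibro_sig import (
    default_gene_sets,
    dge_loy_vs_wt,
    expression_condition_test,
    loy_activation_regression,
    module_score,
    ora,
    read_gmt,
    score_group_test,
    write_gmt,
)
from mloykit.sc_loy import call_loy, qc_filter_cells


def ranksum_permutation_oracle(x, y):
    """Exact two-sided rank-sum p by full enumeration of group assignments."""
    pooled = np.concatenate([x, y])
    n1 = len(x)
    ranks = stats.rankdata(pooled)
    obs = ranks[:n1].sum()
    mean = n1 * (len(pooled) + 1) / 2
    stat_obs = abs(obs - mean)
    count = total = 0
    for comb in itertools.combinations(range(len(pooled)), n1):
        s = ranks[list(comb)].sum()
        total += 1
        if abs(s - mean) >= stat_obs - 1e-9:
            count += 1
    return count / total


def newton_logistic(X, y, iters=50):
    """From-scratch Newton-Raphson logistic fit (oracle)."""
    beta = np.zeros(X.shape[1])
    for _ in range(iters):
        p = 1 / (1 + np.exp(-X @ beta))
        W = p * (1 - p)
        H = X.T @ (X * W[:, None])
        g = X.T @ (y - p)
        beta = beta + np.linalg.solve(H, g)
    p = 1 / (1 + np.exp(-X @ beta))
    ll = np.sum(y * np.log(p) + (1 - y) * np.log1p(-p))
    return beta, ll


class TestGmt:
    def test_roundtrip(self, tmp_path):
        sets = {"A": ["g1", "g2"], "B": ["g3"]}
        write_gmt(sets, tmp_path / "x.gmt")
        assert read_gmt(tmp_path / "x.gmt") == sets

    def test_default_fixtures_load(self):
        sets = default_gene_sets()
        assert "TGF_SIGNALING" in sets
        assert "FIBROBLAST_ACTIVATION" in sets
        assert all(len(v) > 5 for v in sets.values())


class TestModuleScore:
    def toy(self):
        # 6 genes, 2 bins of 3; genes in g1's bin share identical expression
        # so the control mean is deterministic whatever the sampling does.
        mat = np.array(
            [
                [10, 20, 30],  # g_low_a  (bin 0 after ranking)
                [10, 20, 30],  # g_low_b
                [10, 20, 30],  # g_low_c
                [90, 80, 70],  # g_high_a (bin 1)
                [90, 80, 70],  # g_high_b
                [90, 80, 70],  # g_high_c
            ]
        )
        genes = ["gla", "glb", "glc", "gha", "ghb", "ghc"]
        return make_dense_dataset(mat, genes, msy=["gla"])

    def test_toy_score_matches_hand_computation(self):
        ds = self.toy()
        score = module_score(ds, ["gha"], n_bins=2, n_ctrl=5, seed=0)
        norm = sc_loy.normalize_log1p(ds.counts)
        # all bin-1 genes identical -> control mean == gene value -> score 0
        assert np.allclose(score.values, 0.0, atol=1e-12)

    def test_self_control_expectation_zero(self):
        rng = np.random.default_rng(2)
        mat = rng.poisson(5, size=(60, 40))
        ds = make_dense_dataset(mat, [f"G{i}" for i in range(60)], msy=["G0"])
        all_genes = [f"G{i}" for i in range(60)]
        scores = [
            module_score(ds, all_genes, n_bins=6, n_ctrl=50, seed=s).values
            for s in range(20)
        ]
        assert abs(np.mean(scores)) < 0.02

    def test_additive_shift_invariance(self):
        ds = self.toy()
        s1 = module_score(ds, ["gha", "glb"], n_bins=2, n_ctrl=10, seed=3)
        # shifting every gene's normalised expression by c cancels in the
        # difference of means; emulate via a wrapper matrix check on norm
        norm = sc_loy.normalize_log1p(ds.counts)
        shifted = norm + 1.7
        gidx = ds.genes.index
        rng = np.random.default_rng(3)
        # recompute both scores from the same bins/controls
        avg = norm.mean(axis=1)
        order = np.argsort(avg, kind="stable")
        bins = np.empty(len(avg), dtype=int)
        bins[order] = np.floor(np.arange(len(avg)) * 2 / len(avg)).astype(int)
        rows = gidx.get_indexer(["gha", "glb"])
        ctrl = np.concatenate(
            [
                rng.choice(np.flatnonzero(bins == bins[r]), size=10, replace=True)
                for r in rows
            ]
        )
        for m in (norm, shifted):
            diff = m[rows].mean(axis=0) - m[ctrl].mean(axis=0)
            assert np.allclose(diff, s1.values, atol=1e-12)

    def test_bit_reproducible(self):
        ds = self.toy()
        a = module_score(ds, ["gha", "glb"], seed=11, n_bins=2)
        b = module_score(ds, ["gha", "glb"], seed=11, n_bins=2)
        assert np.array_equal(a.values, b.values)

    def test_variance_shrinks_with_more_controls(self):
        rng = np.random.default_rng(4)
        mat = rng.poisson(5, size=(200, 30))
        ds = make_dense_dataset(mat, [f"G{i}" for i in range(200)], msy=["G0"])
        def spread(n_ctrl):
            reps = [
                module_score(ds, ["G10"], n_bins=10, n_ctrl=n_ctrl, seed=s).values
                for s in range(30)
            ]
            return np.var(np.stack(reps), axis=0).mean()
        assert spread(200) < spread(2)

    def test_empty_intersection_rejected(self):
        with pytest.raises(ValueError, match="no gene of the set"):
            module_score(self.toy(), ["NOPE"], seed=0)


class TestDge:
    def test_identical_groups_null(self, permissive_qc):
        rng = np.random.default_rng(5)
        block = rng.poisson(4, size=(30, 50))
        mat = np.hstack([block, block])  # LOY cells duplicate WT cells
        genes = ["YGENE"] + [f"G{i}" for i in range(29)]
        mat[0, :50] = 1  # WT half expresses the MSY gene
        mat[0, 50:] = 0  # LOY half: absent
        ds = make_dense_dataset(mat, genes, msy=["YGENE"])
        calls = call_loy(ds, qc_filter_cells(ds, **permissive_qc))
        res = dge_loy_vs_wt(ds, calls, min_cells=10, min_reads=0)
        non_msy = res[~res["is_msy"]]
        assert np.allclose(non_msy["log2fc"], 0.0, atol=0.05)
        assert (non_msy["p_value"] > 0.5).mean() > 0.9

    def test_ranksum_matches_permutation_oracle(self):
        rng = np.random.default_rng(6)
        for n1, n2 in [(5, 5), (6, 8), (10, 10), (3, 9)]:
            x = rng.normal(size=n1)
            y = rng.normal(0.5, 1, size=n2)
            p_impl = stats.mannwhitneyu(
                x, y, alternative="two-sided", method="exact"
            ).pvalue
            p_oracle = ranksum_permutation_oracle(x, y)
            assert p_impl == pytest.approx(p_oracle, rel=1e-9)

    def test_recovers_profib_effect(self, permissive_qc):
        ds, truth = synthdata.gen_sc_cohort(
            n_donors_per_condition={"IPF": 2},
            cells_per_donor=1000,
            celltype_props={"macrophage": 1.0},
            loy_frac_by_condition_and_type={"IPF": {"macrophage": 0.5}},
            profib_effect=np.log(2),
            profib_genes=("FN1",),
            profib_base_mean=10.0,
            depth_dist=("constant", 6000.0),
            seed=17,
        )
        calls = call_loy(ds, qc_filter_cells(ds, **permissive_qc))
        res = dge_loy_vs_wt(
            ds, calls, min_cells=100, min_reads=4000, target_sum=1e5
        ).set_index("gene")
        assert res.loc["FN1", "log2fc"] == pytest.approx(1.0, abs=0.1)
        assert res.loc["FN1", "q_value"] < 1e-6
        # MSY genes are flagged and maximally down
        assert res[res["is_msy"]]["log2fc"].max() < 0

    def test_insufficient_cells_raises(self, permissive_qc):
        mat = np.array([[0, 1], [4, 4]])
        ds = make_dense_dataset(mat, ["Y1", "G1"], msy=["Y1"])
        calls = call_loy(ds, qc_filter_cells(ds, **permissive_qc))
        with pytest.raises(ValueError, match="insufficient cells"):
            dge_loy_vs_wt(ds, calls, min_cells=20, min_reads=0)

    def test_bh_monotonicity(self, small_sc_dataset, permissive_qc):
        ds, _ = small_sc_dataset
        calls = call_loy(ds, qc_filter_cells(ds, **permissive_qc))
        res = dge_loy_vs_wt(ds, calls, min_cells=10, min_reads=0)
        s = res.sort_values("p_value")
        assert (np.diff(s["q_value"].values) >= -1e-12).all()
        assert (s["q_value"].values >= s["p_value"].values - 1e-12).all()


class TestScoreGroupTest:
    def test_identical_distributions(self):
        rng = np.random.default_rng(7)
        vals = rng.normal(size=400)
        scores = pd.Series(vals)
        calls = pd.DataFrame(
            {"is_loy": pd.array([True, False] * 200, dtype="boolean")}
        )
        groups = pd.Series(["macrophage"] * 400)
        out = score_group_test(scores, calls, groups)
        assert out.iloc[0]["p_value"] > 0.01

    def test_one_sd_shift_detected(self):
        rng = np.random.default_rng(8)
        loy = rng.normal(1.0, 1.0, 200)
        wt = rng.normal(0.0, 1.0, 200)
        scores = pd.Series(np.concatenate([loy, wt]))
        calls = pd.DataFrame(
            {"is_loy": pd.array([True] * 200 + [False] * 200, dtype="boolean")}
        )
        groups = pd.Series(["g"] * 400)
        out = score_group_test(scores, calls, groups)
        assert out.iloc[0]["p_value"] < 1e-10

    def test_bonferroni_definitional(self):
        rng = np.random.default_rng(9)
        n = 50
        scores, is_loy, groups = [], [], []
        for g in range(4):
            scores += list(rng.normal(size=2 * n))
            is_loy += [True] * n + [False] * n
            groups += [f"lineage{g}"] * 2 * n
        out = score_group_test(
            pd.Series(scores),
            pd.DataFrame({"is_loy": pd.array(is_loy, dtype="boolean")}),
            pd.Series(groups),
        )
        assert np.allclose(
            out["p_adjusted"], np.minimum(1.0, out["p_value"] * len(out))
        )


class TestExpressionConditionTest:
    def test_null_lr_statistic(self):
        rng = np.random.default_rng(10)
        n = 400
        detected = rng.random(n) < 0.4
        mat = np.vstack([detected.astype(int), np.full(n, 5)])
        ds = make_dense_dataset(mat, ["FN1", "G1"], msy=["G1"])
        calls = pd.DataFrame(
            {"is_loy": pd.array(rng.random(n) < 0.5, dtype="boolean")},
            index=ds.cells.index,
        )
        conds = pd.Series(
            np.where(np.arange(n) % 2 == 0, "IPF", "control"), index=ds.cells.index
        )
        out = expression_condition_test(ds, calls, "FN1", conds)
        assert (out["lr_stat"] < 6).all()

    def test_or_recovery(self):
        rng = np.random.default_rng(11)
        n = 1000
        is_loy = np.arange(n) < n // 2
        p = np.where(is_loy, 0.6, 0.3)
        detected = rng.random(n) < p
        mat = np.vstack([detected.astype(int), np.full(n, 5)])
        ds = make_dense_dataset(mat, ["FN1", "G1"], msy=["G1"])
        calls = pd.DataFrame(
            {"is_loy": pd.array(is_loy, dtype="boolean")}, index=ds.cells.index
        )
        conds = pd.Series(["IPF"] * (n // 2) + ["control"] * (n // 2),
                          index=ds.cells.index)
        out = expression_condition_test(ds, calls, "FN1", conds)
        # generating OR = (0.6/0.4)/(0.3/0.7) = 3.5
        for _, row in out.iterrows():
            assert row["odds_ratio"] == pytest.approx(3.5, rel=0.45)
            assert row["p_value"] < 0.01

    def test_lr_matches_newton_oracle(self):
        rng = np.random.default_rng(12)
        n = 100
        is_loy = rng.random(n) < 0.5
        detected = rng.random(n) < np.where(is_loy, 0.7, 0.3)
        mat = np.vstack([detected.astype(int), np.full(n, 5)])
        ds = make_dense_dataset(mat, ["FN1", "G1"], msy=["G1"])
        calls = pd.DataFrame(
            {"is_loy": pd.array(is_loy, dtype="boolean")}, index=ds.cells.index
        )
        conds = pd.Series(["IPF"] * n, index=ds.cells.index)
        conds.iloc[: n // 2] = "control"
        out = expression_condition_test(ds, calls, "FN1", conds).set_index("condition")
        for cond in ("IPF", "control"):
            sub = conds == cond
            y = detected[sub.values].astype(float)
            x = is_loy[sub.values].astype(float)
            X = np.column_stack([np.ones_like(x), x])
            _, ll_full = newton_logistic(X, y)
            _, ll_null = newton_logistic(np.ones((len(y), 1)), y)
            lr = 2 * (ll_full - ll_null)
            assert out.loc[cond, "lr_stat"] == pytest.approx(lr, abs=1e-6)


class TestOra:
    def test_query_equals_universe_set(self):
        res = ora(["a", "b"], {"s": ["a", "b"]}, ["a", "b"])
        assert res.iloc[0]["p_value"] == pytest.approx(1.0)

    def test_brute_force_tail_sum(self):
        universe = [f"g{i}" for i in range(1000)]
        gene_set = universe[:50]
        query = universe[:20] + universe[500:580]  # overlap 20, query 100
        res = ora(query, {"s": gene_set}, universe)
        # oracle: explicit hypergeometric tail sum with exact integers
        total = math.comb(1000, 100)
        tail = sum(
            math.comb(50, k) * math.comb(950, 100 - k) for k in range(20, 51)
        )
        assert res.iloc[0]["p_value"] == pytest.approx(tail / total, rel=1e-9)
        assert res.iloc[0]["overlap"] == 20

    def test_disjoint_query(self):
        universe = [f"g{i}" for i in range(100)]
        res = ora(universe[:10], {"s": universe[50:60]}, universe)
        assert res.iloc[0]["fold_enrichment"] == 0.0
        assert res.iloc[0]["p_value"] == pytest.approx(1.0)

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError, match="empty universe"):
            ora(["a"], {"s": ["a"]}, [])

    def test_query_outside_universe_rejected(self):
        with pytest.raises(ValueError, match="contained"):
            ora(["zz"], {"s": ["a"]}, ["a"])


class TestActivationRegression:
    def test_collinear_points(self):
        df = pd.DataFrame(
            {"percent_loy": [1.0, 2.0, 3.0], "activation_score": [0.1, 0.2, 0.3]}
        )
        res = loy_activation_regression(df)
        assert res.r_squared == pytest.approx(1.0)
        assert res.slope == pytest.approx(0.1)

    def test_recovers_generated_slope(self):
        rng = np.random.default_rng(13)
        pct = rng.uniform(0, 60, 40)
        score = 0.01 * pct + rng.normal(0, 0.05, 40)
        df = pd.DataFrame({"percent_loy": pct, "activation_score": score})
        res = loy_activation_regression(df)
        assert abs(res.slope - 0.01) < 2 * res.slope_se

    def test_order_invariance(self):
        rng = np.random.default_rng(14)
        df = pd.DataFrame(
            {
                "percent_loy": rng.uniform(0, 50, 10),
                "activation_score": rng.normal(size=10),
            }
        )
        res1 = loy_activation_regression(df)
        res2 = loy_activation_regression(df.sample(frac=1, random_state=1))
        assert res1.slope == pytest.approx(res2.slope)

    def test_too_few_donors(self):
        df = pd.DataFrame({"percent_loy": [1, 2], "activation_score": [0, 1]})
        with pytest.raises(ValueError, match=">= 3 donors"):
            loy_activation_regression(df)

    def test_zero_variance_rejected(self):
        df = pd.DataFrame(
            {"percent_loy": [5, 5, 5], "activation_score": [0.0, 0.5, 1.0]}
        )
        with pytest.raises(ValueError, match="zero variance"):
            loy_activation_regression(df)


class TestNormalizationContract:
    def test_rank_tests_invariant_to_target_sum(self, permissive_qc):
        mat = np.random.default_rng(15).poisson(6, size=(20, 60))
        mat[0, :30] = 0  # half the cells lack the MSY gene -> LOY
        mat[0, 30:] = 2
        ds = make_dense_dataset(mat, [f"G{i}" for i in range(20)], msy=["G0"])
        calls = call_loy(ds, qc_filter_cells(ds, **permissive_qc))
        r1 = dge_loy_vs_wt(ds, calls, min_cells=1, min_reads=0, target_sum=1e4)
        r2 = dge_loy_vs_wt(ds, calls, min_cells=1, min_reads=0, target_sum=1e6)
        assert np.allclose(r1["p_value"], r2["p_value"])
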
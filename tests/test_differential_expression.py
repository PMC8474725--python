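"""Two-sample fits, empirical-Bayes moderation, BH and clustering."""

import itertools
import math
import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from mirqpcr.differential_expression import (
    DesignSpec,
    FitResult,
    ModerationParams,
    adjust_pvalues,
    benjamini_hochberg,
    estimate_moderation,
    fit_group_model,
    hierarchical_clustering,
    moderated_t_table,
)
from mirqpcr.errors import DesignError

from conftest import make_nm


def two_group_design(n1=2, n2=2, alpha=0.05):
    groups = {f"T{i}": "test" for i in range(n1)}
    groups.update({f"R{i}": "ref" for i in range(n2)})
    return DesignSpec(groups, ("test", "ref"), alpha)


def nm_from_rows(rows):
    rows = np.asarray(rows, dtype=float)
    n1 = n2 = rows.shape[1] // 2
    samples = [f"T{i}" for i in range(n1)] + [f"R{i}" for i in range(n2)]
    return make_nm(rows, [f"m{i}" for i in range(len(rows))], samples)


class TestFitGroupModel:
    def test_zero_variance_rows(self):
        nm = nm_from_rows([[1.0, 1.0, 0.0, 0.0]])
        fit = fit_group_model(nm, two_group_design())
        row = fit.table.iloc[0]
        assert row["beta"] == 1.0 and row["s2"] == 0.0 and row["df"] == 2.0

    def test_pooled_variance_by_hand(self):
        # test {2,0}: var 2; ref {1,-1}: var 2; pooled (2+2)/2 = 2
        nm = nm_from_rows([[2.0, 0.0, 1.0, -1.0]])
        fit = fit_group_model(nm, two_group_design())
        row = fit.table.iloc[0]
        assert row["beta"] == pytest.approx(1.0)
        assert row["s2"] == pytest.approx(2.0)
        assert row["df"] == 2.0
        assert row["v"] == pytest.approx(1.0)

    def test_mirna_with_one_usable_sample_is_dropped_and_listed(self):
        nm = nm_from_rows([[1.0, np.nan, 0.0, 0.0], [1.0, 2.0, 0.0, 0.0]])
        fit = fit_group_model(nm, two_group_design())
        assert fit.dropped == ["m0"]
        assert list(fit.table.index) == ["m1"]

    def test_too_small_group_is_design_error(self):
        with pytest.raises(DesignError, match=">=2"):
            DesignSpec({"T0": "test", "R0": "ref", "R1": "ref"}, ("test", "ref"))


class TestEstimateModeration:
    def test_equal_variances_give_infinite_prior_df(self):
        table = pd.DataFrame(
            {"beta": [1.0, 2.0], "s2": [1.0, 1.0], "df": [4.0, 4.0], "v": [0.5, 0.5],
             "n_test": [3, 3], "n_ref": [3, 3]},
            index=["m0", "m1"],
        )
        params = estimate_moderation(FitResult(table))
        assert math.isinf(params.d0)
        # MoM on log s2 keeps the chi-square sampling-bias correction even in
        # the homogeneous case: s02 = s2 * (d/2) / exp(psi(d/2))
        from scipy.special import digamma

        expected = 1.0 * 2.0 / math.exp(float(digamma(2.0)))
        assert params.s02 == pytest.approx(expected, rel=1e-9)

    def test_recovers_scaled_f_parameters(self):
        # s_g^2 / s0^2 ~ F(d, d0) under the hierarchical variance model
        rng = np.random.default_rng(2024)
        d, d0_true, s02_true = 10.0, 4.0, 1.0
        s2 = s02_true * stats.f.rvs(d, d0_true, size=2000, random_state=rng)
        table = pd.DataFrame(
            {"beta": 0.0, "s2": s2, "df": d, "v": 0.2, "n_test": 6, "n_ref": 6},
            index=[f"m{i}" for i in range(2000)],
        )
        params = estimate_moderation(FitResult(table))
        assert params.d0 == pytest.approx(d0_true, rel=0.25)
        assert params.s02 == pytest.approx(s02_true, rel=0.10)

    def test_all_zero_variance_raises(self):
        table = pd.DataFrame(
            {"beta": [1.0, 1.0], "s2": [0.0, 0.0], "df": [2.0, 2.0], "v": [1.0, 1.0],
             "n_test": [2, 2], "n_ref": [2, 2]},
            index=["m0", "m1"],
        )
        with pytest.raises(DesignError, match="zero variance"):
            estimate_moderation(FitResult(table))


class TestModeratedT:
    def test_d0_zero_limit_equals_classic_pooled_t(self):
        rng = np.random.default_rng(9)
        rows = rng.normal(0, 1, size=(100, 10))
        nm = nm_from_rows(rows)
        design = two_group_design(5, 5)
        fit = fit_group_model(nm, design)
        params = ModerationParams(d0=1.0, s02=1.0)
        params.d0 = 0.0  # unmoderated limit; construction enforces d0 > 0
        tbl = moderated_t_table(fit, params, design)
        t_ref, p_ref = stats.ttest_ind(rows[:, :5], rows[:, 5:], axis=1)
        tbl = tbl.loc[[f"m{i}" for i in range(100)]]
        np.testing.assert_allclose(tbl["t"].to_numpy(), t_ref, rtol=1e-12)
        np.testing.assert_allclose(tbl["p_value"].to_numpy(), p_ref, rtol=1e-12)

    def test_d0_infinite_uses_prior_variance_and_normal_reference(self):
        nm = nm_from_rows([[1.0, 2.0, 0.0, -1.0]])
        design = two_group_design()
        fit = fit_group_model(nm, design)
        params = ModerationParams(d0=math.inf, s02=4.0)
        tbl = moderated_t_table(fit, params, design)
        beta, v = fit.table["beta"].iloc[0], fit.table["v"].iloc[0]
        assert tbl["t"].iloc[0] == pytest.approx(beta / math.sqrt(4.0 * v))
        assert tbl["p_value"].iloc[0] == pytest.approx(2 * stats.norm.sf(abs(tbl["t"].iloc[0])))

    def test_hand_computed_moderated_statistic(self):
        # beta=1, s2=1, d=2, d0=2, s02=1, v=1 -> s2_post=1, t=1, df=4
        table = pd.DataFrame(
            {"beta": [1.0], "s2": [1.0], "df": [2.0], "v": [1.0], "n_test": [2], "n_ref": [2]},
            index=["m0"],
        )
        tbl = moderated_t_table(
            FitResult(table), ModerationParams(d0=2.0, s02=1.0), two_group_design()
        )
        assert tbl["t"].iloc[0] == pytest.approx(1.0)
        assert tbl["df_total"].iloc[0] == 4.0
        assert tbl["p_value"].iloc[0] == pytest.approx(0.3739, abs=1e-4)

    def test_contrast_swap_negates_effects_keeps_p(self):
        rng = np.random.default_rng(17)
        rows = rng.normal(0, 1, size=(30, 8))
        nm = nm_from_rows(rows)
        fwd = two_group_design(4, 4)
        rev = DesignSpec(fwd.group_of, ("ref", "test"))
        fit_f = fit_group_model(nm, fwd)
        fit_r = fit_group_model(nm, rev)
        params = estimate_moderation(fit_f)
        tf = moderated_t_table(fit_f, params, fwd).sort_index()
        tr = moderated_t_table(fit_r, params, rev).sort_index()
        np.testing.assert_allclose(tf["logFC"], -tr["logFC"], rtol=1e-12)
        np.testing.assert_allclose(tf["t"], -tr["t"], rtol=1e-12)
        np.testing.assert_allclose(tf["p_value"], tr["p_value"], rtol=1e-12)

    def test_matches_limma_reference_implementation(self, tmp_path):
        """Full eBayes route cross-checked against Bioconductor limma via Rscript."""
        if shutil.which("Rscript") is None:
            pytest.skip("Rscript not on PATH")
        rng = np.random.default_rng(3)
        X = rng.normal(0, 1, (50, 8))
        X[:10, 4:] += 1.5
        mat = tmp_path / "mat.tsv"
        out = tmp_path / "limma.csv"
        pd.DataFrame(
            X, index=[f"m{i}" for i in range(50)], columns=[f"s{j}" for j in range(8)]
        ).to_csv(mat, sep="\t")
        rcode = f"""
        suppressMessages(library(limma))
        x <- as.matrix(read.delim("{mat}", row.names=1))
        design <- cbind(Intercept=1, grp=c(0,0,0,0,1,1,1,1))
        fit <- eBayes(lmFit(x, design))
        out <- data.frame(t=fit$t[,"grp"], p=fit$p.value[,"grp"],
                          d0=fit$df.prior, s02=fit$s2.prior)
        write.csv(out, "{out}")
        """
        subprocess.run(["Rscript", "-e", rcode], check=True, capture_output=True)
        ref = pd.read_csv(out, index_col=0)

        nm = make_nm(X, [f"m{i}" for i in range(50)], [f"s{j}" for j in range(8)])
        design = DesignSpec(
            {f"s{j}": ("test" if j >= 4 else "ref") for j in range(8)}, ("test", "ref")
        )
        fit = fit_group_model(nm, design)
        params = estimate_moderation(fit)
        tbl = moderated_t_table(fit, params, design)
        ref = ref.loc[tbl.index]
        assert params.d0 == pytest.approx(ref["d0"].iloc[0], rel=1e-5)
        assert params.s02 == pytest.approx(ref["s02"].iloc[0], rel=1e-5)
        np.testing.assert_allclose(tbl["t"], ref["t"], rtol=1e-9)
        np.testing.assert_allclose(tbl["p_value"], ref["p"], rtol=1e-9)


def bh_stepwise(p):
    """Textbook step-up BH, written from the definition."""
    p = list(p)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adj_sorted = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        running = min(running, m * p[order[rank - 1]] / rank)
        adj_sorted[rank - 1] = running
    adj = [0.0] * m
    for rank, i in enumerate(order):
        adj[i] = adj_sorted[rank]
    return adj


class TestBenjaminiHochberg:
    @pytest.mark.parametrize(
        "p,expected",
        [
            ([0.03], [0.03]),
            ([0.01, 0.02, 0.04], [0.03, 0.03, 0.04]),
            ([1.0, 1.0, 1.0], [1.0, 1.0, 1.0]),
        ],
    )
    def test_hand_examples(self, p, expected):
        np.testing.assert_allclose(benjamini_hochberg(p), expected, rtol=1e-12)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            benjamini_hochberg([0.5, 1.5])

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=10))
    def test_matches_stepwise_definition_and_dominates_raw(self, p):
        adj = benjamini_hochberg(p)
        np.testing.assert_allclose(adj, bh_stepwise(p), rtol=1e-12, atol=1e-15)
        assert np.all(adj >= np.asarray(p) - 1e-15)

    @settings(derandomize=True, max_examples=30)
    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=2, max_size=10),
        st.randoms(use_true_random=False),
    )
    def test_permutation_equivariance(self, p, rnd):
        perm = list(range(len(p)))
        rnd.shuffle(perm)
        adj = benjamini_hochberg(p)
        adj_perm = benjamini_hochberg([p[i] for i in perm])
        np.testing.assert_allclose(adj_perm, [adj[i] for i in perm], rtol=1e-12, atol=1e-15)

    def test_bonferroni_option(self):
        np.testing.assert_allclose(
            adjust_pvalues([0.01, 0.4], method="bonferroni"), [0.02, 0.8]
        )


def naive_complete_linkage(X):
    """O(n^3) agglomeration; returns [(merged leaf set, height), ...]."""
    clusters = [frozenset([i]) for i in range(len(X))]
    merges = []
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(range(len(clusters)), 2):
            d = max(
                np.linalg.norm(X[i] - X[j])
                for i in clusters[a]
                for j in clusters[b]
            )
            if best is None or d < best[0]:
                best = (d, a, b)
        d, a, b = best
        merged = clusters[a] | clusters[b]
        clusters = [c for k, c in enumerate(clusters) if k not in (a, b)] + [merged]
        merges.append((merged, d))
    return merges


def linkage_merges(Z, n):
    members = {i: frozenset([i]) for i in range(n)}
    merges = []
    for step, (a, b, h, _) in enumerate(Z):
        merged = members[int(a)] | members[int(b)]
        members[n + step] = merged
        merges.append((merged, h))
    return merges


class TestHierarchicalClustering:
    def test_identical_rows_merge_at_height_zero(self):
        df = pd.DataFrame([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0], [9.0, 1.0, 4.0]],
                          index=["a", "b", "c"])
        res = hierarchical_clustering(df)
        merged = linkage_merges(res.row_linkage, 3)
        assert merged[0] == (frozenset({0, 1}), 0.0)

    def test_fewer_than_two_rows_skips(self):
        df = pd.DataFrame([[1.0, 2.0]], index=["a"])
        assert hierarchical_clustering(df) is None

    def test_matches_naive_agglomeration(self):
        rng = np.random.default_rng(21)
        df = pd.DataFrame(rng.normal(size=(6, 5)), index=[f"m{i}" for i in range(6)])
        res = hierarchical_clustering(df)
        from mirqpcr.differential_expression import zscore_rows

        Z = zscore_rows(df).to_numpy()
        expected = naive_complete_linkage(Z)
        got = linkage_merges(res.row_linkage, 6)
        for (set_e, h_e), (set_g, h_g) in zip(expected, got):
            assert set_e == set_g
            assert h_g == pytest.approx(h_e, rel=1e-9)

    def test_deterministic(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame(rng.normal(size=(8, 6)))
        r1 = hierarchical_clustering(df)
        r2 = hierarchical_clustering(df)
        np.testing.assert_array_equal(r1.row_linkage, r2.row_linkage)
        assert r1.row_order == r2.row_order
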
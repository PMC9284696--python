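"""Moderated t, BH adjustment, screening and clustering tests."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.multitest import multipletests

from cernet import diffexpr
from cernet.datatypes import ExpressionMatrix, InputError

from oracles import bh_stepup


def make_matrix(values, n_control, n_case):
    values = np.asarray(values, dtype=float)
    cols = [f"c{i}" for i in range(n_control)] + [f"t{i}" for i in range(n_case)]
    df = pd.DataFrame(values, columns=cols,
                      index=[f"f{i}" for i in range(values.shape[0])])
    groups = pd.Series(["control"] * n_control + ["case"] * n_case, index=cols)
    return ExpressionMatrix(df, groups)


class TestLog2FoldChange:
    def test_mean_difference(self):
        m = make_matrix([[6, 6, 6, 8, 8, 8], [5, 5, 5, 6, 6, 6]], 3, 3)
        lfc = diffexpr.log2_fold_change(m)
        assert lfc["f0"] == pytest.approx(2.0)
        assert lfc["f1"] == pytest.approx(1.0)

    def test_sign_convention_case_minus_control(self):
        m = make_matrix([[6, 6, 6, 6, 6, 5, 5, 5, 5, 5]], 5, 5)
        assert diffexpr.log2_fold_change(m)["f0"] == pytest.approx(-1.0)

    def test_identical_groups_zero(self):
        m = make_matrix([[7, 8, 9, 7, 8, 9]], 3, 3)
        assert diffexpr.log2_fold_change(m)["f0"] == pytest.approx(0.0)


class TestModeratedT:
    def test_identical_groups_give_t0_p1(self):
        rng = np.random.default_rng(0)
        block = rng.normal(8, 1, (30, 4))
        m = make_matrix(np.hstack([block, block]), 4, 4)
        tab = diffexpr.moderated_t_test(m)
        assert np.allclose(tab["log2fc"], 0)
        assert np.allclose(tab["t"], 0)
        assert np.allclose(tab["p"], 1)

    def test_equal_variances_reduce_to_ordinary_t(self):
        # every feature has the same sample variance: shrinkage is a no-op
        base = np.array([[0.0, 1.0, 2.0, 3.0, 5.0, 6.0]])
        offsets = np.arange(12)[:, None]
        m = make_matrix(base + offsets, 3, 3)
        mod = diffexpr.moderated_t_test(m, moderated=True)
        plain = diffexpr.moderated_t_test(m, moderated=False)
        assert np.max(np.abs(mod["t"] - plain["t"])) < 1e-9

    def test_matches_limma_ebayes(self, tmp_path):
        """Cross-check statistic, p and prior fit against R/limma."""
        rng = np.random.default_rng(42)
        vals = rng.normal(8, 1, (60, 10)) * rng.gamma(2, 1, (60, 1)) ** 0.5
        vals[:8, 5:] += 2.0
        m = make_matrix(vals, 5, 5)
        expr = tmp_path / "expr.tsv"
        m.values.to_csv(expr, sep="\t")
        script = tmp_path / "limma.R"
        script.write_text(textwrap.dedent(f"""
            suppressMessages(library(limma))
            x <- as.matrix(read.delim("{expr}", row.names=1))
            design <- cbind(Intercept=1, case=c(rep(0,5), rep(1,5)))
            fit <- eBayes(lmFit(x, design))
            out <- data.frame(t=fit$t[,"case"], p=fit$p.value[,"case"])
            write.table(format(out, digits=15), "{tmp_path}/out.tsv",
                        sep="\t", quote=FALSE)
        """))
        subprocess.run(["Rscript", str(script)], check=True,
                       capture_output=True)
        want = pd.read_csv(tmp_path / "out.tsv", sep="\t", index_col=0)
        got = diffexpr.moderated_t_test(m)
        assert np.max(np.abs(got["t"] - want["t"])) < 1e-8
        assert np.max(np.abs(got["p"] - want["p"])) < 1e-8

    def test_null_type_one_error_calibrated(self):
        """~5% of null features reach p < 0.05, averaged over 10 seeds."""
        fractions = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            m = make_matrix(rng.normal(8, 1, (200, 10)), 5, 5)
            tab = diffexpr.moderated_t_test(m)
            fractions.append((tab["p"] < 0.05).mean())
        assert abs(np.mean(fractions) - 0.05) < 0.02

    def test_all_zero_variance_is_an_error(self):
        m = make_matrix([[1, 1, 1, 2, 2, 2], [3, 3, 3, 5, 5, 5]], 3, 3)
        with pytest.raises(InputError, match="zero residual variance"):
            diffexpr.moderated_t_test(m)

    def test_single_zero_variance_floored(self):
        m = make_matrix([[1, 1, 1, 2, 2, 2], [3, 3.5, 3.1, 5, 5.2, 5.4]], 3, 3)
        tab = diffexpr.moderated_t_test(m)
        assert np.all(np.isfinite(tab["t"]))


class TestBenjaminiHochberg:
    def test_worked_example(self):
        got = diffexpr.adjust_bh([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(got, [0.04, 0.04, 0.04, 0.04])

    def test_single_and_degenerate(self):
        assert diffexpr.adjust_bh([0.3]) == pytest.approx([0.3])
        assert np.allclose(diffexpr.adjust_bh([1.0, 1.0]), [1.0, 1.0])

    def test_out_of_range_rejected(self):
        with pytest.raises(InputError):
            diffexpr.adjust_bh([0.5, 1.5])

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_stepup_oracle_and_statsmodels(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.uniform(0, 1, size=int(rng.integers(1, 60)))
        got = diffexpr.adjust_bh(p)
        assert np.allclose(got, bh_stepup(list(p)))
        assert np.allclose(got, multipletests(p, method="fdr_bh")[1])

    @pytest.mark.parametrize("seed", range(10))
    def test_pointwise_dominance_and_monotonicity(self, seed):
        rng = np.random.default_rng(100 + seed)
        p = rng.uniform(0, 1, 40)
        adj = diffexpr.adjust_bh(p)
        assert np.all(adj >= p - 1e-12)  # equality up to float rounding
        order = np.argsort(p, kind="mergesort")
        assert np.all(np.diff(adj[order]) >= -1e-15)


class TestScreen:
    @pytest.mark.parametrize("fdr,lfc,expect", [
        (0.04, 1.2, "up"),       # passes both thresholds
        (0.01, 0.9, "ns"),       # |log2FC| must exceed 1
        (0.05, 2.0, "ns"),       # FDR threshold is strict
        (0.04, -1.2, "down"),
        (0.04, 1.0, "ns"),       # |log2FC| threshold is strict
    ])
    def test_threshold_rules(self, fdr, lfc, expect):
        tab = pd.DataFrame({"log2fc": [lfc], "t": [1.0], "p": [fdr],
                            "fdr": [fdr]}, index=["f"])
        assert diffexpr.screen_de(tab)["direction"].iloc[0] == expect

    def test_idempotent_and_order_invariant(self):
        rng = np.random.default_rng(1)
        tab = pd.DataFrame({
            "log2fc": rng.normal(0, 2, 50), "t": rng.normal(0, 3, 50),
            "p": rng.uniform(0, 1, 50)}, index=[f"f{i}" for i in range(50)])
        tab["fdr"] = diffexpr.adjust_bh(tab["p"].to_numpy())
        once = diffexpr.screen_de(tab)
        twice = diffexpr.screen_de(once)
        pd.testing.assert_frame_equal(once, twice)
        shuffled = diffexpr.screen_de(tab.sample(frac=1, random_state=0))
        assert set(diffexpr.retained(shuffled).index) == \
            set(diffexpr.retained(once).index)


class TestClusterOrder:
    def test_identical_rows_are_adjacent(self):
        m = make_matrix([[1, 2, 3, 4], [9, 9, 9, 9], [1, 2, 3, 4]], 2, 2)
        rows, _ = diffexpr.cluster_order(m)
        i0, i2 = rows.index(0), rows.index(2)
        assert abs(i0 - i2) == 1

    def test_closest_pair_merges_first(self):
        # distances: d(f0,f1)=1, d(f0,f2)=sqrt(200), d(f1,f2)=sqrt(181)
        m = make_matrix([[0, 0, 0, 0], [0, 1, 0, 1], [10, 10, 10, 10]], 2, 2)
        rows, _ = diffexpr.cluster_order(m)
        assert abs(rows.index(0) - rows.index(1)) == 1

    def test_topology_invariant_to_row_permutation(self):
        rng = np.random.default_rng(2)
        vals = rng.normal(0, 1, (8, 6))
        m = make_matrix(vals, 3, 3)
        rows, cols = diffexpr.cluster_order(m)
        perm = rng.permutation(8)
        m2 = make_matrix(vals[perm], 3, 3)
        rows2, cols2 = diffexpr.cluster_order(m2)
        # column clustering ignores row order entirely
        assert cols == cols2
        # row adjacency structure is preserved under relabelling
        adj = {frozenset((perm[rows2[i]], perm[rows2[i + 1]]))
               for i in range(len(rows2) - 1)}
        adj_orig = {frozenset((rows[i], rows[i + 1]))
                    for i in range(len(rows) - 1)}
        assert len(adj) == len(adj_orig)

    def test_too_few_features_rejected(self):
        m = make_matrix([[1, 2, 3, 4], [2, 3, 4, 5]], 2, 2)
        with pytest.raises(InputError):
            diffexpr.cluster_order(m, features=["f0"])
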
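"""Moderated-t model, hit calling, BH adjustment, and the skewness test."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import oxbspipe as ox
from conftest import make_matrix, make_sheet


def _two_group(rng, n_probes, n1=7, n2=8, sd=0.03, base=0.5):
    vals = np.clip(base + rng.normal(0, sd, (n_probes, n1 + n2)), 0, 1)
    sheet = make_sheet(["control"] * n1 + ["WT"] * n2)
    return make_matrix(vals, "mC"), sheet


class TestFitModerated:
    def test_identical_groups_effect_zero_p_one(self):
        vals = np.tile([[0.4, 0.4, 0.4, 0.4, 0.4, 0.4]], (3, 1))
        sheet = make_sheet(["control"] * 3 + ["WT"] * 3)
        table, _ = ox.fit_moderated(make_matrix(vals, "mC"), sheet,
                                    ("WT", "control"))
        assert (table.data["effect"] == 0).all()
        assert (table.data["p"] == 1).all()

    def test_zero_prior_df_equals_ols_oracle(self):
        rng = np.random.default_rng(10)
        m, sheet = _two_group(rng, 300)
        table, params = ox.fit_moderated(m, sheet, ("WT", "control"),
                                         prior_df=0)
        assert params.d0 == 0
        # independent oracle: per-probe two-group OLS t
        g = sheet.data.genotype.to_numpy()
        X = np.column_stack([np.ones(15), (g == "WT").astype(float)])
        XtX_inv = np.linalg.inv(X.T @ X)
        Y = m.values.to_numpy()
        beta = Y @ X @ XtX_inv.T
        resid = Y - beta @ X.T
        s2 = (resid ** 2).sum(axis=1) / (15 - 2)
        t_ols = beta[:, 1] / np.sqrt(s2 * XtX_inv[1, 1])
        np.testing.assert_allclose(table.data["t"].to_numpy(), t_ols,
                                   atol=1e-10)

    def test_infinite_prior_df_limit(self):
        rng = np.random.default_rng(11)
        m, sheet = _two_group(rng, 200)
        table, params = ox.fit_moderated(m, sheet, ("WT", "control"),
                                         prior_df=np.inf)
        g = sheet.data.genotype.to_numpy()
        X = np.column_stack([np.ones(15), (g == "WT").astype(float)])
        cxc = np.linalg.inv(X.T @ X)[1, 1]
        expected = table.data["effect"] / np.sqrt(params.s0_sq * cxc)
        np.testing.assert_allclose(table.data["t"], expected, atol=1e-10)

    def test_effect_sign_convention(self):
        # planted group-mean increase -> positive effect (group - reference)
        rng = np.random.default_rng(12)
        m, sheet = _two_group(rng, 50)
        vals = m.values.copy()
        vals.iloc[0, 7:] += 0.2  # raise WT samples of probe 0
        table, _ = ox.fit_moderated(make_matrix(vals.to_numpy(), "mC"), sheet,
                                    ("WT", "control"))
        assert table.data.loc[0, "effect"] == pytest.approx(0.2, abs=0.05)

    def test_planted_large_negative_effect_recovered(self):
        # effect size modeled on a strong decrease (~-0.2) at n = 7 vs 8,
        # sd 0.03: the estimate lands within +/- 0.02 on average and is a hit
        rng = np.random.default_rng(13)
        m, sheet = _two_group(rng, 2000)
        vals = m.values.to_numpy()
        planted = rng.choice(2000, 10, replace=False)
        vals[np.ix_(planted, np.arange(7, 15))] -= 0.1995
        vals = np.clip(vals, 0, 1)
        table, _ = ox.fit_moderated(make_matrix(vals, "mC"), sheet,
                                    ("WT", "control"))
        est = table.data.loc[planted, "effect"]
        assert est.mean() == pytest.approx(-0.1995, abs=0.02)
        assert (table.data.loc[planted, "padj"] < 0.05).all()

    def test_three_group_design_single_model(self):
        rng = np.random.default_rng(14)
        vals = np.clip(0.5 + rng.normal(0, 0.03, (100, 23)), 0, 1)
        sheet = make_sheet(["control"] * 7 + ["WT"] * 8 + ["A30P"] * 8)
        t_wt, _ = ox.fit_moderated(make_matrix(vals, "mC"), sheet,
                                   ("WT", "control"))
        t_ab, _ = ox.fit_moderated(make_matrix(vals, "mC"), sheet,
                                   ("A30P", "WT"))
        g = sheet.data.genotype.to_numpy()
        exp = vals[:, g == "A30P"].mean(1) - vals[:, g == "WT"].mean(1)
        np.testing.assert_allclose(t_ab.data["effect"], exp, atol=1e-12)
        assert len(t_wt.data) == 100

    def test_missing_probe_excluded(self):
        vals = np.full((3, 6), 0.5)
        vals[1, 2] = np.nan
        sheet = make_sheet(["control"] * 3 + ["WT"] * 3)
        table, _ = ox.fit_moderated(make_matrix(vals, "mC"), sheet,
                                    ("WT", "control"))
        assert len(table.data) == 2

    def test_absent_group_rejected(self):
        rng = np.random.default_rng(15)
        m, sheet = _two_group(rng, 10)
        with pytest.raises(ox.ValidationError):
            ox.fit_moderated(m, sheet, ("A30P", "control"))

    def test_matches_limma_oracle(self, tmp_path):
        """Cross-check against the reference empirical-Bayes implementation in R."""
        rng = np.random.default_rng(16)
        m, sheet = _two_group(rng, 60)
        table, params = ox.fit_moderated(m, sheet, ("WT", "control"))
        mat_path = tmp_path / "m.tsv"
        m.values.to_csv(mat_path, sep="\t")
        out_path = tmp_path / "limma.tsv"
        script = textwrap.dedent(f"""
            suppressMessages(library(limma))
            x <- as.matrix(read.delim("{mat_path}", row.names=1))
            g <- factor(c(rep("control", 7), rep("WT", 8)), levels=c("control","WT"))
            design <- model.matrix(~g)
            fit <- eBayes(lmFit(x, design))
            res <- data.frame(t=fit$t[,2], p=fit$p.value[,2], d0=fit$df.prior,
                              s0=fit$s2.prior)
            write.table(res, "{out_path}", sep="\\t", quote=FALSE)
        """)
        r_file = tmp_path / "oracle.R"
        r_file.write_text(script)
        subprocess.run(["Rscript", "--vanilla", str(r_file)], check=True,
                       capture_output=True)
        ref = pd.read_csv(out_path, sep="\t")
        np.testing.assert_allclose(table.data["t"], ref["t"], atol=1e-6)
        np.testing.assert_allclose(table.data["p"], ref["p"], atol=1e-8)
        assert params.d0 == pytest.approx(ref["d0"].iloc[0], rel=1e-4)


class TestCallHits:
    @pytest.mark.parametrize("effect,padj,expected", [
        (-0.1995, 2.54e-06, "decreased"),  # strong decrease, significant
        (0.049, 1e-5, None),  # effect below threshold
        (0.20, 0.06, None),  # padj above threshold
        (0.06, 0.01, "increased"),
    ])
    def test_threshold_logic(self, effect, padj, expected):
        table = ox.DiffTable(pd.DataFrame({
            "probe_id": ["cgX"], "effect": [effect], "t": [1.0],
            "p": [padj / 2], "padj": [padj], "hit": [False]}))
        hits = ox.call_hits(table)
        if expected is None:
            assert not hits["increased"] and not hits["decreased"]
        else:
            assert hits[expected] == {"cgX"}


class TestBhAdjust:
    def test_hand_computed(self):
        np.testing.assert_allclose(ox.bh_adjust(np.array([0.01, 0.02, 0.03])),
                                   [0.03, 0.03, 0.03], atol=1e-12)

    def test_single_value_unchanged(self):
        assert ox.bh_adjust(np.array([0.2]))[0] == pytest.approx(0.2)

    def test_all_ones(self):
        assert (ox.bh_adjust(np.ones(5)) == 1).all()

    def test_nan_propagates_excluded_from_ranking(self):
        out = ox.bh_adjust(np.array([0.01, np.nan, 0.02]))
        assert np.isnan(out[1])
        np.testing.assert_allclose(out[[0, 2]],
                                   ox.bh_adjust(np.array([0.01, 0.02])))

    def test_monotone_in_rank(self):
        rng = np.random.default_rng(17)
        p = rng.uniform(0, 1, 200)
        adj = ox.bh_adjust(p)
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-15).all()


class TestSkewness:
    def test_symmetric_input_zero_statistic(self):
        x = np.tile([-2, -1, 0, 1, 2], 4)
        res = ox.skewness_mc_test(x, n_sim=200, seed=1)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p > 0.5

    def test_replicated_three_point_symmetry(self):
        x = np.tile([-1.0, 0.0, 1.0], 3)
        res = ox.skewness_mc_test(x, n_sim=100, seed=2)
        assert res.statistic == 0.0

    def test_exponential_sample_at_floor(self):
        rng = np.random.default_rng(3)
        x = rng.exponential(size=1000)
        res = ox.skewness_mc_test(x, n_sim=1000, seed=4)
        assert res.p == pytest.approx(1 / 1001)

    def test_constant_vector_rejected(self):
        with pytest.raises(ox.ValidationError):
            ox.skewness_mc_test(np.ones(20), n_sim=10, seed=0)

    def test_minimum_sample_size(self):
        with pytest.raises(ox.ValidationError):
            ox.skewness_mc_test(np.array([-1.0, 0.0, 1.0]), n_sim=10, seed=0)

    def test_statistic_is_population_g1(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=50)
        res = ox.skewness_mc_test(x, n_sim=10, seed=0)
        assert res.statistic == pytest.approx(stats.skew(x, bias=True))
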
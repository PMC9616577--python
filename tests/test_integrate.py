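"""Region assignment, p-value combination, ORA, and module search."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import oxbspipe as ox
from conftest import make_manifest


def _intervals(rows):
    return ox.IntervalSet(pd.DataFrame(
        rows, columns=["chromosome", "start", "end", "name"]))


class TestAssignRegions:
    def _fixtures(self):
        # gene G spans 10000-20000 (0-based); TSS at 10000; peak at 14000-14200
        tss = _intervals([("chr1", 10000, 10001, "G")])
        spans = _intervals([("chr1", 10000, 20000, "G")])
        peaks = _intervals([("chr1", 14000, 14200, "peak1")])
        return tss, peaks, spans

    def test_promoter_within_pad(self):
        tss, peaks, spans = self._fixtures()
        manifest = make_manifest(["cg1"], ["chr1"], [9201])  # 800 bp upstream
        out = ox.assign_regions(manifest, tss, peaks, spans)
        assert ("G", "promoter") in out["cg1"]

    def test_enhancer_and_body_multi_assignment(self):
        tss, peaks, spans = self._fixtures()
        # 4 kb from the peak edge, inside the gene span, not promoter
        manifest = make_manifest(["cg1"], ["chr1"], [18001])
        out = ox.assign_regions(manifest, tss, peaks, spans)
        assert out["cg1"] == {("G", "enhancer"), ("G", "body")}

    def test_body_only(self):
        tss, peaks, spans = self._fixtures()
        # 1.5 kb downstream of TSS, > 5 kb from the peak pad? peak pad covers
        # 9000-19200, so move the peak away for this case
        peaks_far = _intervals([("chr1", 50000, 50200, "peak1")])
        manifest = make_manifest(["cg1"], ["chr1"], [11501])
        out = ox.assign_regions(manifest, tss, peaks_far, spans)
        assert out["cg1"] == {("G", "body")}

    def test_chromosome_mismatch_rejected(self):
        tss, peaks, spans = self._fixtures()
        manifest = make_manifest(["cg1"], ["chr2"], [100])
        with pytest.raises(ox.ValidationError):
            ox.assign_regions(manifest, tss, peaks, spans)


class TestAssignGene:
    def _manifest(self, transcripts):
        tx = pd.DataFrame(transcripts, columns=[
            "probe_id", "gene", "transcript_id", "transcript_length",
            "genomic_context"])
        return make_manifest(["cg1", "cg2"], ["chr1"] * 2, [100, 200],
                             transcripts=tx)

    def test_longest_transcript_wins(self):
        m = self._manifest([("cg1", "GENE_A", "t1", 5000, "Body"),
                            ("cg1", "GENE_B", "t2", 12000, "Body")])
        assert ox.assign_gene(m)["cg1"] == "GENE_B"

    def test_tie_breaks_lexicographically(self):
        m = self._manifest([("cg1", "B", "t1", 5000, "Body"),
                            ("cg1", "A", "t2", 5000, "Body")])
        assert ox.assign_gene(m)["cg1"] == "A"

    def test_intergenic_unmapped(self):
        m = self._manifest([("cg1", "A", "t1", 5000, "Body")])
        assert "cg2" not in ox.assign_gene(m)


class TestStoufferRegion:
    def test_single_input_identity(self):
        assert ox.stouffer_region(np.array([0.037]),
                                  np.array([0.5])) == pytest.approx(0.037)

    def test_two_equal_same_sign(self):
        p = ox.stouffer_region(np.array([0.05, 0.05]), np.array([0.3, 0.3]))
        # closed form: |z| = 1.95996 * 2w / (w sqrt 2) = 2.7718 -> 0.005574
        z = stats.norm.isf(0.025) * math.sqrt(2)
        assert p == pytest.approx(2 * stats.norm.sf(z), abs=1e-12)
        assert p == pytest.approx(0.00557, abs=1e-5)

    def test_opposite_signs_cancel(self):
        p = ox.stouffer_region(np.array([0.01, 0.01]), np.array([0.2, -0.2]))
        assert p == pytest.approx(1.0)

    def test_order_invariance(self):
        rng = np.random.default_rng(1)
        pv = rng.uniform(0.001, 0.9, 6)
        ev = rng.normal(0, 0.1, 6)
        perm = rng.permutation(6)
        assert ox.stouffer_region(pv, ev) == pytest.approx(
            ox.stouffer_region(pv[perm], ev[perm]))

    def test_significance_weighting(self):
        # a large-effect CpG dominates the combination
        p_dom = ox.stouffer_region(np.array([0.001, 0.9]),
                                   np.array([0.5, 0.001]))
        assert p_dom < 0.01


class TestGeneScore:
    def test_single_component_identity(self):
        z, p = ox.gene_score({"expression": 0.01})
        assert p == pytest.approx(0.01)

    def test_seven_components_brute_force(self):
        z, p = ox.gene_score({k: 0.05 for k in ox.DEFAULT_WEIGHTS})
        # brute-force recomputation from the printed weight vector
        w = np.array(list(ox.DEFAULT_WEIGHTS.values()))
        zi = stats.norm.isf(0.05 / 2)
        z_exp = (w * zi).sum() / np.sqrt((w ** 2).sum())
        assert z == pytest.approx(z_exp, abs=1e-10)
        assert z == pytest.approx(4.3781, abs=1e-4)
        assert p == pytest.approx(2 * stats.norm.sf(z_exp), rel=1e-10)

    def test_equal_weights_match_unweighted_stouffer(self):
        comps = {"promoter_m": 0.02, "body_m": 0.3, "expression": 0.1}
        z, p = ox.gene_score(comps, weights={k: 1.0 for k in comps})
        # independent unweighted implementation
        zi = stats.norm.isf(np.array([0.02, 0.3, 0.1]) / 2)
        z_ref = zi.sum() / math.sqrt(3)
        assert z == pytest.approx(z_ref, abs=1e-12)

    def test_missing_components_renormalized(self):
        z_full, p_full = ox.gene_score({"expression": 0.01})
        z_part, p_part = ox.gene_score(
            {"expression": 0.01, "promoter_m": np.nan})
        assert p_part == pytest.approx(p_full)

    def test_no_components_rejected(self):
        with pytest.raises(ox.ValidationError):
            ox.gene_score({"expression": np.nan})


class TestFisherCombine:
    def test_single_p_identity(self):
        assert ox.fisher_combine(np.array([0.3])) == pytest.approx(0.3)

    def test_two_halves(self):
        assert ox.fisher_combine(np.array([0.5, 0.5])) == pytest.approx(
            0.597, abs=1e-3)

    def test_all_ones(self):
        assert ox.fisher_combine(np.array([1.0, 1.0])) == pytest.approx(1.0)

    def test_matches_scipy_reference(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(0.001, 1, 5)
        ref = stats.combine_pvalues(p, method="fisher").pvalue
        assert ox.fisher_combine(p) == pytest.approx(ref, rel=1e-12)


class TestGoOra:
    def test_worked_hypergeometric_example(self):
        bg = {f"G{i}" for i in range(20)}
        hits = {f"G{i}" for i in range(5)}
        sets = {"S": {"G0", "G1", "G2", "G10", "G11"}}  # overlap 3
        out = ox.go_ora(hits, bg, sets)
        assert out["p"].iloc[0] == pytest.approx(1126 / 15504, rel=1e-12)

    def test_hits_equal_background(self):
        bg = {f"G{i}" for i in range(30)}
        sets = {"S": {f"G{i}" for i in range(10)}}
        out = ox.go_ora(bg, bg, sets)
        assert (out["p"] == 1.0).all()

    def test_disjoint_set_excluded(self):
        bg = {f"G{i}" for i in range(20)}
        out = ox.go_ora({"G1"}, bg, {"S": {"X1", "X2", "X3", "X4", "X5"}})
        assert len(out) == 0

    def test_size_bounds(self):
        bg = {f"G{i}" for i in range(20)}
        out = ox.go_ora({"G1"}, bg, {"tiny": {"G1", "G2"}})
        assert len(out) == 0


class TestFindModules:
    def _barbell(self):
        # two 6-cliques joined by one edge; clique A planted significant
        edges = []
        a = [f"A{i}" for i in range(6)]
        b = [f"B{i}" for i in range(6)]
        for grp in (a, b):
            edges += [(x, y) for i, x in enumerate(grp) for y in grp[i + 1:]]
        edges.append((a[0], b[0]))
        scores = pd.DataFrame({
            "gene": a + b,
            "p": [1e-4] * 6 + list(np.linspace(0.3, 0.9, 6)),
        })
        return edges, scores, set(a)

    def test_planted_clique_recovered(self):
        edges, scores, planted = self._barbell()
        recovered = 0
        for seed in range(10):
            modules = ox.find_modules(edges, scores, n_null=50, seed=seed)
            top = set(modules[0].genes)
            jac = len(top & planted) / len(top | planted)
            recovered += jac >= 0.8
        assert recovered >= 9

    def test_determinism(self):
        edges, scores, _ = self._barbell()
        m1 = ox.find_modules(edges, scores, n_null=50, seed=3)
        m2 = ox.find_modules(edges, scores, n_null=50, seed=3)
        assert [(m.genes, m.score, m.p) for m in m1] == \
               [(m.genes, m.score, m.p) for m in m2]

    def test_uniform_scores_no_significant_module(self):
        rng = np.random.default_rng(4)
        genes = [f"G{i}" for i in range(60)]
        edges = [(genes[rng.integers(60)], genes[rng.integers(60)])
                 for _ in range(150)]
        edges = [(u, v) for u, v in edges if u != v]
        scores = pd.DataFrame({"gene": genes,
                               "p": rng.uniform(0.001, 1, 60)})
        hits = 0
        for seed in range(5):
            modules = ox.find_modules(edges, scores, n_null=100, seed=seed)
            hits += any(m.p <= 0.05 for m in modules[:1])
        assert hits <= 1

    def test_empty_candidate_set(self):
        scores = pd.DataFrame({"gene": ["G1", "G2"], "p": [0.9, 0.8]})
        assert ox.find_modules([("G1", "G2")], scores, seed=0) == []


class TestBuildGeneScores:
    def test_components_assembled_per_region(self):
        dm = ox.DiffTable(pd.DataFrame({
            "probe_id": ["cg1", "cg2"], "effect": [0.1, -0.05],
            "t": [4.0, -2.0], "p": [0.001, 0.04], "padj": [0.01, 0.1],
            "hit": [True, False]}))
        dhm = ox.DiffTable(pd.DataFrame({
            "probe_id": ["cg1"], "effect": [0.05], "t": [2.0], "p": [0.03],
            "padj": [0.1], "hit": [False]}))
        expr = ox.ExpressionTable(pd.DataFrame({
            "gene": ["G"], "log2FC": [1.0], "p": [0.005], "padj": [0.01]}))
        assignment = {"cg1": {("G", "promoter")}, "cg2": {("G", "body")}}
        out = ox.build_gene_scores(dm, dhm, expr, assignment).set_index("gene")
        row = out.loc["G"]
        assert row["promoter_m"] == pytest.approx(0.001)
        assert row["body_m"] == pytest.approx(0.04)
        assert row["promoter_hm"] == pytest.approx(0.03)
        assert row["expression"] == pytest.approx(0.005)
        assert np.isnan(row["enhancer_m"])
        assert 0 < row["p"] < 0.01
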
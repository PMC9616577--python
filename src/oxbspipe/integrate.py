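"""Multi-omic region-weighted gene scoring and module identification.

CpG probes are assigned to genomic regions per gene — promoters (within
+/- 1 kb of a TSS), enhancers (within +/- 5 kb of an H3K4me1 peak that lies
in or near the gene's span), and gene bodies (inside the span and not
promoter).  Within each (gene, region, modification) the probe p-values are
combined by significance-weighted Stouffer (weights = |effect|), giving a
region-level p.  The region p-values plus the expression p are combined into
a gene score by weighted Stouffer on |z| with the seven-component weight
vector {expression 0.4; enhancer/promoter methylation 0.125 each; body
methylation 0.1; enhancer/promoter hydroxymethylation 0.125 each; body
hydroxymethylation 0.1}, renormalized over present components.  Category
p-values combine across comparisons by Fisher's method.  High-scoring genes
are mapped onto an interaction network and modules are found by spin-glass
(simulated-annealing modularity) community detection, with empirical module
p-values from score-label permutations on the fixed topology.
"""

from __future__ import annotations

import random
import warnings
from dataclasses import dataclass

import igraph as ig
import numpy as np
import pandas as pd
from scipy import stats

from .differential import bh_adjust
from .io import (DiffTable, ExpressionTable, IntervalSet, ProbeManifest,
                 ValidationError)

__all__ = [
    "DEFAULT_WEIGHTS", "Module", "assign_regions", "assign_gene",
    "stouffer_region", "gene_score", "fisher_combine", "build_gene_scores",
    "find_modules", "go_ora",
]

DEFAULT_WEIGHTS = {
    "expression": 0.4,
    "enhancer_m": 0.125,
    "promoter_m": 0.125,
    "body_m": 0.1,
    "enhancer_hm": 0.125,
    "promoter_hm": 0.125,
    "body_hm": 0.1,
}

_P_FLOOR = 1e-300


@dataclass
class Module:
    """A community of genes on the scored network."""

    id: str
    genes: list[str]
    score: float  # mean(-log10 p) over members
    p: float  # empirical, from score-label permutation
    seed: int


# ---------------------------------------------------------------------------
# region and gene assignment
# ---------------------------------------------------------------------------

def _overlaps(pos: np.ndarray, chrom: np.ndarray,
              intervals: IntervalSet) -> list[set[str]]:
    """For each 0-based point, the interval names covering it."""
    out: list[set[str]] = [set() for _ in pos]
    d = intervals.data
    for chr_name, sub in d.groupby("chromosome"):
        sel = np.flatnonzero(chrom == chr_name)
        if not len(sel):
            continue
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        names = sub["name"].to_numpy()
        for i in sel:
            hit = (starts <= pos[i]) & (pos[i] < ends)
            if hit.any():
                out[i].update(names[hit])
    return out


def assign_regions(manifest: ProbeManifest, tss: IntervalSet,
                   peaks: IntervalSet, gene_spans: IntervalSet,
                   promoter_pad: int = 1000, enhancer_pad: int = 5000
                   ) -> dict[str, set[tuple[str, str]]]:
    """Map probes to (gene, region) pairs; multi-assignment is permitted.

    ``tss`` and ``gene_spans`` carry gene symbols in their name column.  A
    probe is a promoter probe of G when within +/- promoter_pad of a TSS of
    G; an enhancer probe of G when inside a +/- enhancer_pad padded peak that
    also lies within G's padded span; a body probe of G when inside G's span
    and not a promoter probe of G.
    """
    probes = manifest.probes
    chrom_labels = set(probes["chromosome"])
    for iv, what in ((tss, "TSS"), (gene_spans, "gene spans")):
        bad = set(iv.data["chromosome"]) - chrom_labels
        if bad:
            raise ValidationError(f"{what} chromosomes absent from manifest: {sorted(bad)}")
    pos0 = probes["position"].to_numpy() - 1  # manifest is 1-based
    chrom = probes["chromosome"].to_numpy()

    prom_genes = _overlaps(pos0, chrom, tss.padded(promoter_pad))
    span_genes = _overlaps(pos0, chrom, gene_spans)
    near_genes = _overlaps(pos0, chrom, gene_spans.padded(enhancer_pad))
    in_peak = [len(s) > 0 for s in _overlaps(pos0, chrom, peaks.padded(enhancer_pad))]

    out: dict[str, set[tuple[str, str]]] = {}
    for i, pid in enumerate(probes.index):
        assign: set[tuple[str, str]] = set()
        for g in prom_genes[i]:
            assign.add((g, "promoter"))
        if in_peak[i]:
            for g in near_genes[i]:
                assign.add((g, "enhancer"))
        for g in span_genes[i]:
            if (g, "promoter") not in assign:
                assign.add((g, "body"))
        if assign:
            out[pid] = assign
    return out


def assign_gene(manifest: ProbeManifest) -> dict[str, str]:
    """Single-gene probe assignment: gene of the longest annotated transcript.

    Ties break lexicographically by gene symbol; unannotated (intergenic)
    probes are unmapped.
    """
    t = manifest.transcripts
    if not len(t):
        return {}
    ranked = t.sort_values(["probe_id", "transcript_length", "gene"],
                           ascending=[True, False, True], kind="mergesort")
    # among equal max lengths, prefer the lexicographically smallest gene
    best = ranked.groupby("probe_id", sort=False).apply(
        lambda d: d.loc[d["transcript_length"] == d["transcript_length"].max(),
                        "gene"].min(),
        include_groups=False,
    )
    return dict(best)


# ---------------------------------------------------------------------------
# p-value combination
# ---------------------------------------------------------------------------

def stouffer_region(p: np.ndarray, effects: np.ndarray) -> float:
    """Signed, significance-weighted Stouffer combination within a region.

    z_i = Phi^-1(1 - p_i/2) * sign(effect_i), weights w_i = |effect_i|
    (equal weights when all effects are zero); combined two-sided
    p = 2 (1 - Phi(|sum w z / sqrt(sum w^2)|)).  A single input returns its
    own p.
    """
    p = np.asarray(p, float)
    effects = np.asarray(effects, float)
    if p.size == 0:
        raise ValidationError("empty p-value vector")
    if (p == 0).any():
        warnings.warn("p = 0 shrunk to floor")
        p = np.maximum(p, _P_FLOOR)
    z = stats.norm.isf(p / 2) * np.where(effects < 0, -1.0, 1.0)
    w = np.abs(effects)
    if not w.any():
        w = np.ones_like(w)
    z_comb = (w * z).sum() / np.sqrt((w ** 2).sum())
    return float(2 * stats.norm.sf(abs(z_comb)))


def gene_score(components: dict[str, float],
               weights: dict[str, float] | None = None) -> tuple[float, float]:
    """Weighted Stouffer across modality components on |z|.

    Weights are renormalized over the components present; direction is not
    propagated across modality types because methylation and expression sign
    conventions are not commensurable.  Returns (combined z, two-sided p).
    """
    if weights is None:
        weights = DEFAULT_WEIGHTS
    present = {k: v for k, v in components.items() if v is not None
               and not np.isnan(v)}
    if not present:
        raise ValidationError("gene has no components")
    p = np.maximum(np.array([present[k] for k in present]), _P_FLOOR)
    w = np.array([weights.get(k, 0.0) for k in present])
    if not w.any():
        w = np.ones_like(w)
    w = w / w.sum()
    z = stats.norm.isf(p / 2)
    z_comb = float((w * z).sum() / np.sqrt((w ** 2).sum()))
    return z_comb, float(2 * stats.norm.sf(abs(z_comb)))


def fisher_combine(p: np.ndarray) -> float:
    """Fisher's method: X^2 = -2 sum ln p on chi-square with 2k df."""
    p = np.asarray(p, float)
    if p.size == 0:
        raise ValidationError("empty p-value vector")
    p = np.maximum(p, _P_FLOOR)
    x2 = -2 * np.log(p).sum()
    return float(stats.chi2.sf(x2, 2 * p.size))


def build_gene_scores(dm: DiffTable, dhm: DiffTable, expression: ExpressionTable,
                      assignment: dict[str, set[tuple[str, str]]],
                      weights: dict[str, float] | None = None) -> pd.DataFrame:
    """Assemble the per-gene score table from site tables and assignments.

    For each gene, probe p/effect pairs are pooled per (region, modification)
    and Stouffer-combined into component p-values; the expression p joins as
    its own component; the weighted gene score follows.  Genes with no
    component at all are dropped.
    """
    comp_names = {("m", "promoter"): "promoter_m", ("m", "enhancer"): "enhancer_m",
                  ("m", "body"): "body_m", ("hm", "promoter"): "promoter_hm",
                  ("hm", "enhancer"): "enhancer_hm", ("hm", "body"): "body_hm"}
    pools: dict[str, dict[str, tuple[list[float], list[float]]]] = {}
    for mod, table in (("m", dm), ("hm", dhm)):
        d = table.data.set_index("probe_id")
        for pid, assigns in assignment.items():
            if pid not in d.index:
                continue
            pv, ev = float(d.at[pid, "p"]), float(d.at[pid, "effect"])
            if np.isnan(pv):
                continue
            for gene, region in assigns:
                comp = comp_names[(mod, region)]
                slot = pools.setdefault(gene, {}).setdefault(comp, ([], []))
                slot[0].append(pv)
                slot[1].append(ev)

    expr_p = expression.data.set_index("gene")["p"]
    genes = sorted(set(pools) | set(expr_p.index))
    rows = []
    for g in genes:
        comps: dict[str, float] = {}
        for comp, (ps, es) in pools.get(g, {}).items():
            comps[comp] = stouffer_region(np.array(ps), np.array(es))
        if g in expr_p.index and not np.isnan(expr_p[g]):
            comps["expression"] = float(expr_p[g])
        if not comps:
            continue
        z, p = gene_score(comps, weights)
        rows.append({"gene": g, **{c: comps.get(c, np.nan)
                                   for c in DEFAULT_WEIGHTS}, "z": z, "p": p})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# network modules
# ---------------------------------------------------------------------------

def find_modules(edges: list[tuple[str, str]], scores: pd.DataFrame,
                 n_null: int = 100, seed: int = 0,
                 candidate_p: float = 0.05, spins: int = 15) -> list[Module]:
    """Spin-glass community detection on the scored interaction network.

    ``scores`` needs columns gene, p.  Nodes without a score get a neutral
    p = 0.5.  Simulated-annealing modularity optimization runs on each
    connected component that contains at least one candidate gene
    (p <= candidate_p); communities with >= 2 members become modules.
    Module score = mean(-log10 p) over members; the empirical p compares the
    observed score against ``n_null`` random permutations of the score
    labels on the same topology.  Deterministic given ``seed``.
    """
    g = ig.Graph.TupleList(edges, directed=False)
    g.simplify()
    names = g.vs["name"]
    p_map = dict(zip(scores["gene"], scores["p"]))
    covered = sum(n in p_map for n in names)
    if len(names) and covered / len(names) < 0.5:
        warnings.warn("scores cover < 50% of network nodes; rest set neutral")
    node_p = np.array([max(p_map.get(n, 0.5), _P_FLOOR) for n in names])
    if not (node_p <= candidate_p).any():
        return []

    random.seed(seed)  # igraph's annealing draws from Python's random module
    rng = np.random.default_rng(seed)
    member_lists: list[list[int]] = []
    for comp in g.connected_components():
        if len(comp) < 2 or not (node_p[comp] <= candidate_p).any():
            continue
        block = g.induced_subgraph(comp)
        if len(comp) <= 3:
            communities = [list(range(len(comp)))]
        else:
            cl = block.community_spinglass(spins=min(spins, len(comp)))
            communities = [list(c) for c in cl]
        for c in communities:
            if len(c) < 2:
                continue
            member_lists.append([comp[i] for i in c])

    logs = -np.log10(node_p)
    modules: list[Module] = []
    null_scores = np.empty((n_null, len(member_lists)))
    for it in range(n_null):
        perm = rng.permutation(logs)
        for j, members in enumerate(member_lists):
            null_scores[it, j] = perm[members].mean()
    for j, members in enumerate(member_lists):
        score = float(logs[members].mean())
        emp_p = (1 + np.sum(null_scores[:, j] >= score)) / (n_null + 1)
        modules.append(Module(
            id=f"module_{j + 1:03d}",
            genes=[names[i] for i in members],
            score=score, p=float(emp_p), seed=seed,
        ))
    modules.sort(key=lambda m: -m.score)
    for rank, m in enumerate(modules, 1):
        m.id = f"module_{rank:03d}"
    return modules


# ---------------------------------------------------------------------------
# over-representation analysis
# ---------------------------------------------------------------------------

def go_ora(hit_genes: set[str], background_genes: set[str],
           gene_sets: dict[str, set[str]], min_size: int = 5,
           max_size: int = 500) -> pd.DataFrame:
    """Hypergeometric over-representation of hit genes in each gene set.

    Set membership is intersected with the background; sets whose effective
    size falls outside [min_size, max_size] (or is zero) are excluded.  The
    upper-tail p is P(X >= overlap); BH adjustment runs across tested sets.
    """
    if not background_genes:
        raise ValidationError("empty background")
    if not hit_genes <= background_genes:
        raise ValidationError("hits not contained in background")
    N, n = len(background_genes), len(hit_genes)
    rows = []
    for name, members in gene_sets.items():
        eff = members & background_genes
        K = len(eff)
        if K == 0 or not min_size <= K <= max_size:
            continue
        k = len(eff & hit_genes)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append((name, K, k, p))
    out = pd.DataFrame(rows, columns=["set", "set_size", "overlap", "p"])
    out["padj"] = bh_adjust(out["p"].to_numpy())
    return out.sort_values("p", kind="mergesort").reset_index(drop=True)
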
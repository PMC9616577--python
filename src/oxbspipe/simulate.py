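"""Synthetic paired BS/oxBS data with planted truth.

Emulates the statistical structure of a three-genotype neuronal methylome
experiment (control n=7, WT n=8, A30P n=8 by default): beta-distributed
methylation, paired-arm technical noise that produces negative subtraction
values, genotype effects planted at designated CpGs, locally correlated CpG
blocks driven by a shared latent factor, and chip/position batch offsets.
Every generator is fully reproducible from its seed.

Planted effects are applied on the logit scale and mapped back, sized so that
the realized beta-scale change at the probe's baseline equals the requested
effect; near the [0, 1] boundaries effects therefore shrink rather than clip.
Technical noise is shared-then-independent: a per-cell baseline common to both
conversion arms plus independent per-arm noise, so BS - oxBS subtraction noise
has standard deviation sqrt(2) * noise_sd regardless of the shared component.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .io import (
    CPG_RELATIONS,
    GENOMIC_CONTEXTS,
    BetaMatrix,
    ExpressionTable,
    ProbeManifest,
    QCMetrics,
    SampleSheet,
    ValidationError,
)
from .rrbs import CountTable

__all__ = ["SimConfig", "TruthSet", "simulate_paired_dataset",
           "simulate_expression", "simulate_rrbs", "RrbsSimConfig"]

_Z975 = 1.959963984540054  # standard-normal 97.5% point


@dataclass
class TruthSet:
    """Planted ground truth recorded alongside a simulated dataset."""

    dm_probes: pd.DataFrame  # probe_id, group, direction, effect (beta scale)
    dhm_probes: pd.DataFrame
    true_hmc_floor: float  # 95th abs percentile of subtraction noise
    cmr_blocks: list[list[str]]  # position-ordered member probe IDs
    de_genes: dict[str, float] = field(default_factory=dict)
    module_genes: list[str] = field(default_factory=list)
    dm_cytosines: pd.DataFrame | None = None
    true_mc: pd.DataFrame | None = None  # noise-free mC, probe x sample
    true_hmc: pd.DataFrame | None = None  # noise-free hmC, probe x sample


@dataclass
class SimConfig:
    """Study-design parameters for the paired-array generator.

    Group sizes default to the three-genotype design (7/8/8).  Effect
    fractions give the share of probes carrying a planted group effect; the
    WT-like group carries more and larger changes than the A30P-like group,
    and hydroxymethylation effects are predominantly increases.
    """

    n_probes: int = 20000
    groups: tuple[str, ...] = ("control", "WT", "A30P")
    n_per_group: tuple[int, ...] = (7, 8, 8)
    dm_effect_fraction: tuple[float, ...] = (0.02, 0.005)  # per non-ref group
    dm_effect_size: tuple[float, ...] = (0.15, 0.10)  # beta scale
    dm_increase_prob: tuple[float, ...] = (0.5, 0.5)
    dhm_effect_fraction: tuple[float, ...] = (0.01, 0.005)
    dhm_effect_size: tuple[float, ...] = (0.10, 0.08)
    dhm_increase_prob: tuple[float, ...] = (0.9, 0.9)
    high_hmc_fraction: float = 0.3
    noise_sd: float = 0.02  # independent per-arm noise, beta scale
    shared_sd: float = 0.01  # per-cell baseline shared by both arms
    n_cmr_blocks: int = 50
    cmr_block_size: tuple[int, int] = (2, 5)
    cmr_latent_sd: float = 0.06  # latent-factor loading, beta scale
    cmr_effect_fraction: float = 0.2  # share of blocks with a planted effect
    cmr_effect_size: float = 0.1  # beta scale, applied in the second group
    n_chips: int = 3
    chip_offset_sd: float = 0.01
    n_positions: int = 8
    position_offset_sd: float = 0.005
    qc_fail_fraction: float = 0.0005
    blacklist_fraction: float = 0.005
    annotated_fraction: float = 0.7
    n_genes: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        k = len(self.groups) - 1
        for name in ("dm_effect_fraction", "dhm_effect_fraction"):
            fr = getattr(self, name)
            if len(fr) != k:
                raise ValidationError(f"{name} needs one entry per non-reference group")
            if any(not 0 <= f <= 1 for f in fr):
                raise ValidationError(f"{name} entries must lie in [0, 1]")
        if min(self.n_per_group) < 2:
            raise ValidationError("need >= 2 samples per group")
        if self.noise_sd <= 0:
            raise ValidationError("noise_sd must be positive")


def _plant_logit(base: np.ndarray, effect: np.ndarray) -> np.ndarray:
    """Logit-scale offset realizing ``effect`` on the beta scale at ``base``."""
    target = np.clip(base + effect, 1e-4, 1 - 1e-4)
    return logit(target) - logit(np.clip(base, 1e-4, 1 - 1e-4))


def simulate_paired_dataset(config: SimConfig) -> tuple[
    BetaMatrix, BetaMatrix, SampleSheet, ProbeManifest, QCMetrics, TruthSet
]:
    """Generate one paired BS/oxBS dataset with planted truth.

    Returns (bs, oxbs, sample_sheet, manifest, qc, truth).  True mC per probe
    comes from a bimodal mixture on [0, 1]; true hmC is near zero for most
    probes and substantial for a ``high_hmc_fraction`` subset, always capped
    at 1 - mC.  oxBS beta = mC + noise and BS beta = mC + hmC + noise, both
    clipped to [0, 1].
    """
    rng = np.random.default_rng(config.seed)
    P, G = config.n_probes, config.groups
    n_samples = sum(config.n_per_group)
    sample_ids = []
    genotypes = []
    for g, n in zip(G, config.n_per_group):
        for i in range(n):
            sample_ids.append(f"{g}_{i + 1}")
            genotypes.append(g)
    genotypes = np.array(genotypes)
    probe_ids = np.array([f"cg{i:08d}" for i in range(P)])

    # --- genomic layout: inter-probe gaps > 1 kb except inside CMR blocks ---
    sizes = rng.integers(config.cmr_block_size[0], config.cmr_block_size[1] + 1,
                         size=config.n_cmr_blocks)
    block_members: list[list[str]] = []
    is_block = np.zeros(P, bool)
    block_of = np.full(P, -1)
    start_idx = np.sort(rng.choice(np.arange(0, P - max(config.cmr_block_size) - 1, 10),
                                   size=config.n_cmr_blocks, replace=False))
    for b, (s, sz) in enumerate(zip(start_idx, sizes)):
        idx = np.arange(s, s + sz)
        if is_block[idx].any():  # avoid merged blocks
            continue
        is_block[idx] = True
        block_of[idx] = b
        block_members.append([str(p) for p in probe_ids[idx]])
    gaps = rng.integers(2000, 10001, size=P)
    in_block_follow = np.zeros(P, bool)
    in_block_follow[1:] = is_block[1:] & (block_of[1:] == block_of[:-1])
    gaps[in_block_follow] = rng.integers(100, 801, size=in_block_follow.sum())
    positions = 1 + np.cumsum(gaps)
    chromosomes = np.where(np.arange(P) < P // 2, "chr1", "chr2")
    # restart coordinates on the second chromosome
    half = P // 2
    positions = positions.copy()
    positions[half:] = positions[half:] - positions[half] + 1 + gaps[half]

    # --- true modification levels ---
    comp = rng.random(P)
    base_mc = np.where(
        comp < 0.4, rng.beta(2, 10, P), np.where(comp < 0.8, rng.beta(10, 2, P),
                                                 rng.beta(5, 5, P))
    )
    base_mc[is_block] = rng.uniform(0.3, 0.7, is_block.sum())
    high_hmc = rng.random(P) < config.high_hmc_fraction
    base_hmc = np.abs(rng.normal(0, 0.005, P))
    base_hmc[high_hmc] = rng.uniform(0.08, 0.30, high_hmc.sum())
    base_hmc = np.minimum(base_hmc, 1 - base_mc - 0.02)
    base_hmc = np.clip(base_hmc, 0, None)

    # --- planted genotype effects (logit scale, sized on the beta scale) ---
    group_mask = {g: genotypes == g for g in G}
    mc_shift = np.zeros((P, n_samples))
    hmc_shift = np.zeros((P, n_samples))
    dm_rows, dhm_rows = [], []
    free = ~is_block
    for gi, g in enumerate(G[1:]):
        for kind, frac, size, up_p, shift, base, rows, needs_high in (
            ("dm", config.dm_effect_fraction[gi], config.dm_effect_size[gi],
             config.dm_increase_prob[gi], mc_shift, base_mc, dm_rows, False),
            ("dhm", config.dhm_effect_fraction[gi], config.dhm_effect_size[gi],
             config.dhm_increase_prob[gi], hmc_shift, base_hmc, dhm_rows, True),
        ):
            pool = np.flatnonzero(free & (high_hmc if needs_high else np.ones(P, bool)))
            n_eff = int(round(frac * P))
            if n_eff == 0:
                continue
            chosen = rng.choice(pool, size=min(n_eff, len(pool)), replace=False)
            direction = np.where(rng.random(len(chosen)) < up_p, 1.0, -1.0)
            effect = direction * size
            d_logit = _plant_logit(base[chosen], effect)
            shift[np.ix_(chosen, np.flatnonzero(group_mask[g]))] = d_logit[:, None]
            realized = expit(logit(np.clip(base[chosen], 1e-4, 1 - 1e-4)) + d_logit) \
                - base[chosen]
            for pid, d, e in zip(probe_ids[chosen], direction, realized):
                rows.append((pid, g, "increase" if d > 0 else "decrease", float(e)))

    # --- planted region-wide effects on a subset of CMR blocks ---
    n_eff_blocks = int(round(config.cmr_effect_fraction * len(block_members)))
    eff_blocks: list[int] = []
    if n_eff_blocks and len(G) > 1:
        eff_blocks = list(rng.choice(len(block_members), size=n_eff_blocks,
                                     replace=False))
        g_target = G[1]
        cols = np.flatnonzero(group_mask[g_target])
        for b in eff_blocks:
            idx = np.searchsorted(probe_ids, block_members[b])
            direction = 1.0 if rng.random() < 0.5 else -1.0
            d_logit = _plant_logit(base_mc[idx],
                                   np.full(len(idx), direction
                                           * config.cmr_effect_size))
            mc_shift[np.ix_(idx, cols)] += d_logit[:, None]
            realized = expit(logit(np.clip(base_mc[idx], 1e-4, 1 - 1e-4))
                             + d_logit) - base_mc[idx]
            for pid, e in zip(block_members[b], realized):
                dm_rows.append((pid, g_target,
                                "increase" if direction > 0 else "decrease",
                                float(e)))

    # --- latent CMR factors ---
    latent = rng.normal(0, 1, (len(block_members), n_samples))
    lat_term = np.zeros((P, n_samples))
    for b, members in enumerate(block_members):
        idx = np.searchsorted(probe_ids, members)
        lat_term[idx, :] = config.cmr_latent_sd * latent[b]

    base_l = logit(np.clip(base_mc, 1e-4, 1 - 1e-4))[:, None]
    true_mc = expit(base_l + mc_shift)
    true_mc = np.clip(true_mc + lat_term, 1e-4, 1 - 1e-4)
    hbase_l = logit(np.clip(base_hmc, 1e-4, 1 - 1e-4))[:, None]
    true_hmc = np.where(base_hmc[:, None] > 1e-3, expit(hbase_l + hmc_shift),
                        base_hmc[:, None])
    true_hmc = np.minimum(true_hmc, 1 - true_mc)

    # --- batch offsets and technical noise ---
    chip = np.array([f"chip{(i % config.n_chips) + 1}" for i in range(n_samples)])
    position = np.array([f"R{(i % config.n_positions) + 1}" for i in range(n_samples)])
    chip_off = dict(zip(sorted(set(chip)),
                        rng.normal(0, config.chip_offset_sd, len(set(chip)))))
    pos_off = dict(zip(sorted(set(position)),
                       rng.normal(0, config.position_offset_sd, len(set(position)))))
    batch = np.array([chip_off[c] + pos_off[p] for c, p in zip(chip, position)])

    shared = rng.normal(0, config.shared_sd, (P, n_samples))
    e_ox = rng.normal(0, config.noise_sd, (P, n_samples))
    e_bs = rng.normal(0, config.noise_sd, (P, n_samples))
    oxbs = np.clip(true_mc + shared + e_ox + batch, 0, 1)
    bs = np.clip(true_mc + true_hmc + shared + e_bs + batch, 0, 1)

    bs_m = BetaMatrix(pd.DataFrame(bs, index=probe_ids, columns=sample_ids), "BS")
    ox_m = BetaMatrix(pd.DataFrame(oxbs, index=probe_ids, columns=sample_ids), "oxBS")

    passage = 10 + rng.integers(0, 6, n_samples)
    sheet = SampleSheet(pd.DataFrame({
        "sample_id": sample_ids, "genotype": genotypes, "chip": chip,
        "position": position, "passage": passage,
    }))

    # --- manifest ---
    blacklist = rng.random(P) < config.blacklist_fraction
    cpg_rel = rng.choice(CPG_RELATIONS, P, p=[0.3, 0.1, 0.1, 0.05, 0.05, 0.4])
    probes_df = pd.DataFrame({
        "chromosome": chromosomes, "position": positions,
        "cpg_relation": cpg_rel, "blacklist": blacklist,
    }, index=pd.Index(probe_ids, name="probe_id"))
    annotated = rng.random(P) < config.annotated_fraction
    t_rows = []
    gene_of_probe = rng.integers(0, config.n_genes, P)
    contexts = [c for c in GENOMIC_CONTEXTS if c != "intergenic"]
    for i in np.flatnonzero(annotated):
        n_tx = 1 + int(rng.random() < 0.3)
        for t in range(n_tx):
            gene = f"G{gene_of_probe[i] + t:05d}"
            t_rows.append((probe_ids[i], gene, f"NM_{i:06d}_{t}",
                           int(rng.integers(1000, 100001)),
                           contexts[int(rng.integers(0, len(contexts)))]))
    transcripts = pd.DataFrame(t_rows, columns=[
        "probe_id", "gene", "transcript_id", "transcript_length", "genomic_context"])
    manifest = ProbeManifest(probes_df, transcripts)

    # --- QC metrics ---
    det = rng.uniform(0, 0.04, (P, n_samples))
    fail = rng.random((P, n_samples)) < config.qc_fail_fraction
    det[fail] = rng.uniform(0.051, 1.0, fail.sum())
    beads = 3 + rng.poisson(12, (P, n_samples))
    low = rng.random((P, n_samples)) < config.qc_fail_fraction
    beads[low] = rng.integers(0, 3, low.sum())
    qc = QCMetrics(pd.DataFrame(det, index=probe_ids, columns=sample_ids),
                   pd.DataFrame(beads, index=probe_ids, columns=sample_ids))

    truth = TruthSet(
        dm_probes=pd.DataFrame(dm_rows, columns=["probe_id", "group", "direction",
                                                 "effect"]),
        dhm_probes=pd.DataFrame(dhm_rows, columns=["probe_id", "group", "direction",
                                                   "effect"]),
        true_hmc_floor=float(np.sqrt(2) * config.noise_sd * _Z975),
        cmr_blocks=block_members,
        true_mc=pd.DataFrame(true_mc, index=probe_ids, columns=sample_ids),
        true_hmc=pd.DataFrame(true_hmc, index=probe_ids, columns=sample_ids),
    )
    return bs_m, ox_m, sheet, manifest, qc, truth


def simulate_expression(genes: Sequence[str], de_fraction: float = 0.05,
                        lfc_scale: float = 1.0, seed: int = 0
                        ) -> tuple[ExpressionTable, TruthSet]:
    """Differential-expression table with planted DE genes.

    DE genes receive |log2FC| above 0.5 and padj below 0.01 by construction;
    the remainder are null (log2FC near 0, p roughly uniform).
    """
    if not 0 <= de_fraction <= 1:
        raise ValidationError("de_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    genes = list(genes)
    n = len(genes)
    n_de = int(round(de_fraction * n))
    de_idx = rng.choice(n, size=n_de, replace=False)
    is_de = np.zeros(n, bool)
    is_de[de_idx] = True
    lfc = rng.normal(0, 0.15, n)
    lfc[is_de] = np.sign(rng.normal(size=n_de)) * (0.6 + np.abs(
        rng.normal(0, lfc_scale, n_de)))
    p = rng.uniform(0.01, 1.0, n)
    p[is_de] = 10.0 ** rng.uniform(-12, -5, n_de)
    # conservative stand-in for an upstream BH column; DE genes well below 0.01
    padj = np.minimum(p * 2, 1.0)
    padj[is_de] = np.minimum(p[is_de] * 50, 0.009)
    table = ExpressionTable(pd.DataFrame({
        "gene": genes, "log2FC": lfc, "p": p, "padj": padj,
        "mean_count": rng.gamma(2, 200, n),
    }))
    truth = TruthSet(
        dm_probes=pd.DataFrame(columns=["probe_id", "group", "direction", "effect"]),
        dhm_probes=pd.DataFrame(columns=["probe_id", "group", "direction", "effect"]),
        true_hmc_floor=0.0, cmr_blocks=[],
        de_genes={genes[i]: float(lfc[i]) for i in de_idx},
    )
    return table, truth


@dataclass
class RrbsSimConfig:
    """Parameters for the sequencing-based (RRBS-style) generator."""

    n_cytosines: int = 2000
    mean_depth: float = 30.0
    depth_dispersion: float = 5.0  # negative-binomial size parameter
    groups: tuple[str, ...] = ("control", "WT")
    n_per_group: tuple[int, ...] = (4, 4)
    effect_fraction: float = 0.05
    effect_logit: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mean_depth < 1:
            raise ValidationError("mean depth must be >= 1")
        if not 0 <= self.effect_fraction <= 1:
            raise ValidationError("effect_fraction must lie in [0, 1]")


def simulate_rrbs(config: RrbsSimConfig) -> tuple[dict[str, CountTable], TruthSet]:
    """Per-cytosine methylated/total read counts for both conversion arms.

    Depths are negative-binomial; methylated counts are binomial with a
    group-specific success probability carrying logit-scale planted effects.
    The oxBS arm reads mC only; the BS arm reads mC plus a small hmC component.
    """
    rng = np.random.default_rng(config.seed)
    C = config.n_cytosines
    n_samples = sum(config.n_per_group)
    sample_ids, genotypes = [], []
    for g, n in zip(config.groups, config.n_per_group):
        for i in range(n):
            sample_ids.append(f"{g}_{i + 1}")
            genotypes.append(g)
    genotypes = np.array(genotypes)

    positions = 1 + np.cumsum(rng.integers(50, 500, C))
    chroms = np.repeat("chr1", C)
    base = rng.beta(3, 3, C)
    hmc = np.abs(rng.normal(0, 0.01, C))
    n_eff = int(round(config.effect_fraction * C))
    eff_idx = rng.choice(C, size=n_eff, replace=False)
    direction = np.sign(rng.normal(size=n_eff))
    direction[direction == 0] = 1.0

    l_base = logit(np.clip(base, 1e-4, 1 - 1e-4))
    p_mc = np.tile(l_base[:, None], (1, n_samples))
    target = genotypes == config.groups[1]
    p_mc[np.ix_(eff_idx, np.flatnonzero(target))] += (direction
                                                      * config.effect_logit)[:, None]
    p_mc = expit(p_mc)

    nb_n = config.depth_dispersion
    nb_p = nb_n / (nb_n + config.mean_depth)
    tables: dict[str, CountTable] = {}
    for arm, p_true in (("oxBS", p_mc), ("BS", np.clip(p_mc + hmc[:, None], 0, 1))):
        depth = rng.negative_binomial(nb_n, nb_p, (C, n_samples))
        meth = rng.binomial(depth, p_true)
        sites = pd.DataFrame({"chromosome": chroms, "position": positions})
        tables[arm] = CountTable(
            sites=sites,
            methylated=pd.DataFrame(meth, columns=sample_ids),
            total=pd.DataFrame(depth, columns=sample_ids),
            arm=arm,
        )
    dm = pd.DataFrame({
        "cytosine": [f"chr1:{positions[i]}" for i in eff_idx],
        "group": config.groups[1],
        "direction": np.where(direction > 0, "increase", "decrease"),
        "effect": direction * config.effect_logit,
    })
    truth = TruthSet(
        dm_probes=pd.DataFrame(columns=["probe_id", "group", "direction", "effect"]),
        dhm_probes=pd.DataFrame(columns=["probe_id", "group", "direction", "effect"]),
        true_hmc_floor=0.0, cmr_blocks=[], dm_cytosines=dm,
    )
    return tables, truth
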
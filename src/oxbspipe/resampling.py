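"""Seeded permutation-null procedures for enrichment and overlap statistics.

All four procedures share the same reporting convention: the observed
statistic, the vector of null draws, and two one-sided empirical p-values.
By default a draw tied with the observed value counts toward both tails
(inclusive counting), which keeps p-values strictly positive and
conservative; ``strict=True`` implements literal more-than/fewer-than
counting, floored at 1/n_iter because an empirical p of exactly zero is not
reportable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .cmr import CMRSet
from .differential import bh_adjust
from .io import ValidationError

__all__ = ["PermutationResult", "permute_set_overlap",
           "permute_feature_enrichment", "permute_cmr_site_overlap",
           "permute_cross_species_genes", "permute_threeway_genes"]


@dataclass
class PermutationResult:
    """Observed statistic, null draws, and tail p-values of one procedure."""

    observed: float
    null_draws: np.ndarray
    p_enrich: float
    p_deplete: float
    n_iter: int
    seed: int
    at_floor: bool = False  # true when a strict count was 0 (report "< 1/n_iter")

    @property
    def null_mean(self) -> float:
        return float(np.mean(self.null_draws))


def _tail_p(null: np.ndarray, observed: float, n_iter: int,
            strict: bool) -> tuple[float, float, bool]:
    if strict:
        up = int(np.sum(null > observed))
        dn = int(np.sum(null < observed))
    else:
        up = int(np.sum(null >= observed))
        dn = int(np.sum(null <= observed))
    floor = up == 0 or dn == 0
    p_up = max(up, 1) / n_iter
    p_dn = max(dn, 1) / n_iter
    return p_up, p_dn, floor


def _check_subset(hits: set, background: set, what: str) -> None:
    if not hits <= background:
        raise ValidationError(f"{what} not contained in its background")


def _sample_indices(rng: np.random.Generator, n: int, k: int) -> np.ndarray:
    return rng.choice(n, size=k, replace=False)


def permute_set_overlap(hits_a: Iterable[str], hits_b: Iterable[str],
                        background: Iterable[str], n_iter: int = 10000,
                        seed: int = 0, strict: bool = False) -> PermutationResult:
    """Null distribution of |A intersect B| under independent resampling.

    Each draw resamples both sets uniformly without replacement from the
    background at their observed sizes; under independence the null mean is
    the product-form expectation |A||B|/N.
    """
    A, B = set(hits_a), set(hits_b)
    bg = sorted(set(background))
    _check_subset(A, set(bg), "hits_a")
    _check_subset(B, set(bg), "hits_b")
    rng = np.random.default_rng(seed)
    N, a, b = len(bg), len(A), len(B)
    observed = len(A & B)
    null = np.empty(n_iter, dtype=np.int64)
    mask = np.zeros(N, dtype=bool)
    for it in range(n_iter):
        ia = _sample_indices(rng, N, a)
        ib = _sample_indices(rng, N, b)
        mask[ia] = True
        null[it] = int(mask[ib].sum())
        mask[ia] = False
    p_up, p_dn, floor = _tail_p(null, observed, n_iter, strict)
    return PermutationResult(float(observed), null, p_up, p_dn, n_iter, seed,
                             at_floor=floor)


def permute_feature_enrichment(hits: Iterable[str],
                               categories: Mapping[str, str],
                               background: Iterable[str],
                               n_iter: int = 10000, seed: int = 0,
                               strict: bool = False) -> pd.DataFrame:
    """Per-label enrichment/depletion of hits against the labeled background.

    Each draw resamples |hits| probes from the background and tallies them by
    label.  Returns one row per label with observed and expected counts, the
    fold (observed over null mean), both tail p-values, and BH adjustment
    across labels within each tail.
    """
    hits = set(hits)
    bg = sorted(set(background))
    _check_subset(hits, set(bg), "hits")
    unlabeled = [p for p in bg if p not in categories]
    if unlabeled:
        raise ValidationError(f"unlabeled background probes: {unlabeled[:5]}")
    labels = sorted({categories[p] for p in bg})
    if not labels:
        raise ValidationError("empty label set")
    code = {lab: i for i, lab in enumerate(labels)}
    bg_codes = np.array([code[categories[p]] for p in bg])
    observed = np.bincount([code[categories[p]] for p in hits], minlength=len(labels))

    rng = np.random.default_rng(seed)
    N, k = len(bg), len(hits)
    counts = np.empty((n_iter, len(labels)), dtype=np.int64)
    for it in range(n_iter):
        idx = _sample_indices(rng, N, k)
        counts[it] = np.bincount(bg_codes[idx], minlength=len(labels))

    rows = []
    for j, lab in enumerate(labels):
        null = counts[:, j]
        p_up, p_dn, _ = _tail_p(null, observed[j], n_iter, strict)
        mean = null.mean()
        fold = observed[j] / mean if mean > 0 else np.nan
        rows.append((lab, int(observed[j]), float(mean), float(fold), p_up, p_dn))
    out = pd.DataFrame(rows, columns=["label", "observed", "expected", "fold",
                                      "p_enrich", "p_deplete"])
    out["padj_enrich"] = bh_adjust(out["p_enrich"].to_numpy())
    out["padj_deplete"] = bh_adjust(out["p_deplete"].to_numpy())
    return out


def permute_cmr_site_overlap(site_hits: Iterable[str], cmr_hits: Iterable[str],
                             site_background: Iterable[str],
                             cmr_background: Iterable[str], cmrs: CMRSet,
                             n_iter: int = 10000, seed: int = 0,
                             strict: bool = False) -> PermutationResult:
    """Overlap between significant sites and significant CMRs.

    ``cmr_hits`` and ``cmr_background`` are representative probe IDs; the
    statistic is the number of site hits that are members of hit CMRs.  Both
    lists are resampled at their observed sizes each draw.
    """
    reps = cmrs.representatives()
    membership = cmrs.membership()
    if not membership:
        raise ValidationError("CMRSet has no membership")
    site_hits = set(site_hits)
    cmr_hits = set(cmr_hits)
    site_bg = sorted(set(site_background))
    cmr_bg = sorted(set(cmr_background))
    _check_subset(site_hits, set(site_bg), "site_hits")
    _check_subset(cmr_hits, set(cmr_bg), "cmr_hits")
    bad = [p for p in cmr_bg if p not in reps]
    if bad:
        raise ValidationError(f"not representative probes: {bad[:5]}")

    members_by_rep = {}
    for c in cmrs:
        members_by_rep[c.representative_probe] = set(c.probes)

    def overlap(sites: set[str], rep_set: Iterable[str]) -> int:
        covered = set()
        for r in rep_set:
            covered |= members_by_rep[r]
        return len(sites & covered)

    observed = overlap(site_hits, cmr_hits)
    rng = np.random.default_rng(seed)
    site_arr = np.array(site_bg)
    cmr_arr = np.array(cmr_bg)
    null = np.empty(n_iter, dtype=np.int64)
    for it in range(n_iter):
        s = set(site_arr[_sample_indices(rng, len(site_arr), len(site_hits))])
        r = cmr_arr[_sample_indices(rng, len(cmr_arr), len(cmr_hits))]
        null[it] = overlap(s, r)
    p_up, p_dn, floor = _tail_p(null, observed, n_iter, strict)
    return PermutationResult(float(observed), null, p_up, p_dn, n_iter, seed,
                             at_floor=floor)


def permute_cross_species_genes(hit_cytosines: Iterable[str],
                                background_cytosines: Iterable[str],
                                cytosine_to_gene: Mapping[str, str],
                                n_iter: int = 10000, seed: int = 0,
                                strict: bool = False) -> PermutationResult:
    """Distinct genes covered by hit cytosines vs resampled cytosine sets.

    The background is assumed already restricted to cytosines in the genes of
    interest.  Unmapped cytosines are excluded with a warning.
    """
    hits = set(hit_cytosines)
    bg = set(background_cytosines)
    _check_subset(hits, bg, "hit_cytosines")
    unmapped = {c for c in bg if c not in cytosine_to_gene}
    if unmapped:
        warnings.warn(f"excluding {len(unmapped)} unmapped cytosines")
        bg -= unmapped
        hits -= unmapped
    bg_list = sorted(bg)
    genes = np.array([cytosine_to_gene[c] for c in bg_list])
    hit_idx = {c: i for i, c in enumerate(bg_list)}
    observed = len({cytosine_to_gene[c] for c in hits})
    rng = np.random.default_rng(seed)
    null = np.empty(n_iter, dtype=np.int64)
    for it in range(n_iter):
        idx = _sample_indices(rng, len(bg_list), len(hits))
        null[it] = len(np.unique(genes[idx]))
    p_up, p_dn, floor = _tail_p(null, observed, n_iter, strict)
    return PermutationResult(float(observed), null, p_up, p_dn, n_iter, seed,
                             at_floor=floor)


def permute_threeway_genes(dm_probes: Iterable[str], dhm_probes: Iterable[str],
                           de_genes: Iterable[str],
                           dm_background: Iterable[str],
                           dhm_background: Iterable[str],
                           de_background: Iterable[str],
                           probe_to_gene: Mapping[str, str],
                           n_iter: int = 10000, seed: int = 0,
                           strict: bool = False) -> PermutationResult:
    """Three-way gene-level overlap of DNAm, DNAhm, and expression hits.

    Probe lists map to genes via ``probe_to_gene`` (longest-transcript rule
    upstream); each draw resamples all three hit lists from their backgrounds
    and intersects at the gene level.
    """
    def genes_of(probes: Iterable[str]) -> set[str]:
        return {probe_to_gene[p] for p in probes if p in probe_to_gene}

    dm, dhm, de = set(dm_probes), set(dhm_probes), set(de_genes)
    dm_bg, dhm_bg = sorted(set(dm_background)), sorted(set(dhm_background))
    de_bg = sorted(set(de_background))
    _check_subset(dm, set(dm_bg), "dm_probes")
    _check_subset(dhm, set(dhm_bg), "dhm_probes")
    _check_subset(de, set(de_bg), "de_genes")

    observed = len(genes_of(dm) & genes_of(dhm) & de)
    rng = np.random.default_rng(seed)
    dm_arr, dhm_arr, de_arr = map(np.array, (dm_bg, dhm_bg, de_bg))
    null = np.empty(n_iter, dtype=np.int64)
    for it in range(n_iter):
        g1 = genes_of(dm_arr[_sample_indices(rng, len(dm_arr), len(dm))])
        g2 = genes_of(dhm_arr[_sample_indices(rng, len(dhm_arr), len(dhm))])
        g3 = set(de_arr[_sample_indices(rng, len(de_arr), len(de))])
        null[it] = len(g1 & g2 & g3)
    p_up, p_dn, floor = _tail_p(null, observed, n_iter, strict)
    return PermutationResult(float(observed), null, p_up, p_dn, n_iter, seed,
                             at_floor=floor)
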
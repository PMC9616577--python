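"""Co-methylated region (CMR) detection and composite-beta testing.

CMRs are runs of nearby CpGs whose beta values are correlated across samples.
Detection is greedy chaining over position-sorted probes: a probe extends the
open run iff its genomic gap to the previous probe is at most ``max_gap`` and
its Pearson correlation with the previous probe's values is at least
``min_r``; runs with at least ``min_probes`` members become CMRs.  Each CMR
is summarized per sample by a composite beta: a convex combination of member
betas weighted by the absolute first-principal-component loadings, then
tested exactly like a single probe.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .differential import fit_moderated
from .io import BetaMatrix, DiffTable, ProbeManifest, SampleSheet, ValidationError

__all__ = ["CMR", "CMRSet", "detect_cmrs", "composite_betas", "diff_cmrs",
           "CompositeMatrix"]


@dataclass
class CMR:
    """One co-methylated region: position-ordered member probes on one chromosome."""

    id: str
    chromosome: str
    start: int  # 1-based inclusive span of member probes
    end: int
    probes: list[str]
    min_pair_r: float

    @property
    def representative_probe(self) -> str:
        return self.probes[0]


@dataclass
class CMRSet:
    """Collection of CMRs with membership lookup."""

    cmrs: list[CMR]

    def __len__(self) -> int:
        return len(self.cmrs)

    def __iter__(self):
        return iter(self.cmrs)

    def by_id(self, cmr_id: str) -> CMR:
        return next(c for c in self.cmrs if c.id == cmr_id)

    def membership(self) -> dict[str, str]:
        """probe_id -> cmr_id for every member probe."""
        return {p: c.id for c in self.cmrs for p in c.probes}

    def representatives(self) -> dict[str, str]:
        """representative probe_id -> cmr_id."""
        return {c.representative_probe: c.id for c in self.cmrs}

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(c.chromosome, c.start, c.end, c.id, len(c.probes), c.min_pair_r)
             for c in self.cmrs],
            columns=["chromosome", "start", "end", "id", "n_probes", "min_pair_r"],
        )


@dataclass
class CompositeMatrix:
    """CMR x sample composite beta values."""

    values: pd.DataFrame  # index cmr_id, columns sample_ids


def _pairwise_r(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Rowwise Pearson correlation of paired rows, NaN-pairwise-complete."""
    out = np.full(a.shape[0], np.nan)
    both = ~(np.isnan(a) | np.isnan(b))
    for i in range(a.shape[0]):
        m = both[i]
        if m.sum() < 3:
            continue
        x, y = a[i, m], b[i, m]
        sx, sy = x.std(), y.std()
        if sx == 0 or sy == 0:
            continue
        out[i] = ((x - x.mean()) * (y - y.mean())).mean() / (sx * sy)
    return out


def detect_cmrs(matrix: BetaMatrix, manifest: ProbeManifest,
                max_gap: int = 1000, min_r: float = 0.4,
                min_probes: int = 2) -> CMRSet:
    """Greedy correlation chaining over position-sorted probes."""
    if matrix.shape[1] < 3:
        raise ValidationError("CMR detection needs >= 3 samples")
    missing = set(matrix.probe_ids) - set(manifest.probes.index)
    if missing:
        raise ValidationError(f"manifest missing probes: {sorted(missing)[:5]}")
    pos = manifest.probes.loc[matrix.probe_ids, ["chromosome", "position"]]
    order = pos.sort_values(["chromosome", "position"], kind="mergesort").index
    vals = matrix.values.loc[order].to_numpy(float)
    chrom = pos.loc[order, "chromosome"].to_numpy()
    coord = pos.loc[order, "position"].to_numpy()

    r = _pairwise_r(vals[:-1], vals[1:]) if len(order) > 1 else np.array([])
    gap_ok = (coord[1:] - coord[:-1]) <= max_gap
    same = chrom[1:] == chrom[:-1]
    link = same & gap_ok & (r >= min_r)

    cmrs: list[CMR] = []
    i = 0
    n = len(order)
    while i < n - 1:
        if not link[i]:
            i += 1
            continue
        j = i
        while j < n - 1 and link[j]:
            j += 1
        members = list(order[i:j + 1])
        if len(members) >= min_probes:
            pair_rs = r[i:j]
            cmrs.append(CMR(
                id=f"cmr_{len(cmrs) + 1:05d}",
                chromosome=str(chrom[i]),
                start=int(coord[i]),
                end=int(coord[j]),
                probes=members,
                min_pair_r=float(np.min(pair_rs)),
            ))
        i = j + 1
    return CMRSet(cmrs)


def composite_betas(matrix: BetaMatrix, cmrs: CMRSet) -> CompositeMatrix:
    """PC1-weighted convex combination of member betas, per CMR and sample.

    Loadings come from the first principal component of the member-probe x
    sample matrix (probes as variables, samples as observations); weights are
    absolute loadings normalized to sum 1, so the composite stays within the
    member range.  Zero-variance CMRs fall back to the plain probe mean.
    """
    rows, ids = [], []
    for c in cmrs:
        missing = set(c.probes) - set(matrix.probe_ids)
        if missing:
            raise ValidationError(f"{c.id}: member probes absent: {sorted(missing)}")
        M = matrix.values.loc[c.probes].to_numpy(float)
        centered = M - M.mean(axis=1, keepdims=True)
        if not np.any(centered):
            warnings.warn(f"{c.id}: zero variance; composite = probe mean")
            w = np.full(M.shape[0], 1.0 / M.shape[0])
        else:
            # PC1 probe loadings via SVD of the centered (probes x samples) matrix
            u, s, _ = np.linalg.svd(centered, full_matrices=False)
            load = u[:, 0]
            if np.corrcoef(load @ centered, centered.mean(axis=0))[0, 1] < 0:
                load = -load
            w = np.abs(load)
            w = w / w.sum() if w.sum() > 0 else np.full(len(load), 1.0 / len(load))
        rows.append(w @ M)
        ids.append(c.id)
    df = pd.DataFrame(rows, index=ids, columns=matrix.sample_ids)
    return CompositeMatrix(df)


def diff_cmrs(comp: CompositeMatrix, sheet: SampleSheet,
              contrast: tuple[str, str], delta_min: float = 0.05,
              padj_max: float = 0.05, arm: str = "mC") -> DiffTable:
    """Moderated-t test of composite betas; thresholds match site-level."""
    bm = BetaMatrix(comp.values, arm)
    table, _ = fit_moderated(bm, sheet, contrast, delta_min=delta_min,
                             padj_max=padj_max)
    return table
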
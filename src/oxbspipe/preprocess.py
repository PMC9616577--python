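"""Probe QC filtering, per-arm quantile normalization, and batch adjustment.

The preprocessing contract is: (1) remove blacklisted probes (SNP controls,
cross-hybridizing), probes failing the detection-p rule, and probes failing
the bead-count rule, in that order, with each probe attributed to the first
rule that removes it; (2) full quantile normalization applied to each
conversion arm separately; (3) location/scale empirical-Bayes batch
adjustment (parametric ComBat) for categorical batch variables applied
sequentially, with continuous covariates (passage) removed by linear
residualization while protecting the genotype effect.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .io import BetaMatrix, ProbeManifest, QCMetrics, SampleSheet, ValidationError

__all__ = ["FilterReport", "filter_probes", "normalize_arm", "adjust_batch"]


@dataclass
class FilterReport:
    """Counts of probes removed per rule, attributed sequentially."""

    removed: dict[str, int] = field(default_factory=dict)
    surviving: int = 0

    @property
    def total_removed(self) -> int:
        return sum(self.removed.values())


def filter_probes(
    bs: BetaMatrix,
    oxbs: BetaMatrix,
    qc: QCMetrics,
    manifest: ProbeManifest,
    det_p_max: float = 0.05,
    det_frac: float = 0.01,
    bead_min: int = 3,
    bead_frac: float = 0.05,
) -> tuple[BetaMatrix, BetaMatrix, FilterReport]:
    """Apply blacklist, detection-p, and bead-count filters to both arms.

    A probe fails the detection rule when its fraction of samples with
    detection p > ``det_p_max`` exceeds ``det_frac``, and the bead rule when
    its fraction of samples with bead count < ``bead_min`` exceeds
    ``bead_frac``.  Both arms are filtered to the identical surviving set.
    """
    if not bs.probe_ids.equals(oxbs.probe_ids) or not bs.sample_ids.equals(oxbs.sample_ids):
        raise ValidationError("BS and oxBS matrices must share probes and samples")
    if not bs.probe_ids.equals(qc.detection_p.index):
        raise ValidationError("QC metrics must cover the same probes as the matrices")

    probes = bs.probe_ids
    alive = pd.Series(True, index=probes)
    report = FilterReport()

    black = manifest.probes.reindex(probes)["blacklist"].fillna(False).astype(bool)
    hit = alive & black
    report.removed["blacklist"] = int(hit.sum())
    alive &= ~black

    det_fail = (qc.detection_p.loc[probes, bs.sample_ids] > det_p_max).mean(axis=1)
    hit = alive & (det_fail > det_frac)
    report.removed["detection_p"] = int(hit.sum())
    alive &= ~hit

    bead_fail = (qc.bead_count.loc[probes, bs.sample_ids] < bead_min).mean(axis=1)
    hit = alive & (bead_fail > bead_frac)
    report.removed["bead_count"] = int(hit.sum())
    alive &= ~hit

    keep = list(probes[alive])
    report.surviving = len(keep)
    return bs.subset_probes(keep), oxbs.subset_probes(keep), report


def normalize_arm(matrix: BetaMatrix) -> BetaMatrix:
    """Full quantile normalization across samples within one conversion arm.

    Every sample's sorted values are replaced by the across-sample mean of
    sorted values, so all per-sample quantiles become identical while ranks
    within each sample are preserved.  Missing values keep their position and
    the remaining values are mapped through the reference quantile function.
    """
    X = matrix.values.to_numpy(float)
    P, S = X.shape
    if S < 2:
        warnings.warn("quantile normalization skipped: fewer than 2 samples")
        return matrix
    if not np.isnan(X).any():
        order = np.argsort(X, axis=0, kind="stable")
        ref = np.sort(X, axis=0).mean(axis=1)
        out = np.empty_like(X)
        rows = order
        cols = np.broadcast_to(np.arange(S), (P, S))
        out[rows, cols] = ref[:, None]
    else:
        # reference quantile function from NaN-skipping per-sample quantiles
        grid = np.linspace(0, 1, P)
        ref = np.nanmean(
            np.stack([np.nanquantile(X[:, j], grid) for j in range(S)]), axis=0
        )
        out = np.full_like(X, np.nan)
        for j in range(S):
            col = X[:, j]
            ok = ~np.isnan(col)
            k = ok.sum()
            if k == 0:
                continue
            r = rankdata(col[ok], method="ordinal") - 1
            pos = r / (k - 1) if k > 1 else np.zeros(1)
            out[ok, j] = np.interp(pos, grid, ref)
    out = np.clip(out, 0.0, 1.0)
    return matrix.with_values(pd.DataFrame(out, index=matrix.probe_ids,
                                           columns=matrix.sample_ids))


def _design(values: np.ndarray) -> np.ndarray:
    """Dummy-coded design with intercept for a categorical vector."""
    levels = pd.unique(values)
    cols = [np.ones(len(values))]
    for lv in levels[1:]:
        cols.append((values == lv).astype(float))
    return np.column_stack(cols)


def _combat_one(X: np.ndarray, batch: np.ndarray, protect: np.ndarray,
                max_iter: int = 100, tol: float = 1e-4) -> np.ndarray:
    """Parametric ComBat for one categorical batch variable.

    ``X`` is probes x samples; ``protect`` is the biological grouping whose
    effect must survive adjustment.  Per-batch location and scale parameters
    are shrunk toward across-probe priors (normal prior for locations,
    inverse-gamma for scales, hyperparameters by method of moments) and
    removed on the standardized scale.
    """
    levels = pd.unique(batch)
    if len(levels) < 2:
        return X.copy()
    n = X.shape[1]
    B = np.column_stack([(batch == lv).astype(float) for lv in levels])
    n_batch = B.sum(axis=0)
    if (n_batch < 2).any():
        raise ValidationError("each batch level needs >= 2 samples")
    prot = _design(protect)[:, 1:]  # protected effects, no intercept
    design = np.column_stack([B, prot]) if prot.size else B
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        raise ValidationError(
            "batch variable is confounded with the protected variable"
        )

    beta, *_ = np.linalg.lstsq(design, X.T, rcond=None)
    grand = (n_batch / n) @ beta[: len(levels)]  # weighted grand mean per probe
    stand_mean = np.tile(grand[:, None], (1, n))
    if prot.size:
        stand_mean += (prot @ beta[len(levels):]).T
    resid = X - (design @ beta).T
    # residual-df normalization keeps delta_hat = 1 exactly when batches are
    # identically distributed, making the adjustment a no-op in that case
    var_pooled = (resid ** 2).sum(axis=1) / (n - rank)
    var_pooled = np.maximum(var_pooled, 1e-12)
    sd = np.sqrt(var_pooled)[:, None]
    Z = (X - stand_mean) / sd

    # batch effect estimates on the standardized scale; per-batch scale uses
    # the batch's share of the residual df so identically distributed batches
    # give delta_hat = 1 exactly
    gamma_hat = np.stack([Z[:, batch == lv].mean(axis=1) for lv in levels])
    delta_hat = np.stack([
        ((Z[:, batch == lv] - gamma_hat[i][:, None]) ** 2).sum(axis=1)
        / ((n - rank) * (batch == lv).sum() / n)
        for i, lv in enumerate(levels)
    ])
    delta_hat = np.maximum(delta_hat, 1e-12)

    gamma_bar = gamma_hat.mean(axis=1)
    t2 = gamma_hat.var(axis=1, ddof=1)
    m = delta_hat.mean(axis=1)
    s2 = delta_hat.var(axis=1, ddof=1)
    s2 = np.maximum(s2, 1e-12)
    a_prior = (2 * s2 + m ** 2) / s2
    b_prior = (m * s2 + m ** 3) / s2

    Z_adj = Z.copy()
    for i, lv in enumerate(levels):
        sel = batch == lv
        nb = sel.sum()
        zb = Z[:, sel]
        g, d = gamma_hat[i].copy(), delta_hat[i].copy()
        for _ in range(max_iter):
            g_new = (nb * t2[i] * gamma_hat[i] + d * gamma_bar[i]) / (nb * t2[i] + d)
            ss = ((zb - g_new[:, None]) ** 2).sum(axis=1)
            d_new = (0.5 * ss + b_prior[i]) / (nb / 2 + a_prior[i] - 1)
            change = max(np.max(np.abs(g_new - g) / (np.abs(g) + 1e-12)),
                         np.max(np.abs(d_new - d) / (d + 1e-12)))
            g, d = g_new, d_new
            if change < tol:
                break
        Z_adj[:, sel] = (zb - g[:, None]) / np.sqrt(d)[:, None]

    return Z_adj * sd + stand_mean


def adjust_batch(matrix: BetaMatrix, sheet: SampleSheet,
                 batch_vars: list[str] | None = None,
                 protect: str = "genotype") -> BetaMatrix:
    """Remove batch effects while protecting the biological grouping.

    Categorical variables (chip, position) are adjusted sequentially with
    parametric ComBat; numeric variables (passage) are removed by linear
    residualization on a design that includes the protected grouping.
    Output is clipped back to [0, 1].
    """
    if batch_vars is None:
        batch_vars = ["chip", "position", "passage"]
    sheet.require_samples(matrix.sample_ids)
    X = matrix.values.to_numpy(float)
    if np.isnan(X).any():
        raise ValidationError("batch adjustment requires complete values")
    prot = sheet.column(protect, list(matrix.sample_ids)).to_numpy()

    for var in batch_vars:
        v = sheet.column(var, list(matrix.sample_ids)).to_numpy()
        if np.issubdtype(np.asarray(v).dtype, np.number) and len(set(v)) > 4:
            # continuous covariate: residualize, protecting the grouping
            centered = (v - v.mean()).astype(float)
            D = np.column_stack([_design(prot), centered])
            beta, *_ = np.linalg.lstsq(D, X.T, rcond=None)
            X = X - np.outer(beta[-1], centered)
        else:
            X = _combat_one(X, np.asarray(v), prot)

    X = np.clip(X, 0.0, 1.0)
    return matrix.with_values(pd.DataFrame(X, index=matrix.probe_ids,
                                           columns=matrix.sample_ids))
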
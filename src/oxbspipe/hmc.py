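"""Hydroxymethylation estimation by paired-arm subtraction.

BS conversion reads mC + hmC while oxBS reads mC alone, so the elementwise
difference of the two normalized beta matrices estimates hmC.  At truly
unhydroxymethylated sites the difference is pure technical noise, symmetric
around zero; the magnitudes of the *negative* differences therefore
characterize that noise, and their upper quantile (default 0.95) serves as a
detectability floor.  Probes whose mean hmC falls below the floor are
indistinguishable from noise and are discarded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import BetaMatrix, ValidationError

__all__ = ["HmcThreshold", "compute_hmc", "detectability_threshold",
           "mask_undetectable"]


@dataclass
class HmcThreshold:
    """Detectability floor derived from negative subtraction values."""

    value: float
    n_negative: int
    quantile: float

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ValidationError("threshold must be non-negative")
        if not 0 < self.quantile < 1:
            raise ValidationError("quantile must lie in (0, 1)")


def compute_hmc(bs: BetaMatrix, oxbs: BetaMatrix,
                clip_negatives: bool = False) -> BetaMatrix:
    """Elementwise BS - oxBS difference; negatives are retained by default.

    Retaining negative values keeps downstream linear models unbiased at
    near-zero sites; ``clip_negatives`` floors them at 0 instead.
    """
    if not bs.probe_ids.equals(oxbs.probe_ids) or not bs.sample_ids.equals(oxbs.sample_ids):
        raise ValidationError("BS and oxBS matrices must share probes and samples")
    diff = bs.values - oxbs.values
    if clip_negatives:
        diff = diff.clip(lower=0.0)
    return BetaMatrix(diff, "hmC")


def detectability_threshold(hmc: BetaMatrix, quantile: float = 0.95,
                            per_sample: bool = False) -> HmcThreshold:
    """Quantile of the magnitudes of negative hmC entries.

    Entries are pooled over probes and samples (``per_sample=True`` instead
    takes the median of per-sample quantiles).  The quantile uses linear
    interpolation.  With no negative entries the threshold is 0.
    """
    vals = hmc.values.to_numpy(float)
    if vals.size == 0:
        raise ValidationError("empty hmC matrix")
    if per_sample:
        per = []
        for j in range(vals.shape[1]):
            neg = vals[:, j][vals[:, j] < 0]
            per.append(float(np.quantile(-neg, quantile)) if neg.size else 0.0)
        neg_all = vals[vals < 0]
        return HmcThreshold(float(np.median(per)), int(neg_all.size), quantile)
    neg = vals[vals < 0]
    value = float(np.quantile(-neg, quantile)) if neg.size else 0.0
    return HmcThreshold(value, int(neg.size), quantile)


def mask_undetectable(hmc: BetaMatrix, thr: HmcThreshold) -> BetaMatrix:
    """Drop probes whose across-sample mean hmC is below the floor.

    Surviving probes keep their negative entries as-is.  A zero threshold is
    the identity (no detectability floor means nothing is discarded).
    """
    if thr.value == 0:
        return BetaMatrix(hmc.values.copy(), "hmC")
    means = hmc.values.mean(axis=1, skipna=True)
    keep = means >= thr.value
    return BetaMatrix(hmc.values.loc[keep], "hmC")
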
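"""Domain types and tabular/interval readers and writers.

The pipeline operates on paired bisulfite (BS) and oxidative-bisulfite (oxBS)
beta-value matrices.  BS conversion reads mC + hmC; oxBS reads mC only, so the
arm difference estimates hydroxymethylation.  All matrices are probes x samples
with fractions in [0, 1], except derived hmC matrices which may legitimately
hold negative entries before detectability thresholding.

Coordinate conventions: interval files (BED) are 0-based half-open and kept
that way internally; array-manifest probe positions are 1-based and converted
exactly once, at the manifest boundary, when intervals are derived from them.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ValidationError",
    "FormatError",
    "ARMS",
    "GENOMIC_CONTEXTS",
    "CPG_RELATIONS",
    "BetaMatrix",
    "SampleSheet",
    "ProbeManifest",
    "QCMetrics",
    "IntervalSet",
    "ExpressionTable",
    "DiffTable",
    "RunConfig",
    "read_beta_matrix",
    "write_beta_matrix",
    "read_intervals",
    "write_intervals",
    "read_diff_table",
    "write_diff_table",
    "read_expression_table",
    "read_gmt",
    "read_edge_list",
]


class ValidationError(ValueError):
    """Input violates a domain invariant (exit code 1 in the CLI)."""


class FormatError(ValueError):
    """File structure cannot be parsed as the expected format."""


ARMS = ("BS", "oxBS", "mC", "hmC")

GENOMIC_CONTEXTS = (
    "TSS1500",
    "TSS200",
    "5'UTR",
    "1stExon",
    "Body",
    "3'UTR",
    "intergenic",
)

CPG_RELATIONS = ("Island", "N_Shore", "S_Shore", "N_Shelf", "S_Shelf", "OpenSea")


def _check_unique(labels: Iterable[str], what: str) -> None:
    labels = list(labels)
    if len(set(labels)) != len(labels):
        seen, dups = set(), []
        for x in labels:
            if x in seen:
                dups.append(x)
            seen.add(x)
        raise FormatError(f"duplicate {what}: {sorted(set(dups))[:5]}")


@dataclass
class BetaMatrix:
    """Probes x samples modification-fraction matrix for one conversion arm.

    ``arm`` is one of BS, oxBS (measured), mC, hmC (derived).  BS/oxBS/mC
    values must lie in [0, 1]; hmC values may lie in [-1, 1] because paired-arm
    noise makes the BS - oxBS subtraction negative at truly unmodified sites.
    Missing values (NaN) are allowed and propagate through downstream steps
    according to each step's contract.
    """

    values: pd.DataFrame
    arm: str

    def __post_init__(self) -> None:
        if self.arm not in ARMS:
            raise ValidationError(f"unknown arm {self.arm!r}; expected one of {ARMS}")
        _check_unique(self.values.index, "probe IDs")
        _check_unique(self.values.columns, "sample IDs")
        self.values = self.values.astype(float)
        lo = -1.0 if self.arm == "hmC" else 0.0
        vals = self.values.to_numpy()
        bad = (vals < lo) | (vals > 1.0)
        bad &= ~np.isnan(vals)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValidationError(
                f"value {vals[i, j]:g} outside [{lo}, 1] for arm {self.arm} "
                f"at probe {self.values.index[i]!r}, sample {self.values.columns[j]!r}"
            )

    @property
    def probe_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_probes(self, probes: Sequence[str]) -> "BetaMatrix":
        return BetaMatrix(self.values.loc[list(probes)], self.arm)

    def with_values(self, values: pd.DataFrame, arm: str | None = None) -> "BetaMatrix":
        return BetaMatrix(values, self.arm if arm is None else arm)


@dataclass
class SampleSheet:
    """Per-sample metadata: genotype plus the batch/covariate columns."""

    data: pd.DataFrame  # columns: sample_id, genotype, chip, position, passage

    REQUIRED = ("sample_id", "genotype", "chip", "position", "passage")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.data.columns]
        if missing:
            raise FormatError(f"sample sheet missing columns: {missing}")
        _check_unique(self.data["sample_id"], "sample IDs")
        self.data = self.data.reset_index(drop=True)

    def require_samples(self, sample_ids: Iterable[str]) -> None:
        absent = set(sample_ids) - set(self.data["sample_id"])
        if absent:
            raise ValidationError(f"samples absent from sheet: {sorted(absent)[:5]}")

    def genotype_of(self, sample_ids: Sequence[str]) -> pd.Series:
        s = self.data.set_index("sample_id")["genotype"]
        return s.loc[list(sample_ids)]

    def column(self, name: str, sample_ids: Sequence[str]) -> pd.Series:
        s = self.data.set_index("sample_id")[name]
        return s.loc[list(sample_ids)]


@dataclass
class ProbeManifest:
    """Array manifest: probe coordinates, annotation, and blacklist flags.

    ``probes`` has one row per probe (index probe_id) with columns
    chromosome, position (1-based), cpg_relation, blacklist (bool).
    ``transcripts`` is long-format: probe_id, gene, transcript_id,
    transcript_length, genomic_context; intergenic probes have no rows there.
    """

    probes: pd.DataFrame
    transcripts: pd.DataFrame

    def __post_init__(self) -> None:
        need = {"chromosome", "position", "cpg_relation", "blacklist"}
        missing = need - set(self.probes.columns)
        if missing:
            raise FormatError(f"manifest missing columns: {sorted(missing)}")
        _check_unique(self.probes.index, "probe IDs")
        if (self.probes["position"] < 0).any():
            raise ValidationError("manifest positions must be non-negative")
        bad_rel = set(self.probes["cpg_relation"]) - set(CPG_RELATIONS)
        if bad_rel:
            raise ValidationError(f"unknown cpg_relation values: {sorted(bad_rel)}")
        if len(self.transcripts):
            bad_ctx = set(self.transcripts["genomic_context"]) - set(GENOMIC_CONTEXTS)
            if bad_ctx:
                raise ValidationError(f"unknown genomic_context values: {sorted(bad_ctx)}")

    def positions(self, probe_ids: Sequence[str]) -> pd.DataFrame:
        return self.probes.loc[list(probe_ids), ["chromosome", "position"]]


@dataclass
class QCMetrics:
    """Per-cell detection p-values and bead counts from array scanning."""

    detection_p: pd.DataFrame
    bead_count: pd.DataFrame

    def __post_init__(self) -> None:
        dp = self.detection_p.to_numpy(float)
        if np.nanmin(dp) < 0 or np.nanmax(dp) > 1:
            raise ValidationError("detection p-values must lie in [0, 1]")
        if (self.bead_count.to_numpy() < 0).any():
            raise ValidationError("bead counts must be non-negative")


@dataclass
class IntervalSet:
    """Genomic intervals, 0-based half-open (BED convention)."""

    data: pd.DataFrame  # columns: chromosome, start, end, name

    def __post_init__(self) -> None:
        need = {"chromosome", "start", "end", "name"}
        missing = need - set(self.data.columns)
        if missing:
            raise FormatError(f"interval set missing columns: {sorted(missing)}")
        if (self.data["start"] >= self.data["end"]).any():
            row = self.data[self.data["start"] >= self.data["end"]].iloc[0]
            raise FormatError(
                f"interval start >= end: {row['chromosome']}:{row['start']}-{row['end']}"
            )
        self.data = self.data.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.data)

    def padded(self, pad: int) -> "IntervalSet":
        d = self.data.copy()
        d["start"] = np.maximum(d["start"] - pad, 0)
        d["end"] = d["end"] + pad
        return IntervalSet(d)


@dataclass
class ExpressionTable:
    """Differential-expression results consumed as an upstream input."""

    data: pd.DataFrame  # columns: gene, log2FC, p, padj, mean_count

    def __post_init__(self) -> None:
        need = {"gene", "log2FC", "p", "padj"}
        missing = need - set(self.data.columns)
        if missing:
            raise FormatError(f"expression table missing columns: {sorted(missing)}")
        for col in ("p", "padj"):
            v = self.data[col].to_numpy(float)
            v = v[~np.isnan(v)]
            if len(v) and (v.min() < 0 or v.max() > 1):
                raise ValidationError(f"{col} outside [0, 1]")
        if "mean_count" not in self.data.columns:
            self.data = self.data.assign(mean_count=np.nan)

    def hits(self, lfc_min: float = 0.5, padj_max: float = 0.01) -> set[str]:
        d = self.data
        sel = (d["log2FC"].abs() > lfc_min) & (d["padj"] < padj_max)
        return set(d.loc[sel, "gene"])


DIFF_COLUMNS = ("probe_id", "effect", "t", "p", "padj", "hit")


@dataclass
class DiffTable:
    """Per-feature differential statistics from the moderated-t model."""

    data: pd.DataFrame  # columns per DIFF_COLUMNS

    def __post_init__(self) -> None:
        missing = [c for c in DIFF_COLUMNS if c not in self.data.columns]
        if missing:
            raise FormatError(f"diff table missing columns: {missing}")
        self.data = self.data.reset_index(drop=True)

    def hit_probes(self) -> set[str]:
        return set(self.data.loc[self.data["hit"].astype(bool), "probe_id"])


@dataclass
class RunConfig:
    """Thresholds, permutation counts, and region parameters for a run.

    Defaults mirror the analysis contract: site/CMR hits at BH padj <= 0.05
    and |delta beta| >= 0.05, RRBS hits at |delta beta| >= 0.1, hmC
    detectability from the 0.95 quantile of negative subtraction magnitudes,
    10000 permutation iterations, CMR chaining at max 1 kb gap, Pearson
    r >= 0.4, >= 2 probes.
    """

    delta_beta_min: float = 0.05
    padj_max: float = 0.05
    rrbs_delta_min: float = 0.1
    hmc_quantile: float = 0.95
    n_permutations: int = 10000
    cmr_max_gap: int = 1000
    cmr_min_r: float = 0.4
    cmr_min_probes: int = 2
    integration_weights: dict = field(
        default_factory=lambda: {
            "expression": 0.4,
            "enhancer_m": 0.125,
            "promoter_m": 0.125,
            "body_m": 0.1,
            "enhancer_hm": 0.125,
            "promoter_hm": 0.125,
            "body_hm": 0.1,
        }
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.hmc_quantile < 1:
            raise ValidationError("hmc_quantile must lie in (0, 1)")
        for name in ("delta_beta_min", "padj_max", "rrbs_delta_min"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValidationError(f"{name} must lie in [0, 1]")
        if self.n_permutations < 1 or self.cmr_min_probes < 2:
            raise ValidationError("n_permutations >= 1 and cmr_min_probes >= 2 required")
        if any(w < 0 for w in self.integration_weights.values()):
            raise ValidationError("integration weights must be non-negative")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise FormatError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# Readers / writers.  All delimited files are TSV; round trips are lossless
# for labels and preserve numerics to >= 12 significant digits.
# ---------------------------------------------------------------------------

_FLOAT_FMT = "%.15g"


def read_beta_matrix(path: str | Path, arm: str) -> BetaMatrix:
    """Read a TSV of probe rows x sample columns as a :class:`BetaMatrix`.

    The first column holds probe IDs; the header row holds sample IDs.
    Non-numeric cells become missing values.  Values outside the arm's legal
    range raise :class:`ValidationError` naming the offending cell.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    df = df.apply(pd.to_numeric, errors="coerce")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return BetaMatrix(df, arm)


def write_beta_matrix(matrix: BetaMatrix, path: str | Path) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="probe_id",
                         na_rep="NA", float_format=_FLOAT_FMT)


def read_intervals(path: str | Path) -> IntervalSet:
    """Read a BED file (>= 3 tab-separated columns) as 0-based half-open records.

    A missing name column defaults to ``chrom:start-end``.  Overlapping
    records are retained as-is; no merging is performed.
    """
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{ln}: expected >= 3 tab-separated columns")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            name = parts[3] if len(parts) > 3 else f"{chrom}:{start}-{end}"
            rows.append((chrom, start, end, name))
    df = pd.DataFrame(rows, columns=["chromosome", "start", "end", "name"])
    return IntervalSet(df)


def write_intervals(intervals: IntervalSet, path: str | Path) -> None:
    intervals.data[["chromosome", "start", "end", "name"]].to_csv(
        path, sep="\t", header=False, index=False
    )


def write_diff_table(table: DiffTable, path: str | Path) -> None:
    """Write a diff table as TSV; NaN serialized as ``NA``."""
    df = table.data[list(DIFF_COLUMNS)].copy()
    df["hit"] = df["hit"].astype(bool)
    df.to_csv(path, sep="\t", index=False, na_rep="NA", float_format=_FLOAT_FMT)


def read_diff_table(path: str | Path) -> DiffTable:
    df = pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=False)
    df["probe_id"] = df["probe_id"].astype(str)
    df["hit"] = df["hit"].astype(bool)
    for c in ("effect", "t", "p", "padj"):
        df[c] = pd.to_numeric(df[c], errors="coerce")
    return DiffTable(df)


def read_expression_table(path: str | Path) -> ExpressionTable:
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    return ExpressionTable(df)


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read gene sets in GMT format: name, description, then member genes."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{ln}: GMT rows need >= 3 columns")
            sets[parts[0]] = {g for g in parts[2:] if g}
    return sets


def read_edge_list(path: str | Path) -> list[tuple[str, str]]:
    """Read an interaction network as a two-column TSV of gene pairs."""
    edges = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise FormatError("edge list rows need two columns")
            edges.append((parts[0], parts[1]))
    return edges
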
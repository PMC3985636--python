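"""Readers, writers and validators for the pipeline's tabular artifacts.

Every artifact is a UTF-8, tab-separated table with a mandatory header row,
``.`` decimal separator and unquoted identifiers.  Readers reject malformed
input with located errors (row/column coordinates); writers emit numbers at
17 significant digits so that write∘read round-trips are lossless.

All-zero motif columns in the site-count matrix are *kept* at load time (a
warning is logged); dropping unidentifiable motifs is a modelling decision
that belongs to the fitting stage, not to I/O.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd

if TYPE_CHECKING:  # pragma: no cover - typing only
    from .mara_core import ActivityTable

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.17g"

__all__ = [
    "ExpressionMatrix",
    "SiteCountMatrix",
    "SampleDesign",
    "MotifTFMap",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_site_counts",
    "write_site_counts",
    "read_sample_design",
    "write_sample_design",
    "read_motif_tf_map",
    "write_motif_tf_map",
    "read_activity_table",
    "write_activity_table",
    "align",
]


class DataValidationError(ValueError):
    """Raised when an artifact violates its structural invariants."""


def _check_unique(ids, what: str) -> None:
    seen: dict[str, int] = {}
    dups = []
    for i in ids:
        seen[i] = seen.get(i, 0) + 1
    dups = sorted(k for k, n in seen.items() if n > 1)
    if dups:
        raise DataValidationError(f"duplicate {what}: {', '.join(map(str, dups))}")


@dataclass
class ExpressionMatrix:
    """Promoter x sample matrix of log2 expression values ``e_ps``."""

    promoter_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.promoter_ids = [str(p) for p in self.promoter_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        _check_unique(self.promoter_ids, "promoter ids")
        _check_unique(self.sample_ids, "sample ids")
        if self.values.shape != (len(self.promoter_ids), len(self.sample_ids)):
            raise DataValidationError(
                f"expression shape {self.values.shape} does not match "
                f"{len(self.promoter_ids)} promoters x {len(self.sample_ids)} samples"
            )
        if not np.all(np.isfinite(self.values)):
            r, c = np.argwhere(~np.isfinite(self.values))[0]
            raise DataValidationError(
                f"non-finite expression value at promoter {self.promoter_ids[r]!r}, "
                f"sample {self.sample_ids[c]!r}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.promoter_ids, columns=self.sample_ids)


@dataclass
class SiteCountMatrix:
    """Promoter x motif matrix of predicted binding-site counts ``N_pm``."""

    promoter_ids: list[str]
    motif_ids: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.promoter_ids = [str(p) for p in self.promoter_ids]
        self.motif_ids = [str(m) for m in self.motif_ids]
        self.counts = np.asarray(self.counts, dtype=float)
        _check_unique(self.promoter_ids, "promoter ids")
        _check_unique(self.motif_ids, "motif ids")
        if self.counts.shape != (len(self.promoter_ids), len(self.motif_ids)):
            raise DataValidationError(
                f"site-count shape {self.counts.shape} does not match "
                f"{len(self.promoter_ids)} promoters x {len(self.motif_ids)} motifs"
            )
        if not np.all(np.isfinite(self.counts)):
            raise DataValidationError("non-finite site count")
        if np.any(self.counts < 0):
            r, c = np.argwhere(self.counts < 0)[0]
            raise DataValidationError(
                f"negative site count at promoter {self.promoter_ids[r]!r}, "
                f"motif {self.motif_ids[c]!r}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def zero_motifs(self) -> list[str]:
        """Motif columns with no predicted site in any promoter."""
        mask = ~self.counts.any(axis=0)
        return [m for m, z in zip(self.motif_ids, mask) if z]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.promoter_ids, columns=self.motif_ids)


_REQUIRED_DESIGN_COLS = ("sample_id", "dataset", "condition")
_OPTIONAL_DESIGN_COLS = ("time", "replicate", "genotype")


@dataclass
class SampleDesign:
    """Per-sample study metadata: dataset (batch), condition, time, replicate.

    ``time`` is in days; it may be absent (NaN) for two-group designs.
    Missing replicate numbers default to a running index within each
    (dataset, condition, time) cell.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.table.copy()
        missing = [c for c in _REQUIRED_DESIGN_COLS if c not in df.columns]
        if missing:
            raise DataValidationError(f"design is missing required column(s): {missing}")
        unknown = [
            c for c in df.columns
            if c not in _REQUIRED_DESIGN_COLS + _OPTIONAL_DESIGN_COLS
        ]
        if unknown:
            raise DataValidationError(f"design has unknown column(s): {unknown}")
        df["sample_id"] = df["sample_id"].astype(str)
        _check_unique(df["sample_id"].tolist(), "sample ids")
        if "time" in df.columns:
            df["time"] = pd.to_numeric(df["time"], errors="raise")
            if (df["time"].dropna() < 0).any():
                raise DataValidationError("negative time in design")
        else:
            df["time"] = np.nan
        if "replicate" in df.columns:
            df["replicate"] = pd.to_numeric(df["replicate"], errors="raise")
        else:
            df["replicate"] = np.nan
        if df["replicate"].isna().any():
            key = [df["dataset"], df["condition"], df["time"].fillna(-1.0)]
            running = df.groupby(key, sort=False).cumcount() + 1
            df["replicate"] = df["replicate"].fillna(running).astype(int)
        else:
            df["replicate"] = df["replicate"].astype(int)
        if (df["replicate"] < 1).any():
            raise DataValidationError("replicate numbers must be >= 1")
        if "genotype" not in df.columns:
            df["genotype"] = ""
        self.table = df.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return self.table["sample_id"].tolist()

    def subset(self, sample_ids) -> "SampleDesign":
        keep = self.table[self.table["sample_id"].isin(set(sample_ids))]
        return SampleDesign(keep.reset_index(drop=True))

    def select(self, dataset=None, condition=None, time=None) -> list[str]:
        """Sample ids matching a (dataset, condition, time) key; None = any."""
        df = self.table
        mask = np.ones(len(df), dtype=bool)
        if dataset is not None:
            mask &= (df["dataset"] == dataset).to_numpy()
        if condition is not None:
            mask &= (df["condition"] == condition).to_numpy()
        if time is not None:
            mask &= np.isclose(df["time"].to_numpy(dtype=float), float(time))
        return df.loc[mask, "sample_id"].tolist()

    def timepoints(self, dataset=None) -> list[float]:
        df = self.table
        if dataset is not None:
            df = df[df["dataset"] == dataset]
        ts = sorted(set(df["time"].dropna().tolist()))
        return ts

    def datasets(self) -> list[str]:
        seen: list[str] = []
        for d in self.table["dataset"]:
            if d not in seen:
                seen.append(d)
        return seen


@dataclass
class MotifTFMap:
    """Motif -> cognate TF gene map with per-TF log2 expression profiles.

    ``tf_expression`` is a TF-gene x sample frame used by the downstream
    expression filter (a motif is considered expressed when at least one of
    its cognate TFs is).
    """

    motif_to_tfs: dict[str, list[str]]
    tf_expression: pd.DataFrame  # tf gene x sample, log2 units

    def __post_init__(self) -> None:
        self.motif_to_tfs = {
            str(m): [str(t) for t in tfs] for m, tfs in self.motif_to_tfs.items()
        }
        expr = self.tf_expression
        if not expr.empty and not np.all(np.isfinite(expr.to_numpy(dtype=float))):
            raise DataValidationError("non-finite TF expression value")
        _check_unique(list(expr.index), "TF gene ids")

    def tfs_for(self, motif: str) -> list[str]:
        return self.motif_to_tfs.get(motif, [])

    def mean_tf_expression(self, motif: str) -> dict[str, float]:
        """Mean log2 expression across samples for each cognate TF with data."""
        out: dict[str, float] = {}
        for tf in self.tfs_for(motif):
            if tf in self.tf_expression.index:
                out[tf] = float(self.tf_expression.loc[tf].mean())
        return out


# ---------------------------------------------------------------------------
# matrix readers / writers


def _read_matrix(path, what: str) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    if df.index.name is None and df.columns.size == 0:
        raise DataValidationError(f"{what} file {path} is empty")
    _check_unique(list(df.index.astype(str)), f"{what} row ids in {path.name}")
    _check_unique(list(df.columns.astype(str)), f"{what} column ids in {path.name}")
    num = df.apply(pd.to_numeric, errors="coerce")
    bad = num.isna() | (df == "")
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise DataValidationError(
            f"non-numeric or missing {what} value at row {df.index[r]!r}, "
            f"column {df.columns[c]!r} in {path.name}"
        )
    num.index = df.index.astype(str)
    num.columns = df.columns.astype(str)
    return num


def read_expression_matrix(path) -> ExpressionMatrix:
    """Read a promoter x sample log2 expression TSV (row/column order kept)."""
    df = _read_matrix(path, "expression")
    return ExpressionMatrix(list(df.index), list(df.columns), df.to_numpy(dtype=float))


def write_expression_matrix(expr: ExpressionMatrix, path) -> None:
    expr.to_frame().to_csv(path, sep="\t", index_label="promoter_id",
                           float_format=_FLOAT_FMT)


def read_site_counts(path) -> SiteCountMatrix:
    """Read a promoter x motif site-count TSV; all-zero columns are kept."""
    df = _read_matrix(path, "site count")
    counts = SiteCountMatrix(list(df.index), list(df.columns), df.to_numpy(dtype=float))
    zeros = counts.zero_motifs()
    if zeros:
        logger.warning("site-count matrix has all-zero motif column(s): %s", zeros)
    return counts


def write_site_counts(counts: SiteCountMatrix, path) -> None:
    counts.to_frame().to_csv(path, sep="\t", index_label="promoter_id",
                             float_format=_FLOAT_FMT)


def read_sample_design(path) -> SampleDesign:
    df = pd.read_csv(Path(path), sep="\t", dtype=str, keep_default_na=False)
    df = df.mask(df == "")
    if "sample_id" in df.columns:
        df["sample_id"] = df["sample_id"].astype(str)
    if "genotype" in df.columns:
        df["genotype"] = df["genotype"].fillna("")
    return SampleDesign(df)


def write_sample_design(design: SampleDesign, path) -> None:
    design.table.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_motif_tf_map(map_path, tf_expression_path=None) -> MotifTFMap:
    """Read a (motif_id, tf_gene_id) pair table plus an optional TF x sample
    log2-expression matrix."""
    pairs = pd.read_csv(Path(map_path), sep="\t", dtype=str)
    for col in ("motif_id", "tf_gene_id"):
        if col not in pairs.columns:
            raise DataValidationError(f"motif-TF map is missing column {col!r}")
    mapping: dict[str, list[str]] = {}
    for m, t in zip(pairs["motif_id"], pairs["tf_gene_id"]):
        mapping.setdefault(str(m), [])
        if str(t) not in mapping[str(m)]:
            mapping[str(m)].append(str(t))
    if tf_expression_path is not None:
        expr = _read_matrix(tf_expression_path, "TF expression")
    else:
        expr = pd.DataFrame()
    return MotifTFMap(mapping, expr)


def write_motif_tf_map(tf_map: MotifTFMap, map_path, tf_expression_path=None) -> None:
    rows = [(m, t) for m, tfs in tf_map.motif_to_tfs.items() for t in tfs]
    pd.DataFrame(rows, columns=["motif_id", "tf_gene_id"]).to_csv(
        map_path, sep="\t", index=False
    )
    if tf_expression_path is not None:
        tf_map.tf_expression.to_csv(tf_expression_path, sep="\t",
                                    index_label="tf_gene_id",
                                    float_format=_FLOAT_FMT)


# ---------------------------------------------------------------------------
# activity table I/O (three files sharing a prefix)


def write_activity_table(table: "ActivityTable", prefix) -> dict[str, Path]:
    """Write activities, standard errors and per-motif z under ``prefix``.

    Emits ``<prefix>.activities.tsv``, ``<prefix>.std_errors.tsv`` and
    ``<prefix>.motif_z.tsv``; numbers survive a read/write cycle losslessly.
    """
    if len(table.motif_ids) == 0:
        raise DataValidationError("activity table has no motifs; nothing to write")
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = {
        "activities": prefix.with_suffix(prefix.suffix + ".activities.tsv"),
        "std_errors": prefix.with_suffix(prefix.suffix + ".std_errors.tsv"),
        "motif_z": prefix.with_suffix(prefix.suffix + ".motif_z.tsv"),
    }
    pd.DataFrame(table.activities, index=table.motif_ids,
                 columns=table.sample_ids).to_csv(
        paths["activities"], sep="\t", index_label="motif_id", float_format=_FLOAT_FMT)
    pd.DataFrame(table.std_errors, index=table.motif_ids,
                 columns=table.sample_ids).to_csv(
        paths["std_errors"], sep="\t", index_label="motif_id", float_format=_FLOAT_FMT)
    pd.DataFrame({"motif_id": table.motif_ids, "z": table.motif_z}).to_csv(
        paths["motif_z"], sep="\t", index=False, float_format=_FLOAT_FMT)
    return paths


def read_activity_table(prefix) -> "ActivityTable":
    from .mara_core import ActivityTable

    prefix = Path(prefix)
    act = _read_matrix(prefix.with_suffix(prefix.suffix + ".activities.tsv"),
                       "activity")
    err = _read_matrix(prefix.with_suffix(prefix.suffix + ".std_errors.tsv"),
                       "standard error")
    zdf = pd.read_csv(prefix.with_suffix(prefix.suffix + ".motif_z.tsv"), sep="\t")
    z = zdf.set_index(zdf["motif_id"].astype(str))["z"].reindex(act.index)
    if not (list(act.index) == list(err.index)
            and list(act.columns) == list(err.columns)):
        raise DataValidationError("activity and standard-error tables disagree")
    return ActivityTable(
        motif_ids=list(act.index),
        sample_ids=list(act.columns),
        activities=act.to_numpy(dtype=float),
        std_errors=err.to_numpy(dtype=float),
        motif_z=z.to_numpy(dtype=float),
    )


# ---------------------------------------------------------------------------
# alignment


def align(expr: ExpressionMatrix, counts: SiteCountMatrix, design: SampleDesign):
    """Restrict the three artifacts to their common promoters and samples.

    Promoters are taken in the expression matrix's order; samples follow the
    design table's order.  Dropped identifiers are logged.  Idempotent.
    """
    promoters = [p for p in expr.promoter_ids if p in set(counts.promoter_ids)]
    if not promoters:
        raise DataValidationError("no promoter shared between expression and site counts")
    expr_samples = set(expr.sample_ids)
    samples = [s for s in design.sample_ids if s in expr_samples]
    if not samples:
        raise DataValidationError("no sample shared between expression and design")

    dropped_prom = sorted((set(expr.promoter_ids) | set(counts.promoter_ids))
                          - set(promoters))
    dropped_samp = sorted((expr_samples | set(design.sample_ids)) - set(samples))
    if dropped_prom:
        logger.info("align: dropped %d promoter(s): %s", len(dropped_prom),
                    dropped_prom[:20])
    if dropped_samp:
        logger.info("align: dropped %d sample(s): %s", len(dropped_samp),
                    dropped_samp[:20])

    e = expr.to_frame().loc[promoters, samples]
    n = counts.to_frame().loc[promoters]
    return (
        ExpressionMatrix(promoters, samples, e.to_numpy(dtype=float)),
        SiteCountMatrix(promoters, list(n.columns), n.to_numpy(dtype=float)),
        design.subset(samples),
    )
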
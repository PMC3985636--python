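"""Differential motif activity between pairs of experimental conditions.

Activities are first averaged over replicates within a condition; the
difference between two condition means, scaled by the combined standard
error, gives a z-statistic per motif.  A highly positive z means the motif's
predicted targets are coherently upregulated in the first condition relative
to the second.  Contrasts are only ever computed within a single dataset
(batch): crossing batches would confound treatment with array batch.

Two small categorical rules build on the z-calls: pathway dependence
(does a treatment response vanish in a pathway knockout?) and tumor
specificity (is a motif dysregulated only in promoted tumors?).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .data_io import SampleDesign
from .mara_core import ActivityTable

__all__ = [
    "ConditionSummary",
    "ContrastResult",
    "summarize_condition",
    "differential_z",
    "classify_motifs",
    "dependency_call",
    "tumor_specificity_call",
    "contrast",
    "timepoint_contrast_table",
]

UP, DOWN, NS = "up", "down", "ns"


@dataclass
class ConditionSummary:
    """Replicate-averaged activities for one (dataset, condition[, time]) cell."""

    dataset: str
    condition: str
    time: Optional[float]
    motif_ids: list[str]
    mean_activity: np.ndarray   # per motif
    std_error: np.ndarray       # per motif, > 0
    n_replicates: int

    def __post_init__(self) -> None:
        self.mean_activity = np.asarray(self.mean_activity, dtype=float)
        self.std_error = np.asarray(self.std_error, dtype=float)
        if np.any(self.std_error <= 0):
            raise ValueError("condition standard errors must be > 0")


@dataclass
class ContrastResult:
    """z and categorical calls for one condition pair within a dataset."""

    contrast_id: str
    motif_ids: list[str]
    z: np.ndarray
    calls: np.ndarray           # 'up' / 'down' / 'ns'
    threshold: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"motif_id": self.motif_ids, "z": self.z,
                             "call": self.calls,
                             "contrast": self.contrast_id,
                             "threshold": self.threshold})


def summarize_condition(table: ActivityTable, design: SampleDesign,
                        dataset: str, condition: str,
                        time: Optional[float] = None) -> ConditionSummary:
    """Average activities over the replicates of one condition cell.

    The mean's standard error combines the per-sample posterior errors as
    independent: sigma_bar = sqrt(sum_r sigma_r^2) / R.
    """
    sample_ids = [s for s in design.select(dataset=dataset, condition=condition,
                                           time=time)
                  if s in set(table.sample_ids)]
    if not sample_ids:
        key = (dataset, condition) if time is None else (dataset, condition, time)
        raise ValueError(f"no samples match condition key {key}")
    idx = table.sample_index(sample_ids)
    R = len(idx)
    mean = table.activities[:, idx].mean(axis=1)
    sem = np.sqrt(np.sum(table.std_errors[:, idx] ** 2, axis=1)) / R
    return ConditionSummary(dataset=dataset, condition=condition, time=time,
                            motif_ids=list(table.motif_ids),
                            mean_activity=mean, std_error=sem, n_replicates=R)


def differential_z(s1: ConditionSummary, s2: ConditionSummary) -> np.ndarray:
    """Per-motif z = (mean1 - mean2) / sqrt(se1^2 + se2^2).

    Refuses cross-dataset pairs: batch and biology would be confounded.
    Exactly antisymmetric under swapping the two summaries.
    """
    if s1.dataset != s2.dataset:
        raise ValueError(
            f"batch-confounded contrast: {s1.dataset!r} vs {s2.dataset!r}; "
            "differential activities are only comparable within one dataset"
        )
    if s1.motif_ids != s2.motif_ids:
        raise ValueError("condition summaries cover different motifs")
    return ((s1.mean_activity - s2.mean_activity)
            / np.sqrt(s1.std_error ** 2 + s2.std_error ** 2))


def classify_motifs(z: np.ndarray, threshold: float) -> np.ndarray:
    """'up' if z >= threshold, 'down' if z <= -threshold, else 'ns'."""
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    z = np.asarray(z, dtype=float)
    calls = np.full(z.shape, NS, dtype=object)
    calls[z >= threshold] = UP
    calls[z <= -threshold] = DOWN
    return calls


def dependency_call(wt_call: str, ko_call: str) -> str:
    """Is a treatment response downstream of a knocked-out pathway?

    'downstream' when the wild-type response disappears in the knockout,
    'independent' when both genotypes respond in the same direction,
    'none' otherwise (no wild-type response, or discordant responses).
    """
    if wt_call == NS:
        return "none"
    if ko_call == NS:
        return "downstream"
    return "independent" if wt_call == ko_call else "none"


def tumor_specificity_call(promoted_call: str, nonpromoted_call: str) -> str:
    """'promoted_specific' when dysregulated only in promoted tumors,
    'shared' when dysregulated in both tumor types, 'none' otherwise."""
    if promoted_call != NS and nonpromoted_call == NS:
        return "promoted_specific"
    if promoted_call != NS and nonpromoted_call != NS:
        return "shared"
    return "none"


def contrast(table: ActivityTable, design: SampleDesign, dataset: str,
             condition1: str, condition2: str, threshold: float = 2.0,
             time: Optional[float] = None) -> ContrastResult:
    """Convenience wrapper: summarize both conditions, compute z and calls."""
    s1 = summarize_condition(table, design, dataset, condition1, time=time)
    s2 = summarize_condition(table, design, dataset, condition2, time=time)
    z = differential_z(s1, s2)
    cid = f"{dataset}:{condition1}-vs-{condition2}"
    if time is not None:
        cid += f"@t{time:g}"
    return ContrastResult(contrast_id=cid, motif_ids=list(table.motif_ids),
                          z=z, calls=classify_motifs(z, threshold),
                          threshold=threshold)


def timepoint_contrast_table(table: ActivityTable, design: SampleDesign,
                             dataset: str, condition1: str,
                             condition2: str) -> pd.DataFrame:
    """Motif x timepoint frame of z for condition1-vs-condition2 at each time.

    Used by the per-timepoint refinement filter on kinetic studies.
    """
    times = design.timepoints(dataset=dataset)
    if not times:
        raise ValueError(f"dataset {dataset!r} has no timepoints in the design")
    cols = {}
    for t in times:
        s1 = summarize_condition(table, design, dataset, condition1, time=t)
        s2 = summarize_condition(table, design, dataset, condition2, time=t)
        cols[t] = differential_z(s1, s2)
    return pd.DataFrame(cols, index=list(table.motif_ids))
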
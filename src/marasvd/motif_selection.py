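"""Representative-motif selection for each regulatory program.

A motif represents a program when it ranks highly by *both* projection and
correlation with the program's singular vector (large-activity motifs can
project strongly onto profiles they do not resemble; quiet motifs can
correlate perfectly while projecting weakly).  Candidates per direction are
the intersection of the two top-n lists, then refined by three filters:

1. overall-significance filter — drop motifs whose per-motif z is too low;
2. expression filter — drop motifs none of whose cognate TFs reaches a
   log2-expression threshold (default 6.0) in the tissue;
3. per-timepoint pattern filter — require the treated-vs-control z at
   individual timepoints to match the program's temporal character
   (sustained: significant at a minimum number of timepoints; transient:
   significant at the first timepoint; late: significant at the last).

Every removal is recorded in an audit trail naming the filter responsible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .data_io import MotifTFMap
from .mara_core import ActivityTable
from .svd_programs import ComponentScores

__all__ = [
    "SelectionConfig",
    "MotifSelection",
    "rank_by_component",
    "apply_significance_filter",
    "apply_expression_filter",
    "apply_timepoint_pattern_filter",
    "select_representatives",
    "tf_expression_activity_correlation",
]

TIMEPOINT_RULES = ("sustained", "day_first", "day_last", "none")


@dataclass
class SelectionConfig:
    """Tunable thresholds for one program's representative-motif selection.

    component is 1-based (component 1 = largest singular value).
    """

    component: int = 1
    top_n: int = 10
    min_motif_z: float = 0.0
    min_tf_log_expression: float = 6.0
    timepoint_rule: str = "none"
    timepoint_z_threshold: float = 2.0
    min_timepoints_hit: int = 4
    direction_sign: bool = False

    def __post_init__(self) -> None:
        if self.component < 1:
            raise ValueError("component index is 1-based and must be >= 1")
        if self.top_n < 1:
            raise ValueError("top_n must be >= 1")
        if self.min_motif_z < 0 or self.timepoint_z_threshold < 0:
            raise ValueError("thresholds must be >= 0")
        if self.timepoint_rule not in TIMEPOINT_RULES:
            raise ValueError(f"timepoint_rule must be one of {TIMEPOINT_RULES}")


@dataclass
class MotifSelection:
    """Signed motif clusters for one program plus a removal audit trail."""

    component: int
    positive_cluster: list[str]
    negative_cluster: list[str]
    audit: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        if set(self.positive_cluster) & set(self.negative_cluster):
            raise ValueError("positive and negative clusters overlap")

    def removals(self) -> pd.DataFrame:
        return pd.DataFrame(self.audit,
                            columns=["motif_id", "direction", "stage", "detail"])

    def removal_stage(self, motif_id: str) -> Optional[str]:
        for rec in self.audit:
            if rec["motif_id"] == motif_id:
                return rec["stage"]
        return None


def _ordered_top(ids: list[str], score: np.ndarray, n: int,
                 descending: bool) -> list[str]:
    sign = -1.0 if descending else 1.0
    order = sorted(range(len(ids)), key=lambda i: (sign * score[i], ids[i]))
    return [ids[i] for i in order[:n]]


def rank_by_component(scores: ComponentScores, component: int,
                      top_n: int = 10) -> tuple[list[str], list[str]]:
    """Candidates per direction: intersection of top-n by P and top-n by rho.

    Positive candidates must be top-n by *descending* projection and
    correlation; negative candidates by ascending.  Candidate lists are
    ordered by |P| descending, ties broken by |rho| then motif id.
    """
    k = component - 1
    if not (0 <= k < scores.projections.shape[1]):
        raise ValueError(f"component {component} out of range")
    ids = scores.motif_ids
    P = scores.projections[:, k]
    rho = scores.correlations[:, k]
    pos = set(_ordered_top(ids, P, top_n, True)) & set(_ordered_top(ids, rho, top_n, True))
    neg = set(_ordered_top(ids, P, top_n, False)) & set(_ordered_top(ids, rho, top_n, False))
    # with top_n >= half the motifs a middling motif can qualify both ways;
    # resolve by the sign of its scores (zero-score motifs are dropped)
    score = {m: P[i] if P[i] != 0 else rho[i] for i, m in enumerate(ids)}
    for m in pos & neg:
        (neg if score[m] > 0 else pos).discard(m)
        if score[m] == 0:
            pos.discard(m)
    absP = {m: abs(P[i]) for i, m in enumerate(ids)}
    absR = {m: abs(rho[i]) for i, m in enumerate(ids)}
    key = lambda m: (-absP[m], -absR[m], m)
    return sorted(pos, key=key), sorted(neg, key=key)


def apply_significance_filter(candidates: list[str], motif_z: dict,
                              min_z: float, audit: Optional[list] = None,
                              direction: str = "") -> list[str]:
    """Keep motifs whose overall z reaches min_z; log removals."""
    if min_z < 0:
        raise ValueError("min_z must be >= 0")
    kept = []
    for m in candidates:
        z = float(motif_z[m])
        if z >= min_z:
            kept.append(m)
        elif audit is not None:
            audit.append({"motif_id": m, "direction": direction,
                          "stage": "significance",
                          "detail": f"z={z:.3g} < {min_z:g}"})
    return kept


def apply_expression_filter(candidates: list[str], tf_map: MotifTFMap,
                            min_expr: float, audit: Optional[list] = None,
                            direction: str = "") -> list[str]:
    """Keep motifs with at least one cognate TF at mean log2 expression
    >= min_expr.  Motifs absent from the map are kept (with an audit note):
    no expression evidence is not evidence of absence."""
    kept = []
    for m in candidates:
        tfs = tf_map.tfs_for(m)
        if not tfs:
            kept.append(m)
            if audit is not None:
                audit.append({"motif_id": m, "direction": direction,
                              "stage": "expression_unmapped",
                              "detail": "kept: motif not in TF map"})
            continue
        means = tf_map.mean_tf_expression(m)
        if means and max(means.values()) >= min_expr:
            kept.append(m)
        elif audit is not None:
            best = max(means.values()) if means else float("nan")
            audit.append({"motif_id": m, "direction": direction,
                          "stage": "expression",
                          "detail": f"max TF mean log2 expr {best:.3g} < {min_expr:g}"})
    return kept


def apply_timepoint_pattern_filter(candidates: list[str],
                                   contrast_z: pd.DataFrame,
                                   config: SelectionConfig,
                                   audit: Optional[list] = None,
                                   direction: str = "") -> list[str]:
    """Require per-timepoint treated-vs-control z to match the program shape.

    contrast_z is a motif x timepoint frame (columns sorted by time).  With
    ``direction_sign`` on, only z of the candidate's cluster sign counts as
    a hit ('+' direction needs z >= thr, '-' needs z <= -thr); otherwise |z|
    is compared to the threshold.
    """
    if config.timepoint_rule == "none":
        return list(candidates)
    cols = sorted(contrast_z.columns)
    thr = config.timepoint_z_threshold
    kept = []
    for m in candidates:
        if m not in contrast_z.index:
            raise ValueError(f"no per-timepoint contrast for motif {m!r}")
        z = contrast_z.loc[m, cols].to_numpy(dtype=float)
        if config.direction_sign and direction in ("+", "-"):
            hits = z >= thr if direction == "+" else z <= -thr
        else:
            hits = np.abs(z) >= thr
        if config.timepoint_rule == "sustained":
            if config.min_timepoints_hit > len(cols):
                raise ValueError("min_timepoints_hit exceeds number of timepoints")
            ok = int(hits.sum()) >= config.min_timepoints_hit
            detail = f"{int(hits.sum())}/{len(cols)} timepoints at |z|>={thr:g}"
        elif config.timepoint_rule == "day_first":
            ok = bool(hits[0])
            detail = f"first-timepoint z={z[0]:.3g}"
        elif config.timepoint_rule == "day_last":
            ok = bool(hits[-1])
            detail = f"last-timepoint z={z[-1]:.3g}"
        else:  # pragma: no cover - guarded in config
            raise ValueError(config.timepoint_rule)
        if ok:
            kept.append(m)
        elif audit is not None:
            audit.append({"motif_id": m, "direction": direction,
                          "stage": "timepoint_pattern", "detail": detail})
    return kept


def select_representatives(scores: ComponentScores, motif_z,
                           tf_map: MotifTFMap,
                           contrast_z: Optional[pd.DataFrame],
                           config: SelectionConfig) -> MotifSelection:
    """Full pipeline: rank -> significance -> expression -> timepoint filters.

    motif_z may be a dict, a pandas Series or an array aligned with the
    score table's motif order.
    """
    if isinstance(motif_z, pd.Series):
        zmap = motif_z.to_dict()
    elif isinstance(motif_z, dict):
        zmap = motif_z
    else:
        zmap = dict(zip(scores.motif_ids, np.asarray(motif_z, dtype=float)))

    pos, neg = rank_by_component(scores, config.component, config.top_n)
    audit: list[dict] = []
    clusters = {}
    for direction, cands in (("+", pos), ("-", neg)):
        kept = apply_significance_filter(cands, zmap, config.min_motif_z,
                                         audit, direction)
        kept = apply_expression_filter(kept, tf_map,
                                       config.min_tf_log_expression,
                                       audit, direction)
        if config.timepoint_rule != "none":
            if contrast_z is None:
                raise ValueError("timepoint rule requires per-timepoint contrasts")
            kept = apply_timepoint_pattern_filter(kept, contrast_z, config,
                                                  audit, direction)
        clusters[direction] = kept
    return MotifSelection(component=config.component,
                          positive_cluster=clusters["+"],
                          negative_cluster=clusters["-"],
                          audit=audit)


def tf_expression_activity_correlation(table: ActivityTable,
                                       tf_map: MotifTFMap,
                                       motif: str) -> dict[str, Optional[float]]:
    """Pearson r between a motif's activity profile and each cognate TF's
    log2-expression profile across the shared samples.

    A positive r suggests the TF's own transcription drives the motif's
    activity; None is reported when either profile has zero variance.
    """
    if motif not in table.motif_ids:
        raise ValueError(f"motif {motif!r} not in activity table")
    expr = tf_map.tf_expression
    missing = [s for s in table.sample_ids if s not in expr.columns]
    if missing:
        raise ValueError(f"TF expression lacks sample(s) {missing}")
    a = table.activities[table.motif_ids.index(motif)]
    out: dict[str, Optional[float]] = {}
    for tf in tf_map.tfs_for(motif):
        if tf not in expr.index:
            continue
        x = expr.loc[tf, table.sample_ids].to_numpy(dtype=float)
        if np.std(x) == 0 or np.std(a) == 0:
            out[tf] = None
        else:
            out[tf] = float(stats.pearsonr(a, x).statistic)
    return out
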
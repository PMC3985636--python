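"""SVD decomposition of the motif-activity matrix into regulatory programs.

The motif x sample activity matrix A (rows mean-centered by the fit) is
factored as A = U diag(lambda) V', where the columns of V — the right
singular vectors over samples — are orthonormal "characteristic activity
profiles": mutually independent temporal/condition patterns shared by many
motifs.  Because A's rows are mean-centered, each profile is mean-centered
too, which makes two derived quantities exact:

* projections  P = U diag(lambda): how much of a motif's activity lies along
  each profile, in raw activity units (scale-sensitive);
* correlations rho_ik = P_ik / ||A_i||: the Pearson correlation between the
  motif's profile and the k-th singular vector (scale-free).

A motif with large activities can have a big projection on a profile it
barely resembles, and a quiet motif can correlate perfectly while projecting
weakly — representative-motif selection therefore ranks on both.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
import pandas as pd

from .data_io import SampleDesign
from .mara_core import ActivityTable

__all__ = [
    "ProgramDecomposition",
    "ComponentScores",
    "decompose_activities",
    "variance_explained",
    "component_scores",
    "orient_components",
    "component_profile_table",
]

_RANK_TOL = 1e-12


@dataclass
class ProgramDecomposition:
    """Thin SVD of the activity matrix with variance bookkeeping."""

    motif_ids: list[str]
    sample_ids: list[str]
    U: np.ndarray                 # motif x component
    singular_values: np.ndarray   # non-increasing, >= 0
    V: np.ndarray                 # sample x component, columns orthonormal
    variance_fraction: np.ndarray
    sign_convention: str = "raw"

    @property
    def n_components(self) -> int:
        return len(self.singular_values)

    def reconstruct(self) -> np.ndarray:
        return self.U @ np.diag(self.singular_values) @ self.V.T


@dataclass
class ComponentScores:
    """Projections (raw units) and correlations (scale-free) per motif."""

    motif_ids: list[str]
    projections: np.ndarray    # motif x component, P = U diag(lambda)
    correlations: np.ndarray   # motif x component, in [-1, 1]


def decompose_activities(table: ActivityTable) -> ProgramDecomposition:
    """Thin SVD of A (motif x sample), components ordered by singular value.

    Components with singular value below 1e-12 x the largest are reported as
    exactly zero (numerical rank control).
    """
    A = table.activities
    if not np.all(np.isfinite(A)):
        raise ValueError("non-finite activities")
    if A.shape[1] < 2:
        raise ValueError("SVD of activities needs at least 2 samples")
    U, s, Vt = np.linalg.svd(A, full_matrices=False)
    total = float(np.sum(s ** 2))
    if total == 0.0:
        raise ValueError("activity matrix is zero; no programs to extract")
    # components below the numerical-rank tolerance carry arbitrary basis
    # vectors from the null space (row-centered A always has one); drop them
    keep = s >= _RANK_TOL * s[0]
    U, s, Vt = U[:, keep], s[keep], Vt[keep]
    return ProgramDecomposition(
        motif_ids=list(table.motif_ids),
        sample_ids=list(table.sample_ids),
        U=U, singular_values=s, V=Vt.T,
        variance_fraction=s ** 2 / total,
    )


def variance_explained(decomp: ProgramDecomposition, k: int) -> float:
    """Fraction of activity variance captured by the first k components."""
    if not (1 <= k <= decomp.n_components):
        raise ValueError(f"k={k} outside 1..{decomp.n_components}")
    return float(np.sum(decomp.variance_fraction[:k]))


def component_scores(decomp: ProgramDecomposition) -> ComponentScores:
    """P = U diag(lambda); rho_ik = P_ik / ||A_i|| (0 for zero-profile motifs)."""
    P = decomp.U * decomp.singular_values[None, :]
    norms = np.sqrt(np.sum(P ** 2, axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.where(norms[:, None] > 0, P / norms[:, None], 0.0)
    return ComponentScores(motif_ids=list(decomp.motif_ids),
                           projections=P, correlations=rho)


def orient_components(decomp: ProgramDecomposition,
                      design: Optional[SampleDesign] = None,
                      mode: str = "max_abs_positive",
                      treated_label: str = "treated",
                      control_label: str = "control") -> ProgramDecomposition:
    """Fix the arbitrary SVD sign of each (u_k, v_k) pair.

    ``max_abs_positive`` flips so the largest-magnitude entry of each v_k is
    positive; ``treatment_positive`` flips so the treated-sample mean of v_k
    is at least the control mean.  Either way U diag(lambda) V' is unchanged.
    Idempotent.
    """
    V = decomp.V.copy()
    U = decomp.U.copy()
    if mode == "max_abs_positive":
        for k in range(V.shape[1]):
            j = int(np.argmax(np.abs(V[:, k])))
            if V[j, k] < 0:
                V[:, k] *= -1
                U[:, k] *= -1
    elif mode == "treatment_positive":
        if design is None:
            raise ValueError("treatment_positive orientation needs a design")
        conditions = dict(zip(design.table["sample_id"], design.table["condition"]))
        treated = [i for i, s in enumerate(decomp.sample_ids)
                   if conditions.get(s) == treated_label]
        controls = [i for i, s in enumerate(decomp.sample_ids)
                    if conditions.get(s) == control_label]
        if not treated or not controls:
            raise ValueError(
                f"treatment_positive needs both {treated_label!r} and "
                f"{control_label!r} samples in the design"
            )
        for k in range(V.shape[1]):
            if V[treated, k].mean() < V[controls, k].mean():
                V[:, k] *= -1
                U[:, k] *= -1
    else:
        raise ValueError(f"unknown orientation mode {mode!r}")
    return replace(decomp, U=U, V=V, sign_convention=mode)


def component_profile_table(decomp: ProgramDecomposition,
                            design: SampleDesign) -> pd.DataFrame:
    """Long (component, sample, time, condition, v) table for plotting."""
    meta = design.table.set_index("sample_id")
    missing = [s for s in decomp.sample_ids if s not in meta.index]
    if missing:
        raise ValueError(f"design lacks sample(s) {missing}")
    times = meta.loc[decomp.sample_ids, "time"]
    if times.isna().any():
        bad = [s for s, t in zip(decomp.sample_ids, times) if pd.isna(t)]
        raise ValueError(f"kinetic profile table needs a time for sample(s) {bad}")
    rows = []
    for k in range(decomp.n_components):
        for i, s in enumerate(decomp.sample_ids):
            rows.append({
                "component": k + 1,
                "sample_id": s,
                "time": float(meta.loc[s, "time"]),
                "condition": meta.loc[s, "condition"],
                "v": decomp.V[i, k],
            })
    return pd.DataFrame(rows)
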
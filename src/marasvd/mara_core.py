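"""Motif activity inference by ridge-regularized linear modelling.

The model treats the log2 expression of promoter ``p`` in sample ``s`` as

    e_ps = c_p + n_s + sum_m N_pm * A_ms + noise,

where ``N_pm`` is the predicted binding-site count of motif ``m`` in the
promoter, ``A_ms`` the latent activity of the motif in the sample, ``c_p``
the basal activity of the promoter and ``n_s`` a per-sample normalization
offset.  The two nuisance blocks are eliminated exactly by double-centering
the expression matrix and column-centering the site-count matrix: the
resulting ridge problem per sample

    min_A || E~_s - N~ A_s ||^2 + lambda ||A_s||^2

has the same least-squares optimum as fitting ``c_p`` and ``n_s``
explicitly, and guarantees mean-centered activity profiles.

Standard errors come from the Gaussian ridge posterior covariance
``sigma^2 (N~' N~ + lambda I)^{-1}`` with the residual variance pooled over
samples using the trace of the hat matrix as the effective number of fitted
parameters per sample.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import scipy.linalg

from .data_io import ExpressionMatrix, SiteCountMatrix

logger = logging.getLogger(__name__)

DEFAULT_CV_GRID = tuple(float(x) for x in np.logspace(-4, 2, 7))

__all__ = [
    "FitConfig",
    "CenteringOffsets",
    "ActivityTable",
    "double_center",
    "fit_activities",
    "motif_significance",
    "choose_ridge_penalty",
]


@dataclass
class FitConfig:
    """Settings for the activity fit.

    ridge_penalty
        Positive ridge strength lambda, or the string ``"cv"`` to pick it by
        promoter-fold cross-validation over ``cv_grid``.
    known_noise_sd
        If given, used instead of the pooled residual SD when computing
        standard errors.
    """

    ridge_penalty: float | str = "cv"
    cv_folds: int = 5
    cv_grid: Sequence[float] = DEFAULT_CV_GRID
    known_noise_sd: Optional[float] = None
    drop_zero_motifs: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ridge_penalty == "cv":
            if not len(self.cv_grid):
                raise ValueError("cv_grid must be non-empty when ridge_penalty='cv'")
            if any(l <= 0 for l in self.cv_grid):
                raise ValueError("cv_grid values must be > 0")
            if self.cv_folds < 2:
                raise ValueError("cv_folds must be >= 2")
        else:
            if float(self.ridge_penalty) <= 0:
                raise ValueError("ridge_penalty must be > 0")


@dataclass
class CenteringOffsets:
    """Stored offsets that reconstruct the raw matrices from centered ones."""

    promoter_means: np.ndarray  # per promoter (includes the grand mean)
    sample_means: np.ndarray    # per sample, grand mean removed
    site_count_column_means: Optional[np.ndarray] = None

    def reconstruct_expression(self, centered: np.ndarray) -> np.ndarray:
        return (centered + self.promoter_means[:, None]
                + self.sample_means[None, :])


@dataclass
class ActivityTable:
    """Fitted motif activities with error bars and per-motif significance."""

    motif_ids: list[str]
    sample_ids: list[str]
    activities: np.ndarray        # motif x sample
    std_errors: np.ndarray        # motif x sample, > 0
    motif_z: Optional[np.ndarray] = None
    fit_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.activities = np.asarray(self.activities, dtype=float)
        self.std_errors = np.asarray(self.std_errors, dtype=float)
        M, S = len(self.motif_ids), len(self.sample_ids)
        if self.activities.shape != (M, S) or self.std_errors.shape != (M, S):
            raise ValueError("activity/std-error shapes inconsistent with ids")
        if not np.all(np.isfinite(self.activities)):
            raise ValueError("non-finite activity")
        if not np.all(np.isfinite(self.std_errors)) or np.any(self.std_errors <= 0):
            raise ValueError("standard errors must be finite and > 0")
        if self.motif_z is not None:
            self.motif_z = np.asarray(self.motif_z, dtype=float)
            if self.motif_z.shape != (M,):
                raise ValueError("motif_z shape inconsistent")

    def sample_index(self, sample_ids) -> np.ndarray:
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        return np.array([pos[s] for s in sample_ids], dtype=int)


def double_center(expr: ExpressionMatrix):
    """Remove promoter and sample offsets; returns (centered values, offsets).

    The output has every row mean and column mean equal to zero; adding the
    stored offsets back reconstructs the input exactly.
    """
    E = expr.values
    if E.shape[0] < 2 or E.shape[1] < 2:
        raise ValueError("double-centering needs at least 2 promoters and 2 samples")
    row_means = E.mean(axis=1)
    grand = float(E.mean())
    col_means = E.mean(axis=0) - grand
    centered = E - row_means[:, None] - col_means[None, :]
    return centered, CenteringOffsets(promoter_means=row_means,
                                      sample_means=col_means)


def _prepare(expr: ExpressionMatrix, counts: SiteCountMatrix,
             drop_zero_motifs: bool):
    if expr.promoter_ids != counts.promoter_ids:
        raise ValueError("expression and site-count matrices are not aligned "
                         "on promoters; run data_io.align first")
    N = counts.counts
    motif_ids = list(counts.motif_ids)
    if drop_zero_motifs:
        keep = N.any(axis=0)
        dropped = [m for m, k in zip(motif_ids, keep) if not k]
        if dropped:
            logger.warning("dropping %d all-zero motif column(s): %s",
                           len(dropped), dropped)
        N = N[:, keep]
        motif_ids = [m for m, k in zip(motif_ids, keep) if k]
    if N.shape[1] == 0:
        raise ValueError("no informative motifs: every site-count column is zero")
    col_means = N.mean(axis=0)
    Nc = N - col_means[None, :]
    return Nc, motif_ids, col_means


def fit_activities(expr: ExpressionMatrix, counts: SiteCountMatrix,
                   config: FitConfig) -> ActivityTable:
    """Infer motif activities A (motif x sample) with standard errors.

    Solves the per-sample ridge problem on the double-centered expression and
    column-centered site counts, then re-centers each motif's activity
    profile to zero mean across samples (the removed means are kept in
    ``fit_meta['activity_row_means']``).
    """
    Ec, offsets = double_center(expr)
    Nc, motif_ids, ncol_means = _prepare(expr, counts, config.drop_zero_motifs)
    offsets.site_count_column_means = ncol_means

    if config.ridge_penalty == "cv":
        lam = choose_ridge_penalty(expr, counts, config)
    else:
        lam = float(config.ridge_penalty)
        if lam <= 0:
            raise ValueError("ridge penalty must be > 0")

    P, S = Ec.shape
    M = Nc.shape[1]
    G = Nc.T @ Nc + lam * np.eye(M)
    try:
        cho = scipy.linalg.cho_factor(G)
    except scipy.linalg.LinAlgError as exc:  # pragma: no cover - lam>0 makes G SPD
        raise ValueError(f"ridge system not positive definite: {exc}") from exc
    A = scipy.linalg.cho_solve(cho, Nc.T @ Ec)          # M x S
    if not np.all(np.isfinite(A)):
        bad = [motif_ids[i] for i in
               np.unique(np.argwhere(~np.isfinite(A))[:, 0])]
        raise ValueError(f"non-finite solution for motif block: {bad}")

    Ginv = scipy.linalg.cho_solve(cho, np.eye(M))
    m_eff = float(np.trace(Ginv @ (Nc.T @ Nc)))         # hat-matrix trace per sample
    resid = Ec - Nc @ A
    if config.known_noise_sd is not None:
        sigma2 = float(config.known_noise_sd) ** 2
    else:
        dof = max(P * S - S * m_eff, 1.0)
        sigma2 = float(np.sum(resid ** 2)) / dof
    # strictly positive error bars even on noise-free input
    sigma2 = max(sigma2, np.finfo(float).tiny)
    se = np.sqrt(sigma2 * np.clip(np.diag(Ginv), np.finfo(float).tiny, None))
    std_errors = np.broadcast_to(se[:, None], (M, S)).copy()

    row_means = A.mean(axis=1)
    A = A - row_means[:, None]

    table = ActivityTable(
        motif_ids=motif_ids,
        sample_ids=list(expr.sample_ids),
        activities=A,
        std_errors=std_errors,
        fit_meta={
            "ridge_penalty": lam,
            "residual_variance": sigma2,
            "effective_parameters": m_eff,
            "activity_row_means": row_means,
            "centering_offsets": offsets,
        },
    )
    table.motif_z = motif_significance(table)
    return table


def motif_significance(table: ActivityTable) -> np.ndarray:
    """Per-motif z: root-mean-square of A_ms / sigma_ms across samples.

    Quantifies how significantly a motif's activity varies over the samples
    relative to its error bars.
    """
    if np.any(table.std_errors <= 0):
        raise ValueError("standard errors must be > 0")
    ratios = table.activities / table.std_errors
    return np.sqrt(np.mean(ratios ** 2, axis=1))


def choose_ridge_penalty(expr: ExpressionMatrix, counts: SiteCountMatrix,
                         config: FitConfig) -> float:
    """Pick lambda from ``cv_grid`` by promoter-fold cross-validation.

    Promoters are shuffled with the config seed and split into ``cv_folds``
    folds; for each lambda, activities fitted on the training promoters
    predict the held-out promoters' centered expression.  The grid value
    with the smallest mean held-out squared error wins (ties go to the
    smaller lambda).  Deterministic given the seed.
    """
    grid = sorted(float(l) for l in config.cv_grid)
    if not grid:
        raise ValueError("cv_grid must be non-empty")
    if len(grid) == 1:
        return grid[0]
    Ec, _ = double_center(expr)
    Nc, _, _ = _prepare(expr, counts, config.drop_zero_motifs)
    P = Ec.shape[0]
    if P < config.cv_folds:
        raise ValueError(f"{P} promoters is fewer than {config.cv_folds} folds")
    rng = np.random.default_rng(config.seed)
    order = rng.permutation(P)
    folds = np.array_split(order, config.cv_folds)
    M = Nc.shape[1]
    errors = np.zeros(len(grid))
    for fold in folds:
        mask = np.ones(P, dtype=bool)
        mask[fold] = False
        Ntr, Etr = Nc[mask], Ec[mask]
        Nte, Ete = Nc[~mask], Ec[~mask]
        NtN = Ntr.T @ Ntr
        NtE = Ntr.T @ Etr
        for i, lam in enumerate(grid):
            A = np.linalg.solve(NtN + lam * np.eye(M), NtE)
            errors[i] += float(np.sum((Ete - Nte @ A) ** 2))
    best = int(np.argmin(errors))
    return grid[best]
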
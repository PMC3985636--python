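"""Synthetic toxicogenomics studies with planted regulatory programs.

The generator mirrors the structure of a liver phenobarbital time-course
experiment: a kinetic design with seven timepoints (days 1, 3, 7, 14, 28,
57, 91) in treated and control animals, or two-group designs
(knockout/wild-type, tumor/surrounding).  Motif activities are composed as
sparse mixtures of a small number of characteristic temporal programs:

* ``development_decay``   — high early, drops after two weeks, identical in
  treated and control animals (postnatal liver development);
* ``sustained_offset``    — constant treated/control gap at every timepoint
  (sustained xenobiotic response);
* ``transient_first``     — treated/control divergence at the first
  timepoint only (acute mitogenic response);
* ``late_divergence``     — treated and control drift apart over the last
  month (adaptive late response).

The raw shapes are mean-centered and sequentially orthonormalized, so the
planted basis lives in exactly the subspace a singular value decomposition
of the activities should recover.  Expression follows the same linear model
the fitter assumes — e = c_p + n_s + N A + noise — so that at zero noise and
vanishing ridge penalty, recovery is an identity up to centering.

Every draw flows from one ``numpy`` Generator seeded by the config;
identical configs give byte-identical bundles.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .data_io import (
    ExpressionMatrix,
    MotifTFMap,
    SampleDesign,
    SiteCountMatrix,
    write_expression_matrix,
    write_motif_tf_map,
    write_sample_design,
    write_site_counts,
)

__all__ = [
    "GeneratorConfig",
    "SyntheticTruth",
    "SyntheticStudy",
    "generate_design",
    "generate_site_counts",
    "generate_program_profiles",
    "generate_activities",
    "generate_expression",
    "generate_study",
    "selection_benchmark_config",
]

DEFAULT_TIMEPOINTS = (1.0, 3.0, 7.0, 14.0, 28.0, 57.0, 91.0)
DEFAULT_SHAPES = ("development_decay", "sustained_offset",
                  "transient_first", "late_divergence")
SHAPE_NAMES = DEFAULT_SHAPES + ("custom",)


@dataclass
class GeneratorConfig:
    """Study-generation settings; ``seed`` is mandatory.

    ``noise_mode='relative'`` scales the expression noise SD by the SD of
    the signal term N·A, so ``noise_sd`` is a signal-to-noise dial; with
    ``'absolute'`` it is in log2 expression units directly.  The default
    (2.0x the signal SD) is calibrated so that, at the default study size,
    the fitter recovers planted activities at a median per-motif Pearson
    correlation of about 0.9 — noisy enough that subtle solver mistakes
    move the recovery numbers.
    ``motif_programs`` assigns each motif a 0-based program index (−1 for a
    decoy loading nothing); default is round-robin over all programs.
    """

    seed: int
    n_promoters: int = 500
    n_motifs: int = 20
    timepoints: Sequence[float] = DEFAULT_TIMEPOINTS
    conditions: Sequence[str] = ("treated", "control")
    replicates: int = 1
    groups: Optional[Sequence[str]] = None   # two-group designs; overrides timepoints
    group_size: int = 3
    dataset: str = "kinetic"
    n_programs: int = 4
    shapes: Sequence[str] = DEFAULT_SHAPES
    motif_programs: Optional[Sequence[int]] = None
    signal_scale: float = 1.0
    program_scales: Optional[Sequence[float]] = None
    activity_noise_sd: float = 0.0
    site_count_rate: float = 0.5
    noise_sd: float = 2.0
    noise_mode: str = "relative"
    baseline_mean: float = 7.0
    baseline_sd: float = 1.5
    sample_offset_sd: float = 0.1
    tf_tracks_activity: bool = True
    unexpressed_tf_motifs: Sequence[int] = ()
    expressed_tf_level: float = 8.0
    unexpressed_tf_level: float = 4.0

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.n_promoters < 1 or self.n_motifs < 1 or self.replicates < 1:
            raise ValueError("counts must be >= 1")
        if self.noise_sd < 0 or self.activity_noise_sd < 0:
            raise ValueError("noise SDs must be >= 0")
        if self.noise_mode not in ("relative", "absolute"):
            raise ValueError("noise_mode must be 'relative' or 'absolute'")
        if len(self.shapes) < self.n_programs:
            raise ValueError("need at least n_programs shapes")
        for s in self.shapes:
            if s not in SHAPE_NAMES:
                raise ValueError(f"unknown program shape {s!r}")


@dataclass
class SyntheticTruth:
    """Planted ground truth accompanying a generated study."""

    activities: np.ndarray        # motif x sample, rows mean-centered
    basis: np.ndarray             # program x sample, orthonormal rows
    loadings: np.ndarray          # motif x program
    promoter_baselines: np.ndarray
    sample_offsets: np.ndarray
    noise_sd: float               # realized absolute noise SD
    seed: int


@dataclass
class SyntheticStudy:
    expression: ExpressionMatrix
    counts: SiteCountMatrix
    design: SampleDesign
    tf_map: MotifTFMap
    truth: SyntheticTruth

    def write(self, outdir) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "expression": outdir / "expression.tsv",
            "counts": outdir / "site_counts.tsv",
            "design": outdir / "design.tsv",
            "tf_map": outdir / "tf_map.tsv",
            "tf_expression": outdir / "tf_expression.tsv",
            "true_activities": outdir / "true_activities.tsv",
        }
        write_expression_matrix(self.expression, paths["expression"])
        write_site_counts(self.counts, paths["counts"])
        write_sample_design(self.design, paths["design"])
        write_motif_tf_map(self.tf_map, paths["tf_map"], paths["tf_expression"])
        pd.DataFrame(self.truth.activities, index=self.counts.motif_ids,
                     columns=self.expression.sample_ids).to_csv(
            paths["true_activities"], sep="\t", index_label="motif_id",
            float_format="%.17g")
        return paths


def generate_design(config: GeneratorConfig) -> SampleDesign:
    """Kinetic design (conditions x timepoints x replicates) or two-group.

    The default emulates a 91-day treated/control time course sampled at
    seven timepoints; with one replicate that is 14 samples.
    """
    rows = []
    if config.groups is not None:
        if not config.groups:
            raise ValueError("empty group specification")
        for cond in config.groups:
            for r in range(1, config.group_size + 1):
                rows.append({"sample_id": f"{cond}_r{r}",
                             "dataset": config.dataset, "condition": cond,
                             "time": np.nan, "replicate": r})
    else:
        if not config.timepoints or not config.conditions:
            raise ValueError("empty kinetic design specification")
        for t in config.timepoints:
            for cond in config.conditions:
                for r in range(1, config.replicates + 1):
                    rows.append({"sample_id": f"{cond}_d{t:g}_r{r}",
                                 "dataset": config.dataset, "condition": cond,
                                 "time": float(t), "replicate": r})
    return SampleDesign(pd.DataFrame(rows))


def generate_site_counts(config: GeneratorConfig,
                         rng: Optional[np.random.Generator] = None
                         ) -> SiteCountMatrix:
    """Poisson site counts with every motif column non-zero and the
    column-centered matrix at full column rank."""
    if config.site_count_rate <= 0:
        raise ValueError("site_count_rate must be > 0")
    rng = np.random.default_rng(config.seed) if rng is None else rng
    P, M = config.n_promoters, config.n_motifs
    N = rng.poisson(config.site_count_rate, size=(P, M)).astype(float)
    for _ in range(100):
        zero = ~N.any(axis=0)
        if not zero.any():
            break
        N[:, zero] = rng.poisson(config.site_count_rate,
                                 size=(P, int(zero.sum())))
    else:
        raise ValueError("could not avoid all-zero motif columns in 100 attempts")
    Nc = N - N.mean(axis=0)
    if np.linalg.matrix_rank(Nc) < M:
        raise ValueError(
            f"centered site-count matrix is column-rank deficient "
            f"({config.n_promoters} promoters x {M} motifs)"
        )
    promoters = [f"prom_{i:05d}" for i in range(P)]
    motifs = [f"motif_{j:03d}" for j in range(M)]
    return SiteCountMatrix(promoters, motifs, N)


def _raw_shape(name: str, times: np.ndarray, treated: np.ndarray) -> np.ndarray:
    t_first = times.min()
    t_last = times.max()
    sign = np.where(treated, 1.0, -1.0)
    if name == "development_decay":
        # same in both arms; high until day 14, low after
        return np.where(times <= 14.0, 1.0, -1.0)
    if name == "sustained_offset":
        return sign
    if name == "transient_first":
        return np.where(times == t_first, sign, 0.0)
    if name == "late_divergence":
        ramp = np.clip((times - 28.0) / max(t_last - 28.0, 1.0), 0.0, None)
        return sign * ramp
    raise ValueError(f"shape {name!r} has no built-in profile")


def generate_program_profiles(design: SampleDesign,
                              shapes: Sequence[str]) -> np.ndarray:
    """Orthonormal program basis B (program x sample).

    Raw shape vectors are built from each sample's (time, condition), then
    mean-centered and sequentially orthogonalized (stable modified
    Gram-Schmidt) preserving row order.
    """
    df = design.table
    S = len(df)
    if len(shapes) > S - 1:
        raise ValueError(f"{len(shapes)} programs need at most {S - 1}")
    times = df["time"].to_numpy(dtype=float)
    if np.isnan(times).any():
        raise ValueError("kinetic program shapes need a time for every sample")
    treated = (df["condition"] == "treated").to_numpy()
    B = np.zeros((len(shapes), S))
    for k, name in enumerate(shapes):
        v = _raw_shape(name, times, treated).astype(float)
        v = v - v.mean()
        for j in range(k):
            v = v - (v @ B[j]) * B[j]
        norm = np.linalg.norm(v)
        if norm < 1e-10:
            raise ValueError(
                f"program shape {name!r} is degenerate on this design "
                "(collinear with earlier shapes)"
            )
        B[k] = v / norm
    return B


def generate_activities(B: np.ndarray, config: GeneratorConfig,
                        rng: Optional[np.random.Generator] = None
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Sparse loadings W and planted activities A = W B (+ optional noise).

    Each signal motif loads on exactly one program with a magnitude drawn
    around the program's scale and a random sign; decoys load nothing.
    Rows of A are re-centered after any activity noise.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    K, S = B.shape
    M = config.n_motifs
    if config.motif_programs is None:
        programs = [i % K for i in range(M)]
    else:
        programs = list(config.motif_programs)
        if len(programs) != M:
            raise ValueError("motif_programs length must equal n_motifs")
    scales = (list(config.program_scales) if config.program_scales is not None
              else [config.signal_scale] * K)
    W = np.zeros((M, K))
    for i, p in enumerate(programs):
        if p < 0:
            continue
        if p >= K:
            raise ValueError(f"motif {i} assigned to missing program {p}")
        W[i, p] = scales[p] * rng.uniform(0.8, 1.2) * rng.choice([-1.0, 1.0])
    A = W @ B
    if config.activity_noise_sd > 0:
        A = A + rng.normal(0.0, config.activity_noise_sd, size=A.shape)
    A = A - A.mean(axis=1, keepdims=True)
    return A, W


def generate_expression(counts: SiteCountMatrix, A_true: np.ndarray,
                        config: GeneratorConfig,
                        rng: Optional[np.random.Generator] = None
                        ) -> tuple[ExpressionMatrix, np.ndarray, np.ndarray, float]:
    """e = c_p + n_s + N A + noise; returns (expr, baselines, offsets, sd).

    Promoter baselines emulate RMA-like log2 levels (centered near 7); the
    realized absolute noise SD is returned (relevant in 'relative' mode).
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    N = counts.counts
    P, S = N.shape[0], A_true.shape[1]
    c = rng.normal(config.baseline_mean, config.baseline_sd, size=P)
    n = rng.normal(0.0, config.sample_offset_sd, size=S)
    signal = N @ A_true
    if config.noise_mode == "relative":
        sd = config.noise_sd * float(np.std(signal))
    else:
        sd = config.noise_sd
    E = c[:, None] + n[None, :] + signal
    if sd > 0:
        E = E + rng.normal(0.0, sd, size=E.shape)
    sample_ids = [f"sample_{i:03d}" for i in range(S)]
    return (ExpressionMatrix(list(counts.promoter_ids), sample_ids, E), c, n, sd)


def _make_tf_map(A_true: np.ndarray, motif_ids: list[str],
                 sample_ids: list[str], config: GeneratorConfig,
                 rng: np.random.Generator) -> MotifTFMap:
    unexpressed = set(int(i) for i in config.unexpressed_tf_motifs)
    rows, index = [], []
    for i, m in enumerate(motif_ids):
        tf = f"TF_{m}"
        base = (config.unexpressed_tf_level if i in unexpressed
                else config.expressed_tf_level)
        if config.tf_tracks_activity and i not in unexpressed:
            prof = base + 0.8 * A_true[i] + rng.normal(0.0, 0.02, len(sample_ids))
        else:
            prof = base + rng.normal(0.0, 0.1, len(sample_ids))
        rows.append(prof)
        index.append(tf)
    expr = pd.DataFrame(np.asarray(rows), index=index, columns=sample_ids)
    return MotifTFMap({m: [f"TF_{m}"] for m in motif_ids}, expr)


def generate_study(config: GeneratorConfig) -> SyntheticStudy:
    """One-call factory for a consistent study bundle with ground truth."""
    rng = np.random.default_rng(config.seed)
    design = generate_design(config)
    counts = generate_site_counts(config, rng)
    B = generate_program_profiles(design, list(config.shapes)[:config.n_programs])
    A_true, W = generate_activities(B, config, rng)
    expr, c, n, sd = generate_expression(counts, A_true, config, rng)
    # expression columns take the design's sample ids
    expr = ExpressionMatrix(expr.promoter_ids, design.sample_ids, expr.values)
    tf_map = _make_tf_map(A_true, counts.motif_ids, design.sample_ids, config, rng)
    truth = SyntheticTruth(activities=A_true, basis=B, loadings=W,
                           promoter_baselines=c, sample_offsets=n,
                           noise_sd=sd, seed=config.seed)
    return SyntheticStudy(expr, counts, design, tf_map, truth)


def selection_benchmark_config(seed: int) -> GeneratorConfig:
    """Planted-selection benchmark: 3 sustained-program motifs with
    expressed TFs, plus 20 decoys of which 2 also load on the sustained
    program but have unexpressed TFs (log2 < 6) and 18 load nothing.

    The 2 unexpressed decoys are indistinguishable from true positives by
    ranking and significance; only the TF-expression filter removes them.
    """
    n_motifs = 23
    programs = [-1] * n_motifs
    for i in (0, 1, 2, 3, 4):
        programs[i] = 1            # sustained_offset in the default shape order
    return GeneratorConfig(
        seed=seed,
        n_promoters=500,
        n_motifs=n_motifs,
        motif_programs=programs,
        signal_scale=2.0,
        noise_sd=0.05,
        noise_mode="relative",
        unexpressed_tf_motifs=(3, 4),
        replicates=2,
    )
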
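# Methods

## Model

Motif activity response analysis (MARA) treats the log2 expression of
promoter *p* in sample *s* as a linear function of the promoter's predicted
transcription-factor binding sites:

    e_ps = c_p + n_s + Σ_m N_pm A_ms + ε_ps

where *N_pm* is the predicted number of binding sites for motif *m* in
promoter *p* (produced upstream by probabilistic TFBS prediction and taken
as input here), *A_ms* is the latent activity of motif *m* in sample *s*,
*c_p* is the basal activity of the promoter, *n_s* a per-sample
normalization offset, and ε Gaussian noise. An activity is the amount by
which a promoter's expression would change per binding site of the motif:
it rises when the motif's predicted targets are coherently upregulated
beyond what the other motifs explain. The model deliberately never looks at
the expression of the TFs themselves, so activity changes driven by
post-translational modification or nuclear translocation are visible.

### Nuisance elimination by centering

`mara_core` removes *c_p* and *n_s* exactly rather than fitting them:
the expression matrix is double-centered (every row and column mean zero)
and the site-count matrix column-centered. This has the same least-squares
optimum as the explicit fit, removes two nuisance blocks from the solve,
and guarantees that every fitted activity profile is mean-centered across
samples — a property the SVD stage relies on (see below). The removed
offsets are stored and reconstruct the raw inputs exactly.

### Ridge solve and error bars

Per sample the model is the ridge problem

    min_A ‖Ẽ_s − Ñ A_s‖² + λ‖A_s‖²,   A = (ÑᵀÑ + λI)⁻¹ Ñᵀ Ẽ

solved for all samples at once through one Cholesky factorization.
Standard errors come from the Gaussian posterior covariance
σ̂²(ÑᵀÑ + λI)⁻¹. The residual variance σ̂² is pooled over samples with
degrees of freedom P·S − S·M_eff, where M_eff = tr[(ÑᵀÑ+λI)⁻¹ÑᵀÑ] is the
hat-matrix trace (the effective number of parameters per sample); pooling
stabilizes the error bars when the number of samples is small. A
`known_noise_sd` override exists for simulations with known noise. After
the solve each motif's activity row is re-centered to zero mean (the means
are kept in `fit_meta`); this is near-automatic but enforcing it makes the
SVD correlation identity exact. σ̂² is floored at the smallest positive
float so error bars stay strictly positive even on noise-free input.

Per-motif significance is z_m = √(1/S · Σ_s (A_ms/σ̃_ms)²), the
root-mean-square activity in error-bar units: how significantly the motif's
activity varies across samples.

### Choice of the penalty

λ is not given by the modelling problem, so the default chooses it by
promoter-fold cross-validation: promoters are shuffled with the run seed
and split into 5 folds; activities fitted on the training promoters predict
the held-out promoters' centered expression; the grid value (7 log-spaced
points, 10⁻⁴…10²) with the smallest mean held-out squared error wins, ties
going to the smaller λ. The procedure is deterministic given the seed. On
noise-free data it selects the smallest grid value, as it should. A fixed
numeric λ can be supplied instead; unit tests and recovery benchmarks use
small fixed penalties so that their tolerances are meaningful.

All-zero site-count columns are unidentifiable and are dropped (with a
logged warning) at fit time, not at load time — keeping I/O free of
modelling policy.

## Differential activity

Activities are averaged over the replicates of a condition; the standard
error of the mean combines the per-sample posterior errors as independent:
σ̄ = √(Σ_r σ̃_r²)/R. The differential activity between two conditions is

    z_m = (Ā_m,c1 − Ā_m,c2) / √(σ̄²_m,c1 + σ̄²_m,c2)

and is exactly antisymmetric under swapping the conditions. Contrasts are
refused across datasets (batches): batch and biology would be confounded,
and the pipeline enforces this both in the statistics layer and in the
orchestration. Calls use a configurable threshold (default 2.0, roughly
two-sided 95%); thresholds are config values, never hard-coded.

Two categorical rules build on the calls. Pathway dependence compares a
treatment response in wild-type and knockout genotypes: *downstream* when
the wild-type response disappears in the knockout, *independent* when both
respond in the same direction, *none* otherwise (including the discordant
case, which the simple epistasis logic cannot interpret). Tumor specificity
compares tumor-vs-surrounding calls between promoted and non-promoted
tumors: *promoted_specific* when only the promoted tumor responds, *shared*
when both do.

No multiple-testing correction is applied across motifs: the method uses
fixed z cutoffs by design, and the per-motif error bars already encode the
fit uncertainty.

## Program decomposition

The motif × sample activity matrix is factored by thin SVD, A = UΛVᵀ. The
right singular vectors (columns of V) are orthonormal "characteristic
activity profiles": mutually independent temporal/condition patterns shared
by many motifs. Because the activity rows are mean-centered, each profile
is mean-centered too. Variance fractions are λ_k²/Σλ_j².

Two motif-level scores follow directly from the factorization:
projections P = UΛ (raw activity units, scale-sensitive) and correlations
ρ_ik = P_ik/‖A_i‖ with ‖A_i‖ = √(Σ_k P_ik²), which equal the Pearson
correlation between the motif's profile and each singular vector — an
identity that holds exactly *because* rows are mean-centered, and that the
tests verify both positively and with a negative control (breaking the
centering breaks the identity). A large-activity motif can project strongly
onto a profile it does not resemble; a quiet motif can correlate perfectly
while projecting weakly. Selection therefore requires both.

Numerical choices: components below 10⁻¹² of the leading singular value are
dropped rather than carried — a row-centered matrix always has at least one
null direction, and the basis vector the SVD returns for it is arbitrary
(it would violate the zero-mean property and the ρ-identity). The activity
matrix is decomposed exactly as fitted, not re-standardized per motif,
precisely so that projections and correlations carry different information.
SVD signs are arbitrary, so an orientation pass canonicalizes them:
`max_abs_positive` (default; deterministic without any metadata) flips each
component so its largest-magnitude sample entry is positive;
`treatment_positive` flips so the treated-arm mean is at least the control
mean, for biological readability. Either flip changes (u_k, v_k) jointly
and leaves the reconstruction unchanged.

## Representative-motif selection

Candidates per program and direction are the intersection of the top-n
(default 10) motifs by projection and the top-n by correlation, ordered by
|P| with |ρ| and then the motif id as tie-breaks, giving a total
deterministic order. When top-n exceeds half the motif count a middling
motif can qualify in both directions; it is assigned to the direction
matching the sign of its projection. Three refinement filters follow, in a
fixed order for audit stability:

1. **Significance** — drop motifs with overall z below a per-program
   threshold. Defaults: 3.0 for the two highest-variance programs, 1.5 for
   programs three and four (stricter where more variance is claimed);
   always configurable.
2. **TF expression** — drop motifs none of whose cognate TFs reaches mean
   log2 expression 6.0 across samples. Motifs are bound by TF families, so
   one expressed member suffices to keep the motif (any-TF rule); motifs
   absent from the map are kept with an audit note — missing evidence is
   not evidence of absence. The scalar cutoff needs a summary rule; the
   mean across samples is used.
3. **Per-timepoint pattern** — require the treated-vs-control z at
   individual timepoints to match the program's temporal character:
   `sustained` needs |z| ≥ threshold at a minimum number of timepoints
   (default 4 of 7), `day_first` at the first timepoint, `day_last` at the
   last. An optional `direction_sign` mode counts only z of the candidate's
   cluster sign; both variants are offered because either reading is
   defensible.

Every removal is recorded with the motif, direction, filter and a
human-readable detail string. A helper computes the Pearson correlation
between a motif's activity profile and each cognate TF's expression profile
(undefined profiles with zero variance are reported as absent), which is
how candidate driver TFs within a family are flagged.

## Synthetic studies

The generator emulates the structure of an in-vivo liver toxicogenomics
experiment: a kinetic design with seven timepoints (days 1, 3, 7, 14, 28,
57, 91) in treated and control arms with configurable replication
(14 samples at one replicate), plus two-group designs (knockout/wild-type,
tumor/surrounding) for the contrast logic. Activities are sparse mixtures
of four characteristic temporal programs — development decay (identical in
both arms, high until day 14), sustained treated/control offset, first-day
transient divergence, late divergence over the last month — mean-centered
and sequentially orthonormalized so the planted basis spans exactly the
subspace the SVD should recover. Site counts are Poisson(0.5): what matters
for exercising the linear algebra is the non-negative, sparse, integer
character of binding-site counts, not their upstream posterior provenance.
Expression follows the fitted model exactly (e = c_p + n_s + NA + ε with
baselines ~ N(7, 1.5²) log2 units and small sample offsets), so zero-noise,
vanishing-penalty recovery is an identity up to centering — the module's
core verification role.

Noise defaults: `noise_sd` is interpreted relative to the SD of the signal
term N·A (an interpretable signal-to-noise dial) and defaults to 2.0,
calibrated so that activity recovery at the default study size has a median
per-motif Pearson correlation of about 0.9 — a sensitive regression
surface on which subtle solver mistakes move the numbers, rather than a
trivially easy setting. Recovery benchmarks that specify their own noise
(0.1× signal SD, or exact zero) set it explicitly. TF expression profiles
for the motif–TF map either track the planted activity (for the
expression–activity correlation logic) around log2 level 8, or sit near
level 4 for designated "unexpressed" motifs used to exercise the expression
filter.

What the generator does *not* emulate: probe-level microarray noise,
cross-dataset batch effects, correlated site counts between similar motifs,
promoter-length or GC biases, and tumor mutation processes. Passing
recovery tests therefore demonstrates correctness of the inference under
the model's own assumptions, not robustness to the violations real data
brings.

## Problem sizes and verification

The verification suite runs entirely on generated data: solver–oracle
agreement on 20×5×4 instances against an independent normal-equations
solve (agreement to 10⁻¹⁰), noise-free planted recovery on the default
500×20×14 study (10⁻⁶), noisy recovery at 0.1× signal SD (median r ≥ 0.9),
planted 4-program subspace recovery at activity noise 0.05 (principal
angles < 5°), the ρ-identity on 30×10 matrices (10⁻¹⁰), null calibration
of the differential z over 10,000 draws (tail mass, mean, variance), exact
planted-selection recovery on a 23-motif benchmark, and byte-identical
reruns of the full pipeline. `scripts/acceptance.py` recomputes all of
these from scratch at any seed. These sizes keep each check specific — the
oracle instances small enough to trust an explicit solve, the recovery
studies large enough that shrinkage and noise matter.

## Known limitations

- The error bars are the ridge-Gaussian posterior, an analogue of (not a
  reimplementation of) the full Bayesian treatment of the original method;
  per-sample activity uncertainties share one pooled residual variance.
- Samples are fitted with a shared penalty but independent per-sample
  solves; a joint fit with a shared prior across samples is not offered.
- Motif-level target lists are out of scope; the selection stage works at
  the motif level only.
- Promoters and samples are opaque identifiers; no genomic coordinates are
  modelled, and upstream steps (normalization, probe-to-promoter mapping,
  binding-site prediction) are inputs, not code.
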
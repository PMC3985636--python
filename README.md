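# marasvd

Inference of transcription-factor **motif activities** from promoter
expression and predicted binding-site counts, with **SVD decomposition** of
the activity matrix into independent regulatory programs, differential
activity contrasts between experimental conditions, and rule-based
selection of the motifs that represent each program.

The package is aimed at regulatory genomics analyses of designed *in vivo*
expression studies — time courses with treated/control arms, knockout vs
wild-type comparisons, tumor vs surrounding tissue — where the question is
*which regulators drive the observed expression changes, and through which
independent biological programs*.

## The model

Promoter log2 expression is modelled as a linear function of predicted
transcription-factor binding sites (motif activity response analysis,
MARA):

    e_ps = c_p + n_s + Σ_m N_pm · A_ms + ε_ps

- `N_pm` — predicted number of binding sites for motif *m* in promoter *p*
  (input, from upstream TFBS prediction);
- `A_ms` — latent activity of motif *m* in sample *s*, inferred by ridge
  regression with error bars from the Gaussian posterior;
- `c_p`, `n_s` — promoter baseline and per-sample normalization, removed
  exactly by double-centering.

A motif's activity rises when its predicted targets are coherently
upregulated beyond what other motifs explain — the TF's own mRNA never
enters the model, so post-translational regulation is visible. Each motif
gets a significance z = rms(A/σ̃) across samples.

The motif × sample activity matrix is then factored, A = UΛVᵀ. The right
singular vectors are orthonormal *characteristic activity profiles*
(regulatory programs); projections P = UΛ and correlations ρ = P/‖A_i‖
measure how much, and how cleanly, each motif follows each program.
Differential activity between conditions *c₁, c₂* of the same dataset is
z = (Ā₁−Ā₂)/√(σ̄₁²+σ̄₂²). Representative motifs per program are the
intersection of top ranks by projection *and* correlation, refined by
significance, TF-expression (log2 ≥ 6.0) and per-timepoint pattern
filters. A synthetic-study generator with planted programs makes every
stage verifiable by recovery.

## Worked example

```python
import numpy as np
from marasvd import synthetic_data as sd, mara_core as mc, svd_programs as sp

# a 91-day treated/control time course: 500 promoters, 20 motifs,
# 7 timepoints x 2 arms, activities mixing 4 temporal programs
study = sd.generate_study(sd.GeneratorConfig(seed=2014))

table = mc.fit_activities(study.expression, study.counts,
                          mc.FitConfig(ridge_penalty="cv", seed=2014))
print(f"lambda = {table.fit_meta['ridge_penalty']:g}")

rs = [np.corrcoef(table.activities[i], study.truth.activities[i])[0, 1]
      for i in range(20)]
print(f"median recovery r = {np.median(rs):.3f}")

decomp = sp.decompose_activities(table)
print("variance fractions:", decomp.variance_fraction[:4].round(3))
```

prints

```
lambda = 100
median recovery r = 0.891
variance fractions: [0.29  0.234 0.179 0.165]
```

Cross-validation picks a heavy penalty (λ = 100) because the default study
is deliberately noisy (noise at 2× the signal SD); the planted activities
are still recovered at a median per-motif correlation of 0.89, and the four
planted programs dominate the variance spectrum (87% in the top four
components). At low noise the same pipeline recovers activities to
numerical precision — `analysis/` and the test suite walk through both
regimes.

The `analysis/` directory contains the full narrative as numbered scripts
(`01_simulate.py` … `05_select_motifs.py`: simulate → fit → decompose →
contrast → select), each printing what it found and writing its tables
under `results/`. The same functionality is available from the shell via
the `marasvd` CLI (`simulate`, `fit`, `svd`, `contrast`, `select`,
`run-all`), with `run-all` driving the whole pipeline from a YAML config
and writing a manifest with SHA-256 hashes of every artifact.

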
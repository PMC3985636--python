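#!/usr/bin/env python
"""Differential motif activity between conditions, within each dataset.

Two demonstrations on synthetic data with known truth:

1. Kinetic study — treated-vs-control z per timepoint; motifs planted on
   treatment-responsive programs should cross |z| >= 2 at the timepoints
   where their program separates the arms.
2. Knockout-style two-group study — treated-vs-control calls in wild-type
   and knockout genotypes combined into pathway-dependence calls
   (downstream / independent / none).

Writes results/04_timepoint_z.tsv and results/04_dependency_calls.tsv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from marasvd import contrasts as ct, mara_core, synthetic_data as sd

SEED = 2014
ROOT = Path(__file__).resolve().parent.parent


def kinetic_contrasts(outdir: Path) -> None:
    study = sd.generate_study(sd.GeneratorConfig(seed=SEED, replicates=2))
    table = mara_core.fit_activities(
        study.expression, study.counts,
        mara_core.FitConfig(ridge_penalty="cv", seed=SEED))
    cz = ct.timepoint_contrast_table(table, study.design, "kinetic",
                                     "treated", "control")
    cz.round(4).to_csv(outdir / "04_timepoint_z.tsv", sep="\t",
                       index_label="motif_id")
    n_sig = (cz.abs() >= 2.0).sum(axis=0)
    print("kinetic study: motifs with |z| >= 2 per timepoint (day: count)")
    print("  " + ", ".join(f"{t:g}: {int(c)}" for t, c in n_sig.items()))


def dependency_demo(outdir: Path) -> None:
    """WT responds to treatment through the planted programs; the KO study
    has all treatment loadings silenced, mimicking a response that is fully
    downstream of the knocked-out pathway."""
    wt = sd.generate_study(sd.GeneratorConfig(
        seed=SEED + 1, dataset="wt_study", replicates=2))
    ko = sd.generate_study(sd.GeneratorConfig(
        seed=SEED + 1, dataset="ko_study", replicates=2,
        motif_programs=[-1] * 20))
    rows = []
    calls = {}
    for name, study in (("wt", wt), ("ko", ko)):
        table = mara_core.fit_activities(
            study.expression, study.counts,
            mara_core.FitConfig(ridge_penalty="cv", seed=SEED))
        res = ct.contrast(table, study.design, study.design.datasets()[0],
                          "treated", "control", threshold=2.0, time=91.0)
        calls[name] = dict(zip(res.motif_ids, res.calls))
    for m in sorted(calls["wt"]):
        dep = ct.dependency_call(calls["wt"][m], calls["ko"][m])
        rows.append({"motif_id": m, "wt_call": calls["wt"][m],
                     "ko_call": calls["ko"][m], "dependency": dep})
    df = pd.DataFrame(rows)
    df.to_csv(outdir / "04_dependency_calls.tsv", sep="\t", index=False)
    counts = df["dependency"].value_counts().to_dict()
    print(f"knockout comparison at day 91: {counts}")
    print("(planted truth: every treatment response silenced in the KO, so "
          "responding motifs should be called 'downstream')")


def main() -> None:
    outdir = ROOT / "results"
    outdir.mkdir(exist_ok=True)
    kinetic_contrasts(outdir)
    dependency_demo(outdir)
    print("\ntables -> results/04_timepoint_z.tsv, "
          "results/04_dependency_calls.tsv")


if __name__ == "__main__":
    main()
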
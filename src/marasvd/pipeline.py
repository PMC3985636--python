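"""Config-driven end-to-end orchestration: fit -> svd -> contrasts -> select.

Each dataset (batch) is fitted independently and contrasts never cross
datasets — the batch rule is enforced here as well as in ``contrasts``.
A JSON manifest records, per stage, the parameters and the SHA-256 hashes
of every input and output file, so identical reruns are verifiably
identical and any change in inputs or parameters changes the manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import List, Literal, Optional, Sequence, Union

import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field

from . import contrasts as ct
from . import data_io, mara_core, motif_selection, svd_programs

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineError", "validate_config", "run_analysis"]

_FLOAT_FMT = "%.17g"


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


class _Forbid(BaseModel):
    model_config = ConfigDict(extra="forbid")


class InputPaths(_Forbid):
    expression: str
    counts: str
    design: str
    tf_map: Optional[str] = None
    tf_expression: Optional[str] = None


class FitSettings(_Forbid):
    ridge_penalty: Union[float, Literal["cv"]] = "cv"
    cv_folds: int = 5
    cv_grid: List[float] = Field(default_factory=lambda: list(mara_core.DEFAULT_CV_GRID))
    known_noise_sd: Optional[float] = None
    drop_zero_motifs: bool = True

    def to_fit_config(self, seed: int) -> mara_core.FitConfig:
        return mara_core.FitConfig(
            ridge_penalty=self.ridge_penalty, cv_folds=self.cv_folds,
            cv_grid=tuple(self.cv_grid), known_noise_sd=self.known_noise_sd,
            drop_zero_motifs=self.drop_zero_motifs, seed=seed)


class SvdSettings(_Forbid):
    orient: Literal["max_abs_positive", "treatment_positive"] = "max_abs_positive"
    treated_label: str = "treated"
    control_label: str = "control"


class ContrastPair(_Forbid):
    dataset: str
    condition1: str
    condition2: str
    time: Optional[float] = None


class ContrastSettings(_Forbid):
    threshold: float = 2.0
    pairs: List[ContrastPair] = Field(default_factory=list)


class SelectionSettings(_Forbid):
    dataset: str
    component: int = 1
    top_n: int = 10
    min_motif_z: float = 0.0
    min_tf_log_expression: float = 6.0
    timepoint_rule: Literal["sustained", "day_first", "day_last", "none"] = "none"
    timepoint_z_threshold: float = 2.0
    min_timepoints_hit: int = 4
    direction_sign: bool = False
    treated_label: str = "treated"
    control_label: str = "control"

    def to_selection_config(self) -> motif_selection.SelectionConfig:
        return motif_selection.SelectionConfig(
            component=self.component, top_n=self.top_n,
            min_motif_z=self.min_motif_z,
            min_tf_log_expression=self.min_tf_log_expression,
            timepoint_rule=self.timepoint_rule,
            timepoint_z_threshold=self.timepoint_z_threshold,
            min_timepoints_hit=self.min_timepoints_hit,
            direction_sign=self.direction_sign)


class RunConfig(_Forbid):
    seed: int
    output_dir: str
    inputs: InputPaths
    fit: FitSettings = Field(default_factory=FitSettings)
    svd: SvdSettings = Field(default_factory=SvdSettings)
    contrasts: ContrastSettings = Field(default_factory=ContrastSettings)
    selection: List[SelectionSettings] = Field(default_factory=list)
    log_level: str = "INFO"


def validate_config(path) -> RunConfig:
    """Parse, default and schema-validate a YAML run config.

    Unknown keys are rejected with a message naming them; referenced input
    files must exist.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"config {path} is not a mapping")
    config = RunConfig.model_validate(raw)
    for name, p in config.inputs.model_dump().items():
        if p is not None and not Path(p).exists():
            raise FileNotFoundError(f"input {name!r} not found: {p}")
    return config


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _hash_paths(paths, relative_to: Optional[Path] = None) -> dict[str, str]:
    out = {}
    for p in paths:
        if p is None:
            continue
        p = Path(p)
        key = str(p.relative_to(relative_to)) if relative_to else str(p)
        out[key] = _sha256(p)
    return out


def run_analysis(config: RunConfig) -> dict:
    """Execute all stages in order, writing artifacts and a run manifest.

    Returns the manifest dict (also written to ``<output_dir>/manifest.json``).
    Any stage error aborts the run; the manifest still records the failed
    stage before a :class:`PipelineError` is raised.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": []}
    state: dict = {}

    def record(stage: str, params: dict, inputs, outputs, status="completed"):
        # outputs are keyed relative to output_dir so identical reruns in
        # different directories produce identical manifests
        in_rel = outdir if all(
            Path(p).is_relative_to(outdir) for p in inputs if p) else None
        manifest["stages"].append({
            "stage": stage, "status": status, "parameters": params,
            "input_hashes": _hash_paths(inputs, in_rel),
            "output_hashes": _hash_paths(outputs, outdir),
        })

    def fail(stage: str, exc: Exception):
        manifest["stages"].append({"stage": stage, "status": "failed",
                                   "error": str(exc)})
        _write_manifest(manifest, outdir)
        raise PipelineError(stage, str(exc)) from exc

    input_paths = [p for p in config.inputs.model_dump().values() if p]

    # ----- stage: fit (per dataset) ------------------------------------
    try:
        expr = data_io.read_expression_matrix(config.inputs.expression)
        counts = data_io.read_site_counts(config.inputs.counts)
        design = data_io.read_sample_design(config.inputs.design)
        expr, counts, design = data_io.align(expr, counts, design)
        if config.inputs.tf_map:
            tf_map = data_io.read_motif_tf_map(config.inputs.tf_map,
                                               config.inputs.tf_expression)
        else:
            tf_map = data_io.MotifTFMap({}, pd.DataFrame())
        fit_outputs = []
        for ds in design.datasets():
            ds_samples = design.select(dataset=ds)
            ds_expr = data_io.ExpressionMatrix(
                expr.promoter_ids, ds_samples,
                expr.to_frame()[ds_samples].to_numpy())
            table = mara_core.fit_activities(
                ds_expr, counts, config.fit.to_fit_config(config.seed))
            paths = data_io.write_activity_table(table, outdir / f"activities_{ds}")
            fit_outputs.extend(paths.values())
            state[ds] = {"table": table}
        record("fit", config.fit.model_dump(), input_paths, fit_outputs)
    except PipelineError:
        raise
    except Exception as exc:
        fail("fit", exc)

    # ----- stage: svd (per dataset) ------------------------------------
    try:
        svd_outputs = []
        for ds in design.datasets():
            table = state[ds]["table"]
            decomp = svd_programs.decompose_activities(table)
            if config.svd.orient == "treatment_positive":
                decomp = svd_programs.orient_components(
                    decomp, design, "treatment_positive",
                    config.svd.treated_label, config.svd.control_label)
            else:
                decomp = svd_programs.orient_components(decomp)
            scores = svd_programs.component_scores(decomp)
            prefix = outdir / f"svd_{ds}"
            comp = [f"comp{k+1}" for k in range(decomp.n_components)]
            frames = {
                ".U.tsv": pd.DataFrame(decomp.U, index=decomp.motif_ids, columns=comp),
                ".V.tsv": pd.DataFrame(decomp.V, index=decomp.sample_ids, columns=comp),
                ".lambda.tsv": pd.DataFrame(
                    {"singular_value": decomp.singular_values,
                     "variance_fraction": decomp.variance_fraction}, index=comp),
                ".projections.tsv": pd.DataFrame(
                    scores.projections, index=scores.motif_ids, columns=comp),
                ".correlations.tsv": pd.DataFrame(
                    scores.correlations, index=scores.motif_ids, columns=comp),
            }
            for suffix, frame in frames.items():
                p = prefix.with_suffix(prefix.suffix + suffix)
                frame.to_csv(p, sep="\t", index_label="id", float_format=_FLOAT_FMT)
                svd_outputs.append(p)
            state[ds]["decomp"] = decomp
            state[ds]["scores"] = scores
        record("svd", config.svd.model_dump(), list(fit_outputs), svd_outputs)
    except PipelineError:
        raise
    except Exception as exc:
        fail("svd", exc)

    # ----- stage: contrasts --------------------------------------------
    try:
        frames = []
        for pair in config.contrasts.pairs:
            if pair.dataset not in state:
                raise ValueError(f"contrast references unknown dataset {pair.dataset!r}")
            res = ct.contrast(state[pair.dataset]["table"], design, pair.dataset,
                              pair.condition1, pair.condition2,
                              threshold=config.contrasts.threshold,
                              time=pair.time)
            frames.append(res.to_frame())
        contrast_path = outdir / "contrasts.tsv"
        out = (pd.concat(frames, ignore_index=True) if frames
               else pd.DataFrame(columns=["motif_id", "z", "call",
                                          "contrast", "threshold"]))
        out.to_csv(contrast_path, sep="\t", index=False, float_format=_FLOAT_FMT)
        record("contrast", config.contrasts.model_dump(), list(fit_outputs),
               [contrast_path])
    except PipelineError:
        raise
    except Exception as exc:
        fail("contrast", exc)

    # ----- stage: select ------------------------------------------------
    try:
        sel_outputs = []
        sel_rows, audit_frames = [], []
        for sel in config.selection:
            if sel.dataset not in state:
                raise ValueError(f"selection references unknown dataset {sel.dataset!r}")
            table = state[sel.dataset]["table"]
            scores = state[sel.dataset]["scores"]
            cz = None
            if sel.timepoint_rule != "none":
                cz = ct.timepoint_contrast_table(table, design, sel.dataset,
                                                 sel.treated_label,
                                                 sel.control_label)
            selection = motif_selection.select_representatives(
                scores, dict(zip(table.motif_ids, table.motif_z)), tf_map,
                cz, sel.to_selection_config())
            for direction, cluster in (("+", selection.positive_cluster),
                                       ("-", selection.negative_cluster)):
                for rank, m in enumerate(cluster, 1):
                    sel_rows.append({"dataset": sel.dataset,
                                     "component": sel.component,
                                     "direction": direction, "rank": rank,
                                     "motif_id": m})
            audit = selection.removals()
            audit.insert(0, "component", sel.component)
            audit.insert(0, "dataset", sel.dataset)
            audit_frames.append(audit)
        sel_path = outdir / "selection.tsv"
        audit_path = outdir / "selection_audit.tsv"
        pd.DataFrame(sel_rows, columns=["dataset", "component", "direction",
                                        "rank", "motif_id"]).to_csv(
            sel_path, sep="\t", index=False)
        (pd.concat(audit_frames, ignore_index=True) if audit_frames
         else pd.DataFrame(columns=["dataset", "component", "motif_id",
                                    "direction", "stage", "detail"])).to_csv(
            audit_path, sep="\t", index=False)
        sel_outputs = [sel_path, audit_path]
        record("select", [s.model_dump() for s in config.selection],
               list(fit_outputs), sel_outputs)
    except PipelineError:
        raise
    except Exception as exc:
        fail("select", exc)

    _write_manifest(manifest, outdir)
    return manifest


def _write_manifest(manifest: dict, outdir: Path) -> None:
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
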
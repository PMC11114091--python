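"""End-to-end runs: simulate (or ingest) -> fit -> shells -> extract -> stats.

Each stage writes its artifacts under the run directory (one directory per
subject/timepoint, cohort-level tables and statistics at the root) and the
run report records versions, seeds, per-stage wall time and warning counts.
A stage failure aborts the run with the stage name and a machine-readable
code; artifacts already written are retained.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, fwmodel, io, phantom, shells, stats
from .config import RunConfig
from .gradients import make_gradient_table, read_fsl_gradients, write_fsl_gradients

log = logging.getLogger(__name__)

STAGES = ("simulate", "fit", "shells", "extract", "stats")


class PipelineError(RuntimeError):
    """Stage failure with a machine-readable code."""

    def __init__(self, stage: str, code: str, message: str):
        self.stage = stage
        self.code = code
        super().__init__(f"[{stage}:{code}] {message}")


class _WarningCounter(logging.Handler):
    def __init__(self):
        super().__init__(level=logging.WARNING)
        self.count = 0

    def emit(self, record):
        self.count += 1


def run_pipeline(config: RunConfig, out_dir: str | None = None) -> dict:
    """Execute the full pipeline described by ``config``.

    Returns the run report (also written to ``report.json`` in the run
    directory). In simulate mode every scan of the simulated cohort is
    forward-modelled, fitted and analyzed; measures and statistics are
    written as TSV/JSON at the cohort root.
    """
    root = Path(out_dir or config.out_dir)
    root.mkdir(parents=True, exist_ok=True)
    config.to_yaml(root / "config.yaml")
    counter = _WarningCounter()
    logging.getLogger("periwater").addHandler(counter)
    report = {
        "version": __version__,
        "seed": config.seed,
        "mode": config.mode,
        "stages": [],
    }
    try:
        if config.mode == "simulate":
            measures, subject_table = _run_simulated(config, root, report)
        else:
            measures, subject_table = _run_ingest(config, root, report)
        _stage_stats(config, root, report, measures, subject_table)
    finally:
        logging.getLogger("periwater").removeHandler(counter)
        report["n_warnings"] = counter.count
        (root / "report.json").write_text(json.dumps(report, indent=2, default=str))
    return report


def _timed(report: dict, name: str):
    class _Ctx:
        def __enter__(self):
            self.t0 = time.perf_counter()
            return self

        def __exit__(self, exc_type, exc, tb):
            entry = {
                "stage": name,
                "wall_time_s": round(time.perf_counter() - self.t0, 3),
                "ok": exc_type is None,
            }
            report["stages"].append(entry)
            return False

    return _Ctx()


def _process_scan(config, root, subject_id, timepoint, truth, noise_seed, table,
                  affine, timers):
    """fit -> shells -> extract for one scan; returns the measure rows."""
    scan_dir = root / subject_id / timepoint
    scan_dir.mkdir(parents=True, exist_ok=True)
    cfg = fwmodel.FitConfig(**config.fit.model_dump())
    dwi = phantom.simulate_dwi(
        truth,
        table,
        s0=config.acquisition.s0,
        snr=config.acquisition.snr,
        seed=noise_seed,
    )
    masks = truth.masks
    t0 = time.perf_counter()
    fit = fwmodel.fit_bitensor(dwi, table, masks.brain, cfg)
    vox = config.phantom.voxel_size_mm
    io.save_nifti(fit.fw_map, scan_dir / "fw.nii.gz", affine)
    io.save_nifti(fit.fat_map, scan_dir / "fat.nii.gz", affine)
    io.save_nifti(fit.md_t_map, scan_dir / "md_t.nii.gz", affine)
    io.save_nifti(fit.residual_map, scan_dir / "residual.nii.gz", affine)
    t1 = time.perf_counter()
    shellset = shells.build_shellset(
        masks.lesion,
        masks.wm,
        masks.ventricles,
        n_shells=config.shells.n_shells,
        wm_erode_iterations=config.shells.wm_erode_iterations,
        voxel_size_mm=vox,
    )
    io.save_mask(masks.lesion, scan_dir / "lesion.nii.gz", affine)
    io.save_mask(shellset.flipped_lesion, scan_dir / "lesion_flipped.nii.gz", affine)
    t2 = time.perf_counter()
    rows = shells.extract_measures(
        {"fw": fit.fw_map, "fat": fit.fat_map},
        shellset,
        subject=subject_id,
        timepoint=timepoint,
    )
    t3 = time.perf_counter()
    timers["fit"] += t1 - t0
    timers["shells"] += t2 - t1
    timers["extract"] += t3 - t2
    return rows


def _run_simulated(config: RunConfig, root: Path, report: dict):
    with _timed(report, "simulate"):
        effect = config.effect.to_effect()
        design = config.cohort.to_design(
            effect,
            seed=config.seed,
            baseline_fw=config.phantom.baseline_fw,
            baseline_fat=config.phantom.baseline_fat,
        )
        cohort = phantom.simulate_cohort(design)
        subject_table = cohort.subject_table
        subject_table.to_csv(root / "subjects.tsv", sep="\t", index=False)
        table = make_gradient_table(
            config.acquisition.n_directions,
            config.acquisition.b_value,
            config.acquisition.n_b0,
            seed=config.seed,
        )
        write_fsl_gradients(table, root / "bvals", root / "bvecs")
    affine = io.affine_for(config.phantom.voxel_size_mm)
    all_rows = []
    timers = {"fit": 0.0, "shells": 0.0, "extract": 0.0}
    for subject_id, timepoint in cohort.scan_list():
        spec = cohort.phantom_spec_for(
            subject_id, timepoint, config.phantom.to_spec(seed=config.seed)
        )
        tp_index = list(design.timepoints).index(timepoint)
        try:
            masks = phantom.build_phantom(spec)
            truth = phantom.make_truth_maps(
                spec, effect, tp_index, masks, config.shells.n_shells
            )
        except phantom.PhantomSpecError as exc:
            raise PipelineError("simulate", "bad-phantom", str(exc)) from exc
        rows = _process_scan(
            config, root, subject_id, timepoint, truth, spec.seed, table, affine,
            timers,
        )
        all_rows.append(rows)
    for name in ("fit", "shells", "extract"):
        report["stages"].append(
            {"stage": name, "wall_time_s": round(timers[name], 3), "ok": True}
        )
    measures = pd.concat(all_rows, ignore_index=True)
    measures.to_csv(root / "measures.tsv", sep="\t", index=False)
    return measures, subject_table


def _run_ingest(config: RunConfig, root: Path, report: dict):
    ing = config.ingest
    with _timed(report, "simulate"):  # stage slot: ingest replaces simulation
        for name in ("dwi", "bvals", "bvecs", "lesion_mask", "wm_mask",
                     "ventricle_mask", "subject_table"):
            path = getattr(ing, name)
            if not Path(path).exists():
                raise PipelineError("simulate", "missing-input", f"{name}: {path}")
        dwi, affine = io.load_nifti(ing.dwi)
        table = read_fsl_gradients(ing.bvals, ing.bvecs)
        lesion, aff_l = io.load_nifti(ing.lesion_mask)
        wm, aff_w = io.load_nifti(ing.wm_mask)
        vent, aff_v = io.load_nifti(ing.ventricle_mask)
        subject_table = pd.read_csv(ing.subject_table, sep="\t")
        check = io.validate_inputs(
            dwi, affine,
            {"lesion": (lesion, aff_l), "wm": (wm, aff_w), "ventricles": (vent, aff_v)},
            subject_table,
        )
        if not check.ok:
            raise PipelineError("simulate", "validation", "; ".join(check.failures))
    with _timed(report, "fit"):
        cfg = fwmodel.FitConfig(**config.fit.model_dump())
        brain = (wm > 0) | (lesion > 0) | (vent > 0)
        fit = fwmodel.fit_bitensor(dwi, table, brain, cfg)
        io.save_nifti(fit.fw_map, root / "fw.nii.gz", affine)
        io.save_nifti(fit.fat_map, root / "fat.nii.gz", affine)
        io.save_nifti(fit.md_t_map, root / "md_t.nii.gz", affine)
    with _timed(report, "shells"):
        shellset = shells.build_shellset(
            lesion > 0, wm > 0, vent > 0,
            n_shells=config.shells.n_shells,
            wm_erode_iterations=config.shells.wm_erode_iterations,
        )
    with _timed(report, "extract"):
        sid = str(subject_table["subject_id"].iloc[0]) if len(subject_table) else "sub-01"
        tp = str(subject_table["timepoint"].iloc[0]) if len(subject_table) else "TP1"
        measures = shells.extract_measures(
            {"fw": fit.fw_map, "fat": fit.fat_map}, shellset, subject=sid, timepoint=tp
        )
        measures.to_csv(root / "measures.tsv", sep="\t", index=False)
    return measures, subject_table


def _stage_stats(config, root, report, measures, subject_table):
    with _timed(report, "stats"):
        merged = measures.merge(
            subject_table, on=["subject_id", "timepoint"], how="left"
        )
        ttests = stats.ttest_table(measures, alpha=config.stats.alpha)
        ttests.to_csv(root / "ttests.tsv", sep="\t", index=False)
        summary = {"alpha": config.stats.alpha, "models": {}}
        enough = (
            merged["subject_id"].nunique() >= 3
            and merged["timepoint"].nunique() >= 2
            and "days_since_stroke" in merged.columns
        )
        if enough:
            for measure in ("fw", "fat"):
                try:
                    res = stats.fit_longitudinal_lmm(
                        merged, measure, omnibus=config.stats.omnibus
                    )
                except stats.DegenerateDataError as exc:
                    summary["models"][measure] = {"error": str(exc)}
                    continue
                res.contrasts.to_csv(
                    root / f"tukey_{measure}.tsv", sep="\t", index=False
                )
                res.fixed.to_csv(root / f"lmm_{measure}.tsv", sep="\t")
                summary["models"][measure] = {
                    "omnibus_chi2": res.omnibus_chi2,
                    "omnibus_dof": res.omnibus_dof,
                    "omnibus_p": res.omnibus_p,
                    "r2_marginal": res.r2_marginal,
                    "r2_conditional": res.r2_conditional,
                    "converged": res.converged,
                }
        (root / "stats.json").write_text(json.dumps(summary, indent=2))
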
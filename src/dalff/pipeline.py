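"""End-to-end runner: simulate -> preprocess -> dALFF-CV -> group -> clinical.

Each stage is an importable function consuming and producing in-memory
objects; :func:`run_pipeline` chains them in the standard order and writes
every product (maps, tables, manifest, log) to the output directory. A
single top-level seed deterministically derives all stage seeds, so a rerun
with the same config reproduces all deterministic outputs.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from dalff import __version__
from dalff.alff import dalff_cv_map
from dalff.clinical import (
    correlation_table,
    demographics_report,
    extract_roi_means,
    roc_auc,
)
from dalff.config import PipelineConfig, RunManifest, save_config
from dalff.datatypes import BoldRun, FrequencyBand, ScalarMap, WindowSpec
from dalff.glm import VoxelwiseGroupModel, report_cluster_table
from dalff.io import read_regressors, read_volume, save_cohort, write_volume
from dalff.preprocess import (
    detrend_linear,
    drop_initial_volumes,
    mean_framewise_displacement,
    regress_nuisance,
    smooth_gaussian,
)
from dalff.synthetic import CohortBundle, CohortConfig, generate_cohort

__all__ = ["preprocess_run", "cv_map_for_run", "load_cohort", "run_pipeline"]

logger = logging.getLogger(__name__)


def preprocess_run(run: BoldRun, regressors, drop_k: int, fwhm_mm: float) -> BoldRun:
    """Standard temporal/spatial preprocessing in the fixed stage order:
    drop initial volumes -> linear detrend -> nuisance regression ->
    Gaussian smoothing. Regressor rows are sliced to the retained volumes.
    """
    out = drop_initial_volumes(run, drop_k)
    out = detrend_linear(out)
    if regressors is not None:
        from dalff.preprocess import RegressorSet

        sliced = RegressorSet(matrix=regressors.matrix[drop_k:], names=regressors.names)
        out = regress_nuisance(out, sliced)
    out = smooth_gaussian(out, (fwhm_mm,) * 3)
    return out


def cv_map_for_run(run: BoldRun, mask, alff_cfg) -> ScalarMap:
    spec = WindowSpec(length_tr=alff_cfg.window_length, step_tr=alff_cfg.window_step,
                      n_timepoints=run.n_timepoints)
    band = FrequencyBand(alff_cfg.f_lo, alff_cfg.f_hi)
    return dalff_cv_map(run, spec, band, mask, normalize=alff_cfg.normalize)


def load_cohort(in_dir) -> CohortBundle:
    """Load a previously written cohort directory back into a bundle."""
    d = Path(in_dir)
    participants = pd.read_csv(d / "participants.tsv", sep="\t")
    clinical = pd.read_csv(d / "clinical.tsv", sep="\t")
    mask_map = read_volume(d / "brain_mask.nii.gz")
    mask = mask_map.values > 0.5
    roi_masks = {}
    for p in sorted(d.glob("roi_*.nii.gz")):
        label = p.name[len("roi_"):-len(".nii.gz")]
        roi_masks[label] = read_volume(p).values > 0.5
    runs, regressors = [], []
    tr = None
    for sid in participants["subject_id"]:
        run = read_volume(d / f"{sid}_bold.nii.gz")
        run.mask = mask
        tr = run.tr_s
        runs.append(run)
        regressors.append(read_regressors(d / f"{sid}_regressors.tsv"))
    n_pat = int((participants["group"] == "patient").sum())
    n_ctl = len(participants) - n_pat
    cfg = CohortConfig(
        n_patients=max(n_pat, 2), n_controls=max(n_ctl, 2),
        grid_shape=runs[0].spatial_shape,
        voxel_size_mm=tuple(runs[0].voxel_size_mm),
        n_timepoints=runs[0].n_timepoints, tr_s=tr, effect_rois=[],
    )
    return CohortBundle(runs=runs, brain_mask=mask, roi_masks=roi_masks,
                        participants=participants, clinical=clinical,
                        regressors=regressors, config=cfg)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the full analysis and write all products to ``cfg.out_dir``.

    Returns a dict with the in-memory results: the cohort bundle, subject
    CV maps, the fitted GLM results, cluster table, clinical association
    tables and ROC AUC.
    """
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest.start(cfg, __version__)
    log_lines: list[str] = [f"dalff {__version__} pipeline run, seed={cfg.seed}"]

    # ---- stage 1: cohort ------------------------------------------------
    if cfg.in_dir:
        bundle = load_cohort(cfg.in_dir)
        log_lines.append(f"loaded cohort from {cfg.in_dir}: {len(bundle.runs)} runs")
    else:
        bundle = generate_cohort(cfg.simulate.to_cohort_config(cfg.seed))
        cohort_dir = out / "cohort"
        written = save_cohort(bundle, cohort_dir)
        for name, path in written.items():
            manifest.add_file(f"cohort/{name}", path)
        log_lines.append(
            f"simulated cohort: {bundle.config.n_patients} patients, "
            f"{bundle.config.n_controls} controls, grid {bundle.config.grid_shape}, "
            f"T={bundle.config.n_timepoints}, TR={bundle.config.tr_s}s"
        )

    mask = bundle.brain_mask

    # ---- stage 2: preprocessing ----------------------------------------
    pre = cfg.preprocess
    fds = []
    pre_runs = []
    for run, regs in zip(bundle.runs, bundle.regressors):
        pre_runs.append(preprocess_run(run, regs, pre.drop_k, pre.fwhm_mm))
        motion = regs.matrix[pre.drop_k:, :6] if regs.matrix.shape[1] >= 6 else None
        fds.append(mean_framewise_displacement(motion) if motion is not None else np.nan)
    log_lines.append(
        f"preprocessing: drop_k={pre.drop_k}, detrend, nuisance regression, "
        f"smoothing FWHM={pre.fwhm_mm} mm; mean FD across subjects = {np.nanmean(fds):.4f} mm"
    )

    # ---- stage 3: dALFF-CV maps ----------------------------------------
    cv_maps = [cv_map_for_run(r, mask, cfg.alff) for r in pre_runs]
    spec = WindowSpec(length_tr=cfg.alff.window_length, step_tr=cfg.alff.window_step,
                      n_timepoints=pre_runs[0].n_timepoints)
    log_lines.append(
        f"dALFF: retained T={spec.n_timepoints}, window={spec.length_tr} TR, "
        f"step={spec.step_tr} TR -> {spec.n_windows} windows; band "
        f"[{cfg.alff.f_lo}, {cfg.alff.f_hi}] Hz; normalization={cfg.alff.normalize}"
    )
    maps_dir = out / "cv_maps"
    maps_dir.mkdir(exist_ok=True)
    for sid, m in zip(bundle.participants["subject_id"], cv_maps):
        p = maps_dir / f"{sid}_dalff_cv.nii.gz"
        write_volume(m, p)
        manifest.add_file(f"cv_maps/{p.name}", p)

    # ---- stage 4: group inference --------------------------------------
    inf = cfg.inference
    model = VoxelwiseGroupModel.from_dataframe(cv_maps, bundle.participants)
    results = model.fit()
    sm = results.smoothness()
    if inf.method == "grf":
        table = results.grf_clusters(voxel_p=inf.voxel_p, cluster_p=inf.cluster_p,
                                     two_sided=inf.two_sided, connectivity=inf.connectivity)
    else:
        table = results.permutation_clusters(voxel_p=inf.voxel_p, cluster_p=inf.cluster_p,
                                             n_perm=inf.n_perm, seed=cfg.seed,
                                             connectivity=inf.connectivity,
                                             two_sided=inf.two_sided)
    labeled = report_cluster_table(table, bundle.roi_masks)
    table.frame = labeled
    write_volume(results.tmap, out / "tstat.nii.gz")
    write_volume(results.zmap, out / "zstat.nii.gz")
    table.to_tsv(out / "clusters.tsv")
    for name in ("tstat.nii.gz", "zstat.nii.gz", "clusters.tsv"):
        manifest.add_file(name, out / name)
    log_lines.append(
        f"group inference ({inf.method}): voxel_p={inf.voxel_p}, cluster_p={inf.cluster_p}, "
        f"two_sided={inf.two_sided}, connectivity={inf.connectivity}; "
        f"estimated FWHM (mm) = ({sm.fwhm_mm[0]:.2f}, {sm.fwhm_mm[1]:.2f}, {sm.fwhm_mm[2]:.2f}), "
        f"resels = {sm.resels:.1f}; {len(table)} significant cluster(s)"
    )

    # ---- stage 5: clinical association ---------------------------------
    patient_rows = bundle.participants["group"] == "patient"
    patient_maps = [m for m, keep in zip(cv_maps, patient_rows) if keep]
    roi_names = cfg.clinical.rois or list(bundle.roi_masks)
    roi_means = {
        name: extract_roi_means(patient_maps, bundle.roi_masks[name])
        for name in roi_names if name in bundle.roi_masks
    }
    if roi_means and len(patient_maps) >= 4:
        corr = correlation_table(roi_means, bundle.clinical, scales=tuple(cfg.clinical.scales))
    else:
        corr = pd.DataFrame()
        log_lines.append("clinical correlations skipped: need >= 4 patients and >= 1 ROI")
    corr.to_csv(out / "correlations.tsv", sep="\t", index=False)
    manifest.add_file("correlations.tsv", out / "correlations.tsv")

    auc_by_roi = {}
    labels = patient_rows.to_numpy().astype(int)
    for name in roi_means:
        all_means = extract_roi_means(cv_maps, bundle.roi_masks[name])
        auc, curve = roc_auc(all_means, labels)
        auc_by_roi[name] = auc
        curve.to_csv(out / f"roc_{name}.tsv", sep="\t", index=False)
        log_lines.append(f"ROC: patient-vs-control on mean CV in {name}: AUC = {auc:.3f}")

    demo = demographics_report(bundle.participants, bundle.clinical)
    demo.to_csv(out / "demographics.tsv", sep="\t", index=False)
    manifest.add_file("demographics.tsv", out / "demographics.tsv")

    # ---- manifest + log -------------------------------------------------
    import time

    save_config(cfg, out / "config.yaml")
    manifest.finished = time.strftime("%Y-%m-%dT%H:%M:%S")
    manifest.write(out / "manifest.json")
    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    for line in log_lines:
        logger.info("%s", line)

    return {
        "bundle": bundle,
        "cv_maps": cv_maps,
        "results": results,
        "cluster_table": table,
        "correlations": corr,
        "auc_by_roi": auc_by_roi,
        "demographics": demo,
        "smoothness": sm,
        "window_spec": spec,
        "mean_fd": fds,
    }
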
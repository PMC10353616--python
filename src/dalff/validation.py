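"""Self-validation experiments for the dALFF pipeline.

These functions run the package end to end on seeded synthetic cohorts and
measure the properties the method is supposed to have: window bookkeeping,
error control of the cluster inference on null cohorts, recovery of a
planted effect (spatial Dice and clinical-coupling Spearman signs), and
scale invariance of the CV statistic. They back both the acceptance-style
tests and the reproduction script.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from dalff.alff import dalff_cv_map
from dalff.clinical import extract_roi_means, moment_matched_sample, roc_auc, spearman, two_sample_t_pooled
from dalff.config import AlffConfig
from dalff.datatypes import BoldRun, FrequencyBand, WindowSpec
from dalff.glm import VoxelwiseGroupModel
from dalff.pipeline import cv_map_for_run, preprocess_run
from dalff.preprocess import smooth_gaussian
from dalff.synthetic import CohortConfig, generate_cohort

__all__ = [
    "window_bookkeeping",
    "demographics_statistics",
    "analytic_alff_value",
    "scale_invariance_error",
    "null_fwer",
    "planted_recovery",
]

#: clinical scales and the sign their default coupling plants
SCALE_SIGNS = {"NIHSS": -1, "WE_FMA": +1, "UE_FMA": +1, "LE_FMA": +1, "BI": +1}


def window_bookkeeping(n_acquired: int = 186, drop_k: int = 10,
                       length_tr: int = 50, step_tr: int = 1) -> dict:
    """Retained volume count and window count of the standard scheme."""
    from dalff.preprocess import drop_initial_volumes

    run = BoldRun(data=np.zeros((2, 2, 2, n_acquired)), tr_s=2.0)
    retained = drop_initial_volumes(run, drop_k).n_timepoints
    spec = WindowSpec(length_tr=length_tr, step_tr=step_tr, n_timepoints=retained)
    return {"retained_timepoints": retained, "n_windows": spec.n_windows}


def demographics_statistics(seed: int = 0) -> dict:
    """Pooled t on age moments and the sex chi-square of the emulated study.

    Age groups are moment-matched samples (n=34: 56.500 +/- 10.999 vs
    n=44: 55.340 +/- 11.485); sex counts are 25/9 vs 19/25 male/female.
    """
    from dalff.clinical import chi_square_2x2

    a = moment_matched_sample(34, 56.500, 10.999, seed=seed * 2 + 1)
    b = moment_matched_sample(44, 55.340, 11.485, seed=seed * 2 + 2)
    t, _, _ = two_sample_t_pooled(a, b)
    chi2, _, _ = chi_square_2x2([[25, 9], [19, 25]])
    return {"age_t": t, "sex_chi2": chi2}


def analytic_alff_value() -> float:
    """ALFF of a unit sinusoid at an exact DFT bin: N=50, TR=2 s, 0.04 Hz,
    band 0.01-0.08 Hz (8 bins) -> 1/8."""
    from dalff.alff import compute_alff

    t = np.arange(50) * 2.0
    return compute_alff(np.sin(2 * np.pi * 0.04 * t), 2.0, FrequencyBand(0.01, 0.08))


def scale_invariance_error(seed: int = 0, factor: float = 3.7) -> float:
    """Max |change| of any dALFF-CV voxel when a run is rescaled by ``factor``."""
    rng = np.random.default_rng(seed)
    data = rng.normal(size=(6, 6, 5, 80))
    mask = np.ones((6, 6, 5), bool)
    spec = WindowSpec(40, 2, 80)
    band = FrequencyBand(0.01, 0.08)
    cv1 = dalff_cv_map(BoldRun(data=data, tr_s=2.0), spec, band, mask)
    cv2 = dalff_cv_map(BoldRun(data=factor * data, tr_s=2.0), spec, band, mask)
    return float(np.abs(cv1.values - cv2.values).max())


def _null_cohort_config(seed: int) -> CohortConfig:
    return CohortConfig(
        n_patients=10, n_controls=10, grid_shape=(12, 12, 10), n_timepoints=80,
        modulation_depth_patient=0.0, modulation_depth_control=0.0,
        effect_rois=[], seed=seed,
    )


def null_fwer(n_cohorts: int = 400, seed: int = 0, n_perm: int = 100) -> dict:
    """Empirical family-wise error rate on null synthetic cohorts.

    Each cohort (10 vs 10 subjects, 12x12x10 grid, T=80, no planted effect)
    is preprocessed, CV-mapped, given an extra 6 mm smoothing of the CV map
    itself (to put the fields in the well-smoothed regime GRF assumes), and
    tested at voxel p < 0.05, cluster p < 0.05 with both the permutation
    and the GRF path; a family error is any significant cluster.
    """
    acfg = AlffConfig(window_length=40, window_step=2)
    hits_perm = hits_grf = 0
    for i in range(n_cohorts):
        cseed = seed * 100000 + i
        bundle = generate_cohort(_null_cohort_config(cseed))
        pre = [preprocess_run(r, g, 8, 6.0) for r, g in zip(bundle.runs, bundle.regressors)]
        cvs = [cv_map_for_run(r, bundle.brain_mask, acfg) for r in pre]
        for m in cvs:
            m.values = smooth_gaussian(m.values, (6.0,) * 3, (3.0, 3.0, 3.0))
        res = VoxelwiseGroupModel.from_dataframe(cvs, bundle.participants).fit()
        hits_perm += len(res.permutation_clusters(n_perm=n_perm, seed=cseed)) > 0
        hits_grf += len(res.grf_clusters()) > 0
    return {
        "perm_fwer": hits_perm / n_cohorts,
        "grf_fwer": hits_grf / n_cohorts,
        "n_cohorts": n_cohorts,
    }


def planted_recovery(seeds=(0, 1, 2), n_patients: int = 15, n_controls: int = 15) -> dict:
    """Planted-effect recovery at the study's standard scale.

    For each seeded cohort (default depth 0.6, full 20x24x18 grid, T=186):
    GRF cluster inference at 0.05/0.05 gives a detected-voxel set whose Dice
    overlap with the planted ROI is recorded; patient ROI-mean CV values are
    pooled across cohorts and correlated (Spearman) with each generated
    clinical scale; ROC AUC separates patients from controls on ROI-mean CV.
    """
    acfg = AlffConfig()
    dices = []
    pooled_means: list[np.ndarray] = []
    pooled_clinical: dict[str, list] = {s: [] for s in SCALE_SIGNS}
    pooled_all_means: list[np.ndarray] = []
    pooled_labels: list[np.ndarray] = []
    for s in seeds:
        cfg = CohortConfig(n_patients=n_patients, n_controls=n_controls, seed=s)
        bundle = generate_cohort(cfg)
        pre = [preprocess_run(r, g, 10, 6.0) for r, g in zip(bundle.runs, bundle.regressors)]
        cvs = [cv_map_for_run(r, bundle.brain_mask, acfg) for r in pre]
        res = VoxelwiseGroupModel.from_dataframe(cvs, bundle.participants).fit()
        table = res.grf_clusters()
        roi = bundle.roi_masks["rectus_r"]
        detected = np.zeros_like(roi)
        for cmask in table.cluster_masks:
            detected |= cmask
        denom = detected.sum() + roi.sum()
        dices.append(2.0 * (detected & roi).sum() / denom if denom else 0.0)
        means = extract_roi_means(cvs, roi)
        pooled_means.append(means[:n_patients])
        pooled_all_means.append(means)
        pooled_labels.append((bundle.participants["group"] == "patient").to_numpy(int))
        for scale in SCALE_SIGNS:
            pooled_clinical[scale].extend(bundle.clinical[scale])
    patient_cv = np.concatenate(pooled_means)
    rhos = {}
    for scale in SCALE_SIGNS:
        rho, _ = spearman(patient_cv, np.asarray(pooled_clinical[scale]))
        rhos[scale] = rho
    auc, _ = roc_auc(np.concatenate(pooled_all_means), np.concatenate(pooled_labels))
    return {
        "dice_per_cohort": dices,
        "mean_dice": float(np.mean(dices)),
        "spearman_by_scale": rhos,
        "roc_auc": auc,
        "n_cohorts": len(list(seeds)),
    }
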
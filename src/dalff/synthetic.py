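"""Seeded synthetic two-group BOLD cohorts with planted amplitude dynamics.

The generator emulates the statistical structure the dALFF analysis
assumes: every in-brain voxel carries a band-limited oscillation whose
amplitude is slowly modulated over time,

    y(t) = [1 + d * m(t)] * sin(2*pi*f*t + phi_v)
           + drift_v * t + sum_j w_vj * g_j(t) + eps(t),

with carrier frequency ``f`` drawn per subject from the carrier band,
per-voxel phase ``phi_v``, a raised-sinusoid envelope
``m(t) = sin(2*pi*t/P + psi)`` with subject-random phase ``psi``,
modulation depth ``d`` set to the patient depth inside the planted effect
ROIs (patients only) and the control depth elsewhere, nuisance components
``g_j`` (Friston-24 motion expansion, white-matter and CSF signals, linear
drift) with small per-voxel loadings, and stationary AR(1) noise.
Sliding-window ALFF variability (CV) is by construction monotone in the
modulation depth, giving a clean parameter-recovery axis.

Clinical scales are monotone affine functions of each patient's realized
ROI temporal variability (positive coupling for Barthel/Fugl-Meyer-type
scales, negative for NIHSS-type) plus Gaussian noise, clipped to each
scale's admissible range.

Everything is deterministic given the seed: subject-level generators are
derived from (seed, subject_index), so cohorts are bit-reproducible and
individual subjects can be regenerated in isolation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from dalff.datatypes import BoldRun
from dalff.preprocess import RegressorSet, friston24_expand

__all__ = [
    "RoiSphere",
    "ScaleCoupling",
    "CohortConfig",
    "CohortBundle",
    "generate_brain_mask",
    "roi_sphere_mask",
    "generate_nuisance_regressors",
    "generate_subject_bold",
    "generate_clinical_scores",
    "generate_cohort",
    "DEFAULT_CLINICAL_COUPLING",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RoiSphere:
    """Spherical effect region: voxel-index center, radius in mm, label."""

    center_voxel: tuple[int, int, int]
    radius_mm: float
    label: str


@dataclass(frozen=True)
class ScaleCoupling:
    """Monotone affine coupling of one clinical scale to ROI variability.

    score = center + slope * z(ROI CV) + noise_sd * N(0,1), clipped to
    [lo, hi]. The slope's sign carries the clinical direction (negative
    for severity scales like NIHSS, positive for function scales).
    """

    center: float
    slope: float
    noise_sd: float
    lo: float
    hi: float


#: Default couplings; ranges follow the instruments (NIHSS 0-42, BI 0-100,
#: Fugl-Meyer UE max 66, LE max 34). Centers/slopes keep noiseless scores
#: inside range for |z| <= 3 so the monotone coupling is exactly rank-preserving.
DEFAULT_CLINICAL_COUPLING: dict[str, ScaleCoupling] = {
    "NIHSS": ScaleCoupling(center=15.0, slope=-4.0, noise_sd=2.0, lo=0.0, hi=42.0),
    "WE_FMA": ScaleCoupling(center=50.0, slope=12.0, noise_sd=6.0, lo=0.0, hi=100.0),
    "UE_FMA": ScaleCoupling(center=33.0, slope=8.0, noise_sd=4.0, lo=0.0, hi=66.0),
    "LE_FMA": ScaleCoupling(center=17.0, slope=5.0, noise_sd=2.5, lo=0.0, hi=34.0),
    "BI": ScaleCoupling(center=60.0, slope=12.0, noise_sd=6.0, lo=0.0, hi=100.0),
}


@dataclass
class CohortConfig:
    """Study conditions for one synthetic cohort.

    Defaults mirror the emulated study: 34 patients vs 44 controls, 186
    volumes at TR = 2 s on a 3 mm grid (desk-scale 20x24x18 field of view),
    one planted right-orbitofrontal-like effect sphere, patient-only
    amplitude modulation of depth 0.6 on a 150 s envelope.
    """

    n_patients: int = 34
    n_controls: int = 44
    grid_shape: tuple[int, int, int] = (20, 24, 18)
    voxel_size_mm: tuple[float, float, float] = (3.0, 3.0, 3.0)
    n_timepoints: int = 186
    tr_s: float = 2.0
    carrier_band_hz: tuple[float, float] = (0.02, 0.06)
    modulation_depth_patient: float = 0.6
    modulation_depth_control: float = 0.0
    modulation_depth_heterogeneity: float = 0.6
    modulation_period_s: float = 150.0
    noise_sd: float = 0.12
    ar1_coef: float = 0.3
    effect_rois: list[RoiSphere] = field(
        default_factory=lambda: [RoiSphere(center_voxel=(14, 16, 6), radius_mm=9.0, label="rectus_r")]
    )
    nuisance_amplitudes: dict = field(
        default_factory=lambda: {"motion": 0.05, "wm": 0.1, "csf": 0.1, "drift": 0.5}
    )
    clinical_coupling: dict = field(default_factory=lambda: dict(DEFAULT_CLINICAL_COUPLING))
    sex_male_prop: tuple[float, float] = (25 / 34, 19 / 44)  # (patients, controls)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 2 or self.n_controls < 2:
            raise ValueError("need >= 2 subjects per group")
        if not 0.0 <= self.modulation_depth_heterogeneity <= 1.0:
            raise ValueError("modulation_depth_heterogeneity must lie in [0, 1]")
        for name in ("modulation_depth_patient", "modulation_depth_control"):
            d = getattr(self, name)
            if not 0.0 <= d <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {d}")
        nyq = 1.0 / (2.0 * self.tr_s)
        lo, hi = self.carrier_band_hz
        if not (0.0 < lo < hi < nyq):
            raise ValueError(
                f"carrier band {self.carrier_band_hz} must lie within (0, Nyquist={nyq:.4g}) Hz"
            )
        if not -1.0 < self.ar1_coef < 1.0:
            raise ValueError(f"AR(1) coefficient must lie in (-1, 1), got {self.ar1_coef}")
        if self.modulation_period_s <= 0 or self.noise_sd < 0:
            raise ValueError("modulation period must be > 0 and noise SD >= 0")
        mask = generate_brain_mask(self.grid_shape, self.voxel_size_mm)
        for roi in self.effect_rois:
            if roi.radius_mm < min(self.voxel_size_mm):
                raise ValueError(f"ROI {roi.label!r}: radius below one voxel edge")
            sphere = roi_sphere_mask(roi, self.grid_shape, self.voxel_size_mm)
            if not (sphere & mask).any():
                raise ValueError(f"ROI {roi.label!r} does not intersect the brain mask")

    @property
    def affine(self) -> np.ndarray:
        aff = np.eye(4)
        aff[0, 0], aff[1, 1], aff[2, 2] = self.voxel_size_mm
        # center the grid on the world origin, MNI-style
        aff[:3, 3] = -(np.asarray(self.grid_shape) - 1) / 2.0 * np.asarray(self.voxel_size_mm)
        return aff


@dataclass
class CohortBundle:
    """A generated cohort: runs, masks, tables and nuisance regressors."""

    runs: list[BoldRun]
    brain_mask: np.ndarray
    roi_masks: dict[str, np.ndarray]
    participants: pd.DataFrame
    clinical: pd.DataFrame
    regressors: list[RegressorSet]
    config: CohortConfig

    def __post_init__(self) -> None:
        n = len(self.runs)
        if len(self.participants) != n or len(self.regressors) != n:
            raise ValueError("participants rows and regressor sets must match run count")
        ref = self.runs[0]
        for r in self.runs[1:]:
            if r.spatial_shape != ref.spatial_shape or r.n_timepoints != ref.n_timepoints:
                raise ValueError("all runs must share grid geometry and time length")
        if not np.all(np.isfinite(self.clinical.drop(columns=["subject_id"]).to_numpy(float))):
            raise ValueError("clinical table contains non-finite scores")

    @property
    def patient_ids(self) -> list[str]:
        return list(self.participants.loc[self.participants["group"] == "patient", "subject_id"])


def generate_brain_mask(grid_shape, voxel_size_mm=(3.0, 3.0, 3.0)) -> np.ndarray:
    """Axis-aligned ellipsoid 'brain' inscribed in the grid.

    Semi-axes are 0.45 of each axis extent, centered in the box;
    deterministic given the inputs.
    """
    grid_shape = tuple(int(g) for g in grid_shape)
    if any(g < 8 for g in grid_shape):
        raise ValueError(f"grid too small for an ellipsoid brain: {grid_shape} (all dims must be >= 8)")
    idx = np.indices(grid_shape, dtype=np.float64)
    center = (np.asarray(grid_shape) - 1) / 2.0
    semi = 0.45 * np.asarray(grid_shape, dtype=np.float64)
    r2 = sum(((idx[a] - center[a]) / semi[a]) ** 2 for a in range(3))
    return r2 <= 1.0


def roi_sphere_mask(roi: RoiSphere, grid_shape, voxel_size_mm) -> np.ndarray:
    """Binary mask of voxels whose centers lie within the sphere (mm metric)."""
    idx = np.indices(tuple(grid_shape), dtype=np.float64)
    vs = np.asarray(voxel_size_mm, dtype=np.float64)
    d2 = sum(((idx[a] - roi.center_voxel[a]) * vs[a]) ** 2 for a in range(3))
    return d2 <= roi.radius_mm**2


def _ar1_noise(rng, shape, rho, sd, burn_in=50):
    """Stationary AR(1) noise with marginal SD ``sd`` along the last axis."""
    t = shape[-1]
    innov_sd = sd * np.sqrt(1.0 - rho * rho) if rho != 0 else sd
    eta = rng.normal(0.0, innov_sd, size=(*shape[:-1], t + burn_in))
    eps = lfilter([1.0], [1.0, -rho], eta, axis=-1)
    return eps[..., burn_in:]


def generate_nuisance_regressors(rng, n_timepoints: int, tr_s: float) -> RegressorSet:
    """Motion-like, tissue-signal and trend nuisance regressors.

    Six smooth random-walk 'motion' series (3 translations in mm, 3
    rotations in rad) expanded to 24 Friston-style columns, one white-matter
    and one CSF signal (smooth AR(1) series, unit SD), and a linear trend.
    """
    t = n_timepoints
    steps = rng.normal(0.0, 1.0, size=(t, 6)) * np.array([0.02] * 3 + [4e-4] * 3)
    motion = np.cumsum(steps, axis=0)
    fr24 = friston24_expand(motion)
    wm = _ar1_noise(rng, (t,), 0.9, 1.0)
    csf = _ar1_noise(rng, (t,), 0.9, 1.0)
    trend = np.linspace(-0.5, 0.5, t)
    names = (
        [f"motion_{i+1}" for i in range(6)]
        + [f"motion_lag_{i+1}" for i in range(6)]
        + [f"motion_sq_{i+1}" for i in range(6)]
        + [f"motion_lag_sq_{i+1}" for i in range(6)]
        + ["wm", "csf", "trend"]
    )
    mat = np.column_stack([fr24, wm, csf, trend])
    return RegressorSet(matrix=mat, names=names)


def _standardize_columns(mat: np.ndarray) -> np.ndarray:
    mat = mat - mat.mean(axis=0)
    sd = mat.std(axis=0)
    sd[sd == 0] = 1.0
    return mat / sd


def generate_subject_bold(
    config: CohortConfig, subject_index: int, group_label: str, seed: int | None = None
) -> tuple[BoldRun, RegressorSet]:
    """One subject's 4D run plus the nuisance regressors injected into it.

    The subject generator is seeded from (seed, subject_index), so the
    same pair always yields a bit-identical run. Outside the brain mask
    the series is pure AR(1) noise. The returned run carries a
    ``planted_roi_cv`` attribute: the windowed-ALFF CV of the pure signal
    component averaged over the effect ROIs — the ground-truth subject
    variability that clinical scores are coupled to.
    """
    if group_label not in ("patient", "control"):
        raise ValueError(f"group_label must be 'patient' or 'control', got {group_label!r}")
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), int(subject_index)]))

    t = np.arange(config.n_timepoints) * config.tr_s
    mask = generate_brain_mask(config.grid_shape, config.voxel_size_mm)
    nvox = int(mask.sum())

    f = rng.uniform(*config.carrier_band_hz)
    psi = rng.uniform(0.0, 2.0 * np.pi)
    envelope = np.sin(2.0 * np.pi * t / config.modulation_period_s + psi)

    # subject severity: each subject's effect depth scatters around the
    # group level (patients vary in how strongly amplitude is modulated,
    # which is what the clinical coupling rides on)
    h = config.modulation_depth_heterogeneity
    depth_scale = 1.0 + h * rng.uniform(-1.0, 1.0)

    # depth field: patient depth inside effect ROIs (patients only), control elsewhere
    depth = np.full(config.grid_shape, config.modulation_depth_control)
    if group_label == "patient":
        for roi in config.effect_rois:
            sphere = roi_sphere_mask(roi, config.grid_shape, config.voxel_size_mm)
            depth[sphere] = config.modulation_depth_patient
    d = np.clip(depth[mask][:, None] * depth_scale, 0.0, 1.0)

    phi = rng.uniform(0.0, 2.0 * np.pi, size=(nvox, 1))
    carrier = np.sin(2.0 * np.pi * f * t[None, :] + phi)
    signal = (1.0 + d * envelope[None, :]) * carrier

    # planted temporal variability: windowed-ALFF CV of the pure signal
    # component inside the effect ROIs — the ground truth that clinical
    # scores couple to (noise, drift and nuisance enter only the data)
    roi_union = np.zeros(config.grid_shape, dtype=bool)
    for roi in config.effect_rois:
        roi_union |= roi_sphere_mask(roi, config.grid_shape, config.voxel_size_mm)
    in_roi = roi_union[mask]
    planted_cv = _signal_roi_cv(signal[in_roi], config) if in_roi.any() else float("nan")

    regs = generate_nuisance_regressors(rng, config.n_timepoints, config.tr_s)
    g = _standardize_columns(regs.matrix.copy())
    amp = config.nuisance_amplitudes
    loading_sd = np.array(
        [amp.get("motion", 0.0)] * 24 + [amp.get("wm", 0.0), amp.get("csf", 0.0)] + [0.0]
    )
    w = rng.normal(0.0, 1.0, size=(nvox, g.shape[1])) * loading_sd
    nuisance = w @ g.T

    t_norm = np.linspace(0.0, 1.0, config.n_timepoints)
    drift = rng.normal(0.0, amp.get("drift", 0.0), size=(nvox, 1)) * t_norm[None, :]

    data = _ar1_noise(rng, (*config.grid_shape, config.n_timepoints), config.ar1_coef, config.noise_sd)
    data[mask] += signal + nuisance + drift

    run = BoldRun(data=data, tr_s=config.tr_s, affine=config.affine, mask=mask)
    run.planted_roi_cv = planted_cv  # ground-truth ROI variability (see docstring)
    return run, regs


def _signal_roi_cv(signal: np.ndarray, config: CohortConfig) -> float:
    """Windowed-ALFF CV of the pure in-ROI signal component, ROI-averaged.

    Uses the analysis-default windowing, adapted when the run is short:
    drop 10 volumes for runs of at least 100 (else T//10), window length
    min(50, half the retained series), step sized to keep at most ~127
    windows.
    """
    from dalff.alff import dalff_cv_map
    from dalff.datatypes import FrequencyBand, WindowSpec

    t = signal.shape[-1]
    k = 10 if t >= 100 else max(2, t // 10)
    sub = BoldRun(data=signal[None, None, :, k:], tr_s=config.tr_s)
    t2 = sub.n_timepoints
    length = min(50, t2 // 2)
    step = max(1, int(np.ceil((t2 - length) / 126)))
    spec = WindowSpec(length_tr=length, step_tr=step, n_timepoints=t2)
    band = FrequencyBand(0.01, 0.08)
    full = np.ones(sub.spatial_shape, dtype=bool)
    cv = dalff_cv_map(sub, spec, band, full, normalize="none")
    return float(cv.in_mask.mean())


def generate_clinical_scores(
    roi_cv_per_patient: np.ndarray,
    patient_ids: list[str],
    coupling: dict[str, ScaleCoupling] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Clinical scales as monotone affine functions of patient ROI CV.

    The CV values are standardized across patients; each scale is
    center + slope*z + noise, clipped to its admissible range. Negative
    slopes encode severity scales (NIHSS), positive slopes function scales
    (BI, Fugl-Meyer).
    """
    cv = np.asarray(roi_cv_per_patient, dtype=np.float64)
    if cv.size == 0:
        raise ValueError("empty patient set: no ROI CV values to couple to")
    if cv.size != len(patient_ids):
        raise ValueError("one ROI CV value per patient id required")
    coupling = DEFAULT_CLINICAL_COUPLING if coupling is None else coupling
    sd = cv.std(ddof=0)
    z = (cv - cv.mean()) / sd if sd > 0 else np.zeros_like(cv)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 777001]))
    out = {"subject_id": list(patient_ids)}
    for scale, cp in coupling.items():
        raw = cp.center + cp.slope * z + rng.normal(0.0, cp.noise_sd, size=cv.size)
        out[scale] = np.clip(raw, cp.lo, cp.hi)
    return pd.DataFrame(out)


def _truncated_normal(rng, mean, sd, lo, hi, size):
    out = rng.normal(mean, sd, size=size)
    bad = (out < lo) | (out > hi)
    while bad.any():
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = (out < lo) | (out > hi)
    return out


def generate_cohort(config: CohortConfig) -> CohortBundle:
    """Full seeded cohort: runs, masks, demographics and clinical tables.

    Ages are Normal(56, 11) truncated to [30, 75]; sex is Bernoulli with
    per-group male proportions from the config; education Normal(9, 3)
    clipped to [1, 19] years. Clinical scales are coupled to each
    patient's realized in-ROI temporal variability.
    """
    cfg = config
    n = cfg.n_patients + cfg.n_controls
    groups = ["patient"] * cfg.n_patients + ["control"] * cfg.n_controls
    ids = [f"sub-{i + 1:03d}" for i in range(n)]

    demo_rng = np.random.default_rng(np.random.SeedSequence([int(cfg.seed), 999983]))
    age = _truncated_normal(demo_rng, 56.0, 11.0, 30.0, 75.0, n)
    p_male = np.where(np.array(groups) == "patient", cfg.sex_male_prop[0], cfg.sex_male_prop[1])
    sex = (demo_rng.random(n) < p_male).astype(int)
    education = np.clip(np.round(demo_rng.normal(9.0, 3.0, size=n)), 1, 19)
    participants = pd.DataFrame(
        {"subject_id": ids, "group": groups, "age": np.round(age, 1),
         "sex": sex, "education": education.astype(int)}
    )

    mask = generate_brain_mask(cfg.grid_shape, cfg.voxel_size_mm)
    roi_masks = {
        roi.label: roi_sphere_mask(roi, cfg.grid_shape, cfg.voxel_size_mm) & mask
        for roi in cfg.effect_rois
    }

    runs, regressors = [], []
    for i, grp in enumerate(groups):
        run, regs = generate_subject_bold(cfg, i, grp, seed=cfg.seed)
        runs.append(run)
        regressors.append(regs)

    patient_cv = np.array([runs[i].planted_roi_cv for i in range(cfg.n_patients)])
    if not np.all(np.isfinite(patient_cv)):  # no effect ROI planted
        patient_cv = np.zeros_like(patient_cv)
    clinical = generate_clinical_scores(
        patient_cv, ids[: cfg.n_patients], coupling=cfg.clinical_coupling, seed=cfg.seed
    )

    return CohortBundle(
        runs=runs, brain_mask=mask, roi_masks=roi_masks, participants=participants,
        clinical=clinical, regressors=regressors, config=cfg,
    )
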
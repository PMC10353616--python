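"""Temporal and spatial preprocessing of BOLD runs.

Desk-scale analogues of the standard resting-state stream: initial-volume
removal (steady-state magnetization), linear detrending, nuisance regression
(Friston-24 motion expansion, white-matter and CSF signals), and Gaussian
spatial smoothing. Realignment, slice timing and spatial normalization are
out of scope: inputs are assumed pre-aligned on a common grid, with motion
parameters supplied as regressors rather than estimated.

All operations are deterministic (no RNG). Smoothing uses zero padding
outside the grid; synthetic brains are interior so the edge policy is
immaterial, but it is fixed and documented.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from dalff.datatypes import BoldRun

__all__ = [
    "RegressorSet",
    "drop_initial_volumes",
    "detrend_linear",
    "regress_nuisance",
    "smooth_gaussian",
    "mean_framewise_displacement",
    "friston24_expand",
]

#: FWHM -> Gaussian sigma conversion factor, 2*sqrt(2*ln 2)
_FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))


@dataclass
class RegressorSet:
    """Named nuisance regressors, one column per regressor, one row per TR."""

    matrix: np.ndarray
    names: list[str]

    def __post_init__(self) -> None:
        self.matrix = np.atleast_2d(np.asarray(self.matrix, dtype=np.float64))
        if self.matrix.ndim != 2:
            raise ValueError("regressor matrix must be 2D (time x regressor)")
        if self.matrix.shape[1] != len(self.names):
            raise ValueError(
                f"{self.matrix.shape[1]} columns but {len(self.names)} names"
            )
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("regressor matrix contains non-finite values")
        zero = [n for n, col in zip(self.names, self.matrix.T) if np.all(col == 0)]
        if zero:
            raise ValueError(f"all-zero regressor column(s): {zero}")

    @property
    def n_timepoints(self) -> int:
        return self.matrix.shape[0]


def drop_initial_volumes(run: BoldRun, k: int) -> BoldRun:
    """Remove the first ``k`` volumes of a run (e.g. 10 of 186 leaves 176)."""
    if k < 0:
        raise ValueError(f"k must be >= 0, got {k}")
    if k >= run.n_timepoints:
        raise ValueError(
            f"cannot drop {k} of {run.n_timepoints} volumes: empty run would remain"
        )
    if k == 0:
        return run.copy_with(run.data.copy())
    return run.copy_with(run.data[..., k:].copy())


def detrend_linear(run: BoldRun) -> BoldRun:
    """Remove the per-voxel least-squares line a + b*t.

    Output series have zero mean and zero linear trend.
    """
    t = run.n_timepoints
    if t < 3:
        raise ValueError(f"linear detrend needs >= 3 time points, got {t}")
    x = np.arange(t, dtype=np.float64)
    design = np.column_stack([np.ones(t), x])
    flat = run.data.reshape(-1, t).T  # (t, nvox)
    coef, *_ = np.linalg.lstsq(design, flat, rcond=None)
    resid = flat - design @ coef
    return run.copy_with(resid.T.reshape(run.data.shape))


def regress_nuisance(run: BoldRun, regressors: RegressorSet) -> BoldRun:
    """Per-voxel OLS residuals of the series on [intercept | regressors].

    Residuals are orthogonal to every design column. The design must have
    full column rank; near-collinear columns are rejected by name.
    """
    t = run.n_timepoints
    if regressors.n_timepoints != t:
        raise ValueError(
            f"regressors have {regressors.n_timepoints} rows but run has {t} volumes"
        )
    design = np.column_stack([np.ones(t), regressors.matrix])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # identify offending columns by greedy rank growth
        bad = []
        kept = design[:, :1]
        for j in range(1, design.shape[1]):
            cand = np.column_stack([kept, design[:, j]])
            if np.linalg.matrix_rank(cand) > kept.shape[1]:
                kept = cand
            else:
                bad.append(regressors.names[j - 1])
        raise ValueError(f"nuisance design is rank deficient; redundant columns: {bad}")
    flat = run.data.reshape(-1, t).T
    coef, *_ = np.linalg.lstsq(design, flat, rcond=None)
    resid = flat - design @ coef
    return run.copy_with(resid.T.reshape(run.data.shape))


def _sigmas_vox(fwhm_mm, voxel_size_mm) -> np.ndarray:
    fwhm = np.broadcast_to(np.asarray(fwhm_mm, dtype=np.float64), (3,)).copy()
    if not np.all(np.isfinite(fwhm)) or np.any(fwhm < 0):
        raise ValueError(f"FWHM must be finite and >= 0 per axis, got {fwhm}")
    return fwhm / _FWHM_TO_SIGMA / np.asarray(voxel_size_mm, dtype=np.float64)


def smooth_gaussian(obj, fwhm_mm, voxel_size_mm=None):
    """Separable Gaussian smoothing of a run (frame-wise) or a 3D map.

    sigma per axis is FWHM / (2*sqrt(2 ln 2)) converted to voxel units via
    the affine's scales (or ``voxel_size_mm`` for a bare array). Kernel is
    truncated at 4 sigma and normalized to unit sum; zero padding outside
    the grid.
    """
    if isinstance(obj, BoldRun):
        sig = _sigmas_vox(fwhm_mm, obj.voxel_size_mm)
        if np.all(sig == 0):
            return obj.copy_with(obj.data.copy())
        out = ndimage.gaussian_filter(
            obj.data, sigma=(*sig, 0.0), mode="constant", cval=0.0, truncate=4.0
        )
        return obj.copy_with(out)
    arr = np.asarray(obj, dtype=np.float64)
    if arr.ndim != 3:
        raise ValueError(f"expected a BoldRun or a 3D array, got ndim={arr.ndim}")
    if voxel_size_mm is None:
        voxel_size_mm = (1.0, 1.0, 1.0)
    sig = _sigmas_vox(fwhm_mm, voxel_size_mm)
    if np.all(sig == 0):
        return arr.copy()
    return ndimage.gaussian_filter(arr, sigma=tuple(sig), mode="constant", cval=0.0, truncate=4.0)


def friston24_expand(motion: np.ndarray) -> np.ndarray:
    """Friston-24 expansion of 6 rigid-body motion parameters.

    Columns: the 6 parameters R, their one-TR lag R(t-1) (zero first row),
    and the squares of both, giving 24 columns.
    """
    motion = np.asarray(motion, dtype=np.float64)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise ValueError(f"motion must be (t, 6), got {motion.shape}")
    lagged = np.vstack([np.zeros((1, 6)), motion[:-1]])
    return np.hstack([motion, lagged, motion**2, lagged**2])


def mean_framewise_displacement(motion: np.ndarray, head_radius_mm: float = 50.0) -> float:
    """Mean framewise displacement (Power-style) from 6 motion parameters.

    Columns 0-2 are translations (mm), 3-5 rotations (radians) converted to
    arc length on a sphere of ``head_radius_mm``. Reported for QC only; no
    frame censoring is applied.
    """
    motion = np.asarray(motion, dtype=np.float64)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise ValueError(f"motion must be (t, 6), got {motion.shape}")
    d = np.diff(motion, axis=0)
    d[:, 3:] *= head_radius_mm
    return float(np.abs(d).sum(axis=1).mean()) if len(d) else 0.0
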
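"""Static and sliding-window ALFF and the dALFF coefficient-of-variation map.

ALFF (amplitude of low-frequency fluctuation) is the mean one-sided discrete
Fourier amplitude ``a_k = 2|X_k|/N`` of a voxel's time series over the bins
falling in a low-frequency band (default 0.01-0.08 Hz). mALFF divides the
map by its in-mask mean so the normalized map averages 1. The dynamic
variant computes ALFF in a sliding window (50 TRs long, step 1 TR by
default, so 176 retained TRs give 127 windows), normalizes each window's
map by that window's own global mean, and summarizes temporal variability
per voxel as the coefficient of variation CV = SD / mean across windows
(SD with the n-1 denominator).

The amplitude convention makes an exact-bin unit sinusoid have amplitude 1
at its bin; any fixed convention cancels in mALFF and CV.
"""

from __future__ import annotations

import logging

import numpy as np

from dalff.datatypes import BoldRun, FrequencyBand, ScalarMap, WindowSpec

__all__ = [
    "sliding_windows",
    "band_bins",
    "compute_alff",
    "alff_map",
    "normalize_global_mean",
    "dalff_cv_map",
]

logger = logging.getLogger(__name__)


def sliding_windows(n_timepoints: int, length_tr: int, step_tr: int) -> list[tuple[int, int]]:
    """Half-open [start, end) windows; count = floor((T-L)/step) + 1."""
    return WindowSpec(length_tr=length_tr, step_tr=step_tr, n_timepoints=n_timepoints).ranges()


def band_bins(n: int, tr_s: float, band: FrequencyBand) -> np.ndarray:
    """DFT bin indices k (1..floor(N/2)) with f_lo <= k/(N*tr) <= f_hi.

    Band edges are inclusive, with a tiny relative tolerance so that exact
    edge frequencies are not lost to floating-point rounding.
    """
    band.validate_against_tr(tr_s)
    k = np.arange(1, n // 2 + 1)
    f = k / (n * tr_s)
    tol = 1e-12 * max(1.0, band.f_hi)
    sel = k[(f >= band.f_lo - tol) & (f <= band.f_hi + tol)]
    if sel.size == 0:
        raise ValueError(
            f"no DFT bin inside band [{band.f_lo}, {band.f_hi}] Hz: "
            f"N={n}, TR={tr_s}s gives resolution {1.0 / (n * tr_s):.6g} Hz"
        )
    return sel


def _amplitude_in_band(series2d: np.ndarray, bins: np.ndarray) -> np.ndarray:
    """Mean one-sided amplitude 2|X_k|/N over band bins; series2d is (nvox, t)."""
    n = series2d.shape[-1]
    spec = np.fft.rfft(series2d, axis=-1)
    amp = 2.0 * np.abs(spec[..., bins]) / n
    return amp.mean(axis=-1)


def compute_alff(series: np.ndarray, tr_s: float, band: FrequencyBand) -> float:
    """ALFF of one time series: mean of a_k = 2|X_k|/N over in-band bins."""
    series = np.asarray(series, dtype=np.float64)
    if series.ndim != 1 or series.size < 2:
        raise ValueError("series must be 1D with >= 2 samples")
    if not np.all(np.isfinite(series)):
        raise ValueError("series contains non-finite values")
    bins = band_bins(series.size, tr_s, band)
    return float(_amplitude_in_band(series[None, :], bins)[0])


def alff_map(run: BoldRun, band: FrequencyBand, mask: np.ndarray) -> ScalarMap:
    """Voxelwise ALFF inside ``mask``; out-of-mask voxels set to 0."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != run.spatial_shape:
        raise ValueError(f"mask shape {mask.shape} != run shape {run.spatial_shape}")
    bins = band_bins(run.n_timepoints, run.tr_s, band)
    values = np.zeros(run.spatial_shape)
    values[mask] = _amplitude_in_band(run.data[mask], bins)
    return ScalarMap(values=values, mask=mask, affine=run.affine.copy(), kind="alff")


def normalize_global_mean(scalar_map: ScalarMap, mask: np.ndarray | None = None) -> ScalarMap:
    """Divide in-mask values by the in-mask mean, so the mALFF mean is 1."""
    mask = scalar_map.mask if mask is None else np.asarray(mask, dtype=bool)
    mean = scalar_map.values[mask].mean()
    if not mean > 0:
        raise ValueError(f"global mean must be positive to normalize, got {mean}")
    values = np.zeros_like(scalar_map.values)
    values[mask] = scalar_map.values[mask] / mean
    return ScalarMap(values=values, mask=mask, affine=scalar_map.affine.copy(), kind="malff")


def dalff_cv_map(
    run: BoldRun,
    window: WindowSpec,
    band: FrequencyBand,
    mask: np.ndarray,
    normalize: str = "window",
) -> ScalarMap:
    """dALFF coefficient-of-variation map across sliding windows.

    For each window, the windowed ALFF map is computed and divided by the
    window's own in-mask mean (``normalize="window"``, the default); with
    ``"static"`` every window is divided by the whole-run in-mask mean ALFF
    instead, and ``"none"`` skips normalization. Per voxel,
    CV = SD across windows / mean across windows (SD uses ddof=1). Voxels
    whose window-mean is not positive (possible only for identically zero
    series) get CV = 0 and are counted in the log.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != run.spatial_shape:
        raise ValueError(f"mask shape {mask.shape} != run shape {run.spatial_shape}")
    if window.n_timepoints != run.n_timepoints:
        raise ValueError(
            f"window spec is for T={window.n_timepoints} but run has T={run.n_timepoints}"
        )
    if window.n_windows < 2:
        raise ValueError(f"CV needs >= 2 windows, got {window.n_windows}")
    if normalize not in ("window", "static", "none"):
        raise ValueError(f"normalize must be window|static|none, got {normalize!r}")

    bins = band_bins(window.length_tr, run.tr_s, band)
    series = run.data[mask]  # (nvox, T)
    n_win = window.n_windows
    walff = np.empty((n_win, series.shape[0]))
    for i, (s, e) in enumerate(window.ranges()):
        walff[i] = _amplitude_in_band(series[:, s:e], bins)

    if normalize == "window":
        means = walff.mean(axis=1, keepdims=True)
        if np.any(means <= 0):
            raise ValueError("a window has nonpositive in-mask mean ALFF; cannot normalize")
        walff = walff / means
    elif normalize == "static":
        static = alff_map(run, band, mask).in_mask.mean()
        if not static > 0:
            raise ValueError("whole-run in-mask mean ALFF is nonpositive; cannot normalize")
        walff = walff / static

    mean_w = walff.mean(axis=0)
    sd_w = walff.std(axis=0, ddof=1)
    cv = np.zeros_like(mean_w)
    ok = mean_w > 0
    cv[ok] = sd_w[ok] / mean_w[ok]
    n_bad = int((~ok).sum())
    if n_bad:
        logger.info("dalff_cv_map: %d in-mask voxel(s) with nonpositive window-mean ALFF set to CV=0", n_bad)

    values = np.zeros(run.spatial_shape)
    values[mask] = cv
    return ScalarMap(values=values, mask=mask, affine=run.affine.copy(), kind="dalff_cv")
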
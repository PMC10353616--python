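"""Core in-memory containers shared across the pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["BoldRun", "WindowSpec", "FrequencyBand", "ScalarMap"]


@dataclass
class BoldRun:
    """One subject's 4D BOLD time series.

    Parameters
    ----------
    data : ndarray, shape (x, y, z, t)
        BOLD intensities in arbitrary units.
    tr_s : float
        Repetition time (sampling interval) in seconds.
    affine : ndarray, shape (4, 4)
        Voxel-to-world map in mm (RAS+).
    mask : ndarray of bool, shape (x, y, z), optional
        Analysis mask; spatial shape must match ``data``.
    """

    data: np.ndarray
    tr_s: float
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.data.ndim != 4:
            raise ValueError(f"BOLD data must be 4D (x,y,z,t); got shape {self.data.shape}")
        if self.n_timepoints < 2:
            raise ValueError("BOLD run needs at least 2 time points")
        if self.tr_s <= 0:
            raise ValueError(f"TR must be positive, got {self.tr_s}")
        if self.affine.shape != (4, 4) or abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine must be an invertible 4x4 matrix")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.spatial_shape:
                raise ValueError(
                    f"mask shape {self.mask.shape} != spatial shape {self.spatial_shape}"
                )

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[3]

    @property
    def voxel_size_mm(self) -> np.ndarray:
        """Axis voxel edge lengths (mm), from the affine's column norms."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    def copy_with(self, data: np.ndarray) -> "BoldRun":
        return BoldRun(data=data, tr_s=self.tr_s, affine=self.affine.copy(), mask=self.mask)


@dataclass(frozen=True)
class WindowSpec:
    """Sliding-window scheme over a time series of ``n_timepoints`` samples.

    ``n_windows`` is derived as floor((T - L) / step) + 1.
    """

    length_tr: int
    step_tr: int
    n_timepoints: int

    def __post_init__(self) -> None:
        if not (1 <= self.length_tr <= self.n_timepoints):
            raise ValueError(
                f"window length {self.length_tr} must be in [1, {self.n_timepoints}]"
            )
        if self.step_tr < 1:
            raise ValueError(f"window step must be >= 1, got {self.step_tr}")

    @property
    def n_windows(self) -> int:
        return (self.n_timepoints - self.length_tr) // self.step_tr + 1

    def ranges(self) -> list[tuple[int, int]]:
        """Half-open 0-based [start, end) index ranges of all windows."""
        return [
            (s, s + self.length_tr)
            for s in range(0, self.n_timepoints - self.length_tr + 1, self.step_tr)
        ]


@dataclass(frozen=True)
class FrequencyBand:
    """Low-frequency band of interest in Hz. Default 0.01-0.08 Hz."""

    f_lo: float = 0.01
    f_hi: float = 0.08

    def __post_init__(self) -> None:
        if not (0 < self.f_lo < self.f_hi):
            raise ValueError(f"need 0 < f_lo < f_hi, got ({self.f_lo}, {self.f_hi})")

    def validate_against_tr(self, tr_s: float) -> None:
        nyquist = 1.0 / (2.0 * tr_s)
        if self.f_hi > nyquist + 1e-12:
            raise ValueError(
                f"band upper edge {self.f_hi} Hz exceeds Nyquist {nyquist:.4f} Hz for TR={tr_s}s"
            )


@dataclass
class ScalarMap:
    """A 3D per-voxel scalar map (ALFF, mALFF, dALFF-CV, t or z statistic)."""

    KINDS = ("alff", "malff", "dalff_cv", "tstat", "zstat")

    values: np.ndarray
    mask: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    kind: str = "alff"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.mask = np.asarray(self.mask, dtype=bool)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError(f"map values must be 3D, got shape {self.values.shape}")
        if self.values.shape != self.mask.shape:
            raise ValueError(
                f"values shape {self.values.shape} != mask shape {self.mask.shape}"
            )
        if self.kind not in self.KINDS:
            raise ValueError(f"kind must be one of {self.KINDS}, got {self.kind!r}")
        if not np.all(np.isfinite(self.values[self.mask])):
            raise ValueError("map contains non-finite values inside mask")

    @property
    def in_mask(self) -> np.ndarray:
        """In-mask values as a flat vector (C scan order)."""
        return self.values[self.mask]

    def copy_with(self, values: np.ndarray, kind: str | None = None) -> "ScalarMap":
        return ScalarMap(
            values=values, mask=self.mask, affine=self.affine.copy(), kind=kind or self.kind
        )
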
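"""Pipeline configuration (YAML) and run manifests.

One flat human-readable file drives the whole pipeline; unknown keys are
errors (typo safety) and every violation is reported in a single pass.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from dalff.synthetic import CohortConfig, RoiSphere

__all__ = ["PipelineConfig", "RunManifest", "load_config", "save_config"]


@dataclass
class PreprocessConfig:
    drop_k: int = 10
    fwhm_mm: float = 6.0
    polynomial_degree: int = 0  # trend handled by the detrend step; 0 = intercept only


@dataclass
class AlffConfig:
    window_length: int = 50
    window_step: int = 1
    f_lo: float = 0.01
    f_hi: float = 0.08
    normalize: str = "window"  # window | static | none


@dataclass
class InferenceConfig:
    voxel_p: float = 0.05
    cluster_p: float = 0.05
    method: str = "grf"  # grf | perm
    n_perm: int = 1000
    connectivity: int = 26
    two_sided: bool = True


@dataclass
class ClinicalConfig:
    rois: list[str] = field(default_factory=list)  # empty = all cohort ROI masks
    scales: list[str] = field(default_factory=lambda: ["NIHSS", "WE_FMA", "UE_FMA", "LE_FMA", "BI"])


@dataclass
class SimulateConfig:
    n_patients: int = 34
    n_controls: int = 44
    grid_shape: list[int] = field(default_factory=lambda: [20, 24, 18])
    voxel_size_mm: list[float] = field(default_factory=lambda: [3.0, 3.0, 3.0])
    n_timepoints: int = 186
    tr_s: float = 2.0
    carrier_band_hz: list[float] = field(default_factory=lambda: [0.02, 0.06])
    modulation_depth_patient: float = 0.6
    modulation_depth_control: float = 0.0
    modulation_depth_heterogeneity: float = 0.6
    modulation_period_s: float = 150.0
    noise_sd: float = 0.12
    ar1_coef: float = 0.3
    effect_rois: list[dict] = field(
        default_factory=lambda: [{"center_voxel": [14, 16, 6], "radius_mm": 9.0, "label": "rectus_r"}]
    )

    def to_cohort_config(self, seed: int) -> CohortConfig:
        rois = [RoiSphere(center_voxel=tuple(r["center_voxel"]),
                          radius_mm=float(r["radius_mm"]), label=str(r["label"]))
                for r in self.effect_rois]
        return CohortConfig(
            n_patients=self.n_patients, n_controls=self.n_controls,
            grid_shape=tuple(self.grid_shape), voxel_size_mm=tuple(self.voxel_size_mm),
            n_timepoints=self.n_timepoints, tr_s=self.tr_s,
            carrier_band_hz=tuple(self.carrier_band_hz),
            modulation_depth_patient=self.modulation_depth_patient,
            modulation_depth_control=self.modulation_depth_control,
            modulation_depth_heterogeneity=self.modulation_depth_heterogeneity,
            modulation_period_s=self.modulation_period_s,
            noise_sd=self.noise_sd, ar1_coef=self.ar1_coef,
            effect_rois=rois, seed=seed,
        )


@dataclass
class PipelineConfig:
    out_dir: str = "dalff_out"
    in_dir: str | None = None  # existing cohort directory; None = simulate
    seed: int = 0
    simulate: SimulateConfig = field(default_factory=SimulateConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    alff: AlffConfig = field(default_factory=AlffConfig)
    inference: InferenceConfig = field(default_factory=InferenceConfig)
    clinical: ClinicalConfig = field(default_factory=ClinicalConfig)

    def validate(self) -> None:
        errors = []
        if self.preprocess.drop_k < 0:
            errors.append("preprocess.drop_k must be >= 0")
        if self.preprocess.fwhm_mm < 0:
            errors.append("preprocess.fwhm_mm must be >= 0")
        if not 0 < self.alff.f_lo < self.alff.f_hi:
            errors.append(f"alff band requires 0 < f_lo < f_hi, got ({self.alff.f_lo}, {self.alff.f_hi})")
        if self.alff.window_length < 1 or self.alff.window_step < 1:
            errors.append("alff window length and step must be >= 1")
        if self.alff.normalize not in ("window", "static", "none"):
            errors.append(f"alff.normalize must be window|static|none, got {self.alff.normalize!r}")
        for name in ("voxel_p", "cluster_p"):
            v = getattr(self.inference, name)
            if not 0 < v < 1:
                errors.append(f"inference.{name} must lie in (0, 1), got {v}")
        if self.inference.method not in ("grf", "perm"):
            errors.append(f"inference.method must be grf|perm, got {self.inference.method!r}")
        if self.inference.connectivity not in (6, 18, 26):
            errors.append(f"inference.connectivity must be 6, 18 or 26, got {self.inference.connectivity}")
        if self.inference.n_perm < 100:
            errors.append("inference.n_perm must be >= 100")
        if errors:
            raise ValueError("invalid pipeline config:\n  - " + "\n  - ".join(errors))

    def to_dict(self) -> dict:
        return asdict(self)


_BLOCKS = {"simulate": SimulateConfig, "preprocess": PreprocessConfig,
           "alff": AlffConfig, "inference": InferenceConfig, "clinical": ClinicalConfig}


def _build(cls, data: dict, prefix: str, errors: list):
    known = {f.name for f in fields(cls)}
    unknown = set(data) - known
    if unknown:
        errors.append(f"unknown key(s) under {prefix or 'top level'}: {sorted(unknown)}")
    kwargs = {k: v for k, v in data.items() if k in known}
    return cls(**kwargs)


def load_config(path) -> PipelineConfig:
    """Load and validate a pipeline config; all schema errors reported at once."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping")
    errors: list[str] = []
    top_known = {f.name for f in fields(PipelineConfig)}
    unknown = set(raw) - top_known
    if unknown:
        errors.append(f"unknown top-level key(s): {sorted(unknown)}")
    kwargs = {}
    for name, cls in _BLOCKS.items():
        block = raw.get(name, {})
        if not isinstance(block, dict):
            errors.append(f"{name} must be a mapping")
            block = {}
        kwargs[name] = _build(cls, block, name, errors)
    for key in ("out_dir", "in_dir", "seed"):
        if key in raw:
            kwargs[key] = raw[key]
    cfg = PipelineConfig(**kwargs)
    try:
        cfg.validate()
    except ValueError as exc:
        errors.append(str(exc))
    if errors:
        raise ValueError(f"{path}: " + "; ".join(errors))
    return cfg


def save_config(cfg: PipelineConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=False)


@dataclass
class RunManifest:
    """Record of one pipeline run, sufficient to re-execute deterministically."""

    config: dict
    version: str
    seed: int
    checksums: dict[str, str] = field(default_factory=dict)
    started: str = ""
    finished: str = ""

    @staticmethod
    def sha256(path) -> str:
        h = hashlib.sha256()
        with open(path, "rb") as fh:
            for chunk in iter(lambda: fh.read(1 << 20), b""):
                h.update(chunk)
        return h.hexdigest()

    def add_file(self, name: str, path) -> None:
        self.checksums[name] = self.sha256(path)

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)

    @classmethod
    def start(cls, cfg: PipelineConfig, version: str) -> "RunManifest":
        return cls(config=cfg.to_dict(), version=version, seed=cfg.seed,
                   started=time.strftime("%Y-%m-%dT%H:%M:%S"))
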
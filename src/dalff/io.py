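"""NIfTI-1 and TSV input/output for runs, maps and cohort bundles."""

from __future__ import annotations

import logging
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from dalff.datatypes import BoldRun, ScalarMap
from dalff.preprocess import RegressorSet
from dalff.synthetic import CohortBundle

__all__ = ["read_volume", "write_volume", "read_regressors", "write_regressors", "save_cohort"]

logger = logging.getLogger(__name__)


def read_volume(path, tr_s: float | None = None, kind: str = "alff"):
    """Read a NIfTI-1 file: 4D -> :class:`BoldRun`, 3D -> :class:`ScalarMap`.

    For runs the TR is taken from the header's 4th zoom; when absent or
    zero it falls back to ``tr_s`` with a logged warning. Plain ``.nii``
    and gzipped ``.nii.gz`` are both accepted.
    """
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), dtype=np.float64)
    affine = np.asarray(img.affine, dtype=np.float64)
    if data.ndim == 4:
        zooms = img.header.get_zooms()
        tr = float(zooms[3]) if len(zooms) > 3 else 0.0
        time_units = img.header.get_xyzt_units()[1]
        if time_units == "unknown" or tr <= 0:  # TR not recorded in header
            if tr_s is None:
                raise ValueError(f"{path}: TR missing from header and no fallback given")
            logger.warning("%s: TR missing from header; using configured %g s", path, tr_s)
            tr = float(tr_s)
        return BoldRun(data=data, tr_s=tr, affine=affine)
    if data.ndim == 3:
        return ScalarMap(values=data, mask=np.ones(data.shape, dtype=bool),
                         affine=affine, kind=kind)
    raise ValueError(f"{path}: expected a 3D map or 4D run, got {data.ndim}D data")


def write_volume(obj, path) -> None:
    """Write a BoldRun, ScalarMap or bare binary mask to NIfTI-1."""
    path = str(path)
    if isinstance(obj, BoldRun):
        img = nib.Nifti1Image(obj.data.astype(np.float32), obj.affine)
        zooms = (*np.linalg.norm(obj.affine[:3, :3], axis=0), obj.tr_s)
        img.header.set_zooms(zooms)
        img.header.set_xyzt_units("mm", "sec")
    elif isinstance(obj, ScalarMap):
        img = nib.Nifti1Image(obj.values.astype(np.float32), obj.affine)
    else:
        arr = np.asarray(obj)
        img = nib.Nifti1Image(arr.astype(np.uint8 if arr.dtype == bool else np.float32), np.eye(4))
    nib.save(img, path)


def write_regressors(regs: RegressorSet, path) -> None:
    pd.DataFrame(regs.matrix, columns=regs.names).to_csv(path, sep="\t", index=False)


def read_regressors(path) -> RegressorSet:
    df = pd.read_csv(path, sep="\t")
    return RegressorSet(matrix=df.to_numpy(dtype=np.float64), names=list(df.columns))


def save_cohort(bundle: CohortBundle, out_dir) -> dict[str, str]:
    """Write a cohort to disk: per-subject runs and regressors, masks,
    participants.tsv and clinical.tsv. Returns {relative name: path}."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, str] = {}

    def _put(name, fn):
        p = out / name
        fn(p)
        written[name] = str(p)

    aff = bundle.config.affine
    _put("brain_mask.nii.gz", lambda p: nib.save(
        nib.Nifti1Image(bundle.brain_mask.astype(np.uint8), aff), str(p)))
    for label, m in bundle.roi_masks.items():
        _put(f"roi_{label}.nii.gz", lambda p, m=m: nib.save(
            nib.Nifti1Image(m.astype(np.uint8), aff), str(p)))
    for sid, run, regs in zip(bundle.participants["subject_id"], bundle.runs, bundle.regressors):
        _put(f"{sid}_bold.nii.gz", lambda p, run=run: write_volume(run, p))
        _put(f"{sid}_regressors.tsv", lambda p, regs=regs: write_regressors(regs, p))
    _put("participants.tsv", lambda p: bundle.participants.to_csv(p, sep="\t", index=False))
    _put("clinical.tsv", lambda p: bundle.clinical.to_csv(p, sep="\t", index=False))
    return written
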
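"""Voxelwise covariate-adjusted group inference with cluster correction.

The model is a per-voxel ordinary least squares fit of a subject-level
scalar map (here the dALFF-CV map) on ``[intercept, group, age, sex,
education]``, with the two-sample contrast on the group column. The
suprathreshold topology of the resulting t field is corrected for multiple
comparisons either by Gaussian-random-field (GRF) theory — cluster-level
p-values from the expected Euler characteristic and the exponential
cluster-extent approximation for a 3D Gaussian field — or by a
Freedman-Lane permutation scheme whose maximum-cluster-size null
distribution provides exact FWER control and serves as the ground-truth
oracle for the GRF path.

Usage follows the Model/Results convention::

    model = VoxelwiseGroupModel.from_dataframe(cv_maps, participants)
    res = model.fit()
    table = res.grf_clusters(voxel_p=0.05, cluster_p=0.05)
    print(res.summary())
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from dalff.datatypes import ScalarMap

__all__ = [
    "GroupDesign",
    "VoxelwiseGroupModel",
    "GroupGLMResults",
    "SmoothnessEstimate",
    "ClusterTable",
    "fit_voxelwise_glm",
    "t_to_z",
    "estimate_smoothness",
    "label_clusters",
    "grf_cluster_inference",
    "permutation_cluster_inference",
    "report_cluster_table",
]

logger = logging.getLogger(__name__)

_4LN2 = 4.0 * np.log(2.0)


# --------------------------------------------------------------------------
# design
# --------------------------------------------------------------------------

@dataclass
class GroupDesign:
    """Two-sample design with optional nuisance covariates.

    ``group`` codes patients as 1 and controls as 0. Covariates (age, sex,
    education by convention, but any numeric columns are accepted) are
    mean-centered so the group coefficient is the adjusted group difference
    at covariate means.
    """

    subject_ids: list[str]
    group: np.ndarray
    covariates: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.group = np.asarray(self.group, dtype=np.float64)
        n = len(self.subject_ids)
        if self.group.shape != (n,):
            raise ValueError(f"group must have one entry per subject ({n})")
        if not set(np.unique(self.group)) <= {0.0, 1.0}:
            raise ValueError("group must be coded 0 (control) / 1 (patient)")
        if self.group.sum() == 0 or self.group.sum() == n:
            raise ValueError("both groups must be nonempty")
        if self.covariates is not None:
            if len(self.covariates) != n:
                raise ValueError("covariate rows must match subject count")
            if not np.all(np.isfinite(self.covariates.to_numpy(dtype=float))):
                raise ValueError("covariates contain non-finite values")
        X = self.matrix
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError("design matrix [intercept|group|covariates] is rank deficient")

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def column_names(self) -> list[str]:
        cols = ["intercept", "group"]
        if self.covariates is not None:
            cols += list(self.covariates.columns)
        return cols

    @property
    def matrix(self) -> np.ndarray:
        """Design matrix [intercept | group | mean-centered covariates]."""
        cols = [np.ones(self.n_subjects), self.group]
        if self.covariates is not None:
            C = self.covariates.to_numpy(dtype=np.float64)
            cols.extend((C - C.mean(axis=0)).T)
        return np.column_stack(cols)

    @property
    def contrast(self) -> np.ndarray:
        c = np.zeros(len(self.column_names))
        c[1] = 1.0
        return c

    @classmethod
    def from_dataframe(
        cls,
        participants: pd.DataFrame,
        group_col: str = "group",
        patient_label: str = "patient",
        covariate_cols: tuple[str, ...] = ("age", "sex", "education"),
        id_col: str = "subject_id",
    ) -> "GroupDesign":
        ids = [str(s) for s in participants[id_col]]
        grp = (participants[group_col] == patient_label).to_numpy(dtype=np.float64)
        cov_cols = [c for c in covariate_cols if c in participants.columns]
        cov = participants[cov_cols].astype(float).reset_index(drop=True) if cov_cols else None
        return cls(subject_ids=ids, group=grp, covariates=cov)


# --------------------------------------------------------------------------
# smoothness / cluster containers
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SmoothnessEstimate:
    """Estimated field smoothness: per-axis FWHM (mm) and resel count."""

    fwhm_mm: tuple[float, float, float]
    resels: float
    n_mask_voxels: int


@dataclass
class ClusterTable:
    """Significant clusters with size, peak statistic and world coordinates.

    ``frame`` holds one row per cluster, sorted by size descending with
    ties broken by peak statistic magnitude then coordinates. Cluster
    voxel masks are retained in ``cluster_masks`` (same order) for ROI
    overlap labeling.
    """

    frame: pd.DataFrame
    method: str
    cluster_masks: list[np.ndarray] = field(default_factory=list)

    COLUMNS = ["label", "size_voxels", "peak_stat", "peak_x_mm", "peak_y_mm",
               "peak_z_mm", "cluster_p", "tail"]

    def __len__(self) -> int:
        return len(self.frame)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# cluster-level inference method: {self.method}\n")
            fh.write("# coordinates are world-space mm (affine-mapped peak voxel)\n")
            self.frame.to_csv(fh, sep="\t", index=False)

    @staticmethod
    def _sorted(frame: pd.DataFrame, masks: list[np.ndarray]):
        if len(frame) == 0:
            return frame, masks
        order = frame.assign(_abs=frame["peak_stat"].abs()).sort_values(
            by=["size_voxels", "_abs", "peak_x_mm", "peak_y_mm", "peak_z_mm"],
            ascending=[False, False, True, True, True],
            kind="mergesort",
        ).index
        return (frame.loc[order].reset_index(drop=True), [masks[i] for i in order])


# --------------------------------------------------------------------------
# elementary operations
# --------------------------------------------------------------------------

def t_to_z(t, df: float):
    """Map t statistics to z scores via the quantile transform.

    z = Phi^{-1}(F_t(t; df)), computed tail-symmetrically (survival
    functions on the matching side) so large |t| stay finite and
    sign(z) = sign(t). Non-finite t propagate as NaN with a warning.
    """
    if df < 1:
        raise ValueError(f"df must be >= 1, got {df}")
    t = np.asarray(t, dtype=np.float64)
    scalar = t.ndim == 0
    t = np.atleast_1d(t)
    z = np.full_like(t, np.nan)
    finite = np.isfinite(t)
    if not finite.all():
        logger.warning("t_to_z: %d non-finite t value(s) propagated as NaN", (~finite).sum())
    ta = np.abs(t[finite])
    z[finite] = np.sign(t[finite]) * stats.norm.isf(stats.t.sf(ta, df))
    return float(z[0]) if scalar else z


def estimate_smoothness(residual_maps, mask, voxel_size_mm) -> SmoothnessEstimate:
    """Spatial smoothness of the error field from standardized residuals.

    Residuals are normalized per voxel to unit sum of squares across
    subjects; per axis, lambda_i is the average over in-mask neighbor pairs
    of the squared normalized first difference, and
    FWHM_i = voxel_size_i * sqrt(4 ln 2 / lambda_i). The resel count is
    mask volume divided by the product of the FWHMs.
    """
    R = np.asarray(residual_maps, dtype=np.float64)
    if R.ndim != 4:
        raise ValueError("residual_maps must be (n_subjects, x, y, z)")
    if R.shape[0] < 3:
        raise ValueError("need >= 3 residual maps to estimate smoothness")
    mask = np.asarray(mask, dtype=bool)
    vs = np.broadcast_to(np.asarray(voxel_size_mm, dtype=np.float64), (3,))

    ssq = np.einsum("sxyz,sxyz->xyz", R, R)
    if np.any(ssq[mask] <= 0):
        raise ValueError("zero-variance residuals inside mask; smoothness undefined")
    norm = np.zeros_like(R)
    norm[:, mask] = R[:, mask] / np.sqrt(ssq[mask])

    fwhm = np.empty(3)
    for ax in range(3):
        sl_hi = [slice(None)] * 3
        sl_lo = [slice(None)] * 3
        sl_hi[ax] = slice(1, None)
        sl_lo[ax] = slice(None, -1)
        pair = mask[tuple(sl_hi)] & mask[tuple(sl_lo)]
        if not pair.any():
            raise ValueError(f"mask has no interior neighbor pairs along axis {ax}")
        diff = norm[(slice(None), *sl_hi)] - norm[(slice(None), *sl_lo)]
        lam = float(np.einsum("sxyz,sxyz->xyz", diff, diff)[pair].mean())
        lam = max(lam, 1e-12)
        fwhm[ax] = vs[ax] * math.sqrt(_4LN2 / lam)

    n_vox = int(mask.sum())
    resels = n_vox * float(np.prod(vs)) / float(np.prod(fwhm))
    return SmoothnessEstimate(fwhm_mm=tuple(fwhm), resels=resels, n_mask_voxels=n_vox)


_STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


def label_clusters(binary_map: np.ndarray, connectivity: int = 26):
    """Connected components of a binary 3D map.

    Returns ``(labels, sizes)`` where labels is an int array (0 =
    background, clusters numbered 1..k in deterministic scan order) and
    sizes[i] is the voxel count of cluster i+1.
    """
    if connectivity not in _STRUCTURES:
        raise ValueError(f"connectivity must be one of {sorted(_STRUCTURES)}, got {connectivity}")
    binary_map = np.asarray(binary_map, dtype=bool)
    labels, k = ndimage.label(binary_map, structure=_STRUCTURES[connectivity])
    sizes = np.bincount(labels.ravel(), minlength=k + 1)[1:]
    return labels, sizes


# --------------------------------------------------------------------------
# GRF cluster-level p-values
# --------------------------------------------------------------------------

def _ec_density_3d(u: float) -> float:
    """Expected Euler characteristic per resel of a 3D Gaussian field at z=u."""
    return (_4LN2 ** 1.5) / (2.0 * np.pi) ** 2 * (u * u - 1.0) * math.exp(-u * u / 2.0)


def _grf_cluster_p(k_voxels: int, u: float, smoothness: SmoothnessEstimate) -> float:
    """Corrected cluster-level p for a cluster of ``k_voxels`` at threshold u.

    Uses E[m] = resels * EC density (expected cluster count), the expected
    suprathreshold volume E[N] = |mask| * P(Z > u), and the exponential
    extent tail P(n >= k) = exp(-beta k^{2/3}) with
    beta = (Gamma(5/2) * E[m] / E[N])^{2/3}; the corrected p is
    1 - exp(-E[m] * P(n >= k)).
    """
    em = max(smoothness.resels * _ec_density_3d(u), 1e-300)
    en = smoothness.n_mask_voxels * stats.norm.sf(u)
    if en <= 0:
        return 1.0
    beta = (math.gamma(2.5) * em / en) ** (2.0 / 3.0)
    p_extent = math.exp(-beta * k_voxels ** (2.0 / 3.0))
    return float(-math.expm1(-em * p_extent))


def _extract_clusters(statvals, zvals, mask, affine, threshold_z, tail, connectivity):
    """Threshold one tail of the z field and return per-cluster records."""
    sign = 1.0 if tail == "positive" else -1.0
    excursion = (sign * zvals > threshold_z) & mask
    labels, sizes = label_clusters(excursion, connectivity)
    records, masks = [], []
    for ci, size in enumerate(sizes, start=1):
        cmask = labels == ci
        stat_in = np.where(cmask, sign * statvals, -np.inf)
        peak_idx = np.unravel_index(np.argmax(stat_in), stat_in.shape)
        peak_stat = float(statvals[peak_idx])
        world = affine @ np.array([*peak_idx, 1.0])
        records.append(
            {"label": "", "size_voxels": int(size), "peak_stat": peak_stat,
             "peak_x_mm": float(world[0]), "peak_y_mm": float(world[1]),
             "peak_z_mm": float(world[2]), "tail": tail}
        )
        masks.append(cmask)
    return records, masks


def grf_cluster_inference(
    results: "GroupGLMResults",
    smoothness: SmoothnessEstimate | None = None,
    voxel_p: float = 0.05,
    cluster_p: float = 0.05,
    two_sided: bool = True,
    connectivity: int = 26,
) -> ClusterTable:
    """GRF-corrected cluster table from a fitted voxelwise GLM.

    The z field is thresholded at u = Phi^{-1}(1 - voxel_p) (voxel_p halved
    per tail when two-sided); clusters are retained when their GRF
    cluster-level p-value is below ``cluster_p``.
    """
    if not (0 < voxel_p < 1 and 0 < cluster_p < 1):
        raise ValueError("voxel_p and cluster_p must lie in (0, 1)")
    if smoothness is None:
        smoothness = results.smoothness()
    p_tail = voxel_p / 2.0 if two_sided else voxel_p
    u = float(stats.norm.isf(p_tail))
    if u <= 0:
        raise ValueError(f"voxel threshold u = {u:.3f} <= 0 is not supported by GRF")
    tails = ("positive", "negative") if two_sided else ("positive",)
    records, masks = [], []
    for tail in tails:
        recs, ms = _extract_clusters(
            results.tmap.values, results.zmap.values, results.mask,
            results.affine, u, tail, connectivity,
        )
        for r, m in zip(recs, ms):
            r["cluster_p"] = _grf_cluster_p(r["size_voxels"], u, smoothness)
            if r["cluster_p"] < cluster_p:
                records.append(r)
                masks.append(m)
    frame = pd.DataFrame(records, columns=ClusterTable.COLUMNS)
    frame, masks = ClusterTable._sorted(frame, masks)
    return ClusterTable(frame=frame, method="grf", cluster_masks=masks)


# --------------------------------------------------------------------------
# permutation cluster inference (Freedman-Lane)
# --------------------------------------------------------------------------

def permutation_cluster_inference(
    results: "GroupGLMResults",
    voxel_p: float = 0.05,
    cluster_p: float = 0.05,
    n_perm: int = 1000,
    seed: int = 0,
    connectivity: int = 26,
    two_sided: bool = True,
) -> ClusterTable:
    """Permutation (max cluster size) cluster-level inference.

    Freedman-Lane scheme: the data are residualized against the reduced
    model (intercept + covariates), the residual rows are permuted, the
    reduced-model fit is added back and the full model refitted; the
    maximum suprathreshold cluster size over both tails per permutation
    forms the null distribution. Cluster p-values are
    (1 + #{perm max >= k}) / (1 + n_perm) and therefore never zero.
    """
    if n_perm < 100:
        raise ValueError(f"n_perm must be >= 100, got {n_perm}")
    if not (0 < voxel_p < 1 and 0 < cluster_p < 1):
        raise ValueError("voxel_p and cluster_p must lie in (0, 1)")
    model = results.model
    X = model.design.matrix
    c = model.design.contrast
    n = X.shape[0]
    Y = model._Y  # (n, nvox) in-mask data
    df = results.df
    p_tail = voxel_p / 2.0 if two_sided else voxel_p
    t_u = float(stats.t.isf(p_tail, df))
    z_u = float(stats.norm.isf(p_tail))

    # observed clusters at the same per-tail threshold
    tails = ("positive", "negative") if two_sided else ("positive",)
    records, masks = [], []
    for tail in tails:
        recs, ms = _extract_clusters(
            results.tmap.values, results.tmap.values, results.mask,
            results.affine, t_u, tail, connectivity,
        )
        records.extend(recs)
        masks.extend(ms)

    # reduced model: everything but the contrast column
    reduced_cols = np.where(c == 0)[0]
    Z = X[:, reduced_cols]
    HZ = Z @ np.linalg.pinv(Z)
    fitted_reduced = HZ @ Y
    E = Y - fitted_reduced

    rng = np.random.default_rng(seed)
    total = math.factorial(n)
    if total <= n_perm:
        logger.warning(
            "only %d distinct relabelings available (< n_perm=%d); enumerating exactly",
            total, n_perm,
        )
        perms = [np.array(p) for p in itertools.permutations(range(n))]
    else:
        perms = [rng.permutation(n) for _ in range(n_perm)]

    pinvX = np.linalg.pinv(X)
    xtx_inv_cc = float(c @ np.linalg.inv(X.T @ X) @ c)
    struct = _STRUCTURES[connectivity]
    shape = results.mask.shape
    maxes = np.zeros(len(perms), dtype=np.int64)
    tvol = np.zeros(shape)
    for i, perm in enumerate(perms):
        Ystar = fitted_reduced + E[perm]
        beta = pinvX @ Ystar
        resid = Ystar - X @ beta
        sigma2 = np.einsum("ij,ij->j", resid, resid) / df
        se = np.sqrt(xtx_inv_cc * sigma2)
        tstar = np.divide(c @ beta, se, out=np.zeros_like(se), where=se > 0)
        best = 0
        tvol[results.mask] = tstar
        for sign in (1.0, -1.0) if two_sided else (1.0,):
            supra = (sign * tvol > t_u) & results.mask
            if supra.any():
                lab, k = ndimage.label(supra, structure=struct)
                if k:
                    best = max(best, int(np.bincount(lab.ravel())[1:].max()))
        maxes[i] = best
        tvol[results.mask] = 0.0

    kept_records, kept_masks = [], []
    for r, m in zip(records, masks):
        p = (1.0 + np.sum(maxes >= r["size_voxels"])) / (1.0 + len(perms))
        r["cluster_p"] = float(p)
        if p < cluster_p:
            kept_records.append(r)
            kept_masks.append(m)
    frame = pd.DataFrame(kept_records, columns=ClusterTable.COLUMNS)
    frame, kept_masks = ClusterTable._sorted(frame, kept_masks)
    table = ClusterTable(frame=frame, method="permutation", cluster_masks=kept_masks)
    table.null_max_sizes = maxes  # retained for FWER diagnostics
    table.threshold_t = t_u
    table.threshold_z = z_u
    return table


def report_cluster_table(table: ClusterTable, roi_masks: dict[str, np.ndarray] | None = None):
    """Finished report frame: ROI labels by maximal overlap, size-sorted rows."""
    frame = table.frame.copy()
    if roi_masks and len(frame):
        for i, cmask in enumerate(table.cluster_masks):
            best_name, best_ov = "", 0
            for name, rmask in roi_masks.items():
                ov = int((cmask & np.asarray(rmask, dtype=bool)).sum())
                if ov > best_ov:
                    best_name, best_ov = name, ov
            frame.loc[i, "label"] = best_name
    return frame


# --------------------------------------------------------------------------
# Model / Results
# --------------------------------------------------------------------------

class VoxelwiseGroupModel:
    """Per-voxel OLS of subject maps on a two-sample design with covariates.

    Parameters
    ----------
    maps : sequence of ScalarMap
        One map per subject, identical mask and affine, ordered as the
        design rows.
    design : GroupDesign
    """

    def __init__(self, maps, design: GroupDesign):
        maps = list(maps)
        if len(maps) != design.n_subjects:
            raise ValueError(f"{len(maps)} maps but design has {design.n_subjects} subjects")
        ref = maps[0]
        for m in maps[1:]:
            if m.values.shape != ref.values.shape or not np.array_equal(m.mask, ref.mask):
                raise ValueError("all subject maps must share geometry and mask")
        X = design.matrix
        if X.shape[0] <= X.shape[1]:
            raise ValueError(
                f"n={X.shape[0]} subjects <= p={X.shape[1]} design columns; GLM underdetermined"
            )
        self.design = design
        self.mask = ref.mask
        self.affine = ref.affine
        self.voxel_size_mm = np.linalg.norm(ref.affine[:3, :3], axis=0)
        self._Y = np.stack([m.in_mask for m in maps])  # (n, nvox)

    @classmethod
    def from_dataframe(
        cls,
        maps,
        participants: pd.DataFrame,
        group_col: str = "group",
        patient_label: str = "patient",
        covariate_cols: tuple[str, ...] = ("age", "sex", "education"),
        id_col: str = "subject_id",
    ) -> "VoxelwiseGroupModel":
        design = GroupDesign.from_dataframe(
            participants, group_col=group_col, patient_label=patient_label,
            covariate_cols=covariate_cols, id_col=id_col,
        )
        return cls(maps, design)

    def fit(self) -> "GroupGLMResults":
        X = self.design.matrix
        c = self.design.contrast
        n, p = X.shape
        df = n - p
        beta = np.linalg.pinv(X) @ self._Y
        resid = self._Y - X @ beta
        sigma2 = np.einsum("ij,ij->j", resid, resid) / df
        cxx = float(c @ np.linalg.inv(X.T @ X) @ c)
        # voxels fit exactly (e.g. identical values across subjects) get t = 0
        # rather than 0/0 noise; detect via variance relative to data scale
        scale = np.einsum("ij,ij->j", self._Y, self._Y) / n
        degenerate = sigma2 <= scale * 1e-24 + 1e-300
        sigma2 = np.where(degenerate, 0.0, sigma2)
        se = np.sqrt(cxx * sigma2)
        tvals = np.divide(c @ beta, se, out=np.zeros_like(se), where=se > 0)
        sd = np.sqrt(sigma2)
        std_resid = np.divide(resid, sd, out=np.zeros_like(resid), where=sd > 0)
        return GroupGLMResults(model=self, beta=beta, tvalues_flat=tvals, df=df,
                               std_resid_flat=std_resid)


class GroupGLMResults:
    """Fitted voxelwise two-sample GLM: t/z fields, residuals, inference."""

    def __init__(self, model, beta, tvalues_flat, df, std_resid_flat):
        self.model = model
        self.beta = beta
        self.df = int(df)
        self.mask = model.mask
        self.affine = model.affine
        shape = self.mask.shape
        tvol = np.zeros(shape)
        tvol[self.mask] = tvalues_flat
        self.tmap = ScalarMap(values=tvol, mask=self.mask, affine=self.affine, kind="tstat")
        zvol = np.zeros(shape)
        zvol[self.mask] = t_to_z(tvalues_flat, self.df)
        self.zmap = ScalarMap(values=zvol, mask=self.mask, affine=self.affine, kind="zstat")
        n = std_resid_flat.shape[0]
        self.residual_maps = np.zeros((n, *shape))
        self.residual_maps[:, self.mask] = std_resid_flat
        self._smoothness: SmoothnessEstimate | None = None

    @property
    def tvalues(self) -> ScalarMap:
        return self.tmap

    @property
    def zvalues(self) -> ScalarMap:
        return self.zmap

    def smoothness(self) -> SmoothnessEstimate:
        if self._smoothness is None:
            self._smoothness = estimate_smoothness(
                self.residual_maps, self.mask, self.model.voxel_size_mm
            )
        return self._smoothness

    def grf_clusters(self, voxel_p=0.05, cluster_p=0.05, two_sided=True,
                     connectivity=26) -> ClusterTable:
        return grf_cluster_inference(self, self.smoothness(), voxel_p=voxel_p,
                                     cluster_p=cluster_p, two_sided=two_sided,
                                     connectivity=connectivity)

    def permutation_clusters(self, voxel_p=0.05, cluster_p=0.05, n_perm=1000,
                             seed=0, connectivity=26, two_sided=True) -> ClusterTable:
        return permutation_cluster_inference(
            self, voxel_p=voxel_p, cluster_p=cluster_p, n_perm=n_perm,
            seed=seed, connectivity=connectivity, two_sided=two_sided,
        )

    def summary(self) -> str:
        d = self.model.design
        sm = self.smoothness()
        tv = self.tmap.in_mask
        lines = [
            "Voxelwise two-sample GLM (OLS per voxel)",
            "=" * 46,
            f"subjects:       {d.n_subjects} ({int(d.group.sum())} patients, "
            f"{int(d.n_subjects - d.group.sum())} controls)",
            f"design columns: {', '.join(d.column_names)}",
            f"residual df:    {self.df}",
            f"mask voxels:    {int(self.mask.sum())}",
            f"t range:        [{tv.min():.3f}, {tv.max():.3f}]",
            f"est. FWHM (mm): ({sm.fwhm_mm[0]:.2f}, {sm.fwhm_mm[1]:.2f}, {sm.fwhm_mm[2]:.2f})",
            f"resels:         {sm.resels:.1f}",
        ]
        return "\n".join(lines)


def fit_voxelwise_glm(maps, design: GroupDesign) -> GroupGLMResults:
    """Functional wrapper: build and fit :class:`VoxelwiseGroupModel`."""
    return VoxelwiseGroupModel(maps, design).fit()
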
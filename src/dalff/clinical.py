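"""Clinical-scale association and demographics statistics.

ROI-mean extraction from subject CV maps, Spearman rank correlation with
clinical scales (NIHSS, Barthel Index, Fugl-Meyer subscores), ROC/AUC
discrimination between patients and controls, and the demographics table
statistics (pooled two-sample t for continuous variables, Pearson
chi-square without continuity correction for sex).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_curve

__all__ = [
    "extract_roi_means",
    "spearman",
    "roc_auc",
    "two_sample_t_pooled",
    "chi_square_2x2",
    "demographics_report",
    "correlation_table",
]


def extract_roi_means(cv_maps, roi_mask: np.ndarray) -> np.ndarray:
    """Per-subject arithmetic mean of in-ROI map values.

    The ROI must be nonempty and contained in each map's analysis mask.
    """
    roi = np.asarray(roi_mask, dtype=bool)
    if not roi.any():
        raise ValueError("ROI mask is empty")
    out = np.empty(len(cv_maps))
    for i, m in enumerate(cv_maps):
        if np.any(roi & ~m.mask):
            raise ValueError("ROI extends outside the analysis mask")
        out[i] = float(m.values[roi].mean())
    return out


def spearman(x, y, exact: bool = False) -> tuple[float, float]:
    """Spearman rank correlation with two-sided p.

    rho is the Pearson correlation of average-ranked data (ties get average
    ranks); p comes from the t approximation
    t = rho * sqrt((n-2) / (1-rho^2)) by default, or from exact permutation
    enumeration when ``exact=True`` (intended for n <= 10).
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1D of equal length")
    if x.size < 4:
        raise ValueError(f"need n >= 4, got {x.size}")
    rx, ry = stats.rankdata(x), stats.rankdata(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        raise ValueError("zero variance in ranks; Spearman correlation undefined")
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if exact:
        if x.size > 8:
            raise ValueError("exact permutation p supported only for n <= 8")
        from itertools import permutations

        rxc = rx - rx.mean()
        ryc = ry - ry.mean()
        obs = abs(float(rxc @ ryc))
        count = total = 0
        for perm in permutations(range(x.size)):
            count += abs(float(rxc @ ryc[list(perm)])) >= obs - 1e-9
            total += 1
        return rho, count / total
    n = x.size
    if abs(rho) >= 1.0:
        return float(np.sign(rho)), 0.0
    t = rho * np.sqrt((n - 2) / (1.0 - rho * rho))
    p = float(2.0 * stats.t.sf(abs(t), n - 2))
    return rho, p


def roc_auc(scores, labels) -> tuple[float, pd.DataFrame]:
    """ROC curve and AUC for separating the positive class by score.

    AUC is the Mann-Whitney probability that a random positive outscores a
    random negative, with ties credited 0.5. Returns ``(auc, curve)`` where
    curve has columns threshold/fpr/tpr at every distinct score threshold.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels).astype(int)
    if set(np.unique(labels)) != {0, 1}:
        raise ValueError("labels must contain both classes, coded 0/1")
    pos, neg = scores[labels == 1], scores[labels == 0]
    # Mann-Whitney probability via midranks (ties half-credited)
    ranks = stats.rankdata(scores)
    u = ranks[labels == 1].sum() - pos.size * (pos.size + 1) / 2.0
    auc = float(u / (pos.size * neg.size))
    fpr, tpr, thr = roc_curve(labels, scores, drop_intermediate=False)
    curve = pd.DataFrame({"threshold": thr, "fpr": fpr, "tpr": tpr})
    return auc, curve


def two_sample_t_pooled(a, b) -> tuple[float, int, float]:
    """Pooled-variance two-sample t with df = n_a + n_b - 2, two-sided p."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs >= 2 observations")
    df = a.size + b.size - 2
    sp2 = ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) / df
    if sp2 == 0:
        if a.mean() == b.mean():
            return 0.0, df, 1.0
        raise ValueError("zero pooled variance with unequal means: degenerate input")
    t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1.0 / a.size + 1.0 / b.size))
    p = float(2.0 * stats.t.sf(abs(t), df))
    return float(t), df, p


def chi_square_2x2(table) -> tuple[float, int, float]:
    """Pearson chi-square on a 2x2 table, no continuity correction.

    Expected counts come from the marginals; all four marginals must be
    positive.
    """
    obs = np.asarray(table, dtype=np.float64)
    if obs.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {obs.shape}")
    if np.any(obs < 0):
        raise ValueError("counts must be nonnegative")
    if np.any(obs.sum(axis=0) == 0) or np.any(obs.sum(axis=1) == 0):
        raise ValueError("zero marginal; chi-square undefined")
    chi2, p, dof, _ = stats.chi2_contingency(obs, correction=False)
    return float(chi2), int(dof), float(p)


def moment_matched_sample(n: int, mean: float, sd: float, seed: int = 0) -> np.ndarray:
    """A sample of size n with exactly the requested mean and SD (ddof=1).

    Arbitrary normal draws are affinely rescaled; useful for recomputing
    published summary statistics from printed moments.
    """
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(n)
    x = (x - x.mean()) / x.std(ddof=1)
    return mean + sd * x


_CONTINUOUS = ["age", "education"]
_SCALES = ["NIHSS", "WE_FMA", "UE_FMA", "LE_FMA", "BI"]


def demographics_report(participants: pd.DataFrame, clinical: pd.DataFrame | None = None) -> pd.DataFrame:
    """Demographics summary: mean +/- SD with pooled t per continuous
    variable, sex counts with chi-square, and median (Q1, Q3) for clinical
    scales (patients only). Quartiles use linear interpolation.
    """
    required = {"group"}
    missing = required - set(participants.columns)
    if missing:
        raise ValueError(f"participants table missing column(s): {sorted(missing)}")
    pat = participants[participants["group"] == "patient"]
    ctl = participants[participants["group"] == "control"]
    rows = []
    single_group = pat.empty or ctl.empty
    for col in _CONTINUOUS:
        if col not in participants.columns:
            continue
        if single_group:
            grp = pat if not pat.empty else ctl
            rows.append({"variable": col,
                         "patients" if not pat.empty else "controls":
                         f"{grp[col].mean():.3f} ± {grp[col].std(ddof=1):.3f}",
                         "statistic": "", "p": "",
                         "note": "single group: comparison omitted"})
            continue
        t, df, p = two_sample_t_pooled(pat[col].to_numpy(float), ctl[col].to_numpy(float))
        rows.append({"variable": col,
                     "patients": f"{pat[col].mean():.3f} ± {pat[col].std(ddof=1):.3f}",
                     "controls": f"{ctl[col].mean():.3f} ± {ctl[col].std(ddof=1):.3f}",
                     "statistic": f"t = {t:.3f}", "p": f"{p:.3f}", "note": ""})
    if "sex" in participants.columns and not single_group:
        tab = [[int((pat["sex"] == 1).sum()), int((pat["sex"] == 0).sum())],
               [int((ctl["sex"] == 1).sum()), int((ctl["sex"] == 0).sum())]]
        chi2, _, p = chi_square_2x2(tab)
        rows.append({"variable": "sex (male/female)",
                     "patients": f"{tab[0][0]}/{tab[0][1]}",
                     "controls": f"{tab[1][0]}/{tab[1][1]}",
                     "statistic": f"chi2 = {chi2:.3f}", "p": f"{p:.3f}", "note": ""})
    if clinical is not None:
        for col in _SCALES:
            if col not in clinical.columns:
                continue
            v = clinical[col].to_numpy(float)
            q1, med, q3 = np.percentile(v, [25, 50, 75])
            rows.append({"variable": col, "patients": f"{med:.1f} ({q1:.1f}, {q3:.1f})",
                         "controls": "", "statistic": "", "p": "", "note": "median (Q1, Q3)"})
    return pd.DataFrame(rows)


def correlation_table(roi_means: dict[str, np.ndarray], clinical: pd.DataFrame,
                      scales: tuple[str, ...] = tuple(_SCALES)) -> pd.DataFrame:
    """Spearman rho and p for every ROI x clinical-scale pair.

    ``roi_means`` maps ROI name to the per-patient mean CV values aligned
    with the clinical table rows.
    """
    rows = []
    for roi, vals in roi_means.items():
        row: dict = {"roi": roi}
        for s in scales:
            if s not in clinical.columns:
                continue
            rho, p = spearman(vals, clinical[s].to_numpy(float))
            row[f"{s}_rho"] = rho
            row[f"{s}_p"] = p
        rows.append(row)
    return pd.DataFrame(rows)
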
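"""Variance-weighted RMSD heterogeneity statistics.

The dispersion of a set of points about a centroid in retained principal
components (PCs 2-4 by default) is summarized by

    RMSD = sqrt( sum_i d_i^2 / (N - 1) ),
    d_i  = sqrt( (x_i - xbar)^2 w_x^2 + (y_i - ybar)^2 w_y^2
                 + (z_i - zbar)^2 w_z^2 ),

where the weights w are the proportions of overall variance explained by the
retained components, entering *squared* inside the distance.  Per-patient
heterogeneity uses each patient's plaque scores about the patient centroid
(N = the patient's vector count); per-cohort heterogeneity uses the patient
centroids about the cohort centroid (N = the cohort's patient count).  With
fewer than two points the statistic is undefined and reported as NaN.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .strainspace import ScoreSet, StrainSpacePCA


@dataclass
class HeterogeneityReport:
    per_patient: pd.DataFrame  # patient_id, cohort, n_vectors, rmsd
    per_cohort: pd.DataFrame  # cohort, n_patients, rmsd
    retained: tuple[int, ...]
    weights: np.ndarray


def weighted_distance(point, center, weights) -> float:
    """Weighted Euclidean distance with weights squared inside the sum."""
    point = np.asarray(point, dtype=float)
    center = np.asarray(center, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if not point.shape == center.shape == weights.shape:
        raise ValueError("point, center, and weights must share dimensionality")
    return float(np.sqrt(np.sum((point - center) ** 2 * weights**2)))


def weighted_rmsd(points, center, weights) -> float:
    """Root of the summed squared weighted distances over N - 1.

    Returns NaN for fewer than two points (undefined).
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    n = points.shape[0]
    if n < 2:
        return float("nan")
    center = np.asarray(center, dtype=float)
    weights = np.asarray(weights, dtype=float)
    d_sq = np.sum((points - center) ** 2 * weights**2, axis=1)
    return float(np.sqrt(d_sq.sum() / (n - 1)))


def weights_from_space(
    space: StrainSpacePCA, retained: tuple[int, ...] = (2, 3, 4)
) -> np.ndarray:
    """Explained-variance proportions of the retained components, frozen at
    fit time for reproducibility of downstream reports."""
    return space.variance_weights(retained)


def per_patient_heterogeneity(
    scores: ScoreSet, centroids: pd.DataFrame, weights
) -> pd.DataFrame:
    """Weighted RMSD of each patient's plaque scores about their centroid."""
    weights = np.asarray(weights, dtype=float)
    df = scores.to_frame()
    cols = scores.columns
    cent = centroids.set_index("patient_id")
    rows = []
    for patient_id, sub in df.groupby("patient_id", sort=True):
        pts = sub[cols].to_numpy()
        center = cent.loc[patient_id, cols].to_numpy(dtype=float)
        rows.append(
            {
                "patient_id": patient_id,
                "cohort": sub["cohort"].iloc[0],
                "n_vectors": len(pts),
                "rmsd": weighted_rmsd(pts, center, weights),
            }
        )
    return pd.DataFrame(rows)


def per_cohort_heterogeneity(centroids: pd.DataFrame, weights) -> pd.DataFrame:
    """Weighted RMSD of patient centroids about each cohort's centroid."""
    weights = np.asarray(weights, dtype=float)
    cols = [c for c in centroids.columns if c.startswith("pc")]
    rows = []
    for cohort, sub in centroids.groupby("cohort", sort=True):
        pts = sub[cols].to_numpy(dtype=float)
        center = pts.mean(axis=0)
        rows.append(
            {
                "cohort": cohort,
                "n_patients": len(pts),
                "rmsd": weighted_rmsd(pts, center, weights),
            }
        )
    return pd.DataFrame(rows)


def compute_heterogeneity(
    scores: ScoreSet,
    space: StrainSpacePCA,
    centroids: pd.DataFrame | None = None,
) -> HeterogeneityReport:
    """Per-patient and per-cohort reports with weights frozen from the space."""
    from .strainspace import patient_centroids

    if centroids is None:
        centroids = patient_centroids(scores)
    weights = weights_from_space(space, scores.retained)
    return HeterogeneityReport(
        per_patient=per_patient_heterogeneity(scores, centroids, weights),
        per_cohort=per_cohort_heterogeneity(centroids, weights),
        retained=scores.retained,
        weights=weights,
    )


def stratified_heterogeneity(
    report: HeterogeneityReport, strata: pd.Series | dict
) -> dict:
    """Per-stratum per-patient RMSD values plus a smoothed (KDE) summary.

    ``strata`` maps patient_id to a stratum label (e.g. the tau grade).
    Patients with undefined RMSD are dropped from the summaries; empty strata
    yield empty value lists.
    """
    strata = pd.Series(strata)
    df = report.per_patient.copy()
    df["stratum"] = df["patient_id"].map(strata)
    out: dict = {}
    for stratum in sorted(strata.unique(), key=str):
        vals = df.loc[df["stratum"] == stratum, "rmsd"].dropna().to_numpy()
        entry: dict = {"n": int(vals.size), "values": vals.tolist()}
        if vals.size >= 2 and np.ptp(vals) > 0:
            kde = stats.gaussian_kde(vals)
            grid = np.linspace(vals.min(), vals.max(), 128)
            entry["kde_grid"] = grid.tolist()
            entry["kde_density"] = kde(grid).tolist()
        out[stratum] = entry
    return out
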
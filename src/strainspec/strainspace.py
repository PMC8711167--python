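"""The PCA strain space and KDE coverage regions.

Composite spectral vectors are decomposed by mean-centered PCA.  In the study
design the first component absorbs a microscope-calibration batch artifact, so
downstream analyses use PCs 2-3 (eigenspace plots, centroids, MANOVA) and
PCs 2-4 (heterogeneity), with component numbering 1-based throughout.

"Shared" strain space is operationalized per reference cohort as a Gaussian-KDE
density super-level set whose threshold is calibrated so that a stated fraction
(default 99.5%) of the reference cohort's own scores fall inside.  Query
plaques are labeled by the four-way partition of the two reference regions;
points outside both are candidate cohort-unique strains.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA
from sklearn.utils.validation import check_array, check_is_fitted

from .spectra import SpectralMatrix

MEMBERSHIP_LABELS = ("in_ADNC_region", "in_AD_region", "in_both", "outside_both")


class InsufficientDataError(ValueError):
    """Too few rows to fit the requested model."""


class DegenerateReferenceError(ValueError):
    """Zero-variance reference sample; the Gaussian KDE is singular."""


def _as_values(data) -> np.ndarray:
    if isinstance(data, SpectralMatrix):
        return data.values
    return np.asarray(data, dtype=float)


class StrainSpacePCA(TransformerMixin, BaseEstimator):
    """Mean-centered PCA over composite spectral vectors.

    The full component set is retained internally; a deterministic sign
    convention (the largest-magnitude loading of each component is positive)
    removes the eigenvector sign ambiguity across runs and platforms.

    Attributes set by :meth:`fit`: ``mean_``, ``components_``,
    ``explained_variance_``, ``explained_variance_ratio_``, ``n_features_in_``.
    """

    def __init__(self, n_components: int | None = None):
        self.n_components = n_components

    def fit(self, X, y=None):
        X = check_array(_as_values(X))
        if X.shape[0] < 2:
            raise InsufficientDataError("PCA requires at least 2 rows")
        pca = PCA(n_components=self.n_components, svd_solver="full")
        pca.fit(X)
        components = pca.components_.copy()
        for i in range(components.shape[0]):
            j = int(np.argmax(np.abs(components[i])))
            if components[i, j] < 0:
                components[i] = -components[i]
        self.mean_ = pca.mean_
        self.components_ = components
        self.explained_variance_ = pca.explained_variance_
        self.explained_variance_ratio_ = pca.explained_variance_ratio_
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X) -> np.ndarray:
        """Scores on every retained component (columns ordered PC1, PC2, ...)."""
        check_is_fitted(self, "components_")
        X = check_array(_as_values(X))
        return (X - self.mean_) @ self.components_.T

    def project(self, X, retained: tuple[int, ...] = (2, 3)) -> np.ndarray:
        """Scores on a subset of components selected by 1-based PC number."""
        check_is_fitted(self, "components_")
        n_comp = self.components_.shape[0]
        for pc in retained:
            if not 1 <= pc <= n_comp:
                raise ValueError(f"PC index {pc} out of range 1..{n_comp}")
        cols = [pc - 1 for pc in retained]
        return self.transform(X)[:, cols]

    def variance_weights(self, retained: tuple[int, ...]) -> np.ndarray:
        """Explained-variance proportions of the retained components (the
        weights of the heterogeneity statistic)."""
        check_is_fitted(self, "components_")
        return self.explained_variance_ratio_[[pc - 1 for pc in retained]]


@dataclass
class ScoreSet:
    """Plaque coordinates on retained components with aligned metadata."""

    coords: np.ndarray  # (n, d)
    retained: tuple[int, ...]  # 1-based PC numbers
    meta: pd.DataFrame  # plaque_id, patient_id, cohort

    def __post_init__(self) -> None:
        self.coords = np.atleast_2d(np.asarray(self.coords, dtype=float))
        if self.coords.shape[1] != len(self.retained):
            raise ValueError("coordinate dimensionality must match retained list")
        if len(self.meta) != self.coords.shape[0]:
            raise ValueError("meta rows must align with coordinate rows")
        self.meta = self.meta.reset_index(drop=True)

    @property
    def columns(self) -> list[str]:
        return [f"pc{i}" for i in self.retained]

    def to_frame(self) -> pd.DataFrame:
        return pd.concat(
            [
                self.meta.reset_index(drop=True),
                pd.DataFrame(self.coords, columns=self.columns),
            ],
            axis=1,
        )

    def subset(self, mask: np.ndarray) -> "ScoreSet":
        return ScoreSet(
            coords=self.coords[mask],
            retained=self.retained,
            meta=self.meta.loc[np.asarray(mask)].reset_index(drop=True),
        )


def fit_strain_space(matrix: SpectralMatrix | np.ndarray) -> StrainSpacePCA:
    """Fit the full PCA strain space on composite vectors."""
    return StrainSpacePCA().fit(matrix)


def project_scores(
    matrix: SpectralMatrix,
    space: StrainSpacePCA,
    retained: tuple[int, ...] = (2, 3),
) -> ScoreSet:
    """Project composite vectors onto retained components, carrying metadata."""
    coords = space.project(matrix.values, retained=retained)
    return ScoreSet(coords=coords, retained=tuple(retained), meta=matrix.meta.copy())


def patient_centroids(scores: ScoreSet) -> pd.DataFrame:
    """Per-patient mean coordinate ("the average coordinate") per component."""
    df = scores.to_frame()
    out = (
        df.groupby(["patient_id", "cohort"], sort=True, as_index=False)[scores.columns]
        .mean()
    )
    return out


class KDECoverageRegion(BaseEstimator):
    """Gaussian-KDE density region covering a stated fraction of its reference.

    ``fit`` estimates a Gaussian KDE on the reference scores and sets
    ``threshold_`` so that at least ``ceil(coverage * N)`` reference points
    have estimated density >= threshold (``calibration="quantile"``, default).
    The alternative ``calibration="mass"`` chooses the density level whose
    super-level set integrates to ``coverage`` probability mass on a mesh grid.

    Parameters
    ----------
    coverage : float in (0, 1), default 0.995
    bandwidth : "scott", "silverman", or a fixed scalar factor
    calibration : "quantile" or "mass"
    grid_size : mesh resolution per axis for ``calibration="mass"``
    """

    def __init__(
        self,
        coverage: float = 0.995,
        bandwidth="scott",
        calibration: str = "quantile",
        grid_size: int = 200,
    ):
        self.coverage = coverage
        self.bandwidth = bandwidth
        self.calibration = calibration
        self.grid_size = grid_size

    def fit(self, X, y=None):
        if not 0 < self.coverage < 1:
            raise ValueError("coverage must be in (0, 1)")
        X = check_array(np.asarray(X, dtype=float))
        n, d = X.shape
        if n < d + 1:
            raise InsufficientDataError(
                f"KDE needs at least dimensionality+1 = {d + 1} points, got {n}"
            )
        try:
            kde = stats.gaussian_kde(X.T, bw_method=self.bandwidth)
        except np.linalg.LinAlgError as exc:
            raise DegenerateReferenceError(
                "reference sample has zero variance in some direction"
            ) from exc
        self_density = kde(X.T)
        if self.calibration == "quantile":
            k = int(np.ceil(self.coverage * n))
            # the (n-k)-th smallest self-density: >= k points sit at or above it
            self.threshold_ = float(np.sort(self_density)[n - k])
        elif self.calibration == "mass":
            self.threshold_ = self._mass_threshold(kde, X)
        else:
            raise ValueError("calibration must be 'quantile' or 'mass'")
        self.kde_ = kde
        self.reference_ = X
        self.self_density_ = self_density
        self.n_features_in_ = d
        return self

    def _mass_threshold(self, kde, X: np.ndarray) -> float:
        d = X.shape[1]
        if d > 3:
            raise ValueError("mass calibration supported up to 3 dimensions")
        pad = 4.0 * np.sqrt(np.diag(np.atleast_2d(kde.covariance)))
        axes = [
            np.linspace(X[:, j].min() - pad[j], X[:, j].max() + pad[j], self.grid_size)
            for j in range(d)
        ]
        mesh = np.meshgrid(*axes, indexing="ij")
        pts = np.vstack([m.ravel() for m in mesh])
        dens = kde(pts)
        cell = np.prod([ax[1] - ax[0] for ax in axes])
        order = np.argsort(dens)[::-1]
        cum_mass = np.cumsum(dens[order]) * cell
        idx = int(np.searchsorted(cum_mass, self.coverage))
        idx = min(idx, len(order) - 1)
        return float(dens[order][idx])

    def score_samples(self, X) -> np.ndarray:
        """Estimated density at each query point."""
        check_is_fitted(self, "kde_")
        X = check_array(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_features_in_:
            raise ValueError("query dimensionality does not match the region")
        return self.kde_(X.T)

    def predict(self, X) -> np.ndarray:
        """True where a query point lies inside the coverage region."""
        check_is_fitted(self, "kde_")
        if np.asarray(X).size == 0:
            return np.zeros(0, dtype=bool)
        return self.score_samples(X) >= self.threshold_

    def contains(self, X) -> np.ndarray:
        return self.predict(X)


def fit_density_region(
    reference: ScoreSet | np.ndarray,
    coverage: float = 0.995,
    bandwidth_rule="scott",
    calibration: str = "quantile",
) -> KDECoverageRegion:
    """Fit a coverage region on a reference cohort's scores."""
    X = reference.coords if isinstance(reference, ScoreSet) else reference
    return KDECoverageRegion(
        coverage=coverage, bandwidth=bandwidth_rule, calibration=calibration
    ).fit(X)


def classify_membership(
    query: ScoreSet,
    adnc_region: KDECoverageRegion,
    ad_region: KDECoverageRegion,
) -> pd.Series:
    """Label each query plaque by the four-way region partition."""
    for region in (adnc_region, ad_region):
        check_is_fitted(region, "kde_")
        if region.n_features_in_ != query.coords.shape[1]:
            raise ValueError("region and query dimensionality differ")
    if query.coords.shape[0] == 0:
        return pd.Series([], dtype=object, name="membership")
    in_adnc = adnc_region.predict(query.coords)
    in_ad = ad_region.predict(query.coords)
    labels = np.where(
        in_adnc & in_ad,
        "in_both",
        np.where(
            in_adnc, "in_ADNC_region", np.where(in_ad, "in_AD_region", "outside_both")
        ),
    )
    return pd.Series(labels, index=query.meta.index, name="membership")


def membership_summary(
    labels: pd.Series, meta: pd.DataFrame, stratify_by: pd.Series | None = None
) -> pd.DataFrame:
    """Counts of each membership label per cohort (and optional patient stratum)."""
    df = meta.copy()
    df["membership"] = labels.to_numpy()
    keys = ["cohort"]
    if stratify_by is not None:
        df["stratum"] = df["patient_id"].map(stratify_by)
        keys.append("stratum")
    counts = (
        df.groupby(keys + ["membership"], sort=True).size().unstack(fill_value=0)
    )
    for lab in MEMBERSHIP_LABELS:
        if lab not in counts.columns:
            counts[lab] = 0
    return counts[list(MEMBERSHIP_LABELS)].reset_index()


def _matched_score_correlations(
    space_a: StrainSpacePCA,
    space_b: StrainSpacePCA,
    X: np.ndarray,
    retained: tuple[int, ...],
) -> dict[int, float]:
    """Sign-aligned |Pearson r| of matched retained-component scores, computed
    by projecting one common matrix into both fitted spaces."""
    sa = space_a.project(X, retained)
    sb = space_b.project(X, retained)
    out = {}
    for j, pc in enumerate(retained):
        r = np.corrcoef(sa[:, j], sb[:, j])[0, 1]
        out[pc] = float(abs(r))
    return out


def subsample_robustness_check(
    matrix: SpectralMatrix,
    cap: int = 30,
    cap_seeds: tuple[int, ...] = (0, 1),
    retained: tuple[int, ...] = (2, 3),
    oversample_cohort: str | None = None,
    oversample_seed: int = 0,
    alpha: float = 0.05,
) -> dict:
    """Validate that the eigenspace is insensitive to the per-patient cap and
    to cohort balancing.

    Fits the strain space (a) on all vectors, (b) under the cap at each seed,
    (c) with the minority cohort oversampled with replacement to the majority
    size.  For every pair of runs, reports the absolute Pearson correlation of
    matched retained-component scores (all rows projected into both spaces,
    sign-aligned) and whether the cohort-separation MANOVA verdict agrees.
    """
    from .cohort_stats import manova_on_centroids
    from .spectra import cap_vectors_per_patient

    runs: dict[str, SpectralMatrix] = {"nocap": matrix}
    for s in cap_seeds:
        runs[f"cap_seed{s}"] = cap_vectors_per_patient(matrix, cap=cap, seed=s)

    cohort_sizes = matrix.meta["cohort"].value_counts()
    if oversample_cohort is None and len(cohort_sizes) >= 2:
        oversample_cohort = cohort_sizes.idxmin()
    if oversample_cohort is not None:
        rng = np.random.default_rng(oversample_seed)
        minority = np.flatnonzero(
            (matrix.meta["cohort"] == oversample_cohort).to_numpy()
        )
        others = np.flatnonzero(
            (matrix.meta["cohort"] != oversample_cohort).to_numpy()
        )
        target = int(cohort_sizes.max())
        boosted = rng.choice(minority, size=target, replace=True)
        runs["oversample"] = matrix.subset(np.concatenate([others, boosted]))

    spaces = {name: fit_strain_space(m) for name, m in runs.items()}
    manova_p: dict[str, float] = {}
    for name, m in runs.items():
        scores = project_scores(m, spaces[name], retained=retained)
        cents = patient_centroids(scores)
        if cents["cohort"].nunique() >= 2:
            manova_p[name] = manova_on_centroids(cents).p_value
        else:
            manova_p[name] = float("nan")

    names = list(runs)
    pairs = {}
    X = matrix.values
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            corr = _matched_score_correlations(spaces[a], spaces[b], X, retained)
            agree = (manova_p[a] < alpha) == (manova_p[b] < alpha)
            pairs[f"{a}|{b}"] = {
                "score_abs_correlation": corr,
                "manova_agreement": bool(agree),
            }
    return {
        "retained": list(retained),
        "runs": {n: {"n_rows": runs[n].n_rows, "manova_p": manova_p[n]} for n in names},
        "pairs": pairs,
    }
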
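"""Cohort-level inference on patient centroids.

Group separation in the retained eigenspace is tested by one-way MANOVA with
Wilks' lambda, Lambda = det(E) / det(E + H), where E and H are the within- and
between-group cross-product matrices of the centroid coordinates; the p-value
uses Rao's F approximation (exact for 2 groups or up to 2 response
dimensions).  Associations between centroid coordinates and numerical patient
covariates use ordinary least squares (Pearson r with a two-sided p); for
categorical attributes a rank-based test is used (Mann-Whitney for two groups,
Kruskal-Wallis for more).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


class SingularScatterError(np.linalg.LinAlgError):
    """The within-group scatter matrix is singular.

    Usually the centroid coordinates are collinear or a group is too small;
    reduce the dimensionality of the retained components or pool groups.
    """


@dataclass(frozen=True)
class ManovaResult:
    wilks_lambda: float
    approx_f: float
    df_num: float
    df_den: float
    p_value: float
    groups: tuple[str, ...]
    n_per_group: tuple[int, ...]


@dataclass(frozen=True)
class RegressionResult:
    r: float
    slope: float
    intercept: float
    p_value: float
    n: int
    stderr: float


@dataclass(frozen=True)
class CategoricalResult:
    test_name: str
    statistic: float
    p_value: float
    groups: tuple[str, ...]
    n_per_group: tuple[int, ...]


def scatter_matrices(Y: np.ndarray, groups: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Within-group (E) and between-group (H) cross-product matrices."""
    Y = np.asarray(Y, dtype=float)
    grand = Y.mean(axis=0)
    p = Y.shape[1]
    E = np.zeros((p, p))
    H = np.zeros((p, p))
    for g in np.unique(groups):
        Yg = Y[groups == g]
        mg = Yg.mean(axis=0)
        resid = Yg - mg
        E += resid.T @ resid
        diff = (mg - grand)[:, None]
        H += Yg.shape[0] * (diff @ diff.T)
    return E, H


def wilks_lambda_manova(Y, group_labels) -> ManovaResult:
    """One-way MANOVA via Wilks' lambda with Rao's F approximation."""
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    groups = np.asarray(group_labels)
    uniq, counts = np.unique(groups, return_counts=True)
    g = len(uniq)
    n, p = Y.shape
    if g < 2:
        raise ValueError("MANOVA requires at least 2 groups")
    if np.any(counts < 2):
        raise ValueError("every group needs at least 2 centroids")
    if n <= p + g:
        raise ValueError("total n must exceed dimensionality + number of groups")

    E, H = scatter_matrices(Y, groups)
    det_e = max(np.linalg.det(E), 0.0)
    det_eh = np.linalg.det(E + H)
    if det_eh <= 0:
        raise SingularScatterError(SingularScatterError.__doc__)
    # det(E) = 0 with det(E+H) > 0 is complete separation: Lambda = 0, p -> 0
    lam = float(det_e / det_eh)

    q = g - 1  # hypothesis degrees of freedom
    df1 = p * q
    denom = p**2 + q**2 - 5
    t = np.sqrt((p**2 * q**2 - 4) / denom) if denom > 0 else 1.0
    w = n - 1 - (p + g) / 2
    df2 = w * t - (p * q - 2) / 2
    if lam == 0.0:
        f_stat, p_value = float("inf"), 0.0
    else:
        lam_t = lam ** (1.0 / t)
        f_stat = ((1 - lam_t) / lam_t) * (df2 / df1)
        p_value = float(stats.f.sf(f_stat, df1, df2))
    return ManovaResult(
        wilks_lambda=lam,
        approx_f=float(f_stat),
        df_num=float(df1),
        df_den=float(df2),
        p_value=p_value,
        groups=tuple(str(u) for u in uniq),
        n_per_group=tuple(int(c) for c in counts),
    )


def manova_on_centroids(
    centroids: pd.DataFrame,
    group_col: str = "cohort",
    value_cols: list[str] | None = None,
) -> ManovaResult:
    """MANOVA on a patient-centroid table (default: cohorts in PC2-PC3)."""
    if value_cols is None:
        value_cols = [c for c in centroids.columns if c.startswith("pc")]
    return wilks_lambda_manova(
        centroids[value_cols].to_numpy(dtype=float),
        centroids[group_col].to_numpy(),
    )


def centroid_covariate_regression(
    centroids: pd.DataFrame,
    component: str,
    covariate: pd.Series | dict,
) -> RegressionResult:
    """OLS of one centroid coordinate on a patient covariate.

    Missing covariates are dropped pairwise; the returned ``n`` is the number
    of patients actually used.
    """
    covariate = pd.Series(covariate)
    y = centroids.set_index("patient_id")[component]
    paired = pd.DataFrame({"y": y, "x": covariate}).dropna()
    if len(paired) < 3:
        raise ValueError("need at least 3 patients with non-missing covariate")
    if np.ptp(paired["x"].to_numpy()) == 0:
        raise ValueError("covariate has zero variance; r is undefined")
    res = stats.linregress(paired["x"], paired["y"])
    return RegressionResult(
        r=float(res.rvalue),
        slope=float(res.slope),
        intercept=float(res.intercept),
        p_value=float(res.pvalue),
        n=len(paired),
        stderr=float(res.stderr),
    )


def regression_grid(
    centroids: pd.DataFrame,
    covariates: pd.DataFrame,
    components: list[str] | None = None,
    covariate_cols: list[str] | None = None,
    bh_correct: bool = False,
) -> pd.DataFrame:
    """Tidy component x covariate regression table (optionally BH-adjusted)."""
    if components is None:
        components = [c for c in centroids.columns if c.startswith("pc")]
    if covariate_cols is None:
        covariate_cols = [
            c
            for c in covariates.columns
            if c not in ("patient_id", "cohort", "batch")
            and pd.api.types.is_numeric_dtype(covariates[c])
        ]
    cov = covariates.set_index("patient_id")
    rows = []
    for comp in components:
        for col in covariate_cols:
            try:
                res = centroid_covariate_regression(centroids, comp, cov[col])
            except ValueError:
                continue
            rows.append(
                {
                    "component": comp,
                    "covariate": col,
                    "r": res.r,
                    "slope": res.slope,
                    "intercept": res.intercept,
                    "p_value": res.p_value,
                    "n": res.n,
                }
            )
    out = pd.DataFrame(rows)
    if bh_correct and not out.empty:
        from statsmodels.stats.multitest import multipletests

        out["p_adj_bh"] = multipletests(out["p_value"], method="fdr_bh")[1]
    return out


def categorical_association(
    values: pd.Series | dict, category: pd.Series | dict
) -> CategoricalResult:
    """Rank-based test of a per-patient value against a categorical attribute.

    Two categories: Mann-Whitney U; more: Kruskal-Wallis.  When every value is
    identical there is nothing to discriminate and p = 1 by policy.
    """
    values = pd.Series(values)
    category = pd.Series(category)
    paired = pd.DataFrame({"v": values, "g": category}).dropna()
    uniq = sorted(paired["g"].unique(), key=str)
    samples = [paired.loc[paired["g"] == g, "v"].to_numpy() for g in uniq]
    if len(samples) < 2 or any(len(s) < 2 for s in samples):
        raise ValueError("need at least 2 categories with at least 2 patients each")
    if np.ptp(paired["v"].to_numpy()) == 0:
        return CategoricalResult(
            test_name="degenerate",
            statistic=float("nan"),
            p_value=1.0,
            groups=tuple(str(g) for g in uniq),
            n_per_group=tuple(len(s) for s in samples),
        )
    if len(samples) == 2:
        no_ties = len(np.unique(paired["v"])) == len(paired)
        method = "exact" if (no_ties and len(paired) <= 40) else "asymptotic"
        stat, p = stats.mannwhitneyu(
            samples[0], samples[1], alternative="two-sided", method=method
        )
        name = "mann-whitney"
    else:
        stat, p = stats.kruskal(*samples)
        name = "kruskal-wallis"
    return CategoricalResult(
        test_name=name,
        statistic=float(stat),
        p_value=float(p),
        groups=tuple(str(g) for g in uniq),
        n_per_group=tuple(len(s) for s in samples),
    )
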
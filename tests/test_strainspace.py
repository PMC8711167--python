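"""PCA strain space, KDE coverage regions, and membership classification."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from strainspec import (
    KDECoverageRegion,
    ScoreSet,
    classify_membership,
    fit_density_region,
    fit_strain_space,
    membership_summary,
    patient_centroids,
    project_scores,
    subsample_robustness_check,
)
from strainspec.strainspace import DegenerateReferenceError, InsufficientDataError


def pca_oracle(X):
    """Eigendecomposition of the sample covariance: independent PCA route."""
    Xc = X - X.mean(axis=0)
    cov = Xc.T @ Xc / (X.shape[0] - 1)
    vals, vecs = np.linalg.eigh(cov)
    order = np.argsort(vals)[::-1]
    return vals[order], vecs[:, order]


def make_scores(coords, patient_ids, cohorts, retained=(2, 3)):
    coords = np.asarray(coords, dtype=float)
    return ScoreSet(
        coords=coords,
        retained=retained[: coords.shape[1]],
        meta=pd.DataFrame(
            {
                "plaque_id": [f"p{i}" for i in range(len(coords))],
                "patient_id": patient_ids,
                "cohort": cohorts,
            }
        ),
    )


class TestPCA:
    def test_scores_match_covariance_eigendecomposition_oracle(self, rng):
        X = rng.normal(size=(40, 10))
        space = fit_strain_space(X)
        vals, vecs = pca_oracle(X)
        scores = space.transform(X)
        oracle_scores = (X - X.mean(axis=0)) @ vecs
        for j in range(10):
            sign = np.sign(oracle_scores[:, j] @ scores[:, j]) or 1.0
            np.testing.assert_allclose(
                scores[:, j], sign * oracle_scores[:, j], atol=1e-8
            )
        np.testing.assert_allclose(
            space.explained_variance_ratio_, vals / vals.sum(), atol=1e-10
        )

    def test_rank_one_data_has_single_nonzero_variance_ratio(self, rng):
        direction = rng.normal(size=12)
        X = np.outer(rng.normal(size=25), direction)
        space = fit_strain_space(X)
        assert space.explained_variance_ratio_[0] == pytest.approx(1.0)
        assert np.all(space.explained_variance_ratio_[1:] < 1e-10)

    def test_variance_ratios_sum_to_one(self, capped_matrix):
        space = fit_strain_space(capped_matrix)
        assert space.explained_variance_ratio_.sum() == pytest.approx(1.0)
        assert np.all(np.diff(space.explained_variance_ratio_) <= 1e-12)
        # components orthonormal
        G = space.components_ @ space.components_.T
        np.testing.assert_allclose(G, np.eye(G.shape[0]), atol=1e-8)

    def test_sign_convention_largest_loading_positive(self, capped_matrix):
        space = fit_strain_space(capped_matrix)
        for comp in space.components_:
            assert comp[np.argmax(np.abs(comp))] > 0

    def test_fewer_than_two_rows_rejected(self):
        with pytest.raises(InsufficientDataError):
            fit_strain_space(np.ones((1, 5)))


class TestProjection:
    def test_reference_mean_projects_to_origin(self, capped_matrix):
        space = fit_strain_space(capped_matrix)
        coords = space.project(space.mean_[None, :], retained=(2, 3))
        np.testing.assert_allclose(coords, 0.0, atol=1e-10)

    def test_full_retention_is_an_isometry(self, rng):
        X = rng.normal(size=(15, 6))
        space = fit_strain_space(X)
        Z = space.project(X, retained=tuple(range(1, 7)))
        orig = np.linalg.norm(X[:, None] - X[None, :], axis=-1)
        proj = np.linalg.norm(Z[:, None] - Z[None, :], axis=-1)
        np.testing.assert_allclose(orig, proj, atol=1e-8)

    def test_out_of_range_component_rejected(self, rng):
        X = rng.normal(size=(10, 4))
        space = fit_strain_space(X)
        with pytest.raises(ValueError, match="out of range"):
            space.project(X, retained=(2, 9))

    def test_scoreset_carries_metadata(self, capped_matrix):
        space = fit_strain_space(capped_matrix)
        scores = project_scores(capped_matrix, space, retained=(2, 3))
        assert scores.columns == ["pc2", "pc3"]
        assert scores.to_frame()["patient_id"].equals(capped_matrix.meta["patient_id"])


class TestCentroids:
    def test_single_plaque_patient_centroid_is_that_plaque(self):
        scores = make_scores([[1.5, -2.0]], ["pA"], ["DS"])
        cents = patient_centroids(scores)
        assert cents.loc[0, "pc2"] == 1.5 and cents.loc[0, "pc3"] == -2.0

    def test_two_point_centroid_is_midpoint(self):
        scores = make_scores([[0, 0], [2, 2]], ["pA", "pA"], ["DS", "DS"])
        cents = patient_centroids(scores)
        assert cents.loc[0, "pc2"] == 1.0 and cents.loc[0, "pc3"] == 1.0

    def test_matches_group_mean_loop_oracle(self, rng):
        n = 30
        pids = rng.choice(["a", "b", "c"], size=n)
        coords = rng.normal(size=(n, 2))
        scores = make_scores(coords, pids, ["DS"] * n)
        cents = patient_centroids(scores).set_index("patient_id")
        for pid in "abc":
            expected = coords[pids == pid].mean(axis=0)
            np.testing.assert_allclose(
                cents.loc[pid, ["pc2", "pc3"]].to_numpy(dtype=float),
                expected,
                atol=1e-12,
            )


class TestKDERegion:
    def test_coverage_holds_on_reference_by_construction(self, rng):
        for coverage in (0.9, 0.995):
            X = rng.normal(size=(400, 2))
            region = KDECoverageRegion(coverage=coverage).fit(X)
            inside = region.predict(X).sum()
            assert inside >= int(np.ceil(coverage * 400))

    def test_far_query_point_is_outside(self, rng):
        X = rng.normal(size=(100, 2))
        region = KDECoverageRegion().fit(X)
        bw = np.sqrt(np.max(np.diag(np.atleast_2d(region.kde_.covariance))))
        far = X.max(axis=0) + 25 * bw
        assert not region.predict(far[None, :])[0]

    def test_threshold_matches_pairwise_kernel_sum_oracle(self, rng):
        X = rng.normal(size=(150, 2))
        region = KDECoverageRegion(coverage=0.95).fit(X)
        # O(N^2) brute force: mean of Gaussian kernels with Scott bandwidth
        n, d = X.shape
        factor = n ** (-1.0 / (d + 4))
        cov = np.cov(X.T, ddof=1) * factor**2
        inv = np.linalg.inv(cov)
        norm = 1.0 / (2 * np.pi * np.sqrt(np.linalg.det(cov)))
        dens = np.empty(n)
        for i in range(n):
            diff = X - X[i]
            q = np.einsum("ij,jk,ik->i", diff, inv, diff)
            dens[i] = norm * np.exp(-0.5 * q).mean()
        k = int(np.ceil(0.95 * n))
        expected = np.sort(dens)[n - k]
        assert region.threshold_ == pytest.approx(expected, rel=1e-10)

    def test_mass_calibration_region_holds_stated_probability(self, rng):
        X = rng.normal(size=(500, 2))
        mass = KDECoverageRegion(coverage=0.9, calibration="mass").fit(X)
        fresh = rng.normal(size=(2000, 2))
        frac = mass.predict(fresh).mean()
        assert 0.85 <= frac <= 0.97

    def test_degenerate_reference_raises(self):
        X = np.zeros((20, 2))
        with pytest.raises(DegenerateReferenceError):
            KDECoverageRegion().fit(X)

    def test_too_few_points_rejected(self):
        with pytest.raises(InsufficientDataError):
            KDECoverageRegion().fit(np.zeros((2, 2)))


class TestMembership:
    def _regions(self, rng):
        adnc = rng.normal(0, 1, size=(200, 2))
        ad = rng.normal([3.0, 0.0], 1, size=(200, 2))
        return (
            fit_density_region(adnc, coverage=0.995),
            fit_density_region(ad, coverage=0.995),
            adnc,
        )

    def test_reference_classifies_inside_its_own_region(self, rng):
        adnc_region, ad_region, adnc = self._regions(rng)
        scores = make_scores(adnc, ["p"] * 200, ["ADNC"] * 200)
        labels = classify_membership(scores, adnc_region, ad_region)
        frac = labels.isin(["in_ADNC_region", "in_both"]).mean()
        assert frac >= 0.995

    def test_empty_query_yields_empty_labels(self, rng):
        adnc_region, ad_region, _ = self._regions(rng)
        scores = make_scores(np.empty((0, 2)), [], [])
        labels = classify_membership(scores, adnc_region, ad_region)
        assert len(labels) == 0

    def test_distant_points_are_outside_both(self, rng):
        adnc_region, ad_region, _ = self._regions(rng)
        scores = make_scores([[50.0, 50.0]], ["p"], ["DS"])
        labels = classify_membership(scores, adnc_region, ad_region)
        assert labels.iloc[0] == "outside_both"

    def test_dimensionality_mismatch_rejected(self, rng):
        adnc_region, ad_region, _ = self._regions(rng)
        scores = ScoreSet(
            coords=np.zeros((3, 3)),
            retained=(2, 3, 4),
            meta=pd.DataFrame(
                {"plaque_id": list("abc"), "patient_id": list("abc"),
                 "cohort": ["DS"] * 3}
            ),
        )
        with pytest.raises(ValueError, match="dimensionality"):
            classify_membership(scores, adnc_region, ad_region)

    def test_summary_counts_all_four_labels_per_cohort(self, rng):
        adnc_region, ad_region, adnc = self._regions(rng)
        scores = make_scores(adnc[:50], ["p"] * 50, ["ADNC"] * 50)
        labels = classify_membership(scores, adnc_region, ad_region)
        summary = membership_summary(labels, scores.meta)
        assert set(summary.columns) >= {
            "cohort", "in_ADNC_region", "in_AD_region", "in_both", "outside_both",
        }
        assert summary.drop(columns="cohort").to_numpy().sum() == 50


class TestRobustness:
    def test_cap_inactive_equals_no_cap(self, small_matrix):
        # every patient has fewer rows than the cap: subsampling is a no-op
        report = subsample_robustness_check(small_matrix, cap=30, cap_seeds=(0,))
        corr = report["pairs"]["nocap|cap_seed0"]["score_abs_correlation"]
        assert corr[2] == pytest.approx(1.0, abs=1e-9)
        assert corr[3] == pytest.approx(1.0, abs=1e-9)

    def test_two_cap_seeds_agree_on_oversized_data(self):
        from strainspec import CohortConfig, composites_from_table, generate_archetypes
        from strainspec.synthetic import generate_cohort_dataset

        arch = generate_archetypes(3, seed=2, peak_shift_nm=20)
        config = CohortConfig(
            patients_per_cohort={"DS": 5, "AD": 5, "ADNC": 5},
            plaques_per_patient=(40, 60),
            noise_sd=0.05,
            seed=8,
        )
        ds = generate_cohort_dataset(config, arch)
        matrix = composites_from_table(ds.spectra_table, seed=1)
        report = subsample_robustness_check(matrix, cap=30, cap_seeds=(0, 1))
        corr = report["pairs"]["cap_seed0|cap_seed1"]["score_abs_correlation"]
        assert corr[2] >= 0.9 and corr[3] >= 0.9
        assert report["pairs"]["cap_seed0|cap_seed1"]["manova_agreement"]
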
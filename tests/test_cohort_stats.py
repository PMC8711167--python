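"""Wilks'-lambda MANOVA, centroid regressions, and categorical rank tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from strainspec import (
    categorical_association,
    centroid_covariate_regression,
    wilks_lambda_manova,
)
from strainspec.cohort_stats import SingularScatterError, regression_grid


def explicit_scatter_oracle(Y, groups):
    """Independent explicit-loop computation of det(E)/det(E+H)."""
    Y = np.asarray(Y, dtype=float)
    grand = Y.mean(axis=0)
    p = Y.shape[1]
    E = np.zeros((p, p))
    H = np.zeros((p, p))
    for g in set(groups):
        rows = [y for y, lab in zip(Y, groups) if lab == g]
        mg = np.mean(rows, axis=0)
        for y in rows:
            E += np.outer(y - mg, y - mg)
        H += len(rows) * np.outer(mg - grand, mg - grand)
    return np.linalg.det(E) / np.linalg.det(E + H)


FIXTURE_12PT = np.array(
    [
        [0.2, 1.1], [-0.3, 0.8], [0.5, 1.4], [0.1, 0.6], [-0.2, 1.0], [0.4, 1.2],
        [1.2, -0.1], [1.6, 0.3], [0.9, -0.4], [1.4, 0.2], [1.1, 0.0], [1.8, -0.2],
    ]
)
FIXTURE_GROUPS = np.repeat(["g1", "g2"], 6)


class TestManova:
    def test_lambda_matches_explicit_scatter_oracle_on_fixture(self):
        res = wilks_lambda_manova(FIXTURE_12PT, FIXTURE_GROUPS)
        expected = explicit_scatter_oracle(FIXTURE_12PT, FIXTURE_GROUPS)
        assert res.wilks_lambda == pytest.approx(expected, abs=1e-12)
        assert 0 < res.wilks_lambda <= 1
        assert 0 <= res.p_value <= 1

    def test_matches_statsmodels_manova(self):
        from statsmodels.multivariate.manova import MANOVA

        df = pd.DataFrame(FIXTURE_12PT, columns=["y1", "y2"])
        df["g"] = FIXTURE_GROUPS
        sm_res = (
            MANOVA.from_formula("y1 + y2 ~ C(g)", data=df)
            .mv_test()
            .results["C(g)"]["stat"]
        )
        ours = wilks_lambda_manova(FIXTURE_12PT, FIXTURE_GROUPS)
        assert ours.wilks_lambda == pytest.approx(
            float(sm_res.loc["Wilks' lambda", "Value"]), abs=1e-10
        )
        assert ours.approx_f == pytest.approx(
            float(sm_res.loc["Wilks' lambda", "F Value"]), rel=1e-8
        )
        assert ours.p_value == pytest.approx(
            float(sm_res.loc["Wilks' lambda", "Pr > F"]), abs=1e-10
        )

    def test_complete_separation_gives_lambda_zero(self):
        # zero within-group scatter (E = 0) with non-collinear group means
        # (E + H nonsingular): complete separation, Lambda = 0
        Y = np.array([[0.0, 0.0]] * 3 + [[5.0, 0.0]] * 3 + [[0.0, 5.0]] * 3)
        res = wilks_lambda_manova(Y, np.repeat(["a", "b", "c"], 3))
        assert res.wilks_lambda == 0.0 and res.p_value == 0.0

    def test_affine_invariance_of_lambda(self, rng):
        Y = rng.normal(size=(40, 2))
        Y[20:] += [1.0, -0.5]
        groups = np.repeat(["a", "b"], 20)
        base = wilks_lambda_manova(Y, groups).wilks_lambda
        for _ in range(5):
            A = rng.normal(size=(2, 2))
            while abs(np.linalg.det(A)) < 0.1:
                A = rng.normal(size=(2, 2))
            b = rng.normal(size=2)
            mapped = wilks_lambda_manova(Y @ A.T + b, groups).wilks_lambda
            assert mapped == pytest.approx(base, rel=1e-8)

    def test_identically_distributed_groups_give_lambda_near_one(self, rng):
        Y = rng.normal(size=(600, 2))
        res = wilks_lambda_manova(Y, np.repeat(["a", "b", "c"], 200))
        assert res.wilks_lambda > 0.97

    def test_degenerate_collinear_coordinates_raise(self):
        Y = np.zeros((12, 2))
        Y[:, 0] = np.arange(12)
        Y[:, 1] = 2 * Y[:, 0]  # E + H singular
        with pytest.raises(SingularScatterError):
            wilks_lambda_manova(Y, np.repeat(["a", "b"], 6))

    @pytest.mark.parametrize(
        "Y, groups, message",
        [
            (np.ones((4, 2)), ["a"] * 4, "2 groups"),
            (np.ones((3, 2)), ["a", "a", "b"], "at least 2 centroids"),
            (np.ones((4, 3)), ["a", "a", "b", "b"], "must exceed"),
        ],
    )
    def test_precondition_violations_rejected(self, Y, groups, message):
        with pytest.raises(ValueError, match=message):
            wilks_lambda_manova(Y, groups)


class TestRegression:
    def _centroids(self, coords, pids):
        return pd.DataFrame(
            {"patient_id": pids, "cohort": ["DS"] * len(pids),
             "pc2": coords, "pc3": np.zeros(len(pids))}
        )

    def test_covariate_identical_to_coordinate_gives_r_one(self):
        coords = [0.1, 0.5, -0.3, 0.9, 0.2]
        pids = list("abcde")
        cents = self._centroids(coords, pids)
        res = centroid_covariate_regression(
            cents, "pc2", pd.Series(coords, index=pids)
        )
        assert res.r == pytest.approx(1.0)
        assert res.slope == pytest.approx(1.0)

    def test_r_matches_covariance_over_variance_oracle(self, rng):
        coords = rng.normal(size=20)
        covar = 0.5 * coords + rng.normal(size=20)
        pids = [f"p{i}" for i in range(20)]
        res = centroid_covariate_regression(
            self._centroids(coords, pids), "pc2", pd.Series(covar, index=pids)
        )
        num = np.cov(covar, coords, ddof=1)[0, 1]
        expected_r = num / np.sqrt(np.var(covar, ddof=1) * np.var(coords, ddof=1))
        expected_slope = num / np.var(covar, ddof=1)
        assert res.r == pytest.approx(expected_r, abs=1e-12)
        assert res.slope == pytest.approx(expected_slope, abs=1e-12)

    def test_missing_covariates_dropped_pairwise(self, rng):
        coords = rng.normal(size=6)
        pids = list("abcdef")
        covar = pd.Series([1.0, 2.0, np.nan, 4.0, 5.0, np.nan], index=pids)
        res = centroid_covariate_regression(
            self._centroids(coords, pids), "pc2", covar
        )
        assert res.n == 4

    def test_zero_variance_covariate_rejected(self):
        cents = self._centroids([0.1, 0.2, 0.3], list("abc"))
        with pytest.raises(ValueError, match="zero variance"):
            centroid_covariate_regression(
                cents, "pc2", pd.Series([1.0, 1.0, 1.0], index=list("abc"))
            )

    def test_known_coupling_slope_recovered_within_two_stderr(self, rng):
        hits = 0
        for _ in range(100):
            x = rng.uniform(0, 1, 30)
            y = 1.0 + 2.5 * x + rng.normal(0, 0.5, 30)
            pids = [f"p{i}" for i in range(30)]
            res = centroid_covariate_regression(
                self._centroids(y, pids), "pc2", pd.Series(x, index=pids)
            )
            hits += abs(res.slope - 2.5) <= 2 * res.stderr
        assert hits >= 90

    def test_grid_runs_all_pairs_and_bh_adjusts(self, rng):
        pids = [f"p{i}" for i in range(12)]
        cents = pd.DataFrame(
            {"patient_id": pids, "cohort": ["DS"] * 12,
             "pc2": rng.normal(size=12), "pc3": rng.normal(size=12)}
        )
        cov = pd.DataFrame(
            {"patient_id": pids, "abeta40": rng.normal(size=12),
             "abeta42": rng.normal(size=12)}
        )
        out = regression_grid(cents, cov, bh_correct=True)
        assert len(out) == 4
        assert "p_adj_bh" in out.columns
        assert (out["p_adj_bh"] >= out["p_value"] - 1e-12).all()


class TestCategorical:
    def test_two_group_separation_reaches_minimal_exact_p(self):
        vals = pd.Series(np.arange(20.0), index=[f"p{i}" for i in range(20)])
        cats = pd.Series(["lo"] * 10 + ["hi"] * 10, index=vals.index)
        res = categorical_association(vals, cats)
        # completely separated ranks: two-sided exact p = 2 / C(20, 10)
        from math import comb

        assert res.test_name == "mann-whitney"
        assert res.p_value == pytest.approx(2 / comb(20, 10), rel=1e-9)

    def test_three_groups_use_kruskal_wallis(self, rng):
        vals = pd.Series(rng.normal(size=30), index=[f"p{i}" for i in range(30)])
        cats = pd.Series(
            np.repeat(["a", "b", "c"], 10), index=vals.index
        )
        res = categorical_association(vals, cats)
        assert res.test_name == "kruskal-wallis"
        stat, p = stats.kruskal(
            vals[cats == "a"], vals[cats == "b"], vals[cats == "c"]
        )
        assert res.p_value == pytest.approx(p)

    def test_all_identical_values_give_p_one(self):
        vals = pd.Series([3.0] * 8, index=[f"p{i}" for i in range(8)])
        cats = pd.Series(["a"] * 4 + ["b"] * 4, index=vals.index)
        res = categorical_association(vals, cats)
        assert res.p_value == 1.0

    def test_null_p_values_roughly_uniform_under_permutation(self, rng):
        pvals = []
        for _ in range(300):
            vals = pd.Series(rng.normal(size=20), index=[f"p{i}" for i in range(20)])
            cats = pd.Series(
                rng.permutation(["a"] * 10 + ["b"] * 10), index=vals.index
            )
            pvals.append(categorical_association(vals, cats).p_value)
        rate = np.mean(np.asarray(pvals) < 0.05)
        assert 0.01 <= rate <= 0.10

    def test_too_small_category_rejected(self):
        vals = pd.Series([1.0, 2.0, 3.0], index=list("abc"))
        cats = pd.Series(["x", "x", "y"], index=list("abc"))
        with pytest.raises(ValueError):
            categorical_association(vals, cats)
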
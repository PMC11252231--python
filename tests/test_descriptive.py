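"""Summary statistics, Spearman matrix, normality, KMO and Bartlett.

The KMO and Bartlett implementations are checked against independent
brute-force oracles (partial correlations from residual regressions;
the closed-form chi-square).
"""
import numpy as np
import pandas as pd
import pytest
from scipy import stats as ss

import soiltrace as st
from soiltrace.descriptive import pearson_matrix

from conftest import standardized_column


def make_table(arr, elements=None):
    arr = np.asarray(arr, dtype=float)
    elements = elements or [f"E{j}" for j in range(arr.shape[1])]
    return st.SampleTable(
        pd.DataFrame(arr, index=[f"s{i}" for i in range(arr.shape[0])], columns=elements)
    )


class TestSummarize:
    def test_matches_survey_cv_and_se_conventions(self):
        # a column with sample sd 5623 around mean 22521 must print
        # CV 24.97% and SE 495, the published convention
        x = standardized_column(129, mean=22521, sd=5623, seed=1)
        table = make_table(np.column_stack([x, np.abs(x) + 1]), ["Al", "X"])
        row = st.summarize(table).loc["Al"]
        assert round(row["cv_percent"], 2) == 24.97
        assert round(row["se"]) == 495
        assert row["min"] <= row["median"] <= row["max"]

    def test_row_order_invariance_and_unit_scaling(self, toy_table):
        base = st.summarize(toy_table)
        shuffled = st.SampleTable(toy_table.data.sample(frac=1, random_state=0))
        pd.testing.assert_frame_equal(base, st.summarize(shuffled))
        scaled = st.SampleTable(toy_table.data * 1000.0)  # mg/kg -> ug/kg
        s = st.summarize(scaled)
        assert np.allclose(s["mean"], base["mean"] * 1000)
        assert np.allclose(s["sd"], base["sd"] * 1000)
        assert np.allclose(s["cv_percent"], base["cv_percent"])  # dimensionless
        assert np.allclose(s["skewness"], base["skewness"])

    def test_skewness_is_adjusted_fisher_pearson(self):
        x = np.array([1.0, 2.0, 2.5, 3.0, 10.0])
        table = make_table(x[:, None], ["Cd"])
        n = len(x)
        m2 = np.mean((x - x.mean()) ** 2)
        m3 = np.mean((x - x.mean()) ** 3)
        expected = (m3 / m2**1.5) * np.sqrt(n * (n - 1)) / (n - 2)
        assert st.summarize(table).loc["Cd", "skewness"] == pytest.approx(expected, rel=1e-12)

    def test_constant_column_degenerates_with_warning(self):
        table = make_table(np.column_stack([np.full(5, 7.0), np.arange(1.0, 6.0)]))
        with pytest.warns(UserWarning, match="constant column"):
            row = st.summarize(table).loc["E0"]
        assert row["sd"] == 0 and row["cv_percent"] == 0 and row["skewness"] == 0

    def test_too_few_samples(self):
        with pytest.raises(ValueError, match="insufficient samples"):
            st.summarize(make_table([[1.0], [2.0]]))


class TestSpearman:
    def test_monotone_pairs_hit_unity(self):
        x = np.array([1.0, 2.0, 5.0, 9.0, 11.0, 20.0])
        table = make_table(np.column_stack([x, np.exp(x / 10), x.max() + 1 - x]))
        corr = st.spearman_matrix(table)
        assert corr.r.iloc[0, 1] == pytest.approx(1.0)
        assert corr.r.iloc[0, 2] == pytest.approx(-1.0)
        assert np.allclose(corr.r, corr.r.T)
        assert np.allclose(np.diag(corr.r), 1.0)

    def test_matches_rank_then_pearson_oracle(self):
        rng = np.random.default_rng(5)
        arr = rng.normal(size=(8, 4))
        arr[3, 1] = arr[4, 1]  # force a tie -> mid-ranks
        table = make_table(np.exp(arr))
        corr = st.spearman_matrix(table)
        ranks = np.column_stack([ss.rankdata(np.exp(arr)[:, j]) for j in range(4)])
        for i in range(4):
            for j in range(4):
                oracle = np.corrcoef(ranks[:, i], ranks[:, j])[0, 1]
                assert corr.r.iloc[i, j] == pytest.approx(oracle, abs=1e-12)

    def test_invariant_under_monotone_transforms(self, toy_table):
        base = st.spearman_matrix(toy_table).r
        warped = st.SampleTable(
            pd.DataFrame(
                {
                    "Cd": np.log(toy_table.column("Cd")),
                    "Ni": toy_table.column("Ni") ** 3,
                    "Pb": toy_table.column("Pb"),
                }
            )
        )
        assert np.allclose(st.spearman_matrix(warped).r, base)


class TestNormalityFlags:
    def test_type_i_error_near_nominal_under_normal_data(self):
        passes = 0
        n_seeds = 100
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            table = make_table(rng.normal(10.0, 2.0, size=(200, 1)))
            passes += int(st.normality_flags(table, alpha=0.05).iloc[0])
        assert passes / n_seeds >= 0.90  # nominal retention is 95%

    def test_heavy_tailed_lognormal_flagged_non_normal(self):
        rng = np.random.default_rng(7)
        table = make_table(rng.lognormal(0.0, 1.0, size=(200, 1)))
        assert not st.normality_flags(table).iloc[0]

    def test_sample_size_bounds(self):
        with pytest.raises(ValueError):
            st.normality_flags(make_table(np.ones((2, 1))))


class TestKMO:
    def test_two_variable_system_is_half(self):
        # with p = 2 the partial correlation equals the correlation,
        # so KMO = r^2 / (r^2 + r^2) = 0.5 for any r != 0
        for r in (0.2, -0.7, 0.95):
            m = np.array([[1.0, r], [r, 1.0]])
            assert st.kmo_statistic(m) == pytest.approx(0.5, abs=1e-12)

    def test_matches_residual_regression_oracle(self):
        rng = np.random.default_rng(11)
        latent = rng.normal(size=(300, 2))
        X = np.column_stack(
            [
                latent[:, 0] + 0.3 * rng.normal(size=300),
                latent[:, 0] + 0.3 * rng.normal(size=300),
                latent[:, 0] + 0.5 * rng.normal(size=300),
                latent[:, 1] + 0.3 * rng.normal(size=300),
                latent[:, 1] + 0.4 * rng.normal(size=300),
                latent[:, 1] + 0.5 * rng.normal(size=300),
            ]
        )
        R = np.corrcoef(X, rowvar=False)
        m = R.shape[0]
        # oracle: partial r(i,j | rest) from residuals of OLS on the others
        r2_sum, q2_sum = 0.0, 0.0
        for i in range(m):
            for j in range(m):
                if i == j:
                    continue
                rest = [k for k in range(m) if k not in (i, j)]
                A = np.column_stack([X[:, rest], np.ones(len(X))])
                ri = X[:, i] - A @ np.linalg.lstsq(A, X[:, i], rcond=None)[0]
                rj = X[:, j] - A @ np.linalg.lstsq(A, X[:, j], rcond=None)[0]
                q2_sum += np.corrcoef(ri, rj)[0, 1] ** 2
                r2_sum += R[i, j] ** 2
        assert st.kmo_statistic(R) == pytest.approx(r2_sum / (r2_sum + q2_sum), abs=1e-10)

    def test_near_identity_matrix_undefined(self):
        m = np.eye(4)
        with pytest.raises(ValueError, match="KMO undefined"):
            st.kmo_statistic(m)


class TestBartlett:
    def test_identity_matrix_gives_zero(self):
        chi2, p = st.bartlett_sphericity(np.eye(5), n=100)
        assert chi2 == pytest.approx(0.0, abs=1e-10)
        assert p == pytest.approx(1.0)

    def test_closed_form_for_known_determinant(self):
        # equicorrelated 3x3 with rho = 0.5 has det (1-rho)^2 (1+2rho) = 0.5
        R = np.full((3, 3), 0.5)
        np.fill_diagonal(R, 1.0)
        chi2, _ = st.bartlett_sphericity(R, n=50)
        assert chi2 == pytest.approx((50 - 1 - 11 / 6) * np.log(2.0), rel=1e-12)

    def test_type_i_error_near_nominal(self):
        rejections = 0
        n_seeds = 100
        for seed in range(n_seeds):
            rng = np.random.default_rng(1000 + seed)
            X = rng.normal(size=(60, 4))
            _, p = st.bartlett_sphericity(np.corrcoef(X, rowvar=False), n=60)
            rejections += int(p < 0.05)
        assert 0.0 <= rejections / n_seeds <= 0.12

    def test_requires_more_samples_than_variables(self):
        with pytest.raises(ValueError):
            st.bartlett_sphericity(np.eye(5), n=5)


def test_kmo_bartlett_on_random_spd_matrices_match_inversion_oracle():
    """Random 5x5 SPD correlation matrices: KMO via the scaled-inverse
    formula must equal a literal element-by-element reimplementation."""
    rng = np.random.default_rng(3)
    for _ in range(10):
        A = rng.normal(size=(40, 5))
        R = np.corrcoef(A, rowvar=False)
        inv = np.linalg.inv(R)
        num = 0.0
        den = 0.0
        for i in range(5):
            for j in range(5):
                if i == j:
                    continue
                partial = -inv[i, j] / np.sqrt(inv[i, i] * inv[j, j])
                num += R[i, j] ** 2
                den += R[i, j] ** 2 + partial**2
        assert st.kmo_statistic(R) == pytest.approx(num / den, abs=1e-12)


def test_pearson_matrix_shape(toy_table):
    corr = pearson_matrix(toy_table)
    assert np.allclose(np.diag(corr.r), 1.0)
    assert np.allclose(corr.r, corr.r.T)
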
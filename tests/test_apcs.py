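"""APCS-MLR receptor model: rotation oracle, identities, recovery."""
import warnings
from itertools import permutations

import numpy as np
import pandas as pd
import pytest

import soiltrace as st


def jacobi_varimax(L, max_sweeps=200, tol=1e-12):
    """Independent varimax oracle: classical pairwise planar rotations
    (Kaiser's quartic angle formula), with Kaiser row normalization."""
    L = np.asarray(L, dtype=float).copy()
    m, k = L.shape
    h = np.sqrt((L**2).sum(axis=1))
    h[h == 0] = 1.0
    L = L / h[:, None]
    for _ in range(max_sweeps):
        moved = 0.0
        for p in range(k - 1):
            for q in range(p + 1, k):
                x, y = L[:, p], L[:, q]
                u = x**2 - y**2
                v = 2 * x * y
                A, B = u.sum(), v.sum()
                C = (u**2 - v**2).sum()
                D = (2 * u * v).sum()
                num = D - 2 * A * B / m
                den = C - (A**2 - B**2) / m
                phi = 0.25 * np.arctan2(num, den)
                if abs(phi) < 1e-13:
                    continue
                c, s = np.cos(phi), np.sin(phi)
                L[:, p], L[:, q] = c * x + s * y, -s * x + c * y
                moved = max(moved, abs(phi))
        if moved < tol:
            break
    return L * h[:, None]


def varimax_criterion(L):
    m = L.shape[0]
    h = np.sqrt((L**2).sum(axis=1))
    h[h == 0] = 1.0
    B = (L / h[:, None]) ** 2
    return float(np.sum(B.var(axis=0)))


def align_columns(est, ref):
    """Best column permutation/sign of ``est`` against ``ref``."""
    k = ref.shape[1]
    best = None
    for perm in permutations(range(k)):
        for signs in np.ndindex(*(2,) * k):
            s = np.array(signs) * 2 - 1
            cand = est[:, list(perm)] * s
            err = float(np.abs(cand - ref).max())
            if best is None or err < best[0]:
                best = (err, cand)
    return best


def fit_quiet(table, **kw):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return st.run_apcs_mlr(table, **kw)


class TestVarimax:
    def test_matches_jacobi_oracle_on_fixed_case(self):
        # unrotated loadings of a seeded 3-source mixing table (10 x 3)
        table, _ = st.generate_mixing(129, 3, seed=12, noise_cv=0.1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = st.fit_pca_varimax(table, n_components=3, rotate=False)
        L0 = fit.loadings.to_numpy()
        # both algorithms run to tight convergence so the flat optimum
        # cannot hide loading-level differences
        ours, _ = st.varimax(L0, tol=1e-15, max_iter=10000)
        oracle = jacobi_varimax(L0, max_sweeps=2000, tol=1e-14)
        assert varimax_criterion(ours) == pytest.approx(varimax_criterion(oracle), abs=1e-9)
        err, _ = align_columns(ours, oracle)
        assert err < 1e-6

    def test_rotation_is_orthogonal_and_preserves_communalities(self):
        rng = np.random.default_rng(4)
        L0 = rng.normal(size=(8, 3))
        L, R = st.varimax(L0)
        assert np.allclose(R @ R.T, np.eye(3), atol=1e-10)
        assert np.allclose((L**2).sum(axis=1), (L0**2).sum(axis=1), atol=1e-10)

    def test_criterion_not_below_random_rotations(self):
        rng = np.random.default_rng(9)
        L0 = rng.normal(size=(10, 3))
        L, _ = st.varimax(L0)
        ours = varimax_criterion(L)
        for _ in range(50):
            Q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
            assert varimax_criterion(L0 @ Q) <= ours + 1e-9


class TestFit:
    def test_three_latent_sources_retained_with_small_noise(self):
        table, _ = st.generate_mixing(129, 3, seed=0, noise_cv=0.05)
        fit = fit_quiet(table).fit
        assert fit.n_components == 3
        assert fit.variance_explained.sum() > 75.0

    def test_single_dominant_factor(self):
        table, _ = st.generate_mixing(129, 1, seed=0, noise_cv=0.05)
        fit = fit_quiet(table).fit
        assert fit.n_components == 1
        # sign convention: the largest-|loading| element loads positively
        col = fit.loadings.iloc[:, 0]
        assert col.iloc[int(np.argmax(np.abs(col)))] > 0

    def test_scores_standardized(self, emulated):
        fit = fit_quiet(emulated).fit
        assert np.allclose(fit.scores.mean(axis=0), 0.0, atol=1e-10)
        assert np.allclose(fit.scores.std(axis=0, ddof=1), 1.0, atol=1e-8)


class TestAbsoluteScores:
    def test_mean_sample_sits_at_minus_zero_score(self, emulated):
        model = fit_quiet(emulated)
        fit = model.fit
        # a site whose raw values equal the element means has score 0,
        # hence APCS = -score(z0)
        z0 = (-fit.means / fit.sds).to_numpy()
        score0 = z0 @ fit.score_coefficients.to_numpy()
        apcs = st.absolute_scores(fit)
        assert np.allclose(apcs.to_numpy(), fit.scores.to_numpy() - score0)

    def test_translation_leaves_site_differences_unchanged(self, emulated):
        fit = fit_quiet(emulated).fit
        apcs = st.absolute_scores(fit)
        d_apcs = apcs.iloc[1:].to_numpy() - apcs.iloc[:-1].to_numpy()
        d_scores = fit.scores.iloc[1:].to_numpy() - fit.scores.iloc[:-1].to_numpy()
        assert np.allclose(d_apcs, d_scores, atol=1e-10)

    def test_single_source_apcs_tracks_true_strength(self):
        table, truth = st.generate_mixing(129, 1, seed=3, noise_cv=0.02)
        model = fit_quiet(table)
        apcs = model.apcs.iloc[:, 0]
        r = np.corrcoef(apcs, truth.strengths.iloc[:, 0])[0, 1]
        assert abs(r) > 0.99


class TestRegression:
    def test_exact_linear_response_gives_r2_one(self, emulated):
        model = fit_quiet(emulated)
        y = 3.0 + model.apcs @ np.array([2.0, -1.0, 0.5])
        b, slopes, r2, pred = st.regress_element(pd.Series(y), model.apcs)
        assert r2 == pytest.approx(1.0, abs=1e-12)
        assert b == pytest.approx(3.0, abs=1e-8)
        assert np.allclose(pred, y)

    def test_independent_noise_gives_near_zero_r2(self, emulated):
        model = fit_quiet(emulated)
        r2s = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            y = pd.Series(rng.normal(size=model.apcs.shape[0]), index=model.apcs.index)
            _, _, r2, _ = st.regress_element(y, model.apcs)
            r2s.append(r2)
        assert np.mean(r2s) < 0.05

    def test_mp_ratio_is_exactly_one_for_every_element(self, emulated):
        model = fit_quiet(emulated)
        assert np.allclose(model.mp_ratio, 1.0, atol=1e-9)

    def test_collinear_regressors_rejected(self, emulated):
        model = fit_quiet(emulated)
        bad = model.apcs.copy()
        bad.iloc[:, 1] = 2.0 * bad.iloc[:, 0]
        with pytest.raises(ValueError, match="degenerate regressors"):
            st.regress_element(emulated.column("Cd"), bad)


class TestContributions:
    def test_absolute_value_normalization(self):
        apcs = pd.DataFrame({"PC1": [3.0, 3.0], "PC2": [1.0, 1.0]})
        slopes = pd.Series({"PC1": 1.0, "PC2": -1.0})
        raw, pct = st.source_contributions(slopes, apcs)
        assert raw.tolist() == [3.0, -1.0]
        assert pct.tolist() == [75.0, 25.0]

    def test_single_source_noiseless_gets_everything(self):
        table, _ = st.generate_mixing(129, 1, seed=5, noise_cv=0.0)
        model = fit_quiet(table)
        assert np.allclose(model.contribution_pct.iloc[:, 0], 100.0)

    def test_rows_sum_to_hundred(self, emulated):
        model = fit_quiet(emulated)
        assert np.allclose(model.contribution_pct.sum(axis=1), 100.0, atol=1e-9)
        assert model.mean_contribution_pct.sum() == pytest.approx(100.0, abs=1e-9)

    def test_mean_contribution_trivia(self):
        pct = pd.DataFrame([[100.0, 0.0], [0.0, 100.0]], columns=["PC1", "PC2"])
        assert st.mean_source_contributions(pct).tolist() == [50.0, 50.0]


class TestInvariances:
    def test_sample_permutation_changes_nothing(self, emulated):
        model = fit_quiet(emulated)
        shuffled = st.SampleTable(emulated.data.sample(frac=1, random_state=1))
        model2 = fit_quiet(shuffled)
        pd.testing.assert_frame_equal(
            model.contribution_pct, model2.contribution_pct, atol=1e-8, rtol=1e-6
        )

    def test_unit_rescaling_one_element_keeps_percentages(self, emulated):
        data = emulated.data.copy()
        data["Cd"] = data["Cd"] * 1000.0  # mg/kg -> ug/kg
        model = fit_quiet(emulated)
        model2 = fit_quiet(st.SampleTable(data))
        pd.testing.assert_frame_equal(
            model.contribution_pct, model2.contribution_pct, atol=1e-6, rtol=1e-5
        )
        assert model2.slopes.loc["Cd"].abs().sum() == pytest.approx(
            1000 * model.slopes.loc["Cd"].abs().sum(), rel=1e-6
        )


class TestRecovery:
    def test_dominant_sources_and_contributions_recovered(self):
        """3-source mixing, n=129, 10% noise: the model, fit at the true
        source count, recovers each element's dominant source and its
        contribution percentages."""
        for seed in range(5):
            table, truth = st.generate_mixing(129, 3, seed=seed, noise_cv=0.1)
            model = fit_quiet(table, n_components=3)
            est = model.contribution_pct.to_numpy()
            tru = truth.true_contribution_pct.to_numpy()
            best = None
            for perm in permutations(range(3)):
                mae = float(np.abs(est[:, list(perm)] - tru).mean())
                if best is None or mae < best[0]:
                    best = (mae, perm)
            mae, perm = best
            dominant_ok = int(
                (est[:, list(perm)].argmax(axis=1) == tru.argmax(axis=1)).sum()
            )
            assert mae < 10.0
            assert dominant_ok >= 8
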
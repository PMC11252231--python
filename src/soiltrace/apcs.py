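"""APCS-MLR receptor model for quantitative source apportionment.

The model proceeds in four steps:

1. PCA on the correlation matrix of the site-by-element table (i.e. on
   standardized concentrations), components with eigenvalue > 1 retained
   (Kaiser rule) and varimax-rotated; factor scores by the regression
   method, which for principal components gives exactly unit-variance
   scores.
2. Absolute principal component scores: the score of an artificial sample
   with zero concentration in every element (z0_j = -mean_j/sd_j) is
   subtracted from every site's score, removing the arbitrary origin of
   standardized scores.
3. Per-element multiple linear regression of raw concentration on the
   APCS with intercept: C_j = b_j + sum_h r_hj * APCS_hj. Because OLS with
   an intercept passes through the mean, the predicted mean equals the
   measured mean for every element (the M/P = 1 diagnostic is an exact
   identity, not a fit-quality statement); R^2 is the adequacy diagnostic.
4. The mean contribution of source h to element j is r_hj * mean(APCS_h);
   negative raw contributions are converted by absolute-value
   normalization, |raw_hj| / sum_h |raw_hj| * 100, over the retained
   components only, so each element's percentages sum to 100.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .descriptive import bartlett_sphericity, kmo_statistic
from .reference_data import SampleTable

__all__ = [
    "varimax",
    "fit_pca_varimax",
    "absolute_scores",
    "regress_element",
    "source_contributions",
    "mean_source_contributions",
    "run_apcs_mlr",
    "ApcsFit",
    "ApcsModel",
]


def varimax(
    loadings: np.ndarray,
    kaiser_normalize: bool = True,
    tol: float = 1e-8,
    max_iter: int = 1000,
) -> tuple[np.ndarray, np.ndarray]:
    """Varimax rotation of a loading matrix.

    Maximizes the variance of squared loadings within each column over
    orthogonal rotations; with ``kaiser_normalize`` rows are scaled to unit
    communality during rotation (the convention of mainstream statistics
    packages). Returns (rotated loadings, rotation matrix).
    """
    L = np.asarray(loadings, dtype=float).copy()
    m, k = L.shape
    if k < 2:
        return L, np.eye(k)
    if kaiser_normalize:
        h = np.sqrt(np.sum(L**2, axis=1))
        h[h == 0] = 1.0
        L = L / h[:, None]
    R = np.eye(k)
    d = 0.0
    for _ in range(max_iter):
        Lr = L @ R
        grad = L.T @ (Lr**3 - Lr @ np.diag(np.sum(Lr**2, axis=0)) / m)
        u, s, vt = np.linalg.svd(grad)
        R = u @ vt
        d_old, d = d, float(np.sum(s))
        if d_old != 0 and d <= d_old * (1 + tol):
            break
    out = L @ R
    if kaiser_normalize:
        out = out * h[:, None]
    return out, R


@dataclass
class ApcsFit:
    """Retained, rotated PCA of a standardized sample table."""

    elements: list[str]
    site_ids: list[str]
    means: pd.Series
    sds: pd.Series
    eigenvalues: np.ndarray            # all m eigenvalues, descending
    loadings: pd.DataFrame             # element x retained component (rotated)
    variance_explained: pd.Series      # % per retained component (rotated)
    scores: pd.DataFrame               # site x component, mean 0 / variance 1
    score_coefficients: pd.DataFrame   # element x component (regression method)
    kmo: float
    bartlett_p: float

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]


def fit_pca_varimax(
    table: SampleTable,
    eigenvalue_threshold: float = 1.0,
    n_components: int | None = None,
    rotate: bool = True,
) -> ApcsFit:
    """Correlation-matrix PCA with Kaiser retention and varimax rotation.

    Emits warnings (never errors) when the factorability prerequisites
    look weak: KMO < 0.5, Bartlett p >= 0.05, or n < m + 50 (the usual
    sample-size rule for APCS-MLR receptor modelling).
    """
    table.require_multivariate()
    X = table.data.to_numpy(dtype=float)
    n, m = X.shape
    means = table.data.mean()
    sds = table.data.std(ddof=1)
    if (sds <= 0).any():
        bad = sds.index[sds <= 0].tolist()
        raise ValueError(f"constant element columns, PCA undefined: {bad}")
    Z = (X - means.to_numpy()) / sds.to_numpy()
    R = np.corrcoef(X, rowvar=False)

    kmo = np.nan
    bart_p = np.nan
    try:
        kmo = kmo_statistic(R)
        _, bart_p = bartlett_sphericity(R, n=n)
        if kmo < 0.5:
            warnings.warn(f"KMO = {kmo:.3f} < 0.5: weak sampling adequacy")
        if bart_p >= 0.05:
            warnings.warn(f"Bartlett sphericity p = {bart_p:.3f} >= 0.05")
    except ValueError as exc:
        warnings.warn(f"factorability diagnostics unavailable: {exc}")
    if n < m + 50:
        warnings.warn(f"n = {n} < m + 50 = {m + 50}: below the receptor-model sample-size rule")

    eigval, eigvec = np.linalg.eigh(R)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]

    if n_components is None:
        k = int(np.sum(eigval > eigenvalue_threshold))
    else:
        k = int(n_components)
    if k < 1:
        raise ValueError("no component passes the retention rule")
    L = eigvec[:, :k] * np.sqrt(eigval[:k])
    if rotate and k > 1:
        L, _ = varimax(L)
    # sign convention: the largest-|loading| element of each component loads +
    for j in range(k):
        idx = int(np.argmax(np.abs(L[:, j])))
        if L[idx, j] < 0:
            L[:, j] = -L[:, j]
    # order components by explained variance after rotation
    ssl = np.sum(L**2, axis=0)
    comp_order = np.argsort(ssl)[::-1]
    L = L[:, comp_order]
    ssl = ssl[comp_order]

    comp_names = [f"PC{j + 1}" for j in range(k)]
    loadings = pd.DataFrame(L, index=table.elements, columns=comp_names)
    # regression-method score coefficients; scores have unit variance exactly
    W = np.linalg.solve(R, L)
    scores = Z @ W
    return ApcsFit(
        elements=table.elements,
        site_ids=table.site_ids,
        means=means,
        sds=sds,
        eigenvalues=eigval,
        loadings=loadings,
        variance_explained=pd.Series(100.0 * ssl / m, index=comp_names),
        scores=pd.DataFrame(scores, index=table.site_ids, columns=comp_names),
        score_coefficients=pd.DataFrame(W, index=table.elements, columns=comp_names),
        kmo=float(kmo),
        bartlett_p=float(bart_p),
    )


def absolute_scores(fit: ApcsFit) -> pd.DataFrame:
    """APCS: factor scores minus the score of the artificial zero sample.

    The zero sample has raw concentration 0 in every element, hence
    standardized value -mean_j/sd_j; subtracting its score anchors the
    score scale at true zero concentration so that regression slopes on
    APCS translate into mass contributions.
    """
    z0 = (-fit.means / fit.sds).to_numpy()
    score0 = z0 @ fit.score_coefficients.to_numpy()
    return fit.scores - score0


def regress_element(conc_j: pd.Series, apcs: pd.DataFrame):
    """OLS of one element's concentrations on the APCS, with intercept.

    Returns (b_j, slopes, r2, predicted). The intercept identity makes
    mean(predicted) == mean(conc_j) exactly.
    """
    if len(conc_j) <= apcs.shape[1] + 1:
        raise ValueError("need n > number of components + 1")
    X = sm.add_constant(apcs.to_numpy())
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("degenerate regressors: collinear APCS columns")
    res = sm.OLS(conc_j.to_numpy(), X).fit()
    b = float(res.params[0])
    slopes = pd.Series(res.params[1:], index=apcs.columns)
    predicted = pd.Series(res.fittedvalues, index=conc_j.index)
    return b, slopes, float(res.rsquared), predicted


def source_contributions(slopes: pd.Series, apcs: pd.DataFrame) -> tuple[pd.Series, pd.Series]:
    """Raw and percentage contributions of each source to one element.

    raw_h = r_hj * mean(APCS_h); percentages by absolute-value
    normalization over the retained components (intercept excluded), so
    they sum to 100 even when some raw contributions are negative.
    """
    raw = slopes * apcs.mean(axis=0)
    denom = float(np.abs(raw).sum())
    if denom == 0:
        raise ValueError("all-zero raw contributions")
    pct = 100.0 * np.abs(raw) / denom
    return raw, pct


def mean_source_contributions(contribution_pct: pd.DataFrame) -> pd.Series:
    """Unweighted mean over elements of each source's percentage share."""
    return contribution_pct.mean(axis=0)


@dataclass
class ApcsModel:
    """Complete APCS-MLR result for one sample table."""

    fit: ApcsFit
    apcs: pd.DataFrame                  # site x component absolute scores
    intercepts: pd.Series               # b_j per element
    slopes: pd.DataFrame                # element x component r_hj
    r2: pd.Series
    predicted_mean: pd.Series
    measured_mean: pd.Series
    raw_contributions: pd.DataFrame     # element x component, signed
    contribution_pct: pd.DataFrame      # element x component, rows sum to 100
    mean_contribution_pct: pd.Series    # per component, sums to 100

    @property
    def mp_ratio(self) -> pd.Series:
        """Measured-to-predicted mean ratio (exactly 1 by the OLS identity)."""
        return self.measured_mean / self.predicted_mean

    def summary(self) -> pd.DataFrame:
        """Survey-style model table: M, P, M/P, R^2, per-source %."""
        out = pd.DataFrame(
            {
                "measured_mean": self.measured_mean,
                "predicted_mean": self.predicted_mean,
                "MP_ratio": self.mp_ratio,
                "R2": self.r2,
            }
        )
        return out.join(self.contribution_pct)


def run_apcs_mlr(
    table: SampleTable,
    eigenvalue_threshold: float = 1.0,
    n_components: int | None = None,
) -> ApcsModel:
    """Fit the full APCS-MLR receptor model to a sample table."""
    fit = fit_pca_varimax(
        table, eigenvalue_threshold=eigenvalue_threshold, n_components=n_components
    )
    apcs = absolute_scores(fit)
    intercepts, slopes, r2s, pred_means, raws, pcts = {}, {}, {}, {}, {}, {}
    for el in table.elements:
        y = table.column(el)
        b, slope, r2, predicted = regress_element(y, apcs)
        raw, pct = source_contributions(slope, apcs)
        intercepts[el] = b
        slopes[el] = slope
        r2s[el] = r2
        pred_means[el] = float(predicted.mean())
        raws[el] = raw
        pcts[el] = pct
    slopes_df = pd.DataFrame(slopes).T.loc[table.elements]
    raw_df = pd.DataFrame(raws).T.loc[table.elements]
    pct_df = pd.DataFrame(pcts).T.loc[table.elements]
    return ApcsModel(
        fit=fit,
        apcs=apcs,
        intercepts=pd.Series(intercepts),
        slopes=slopes_df,
        r2=pd.Series(r2s),
        predicted_mean=pd.Series(pred_means),
        measured_mean=table.data.mean(),
        raw_contributions=raw_df,
        contribution_pct=pct_df,
        mean_contribution_pct=mean_source_contributions(pct_df),
    )
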
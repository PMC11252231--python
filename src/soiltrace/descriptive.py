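"""Descriptive statistics and factorability diagnostics.

Reproduces the survey-style summary table (mean, median, sd, se, CV%,
skewness, min, max per element), the Spearman correlation matrix, per-element
Shapiro-Wilk normality flags, and the two factor-analysis prerequisites
(Kaiser-Meyer-Olkin sampling adequacy and Bartlett's test of sphericity).

Conventions: sd and CV use the n-1 sample denominator; skewness is the
adjusted Fisher-Pearson coefficient (the form reported by mainstream
statistics packages), so se = sd/sqrt(n) and CV = 100*sd/mean tie out
against a published summary row exactly.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .reference_data import SampleTable

SUMMARY_COLUMNS = ("mean", "median", "sd", "se", "cv_percent", "skewness", "min", "max")


def summarize(table: SampleTable) -> pd.DataFrame:
    """Per-element summary statistics (one row per element).

    Requires n >= 3 (skewness is undefined below that). A constant column
    is reported with sd = cv = skewness = 0 and a degenerate-data warning.
    """
    n = table.n_sites
    if n < 3:
        raise ValueError("insufficient samples for skewness (need n >= 3)")
    rows = {}
    for el in table.elements:
        x = table.column(el).to_numpy()
        sd = float(np.std(x, ddof=1))
        mean = float(np.mean(x))
        if sd == 0.0:
            warnings.warn(f"element {el}: constant column, degenerate statistics")
            skew = 0.0
            cv = 0.0
        else:
            skew = float(stats.skew(x, bias=False))
            cv = 100.0 * sd / mean
        rows[el] = {
            "mean": mean,
            "median": float(np.median(x)),
            "sd": sd,
            "se": sd / np.sqrt(n),
            "cv_percent": cv,
            "skewness": skew,
            "min": float(np.min(x)),
            "max": float(np.max(x)),
        }
    out = pd.DataFrame.from_dict(rows, orient="index")[list(SUMMARY_COLUMNS)]
    out.index.name = "element"
    return out


@dataclass
class CorrelationMatrix:
    """Element-by-element correlation matrix with two-sided p-values."""

    method: str
    r: pd.DataFrame
    p: pd.DataFrame
    n: int


def spearman_matrix(table: SampleTable) -> CorrelationMatrix:
    """Spearman rank correlation matrix (mid-rank ties, t-approximation p).

    A constant column has no defined rank correlation; its pairs are
    reported as NaN.
    """
    table.require_multivariate()
    if table.n_sites < 4:
        raise ValueError("need n >= 4 for a Spearman matrix")
    data = table.data
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant columns -> NaN, flagged below
        r, p = stats.spearmanr(data.to_numpy(), axis=0)
    r = np.atleast_2d(r)
    p = np.atleast_2d(p)
    np.fill_diagonal(r, 1.0)
    np.fill_diagonal(p, 0.0)
    els = table.elements
    return CorrelationMatrix(
        method="spearman",
        r=pd.DataFrame(r, index=els, columns=els),
        p=pd.DataFrame(p, index=els, columns=els),
        n=table.n_sites,
    )


def pearson_matrix(table: SampleTable) -> CorrelationMatrix:
    table.require_multivariate()
    data = table.data
    els = table.elements
    m = len(els)
    r = np.eye(m)
    p = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            ri, pi = stats.pearsonr(data.iloc[:, i], data.iloc[:, j])
            r[i, j] = r[j, i] = ri
            p[i, j] = p[j, i] = pi
    return CorrelationMatrix(
        method="pearson",
        r=pd.DataFrame(r, index=els, columns=els),
        p=pd.DataFrame(p, index=els, columns=els),
        n=table.n_sites,
    )


def normality_flags(table: SampleTable, alpha: float = 0.05) -> pd.Series:
    """Shapiro-Wilk per element: True iff p > alpha (no evidence against
    normality). Supported for 3 <= n <= 5000."""
    n = table.n_sites
    if not (3 <= n <= 5000):
        raise ValueError("Shapiro-Wilk supported for 3 <= n <= 5000")
    flags = {}
    for el in table.elements:
        w, p = stats.shapiro(table.column(el).to_numpy())
        flags[el] = bool(p > alpha)
    return pd.Series(flags, name="normal")


# ---------------------------------------------------------------------------
# Factorability diagnostics
# ---------------------------------------------------------------------------

def _partial_correlations(r: np.ndarray) -> np.ndarray:
    """Partial correlation matrix from the scaled inverse correlation matrix."""
    rinv = np.linalg.inv(r)
    d = np.sqrt(np.outer(np.diag(rinv), np.diag(rinv)))
    partial = -rinv / d
    np.fill_diagonal(partial, 1.0)
    return partial


def kmo_statistic(corr: CorrelationMatrix | pd.DataFrame | np.ndarray) -> float:
    """Overall Kaiser-Meyer-Olkin measure of sampling adequacy.

    KMO = sum r_ij^2 / (sum r_ij^2 + sum q_ij^2) over off-diagonal pairs,
    where q are partial correlations from the inverted correlation matrix.
    Values near 1 indicate compact factors; below 0.5 the data are usually
    judged unsuited to factor analysis.
    """
    r = _as_corr_array(corr)
    try:
        partial = _partial_correlations(r)
    except np.linalg.LinAlgError:
        raise ValueError("KMO undefined: singular correlation matrix") from None
    off = ~np.eye(len(r), dtype=bool)
    r2 = float(np.sum(r[off] ** 2))
    q2 = float(np.sum(partial[off] ** 2))
    if r2 + q2 < 1e-12:
        raise ValueError("KMO undefined: negligible off-diagonal correlation")
    return r2 / (r2 + q2)


def bartlett_sphericity(
    corr: CorrelationMatrix | pd.DataFrame | np.ndarray, n: int | None = None
) -> tuple[float, float]:
    """Bartlett's test that the correlation matrix is the identity.

    chi2 = -(n - 1 - (2m + 5)/6) * ln det(R) on m(m-1)/2 degrees of freedom.
    """
    r = _as_corr_array(corr)
    if n is None:
        if isinstance(corr, CorrelationMatrix):
            n = corr.n
        else:
            raise ValueError("sample size n required")
    m = len(r)
    if n <= m:
        raise ValueError("Bartlett test needs n > number of variables")
    sign, logdet = np.linalg.slogdet(r)
    if sign <= 0:
        raise ValueError("correlation matrix not positive definite")
    chi2 = -(n - 1 - (2 * m + 5) / 6.0) * logdet
    df = m * (m - 1) / 2.0
    p = float(stats.chi2.sf(chi2, df))
    return float(chi2), p


def _as_corr_array(corr) -> np.ndarray:
    if isinstance(corr, CorrelationMatrix):
        r = corr.r.to_numpy(dtype=float)
    elif isinstance(corr, pd.DataFrame):
        r = corr.to_numpy(dtype=float)
    else:
        r = np.asarray(corr, dtype=float)
    if r.ndim != 2 or r.shape[0] != r.shape[1]:
        raise ValueError("correlation matrix must be square")
    return r
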
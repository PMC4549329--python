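"""Composition change between sampling years and periods.

Bray-Curtis dissimilarity among year-samples, a 2-D non-metric ordination
contract (the optimizer itself is delegated to a standard multidimensional
scaling routine), ordinary least-squares regressions of axis scores on year
and sampling effort, a family-composition chi-square between periods, and
Spearman rank correlations of per-species abundances between periods.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from sklearn.manifold import MDS

__all__ = [
    "RegressionResult",
    "CompositionTest",
    "OrdinationResult",
    "bray_curtis_matrix",
    "ordinate",
    "axis_trend_regression",
    "family_composition_test",
    "period_rank_correlation",
    "filter_year_samples",
]


def filter_year_samples(abundance: pd.DataFrame, min_individuals: int = 300) -> pd.DataFrame:
    """Keep year columns with at least ``min_individuals`` recorded."""
    totals = abundance.sum(axis=0)
    return abundance.loc[:, totals >= min_individuals]


def bray_curtis_matrix(abundance: pd.DataFrame) -> pd.DataFrame:
    """Bray-Curtis dissimilarity between samples (columns).

    d(i, j) = 1 - 2*sum(min(x_i, x_j)) / (sum(x_i) + sum(x_j)); symmetric,
    zero diagonal, values in [0, 1].
    """
    if abundance.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    totals = abundance.sum(axis=0)
    empty = totals[totals <= 0]
    if len(empty):
        raise ValueError(f"samples with zero total individuals: {list(empty.index)}")
    d = squareform(pdist(abundance.to_numpy().T, metric="braycurtis"))
    return pd.DataFrame(d, index=abundance.columns, columns=abundance.columns)


@dataclass
class OrdinationResult:
    coordinates: pd.DataFrame  # samples x dims
    stress: float
    dims: int


def ordinate(dissimilarity: pd.DataFrame, dims: int = 2, seed: int | None = 0,
             n_init: int = 8) -> OrdinationResult:
    """Non-metric multidimensional scaling of a dissimilarity matrix.

    The contract is rank preservation: embedded inter-point distances must
    correlate positively in rank with the input dissimilarities; the internal
    stress optimizer is standard methodology and delegated wholesale.
    """
    n = dissimilarity.shape[0]
    if dims >= n:
        raise ValueError(f"dims={dims} must be < number of samples ({n})")
    mds = MDS(
        n_components=dims, metric=False, dissimilarity="precomputed",
        random_state=seed, n_init=n_init, normalized_stress=True, max_iter=500,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        coords = mds.fit_transform(dissimilarity.to_numpy())
    return OrdinationResult(
        coordinates=pd.DataFrame(
            coords, index=dissimilarity.index,
            columns=[f"axis{k + 1}" for k in range(dims)],
        ),
        stress=float(mds.stress_),
        dims=dims,
    )


@dataclass
class RegressionResult:
    coefficients: dict[str, float]
    coef_p: dict[str, float]
    F: float
    p: float
    r2: float
    n: int


def axis_trend_regression(axis_scores, year, effort) -> RegressionResult:
    """OLS of ordination axis scores on calendar year and sampling effort."""
    y = np.asarray(axis_scores, dtype=float)
    year = np.asarray(year, dtype=float)
    effort = np.asarray(effort, dtype=float)
    n = y.size
    if n < 4:
        raise ValueError("need at least 4 samples")
    r = np.corrcoef(year, effort)[0, 1]
    if not np.isfinite(r) or abs(r) > 0.999:
        raise ValueError("year and effort are collinear")
    X = sm.add_constant(pd.DataFrame({"year": year, "effort": effort}))
    fit = sm.OLS(y, X).fit()
    return RegressionResult(
        coefficients={k: float(v) for k, v in fit.params.items()},
        coef_p={k: float(v) for k, v in fit.pvalues.items()},
        F=float(fit.fvalue),
        p=float(fit.f_pvalue),
        r2=float(fit.rsquared),
        n=n,
    )


@dataclass
class CompositionTest:
    table: pd.DataFrame
    chi2: float
    df: int
    p: float
    shares: pd.DataFrame  # per-family percentage by period


def family_composition_test(family_period_table: pd.DataFrame) -> CompositionTest:
    """Pearson chi-square on a family x period table of individuals.

    No continuity correction (the intended use is large multi-row tables).
    All-zero rows are dropped with a warning; remaining expected counts must
    be positive.
    """
    tab = family_period_table.copy()
    if tab.shape[1] != 2:
        raise ValueError("expected exactly 2 period columns")
    zero = tab.sum(axis=1) == 0
    if zero.any():
        warnings.warn(f"dropping all-zero rows: {list(tab.index[zero])}", stacklevel=2)
        tab = tab.loc[~zero]
    if tab.shape[0] < 2:
        raise ValueError("need at least 2 non-zero rows")
    chi2, p, df, expected = stats.chi2_contingency(tab.to_numpy(), correction=False)
    if np.any(expected <= 0):
        raise ValueError("zero expected counts in chi-square table")
    shares = 100.0 * tab / tab.sum(axis=0)
    return CompositionTest(table=tab, chi2=float(chi2), df=int(df), p=float(p),
                           shares=shares)


def period_rank_correlation(
    counts_a: pd.Series,
    counts_b: pd.Series,
    inclusion_rule=None,
) -> tuple[float, int, float]:
    """Spearman correlation of per-species counts between two samples.

    ``inclusion_rule(a, b) -> bool mask`` selects species; the default keeps
    species non-zero in at least one of the two vectors.  Returns
    ``(r_s, n, p)`` with average-rank tie handling.
    """
    a, b = counts_a.align(counts_b, fill_value=0)
    if inclusion_rule is None:
        mask = (a > 0) | (b > 0)
    else:
        mask = inclusion_rule(a, b)
    a, b = a[mask], b[mask]
    n = int(mask.sum())
    if n < 3:
        raise ValueError("fewer than 3 species included")
    if a.nunique() == 1 or b.nunique() == 1:
        raise ValueError("correlation undefined: a vector is constant")
    rho, p = stats.spearmanr(a, b)
    return float(rho), n, float(p)
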
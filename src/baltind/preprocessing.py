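"""Transformation, normality checks, gap imputation and baselining.

Indicator series from monitoring data are strongly right-skewed
(lognormal-like), so each series is Box-Cox transformed before any
control-chart or regression analysis.  Gaps (missing years) in the
transformed indicator matrix are filled by eigenvector filtering — an
EM-style reconstruction from the leading principal axes.  Finally each
transformed series is standardised to z-scores

    z_t = (x_t - mu) / sigma

against a *baseline*: either the whole series or a reference-condition
year window, whose mean and SD become the controlling parameters of the
control charts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from scipy.optimize import minimize_scalar
from statsmodels.stats.diagnostic import lilliefors

from .io import RefConKind, RefConWindow

log = logging.getLogger(__name__)

__all__ = [
    "TransformResult",
    "Baseline",
    "ZScoreSeries",
    "NormalityResult",
    "EvfResult",
    "boxcox_fit_transform",
    "apply_boxcox",
    "inverse_boxcox",
    "ks_normality",
    "evf_impute",
    "make_baseline",
    "standardize",
    "cv_percent",
    "zscore_matrix",
]

#: bounds of the Box-Cox exponent search
LAMBDA_BOUNDS = (-2.0, 3.0)


@dataclass(frozen=True)
class TransformResult:
    """A fitted Box-Cox transform: exponent, pre-shift and transformed values."""

    lmbda: float
    shift: float
    transformed: pd.Series

    def inverse(self, y: pd.Series | np.ndarray) -> np.ndarray:
        """Map transformed values back to the original indicator scale."""
        return inverse_boxcox(y, self.lmbda, self.shift)


@dataclass(frozen=True)
class Baseline:
    """Controlling mean/SD of a transformed series over a year window."""

    mu: float
    sigma: float
    kind: RefConKind
    window: RefConWindow | None
    n_years: int

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise ValueError(f"baseline sigma must be > 0, got {self.sigma}")


@dataclass(frozen=True)
class ZScoreSeries:
    """z-scores of one indicator series against a baseline."""

    values: pd.Series
    baseline: Baseline


@dataclass(frozen=True)
class NormalityResult:
    """Lilliefors-corrected Kolmogorov-Smirnov test against normality."""

    eligible: bool
    n: int
    statistic: float | None = None
    pvalue: float | None = None


@dataclass(frozen=True)
class EvfResult:
    """Eigenvector-filtering imputation output."""

    completed: pd.DataFrame
    imputed: pd.DataFrame  # boolean mask of filled cells
    n_iter: int
    n_axes: int


# ---------------------------------------------------------------------------
# Box-Cox

def _shift_for(x: np.ndarray) -> float:
    """Additive offset making all values strictly positive.

    Zero if the minimum is already positive; half the smallest positive
    value when zeros occur (ratios can be exactly 0 in predator-free
    years).  Negative values are not meaningful for these indicators.
    """
    mn = np.min(x)
    if mn > 0:
        return 0.0
    if mn < 0:
        raise ValueError("negative values cannot be Box-Cox transformed")
    pos = x[x > 0]
    if pos.size == 0:
        raise ValueError("all-zero series cannot be Box-Cox transformed")
    return float(pos.min() / 2.0)


def apply_boxcox(x, lmbda: float, shift: float = 0.0) -> np.ndarray:
    """Box-Cox transform with a fixed exponent: ((x+shift)^l - 1)/l, log at l=0."""
    return stats.boxcox(np.asarray(x, dtype=float) + shift, lmbda=lmbda)


def inverse_boxcox(y, lmbda: float, shift: float = 0.0) -> np.ndarray:
    """Inverse of :func:`apply_boxcox`."""
    return special.inv_boxcox(np.asarray(y, dtype=float), lmbda) - shift


def boxcox_fit_transform(
    series: pd.Series,
    lmbda: float | None = None,
    bounds: tuple[float, float] = LAMBDA_BOUNDS,
) -> TransformResult:
    """Fit a Box-Cox exponent by maximum likelihood and transform.

    The exponent is found by bounded scalar maximisation of the Box-Cox
    log-likelihood on ``bounds`` (default [-2, 3], convergence tolerance
    1e-4).  Missing values are ignored for fitting and preserved in the
    output.  Requires >= 5 non-missing values; a constant series is an
    error (the exponent is undefined).
    """
    obs = series.dropna()
    if len(obs) < 5:
        raise ValueError(f"need >= 5 non-missing values, got {len(obs)}")
    x = obs.to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("constant series: Box-Cox exponent undefined")
    shift = _shift_for(x)
    if lmbda is None:
        res = minimize_scalar(
            lambda l: -stats.boxcox_llf(l, x + shift),
            bounds=bounds,
            method="bounded",
            options={"xatol": 1e-4},
        )
        lmbda = float(res.x)
    transformed = pd.Series(np.nan, index=series.index, name=series.name)
    transformed[obs.index] = apply_boxcox(x, lmbda, shift)
    return TransformResult(lmbda=float(lmbda), shift=shift, transformed=transformed)


# ---------------------------------------------------------------------------
# normality

def ks_normality(series: pd.Series, n_min: int = 12) -> NormalityResult:
    """Kolmogorov-Smirnov test against a normal with estimated mean/SD.

    Uses the Lilliefors correction for estimated parameters (the plain KS
    test is anti-conservative when mu and sigma come from the sample).
    Series shorter than ``n_min`` (default 12 years) are reported as not
    eligible rather than tested.
    """
    x = pd.Series(series).dropna().to_numpy(dtype=float)
    n = x.size
    if n < n_min:
        return NormalityResult(eligible=False, n=n)
    stat, p = lilliefors(x, dist="norm", pvalmethod="table")
    return NormalityResult(eligible=True, n=n, statistic=float(stat), pvalue=float(p))


# ---------------------------------------------------------------------------
# eigenvector-filtering imputation

def evf_impute(
    matrix: pd.DataFrame,
    max_axes: int = 3,
    var_frac: float = 0.8,
    tol: float = 1e-6,
    max_iter: int = 500,
    min_obs_frac: float = 0.6,
) -> EvfResult:
    """Fill gaps in a years x indicators matrix from its leading axes.

    EM-style iteration: gaps start at column means; the standardised
    matrix is decomposed by SVD, reconstructed from the leading ``m``
    axes (the smallest number explaining ``var_frac`` of the variance,
    capped at ``max_axes`` and at n_columns - 1), the gap cells are
    replaced by the reconstruction, and the loop repeats until the
    relative change on the gap cells drops below ``tol``.  Observed cells
    are never modified.

    Raises on columns with more than ``1 - min_obs_frac`` missing, on
    fewer than two columns, and on non-convergence (the error carries the
    iteration trace).
    """
    if matrix.shape[1] < 2:
        raise ValueError("need at least two indicator columns")
    X = matrix.to_numpy(dtype=float).copy()
    mask = np.isnan(X)
    obs_frac = 1.0 - mask.mean(axis=0)
    thin = obs_frac < min_obs_frac
    if thin.any():
        bad = list(matrix.columns[thin])
        raise ValueError(f"columns with < {min_obs_frac:.0%} observed: {bad}")
    if not mask.any():
        return EvfResult(matrix.copy(), pd.DataFrame(mask, index=matrix.index,
                                                     columns=matrix.columns), 0, 0)

    col_mean = np.nanmean(np.where(mask, np.nan, X), axis=0)
    X[mask] = np.take(col_mean, np.nonzero(mask)[1])

    trace: list[float] = []
    n_axes = 1
    for it in range(1, max_iter + 1):
        mu = X.mean(axis=0)
        sd = X.std(axis=0, ddof=1)
        if np.any(sd == 0):
            raise ValueError("constant column in imputation matrix")
        Z = (X - mu) / sd
        U, s, Vt = np.linalg.svd(Z, full_matrices=False)
        var = s**2 / np.sum(s**2)
        m = int(np.searchsorted(np.cumsum(var), var_frac) + 1)
        n_axes = max(1, min(m, max_axes, X.shape[1] - 1))
        Zhat = (U[:, :n_axes] * s[:n_axes]) @ Vt[:n_axes]
        Xhat = Zhat * sd + mu
        old = X[mask]
        new = Xhat[mask]
        scale = np.maximum(np.max(np.abs(new)), 1e-12)
        delta = float(np.max(np.abs(new - old)) / scale)
        X[mask] = new
        trace.append(delta)
        if delta < tol:
            completed = pd.DataFrame(X, index=matrix.index, columns=matrix.columns)
            return EvfResult(
                completed,
                pd.DataFrame(mask, index=matrix.index, columns=matrix.columns),
                it,
                n_axes,
            )
    raise RuntimeError(
        f"eigenvector imputation did not converge in {max_iter} iterations; "
        f"last deltas: {trace[-5:]}"
    )


# ---------------------------------------------------------------------------
# baselining

def make_baseline(
    transformed: pd.Series,
    window: RefConWindow | None = None,
    min_years: int = 5,
) -> Baseline:
    """Controlling mean/SD of a (transformed) series.

    ``window=None`` uses the entire series (first reference-setting
    strategy); otherwise only the years inside the window (second
    strategy, RefCon windows supplied by the user).  The SD is the sample
    SD (ddof=1) of the window years with data; at least ``min_years``
    such years are required.
    """
    s = transformed.dropna()
    if window is not None:
        s = s[(s.index >= window.start_year) & (s.index <= window.end_year)]
        kind = window.kind
    else:
        kind = RefConKind.entire
    n = len(s)
    if n < min_years:
        raise ValueError(
            f"baseline window has {n} years with data; need >= {min_years}"
        )
    sigma = float(s.std(ddof=1))
    if sigma <= 0:
        raise ValueError("baseline sigma is zero (constant window)")
    return Baseline(mu=float(s.mean()), sigma=sigma, kind=kind, window=window, n_years=n)


def standardize(transformed: pd.Series, baseline: Baseline) -> ZScoreSeries:
    """z = (x - mu) / sigma for every year, including years outside the window."""
    z = (transformed - baseline.mu) / baseline.sigma
    return ZScoreSeries(values=z, baseline=baseline)


def cv_percent(series) -> float:
    """Coefficient of variation, 100 x SD / |mean| (SD with n-1 denominator)."""
    x = pd.Series(series).dropna().to_numpy(dtype=float)
    mean = x.mean()
    if mean == 0:
        raise ValueError("CV%% undefined for zero mean")
    return float(100.0 * x.std(ddof=1) / abs(mean))


# ---------------------------------------------------------------------------
# pipeline helper

def zscore_matrix(
    indicator_wide: pd.DataFrame,
    window: RefConWindow | None = None,
    impute: bool = True,
    min_years: int = 5,
) -> tuple[pd.DataFrame, dict[str, Baseline], dict[str, TransformResult], pd.DataFrame]:
    """Transform, impute and standardise one dataset's indicator matrix.

    Order of operations: Box-Cox each column, eigenvector-impute the
    transformed matrix, then z-score each column against its baseline
    (entire series or the given window).

    Parameters
    ----------
    indicator_wide
        Years x indicators values for a single dataset (index = year).

    Returns
    -------
    (z, baselines, transforms, imputed_mask) where ``z`` is the years x
    indicators z-score matrix.
    """
    transforms: dict[str, TransformResult] = {}
    tmat = pd.DataFrame(index=indicator_wide.index)
    for col in indicator_wide.columns:
        tr = boxcox_fit_transform(indicator_wide[col])
        transforms[col] = tr
        tmat[col] = tr.transformed

    if impute and tmat.isna().any().any():
        evf = evf_impute(tmat)
        tmat, imputed = evf.completed, evf.imputed
    else:
        imputed = pd.DataFrame(False, index=tmat.index, columns=tmat.columns)

    baselines: dict[str, Baseline] = {}
    z = pd.DataFrame(index=tmat.index)
    for col in tmat.columns:
        b = make_baseline(tmat[col], window=window, min_years=min_years)
        baselines[col] = b
        z[col] = standardize(tmat[col], b).values
    return z, baselines, transforms, imputed
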
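"""Logistic GES-prediction models and the two-dimensional MSTS status.

Which indicators predict whether the zooplankton community is inside a
reference state?  Years are labelled 1 (*in control*) or 0 (*out of
control*) from the control-chart classification and modelled with
binomial (logistic) regression on the indicator z-scores.  Candidate
predictor subsets (up to ``max_terms``) are screened for collinearity by
variance inflation factors, fitted exhaustively, ranked by AIC, and a
parsimony rule resolves near-ties: when a simpler nested model has a
similar AIC (within 2) and a likelihood-ratio test finds no significant
difference (p > 0.05), the simpler model wins.  Prediction accuracy is
reported as in-sample percent-correct at a 0.5 probability cutoff, with a
confusion-table odds ratio.

The **MSTS** status combines the community mean individual size
(MeanSize) with the total stock (TZA or TZB), both as z-scores against a
reference baseline: both at or above the threshold is in-GES (green),
one failing is sub-GES (orange), both failing is red.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

log = logging.getLogger(__name__)

__all__ = [
    "LogisticModel",
    "ClassificationMetrics",
    "MSTSStatus",
    "fit_logistic",
    "vif_scores",
    "aic_model_search",
    "ModelSearchResult",
    "classification_metrics",
    "msts_classify",
]

#: |coefficient| beyond which a binary-predictor fit is treated as separated
_SEPARATION_BETA = 15.0


@dataclass
class LogisticModel:
    """A fitted binomial regression of in-control state on indicators."""

    predictors: list[str]
    beta: pd.Series  # includes "const"
    se: pd.Series
    wald: pd.Series  # (beta/se)^2, chi-square with 1 df
    p: pd.Series
    aic: float
    loglik: float
    deviance: float
    pearson_chi2: float
    n_obs: int
    separation: bool = False

    @property
    def n_params(self) -> int:
        return len(self.beta)

    @property
    def odds_ratios(self) -> pd.Series:
        """exp(beta): multiplicative change in the in-control odds per z-unit."""
        return np.exp(self.beta.drop("const", errors="ignore"))

    def predict(self, zmat: pd.DataFrame) -> pd.Series:
        X = _design(zmat, self.predictors)
        eta = X.to_numpy() @ self.beta.reindex(X.columns).to_numpy()
        return pd.Series(1.0 / (1.0 + np.exp(-eta)), index=zmat.index)


@dataclass(frozen=True)
class ClassificationMetrics:
    cutoff: float
    sensitivity: float | None  # % of in-control years predicted in-control
    specificity: float | None  # % of out-of-control years predicted out
    overall: float
    odds_ratio: float | None  # (TP*TN)/(FP*FN) from the confusion table


@dataclass(frozen=True)
class MSTSStatus:
    """Quadrant of the (MeanSize, stock) z-score plane.

    ``status`` is ``green`` when both components are at or above the
    threshold, ``red`` when both are below, and names the *adequate*
    component otherwise: ``orange_size_only`` = size adequate but stock
    failing, ``orange_stock_only`` = stock adequate but size failing.
    """

    z_size: float
    z_stock: float
    stock_metric: str  # TZA or TZB
    threshold: float
    status: str


def _design(zmat: pd.DataFrame, predictors: list[str]) -> pd.DataFrame:
    missing = [p for p in predictors if p not in zmat.columns]
    if missing:
        raise KeyError(f"predictors not in z matrix: {missing}")
    X = zmat[list(predictors)].copy() if predictors else pd.DataFrame(index=zmat.index)
    X.insert(0, "const", 1.0)
    return X


def fit_logistic(
    labels: pd.Series,
    zmat: pd.DataFrame,
    predictors: list[str] | None = None,
    dataset: pd.Series | None = None,
    min_per_class: int = 3,
) -> LogisticModel:
    """Maximum-likelihood binomial regression (IRLS).

    ``labels`` is 1 for in-control years, 0 for out-of-control years,
    indexed like ``zmat``.  ``dataset`` optionally adds a categorical
    area term via reference-coded dummies.  Complete separation is
    flagged on the result (diverging coefficients), not silently
    returned.
    """
    predictors = list(predictors or [])
    y = labels.reindex(zmat.index).astype(float)
    if y.isna().any():
        raise ValueError("labels missing for some years in the z matrix")
    counts = y.value_counts()
    if counts.get(0.0, 0) < min_per_class or counts.get(1.0, 0) < min_per_class:
        raise ValueError(
            f"need >= {min_per_class} years per class, got {counts.to_dict()}"
        )
    X = _design(zmat, predictors)
    if dataset is not None:
        dummies = pd.get_dummies(
            dataset.reindex(zmat.index), prefix="dataset", drop_first=True
        ).astype(float)
        X = pd.concat([X, dummies], axis=1)

    with warnings.catch_warnings(record=True) as caught, np.errstate(
        over="ignore", divide="ignore", invalid="ignore"
    ):
        warnings.simplefilter("always")
        res = sm.GLM(y, X, family=sm.families.Binomial()).fit(
            maxiter=200, tol=1e-10
        )
        # force lazy statistics inside the suppression context: they hit
        # overflow on separated fits
        aic, llf = float(res.aic), float(res.llf)
        deviance, pearson = float(res.deviance), float(res.pearson_chi2)
    separated = any("separat" in str(w.message).lower() for w in caught)
    slopes = res.params.drop("const", errors="ignore")
    if len(slopes) and np.max(np.abs(slopes)) > _SEPARATION_BETA:
        separated = True
    if separated:
        log.warning("fit_logistic: complete or quasi-separation detected")

    beta = res.params
    se = res.bse
    wald = (beta / se) ** 2
    p = pd.Series(stats.chi2.sf(wald, df=1), index=beta.index)
    return LogisticModel(
        predictors=predictors,
        beta=beta,
        se=se,
        wald=wald,
        p=p,
        aic=aic,
        loglik=llf,
        deviance=deviance,
        pearson_chi2=pearson,
        n_obs=int(res.nobs),
        separation=bool(separated),
    )


def vif_scores(zmat: pd.DataFrame, predictors: list[str]) -> pd.Series:
    """Variance inflation factors: VIF_j = 1 / (1 - R2_j).

    R2_j comes from regressing predictor j (with intercept) on the other
    predictors.  Perfect collinearity is reported as ``inf``.
    """
    if len(predictors) < 2:
        raise ValueError("need >= 2 predictors for VIF")
    X = zmat[list(predictors)].to_numpy(dtype=float)
    if X.shape[0] <= X.shape[1] + 1:
        raise ValueError("need n > number of predictors + 1")
    out = {}
    for j, name in enumerate(predictors):
        yj = X[:, j]
        others = np.column_stack(
            [np.ones(X.shape[0]), np.delete(X, j, axis=1)]
        )
        coef, *_ = np.linalg.lstsq(others, yj, rcond=None)
        resid = yj - others @ coef
        sst = np.sum((yj - yj.mean()) ** 2)
        r2 = 1.0 - np.sum(resid**2) / sst if sst > 0 else 1.0
        out[name] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out, name="VIF")


@dataclass
class ModelSearchResult:
    winner: LogisticModel
    ranked: list[LogisticModel] = field(default_factory=list)

    def table(self) -> pd.DataFrame:
        """Summary table: predictors, AIC, log-likelihood per candidate."""
        return pd.DataFrame(
            {
                "predictors": ["+".join(m.predictors) or "(intercept)" for m in self.ranked],
                "aic": [m.aic for m in self.ranked],
                "loglik": [m.loglik for m in self.ranked],
                "n_params": [m.n_params for m in self.ranked],
            }
        )


def _lrt_p(simple: LogisticModel, complex_: LogisticModel) -> float:
    lr = 2.0 * (complex_.loglik - simple.loglik)
    df = complex_.n_params - simple.n_params
    return float(stats.chi2.sf(max(lr, 0.0), df=max(df, 1)))


def aic_model_search(
    labels: pd.Series,
    zmat: pd.DataFrame,
    candidates: list[str],
    max_terms: int = 3,
    vif_threshold: float = 3.0,
    delta_aic: float = 2.0,
    lrt_alpha: float = 0.05,
    dataset: pd.Series | None = None,
) -> ModelSearchResult:
    """Exhaustive AIC search over predictor subsets with a parsimony rule.

    Subsets of size <= ``max_terms`` (including the intercept-only model)
    are fitted after screening out subsets with any within-subset VIF >=
    ``vif_threshold``.  Models are ranked by AIC; then, among models with
    AIC within ``delta_aic`` of the best that are nested inside the best
    model, the simplest one whose likelihood-ratio test against the best
    is non-significant (p > ``lrt_alpha``) is chosen instead.
    """
    fitted: list[LogisticModel] = []
    for size in range(0, max_terms + 1):
        for subset in itertools.combinations(candidates, size):
            subset = list(subset)
            if len(subset) >= 2:
                vifs = vif_scores(zmat, subset)
                if (vifs >= vif_threshold).any():
                    continue
            try:
                m = fit_logistic(labels, zmat, subset, dataset=dataset)
            except (ValueError, np.linalg.LinAlgError):
                continue
            fitted.append(m)
    if not fitted:
        raise RuntimeError("no candidate model converged")
    ranked = sorted(fitted, key=lambda m: (m.aic, m.n_params))
    best = ranked[0]
    winner = best
    near = [
        m
        for m in ranked
        if m.aic - best.aic <= delta_aic
        and m.n_params < winner.n_params
        and set(m.predictors) < set(winner.predictors)
    ]
    for m in sorted(near, key=lambda m: (m.n_params, m.aic)):
        if _lrt_p(m, winner) > lrt_alpha:
            winner = m
            break
    return ModelSearchResult(winner=winner, ranked=ranked)


def classification_metrics(
    model: LogisticModel,
    labels: pd.Series,
    zmat: pd.DataFrame,
    cutoff: float = 0.5,
) -> ClassificationMetrics:
    """In-sample confusion-table accuracy at the probability cutoff.

    Sensitivity = % of in-control (label 1) years predicted in-control,
    specificity = % of out-of-control years predicted out-of-control.
    With a class absent the corresponding percentage is undefined
    (``None``), as is the odds ratio when any cell is empty.
    """
    y = labels.reindex(zmat.index).astype(int)
    pred = (model.predict(zmat) >= cutoff).astype(int)
    tp = int(((y == 1) & (pred == 1)).sum())
    fn = int(((y == 1) & (pred == 0)).sum())
    tn = int(((y == 0) & (pred == 0)).sum())
    fp = int(((y == 0) & (pred == 1)).sum())
    n_in = tp + fn
    n_out = tn + fp
    sens = 100.0 * tp / n_in if n_in else None
    spec = 100.0 * tn / n_out if n_out else None
    overall = 100.0 * (tp + tn) / len(y)
    odds = (tp * tn) / (fp * fn) if fp and fn else None
    return ClassificationMetrics(
        cutoff=cutoff, sensitivity=sens, specificity=spec,
        overall=overall, odds_ratio=odds,
    )


def msts_classify(
    z_size: float,
    z_stock: float,
    threshold: float = 0.0,
    stock_metric: str = "TZB",
) -> MSTSStatus:
    """Quadrant classification of mean size and total stock z-scores.

    Both components at or above ``threshold`` (default 0, the baseline
    mean): green / in-GES.  Both below: red.  Exactly one adequate:
    orange, named after the adequate component.  A missing component
    yields status ``undetermined``.
    """
    if stock_metric not in ("TZA", "TZB"):
        raise ValueError("stock_metric must be 'TZA' or 'TZB'")
    if pd.isna(z_size) or pd.isna(z_stock):
        status = "undetermined"
    else:
        size_ok = z_size >= threshold
        stock_ok = z_stock >= threshold
        if size_ok and stock_ok:
            status = "green"
        elif size_ok:
            status = "orange_size_only"
        elif stock_ok:
            status = "orange_stock_only"
        else:
            status = "red"
    return MSTSStatus(
        z_size=float(z_size) if not pd.isna(z_size) else np.nan,
        z_stock=float(z_stock) if not pd.isna(z_stock) else np.nan,
        stock_metric=stock_metric,
        threshold=threshold,
        status=status,
    )
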
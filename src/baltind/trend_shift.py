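"""Monotonic trends, chronological breakpoints and variance shifts.

Three questions about an indicator (z-score) series:

* is there a monotonic trend? — non-parametric **Mann-Kendall** test
  (score S, tie-corrected Kendall tau, continuity-corrected normal
  p-value, exact null distribution for short tie-free series);
* when did the community shift abruptly? — **chronological clustering**:
  agglomerative clustering constrained to temporally adjacent groups of
  years, where two neighbouring groups merge only while a permutation
  test cannot reject their homogeneity at sensitivity ``alpha``; group
  distances use proportional-link linkage at the ``connectedness``
  level (0.5 = median inter-group link).  Boundaries of the final groups
  are the breakpoint years; a larger ``alpha`` is a stricter merge gate
  and so yields at least as fine a partition;
* did variability change after a split year? — a variance-ratio
  **F-test** of the post- versus pre-split sample variances.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

__all__ = [
    "TrendResult",
    "ClusteringParams",
    "ClusteringResult",
    "mann_kendall",
    "chronological_clustering",
    "breakpoints_by_alpha",
    "variance_shift_test",
]


@dataclass(frozen=True)
class TrendResult:
    S: int
    tau: float
    p: float
    direction: str  # up / down / none


@dataclass(frozen=True)
class ClusteringParams:
    alpha: float = 0.05
    connectedness: float = 0.5
    n_permutations: int = 999
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not 0 < self.connectedness <= 1:
            raise ValueError("connectedness must be in (0, 1]")


@dataclass
class ClusteringResult:
    groups: list[list[int]]  # year labels, temporally contiguous
    breakpoints: list[int]  # first year of each group after the first
    singletons: list[int] = field(default_factory=list)
    params: ClusteringParams = field(default_factory=ClusteringParams)


# ---------------------------------------------------------------------------
# Mann-Kendall

def _exact_s_pvalue(s_obs: int, n: int) -> float:
    """Two-sided exact P(|S| >= |s_obs|) for tie-free data.

    The null distribution of the number of inversions has generating
    function prod_{i=1..n} (1 + x + ... + x^(i-1)); S = n(n-1)/2 - 2*inv.
    """
    counts = np.array([1.0])
    for i in range(2, n + 1):
        counts = np.convolve(counts, np.ones(i))
    total = counts.sum()
    m = n * (n - 1) // 2
    s_vals = m - 2 * np.arange(counts.size)  # S for each inversion count
    return float(counts[np.abs(s_vals) >= abs(s_obs)].sum() / total)


def mann_kendall(series, alpha: float = 0.05, exact_n_max: int = 9) -> TrendResult:
    """Mann-Kendall test for a monotonic upward or downward trend.

    S is the sum of signs over all ordered pairs; tau is the tie-corrected
    (tau-b) correlation with time; the p-value uses the tie-corrected
    variance with continuity correction for n >= 10 and the exact null
    distribution for shorter tie-free series.  A constant series returns
    tau = 0, p = 1.  ``direction`` reports the trend sign when p < alpha.
    """
    x = pd.Series(series).dropna().to_numpy(dtype=float)
    n = x.size
    if n < 4:
        raise ValueError(f"need >= 4 values, got {n}")

    sign = np.sign(x[None, :] - x[:, None])
    S = int(np.triu(sign, k=1).sum())

    _, tie_counts = np.unique(x, return_counts=True)
    ties = tie_counts[tie_counts > 1]
    n0 = n * (n - 1) / 2
    t_corr = float(np.sum(ties * (ties - 1) / 2))
    denom = np.sqrt((n0 - t_corr) * n0)
    tau = 0.0 if denom == 0 else S / denom

    if denom == 0:  # constant series
        return TrendResult(S=0, tau=0.0, p=1.0, direction="none")

    if n <= exact_n_max and ties.size == 0:
        p = _exact_s_pvalue(S, n)
    else:
        var = (
            n * (n - 1) * (2 * n + 5) - np.sum(ties * (ties - 1) * (2 * ties + 5))
        ) / 18.0
        if S > 0:
            zstat = (S - 1) / np.sqrt(var)
        elif S < 0:
            zstat = (S + 1) / np.sqrt(var)
        else:
            zstat = 0.0
        p = float(2 * stats.norm.sf(abs(zstat)))

    direction = "none"
    if p < alpha:
        direction = "up" if S > 0 else "down"
    return TrendResult(S=S, tau=float(tau), p=p, direction=direction)


# ---------------------------------------------------------------------------
# chronological clustering

def _block_rng(seed: int | None, span: tuple[int, int]):
    # deterministic per-block stream so the same pooled block gets the
    # same permutations at every alpha level
    base = 0 if seed is None else int(seed)
    return np.random.default_rng([base, *span])


def _max_split_ratio(X: np.ndarray) -> np.ndarray:
    """Max between/within dispersion ratio over all contiguous splits.

    ``X`` has shape (..., n, d); the ratio SSB/(SST-SSB) is maximised
    over split points 1..n-1 of the last-but-one axis.
    """
    n = X.shape[-2]
    grand = X.mean(axis=-2, keepdims=True)
    sst = np.sum((X - grand) ** 2, axis=(-2, -1))
    cs = np.cumsum(X, axis=-2)
    total = cs[..., -1, :]
    sizes = np.arange(1, n)
    best = np.zeros(X.shape[:-2])
    for s in sizes:
        mean_a = cs[..., s - 1, :] / s
        mean_b = (total - cs[..., s - 1, :]) / (n - s)
        g = grand[..., 0, :]
        ssb = s * np.sum((mean_a - g) ** 2, axis=-1) + (n - s) * np.sum(
            (mean_b - g) ** 2, axis=-1
        )
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(ssb >= sst, np.inf, ssb / (sst - ssb))
        best = np.maximum(best, ratio)
    return best


def _homogeneity_p(X: np.ndarray, n_perm: int, rng: np.random.Generator) -> float:
    """Permutation test: is this block of consecutive years homogeneous?

    The statistic is the maximum between/within dispersion ratio over all
    contiguous splits of the block, for the observed ordering and for row
    permutations alike.  Taking the max on both sides corrects for the
    fact that candidate boundaries are data-selected, so a rejected block
    is heterogeneous at level alpha regardless of where its boundary was
    proposed.
    """
    n = X.shape[0]
    sst = float(np.sum((X - X.mean(axis=0)) ** 2))
    if sst == 0:
        return 1.0
    obs = float(_max_split_ratio(X))
    perms = np.argsort(rng.random((n_perm, n)), axis=1)
    sim = _max_split_ratio(X[perms])
    return float((1 + np.sum(sim >= obs)) / (n_perm + 1))


def _prop_link_distance(
    XA: np.ndarray, XB: np.ndarray, connectedness: float
) -> float:
    """Proportional-link linkage: the ``connectedness`` quantile of the
    inter-group Euclidean distances (0.5 = median link, 1 = complete)."""
    d = np.sqrt(
        np.sum((XA[:, None, :] - XB[None, :, :]) ** 2, axis=-1)
    ).ravel()
    return float(np.quantile(d, connectedness))


def chronological_clustering(
    zmat: pd.DataFrame,
    params: ClusteringParams = ClusteringParams(),
) -> ClusteringResult:
    """Partition a years x indicators matrix into homogeneous eras.

    Starts from singleton years and repeatedly merges the pair of
    temporally adjacent groups with the smallest proportional-link
    distance, provided the permutation homogeneity test does not reject
    at level ``params.alpha``.  A rejected boundary is retested only when
    one of its groups changes.  Boundaries remaining at the end are the
    breakpoints (reported as the first year of the later group).
    """
    if zmat.isna().any().any():
        raise ValueError("z matrix contains missing cells; impute first")
    years = np.asarray(zmat.index)
    if years.size < 6:
        raise ValueError(f"need >= 6 years, got {years.size}")
    if np.any(np.diff(years) <= 0):
        raise ValueError("years must be strictly increasing")

    X = zmat.to_numpy(dtype=float)
    groups: list[list[int]] = [[i] for i in range(len(years))]
    rejected: set[tuple[int, int]] = set()  # keyed by (start_idx_A, start_idx_B)

    def span(g: list[int]) -> tuple[int, int]:
        return int(years[g[0]]), int(years[g[-1]])

    while True:
        candidates = []
        for gi in range(len(groups) - 1):
            key = (groups[gi][0], groups[gi + 1][0])
            if key in rejected:
                continue
            d = _prop_link_distance(
                X[groups[gi]], X[groups[gi + 1]], params.connectedness
            )
            candidates.append((d, gi, key))
        if not candidates:
            break
        _, gi, key = min(candidates, key=lambda c: (c[0], c[1]))
        A, B = groups[gi], groups[gi + 1]
        block_span = (span(A)[0], span(B)[1])
        rng = _block_rng(params.seed, block_span)
        p = _homogeneity_p(X[A + B], params.n_permutations, rng)
        if p > params.alpha:
            groups[gi : gi + 2] = [A + B]
            # boundaries touching the changed group must be retested;
            # keys whose groups no longer exist are dropped too
            starts = {g[0] for g in groups}
            merged_start = groups[gi][0]
            rejected = {
                k
                for k in rejected
                if k[0] in starts
                and k[1] in starts
                and merged_start not in k
            }
        else:
            rejected.add(key)

    breakpoints = [int(years[g[0]]) for g in groups[1:]]
    singletons = [int(years[g[0]]) for g in groups if len(g) == 1]
    if singletons:
        log.info("chronological_clustering: singleton groups at %s", singletons)
    return ClusteringResult(
        groups=[[int(years[i]) for i in g] for g in groups],
        breakpoints=breakpoints,
        singletons=singletons,
        params=params,
    )


def breakpoints_by_alpha(
    zmat: pd.DataFrame,
    alphas=(0.01, 0.05, 0.1),
    connectedness: float = 0.5,
    n_permutations: int = 999,
    seed: int | None = None,
) -> dict[float, list[int]]:
    """Breakpoint years at each sensitivity level (shared permutations)."""
    out = {}
    for a in alphas:
        res = chronological_clustering(
            zmat,
            ClusteringParams(
                alpha=a,
                connectedness=connectedness,
                n_permutations=n_permutations,
                seed=seed,
            ),
        )
        out[a] = res.breakpoints
    return out


# ---------------------------------------------------------------------------
# variance shift

def variance_shift_test(
    series: pd.Series,
    split_year: int,
    alternative: str = "greater",
) -> tuple[float, float]:
    """F-test of a variance change after ``split_year``.

    F = s2_post / s2_pre with (n_post - 1, n_pre - 1) degrees of freedom;
    years >= ``split_year`` form the post group.  ``alternative`` is
    ``"greater"`` (variance increase, the usual question) or
    ``"two-sided"``.  Needs >= 3 years with data on each side; zero
    pre-split variance is an error.
    """
    s = pd.Series(series).dropna()
    pre = s[s.index < split_year].to_numpy(dtype=float)
    post = s[s.index >= split_year].to_numpy(dtype=float)
    if pre.size < 3 or post.size < 3:
        raise ValueError(
            f"need >= 3 years each side of {split_year}; "
            f"got {pre.size} pre, {post.size} post"
        )
    v_pre = pre.var(ddof=1)
    v_post = post.var(ddof=1)
    if v_pre == 0:
        raise ValueError("zero pre-split variance")
    F = float(v_post / v_pre)
    dfn, dfd = post.size - 1, pre.size - 1
    sf = stats.f.sf(F, dfn, dfd)
    if alternative == "greater":
        p = float(sf)
    elif alternative == "two-sided":
        p = float(2 * min(sf, stats.f.cdf(F, dfn, dfd)))
    else:
        raise ValueError("alternative must be 'greater' or 'two-sided'")
    return F, p
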
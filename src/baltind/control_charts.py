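"""Shewhart and decision-interval CuSum control charts on z-score series.

Given z-scores of an indicator against a baseline (controlling mean mu
and SD sigma), two complementary charts flag departures from reference
conditions:

* the **Shewhart chart** flags single years beyond fixed limits — +/-3
  z-units for reference-window baselines, or the z-equivalent of a
  two-sided 99% normal interval (+/-2.576) for entire-series baselines;
* the **decision-interval CuSum** accumulates persistent small shifts:

      S+_i = max(0, S+_{i-1} + z_i - k)      (upper, Eq. S+_0 = 0)
      S-_i = min(0, S-_{i-1} + z_i + k)      (lower, S-_0 = 0)

  with allowance ``k`` (default 0.5, tuned to detect a 1-sigma shift in
  the process mean) and an alarm when S+ exceeds the decision interval
  ``h`` (default 5) or S- drops below -h.  The statistic is *not* reset
  after an alarm, so excursions persist until the process returns.

Out-of-control *periods* are maximal runs of same-direction CuSum
violations of at least ``min_run`` years (default 4, i.e. "more than 3
consecutive years").  A year is *out of control* for a given reference
state if any of the nine indicators violates its CuSum limits that year.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import RefConKind
from .preprocessing import ZScoreSeries

log = logging.getLogger(__name__)

__all__ = [
    "CusumParams",
    "ControlChartResult",
    "di_cusum",
    "shewhart_flags",
    "cusum_flags",
    "detect_out_of_control_periods",
    "control_chart",
    "classify_years_by_refcon",
    "run_lengths_to_alarm",
]

IN_CONTROL = "in_control"
OUT_OF_CONTROL = "out_of_control"


@dataclass(frozen=True)
class CusumParams:
    """Chart tuning constants (all in z units)."""

    k: float = 0.5  # allowance: deviations smaller than k are ignored
    h: float = 5.0  # decision interval
    shewhart_limit: float = 3.0  # for reference-window baselines
    ci_level: float = 0.99  # entire-series Shewhart limit quantile

    def __post_init__(self) -> None:
        if self.k < 0:
            raise ValueError("allowance k must be >= 0")
        if self.h <= 0:
            raise ValueError("decision interval h must be > 0")

    def shewhart_limit_for(self, kind: RefConKind) -> float:
        """Per-year Shewhart limit for the given baseline strategy.

        Entire-series baselines use the two-sided ``ci_level`` normal
        quantile applied per observation (2.576 at 99%); a CI of the
        *mean* would shrink with n and flag nearly every year.
        """
        if kind is RefConKind.entire:
            return float(stats.norm.ppf(0.5 + self.ci_level / 2.0))
        return self.shewhart_limit


@dataclass
class ControlChartResult:
    """Everything the charts produce for one indicator series."""

    z: ZScoreSeries
    s_plus: pd.Series
    s_minus: pd.Series
    shewhart: pd.Series  # ok / above_UCL / below_LCL
    cusum: pd.Series  # ok / upper / lower
    periods: list[tuple[str, int, int]] = field(default_factory=list)
    params: CusumParams = field(default_factory=CusumParams)


def _check_years(index: pd.Index) -> np.ndarray:
    years = np.asarray(index)
    if np.any(np.diff(years) <= 0):
        raise ValueError("z series must be ordered by strictly increasing year")
    return years


def di_cusum(z: pd.Series, params: CusumParams = CusumParams()) -> tuple[pd.Series, pd.Series]:
    """One-sided upper/lower decision-interval CuSum recursions.

    ``z`` must be indexed by strictly increasing year.  Missing values
    should not occur after imputation; if present, the statistic carries
    its previous value forward and the year is logged as unflaggable.
    """
    _check_years(z.index)
    k = params.k
    zv = z.to_numpy(dtype=float)
    sp = np.zeros(zv.size)
    sm = np.zeros(zv.size)
    prev_p = 0.0
    prev_m = 0.0
    n_missing = 0
    for i, zi in enumerate(zv):
        if np.isnan(zi):
            n_missing += 1
            sp[i], sm[i] = prev_p, prev_m
        else:
            prev_p = max(0.0, prev_p + zi - k)
            prev_m = min(0.0, prev_m + zi + k)
            sp[i], sm[i] = prev_p, prev_m
    if n_missing:
        log.warning("di_cusum: %d missing z values carried forward", n_missing)
    return (
        pd.Series(sp, index=z.index, name="s_plus"),
        pd.Series(sm, index=z.index, name="s_minus"),
    )


def shewhart_flags(
    z: pd.Series,
    params: CusumParams = CusumParams(),
    kind: RefConKind = RefConKind.entire,
) -> pd.Series:
    """Flag single years beyond the Shewhart limits (strict inequality)."""
    limit = params.shewhart_limit_for(kind)
    flags = pd.Series("ok", index=z.index, name="shewhart")
    flags[z > limit] = "above_UCL"
    flags[z < -limit] = "below_LCL"
    flags[z.isna()] = "ok"
    return flags


def cusum_flags(
    s_plus: pd.Series,
    s_minus: pd.Series,
    params: CusumParams = CusumParams(),
) -> pd.Series:
    """Flag years where a CuSum statistic exceeds the decision interval.

    A tie (S = h exactly) is not a violation: the limits must be
    *exceeded*.
    """
    flags = pd.Series("ok", index=s_plus.index, name="cusum")
    up = s_plus > params.h
    lo = s_minus < -params.h
    flags[up] = "upper"
    flags[lo] = "lower"
    both = up & lo
    if both.any():  # pick the larger excursion; essentially unreachable
        pick_up = (s_plus[both] - params.h) >= (-params.h - s_minus[both])
        flags[both] = np.where(pick_up, "upper", "lower")
    return flags


def detect_out_of_control_periods(
    flags: pd.Series, min_run: int = 4
) -> list[tuple[str, int, int]]:
    """Maximal same-direction CuSum violation runs of >= ``min_run`` years.

    The default of 4 implements the "more than 3 consecutive years"
    reporting rule.  Returns ``(direction, start_year, end_year)`` tuples.
    """
    periods: list[tuple[str, int, int]] = []
    years = list(flags.index)
    vals = list(flags.to_numpy())
    i = 0
    while i < len(vals):
        if vals[i] in ("upper", "lower"):
            j = i
            while j + 1 < len(vals) and vals[j + 1] == vals[i]:
                j += 1
            if j - i + 1 >= min_run:
                periods.append((vals[i], int(years[i]), int(years[j])))
            i = j + 1
        else:
            i += 1
    return periods


def control_chart(
    z: ZScoreSeries,
    params: CusumParams = CusumParams(),
    min_run: int = 4,
) -> ControlChartResult:
    """Run both charts on one z-score series and extract periods."""
    sp, sm = di_cusum(z.values, params)
    shew = shewhart_flags(z.values, params, z.baseline.kind)
    cus = cusum_flags(sp, sm, params)
    periods = detect_out_of_control_periods(cus, min_run=min_run)
    return ControlChartResult(
        z=z, s_plus=sp, s_minus=sm, shewhart=shew, cusum=cus,
        periods=periods, params=params,
    )


def classify_years_by_refcon(
    charts: dict[str, ControlChartResult],
) -> pd.Series:
    """Label each year in/out of control across an indicator suite.

    A year is out of control if *any* indicator's CuSum flag is not
    ``ok`` that year.  All charts must target the same reference state;
    differing year coverage is restricted to the intersection with a
    warning.
    """
    if not charts:
        raise ValueError("no charts given")
    idx = None
    for res in charts.values():
        idx = res.cusum.index if idx is None else idx.intersection(res.cusum.index)
    for name, res in charts.items():
        if len(res.cusum.index) != len(idx):
            log.warning(
                "classify_years_by_refcon: %s restricted to common years", name
            )
            break
    any_violation = pd.Series(False, index=idx)
    for res in charts.values():
        any_violation |= res.cusum.reindex(idx).ne("ok")
    labels = pd.Series(
        np.where(any_violation, OUT_OF_CONTROL, IN_CONTROL), index=idx, name="label"
    )
    return labels


# ---------------------------------------------------------------------------
# chart-design utilities

def run_lengths_to_alarm(
    params: CusumParams = CusumParams(),
    n_runs: int = 2000,
    shift: float = 0.0,
    seed: int | None = None,
    max_steps: int = 1_000_000,
) -> np.ndarray:
    """Simulated run lengths to the first two-sided CuSum alarm.

    Draws z ~ N(shift, 1) step by step for each run until S+ > h or
    S- < -h.  With the defaults (k=0.5, h=5), the in-control mean run
    length is about 465 years and the mean delay under a 1-sigma shift is
    about 10 years — the design point the default allowance targets.
    """
    rng = np.random.default_rng(seed)
    sp = np.zeros(n_runs)
    sm = np.zeros(n_runs)
    rl = np.zeros(n_runs, dtype=np.int64)
    active = np.ones(n_runs, dtype=bool)
    t = 0
    while active.any():
        t += 1
        if t > max_steps:
            raise RuntimeError("run length simulation exceeded max_steps")
        n_act = int(active.sum())
        z = rng.standard_normal(n_act) + shift
        sp_a = np.maximum(0.0, sp[active] + z - params.k)
        sm_a = np.minimum(0.0, sm[active] + z + params.k)
        alarmed = (sp_a > params.h) | (sm_a < -params.h)
        idx = np.flatnonzero(active)
        rl[idx[alarmed]] = t
        sp[idx] = sp_a
        sm[idx] = sm_a
        active[idx[alarmed]] = False
    return rl
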
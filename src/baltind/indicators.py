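"""Annual summer zooplankton community indicators.

Nine indicators summarise the June-September community each year:

========== =============================================== ==================
name       definition                                      units
========== =============================================== ==================
TZA        total non-predatory zooplankton abundance       10^3 ind m-3
TZB        total non-predatory zooplankton biomass         mg WW m-3
CB         copepod biomass (all copepods, all stages)      mg WW m-3
CB_pct     100 x CB / TZB                                  %
MMB        microphagous mesozooplankton biomass            mg WW m-3
MMB_pct    100 x MMB / TZB                                 %
MeanSize   TZB / TZA (community mean individual mass)      ug WW ind-1
ClaCop     herbivorous cladoceran / calanoid biomass       --
RotClaCop  (rotifer + herb. cladoceran) / calanoid biomass --
========== =============================================== ==================

Predatory cladocerans (Cercopagis, Bythotrephes, Leptodora, ...) are
excluded from every pool.  The microphagous set comprises taxa flagged
microphagous in the trait registry (rotifers, tintinnids,
appendicularians, small ctenophores, pelagic harpacticoids) plus
herbivorous cladocerans.  CB deliberately counts *all* copepods while the
two community ratios use *calanoid* biomass only; both readings are kept
as stated rather than harmonised.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd

from .io import MajorGroup, SUMMER_MONTHS, Stage, ValidationError

log = logging.getLogger(__name__)

__all__ = [
    "INDICATORS",
    "summer_annual_mean",
    "compute_group_aggregates",
    "compute_indicator_suite",
    "compute_indicators",
    "indicator_long",
]

#: canonical indicator order
INDICATORS = (
    "TZA",
    "TZB",
    "CB",
    "CB_pct",
    "MMB",
    "MMB_pct",
    "MeanSize",
    "ClaCop",
    "RotClaCop",
)

_COPEPOD_GROUPS = {MajorGroup.copepod.value, MajorGroup.harpacticoid.value}


def summer_annual_mean(
    samples: pd.DataFrame,
    months: Sequence[int] = SUMMER_MONTHS,
    station_averaging: str = "station",
) -> pd.DataFrame:
    """Average sample densities to one value per dataset x year x taxon.

    A taxon not recorded in a given sampling event (station x date) is
    counted as density zero in that event, so that annual means are taken
    over a consistent set of events for every taxon.

    Parameters
    ----------
    months
        Calendar months retained (default June-September).  Years with no
        sample in these months are absent from the output.
    station_averaging
        ``"station"`` (default): mean over dates within each station,
        then mean over stations — prevents heavily sampled stations from
        dominating the annual value.  ``"grand"``: plain mean over all
        retained events.

    Returns
    -------
    Tidy frame with columns ``dataset, year, taxon, stage, abundance,
    biomass``.
    """
    if not len(months):
        raise ValueError("months must be a non-empty set of month numbers")
    if station_averaging not in ("station", "grand"):
        raise ValueError("station_averaging must be 'station' or 'grand'")
    if samples.empty:
        return pd.DataFrame(
            columns=["dataset", "year", "taxon", "stage", "abundance", "biomass"]
        )

    dates = pd.to_datetime(samples["date"])
    d = samples.loc[dates.dt.month.isin(list(months))].copy()
    if d.empty:
        return pd.DataFrame(
            columns=["dataset", "year", "taxon", "stage", "abundance", "biomass"]
        )
    d["year"] = pd.to_datetime(d["date"]).dt.year

    out = []
    for ds, g in d.groupby("dataset"):
        # sum duplicates within one event, then zero-fill the event x
        # (taxon, stage) grid so absences count as zero density
        ev = (
            g.groupby(["year", "station", "date", "taxon", "stage"])[
                ["abundance", "biomass"]
            ]
            .sum(min_count=1)
        )
        wide = ev.unstack(["taxon", "stage"])  # columns: (var, taxon, stage)
        wide = wide.fillna(0.0)
        if station_averaging == "station":
            per_station = wide.groupby(level=["year", "station"]).mean()
            annual = per_station.groupby(level="year").mean()
        else:
            annual = wide.groupby(level="year").mean()
        tidy = (
            annual.stack(["taxon", "stage"], future_stack=True)
            .reset_index()
            .assign(dataset=ds)
        )
        out.append(tidy)
    res = pd.concat(out, ignore_index=True)
    return res[["dataset", "year", "taxon", "stage", "abundance", "biomass"]]


def compute_group_aggregates(
    annual_means: pd.DataFrame,
    traits: pd.DataFrame,
    nauplii_microphagous: bool = False,
) -> pd.DataFrame:
    """Sum annual per-taxon means into the functional pools.

    Parameters
    ----------
    annual_means
        Output of :func:`summer_annual_mean`.
    traits
        Trait registry indexed by taxon (see :mod:`baltind.io`).
    nauplii_microphagous
        When True, copepod nauplius-stage records are also counted in the
        microphagous pool.  Default False: the microphagous set is taken
        from the trait flags (plus herbivorous cladocerans) only.

    Returns
    -------
    Frame indexed by ``(dataset, year)`` with columns ``tz_abundance,
    tz_biomass, copepod_abundance, copepod_biomass, calanoid_biomass,
    herb_clad_biomass, rotifer_biomass, micro_biomass``; predatory
    cladocerans contribute to none of them.
    """
    unmapped = sorted(set(annual_means["taxon"]) - set(traits.index))
    if unmapped:
        raise ValidationError(f"taxa missing from trait registry: {unmapped}")

    d = annual_means.merge(
        traits.reset_index()[
            [
                "taxon",
                "major_group",
                "is_calanoid",
                "is_predatory_cladoceran",
                "is_microphagous",
            ]
        ],
        on="taxon",
        how="left",
    )
    pred = d["is_predatory_cladoceran"].astype(bool)
    copepod = d["major_group"].isin(_COPEPOD_GROUPS)
    calanoid = d["is_calanoid"].astype(bool)
    herb_clad = (d["major_group"] == MajorGroup.cladoceran.value) & ~pred
    rotifer = d["major_group"] == MajorGroup.rotifer.value
    micro = (d["is_microphagous"].astype(bool) | herb_clad) & ~pred
    if nauplii_microphagous:
        micro |= copepod & (d["stage"] == Stage.nauplius.value)

    key = ["dataset", "year"]

    def _sum(mask: pd.Series, col: str) -> pd.Series:
        return (
            d.loc[mask]
            .groupby(key)[col]
            .sum()
        )

    base = d.groupby(key).size().rename("n_taxa").to_frame()
    agg = pd.DataFrame(
        {
            "tz_abundance": _sum(~pred, "abundance"),
            "tz_biomass": _sum(~pred, "biomass"),
            "copepod_abundance": _sum(copepod, "abundance"),
            "copepod_biomass": _sum(copepod, "biomass"),
            "calanoid_biomass": _sum(calanoid, "biomass"),
            "herb_clad_biomass": _sum(herb_clad, "biomass"),
            "rotifer_biomass": _sum(rotifer, "biomass"),
            "micro_biomass": _sum(micro, "biomass"),
        },
        index=base.index,
    ).fillna(0.0)
    return agg


def compute_indicator_suite(aggregates: pd.DataFrame) -> pd.DataFrame:
    """Derive the nine indicators from the functional-pool aggregates.

    Returns a wide frame indexed by ``(dataset, year)`` with one column
    per indicator (see module docstring for units).  Ratios and
    percentages with a zero denominator are set to missing with a
    warning, never to zero or infinity.
    """
    if aggregates.empty:
        raise ValueError("aggregates are empty")
    a = aggregates
    tza = a["tz_abundance"] / 1e3  # 10^3 ind m-3
    tzb = a["tz_biomass"]

    def _ratio(num: pd.Series, den: pd.Series, name: str) -> pd.Series:
        zero = den == 0
        if zero.any():
            log.warning(
                "%s undefined for %d year(s) with zero denominator", name, int(zero.sum())
            )
        return num.where(~zero) / den.where(~zero)

    out = pd.DataFrame(index=a.index)
    out["TZA"] = tza
    out["TZB"] = tzb
    out["CB"] = a["copepod_biomass"]
    out["CB_pct"] = 100.0 * _ratio(a["copepod_biomass"], tzb, "CB_pct")
    out["MMB"] = a["micro_biomass"]
    out["MMB_pct"] = 100.0 * _ratio(a["micro_biomass"], tzb, "MMB_pct")
    out["MeanSize"] = _ratio(tzb, tza, "MeanSize")
    out["ClaCop"] = _ratio(a["herb_clad_biomass"], a["calanoid_biomass"], "ClaCop")
    out["RotClaCop"] = _ratio(
        a["rotifer_biomass"] + a["herb_clad_biomass"],
        a["calanoid_biomass"],
        "RotClaCop",
    )
    return out


def compute_indicators(
    samples: pd.DataFrame,
    traits: pd.DataFrame,
    months: Sequence[int] = SUMMER_MONTHS,
    station_averaging: str = "station",
    nauplii_microphagous: bool = False,
) -> pd.DataFrame:
    """Samples -> annual means -> pools -> indicator suite, in one call."""
    annual = summer_annual_mean(samples, months, station_averaging)
    agg = compute_group_aggregates(annual, traits, nauplii_microphagous)
    return compute_indicator_suite(agg)


def indicator_long(wide: pd.DataFrame) -> pd.DataFrame:
    """Melt a wide indicator table to ``dataset,year,indicator,value``."""
    return (
        wide.reset_index()
        .melt(id_vars=["dataset", "year"], var_name="indicator", value_name="value")
        .sort_values(["dataset", "indicator", "year"])
        .reset_index(drop=True)
    )
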